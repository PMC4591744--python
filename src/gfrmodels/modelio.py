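"""Flat text serialization of fitted models.

Every model file is a plain ``key = value`` document (one pair per line,
``#`` comments allowed), so fitted equations and networks can be diffed,
versioned and audited without binary tooling.  ``repr`` formatting keeps
round-trips bit-exact for double-precision coefficients.
"""

from __future__ import annotations

from typing import Union

import numpy as np

from .ann import AnnModel
from .calibration import CalibrationModel
from .equations import SplineEquationModel
from .errors import FormatError

__all__ = ["save_model", "load_model"]

AnyModel = Union[SplineEquationModel, AnnModel, CalibrationModel]


def _dump(pairs: list[tuple[str, object]]) -> str:
    lines = []
    for key, val in pairs:
        if isinstance(val, float):
            val = repr(val)
        lines.append(f"{key} = {val}")
    return "\n".join(lines) + "\n"


def save_model(model: AnyModel, path) -> None:
    if isinstance(model, SplineEquationModel):
        pairs: list[tuple[str, object]] = [("type", "spline")]
        for name in ("intercept", "slope_below", "slope_above", "age_coef",
                     "female_coef", "knot_female", "knot_male"):
            pairs.append((name, float(getattr(model, name))))
        for cov, coef in model.covariate_coefs.items():
            pairs.append((f"covariate.{cov}", float(coef)))
    elif isinstance(model, AnnModel):
        pairs = [("type", "ann"),
                 ("inputs", ",".join(model.inputs)),
                 ("n_hidden", model.n_hidden)]
        H, I = model.weights_in.shape
        for j in range(H):
            for i in range(I):
                pairs.append((f"w_in.{j}.{i}", float(model.weights_in[j, i])))
        for j in range(H):
            pairs.append((f"th_hidden.{j}", float(model.thresholds_hidden[j])))
        for j in range(H):
            pairs.append((f"w_out.{j}", float(model.weights_out[j])))
        pairs.append(("th_out", float(model.threshold_out)))
        for i, name in enumerate(model.inputs):
            pairs.append((f"in_min.{i}", float(model.input_scaling[i, 0])))
            pairs.append((f"in_max.{i}", float(model.input_scaling[i, 1])))
        pairs.append(("out_min", float(model.output_scaling[0])))
        pairs.append(("out_max", float(model.output_scaling[1])))
    elif isinstance(model, CalibrationModel):
        pairs = [("type", "calibration"),
                 ("intercept", float(model.intercept)),
                 ("slope", float(model.slope)),
                 ("r_squared", float(model.r_squared)),
                 ("n", model.n)]
    else:
        raise FormatError(f"cannot serialize {type(model).__name__}")
    with open(path, "w") as fh:
        fh.write(_dump(pairs))


def _parse(path) -> dict[str, str]:
    kv: dict[str, str] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            if "=" not in line:
                raise FormatError(f"{path}:{lineno}: expected 'key = value'")
            key, val = line.split("=", 1)
            kv[key.strip()] = val.strip()
    return kv


def load_model(path) -> AnyModel:
    kv = _parse(path)
    kind = kv.get("type")
    if kind == "spline":
        covs = {k.split(".", 1)[1]: float(v)
                for k, v in kv.items() if k.startswith("covariate.")}
        return SplineEquationModel(
            intercept=float(kv["intercept"]),
            slope_below=float(kv["slope_below"]),
            slope_above=float(kv["slope_above"]),
            age_coef=float(kv["age_coef"]),
            female_coef=float(kv["female_coef"]),
            covariate_coefs=covs,
            knot_female=float(kv["knot_female"]),
            knot_male=float(kv["knot_male"]),
        )
    if kind == "ann":
        inputs = tuple(kv["inputs"].split(","))
        H, I = int(kv["n_hidden"]), len(inputs)
        W = np.array([[float(kv[f"w_in.{j}.{i}"]) for i in range(I)] for j in range(H)])
        return AnnModel(
            inputs=inputs,
            weights_in=W,
            thresholds_hidden=np.array([float(kv[f"th_hidden.{j}"]) for j in range(H)]),
            weights_out=np.array([float(kv[f"w_out.{j}"]) for j in range(H)]),
            threshold_out=float(kv["th_out"]),
            input_scaling=np.array([[float(kv[f"in_min.{i}"]), float(kv[f"in_max.{i}"])]
                                    for i in range(I)]),
            output_scaling=(float(kv["out_min"]), float(kv["out_max"])),
        )
    if kind == "calibration":
        return CalibrationModel(
            intercept=float(kv["intercept"]),
            slope=float(kv["slope"]),
            r_squared=float(kv["r_squared"]),
            n=int(kv["n"]),
        )
    raise FormatError(f"unknown or missing model type in {path}: {kind!r}")
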