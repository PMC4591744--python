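"""End-to-end orchestration: simulate → split → fit equations → fit
networks → evaluate on an external set.

The stage order mirrors a standard model-development study: a combined
development + internal cohort is randomized 2:1 into development (equation
fitting, network gradients) and internal validation (network snapshot and
size selection); a temporally separate external cohort is reserved for the
final comparison of the new equations and networks against the published
comparator equations (CKD-EPI and the two Japanese equations).

Every artifact is plain text: cohort files in the canonical delimited
format, models as flat key = value documents, the final report as CSV, and
a run log with ISO timestamps.
"""

from __future__ import annotations

import datetime as _dt
import os
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

from . import ann as ann_mod
from . import equations as eq_mod
from .cohort import Cohort, split_cohort, write_cohort
from .errors import ConfigurationError, GfrModelsError
from .evaluation import paired_predictions, report_to_rows, table3_report
from .modelio import save_model
from .simulate import CohortSimConfig, generate_cohort
from .spline import VARIABLE_SETS, fit_all_equations

__all__ = ["RunConfig", "run_pipeline"]


@dataclass(frozen=True)
class RunConfig:
    """Parameters of the end-to-end pipeline.

    Cohort sizes default to the reference design: 414 development+internal
    records split 2:1 (276/138) and 105 external records.  The network
    search defaults are desk-scale (three candidate hidden sizes, a small GA)
    so a full 8-equation + 8-network run completes in minutes; all of them
    widen via configuration.
    """

    outdir: str = "gfr-run"
    seed: int = 0
    n_devint: int = 414
    n_external: int = 105
    dev_fraction: float = 2.0 / 3.0
    noise_sigma: float = 0.2
    equation_vsets: Sequence[str] = tuple(VARIABLE_SETS)
    ann_vsets: Sequence[str] = tuple(VARIABLE_SETS)
    ann_sizes: Sequence[int] = (2, 4, 6)
    train_cfg: ann_mod.TrainConfig = field(
        default_factory=lambda: ann_mod.TrainConfig(max_epochs=600, patience=100))
    ga_cfg: GaConfig = field(
        default_factory=lambda: ann_mod.GaConfig(
            population_size=12, generations=8, inner_training_epochs=30))
    bootstrap_reps: int = 2000
    reference_model: str = "ckd_epi"
    pool_internal_for_equations: bool = False

    def __post_init__(self) -> None:
        if self.n_devint < 2 or self.n_external < 1:
            raise ConfigurationError("cohort sizes too small")
        unknown = set(self.equation_vsets) | set(self.ann_vsets)
        unknown -= set(VARIABLE_SETS)
        if unknown:
            raise ConfigurationError(f"unknown variable sets {sorted(unknown)}")


GaConfig = ann_mod.GaConfig  # re-export for config files


def _log(fh, message: str) -> None:
    stamp = _dt.datetime.now().isoformat(timespec="seconds")
    fh.write(f"{stamp} {message}\n")
    fh.flush()


def _comparator_callables() -> dict:
    return {
        "ckd_epi": lambda r: eq_mod.ckd_epi(r.sex, r.age, r.scr),
        "japanese_1": lambda r: eq_mod.japanese_1(r.sex, r.age, r.scr),
        "japanese_2": lambda r: eq_mod.japanese_2(r.sex, r.age, r.scr, r.hba1c),
    }


def run_pipeline(config: RunConfig) -> dict:
    """Execute the configured stage sequence; returns a summary dict with the
    fitted models, the report rows, and artifact paths.  Deterministic for a
    fixed config (byte-identical model files and reports)."""
    os.makedirs(config.outdir, exist_ok=True)
    paths: dict[str, str] = {}
    summary: dict = {"paths": paths}
    log_path = os.path.join(config.outdir, "run.log")
    with open(log_path, "w") as log:
        stage = "simulate"
        try:
            sim = CohortSimConfig(n=config.n_devint, seed=config.seed,
                                  noise_sigma=config.noise_sigma)
            devint = generate_cohort(sim)
            ext_sim = replace(sim, n=config.n_external, seed=config.seed + 1,
                              id_prefix="ext")
            external = generate_cohort(ext_sim)
            _log(log, f"simulate: n_devint={len(devint)} n_external={len(external)} "
                      f"seed={config.seed}")
            save_model(sim.truth, os.path.join(config.outdir, "truth_model.txt"))

            stage = "split"
            devint = split_cohort(devint, config.dev_fraction, seed=config.seed + 2)
            dev = devint.subset("development")
            internal = devint.subset("internal")
            _log(log, f"split: development={len(dev)} internal={len(internal)} "
                      f"dev_fraction={config.dev_fraction}")
            devint_path = os.path.join(config.outdir, "cohort_devint.csv")
            ext_path = os.path.join(config.outdir, "cohort_external.csv")
            write_cohort(devint, devint_path)
            ext_labels = Cohort(records=list(external.records),
                                split=["external"] * len(external))
            write_cohort(ext_labels, ext_path)
            paths["cohort_devint"] = devint_path
            paths["cohort_external"] = ext_path

            stage = "fit-equation"
            fits = fit_all_equations(
                devint, pool_internal=config.pool_internal_for_equations,
                warn=lambda m: _log(log, f"fit-equation: {m}"))
            equations = {name: fits[name][0] for name in config.equation_vsets
                         if name in fits}
            for name, model in equations.items():
                p = os.path.join(config.outdir, f"model_{name}.txt")
                save_model(model, p)
                paths[f"model_{name}"] = p
                _log(log, f"fit-equation: {name} r2="
                          f"{fits[name][1].r_squared:.4f} n={fits[name][1].n_used}")

            stage = "fit-ann"
            networks = {}
            for k, vs in enumerate(config.ann_vsets):
                ann_name = f"ann{vs[2:]}" if vs.startswith("eq") else f"ann_{vs}"
                model, info = ann_mod.train_gabp(
                    dev, internal, vs, sizes=config.ann_sizes,
                    train_cfg=replace(config.train_cfg, seed=config.seed + 10 + k),
                    ga_cfg=replace(config.ga_cfg, seed=config.seed + 100 + k),
                )
                networks[ann_name] = model
                p = os.path.join(config.outdir, f"model_{ann_name}.txt")
                save_model(model, p)
                paths[f"model_{ann_name}"] = p
                _log(log, f"fit-ann: {ann_name} topology={model.topology} "
                          f"internal_mse_by_size={info['internal_mse_by_size']}")

            stage = "evaluate"
            predictors = dict(_comparator_callables())
            predictors.update({n: m.predict for n, m in equations.items()})
            predictors.update({n: m.predict for n, m in networks.items()})
            paired = paired_predictions(external, predictors)
            reports = table3_report(paired, reference=config.reference_model,
                                    reps=config.bootstrap_reps,
                                    seed=config.seed + 1000)
            rows = report_to_rows(reports)
            report_path = os.path.join(config.outdir, "report.csv")
            _write_rows(rows, report_path)
            paths["report"] = report_path
            for row in rows:
                _log(log, "evaluate: {model} bias={bias:.2f} precision={precision:.2f} "
                          "p30={accuracy_p30:.1f}".format(**row))
        except GfrModelsError as exc:
            _log(log, f"FAILED at stage {stage}: {exc}")
            raise GfrModelsError(f"pipeline stage {stage!r} failed: {exc}") from exc

    summary.update({
        "n_development": len(dev),
        "n_internal": len(internal),
        "n_external": len(external),
        "equations": equations,
        "networks": networks,
        "reports": reports,
        "report_rows": rows,
    })
    return summary


def _write_rows(rows: list[dict], path: str) -> None:
    import csv

    with open(path, "w", newline="") as fh:
        writer = csv.DictWriter(fh, fieldnames=list(rows[0].keys()))
        writer.writeheader()
        writer.writerows(rows)
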