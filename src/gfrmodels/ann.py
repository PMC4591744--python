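"""Three-layer back-propagation networks for GFR prediction, with
hidden-size search and genetic-algorithm optimization of the initial
weights and thresholds (GABP).

Architecture
------------
A single hidden layer of 1–11 logistic ("S-function") neurons between an
input layer (age, female indicator, serum creatinine, plus the variable
set's covariates) and one linear output neuron predicting standard GFR.
Inputs and the output are min-max scaled to [0, 1] using the development
data only; the scaling is stored in the model so prediction is
self-contained.

Training is full-batch gradient descent with momentum on the development-set
mean square error of the scaled output.  Model selection — both the epoch
snapshot kept during training and the hidden-layer size — minimizes the
*internal-validation* MSE, keeping the selection data strictly separate from
the gradient data.

GABP
----
All weights and thresholds of one network are concatenated into a
real-valued chromosome.  A generational genetic algorithm with elitism,
arithmetic crossover and Gaussian mutation evolves a population of
chromosomes; a chromosome's fitness is the internal-validation MSE reached
after a short burst of back-propagation started from it.  The best
chromosome ever seen initializes the final training run.  This replaces a
single random initialization with a search over many, selected on held-out
error.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence, Union

import numpy as np
from scipy.special import expit

from .cohort import PatientRecord
from .errors import ConfigurationError, EvaluationError, TrainingError, ValidationError
from .spline import VARIABLE_SETS, VariableSet

__all__ = [
    "AnnModel",
    "TrainConfig",
    "GaConfig",
    "vset_inputs",
    "make_model",
    "forward",
    "train_bp",
    "select_hidden_size",
    "ga_optimize_init",
    "train_gabp",
    "gabp_benchmark",
]

HIDDEN_RANGE = range(1, 12)  # 1..11 hidden neurons are searched by default


def vset_inputs(vset: Union[VariableSet, str]) -> tuple[str, ...]:
    """Input features of a variable set: age, female indicator, creatinine,
    plus its covariates (3–6 inputs)."""
    if isinstance(vset, str):
        vset = VariableSet(vset)
    return ("age", "female", "scr") + vset.covariates


def _feature(rec: PatientRecord, name: str) -> float:
    if name == "female":
        return 1.0 if rec.female else 0.0
    val = rec.get(name)
    if val is None:
        raise EvaluationError(f"record {rec.id!r} lacks input {name!r}")
    return float(val)


def _design(records: Sequence[PatientRecord], inputs: Sequence[str],
            need_sgfr: bool = True) -> tuple[np.ndarray, np.ndarray]:
    X = np.array([[_feature(r, nm) for nm in inputs] for r in records])
    y = np.full(len(records), np.nan)
    if need_sgfr:
        missing = [r.id for r in records if r.sgfr is None]
        if missing:
            raise ValidationError(f"records lacking sgfr: {missing[:5]}")
        y = np.array([r.sgfr for r in records])
    return X, y


@dataclass(frozen=True)
class AnnModel:
    """A trained (or initialized) 4-layer-parameter feed-forward network.

    ``weights_in`` is (n_hidden, n_inputs); ``input_scaling`` rows are
    (min, max) per input; ``output_scaling`` is (min, max) of the training
    sGFR.  Prediction: scale inputs to [0,1], logistic hidden layer, linear
    output on the scaled range, inverse-scale to mL/min/1.73 m².
    """

    inputs: tuple[str, ...]
    weights_in: np.ndarray
    thresholds_hidden: np.ndarray
    weights_out: np.ndarray
    threshold_out: float
    input_scaling: np.ndarray  # (n_inputs, 2)
    output_scaling: tuple[float, float]

    def __post_init__(self) -> None:
        H, I = self.weights_in.shape
        if not 1 <= H <= 11:
            raise ValidationError(f"n_hidden must lie in [1, 11], got {H}")
        if I != len(self.inputs):
            raise ValidationError("weights_in width must match inputs")
        for arr in (self.weights_in, self.thresholds_hidden, self.weights_out):
            if not np.all(np.isfinite(arr)):
                raise ValidationError("non-finite network parameters")

    @property
    def n_inputs(self) -> int:
        return len(self.inputs)

    @property
    def n_hidden(self) -> int:
        return self.weights_in.shape[0]

    @property
    def topology(self) -> tuple[int, int, int]:
        return (self.n_inputs, self.n_hidden, 1)

    # -- scaled-space forward pass -------------------------------------
    def _scale_inputs(self, X: np.ndarray) -> np.ndarray:
        lo, hi = self.input_scaling[:, 0], self.input_scaling[:, 1]
        denom = np.where(hi > lo, hi - lo, 1.0)
        return (X - lo) / denom

    def _forward_scaled(self, Xs: np.ndarray) -> np.ndarray:
        z = Xs @ self.weights_in.T + self.thresholds_hidden
        h = expit(z)
        return h @ self.weights_out + self.threshold_out

    def predict_batch(self, records: Sequence[PatientRecord]) -> np.ndarray:
        X, _ = _design(records, self.inputs, need_sgfr=False)
        ys = self._forward_scaled(self._scale_inputs(X))
        lo, hi = self.output_scaling
        return ys * (hi - lo) + lo

    def predict(self, record: PatientRecord) -> float:
        return float(self.predict_batch([record])[0])

    # -- chromosome packing --------------------------------------------
    def to_chromosome(self) -> np.ndarray:
        return np.concatenate([
            self.weights_in.ravel(),
            self.thresholds_hidden,
            self.weights_out,
            [self.threshold_out],
        ])

    def with_chromosome(self, chrom: np.ndarray) -> "AnnModel":
        H, I = self.weights_in.shape
        expect = H * I + H + H + 1
        if chrom.shape != (expect,):
            raise ValidationError(f"chromosome length {chrom.shape} != {expect}")
        return replace(
            self,
            weights_in=chrom[: H * I].reshape(H, I).copy(),
            thresholds_hidden=chrom[H * I: H * I + H].copy(),
            weights_out=chrom[H * I + H: H * I + 2 * H].copy(),
            threshold_out=float(chrom[-1]),
        )


def forward(model: AnnModel, record: PatientRecord) -> float:
    """Predicted eGFR (mL/min/1.73 m²) for one record."""
    return model.predict(record)


@dataclass(frozen=True)
class TrainConfig:
    """Back-propagation settings: full-batch gradient descent with momentum."""

    learning_rate: float = 0.05
    momentum: float = 0.9
    max_epochs: int = 2000
    patience: int = 200  # epochs without internal-MSE improvement
    init_scale: float = 0.5  # half-width of the uniform random initialization
    seed: int = 0

    def __post_init__(self) -> None:
        if self.learning_rate < 0:
            raise ConfigurationError("learning_rate must be >= 0")
        if self.max_epochs < 1:
            raise ConfigurationError("max_epochs must be >= 1")
        if not 0 <= self.momentum < 1:
            raise ConfigurationError("momentum must lie in [0, 1)")


@dataclass(frozen=True)
class GaConfig:
    """Genetic-algorithm settings for initial-weight optimization."""

    population_size: int = 40
    generations: int = 50
    crossover_rate: float = 0.8
    mutation_rate: float = 0.1
    mutation_scale: float = 0.1
    inner_training_epochs: int = 50  # BP epochs inside each fitness evaluation
    init_scale: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.population_size < 2:
            raise ConfigurationError("population_size must be >= 2")
        for nm in ("crossover_rate", "mutation_rate"):
            if not 0.0 <= getattr(self, nm) <= 1.0:
                raise ConfigurationError(f"{nm} must lie in [0, 1]")
        if self.generations < 0 or self.inner_training_epochs < 0:
            raise ConfigurationError("generations / inner epochs must be >= 0")


def make_model(
    vset: Union[VariableSet, str],
    n_hidden: int,
    dev_records: Sequence[PatientRecord],
    rng: Optional[np.random.Generator] = None,
    init_scale: float = 0.5,
) -> AnnModel:
    """Build a network with min-max scaling from the development records and
    (when ``rng`` is given) uniform random weights in ±init_scale."""
    inputs = vset_inputs(vset)
    X, y = _design(dev_records, inputs)
    n_params_in = (n_hidden, len(inputs))
    if rng is None:
        W = np.zeros(n_params_in)
        th = np.zeros(n_hidden)
        v = np.zeros(n_hidden)
        t_out = 0.0
    else:
        W = rng.uniform(-init_scale, init_scale, n_params_in)
        th = rng.uniform(-init_scale, init_scale, n_hidden)
        v = rng.uniform(-init_scale, init_scale, n_hidden)
        t_out = float(rng.uniform(-init_scale, init_scale))
    scaling = np.column_stack([X.min(axis=0), X.max(axis=0)])
    return AnnModel(
        inputs=inputs,
        weights_in=W,
        thresholds_hidden=th,
        weights_out=v,
        threshold_out=t_out,
        input_scaling=scaling,
        output_scaling=(float(y.min()), float(y.max())),
    )


def _scaled_sets(model: AnnModel, dev, internal):
    Xd, yd = _design(dev, model.inputs)
    Xi, yi = _design(internal, model.inputs)
    lo, hi = model.output_scaling
    denom = hi - lo if hi > lo else 1.0
    return (model._scale_inputs(Xd), (yd - lo) / denom,
            model._scale_inputs(Xi), (yi - lo) / denom)


def _mse_and_grads(model, Xs, ys):
    z = Xs @ model.weights_in.T + model.thresholds_hidden
    h = expit(z)
    pred = h @ model.weights_out + model.threshold_out
    err = pred - ys
    n = len(ys)
    with np.errstate(over="ignore", invalid="ignore"):
        mse = float(err @ err / n)
    d = 2.0 * err / n
    g_v = h.T @ d
    g_tout = float(d.sum())
    dh = np.outer(d, model.weights_out) * h * (1.0 - h)
    g_W = dh.T @ Xs
    g_th = dh.sum(axis=0)
    return mse, g_W, g_th, g_v, g_tout


def _internal_mse(model, Xs, ys) -> float:
    err = model._forward_scaled(Xs) - ys
    with np.errstate(over="ignore", invalid="ignore"):
        return float(err @ err / len(ys))


def train_bp(
    model: AnnModel,
    dev_records: Sequence[PatientRecord],
    internal_records: Sequence[PatientRecord],
    cfg: TrainConfig = TrainConfig(),
) -> tuple[AnnModel, dict]:
    """Full-batch back-propagation with momentum.

    Gradients come from the development set; after every epoch the
    internal-validation MSE is recorded and the epoch snapshot with the
    lowest internal MSE is the one returned.  Training stops early after
    ``cfg.patience`` epochs without internal improvement.  Deterministic:
    no randomness beyond the caller-supplied initial weights.
    """
    if not dev_records or not internal_records:
        raise ValidationError("development and internal record sets must be non-empty")
    Xd, yd, Xi, yi = _scaled_sets(model, dev_records, internal_records)
    cur = model
    vel = [np.zeros_like(cur.weights_in), np.zeros_like(cur.thresholds_hidden),
           np.zeros_like(cur.weights_out), 0.0]
    best = cur
    best_internal = _internal_mse(cur, Xi, yi)
    best_epoch = 0
    dev_trace, int_trace = [], []
    since_improve = 0
    for epoch in range(cfg.max_epochs):
        mse, g_W, g_th, g_v, g_tout = _mse_and_grads(cur, Xd, yd)
        if not math.isfinite(mse):
            raise TrainingError(
                "development MSE became non-finite; reduce learning_rate"
            )
        dev_trace.append(mse)
        vel[0] = cfg.momentum * vel[0] - cfg.learning_rate * g_W
        vel[1] = cfg.momentum * vel[1] - cfg.learning_rate * g_th
        vel[2] = cfg.momentum * vel[2] - cfg.learning_rate * g_v
        vel[3] = cfg.momentum * vel[3] - cfg.learning_rate * g_tout
        cur = replace(
            cur,
            weights_in=cur.weights_in + vel[0],
            thresholds_hidden=cur.thresholds_hidden + vel[1],
            weights_out=cur.weights_out + vel[2],
            threshold_out=cur.threshold_out + vel[3],
        )
        internal = _internal_mse(cur, Xi, yi)
        if not math.isfinite(internal):
            raise TrainingError("internal MSE became non-finite; reduce learning_rate")
        int_trace.append(internal)
        if internal < best_internal:
            best, best_internal, best_epoch = cur, internal, epoch + 1
            since_improve = 0
        else:
            since_improve += 1
            if since_improve >= cfg.patience:
                break
    trace = {
        "dev_mse": np.array(dev_trace),
        "internal_mse": np.array(int_trace),
        "best_internal_mse": best_internal,
        "best_epoch": best_epoch,
        "final_dev_mse": _internal_mse(best, Xd, yd),
    }
    return best, trace


def select_hidden_size(
    dev_records: Sequence[PatientRecord],
    internal_records: Sequence[PatientRecord],
    vset: Union[VariableSet, str],
    sizes: Sequence[int] = tuple(HIDDEN_RANGE),
    cfg: TrainConfig = TrainConfig(),
    initial_chromosomes: Optional[dict] = None,
) -> tuple[AnnModel, dict]:
    """Train one network per hidden size and keep the internal-MSE argmin;
    ties go to the smaller network.  ``initial_chromosomes`` optionally maps
    a size to a starting chromosome (e.g. from the GA)."""
    if not sizes:
        raise ConfigurationError("sizes must be non-empty")
    results: dict[int, float] = {}
    best_model, best_mse, best_size = None, np.inf, None
    rng = np.random.default_rng(cfg.seed)
    for size in sorted(sizes):
        model = make_model(vset, size, dev_records, rng=rng, init_scale=cfg.init_scale)
        if initial_chromosomes is not None and size in initial_chromosomes:
            model = model.with_chromosome(np.asarray(initial_chromosomes[size]))
        trained, trace = train_bp(model, dev_records, internal_records, cfg)
        mse = trace["best_internal_mse"]
        results[size] = mse
        if mse < best_mse:  # strict: ties keep the earlier (smaller) size
            best_model, best_mse, best_size = trained, mse, size
    return best_model, {"internal_mse_by_size": results, "selected_size": best_size}


def ga_optimize_init(
    vset: Union[VariableSet, str],
    n_hidden: int,
    dev_records: Sequence[PatientRecord],
    internal_records: Sequence[PatientRecord],
    ga_cfg: GaConfig = GaConfig(),
    train_cfg: TrainConfig = TrainConfig(),
) -> tuple[np.ndarray, dict]:
    """Evolve initial weights/thresholds; returns (best chromosome, history).

    Fitness of a chromosome is the internal-validation MSE after
    ``ga_cfg.inner_training_epochs`` epochs of back-propagation started from
    it (0 epochs scores the raw initialization).  Elitist generational
    replacement with arithmetic crossover and Gaussian mutation; the best
    chromosome ever seen is returned, so best fitness is non-increasing.
    """
    rng = np.random.default_rng(ga_cfg.seed)
    template = make_model(vset, n_hidden, dev_records)
    n_genes = template.to_chromosome().shape[0]
    inner_cfg = replace(
        train_cfg,
        max_epochs=max(ga_cfg.inner_training_epochs, 1),
        patience=max(ga_cfg.inner_training_epochs, 1),
    )

    def fitness(chrom: np.ndarray) -> float:
        model = template.with_chromosome(chrom)
        if ga_cfg.inner_training_epochs == 0:
            Xd, yd, Xi, yi = _scaled_sets(model, dev_records, internal_records)
            return _internal_mse(model, Xi, yi)
        try:
            _, trace = train_bp(model, dev_records, internal_records, inner_cfg)
            return trace["best_internal_mse"]
        except TrainingError:
            return np.inf

    pop = rng.uniform(-ga_cfg.init_scale, ga_cfg.init_scale,
                      (ga_cfg.population_size, n_genes))
    fits = np.array([fitness(c) for c in pop])
    best_idx = int(np.argmin(fits))
    best_chrom, best_fit = pop[best_idx].copy(), float(fits[best_idx])
    history = [best_fit]

    for _ in range(ga_cfg.generations):
        order = np.argsort(fits, kind="stable")
        new_pop = [pop[order[0]].copy()]  # elitism
        # fitness-rank tournament selection
        while len(new_pop) < ga_cfg.population_size:
            i, j = rng.integers(0, ga_cfg.population_size, 2)
            a = pop[i] if fits[i] <= fits[j] else pop[j]
            i, j = rng.integers(0, ga_cfg.population_size, 2)
            b = pop[i] if fits[i] <= fits[j] else pop[j]
            if rng.uniform() < ga_cfg.crossover_rate:
                lam = rng.uniform(size=n_genes)
                child = lam * a + (1.0 - lam) * b
            else:
                child = a.copy()
            mask = rng.uniform(size=n_genes) < ga_cfg.mutation_rate
            child = child + mask * rng.normal(0.0, ga_cfg.mutation_scale, n_genes)
            new_pop.append(child)
        pop = np.array(new_pop)
        fits = np.array([fitness(c) for c in pop])
        gen_best = int(np.argmin(fits))
        if fits[gen_best] < best_fit:
            best_chrom, best_fit = pop[gen_best].copy(), float(fits[gen_best])
        history.append(best_fit)

    return best_chrom, {"best_fitness": best_fit,
                        "best_fitness_by_generation": np.array(history)}


def train_gabp(
    dev_records: Sequence[PatientRecord],
    internal_records: Sequence[PatientRecord],
    vset: Union[VariableSet, str],
    sizes: Sequence[int] = tuple(HIDDEN_RANGE),
    train_cfg: TrainConfig = TrainConfig(),
    ga_cfg: GaConfig = GaConfig(),
) -> tuple[AnnModel, dict]:
    """GA-initialized training with hidden-size search.

    For each candidate hidden size the GA proposes initial weights, a full
    back-propagation run refines them, and the size with the lowest
    internal-validation MSE wins (ties to fewer neurons).
    """
    if not sizes:
        raise ConfigurationError("sizes must be non-empty")
    chroms: dict[int, np.ndarray] = {}
    for k, size in enumerate(sorted(sizes)):
        chrom, _ = ga_optimize_init(
            vset, size, dev_records, internal_records,
            replace(ga_cfg, seed=ga_cfg.seed + k), train_cfg,
        )
        chroms[size] = chrom
    return select_hidden_size(dev_records, internal_records, vset,
                              sizes, train_cfg, initial_chromosomes=chroms)


def _self_realizable_target(seed: int, n_dev: int, n_internal: int,
                            n_hidden: int, weight_scale: float,
                            vset: str = "eq3"):
    """Noise-free regression target generated by a fixed random network.

    Covariates come from the synthetic cohort simulator; the reference GFR is
    replaced by the output of a random network of the benchmark topology
    (shifted into the positive range — an affine change the linear output
    layer absorbs, so the target stays exactly realizable)."""
    from dataclasses import replace as _replace

    from .simulate import CohortSimConfig, generate_cohort

    cohort = generate_cohort(CohortSimConfig(n=n_dev + n_internal, seed=seed,
                                             noise_sigma=0.0))
    dev = cohort.records[:n_dev]
    internal = cohort.records[n_dev:]
    gen = make_model(vset, n_hidden, dev,
                     rng=np.random.default_rng(seed + 977),
                     init_scale=weight_scale)
    pred_d = gen.predict_batch(dev)
    pred_i = gen.predict_batch(internal)
    shift = -min(pred_d.min(), pred_i.min()) + 20.0
    dev = [_replace(r, sgfr=float(p + shift)) for r, p in zip(dev, pred_d)]
    internal = [_replace(r, sgfr=float(p + shift)) for r, p in zip(internal, pred_i)]
    return dev, internal


def gabp_benchmark(
    n_seeds: int = 20,
    seed: int = 0,
    vset: str = "eq3",
    n_hidden: int = 6,
    n_dev: int = 130,
    n_internal: int = 70,
    target_weight_scale: float = 4.0,
    init_scale: float = 2.5,
    learning_rate: float = 0.5,
    final_epochs: int = 300,
    population_size: int = 20,
    generations: int = 40,
    mutation_scale: float = 0.3,
) -> dict:
    """Paired comparison of GA-optimized versus plain random initialization
    at an equal total compute budget.

    For each of ``n_seeds`` independent synthetic problems (noise-free
    targets realizable by the benchmark topology), two networks are trained:

    * **GABP** — a GA (fitness: internal MSE of the untrained chromosome)
      evolves the initial weights, then ``final_epochs`` of back-propagation
      refine them;
    * **plain** — one random draw from the same initialization distribution,
      trained for ``final_epochs`` plus the GA's compute converted to epoch
      equivalents (a fitness evaluation is one forward pass over the
      internal set; an epoch is a forward+backward pass over the development
      set plus an internal forward pass).

    The benchmark runs at an aggressive full-batch learning rate, the regime
    where single random starts train unreliably and initialization quality
    matters; a run whose loss diverges scores infinity.  Returns per-seed
    MSEs, the two medians, and the fraction of seeds where GABP is at least
    as good.
    """
    n_evals = population_size * (generations + 1)
    eval_epoch_equiv = n_internal / (2.0 * n_dev + n_internal)
    plain_epochs = final_epochs + int(round(n_evals * eval_epoch_equiv))
    gabp_mse = np.empty(n_seeds)
    plain_mse = np.empty(n_seeds)
    for i in range(n_seeds):
        s = seed * 1000 + i
        dev, internal = _self_realizable_target(
            s, n_dev, n_internal, n_hidden, target_weight_scale, vset)
        ga_cfg = GaConfig(population_size=population_size, generations=generations,
                          inner_training_epochs=0, init_scale=init_scale,
                          mutation_scale=mutation_scale, seed=2 * s + 1)
        cfg = TrainConfig(learning_rate=learning_rate, max_epochs=final_epochs,
                          patience=final_epochs, seed=2 * s)
        try:
            chrom, _ = ga_optimize_init(vset, n_hidden, dev, internal, ga_cfg, cfg)
            model = make_model(vset, n_hidden, dev).with_chromosome(chrom)
            _, trace = train_bp(model, dev, internal, cfg)
            gabp_mse[i] = trace["best_internal_mse"]
        except TrainingError:
            gabp_mse[i] = np.inf
        plain = make_model(vset, n_hidden, dev,
                           rng=np.random.default_rng(2 * s), init_scale=init_scale)
        try:
            _, trace = train_bp(plain, dev, internal,
                                replace(cfg, max_epochs=plain_epochs,
                                        patience=plain_epochs))
            plain_mse[i] = trace["best_internal_mse"]
        except TrainingError:
            plain_mse[i] = np.inf
    return {
        "gabp_mse": gabp_mse,
        "plain_mse": plain_mse,
        "median_gabp": float(np.median(gabp_mse)),
        "median_plain": float(np.median(plain_mse)),
        "win_fraction": float(np.mean(gabp_mse <= plain_mse)),
        "plain_epochs": plain_epochs,
        "final_epochs": final_epochs,
    }
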