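"""Genetic-algorithm feature selection wrapped around a soft-margin SVM.

A chromosome is a binary mask over the feature vector (bit i set means
feature i enters the classifier).  Chromosome fitness is the stratified
cross-validated accuracy of an SVM restricted to the masked features;
multiclass decisions use pairwise (one-vs-one) binary machines internally,
as implemented by scikit-learn's SVC.  Each generation holds a fixed number
of chromosomes; selection is a size-2 tournament with single elitism,
crossover is uniform, and every bit mutates with a small probability
(1% by default) to maintain diversity.  The search stops at a fitness
plateau or at the generation cap, and the best-ever mask is refit on the
full training set.

Features are standardized (zero mean, unit SD learned on training data)
before the SVM, since the raw features mix scales (uV^2 energies, entropies,
unitless skewness).  The all-ones mask is evaluated at initialization and
competes through elitism, so the returned fitness can never fall below the
no-selection baseline on the same data and seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import joblib
import numpy as np
from sklearn.model_selection import StratifiedKFold, cross_val_score
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

CLASS_ORDER = ("normal", "spike", "seizure")


@dataclass(frozen=True)
class SvmConfig:
    """Soft-margin SVM settings; C is the error penalty of the margin."""

    C: float = 10.0
    kernel: str = "rbf"
    gamma: float | str = "scale"
    class_weight: str | None = None
    tune: bool = True
    c_grid: tuple[float, ...] = (1.0, 10.0, 100.0)

    def __post_init__(self) -> None:
        if self.C <= 0:
            raise ValueError("C must be positive")
        if self.kernel not in ("linear", "rbf"):
            raise ValueError("kernel must be linear or rbf")


@dataclass(frozen=True)
class GaConfig:
    """GA bookkeeping: 100 chromosomes per generation, 1% mutation, stop at
    a performance plateau or the 200th generation."""

    population: int = 100
    mutation_rate: float = 0.01
    max_generations: int = 200
    plateau_patience: int = 20
    plateau_tol: float = 1e-4
    crossover_rate: float = 0.9
    tournament_size: int = 2
    init_density: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.mutation_rate < 1:
            raise ValueError("mutation_rate must lie in (0, 1)")
        if self.population < 2:
            raise ValueError("population must be >= 2")


@dataclass
class Chromosome:
    mask: np.ndarray
    fitness: float | None = None


@dataclass
class TrainedModel:
    """A fitted classifier: mask, scaling, SVM state and config snapshot."""

    mask: np.ndarray
    pipeline: Pipeline
    feature_names: tuple[str, ...]
    svm_config: SvmConfig
    seed: int
    classes_: np.ndarray
    ga_log: dict = field(default_factory=dict)

    def save(self, path: str | Path) -> None:
        joblib.dump(self, path)

    @staticmethod
    def load(path: str | Path) -> "TrainedModel":
        return joblib.load(path)


def _make_pipeline(svm_config: SvmConfig) -> Pipeline:
    return Pipeline(
        [
            ("scale", StandardScaler()),
            (
                "svm",
                SVC(
                    C=svm_config.C,
                    kernel=svm_config.kernel,
                    gamma=svm_config.gamma,
                    class_weight=svm_config.class_weight,
                    decision_function_shape="ovr",
                ),
            ),
        ]
    )


def fitness(
    mask: np.ndarray,
    X: np.ndarray,
    y: np.ndarray,
    svm_config: SvmConfig | None = None,
    n_splits: int = 5,
    seed: int = 0,
) -> float:
    """Stratified cross-validated accuracy of the SVM on the masked features.

    An empty mask scores 0 (logged as such, not an error).  Deterministic
    for a given (mask, data, config, seed).
    """
    mask = np.asarray(mask, dtype=bool)
    if mask.sum() == 0:
        return 0.0
    cfg = svm_config or SvmConfig()
    y = np.asarray(y)
    _, counts = np.unique(y, return_counts=True)
    splits = int(min(n_splits, counts.min()))
    if splits < 2:
        raise ValueError("each class needs at least 2 members for CV fitness")
    cv = StratifiedKFold(n_splits=splits, shuffle=True, random_state=seed)
    scores = cross_val_score(_make_pipeline(cfg), X[:, mask], y, cv=cv, scoring="accuracy")
    return float(scores.mean())


def tune_svm(
    X: np.ndarray,
    y: np.ndarray,
    svm_config: SvmConfig,
    seed: int = 0,
) -> SvmConfig:
    """One small C grid search on the all-ones mask, frozen before the GA."""
    best_cfg, best_fit = svm_config, -np.inf
    all_ones = np.ones(X.shape[1], dtype=bool)
    for c in svm_config.c_grid:
        cand = replace(svm_config, C=c, tune=False)
        f = fitness(all_ones, X, y, cand, seed=seed)
        if f > best_fit:
            best_cfg, best_fit = cand, f
    return best_cfg


def _ensure_nonempty(mask: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    if not mask.any():
        mask = mask.copy()
        mask[rng.integers(mask.size)] = True
    return mask


def ga_select(
    X: np.ndarray,
    y: np.ndarray,
    ga_config: GaConfig | None = None,
    svm_config: SvmConfig | None = None,
    feature_names: tuple[str, ...] | None = None,
) -> TrainedModel:
    """Run the GA search and refit the best-ever mask on the full data.

    The best-fitness trace is non-decreasing (single elitism); the number of
    fitness invocations is logged both as the per-generation sum (operative)
    and as the log10 of the product form.
    """
    ga = ga_config or GaConfig()
    svm = svm_config or SvmConfig()
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    if np.unique(y).size < 2:
        raise ValueError("at least two classes are required")
    n_features = X.shape[1]
    rng = np.random.default_rng(ga.seed)
    if svm.tune:
        svm = tune_svm(X, y, svm, seed=ga.seed)

    def evaluate(mask: np.ndarray) -> float:
        return fitness(mask, X, y, svm, seed=ga.seed)

    n_evals = 0
    generation_sizes: list[int] = []

    all_ones = np.ones(n_features, dtype=bool)
    best_mask, best_fit = all_ones, evaluate(all_ones)
    n_evals += 1

    population = [
        _ensure_nonempty(rng.random(n_features) < ga.init_density, rng)
        for _ in range(ga.population)
    ]
    trace: list[float] = []
    no_improve = 0
    generations = 0
    for _ in range(ga.max_generations):
        generations += 1
        fits = np.array([evaluate(m) for m in population])
        n_evals += len(population)
        generation_sizes.append(len(population))
        gen_best = int(np.argmax(fits))
        improved = fits[gen_best] > best_fit + ga.plateau_tol
        if fits[gen_best] > best_fit:
            best_fit = float(fits[gen_best])
            best_mask = population[gen_best].copy()
        trace.append(best_fit)
        no_improve = 0 if improved else no_improve + 1
        if no_improve >= ga.plateau_patience or generations >= ga.max_generations:
            break
        # next generation: elite + tournament offspring
        nxt = [best_mask.copy()]
        while len(nxt) < ga.population:
            parents = []
            for _ in range(2):
                contestants = rng.integers(0, len(population), ga.tournament_size)
                parents.append(population[max(contestants, key=lambda i: fits[i])])
            if rng.random() < ga.crossover_rate:
                take = rng.random(n_features) < 0.5
                child = np.where(take, parents[0], parents[1])
            else:
                child = parents[0].copy()
            flip = rng.random(n_features) < ga.mutation_rate
            child = np.logical_xor(child, flip)
            nxt.append(child)
        population = nxt

    pipeline = _make_pipeline(svm)
    pipeline.fit(X[:, best_mask], y)
    log = {
        "generations": generations,
        "fitness_trace": trace,
        "best_fitness": best_fit,
        "n_fitness_calls": n_evals,
        "invocations_sum": int(np.sum(generation_sizes)),
        "invocations_log10_product": float(np.sum(np.log10(generation_sizes)))
        if generation_sizes
        else 0.0,
    }
    return TrainedModel(
        mask=best_mask,
        pipeline=pipeline,
        feature_names=tuple(feature_names or ()),
        svm_config=svm,
        seed=ga.seed,
        classes_=pipeline.named_steps["svm"].classes_,
        ga_log=log,
    )


def train_svm(
    X: np.ndarray,
    y: np.ndarray,
    svm_config: SvmConfig | None = None,
    mask: np.ndarray | None = None,
    seed: int = 0,
    feature_names: tuple[str, ...] | None = None,
) -> TrainedModel:
    """Fit the SVM without feature selection (optionally on a fixed mask)."""
    svm = svm_config or SvmConfig()
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    if np.unique(y).size < 2:
        raise ValueError("at least two classes are required")
    m = np.ones(X.shape[1], dtype=bool) if mask is None else np.asarray(mask, dtype=bool)
    if svm.tune:
        svm = tune_svm(X[:, m], y, svm, seed=seed)
    pipeline = _make_pipeline(svm)
    pipeline.fit(X[:, m], y)
    return TrainedModel(
        mask=m,
        pipeline=pipeline,
        feature_names=tuple(feature_names or ()),
        svm_config=svm,
        seed=seed,
        classes_=pipeline.named_steps["svm"].classes_,
    )


def predict(model: TrainedModel, X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Class labels and per-class decision scores for feature vectors.

    The vectors must match the training feature order; the mask stored in
    the model picks the selected columns.  Scores are one-vs-rest decision
    values (for two classes the single margin is mirrored to both columns).
    """
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[None, :]
    if X.shape[1] != model.mask.size:
        raise ValueError(
            f"feature length {X.shape[1]} does not match the trained mask "
            f"({model.mask.size})"
        )
    Xm = X[:, model.mask]
    labels = model.pipeline.predict(Xm)
    raw = model.pipeline.decision_function(Xm)
    if raw.ndim == 1:
        scores = np.column_stack([-raw, raw])
    else:
        scores = raw
    return labels, scores


def class_score(model: TrainedModel, scores: np.ndarray, klass: str) -> np.ndarray:
    """The decision-score column of one class."""
    classes = list(model.classes_)
    return scores[:, classes.index(klass)]
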