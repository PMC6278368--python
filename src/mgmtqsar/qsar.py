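"""Multiple linear regression with GA descriptor selection.

The modelling core: ordinary-least-squares MLR fitting and prediction,
leave-one-out cross-validation via the hat-matrix shortcut, exhaustive
all-subsets search for low-dimensional seeds, and a genetic algorithm
that maximises Q2_LOO over descriptor subsets subject to the
rule-of-thumb cap of one descriptor per five training compounds.

The literature models for MGMT inhibition by base analogs are shipped
as fixtures: ``MODEL_I`` (5 descriptors, 83 training compounds) and
``MODEL_II`` (9 descriptors, 68 training compounds).
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "MlrModel",
    "GaConfig",
    "GaResult",
    "fit_mlr",
    "predict",
    "loo_press",
    "all_subsets",
    "ga_select",
    "rule_of_thumb_cap",
    "MODEL_I",
    "MODEL_II",
]


class RankDeficiencyError(ValueError):
    """Design matrix is singular; names the offending columns."""


@dataclass
class MlrModel:
    """An MLR model: intercept plus named descriptor coefficients."""

    intercept: float
    coefficients: dict[str, float]
    n_train: int = 0
    fitted: bool = True

    @property
    def p(self) -> int:
        """Number of descriptors."""
        return len(self.coefficients)

    @property
    def descriptor_names(self) -> list[str]:
        return list(self.coefficients)

    def to_json(self, path: str | Path) -> None:
        payload = {
            "intercept": self.intercept,
            "coefficients": self.coefficients,
            "n_train": self.n_train,
        }
        Path(path).write_text(json.dumps(payload, indent=2) + "\n")

    @classmethod
    def from_json(cls, path: str | Path) -> "MlrModel":
        payload = json.loads(Path(path).read_text())
        return cls(
            intercept=payload["intercept"],
            coefficients=payload["coefficients"],
            n_train=payload.get("n_train", 0),
        )


#: Best 5-descriptor model on the 103-compound series (83 train / 20 test).
MODEL_I = MlrModel(
    intercept=12.80,
    coefficients={
        "J_Dz(p)": -4.39,
        "VE1sign_B(i)": -8.05,
        "GATS1p": -5.02,
        "JGI4": 104.16,
        "CATS2D_05_AA": -0.39,
    },
    n_train=83,
)

#: Best 9-descriptor model on the 84-compound series (68 train / 16 test).
MODEL_II = MlrModel(
    intercept=19.47,
    coefficients={
        "VE3sign_X": -0.17,
        "J_Dz(p)": -6.04,
        "SpPosA_B(p)": 22.5,
        "VE3sign_B(s)": 0.28,
        "MATS1i": 3.05,
        "JGI4": 138.84,
        "nArNH2": 0.60,
        "CATS2D_07_DA": -0.19,
        "B09[C-C]": -1.36,
    },
    n_train=68,
)


def _design(X: pd.DataFrame) -> np.ndarray:
    return np.column_stack([np.ones(len(X)), X.to_numpy(dtype=float)])


def _check_rank(X: pd.DataFrame) -> None:
    A = _design(X)
    rank = np.linalg.matrix_rank(A)
    if rank < A.shape[1]:
        # identify columns that add no rank, scanning in order
        bad: list[str] = []
        base = np.ones((len(X), 1))
        r = 1
        for name in X.columns:
            cand = np.column_stack([base, X[name].to_numpy(dtype=float)])
            r_new = np.linalg.matrix_rank(cand)
            if r_new == r:
                bad.append(name)
            else:
                base, r = cand, r_new
        raise RankDeficiencyError(
            f"singular design matrix; linearly dependent columns: {bad}"
        )


def fit_mlr(X: pd.DataFrame, y: pd.Series | np.ndarray) -> MlrModel:
    """Fit ordinary least squares with intercept.

    Requires n > p + 1 and a full-rank design; a singular design raises
    :class:`RankDeficiencyError` naming the dependent columns.
    """
    y = np.asarray(y, dtype=float)
    n, p = X.shape
    if n <= p + 1:
        raise ValueError(f"need n > p + 1 (got n={n}, p={p})")
    _check_rank(X)
    A = _design(X)
    beta, *_ = np.linalg.lstsq(A, y, rcond=None)
    return MlrModel(
        intercept=float(beta[0]),
        coefficients={c: float(b) for c, b in zip(X.columns, beta[1:])},
        n_train=n,
    )


def predict(model: MlrModel, X: pd.DataFrame) -> pd.Series:
    """Predicted pED50 = intercept + sum(coefficient * descriptor value)."""
    missing = [c for c in model.coefficients if c not in X.columns]
    if missing:
        raise KeyError(f"descriptor columns missing from input: {missing}")
    names = model.descriptor_names
    beta = np.array([model.coefficients[c] for c in names])
    yhat = model.intercept + X[names].to_numpy(dtype=float) @ beta
    return pd.Series(yhat, index=X.index, name="ped50_pred")


def loo_press(
    X: pd.DataFrame, y: pd.Series | np.ndarray
) -> tuple[float, float, np.ndarray]:
    """Leave-one-out PRESS and Q2_LOO via the hat-matrix shortcut.

    The deleted residual for compound i is e_i / (1 - h_i) where e_i is
    the ordinary residual and h_i the leverage; PRESS is the sum of
    squared deleted residuals and Q2_LOO = 1 - PRESS / SS_tot.

    Returns ``(press, q2_loo, deleted_residuals)``.
    """
    y = np.asarray(y, dtype=float)
    n, p = X.shape
    if n <= p + 2:
        raise ValueError(f"need n > p + 2 for LOO (got n={n}, p={p})")
    _check_rank(X)
    A = _design(X)
    beta, *_ = np.linalg.lstsq(A, y, rcond=None)
    resid = y - A @ beta
    # leverages = row sums of A * (A'A)^-1 A' without forming the full hat
    AtA_inv = np.linalg.inv(A.T @ A)
    h = np.einsum("ij,jk,ik->i", A, AtA_inv, A)
    if np.any(h >= 1 - 1e-12):
        raise ValueError("a training leverage equals 1; deleted residual undefined")
    deleted = resid / (1 - h)
    press = float(deleted @ deleted)
    ss_tot = float(((y - y.mean()) ** 2).sum())
    if ss_tot == 0:
        raise ValueError("response has zero variance")
    return press, 1 - press / ss_tot, deleted


def _q2_of(X: pd.DataFrame, y: np.ndarray, cols: tuple[int, ...]) -> float:
    sub = X.iloc[:, list(cols)]
    try:
        _, q2, _ = loo_press(sub, y)
    except (ValueError, np.linalg.LinAlgError):
        return -np.inf
    return q2


def all_subsets(
    X: pd.DataFrame,
    y: pd.Series | np.ndarray,
    max_size: int = 3,
    guard_limit: int = 200_000,
) -> list[tuple[tuple[str, ...], float]]:
    """Exhaustive search of descriptor subsets up to ``max_size``.

    Returns ``(descriptor_names, q2_loo)`` pairs sorted by descending
    Q2_LOO (ties broken lexicographically by name list, for
    determinism).  Raises if the enumeration would exceed
    ``guard_limit`` candidate subsets; use :func:`ga_select` instead.
    """
    y = np.asarray(y, dtype=float)
    p = X.shape[1]
    total = sum(_ncomb(p, k) for k in range(1, max_size + 1))
    if total > guard_limit:
        raise ValueError(
            f"all-subsets enumeration of {total} candidates exceeds the guard "
            f"limit ({guard_limit}); use the genetic algorithm instead"
        )
    results: list[tuple[tuple[str, ...], float]] = []
    for k in range(1, max_size + 1):
        for cols in itertools.combinations(range(p), k):
            q2 = _q2_of(X, y, cols)
            results.append((tuple(X.columns[list(cols)]), q2))
    results.sort(key=lambda t: (-t[1], t[0]))
    return results


def _ncomb(n: int, k: int) -> int:
    from math import comb

    return comb(n, k)


def rule_of_thumb_cap(n_train: int) -> int:
    """At most one descriptor per five training compounds."""
    return max(1, n_train // 5)


@dataclass
class GaConfig:
    """Genetic-algorithm settings for descriptor selection.

    Defaults follow the published protocol: population 200, mutation
    rate 20 (read as a 20% per-chromosome gene-flip probability),
    2000 generations, with Q2_LOO as the fitness function.  Crossover
    (uniform, 80%) and elitism (2) are standard choices.
    ``max_descriptors`` defaults to the rule-of-thumb cap
    floor(n_train / 5).
    """

    population_size: int = 200
    mutation_rate: float = 20.0
    generations: int = 2000
    max_descriptors: int | None = None
    elitism_count: int = 2
    crossover_rate: float = 80.0
    seed_subset_size: int = 2
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 <= self.mutation_rate <= 100 and 0 <= self.crossover_rate <= 100):
            raise ValueError("rates are percentages in [0, 100]")
        if self.max_descriptors is not None and self.max_descriptors < 1:
            raise ValueError("max_descriptors must be at least 1")


@dataclass
class GaResult:
    """Final population with fitness trace, best first."""

    population: list[tuple[tuple[str, ...], float]]
    best_trace: list[float] = field(default_factory=list)

    @property
    def best(self) -> tuple[tuple[str, ...], float]:
        return self.population[0]


def _subset_key(X: pd.DataFrame, cols: frozenset[int]) -> tuple[str, ...]:
    return tuple(sorted(X.columns[i] for i in cols))


def ga_select(
    X: pd.DataFrame, y: pd.Series | np.ndarray, config: GaConfig | None = None
) -> GaResult:
    """Select descriptor subsets maximising Q2_LOO with a GA.

    Chromosomes are descriptor subsets of size <= ``max_descriptors``.
    The initial population is seeded from the all-subsets winners at
    low dimension, then evolved with tournament selection, uniform
    (set-union) crossover, per-chromosome mutation and elitism.  The
    best-fitness trace is non-decreasing; runs are deterministic under
    a fixed seed.
    """
    config = config or GaConfig()
    y = np.asarray(y, dtype=float)
    n, p = X.shape
    cap = config.max_descriptors or rule_of_thumb_cap(n)
    if cap < 1:
        raise ValueError("max_descriptors must be at least 1")
    rng = np.random.default_rng(np.random.SeedSequence(config.seed))

    cache: dict[frozenset[int], float] = {}

    def fitness(chrom: frozenset[int]) -> float:
        if chrom not in cache:
            cache[chrom] = _q2_of(X, y, tuple(sorted(chrom)))
        return cache[chrom]

    def repair(chrom: set[int]) -> frozenset[int]:
        chrom = set(chrom)
        while len(chrom) > cap:
            chrom.remove(int(rng.choice(sorted(chrom))))
        if not chrom:
            chrom.add(int(rng.integers(p)))
        return frozenset(chrom)

    # seed from all-subsets winners at low dimension
    seeds = all_subsets(X, y, max_size=min(config.seed_subset_size, cap))
    col_index = {c: i for i, c in enumerate(X.columns)}
    population: list[frozenset[int]] = []
    seen: set[frozenset[int]] = set()
    for names, _ in seeds:
        chrom = frozenset(col_index[c] for c in names)
        if chrom not in seen:
            population.append(chrom)
            seen.add(chrom)
        if len(population) >= config.population_size:
            break
    attempts = 0
    while len(population) < config.population_size:
        size = int(rng.integers(1, cap + 1))
        chrom = frozenset(rng.choice(p, size=size, replace=False).tolist())
        attempts += 1
        # small search spaces can't fill the population with unique
        # chromosomes; admit duplicates after enough failed draws
        if chrom not in seen or attempts > 20 * config.population_size:
            population.append(chrom)
            seen.add(chrom)

    def sort_key(chrom: frozenset[int]) -> tuple[float, tuple[str, ...]]:
        return (-fitness(chrom), _subset_key(X, chrom))

    population.sort(key=sort_key)
    trace = [fitness(population[0])]

    for _ in range(config.generations):
        nxt: list[frozenset[int]] = population[: config.elitism_count]
        while len(nxt) < config.population_size:
            # tournament selection, size 2
            a, b = rng.integers(len(population), size=2)
            pa = population[min(a, b)]  # population sorted: lower index fitter
            a, b = rng.integers(len(population), size=2)
            pb = population[min(a, b)]
            if rng.random() < config.crossover_rate / 100:
                union = sorted(pa | pb)
                # uniform crossover on the union of genes
                child = {g for g in union if rng.random() < 0.5}
                if not child:
                    child = {union[int(rng.integers(len(union)))]}
            else:
                child = set(pa)
            if rng.random() < config.mutation_rate / 100:
                # flip one gene: swap a member for a random non-member
                if child and rng.random() < 0.5:
                    child.remove(int(rng.choice(sorted(child))))
                child.add(int(rng.integers(p)))
            nxt.append(repair(child))
        population = sorted(set(nxt) | set(population[: config.elitism_count]),
                            key=sort_key)[: config.population_size]
        trace.append(fitness(population[0]))

    final = [(_subset_key(X, c), fitness(c)) for c in population]
    return GaResult(population=final, best_trace=trace)
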