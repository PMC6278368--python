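"""Regression-model quality suite.

Implements the full validation battery used to accept or reject a QSAR
model: goodness-of-fit statistics (R2, adjusted R2, RMSE, F, Lin's
concordance correlation coefficient), external predictivity in all its
flavours (Q2_ext = Q2_F1, Q2_F2, Q2_F3, CCC_ext, R2_ext), the
Golbraikh-Tropsha through-origin acceptance criteria, the QUIK
multivariate-correlation rule against multicollinearity, Y-scrambling
as a chance-correlation null, and a desirability-based multi-criteria
(MCDM) score for ranking candidate models.

Acceptance conditions for an externally predictive model:

  (i)   Q2_LOO > 0.5
  (ii)  R2_ext > 0.6
  (iii) (R2_ext - R0^2)/R2_ext < 0.1 and 0.85 <= k <= 1.15
        (or the primed variant)
  (iv)  |R0^2 - R0'^2| < 0.3
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Callable, Mapping

import numpy as np
import pandas as pd

from .qsar import fit_mlr, loo_press, predict

__all__ = [
    "FitStats",
    "ExternalStats",
    "GtCriteria",
    "QuikResult",
    "ScramblingResult",
    "ValidationReport",
    "fit_stats",
    "external_stats",
    "golbraikh_tropsha",
    "quik_check",
    "k_index",
    "y_scramble",
    "mcdm_score",
    "validate_model",
]


def _ccc(x: np.ndarray, y: np.ndarray) -> float:
    """Lin's concordance correlation coefficient (population moments)."""
    sxy = np.mean((x - x.mean()) * (y - y.mean()))
    return float(2 * sxy / (x.var() + y.var() + (x.mean() - y.mean()) ** 2))


@dataclass
class FitStats:
    r2: float
    r2_adj: float
    rmse: float
    f: float
    ccc: float


def fit_stats(
    y: np.ndarray, yhat: np.ndarray, n: int, p: int, rmse_divisor_n: bool = True
) -> FitStats:
    """Training-set goodness-of-fit statistics.

    R2 = 1 - SS_res/SS_tot; R2_adj = 1 - (1-R2)(n-1)/(n-p-1);
    RMSE = sqrt(SS_res/n) (divisor n, the common QSAR reporting
    convention; set ``rmse_divisor_n=False`` for n-p-1);
    F = (SS_reg/p)/(SS_res/(n-p-1)); CCC per Lin.
    """
    y = np.asarray(y, dtype=float)
    yhat = np.asarray(yhat, dtype=float)
    if n <= p + 1:
        raise ValueError("need n > p + 1")
    ss_tot = float(((y - y.mean()) ** 2).sum())
    if ss_tot == 0:
        raise ValueError("zero variance in y; R2 undefined")
    ss_res = float(((y - yhat) ** 2).sum())
    ss_reg = float(((yhat - y.mean()) ** 2).sum())
    r2 = 1 - ss_res / ss_tot
    r2_adj = 1 - (1 - r2) * (n - 1) / (n - p - 1)
    denom = n if rmse_divisor_n else n - p - 1
    rmse = float(np.sqrt(ss_res / denom))
    f = (ss_reg / p) / (ss_res / (n - p - 1)) if ss_res > 0 else float("inf")
    return FitStats(r2=r2, r2_adj=r2_adj, rmse=rmse, f=f, ccc=_ccc(y, yhat))


@dataclass
class ExternalStats:
    q2_ext: float  # == q2_f1
    q2_f1: float
    q2_f2: float
    q2_f3: float
    rmse_test: float
    ccc_test: float
    r2_ext: float


def external_stats(
    y_test: np.ndarray,
    yhat_test: np.ndarray,
    y_train_mean: float,
    ss_train: float,
    n_train: int,
    n_test: int | None = None,
) -> ExternalStats:
    """External predictivity statistics.

    Q2_F1 = Q2_ext = 1 - PRESS / sum((y_test - mean(y_train))^2);
    Q2_F2 uses the test-set mean in the denominator; Q2_F3 compares
    per-datum mean squared errors (test PRESS/n_test against training
    SS/n_train); R2_ext is the squared Pearson correlation of observed
    and predicted test values.  ``ss_train`` is the training response's
    sum of squares about its own mean.
    """
    y = np.asarray(y_test, dtype=float)
    yhat = np.asarray(yhat_test, dtype=float)
    if y.size == 0:
        raise ValueError("empty test set")
    n_test = n_test or y.size
    press = float(((y - yhat) ** 2).sum())
    sd = float(((y - y_train_mean) ** 2).sum())
    q2_f1 = 1 - press / sd
    q2_f2 = 1 - press / float(((y - y.mean()) ** 2).sum())
    q2_f3 = 1 - (press / n_test) / (ss_train / n_train)
    # a constant predictor has no defined correlation with the response
    if yhat.std() == 0 or y.std() == 0:
        r2_ext = float("nan")
    else:
        r2_ext = float(np.corrcoef(y, yhat)[0, 1] ** 2)
    return ExternalStats(
        q2_ext=q2_f1,
        q2_f1=q2_f1,
        q2_f2=q2_f2,
        q2_f3=q2_f3,
        rmse_test=float(np.sqrt(press / n_test)),
        ccc_test=_ccc(y, yhat),
        r2_ext=r2_ext,
    )


@dataclass
class GtCriteria:
    """Through-origin regression diagnostics and acceptance flags."""

    r0_sq: float  # observed vs predicted through origin
    r0_sq_prime: float  # predicted vs observed through origin
    k: float
    k_prime: float
    r2_ext: float
    q2_loo: float | None = None
    cond_i: bool | None = None  # Q2_LOO > 0.5
    cond_ii: bool = False  # R2_ext > 0.6
    cond_iii: bool = False  # through-origin closeness + slope band
    cond_iv: bool = False  # |R0^2 - R0'^2| < 0.3

    @property
    def passed(self) -> bool:
        conds = [self.cond_ii, self.cond_iii, self.cond_iv]
        if self.cond_i is not None:
            conds.append(self.cond_i)
        return all(conds)


def golbraikh_tropsha(
    y_test: np.ndarray, yhat_test: np.ndarray, q2_loo: float | None = None
) -> GtCriteria:
    """Golbraikh-Tropsha external acceptance criteria.

    Through-origin slopes k = sum(y*yhat)/sum(yhat^2) and
    k' = sum(y*yhat)/sum(y^2); the through-origin determination
    coefficients are R0^2 = 1 - sum((y - k*yhat)^2)/sum((y - ybar)^2)
    and the primed analogue with the roles of y and yhat exchanged.
    """
    y = np.asarray(y_test, dtype=float)
    yhat = np.asarray(yhat_test, dtype=float)
    if y.size == 0:
        raise ValueError("empty test set")
    if not (np.any(y) and np.any(yhat)):
        raise ValueError("all-zero vectors: through-origin slopes undefined")
    k = float((y @ yhat) / (yhat @ yhat))
    k_prime = float((y @ yhat) / (y @ y))
    r0_sq = 1 - float(((y - k * yhat) ** 2).sum() / ((y - y.mean()) ** 2).sum())
    r0_sq_prime = 1 - float(
        ((yhat - k_prime * y) ** 2).sum() / ((yhat - yhat.mean()) ** 2).sum()
    )
    r2_ext = float(np.corrcoef(y, yhat)[0, 1] ** 2)

    cond_iii = (
        ((r2_ext - r0_sq) / r2_ext < 0.1 and 0.85 <= k <= 1.15)
        or ((r2_ext - r0_sq_prime) / r2_ext < 0.1 and 0.85 <= k_prime <= 1.15)
    )
    return GtCriteria(
        r0_sq=r0_sq,
        r0_sq_prime=r0_sq_prime,
        k=k,
        k_prime=k_prime,
        r2_ext=r2_ext,
        q2_loo=q2_loo,
        cond_i=None if q2_loo is None else q2_loo > 0.5,
        cond_ii=r2_ext > 0.6,
        cond_iii=cond_iii,
        cond_iv=abs(r0_sq - r0_sq_prime) < 0.3,
    )


def k_index(columns: np.ndarray) -> float:
    """Multivariate K correlation index of a set of columns.

    K = sum_j |lambda_j / sum(lambda) - 1/m| / (2(m-1)/m), with
    lambda_j the eigenvalues of the column correlation matrix of m
    columns.  K = 0 for mutually orthogonal columns and 1 for perfectly
    collinear ones; invariant to per-column scaling and sign.
    """
    X = np.asarray(columns, dtype=float)
    m = X.shape[1]
    if m < 2:
        raise ValueError("K index needs at least 2 columns")
    sd = X.std(axis=0)
    if np.any(sd == 0):
        raise ValueError("constant column: correlation undefined")
    corr = np.corrcoef(X, rowvar=False)
    lam = np.linalg.eigvalsh(corr)
    lam = np.clip(lam, 0, None)
    frac = lam / lam.sum()
    return float(np.abs(frac - 1 / m).sum() / (2 * (m - 1) / m))


@dataclass
class QuikResult:
    k_x: float
    k_xy: float
    delta: float

    @property
    def passed(self) -> bool:
        return self.k_xy - self.k_x >= self.delta


def quik_check(
    X_model: pd.DataFrame, y: np.ndarray, delta: float = 0.05
) -> QuikResult:
    """QUIK rule: reject multicollinear models.

    The K correlation index of the model descriptors plus the response
    (K_XY) must exceed that of the descriptors alone (K_X) by at least
    ``delta``; otherwise the descriptors are more correlated with each
    other than with the response.
    """
    Xv = X_model.to_numpy(dtype=float)
    if Xv.shape[1] < 2:
        raise ValueError("QUIK rule needs at least 2 descriptor columns")
    y = np.asarray(y, dtype=float).reshape(-1, 1)
    return QuikResult(
        k_x=k_index(Xv), k_xy=k_index(np.hstack([Xv, y])), delta=delta
    )


@dataclass
class ScramblingResult:
    iterations: int
    r2_scrambled: np.ndarray
    q2_scrambled: np.ndarray
    seed: int

    @property
    def r2_mean(self) -> float:
        return float(self.r2_scrambled.mean())

    @property
    def q2_mean(self) -> float:
        return float(self.q2_scrambled.mean())

    def q2_percentile(self, q: float) -> float:
        return float(np.percentile(self.q2_scrambled, q))


def y_scramble(
    X: pd.DataFrame, y: np.ndarray, iterations: int = 2000, seed: int = 0
) -> ScramblingResult:
    """Chance-correlation null by response permutation.

    Each iteration permutes y (X untouched), refits the model on the
    selected descriptors and records R2 and Q2_LOO.  A real model's
    statistics should sit far above this null distribution.
    """
    import warnings

    if iterations < 1:
        warnings.warn("y_scramble called with iterations < 1; empty result")
        return ScramblingResult(0, np.array([]), np.array([]), seed)
    y = np.asarray(y, dtype=float)
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    n, p = X.shape
    r2s = np.empty(iterations)
    q2s = np.empty(iterations)
    for i in range(iterations):
        yp = rng.permutation(y)
        model = fit_mlr(X, yp)
        yhat = predict(model, X).to_numpy()
        ss_res = ((yp - yhat) ** 2).sum()
        ss_tot = ((yp - yp.mean()) ** 2).sum()
        r2s[i] = 1 - ss_res / ss_tot
        _, q2s[i], _ = loo_press(X, yp)
    return ScramblingResult(iterations, r2s, q2s, seed)


def mcdm_score(
    criteria: Mapping[str, tuple[float, float, float]]
) -> float:
    """Desirability-based multi-criteria score in [0, 1].

    ``criteria`` maps a name to ``(value, ideal, worst)``.  Each
    criterion is mapped linearly onto [0, 1] (clipped), with 1 at the
    ideal and 0 at the worst — the direction is implied by which of
    ideal/worst is larger — and the score is the arithmetic mean.
    """
    if not criteria:
        raise ValueError("at least one criterion required")
    ds = []
    for name, (value, ideal, worst) in criteria.items():
        if ideal == worst:
            raise ValueError(f"criterion {name!r}: ideal equals worst")
        d = (value - worst) / (ideal - worst)
        ds.append(min(1.0, max(0.0, d)))
    return float(np.mean(ds))


@dataclass
class ValidationReport:
    """Everything needed to judge one MLR model."""

    n_train: int
    n_test: int
    p: int
    fit: FitStats
    q2_loo: float
    external: ExternalStats | None
    gt: GtCriteria | None
    quik: QuikResult | None
    scrambling: ScramblingResult | None
    mcdm: float | None

    def to_dict(self) -> dict:
        out = {
            "n_train": self.n_train,
            "n_test": self.n_test,
            "p": self.p,
            "q2_loo": self.q2_loo,
            "fit": asdict(self.fit),
        }
        if self.external:
            out["external"] = asdict(self.external)
        if self.gt:
            g = asdict(self.gt)
            g["passed"] = self.gt.passed
            out["golbraikh_tropsha"] = g
        if self.quik:
            out["quik"] = {
                "k_x": self.quik.k_x,
                "k_xy": self.quik.k_xy,
                "delta": self.quik.delta,
                "passed": self.quik.passed,
            }
        if self.scrambling and self.scrambling.iterations:
            out["y_scrambling"] = {
                "iterations": self.scrambling.iterations,
                "r2_mean": self.scrambling.r2_mean,
                "r2_max": float(self.scrambling.r2_scrambled.max()),
                "q2_mean": self.scrambling.q2_mean,
                "q2_max": float(self.scrambling.q2_scrambled.max()),
                "seed": self.scrambling.seed,
            }
        if self.mcdm is not None:
            out["mcdm"] = self.mcdm
        return out

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2) + "\n")

    def summary(self) -> str:
        """Two-line text block in the style of a published model report."""
        f = self.fit
        lines = [
            f"N_tr = {self.n_train}, Q2_LOO = {self.q2_loo:.2f}, "
            f"R2 = {f.r2:.2f}, R2_adj = {f.r2_adj:.2f}, F = {f.f:.2f}, "
            f"RMSE_tr = {f.rmse:.2f}, CCC_tr = {f.ccc:.2f}"
        ]
        if self.external and self.gt:
            e, g = self.external, self.gt
            lines.append(
                f"N_test = {self.n_test}, Q2_ext = {e.q2_ext:.2f}, "
                f"R2_ext = {e.r2_ext:.2f}, RMSE_test = {e.rmse_test:.2f}, "
                f"Q2_F1 = {e.q2_f1:.2f}, Q2_F2 = {e.q2_f2:.2f}, "
                f"Q2_F3 = {e.q2_f3:.2f}, CCC_test = {e.ccc_test:.2f}, "
                f"(R2_ext - R0^2)/R2_ext = {(g.r2_ext - g.r0_sq) / g.r2_ext:.2f}, "
                f"k = {g.k:.2f}, k' = {g.k_prime:.2f}, "
                f"|R0^2 - R0'^2| = {abs(g.r0_sq - g.r0_sq_prime):.3f}"
            )
        return "\n".join(lines)


def validate_model(
    X_train: pd.DataFrame,
    y_train: np.ndarray,
    X_test: pd.DataFrame | None = None,
    y_test: np.ndarray | None = None,
    scramble_iterations: int = 2000,
    seed: int = 0,
    mcdm_criteria: Mapping[str, tuple[float, float, float]] | None = None,
) -> ValidationReport:
    """Fit an MLR model on the chosen descriptors and run the full suite."""
    y_train = np.asarray(y_train, dtype=float)
    model = fit_mlr(X_train, y_train)
    yhat = predict(model, X_train).to_numpy()
    n, p = X_train.shape
    fs = fit_stats(y_train, yhat, n, p)
    _, q2, _ = loo_press(X_train, y_train)

    ext = gt = None
    n_test = 0
    if X_test is not None and y_test is not None and len(X_test):
        y_test = np.asarray(y_test, dtype=float)
        yhat_test = predict(model, X_test).to_numpy()
        ss_train = float(((y_train - y_train.mean()) ** 2).sum())
        ext = external_stats(
            y_test, yhat_test, float(y_train.mean()), ss_train, n, len(y_test)
        )
        gt = golbraikh_tropsha(y_test, yhat_test, q2_loo=q2)
        n_test = len(y_test)

    quik = quik_check(X_train, y_train) if p >= 2 else None
    scr = (
        y_scramble(X_train, y_train, scramble_iterations, seed)
        if scramble_iterations > 0
        else None
    )

    mcdm = None
    if mcdm_criteria is not None:
        mcdm = mcdm_score(mcdm_criteria)
    elif ext is not None:
        mcdm = mcdm_score(
            {
                "q2_loo": (q2, 1.0, 0.0),
                "r2": (fs.r2, 1.0, 0.0),
                "q2_f1": (ext.q2_f1, 1.0, 0.0),
                "ccc_test": (ext.ccc_test, 1.0, 0.0),
            }
        )

    return ValidationReport(
        n_train=n,
        n_test=n_test,
        p=p,
        fit=fs,
        q2_loo=q2,
        external=ext,
        gt=gt,
        quik=quik,
        scrambling=scr,
        mcdm=mcdm,
    )
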