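"""Leverage-based applicability domain and Williams plots.

A QSAR model is only trusted inside its applicability domain (AD).
Here the AD is delimited by leverage: the hat value
h = x'(X'X)^-1 x of a compound against the training design, with
warning threshold h* = 3(p + 1)/n.  Training compounds with h > h*
unduly influence the fit; test compounds with h > h* are structural
extrapolations whose predictions are unreliable.  Response outliers are
compounds whose standardized residual exceeds +/-3.  The Williams plot
(standardized residual versus leverage) visualises both at once.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .qsar import MlrModel, predict

__all__ = ["leverages", "warning_leverage", "williams_report"]


def _design(X: pd.DataFrame) -> np.ndarray:
    return np.column_stack([np.ones(len(X)), X.to_numpy(dtype=float)])


def leverages(X_train: pd.DataFrame, X_query: pd.DataFrame | None = None) -> np.ndarray:
    """Hat values of query rows against the training design.

    The design includes an intercept column.  With no query set, the
    training compounds' own leverages are returned (these sum to p+1).
    """
    A = _design(X_train)
    gram = A.T @ A
    if np.linalg.matrix_rank(gram) < gram.shape[0]:
        raise np.linalg.LinAlgError("training design is rank deficient")
    gram_inv = np.linalg.inv(gram)
    Q = A if X_query is None else _design(X_query[X_train.columns])
    return np.einsum("ij,jk,ik->i", Q, gram_inv, Q)


def warning_leverage(p: int, n: int) -> float:
    """h* = 3(p + 1)/n, with p the number of descriptors (intercept excluded)."""
    if n <= 0:
        raise ValueError("n must be positive")
    return 3 * (p + 1) / n


def williams_report(
    model: MlrModel,
    X_train: pd.DataFrame,
    y_train: np.ndarray,
    X_test: pd.DataFrame | None = None,
    y_test: np.ndarray | None = None,
    residual_cutoff: float = 3.0,
    studentized: bool = False,
) -> pd.DataFrame:
    """Williams-plot table: leverage, standardized residual and flags.

    One row per compound with columns ``leverage``, ``std_residual``,
    ``set`` (train/test), ``high_leverage`` (h > h*) and
    ``response_outlier`` (|standardized residual| > ``residual_cutoff``).
    Residuals are standardized by the training RMSE by default; with
    ``studentized=True`` each training residual is additionally scaled
    by sqrt(1 - h).  The table carries h* in ``attrs["h_star"]``.
    """
    names = model.descriptor_names
    missing = [c for c in names if c not in X_train.columns]
    if missing:
        raise KeyError(f"training matrix lacks model descriptors: {missing}")
    Xtr = X_train[names]
    y_train = np.asarray(y_train, dtype=float)
    resid_tr = y_train - predict(model, Xtr).to_numpy()
    rmse = float(np.sqrt((resid_tr**2).mean()))
    h_star = warning_leverage(len(names), len(Xtr))

    parts = []
    h_tr = leverages(Xtr)
    std_tr = resid_tr / rmse if rmse > 0 else np.zeros_like(resid_tr)
    if studentized:
        std_tr = std_tr / np.sqrt(np.clip(1 - h_tr, 1e-12, None))
    parts.append(
        pd.DataFrame(
            {"leverage": h_tr, "std_residual": std_tr, "set": "train"},
            index=Xtr.index,
        )
    )
    if X_test is not None and len(X_test):
        Xte = X_test[names] if all(c in X_test.columns for c in names) else None
        if Xte is None:
            raise KeyError("test matrix lacks model descriptors")
        h_te = leverages(Xtr, Xte)
        if y_test is not None:
            resid_te = np.asarray(y_test, dtype=float) - predict(model, Xte).to_numpy()
            std_te = resid_te / rmse if rmse > 0 else np.zeros_like(resid_te)
        else:
            std_te = np.full(len(Xte), np.nan)
        parts.append(
            pd.DataFrame(
                {"leverage": h_te, "std_residual": std_te, "set": "test"},
                index=Xte.index,
            )
        )

    table = pd.concat(parts)
    table["high_leverage"] = table["leverage"] > h_star
    table["response_outlier"] = table["std_residual"].abs() > residual_cutoff
    table.attrs["h_star"] = h_star
    table.attrs["rmse_train"] = rmse
    return table
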