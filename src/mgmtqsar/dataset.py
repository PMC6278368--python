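"""Compound curation, activity labelling, splitting and filtering.

Handles the bookkeeping around an MGMT-inhibition compound series:
the pED50 transform, inhibitor/non-inhibitor labelling against the
reference inhibitor O6-benzylguanine (including censored ED50 bounds
such as ">10" or "<1" uM), the ranked every-fifth train/test split used
for regression modelling, the stratified 4:1 random split used for
classification, descriptor pre-filtering (near-constant and highly
inter-correlated columns), and chemical-diversity summaries.
"""

from __future__ import annotations

import json
import logging
import math
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.spatial.distance import squareform, pdist

logger = logging.getLogger(__name__)

__all__ = [
    "CompoundRecord",
    "CensoredValue",
    "parse_ed50",
    "to_ped50",
    "label_activity",
    "split_qsar_ranked",
    "split_classification",
    "filter_descriptors",
    "diversity_summary",
    "read_activity_table",
]


@dataclass
class CensoredValue:
    """A censored activity bound: ``">10"`` or ``"<1"`` (uM)."""

    bound: float
    direction: str  # ">" or "<"

    def __post_init__(self) -> None:
        if self.direction not in (">", "<"):
            raise ValueError("direction must be '>' or '<'")
        if self.bound <= 0:
            raise ValueError("bound must be positive")

    def __str__(self) -> str:  # round-trips through parse_ed50
        return f"{self.direction}{self.bound:g}"


@dataclass
class CompoundRecord:
    """One molecule in the series."""

    id: str
    ed50: float | CensoredValue | None = None  # uM
    smiles: str | None = None
    ped50: float | None = None
    class_label: str = "unlabeled"  # P | N | unlabeled
    split: str = "excluded"  # train | test | excluded

    def __post_init__(self) -> None:
        if self.ped50 is None and isinstance(self.ed50, (int, float)):
            self.ped50 = to_ped50(float(self.ed50))


_CENSOR_RE = re.compile(r"^\s*([<>])\s*([0-9.eE+-]+)\s*$")


def parse_ed50(text: str | float) -> float | CensoredValue:
    """Parse an ED50 cell: a number, or a censored bound like ``">10"``."""
    if isinstance(text, (int, float)):
        return float(text)
    m = _CENSOR_RE.match(text)
    if m:
        return CensoredValue(bound=float(m.group(2)), direction=m.group(1))
    return float(text)


def to_ped50(ed50: float) -> float:
    """pED50 = -log10(ED50 in uM).

    Censored or non-positive inputs are a domain error: the transform
    is only defined for measured, positive potencies.
    """
    if isinstance(ed50, CensoredValue):
        raise ValueError(f"cannot transform censored activity {ed50}")
    if not isinstance(ed50, (int, float)) or ed50 <= 0:
        raise ValueError(f"ED50 must be a positive number, got {ed50!r}")
    return -math.log10(ed50)


def label_activity(
    records: Iterable[CompoundRecord],
    reference_ed50: float | CensoredValue,
    fold_cutoff: float = 50.0,
    censor_cutoff: float = 10.0,
) -> list[CompoundRecord]:
    """Label compounds P/N relative to a reference inhibitor.

    A compound is an inhibitor (P) iff its potency exceeds 1/fold_cutoff
    of the reference, i.e. ed50 < fold_cutoff * reference_ed50 (strict:
    potency exactly at the cutoff is N).  Censored records:

    - ``">x"`` with x >= censor_cutoff -> N (too weak to measure);
    - ``"<x"`` with x <= the activity cutoff -> P (at least that potent);
    - anything whose bound straddles the cutoff stays unlabeled, with a
      warning.

    The reference may itself be censored (``"<1"`` uM for
    O6-benzylguanine); the cutoff is then taken at the bound, which is
    conservative for P labels.
    """
    ref = reference_ed50.bound if isinstance(reference_ed50, CensoredValue) else reference_ed50
    cutoff = fold_cutoff * ref
    out = []
    for rec in records:
        if rec.ed50 is None:
            rec.class_label = "unlabeled"
            logger.warning("compound %s has no activity; left unlabeled", rec.id)
        elif isinstance(rec.ed50, CensoredValue):
            if rec.ed50.direction == ">" and rec.ed50.bound >= censor_cutoff:
                rec.class_label = "N"
            elif rec.ed50.direction == "<" and rec.ed50.bound <= cutoff:
                rec.class_label = "P"
            else:
                rec.class_label = "unlabeled"
                logger.warning(
                    "compound %s: censored bound %s straddles the cutoff %.3g; "
                    "left unlabeled",
                    rec.id, rec.ed50, cutoff,
                )
        else:
            rec.class_label = "P" if rec.ed50 < cutoff else "N"
        out.append(rec)
    return out


def split_qsar_ranked(
    records: Sequence[CompoundRecord], offset: int = 2
) -> list[CompoundRecord]:
    """Ranked every-fifth split for regression modelling.

    Compounds are sorted by descending pED50 and walked in blocks of
    five; the compound at position ``offset`` (0-based, default the
    middle of the block) of each *complete* block goes to the test set,
    the rest to training.  A trailing partial block contributes no test
    compound, so 103 compounds give an 83/20 split and 84 give 68/16.
    """
    if not 0 <= offset < 5:
        raise ValueError("offset must be in 0..4")
    if any(r.ped50 is None for r in records):
        raise ValueError("all records need a pED50 before ranked splitting")
    if len(records) < 5:
        for r in records:
            r.split = "train"
        logger.warning("fewer than 5 records; all assigned to training")
        return list(records)
    ranked = sorted(records, key=lambda r: (-r.ped50, r.id))
    for i, rec in enumerate(ranked):
        block, pos = divmod(i, 5)
        complete = (block + 1) * 5 <= len(ranked)
        rec.split = "test" if (complete and pos == offset) else "train"
    return list(records)


def split_classification(
    records: Sequence[CompoundRecord],
    test_fraction: float = 0.2,
    seed: int = 0,
) -> list[CompoundRecord]:
    """Stratified random train/test split at a 4:1 ratio.

    Each class contributes ``round(test_fraction * n_class)`` compounds
    to the test set (so 62 P / 67 N gives a 12 P + 13 N test set and a
    104-compound training set).  Unlabeled records are excluded.
    Deterministic under ``seed``.
    """
    by_class: dict[str, list[CompoundRecord]] = {"P": [], "N": []}
    for rec in records:
        if rec.class_label in by_class:
            by_class[rec.class_label].append(rec)
        else:
            rec.split = "excluded"
    if not by_class["P"] or not by_class["N"]:
        raise ValueError("both classes must be present for a stratified split")
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    for members in by_class.values():
        members.sort(key=lambda r: r.id)
        n_test = int(round(test_fraction * len(members)))
        test_idx = set(rng.choice(len(members), size=n_test, replace=False).tolist())
        for i, rec in enumerate(members):
            rec.split = "test" if i in test_idx else "train"
    return list(records)


def filter_descriptors(
    matrix: pd.DataFrame,
    near_constant_frac: float = 0.80,
    corr_cutoff: float = 0.95,
) -> tuple[pd.DataFrame, dict[str, str]]:
    """Pre-filter a descriptor matrix.

    First drops columns whose modal value occupies more than
    ``near_constant_frac`` of the rows (constant or near-constant);
    then scans the remaining columns in order and, for every pair with
    |Pearson r| > ``corr_cutoff``, drops the later column.  Returns the
    reduced matrix and a removal log mapping dropped column -> reason.

    A second pass over the output removes nothing (idempotence).
    """
    if matrix.empty:
        raise ValueError("empty descriptor matrix")
    removal: dict[str, str] = {}
    n = len(matrix)

    keep: list[str] = []
    for col in matrix.columns:
        modal = matrix[col].value_counts().iloc[0]
        if modal / n > near_constant_frac:
            removal[col] = (
                f"near-constant: modal value frequency {modal / n:.2f} "
                f"> {near_constant_frac:.2f}"
            )
        else:
            keep.append(col)

    if keep:
        corr = matrix[keep].corr().abs().to_numpy()
        alive = np.ones(len(keep), dtype=bool)
        for i in range(len(keep)):
            if not alive[i]:
                continue
            for j in range(i + 1, len(keep)):
                if alive[j] and corr[i, j] > corr_cutoff:
                    alive[j] = False
                    removal[keep[j]] = (
                        f"inter-correlated: |r| = {corr[i, j]:.3f} with "
                        f"{keep[i]} > {corr_cutoff:.2f}"
                    )
        keep = [c for c, a in zip(keep, alive) if a]

    return matrix[keep], removal


def diversity_summary(
    fingerprints: pd.DataFrame,
    mw: pd.Series | None = None,
    alogp: pd.Series | None = None,
) -> tuple[pd.DataFrame | None, pd.DataFrame]:
    """Chemical-diversity summary of a compound set.

    Returns a (MW, ALogP) scatter table (or None when properties are
    absent) and the min-max-normalized pairwise Euclidean distance
    matrix over the binary fingerprints: symmetric, zero diagonal,
    values in [0, 1].
    """
    if fingerprints.empty:
        raise ValueError("missing fingerprints")
    raw = squareform(pdist(fingerprints.to_numpy(dtype=float), metric="euclidean"))
    dmax = raw.max()
    norm = raw / dmax if dmax > 0 else raw
    dist = pd.DataFrame(norm, index=fingerprints.index, columns=fingerprints.index)

    scatter = None
    if mw is not None and alogp is not None:
        scatter = pd.DataFrame({"MW": mw, "ALogP": alogp})
    return scatter, dist


def read_activity_table(path: str | Path, sep: str = "\t") -> list[CompoundRecord]:
    """Read an activity table: columns id, ed50 [, smiles].

    ED50 cells may be numeric or censored bounds like ``">10"``.
    """
    frame = pd.read_csv(path, sep=sep, dtype={"id": str, "ed50": str})
    records = []
    for row in frame.itertuples(index=False):
        records.append(
            CompoundRecord(
                id=str(row.id),
                ed50=parse_ed50(row.ed50),
                smiles=getattr(row, "smiles", None),
            )
        )
    return records


def write_split_assignment(records: Sequence[CompoundRecord], path: str | Path) -> None:
    payload = {r.id: {"split": r.split, "class": r.class_label} for r in records}
    Path(path).write_text(json.dumps(payload, indent=2) + "\n")
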