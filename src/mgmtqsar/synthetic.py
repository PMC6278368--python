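"""Synthetic descriptor and fingerprint data with known ground truth.

Every downstream stage of the pipeline (filtering, GA-MLR selection,
validation, applicability domain, classification benchmarking,
substructure mining) is testable against these generators without any
external download.  The QSAR generator plants a sparse linear model for
pED50 inside a pool of block-correlated nuisance descriptors; the
fingerprint generator plants class-enriched bits on a Bernoulli
background, emulating the occurrence patterns of privileged-substructure
tables (e.g. a bit present in 11 of 62 actives and 0 of 67 inactives).

One global integer seed drives all random streams: each generator
derives independent sub-streams via ``numpy.random.SeedSequence.spawn``,
so a full pipeline run is reproducible from a single seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .qsar import MlrModel

__all__ = [
    "QsarSimSpec",
    "FingerprintSimSpec",
    "simulate_qsar",
    "simulate_fingerprints",
    "write_matrix",
    "write_ground_truth",
]


@dataclass
class QsarSimSpec:
    """Specification for a synthetic QSAR dataset.

    Defaults mirror the study conditions: ~104 compounds, a pool of 520
    retained descriptors of which a handful carry signal, response
    spanning more than 5 log units.

    Parameters
    ----------
    n_compounds, n_descriptors, n_informative
        Dataset dimensions.  Informative descriptors come first in
        column order (named ``D001``...), nuisance descriptors follow.
    true_intercept, true_coefficients
        The planted linear model.  ``true_coefficients`` maps descriptor
        name to coefficient; if empty, ``n_informative`` coefficients
        alternating +/- are generated with magnitudes sized so the
        noiseless response spans ``response_span_target`` log units.
    noise_sd
        Gaussian noise on the response, in pED50 units.
    block_correlation
        Equicorrelation within nuisance-descriptor blocks, in [0, 1).
        Reproduces the high inter-correlation regime that the >95%
        pre-filter targets.
    block_size
        Number of nuisance descriptors per correlated block.
    """

    n_compounds: int = 104
    n_descriptors: int = 520
    n_informative: int = 5
    true_intercept: float = 0.0
    true_coefficients: dict[str, float] = field(default_factory=dict)
    noise_sd: float = 0.5
    block_correlation: float = 0.7
    block_size: int = 10
    response_span_target: float = 5.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_informative > self.n_descriptors:
            raise ValueError(
                f"n_informative ({self.n_informative}) exceeds "
                f"n_descriptors ({self.n_descriptors})"
            )
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        if not 0 <= self.block_correlation < 1:
            raise ValueError("block_correlation must lie in [0, 1)")


@dataclass
class FingerprintSimSpec:
    """Specification for a synthetic binary fingerprint dataset.

    ``planted_bits`` is a list of ``(bit_name, prob_in_P, prob_in_N)``
    triples; all remaining bits fire independently at
    ``background_prob`` in both classes.  Defaults mirror the study:
    62 inhibitors (P), 67 non-inhibitors (N), 881 PubChem-style bits.
    """

    n_positive: int = 62
    n_negative: int = 67
    n_bits: int = 881
    planted_bits: list[tuple[str, float, float]] = field(default_factory=list)
    background_prob: float = 0.2
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_positive < 1 or self.n_negative < 1:
            raise ValueError("both classes must contain at least one compound")
        names = [name for name, _, _ in self.planted_bits]
        if len(names) != len(set(names)):
            raise ValueError("planted bit names must be unique")
        for name, p, q in self.planted_bits:
            if not (0 <= p <= 1 and 0 <= q <= 1):
                raise ValueError(f"probabilities for bit {name!r} outside [0, 1]")
        if not 0 <= self.background_prob <= 1:
            raise ValueError("background_prob outside [0, 1]")


def _descriptor_names(n: int) -> list[str]:
    width = max(3, len(str(n)))
    return [f"D{i + 1:0{width}d}" for i in range(n)]


def simulate_qsar(
    spec: QsarSimSpec,
) -> tuple[pd.DataFrame, pd.Series, MlrModel]:
    """Draw a descriptor matrix, response vector and the true model.

    Informative descriptors are iid standard normal; nuisance
    descriptors are equicorrelated Gaussians within blocks of
    ``spec.block_size`` at correlation ``spec.block_correlation``.
    Response = intercept + X beta + N(0, noise_sd).

    Returns ``(X, y, truth)`` where ``truth`` is the planted
    :class:`~mgmtqsar.qsar.MlrModel`.
    """
    ss = np.random.SeedSequence(spec.seed)
    rng_x, rng_y = (np.random.default_rng(s) for s in ss.spawn(2))

    names = _descriptor_names(spec.n_descriptors)
    n, p = spec.n_compounds, spec.n_descriptors
    k = spec.n_informative

    X = np.empty((n, p))
    X[:, :k] = rng_x.standard_normal((n, k))
    # equicorrelated blocks: x = sqrt(rho) * shared + sqrt(1-rho) * idio
    rho = spec.block_correlation
    j = k
    while j < p:
        width = min(spec.block_size, p - j)
        shared = rng_x.standard_normal((n, 1))
        idio = rng_x.standard_normal((n, width))
        X[:, j : j + width] = np.sqrt(rho) * shared + np.sqrt(1 - rho) * idio
        j += width

    if spec.true_coefficients:
        coeffs = dict(spec.true_coefficients)
        unknown = set(coeffs) - set(names)
        if unknown:
            raise ValueError(f"unknown descriptor names in coefficients: {sorted(unknown)}")
    else:
        # size betas so the noiseless response comfortably spans the
        # target range: each standard-normal column contributes ~4 sd
        # of spread, so |beta| ~ span / (4 sqrt(k)) per column.
        scale = spec.response_span_target / (4.0 * np.sqrt(max(k, 1))) if k else 0.0
        coeffs = {
            names[i]: (1 if i % 2 == 0 else -1) * scale * (1.0 + 0.5 * i)
            for i in range(k)
        }

    frame = pd.DataFrame(X, columns=names)
    frame.index = [f"C{i + 1:03d}" for i in range(n)]
    frame.index.name = "compound"

    beta = np.array([coeffs.get(c, 0.0) for c in names])
    y_clean = spec.true_intercept + X @ beta
    y = y_clean + (rng_y.standard_normal(n) * spec.noise_sd if spec.noise_sd else 0.0)
    response = pd.Series(y, index=frame.index, name="ped50")

    truth = MlrModel(intercept=spec.true_intercept, coefficients=coeffs, n_train=n)
    return frame, response, truth


def simulate_fingerprints(
    spec: FingerprintSimSpec,
) -> tuple[pd.DataFrame, pd.Series]:
    """Draw a binary fingerprint matrix and a P/N label vector.

    Each bit is drawn independently per compound at its class-conditional
    probability.  Returns ``(bits, labels)`` with labels in {"P", "N"}.
    """
    rng = np.random.default_rng(np.random.SeedSequence(spec.seed))
    n = spec.n_positive + spec.n_negative
    labels = np.array(["P"] * spec.n_positive + ["N"] * spec.n_negative)

    planted = {name: (p, q) for name, p, q in spec.planted_bits}
    width = max(3, len(str(spec.n_bits)))
    names: list[str] = list(planted)
    names += [
        f"FP{i + 1:0{width}d}"
        for i in range(spec.n_bits - len(planted))
    ]
    if len(names) != len(set(names)):
        raise ValueError("planted bit names collide with background bit names")

    probs = np.full((n, len(names)), spec.background_prob)
    is_pos = labels == "P"
    for col, name in enumerate(names):
        if name in planted:
            p_pos, p_neg = planted[name]
            probs[is_pos, col] = p_pos
            probs[~is_pos, col] = p_neg

    bits = (rng.random((n, len(names))) < probs).astype(np.int8)
    ids = [f"C{i + 1:03d}" for i in range(n)]
    frame = pd.DataFrame(bits, index=ids, columns=names)
    frame.index.name = "compound"
    return frame, pd.Series(labels, index=ids, name="label")


def write_matrix(matrix: pd.DataFrame, path: str | Path, sep: str = "\t") -> None:
    """Write a descriptor/fingerprint matrix as delimited text.

    First column is the compound id, header row carries the
    descriptor/bit names.
    """
    matrix.to_csv(path, sep=sep)


def write_ground_truth(truth: MlrModel, path: str | Path) -> None:
    """Serialize the planted model as a JSON sidecar."""
    payload = {
        "intercept": truth.intercept,
        "coefficients": truth.coefficients,
        "n_train": truth.n_train,
    }
    Path(path).write_text(json.dumps(payload, indent=2) + "\n")
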