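"""Fingerprint computation and ingestion.

MACCS keys (166 structural keys), molecular weight and Ghose-Crippen
ALogP are computed natively from SMILES with RDKit.  The other
fingerprint dialects used in fingerprint benchmarking (PubChem 881,
Extended/Graph 1024, Estate 79, Substructure 307 bits) are defined by
external tools; their bit matrices are ingested from delimited text and
validated against the dialect's expected width.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from rdkit import Chem
from rdkit.Chem import Crippen, Descriptors, MACCSkeys

__all__ = [
    "DIALECT_BITS",
    "FingerprintFormatError",
    "compute_maccs",
    "compute_properties",
    "ingest_matrix",
    "write_matrix",
]

#: Expected bit widths per fingerprint dialect.
DIALECT_BITS = {
    "MACCS": 166,
    "PubChem": 881,
    "Ext": 1024,
    "Est": 79,
    "Graph": 1024,
    "SubFP": 307,
}


class FingerprintFormatError(ValueError):
    """Ingested matrix violates the dialect contract."""


def compute_maccs(
    smiles: dict[str, str] | pd.Series,
) -> tuple[pd.DataFrame, dict[str, str]]:
    """166-bit MACCS keys per compound.

    ``smiles`` maps compound id to SMILES.  Returns the binary matrix
    (columns ``MACCS1``..``MACCS166``; RDKit's unused bit 0 dropped)
    and a dict of per-compound parse errors; unparseable compounds are
    omitted from the matrix rather than aborting the batch.
    """
    rows, errors = {}, {}
    for cid, smi in dict(smiles).items():
        mol = Chem.MolFromSmiles(smi)
        if mol is None:
            errors[cid] = f"unparseable SMILES: {smi!r}"
            continue
        fp = MACCSkeys.GenMACCSKeys(mol)
        rows[cid] = np.array(fp)[1:]  # bit 0 is a placeholder
    frame = pd.DataFrame.from_dict(rows, orient="index", dtype=np.int8)
    frame.columns = [f"MACCS{i}" for i in range(1, DIALECT_BITS["MACCS"] + 1)]
    frame.index.name = "compound"
    frame.attrs["dialect"] = "MACCS"
    return frame, errors


def compute_properties(smiles: dict[str, str] | pd.Series) -> pd.DataFrame:
    """Molecular weight and Ghose-Crippen ALogP per compound."""
    rows = {}
    for cid, smi in dict(smiles).items():
        mol = Chem.MolFromSmiles(smi)
        if mol is None:
            continue
        rows[cid] = {"MW": Descriptors.MolWt(mol), "ALogP": Crippen.MolLogP(mol)}
    frame = pd.DataFrame.from_dict(rows, orient="index")
    frame.index.name = "compound"
    return frame


def ingest_matrix(path: str | Path, dialect: str, sep: str = "\t") -> pd.DataFrame:
    """Read an externally computed fingerprint matrix.

    Delimited text, first column compound id, one column per bit.
    The column count must match the dialect width exactly and every
    cell must be 0 or 1; violations raise
    :class:`FingerprintFormatError` citing the location.
    """
    if dialect not in DIALECT_BITS:
        raise ValueError(f"unknown dialect {dialect!r}; expected one of {list(DIALECT_BITS)}")
    frame = pd.read_csv(path, sep=sep, index_col=0)
    expected = DIALECT_BITS[dialect]
    if frame.shape[1] != expected:
        raise FingerprintFormatError(
            f"{path}: {dialect} requires {expected} bit columns, found {frame.shape[1]}"
        )
    values = frame.to_numpy()
    bad = np.argwhere(~np.isin(values, (0, 1)))
    if bad.size:
        r, c = bad[0]
        raise FingerprintFormatError(
            f"{path}: non-binary value {values[r, c]!r} at row "
            f"{frame.index[r]!r}, column {frame.columns[c]!r}"
        )
    out = frame.astype(np.int8)
    out.attrs["dialect"] = dialect
    return out


def write_matrix(matrix: pd.DataFrame, path: str | Path, sep: str = "\t") -> None:
    """Write a fingerprint matrix as delimited text (round-trip safe)."""
    matrix.to_csv(path, sep=sep)
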