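"""Probe-by-sample matrices, sample designs, and the TSV dialects they use.

The canonical on-disk form is plain TSV: a matrix file has a header row of
sample identifiers with ``probe_id`` in the first column; a design file has
columns ``sample_id``, ``subject_id``, ``tissue``. Missing measurements are
an empty cell, ``NA`` or ``NaN`` and are kept as missing (NaN) in memory —
the zero substitution the PCA step requires is an explicit, separate
operation (:func:`substitute_missing_with_zero`), never an import side
effect.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Tissue classes in their ordinal order; the class code y is 1-based in
#: this order (blood=1, normal=2, tumor=3).
TISSUES = ("blood", "normal", "tumor")

MISSING_MARKERS = ("", "NA", "NaN")

MODALITIES = ("genotype", "methylation")


class FormatError(ValueError):
    """Raised for malformed matrix/design/fingerprint files."""


class AlignmentError(ValueError):
    """Raised when two matrices cannot be placed on a common probe universe."""


@dataclass
class OmicsMatrix:
    """A probe x sample numeric matrix tagged with its modality.

    ``data`` is a DataFrame indexed by probe id with sample ids as columns;
    entries are float, with NaN marking missing measurements.
    """

    data: pd.DataFrame
    modality: str

    def __post_init__(self) -> None:
        if self.modality not in MODALITIES:
            raise ValueError(f"modality must be one of {MODALITIES}, got {self.modality!r}")
        if self.data.index.duplicated().any():
            dupes = self.data.index[self.data.index.duplicated()][:3].tolist()
            raise FormatError(f"duplicate probe ids: {dupes}")
        if self.data.columns.duplicated().any():
            dupes = self.data.columns[self.data.columns.duplicated()][:3].tolist()
            raise FormatError(f"duplicate sample ids: {dupes}")
        self.data = self.data.astype(float)
        self.data.index.name = "probe_id"
        self.data.columns.name = None

    @property
    def probe_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def n_probes(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy()

    def has_missing(self) -> bool:
        return bool(self.data.isna().any().any())


@dataclass
class SampleDesign:
    """Map sample id -> (subject id, tissue class).

    ``table`` is indexed by sample id with columns ``subject_id`` and
    ``tissue``. The derived ordinal code y is 1 for blood, 2 for normal
    tissue, 3 for tumor.
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        missing_cols = {"subject_id", "tissue"} - set(self.table.columns)
        if missing_cols:
            raise FormatError(f"design table lacks columns {sorted(missing_cols)}")
        if self.table.index.duplicated().any():
            raise FormatError("duplicate sample ids in design")
        bad = set(self.table["tissue"]) - set(TISSUES)
        if bad:
            raise FormatError(f"unknown tissue classes {sorted(bad)}; expected {TISSUES}")
        self.table.index.name = "sample_id"

    @property
    def sample_ids(self) -> list[str]:
        return list(self.table.index)

    @property
    def y(self) -> pd.Series:
        """Ordinal class code per sample: blood=1, normal=2, tumor=3."""
        code = {t: i + 1 for i, t in enumerate(TISSUES)}
        return self.table["tissue"].map(code).astype(int)

    def samples_of(self, tissue: str) -> list[str]:
        if tissue not in TISSUES:
            raise ValueError(f"unknown tissue {tissue!r}")
        return list(self.table.index[self.table["tissue"] == tissue])

    def check_covers(self, sample_ids: Iterable[str]) -> None:
        missing = set(sample_ids) - set(self.table.index)
        if missing:
            raise FormatError(f"samples without design entry: {sorted(missing)[:5]}")


def _check_rectangular(path: Path) -> None:
    """Reject ragged TSV before pandas silently pads short rows with NaN."""
    with open(path, newline="") as fh:
        reader = csv.reader(fh, delimiter="\t")
        widths = {len(row) for row in reader if row}
    if len(widths) > 1:
        raise FormatError(f"{path}: ragged rows (field counts {sorted(widths)})")


def read_matrix(path: str | Path, modality: str) -> OmicsMatrix:
    """Read a probe x sample TSV matrix; empty/NA/NaN cells become missing."""
    path = Path(path)
    _check_rectangular(path)
    df = pd.read_csv(
        path,
        sep="\t",
        index_col=0,
        na_values=list(MISSING_MARKERS),
        keep_default_na=False,
        dtype=str,
    )
    try:
        df = df.astype(float)
    except ValueError as exc:
        raise FormatError(f"{path}: non-numeric cell: {exc}") from exc
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    return OmicsMatrix(df, modality)


def write_matrix(m: OmicsMatrix, path: str | Path) -> None:
    df = m.data.copy()
    df.index.name = "probe_id"
    df.to_csv(path, sep="\t", na_rep="NA")


def read_design(path: str | Path) -> SampleDesign:
    path = Path(path)
    _check_rectangular(path)
    df = pd.read_csv(path, sep="\t", dtype=str)
    if "sample_id" not in df.columns:
        raise FormatError(f"{path}: first column must be sample_id")
    df = df.set_index("sample_id")
    return SampleDesign(df)


def write_design(d: SampleDesign, path: str | Path) -> None:
    df = d.table.copy()
    df.index.name = "sample_id"
    df.to_csv(path, sep="\t")


def substitute_missing_with_zero(m: OmicsMatrix) -> OmicsMatrix:
    """Replace missing entries with zero; non-missing entries are untouched.

    This mirrors the preprocessing convention of analyzing normalized array
    intensities "after substituting a zero for missing values"; it is
    idempotent and leaves a matrix without missing values unchanged.
    """
    if not m.has_missing():
        return OmicsMatrix(m.data.copy(), m.modality)
    return OmicsMatrix(m.data.fillna(0.0), m.modality)


def align_modalities(a: OmicsMatrix, b: OmicsMatrix) -> tuple[OmicsMatrix, OmicsMatrix]:
    """Restrict both matrices to their common probe set, same order.

    Sample id sets must be identical (order may differ; the second matrix is
    re-ordered to the first). Probe order in both outputs is the sorted
    common probe set, making downstream selections deterministic.
    """
    if set(a.sample_ids) != set(b.sample_ids):
        raise AlignmentError("sample id sets differ between modalities")
    common = sorted(set(a.probe_ids) & set(b.probe_ids))
    if not common:
        raise AlignmentError("no probes in common between the two matrices")
    a2 = OmicsMatrix(a.data.loc[common], a.modality)
    b2 = OmicsMatrix(b.data.loc[common, a.sample_ids], b.modality)
    return a2, b2
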