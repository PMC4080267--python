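"""PCA of probe-by-sample matrices and outlier-probe selection.

The decomposition embeds *probes* as PC scores and *samples* as PC
loadings: for a probe x sample matrix X, the economy SVD X = U S V' gives
probe scores U S (probe coordinates along each component) and sample
loadings V' (the per-sample profile of each component). The fraction of
variance carried by component i is s_i^2 / sum(s^2).

By default the matrix is decomposed uncentered: normalized array
intensities are positive, so the leading component is a dominant,
non-discriminating baseline axis (typically ~80% or more of the variance)
while class-discriminating structure appears in later components. Probes
are selected as the N largest-|score| outliers along a chosen component;
which component discriminates the tissue classes is decided by a one-way
F statistic on the sample loadings (:func:`rank_discriminating_pcs`), a
reproducible stand-in for choosing the component by eye.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .matrixio import TISSUES, OmicsMatrix, SampleDesign

logger = logging.getLogger(__name__)

__all__ = ["PCAResult", "SelectionSet", "fit_pca", "rank_discriminating_pcs", "select_outliers"]


@dataclass
class PCAResult:
    """Probe scores, sample loadings and per-PC contribution fractions.

    ``probe_scores`` is probe x PC (columns ``PC1``..); ``sample_loadings``
    is PC x sample; ``contribution`` is the per-PC variance fraction and
    sums to 1 over all retained PCs. ``probe_scores @ sample_loadings``
    reconstructs the decomposed matrix (after centering, if used, the
    centered matrix).
    """

    probe_scores: pd.DataFrame
    sample_loadings: pd.DataFrame
    contribution: pd.Series
    modality: str
    centered: bool = False
    row_means: pd.Series | None = None

    @property
    def n_components(self) -> int:
        return self.probe_scores.shape[1]


@dataclass
class SelectionSet:
    """Top-N outlier probes along one PC, ranked by |score| descending.

    ``table`` has columns ``rank``, ``probe_id``, ``score`` (the signed PC
    score). ``criterion`` records how the ranking was produced (``pc`` for
    the PCA route; comparison selectors reuse this container with their own
    criterion label and ``pc_index=None``).
    """

    modality: str
    pc_index: int | None
    N: int
    table: pd.DataFrame
    criterion: str = "pc"

    @property
    def probe_ids(self) -> list[str]:
        return list(self.table["probe_id"])

    def __len__(self) -> int:
        return len(self.table)


def fit_pca(m: OmicsMatrix, center: bool = False) -> PCAResult:
    """Economy-SVD principal component analysis of a probe x sample matrix.

    Requires a matrix without missing entries (apply
    :func:`gsmeth.matrixio.substitute_missing_with_zero` first). The sign of
    each component is fixed so that the sum of its sample loadings is
    nonnegative, making reports reproducible across BLAS backends.
    """
    if m.n_samples < 2 or m.n_probes < 2:
        raise ValueError(f"need at least 2 probes and 2 samples, got {m.data.shape}")
    x = m.values
    if np.isnan(x).any():
        raise ValueError("matrix contains missing values; substitute them first")
    row_means = None
    if center:
        row_means = x.mean(axis=1)
        x = x - row_means[:, None]
    u, s, vt = np.linalg.svd(x, full_matrices=False)
    # sign convention: sum of sample loadings >= 0 per component
    signs = np.where(vt.sum(axis=1) < 0, -1.0, 1.0)
    u = u * signs[None, :]
    vt = vt * signs[:, None]
    total = float((s**2).sum())
    contrib = s**2 / total if total > 0 else np.zeros_like(s)
    pcs = [f"PC{i + 1}" for i in range(len(s))]
    return PCAResult(
        probe_scores=pd.DataFrame(u * s[None, :], index=m.data.index, columns=pcs),
        sample_loadings=pd.DataFrame(vt, index=pd.Index(pcs), columns=m.data.columns),
        contribution=pd.Series(contrib, index=pd.Index(pcs), name="contribution"),
        modality=m.modality,
        centered=center,
        row_means=None if row_means is None else pd.Series(row_means, index=m.data.index),
    )


def rank_discriminating_pcs(
    p: PCAResult, d: SampleDesign, n_candidates: int = 10
) -> pd.DataFrame:
    """Order PCs by how well their sample loadings separate the tissues.

    Computes a one-way three-class ANOVA F statistic on each candidate PC's
    sample loadings grouped by tissue and returns a DataFrame with columns
    ``pc_index`` (1-based), ``f_stat``, ``p_value``, sorted by decreasing F.
    A PC whose loadings are constant has no separation; its F is reported
    as 0 and it sorts last. The ranking is advisory — an explicit PC choice
    can always be passed downstream.
    """
    d.check_covers(p.sample_loadings.columns)
    groups_idx = []
    for tissue in TISSUES:
        cols = [s for s in p.sample_loadings.columns if d.table.loc[s, "tissue"] == tissue]
        if len(cols) < 2:
            raise ValueError(f"tissue class {tissue!r} has fewer than 2 samples")
        groups_idx.append(cols)
    k = min(n_candidates, p.n_components)
    rows = []
    for i in range(k):
        pc = p.sample_loadings.index[i]
        loadings = p.sample_loadings.loc[pc]
        groups = [loadings[cols].to_numpy() for cols in groups_idx]
        if all(np.ptp(g) == 0 for g in groups):
            f, pval = 0.0, 1.0
        else:
            f, pval = stats.f_oneway(*groups)
            if not np.isfinite(f):
                f, pval = 0.0, 1.0
        rows.append({"pc_index": i + 1, "f_stat": float(f), "p_value": float(pval)})
    out = pd.DataFrame(rows).sort_values(
        ["f_stat", "pc_index"], ascending=[False, True], kind="mergesort"
    )
    return out.reset_index(drop=True)


def select_outliers(p: PCAResult, pc_index: int, N: int) -> SelectionSet:
    """Select the N probes with largest absolute score along one PC.

    Outliers are two-sided (largest |score|, either end of the axis). Ties
    are broken lexicographically by probe id so selections are
    deterministic; the selection is invariant to the arbitrary sign of the
    component. ``N`` larger than the probe count is clamped with a warning.
    """
    if not 1 <= pc_index <= p.n_components:
        raise ValueError(f"pc_index must be in 1..{p.n_components}, got {pc_index}")
    if N < 1:
        raise ValueError("N must be >= 1")
    scores = p.probe_scores[f"PC{pc_index}"]
    n_probes = len(scores)
    if N > n_probes:
        logger.warning("N=%d exceeds probe count %d; clamping", N, n_probes)
        N = n_probes
    order = sorted(zip(-scores.abs().to_numpy(), scores.index))[:N]
    ids = [pid for _, pid in order]
    table = pd.DataFrame(
        {
            "rank": np.arange(1, N + 1),
            "probe_id": ids,
            "score": scores.loc[ids].to_numpy(),
        }
    )
    return SelectionSet(modality=p.modality, pc_index=pc_index, N=N, table=table)
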