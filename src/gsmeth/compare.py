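"""Comparison feature selectors: Pearson, Spearman, PLS — and the benchmark.

Each selector ranks probes against the ordinal class code y (blood=1,
normal=2, tumor=3) and takes the top N; the benchmark counts, per method,
how many probes the genotype and methylation selections share. Stepwise
LDA and lasso selectors are deliberately absent — at array scale they are
not executable — and the benchmark reports ``--`` for them.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy.stats import rankdata
from sklearn.cross_decomposition import PLSRegression

from .matrixio import OmicsMatrix, SampleDesign, substitute_missing_with_zero
from .pca import SelectionSet, fit_pca, rank_discriminating_pcs, select_outliers
from .filters import intersect_selections

logger = logging.getLogger(__name__)

__all__ = ["correlation_select", "pls_select", "compare_methods"]


def _rank_table(ids: np.ndarray, stat: np.ndarray, N: int, descending_abs: bool) -> pd.DataFrame:
    """Top-N by statistic; NaN ranks last; ties broken by probe id."""
    key = -np.abs(stat) if descending_abs else -stat
    key = np.where(np.isnan(key), np.inf, key)
    order = np.lexsort((ids, key))[:N]
    return pd.DataFrame(
        {"rank": np.arange(1, len(order) + 1), "probe_id": ids[order], "score": stat[order]}
    )


def correlation_select(
    m: OmicsMatrix,
    d: SampleDesign,
    method: str = "pearson",
    N: int = 300,
    absolute: bool = False,
) -> SelectionSet:
    """Top-N probes by (Pearson or Spearman) correlation with the class code.

    The per-probe correlation of x_i. with y is computed vectorized; by
    default the *largest signed* coefficients are selected (probes ordered
    with the classes), ``absolute=True`` selects by |r|. A constant probe
    has undefined correlation and is ranked last (logged).
    """
    if method not in ("pearson", "spearman"):
        raise ValueError(f"method must be pearson|spearman, got {method!r}")
    if N < 1:
        raise ValueError("N must be >= 1")
    d.check_covers(m.sample_ids)
    x = m.values
    if np.isnan(x).any():
        raise ValueError("matrix contains missing values; substitute them first")
    y = d.y.loc[m.sample_ids].to_numpy(dtype=float)
    if method == "spearman":
        x = rankdata(x, axis=1)
        y = rankdata(y)
    xc = x - x.mean(axis=1, keepdims=True)
    yc = y - y.mean()
    denom = np.sqrt((xc**2).sum(axis=1)) * np.sqrt((yc**2).sum())
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (xc @ yc) / denom
    n_const = int(np.isnan(r).sum())
    if n_const:
        logger.info("%d constant probe(s) with undefined correlation ranked last", n_const)
    table = _rank_table(np.asarray(m.probe_ids), r, min(N, m.n_probes), descending_abs=absolute)
    return SelectionSet(modality=m.modality, pc_index=None, N=N, table=table, criterion=method)


def pls_select(
    m: OmicsMatrix, d: SampleDesign, N: int = 300, n_components: int = 1
) -> SelectionSet:
    """Top-N probes by aggregate absolute PLS weight (multiclass-as-ordinal).

    A single-response PLS regression (NIPALS) of y on the probe matrix is
    fit with probes as predictors; probes are ranked by the sum over the
    first ``n_components`` components of |weight| times the component's
    score variance, a VIP-like aggregate that reduces to |w_1| for one
    component.
    """
    if N < 1:
        raise ValueError("N must be >= 1")
    d.check_covers(m.sample_ids)
    max_comp = min(m.n_samples - 1, m.n_probes)
    if not 1 <= n_components <= max_comp:
        raise ValueError(f"n_components must be in 1..{max_comp}, got {n_components}")
    x = m.values.T  # samples x probes
    if np.isnan(x).any():
        raise ValueError("matrix contains missing values; substitute them first")
    y = d.y.loc[m.sample_ids].to_numpy(dtype=float)
    # autoscaled predictors (the chemometrics convention): ranking reflects
    # association with y, not raw probe variance
    pls = PLSRegression(n_components=n_components, scale=True)
    pls.fit(x, y)
    weights = np.abs(pls.x_weights_)  # probes x components
    comp_var = pls.x_scores_.var(axis=0)
    agg = weights @ comp_var
    table = _rank_table(np.asarray(m.probe_ids), agg, min(N, m.n_probes), descending_abs=False)
    return SelectionSet(modality=m.modality, pc_index=None, N=N, table=table, criterion="pls")


def _pca_route(
    m: OmicsMatrix, d: SampleDesign, N: int, pc_index: int | None, center: bool
) -> SelectionSet:
    filled = substitute_missing_with_zero(m)
    p = fit_pca(filled, center=center)
    if pc_index is None:
        ranking = rank_discriminating_pcs(p, d)
        pc_index = int(ranking.iloc[0]["pc_index"])
    return select_outliers(p, pc_index, N)


def compare_methods(
    g: OmicsMatrix,
    m: OmicsMatrix,
    d: SampleDesign,
    N: int = 300,
    methods: tuple[str, ...] = ("present", "pearson", "spearman", "pls"),
    pc_indices: tuple[int | None, int | None] = (None, None),
    center: bool = False,
    n_components: int = 1,
) -> pd.DataFrame:
    """Cross-modality overlap of top-N selections, per selection method.

    ``present`` is the PCA-outlier route (automatic discriminating-PC
    choice unless ``pc_indices`` gives explicit 1-based PCs for genotype
    and methylation). Returns a DataFrame with columns ``method`` and
    ``overlap``; the non-executable stepwise/lasso rows are emitted as
    ``--`` to keep the benchmark table complete.
    """
    g_filled = substitute_missing_with_zero(g)
    m_filled = substitute_missing_with_zero(m)
    rows = []
    for method in methods:
        if method == "present":
            sel_g = _pca_route(g, d, N, pc_indices[0], center)
            sel_m = _pca_route(m, d, N, pc_indices[1], center)
        elif method in ("pearson", "spearman"):
            sel_g = correlation_select(g_filled, d, method, N)
            sel_m = correlation_select(m_filled, d, method, N)
        elif method == "pls":
            sel_g = pls_select(g_filled, d, N, n_components)
            sel_m = pls_select(m_filled, d, N, n_components)
        else:
            raise ValueError(f"unknown method {method!r}")
        rows.append({"method": method, "overlap": len(intersect_selections(sel_g, sel_m))})
    for method in ("stepclass", "lasso"):
        rows.append({"method": method, "overlap": "--"})
    return pd.DataFrame(rows)
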