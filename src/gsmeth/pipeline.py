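"""End-to-end orchestration of the gene-screening analysis.

One call runs, per PC combination: zero substitution, PCA of both
modalities, discriminating-PC choice (automatic F ranking or an explicit
pair), top-N outlier selection, cross-modality intersection with its
hypergeometric overlap P-value, pairwise one-sided t-test filtering at a
ladder of rank thresholds, the modality-bias table, the resampling null,
and (optionally) the comparison-selector benchmark. The result is a plain
dict of DataFrames plus a JSON-able run manifest; ``write_bundle`` writes
every table as TSV. Identical config and seed give byte-identical output.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Any

import pandas as pd

from .matrixio import OmicsMatrix, SampleDesign, substitute_missing_with_zero
from .pca import fit_pca, rank_discriminating_pcs, select_outliers
from .filters import (
    IntersectionResult,
    intersect_selections,
    overlap_pvalue,
    pairwise_class_ttests,
    modality_bias_test,
    resampling_null,
)
from .compare import compare_methods

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "run_pipeline", "write_bundle"]


@dataclass
class PipelineConfig:
    """Configuration of one screening run.

    ``pc_combinations`` lists (genotype PC, methylation PC) pairs, 1-based;
    ``None`` entries mean "use the top discriminating PC by F statistic".
    Several combinations can be run in one call (e.g. swapped PC choices
    between the modalities), each producing its own report set.
    """

    N: int = 300
    thresholds: tuple[int, ...] = (50, 100, 150, 200, 250, 300)
    alpha: float = 0.05
    adjust: str = "BH"
    direction: str = "increasing"
    center: bool = False
    pc_combinations: tuple[tuple[int | None, int | None], ...] = ((None, None),)
    resampling_iter: int = 1000
    run_comparison: bool = False
    seed: int = 0

    def validate(self) -> None:
        if self.N < 1:
            raise ValueError("N must be >= 1")
        th = list(self.thresholds)
        if th != sorted(th) or any(t < 1 for t in th) or any(t > self.N for t in th):
            raise ValueError("thresholds must be ascending and within 1..N")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must lie in (0, 1)")
        if self.resampling_iter < 1:
            raise ValueError("resampling_iter must be >= 1")


def run_pipeline(
    g: OmicsMatrix,
    m: OmicsMatrix,
    design: SampleDesign,
    cfg: PipelineConfig | None = None,
) -> dict[str, Any]:
    """Run the full screening analysis on aligned paired matrices.

    Returns a bundle dict with a ``manifest`` (parameters, seed, version),
    per-modality PCA summaries, and one entry per PC combination holding
    the two selections, the :class:`IntersectionResult`, the threshold
    table, the modality-bias table and the resampling-null table.
    """
    cfg = cfg or PipelineConfig()
    cfg.validate()
    if g.probe_ids != m.probe_ids:
        raise ValueError("matrices are not aligned (probe sets/order differ); align first")
    design.check_covers(g.sample_ids)

    g_filled = substitute_missing_with_zero(g)
    m_filled = substitute_missing_with_zero(m)
    logger.info("fitting PCA (center=%s) on %d probes x %d samples", cfg.center, g.n_probes, g.n_samples)
    pca_g = fit_pca(g_filled, center=cfg.center)
    pca_m = fit_pca(m_filled, center=cfg.center)
    rank_g = rank_discriminating_pcs(pca_g, design)
    rank_m = rank_discriminating_pcs(pca_m, design)

    def pca_summary(pca, ranking):
        s = ranking.set_index("pc_index")
        out = pd.DataFrame(
            {
                "contribution": pca.contribution.to_numpy()[: len(s)],
                "f_stat": s.sort_index()["f_stat"].to_numpy(),
                "p_value": s.sort_index()["p_value"].to_numpy(),
            },
            index=pd.Index(sorted(s.index), name="pc_index"),
        )
        return out

    from importlib.metadata import version as _pkg_version

    try:
        pkg_version = _pkg_version("gsmeth")
    except Exception:
        pkg_version = "unknown"
    bundle: dict[str, Any] = {
        "manifest": {
            "gsmeth_version": pkg_version,
            "n_probes": g.n_probes,
            "n_samples": g.n_samples,
            "config": {
                k: (list(v) if isinstance(v, tuple) else v) for k, v in asdict(cfg).items()
            },
        },
        "pca_summary": {"genotype": pca_summary(pca_g, rank_g), "methylation": pca_summary(pca_m, rank_m)},
        "combinations": {},
    }

    M = g.n_probes
    for pc_g, pc_m in cfg.pc_combinations:
        pc_g_eff = pc_g if pc_g is not None else int(rank_g.iloc[0]["pc_index"])
        pc_m_eff = pc_m if pc_m is not None else int(rank_m.iloc[0]["pc_index"])
        label = f"g{pc_g_eff}_m{pc_m_eff}"
        logger.info("combination %s: selecting top %d outliers per modality", label, cfg.N)
        sel_g = select_outliers(pca_g, pc_g_eff, cfg.N)
        sel_m = select_outliers(pca_m, pc_m_eff, cfg.N)
        common = intersect_selections(sel_g, sel_m)
        pval = overlap_pvalue(M, len(sel_g), len(sel_m), len(common))
        logp = overlap_pvalue(M, len(sel_g), len(sel_m), len(common), log=True)
        result = IntersectionResult(
            common_probe_ids=common,
            universe_size=M,
            k1=len(sel_g),
            k2=len(sel_m),
            overlap_pvalue=pval,
            log_overlap_pvalue=logp,
        )
        surviving: list[str] = []
        if common:
            for modality, matrix in (("genotype", g_filled), ("methylation", m_filled)):
                result.ttests[modality] = pairwise_class_ttests(
                    matrix, design, common, cfg.direction, cfg.adjust, cfg.alpha
                )
            both_pass = (
                result.ttests["genotype"]["pass_all"] & result.ttests["methylation"]["pass_all"]
            )
            surviving = sorted(both_pass.index[both_pass])
        result.surviving_probe_ids = surviving

        # threshold ladder: survivors among the intersection of top-n sets
        rows = []
        gt = sel_g.table.set_index("probe_id")["rank"]
        mt = sel_m.table.set_index("probe_id")["rank"]
        surv = set(surviving)
        for n in cfg.thresholds:
            common_n = [p for p in common if gt[p] <= n and mt[p] <= n]
            surv_n = sorted(surv & set(common_n))
            rows.append(
                {
                    "threshold": n,
                    "n_common": len(common_n),
                    "n_surviving": len(surv_n),
                    "surviving_probe_ids": ";".join(surv_n),
                }
            )
        threshold_table = pd.DataFrame(rows)

        probes_for_bias = surviving if surviving else common
        bias_table = None
        resample_table = None
        if probes_for_bias:
            bias_table = modality_bias_test(g_filled, m_filled, probes_for_bias, design)
            resample_table = resampling_null(
                g_filled, m_filled, len(probes_for_bias), cfg.resampling_iter, design, cfg.seed
            )
        bundle["combinations"][label] = {
            "pc_genotype": pc_g_eff,
            "pc_methylation": pc_m_eff,
            "selection_genotype": sel_g,
            "selection_methylation": sel_m,
            "intersection": result,
            "threshold_table": threshold_table,
            "modality_bias": bias_table,
            "resampling_null": resample_table,
        }

    if cfg.run_comparison:
        bundle["comparison"] = compare_methods(
            g, m, design, cfg.N, pc_indices=cfg.pc_combinations[0], center=cfg.center
        )
    return bundle


def write_bundle(bundle: dict[str, Any], outdir: str | Path) -> None:
    """Write every table of a pipeline bundle as TSV plus the manifest."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(bundle["manifest"], fh, indent=2, sort_keys=True)
        fh.write("\n")
    for modality, df in bundle["pca_summary"].items():
        df.to_csv(outdir / f"pca_summary_{modality}.tsv", sep="\t")
    for label, combo in bundle["combinations"].items():
        prefix = outdir / label
        prefix.mkdir(exist_ok=True)
        combo["selection_genotype"].table.to_csv(prefix / "selection_genotype.tsv", sep="\t", index=False)
        combo["selection_methylation"].table.to_csv(prefix / "selection_methylation.tsv", sep="\t", index=False)
        res = combo["intersection"]
        with open(prefix / "intersection.json", "w") as fh:
            json.dump(
                {
                    "universe_size": res.universe_size,
                    "k1": res.k1,
                    "k2": res.k2,
                    "n_common": len(res.common_probe_ids),
                    "overlap_pvalue": res.overlap_pvalue,
                    "log_overlap_pvalue": res.log_overlap_pvalue,
                    "common_probe_ids": res.common_probe_ids,
                    "surviving_probe_ids": res.surviving_probe_ids,
                },
                fh,
                indent=2,
                sort_keys=True,
            )
            fh.write("\n")
        for modality, df in res.ttests.items():
            df.to_csv(prefix / f"ttests_{modality}.tsv", sep="\t")
        combo["threshold_table"].to_csv(prefix / "threshold_table.tsv", sep="\t", index=False)
        if combo["modality_bias"] is not None:
            combo["modality_bias"].to_csv(prefix / "modality_bias.tsv", sep="\t")
        if combo["resampling_null"] is not None:
            combo["resampling_null"].to_csv(prefix / "resampling_null.tsv", sep="\t")
    if "comparison" in bundle:
        bundle["comparison"].to_csv(outdir / "comparison.tsv", sep="\t", index=False)
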