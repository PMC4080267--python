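"""Drug-screening statistics: fingerprint filtering and rank concordance.

Two independent pieces share this module because both postprocess a
virtual screen:

* Tanimoto similarity |A & B| / |A | B| between binary molecular
  fingerprints, and the reference-ligand filter that keeps compounds whose
  best similarity to any reference exceeds a threshold (strict
  inequality);
* concordance of repeated scoring trials over the same compound library:
  pairwise score correlations, per-compound rankings, and the top-k
  common-selection curve against its random-null expectation

      n0(k) = k [1 + (1 - k/Nc)(2 - k/Nc)]  =  Nc (1 - (1 - k/Nc)^3),

  the expected number of unique compounds in the union of three
  independent random top-k lists from Nc compounds (generalized here to m
  trials as Nc (1 - (1 - k/Nc)^m)). An observed curve far below n0(k) and
  close to k means the trials agree on the top of the ranking.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "FingerprintSet",
    "RankTrialSet",
    "tanimoto",
    "filter_by_tanimoto",
    "expected_common",
    "observed_common_curve",
    "trial_score_correlations",
    "rank_compounds",
    "read_fingerprints",
    "write_fingerprints",
]


@dataclass
class FingerprintSet:
    """Binary fingerprints over a fixed bit length.

    ``bits`` is a boolean (n_compounds x n_bits) array aligned with
    ``compound_ids``.
    """

    compound_ids: list[str]
    bits: np.ndarray

    def __post_init__(self) -> None:
        self.bits = np.asarray(self.bits, dtype=bool)
        if self.bits.ndim != 2:
            raise ValueError("bits must be a 2-D (compounds x bits) array")
        if len(self.compound_ids) != self.bits.shape[0]:
            raise ValueError("compound_ids and bits row count differ")
        if len(set(self.compound_ids)) != len(self.compound_ids):
            raise ValueError("duplicate compound ids")

    @property
    def n_bits(self) -> int:
        return self.bits.shape[1]

    def __len__(self) -> int:
        return len(self.compound_ids)


@dataclass
class RankTrialSet:
    """Per-compound scores over repeated trials.

    ``scores`` is a DataFrame indexed by compound id with one column per
    trial. Ranks are descending: rank 1 is the best (largest) score in a
    trial, with ties broken by compound id for determinism, so each
    trial's ranks are a permutation of 1..N_c.
    """

    scores: pd.DataFrame

    def __post_init__(self) -> None:
        if self.scores.index.duplicated().any():
            raise ValueError("duplicate compound ids")
        if self.scores.shape[1] < 1:
            raise ValueError("need at least one trial")
        self.scores = self.scores.astype(float)

    @property
    def compound_ids(self) -> list[str]:
        return list(self.scores.index)

    @property
    def n_compounds(self) -> int:
        return self.scores.shape[0]

    @property
    def n_trials(self) -> int:
        return self.scores.shape[1]

    def ranks(self) -> pd.DataFrame:
        """Descending rank per trial (1 = best), ties by compound id."""
        out = {}
        ids = np.asarray(self.scores.index)
        for col in self.scores.columns:
            s = self.scores[col].to_numpy()
            order = np.lexsort((ids, -s))
            r = np.empty(len(s), dtype=int)
            r[order] = np.arange(1, len(s) + 1)
            out[col] = r
        return pd.DataFrame(out, index=self.scores.index)


def tanimoto(a: np.ndarray, b: np.ndarray) -> float:
    """Tanimoto index |a & b| / |a | b| of two equal-length bit vectors.

    Defined as 0 when both vectors are all-zero (logged), the conservative
    convention for featureless compounds.
    """
    a = np.asarray(a, dtype=bool)
    b = np.asarray(b, dtype=bool)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError(f"fingerprint lengths differ: {a.shape} vs {b.shape}")
    union = int(np.count_nonzero(a | b))
    if union == 0:
        logger.info("tanimoto of two all-zero fingerprints defined as 0.0")
        return 0.0
    return int(np.count_nonzero(a & b)) / union


def filter_by_tanimoto(
    library: FingerprintSet, references: FingerprintSet, threshold: float
) -> pd.DataFrame:
    """Keep compounds whose best Tanimoto to any reference is > threshold.

    The inequality is strict. Returns a DataFrame ordered by compound id
    with columns ``compound_id``, ``best_reference``, ``tanimoto`` for the
    passing compounds (best over references, reference ties broken by id).
    """
    if not 0.0 <= threshold <= 1.0:
        raise ValueError("threshold must lie in [0, 1]")
    if len(references) == 0:
        raise ValueError("references must be non-empty")
    if library.n_bits != references.n_bits:
        raise ValueError(
            f"bit lengths differ: library {library.n_bits} vs references {references.n_bits}"
        )
    a = library.bits.astype(np.int64)
    b = references.bits.astype(np.int64)
    inter = a @ b.T
    union = a.sum(axis=1)[:, None] + b.sum(axis=1)[None, :] - inter
    with np.errstate(invalid="ignore", divide="ignore"):
        sim = np.where(union > 0, inter / np.maximum(union, 1), 0.0)
    ref_ids = np.asarray(references.compound_ids)
    # best reference per compound; ties broken by reference id
    ref_order = np.argsort(ref_ids, kind="mergesort")
    sim_sorted = sim[:, ref_order]
    best_j = np.argmax(sim_sorted, axis=1)
    best = sim_sorted[np.arange(sim.shape[0]), best_j]
    best_ref = ref_ids[ref_order][best_j]
    keep = best > threshold
    out = pd.DataFrame(
        {
            "compound_id": np.asarray(library.compound_ids)[keep],
            "best_reference": best_ref[keep],
            "tanimoto": best[keep],
        }
    )
    return out.sort_values("compound_id", kind="mergesort").reset_index(drop=True)


def expected_common(k: int, Nc: int, n_trials: int = 3) -> float:
    """Expected unique compounds in the union of random top-k lists, n0(k).

    For three independent uniform k-subsets of Nc compounds this is
    k [1 + (1 - k/Nc)(2 - k/Nc)], algebraically Nc (1 - (1 - k/Nc)^3);
    the general-m form Nc (1 - (1 - k/Nc)^m) is used so curves for any
    trial count share the same null.
    """
    if Nc < 1:
        raise ValueError("Nc must be >= 1")
    if not 0 <= k <= Nc:
        raise ValueError(f"k must lie in 0..{Nc}, got {k}")
    if n_trials < 1:
        raise ValueError("n_trials must be >= 1")
    frac = k / Nc
    return float(Nc * (1.0 - (1.0 - frac) ** n_trials))


def observed_common_curve(
    t: RankTrialSet, k_values: list[int], mode: str = "union"
) -> pd.DataFrame:
    """Observed top-k commonality across trials, with the random null.

    For each k, counts the unique compounds in the union of the trials'
    top-k sets (``mode="union"``, matching the derivation of n0(k)), or
    the compounds present in *every* trial's top-k set
    (``mode="intersection"``). Returns a DataFrame with columns ``k``,
    ``observed``, ``expected_random`` (n0(k)) and ``complete_match`` (= k,
    the perfectly-concordant reference line).
    """
    if t.n_trials < 2:
        raise ValueError("need at least 2 trials")
    if mode not in ("union", "intersection"):
        raise ValueError(f"mode must be union|intersection, got {mode!r}")
    ranks = t.ranks().to_numpy()
    rows = []
    for k in k_values:
        if not 0 <= k <= t.n_compounds:
            raise ValueError(f"k must lie in 0..{t.n_compounds}, got {k}")
        top = ranks <= k
        if mode == "union":
            observed = int(top.any(axis=1).sum())
        else:
            observed = int(top.all(axis=1).sum())
        rows.append(
            {
                "k": k,
                "observed": observed,
                "expected_random": expected_common(k, t.n_compounds, t.n_trials),
                "complete_match": k,
            }
        )
    return pd.DataFrame(rows)


def trial_score_correlations(t: RankTrialSet) -> pd.DataFrame:
    """Pairwise Pearson correlation matrix between trial score vectors."""
    if t.n_trials < 2:
        raise ValueError("need at least 2 trials")
    if t.n_compounds < 3:
        raise ValueError("need at least 3 compounds")
    x = t.scores.to_numpy().T
    sd = x.std(axis=1)
    if (sd == 0).any():
        logger.warning("constant score vector(s); correlations undefined for those trials")
    with np.errstate(invalid="ignore", divide="ignore"):
        c = np.corrcoef(x)
    np.fill_diagonal(c, 1.0)
    cols = list(t.scores.columns)
    return pd.DataFrame(c, index=pd.Index(cols), columns=cols)


def rank_compounds(t: RankTrialSet, mode: str = "best") -> pd.DataFrame:
    """Rank compounds by their best or mean score over trials.

    ``best`` takes the per-compound maximum over trials (the convention
    for repeated scoring runs of one trial set), ``mean`` the average over
    trials. Ties are broken by compound id. Returns a DataFrame with
    columns ``rank``, ``compound_id``, ``score``.
    """
    if mode not in ("best", "mean"):
        raise ValueError(f"mode must be best|mean, got {mode!r}")
    agg = t.scores.max(axis=1) if mode == "best" else t.scores.mean(axis=1)
    ids = np.asarray(agg.index)
    vals = agg.to_numpy()
    order = np.lexsort((ids, -vals))
    return pd.DataFrame(
        {"rank": np.arange(1, len(order) + 1), "compound_id": ids[order], "score": vals[order]}
    )


def write_fingerprints(fp: FingerprintSet, path: str | Path) -> None:
    """Write fingerprints as TSV: compound_id TAB bitstring."""
    with open(path, "w") as fh:
        fh.write("compound_id\tbits\n")
        for cid, row in zip(fp.compound_ids, fp.bits):
            fh.write(f"{cid}\t{''.join('1' if b else '0' for b in row)}\n")


def read_fingerprints(path: str | Path) -> FingerprintSet:
    ids: list[str] = []
    rows: list[np.ndarray] = []
    with open(path) as fh:
        header = fh.readline()
        if not header.startswith("compound_id"):
            raise ValueError(f"{path}: expected 'compound_id<TAB>bits' header")
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            cid, bitstr = line.split("\t")
            if set(bitstr) - {"0", "1"}:
                raise ValueError(f"{path}: non-binary bitstring for {cid}")
            ids.append(cid)
            rows.append(np.frombuffer(bitstr.encode(), dtype=np.uint8) == ord("1"))
    if rows and len({len(r) for r in rows}) != 1:
        raise ValueError(f"{path}: fingerprints have differing bit lengths")
    bits = np.vstack(rows) if rows else np.zeros((0, 0), dtype=bool)
    return FingerprintSet(ids, bits)
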