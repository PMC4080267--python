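"""Synthetic paired-array data, ranked docking-score trials, fingerprints.

The paired generator emulates the structure the screening pipeline assumes:

* two modalities (genotype signal, DNA methylation signal) measured on the
  same probes and the same 3 x n_subjects samples (blood, normal tissue,
  tumor per subject);
* a planted subset of probes whose class means increase from blood to
  normal to tumor in *both* modalities, with the methylation means sitting
  a fixed offset below the genotype means (the demethylation pattern);
* background probes that fluctuate around a probe-specific baseline shared
  by the two modalities (the same locus read out on the same normalized
  intensity scale), independent of tissue class;
* per-subject offsets shared across a subject's three tissues (the paired
  design), drawn independently per modality;
* missing entries marked missing (NaN), never zero-filled by the generator.

Because baselines are shared across modalities while every noise source is
modality-specific, a background probe carries no systematic genotype-minus-
methylation difference: random probe subsets form a true null for the
modality-bias resampling test, and outlier selections in the two modalities
are independent, so the cross-modality overlap of top-N sets is
hypergeometric under the no-signal configuration.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .matrixio import TISSUES, OmicsMatrix, SampleDesign
from .screening import FingerprintSet, RankTrialSet

__all__ = [
    "SimulationParams",
    "GroundTruth",
    "generate_paired_dataset",
    "generate_rank_trials",
    "generate_fingerprints",
]


@dataclass(frozen=True)
class SimulationParams:
    """Parameters of the paired-array simulation.

    Defaults are chosen to land in the intensity regime of normalized
    SNP-array summaries (class means in the 1-3 range, methylation ~0.4
    units below genotype on affected probes, high call rates).

    Parameters
    ----------
    n_subjects:
        Patients; each contributes one blood, one normal-tissue and one
        tumor sample, so there are ``3 * n_subjects`` samples per modality.
    n_probes:
        Probes (SNPs) per modality; both modalities share the probe set.
    n_signal:
        Number of planted probes carrying the class-ordered signal.
    class_effect:
        Planted genotype class means for (blood, normal, tumor), strictly
        increasing, in array intensity units.
    modality_offset:
        Amount by which planted methylation means sit below the genotype
        means (>= 0).
    noise_sd:
        SD of i.i.d. measurement noise per cell.
    missing_rate:
        Fraction of cells marked missing, independently per modality.
    baseline_mean, baseline_sd:
        Background probes fluctuate around per-probe baselines drawn from
        Normal(baseline_mean, baseline_sd), truncated below at 0.2 and
        shared between the modalities; a wide baseline spread makes the
        leading principal component a dominant but non-discriminating
        baseline axis, as on real arrays.
    subject_sd:
        SD of the per-subject offset shared across a subject's three
        tissues and across the two modalities (the same patient's DNA
        feeds both assays, so sample-level shifts cancel in paired
        genotype-minus-methylation differences, as they must for random
        probe subsets to form a true null).
    seed:
        Seed for all randomness of this generator.
    """

    n_subjects: int = 30
    n_probes: int = 20_000
    n_signal: int = 100
    class_effect: tuple[float, float, float] = (1.3, 2.4, 2.9)
    modality_offset: float = 0.4
    noise_sd: float = 0.25
    missing_rate: float = 0.002
    baseline_mean: float = 2.0
    baseline_sd: float = 0.5
    subject_sd: float = 0.1
    seed: int = 0

    def validate(self) -> None:
        if self.n_subjects < 1:
            raise ValueError("n_subjects must be >= 1")
        if self.n_probes < 1:
            raise ValueError("n_probes must be >= 1")
        if not 0 <= self.n_signal <= self.n_probes:
            raise ValueError("n_signal must satisfy 0 <= n_signal <= n_probes")
        if len(self.class_effect) != len(TISSUES):
            raise ValueError("class_effect must have one value per tissue class")
        if not (self.class_effect[0] < self.class_effect[1] < self.class_effect[2]):
            raise ValueError("class_effect must be strictly increasing (blood < normal < tumor)")
        if self.modality_offset < 0:
            raise ValueError("modality_offset must be nonnegative")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be > 0")
        if not 0.0 <= self.missing_rate <= 1.0:
            raise ValueError("missing_rate must lie in [0, 1]")
        if self.subject_sd < 0:
            raise ValueError("subject_sd must be nonnegative")


@dataclass
class GroundTruth:
    """Planted structure of a simulated dataset (the recovery oracle)."""

    signal_probe_ids: list[str]
    #: class means of planted probes, one DataFrame per modality,
    #: indexed by probe id with one column per tissue class.
    class_means: dict[str, pd.DataFrame] = field(default_factory=dict)


def _probe_ids(n: int) -> list[str]:
    width = max(6, len(str(n)))
    return [f"SNP_{i:0{width}d}" for i in range(n)]


def generate_paired_dataset(
    params: SimulationParams,
) -> tuple[OmicsMatrix, OmicsMatrix, SampleDesign, GroundTruth]:
    """Simulate paired genotype/methylation matrices with planted signal.

    Returns two :class:`OmicsMatrix` over identical probe and sample ids,
    the :class:`SampleDesign`, and the :class:`GroundTruth` describing the
    planted probes. Fully reproducible from ``params.seed``.
    """
    params.validate()
    rng = np.random.default_rng(params.seed)

    n_sub = params.n_subjects
    n_samples = 3 * n_sub
    probes = _probe_ids(params.n_probes)

    subjects = [f"S{i + 1:03d}" for i in range(n_sub)]
    sample_ids, subj_col, tissue_col = [], [], []
    for tissue in TISSUES:  # blood block, then normal, then tumor
        for s in subjects:
            sample_ids.append(f"{tissue}_{s}")
            subj_col.append(s)
            tissue_col.append(tissue)
    design = SampleDesign(
        pd.DataFrame({"subject_id": subj_col, "tissue": tissue_col}, index=pd.Index(sample_ids))
    )
    subj_index = np.tile(np.arange(n_sub), 3)  # subject of each sample column
    class_index = np.repeat(np.arange(3), n_sub)  # tissue code of each column

    # shared per-probe baselines (same locus, same normalized scale)
    baselines = rng.normal(params.baseline_mean, params.baseline_sd, size=params.n_probes)
    baselines = np.clip(baselines, 0.2, None)

    signal_idx = np.sort(rng.choice(params.n_probes, size=params.n_signal, replace=False))
    signal_ids = [probes[i] for i in signal_idx]

    effects = np.asarray(params.class_effect, dtype=float)
    truth = GroundTruth(signal_probe_ids=list(signal_ids))

    # one offset per subject, shared by its three tissues and both assays
    subj_offsets = rng.normal(0.0, params.subject_sd, size=n_sub)

    matrices: dict[str, OmicsMatrix] = {}
    for modality in ("genotype", "methylation"):
        mean = np.tile(baselines[:, None], (1, n_samples))
        if params.n_signal:
            class_means = effects.copy()
            if modality == "methylation":
                class_means = class_means - params.modality_offset
            mean[signal_idx, :] = class_means[class_index][None, :]
            truth.class_means[modality] = pd.DataFrame(
                np.tile(class_means, (params.n_signal, 1)),
                index=pd.Index(signal_ids),
                columns=list(TISSUES),
            )
        else:
            truth.class_means[modality] = pd.DataFrame(columns=list(TISSUES))

        x = mean + subj_offsets[subj_index][None, :]
        x = x + rng.normal(0.0, params.noise_sd, size=(params.n_probes, n_samples))
        if params.missing_rate > 0:
            mask = rng.random((params.n_probes, n_samples)) < params.missing_rate
            x[mask] = np.nan
        matrices[modality] = OmicsMatrix(
            pd.DataFrame(x, index=pd.Index(probes), columns=pd.Index(sample_ids)), modality
        )

    return matrices["genotype"], matrices["methylation"], design, truth


def generate_rank_trials(
    n_compounds: int, n_trials: int, concordance: float, seed: int
) -> RankTrialSet:
    """Simulate repeated per-compound score trials with tunable concordance.

    Each trial's score vector is ``sqrt(c) * latent + sqrt(1 - c) * noise``
    with a shared standard-normal latent score, so the population Pearson
    correlation between any two trials equals ``concordance`` exactly:
    0 gives independent rankings, 1 identical rankings.
    """
    if n_compounds < 2:
        raise ValueError("n_compounds must be >= 2")
    if n_trials < 2:
        raise ValueError("n_trials must be >= 2")
    if not 0.0 <= concordance <= 1.0:
        raise ValueError("concordance must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    latent = rng.standard_normal(n_compounds)
    noise = rng.standard_normal((n_trials, n_compounds))
    scores = np.sqrt(concordance) * latent + np.sqrt(1.0 - concordance) * noise
    width = max(4, len(str(n_compounds)))
    ids = [f"CMP{i:0{width}d}" for i in range(n_compounds)]
    df = pd.DataFrame(
        scores.T, index=pd.Index(ids), columns=[f"trial{t + 1}" for t in range(n_trials)]
    )
    return RankTrialSet(df)


def generate_fingerprints(
    n_compounds: int, n_bits: int, density: float, seed: int
) -> FingerprintSet:
    """Random binary fingerprints with expected set-bit fraction ``density``."""
    if n_compounds < 0:
        raise ValueError("n_compounds must be >= 0")
    if n_bits < 1:
        raise ValueError("n_bits must be >= 1")
    if not 0.0 < density < 1.0:
        raise ValueError("density must lie in (0, 1)")
    rng = np.random.default_rng(seed)
    bits = rng.random((n_compounds, n_bits)) < density
    width = max(4, len(str(max(n_compounds, 1))))
    ids = [f"FP{i:0{width}d}" for i in range(n_compounds)]
    return FingerprintSet(ids, bits.astype(bool))
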