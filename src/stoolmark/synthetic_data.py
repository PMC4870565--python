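"""Synthetic two-group stool-microbiome cohorts with planted structure.

Emulates the statistical shape the downstream analyses assume: a small
case/control cohort (defaults: 16 controls, 18 cases) profiled by 16S-style
counts at ~50,000 reads/sample, in which a handful of planted taxa are
depleted in cases, co-vary as a community through a shared latent factor, and
drive a continuous symptom score on a GUPI-like 0-45 scale (group baselines
1 and 26).  Matched qPCR Ct tables and a metabolite table with planted
case-elevated analytes are generated from the same machinery, with ground
truth returned for recovery tests.

The abundance model is log-normal absolute abundances followed by multinomial
read sampling: feature base log-means are drawn once from a heavy-tailed
normal so a few taxa dominate (core microbiome) while most are rare.  All
randomness flows through :class:`numpy.random.Generator` (PCG64) seeded from
the spec, so outputs are bit-reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .tables_io import CohortMetadata, OtuTable

__all__ = [
    "SimSpec",
    "GroundTruth",
    "simulate_cohort",
    "simulate_ct",
    "simulate_metabolome",
    "CT_MAX_CYCLES",
]

CT_MAX_CYCLES = 40.0  # qPCR cycle ceiling; non-amplifying wells are censored here

# Base log-abundance spread across taxa.  sd=2 on the natural-log scale gives
# the usual 16S picture: the top few taxa take most reads, the tail is rare.
_BASE_LOGMEAN_SD = 2.0
# Planted taxa are drawn as moderately abundant commensals (the candidate
# species a qPCR panel would target), not from the rare tail.
_PLANTED_LOGMEAN_LOC = 1.0
_PLANTED_LOGMEAN_SD = 0.5
# Within-sample biological log-sd per taxon.
_FEATURE_LOG_SD = 1.0
# Scale coupling the planted community's log-abundance deviation to the
# symptom score (score units per log-unit of mean planted deviation).
_SCORE_COUPLING = 6.0


@dataclass
class SimSpec:
    """Conditions for one simulated cohort.

    Defaults mirror the emulated study: 16 controls + 18 cases, ~50,000
    reads/sample, symptom-score group means 1 (control) and 26 (case) on the
    0-45 GUPI scale, five planted case-depleted taxa that co-vary as a
    community (latent-factor loading 0.6) and are depleted 4-fold
    (depletion_factor 0.25) in cases.
    """

    n_control: int = 16
    n_case: int = 18
    n_features: int = 300
    n_planted: int = 5
    depletion_factor: float = 0.25
    community_correlation: float = 0.6
    read_depth: int = 50_000
    score_noise_sd: float = 2.0
    score_scale: tuple[float, float] = (1.0, 26.0)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_planted > self.n_features:
            raise ValueError("n_planted must be <= n_features")
        if not (0.0 < self.depletion_factor <= 1.0):
            raise ValueError("depletion_factor must be in (0, 1]")
        if not (0.0 <= self.community_correlation < 1.0):
            raise ValueError("community_correlation must be in [0, 1)")
        if self.read_depth <= 0:
            raise ValueError("read_depth must be positive")
        if self.n_control < 0 or self.n_case < 0:
            raise ValueError("group sizes must be non-negative")


@dataclass
class GroundTruth:
    """What was planted, for recovery tests."""

    planted_feature_ids: tuple[str, ...] = ()
    true_group_effect: dict[str, float] = field(default_factory=dict)
    latent_factor: pd.Series | None = None
    elevated_metabolite_ids: tuple[str, ...] = ()


def _taxonomy_labels(n_features: int, planted: np.ndarray) -> pd.Series:
    """Generated lineages (synthetic labels, not a real phylogeny)."""
    phyla = ["Firmicutes", "Bacteroidetes", "Actinobacteria", "Proteobacteria", "Verrucomicrobia"]
    ids = [f"OTU_{i:04d}" for i in range(n_features)]
    lineages = []
    for i in range(n_features):
        p = phyla[i % len(phyla)]
        lineages.append(f"k__Bacteria;p__{p};c__C{i % 7};o__O{i % 23};f__F{i % 41};g__G{i};s__S{i}")
    return pd.Series(lineages, index=ids)


def simulate_cohort(spec: SimSpec) -> tuple[OtuTable, CohortMetadata, GroundTruth]:
    """Draw one cohort: counts table, metadata and ground truth.

    Per sample i and taxon j the latent log-abundance is

        z_ij = mu_j + [case_i] * log(depletion_factor) * planted_j
               + lam * f_i * planted_j + s_ij * eps_ij

    with f_i ~ N(0,1) the shared community factor, lam the
    community-correlation loading (residual sd sqrt(1 - lam^2) for planted
    taxa so their marginal log-sd stays 1), and counts drawn multinomially at
    ``read_depth`` from exp(z_i)/sum.  The symptom score is the group
    baseline minus a scaled, group-centred mean of planted-taxon
    log-abundance deviations, plus Gaussian noise, clipped to [0, 45].
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.n_control + spec.n_case
    p = spec.n_features

    sample_ids = [f"C{i:02d}" for i in range(spec.n_control)] + [
        f"P{i:02d}" for i in range(spec.n_case)
    ]
    is_case = np.r_[np.zeros(spec.n_control, bool), np.ones(spec.n_case, bool)]

    planted_idx = rng.choice(p, size=spec.n_planted, replace=False)
    planted_mask = np.zeros(p, bool)
    planted_mask[planted_idx] = True

    mu = rng.normal(0.0, _BASE_LOGMEAN_SD, size=p)
    mu[planted_mask] = rng.normal(_PLANTED_LOGMEAN_LOC, _PLANTED_LOGMEAN_SD, size=spec.n_planted)

    lam = spec.community_correlation
    f = rng.normal(size=n)  # shared community factor
    eps = rng.normal(size=(n, p))
    z = mu[None, :] + eps * _FEATURE_LOG_SD
    if spec.n_planted:
        resid = np.sqrt(max(0.0, 1.0 - lam**2))
        z[:, planted_mask] = (
            mu[planted_mask][None, :]
            + lam * f[:, None]
            + resid * eps[:, planted_mask]
        )
        z[np.ix_(is_case, planted_mask)] += np.log(spec.depletion_factor)

    abund = np.exp(z)
    probs = abund / abund.sum(axis=1, keepdims=True)
    counts = np.vstack([rng.multinomial(spec.read_depth, probs[i]) for i in range(n)])

    feature_ids = [f"OTU_{i:04d}" for i in range(p)]
    taxonomy = _taxonomy_labels(p, planted_idx)
    otu = OtuTable(
        data=pd.DataFrame(counts, index=sample_ids, columns=feature_ids),
        taxonomy=taxonomy,
        kind="counts",
    )

    # symptom score: group baseline - coupled planted-community deviation
    baseline = np.where(is_case, spec.score_scale[1], spec.score_scale[0]).astype(float)
    if spec.n_planted:
        dev = (z[:, planted_mask] - mu[planted_mask][None, :]).mean(axis=1)
        # centre within group so Table-1-like group means are preserved while
        # the within-cohort score still tracks the planted community
        dev = dev - np.where(is_case, np.log(spec.depletion_factor), 0.0)
        score = baseline - _SCORE_COUPLING * dev
    else:
        score = baseline.copy()
    score = score + rng.normal(0.0, spec.score_noise_sd, size=n)
    score = np.clip(score, 0.0, 45.0)

    meta = CohortMetadata(
        frame=pd.DataFrame(
            {"group": np.where(is_case, "case", "control"), "symptom_score": score},
            index=pd.Index(sample_ids),
        )
    )
    truth = GroundTruth(
        planted_feature_ids=tuple(feature_ids[i] for i in sorted(planted_idx)),
        true_group_effect={feature_ids[i]: spec.depletion_factor for i in sorted(planted_idx)},
        latent_factor=pd.Series(f, index=sample_ids),
    )
    return otu, meta, truth


def simulate_ct(
    abundances: pd.DataFrame,
    primer_efficiency: float = 1.0,
    ct_noise_sd: float = 0.15,
    n_replicates: int = 2,
    intercept: float = 22.0,
    seed: int = 0,
) -> pd.DataFrame:
    """qPCR Ct wells from per-sample template abundances.

    ``abundances`` is samples x species.  Each well follows the standard
    amplification model ``Ct = intercept - log2(abundance) / log2(1 + E)``
    with per-well Gaussian noise; at efficiency E = 1 a doubling of template
    lowers Ct by exactly one cycle.  Zero (or non-positive) abundance is
    censored at cycle 40.  Returns the long-format Ct table with columns
    ``sample_id, species, replicate, ct, censored``.
    """
    if primer_efficiency <= 0:
        raise ValueError("primer_efficiency must be positive")
    if n_replicates < 1:
        raise ValueError("n_replicates must be >= 1")
    rng = np.random.default_rng(seed)
    slope = 1.0 / np.log2(1.0 + primer_efficiency)
    records = []
    for sample in abundances.index:
        for species in abundances.columns:
            a = float(abundances.at[sample, species])
            for rep in range(1, n_replicates + 1):
                if a <= 0:
                    records.append((sample, species, rep, CT_MAX_CYCLES, True))
                    continue
                ct = intercept - slope * np.log2(a)
                if ct_noise_sd > 0:
                    ct += rng.normal(0.0, ct_noise_sd)
                if ct >= CT_MAX_CYCLES:
                    records.append((sample, species, rep, CT_MAX_CYCLES, True))
                else:
                    records.append((sample, species, rep, max(ct, 1e-9), False))
    return pd.DataFrame.from_records(
        records, columns=["sample_id", "species", "replicate", "ct", "censored"]
    )


def simulate_metabolome(
    n_control: int = 16,
    n_case: int = 18,
    n_metabolites: int = 60,
    n_elevated: int = 1,
    effect_sd_units: float = 3.0,
    seed: int = 0,
) -> tuple[pd.DataFrame, GroundTruth]:
    """Log-normal metabolite abundances with planted case-elevated analytes.

    Elevated metabolites are shifted upward in cases by ``effect_sd_units``
    latent (log-scale) standard deviations — the default of 3 puts the
    planted analyte in the near-complete-separation regime seen for a strong
    single-metabolite biomarker.  Returns a (n_control + n_case) x
    n_metabolites table and the ground truth.
    """
    if n_elevated > n_metabolites:
        raise ValueError("n_elevated must be <= n_metabolites")
    rng = np.random.default_rng(seed)
    n = n_control + n_case
    sample_ids = [f"C{i:02d}" for i in range(n_control)] + [f"P{i:02d}" for i in range(n_case)]
    is_case = np.r_[np.zeros(n_control, bool), np.ones(n_case, bool)]
    met_ids = [f"MET_{i:03d}" for i in range(n_metabolites)]
    elevated = rng.choice(n_metabolites, size=n_elevated, replace=False)

    mu = rng.normal(0.0, 1.0, size=n_metabolites)
    logv = mu[None, :] + rng.normal(size=(n, n_metabolites))
    logv[np.ix_(is_case, np.isin(np.arange(n_metabolites), elevated))] += effect_sd_units
    table = pd.DataFrame(np.exp(logv), index=sample_ids, columns=met_ids)
    truth = GroundTruth(elevated_metabolite_ids=tuple(met_ids[i] for i in sorted(elevated)))
    return table, truth
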