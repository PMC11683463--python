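"""Synthetic community-time-series generator with planted statistical structure.

The generator emulates post-OTU-picking abundance tables from a multi-year
fertilization field trial: five treatments (no fertilizer CK; NPK fertilizer N;
NPK + straw NS; + straw and manure NSM; + straw biochar NB) sampled yearly in
replicate. Every downstream stage gets ground truth from it:

* taxon–taxon dependence is planted as a block-structured latent correlation
  matrix and realized through a Gaussian copula, so the rank-correlation
  structure the Spearman-based network inference should recover is controlled
  directly (rank correlations survive the monotone log-normal and counting
  transforms);
* a treatment-specific richness trend is implemented by activating taxa from a
  dormant pool (expected abundance zero before their activation year), which
  raises observed richness and Chao1 over years without touching the
  correlation engine;
* an evenness trend tempers the static dominance profile over years;
* counts are drawn from a negative binomial at a configurable sequencing
  depth, and soil properties follow linear per-treatment year trends plus
  Gaussian noise.

All randomness flows from a single mandatory seed; identical seed and
configuration give byte-identical outputs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from phodnet.core_io import OtuTable, SampleMetadata, SoilProperties
from phodnet.errors import GenerationError, ValidationError

DEFAULT_TREATMENTS = ("CK", "N", "NS", "NSM", "NB")

#: Per-treatment richness trend, in taxa activated per year. Straw-amended
#: treatments gain taxa fastest, plain NPK slowest, mirroring the ordering of
#: Chao1 slopes across treatments in long-term straw-return trials.
DEFAULT_RICHNESS_SLOPE: Mapping[str, float] = {
    "CK": 1.0, "N": 0.5, "NS": 2.5, "NSM": 2.5, "NB": 2.5,
}

#: Per-treatment evenness trend (dominance-tempering rate per year, unitless).
DEFAULT_EVENNESS_TREND: Mapping[str, float] = {
    "CK": 0.02, "N": 0.01, "NS": 0.06, "NSM": 0.06, "NB": 0.06,
}

# Soil property model: name -> (baseline, per-treatment yearly slope, noise sd).
# Baselines are typical of a slightly alkaline agricultural soil; straw-amended
# treatments accumulate organic carbon and available nutrients over years.
_SOIL_MODEL: dict[str, tuple[float, Mapping[str, float], float]] = {
    "pH": (8.1, {"CK": 0.0, "N": -0.02, "NS": -0.01, "NSM": -0.01, "NB": 0.0}, 0.05),
    "SOC": (14.0, {"CK": 0.0, "N": 0.1, "NS": 0.6, "NSM": 0.8, "NB": 0.7}, 0.5),
    "TN": (1.1, {"CK": 0.0, "N": 0.02, "NS": 0.04, "NSM": 0.05, "NB": 0.04}, 0.05),
    "TP": (0.8, {"CK": 0.0, "N": 0.02, "NS": 0.03, "NSM": 0.04, "NB": 0.03}, 0.03),
    "TK": (19.0, {"CK": 0.0, "N": 0.0, "NS": 0.1, "NSM": 0.1, "NB": 0.15}, 0.4),
    "AN": (75.0, {"CK": 0.0, "N": 2.0, "NS": 3.0, "NSM": 3.5, "NB": 3.0}, 3.0),
    "AP": (18.0, {"CK": 0.0, "N": 1.0, "NS": 1.5, "NSM": 2.0, "NB": 1.5}, 1.0),
    "AK": (110.0, {"CK": 0.0, "N": 1.0, "NS": 4.0, "NSM": 5.0, "NB": 6.0}, 4.0),
}


@dataclass
class InteractionModel:
    """Latent ground-truth dependence structure among taxa.

    ``latent_correlation`` is symmetric with unit diagonal and (repaired to)
    positive semi-definite; ``planted_edges`` lists the (i, j, sign) pairs that
    were deliberately planted, before any PSD repair — the ground truth for
    edge-recovery evaluation.
    """

    n_taxa: int
    module_assignment: np.ndarray  # taxon index -> module id
    latent_correlation: np.ndarray
    frac_negative: float
    planted_edges: list[tuple[int, int, int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        m = np.asarray(self.latent_correlation, dtype=float)
        if m.shape != (self.n_taxa, self.n_taxa):
            raise ValidationError("latent correlation shape mismatch")
        if not np.allclose(m, m.T, atol=1e-12):
            raise ValidationError("latent correlation not symmetric")
        if not np.allclose(np.diag(m), 1.0, atol=1e-9):
            raise ValidationError("latent correlation diagonal not unit")
        if np.linalg.eigvalsh(m).min() < -1e-8:
            raise ValidationError("latent correlation not positive semi-definite")
        self.latent_correlation = m


@dataclass
class SimulationConfig:
    """Study design and noise parameters for :func:`simulate_dataset`.

    Defaults reproduce the field design the package targets: 5 treatments,
    7 sampling years (0..6), 3 field replicates per treatment-year, with
    straw-amended treatments gaining richness and evenness fastest.
    """

    n_taxa: int = 60
    n_years: int = 7
    n_replicates_per_year: int = 3
    treatments: Sequence[str] = DEFAULT_TREATMENTS
    richness_slope: Mapping[str, float] | None = None
    evenness_trend: Mapping[str, float] | None = None
    target_latent_r: float = 0.9
    sequencing_depth: float = 50_000.0
    dispersion: float = 10.0  # negative-binomial size parameter
    lognormal_sigma: float = 1.5  # sd of the copula-driven log-abundance noise
    base_spread: float = 1.0  # sd of static taxon log-mean profile
    seed: int = 0

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ValidationError("seed is mandatory")
        if min(self.n_taxa, self.n_years, self.n_replicates_per_year) < 1:
            raise ValidationError("n_taxa, n_years, n_replicates_per_year must be >= 1")
        if self.sequencing_depth <= 0 or self.dispersion <= 0:
            raise ValidationError("sequencing_depth and dispersion must be positive")
        if self.richness_slope is None:
            self.richness_slope = {t: DEFAULT_RICHNESS_SLOPE.get(t, 0.0) for t in self.treatments}
        if self.evenness_trend is None:
            self.evenness_trend = {t: DEFAULT_EVENNESS_TREND.get(t, 0.0) for t in self.treatments}
        for t in self.treatments:
            if t not in self.richness_slope or t not in self.evenness_trend:
                raise ValidationError(f"treatment {t} missing a trend entry")
            if self.richness_slope[t] < 0:
                raise ValidationError("richness_slope must be non-negative")


def _repair_psd(matrix: np.ndarray, tol: float = -1e-8, max_iter: int = 200) -> np.ndarray:
    """Nearest-PSD repair by alternating eigenvalue clipping and unit-diagonal
    renormalization (a Higham-style projection without the Frobenius bookkeeping)."""
    m = matrix.copy()
    for _ in range(max_iter):
        vals, vecs = np.linalg.eigh(m)
        if vals.min() >= tol:
            return m
        m = (vecs * np.clip(vals, 0.0, None)) @ vecs.T
        d = np.sqrt(np.clip(np.diag(m), 1e-12, None))
        m = m / np.outer(d, d)
        np.fill_diagonal(m, 1.0)
        m = (m + m.T) / 2.0
    raise GenerationError("latent correlation could not be repaired to PSD")


def build_interaction_model(
    n_taxa: int,
    n_modules: int,
    within_density: float,
    frac_negative: float,
    target_latent_r: float,
    seed: int,
) -> InteractionModel:
    """Plant a block-structured latent correlation matrix.

    Taxa are split into ``n_modules`` contiguous, near-equal modules. Each
    within-module pair is planted with probability ``within_density`` at
    ±``target_latent_r``; cross-module entries are zero. The matrix is then
    repaired to the nearest positive semi-definite correlation matrix by
    eigenvalue clipping (and re-normalized to unit diagonal).

    Signs: for ``frac_negative`` ≤ 0.5 each taxon is assigned a latent sign
    (negative with probability q solving 2q(1−q) = frac_negative) and a pair's
    sign is the product of its taxa's signs. This one-factor sign structure is
    mutually consistent, so at full within-module density the planted block is
    exactly PSD and planted magnitudes survive the repair at the target value;
    independent per-pair signs at high |r| are mutually contradictory and the
    PSD repair would silently shrink them far below target. For
    ``frac_negative`` > 0.5 (unreachable by any consistent sign assignment)
    signs are drawn independently per pair and the repair shrinks accordingly.
    At partial density some shrinkage is unavoidable either way (a zero entry
    between two strongly correlated partners is itself non-PSD).
    """
    if not (0.0 <= within_density <= 1.0 and 0.0 <= frac_negative <= 1.0):
        raise ValidationError("densities and fractions must lie in [0, 1]")
    if not (0.0 <= target_latent_r < 1.0):
        raise ValidationError("target_latent_r must lie in [0, 1)")
    if n_modules < 1 or n_modules > n_taxa:
        raise ValidationError("n_modules must lie in [1, n_taxa]")
    rng = np.random.default_rng(seed)
    modules = np.repeat(np.arange(n_modules), math.ceil(n_taxa / n_modules))[:n_taxa]
    factor_signs: np.ndarray | None = None
    if frac_negative <= 0.5:
        q = (1.0 - math.sqrt(1.0 - 2.0 * frac_negative)) / 2.0
        factor_signs = np.where(rng.random(n_taxa) < q, -1, 1)
    corr = np.eye(n_taxa)
    planted: list[tuple[int, int, int]] = []
    for i in range(n_taxa):
        for j in range(i + 1, n_taxa):
            if modules[i] != modules[j]:
                continue
            if rng.random() >= within_density:
                continue
            if factor_signs is not None:
                sign = int(factor_signs[i] * factor_signs[j])
            else:
                sign = -1 if rng.random() < frac_negative else 1
            corr[i, j] = corr[j, i] = sign * target_latent_r
            planted.append((i, j, sign))
    corr = _repair_psd(corr)
    n_neg = sum(1 for _, _, s in planted if s < 0)
    realized_frac = n_neg / len(planted) if planted else 0.0
    return InteractionModel(n_taxa, modules, corr, realized_frac, planted)


def _copula_factor(corr: np.ndarray) -> np.ndarray:
    """Square-root factor L with L L^T = corr, valid for singular matrices."""
    vals, vecs = np.linalg.eigh(corr)
    return vecs * np.sqrt(np.clip(vals, 0.0, None))


def simulate_dataset(
    model: InteractionModel, config: SimulationConfig
) -> tuple[OtuTable, list[SampleMetadata], list[SoilProperties]]:
    """Simulate the full treatment × year × replicate design.

    Per sample the generator draws a Gaussian copula vector with the model's
    latent correlation, maps it to log-normal expected abundances on top of a
    static taxon dominance profile, applies the treatment's richness (dormant
    activation) and evenness (dominance tempering) year trends, closes the
    composition and draws negative-binomial counts at the configured depth.
    """
    if model.n_taxa != config.n_taxa:
        raise ValidationError(
            f"model has {model.n_taxa} taxa but config expects {config.n_taxa}"
        )
    rng = np.random.default_rng(config.seed)
    n = config.n_taxa
    taxon_ids = [f"OTU{i + 1:04d}" for i in range(n)]

    # Static dominance profile and dormant pool, shared across treatments.
    base_mu = rng.normal(0.0, config.base_spread, size=n)
    max_gain = max(config.richness_slope[t] for t in config.treatments) * (config.n_years - 1)
    pool_size = int(math.ceil(max_gain))
    if pool_size >= n:
        raise GenerationError(
            "richness trend needs a dormant pool at least as large as the community; "
            "increase n_taxa or reduce richness_slope"
        )
    activation_order = rng.permutation(n)[:pool_size]  # dormant taxa, activation order

    factor = _copula_factor(model.latent_correlation)
    sigma = config.lognormal_sigma

    columns: list[np.ndarray] = []
    metadata: list[SampleMetadata] = []
    soils: list[SoilProperties] = []
    for treatment in config.treatments:
        r_slope = config.richness_slope[treatment]
        e_trend = config.evenness_trend[treatment]
        for year in range(config.n_years):
            n_active_dormant = min(pool_size, int(round(r_slope * year)))
            dormant_now = activation_order[n_active_dormant:]
            for rep in range(1, config.n_replicates_per_year + 1):
                z = factor @ rng.standard_normal(n)
                log_abund = base_mu / (1.0 + e_trend * year) + sigma * z
                expected = np.exp(log_abund)
                expected[dormant_now] = 0.0
                total = expected.sum()
                if total <= 0:
                    raise GenerationError("all taxa dormant; infeasible configuration")
                mean_counts = config.sequencing_depth * expected / total
                k = config.dispersion
                counts = np.zeros(n, dtype=float)
                live = mean_counts > 0
                counts[live] = rng.negative_binomial(
                    k, k / (k + mean_counts[live])
                ).astype(float)
                sample_id = f"{treatment}_Y{year}_R{rep}"
                columns.append(counts)
                metadata.append(SampleMetadata(sample_id, treatment, year, rep))
                soils.append(
                    SoilProperties(
                        sample_id,
                        {
                            name: base + slopes.get(treatment, 0.0) * year
                            + rng.normal(0.0, sd)
                            for name, (base, slopes, sd) in _SOIL_MODEL.items()
                        },
                    )
                )
    table = OtuTable(taxon_ids, [m.sample_id for m in metadata], np.column_stack(columns))
    return table, metadata, soils
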