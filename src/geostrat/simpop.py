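"""Synthetic spatially structured cohorts.

Generates cohorts whose genotypes carry smooth ancestry clines
(Balding–Nichols divergence of K source populations around ancestral
allele frequencies, mixed along a geographic gradient), whose complex
traits carry configurable genetic and geographic components, and whose
sampling optionally depends on trait value and distance to the nearest
assessment centre. Matched reference-panel profiles for the admixture
machinery are built from the same source frequencies.

Coordinates are simulated in kilometres on a square grid with the origin
at the south-west corner; a converter to metres is provided because
biobank-style birth coordinates are metre-scale.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "SimulationConfig",
    "SourceFreqs",
    "SpatialCohort",
    "GenotypeMatrix",
    "TraitTable",
    "SimulatedData",
    "simulate_source_freqs",
    "simulate_cohort",
    "assign_centres",
    "build_reference_panel",
    "true_weight_table",
    "km_to_metres",
]


class ConfigurationError(ValueError):
    """Invalid simulation configuration."""


@dataclass
class TraitSpec:
    """One synthetic complex trait.

    The trait is built as ``genetic_weight * Z(score) + geo_weight *
    Z(surface) + Normal(0, noise_sd)`` where ``Z`` standardizes to unit
    variance, ``score`` is the true polygenic score over the causal
    variants and ``surface`` is a fixed smooth function of the position
    projected on the gradient axis.

    ``cline_coupling`` in [0, 1] correlates the causal effect sizes with
    the variants' allele-frequency clines: 0 gives neutral (random-sign)
    effects whose net geographic cline varies by chance, 1 aligns every
    effect with the cline, emulating polygenic differentiation along the
    gradient so the true score itself has a reliable geographic cline.
    """

    name: str
    genetic_weight: float = 0.0
    geo_weight: float = 0.0
    noise_sd: float = 1.0
    cline_coupling: float = 0.0

    def __post_init__(self) -> None:
        if not np.isfinite([self.genetic_weight, self.geo_weight, self.noise_sd]).all():
            raise ConfigurationError(f"trait {self.name!r}: weights must be finite")
        if self.noise_sd <= 0:
            raise ConfigurationError(f"trait {self.name!r}: noise_sd must be > 0")
        if not (0.0 <= self.cline_coupling <= 1.0):
            raise ConfigurationError(f"trait {self.name!r}: cline_coupling must be in [0, 1]")


@dataclass
class ParticipationSpec:
    """Logistic participation model: retained iff
    Bernoulli(sigmoid(intercept + trait_coef*Z(trait) + distance_coef*Z(dist))).

    ``dist`` is Euclidean distance to the nearest centre. Off by default;
    exists to exercise selection/collider narratives qualitatively.
    """

    trait: str
    intercept: float = 1.0
    trait_coef: float = 0.0
    distance_coef: float = 0.0


@dataclass
class SimulationConfig:
    n_individuals: int = 2000
    n_variants: int = 1000
    n_sources: int = 3
    fst: float = 0.05
    grid_extent: float = 1000.0  # km, square region, origin south-west
    centre_coords: Sequence[tuple[float, float]] = ((300.0, 300.0), (700.0, 700.0))
    gradient_axis: tuple[float, float] = (1.0, 0.0)  # (north, east) unit vector
    gradient_strength: float = 3.0  # logit slope per SD of projection
    causal_fraction: float = 0.1
    trait_specs: list[TraitSpec] = field(default_factory=list)
    participation: ParticipationSpec | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_individuals < 1 or self.n_variants < 1 or self.n_sources < 1:
            raise ConfigurationError("n_individuals, n_variants, n_sources must be >= 1")
        if not (0.0 < self.fst < 1.0):
            raise ConfigurationError(f"fst must be in (0,1), got {self.fst}")
        if self.grid_extent <= 0:
            raise ConfigurationError("grid_extent must be positive")
        axis = np.asarray(self.gradient_axis, dtype=float)
        if axis.shape != (2,) or not np.isfinite(axis).all() or np.allclose(axis, 0):
            raise ConfigurationError("gradient_axis must be a nonzero 2-vector")
        self.gradient_axis = tuple(axis / np.linalg.norm(axis))
        self.trait_specs = [
            t if isinstance(t, TraitSpec) else TraitSpec(**t) for t in self.trait_specs
        ]
        if self.participation is not None and not isinstance(
            self.participation, ParticipationSpec
        ):
            self.participation = ParticipationSpec(**self.participation)
        coords = np.asarray(self.centre_coords, dtype=float)
        if coords.ndim != 2 or coords.shape[1] != 2 or coords.shape[0] < 1:
            raise ConfigurationError("centre_coords must be a non-empty list of (north, east)")
        if (coords < 0).any():
            raise ConfigurationError("centre coordinates must be non-negative")
        self.centre_coords = [tuple(c) for c in coords]

    @classmethod
    def from_dict(cls, d: dict) -> "SimulationConfig":
        known = set(cls.__dataclass_fields__)
        unknown = set(d) - known
        if unknown:
            raise ConfigurationError(f"unknown SimulationConfig keys: {sorted(unknown)}")
        return cls(**d)

    @classmethod
    def from_yaml(cls, path: str) -> "SimulationConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


@dataclass
class SourceFreqs:
    """Ancestral and per-source allele frequencies (Balding–Nichols)."""

    base_freqs: np.ndarray  # (M,)
    region_freqs: np.ndarray  # (K, M)


@dataclass
class SpatialCohort:
    """Individuals with birth coordinates (km from the south-west origin),
    assessment-centre label, genotyping-array batch, participation flag.

    Negative coordinates encode missingness (matching biobank conventions);
    the simulator itself only produces non-negative coordinates.
    """

    table: pd.DataFrame  # id, birth_north, birth_east, centre_id, array_batch, participation

    def __post_init__(self) -> None:
        required = {"id", "birth_north", "birth_east", "centre_id", "array_batch", "participation"}
        missing = required - set(self.table.columns)
        if missing:
            raise ValueError(f"cohort table missing columns: {sorted(missing)}")

    @property
    def n(self) -> int:
        return len(self.table)


@dataclass
class GenotypeMatrix:
    """N x M effect-allele dosages in [0, 2] with variant metadata.

    Missing dosages are encoded as NaN, never as 0.
    ``variants`` columns: variant_id, chrom, pos, effect_allele,
    other_allele, maf, info.
    """

    dosages: np.ndarray
    variants: pd.DataFrame
    sample_ids: np.ndarray

    def __post_init__(self) -> None:
        if self.dosages.shape != (len(self.sample_ids), len(self.variants)):
            raise ValueError("dosage matrix shape does not match sample/variant metadata")
        obs = self.dosages[~np.isnan(self.dosages)]
        if obs.size and (obs.min() < 0 or obs.max() > 2):
            raise ValueError("dosages must lie in [0, 2]")

    @property
    def n_samples(self) -> int:
        return self.dosages.shape[0]

    @property
    def n_variants(self) -> int:
        return self.dosages.shape[1]

    def subset_variants(self, mask: np.ndarray) -> "GenotypeMatrix":
        return GenotypeMatrix(
            self.dosages[:, mask],
            self.variants.loc[np.asarray(mask)].reset_index(drop=True),
            self.sample_ids,
        )


@dataclass
class TraitTable:
    """Per-individual trait values (NaN = missing) plus trait metadata."""

    table: pd.DataFrame  # indexed like the cohort, column per trait
    meta: pd.DataFrame  # name, units

    def __post_init__(self) -> None:
        if set(self.meta["name"]) - set(self.table.columns) - {"id"}:
            raise ValueError("trait metadata names missing from table")


@dataclass
class SimulatedData:
    """Bundle returned by :func:`simulate_cohort`."""

    cohort: SpatialCohort
    admixture: np.ndarray  # (N, K), row-stochastic
    genotypes: GenotypeMatrix
    traits: TraitTable
    true_betas: pd.DataFrame  # variant_id x trait, causal effect sizes
    config: SimulationConfig
    source_freqs: SourceFreqs


def km_to_metres(coords_km: np.ndarray) -> np.ndarray:
    """Convert kilometre grid coordinates to metres, preserving negative
    (missing) codes as-is."""
    coords = np.asarray(coords_km, dtype=float)
    return np.where(coords >= 0, coords * 1000.0, coords)


def simulate_source_freqs(cfg: SimulationConfig) -> SourceFreqs:
    """Draw ancestral frequencies and Balding–Nichols source frequencies.

    Ancestral (base) frequencies are uniform on (0.05, 0.95); each of the
    K sources draws region_freqs[k, j] ~ Beta(p(1-F)/F, (1-p)(1-F)/F) with
    p the base frequency and F the fixation index, then clips to
    [0.001, 0.999] to avoid monomorphic variants.
    """
    rng = np.random.default_rng(_substream(cfg.seed, "source_freqs"))
    p = rng.uniform(0.05, 0.95, size=cfg.n_variants)
    ratio = (1.0 - cfg.fst) / cfg.fst
    freqs = rng.beta(p * ratio, (1.0 - p) * ratio, size=(cfg.n_sources, cfg.n_variants))
    freqs = np.clip(freqs, 0.001, 0.999)
    return SourceFreqs(base_freqs=p, region_freqs=freqs)


def _substream(seed: int, label: str) -> np.random.SeedSequence:
    """All randomness derives deterministically from one global seed."""
    digest = sum((i + 1) * b for i, b in enumerate(label.encode())) % (2**16)
    return np.random.SeedSequence(entropy=int(seed), spawn_key=(digest,))


def _geo_surface(projection: np.ndarray) -> np.ndarray:
    """Fixed smooth nonlinear surface of the standardized gradient
    projection; shared by all traits with geo_weight != 0 so that trait
    geography coincides with the ancestry cline."""
    t = (projection - projection.mean()) / projection.std()
    return t + 0.5 * np.sin(2.0 * t)


def _standardize(x: np.ndarray) -> np.ndarray:
    sd = x.std()
    if sd == 0:
        return np.zeros_like(x)
    return (x - x.mean()) / sd


def simulate_cohort(cfg: SimulationConfig, src: SourceFreqs) -> SimulatedData:
    """Simulate locations, admixture, genotypes and traits.

    Locations are uniform on the square grid. Admixture rows are the
    softmax of affine functions of the projection of position on the
    gradient axis: source k has logit ``gradient_strength * u_k * z``
    where the slopes u_k are evenly spaced on [-1, 1] and z is the
    standardized projection, so rows are row-stochastic by construction
    and vary smoothly in space. Individual allele frequencies are the
    admixture-weighted source frequencies, dosages Binomial(2, p_ij).
    """
    K, M, N = cfg.n_sources, cfg.n_variants, cfg.n_individuals
    if src.region_freqs.shape != (K, M):
        raise ConfigurationError("source frequencies do not match configuration")

    rng_loc = np.random.default_rng(_substream(cfg.seed, "locations"))
    north = rng_loc.uniform(0.0, cfg.grid_extent, size=N)
    east = rng_loc.uniform(0.0, cfg.grid_extent, size=N)
    axis = np.asarray(cfg.gradient_axis)
    projection = north * axis[0] + east * axis[1]

    # softmax of affine functions of the gradient projection
    z = (projection - projection.mean()) / projection.std() if N > 1 else np.zeros(N)
    slopes = np.linspace(-1.0, 1.0, K) if K > 1 else np.zeros(1)
    logits = cfg.gradient_strength * np.outer(z, slopes)
    logits -= logits.max(axis=1, keepdims=True)
    q = np.exp(logits)
    q /= q.sum(axis=1, keepdims=True)

    p_ind = q @ src.region_freqs  # (N, M) individual frequencies
    rng_geno = np.random.default_rng(_substream(cfg.seed, "genotypes"))
    dosages = rng_geno.binomial(2, p_ind).astype(float)

    sample_freq = dosages.mean(axis=0) / 2.0
    maf = np.minimum(sample_freq, 1.0 - sample_freq)
    maf = np.clip(maf, 1e-6, 0.5)
    variants = pd.DataFrame(
        {
            "variant_id": [f"rs{j + 1}" for j in range(M)],
            "chrom": (np.arange(M) % 22) + 1,
            "pos": (np.arange(M) // 22 + 1) * 500_000,  # 500 kb spacing per chrom
            "effect_allele": "A",
            "other_allele": "G",
            "maf": maf,
            "info": np.ones(M),
        }
    )

    ids = np.array([f"ind{i + 1}" for i in range(N)])
    rng_batch = np.random.default_rng(_substream(cfg.seed, "array_batch"))
    array_batch = np.where(rng_batch.random(N) < 0.5, "axiom", "bileve")

    # causal effects: a fixed fraction of variants per trait, N(0,1) betas
    rng_beta = np.random.default_rng(_substream(cfg.seed, "causal_betas"))
    n_causal = max(1, int(round(cfg.causal_fraction * M)))
    betas = pd.DataFrame(0.0, index=variants["variant_id"], columns=[t.name for t in cfg.trait_specs])
    trait_values: dict[str, np.ndarray] = {}
    rng_noise = np.random.default_rng(_substream(cfg.seed, "trait_noise"))
    surface = _geo_surface(projection)
    # per-variant frequency cline along the gradient (slope-weighted
    # source frequencies); used when a trait couples effects to the cline
    cline = slopes @ src.region_freqs
    cline_z = _standardize(cline)
    for spec in cfg.trait_specs:
        causal_idx = rng_beta.choice(M, size=n_causal, replace=False)
        eps = rng_beta.normal(0.0, 1.0, size=n_causal)
        rho = spec.cline_coupling
        b = np.zeros(M)
        b[causal_idx] = np.sqrt(1.0 - rho**2) * eps + rho * cline_z[causal_idx]
        betas[spec.name] = b
        genetic = _standardize(dosages @ b)
        value = (
            spec.genetic_weight * genetic
            + spec.geo_weight * _standardize(surface)
            + rng_noise.normal(0.0, spec.noise_sd, size=N)
        )
        trait_values[spec.name] = value

    cohort_table = pd.DataFrame(
        {
            "id": ids,
            "birth_north": north,
            "birth_east": east,
            "centre_id": 0,
            "array_batch": array_batch,
            "participation": True,
        }
    )
    cohort = assign_centres(SpatialCohort(cohort_table), cfg.centre_coords)

    if cfg.participation is not None:
        ps = cfg.participation
        if ps.trait not in trait_values:
            raise ConfigurationError(f"participation trait {ps.trait!r} not simulated")
        centres = np.asarray(cfg.centre_coords)
        d = np.hypot(
            north[:, None] - centres[None, :, 0], east[:, None] - centres[None, :, 1]
        ).min(axis=1)
        eta = (
            ps.intercept
            + ps.trait_coef * _standardize(trait_values[ps.trait])
            + ps.distance_coef * _standardize(d)
        )
        prob = 1.0 / (1.0 + np.exp(-eta))
        rng_part = np.random.default_rng(_substream(cfg.seed, "participation"))
        cohort.table["participation"] = rng_part.random(N) < prob

    traits = TraitTable(
        table=pd.DataFrame({"id": ids, **trait_values}),
        meta=pd.DataFrame(
            {"name": [t.name for t in cfg.trait_specs], "units": "arbitrary"}
        ),
    )
    genotypes = GenotypeMatrix(dosages=dosages, variants=variants, sample_ids=ids)
    return SimulatedData(
        cohort=cohort,
        admixture=q,
        genotypes=genotypes,
        traits=traits,
        true_betas=betas,
        config=cfg,
        source_freqs=src,
    )


def assign_centres(cohort: SpatialCohort, centre_coords: Sequence[tuple[float, float]]) -> SpatialCohort:
    """Assign each individual to the nearest centre by Euclidean distance;
    ties go to the lowest centre index."""
    centres = np.asarray(centre_coords, dtype=float)
    if centres.ndim != 2 or centres.shape[0] < 1:
        raise ConfigurationError("need at least one centre")
    north = cohort.table["birth_north"].to_numpy(dtype=float)
    east = cohort.table["birth_east"].to_numpy(dtype=float)
    d2 = (north[:, None] - centres[None, :, 0]) ** 2 + (east[:, None] - centres[None, :, 1]) ** 2
    table = cohort.table.copy()
    table["centre_id"] = np.argmin(d2, axis=1)  # argmin takes the first (lowest) index on ties
    return SpatialCohort(table)


def build_reference_panel(src: SourceFreqs, n_per_region: int, seed: int):
    """Mean dosage profile of ``n_per_region`` individuals drawn purely
    from each source; the synthetic analogue of averaging painting
    profiles within labelled populations."""
    from .admixmap import ReferencePanel

    if n_per_region < 1:
        raise ConfigurationError("n_per_region must be >= 1")
    rng = np.random.default_rng(_substream(seed, "reference_panel"))
    K, M = src.region_freqs.shape
    profiles = np.empty((K, M))
    for k in range(K):
        draws = rng.binomial(2, src.region_freqs[k], size=(n_per_region, M))
        profiles[k] = draws.mean(axis=0)
    labels = [f"region{k + 1}" for k in range(K)]
    return ReferencePanel(labels=labels, profiles=profiles)


def true_weight_table(sim: SimulatedData, trait: str) -> pd.DataFrame:
    """External-GWAS-style weight table built from the simulator's true
    causal effects: causal variants get p = 1e-12, null variants p drawn
    uniform on (0.05, 1). Columns follow the summary-statistics TSV
    convention (SNP, chr, pos, effect_allele, other_allele, beta, pval)."""
    if trait not in sim.true_betas.columns:
        raise KeyError(f"unknown trait {trait!r}")
    b = sim.true_betas[trait].to_numpy()
    rng = np.random.default_rng(_substream(sim.config.seed, f"weights_{trait}"))
    pval = np.where(b != 0, 1e-12, rng.uniform(0.05, 1.0, size=b.size))
    v = sim.genotypes.variants
    return pd.DataFrame(
        {
            "SNP": v["variant_id"],
            "chr": v["chrom"],
            "pos": v["pos"],
            "effect_allele": v["effect_allele"],
            "other_allele": v["other_allele"],
            "beta": b,
            "pval": pval,
            "trait": trait,
            "source": "simulated",
        }
    )
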