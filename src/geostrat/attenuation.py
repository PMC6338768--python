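"""Polygenic-score-trait models across adjustment tiers and the
geography-matched random-trait null.

Tier 1 is the unadjusted linear model trait ~ PS; tier 2 adds genotyping
array; tier 3 adds principal components and assessment centre; tier 4
adds penalized smooth terms for the north and east birth coordinates.
Attenuation of the PS coefficient across tiers quantifies how much of an
unadjusted association is attributable to shared geographic structure.

The matched null replaces a real trait by draws that preserve its
coarse geographic distribution (per-location-bin mean and SD along each
axis) while severing any within-bin link to genotype.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .simpop import SpatialCohort
from .scores import PolygenicScore
from .geo_assoc import PCSet, tier_covariates
from .smoothfit import SmoothSpec, fit_smooth_model

__all__ = [
    "AttenuationReport",
    "MatchedNullTrait",
    "fit_adjustment_tiers",
    "percent_attenuation",
    "geo_matched_traits",
    "rescale_unadjusted",
]

Z975 = 1.959963984540054


@dataclass
class AttenuationReport:
    """PS coefficient, SE and p per adjustment tier for one trait."""

    trait: str
    ps_label: str
    table: pd.DataFrame  # tier, beta, se, p, n

    def beta(self, tier: int) -> float:
        return float(self.table.set_index("tier").loc[tier, "beta"])

    def se(self, tier: int) -> float:
        return float(self.table.set_index("tier").loc[tier, "se"])

    def ci(self, tier: int) -> tuple[float, float]:
        b, s = self.beta(tier), self.se(tier)
        return (b - Z975 * s, b + Z975 * s)


@dataclass
class MatchedNullTrait:
    values: pd.Series  # indexed by individual id
    n_bins: int
    source_trait: str
    seed: int


def fit_adjustment_tiers(
    trait: np.ndarray | pd.Series,
    ps: PolygenicScore,
    cohort: SpatialCohort,
    pcs: PCSet | None,
    tiers: tuple[int, ...] = (1, 2, 3, 4),
    pc_counts: tuple[int, int] = (40, 40),
    trait_name: str = "trait",
    ps_label: str = "ps",
    basis_dim: int = 10,
) -> AttenuationReport:
    """Linear PS coefficient under tiered adjustment.

    Tiers 1-3 are ordinary least squares; tier 4 adds s(north) + s(east)
    penalized smooths to the tier-3 covariates. The PS enters linearly
    throughout.
    """
    if not ps.standardized:
        raise ValueError("PS must be z-transformed before tier modelling")
    y = np.asarray(trait, dtype=float)
    if not np.isfinite(y).any():
        raise ValueError("trait is entirely missing")
    rows = []
    for tier in tiers:
        # tier 4 = tier-3 covariates + smooth location terms
        cov = tier_covariates(cohort, 3 if tier == 4 else tier, pcs, pc_counts)
        data = cov.copy()
        data["ps"] = ps.scores.to_numpy(dtype=float)
        smooths = []
        if tier == 4:
            data["birth_north"] = cohort.table["birth_north"].to_numpy(dtype=float)
            data["birth_east"] = cohort.table["birth_east"].to_numpy(dtype=float)
            smooths = [
                SmoothSpec("birth_north", basis_dim=basis_dim),
                SmoothSpec("birth_east", basis_dim=basis_dim),
            ]
        linear = ["ps"] + [
            c for c in cov.columns if pd.api.types.is_numeric_dtype(cov[c])
        ]
        factors = [c for c in cov.columns if not pd.api.types.is_numeric_dtype(cov[c])]
        fit = fit_smooth_model(y, data, smooths=smooths, linear=linear, factors=factors)
        rows.append(
            {
                "tier": tier,
                "beta": float(fit.coef["ps"]),
                "se": float(fit.se["ps"]),
                "p": float(fit.p_values["ps"]),
                "n": fit.n,
            }
        )
    return AttenuationReport(trait=trait_name, ps_label=ps_label, table=pd.DataFrame(rows))


def percent_attenuation(report: AttenuationReport, tier_a: int, tier_b: int) -> float:
    """100 * (1 - beta_b / beta_a), the percent of the tier-a coefficient
    removed by tier-b adjustment (signed; negative = amplification,
    >100 = sign flip)."""
    beta_a = report.beta(tier_a)
    beta_b = report.beta(tier_b)
    if beta_a == 0:
        raise ValueError("attenuation undefined for a zero baseline coefficient")
    if abs(beta_a) < 2.0 * report.se(tier_a):
        import warnings

        warnings.warn(
            "baseline coefficient within 2 SE of zero; attenuation is unstable"
        )
    return 100.0 * (1.0 - beta_b / beta_a)


def rescale_unadjusted(report: AttenuationReport) -> pd.DataFrame:
    """Divide every tier's coefficient and 95% CI by the tier-1
    coefficient, so tier 1 is exactly 1 and a value of 0.5 means half the
    unadjusted effect remains."""
    beta1 = report.beta(1)
    if beta1 == 0:
        raise ValueError("cannot rescale: tier-1 coefficient is zero")
    out = report.table.copy()
    lo = out["beta"] - Z975 * out["se"]
    hi = out["beta"] + Z975 * out["se"]
    out["rescaled"] = out["beta"] / beta1
    lo_r, hi_r = lo / beta1, hi / beta1
    # dividing by a negative coefficient flips the interval endpoints
    out["rescaled_lo"] = np.minimum(lo_r, hi_r)
    out["rescaled_hi"] = np.maximum(lo_r, hi_r)
    out.loc[out["tier"] == 1, "rescaled"] = 1.0
    return out


def _bin_edges(order: np.ndarray, n_bins: int) -> list[np.ndarray]:
    """Split ranked indices into n_bins contiguous bins; the remainder r
    gives the first r bins one extra member."""
    n = order.size
    base, extra = divmod(n, n_bins)
    sizes = [base + (1 if i < extra else 0) for i in range(n_bins)]
    bins, start = [], 0
    for s in sizes:
        bins.append(order[start : start + s])
        start += s
    return bins


def geo_matched_traits(
    trait: np.ndarray | pd.Series,
    cohort: SpatialCohort,
    n_bins: int = 100,
    seed: int = 0,
) -> MatchedNullTrait:
    """Geography-matched random trait.

    Rank individuals by northing, split into ``n_bins`` contiguous
    equal-size bins (coordinate ties broken by id), and within each bin
    draw replacement values from Normal(bin mean, bin SD) of the source
    trait; repeat along the easting; the null trait is the equal-weight
    average of the two draws. The result preserves coarse geographic
    structure but is independent of genotype within bins.
    """
    y = np.asarray(trait, dtype=float)
    tab = cohort.table
    north = tab["birth_north"].to_numpy(dtype=float)
    east = tab["birth_east"].to_numpy(dtype=float)
    ids = tab["id"].to_numpy()
    ok = np.isfinite(y) & (north >= 0) & (east >= 0) & np.isfinite(north) & np.isfinite(east)
    n_ok = int(ok.sum())
    if n_bins > n_ok // 2:
        raise ValueError(f"n_bins={n_bins} too large for {n_ok} usable individuals")
    rng = np.random.default_rng(seed)
    idx_ok = np.where(ok)[0]

    draws = np.full((2, y.size), np.nan)
    for a, coord in enumerate((north, east)):
        order = idx_ok[np.lexsort((ids[idx_ok], coord[idx_ok]))]
        for members in _bin_edges(order, n_bins):
            if members.size == 0:
                raise ValueError("empty location bin")
            vals = y[members]
            if vals.size < 2:
                raise ValueError("need at least 2 non-missing trait values per bin")
            mu = vals.mean()
            sd = vals.std(ddof=1)
            draws[a, members] = rng.normal(mu, sd, size=members.size)
    combined = draws.mean(axis=0)
    combined[~ok] = np.nan
    return MatchedNullTrait(
        values=pd.Series(combined, index=pd.Index(ids, name="id")),
        n_bins=n_bins,
        source_trait=getattr(trait, "name", "trait") or "trait",
        seed=seed,
    )
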