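"""Geographic-structure association battery.

Genotype principal components, per-variant regression of birth location
on dosage under tiered covariate adjustment, the genomic inflation
factor, and the polygenic-score-versus-geography tier table (the
smooth-term p-value matrix across adjustment models 1-4).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.sparse.linalg import svds

from .simpop import GenotypeMatrix, SpatialCohort
from .scores import PolygenicScore
from .smoothfit import SmoothSpec, fit_smooth_model, smooth_term_pvalue

__all__ = [
    "PCSet",
    "GwasResults",
    "compute_pcs",
    "structure_gwas",
    "genomic_lambda",
    "ps_geo_battery",
    "tier_covariates",
    "AXES",
    "CHI2_NULL_MEDIAN",
]

AXES = {"north_south": "birth_north", "east_west": "birth_east"}

# median of the chi-square(1) distribution
CHI2_NULL_MEDIAN = 0.4549


@dataclass
class PCSet:
    """Genotype principal components: unit-variance scores, loadings and
    eigenvalues (descending)."""

    scores: np.ndarray  # (N, n_pcs)
    loadings: np.ndarray  # (M_used, n_pcs)
    eigenvalues: np.ndarray
    variant_ids: np.ndarray

    @property
    def n_pcs(self) -> int:
        return self.scores.shape[1]

    def frame(self, prefix: str = "PC") -> pd.DataFrame:
        return pd.DataFrame(
            self.scores, columns=[f"{prefix}{i + 1}" for i in range(self.n_pcs)]
        )


@dataclass
class GwasResults:
    table: pd.DataFrame  # variant_id, beta, se, p, n
    axis: str
    tier: int
    skipped: list


def compute_pcs(geno: GenotypeMatrix, n_pcs: int = 10, thin_kb: float = 100.0) -> PCSet:
    """Principal components of the standardized dosage matrix after
    positional thinning (variants closer than ``thin_kb`` on a chromosome
    are pruned, keeping the first)."""
    if n_pcs >= min(geno.n_samples, geno.n_variants):
        raise ValueError("n_pcs must be smaller than both matrix dimensions")
    v = geno.variants
    keep = np.zeros(geno.n_variants, dtype=bool)
    last_pos: dict = {}
    for j, (chrom, pos) in enumerate(zip(v["chrom"], v["pos"])):
        prev = last_pos.get(chrom)
        if prev is None or pos - prev >= thin_kb * 1000.0:
            keep[j] = True
            last_pos[chrom] = pos
    D = geno.dosages[:, keep]
    col_mean = np.nanmean(D, axis=0)
    D = np.where(np.isnan(D), col_mean, D)
    sd = D.std(axis=0)
    poly = sd > 0
    Z = (D[:, poly] - col_mean[poly]) / sd[poly]
    if n_pcs >= min(Z.shape):
        raise ValueError("too few polymorphic variants for requested n_pcs")
    U, s, Vt = svds(Z, k=n_pcs, random_state=0)
    order = np.argsort(s)[::-1]
    U, s, Vt = U[:, order], s[order], Vt[order]
    scores = U * np.sqrt(Z.shape[0])  # unit variance columns
    eigenvalues = s**2 / Z.shape[0]
    # deterministic sign convention: largest-|loading| entry positive
    for i in range(n_pcs):
        jmax = np.argmax(np.abs(Vt[i]))
        if Vt[i, jmax] < 0:
            Vt[i] *= -1
            scores[:, i] *= -1
    return PCSet(
        scores=scores,
        loadings=Vt.T,
        eigenvalues=eigenvalues,
        variant_ids=v.loc[keep, "variant_id"].to_numpy()[poly],
    )


def tier_covariates(
    cohort: SpatialCohort,
    tier: int,
    pcs: PCSet | None,
    pc_counts: tuple[int, int] = (10, 40),
) -> pd.DataFrame:
    """Covariate frame for adjustment tiers 1-4.

    tier 1: none; tier 2: genotyping array; tier 3: array + pc_counts[0]
    PCs + centre; tier 4: array + pc_counts[1] PCs + centre. Requested PC
    counts are capped at the available PCs with a warning (desk-scale
    cohorts are smaller than biobanks).
    """
    if tier not in (1, 2, 3, 4):
        raise ValueError("tier must be 1-4")
    out = pd.DataFrame(index=cohort.table.index)
    if tier >= 2:
        out["array_batch"] = cohort.table["array_batch"].to_numpy()
    if tier >= 3:
        want = pc_counts[0] if tier == 3 else pc_counts[1]
        if pcs is None:
            raise ValueError("tiers 3-4 require principal components")
        n_avail = pcs.n_pcs
        if want > n_avail:
            warnings.warn(f"requested {want} PCs, only {n_avail} available; capping")
            want = n_avail
        for i in range(want):
            out[f"PC{i + 1}"] = pcs.scores[:, i]
        # centre is a factor variable, never a linear code
        out["centre_id"] = pd.Categorical(cohort.table["centre_id"].to_numpy())
    return out


def _covariate_design(cov: pd.DataFrame) -> tuple[np.ndarray, list[str]]:
    n = len(cov)
    cols = [np.ones((n, 1))]
    names = ["(Intercept)"]
    for name in cov.columns:
        if pd.api.types.is_numeric_dtype(cov[name]):
            cols.append(cov[name].to_numpy(dtype=float)[:, None])
            names.append(name)
        else:
            d = pd.get_dummies(cov[name], prefix=name, drop_first=True, dtype=float)
            cols.append(d.to_numpy())
            names.extend(d.columns)
    return np.hstack(cols), names


def structure_gwas(
    geno: GenotypeMatrix,
    cohort: SpatialCohort,
    axis: str = "north_south",
    tier: int = 1,
    pcs: PCSet | None = None,
    pc_counts: tuple[int, int] = (10, 40),
) -> GwasResults:
    """Per-variant OLS of a birth-location axis on dosage plus tier
    covariates; two-sided p from the t statistic.

    Uses residualization (Frisch-Waugh-Lovell), which reproduces the full
    multiple-regression coefficient, SE and p exactly given the correct
    residual degrees of freedom. Constant-dosage variants are skipped and
    logged.
    """
    if axis not in AXES:
        raise ValueError(f"axis must be one of {sorted(AXES)}")
    coord = cohort.table[AXES[axis]].to_numpy(dtype=float)
    obs = np.isfinite(coord)
    coord = coord[obs]
    cov = tier_covariates(cohort, tier, pcs, pc_counts).loc[obs]
    Q, names = _covariate_design(cov)
    Qq, _ = np.linalg.qr(Q)
    n = coord.size
    p_cov = Qq.shape[1]

    y_res = coord - Qq @ (Qq.T @ coord)
    D = geno.dosages[obs]
    col_mean = np.nanmean(D, axis=0)
    D = np.where(np.isnan(D), col_mean, D)
    skipped = [
        geno.variants["variant_id"].iloc[j]
        for j in np.where(D.std(axis=0) == 0)[0]
    ]
    X_res = D - Qq @ (Qq.T @ D)

    sxx = (X_res**2).sum(axis=0)
    good = sxx > 1e-12
    beta = np.full(geno.n_variants, np.nan)
    se = np.full(geno.n_variants, np.nan)
    pvals = np.full(geno.n_variants, np.nan)
    dof = n - p_cov - 1
    sxy = X_res.T @ y_res
    beta[good] = sxy[good] / sxx[good]
    rss = (y_res**2).sum() - beta[good] ** 2 * sxx[good]
    sigma2 = rss / dof
    se[good] = np.sqrt(sigma2 / sxx[good])
    t = beta[good] / se[good]
    pvals[good] = 2.0 * stats.t.sf(np.abs(t), df=dof)

    table = pd.DataFrame(
        {
            "variant_id": geno.variants["variant_id"],
            "beta": beta,
            "se": se,
            "p": pvals,
            "n": n,
            "axis": axis,
            "tier": tier,
        }
    )
    table = table[good].reset_index(drop=True)
    return GwasResults(table=table, axis=axis, tier=tier, skipped=skipped)


def genomic_lambda(p_values: np.ndarray) -> float:
    """Genomic inflation factor: median chi-square(1) quantile of the
    p-values divided by the null median 0.4549."""
    p = np.asarray(p_values, dtype=float)
    p = p[np.isfinite(p)]
    if p.size < 100:
        raise ValueError("need at least 100 p-values for a stable lambda")
    if (p <= 0).any():
        warnings.warn("p-values of 0 clamped to machine minimum")
        p = np.maximum(p, np.finfo(float).tiny)
    chi2 = stats.chi2.isf(p, df=1)
    return float(np.median(chi2) / CHI2_NULL_MEDIAN)


def ps_geo_battery(
    ps_set: dict[str, PolygenicScore],
    cohort: SpatialCohort,
    pcs: PCSet | None,
    tiers: tuple[int, ...] = (1, 2, 3, 4),
    pc_counts: tuple[int, int] = (10, 40),
    basis_dim: int = 10,
) -> pd.DataFrame:
    """Smooth-term p-values for polygenic score versus each birth-location
    axis at each adjustment tier: ``ps ~ s(coordinate) + tier covariates``.

    Returns the model 1-4 p-value matrix with one row per (score, axis),
    mirroring the standard PS-geography tier-table layout.
    """
    rows = []
    for label, ps in ps_set.items():
        if not ps.standardized:
            raise ValueError(f"score {label!r} must be z-transformed first")
        y_full = ps.scores.to_numpy(dtype=float)
        for axis, coord_col in AXES.items():
            row: dict = {
                "ps": label,
                "mode": ps.mode,
                "p_threshold": ps.p_threshold,
                "axis": axis,
            }
            for tier in tiers:
                cov = tier_covariates(cohort, tier, pcs, pc_counts)
                data = cov.copy()
                data[coord_col] = cohort.table[coord_col].to_numpy(dtype=float)
                numeric = [c for c in cov.columns if pd.api.types.is_numeric_dtype(cov[c]) and c != "centre_id"]
                factors = [c for c in cov.columns if c not in numeric]
                fit = fit_smooth_model(
                    y_full,
                    data,
                    smooths=[SmoothSpec(coord_col, basis_dim=basis_dim)],
                    linear=numeric,
                    factors=factors,
                )
                row[f"model{tier}"] = smooth_term_pvalue(fit, coord_col)
            rows.append(row)
    return pd.DataFrame(rows)
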