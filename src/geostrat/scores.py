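"""Polygenic score construction from external-style weight tables.

Weighted scores sum effect-allele dosage times reported beta over the
variants passing a discovery p-value threshold; unweighted scores use
only the direction of effect. Variants are harmonized to the genotype
effect allele, strand-ambiguous (A/T, C/G) variants are dropped, and a
local distance-based greedy clumping replaces repository-served LD
clumping.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .simpop import GenotypeMatrix

__all__ = [
    "PolygenicScore",
    "greedy_clump",
    "build_ps",
    "ztransform",
    "read_weight_table",
    "write_scores",
]

WEIGHT_COLUMNS = ["SNP", "chr", "pos", "effect_allele", "other_allele", "beta", "pval"]

_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}


@dataclass
class PolygenicScore:
    scores: pd.Series  # indexed by individual id; NaN only if no variant observed
    mode: str  # "weighted" | "unweighted"
    p_threshold: float
    standardized: bool
    n_variants_used: int

    def __post_init__(self) -> None:
        if self.mode not in ("weighted", "unweighted"):
            raise ValueError(f"mode must be weighted/unweighted, got {self.mode!r}")


def read_weight_table(path: str) -> pd.DataFrame:
    """Read a GWAS-summary-statistics-style TSV (SNP, chr, pos,
    effect_allele, other_allele, beta, pval)."""
    table = pd.read_csv(path, sep="\t")
    missing = set(WEIGHT_COLUMNS) - set(table.columns)
    if missing:
        raise ValueError(f"weight table missing columns: {sorted(missing)}")
    return table


def greedy_clump(table: pd.DataFrame, window_kb: float = 250.0, p_threshold: float = 1.0) -> pd.DataFrame:
    """Greedy distance-based clumping.

    Keeps variants below the p threshold, walks them in ascending p order
    (ties broken by position then id) and accepts a variant only when no
    previously accepted variant on the same chromosome lies within
    ``window_kb``. A deterministic stand-in for LD-r2 clumping when no
    linkage structure is modelled.
    """
    if table["pos"].isna().any():
        raise ValueError("clumping requires variant positions")
    cand = table[table["pval"] < p_threshold]
    cand = cand.sort_values(["pval", "pos", "SNP"], kind="mergesort")
    window = window_kb * 1000.0
    accepted: dict = {}  # chrom -> list of positions
    keep_idx = []
    for idx, row in cand.iterrows():
        taken = accepted.setdefault(row["chr"], [])
        if all(abs(row["pos"] - p) > window for p in taken):
            taken.append(row["pos"])
            keep_idx.append(idx)
    return table.loc[keep_idx].sort_values(["chr", "pos"]).reset_index(drop=True)


def _is_strand_ambiguous(a1: str, a2: str) -> bool:
    return _COMPLEMENT.get(str(a1).upper()) == str(a2).upper()


def build_ps(
    geno: GenotypeMatrix,
    table: pd.DataFrame,
    mode: str = "weighted",
    p_threshold: float = 5e-8,
) -> PolygenicScore:
    """Build a per-individual polygenic score.

    Effect-allele dosages are harmonized: where the table's effect allele
    matches the genotype's other allele (and vice versa) the dosage 2-d is
    used. Strand-ambiguous variants (A/T, C/G) are dropped with a warning,
    as are table variants absent from the genotypes. Individuals missing a
    contributing dosage receive their score over observed variants
    rescaled by total/observed variant count.
    """
    if mode not in ("weighted", "unweighted"):
        raise ValueError(f"unknown mode {mode!r}")
    use = table[table["pval"] < p_threshold]
    vmeta = geno.variants.set_index("variant_id")

    cols: list[int] = []
    weights: list[float] = []
    col_of = {vid: j for j, vid in enumerate(geno.variants["variant_id"])}
    dropped_absent, dropped_ambiguous = [], []
    flip: list[bool] = []
    for _, row in use.iterrows():
        vid = row["SNP"]
        if vid not in col_of:
            dropped_absent.append(vid)
            continue
        if _is_strand_ambiguous(row["effect_allele"], row["other_allele"]):
            dropped_ambiguous.append(vid)
            continue
        g_eff = str(vmeta.loc[vid, "effect_allele"]).upper()
        g_oth = str(vmeta.loc[vid, "other_allele"]).upper()
        t_eff = str(row["effect_allele"]).upper()
        t_oth = str(row["other_allele"]).upper()
        if (t_eff, t_oth) == (g_eff, g_oth):
            flip.append(False)
        elif (t_eff, t_oth) == (g_oth, g_eff):
            flip.append(True)
        else:
            dropped_absent.append(vid)
            continue
        cols.append(col_of[vid])
        weights.append(float(row["beta"]))
    if dropped_absent:
        warnings.warn(f"{len(dropped_absent)} weight-table variants absent from genotypes or allele-mismatched")
    if dropped_ambiguous:
        warnings.warn(f"{len(dropped_ambiguous)} strand-ambiguous variants dropped")

    n_used = len(cols)
    if n_used == 0:
        raise ValueError("no usable variants below the p threshold")
    D = geno.dosages[:, cols].copy()
    flip_arr = np.asarray(flip)
    D[:, flip_arr] = 2.0 - D[:, flip_arr]
    w = np.asarray(weights)
    if mode == "unweighted":
        w = np.sign(w)

    observed = ~np.isnan(D)
    contrib = np.where(observed, D, 0.0) @ w
    n_obs = observed.sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        score = np.where(n_obs > 0, contrib * (n_used / np.maximum(n_obs, 1)), np.nan)
    return PolygenicScore(
        scores=pd.Series(score, index=pd.Index(geno.sample_ids, name="id")),
        mode=mode,
        p_threshold=p_threshold,
        standardized=False,
        n_variants_used=n_used,
    )


def ztransform(ps: PolygenicScore) -> PolygenicScore:
    """Z-transform the score over non-missing individuals (applied after
    all sample exclusions, so subset first, then transform)."""
    x = ps.scores.to_numpy(dtype=float)
    obs = x[~np.isnan(x)]
    if obs.size < 2:
        raise ValueError("need at least 2 non-missing scores")
    sd = obs.std(ddof=0)
    if sd == 0:
        raise ValueError("constant score cannot be standardized (SD = 0)")
    z = (x - obs.mean()) / sd
    return PolygenicScore(
        scores=pd.Series(z, index=ps.scores.index),
        mode=ps.mode,
        p_threshold=ps.p_threshold,
        standardized=True,
        n_variants_used=ps.n_variants_used,
    )


def write_scores(ps_raw: PolygenicScore, ps_z: PolygenicScore, path: str) -> None:
    out = pd.DataFrame(
        {"id": ps_raw.scores.index, "score_raw": ps_raw.scores.values, "score_z": ps_z.scores.values}
    )
    out.to_csv(path, sep="\t", index=False)
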