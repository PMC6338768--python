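"""Variant/sample quality control and trait recoding.

Implements the graded imputation-INFO filter by minor-allele-frequency
band, an exact conditional Hardy–Weinberg test, variant-level QC with a
removal log, greedy relatedness pruning, and the categorical recodings
used for household income, sibling counts and birth coordinates.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .simpop import GenotypeMatrix

__all__ = [
    "QCRules",
    "KinshipPairs",
    "graded_info_filter",
    "hwe_exact_test",
    "apply_variant_qc",
    "prune_related",
    "recode_traits",
    "INCOME_MIDPOINTS",
]

# Printed pounds-sterling recodings for the categorical household-income
# bands (1: <18,000; 2: 18,000-30,999; 3: 31,000-51,999; 4: 52,000-100,000;
# 5: >100,000). Used verbatim as a lookup.
INCOME_MIDPOINTS = {1: 11505, 2: 22495, 3: 41499, 4: 76000, 5: 124000}
_INCOME_MISSING_CODES = {-1, -3}

# (maf_lower, maf_upper, min_info): rarer variants need higher INFO.
DEFAULT_GRADED_INFO = [
    (0.03, 0.5, 0.3),
    (0.01, 0.03, 0.6),
    (0.005, 0.01, 0.8),
    (0.001, 0.005, 0.9),
]


@dataclass
class QCRules:
    max_missingness: float = 0.05
    hwe_p_floor: float = 1e-6
    graded_info: list[tuple[float, float, float]] = field(
        default_factory=lambda: list(DEFAULT_GRADED_INFO)
    )
    kinship_threshold: float = 0.125

    def __post_init__(self) -> None:
        for v in (self.max_missingness, self.hwe_p_floor, self.kinship_threshold):
            if not (0.0 <= v <= 1.0):
                raise ValueError("QC thresholds must lie in [0, 1]")
        bands = sorted(self.graded_info, key=lambda b: b[0], reverse=True)
        for (lo1, hi1, _), (lo2, hi2, _) in zip(bands, bands[1:]):
            if hi2 > lo1:
                raise ValueError("graded INFO bands must be non-overlapping and ordered")
        self.graded_info = bands


@dataclass
class KinshipPairs:
    """Pairwise kinship estimates; each unordered pair stored once."""

    pairs: pd.DataFrame  # id_a, id_b, kinship

    def __post_init__(self) -> None:
        p = self.pairs
        if (p["id_a"] == p["id_b"]).any():
            raise ValueError("self-pairs not allowed")
        if (p["kinship"] < 0).any():
            raise ValueError("kinship must be >= 0")
        keys = p.apply(lambda r: tuple(sorted((r["id_a"], r["id_b"]))), axis=1)
        if keys.duplicated().any():
            raise ValueError("symmetric pairs must be stored once")

    @classmethod
    def from_tsv(cls, path: str) -> "KinshipPairs":
        return cls(pd.read_csv(path, sep="\t", names=["id_a", "id_b", "kinship"], header=0))


def graded_info_filter(maf: float, info: float, rules: QCRules | None = None) -> bool:
    """Pass/fail by the INFO threshold of the MAF band containing ``maf``.

    MAF below the lowest band always fails (conservative choice for very
    rare variants).
    """
    rules = rules or QCRules()
    if not (0.0 < maf <= 0.5):
        raise ValueError(f"maf must be in (0, 0.5], got {maf}")
    if not (0.0 < info <= 1.0):
        raise ValueError(f"info must be in (0, 1], got {info}")
    for lo, hi, min_info in rules.graded_info:
        if lo <= maf <= hi:
            return info > min_info
    return False


_MAX_LGAMMA = 4097
_LOGFACT = np.concatenate([[0.0], np.cumsum(np.log(np.arange(1, _MAX_LGAMMA)))])


def _het_log_probs(n: int, n_a: int) -> tuple[np.ndarray, np.ndarray]:
    """Log P(het = h | n genotypes, n_a copies of allele A) for all
    attainable heterozygote counts h (conditional on allele counts).

    P(h) = n! / (nAA! h! naa!) * 2^h / C(2n, nA) up to the shared
    normalizer; returned normalized.
    """
    parity = n_a % 2
    h = np.arange(parity, min(n_a, 2 * n - n_a) + 1, 2)
    n_aa = (n_a - h) // 2
    n_bb = n - n_aa - h
    lf = _LOGFACT
    logp = lf[n] - lf[n_aa] - lf[h] - lf[n_bb] + h * np.log(2.0)
    logp -= logp.max()
    p = np.exp(logp)
    p /= p.sum()
    return h, p


def hwe_exact_test(n_AA: int, n_Aa: int, n_aa: int) -> float:
    """Exact conditional Hardy–Weinberg test.

    Conditions on the observed allele counts and sums the probabilities of
    all heterozygote counts no more probable than the observed one; the
    two-sided exact test used for variant QC (applied to hard-called
    genotypes).
    """
    for c in (n_AA, n_Aa, n_aa):
        if c < 0 or c != int(c):
            raise ValueError("genotype counts must be non-negative integers")
    n = n_AA + n_Aa + n_aa
    if n == 0:
        raise ValueError("at least one genotype required")
    if n >= _MAX_LGAMMA:
        raise ValueError(f"exact test supported for totals < {_MAX_LGAMMA}")
    n_a = 2 * n_AA + n_Aa
    h_vals, probs = _het_log_probs(n, min(n_a, 2 * n - n_a))
    p_obs = probs[np.searchsorted(h_vals, n_Aa)]
    # tolerance guards against float ties in the 'no more probable' rule
    p = probs[probs <= p_obs * (1.0 + 1e-12)].sum()
    return float(min(p, 1.0))


def apply_variant_qc(
    geno: GenotypeMatrix, rules: QCRules | None = None
) -> tuple[GenotypeMatrix, pd.DataFrame]:
    """Remove variants failing missingness, Hardy–Weinberg (on dosages
    hard-called by rounding) or the graded INFO filter.

    Returns the filtered matrix (variant order preserved) and a removal
    log with one row per removed variant. A variant failing several rules
    is logged under the first failing rule in the order missingness, hwe,
    info.
    """
    rules = rules or QCRules()
    D = geno.dosages
    n, m = D.shape
    missing = np.isnan(D)
    miss_rate = missing.mean(axis=0)

    reasons: list[tuple[str, str]] = []
    keep = np.ones(m, dtype=bool)
    hard = np.rint(D)  # NaN stays NaN
    for j in range(m):
        vid = geno.variants["variant_id"].iloc[j]
        if miss_rate[j] > rules.max_missingness:
            keep[j] = False
            reasons.append((vid, "missingness"))
            continue
        calls = hard[~missing[:, j], j].astype(int)
        n_aa = int((calls == 0).sum())
        n_het = int((calls == 1).sum())
        n_AA = int((calls == 2).sum())
        if calls.size and hwe_exact_test(n_AA, n_het, n_aa) < rules.hwe_p_floor:
            keep[j] = False
            reasons.append((vid, "hwe"))
            continue
        maf = float(geno.variants["maf"].iloc[j])
        info = float(geno.variants["info"].iloc[j])
        if not graded_info_filter(min(max(maf, 1e-9), 0.5), min(info, 1.0), rules):
            keep[j] = False
            reasons.append((vid, "info"))
    log = pd.DataFrame(reasons, columns=["variant_id", "reason"])
    return geno.subset_variants(keep), log


def prune_related(pairs: KinshipPairs, threshold: float) -> set:
    """Iteratively drop the individual with the most remaining
    above-threshold relationships (ties: remove the lowest id) until no
    pair exceeds the threshold; returns the surviving ids."""
    if threshold <= 0:
        raise ValueError("threshold must be > 0")
    above = pairs.pairs[pairs.pairs["kinship"] > threshold]
    adj: dict = {}
    ids = set(pairs.pairs["id_a"]) | set(pairs.pairs["id_b"])
    for a, b in zip(above["id_a"], above["id_b"]):
        adj.setdefault(a, set()).add(b)
        adj.setdefault(b, set()).add(a)
    kept = set(ids)
    while True:
        degrees = {i: len(nbrs & kept) for i, nbrs in adj.items() if i in kept}
        degrees = {i: d for i, d in degrees.items() if d > 0}
        if not degrees:
            return kept
        max_d = max(degrees.values())
        victim = min(i for i, d in degrees.items() if d == max_d)
        kept.discard(victim)


def recode_traits(raw: pd.DataFrame) -> pd.DataFrame:
    """Apply the standard trait recodings.

    - ``income``: categorical codes 1..5 map to the printed
      pounds-sterling values; -1 (do not know) and -3 (prefer not to
      answer) become missing; any other code is an error.
    - ``brothers``/``sisters``: summed to ``siblings``; missing if either
      is missing.
    - ``birth_north``/``birth_east``: values below zero become missing.

    Columns not recognized are passed through unchanged.
    """
    out = raw.copy()
    if "income" in out.columns:
        inc = out["income"]
        valid = set(INCOME_MIDPOINTS) | _INCOME_MISSING_CODES
        bad = inc.dropna()[~inc.dropna().isin(valid)]
        if len(bad):
            raise ValueError(f"unknown income categories: {sorted(bad.unique())}")
        out["income"] = inc.map(INCOME_MIDPOINTS).astype(float)
    if {"brothers", "sisters"} <= set(out.columns):
        out["siblings"] = out["brothers"] + out["sisters"]  # NaN propagates
        out = out.drop(columns=["brothers", "sisters"])
    for col in ("birth_north", "birth_east"):
        if col in out.columns:
            vals = out[col].astype(float)
            out[col] = vals.where(vals >= 0)
    return out
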