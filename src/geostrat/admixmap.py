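"""Ancestry-mixture estimation and regional phenotype inference.

Each individual's feature profile (here, a dosage profile; real
haplotype-painting copying vectors fit the same shape) is decomposed as a
non-negative combination of regional reference profiles. Stacking the
mixture rows into A, regional phenotype means B are recovered from
individual phenotypes C by least squares on A B = C, with percentile
bootstrap confidence intervals over individuals. Individual-level
mixtures may be unidentifiable for near-collinear panels; the regional
averages remain meaningful, which is the level at which inference is
made.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import nnls

__all__ = [
    "ReferencePanel",
    "AdmixtureMatrix",
    "RegionalEstimate",
    "nnls_mixture",
    "estimate_admixture",
    "regional_phenotype_solve",
    "bootstrap_regional_ci",
]


@dataclass
class ReferencePanel:
    """K regional profiles over M features (rows = regions)."""

    labels: list[str]
    profiles: np.ndarray  # (K, M)

    def __post_init__(self) -> None:
        self.profiles = np.asarray(self.profiles, dtype=float)
        if self.profiles.ndim != 2 or self.profiles.shape[0] != len(self.labels):
            raise ValueError("profiles must be K x M with one row per label")
        if not np.isfinite(self.profiles).all():
            raise ValueError("panel profiles must be finite")

    @property
    def k(self) -> int:
        return self.profiles.shape[0]

    def to_tsv(self, path: str) -> None:
        pd.DataFrame(self.profiles, index=self.labels).to_csv(path, sep="\t")

    @classmethod
    def from_tsv(cls, path: str) -> "ReferencePanel":
        df = pd.read_csv(path, sep="\t", index_col=0)
        return cls(labels=list(df.index), profiles=df.to_numpy())


@dataclass
class AdmixtureMatrix:
    """Row-stochastic N x K mixture fractions."""

    fractions: np.ndarray
    labels: list[str]

    def __post_init__(self) -> None:
        A = np.asarray(self.fractions, dtype=float)
        if (A < -1e-12).any():
            raise ValueError("mixture fractions must be non-negative")
        if not np.allclose(A.sum(axis=1), 1.0, atol=1e-8):
            raise ValueError("mixture rows must sum to 1")
        self.fractions = A


@dataclass
class RegionalEstimate:
    labels: list[str]
    estimate: np.ndarray  # (K,), trait units
    ci_low: np.ndarray
    ci_high: np.ndarray
    n_boot: int

    def frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "region": self.labels,
                "estimate": self.estimate,
                "ci_low": self.ci_low,
                "ci_high": self.ci_high,
            }
        )


def nnls_mixture(x: np.ndarray, panel: ReferencePanel) -> np.ndarray:
    """Non-negative least-squares mixture weights of one profile against
    the panel, renormalized to sum to 1.

    Solves argmin_w ||x - w^T P||^2 subject to w >= 0 (Lawson-Hanson
    active set), then rescales. An all-zero solution (possible when the
    profile is orthogonal to every panel row) returns the uninformative
    uniform mixture with a warning.
    """
    x = np.asarray(x, dtype=float)
    if x.size == 0:
        raise ValueError("empty profile")
    if x.size != panel.profiles.shape[1]:
        raise ValueError("profile length does not match panel features")
    w, _ = nnls(panel.profiles.T, x)
    total = w.sum()
    if total <= 0:
        warnings.warn("all-zero NNLS solution; returning uniform mixture")
        return np.full(panel.k, 1.0 / panel.k)
    return w / total


def estimate_admixture(profiles: np.ndarray, panel: ReferencePanel) -> AdmixtureMatrix:
    """Row-wise NNLS mixture estimation for an N x M profile matrix."""
    A = np.vstack([nnls_mixture(row, panel) for row in np.asarray(profiles, dtype=float)])
    return AdmixtureMatrix(fractions=A, labels=list(panel.labels))


def regional_phenotype_solve(A: AdmixtureMatrix | np.ndarray, C: np.ndarray) -> np.ndarray:
    """Least-squares solve of A B = C for regional phenotype means B;
    equals (A^T A)^-1 A^T C when A^T A is invertible, with a pseudoinverse
    fallback (and warning) for collinear mixtures.

    Rows of C that are missing are dropped together with their A rows.
    """
    M = A.fractions if isinstance(A, AdmixtureMatrix) else np.asarray(A, dtype=float)
    C = np.asarray(C, dtype=float)
    if M.shape[0] != C.size:
        raise ValueError("phenotype vector must align with admixture rows")
    obs = np.isfinite(C)
    M, C = M[obs], C[obs]
    n, k = M.shape
    if n < k:
        raise ValueError(f"underdetermined: {n} individuals for {k} regions")
    AtA = M.T @ M
    AtC = M.T @ C
    try:
        return np.linalg.solve(AtA, AtC)
    except np.linalg.LinAlgError:
        warnings.warn("A^T A singular; using pseudoinverse")
        return np.linalg.pinv(AtA) @ AtC


def bootstrap_regional_ci(
    A: AdmixtureMatrix | np.ndarray,
    C: np.ndarray,
    n_boot: int = 1000,
    seed: int = 0,
) -> RegionalEstimate:
    """Percentile bootstrap (resampling individuals with replacement) for
    the regional phenotype means."""
    if n_boot < 100:
        raise ValueError("n_boot must be >= 100")
    M = A.fractions if isinstance(A, AdmixtureMatrix) else np.asarray(A, dtype=float)
    labels = A.labels if isinstance(A, AdmixtureMatrix) else [f"region{k+1}" for k in range(M.shape[1])]
    C = np.asarray(C, dtype=float)
    obs = np.isfinite(C)
    M, C = M[obs], C[obs]
    n, k = M.shape
    point = regional_phenotype_solve(M, C)
    rng = np.random.default_rng(seed)
    boots = np.empty((n_boot, k))
    n_singular = 0
    for b in range(n_boot):
        idx = rng.integers(0, n, size=n)
        with warnings.catch_warnings(record=True) as caught:
            warnings.simplefilter("always")
            boots[b] = regional_phenotype_solve(M[idx], C[idx])
            n_singular += any("singular" in str(c.message) for c in caught)
    ci_low = np.percentile(boots, 2.5, axis=0)
    ci_high = np.percentile(boots, 97.5, axis=0)
    if n_singular:
        warnings.warn(f"{n_singular}/{n_boot} bootstrap replicates used a pseudoinverse")
    return RegionalEstimate(
        labels=list(labels), estimate=point, ci_low=ci_low, ci_high=ci_high, n_boot=n_boot
    )
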