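"""Genetic relatedness: HWE testing, LD pruning, GRM construction.

Isolated cohorts carry pervasive close kinship, which inflates association
statistics unless modeled.  The pipeline here mirrors standard practice:
select a well-behaved variant set (common, HWE-consistent, LD-pruned), build
the centered genetic relatedness matrix K = Xc Xc' / p, and hand it to the
mixed model as the covariance of the polygenic random effect.
"""

from __future__ import annotations

from collections import deque
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .containers import GenotypeMatrix


def hwe_test(n_homref: int, n_het: int, n_homalt: int) -> float:
    """1-df chi-square goodness-of-fit test against Hardy-Weinberg proportions.

    Expectations use the sample allele frequency; monomorphic sites return
    P = 1 by convention.
    """
    counts = np.array([n_homref, n_het, n_homalt], float)
    if (counts < 0).any():
        raise ValueError("genotype counts must be non-negative")
    n = counts.sum()
    if n == 0:
        raise ValueError("no genotypes")
    f = (2 * n_homalt + n_het) / (2 * n)
    if f == 0 or f == 1:
        return 1.0
    expected = n * np.array([(1 - f) ** 2, 2 * f * (1 - f), f**2])
    chi2 = float(((counts - expected) ** 2 / expected).sum())
    return float(stats.chi2.sf(chi2, df=1))


def hwe_test_matrix(gm: GenotypeMatrix) -> np.ndarray:
    """Vectorized HWE P-value per site (missing genotypes excluded)."""
    d = gm.dosages
    n0 = (d == 0).sum(axis=0).astype(float)
    n1 = (d == 1).sum(axis=0).astype(float)
    n2 = (d == 2).sum(axis=0).astype(float)
    n = n0 + n1 + n2
    with np.errstate(divide="ignore", invalid="ignore"):
        f = (2 * n2 + n1) / (2 * n)
        e0 = n * (1 - f) ** 2
        e1 = n * 2 * f * (1 - f)
        e2 = n * f**2
        chi2 = (n0 - e0) ** 2 / e0 + (n1 - e1) ** 2 / e1 + (n2 - e2) ** 2 / e2
    p = stats.chi2.sf(chi2, df=1)
    mono = (f == 0) | (f == 1) | (n == 0)
    return np.where(mono, 1.0, p)


def ld_r2(g1: np.ndarray, g2: np.ndarray) -> float:
    """Squared Pearson correlation of two dosage vectors; missing pairwise-deleted."""
    g1 = np.asarray(g1, float)
    g2 = np.asarray(g2, float)
    if g1.shape != g2.shape:
        raise ValueError("dosage vectors must share length")
    ok = (g1 >= 0) & (g2 >= 0)
    a, b = g1[ok], g2[ok]
    if len(a) < 2 or a.std() == 0 or b.std() == 0:
        raise ValueError("LD undefined for (near-)constant dosage vectors")
    r = np.corrcoef(a, b)[0, 1]
    return float(r * r)


def _mean_imputed_centered(gm: GenotypeMatrix, idx: np.ndarray) -> np.ndarray:
    """Dosage block with missing cells set to the site mean, then mean-centered."""
    X = gm.dosages[:, idx].astype(float)
    miss = X < 0
    X[miss] = np.nan
    mean = np.nanmean(X, axis=0)
    inds = np.where(miss)
    X[inds] = mean[inds[1]]
    return X - mean


def select_grm_variants(
    calls: GenotypeMatrix,
    min_maf: float = 0.01,
    hwe_p_min: float = 1e-5,
    prune_r2: float = 0.2,
    prune_window: int = 50,
) -> np.ndarray:
    """Pick well-behaved variants for relatedness estimation.

    Retains sites with MAF >= min_maf (rare variants are excluded: sparse,
    common-enriched sets give the most stable kinship coefficients) and HWE
    P >= hwe_p_min, then LD-prunes greedily left-to-right: a site is dropped
    when its r^2 with any retained site inside the trailing window exceeds
    ``prune_r2``.  Returns retained site indices into ``calls``.
    """
    maf = calls.mafs()
    hwe_p = hwe_test_matrix(calls)
    candidates = np.flatnonzero((maf >= min_maf) & (hwe_p >= hwe_p_min))
    if len(candidates) == 0:
        raise ValueError("no variants pass the GRM MAF/HWE filters")

    X = _mean_imputed_centered(calls, candidates)
    norms = np.sqrt((X**2).sum(axis=0))
    keep: list[int] = []
    window: deque[int] = deque()  # retained sites within prune_window positions
    for j in range(len(candidates)):
        if norms[j] == 0:
            continue
        while window and j - window[0] > prune_window:
            window.popleft()
        if window:
            w = list(window)
            r = (X[:, w].T @ X[:, j]) / (norms[w] * norms[j])
            if (r**2 > prune_r2).any():
                continue
        keep.append(j)
        window.append(j)
    if not keep:
        raise ValueError("LD pruning removed every candidate variant")
    return candidates[np.array(keep)]


@dataclass
class KinshipMatrix:
    """Centered genetic relatedness matrix K = Xc Xc' / p.

    ``values`` is used whole by the mixed model (no thresholding).  For
    close-relative detection, :meth:`pi_hat` rescales to a correlation-like
    matrix whose off-diagonal entries estimate the genotype correlation
    between samples (duplicates ~ 1, first-degree relatives ~ 0.5).
    """

    values: np.ndarray
    samples: list[str] = field(default_factory=list)
    n_variants: int = 0

    def __post_init__(self) -> None:
        K = np.asarray(self.values, float)
        if K.ndim != 2 or K.shape[0] != K.shape[1]:
            raise ValueError("kinship matrix must be square")
        if not np.allclose(K, K.T, atol=1e-8):
            raise ValueError("kinship matrix must be symmetric")
        self.values = K

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    def pi_hat(self) -> np.ndarray:
        d = np.sqrt(np.clip(np.diag(self.values), 1e-12, None))
        return self.values / np.outer(d, d)

    def close_relative_counts(self, threshold: float = 0.1) -> np.ndarray:
        """Per-sample number of relatives with pi-hat above ``threshold``."""
        P = self.pi_hat().copy()
        np.fill_diagonal(P, 0.0)
        return (P > threshold).sum(axis=1)


def centered_grm(gm: GenotypeMatrix, site_idx: np.ndarray | None = None) -> KinshipMatrix:
    """Centered GRM over the given sites (default: all).

    K = Xc Xc' / p with each site mean-centered; missing genotypes are
    imputed to the site mean before centering (so they contribute nothing).
    """
    idx = np.arange(gm.n_sites) if site_idx is None else np.asarray(site_idx, np.intp)
    if len(idx) < 1:
        raise ValueError("need at least one site")
    Xc = _mean_imputed_centered(gm, idx)
    K = (Xc @ Xc.T) / len(idx)
    return KinshipMatrix(values=K, samples=list(gm.samples), n_variants=len(idx))


def mac_filter(gm: GenotypeMatrix, min_mac_exclusive: int = 2) -> np.ndarray:
    """Indices of sites with minor allele count strictly above the cut.

    The default (MAC > 2) removes singletons and doubletons, whose genotype
    quality at very low depth is too poor for single-point association.
    """
    return np.flatnonzero(gm.macs() > min_mac_exclusive)
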