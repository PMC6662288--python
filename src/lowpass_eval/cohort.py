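"""Synthetic cohort generator for benchmarking low-depth sequencing designs.

Emulates the data-generating layers of a very low-depth WGS association
study so that every downstream evaluation stage (call-set comparison,
site quality, mixed-model association, signal cross-referencing) can be
exercised against a known truth without any external download:

* a diploid cohort in Hardy-Weinberg equilibrium with optional family-block
  relatedness,
* shotgun sequencing at mean depth ``lambda`` with per-read error ``epsilon``
  and genotype-likelihood calling,
* an imputation channel with per-MAF-bin genotype accuracy,
* a chip-typed subset of common sites,
* quantitative traits with configurable causal variants, a polygenic
  component with covariance given by the kinship matrix, and iid noise.

All generators are bit-reproducible given (seed, config).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from ._utils import child_rng
from .containers import MISSING, GenotypeMatrix


# ---------------------------------------------------------------------------
# configuration types
# ---------------------------------------------------------------------------

@dataclass
class CohortConfig:
    """Cohort dimensions, allele-frequency spectrum and relatedness structure.

    ``afs_shape`` holds the Beta(a, b) parameters of the minor-allele-frequency
    sampler (folded, truncated below at 1/(2N)); the default Beta(0.2, 4)
    yields a rare-skewed spectrum in which most segregating sites have
    MAF < 1%, as seen in large sequencing studies.  A degenerate spectrum can
    be requested with ``point_mass``.

    ``family_blocks`` is a list of (block_size, relatedness) pairs; each block
    is a group of samples whose pairwise genotype correlation equals the
    relatedness coefficient in expectation (0.5 ~ first-degree relatives).
    Samples are assigned to blocks from the front of the cohort.
    """

    n_samples: int
    n_sites: int
    afs_shape: tuple[float, float] = (0.2, 4.0)
    point_mass: float | None = None
    family_blocks: list[tuple[int, float]] = field(default_factory=list)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_samples < 2:
            raise ValueError("n_samples must be >= 2")
        if self.n_sites < 1:
            raise ValueError("n_sites must be >= 1")
        a, b = self.afs_shape
        if a <= 0 or b <= 0:
            raise ValueError("afs_shape parameters must be positive")
        if self.point_mass is not None and not 0 < self.point_mass <= 0.5:
            raise ValueError("point_mass must lie in (0, 0.5]")
        for size, r in self.family_blocks:
            if size < 2:
                raise ValueError("family block size must be >= 2")
            if not 0 <= r <= 0.5:
                raise ValueError("relatedness coefficients must lie in [0, 0.5]")
        if sum(size for size, _ in self.family_blocks) > self.n_samples:
            raise ValueError("family blocks exceed cohort size")


@dataclass
class SequencingParams:
    """Shotgun layer: reads/site/sample ~ Poisson(mean_depth), miscall prob error_rate."""

    mean_depth: float
    error_rate: float = 0.01
    af_weighted_prior: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.mean_depth < 0:
            raise ValueError("mean_depth must be >= 0")
        if not 0 <= self.error_rate < 0.5:
            raise ValueError("error_rate must lie in [0, 0.5)")


@dataclass
class PileupSummary:
    """Per (sample, site) read evidence: counts of ref- and alt-supporting reads."""

    ref_reads: np.ndarray
    alt_reads: np.ndarray
    sites: pd.DataFrame
    samples: list[str]

    def __post_init__(self) -> None:
        if self.ref_reads.shape != self.alt_reads.shape:
            raise ValueError("ref/alt read matrices must share a shape")
        if (self.ref_reads < 0).any() or (self.alt_reads < 0).any():
            raise ValueError("read counts must be non-negative")


@dataclass
class ImputationChannel:
    """Per-MAF-bin error channel standing in for haplotype-based refinement.

    ``bin_edges`` are MAF breakpoints partitioning (0, 0.5]; a site with truth
    MAF m falls in bin i when edges[i] <= m < edges[i+1] (last bin closed).
    ``accuracy`` is the probability the channel emits the truth genotype in
    that bin; otherwise one of the two wrong genotypes is drawn uniformly.
    ``fill_rate`` is the probability a truth site absent from the raw call set
    is restored by imputation.  Output has a 100% call rate.

    Default accuracies are per-cell genotype concordances: ~0.97 for
    low-frequency sites (the headline calibration figure for MAF >= 1%) and
    higher at the extremes — rare sites are hom-ref dominated so their
    cell-level concordance is high even though their minor alleles impute
    poorly (the derived minor-allele concordance lands near 0.5), and common
    sites are imputed almost perfectly.
    """

    bin_edges: Sequence[float] = (0.0, 0.01, 0.05, 0.5)
    accuracy: Sequence[float] = (0.99, 0.97, 0.995)
    fill_rate: Sequence[float] = (0.5, 0.95, 1.0)

    def __post_init__(self) -> None:
        if len(self.accuracy) != len(self.bin_edges) - 1:
            raise ValueError("need one accuracy per bin")
        if len(self.fill_rate) != len(self.bin_edges) - 1:
            raise ValueError("need one fill rate per bin")
        if any(not 0 <= p <= 1 for p in list(self.accuracy) + list(self.fill_rate)):
            raise ValueError("probabilities must lie in [0, 1]")
        edges = np.asarray(self.bin_edges, float)
        if (np.diff(edges) <= 0).any():
            raise ValueError("bin_edges must be strictly increasing")
        if edges[0] > 0 or edges[-1] < 0.5:
            raise ValueError("bins must cover (0, 0.5]")

    def bin_of(self, maf: np.ndarray) -> np.ndarray:
        edges = np.asarray(self.bin_edges, float)
        idx = np.searchsorted(edges, maf, side="right") - 1
        return np.clip(idx, 0, len(self.accuracy) - 1)


@dataclass
class TraitConfig:
    """Quantitative trait: sparse causal effects + polygenic term + iid noise.

    Effect sizes apply to variance-standardized causal dosages, so each
    beta_j^2 is that variant's trait-variance share; ``polygenic_fraction``
    scales a random effect with covariance prop. to the kinship matrix;
    ``residual_variance`` defaults so the total variance is 1 in expectation.
    """

    causal_sites: Sequence[int] = ()
    effect_sizes: Sequence[float] = ()
    polygenic_fraction: float = 0.0
    residual_variance: float | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.causal_sites) != len(self.effect_sizes):
            raise ValueError("one effect size per causal site")
        explained = float(np.sum(np.square(self.effect_sizes))) + self.polygenic_fraction
        if self.polygenic_fraction < 0:
            raise ValueError("polygenic_fraction must be >= 0")
        if self.residual_variance is None:
            if explained > 1:
                raise ValueError("variance fractions exceed 1; set residual_variance")
            self.residual_variance = 1.0 - explained
        if self.residual_variance < 0:
            raise ValueError("residual_variance must be >= 0")


# ---------------------------------------------------------------------------
# generative operations
# ---------------------------------------------------------------------------

def sample_allele_frequencies(config: CohortConfig) -> np.ndarray:
    """Draw per-site minor allele frequencies in (0, 0.5].

    Beta(a, b) draws folded to the minor allele and truncated below at
    1/(2N) by rejection, so every site is potentially segregating.
    """
    rng = child_rng(config.seed, 0)
    if config.point_mass is not None:
        return np.full(config.n_sites, config.point_mass)
    a, b = config.afs_shape
    floor = 1.0 / (2 * config.n_samples)
    out = np.empty(config.n_sites)
    filled = 0
    while filled < config.n_sites:
        draw = rng.beta(a, b, size=2 * (config.n_sites - filled))
        draw = np.minimum(draw, 1.0 - draw)
        draw = draw[(draw >= floor) & (draw <= 0.5)]
        take = min(len(draw), config.n_sites - filled)
        out[filled:filled + take] = draw[:take]
        filled += take
    return out


def _default_sites(n_sites: int, chrom: str = "1", spacing: int = 1000) -> pd.DataFrame:
    """Evenly spaced synthetic SNVs on one chromosome, alternating allele pairs."""
    refs = np.array(["A", "C", "G", "T"])[np.arange(n_sites) % 4]
    alts = np.array(["G", "T", "A", "C"])[np.arange(n_sites) % 4]  # transitions
    flip = np.arange(n_sites) % 3 == 2  # sprinkle transversions
    alts = np.where(flip, np.array(["C", "G", "T", "A"])[np.arange(n_sites) % 4], alts)
    return pd.DataFrame(
        {
            "chrom": chrom,
            "pos": np.arange(1, n_sites + 1) * spacing,
            "ref": refs,
            "alt": alts,
        }
    )


def simulate_genotypes(
    afs: np.ndarray,
    config: CohortConfig,
    sites: pd.DataFrame | None = None,
) -> GenotypeMatrix:
    """Simulate truth genotypes under HWE with optional family-block relatedness.

    Unrelated samples draw dosage ~ Binomial(2, f) per site.  Within a family
    block with relatedness r, each of a member's two alleles copies a shared
    block allele with probability sqrt(r) (else a fresh Bernoulli(f) draw),
    which makes the within-block genotype correlation equal r in expectation.
    Truth has no missingness.
    """
    afs = np.asarray(afs, float)
    if (afs <= 0).any() or (afs > 0.5).any():
        raise ValueError("allele frequencies must lie in (0, 0.5]")
    if len(afs) != config.n_sites:
        raise ValueError("afs length must equal n_sites")
    rng = child_rng(config.seed, 1)
    n, p = config.n_samples, config.n_sites

    # two allele draws per sample per site
    hap1 = rng.random((n, p)) < afs
    hap2 = rng.random((n, p)) < afs

    start = 0
    for size, r in config.family_blocks:
        members = slice(start, start + size)
        start += size
        if r == 0:
            continue
        phi = np.sqrt(r)
        shared1 = rng.random(p) < afs
        shared2 = rng.random(p) < afs
        copy1 = rng.random((size, p)) < phi
        copy2 = rng.random((size, p)) < phi
        hap1[members] = np.where(copy1, shared1, hap1[members])
        hap2[members] = np.where(copy2, shared2, hap2[members])

    dosages = (hap1.astype(np.int8) + hap2.astype(np.int8))
    if sites is None:
        sites = _default_sites(p)
    samples = [f"S{i:05d}" for i in range(n)]
    return GenotypeMatrix(samples=samples, sites=sites, dosages=dosages)


def simulate_reads(truth: GenotypeMatrix, params: SequencingParams) -> PileupSummary:
    """Shotgun-sequence the truth matrix.

    Per cell: total reads ~ Poisson(mean_depth); each read supports the alt
    allele with probability {eps, 1/2, 1-eps} for truth dosage {0, 1, 2}.
    """
    rng = child_rng(params.seed, 2)
    depth = rng.poisson(params.mean_depth, size=truth.dosages.shape)
    p_alt = np.choose(truth.dosages, [params.error_rate, 0.5, 1.0 - params.error_rate])
    alt = rng.binomial(depth, p_alt)
    return PileupSummary(
        ref_reads=(depth - alt).astype(np.int32),
        alt_reads=alt.astype(np.int32),
        sites=truth.sites.copy(),
        samples=list(truth.samples),
    )


def genotype_log_likelihoods(
    ref_reads: np.ndarray, alt_reads: np.ndarray, error_rate: float
) -> np.ndarray:
    """Per-cell log P(reads | g) for g in {0,1,2}, stacked on the last axis."""
    eps = max(error_rate, 1e-12)  # guard log(0) for error-free simulations
    p_alt = np.array([eps, 0.5, 1.0 - eps])
    lp = np.log(p_alt)
    lq = np.log1p(-p_alt)
    return (
        alt_reads[..., None] * lp[None, None, :]
        + ref_reads[..., None] * lq[None, None, :]
    )


def call_from_pileup(
    pileup: PileupSummary,
    params: SequencingParams,
    allele_freqs: np.ndarray | None = None,
) -> GenotypeMatrix:
    """Genotype-likelihood caller.

    Picks argmax_g P(reads | g); ties break toward the smaller dosage for
    determinism.  Cells with zero reads are missing.  Sites whose called
    genotypes carry no alt allele in any sample are dropped (never reported
    by a variant caller).  With ``params.af_weighted_prior`` and supplied
    allele frequencies, HWE priors are added to the likelihoods.
    """
    log_prior = None
    if params.af_weighted_prior:
        if allele_freqs is None:
            raise ValueError("af_weighted_prior requires allele_freqs")
        f = np.asarray(allele_freqs, float)
        prior = np.stack([(1 - f) ** 2, 2 * f * (1 - f), f**2], axis=-1)
        log_prior = np.log(np.maximum(prior, 1e-300))

    n, p = pileup.ref_reads.shape
    calls = np.empty((n, p), dtype=np.int8)
    # chunk over sites: the 3-genotype likelihood cube would be 3x the pileup
    chunk = max(1, int(4e6 // max(n, 1)))
    for lo in range(0, p, chunk):
        hi = min(lo + chunk, p)
        ll = genotype_log_likelihoods(
            pileup.ref_reads[:, lo:hi], pileup.alt_reads[:, lo:hi], params.error_rate
        )
        if log_prior is not None:
            ll += log_prior[None, lo:hi, :]
        # argmax returns the FIRST maximal index -> ties already favor smaller dosage
        calls[:, lo:hi] = np.argmax(ll, axis=-1).astype(np.int8)
    covered = (pileup.ref_reads + pileup.alt_reads) > 0
    calls[~covered] = MISSING
    gm = GenotypeMatrix(
        samples=list(pileup.samples), sites=pileup.sites.copy(), dosages=calls
    )
    has_alt = np.where(gm.dosages > 0, gm.dosages, 0).sum(axis=0) > 0
    return gm.take_sites(np.flatnonzero(has_alt))


def apply_imputation_channel(
    calls: GenotypeMatrix,
    truth: GenotypeMatrix,
    channel: ImputationChannel,
    seed: int = 0,
) -> GenotypeMatrix:
    """Refine+impute stand-in: fill every cell, perturbing truth per MAF bin.

    Each output cell equals the truth genotype with its bin's accuracy;
    otherwise one of the two other genotypes, uniformly.  Sites absent from
    the raw call set are restored with the bin's fill rate.  The output has a
    100% call rate — the contract of a refined-plus-imputed data set.
    """
    rng = child_rng(seed, 3)
    if calls.samples != truth.samples:
        raise ValueError("calls and truth must share samples")
    truth_keys = pd.MultiIndex.from_frame(truth.sites[["chrom", "pos", "ref", "alt"]])
    call_keys = pd.MultiIndex.from_frame(calls.sites[["chrom", "pos", "ref", "alt"]])
    if not call_keys.isin(truth_keys).all():
        raise ValueError("call set contains sites outside the truth universe")

    maf = truth.mafs()
    bins = channel.bin_of(maf)
    acc = np.asarray(channel.accuracy, float)[bins]
    fill = np.asarray(channel.fill_rate, float)[bins]

    present = truth_keys.isin(call_keys)
    restored = present | (rng.random(truth.n_sites) < fill)
    keep = np.flatnonzero(restored)

    emit_truth = rng.random(truth.dosages.shape) < acc[None, :]
    # wrong genotype: shift truth by +1 or +2 (mod 3) — uniform over the two others
    shift = rng.integers(1, 3, size=truth.dosages.shape, dtype=np.int8)
    wrong = ((truth.dosages + shift) % 3).astype(np.int8)
    out = np.where(emit_truth, truth.dosages, wrong).astype(np.int8)
    return GenotypeMatrix(
        samples=list(truth.samples),
        sites=truth.sites.iloc[keep].reset_index(drop=True),
        dosages=out[:, keep],
    )


def make_chip_subset(
    truth: GenotypeMatrix,
    n_chip_sites: int,
    maf_floor: float = 0.01,
    seed: int = 0,
    chip_error_rate: float = 0.0,
) -> GenotypeMatrix:
    """Genotyping-array stand-in: common sites sampled preferentially by MAF.

    Sites with truth MAF >= maf_floor are sampled without replacement with
    probability proportional to MAF (arrays target common variation), then
    genotypes are copied from truth, miscalled with ``chip_error_rate``
    (default 0: arrays are treated as error-free benchmarks).
    """
    rng = child_rng(seed, 4)
    maf = truth.mafs()
    eligible = np.flatnonzero(maf >= maf_floor)
    if n_chip_sites > len(eligible):
        raise ValueError(
            f"requested {n_chip_sites} chip sites but only {len(eligible)} have "
            f"MAF >= {maf_floor}"
        )
    w = maf[eligible]
    chosen = rng.choice(eligible, size=n_chip_sites, replace=False, p=w / w.sum())
    chosen.sort()
    chip = truth.take_sites(chosen)
    if chip_error_rate > 0:
        flip = rng.random(chip.dosages.shape) < chip_error_rate
        shift = rng.integers(1, 3, size=chip.dosages.shape, dtype=np.int8)
        chip.dosages = np.where(flip, (chip.dosages + shift) % 3, chip.dosages).astype(
            np.int8
        )
    return chip


def simulate_phenotypes(
    truth: GenotypeMatrix,
    trait: TraitConfig,
    kinship: np.ndarray | None = None,
) -> np.ndarray:
    """Draw y = sum_j beta_j g~_j + u + e, standardized to unit total variance.

    Causal dosages are variance-standardized so beta_j^2 is the variant's
    variance share; u ~ MVN(0, polygenic_fraction * K / mean(diag K));
    e ~ N(0, residual_variance), iid.
    """
    rng = child_rng(trait.seed, 5)
    n = truth.n_samples
    y = np.zeros(n)
    if len(trait.causal_sites):
        idx = np.asarray(trait.causal_sites, dtype=np.intp)
        if idx.min() < 0 or idx.max() >= truth.n_sites:
            raise ValueError("causal site index out of range")
        g = truth.dosages[:, idx].astype(float)
        sd = g.std(axis=0, ddof=0)
        if (sd == 0).any():
            raise ValueError("causal site is monomorphic in this cohort")
        g = (g - g.mean(axis=0)) / sd
        y += g @ np.asarray(trait.effect_sizes, float)
    if trait.polygenic_fraction > 0:
        if kinship is None:
            raise ValueError("polygenic_fraction > 0 requires a kinship matrix")
        K = np.asarray(kinship, float)
        scale = trait.polygenic_fraction / max(np.mean(np.diag(K)), 1e-12)
        # jitter keeps the Cholesky stable for rank-deficient K
        L = np.linalg.cholesky(scale * K + 1e-10 * np.eye(n))
        y += L @ rng.standard_normal(n)
    y += np.sqrt(trait.residual_variance) * rng.standard_normal(n)
    return y


# ---------------------------------------------------------------------------
# QUAL score model for VCF export
# ---------------------------------------------------------------------------

def default_qual_model(gm: GenotypeMatrix, rng: np.random.Generator) -> np.ndarray:
    """Phred-like site quality: grows with minor allele evidence, with noise."""
    mac = gm.macs().astype(float)
    return np.round(30.0 + 60.0 * np.log10(1.0 + mac) + rng.normal(0, 3, gm.n_sites), 2)


QualModel = Callable[[GenotypeMatrix, np.random.Generator], np.ndarray]
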