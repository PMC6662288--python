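"""Core in-memory containers shared across the toolkit.

A call set is a :class:`GenotypeMatrix`: a samples x sites matrix of diploid
alternate-allele dosages (0/1/2, -1 for missing) together with a site table
(chrom, pos, ref, alt and optional annotations) held as a pandas DataFrame.
Truth, low-depth, chip and imputed sets all share this container so every
comparison operates on one representation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, NamedTuple, Sequence

import numpy as np
import pandas as pd

MISSING = np.int8(-1)

SITE_COLUMNS = ["chrom", "pos", "ref", "alt"]

_NUCLEOTIDES = frozenset("ACGT")


class SiteKey(NamedTuple):
    """Biallelic SNV identity: chromosome, 1-based position, ref and alt allele."""

    chrom: str
    pos: int
    ref: str
    alt: str


def validate_sites(sites: pd.DataFrame) -> pd.DataFrame:
    """Check a site table: SNV alleles, ref != alt, unique keys. Returns the table."""
    missing = [c for c in SITE_COLUMNS if c not in sites.columns]
    if missing:
        raise ValueError(f"site table missing columns: {missing}")
    if len(sites) == 0:
        return sites
    ref = sites["ref"].astype(str)
    alt = sites["alt"].astype(str)
    bad = ~(ref.isin(_NUCLEOTIDES) & alt.isin(_NUCLEOTIDES))
    if bad.any():
        raise ValueError(f"{int(bad.sum())} sites are not single-nucleotide variants")
    if (ref == alt).any():
        raise ValueError("ref allele equals alt allele at some sites")
    keys = pd.MultiIndex.from_frame(sites[SITE_COLUMNS])
    if keys.has_duplicates:
        raise ValueError("duplicate (chrom, pos, ref, alt) keys in site table")
    return sites


@dataclass
class GenotypeMatrix:
    """Samples x sites diploid dosage matrix with its site table.

    Parameters
    ----------
    samples
        Sample identifiers, one per row of ``dosages``.
    sites
        DataFrame with at least chrom/pos/ref/alt, one row per column of
        ``dosages``.
    dosages
        int8 array of alternate-allele dosages in {0, 1, 2}; -1 marks a
        missing genotype.
    """

    samples: list[str]
    sites: pd.DataFrame
    dosages: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        self.dosages = np.asarray(self.dosages, dtype=np.int8)
        self.sites = self.sites.reset_index(drop=True)
        validate_sites(self.sites)
        if self.dosages.shape != (len(self.samples), len(self.sites)):
            raise ValueError(
                f"dosage shape {self.dosages.shape} does not match "
                f"{len(self.samples)} samples x {len(self.sites)} sites"
            )
        vals = self.dosages
        if vals.size and (vals.min() < -1 or vals.max() > 2):
            raise ValueError("dosages must lie in {-1, 0, 1, 2}")

    # -- shape ----------------------------------------------------------------
    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_sites(self) -> int:
        return len(self.sites)

    def site_keys(self) -> list[SiteKey]:
        return [SiteKey(*row) for row in self.sites[SITE_COLUMNS].itertuples(index=False)]

    # -- per-site statistics --------------------------------------------------
    def allele_numbers(self) -> np.ndarray:
        """AN per site: number of called alleles (2 x non-missing genotypes)."""
        return 2 * (self.dosages >= 0).sum(axis=0)

    def alt_counts(self) -> np.ndarray:
        """AC per site: alternate allele count among called genotypes."""
        d = self.dosages.astype(np.int64)
        return np.where(d >= 0, d, 0).sum(axis=0)

    def alt_freqs(self) -> np.ndarray:
        an = self.allele_numbers()
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(an > 0, self.alt_counts() / np.maximum(an, 1), np.nan)

    def mafs(self) -> np.ndarray:
        """Minor allele frequency per site (folded alt frequency)."""
        af = self.alt_freqs()
        return np.minimum(af, 1.0 - af)

    def macs(self) -> np.ndarray:
        """Minor allele count per site."""
        ac = self.alt_counts()
        an = self.allele_numbers()
        return np.minimum(ac, an - ac)

    def call_rates(self) -> np.ndarray:
        return (self.dosages >= 0).mean(axis=0)

    def site_stats(self) -> pd.DataFrame:
        """Site table augmented with mac, an, maf and call_rate columns."""
        out = self.sites.copy()
        out["an"] = self.allele_numbers()
        out["mac"] = self.macs()
        out["maf"] = self.mafs()
        out["call_rate"] = self.call_rates()
        return out

    # -- subsetting -----------------------------------------------------------
    def take_sites(self, idx: Sequence[int] | np.ndarray) -> "GenotypeMatrix":
        idx = np.asarray(idx, dtype=np.intp)
        return GenotypeMatrix(
            samples=list(self.samples),
            sites=self.sites.iloc[idx].reset_index(drop=True),
            dosages=self.dosages[:, idx],
        )

    def take_samples(self, ids: Iterable[str]) -> "GenotypeMatrix":
        pos = {s: i for i, s in enumerate(self.samples)}
        ids = list(ids)
        unknown = [s for s in ids if s not in pos]
        if unknown:
            raise KeyError(f"unknown sample ids: {unknown[:5]}")
        rows = np.array([pos[s] for s in ids], dtype=np.intp)
        return GenotypeMatrix(samples=ids, sites=self.sites, dosages=self.dosages[rows])

    def restrict_to(self, sites: pd.DataFrame) -> "GenotypeMatrix":
        """Subset to sites whose (chrom, pos, ref, alt) appear in ``sites``."""
        keys = pd.MultiIndex.from_frame(self.sites[SITE_COLUMNS])
        other = pd.MultiIndex.from_frame(sites[SITE_COLUMNS])
        return self.take_sites(np.flatnonzero(keys.isin(other)))

    def drop_monomorphic(self) -> "GenotypeMatrix":
        """Remove sites with no called minor allele (the field's convention)."""
        keep = np.flatnonzero(self.macs() > 0)
        return self.take_sites(keep)
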