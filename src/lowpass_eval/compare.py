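"""Call-set comparison: site matching, MAF-binned sensitivity/PPV/concordance.

The central question for a low-depth design is how much of the truth it
captures and how much of what it reports is real, and how both vary across
the minor-allele-frequency spectrum.  This module compares an evaluated call
set against a designated truth set (chip, exome, high-depth WGS, or simulator
truth) and produces per-MAF-bin tables of:

* capture rate (sensitivity): matched truth sites / all truth sites,
* positive predictive value: matched evaluated sites / all evaluated sites,
* genotype concordance over matched sites and shared samples,
* minor-allele (non-reference) concordance: concordance restricted to cells
  where either set carries at least one minor allele, which penalizes
  trivially concordant hom-ref calls,
* call rate of the evaluated set.

Binning convention: sensitivity bins by truth MAF, PPV by evaluated MAF
(the two axes answer different questions); the convention is recorded in the
report. Percentages are printed at one decimal, round half up.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._utils import round_half_up
from .containers import SITE_COLUMNS, GenotypeMatrix, validate_sites

# default MAF bin scheme; the first bin is selected by MAC, not MAF
SINGLETON_DOUBLETON = "singleton_doubleton"
RARE = "rare"
LOW_FREQUENCY = "low_frequency"
COMMON = "common"

DEFAULT_BINS = (SINGLETON_DOUBLETON, RARE, LOW_FREQUENCY, COMMON)


@dataclass
class BinScheme:
    """MAF bin scheme: a MAC cut for the singleton/doubleton class plus MAF edges.

    The default reproduces the standard reporting bins: singletons/doubletons
    (MAC <= 2), rare (MAF < 1%), low-frequency (1-5%), common (> 5%).
    """

    mac_cut: int = 2
    maf_edges: tuple[float, ...] = (0.01, 0.05)
    labels: tuple[str, ...] = DEFAULT_BINS

    def __post_init__(self) -> None:
        n_maf_bins = len(self.maf_edges) + 1
        expected = n_maf_bins + (1 if self.mac_cut > 0 else 0)
        if len(self.labels) != expected:
            raise ValueError(f"need {expected} labels for this scheme")

    def assign(self, maf: np.ndarray, mac: np.ndarray) -> np.ndarray:
        """Vectorized bin labels; raises on monomorphic sites (mac == 0)."""
        maf = np.asarray(maf, float)
        mac = np.asarray(mac)
        if (mac == 0).any():
            raise ValueError("monomorphic site (MAC = 0): excluded by convention")
        if (maf <= 0).any() or (maf > 0.5).any():
            raise ValueError("MAF must lie in (0, 0.5]")
        maf_labels = np.array(self.labels[-(len(self.maf_edges) + 1):])
        # bins are left-closed: MAF exactly 1% is low-frequency, 5% is common
        idx = np.searchsorted(np.asarray(self.maf_edges), maf, side="right")
        out = maf_labels[idx]
        if self.mac_cut > 0:
            out = np.where(mac <= self.mac_cut, self.labels[0], out)
        return out


def maf_bin(maf: float, mac: int, scheme: BinScheme | None = None) -> str:
    """Bin a single site; see :class:`BinScheme` for the default scheme."""
    scheme = scheme or BinScheme()
    return str(scheme.assign(np.array([maf]), np.array([mac]))[0])


# ---------------------------------------------------------------------------
# site matching
# ---------------------------------------------------------------------------

@dataclass
class MatchResult:
    """Partition of the union of two site tables.

    ``matched`` carries the positional indices of each pair in both tables;
    ``unique_a``/``unique_b`` are positions whose (chrom, pos) is absent from
    the other table; ``conflict_a``/``conflict_b`` share a position but not
    alleles and are excluded from both sides for genotype metrics.
    """

    matched: pd.DataFrame  # columns idx_a, idx_b
    unique_a: np.ndarray
    unique_b: np.ndarray
    conflict_a: np.ndarray
    conflict_b: np.ndarray

    @property
    def n_matched(self) -> int:
        return len(self.matched)


def match_sites(a: pd.DataFrame, b: pd.DataFrame) -> MatchResult:
    """Match two site tables on exact (chrom, pos, ref, alt) agreement.

    Same-position different-allele records are classed as conflicts on both
    sides (the conservative rule: no strand flips, no ref/alt swap rescue).
    Duplicate keys within one table raise.
    """
    validate_sites(a)
    validate_sites(b)
    ka = a.reset_index(drop=True)[SITE_COLUMNS].copy()
    kb = b.reset_index(drop=True)[SITE_COLUMNS].copy()
    ka["idx_a"] = np.arange(len(ka))
    kb["idx_b"] = np.arange(len(kb))
    merged = ka.merge(kb, on=SITE_COLUMNS, how="inner")
    matched = merged[["idx_a", "idx_b"]].reset_index(drop=True)

    pos_a = pd.MultiIndex.from_frame(ka[["chrom", "pos"]])
    pos_b = pd.MultiIndex.from_frame(kb[["chrom", "pos"]])
    in_other_a = pos_a.isin(pos_b)
    in_other_b = pos_b.isin(pos_a)
    is_matched_a = np.zeros(len(ka), bool)
    is_matched_a[matched["idx_a"].to_numpy()] = True
    is_matched_b = np.zeros(len(kb), bool)
    is_matched_b[matched["idx_b"].to_numpy()] = True

    return MatchResult(
        matched=matched,
        unique_a=np.flatnonzero(~in_other_a),
        unique_b=np.flatnonzero(~in_other_b),
        conflict_a=np.flatnonzero(in_other_a & ~is_matched_a),
        conflict_b=np.flatnonzero(in_other_b & ~is_matched_b),
    )


# ---------------------------------------------------------------------------
# per-bin rate tables
# ---------------------------------------------------------------------------

def _per_bin_rate(
    bins_all: np.ndarray,
    hit: np.ndarray,
    scheme: BinScheme,
) -> pd.DataFrame:
    rows = []
    for label in scheme.labels:
        mask = bins_all == label
        n = int(mask.sum())
        rate = float(hit[mask].mean()) if n else np.nan  # empty bin: undefined
        rows.append({"bin": label, "n_sites": n, "rate": rate})
    return pd.DataFrame(rows)


def capture_rate(
    match: MatchResult, truth: GenotypeMatrix, scheme: BinScheme | None = None
) -> pd.DataFrame:
    """Per-bin sensitivity: fraction of truth sites present in the evaluated set.

    Bins by truth MAF. Conflict sites count as not captured (they were
    removed from both sides). Empty bins report NaN, never 0.
    """
    scheme = scheme or BinScheme()
    bins = scheme.assign(truth.mafs(), truth.macs())
    hit = np.zeros(truth.n_sites, bool)
    hit[match.matched["idx_b"].to_numpy()] = True
    out = _per_bin_rate(bins, hit, scheme)
    return out.rename(columns={"rate": "sensitivity"})


def ppv(
    match: MatchResult, evaluated: GenotypeMatrix, scheme: BinScheme | None = None
) -> pd.DataFrame:
    """Per-bin positive predictive value: evaluated sites confirmed in truth.

    Bins by evaluated MAF.
    """
    scheme = scheme or BinScheme()
    bins = scheme.assign(evaluated.mafs(), evaluated.macs())
    hit = np.zeros(evaluated.n_sites, bool)
    hit[match.matched["idx_a"].to_numpy()] = True
    out = _per_bin_rate(bins, hit, scheme)
    return out.rename(columns={"rate": "ppv"})


def genotype_concordance(
    evaluated: GenotypeMatrix,
    truth: GenotypeMatrix,
    match: MatchResult | None = None,
    scheme: BinScheme | None = None,
) -> pd.DataFrame:
    """Per-MAF-bin genotype and minor-allele concordance over matched sites.

    Shared samples are identified by exact ID; cells missing in either set are
    excluded from concordance denominators (call rate is reported separately,
    for the evaluated set).  Minor-allele concordance restricts the comparison
    to cells where either set carries >= 1 minor allele — the minor allele is
    the alt allele when the truth alt frequency is <= 0.5, else the ref.
    Bins follow truth MAF.
    """
    scheme = scheme or BinScheme()
    if match is None:
        match = match_sites(evaluated.sites, truth.sites)
    shared = [s for s in evaluated.samples if s in set(truth.samples)]
    if not shared:
        raise ValueError("no shared samples between the two sets")
    ev = evaluated.take_samples(shared).take_sites(match.matched["idx_a"].to_numpy())
    tr = truth.take_samples(shared).take_sites(match.matched["idx_b"].to_numpy())

    # truth MAF/MAC computed on the full truth cohort, then binned
    t_all = truth.take_sites(match.matched["idx_b"].to_numpy())
    bins = scheme.assign(t_all.mafs(), t_all.macs())
    minor_is_alt = t_all.alt_freqs() <= 0.5

    a = ev.dosages
    b = tr.dosages
    both = (a >= 0) & (b >= 0)
    same = (a == b) & both
    minor_a = np.where(minor_is_alt[None, :], a > 0, (a >= 0) & (a < 2))
    minor_b = np.where(minor_is_alt[None, :], b > 0, (b >= 0) & (b < 2))
    carries_minor = both & (minor_a | minor_b)

    rows = []
    for label in scheme.labels:
        cols = np.flatnonzero(bins == label)
        n = len(cols)
        if n == 0:
            rows.append(
                {
                    "bin": label,
                    "n_sites": 0,
                    "genotype_concordance": np.nan,
                    "minor_allele_concordance": np.nan,
                    "call_rate": np.nan,
                }
            )
            continue
        denom = both[:, cols].sum()
        gc = same[:, cols].sum() / denom if denom else np.nan
        mdenom = carries_minor[:, cols].sum()
        mac_conc = (same[:, cols] & carries_minor[:, cols]).sum() / mdenom if mdenom else np.nan
        rows.append(
            {
                "bin": label,
                "n_sites": n,
                "genotype_concordance": gc,
                "minor_allele_concordance": mac_conc,
                "call_rate": float((a[:, cols] >= 0).mean()),
            }
        )
    return pd.DataFrame(rows)


def concordance_report(
    evaluated: GenotypeMatrix,
    truth: GenotypeMatrix,
    scheme: BinScheme | None = None,
) -> pd.DataFrame:
    """Full per-bin report: sensitivity, PPV, concordances, call rate.

    Sensitivity rows are binned by truth MAF, PPV rows by evaluated MAF
    (stated here because the two axes genuinely differ).
    """
    scheme = scheme or BinScheme()
    match = match_sites(evaluated.sites, truth.sites)
    sens = capture_rate(match, truth, scheme)
    prec = ppv(match, evaluated, scheme)
    conc = genotype_concordance(evaluated, truth, match, scheme)
    out = sens.merge(prec[["bin", "ppv"]], on="bin").merge(
        conc.drop(columns="n_sites"), on="bin"
    )
    out.attrs["binning"] = "sensitivity by truth MAF; ppv by evaluated MAF"
    return out


# ---------------------------------------------------------------------------
# site-rate and unique-variant summaries
# ---------------------------------------------------------------------------

def site_rate_summary(
    n_called: int,
    n_called_absent_from_truth: int,
    n_truth: int,
    n_truth_missed: int,
) -> dict[str, float]:
    """False-positive and false-negative site rates, as one-decimal percentages.

    fpr = called sites absent from truth / all called sites;
    fnr = truth sites not recapitulated / all truth sites.
    """
    if n_called <= 0 or n_truth <= 0:
        raise ZeroDivisionError("site counts must be positive")
    if n_called_absent_from_truth > n_called:
        raise ValueError("absent sites exceed called sites")
    if n_truth_missed > n_truth:
        raise ValueError("missed sites exceed truth sites")
    return {
        "fpr": round_half_up(100.0 * n_called_absent_from_truth / n_called, 1),
        "fnr": round_half_up(100.0 * n_truth_missed / n_truth, 1),
    }


def unique_variant_table(
    match: MatchResult,
    evaluated: GenotypeMatrix,
    truth2: GenotypeMatrix | None = None,
    scheme: BinScheme | None = None,
) -> pd.DataFrame:
    """Tabulate evaluated-set sites absent from the comparison set, by MAF bin.

    When a second, higher-quality truth set is supplied, adds the per-bin
    fraction of unique sites confirmed there (the PPV of the uniques) and the
    minor-allele concordance of the confirmed ones.  The table's ``attrs``
    carry the totals needed for share-of-callset arithmetic:
    ``n_evaluated``, ``n_unique`` and ``unique_share_pct``.
    """
    scheme = scheme or BinScheme()
    uniq = evaluated.take_sites(match.unique_a)
    out_rows = []
    if uniq.n_sites:
        bins = scheme.assign(uniq.mafs(), uniq.macs())
    else:
        bins = np.array([], dtype=object)

    confirmed = np.zeros(uniq.n_sites, bool)
    conc_by_site = np.full(uniq.n_sites, np.nan)
    if truth2 is not None and uniq.n_sites:
        m2 = match_sites(uniq.sites, truth2.sites)
        confirmed[m2.matched["idx_a"].to_numpy()] = True
        if m2.n_matched:
            shared = [s for s in uniq.samples if s in set(truth2.samples)]
            if shared:
                ev = uniq.take_samples(shared).take_sites(m2.matched["idx_a"].to_numpy())
                tr = truth2.take_samples(shared).take_sites(m2.matched["idx_b"].to_numpy())
                both = (ev.dosages >= 0) & (tr.dosages >= 0)
                minor_is_alt = tr.alt_freqs() <= 0.5
                ma = np.where(minor_is_alt[None, :], ev.dosages > 0,
                              (ev.dosages >= 0) & (ev.dosages < 2))
                mb = np.where(minor_is_alt[None, :], tr.dosages > 0,
                              (tr.dosages >= 0) & (tr.dosages < 2))
                carries = both & (ma | mb)
                same = (ev.dosages == tr.dosages) & carries
                with np.errstate(invalid="ignore"):
                    site_conc = np.where(
                        carries.sum(axis=0) > 0,
                        same.sum(axis=0) / np.maximum(carries.sum(axis=0), 1),
                        np.nan,
                    )
                conc_by_site[m2.matched["idx_a"].to_numpy()] = site_conc

    for label in scheme.labels:
        mask = bins == label
        n = int(mask.sum())
        row: dict[str, object] = {"bin": label, "n_unique": n}
        if truth2 is not None:
            row["ppv_vs_truth2"] = float(confirmed[mask].mean()) if n else np.nan
            vals = conc_by_site[mask & confirmed]
            row["minor_allele_concordance"] = (
                float(np.nanmean(vals)) if np.isfinite(vals).any() else np.nan
            )
        out_rows.append(row)
    table = pd.DataFrame(out_rows)
    table.attrs["n_evaluated"] = evaluated.n_sites
    table.attrs["n_unique"] = int(len(match.unique_a))
    if evaluated.n_sites:
        table.attrs["unique_share_pct"] = round_half_up(
            100.0 * len(match.unique_a) / evaluated.n_sites, 1
        )
    return table
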