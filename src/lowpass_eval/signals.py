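"""Association-signal extraction and cross-study truth classification.

A "signal" is an independent association peak: the minimum-P variant below
the suggestive threshold plus every other sub-threshold variant within the
merge window around it.  Signals from one study are then cross-referenced
with a second study — directly when the index variant is present there, via
the best LD tag (r^2 > 0.8) otherwise — and classified as true or false
against a higher-depth reference study at an attenuated threshold.  The
resulting table supports the headline design comparison: how many true
signals each design finds, and how many of one design's true signals the
other fails to recapitulate.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from ._utils import round_half_up
from .compare import BinScheme
from .containers import GenotypeMatrix, SiteKey
from .kinship import ld_r2

SUGGESTIVE_P = 5e-7
TRUTH_P = 5e-5
TAG_R2 = 0.8
WINDOW_BP = 1_000_000

STAT_COLUMNS = ["chrom", "pos", "ref", "alt", "p"]


@dataclass
class Signal:
    """One association peak: index variant plus absorbed members."""

    index: SiteKey
    p: float
    members: list[SiteKey]
    maf_bin: str | None = None

    def __post_init__(self) -> None:
        if self.index not in self.members:
            raise ValueError("index variant must be among the members")


def _check_stats(stats_df: pd.DataFrame) -> pd.DataFrame:
    """Validate summary statistics; adopt the GC-corrected column as 'p' when present."""
    if "p" not in stats_df.columns:
        for alt in ("p_gc", "p_score"):
            if alt in stats_df.columns:
                stats_df = stats_df.rename(columns={alt: "p"})
                break
    missing = [c for c in STAT_COLUMNS if c not in stats_df.columns]
    if missing:
        raise ValueError(f"summary statistics lack columns: {missing}")
    return stats_df


def extract_signals(
    summary_stats: pd.DataFrame,
    p_threshold: float = SUGGESTIVE_P,
    window: int = WINDOW_BP,
    bin_scheme: BinScheme | None = None,
) -> list[Signal]:
    """Greedy peak clustering of sub-threshold variants.

    Variants with p < threshold (strict) are selected; repeatedly the
    smallest-p unassigned variant becomes an index (ties broken by chrom,
    pos) and absorbs all selected variants on the same chromosome within
    +/- window/2.  Output is ordered by (chrom, pos) of the index; every
    selected variant belongs to exactly one signal.
    """
    df = _check_stats(summary_stats)
    sel = df[df["p"] < p_threshold].copy()
    if sel.empty:
        return []
    sel = sel.sort_values(["p", "chrom", "pos"], kind="mergesort").reset_index(drop=True)
    half = window // 2
    assigned = np.zeros(len(sel), bool)
    chrom = sel["chrom"].to_numpy()
    pos = sel["pos"].to_numpy()
    signals: list[Signal] = []
    for i in range(len(sel)):
        if assigned[i]:
            continue
        near = (~assigned) & (chrom == chrom[i]) & (np.abs(pos - pos[i]) <= half)
        assigned |= near
        members_df = sel[near]
        members = [
            SiteKey(str(r.chrom), int(r.pos), str(r.ref), str(r.alt))
            for r in members_df.itertuples()
        ]
        index = SiteKey(str(chrom[i]), int(pos[i]), str(sel["ref"][i]), str(sel["alt"][i]))
        maf_bin = None
        if "maf" in sel.columns and bin_scheme is not None:
            mac = members_df["mac"].iloc[0] if "mac" in sel.columns else 3
            maf_bin = str(
                bin_scheme.assign(
                    np.array([sel["maf"][i]]), np.array([mac])
                )[0]
            )
        signals.append(
            Signal(index=index, p=float(sel["p"][i]), members=members, maf_bin=maf_bin)
        )
    signals.sort(key=lambda s: (s.index.chrom, s.index.pos))
    return signals


@dataclass
class CrossRef:
    """Lookup of one signal in another study.

    Exactly one of three outcomes: the index variant is present there
    (``same_variant_p`` set), or a tag with r^2 above the threshold exists
    (``tag_r2``/``tag_p`` set), or the signal is absent and untagged.
    """

    signal: Signal
    same_variant_p: float | None = None
    tag_r2: float | None = None
    tag_p: float | None = None
    absent_and_untagged: bool = False

    def __post_init__(self) -> None:
        if self.tag_p is not None and not (self.tag_r2 or 0) > TAG_R2:
            raise ValueError("a reported tag must exceed the r^2 threshold")

    def best_p(self) -> float | None:
        """Best available P for this signal in the other study, if any."""
        ps = [p for p in (self.same_variant_p, self.tag_p) if p is not None]
        return min(ps) if ps else None


def crossref_signal(
    signal: Signal,
    other_stats: pd.DataFrame,
    genotypes: GenotypeMatrix | None = None,
    r2_threshold: float = TAG_R2,
    window: int = WINDOW_BP,
) -> CrossRef:
    """Look a signal up in another study, directly or through an LD tag.

    ``genotypes`` is the querying dataset's genotype matrix (it must contain
    the index variant and covers the LD computation); when it is missing or
    lacks the needed sites, tagging is skipped with a warning and presence of
    the index variant alone decides the outcome.
    """
    df = _check_stats(other_stats)
    idx = signal.index
    hit = df[
        (df["chrom"] == idx.chrom)
        & (df["pos"] == idx.pos)
        & (df["ref"] == idx.ref)
        & (df["alt"] == idx.alt)
    ]
    if len(hit):
        return CrossRef(signal=signal, same_variant_p=float(hit["p"].iloc[0]))

    half = window // 2
    nearby = df[(df["chrom"] == idx.chrom) & ((df["pos"] - idx.pos).abs() <= half)]
    if genotypes is None or nearby.empty:
        if genotypes is None and not nearby.empty:
            warnings.warn("no genotypes for LD tagging; signal treated as untagged",
                          stacklevel=2)
        return CrossRef(signal=signal, absent_and_untagged=True)

    gsites = genotypes.sites
    key_to_col = {
        SiteKey(str(c), int(p), str(r), str(a)): j
        for j, (c, p, r, a) in enumerate(
            zip(gsites["chrom"], gsites["pos"], gsites["ref"], gsites["alt"])
        )
    }
    if idx not in key_to_col:
        warnings.warn("index variant missing from LD genotypes; treated as untagged",
                      stacklevel=2)
        return CrossRef(signal=signal, absent_and_untagged=True)
    g_index = genotypes.dosages[:, key_to_col[idx]]

    best_r2, best_p = 0.0, None
    for row in nearby.itertuples():
        key = SiteKey(str(row.chrom), int(row.pos), str(row.ref), str(row.alt))
        col = key_to_col.get(key)
        if col is None:
            continue
        try:
            r2 = ld_r2(g_index, genotypes.dosages[:, col])
        except ValueError:
            continue
        if r2 > r2_threshold and (best_p is None or row.p < best_p or r2 > best_r2):
            if best_p is None or row.p < best_p:
                best_r2, best_p = r2, float(row.p)
    if best_p is None:
        return CrossRef(signal=signal, absent_and_untagged=True)
    return CrossRef(signal=signal, tag_r2=best_r2, tag_p=best_p)


def classify_signals(
    signals: list[Signal],
    reference_stats: pd.DataFrame,
    truth_p: float = TRUTH_P,
) -> list[bool]:
    """Label each signal true/false against a higher-depth reference study.

    True iff the index variant — or, when the index is absent from the
    reference, any member variant — shows reference P < truth_p (an
    attenuation of two orders of magnitude relative to the suggestive
    threshold).  Signals entirely absent from the reference are false.
    """
    df = _check_stats(reference_stats)
    ref = df.set_index(["chrom", "pos", "ref", "alt"])["p"]
    labels = []
    for sig in signals:
        key = tuple(sig.index)
        if key in ref.index:
            labels.append(bool(ref.loc[key] < truth_p))
            continue
        member_ps = [
            float(ref.loc[tuple(m)]) for m in sig.members if tuple(m) in ref.index
        ]
        labels.append(bool(member_ps and min(member_ps) < truth_p))
    return labels


def two_proportion_test(
    k1: int, n1: int, k2: int, n2: int, alternative: str = "less"
) -> dict[str, float]:
    """One-sided two-proportion z test with Yates continuity correction.

    Tests H1: p1 < p2 ('less') or p1 > p2 ('greater').  Returns the z
    statistic and one-sided P-value.
    """
    if min(n1, n2) <= 0:
        raise ZeroDivisionError("group sizes must be positive")
    if alternative not in ("less", "greater"):
        raise ValueError("alternative must be 'less' or 'greater'")
    p1, p2 = k1 / n1, k2 / n2
    pooled = (k1 + k2) / (n1 + n2)
    se = np.sqrt(pooled * (1 - pooled) * (1 / n1 + 1 / n2))
    if se == 0:
        return {"z": 0.0, "p": 1.0}
    diff = p1 - p2
    cc = 0.5 * (1 / n1 + 1 / n2)  # Yates continuity correction
    corrected = np.sign(diff) * max(abs(diff) - cc, 0.0)
    z = corrected / se
    p = stats.norm.cdf(z) if alternative == "less" else stats.norm.sf(z)
    return {"z": float(z), "p": float(p)}


@dataclass
class ComparisonTable:
    """Cross-study truth/tagging tabulation for two designs A and B.

    ``per_study`` has one row per study: n_signals, n_true and the true
    percentage.  ``unique_true`` breaks down, per MAF bin, the true signals
    of each study not recapitulated by the other, split into absent-and-
    untagged versus present-or-tagged-but-not-associated.  ``proportion_test``
    is the one-sided Yates-corrected z test comparing the
    true-but-not-recapitulated fractions.
    """

    per_study: pd.DataFrame
    unique_true: pd.DataFrame
    proportion_test: dict[str, float]
    counts: dict[str, int] = field(default_factory=dict)


def tabulate_comparison(
    labels_a: list[bool],
    labels_b: list[bool],
    crossrefs_a: list[CrossRef],
    crossrefs_b: list[CrossRef],
    recap_p: float = TRUTH_P,
    alternative: str = "less",
) -> ComparisonTable:
    """Build the cross-study comparison table.

    A true signal of study A counts as "not recapitulated" by study B when
    its cross-reference shows no same-variant or tag P below ``recap_p``.
    The proportion test compares these fractions (A vs B) one-sided in the
    direction given by ``alternative``.
    """
    if len(labels_a) != len(crossrefs_a) or len(labels_b) != len(crossrefs_b):
        raise ValueError("labels and crossrefs must align per study")

    def study_rows(labels, crossrefs):
        n = len(labels)
        n_true = int(sum(labels))
        not_recap = []
        for lab, xr in zip(labels, crossrefs):
            if not lab:
                continue
            best = xr.best_p()
            not_recap.append(best is None or best >= recap_p)
        return n, n_true, not_recap

    n_a, true_a, nr_a = study_rows(labels_a, crossrefs_a)
    n_b, true_b, nr_b = study_rows(labels_b, crossrefs_b)

    per_study = pd.DataFrame(
        [
            {"study": "A", "n_signals": n_a, "n_true": true_a,
             "true_pct": round_half_up(100 * true_a / n_a, 1) if n_a else np.nan},
            {"study": "B", "n_signals": n_b, "n_true": true_b,
             "true_pct": round_half_up(100 * true_b / n_b, 1) if n_b else np.nan},
        ]
    )

    rows = []
    for study, labels, crossrefs in (("A", labels_a, crossrefs_a),
                                     ("B", labels_b, crossrefs_b)):
        for lab, xr in zip(labels, crossrefs):
            if not lab:
                continue
            best = xr.best_p()
            if best is not None and best < recap_p:
                continue  # recapitulated by the other study
            rows.append(
                {
                    "study": study,
                    "bin": xr.signal.maf_bin,
                    "absent_and_untagged": xr.absent_and_untagged,
                }
            )
    unique_true = (
        pd.DataFrame(rows, columns=["study", "bin", "absent_and_untagged"])
        .groupby(["study", "bin", "absent_and_untagged"], dropna=False)
        .size()
        .rename("n")
        .reset_index()
    )

    k_a, k_b = int(sum(nr_a)), int(sum(nr_b))
    test = (
        two_proportion_test(k_a, true_a, k_b, true_b, alternative=alternative)
        if true_a and true_b
        else {"z": np.nan, "p": np.nan}
    )
    counts = {
        "n_signals_a": n_a, "n_true_a": true_a, "n_true_not_recap_a": k_a,
        "n_signals_b": n_b, "n_true_b": true_b, "n_true_not_recap_b": k_b,
    }
    return ComparisonTable(
        per_study=per_study, unique_true=unique_true,
        proportion_test=test, counts=counts,
    )
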