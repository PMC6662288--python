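"""Ti/Tv-based site-quality evaluation and the exome high-confidence filter.

True SNVs show a genome-wide transition/transversion ratio around 2.0-2.1,
while random miscalls sit at the combinatorial expectation of 0.5 (2 of the 6
possible unordered allele pairs are transitions).  Sweeping sensitivity
tranches of a quality score and watching where the cumulative Ti/Tv drops
below 2.0 therefore localizes the point where a call set starts admitting
noise, and the distance between an observed and an expected Ti/Tv yields a
mixture-based estimate of the false-positive fraction.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .containers import validate_sites

TRANSITIONS = frozenset({("A", "G"), ("G", "A"), ("C", "T"), ("T", "C")})

#: genome-wide Ti/Tv expectation for true SNVs; override per target region
DEFAULT_TRUE_TITV = 2.1
#: Ti/Tv of uniformly random miscalls: 2 transition pairs of 6
RANDOM_TITV = 0.5


def is_transition(ref: np.ndarray, alt: np.ndarray) -> np.ndarray:
    ref = np.asarray(ref, dtype=object)
    alt = np.asarray(alt, dtype=object)
    purine = np.isin(ref, ["A", "G"]) & np.isin(alt, ["A", "G"])
    pyrimidine = np.isin(ref, ["C", "T"]) & np.isin(alt, ["C", "T"])
    return purine | pyrimidine


def titv_ratio(sites: pd.DataFrame) -> float:
    """Transitions / transversions over a site table; inf when no transversion."""
    validate_sites(sites)
    if len(sites) == 0:
        raise ValueError("Ti/Tv undefined for an empty site table")
    ti = is_transition(sites["ref"].to_numpy(), sites["alt"].to_numpy())
    n_ti = int(ti.sum())
    n_tv = len(sites) - n_ti
    if n_tv == 0:
        return float("inf")
    return n_ti / n_tv


@dataclass
class TrancheRow:
    sensitivity: float
    n_sites: int
    titv: float


def tranche_sweep(
    sites: pd.DataFrame,
    scores: np.ndarray,
    grid: np.ndarray | int = 50,
    dropoff_below: float = 2.0,
) -> tuple[list[TrancheRow], float | None]:
    """Sweep sensitivity tranches of a quality score and find the Ti/Tv dropoff.

    For each sensitivity s in the grid, retain the top-s fraction of sites by
    descending score (ties broken by (chrom, pos) for determinism) and compute
    the cumulative Ti/Tv.  The dropoff is the smallest s whose Ti/Tv falls
    below ``dropoff_below``; tranches with no transversions (infinite ratio)
    are excluded from the search.  Returns (rows, dropoff-or-None).
    """
    validate_sites(sites)
    scores = np.asarray(scores, float)
    if len(scores) != len(sites):
        raise ValueError("one score per site required")
    if len(sites) == 0:
        raise ValueError("empty site table")
    if isinstance(grid, int):
        grid = np.linspace(1.0 / grid, 1.0, grid)
    grid = np.asarray(grid, float)

    order = pd.DataFrame(
        {
            "score": -scores,
            "chrom": sites["chrom"].to_numpy(),
            "pos": sites["pos"].to_numpy(),
        }
    ).sort_values(["score", "chrom", "pos"], kind="mergesort").index.to_numpy()
    ti_sorted = is_transition(
        sites["ref"].to_numpy()[order], sites["alt"].to_numpy()[order]
    )
    cum_ti = np.cumsum(ti_sorted)

    rows: list[TrancheRow] = []
    dropoff: float | None = None
    n = len(sites)
    for s in grid:
        k = max(1, int(np.ceil(s * n)))
        n_ti = int(cum_ti[k - 1])
        n_tv = k - n_ti
        ratio = float("inf") if n_tv == 0 else n_ti / n_tv
        rows.append(TrancheRow(sensitivity=float(s), n_sites=k, titv=ratio))
        if dropoff is None and np.isfinite(ratio) and ratio < dropoff_below:
            dropoff = float(s)
    return rows, dropoff


def estimate_fpr_from_titv(
    observed_titv: float,
    true_titv: float = DEFAULT_TRUE_TITV,
    random_titv: float = RANDOM_TITV,
) -> float:
    """Mixture estimate of the false-positive fraction from an observed Ti/Tv.

    Treats the call set as a mixture of true SNVs (ratio ``true_titv``) and
    random errors (ratio ``random_titv``): the observed ratio interpolates
    between the two, so fpr = (true - observed) / (true - random), clamped
    to [0, 1].
    """
    if not true_titv > random_titv:
        raise ValueError("true_titv must exceed random_titv")
    if observed_titv > true_titv:
        warnings.warn(
            "observed Ti/Tv exceeds the assumed true ratio; FPR clamped to 0",
            stacklevel=2,
        )
    fpr = (true_titv - observed_titv) / (true_titv - random_titv)
    return float(np.clip(fpr, 0.0, 1.0))


@dataclass
class HighConfidenceFilter:
    """Exome high-confidence site filter: QUAL > min_qual, AN == required_an, DP >= min_depth.

    Defaults correspond to a five-sample deep exome benchmark: site quality
    above 200, all 10 alleles called (100% call rate) and total depth of at
    least 250x.
    """

    min_qual: float = 200.0
    required_an: int = 10
    min_depth: float = 250.0

    def __post_init__(self) -> None:
        if self.min_qual <= 0 or self.required_an <= 0 or self.min_depth <= 0:
            raise ValueError("all thresholds must be positive")

    @classmethod
    def for_samples(cls, n_samples: int, **kw) -> "HighConfidenceFilter":
        """AN requirement generalized to 2 x n_samples (100% call rate)."""
        return cls(required_an=2 * n_samples, **kw)


def wes_high_confidence_filter(
    sites: pd.DataFrame, f: HighConfidenceFilter | None = None
) -> pd.DataFrame:
    """Apply the high-confidence filter; requires QUAL, AN and DP columns."""
    f = f or HighConfidenceFilter()
    for col in ("QUAL", "AN", "DP"):
        if col not in sites.columns:
            raise KeyError(f"site table lacks required annotation: {col}")
    keep = (
        (sites["QUAL"] > f.min_qual)
        & (sites["AN"] == f.required_an)
        & (sites["DP"] >= f.min_depth)
    )
    return sites[keep].reset_index(drop=True)
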