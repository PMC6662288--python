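"""End-to-end desk pipeline tying the simulator to the evaluation stack.

``simulate_study`` builds one synthetic cohort and derives the call sets a
real design comparison needs (truth, raw 1x-style calls, refined+imputed set,
chip subset, high-depth set); ``run_association`` scans a call set for one
trait with the kinship-aware mixed model; ``design_comparison`` runs two
designs on the same phenotypes and cross-classifies their signals.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .cohort import (
    CohortConfig,
    ImputationChannel,
    SequencingParams,
    TraitConfig,
    apply_imputation_channel,
    call_from_pileup,
    make_chip_subset,
    sample_allele_frequencies,
    simulate_genotypes,
    simulate_phenotypes,
    simulate_reads,
)
from .containers import GenotypeMatrix
from .kinship import KinshipMatrix, centered_grm, select_grm_variants
from .lmm import MixedModel
from .signals import (
    SUGGESTIVE_P,
    TRUTH_P,
    ComparisonTable,
    classify_signals,
    crossref_signal,
    extract_signals,
    tabulate_comparison,
)


@dataclass
class StudySets:
    """All call sets derived from one synthetic cohort.

    ``raw_calls`` comes from sequencing the full site universe, including
    sites that happened to be monomorphic in this cohort draw — sequencing
    error can therefore create false-positive sites there, which is what
    gives the low-depth set a non-trivial PPV profile.  ``truth`` holds the
    polymorphic sites only (the usual non-monomorphic convention).
    """

    truth: GenotypeMatrix
    raw_calls: GenotypeMatrix
    imputed: GenotypeMatrix
    chip: GenotypeMatrix
    highdepth: GenotypeMatrix
    afs: np.ndarray
    config: CohortConfig


def simulate_study(
    config: CohortConfig,
    low_depth: float = 1.0,
    high_depth: float = 22.0,
    error_rate: float = 0.01,
    channel: ImputationChannel | None = None,
    n_chip_sites: int | None = None,
    chip_maf_floor: float = 0.05,
) -> StudySets:
    """Simulate truth and derive low-depth, imputed, chip and high-depth sets.

    The refinement/imputation channel operates on the truth site universe
    (false-positive raw-call sites are not imputable: no reference haplotype
    carries them), so ``imputed`` is evaluated for concordance and
    association while ``raw_calls`` carries the false-positive channel.
    """
    channel = channel or ImputationChannel()
    afs = sample_allele_frequencies(config)
    universe = simulate_genotypes(afs, config)
    truth = universe.drop_monomorphic()

    low = SequencingParams(mean_depth=low_depth, error_rate=error_rate,
                           seed=config.seed + 1)
    raw_calls = call_from_pileup(simulate_reads(universe, low), low)
    imputed = apply_imputation_channel(
        raw_calls.restrict_to(truth.sites), truth, channel, seed=config.seed + 2
    )

    high = SequencingParams(mean_depth=high_depth, error_rate=error_rate,
                            seed=config.seed + 3)
    highdepth = call_from_pileup(simulate_reads(universe, high), high)

    if n_chip_sites is None:
        eligible = int((truth.mafs() >= chip_maf_floor).sum())
        n_chip_sites = max(1, eligible // 2)
    chip = make_chip_subset(truth, n_chip_sites, maf_floor=chip_maf_floor,
                            seed=config.seed + 4)
    return StudySets(truth=truth, raw_calls=raw_calls, imputed=imputed,
                     chip=chip, highdepth=highdepth, afs=afs, config=config)


def run_association(
    gm: GenotypeMatrix,
    y: np.ndarray,
    kinship: KinshipMatrix | None = None,
    covariates: np.ndarray | None = None,
) -> pd.DataFrame:
    """Fit the null mixed model on ``gm`` (building a GRM if none given) and scan."""
    if kinship is None:
        grm_sites = select_grm_variants(gm)
        kinship = centered_grm(gm, grm_sites)
    fit = MixedModel(y, kinship, covariates).fit()
    return fit.association_scan(gm)


@dataclass
class DesignComparison:
    table: ComparisonTable
    signals_a: list
    signals_b: list
    stats_a: pd.DataFrame = field(repr=False)
    stats_b: pd.DataFrame = field(repr=False)


def design_comparison(
    set_a: GenotypeMatrix,
    set_b: GenotypeMatrix,
    reference: GenotypeMatrix,
    y: np.ndarray,
    kinship: KinshipMatrix,
    p_threshold: float = SUGGESTIVE_P,
    truth_p: float = TRUTH_P,
) -> DesignComparison:
    """Associate one trait under two designs and cross-classify their signals.

    ``reference`` plays the higher-depth study used for truth classification.
    """
    stats_a = run_association(set_a, y, kinship)
    stats_b = run_association(set_b, y, kinship)
    stats_ref = run_association(reference, y, kinship)

    sig_a = extract_signals(stats_a, p_threshold)
    sig_b = extract_signals(stats_b, p_threshold)
    lab_a = classify_signals(sig_a, stats_ref, truth_p)
    lab_b = classify_signals(sig_b, stats_ref, truth_p)
    xr_a = [crossref_signal(s, stats_b, set_a) for s in sig_a]
    xr_b = [crossref_signal(s, stats_a, set_b) for s in sig_b]
    table = tabulate_comparison(lab_a, lab_b, xr_a, xr_b, recap_p=truth_p)
    return DesignComparison(table=table, signals_a=sig_a, signals_b=sig_b,
                            stats_a=stats_a, stats_b=stats_b)
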