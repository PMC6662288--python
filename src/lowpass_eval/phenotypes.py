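"""Standardized quantitative-trait preparation for association analysis.

One pipeline for every trait: exclusions (missing values, optional outlier
cut), least-squares removal of covariate effects, then a rank-based
inverse-normal transform so every prepared trait is N(0, 1)-distributed and
comparable across the phenotype battery.  Exclusions are logged with reasons
so batch runs remain auditable.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal

import numpy as np
import pandas as pd
from scipy import stats

Transform = Literal["inverse-normal", "log", "none"]


@dataclass
class TraitSpec:
    """Preparation recipe for one quantitative trait.

    Parameters
    ----------
    name
        Trait label used in logs and output columns.
    covariates
        Covariate columns to residualize out by ordinary least squares
        (an intercept is always included).
    outlier_sd
        If set, values beyond this many standard deviations from the mean
        (computed after missing-value exclusion) are excluded.
    transform
        'inverse-normal' (default): rank-based with offset ranks (r-0.5)/n and
        average ranks for ties; 'log': natural log of the raw values applied
        before residualization, then z-standardized; 'none': z-standardized.
    residualize_first
        Order knob: residualize covariates before the transform (default) or
        after.  Ignored for 'log', which must see the raw positive values.
    """

    name: str
    covariates: list[str] = field(default_factory=list)
    outlier_sd: float | None = None
    transform: Transform = "inverse-normal"
    residualize_first: bool = True

    def __post_init__(self) -> None:
        if self.transform not in ("inverse-normal", "log", "none"):
            raise ValueError(f"unknown transform: {self.transform!r}")


def inverse_normal_transform(values: np.ndarray) -> np.ndarray:
    """Rank-based inverse-normal transform with offset ranks (r - 0.5) / n.

    Ties receive average ranks, so duplicated raw values map to the same
    quantile.  Invariant under any strictly monotone pre-transform.
    """
    values = np.asarray(values, float)
    ranks = stats.rankdata(values, method="average")
    return stats.norm.ppf((ranks - 0.5) / len(values))


def _residualize(y: np.ndarray, covariates: np.ndarray) -> np.ndarray:
    X = np.column_stack([np.ones(len(y)), covariates])
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    return y - X @ beta


@dataclass
class PreparedTrait:
    name: str
    values: pd.Series  # indexed by retained sample ids
    exclusions: pd.DataFrame  # sample_id, reason


def prepare_trait(
    raw: pd.Series,
    covariates: pd.DataFrame | None,
    spec: TraitSpec,
) -> PreparedTrait:
    """Prepare one trait: exclusions -> residualization -> transform.

    ``raw`` is indexed by sample id; ``covariates`` (if any) must cover the
    retained samples.  Fails on fewer than 10 usable values or a constant
    trait.  Output has mean ~ 0 and variance ~ 1.
    """
    excl: list[dict[str, str]] = []
    vals = raw.astype(float)

    missing = vals.index[vals.isna()]
    excl += [{"sample_id": s, "reason": "missing"} for s in missing]
    vals = vals.dropna()

    if spec.transform == "log":
        nonpos = vals.index[vals <= 0]
        excl += [{"sample_id": s, "reason": "non-positive under log"} for s in nonpos]
        vals = vals[vals > 0]

    if spec.outlier_sd is not None and len(vals) > 1:
        z = (vals - vals.mean()) / vals.std(ddof=0)
        out = vals.index[np.abs(z) > spec.outlier_sd]
        excl += [{"sample_id": s, "reason": f"outlier>{spec.outlier_sd}SD"} for s in out]
        vals = vals.drop(out)

    if len(vals) < 10:
        raise ValueError(f"trait {spec.name!r}: fewer than 10 usable values")
    if vals.nunique() == 1:
        raise ValueError(f"trait {spec.name!r}: constant trait")

    y = vals.to_numpy()
    if spec.transform == "log":
        y = np.log(y)

    C = None
    if spec.covariates:
        if covariates is None:
            raise ValueError("spec names covariates but no covariate table given")
        miss_cov = [c for c in spec.covariates if c not in covariates.columns]
        if miss_cov:
            raise KeyError(f"missing covariate columns: {miss_cov}")
        C = covariates.loc[vals.index, spec.covariates].to_numpy(float)
        if np.isnan(C).any():
            bad = vals.index[np.isnan(C).any(axis=1)]
            excl += [{"sample_id": s, "reason": "missing covariate"} for s in bad]
            vals = vals.drop(bad)
            if len(vals) < 10:
                raise ValueError(f"trait {spec.name!r}: fewer than 10 usable values")
            y = vals.to_numpy()
            if spec.transform == "log":
                y = np.log(y)
            C = covariates.loc[vals.index, spec.covariates].to_numpy(float)

    def transform(v: np.ndarray) -> np.ndarray:
        if spec.transform == "inverse-normal":
            return inverse_normal_transform(v)
        sd = v.std(ddof=0)
        return (v - v.mean()) / sd if sd > 0 else v - v.mean()

    if C is not None and spec.residualize_first:
        y = transform(_residualize(y, C))
    elif C is not None:
        y = _residualize(transform(y), C)
        sd = y.std(ddof=0)
        if sd > 0:
            y = y / sd
    else:
        y = transform(y)

    return PreparedTrait(
        name=spec.name,
        values=pd.Series(y, index=vals.index, name=spec.name),
        exclusions=pd.DataFrame(excl, columns=["sample_id", "reason"]),
    )


def prepare_traits(
    data: pd.DataFrame, specs: list[TraitSpec], covariates: pd.DataFrame | None = None
) -> dict[str, PreparedTrait]:
    """Batch preparation: one :func:`prepare_trait` call per spec."""
    out = {}
    for spec in specs:
        if spec.name not in data.columns:
            raise KeyError(f"trait column missing: {spec.name}")
        out[spec.name] = prepare_trait(data[spec.name], covariates, spec)
    return out
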