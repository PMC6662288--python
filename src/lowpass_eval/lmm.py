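"""Single-variance-component linear mixed model for association testing.

Model: y = W alpha + u + e with u ~ N(0, sg2 K) and e ~ N(0, se2 I), where K
is the genetic relatedness matrix.  The variance ratio delta = sg2/se2 is
estimated once by REML on the eigenbasis of K (bounded 1-D search), and every
variant is then tested with a 1-df score statistic against that null fit —
no per-variant refit, which is what makes genome-wide scans at millions of
sites tractable.  Residual inflation is handled afterwards by genomic
control on the median statistic.

The model/results split follows the statsmodels convention:
``MixedModel(y, K, covariates).fit()`` returns a :class:`MixedModelResults`
carrying the variance components, heritability, covariate coefficients and
a ``score_test`` method for dosage matrices.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .containers import GenotypeMatrix
from .kinship import KinshipMatrix, mac_filter

#: median of the chi-square(1) distribution, the genomic-control denominator
CHI2_1_MEDIAN = 0.4549364231195724


class MixedModel:
    """Null mixed model y = W alpha + u + e, Var(y) = sg2 K + se2 I.

    Parameters
    ----------
    y
        Prepared phenotype vector (length n).
    kinship
        KinshipMatrix or raw symmetric PSD array (n x n).
    covariates
        Optional n x c covariate matrix; an intercept column is always added.
    """

    def __init__(
        self,
        y: np.ndarray,
        kinship: KinshipMatrix | np.ndarray,
        covariates: np.ndarray | None = None,
    ) -> None:
        self.y = np.asarray(y, float)
        n = len(self.y)
        K = kinship.values if isinstance(kinship, KinshipMatrix) else np.asarray(kinship, float)
        if K.shape != (n, n):
            raise ValueError("kinship shape does not match phenotype length")
        W = np.ones((n, 1))
        if covariates is not None:
            C = np.atleast_2d(np.asarray(covariates, float))
            if C.shape[0] != n:
                C = C.T
            W = np.column_stack([W, C])
        self.W = W
        # eigenbasis of K; reused for the fit and for every score test
        s, U = np.linalg.eigh(K)
        if s.min() < -1e-8 * max(s.max(), 1.0):
            raise ValueError("kinship matrix is not positive semi-definite")
        self.eigvals = np.clip(s, 0.0, None)
        self.eigvecs = U
        self.y_rot = U.T @ self.y
        self.W_rot = U.T @ self.W

    # -- REML machinery -------------------------------------------------------
    def _reml_pieces(self, delta: float):
        d = delta * self.eigvals + 1.0
        Wd = self.W_rot / d[:, None]
        WtHiW = self.W_rot.T @ Wd
        alpha = np.linalg.solve(WtHiW, Wd.T @ self.y_rot)
        resid = self.y_rot - self.W_rot @ alpha
        rss = float(resid @ (resid / d))
        return d, WtHiW, alpha, rss

    def reml_loglik(self, delta: float) -> float:
        """Profiled restricted log-likelihood of the variance ratio delta."""
        n, c = self.W.shape[0], self.W.shape[1]
        d, WtHiW, _, rss = self._reml_pieces(delta)
        sign, logdet_w = np.linalg.slogdet(WtHiW)
        if sign <= 0 or rss <= 0:
            return -np.inf
        nc = n - c
        return -0.5 * (np.log(d).sum() + logdet_w + nc * np.log(rss) + nc)

    def fit(
        self,
        log10_bounds: tuple[float, float] = (-5.0, 5.0),
        grid_points: int = 100,
        tol: float = 1e-6,
    ) -> "MixedModelResults":
        """Estimate delta by REML: log-scale grid scan plus bounded refinement."""
        grid = np.logspace(*log10_bounds, grid_points)
        grid = np.concatenate([[0.0], grid])
        ll = np.array([self.reml_loglik(g) for g in grid])
        best = int(np.argmax(ll))
        lo = grid[max(best - 1, 0)]
        hi = grid[min(best + 1, len(grid) - 1)]
        if hi > lo:
            res = optimize.minimize_scalar(
                lambda x: -self.reml_loglik(x),
                bounds=(lo, hi),
                method="bounded",
                options={"xatol": tol},
            )
            delta = float(res.x)
            if self.reml_loglik(delta) < ll[best]:
                delta = float(grid[best])
        else:
            delta = float(grid[best])

        n, c = self.W.shape
        d, WtHiW, alpha, rss = self._reml_pieces(delta)
        se2 = rss / (n - c)
        sg2 = delta * se2
        return MixedModelResults(
            model=self,
            delta=delta,
            sigma_g2=sg2,
            sigma_e2=se2,
            alpha=alpha,
            reml_loglik=self.reml_loglik(delta),
        )


@dataclass
class MixedModelResults:
    """REML fit of the null mixed model; entry point for score tests.

    ``delta`` is sg2/se2; heritability on the K scale is
    sg2 * mean(diag K) / (sg2 * mean(diag K) + se2) when K came from a
    centered GRM.
    """

    model: MixedModel
    delta: float
    sigma_g2: float
    sigma_e2: float
    alpha: np.ndarray
    reml_loglik: float
    _proj: tuple[np.ndarray, np.ndarray, np.ndarray] = field(default=None, repr=False)

    @property
    def total_variance(self) -> float:
        return self.sigma_g2 * float(np.mean(self.model.eigvals)) + self.sigma_e2

    def polygenic_fraction(self, kinship_diag_mean: float | None = None) -> float:
        """Share of trait variance attributed to the polygenic effect."""
        kd = float(np.mean(self.model.eigvals)) if kinship_diag_mean is None else kinship_diag_mean
        g = self.sigma_g2 * kd
        return g / (g + self.sigma_e2)

    # -- score testing --------------------------------------------------------
    def _projection(self):
        """Cache D^{-1/2}-whitened, covariate-projected pieces of the null."""
        if self._proj is None:
            m = self.model
            d = self.sigma_g2 * m.eigvals + self.sigma_e2
            w = 1.0 / np.sqrt(d)
            Wd = m.W_rot * w[:, None]
            Q, _ = np.linalg.qr(Wd)
            b = m.y_rot * w
            b = b - Q @ (Q.T @ b)
            self._proj = (w, Q, b)
        return self._proj

    def score_test(self, dosages: np.ndarray) -> pd.DataFrame:
        """1-df score test of each dosage column against the null fit.

        ``dosages`` is n x m (or a single vector); missing cells (< 0) are
        mean-imputed per column.  Returns a DataFrame with columns
        ``score_stat`` and ``p_score``; zero-variance columns yield NaN.
        """
        m = self.model
        X = np.asarray(dosages, float)
        if X.ndim == 1:
            X = X[:, None]
        if X.shape[0] != len(m.y):
            raise ValueError("dosage rows must match phenotype length")
        X = X.copy()
        miss = X < 0
        if miss.any():
            col_mean = np.where(
                miss.all(axis=0), 0.0,
                np.nanmean(np.where(miss, np.nan, X), axis=0),
            )
            X[miss] = np.take(col_mean, np.where(miss)[1])
        var = X.var(axis=0)

        w, Q, b = self._projection()
        Xr = (m.eigvecs.T @ X) * w[:, None]
        Xr = Xr - Q @ (Q.T @ Xr)
        num = Xr.T @ b
        den = (Xr**2).sum(axis=0)
        with np.errstate(divide="ignore", invalid="ignore"):
            stat = np.where((den > 0) & (var > 0), num**2 / np.maximum(den, 1e-300), np.nan)
        p = stats.chi2.sf(stat, df=1)
        return pd.DataFrame({"score_stat": stat, "p_score": p})

    def association_scan(
        self,
        gm: GenotypeMatrix,
        min_mac_exclusive: int = 2,
        gc: bool = True,
    ) -> pd.DataFrame:
        """Genome scan: MAC filter, score test per site, genomic control.

        Returns one row per retained site: chrom, pos, ref, alt, maf, mac,
        score_stat, p_score and (when ``gc``) p_gc, with lambda_median in
        ``attrs``.
        """
        keep = mac_filter(gm, min_mac_exclusive)
        sub = gm.take_sites(keep)
        res = self.score_test(sub.dosages)
        out = sub.sites[["chrom", "pos", "ref", "alt"]].copy()
        out["maf"] = sub.mafs()
        out["mac"] = sub.macs()
        out["score_stat"] = res["score_stat"].to_numpy()
        out["p_score"] = res["p_score"].to_numpy()
        if gc:
            lam, p_gc = gc_correct(out["p_score"].to_numpy())
            out["p_gc"] = p_gc
            out.attrs["lambda_median"] = lam
        return out

    def summary(self) -> str:
        """Human-readable fit summary, statsmodels-style."""
        n, c = self.model.W.shape
        lines = [
            "Mixed model (single variance component), REML",
            "=" * 46,
            f"n samples            {n:>12d}",
            f"covariates (incl. 1) {c:>12d}",
            f"delta (sg2/se2)      {self.delta:>12.6g}",
            f"sigma_g^2            {self.sigma_g2:>12.6g}",
            f"sigma_e^2            {self.sigma_e2:>12.6g}",
            f"polygenic fraction   {self.polygenic_fraction():>12.4f}",
            f"REML log-likelihood  {self.reml_loglik:>12.4f}",
            "coefficients: " + np.array2string(self.alpha, precision=4),
        ]
        return "\n".join(lines)


def gc_correct(p_values: np.ndarray) -> tuple[float, np.ndarray]:
    """Genomic control: lambda_median and corrected P-values.

    lambda = median(chi2(p)) / median of chi-square(1); statistics are divided
    by lambda only when lambda > 1 (deflation is left untouched).  Fewer than
    100 tests make the median unstable and raise.
    """
    p = np.asarray(p_values, float)
    ok = np.isfinite(p)
    if ok.sum() < 100:
        raise ValueError("need >= 100 tests for a stable lambda_median")
    chi2 = stats.chi2.isf(p[ok], df=1)
    lam = float(np.median(chi2) / CHI2_1_MEDIAN)
    out = p.copy()
    if lam > 1:
        out[ok] = stats.chi2.sf(chi2 / lam, df=1)
    return lam, out
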