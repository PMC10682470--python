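"""Per-gene negative-binomial GLMs with a log2 link for count matrices.

The model for gene *i* and sample *j* is

.. math::

    K_{ij} \\sim \\mathrm{NB}(\\mu_{ij}, \\tau_i), \\qquad
    \\mu_{ij} = s_j q_{ij}, \\qquad
    \\log_2 q_{ij} = \\sum_r \\beta_{ir} x_{jr},

with sample size factors :math:`s_j`, gene dispersion :math:`\\tau_i`
(variance :math:`\\mu + \\tau\\mu^2`) and a dummy-coded design matrix
:math:`x`.  For the two-factor diet/week design the coefficients are the
intercept (log2 expression at the reference cell), the diet main effect, the
week effects and the diet:week interaction effects, all on the log2 scale so
that a coefficient of 3 means a fold change of :math:`2^3 = 8`.

Fitting follows the statsmodels convention: build an :class:`NBGLM` from a
count matrix, metadata and a :class:`~interactdeg.design.DesignSpec`, call
:meth:`NBGLM.fit`, and read estimates and tests off the returned
:class:`NBGLMResults`.  All genes are fitted simultaneously with a vectorised
IRLS; dispersions are estimated by maximising the Cox-Reid adjusted profile
likelihood, alternating once with the coefficient fit.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import special, stats
from statsmodels.stats.multitest import multipletests

from .design import DesignSpec, design_cells
from .io import align, validate_counts

LN2 = float(np.log(2.0))
DISPERSION_FLOOR = 1e-8
DISPERSION_CEILING = 25.0

FLAG_DEGENERATE = "degenerate_cell"
FLAG_NOT_CONVERGED = "not_converged"
FLAG_SE_UNDEFINED = "se_undefined"


class GLMError(ValueError):
    pass


# ---------------------------------------------------------------------------
# size factors
# ---------------------------------------------------------------------------

def estimate_size_factors(counts: pd.DataFrame) -> pd.Series:
    """Median-of-ratios library size factors.

    For each gene with strictly positive counts in every sample, form the
    ratio of each sample's count to the gene's across-sample geometric mean;
    the sample's size factor is the median of these ratios.
    """
    arr = np.asarray(counts, dtype=float)
    all_positive = (arr > 0).all(axis=1)
    if not all_positive.any():
        raise GLMError(
            "no gene has positive counts in every sample; size factors are "
            "undefined — apply stronger gene filtering first"
        )
    logs = np.log(arr[all_positive])
    log_ratios = logs - logs.mean(axis=1, keepdims=True)
    sf = np.exp(np.median(log_ratios, axis=0))
    return pd.Series(sf, index=counts.columns, name="size_factor")


# ---------------------------------------------------------------------------
# likelihood pieces
# ---------------------------------------------------------------------------

def _nb_deviance(K: np.ndarray, mu: np.ndarray, tau: np.ndarray) -> np.ndarray:
    """Per-gene NB deviance; rows are genes. tau broadcast per gene."""
    K = np.asarray(K, float)
    mu = np.maximum(mu, 1e-300)
    tau = np.asarray(tau, float)[:, None]
    with np.errstate(divide="ignore", invalid="ignore"):
        t1 = np.where(K > 0, K * np.log(np.maximum(K, 1e-300) / mu), 0.0)
        r = 1.0 / np.maximum(tau, 1e-300)
        t2 = (K + r) * np.log((1.0 + tau * K) / (1.0 + tau * mu))
        poisson = K - mu
        t2 = np.where(tau > 1e-10, t2, poisson)
    return 2.0 * (t1 - t2).sum(axis=1)


def _nb_loglik(K: np.ndarray, mu: np.ndarray, tau: np.ndarray) -> np.ndarray:
    """Per-gene NB log-likelihood; tau has one value per gene row."""
    r = 1.0 / np.maximum(tau, 1e-300)[:, None]
    mu = np.maximum(mu, 1e-300)
    ll = (
        special.gammaln(K + r)
        - special.gammaln(r)
        - special.gammaln(K + 1.0)
        + r * np.log(r / (r + mu))
        + K * np.log(mu / (r + mu))
    )
    return ll.sum(axis=1)


# ---------------------------------------------------------------------------
# IRLS
# ---------------------------------------------------------------------------

def _init_beta(K: np.ndarray, X: np.ndarray, sf: np.ndarray) -> np.ndarray:
    eta0 = np.log(K / sf + 0.5)
    beta, *_ = np.linalg.lstsq(X, eta0.T, rcond=None)
    return beta.T  # genes x P


def _solve_batch(A: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Solve per-gene normal equations with a tiny ridge fallback."""
    try:
        return np.linalg.solve(A, b[..., None])[..., 0]
    except np.linalg.LinAlgError:
        ridge = 1e-8 * np.eye(A.shape[-1])
        return np.linalg.solve(A + ridge, b[..., None])[..., 0]


def irls_fit(
    K: np.ndarray,
    X: np.ndarray,
    size_factors: np.ndarray,
    dispersion: np.ndarray,
    maxiter: int = 100,
    tol: float = 1e-8,
):
    """Vectorised IRLS for all genes at once (natural-log internals).

    Returns ``(beta_ln, cov_ln, converged, n_iter, mu)`` where ``beta_ln``
    is genes x P on the natural-log scale and ``cov_ln`` the per-gene
    coefficient covariance from the Fisher information at convergence.
    """
    K = np.asarray(K, float)
    X = np.asarray(X, float)
    sf = np.asarray(size_factors, float)
    tau = np.broadcast_to(np.asarray(dispersion, float), (K.shape[0],)).copy()
    G, S = K.shape
    P = X.shape[1]
    off = np.log(sf)

    beta = _init_beta(K, X, sf)

    def mu_of(b):
        lin = np.clip(b @ X.T + off, -70.0, 70.0)
        return np.exp(lin)

    dev = _nb_deviance(K, mu_of(beta), tau)
    converged = np.zeros(G, bool)
    n_iter = np.zeros(G, int)

    for _ in range(maxiter):
        active = ~converged
        if not active.any():
            break
        ba = beta[active]
        Ka = K[active]
        ta = tau[active]
        mu = mu_of(ba)
        w = mu / (1.0 + ta[:, None] * mu)
        z = (np.log(mu) - off) + (Ka - mu) / mu
        XtWX = np.einsum("sp,gs,sq->gpq", X, w, X, optimize=True)
        XtWz = np.einsum("gs,sp,gs->gp", w, X, z, optimize=True)
        bnew = _solve_batch(XtWX, XtWz)
        dnew = _nb_deviance(Ka, mu_of(bnew), ta)
        # step-halving for genes whose deviance increased
        da = dev[active]
        for _h in range(6):
            worse = dnew > da + 1e-10
            if not worse.any():
                break
            bnew[worse] = 0.5 * (bnew[worse] + ba[worse])
            dnew[worse] = _nb_deviance(Ka[worse], mu_of(bnew[worse]), ta[worse])
        just_conv = np.abs(da - dnew) <= tol * (np.abs(dnew) + 0.1)
        idx = np.where(active)[0]
        beta[idx] = bnew
        dev[idx] = dnew
        n_iter[idx] += 1
        converged[idx[just_conv]] = True

    mu = mu_of(beta)
    w = mu / (1.0 + tau[:, None] * mu)
    XtWX = np.einsum("sp,gs,sq->gpq", X, w, X, optimize=True)
    cov = np.full((G, P, P), np.nan)
    for g in range(G):
        try:
            cov[g] = np.linalg.inv(XtWX[g])
        except np.linalg.LinAlgError:
            pass
    return beta, cov, converged, n_iter, mu


# ---------------------------------------------------------------------------
# dispersion
# ---------------------------------------------------------------------------

def _mom_dispersion(K: np.ndarray, mu: np.ndarray) -> np.ndarray:
    """Method-of-moments dispersion from residuals around fitted means."""
    num = ((K - mu) ** 2 - mu).sum(axis=1)
    den = np.maximum((mu**2).sum(axis=1), 1e-300)
    return np.clip(num / den, 1e-4, 10.0)


def _profile_objective(
    K: np.ndarray, mu: np.ndarray, X: np.ndarray, tau: np.ndarray, cr_adjust: bool
) -> np.ndarray:
    ll = _nb_loglik(K, mu, tau)
    if cr_adjust:
        w = mu / (1.0 + tau[:, None] * mu)
        XtWX = np.einsum("sp,gs,sq->gpq", X, w, X, optimize=True)
        sign, logdet = np.linalg.slogdet(XtWX)
        ll = ll - 0.5 * np.where(sign > 0, logdet, np.inf)
    return ll


def estimate_dispersion(
    counts,
    design_matrix,
    size_factors,
    mu: np.ndarray | None = None,
    cr_adjust: bool = True,
    floor: float = DISPERSION_FLOOR,
) -> pd.Series:
    """Per-gene dispersion by maximising the (Cox-Reid adjusted) profile likelihood.

    ``mu`` are fitted means; when omitted, a preliminary IRLS pass with a
    method-of-moments dispersion provides them.  The search is a vectorised
    bracketed grid refinement over log(tau) in [log(floor), log(25)]; genes
    whose profile objective is degenerate fall back to the method-of-moments
    estimate.
    """
    K = np.asarray(counts, float)
    X = np.asarray(design_matrix, float)
    sf = np.asarray(size_factors, float)
    index = counts.index if isinstance(counts, pd.DataFrame) else pd.RangeIndex(K.shape[0])
    G = K.shape[0]

    if mu is None:
        beta0 = _init_beta(K, X, sf)
        mu0 = np.exp(np.clip(beta0 @ X.T + np.log(sf), -70, 70))
        tau0 = _mom_dispersion(K, mu0)
        _, _, _, _, mu = irls_fit(K, X, sf, tau0, maxiter=30)
    mom = _mom_dispersion(K, mu)

    lo = np.full(G, np.log(floor))
    hi = np.full(G, np.log(DISPERSION_CEILING))
    npts = 9
    best = np.full(G, np.log(np.clip(mom, floor, DISPERSION_CEILING)))
    for round_ in range(6):
        grid = lo[:, None] + (hi - lo)[:, None] * np.linspace(0.0, 1.0, npts)
        vals = np.stack(
            [_profile_objective(K, mu, X, np.exp(grid[:, t]), cr_adjust) for t in range(npts)],
            axis=1,
        )
        vals = np.where(np.isfinite(vals), vals, -np.inf)
        arg = np.argmax(vals, axis=1)
        best = np.take_along_axis(grid, arg[:, None], axis=1)[:, 0]
        half = (hi - lo) / (npts - 1)
        lo = np.maximum(best - half, np.log(floor))
        hi = np.minimum(best + half, np.log(DISPERSION_CEILING))
    tau = np.exp(best)

    # degenerate profile (all -inf) -> method of moments fallback
    finite = np.isfinite(
        _profile_objective(K, mu, X, tau, cr_adjust)
    )
    if not finite.all():
        tau = np.where(finite, tau, np.clip(mom, floor, DISPERSION_CEILING))
    tau = np.maximum(tau, floor)
    out = pd.Series(tau, index=index, name="dispersion")
    out.attrs["mom_fallback"] = (~finite).sum()
    return out


# ---------------------------------------------------------------------------
# model / results
# ---------------------------------------------------------------------------

class NBGLM:
    """Per-gene negative binomial GLM with log2 link and size-factor offsets.

    Parameters
    ----------
    counts : DataFrame
        Genes x samples nonnegative integer counts.
    metadata : DataFrame
        Sample metadata indexed by sample id with the design factor columns.
    design : DesignSpec
        Which factors enter the model and whether their interaction does.
    size_factors : Series or array, optional
        Fixed size factors; estimated by median-of-ratios when omitted.
    """

    def __init__(self, counts, metadata, design: DesignSpec, size_factors=None):
        counts = validate_counts(counts)
        metadata = align(counts, metadata)
        self.counts = counts
        self.metadata = metadata
        self.design = design.resolve(metadata)
        self.exog = self.design.matrix(metadata)
        if size_factors is None:
            self.size_factors = estimate_size_factors(counts)
        else:
            sf = np.broadcast_to(np.asarray(size_factors, float), (counts.shape[1],))
            if (sf <= 0).any():
                raise GLMError("size factors must be positive")
            self.size_factors = pd.Series(sf, index=counts.columns, name="size_factor")

    def _degenerate_flags(self) -> np.ndarray:
        K = self.counts.to_numpy()
        flags = np.zeros(K.shape[0], bool)
        for cell_idx in design_cells(self.exog):
            flags |= (K[:, cell_idx] == 0).all(axis=1)
        return flags

    def fit(self, dispersion=None, maxiter: int = 100, tol: float = 1e-8) -> "NBGLMResults":
        """Fit all genes; returns an :class:`NBGLMResults`.

        ``dispersion`` may be a scalar or per-gene array to fix tau (e.g. at
        the floor for a Poisson-limit fit); by default it is estimated by
        Cox-Reid adjusted profile likelihood, alternating once with IRLS.
        """
        K = self.counts.to_numpy(float)
        X = self.exog.to_numpy(float)
        sf = self.size_factors.to_numpy()
        G = K.shape[0]

        if dispersion is not None:
            tau = np.broadcast_to(np.asarray(dispersion, float), (G,)).copy()
            if (tau < 0).any():
                raise GLMError("dispersion must be nonnegative")
            tau = np.maximum(tau, DISPERSION_FLOOR)
            dispersion_estimated = False
        else:
            beta0 = _init_beta(K, X, sf)
            mu0 = np.exp(np.clip(beta0 @ X.T + np.log(sf), -70, 70))
            tau0 = _mom_dispersion(K, mu0)
            _, _, _, _, mu1 = irls_fit(K, X, sf, tau0, maxiter=30, tol=tol)
            tau = estimate_dispersion(
                self.counts, self.exog, sf, mu=mu1
            ).to_numpy()
            dispersion_estimated = True

        beta, cov, converged, n_iter, mu = irls_fit(K, X, sf, tau, maxiter=maxiter, tol=tol)

        se = np.sqrt(np.maximum(np.diagonal(cov, axis1=1, axis2=2), 0.0))
        flags = np.array([""] * G, dtype=object)
        degenerate = self._degenerate_flags()
        flags[degenerate] = _append_flag(flags[degenerate], FLAG_DEGENERATE)
        flags[~converged] = _append_flag(flags[~converged], FLAG_NOT_CONVERGED)
        bad_se = ~np.isfinite(se).all(axis=1) | (se <= 0).any(axis=1)
        flags[bad_se & ~degenerate] = _append_flag(flags[bad_se & ~degenerate], FLAG_SE_UNDEFINED)

        genes = self.counts.index
        coef_names = list(self.exog.columns)
        return NBGLMResults(
            model=self,
            params=pd.DataFrame(beta / LN2, index=genes, columns=coef_names),
            bse=pd.DataFrame(se / LN2, index=genes, columns=coef_names),
            cov_ln=cov,
            dispersion=pd.Series(tau, index=genes, name="dispersion"),
            converged=pd.Series(converged, index=genes, name="converged"),
            n_iter=pd.Series(n_iter, index=genes, name="n_iter"),
            flags=pd.Series(flags, index=genes, name="flag"),
            dispersion_estimated=dispersion_estimated,
        )


def _append_flag(existing: np.ndarray, flag: str) -> np.ndarray:
    return np.array([f"{e};{flag}" if e else flag for e in existing], dtype=object)


@dataclass
class NBGLMResults:
    """Fitted per-gene NB GLM: log2-scale coefficients, SEs, dispersions.

    ``params`` and ``bse`` are genes x coefficients DataFrames on the log2
    scale; ``flags`` marks genes whose estimates are unreliable (degenerate
    all-zero design cell, non-convergence, undefined standard errors).
    """

    model: NBGLM
    params: pd.DataFrame
    bse: pd.DataFrame
    cov_ln: np.ndarray
    dispersion: pd.Series
    converged: pd.Series
    n_iter: pd.Series
    flags: pd.Series
    dispersion_estimated: bool = True

    @property
    def size_factors(self) -> pd.Series:
        return self.model.size_factors

    def predict_log2(self) -> pd.DataFrame:
        """Fitted log2 concentrations (q scale, no size-factor offset); samples x genes."""
        X = self.model.exog.to_numpy()
        return pd.DataFrame(
            (self.params.to_numpy() @ X.T).T,
            index=self.model.exog.index,
            columns=self.params.index,
        )

    def wald_test(self, contrast: str, shrink: bool = True) -> pd.DataFrame:
        """Wald test of a single coefficient against zero for every gene.

        Returns the standard results table: raw and (optionally) shrunken
        log2 fold change, standard error, z statistic, two-sided p-value and
        Benjamini-Hochberg adjusted p-value.  Flagged genes receive NaN
        statistics and keep their flag in the ``flag`` column.
        """
        if contrast not in self.params.columns:
            raise GLMError(
                f"unknown contrast {contrast!r}; available: {list(self.params.columns)}"
            )
        lfc = self.params[contrast].copy()
        se = self.bse[contrast].copy()
        bad = (self.flags != "").to_numpy() | ~np.isfinite(se) | (se <= 0)
        stat = lfc / se
        pval = 2.0 * stats.norm.sf(np.abs(stat))
        pval = pd.Series(np.where(bad, np.nan, pval), index=lfc.index)
        stat = stat.mask(bad)
        padj = adjust_fdr(pval)
        table = pd.DataFrame(
            {
                "contrast": contrast,
                "log2fc_raw": lfc,
                "log2fc_shrunk": np.nan,
                "se": se,
                "stat": stat,
                "pvalue": pval,
                "padj": padj,
                "flag": self.flags,
            }
        )
        table.index.name = "gene_id"
        if shrink:
            table["log2fc_shrunk"] = shrink_lfc(lfc.mask(bad), se.mask(bad))
        return table

    def summary(self) -> str:
        """Plain-text overview of the fit, statsmodels-style."""
        disp = self.dispersion
        lines = [
            "Per-gene negative binomial GLM (log2 link)",
            f"  genes: {self.params.shape[0]}   samples: {self.model.exog.shape[0]}",
            f"  design columns: {list(self.params.columns)}",
            f"  converged: {int(self.converged.sum())}/{len(self.converged)}"
            f"   flagged: {int((self.flags != '').sum())}",
            f"  dispersion quartiles: {np.percentile(disp, 25):.4g} / "
            f"{np.percentile(disp, 50):.4g} / {np.percentile(disp, 75):.4g}",
            f"  size factors: min {self.size_factors.min():.3f}, "
            f"max {self.size_factors.max():.3f}",
        ]
        return "\n".join(lines)


# ---------------------------------------------------------------------------
# testing helpers
# ---------------------------------------------------------------------------

def wald_test(results: NBGLMResults, contrast: str, shrink: bool = True) -> pd.DataFrame:
    """Functional alias of :meth:`NBGLMResults.wald_test`."""
    return results.wald_test(contrast, shrink=shrink)


def adjust_fdr(pvalues: pd.Series) -> pd.Series:
    """Benjamini-Hochberg step-up adjustment; NaNs are excluded and propagate."""
    p = pd.Series(pvalues, dtype=float)
    out = pd.Series(np.nan, index=p.index)
    ok = p.notna()
    if ((p[ok] < 0) | (p[ok] > 1)).any():
        raise GLMError("p-values must lie in [0, 1]")
    if ok.any():
        out[ok] = multipletests(p[ok].to_numpy(), method="fdr_bh")[1]
    return out


def _normal_posterior_mode(raw, se, prior_sd):
    """Posterior mode for a normal likelihood and zero-centred normal prior."""
    pv = float(prior_sd) ** 2
    return np.asarray(raw) * pv / (pv + np.asarray(se) ** 2)


def shrink_lfc(lfc: pd.Series, se: pd.Series) -> pd.Series:
    """Empirical-Bayes shrinkage of log2 fold changes.

    A zero-centred normal prior with scale estimated from the spread of the
    raw estimates in excess of their sampling noise; the shrunken value is
    the posterior mode ``raw * prior^2 / (prior^2 + se^2)``.  Noise-driven
    effects move toward zero while precise large effects are nearly
    untouched.  When the excess spread is degenerate (no evidence of real
    effects beyond noise) the raw values are returned with a warning.
    """
    lfc = pd.Series(lfc, dtype=float)
    se = pd.Series(se, dtype=float)
    ok = lfc.notna() & se.notna() & (se > 0)
    if not ok.any():
        return lfc.copy()
    prior_var = float(np.mean(lfc[ok] ** 2) - np.mean(se[ok] ** 2))
    if not np.isfinite(prior_var) or prior_var <= 1e-12:
        warnings.warn(
            "degenerate shrinkage prior (raw spread does not exceed noise); "
            "returning unshrunken estimates",
            RuntimeWarning,
            stacklevel=2,
        )
        return lfc.copy()
    shrunk = lfc.copy()
    shrunk[ok] = _normal_posterior_mode(lfc[ok], se[ok], np.sqrt(prior_var))
    shrunk.attrs["prior_sd"] = float(np.sqrt(prior_var))
    return shrunk


def fit_glm(
    counts, metadata, design: DesignSpec, size_factors=None, dispersion=None
) -> NBGLMResults:
    """One-call convenience wrapper: build an :class:`NBGLM` and fit it."""
    return NBGLM(counts, metadata, design, size_factors=size_factors).fit(
        dispersion=dispersion
    )
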