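"""Statistical engines for allelic-imbalance testing.

Two model classes in the statsmodels mould (construct from data, ``fit()``
returns a results object with estimates, standard errors, a likelihood-ratio
test and a ``summary()`` table):

:class:`PairedAlleleModel`
    Negative-binomial GLM on the two counts per sample (maternal and
    paternal, or methylated and unmethylated), with one indicator per
    sample absorbing total abundance, an allele main effect, and
    allele x group interactions.  Because every sample contributes a pair,
    the sample effects make the totals ancillary and the likelihood-ratio
    test of the interactions is a test of allelic *balance* between groups.

:class:`BetaBinomialModel`
    Beta-binomial regression of the maternal fraction on group, with the
    intraclass correlation (phi) held fixed.  Used when informativeness
    varies across samples (mosaic backcross designs) and a per-gene
    dispersion cannot be estimated.

Plus Cox-Reid adjusted-profile-likelihood dispersion estimation (common and
tagwise) for the negative-binomial engine.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import statsmodels.api as sm
from scipy import optimize, special, stats

__all__ = [
    "PairedAlleleModel",
    "PairedAlleleResults",
    "BetaBinomialModel",
    "BetaBinomialResults",
    "estimate_dispersions",
]

_POISSON_EPS = 1e-8  # below this the NB family degenerates to Poisson


def _glm_family(dispersion: float):
    if dispersion < _POISSON_EPS:
        return sm.families.Poisson()
    return sm.families.NegativeBinomial(alpha=dispersion)


def _fit_glm(y: np.ndarray, X: np.ndarray, dispersion: float):
    model = sm.GLM(y, X, family=_glm_family(dispersion))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return model.fit(maxiter=200, tol=1e-10)


@dataclass
class PairedAlleleResults:
    """Fit of the paired negative-binomial allelic model."""

    params: dict[str, float]
    bse: dict[str, float]
    llf: float
    llf_null: float
    lrt_statistic: float
    df: int
    pvalue: float
    dispersion: float
    n_samples: int
    term_names: list[str] = field(repr=False, default_factory=list)

    def summary(self) -> str:
        lines = [
            "Paired negative-binomial allelic model",
            f"  samples: {self.n_samples}    dispersion (NB2 alpha): "
            f"{self.dispersion:.4g}",
            f"  LRT of allele x group terms: stat={self.lrt_statistic:.4f}, "
            f"df={self.df}, p={self.pvalue:.4g}",
            "",
            f"  {'term':<24}{'coef':>12}{'std err':>12}",
        ]
        for name in self.term_names:
            lines.append(f"  {name:<24}{self.params[name]:>12.4f}"
                         f"{self.bse[name]:>12.4f}")
        return "\n".join(lines)


class PairedAlleleModel:
    """Paired NB GLM for two counts per sample.

    Parameters
    ----------
    count_a, count_b
        Per-sample counts for the two members of each pair.  ``count_a``
        is the level whose enrichment the allele effect measures (the
        maternal count, or the methylated count).
    groups
        Per-sample group labels (genotypes); effects are coded relative
        to ``reference``.
    strata
        Optional second factor (e.g. Cre line) entering as additional
        allele x stratum interactions when it has more than one level.
    dispersion
        NB2 dispersion alpha (variance mu + alpha mu^2); 0 gives Poisson.
    reference
        Reference group label; defaults to ``"wt"`` when present, else the
        first label in sorted order.
    """

    def __init__(self, count_a, count_b, groups, strata=None,
                 dispersion: float = 0.0, reference: str | None = None):
        count_a = np.asarray(count_a, dtype=float)
        count_b = np.asarray(count_b, dtype=float)
        groups = np.asarray(groups, dtype=object)
        if count_a.shape != count_b.shape or count_a.shape != groups.shape:
            raise ValueError("count_a, count_b and groups must align")
        keep = (count_a + count_b) > 0
        count_a, count_b, groups = count_a[keep], count_b[keep], groups[keep]
        if strata is not None:
            strata = np.asarray(strata, dtype=object)[keep]
        n = count_a.size
        levels = sorted(set(groups))
        if reference is None:
            reference = "wt" if "wt" in levels else levels[0]
        if reference not in levels:
            raise ValueError(f"reference group {reference!r} absent from data")
        test_levels = [g for g in levels if g != reference]
        if not test_levels:
            raise ValueError("need at least two groups with nonzero pairs")
        counts_per_group = {g: int((groups == g).sum()) for g in levels}
        low = [g for g, c in counts_per_group.items() if c < 1]
        if low:
            raise ValueError(f"groups {low} have no usable samples")

        # long format: row 2i = count_a of sample i, row 2i+1 = count_b
        y = np.empty(2 * n)
        y[0::2] = count_a
        y[1::2] = count_b
        allele = np.zeros(2 * n)
        allele[0::2] = 1.0

        names: list[str] = []
        cols: list[np.ndarray] = []
        for i in range(n):
            ind = np.zeros(2 * n)
            ind[2 * i:2 * i + 2] = 1.0
            cols.append(ind)
            names.append(f"sample[{i}]")
        cols.append(allele)
        names.append("allele")
        null_end = len(cols)
        if strata is not None:
            for lev in sorted(set(strata))[1:]:
                col = allele.copy()
                col[0::2] *= (strata == lev)
                col[1::2] *= (strata == lev)
                cols.append(col)
                names.append(f"allele:stratum[{lev}]")
                null_end += 1
        test_start = len(cols)
        for g in test_levels:
            col = allele.copy()
            member = (groups == g).astype(float)
            col[0::2] *= member
            col[1::2] *= member
            cols.append(col)
            names.append(f"allele:group[{g}]")

        self.endog = y
        self.exog = np.column_stack(cols)
        self.exog_null = self.exog[:, :test_start]
        self.term_names = names
        self.df_test = self.exog.shape[1] - test_start
        self.dispersion = float(dispersion)
        self.n_samples = n
        self.reference = reference

    def fit(self) -> PairedAlleleResults:
        full = _fit_glm(self.endog, self.exog, self.dispersion)
        null = _fit_glm(self.endog, self.exog_null, self.dispersion)
        stat = max(0.0, 2.0 * (full.llf - null.llf))
        p = float(stats.chi2.sf(stat, self.df_test)) if self.df_test else np.nan
        return PairedAlleleResults(
            params=dict(zip(self.term_names, full.params)),
            bse=dict(zip(self.term_names, full.bse)),
            llf=float(full.llf), llf_null=float(null.llf),
            lrt_statistic=float(stat), df=self.df_test, pvalue=p,
            dispersion=self.dispersion, n_samples=self.n_samples,
            term_names=self.term_names)


# ---------------------------------------------------------------------------
# beta-binomial regression with fixed intraclass correlation

def _betabin_loglik_grad(beta, X, succ, fail, rho):
    """Log-likelihood and gradient of the logit-linear beta-binomial.

    Variance of ``succ`` given depth n is n pi (1-pi) (1 + (n-1) rho).
    rho == 0 reduces to the binomial.
    """
    eta = np.clip(X @ beta, -30.0, 30.0)
    pi = special.expit(eta)
    n = succ + fail
    const = (special.gammaln(n + 1) - special.gammaln(succ + 1)
             - special.gammaln(fail + 1))
    if rho <= 0.0:
        ll = float(np.sum(const + succ * np.log(pi) + fail * np.log1p(-pi)))
        dl_deta = succ - n * pi
        return ll, X.T @ dl_deta
    s = (1.0 - rho) / rho
    a = pi * s
    b = (1.0 - pi) * s
    ll = float(np.sum(const + special.betaln(succ + a, fail + b)
                      - special.betaln(a, b)))
    dl_dpi = s * (special.digamma(succ + a) - special.digamma(a)
                  - special.digamma(fail + b) + special.digamma(b))
    dl_deta = dl_dpi * pi * (1.0 - pi)
    return ll, X.T @ dl_deta


def _betabin_maximize(X, succ, fail, rho, start):
    def neg(beta):
        ll, grad = _betabin_loglik_grad(beta, X, succ, fail, rho)
        return -ll, -grad

    res = optimize.minimize(neg, start, jac=True, method="BFGS",
                            options={"gtol": 1e-8, "maxiter": 500})
    # fall back to a derivative-free polish if BFGS stalled early
    if not res.success and res.nit < 2:
        res = optimize.minimize(lambda b: neg(b)[0], start,
                                method="Nelder-Mead",
                                options={"xatol": 1e-10, "fatol": 1e-10})
    return res.x, -float(res.fun)


@dataclass
class BetaBinomialResults:
    """Fit of the fixed-dispersion beta-binomial allelic model."""

    params: dict[str, float]
    llf: float
    llf_null: float
    lrt_statistic: float
    df: int
    pvalue: float
    phi: float
    n_samples: int
    fitted_proportions: dict[str, float]

    def summary(self) -> str:
        lines = [
            "Beta-binomial allelic-imbalance model "
            f"(fixed phi={self.phi:g})",
            f"  samples: {self.n_samples}",
            f"  LRT of group terms: stat={self.lrt_statistic:.4f}, "
            f"df={self.df}, p={self.pvalue:.4g}",
            "",
            f"  {'term':<24}{'coef':>12}{'fitted pi':>12}",
        ]
        for name, val in self.params.items():
            pi = self.fitted_proportions.get(name, float("nan"))
            lines.append(f"  {name:<24}{val:>12.4f}{pi:>12.4f}")
        return "\n".join(lines)


class BetaBinomialModel:
    """Beta-binomial regression of a success fraction on group.

    The mean is logit-linear in an intercept plus one effect per non-
    reference group; the intraclass correlation ``phi`` is fixed, never
    re-estimated.  ``fit()`` performs the likelihood-ratio test of the
    group effects against the intercept-only null.
    """

    def __init__(self, success, failure, groups, phi: float,
                 reference: str | None = None):
        success = np.asarray(success, dtype=float)
        failure = np.asarray(failure, dtype=float)
        groups = np.asarray(groups, dtype=object)
        if not 0.0 <= phi < 1.0:
            raise ValueError("phi must lie in [0, 1)")
        keep = (success + failure) > 0
        success, failure, groups = success[keep], failure[keep], groups[keep]
        levels = sorted(set(groups))
        if reference is None:
            reference = "wt" if "wt" in levels else (levels[0] if levels else None)
        if reference not in levels:
            raise ValueError("reference group has no informative samples")
        if len(levels) < 2:
            raise ValueError("need informative samples in at least two groups")
        self.success, self.failure, self.groups = success, failure, groups
        self.levels = levels
        self.reference = reference
        self.phi = float(phi)
        cols = [np.ones(success.size)]
        self.term_names = ["intercept"]
        for g in levels:
            if g == reference:
                continue
            cols.append((groups == g).astype(float))
            self.term_names.append(f"group[{g}]")
        self.exog = np.column_stack(cols)

    @staticmethod
    def _empirical_logit(succ, fail):
        p = (succ.sum() + 0.5) / (succ.sum() + fail.sum() + 1.0)
        return special.logit(p)

    def fit(self) -> BetaBinomialResults:
        start = np.zeros(self.exog.shape[1])
        start[0] = self._empirical_logit(
            self.success[self.groups == self.reference],
            self.failure[self.groups == self.reference])
        for j, name in enumerate(self.term_names[1:], start=1):
            g = name[len("group["):-1]
            mask = self.groups == g
            start[j] = self._empirical_logit(self.success[mask],
                                             self.failure[mask]) - start[0]
        beta, llf = _betabin_maximize(self.exog, self.success, self.failure,
                                      self.phi, start)
        null_start = np.array([self._empirical_logit(self.success, self.failure)])
        beta0, llf0 = _betabin_maximize(np.ones((self.success.size, 1)),
                                        self.success, self.failure,
                                        self.phi, null_start)
        df = self.exog.shape[1] - 1
        stat = max(0.0, 2.0 * (llf - llf0))
        p = float(stats.chi2.sf(stat, df))
        fitted = {"intercept": float(special.expit(beta[0]))}
        for j, name in enumerate(self.term_names[1:], start=1):
            fitted[name] = float(special.expit(beta[0] + beta[j]))
        return BetaBinomialResults(
            params=dict(zip(self.term_names, beta)),
            llf=llf, llf_null=llf0, lrt_statistic=stat, df=df, pvalue=p,
            phi=self.phi, n_samples=int(self.success.size),
            fitted_proportions=fitted)


# ---------------------------------------------------------------------------
# Cox-Reid dispersion estimation

_PHI_GRID = np.logspace(-4, np.log10(3.0), 25)


def _adjusted_profile_loglik(y, X, phi):
    """Cox-Reid adjusted profile log-likelihood at NB dispersion phi."""
    res = _fit_glm(y, X, phi)
    mu = np.clip(res.fittedvalues, 1e-10, None)
    w = mu / (1.0 + phi * mu)  # IRLS working weights, log link
    xtwx = X.T @ (X * w[:, None])
    sign, logdet = np.linalg.slogdet(xtwx)
    if sign <= 0:
        logdet = -np.inf
    return res.llf - 0.5 * logdet


def _interp_argmax(grid_log, scores):
    """Quadratic interpolation of the maximizer on a log-spaced grid."""
    k = int(np.argmax(scores))
    if k == 0 or k == len(scores) - 1:
        return grid_log[k]
    x0, x1, x2 = grid_log[k - 1:k + 2]
    y0, y1, y2 = scores[k - 1:k + 2]
    denom = (y0 - 2 * y1 + y2)
    if denom >= 0 or not np.isfinite(denom):
        return grid_log[k]
    x = x1 - 0.5 * ((x1 - x0) ** 2 * (y1 - y2) - (x1 - x2) ** 2 * (y1 - y0)) \
        / ((x1 - x0) * (y1 - y2) - (x1 - x2) * (y1 - y0))
    return float(np.clip(x, x0, x2))


def estimate_dispersions(observations, mode: str = "tagwise",
                         prior_weight: float = 10.0,
                         phi_grid: np.ndarray | None = None) -> np.ndarray:
    """Estimate NB dispersions across genes by adjusted profile likelihood.

    Parameters
    ----------
    observations
        Sequence of ``(y, X)`` pairs, one per gene: the response counts and
        the full design matrix of that gene's model.
    mode
        ``"common"`` returns the single dispersion maximizing the summed
        APL for every gene; ``"tagwise"`` maximizes each gene's APL plus
        ``prior_weight`` times the mean APL across genes, shrinking
        gene-wise estimates toward the common value.
    prior_weight
        Weight of the shared likelihood in tagwise mode, in units of
        equivalent genes.

    Returns
    -------
    ndarray of per-gene dispersions (constant in common mode).
    """
    if mode not in ("common", "tagwise"):
        raise ValueError(f"unknown dispersion mode {mode!r}")
    all_obs = [(np.asarray(y, dtype=float), np.asarray(X, dtype=float))
               for y, X in observations]
    usable = [i for i, (y, _) in enumerate(all_obs) if y.sum() > 0]
    if not usable:
        raise ValueError("no genes with nonzero counts")
    grid = _PHI_GRID if phi_grid is None else np.asarray(phi_grid, dtype=float)
    grid_log = np.log(grid)
    apl = np.empty((len(usable), grid.size))
    for row, i in enumerate(usable):
        y, X = all_obs[i]
        for k, phi in enumerate(grid):
            apl[row, k] = _adjusted_profile_loglik(y, X, phi)
    mean_apl = apl.mean(axis=0)
    common = float(np.exp(_interp_argmax(grid_log, mean_apl)))
    out = np.full(len(all_obs), common)
    if mode == "tagwise":
        for row, i in enumerate(usable):
            score = apl[row] + prior_weight * mean_apl
            out[i] = float(np.exp(_interp_argmax(grid_log, score)))
    return out
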