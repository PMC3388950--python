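"""Multilevel count models of accessibility on area deprivation.

The workhorse is :class:`MultilevelCountModel`, a random-intercept Poisson
or negative-binomial (NB2) regression for zone-level counts nested in
local authorities:

    y_ij | b_j ~ Poisson(mu_ij)   or   NB2(mu_ij, alpha)
    log mu_ij = x_ij' beta + offset_ij + b_j,      b_j ~ N(0, sigma^2)

The marginal likelihood integrates the local-authority intercepts out by
adaptive Gauss-Hermite quadrature (default 10 nodes, re-centred at the
per-cluster posterior mode each evaluation), so estimates are
deterministic and accurate at small cluster counts. Deprivation enters as
quintile dummies with Q1 (most affluent) as the baseline; population as a
log offset, so exponentiated coefficients are rate ratios (RR) of
accessible facilities per head. Intervals are Wald, reported at the 99%
level by default (residual spatial autocorrelation motivates the
conservative level).

Family choice follows the overdispersion rule: Poisson unless the Poisson
fit's Pearson dispersion exceeds 1 *and* a boundary-corrected likelihood-
ratio test of NB against Poisson is significant at 0.05. A spatial lag
covariate (log of 1 + mean neighbouring response) is offered to the model
only when the pre-model Moran permutation test is significant, and kept
only if it actually reduces the residual Moran's |I|.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
import scipy.optimize
from numpy.polynomial.hermite_e import hermegauss
from scipy.special import gammaln, logsumexp
from scipy.stats import chi2, norm

from .spatial import (
    SpatialDiagnostic,
    ZoneAdjacency,
    morans_i,
    morans_i_permutation_test,
    spatial_lag_covariate,
)

_STRATA = {1: "urban", 2: "urban", 3: "small town", 4: "small town", 5: "rural", 6: "rural"}


def urban_rural_stratum(urc6: int) -> str:
    """Collapse the six-fold urban-rural category to urban / small town /
    rural (1-2, 3-4, 5-6)."""
    try:
        return _STRATA[int(urc6)]
    except (KeyError, ValueError):
        raise ValueError(f"urban-rural category must be 1..6, got {urc6!r}")


# ---------------------------------------------------------------------------
# likelihood machinery


def _poisson_ll(y, eta):
    # eta is the log mean; clipped so wild optimizer steps stay finite
    eta = np.clip(eta, -700.0, 50.0)
    return y * eta - np.exp(eta) - gammaln(y + 1.0)


def _nb2_ll(y, eta, alpha):
    eta = np.clip(eta, -700.0, 50.0)
    mu = np.exp(eta)
    r = 1.0 / max(alpha, 1e-10)
    return (
        gammaln(y + r)
        - gammaln(r)
        - gammaln(y + 1.0)
        + r * (np.log(r) - np.log(r + mu))
        + y * (eta - np.log(r + mu))
    )


class _GHQuad:
    def __init__(self, k: int):
        # probabilists' nodes/weights: integral wrt standard normal density
        x, w = hermegauss(k)
        self.nodes = x
        self.logw = np.log(w) - 0.5 * np.log(2 * np.pi)


class MultilevelCountModel:
    """Random-intercept count regression (statsmodels-style interface).

    Parameters
    ----------
    endog : (n,) counts
    exog : (n, p) design matrix including the constant
    groups : (n,) cluster labels (local authorities)
    offset : (n,) optional log-scale offset, e.g. ``log(population)``
    family : ``"poisson"`` or ``"negbin"``
    exog_names : column names for reporting
    quad_points : Gauss-Hermite node count
    """

    def __init__(
        self,
        endog,
        exog,
        groups,
        offset=None,
        family: str = "negbin",
        exog_names: Sequence[str] | None = None,
        quad_points: int = 10,
    ):
        self.endog = np.asarray(endog, dtype=float)
        self.exog = np.asarray(exog, dtype=float)
        if self.exog.ndim == 1:
            self.exog = self.exog[:, None]
        n = self.endog.size
        if self.exog.shape[0] != n:
            raise ValueError("endog and exog lengths differ")
        if family not in ("poisson", "negbin"):
            raise ValueError(f"unknown family {family!r}")
        if np.any(self.endog < 0) or np.any(self.endog != np.floor(self.endog)):
            raise ValueError("endog must be non-negative counts")
        self.offset = np.zeros(n) if offset is None else np.asarray(offset, dtype=float)
        self.family = family
        codes, uniques = pd.factorize(np.asarray(groups))
        self.group_codes = codes
        self.group_labels = list(uniques)
        self.n_groups = len(uniques)
        self.exog_names = (
            list(exog_names)
            if exog_names is not None
            else [f"x{j}" for j in range(self.exog.shape[1])]
        )
        self.baseline_quintile = 1
        self.quad = _GHQuad(quad_points)

    # -- constructors --------------------------------------------------

    @classmethod
    def from_dataframe(
        cls,
        data: pd.DataFrame,
        response: str,
        group: str,
        quintile: str = "quintile",
        offset_log: str | None = "population",
        extra_covariates: Sequence[str] = (),
        family: str = "negbin",
        quad_points: int = 10,
    ) -> "MultilevelCountModel":
        """Build from a zone-level table with quintile dummies (Q1 baseline).

        ``offset_log`` names a column whose log becomes the offset.
        """
        qs = sorted(int(q) for q in data[quintile].unique())
        cols = [np.ones(len(data))]
        names = ["const"]
        for q in qs:
            if q == qs[0]:
                continue  # baseline: lowest quintile present (Q1 normally)
            cols.append((data[quintile].astype(int) == q).to_numpy(float))
            names.append(f"Q{q}")
        for c in extra_covariates:
            cols.append(data[c].to_numpy(float))
            names.append(c)
        offset = np.log(data[offset_log].to_numpy(float)) if offset_log else None
        model = cls(
            endog=data[response].to_numpy(float),
            exog=np.column_stack(cols),
            groups=data[group].to_numpy(),
            offset=offset,
            family=family,
            exog_names=names,
            quad_points=quad_points,
        )
        model.baseline_quintile = qs[0]
        return model

    # -- likelihood ----------------------------------------------------

    def _cluster_mode(self, eta, sigma, alpha, tol=1e-9, max_iter=50):
        """Posterior mode and curvature of each cluster's random intercept."""
        J = self.n_groups
        g = self.group_codes
        y = self.endog
        # warm start from the previous evaluation's modes (big speed win
        # inside the optimiser; the result is iterated to tolerance anyway)
        b = getattr(self, "_b_warm", np.zeros(J)).copy()
        s2 = max(sigma, 1e-8) ** 2
        for _ in range(max_iter):
            mu = np.exp(np.clip(eta + b[g], -700.0, 50.0))
            if self.family == "poisson":
                score_obs = y - mu
                info_obs = mu
            else:
                denom = 1.0 + alpha * mu
                score_obs = (y - mu) / denom
                info_obs = mu * (1.0 + alpha * y) / denom**2
            score = np.bincount(g, weights=score_obs, minlength=J) - b / s2
            info = np.bincount(g, weights=info_obs, minlength=J) + 1.0 / s2
            step = score / info
            # dampen huge Newton steps for stability
            step = np.clip(step, -5.0, 5.0)
            b = b + step
            if np.max(np.abs(step)) < tol:
                break
        mu = np.exp(np.clip(eta + b[g], -700.0, 50.0))
        if self.family == "poisson":
            info_obs = mu
        else:
            denom = 1.0 + alpha * mu
            info_obs = mu * (1.0 + alpha * y) / denom**2
        curv = np.bincount(g, weights=info_obs, minlength=J) + 1.0 / s2
        self._b_warm = b.copy()
        return b, curv

    def _obs_ll(self, eta_plus_b, alpha):
        if self.family == "poisson":
            return _poisson_ll(self.endog, eta_plus_b)
        return _nb2_ll(self.endog, eta_plus_b, alpha)

    def loglike(self, params) -> float:
        """Marginal log-likelihood by adaptive Gauss-Hermite quadrature."""
        p = self.exog.shape[1]
        beta = params[:p]
        sigma = abs(params[p])
        alpha = abs(params[p + 1]) if self.family == "negbin" else None
        eta = self.exog @ beta + self.offset
        J = self.n_groups
        g = self.group_codes
        s2 = max(sigma, 1e-8) ** 2

        bhat, curv = self._cluster_mode(eta, sigma, alpha)
        shat = 1.0 / np.sqrt(curv)  # adaptive scale per cluster
        K = self.quad.nodes.size
        log_terms = np.empty((J, K))
        for k in range(K):
            bk = bhat + shat * self.quad.nodes[k]
            ll_obs = self._obs_ll(eta + bk[g], alpha)
            ll_cluster = np.bincount(g, weights=ll_obs, minlength=J)
            log_prior = -0.5 * bk**2 / s2 - 0.5 * np.log(2 * np.pi * s2)
            # adaptive GH: divide by the standard-normal kernel at the node
            log_kernel = self.quad.logw[k] - (-0.5 * self.quad.nodes[k] ** 2
                                              - 0.5 * np.log(2 * np.pi))
            log_terms[:, k] = ll_cluster + log_prior + log_kernel + np.log(shat)
        return float(np.sum(logsumexp(log_terms, axis=1)))

    # -- fitting -------------------------------------------------------

    def _start_params(self):
        import statsmodels.api as sm

        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                glm = sm.GLM(
                    self.endog, self.exog, family=sm.families.Poisson(), offset=self.offset
                ).fit()
            beta0 = np.asarray(glm.params, dtype=float)
            mu = np.asarray(glm.fittedvalues, dtype=float)
            if not np.all(np.isfinite(beta0)):
                raise ValueError("non-finite GLM start")
        except Exception:
            # crude but safe: intercept at the mean rate, other slopes 0
            rate = max(self.endog.mean() / max(np.exp(self.offset).mean(), 1e-12), 1e-8)
            beta0 = np.zeros(self.exog.shape[1])
            beta0[0] = np.log(rate)
            mu = np.exp(self.exog @ beta0 + self.offset)
        start = list(beta0) + [0.3]
        if self.family == "negbin":
            resid2 = (self.endog - mu) ** 2
            num = float(np.sum(resid2 - mu))
            den = float(np.sum(mu**2))
            alpha0 = max(num / den, 0.05) if den > 0 else 0.5
            start.append(min(alpha0, 5.0))
        return np.asarray(start)

    def fit(self, maxiter: int = 400) -> "MultilevelCountResults":
        """Maximize the marginal likelihood (BFGS from a single-level GLM
        start, with a Nelder-Mead rescue if the gradient path stalls)."""
        start = self._start_params()
        nll = lambda th: -self.loglike(th)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            opt = scipy.optimize.minimize(
                nll, start, method="BFGS", options={"maxiter": maxiter, "gtol": 1e-5}
            )
            best = opt
            if not opt.success:
                nm = scipy.optimize.minimize(
                    nll, opt.x, method="Nelder-Mead",
                    options={"maxiter": maxiter * 4, "xatol": 1e-6, "fatol": 1e-8},
                )
                if nm.fun <= opt.fun:
                    best = nm
        params = best.x.copy()
        converged = bool(opt.success or best.success)
        p = self.exog.shape[1]
        params[p:] = np.abs(params[p:])  # sigma, alpha are magnitudes
        return MultilevelCountResults(self, params, None, converged, -nll(params))

    def _cov_params(self, params, h: float = 1e-4):
        """Inverse numerical Hessian of the negative log-likelihood."""
        k = params.size
        H = np.empty((k, k))
        f = lambda th: -self.loglike(th)
        steps = h * np.maximum(1.0, np.abs(params))
        f0 = f(params)
        for i in range(k):
            for j in range(i, k):
                ei = np.zeros(k)
                ej = np.zeros(k)
                ei[i] = steps[i]
                ej[j] = steps[j]
                if i == j:
                    val = (f(params + ei) - 2 * f0 + f(params - ei)) / steps[i] ** 2
                else:
                    val = (
                        f(params + ei + ej)
                        - f(params + ei - ej)
                        - f(params - ei + ej)
                        + f(params - ei - ej)
                    ) / (4 * steps[i] * steps[j])
                H[i, j] = H[j, i] = val
        try:
            cov = np.linalg.inv(H)
            if not np.all(np.isfinite(cov)) or np.any(np.diag(cov) < 0):
                raise np.linalg.LinAlgError
        except np.linalg.LinAlgError:
            cov = np.linalg.pinv(H)
            d = np.diag(cov).copy()
            d[d < 0] = np.nan
            np.fill_diagonal(cov, d)
        return cov


class MultilevelCountResults:
    """Fitted multilevel count model: estimates, Wald intervals, rate
    ratios against the baseline quintile, and residual diagnostics."""

    def __init__(self, model, params, cov_params, converged, llf):
        self.model = model
        self.params_all = np.asarray(params)
        self._cov_all = None if cov_params is None else np.asarray(cov_params)
        self.converged = converged
        self.llf = float(llf)
        p = model.exog.shape[1]
        self.params = pd.Series(self.params_all[:p], index=model.exog_names)
        self.sigma_re = float(self.params_all[p])
        self.alpha = float(self.params_all[p + 1]) if model.family == "negbin" else 0.0

    @property
    def cov_all(self) -> np.ndarray:
        # the Hessian is only needed for intervals; computed on first use
        if self._cov_all is None:
            self._cov_all = self.model._cov_params(self.params_all)
        return self._cov_all

    @property
    def bse(self) -> pd.Series:
        p = self.model.exog.shape[1]
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            se = np.sqrt(np.diag(self.cov_all)[:p])
        return pd.Series(se, index=self.model.exog_names)

    @property
    def family(self) -> str:
        return self.model.family

    def conf_int(self, level: float = 0.99) -> pd.DataFrame:
        zcrit = norm.ppf(0.5 + level / 2.0)
        return pd.DataFrame(
            {
                "lower": self.params - zcrit * self.bse,
                "upper": self.params + zcrit * self.bse,
            }
        )

    def rate_ratios(self, level: float = 0.99) -> pd.DataFrame:
        """RR per quintile with Wald CIs; the baseline Q1 row is RR = 1
        with a degenerate interval."""
        ci = self.conf_int(level)
        base_q = getattr(self.model, "baseline_quintile", 1)
        rows = [{"quintile": base_q, "rr": 1.0, "ci_low": 1.0, "ci_high": 1.0,
                 "baseline": True}]
        with np.errstate(over="ignore"):
            for name in self.params.index:
                if name.startswith("Q") and name[1:].isdigit():
                    rows.append(
                        {
                            "quintile": int(name[1:]),
                            "rr": float(np.exp(self.params[name])),
                            "ci_low": float(np.exp(ci.loc[name, "lower"])),
                            "ci_high": float(np.exp(ci.loc[name, "upper"])),
                            "baseline": False,
                        }
                    )
        return pd.DataFrame(rows).sort_values("quintile").reset_index(drop=True)

    def predict_conditional(self) -> np.ndarray:
        """Fitted means at the empirical-Bayes cluster intercepts."""
        m = self.model
        p = m.exog.shape[1]
        eta = m.exog @ self.params_all[:p] + m.offset
        bhat, _ = m._cluster_mode(eta, max(self.sigma_re, 1e-8),
                                  self.alpha if m.family == "negbin" else None)
        return np.exp(eta + bhat[m.group_codes])

    def pearson_dispersion(self) -> float:
        """Pearson chi-square over residual df, under the fitted family's
        variance function."""
        m = self.model
        mu = self.predict_conditional()
        var = mu + (self.alpha * mu**2 if m.family == "negbin" else 0.0)
        chi2_stat = float(np.sum((m.endog - mu) ** 2 / var))
        dof = m.endog.size - m.exog.shape[1]
        return chi2_stat / max(dof, 1)

    def pearson_residuals(self) -> np.ndarray:
        mu = self.predict_conditional()
        var = mu + (self.alpha * mu**2 if self.model.family == "negbin" else 0.0)
        return (self.model.endog - mu) / np.sqrt(var)

    def summary(self, level: float = 0.99) -> str:
        ci = self.conf_int(level)
        tab = pd.DataFrame(
            {
                "coef": self.params,
                "std err": self.bse,
                f"[{(1-level)/2:.3f}": ci["lower"],
                f"{1-(1-level)/2:.3f}]": ci["upper"],
                "RR": np.exp(self.params),
            }
        )
        head = (
            f"Multilevel {self.model.family} regression "
            f"(random intercept: {self.model.n_groups} groups)\n"
            f"n obs: {self.model.endog.size}   log-likelihood: {self.llf:.3f}\n"
            f"sigma_RE: {self.sigma_re:.4f}"
        )
        if self.model.family == "negbin":
            head += f"   alpha (NB2): {self.alpha:.4f}"
        head += f"\nconverged: {self.converged}\n"
        return head + tab.to_string(float_format=lambda v: f"{v: .4f}") + "\n"


# ---------------------------------------------------------------------------
# family choice


@dataclass
class DispersionDecision:
    family: str
    pearson_dispersion: float
    lr_statistic: float | None
    lr_pvalue: float | None
    converged: bool


def overdispersion_decision(
    data: pd.DataFrame,
    response: str,
    group: str,
    quintile: str = "quintile",
    offset_log: str | None = "population",
    extra_covariates: Sequence[str] = (),
    quad_points: int = 10,
) -> DispersionDecision:
    """Choose Poisson vs negative binomial for the multilevel model.

    Negative binomial is selected when the Poisson fit's Pearson
    dispersion exceeds 1 and the boundary-corrected likelihood-ratio test
    of NB vs Poisson (p = 0.5 * P(chi2_1 >= LR)) is significant at 0.05;
    otherwise Poisson. Non-convergence falls back to negative binomial
    (the more robust family) and is flagged.
    """
    build = lambda fam: MultilevelCountModel.from_dataframe(
        data, response=response, group=group, quintile=quintile, offset_log=offset_log,
        extra_covariates=extra_covariates, family=fam, quad_points=quad_points,
    )
    try:
        pois = build("poisson").fit()
    except Exception:
        return DispersionDecision("negbin", np.nan, None, None, converged=False)
    disp = pois.pearson_dispersion()
    if not pois.converged:
        return DispersionDecision("negbin", disp, None, None, converged=False)
    if disp <= 1.0:
        return DispersionDecision("poisson", disp, None, None, converged=True)
    try:
        nb = build("negbin").fit()
    except Exception:
        return DispersionDecision("negbin", disp, None, None, converged=False)
    lr = max(2.0 * (nb.llf - pois.llf), 0.0)
    pval = 0.5 * chi2.sf(lr, df=1)
    family = "negbin" if pval < 0.05 else "poisson"
    return DispersionDecision(family, disp, lr, pval, converged=nb.converged)


# ---------------------------------------------------------------------------
# the full zone-level model with spatial diagnostics


@dataclass
class ModelSpec:
    """What to fit: one stratum x intensity x mode x threshold cell."""

    stratum: str
    intensity: str
    mode: str
    threshold: float
    conf_level: float = 0.99
    n_permutations: int = 999
    seed: int = 0
    quad_points: int = 10


@dataclass
class ModelResult:
    spec: ModelSpec
    rate_ratios: pd.DataFrame | None
    family: str
    sigma_re: float
    alpha: float
    converged: bool
    spatial_cov_included: bool
    pre_moran: SpatialDiagnostic | None
    residual_moran_i: float | None
    dispersion: DispersionDecision | None
    n_zones: int
    n_groups: int
    flags: list[str] = field(default_factory=list)
    results: MultilevelCountResults | None = None


def fit_count_glmm(
    data: pd.DataFrame,
    adjacency: ZoneAdjacency,
    spec: ModelSpec,
    response: str = "count",
    group: str = "la_id",
) -> ModelResult:
    """Fit one stratified accessibility model with spatial screening.

    ``data`` is a zone-level frame (one row per zone) with columns
    ``zone_id``, ``count``, ``quintile``, ``population``, ``la_id``.
    The pre-model Moran permutation test screens the response; when it is
    significant at the conservative 99% level a spatial lag covariate is
    offered, and retained only if it reduces residual Moran's |I|.
    """
    flags: list[str] = []
    data = data.reset_index(drop=True)
    n_zones = len(data)
    n_groups = data[group].nunique()
    if n_zones < 30:
        flags.append("low-n")
    if n_groups < 2:
        flags.append("single-group")
    present_q = sorted(data["quintile"].astype(int).unique())
    if present_q != [1, 2, 3, 4, 5]:
        flags.append(f"missing-quintiles:{sorted(set(range(1, 6)) - set(present_q))}")

    adj = adjacency.subset(list(data["zone_id"]))
    y = data[response].to_numpy(float)
    pre = None
    offer_spatial = False
    if n_zones >= 3 and np.var(y) > 0:
        try:
            pre = morans_i_permutation_test(
                y, adj, n_permutations=spec.n_permutations, seed=spec.seed
            )
            offer_spatial = pre.p_value <= (1.0 - spec.conf_level)
        except ValueError:  # e.g. no bordering pairs inside the stratum
            flags.append("moran-undefined")
    else:
        flags.append("moran-undefined")

    if np.all(y == y[0]):
        # a constant response (e.g. nothing reachable anywhere) carries no
        # deprivation gradient to estimate
        return ModelResult(
            spec=spec, rate_ratios=None, family="poisson", sigma_re=np.nan,
            alpha=np.nan, converged=False, spatial_cov_included=False,
            pre_moran=pre, residual_moran_i=None, dispersion=None,
            n_zones=n_zones, n_groups=n_groups, flags=flags + ["degenerate-constant"],
        )

    decision = overdispersion_decision(
        data, response=response, group=group, quad_points=spec.quad_points
    )
    family = decision.family

    def _fit(extra):
        model = MultilevelCountModel.from_dataframe(
            data, response=response, group=group, offset_log="population",
            extra_covariates=extra, family=family, quad_points=spec.quad_points,
        )
        res = model.fit()
        resid_i = None
        if n_zones >= 3:
            resid = res.pearson_residuals()
            if np.var(resid) > 0:
                try:
                    resid_i = morans_i(resid, adj)
                except ValueError:
                    resid_i = None
        return res, resid_i

    try:
        res_plain, i_plain = _fit([])
    except Exception as exc:  # pragma: no cover - defensive
        return ModelResult(
            spec=spec, rate_ratios=None, family=family, sigma_re=np.nan, alpha=np.nan,
            converged=False, spatial_cov_included=False, pre_moran=pre,
            residual_moran_i=None, dispersion=decision, n_zones=n_zones,
            n_groups=n_groups, flags=flags + [f"fit-error:{exc}"],
        )

    chosen, resid_i, spatial_included = res_plain, i_plain, False
    if offer_spatial:
        data = data.assign(spatial_lag=spatial_lag_covariate(y, adj))
        try:
            res_sp, i_sp = _fit(["spatial_lag"])
            if (
                i_sp is not None
                and i_plain is not None
                and abs(i_sp) < abs(i_plain)
                and res_sp.converged
            ):
                chosen, resid_i, spatial_included = res_sp, i_sp, True
            else:
                flags.append("spatial-cov-rejected")
        except Exception:
            flags.append("spatial-cov-failed")

    if not chosen.converged:
        flags.append("non-converged")
    return ModelResult(
        spec=spec,
        rate_ratios=chosen.rate_ratios(spec.conf_level),
        family=family,
        sigma_re=chosen.sigma_re,
        alpha=chosen.alpha,
        converged=chosen.converged,
        spatial_cov_included=spatial_included,
        pre_moran=pre,
        residual_moran_i=resid_i,
        dispersion=decision,
        n_zones=n_zones,
        n_groups=n_groups,
        flags=flags,
        results=chosen,
    )


def stratified_analysis(
    counts: pd.DataFrame,
    zones: pd.DataFrame,
    adjacency: ZoneAdjacency,
    conf_level: float = 0.99,
    n_permutations: int = 999,
    seed: int = 0,
    quad_points: int = 10,
    modes: Sequence[str] | None = None,
) -> tuple[pd.DataFrame, list[ModelResult]]:
    """One model per stratum x intensity x mode x threshold.

    ``counts`` is the long accessibility table; ``zones`` carries zone_id,
    population, quintile, stratum (or urc6) and la_id. Returns a tidy
    results frame (one row per quintile per fitted model, with
    diagnostics) plus the full :class:`ModelResult` objects; skipped cells
    (empty stratum) are recorded with an explicit row.
    """
    zones = zones.copy()
    if "stratum" not in zones.columns:
        zones["stratum"] = zones["urc6"].map(urban_rural_stratum)
    zcols = zones[["zone_id", "population", "quintile", "stratum", "la_id"]]
    merged = counts.merge(zcols, on="zone_id", how="left")
    modes = list(modes) if modes is not None else sorted(merged["mode"].unique())
    intensities = sorted(merged["intensity"].unique())
    thresholds = sorted(merged["threshold"].unique())
    strata = ["urban", "small town", "rural"]

    rows = []
    results: list[ModelResult] = []
    for stratum in strata:
        for intensity in intensities:
            for mode in modes:
                for thr in thresholds:
                    spec = ModelSpec(
                        stratum=stratum, intensity=intensity, mode=mode, threshold=thr,
                        conf_level=conf_level, n_permutations=n_permutations,
                        seed=seed, quad_points=quad_points,
                    )
                    cell = merged[
                        (merged["stratum"] == stratum)
                        & (merged["intensity"] == intensity)
                        & (merged["mode"] == mode)
                        & (merged["threshold"] == thr)
                    ]
                    if cell.empty:
                        rows.append(_result_row(spec, None, None, skipped=True))
                        continue
                    result = fit_count_glmm(cell, adjacency, spec)
                    results.append(result)
                    if result.rate_ratios is None:
                        rows.append(_result_row(spec, result, None, skipped=False))
                        continue
                    for _, rr in result.rate_ratios.iterrows():
                        rows.append(_result_row(spec, result, rr, skipped=False))
    return pd.DataFrame(rows), results


def _result_row(spec: ModelSpec, result: ModelResult | None, rr, skipped: bool) -> dict:
    row = {
        "stratum": spec.stratum,
        "intensity": spec.intensity,
        "mode": spec.mode,
        "threshold": spec.threshold,
        "skipped": skipped,
        "quintile": None if rr is None else int(rr["quintile"]),
        "rr": None if rr is None else float(rr["rr"]),
        "ci_low": None if rr is None else float(rr["ci_low"]),
        "ci_high": None if rr is None else float(rr["ci_high"]),
    }
    if result is not None:
        row.update(
            family=result.family,
            spatial_cov=result.spatial_cov_included,
            morans_i=None if result.pre_moran is None else result.pre_moran.morans_i,
            p_perm=None if result.pre_moran is None else result.pre_moran.p_value,
            residual_morans_i=result.residual_moran_i,
            converged=result.converged,
            flags=";".join(result.flags),
            n_zones=result.n_zones,
        )
    else:
        row.update(
            family=None, spatial_cov=None, morans_i=None, p_perm=None,
            residual_morans_i=None, converged=None, flags="empty-cell", n_zones=0,
        )
    return row
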