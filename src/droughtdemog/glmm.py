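"""Binomial generalized linear mixed models by Laplace approximation.

Used for monthly fruit-tree mortality: the response for a species-month row
is the (deaths, survivors) outcome of the monitored trees of that species in
that month, and the linear predictor is

    logit p = b0 + b1 * climate + u0_species + u1_species * climate + v_year

with a full 2x2 covariance for the species intercept/slope pair (diagonal
optional) and an independent hydro-year intercept variance.  The crossed
random effects rule out simple quadrature, so the marginal likelihood is
Laplace-approximated: an inner penalized IRLS finds the joint mode of the
fixed and random coefficients at given variance parameters, and an outer
Nelder-Mead maximizes the approximated marginal log-likelihood over the
Cholesky-parameterized covariance.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import optimize
from scipy.special import expit, gammaln

__all__ = ["BinomialGLMM"]


def _binom_loglik(d, n, eta):
    p = expit(eta)
    eps = 1e-12
    ll = d * np.log(np.clip(p, eps, None)) + (n - d) * np.log(np.clip(1 - p, eps, None))
    ll += gammaln(n + 1) - gammaln(d + 1) - gammaln(n - d + 1)
    return float(ll.sum())


class BinomialGLMM:
    """Binomial GLMM with species intercept+slope and year intercept terms.

    Scikit-learn-style estimator.  ``fit`` expects a species-month table
    with columns for the climate covariate, species, hydro-year, deaths and
    at-risk counts.

    Parameters
    ----------
    climate_col : str
        Continuous climate covariate (one per model).
    random_slope : bool
        Include a per-species random slope on the climate covariate.
    random_cov : {'full', 'diag'}
        Correlated or independent species intercept/slope pair.
    random_effects : bool
        False collapses the model to a plain binomial GLM (used for
        reduction checks).

    Attributes (after ``fit``)
    --------------------------
    coef_, se_ : fixed intercept and climate slope (log-odds scale).
    vc_ : dict with ``species_intercept_var``, ``species_slope_var``,
        ``species_cov``, ``year_var`` (absent components omitted).
    ranef_ : dict factor -> DataFrame/Series of modes.
    loglik_ : Laplace-approximated marginal log-likelihood.
    aicc_ : AICc with n = number of species-month rows.
    converged_, boundary_ : diagnostics.
    """

    def __init__(
        self,
        climate_col,
        species_col="species",
        year_col="hydro_year",
        deaths_col="n_deaths",
        at_risk_col="n_at_risk",
        random_slope=True,
        random_cov="full",
        random_effects=True,
        inner_tol=1e-9,
        max_inner=100,
        max_outer_fev=400,
    ):
        self.climate_col = climate_col
        self.species_col = species_col
        self.year_col = year_col
        self.deaths_col = deaths_col
        self.at_risk_col = at_risk_col
        self.random_slope = random_slope
        self.random_cov = random_cov
        self.random_effects = random_effects
        self.inner_tol = inner_tol
        self.max_inner = max_inner
        self.max_outer_fev = max_outer_fev

    def get_params(self, deep=True):
        return {
            k: getattr(self, k)
            for k in (
                "climate_col",
                "species_col",
                "year_col",
                "deaths_col",
                "at_risk_col",
                "random_slope",
                "random_cov",
                "random_effects",
                "inner_tol",
                "max_inner",
                "max_outer_fev",
            )
        }

    def set_params(self, **params):
        for k, v in params.items():
            if not hasattr(self, k):
                raise ValueError(f"unknown parameter {k!r}")
            setattr(self, k, v)
        return self

    # ------------------------------------------------------------------
    def _design(self, df: pd.DataFrame):
        d = df[self.deaths_col].to_numpy(dtype=float)
        n = df[self.at_risk_col].to_numpy(dtype=float)
        if (d < 0).any() or (d > n).any():
            raise ValueError("need 0 <= deaths <= at-risk per row")
        x = df[self.climate_col].to_numpy(dtype=float)
        X = np.column_stack([np.ones(len(df)), x])
        sp = pd.Categorical(df[self.species_col])
        yr = pd.Categorical(df[self.year_col])
        if self.random_effects and (len(sp.categories) < 2 or len(yr.categories) < 2):
            raise ValueError("need >= 2 species and >= 2 hydro-years")
        return d, n, x, X, sp, yr

    def _z_matrix(self, x, sp, yr):
        """Dense random-effect design [species-int | species-slope | year-int]."""
        ns, ny = len(sp.categories), len(yr.categories)
        cols = []
        Zs = np.zeros((len(x), ns))
        Zs[np.arange(len(x)), sp.codes] = 1.0
        cols.append(Zs)
        if self.random_slope:
            cols.append(Zs * x[:, None])
        Zy = np.zeros((len(x), ny))
        Zy[np.arange(len(x)), yr.codes] = 1.0
        cols.append(Zy)
        return np.column_stack(cols), ns, ny

    def _precision(self, theta, ns, ny):
        """Block penalty matrix for the random coefficients; returns
        (precision diag-blocks applied densely, log det of the full
        random-effect covariance)."""
        # clamp the log-scale parameters so extreme optimizer proposals keep
        # the covariance invertible (variances in [1e-6, ~400])
        theta = np.clip(theta, -6.0, 3.0)
        if self.random_slope:
            if self.random_cov == "full":
                a, c, b, lv = theta
            else:
                a, b, lv = theta
                c = 0.0
            L = np.array([[np.exp(a), 0.0], [c, np.exp(b)]])
            sigma2 = L @ L.T
            prec2 = np.linalg.inv(sigma2)
            logdet_sp = float(np.linalg.slogdet(sigma2)[1])
        else:
            a, lv = theta
            sigma2 = np.array([[np.exp(2 * a)]])
            prec2 = np.array([[np.exp(-2 * a)]])
            logdet_sp = 2 * a
        var_y = np.exp(2 * lv)
        q = ns * (2 if self.random_slope else 1) + ny
        P = np.zeros((q, q))
        if self.random_slope:
            P[:ns, :ns] = np.eye(ns) * prec2[0, 0]
            P[ns: 2 * ns, ns: 2 * ns] = np.eye(ns) * prec2[1, 1]
            P[:ns, ns: 2 * ns] = np.eye(ns) * prec2[0, 1]
            P[ns: 2 * ns, :ns] = np.eye(ns) * prec2[1, 0]
            off = 2 * ns
        else:
            P[:ns, :ns] = np.eye(ns) * prec2[0, 0]
            off = ns
        P[off:, off:] = np.eye(ny) / var_y
        logdet = ns * logdet_sp + ny * np.log(var_y)
        return P, logdet, sigma2, var_y

    def _inner(self, d, n, W, P_full, gamma0):
        """Penalized IRLS for the joint (fixed, random) mode."""
        gamma = gamma0.copy()

        def pll(g):
            return _binom_loglik(d, n, W @ g) - 0.5 * float(g @ P_full @ g)

        cur = pll(gamma)
        ok = False
        for _ in range(self.max_inner):
            eta = W @ gamma
            p = expit(eta)
            grad = W.T @ (d - n * p) - P_full @ gamma
            if np.max(np.abs(grad)) < self.inner_tol * max(1.0, abs(cur)):
                ok = True
                break
            wgt = np.clip(n * p * (1 - p), 1e-10, None)
            H = W.T @ (wgt[:, None] * W) + P_full
            try:
                step = np.linalg.solve(H, grad)
            except np.linalg.LinAlgError:
                step = np.linalg.lstsq(H, grad, rcond=None)[0]
            for _ in range(25):
                cand = gamma + step
                val = pll(cand)
                if val >= cur - 1e-12:
                    gamma, cur = cand, val
                    break
                step *= 0.5
            else:
                break
        return gamma, cur, ok

    # ------------------------------------------------------------------
    def fit(self, data: pd.DataFrame, y=None):
        d, n, x, X, sp, yr = self._design(data)
        self.n_rows_ = len(data)

        if not self.random_effects:
            gamma, _, ok = self._inner(d, n, X, np.zeros((2, 2)), np.zeros(2))
            p = expit(X @ gamma)
            H = X.T @ ((n * p * (1 - p))[:, None] * X)
            cov = np.linalg.inv(H)
            self.coef_ = pd.Series(gamma, index=["intercept", self.climate_col])
            self.se_ = pd.Series(np.sqrt(np.diag(cov)), index=self.coef_.index)
            self.vc_ = {}
            self.ranef_ = {}
            self.loglik_ = _binom_loglik(d, n, X @ gamma)
            self.converged_ = ok
            self.boundary_ = False
            self._set_aicc(k_extra=0)
            return self

        Z, ns, ny = self._z_matrix(x, sp, yr)
        W = np.column_stack([X, Z])
        pdim, qdim = X.shape[1], Z.shape[1]
        state = {"gamma": np.zeros(pdim + qdim)}

        def objective(theta):
            P, logdet_sigma, _, _ = self._precision(theta, ns, ny)
            P_full = np.zeros((pdim + qdim, pdim + qdim))
            P_full[pdim:, pdim:] = P
            gamma, _, _ = self._inner(d, n, W, P_full, state["gamma"])
            state["gamma"] = gamma
            eta = W @ gamma
            p = expit(eta)
            wgt = np.clip(n * p * (1 - p), 1e-10, None)
            Huu = Z.T @ (wgt[:, None] * Z) + P
            sign, logdet_h = np.linalg.slogdet(Huu)
            if sign <= 0:
                return np.inf
            u = gamma[pdim:]
            ill = (
                _binom_loglik(d, n, eta)
                - 0.5 * float(u @ P @ u)
                - 0.5 * logdet_sigma
                - 0.5 * logdet_h
            )
            return -ill

        n_theta = (4 if self.random_cov == "full" else 3) if self.random_slope else 2
        x0 = np.zeros(n_theta)
        x0[:] = -1.0
        if self.random_slope and self.random_cov == "full":
            x0[1] = 0.0  # off-diagonal Cholesky entry starts at 0
        res = optimize.minimize(
            objective,
            x0,
            method="Nelder-Mead",
            options={"xatol": 0.02, "fatol": 1e-5, "maxfev": self.max_outer_fev},
        )
        theta = res.x
        neg_ill = objective(theta)
        gamma = state["gamma"]
        P, _, sigma2, var_y = self._precision(theta, ns, ny)
        P_full = np.zeros((pdim + qdim, pdim + qdim))
        P_full[pdim:, pdim:] = P
        eta = W @ gamma
        p = expit(eta)
        wgt = np.clip(n * p * (1 - p), 1e-10, None)
        H = W.T @ (wgt[:, None] * W) + P_full
        cov = np.linalg.inv(H)

        self.coef_ = pd.Series(gamma[:pdim], index=["intercept", self.climate_col])
        self.se_ = pd.Series(np.sqrt(np.diag(cov)[:pdim]), index=self.coef_.index)
        self.vc_ = {"species_intercept_var": float(sigma2[0, 0]), "year_var": float(var_y)}
        if self.random_slope:
            self.vc_["species_slope_var"] = float(sigma2[1, 1])
            if self.random_cov == "full":
                self.vc_["species_cov"] = float(sigma2[0, 1])
        u = gamma[pdim:]
        ranef = {}
        if self.random_slope:
            ranef["species"] = pd.DataFrame(
                {"intercept": u[:ns], "slope": u[ns: 2 * ns]}, index=sp.categories
            )
            ranef["hydro_year"] = pd.Series(u[2 * ns:], index=yr.categories)
        else:
            ranef["species"] = pd.Series(u[:ns], index=sp.categories)
            ranef["hydro_year"] = pd.Series(u[ns:], index=yr.categories)
        self.ranef_ = ranef
        self.loglik_ = -float(neg_ill)
        self.converged_ = bool(res.success and np.isfinite(neg_ill))
        tiny = [v for k, v in self.vc_.items() if k.endswith("_var") and v < 1e-6]
        self.boundary_ = len(tiny) > 0
        if self.boundary_:
            warnings.warn("variance component at the zero boundary", stacklevel=2)
        self._set_aicc(k_extra=n_theta)
        return self

    def _set_aicc(self, k_extra: int):
        from droughtdemog.selection import aicc

        k = 2 + k_extra
        try:
            self.aicc_ = aicc(self.loglik_, k, self.n_rows_)
        except ValueError:
            self.aicc_ = np.nan

    def predict_proba(self, data: pd.DataFrame, use_ranef: bool = False) -> np.ndarray:
        """Fitted monthly death probability for new rows (fixed effects only
        unless ``use_ranef``)."""
        if not hasattr(self, "coef_"):
            raise RuntimeError("estimator is not fitted")
        eta = (
            self.coef_["intercept"]
            + self.coef_[self.climate_col] * data[self.climate_col].to_numpy(dtype=float)
        )
        if use_ranef and self.ranef_:
            sp = self.ranef_["species"]
            if isinstance(sp, pd.DataFrame):
                eta = eta + sp["intercept"].reindex(data[self.species_col]).fillna(0).to_numpy()
                eta = eta + (
                    sp["slope"].reindex(data[self.species_col]).fillna(0).to_numpy()
                    * data[self.climate_col].to_numpy(dtype=float)
                )
            else:
                eta = eta + sp.reindex(data[self.species_col]).fillna(0).to_numpy()
            eta = eta + self.ranef_["hydro_year"].reindex(data[self.year_col]).fillna(0).to_numpy()
        return expit(eta)
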