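"""Time-varying Cox proportional hazards with shared log-normal frailty.

The model is a counting-process Cox partial likelihood on the age-in-months
time axis (each person-month row is the interval ``(m-1, m]``), with
Gaussian random effects ("shared frailty" on the log scale) for grouping
factors such as mother identity and hydro-year:

    h_i(t) = h_0(t) * exp(x_i(t)' beta + b_{mother(i)} + b_{year(i,t)}),
    b_f ~ Normal(0, sigma_f^2) iid within factor f.

Estimation follows the penalized-partial-likelihood / Laplace approach used
for mixed-effects Cox models: for fixed variance components an inner Newton
iteration maximizes the partial likelihood penalized by the Gaussian prior
jointly in (beta, b); an outer optimizer maximizes the Laplace-approximated
integrated partial likelihood over the log variance components.  Efron's
approximation (default) handles the heavy ties produced by the monthly age
grid; Breslow is available for cross-checks against other implementations.

``CoxPHFrailty`` is a scikit-learn-style estimator: hyperparameters in
``__init__``, data in ``fit``, results in trailing-underscore attributes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize
from scipy.stats import norm

__all__ = [
    "CoxPHFrailty",
    "cox_partial_loglik",
    "fit_cox",
    "fit_cox_frailty",
    "hazard_ratios",
    "predict_survival",
]


# ---------------------------------------------------------------------------
# partial-likelihood kernel


@dataclass
class _RiskStructure:
    """Precomputed risk sets: parameter-independent layout of the data."""

    X: np.ndarray  # n x p fixed-effect design
    codes: list  # per-factor integer level codes, each length n
    sizes: list  # per-factor number of levels
    levels: list  # per-factor level labels
    event_times: np.ndarray
    risk_idx: list = field(default_factory=list)  # per event time
    death_idx: list = field(default_factory=list)

    @property
    def p(self) -> int:
        return self.X.shape[1]

    @property
    def q(self) -> int:
        return int(sum(self.sizes))

    @property
    def dim(self) -> int:
        return self.p + self.q


def _build_structure(
    start: np.ndarray,
    stop: np.ndarray,
    event: np.ndarray,
    X: np.ndarray,
    codes: list,
    sizes: list,
    levels: list,
) -> _RiskStructure:
    times = np.unique(stop[event.astype(bool)])
    rs = _RiskStructure(X=X, codes=codes, sizes=sizes, levels=levels, event_times=times)
    for t in times:
        at_risk = (start < t) & (stop >= t)
        rs.risk_idx.append(np.flatnonzero(at_risk))
        rs.death_idx.append(np.flatnonzero((stop == t) & event.astype(bool)))
    return rs


def _moments(rs: _RiskStructure, idx: np.ndarray, w: np.ndarray, need_hess: bool):
    """(sum w, sum w*u, sum w*u*u') over rows idx, u = [x, one-hot factors]."""
    p, q, dim = rs.p, rs.q, rs.dim
    x = rs.X[idx]
    s0 = float(w.sum())
    m1 = np.zeros(dim)
    m1[:p] = x.T @ w
    M2 = np.zeros((dim, dim)) if need_hess else None
    if need_hess and p:
        M2[:p, :p] = x.T @ (w[:, None] * x)
    off = p
    offsets = []
    for f, (c_all, qf) in enumerate(zip(rs.codes, rs.sizes)):
        c = c_all[idx]
        sf = np.bincount(c, weights=w, minlength=qf)
        m1[off: off + qf] = sf
        if need_hess:
            ii = np.arange(off, off + qf)
            M2[ii, ii] = sf
            for j in range(p):
                col = np.bincount(c, weights=w * x[:, j], minlength=qf)
                M2[off: off + qf, j] = col
                M2[j, off: off + qf] = col
            for g, off_g in enumerate(offsets):
                cg = rs.codes[g][idx]
                qg = rs.sizes[g]
                cross = np.bincount(c * qg + cg, weights=w, minlength=qf * qg)
                cross = cross.reshape(qf, qg)
                M2[off: off + qf, off_g: off_g + qg] = cross
                M2[off_g: off_g + qg, off: off + qf] = cross.T
        offsets.append(off)
        off += qf
    return s0, m1, M2


def _loglik_parts(
    rs: _RiskStructure,
    gamma: np.ndarray,
    ties: str,
    order: int = 2,
):
    """Partial log-likelihood and, optionally, gradient and information.

    ``order`` 0 returns only the log-likelihood; 1 adds the gradient; 2 adds
    the (positive semi-definite) observed information of dimension p + q.
    """
    p, dim = rs.p, rs.dim
    eta = rs.X @ gamma[:p] if p else np.zeros(len(rs.X))
    off = p
    for c, qf in zip(rs.codes, rs.sizes):
        eta = eta + gamma[off: off + qf][c]
        off += qf
    # guard against overflow in exp for diverging iterates
    w_all = np.exp(np.clip(eta, -200, 200))

    ll = 0.0
    grad = np.zeros(dim) if order >= 1 else None
    info = np.zeros((dim, dim)) if order >= 2 else None
    need_hess = order >= 2

    for risk, deaths in zip(rs.risk_idx, rs.death_idx):
        d = len(deaths)
        s0, m1, M2 = _moments(rs, risk, w_all[risk], need_hess)
        ll += float(eta[deaths].sum())
        if order >= 1:
            _, u_d, _ = _moments(rs, deaths, np.ones(d), False)
            grad += u_d
        efron = ties == "efron" and d > 1
        if efron:  # denominators shrink by l/d of the deaths' mass
            s0d, m1d, M2d = _moments(rs, deaths, w_all[deaths], need_hess)
            fracs = np.arange(d) / d
        else:
            s0d, fracs = 0.0, np.zeros(d)
        denoms = s0 - fracs * s0d
        ll -= float(np.log(denoms).sum())
        if order >= 1:
            # sum_l mu_l and sum_l (M2_l/denom_l - mu_l mu_l') collapse to a
            # fixed number of rank-one terms regardless of the tie count
            a = 1.0 / denoms
            b = fracs / denoms
            grad -= a.sum() * m1
            if efron:
                grad += b.sum() * m1d
            if order >= 2:
                a2, ab, b2 = float(a @ a), float(a @ b), float(b @ b)
                info += a.sum() * M2 - a2 * np.outer(m1, m1)
                if efron:
                    info -= b.sum() * M2d
                    info += ab * (np.outer(m1, m1d) + np.outer(m1d, m1))
                    info -= b2 * np.outer(m1d, m1d)
    return ll, grad, info


# ---------------------------------------------------------------------------
# estimator


class CoxPHFrailty:
    """Cox proportional hazards with optional shared Gaussian frailty terms.

    Parameters
    ----------
    fixed_terms : list of str
        Numeric covariate columns entering the linear predictor.
    frailty_terms : tuple of str
        Grouping-factor columns receiving iid Gaussian random effects on the
        log hazard (default mother identity and hydro-year).  Empty tuple
        fits a plain fixed-effects Cox model.
    ties : {'efron', 'breslow'}
    start_col, stop_col, event_col : str
        Counting-process columns.  If start/stop are absent but an
        ``interval_index`` column exists, intervals ``(m-1, m]`` are derived
        from it.
    id_col : str
        Subject identifier (for ``n_subjects_`` only).
    inner_tol, outer_tol, max_inner, max_outer : numeric
        Newton gradient tolerance, outer relative tolerance on the
        integrated log-likelihood, and iteration caps.

    Attributes (after ``fit``)
    --------------------------
    coef_, se_ : pandas Series indexed by term (log hazard ratios).
    variance_components_ : dict factor -> variance (0 at the boundary).
    level_effects_ : dict factor -> Series of random-effect modes.
    loglik_ : integrated (Laplace) partial log-likelihood; equals the plain
        partial log-likelihood when there are no frailty terms.
    loglik_null_ : partial log-likelihood at beta = 0, b = 0.
    n_subjects_, n_events_, n_rows_, converged_, boundary_ : diagnostics.
    """

    _BETA_DIVERGED = 12.0

    def __init__(
        self,
        fixed_terms,
        frailty_terms=("mother_id", "hydro_year"),
        ties="efron",
        start_col="start",
        stop_col="stop",
        event_col="event",
        id_col="individual_id",
        inner_tol=1e-8,
        outer_tol=1e-6,
        max_inner=100,
        max_outer=50,
        fixed_variance_components=None,
        initial_variance_components=None,
    ):
        self.fixed_terms = list(fixed_terms)
        self.frailty_terms = tuple(frailty_terms)
        self.ties = ties
        self.start_col = start_col
        self.stop_col = stop_col
        self.event_col = event_col
        self.id_col = id_col
        self.inner_tol = inner_tol
        self.outer_tol = outer_tol
        self.max_inner = max_inner
        self.max_outer = max_outer
        # mapping factor -> variance: skips the outer optimization (used for
        # reduction checks and sensitivity analyses); 0 pins the random
        # effects at (numerically) zero
        self.fixed_variance_components = fixed_variance_components
        # mapping factor -> variance: starting point for the outer
        # optimization (warm starts across a model set)
        self.initial_variance_components = initial_variance_components

    # -- sklearn plumbing ---------------------------------------------------
    def get_params(self, deep=True):
        return {
            k: getattr(self, k)
            for k in (
                "fixed_terms",
                "frailty_terms",
                "ties",
                "start_col",
                "stop_col",
                "event_col",
                "id_col",
                "inner_tol",
                "outer_tol",
                "max_inner",
                "max_outer",
                "fixed_variance_components",
                "initial_variance_components",
            )
        }

    def set_params(self, **params):
        for k, v in params.items():
            if not hasattr(self, k):
                raise ValueError(f"unknown parameter {k!r}")
            setattr(self, k, v)
        return self

    # -- data validation ----------------------------------------------------
    def _extract(self, data: pd.DataFrame):
        if self.ties not in ("efron", "breslow"):
            raise ValueError("ties must be 'efron' or 'breslow'")
        df = data
        if self.start_col in df.columns and self.stop_col in df.columns:
            start = df[self.start_col].to_numpy(dtype=float)
            stop = df[self.stop_col].to_numpy(dtype=float)
        elif "interval_index" in df.columns:
            stop = df["interval_index"].to_numpy(dtype=float)
            start = stop - 1.0
        else:
            raise ValueError(
                f"need {self.start_col!r}/{self.stop_col!r} or 'interval_index' columns"
            )
        if (stop <= start).any():
            raise ValueError("stop must exceed start for every row")
        event = df[self.event_col].to_numpy(dtype=float)
        if not np.isin(event, (0.0, 1.0)).all():
            raise ValueError("event column must be 0/1")
        missing = [t for t in self.fixed_terms if t not in df.columns]
        if missing:
            raise ValueError(f"missing covariate columns: {missing}")
        X = df[self.fixed_terms].to_numpy(dtype=float) if self.fixed_terms else np.empty((len(df), 0))
        if not np.isfinite(X).all():
            raise ValueError("non-finite covariate values")
        if X.shape[1]:
            rank = np.linalg.matrix_rank(X - X.mean(axis=0))
            if rank < X.shape[1]:
                raise ValueError("fixed-effect design is rank deficient")
        codes, sizes, levels = [], [], []
        for f in self.frailty_terms:
            cat = pd.Categorical(df[f])
            if len(cat.categories) < 2:
                raise ValueError(f"frailty factor {f!r} needs >= 2 levels")
            if (np.asarray(cat.codes) < 0).any():
                raise ValueError(f"frailty factor {f!r} has missing values")
            codes.append(np.asarray(cat.codes, dtype=np.int64))
            sizes.append(len(cat.categories))
            levels.append(list(cat.categories))
        return start, stop, event, X, codes, sizes, levels

    # -- inner Newton on (beta, b) ------------------------------------------
    def _inner(self, rs: _RiskStructure, pen: np.ndarray, gamma0: np.ndarray):
        gamma = gamma0.copy()

        def pll(g):
            ll, _, _ = _loglik_parts(rs, g, self.ties, order=0)
            return ll - 0.5 * float(pen @ (g * g))

        if rs.dim == 0:  # intercept-free null model: nothing to maximize
            return gamma, pll(gamma), True
        current = pll(gamma)
        converged = False
        for _ in range(self.max_inner):
            ll, grad, info = _loglik_parts(rs, gamma, self.ties, order=2)
            g_pen = grad - pen * gamma
            H_pen = info + np.diag(pen)
            if np.max(np.abs(g_pen)) < self.inner_tol:
                converged = True
                break
            try:
                step = np.linalg.solve(H_pen, g_pen)
            except np.linalg.LinAlgError:
                step = np.linalg.lstsq(H_pen, g_pen, rcond=None)[0]
            # step halving keeps the penalized log-likelihood increasing
            for _ in range(25):
                cand = gamma + step
                val = pll(cand)
                if val >= current - 1e-12:
                    gamma, current = cand, val
                    break
                step = 0.5 * step
            else:
                break
            if rs.p and np.max(np.abs(gamma[: rs.p])) > self._BETA_DIVERGED:
                return gamma, current, False
        return gamma, current, converged

    # -- Laplace integrated log-likelihood at given log-variances -----------
    def _laplace(self, rs: _RiskStructure, log_var: np.ndarray, gamma0: np.ndarray):
        p = rs.p
        pen = np.zeros(rs.dim)
        off = p
        for f, qf in enumerate(rs.sizes):
            pen[off: off + qf] = np.exp(-log_var[f])
            off += qf
        gamma, _, ok = self._inner(rs, pen, gamma0)
        ll, _, info = _loglik_parts(rs, gamma, self.ties, order=2)
        b = gamma[p:]
        quad = float(pen[p:] @ (b * b))
        H_bb = info[p:, p:] + np.diag(pen[p:])
        sign, logdet = np.linalg.slogdet(H_bb)
        if sign <= 0:
            return -np.inf, gamma, ok
        log_det_sigma = float(np.dot(rs.sizes, log_var))
        ill = ll - 0.5 * quad - 0.5 * log_det_sigma - 0.5 * logdet
        return ill, gamma, ok

    # -- fitting ------------------------------------------------------------
    def fit(self, data: pd.DataFrame, y=None):
        start, stop, event, X, codes, sizes, levels = self._extract(data)
        rs = _build_structure(start, stop, event, X, codes, sizes, levels)
        p, q = rs.p, rs.q
        self.n_rows_ = len(data)
        self.n_events_ = int(event.sum())
        self.n_subjects_ = (
            int(data[self.id_col].nunique()) if self.id_col in data.columns else None
        )
        if self.n_events_ == 0:
            warnings.warn("no events in data; log-likelihood is 0", stacklevel=2)
            self._finalize_null(rs, data)
            return self

        self.loglik_null_ = _loglik_parts(rs, np.zeros(rs.dim), self.ties, order=0)[0]

        if not self.frailty_terms:
            gamma, _, ok = self._inner(rs, np.zeros(rs.dim), np.zeros(rs.dim))
            ll, _, info = _loglik_parts(rs, gamma, self.ties, order=2)
            self.converged_ = bool(ok)
            self.boundary_ = False
            self.variance_components_ = {}
            self.level_effects_ = {}
            self.theta_ = np.empty(0)
            self._finalize(rs, data, gamma, ll, info)
            return self

        if self.fixed_variance_components is not None:
            fixed = [
                float(self.fixed_variance_components[f]) for f in self.frailty_terms
            ]
            log_var = np.log(np.maximum(fixed, 1e-12))
            ill, gamma, inner_ok = self._laplace(rs, log_var, np.zeros(rs.dim))
            _, _, info = _loglik_parts(rs, gamma, self.ties, order=2)
            self.theta_ = np.asarray(fixed)
            self.converged_ = bool(inner_ok)
            self.boundary_ = any(v == 0.0 for v in fixed)
            self.variance_components_ = dict(zip(self.frailty_terms, fixed))
            self.level_effects_ = {}
            off = p
            for f, qf, lev in zip(self.frailty_terms, sizes, levels):
                self.level_effects_[f] = pd.Series(gamma[off: off + qf], index=lev, name=f)
                off += qf
            self._finalize(rs, data, gamma, ill, info, pen_diag=self._pen_from(log_var, rs))
            return self

        # outer maximization of the Laplace integrated likelihood over the
        # log variance components (Nelder-Mead: few parameters, no gradients)
        state = {"gamma": np.zeros(rs.dim), "ok": True}

        def objective(log_var):
            ill, gamma, ok = self._laplace(rs, log_var, state["gamma"])
            if np.isfinite(ill):
                state["gamma"], state["ok"] = gamma, ok
            return -ill

        if self.initial_variance_components is not None:
            x0 = np.log(
                np.maximum(
                    [self.initial_variance_components[f] for f in self.frailty_terms],
                    1e-3,
                )
            )
        else:
            x0 = np.full(len(sizes), np.log(0.25))
        res = optimize.minimize(
            objective,
            x0,
            method="Nelder-Mead",
            options={
                "xatol": 0.02,
                "fatol": self.outer_tol * 10,
                "maxfev": 40 * self.max_outer,
            },
        )
        log_var = res.x
        boundary = log_var < np.log(1e-4)
        log_var = np.where(boundary, np.log(1e-8), log_var)
        ill, gamma, inner_ok = self._laplace(rs, log_var, state["gamma"])
        ll_at_mode, _, info = _loglik_parts(rs, gamma, self.ties, order=2)

        self.theta_ = np.exp(res.x)
        self.converged_ = bool(res.success and inner_ok)
        self.boundary_ = bool(boundary.any())
        self.variance_components_ = {
            f: (0.0 if boundary[i] else float(np.exp(res.x[i])))
            for i, f in enumerate(self.frailty_terms)
        }
        self.level_effects_ = {}
        off = p
        for f, qf, lev in zip(self.frailty_terms, sizes, levels):
            self.level_effects_[f] = pd.Series(gamma[off: off + qf], index=lev, name=f)
            off += qf
        self._finalize(rs, data, gamma, ill, info, pen_diag=self._pen_from(log_var, rs))
        return self

    def _pen_from(self, log_var, rs):
        pen = np.zeros(rs.dim)
        off = rs.p
        for f, qf in enumerate(rs.sizes):
            pen[off: off + qf] = np.exp(-log_var[f])
            off += qf
        return pen

    def _finalize(self, rs, data, gamma, loglik, info, pen_diag=None):
        p = rs.p
        H = info + (np.diag(pen_diag) if pen_diag is not None else 0.0)
        se = np.full(p, np.nan)
        if p:
            try:
                cov = np.linalg.inv(H)
                se = np.sqrt(np.maximum(np.diag(cov)[:p], 0.0))
                self.covariance_ = cov[:p, :p]
            except np.linalg.LinAlgError:
                self.covariance_ = np.full((p, p), np.nan)
                self.converged_ = False
        else:
            self.covariance_ = np.empty((0, 0))
        self.coef_ = pd.Series(gamma[:p], index=self.fixed_terms, name="coef")
        self.se_ = pd.Series(se, index=self.fixed_terms, name="se")
        self.loglik_ = float(loglik)
        self._gamma_ = gamma
        self._rs_ = rs
        self._data_cols_ = {
            "start": self.start_col,
            "stop": self.stop_col,
            "event": self.event_col,
        }

    def _finalize_null(self, rs, data):
        self.converged_ = True
        self.boundary_ = False
        self.variance_components_ = {f: 0.0 for f in self.frailty_terms}
        self.level_effects_ = {}
        self.theta_ = np.zeros(len(self.frailty_terms))
        self.loglik_null_ = 0.0
        self._finalize(rs, data, np.zeros(rs.dim), 0.0, np.zeros((rs.dim, rs.dim)))

    # -- reporting ----------------------------------------------------------
    def hazard_ratios(self, levels=(0.80, 0.95, 0.99)) -> pd.DataFrame:
        """Hazard ratios exp(beta) with Wald confidence intervals."""
        self._check_fitted()
        rows = {}
        for term in self.fixed_terms:
            beta, se = self.coef_[term], self.se_[term]
            row = {"coef": beta, "se": se, "hr": float(np.exp(beta))}
            for lev in levels:
                z = norm.ppf(0.5 + lev / 2.0)
                row[f"hr_lo_{int(lev * 100)}"] = float(np.exp(beta - z * se))
                row[f"hr_hi_{int(lev * 100)}"] = float(np.exp(beta + z * se))
            rows[term] = row
        return pd.DataFrame(rows).T

    def baseline_cumulative_hazard(self) -> pd.DataFrame:
        """Breslow baseline cumulative hazard at b = 0."""
        self._check_fitted()
        rs = self._rs_
        eta = rs.X @ self.coef_.to_numpy() if rs.p else np.zeros(len(rs.X))
        w = np.exp(eta)
        rows = []
        cum = 0.0
        for t, risk, deaths in zip(rs.event_times, rs.risk_idx, rs.death_idx):
            s0 = w[risk].sum()
            cum += len(deaths) / s0
            rows.append({"time": float(t), "cum_hazard": cum, "s0": s0, "d": len(deaths)})
        return pd.DataFrame(rows)

    def predict_survival(
        self, profile: dict, horizon: float | None = None, conf_level: float = 0.95
    ) -> pd.DataFrame:
        """Survival curve S(t) = exp(-Lambda0(t) exp(x'beta)) with a Wald band.

        ``profile`` maps covariate names to constant values held for the
        whole horizon.  Values outside the fitted covariate range trigger a
        warning, not an error.
        """
        self._check_fitted()
        rs = self._rs_
        x = np.array([float(profile[t]) for t in self.fixed_terms])
        if rs.p:
            lo, hi = rs.X.min(axis=0), rs.X.max(axis=0)
            if ((x < lo) | (x > hi)).any():
                warnings.warn("profile outside fitted covariate ranges", stacklevel=2)
        beta = self.coef_.to_numpy()
        eta = rs.X @ beta if rs.p else np.zeros(len(rs.X))
        w = np.exp(eta)
        risk_factor = float(np.exp(x @ beta)) if rs.p else 1.0

        times, surv, se_lam = [0.0], [1.0], [0.0]
        cum, var_nat, g = 0.0, 0.0, np.zeros(rs.p)
        z = norm.ppf(0.5 + conf_level / 2.0)
        bands_lo, bands_hi = [1.0], [1.0]
        for t, risk, deaths in zip(rs.event_times, rs.risk_idx, rs.death_idx):
            if horizon is not None and t > horizon:
                break
            d = len(deaths)
            s0 = w[risk].sum()
            s1 = rs.X[risk].T @ w[risk] if rs.p else np.zeros(0)
            cum += d / s0
            var_nat += d / s0 ** 2
            if rs.p:
                g += (d / s0) * (x - s1 / s0)
            lam = cum * risk_factor
            var = risk_factor ** 2 * (var_nat + (g @ self.covariance_ @ g if rs.p else 0.0))
            se = np.sqrt(max(var, 0.0))
            times.append(float(t))
            surv.append(float(np.exp(-lam)))
            bands_lo.append(float(np.exp(-(lam + z * se))))
            bands_hi.append(float(np.exp(-max(lam - z * se, 0.0))))
        return pd.DataFrame(
            {"time": times, "survival": surv, "lower": bands_lo, "upper": bands_hi}
        )

    def _check_fitted(self):
        if not hasattr(self, "coef_"):
            raise RuntimeError("estimator is not fitted")


# ---------------------------------------------------------------------------
# functional wrappers


def cox_partial_loglik(
    data: pd.DataFrame,
    terms,
    beta,
    ties: str = "efron",
    start_col: str = "start",
    stop_col: str = "stop",
    event_col: str = "event",
) -> float:
    """Cox partial log-likelihood at a given coefficient vector."""
    model = CoxPHFrailty(
        list(terms),
        frailty_terms=(),
        ties=ties,
        start_col=start_col,
        stop_col=stop_col,
        event_col=event_col,
    )
    start, stop, event, X, codes, sizes, levels = model._extract(data)
    if event.sum() == 0:
        warnings.warn("no events; partial log-likelihood is 0", stacklevel=2)
        return 0.0
    rs = _build_structure(start, stop, event, X, codes, sizes, levels)
    ll, _, _ = _loglik_parts(rs, np.asarray(beta, dtype=float), ties, order=0)
    return float(ll)


def fit_cox(data: pd.DataFrame, terms, ties: str = "efron", **kwargs) -> CoxPHFrailty:
    """Fixed-effects Cox fit (no frailty terms)."""
    return CoxPHFrailty(list(terms), frailty_terms=(), ties=ties, **kwargs).fit(data)


def fit_cox_frailty(
    data: pd.DataFrame,
    terms,
    frailty_terms=("mother_id", "hydro_year"),
    ties: str = "efron",
    **kwargs,
) -> CoxPHFrailty:
    """Shared-frailty Cox fit with Gaussian random effects per factor."""
    return CoxPHFrailty(
        list(terms), frailty_terms=tuple(frailty_terms), ties=ties, **kwargs
    ).fit(data)


def hazard_ratios(fit: CoxPHFrailty, levels=(0.80, 0.95, 0.99)) -> pd.DataFrame:
    return fit.hazard_ratios(levels)


def predict_survival(fit: CoxPHFrailty, profile: dict, horizon=None) -> pd.DataFrame:
    return fit.predict_survival(profile, horizon)
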