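"""AICc model set enumeration, ranking, collinearity screening and
conditional model averaging.

The candidate set per species is: one null model, one model per single
environmental variable, and all pairwise combinations of one fruit-related
and one drought-related variable (never two variables of the same family in
one model).  Capuchin specs additionally always contain the infanticide-risk
term, including the null.  Models are ranked by AICc computed from the
integrated partial log-likelihood; Akaike weights give conditional
model-averaged coefficients with unconditional (Burnham-Anderson) standard
errors and 80/95/99% Wald intervals.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import norm

__all__ = [
    "CoxModelSpec",
    "env_variables",
    "enumerate_models",
    "aicc",
    "rank_and_weight",
    "vif",
    "screen_separation",
    "model_average",
    "run_model_set",
]


@dataclass(frozen=True)
class CoxModelSpec:
    """One candidate model: fixed terms plus shared-frailty factors."""

    fixed_terms: tuple = ()
    frailty_terms: tuple = ("mother_id", "hydro_year")
    ties_method: str = "efron"

    def __post_init__(self):
        fruit = [t for t in self.fixed_terms if t.startswith("fruit")]
        drought = [t for t in self.fixed_terms if t.startswith("spei")]
        if len(fruit) > 1 or len(drought) > 1:
            raise ValueError(
                "at most one fruit-related and one drought-related term per model"
            )

    @property
    def label(self) -> str:
        return " + ".join(self.fixed_terms) if self.fixed_terms else "(null)"


def env_variables(scales=(1, 6, 12)) -> tuple[list, list]:
    """Fruit-related and drought-related variable names per scale.

    Six variables per scale: continuous mean fruit biomass, extreme
    high/low fruit, continuous SPEI, extreme high/low SPEI.
    """
    fruit = [f"{stem}_{k}" for k in scales for stem in ("fruit_mean", "fruit_hi", "fruit_lo")]
    drought = [f"{stem}_{k}" for k in scales for stem in ("spei", "spei_hi", "spei_lo")]
    return fruit, drought


def enumerate_models(
    fruit_vars,
    drought_vars,
    species: str,
    frailty_terms=("mother_id", "hydro_year"),
    exclude=(),
) -> list[CoxModelSpec]:
    """Constrained candidate model set.

    One null + one per single variable + one per (fruit, drought) pair,
    with ``exclude`` removed from the variable pool (used for variables that
    caused convergence failures).  Capuchin models always include the
    infanticide-risk indicator, the null model included.
    """
    pool_f = [v for v in fruit_vars if v not in exclude]
    pool_d = [v for v in drought_vars if v not in exclude]
    dupes = set(pool_f) & set(pool_d)
    if dupes:
        raise ValueError(f"variables tagged both fruit and drought: {sorted(dupes)}")
    base = ("risk_low",) if species == "capuchin" else ()
    specs = [CoxModelSpec(base, tuple(frailty_terms))]
    for v in pool_f + pool_d:
        specs.append(CoxModelSpec(base + (v,), tuple(frailty_terms)))
    for f, d in itertools.product(pool_f, pool_d):
        specs.append(CoxModelSpec(base + (f, d), tuple(frailty_terms)))
    return specs


def aicc(loglik: float, k_params: int, n: int) -> float:
    """Small-sample-corrected Akaike information criterion.

    ``AICc = -2 loglik + 2k + 2k(k+1)/(n - k - 1)``, with n the number of
    events (the effective sample size of a Cox partial likelihood) and k the
    number of fixed coefficients plus variance components.
    """
    if n - k_params - 1 <= 0:
        raise ValueError(f"AICc undefined: n={n} too small for k={k_params}")
    return -2.0 * loglik + 2.0 * k_params + 2.0 * k_params * (k_params + 1) / (n - k_params - 1)


def aicc_of_fit(fit) -> float:
    """AICc of a fitted Cox(-frailty) model; k counts each variance component."""
    k = len(fit.fixed_terms) + len(fit.variance_components_)
    return aicc(fit.loglik_, k, fit.n_events_)


def rank_and_weight(records: pd.DataFrame) -> pd.DataFrame:
    """Add delta-AICc and Akaike weights over the converged models.

    ``records`` needs columns ``aicc`` and ``converged``; non-converged rows
    get NaN delta/weight and do not enter the weight normalization.
    """
    out = records.copy()
    ok = out["converged"].astype(bool) & out["aicc"].notna()
    if not ok.any():
        raise ValueError("no converged models to rank")
    best = out.loc[ok, "aicc"].min()
    out["delta_aicc"] = np.where(ok, out["aicc"] - best, np.nan)
    rel = np.exp(-0.5 * out.loc[ok, "delta_aicc"])
    out["akaike_weight"] = np.nan
    out.loc[ok, "akaike_weight"] = rel / rel.sum()
    return out.sort_values("aicc").reset_index(drop=True)


def vif(data: pd.DataFrame, terms) -> pd.Series:
    """Variance inflation factors over the analysis rows.

    VIF_j = 1 / (1 - R^2_j) from the OLS regression of term j on the other
    fixed terms (with intercept).  Perfect collinearity reports +inf.
    """
    terms = list(terms)
    if len(terms) < 2:
        raise ValueError("VIF needs at least two fixed terms")
    X = data[terms].to_numpy(dtype=float)
    out = {}
    for j, term in enumerate(terms):
        y = X[:, j]
        others = np.column_stack([np.ones(len(X)), np.delete(X, j, axis=1)])
        resid = y - others @ np.linalg.lstsq(others, y, rcond=None)[0]
        ss_res = float(resid @ resid)
        ss_tot = float(((y - y.mean()) ** 2).sum())
        if ss_tot == 0.0:
            out[term] = np.inf
            continue
        r2 = 1.0 - ss_res / ss_tot
        out[term] = np.inf if r2 >= 1.0 - 1e-12 else 1.0 / (1.0 - r2)
    return pd.Series(out, name="vif")


def screen_separation(data: pd.DataFrame, terms, event_col: str = "event") -> list:
    """Binary terms with zero events in one condition (monotone likelihood).

    Models containing such a term cannot converge (the coefficient diverges)
    and are excluded before fitting.
    """
    bad = []
    ev = data[event_col].astype(bool)
    for t in terms:
        x = data[t].to_numpy()
        vals = np.unique(x)
        if len(vals) == 2 and set(vals) <= {0.0, 1.0}:
            for v in vals:
                if not (ev & (x == v)).any():
                    bad.append(t)
                    break
    return bad


def model_average(
    table: pd.DataFrame,
    fits: dict,
    levels=(0.80, 0.95, 0.99),
) -> pd.DataFrame:
    """Conditional model-averaged coefficients with unconditional SEs.

    For each term, weights are renormalized over the converged models that
    contain it; the averaged estimate is the weighted mean of the per-model
    coefficients and the unconditional SE follows Burnham & Anderson:
    ``sqrt(sum w_i (se_i^2 + (beta_i - avg)^2))``.  The widest confidence
    level whose Wald interval excludes zero is reported per term.
    """
    ok = table[table["converged"].astype(bool)]
    terms: list[str] = []
    for lbl in ok["label"]:
        for t in fits[lbl].fixed_terms:
            if t not in terms:
                terms.append(t)
    rows = []
    for term in terms:
        entries = [
            (w, fits[lbl])
            for lbl, w in zip(ok["label"], ok["akaike_weight"])
            if term in fits[lbl].fixed_terms
        ]
        if not entries:
            warnings.warn(f"term {term!r} in no converged model; omitted", stacklevel=2)
            continue
        wsum = sum(w for w, _ in entries)
        betas = np.array([f.coef_[term] for _, f in entries])
        ses = np.array([f.se_[term] for _, f in entries])
        w = np.array([wi for wi, _ in entries]) / wsum
        est = float(w @ betas)
        se_u = float(np.sqrt(w @ (ses ** 2 + (betas - est) ** 2)))
        row = {"term": term, "estimate": est, "unconditional_se": se_u}
        widest = None
        for lev in sorted(levels):
            z = norm.ppf(0.5 + lev / 2.0)
            lo, hi = est - z * se_u, est + z * se_u
            row[f"ci_lo_{int(lev * 100)}"] = lo
            row[f"ci_hi_{int(lev * 100)}"] = hi
            if lo > 0.0 or hi < 0.0:
                widest = int(lev * 100)
        row["widest_excluding_zero"] = widest if widest is not None else "none"
        rows.append(row)
    return pd.DataFrame(rows).set_index("term")


def run_model_set(
    data: pd.DataFrame,
    specs,
    scale_terms=(),
    **fit_kwargs,
) -> tuple[pd.DataFrame, dict]:
    """Fit every candidate spec and return the ranked table plus the fits.

    Continuous terms named in ``scale_terms`` are z-scored over the analysis
    rows before fitting (shared scaling across the whole set, as all models
    see the same data).  Terms failing the separation screen are excluded:
    models containing them are recorded as non-converged without fitting.
    """
    from droughtdemog.cox import CoxPHFrailty
    from droughtdemog.prep import scale_continuous

    df = data
    to_scale = [t for t in scale_terms if t in df.columns]
    if to_scale:
        df, _ = scale_continuous(df, to_scale)

    all_terms = sorted({t for s in specs for t in s.fixed_terms})
    screened = set(screen_separation(df, [t for t in all_terms if t in df.columns]))

    records, fits = [], {}
    warm = fit_kwargs.pop("initial_variance_components", None)
    for spec in specs:
        rec = {
            "label": spec.label,
            "k_params": len(spec.fixed_terms) + len(spec.frailty_terms),
            "aicc": np.nan,
            "converged": False,
        }
        if screened & set(spec.fixed_terms):
            rec["note"] = "excluded: zero events in one condition"
            records.append(rec)
            continue
        model = CoxPHFrailty(
            list(spec.fixed_terms),
            frailty_terms=spec.frailty_terms,
            ties=spec.ties_method,
            initial_variance_components=warm,
            **fit_kwargs,
        ).fit(df)
        fits[spec.label] = model
        if model.converged_ and warm is None and spec.frailty_terms:
            # variance components barely move across the candidate set:
            # reuse the first converged fit's estimates as starting values
            warm = model.variance_components_
        rec["converged"] = bool(model.converged_)
        if model.converged_:
            rec["aicc"] = aicc_of_fit(model)
        records.append(rec)
    table = rank_and_weight(pd.DataFrame(records))
    return table, fits
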