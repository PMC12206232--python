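"""Cohort-level mLOY association analyses.

The logistic / Cox / linear fits here are orchestration around established
numerical routines (statsmodels, lifelines) — they are verified against
small-instance oracles in the test suite but are not this package's
contribution. The package-specific pieces are the male-excess attribution
decomposition, the bootstrap mediation estimator and the median-imputation
bookkeeping.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from lifelines import CoxPHFitter
from scipy import stats

__all__ = [
    "ExcessAttribution",
    "MediationResult",
    "excess_attribution",
    "fit_incidence_model",
    "fit_survival_model",
    "fit_lungfunction_model",
    "mediation_bootstrap",
    "impute_missing_exposures",
]


# ---------------------------------------------------------------------------
# Male-excess attribution
# ---------------------------------------------------------------------------

@dataclass
class ExcessAttribution:
    """Decomposition of the male-female excess event count by mLOY status.

    ``excess_g = (rate_g - rate_female) * n_g`` for the male groups with
    and without mLOY; ``share_mloy`` is the mLOY group's fraction of the
    total male excess. Scale-invariant in the rates.
    """

    rate_female: float
    rate_male_no_mloy: float
    rate_male_mloy: float
    n_male_no_mloy: int
    n_male_mloy: int
    excess_mloy: float = field(init=False)
    excess_no_mloy: float = field(init=False)
    excess_total: float = field(init=False)
    share_mloy: Optional[float] = field(init=False)
    annotation: str = field(init=False, default="")

    def __post_init__(self) -> None:
        for name in ("rate_female", "rate_male_no_mloy", "rate_male_mloy"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        for name in ("n_male_no_mloy", "n_male_mloy"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        self.excess_mloy = (
            self.rate_male_mloy - self.rate_female
        ) * self.n_male_mloy
        self.excess_no_mloy = (
            self.rate_male_no_mloy - self.rate_female
        ) * self.n_male_no_mloy
        self.excess_total = self.excess_mloy + self.excess_no_mloy
        if self.excess_total > 0:
            self.share_mloy = self.excess_mloy / self.excess_total
            if self.excess_mloy < 0 or self.excess_no_mloy < 0:
                self.annotation = "negative excess in one group"
        else:
            self.share_mloy = None
            self.annotation = "non-positive total excess: share undefined"


def excess_attribution(
    rate_female: float,
    rate_male_no_mloy: float,
    rate_male_mloy: float,
    n_male_no_mloy: int,
    n_male_mloy: int,
) -> ExcessAttribution:
    """See :class:`ExcessAttribution`."""
    return ExcessAttribution(
        rate_female=rate_female,
        rate_male_no_mloy=rate_male_no_mloy,
        rate_male_mloy=rate_male_mloy,
        n_male_no_mloy=n_male_no_mloy,
        n_male_mloy=n_male_mloy,
    )


# ---------------------------------------------------------------------------
# Model orchestration
# ---------------------------------------------------------------------------

def _design(table: pd.DataFrame, covariates: Sequence[str]) -> pd.DataFrame:
    """Numeric design matrix; categorical columns are dummy-coded
    (first level dropped)."""
    X = table[list(covariates)].copy()
    cat = [c for c in X.columns if not pd.api.types.is_numeric_dtype(X[c])]
    if cat:
        X = pd.get_dummies(X, columns=cat, drop_first=True, dtype=float)
    return X.astype(float)


def fit_incidence_model(
    table: pd.DataFrame,
    outcome: str = "event",
    covariates: Sequence[str] = ("mloy_percent",),
) -> pd.DataFrame:
    """Logistic regression; one row per covariate with OR, Wald CI and p."""
    y = table[outcome].astype(float)
    if not set(np.unique(y)) <= {0.0, 1.0}:
        raise ValueError("outcome must be binary")
    X = sm.add_constant(_design(table, covariates))
    fit = sm.Logit(y, X).fit(disp=0, maxiter=200)
    if not fit.mle_retvals.get("converged", True):
        raise RuntimeError("logistic fit did not converge")
    ci = fit.conf_int()
    out = pd.DataFrame(
        {
            "term": fit.params.index,
            "coef": fit.params.values,
            "odds_ratio": np.exp(fit.params.values),
            "ci_low": np.exp(ci[0].values),
            "ci_high": np.exp(ci[1].values),
            "p_value": fit.pvalues.values,
        }
    )
    out = out[out["term"] != "const"].reset_index(drop=True)
    out.attrs["formula"] = f"{outcome} ~ " + " + ".join(covariates)
    out.attrs["n"] = int(len(y))
    return out


def fit_survival_model(
    table: pd.DataFrame,
    duration: str = "time",
    event: str = "event",
    covariates: Sequence[str] = ("mloy_percent",),
) -> pd.DataFrame:
    """Cox proportional-hazards fit (Efron tie handling, the lifelines
    default); one row per covariate with HR, CI and p."""
    df = pd.concat(
        [table[[duration, event]].astype(float), _design(table, covariates)],
        axis=1,
    )
    cph = CoxPHFitter()
    cph.fit(df, duration_col=duration, event_col=event)
    summ = cph.summary
    out = pd.DataFrame(
        {
            "term": summ.index,
            "coef": summ["coef"].values,
            "hazard_ratio": summ["exp(coef)"].values,
            "ci_low": summ["exp(coef) lower 95%"].values,
            "ci_high": summ["exp(coef) upper 95%"].values,
            "p_value": summ["p"].values,
        }
    ).reset_index(drop=True)
    out.attrs["formula"] = (
        f"Surv({duration}, {event}) ~ " + " + ".join(covariates)
    )
    out.attrs["ties"] = "efron"
    out.attrs["n"] = int(len(df))
    return out


def fit_lungfunction_model(
    table: pd.DataFrame,
    outcome: str = "fvc",
    mloy_var: str = "mloy_percent",
    covariates: Sequence[str] = (),
    condition_number_max: float = 1e8,
) -> pd.DataFrame:
    """Linear regression of a lung-function outcome on mLOY (+ adjusters)."""
    terms = [mloy_var, *covariates]
    y = table[outcome].astype(float)
    X = sm.add_constant(_design(table, terms))
    fit = sm.OLS(y, X).fit()
    if fit.condition_number > condition_number_max:
        raise RuntimeError(
            f"design is ill-conditioned (cond={fit.condition_number:.3g}); "
            "check covariates for collinearity"
        )
    ci = fit.conf_int()
    out = pd.DataFrame(
        {
            "term": fit.params.index,
            "coef": fit.params.values,
            "ci_low": ci[0].values,
            "ci_high": ci[1].values,
            "p_value": fit.pvalues.values,
        }
    )
    out = out[out["term"] != "const"].reset_index(drop=True)
    out.attrs["formula"] = f"{outcome} ~ " + " + ".join(terms)
    out.attrs["n"] = int(len(y))
    return out


# ---------------------------------------------------------------------------
# Mediation
# ---------------------------------------------------------------------------

@dataclass
class MediationResult:
    acme: float
    ade: float
    total: float
    proportion_mediated: float
    acme_ci: tuple[float, float]
    ade_ci: tuple[float, float]
    proportion_ci: tuple[float, float]
    n_boot: int
    seed: int
    outcome_model: str


def _mediation_point(
    table: pd.DataFrame,
    exposure: str,
    mediator: str,
    outcome: str,
    covariates: Sequence[str],
    outcome_model: str,
) -> tuple[float, float]:
    """(ACME, ADE) from parametric mediator/outcome models.

    Mediator model: OLS ``mediator ~ exposure + covariates``.
    Outcome model: ``outcome ~ exposure + mediator + covariates`` (linear
    or logistic). Counterfactual predictions use the mediator's model mean
    under exposure 1 vs 0; effects are averaged over both exposure arms.
    """
    Xc = _design(table, covariates) if covariates else pd.DataFrame(index=table.index)
    t = table[exposure].astype(float).values
    m = table[mediator].astype(float).values
    y = table[outcome].astype(float).values

    Xm = sm.add_constant(
        pd.concat([pd.Series(t, index=table.index, name=exposure), Xc], axis=1)
    ).astype(float)
    med_fit = sm.OLS(m, Xm).fit()

    Xy = sm.add_constant(
        pd.concat(
            [
                pd.Series(t, index=table.index, name=exposure),
                pd.Series(m, index=table.index, name=mediator),
                Xc,
            ],
            axis=1,
        )
    ).astype(float)
    if outcome_model == "linear":
        out_fit = sm.OLS(y, Xy).fit()
        predict = lambda X: out_fit.predict(X)
    elif outcome_model == "logistic":
        out_fit = sm.Logit(y, Xy).fit(disp=0, maxiter=200)
        predict = lambda X: out_fit.predict(X)
    else:
        raise ValueError("outcome_model must be 'linear' or 'logistic'")

    def mediator_mean(t_val: float) -> np.ndarray:
        X = Xm.copy()
        X[exposure] = t_val
        return med_fit.predict(X)

    def outcome_mean(t_val: float, m_vals: np.ndarray) -> np.ndarray:
        X = Xy.copy()
        X[exposure] = t_val
        X[mediator] = m_vals
        return predict(X)

    m0, m1 = mediator_mean(0.0), mediator_mean(1.0)
    acme = 0.0
    ade = 0.0
    for t_val in (0.0, 1.0):
        acme += float(np.mean(outcome_mean(t_val, m1) - outcome_mean(t_val, m0)))
        ade += float(np.mean(outcome_mean(1.0, mediator_mean(t_val)) - outcome_mean(0.0, mediator_mean(t_val))))
    return acme / 2.0, ade / 2.0


def mediation_bootstrap(
    table: pd.DataFrame,
    exposure: str,
    mediator: str,
    outcome: str,
    covariates: Sequence[str] = (),
    outcome_model: str = "logistic",
    n_boot: int = 1000,
    seed: int = 0,
    confidence: float = 0.95,
) -> MediationResult:
    """Product-of-paths mediation with percentile-bootstrap CIs.

    Exposure must be binary 0/1 (re-code other contrasts upstream).
    Deterministic given ``seed``.
    """
    tvals = set(np.unique(table[exposure].astype(float)))
    if not tvals <= {0.0, 1.0}:
        raise ValueError("exposure must be coded 0/1; specify the contrast")
    acme, ade = _mediation_point(
        table, exposure, mediator, outcome, covariates, outcome_model
    )
    total = acme + ade
    prop = acme / total if total != 0 else float("nan")

    rng = np.random.default_rng(seed)
    n = len(table)
    boots = np.empty((n_boot, 3))
    for b in range(n_boot):
        idx = rng.integers(0, n, size=n)
        bt = table.iloc[idx].reset_index(drop=True)
        try:
            a, d = _mediation_point(
                bt, exposure, mediator, outcome, covariates, outcome_model
            )
        except Exception:
            a, d = np.nan, np.nan
        tot = a + d
        boots[b] = (a, d, a / tot if tot not in (0.0,) else np.nan)
    alpha = 1.0 - confidence
    qs = [alpha / 2.0, 1.0 - alpha / 2.0]

    def ci(col: int) -> tuple[float, float]:
        v = boots[:, col]
        v = v[np.isfinite(v)]
        lo, hi = np.quantile(v, qs)
        return float(lo), float(hi)

    return MediationResult(
        acme=acme,
        ade=ade,
        total=total,
        proportion_mediated=prop,
        acme_ci=ci(0),
        ade_ci=ci(1),
        proportion_ci=ci(2),
        n_boot=n_boot,
        seed=seed,
        outcome_model=outcome_model,
    )


# ---------------------------------------------------------------------------
# Imputation
# ---------------------------------------------------------------------------

def impute_missing_exposures(
    table: pd.DataFrame, columns: Optional[Sequence[str]] = None
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Median-impute missing values in exposure columns.

    Returns (imputed table, boolean mask of imputed entries). All-missing
    columns are rejected.
    """
    out = table.copy()
    if columns is None:
        columns = [
            c
            for c in table.columns
            if pd.api.types.is_numeric_dtype(table[c]) and table[c].isna().any()
        ]
    mask = pd.DataFrame(False, index=table.index, columns=list(columns))
    for col in columns:
        vals = out[col]
        if vals.isna().all():
            raise ValueError(f"column {col!r} is entirely missing")
        median = vals.median()
        mask[col] = vals.isna()
        out[col] = vals.fillna(median)
    return out, mask
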