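"""Piecewise multilevel growth models of daily emotion around a lockdown.

Time is coded as four piecewise slopes around the event:

* slope 1 — the pre-event run-up (default 2020-01-20 to 2020-01-22),
* slope 2 — the one-day jump onto the event day (01-22 to 01-23),
* slope 3 — the one-day change off the event day (01-23 to 01-24),
* slope 4 — the longer-term post-event trend (01-24 onward).

Each slope is 0 on/before its start date, increments by one per day
strictly inside its window, and *holds at its maximum* after its window
ends (so slope 1 stays at 2 from 01-23 on).  Slopes 2 and 3 are
therefore 0/1 indicators of "on/after the event day" and "after the
event day".  Under this coding the fitted mean change from 01-22 to
01-23 is exactly the slope-2 coefficient (plus its location interaction
for the locked-down group), and likewise for slope 3.

Person-day emotion scores are modelled with linear mixed models:
observations (level 1) nest in users (level 2), with a person random
intercept and model-specific person random slopes with unstructured
covariance.  Model 1 (immediate response) gives slopes 2 and 3 random
effects and location moderation; model 2 (longer-term impact) gives
slope 4 the random effect and moderation.  Estimation is restricted
maximum likelihood (REML) via statsmodels MixedLM; fixed-effect p-values
are Wald z against the normal reference.  Random-effect structures are
compared by likelihood-ratio tests on the REML -2 log-likelihood at
identical fixed effects, with degrees of freedom equal to the number of
variance/covariance parameters dropped.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from datetime import date, timedelta
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.regression.mixed_linear_model import MixedLM

from .aggregate import StudyWindow

DEFAULT_ANCHORS = (
    date(2020, 1, 20),
    date(2020, 1, 22),
    date(2020, 1, 23),
    date(2020, 1, 24),
)
DEFAULT_FIT_START = date(2020, 1, 20)
SLOPES = ("slope1", "slope2", "slope3", "slope4")

# fixed-effect design per model, in reporting (table) order
MODEL_FIXED = {
    "model1": ("intercept", "slope1", "slope2", "slope3", "slope4",
               "location", "slope2:location", "slope3:location"),
    "model2": ("intercept", "slope1", "slope2", "slope3", "slope4",
               "location", "slope4:location"),
}
MODEL_RANDOM = {
    "model1": ("intercept", "slope2", "slope3"),
    "model2": ("intercept", "slope4"),
}


class ModelError(ValueError):
    pass


def build_slope_design(
    window: StudyWindow,
    anchors: Sequence[date] = DEFAULT_ANCHORS,
) -> pd.DataFrame:
    """Piecewise slope codes for every date in the (fitting) window.

    ``anchors`` are the start dates of the four slopes; each slope's
    window ends at the next anchor (the last at ``window.end``).  The
    code for a date is the day distance past the anchor, clamped to
    [0, window length]; dates before the first anchor carry all zeros.
    """
    anchors = tuple(anchors)
    if len(anchors) != 4:
        raise ModelError(f"need exactly 4 slope anchors, got {len(anchors)}")
    if any(b <= a for a, b in zip(anchors, anchors[1:])):
        raise ModelError(f"slope anchors must be strictly increasing: {anchors}")
    if anchors[0] < window.start or anchors[-1] > window.end:
        raise ModelError(f"anchors {anchors} fall outside window {window}")
    ends = (*anchors[1:], window.end)
    dates = [
        window.start + timedelta(days=i)
        for i in range((window.end - window.start).days + 1)
    ]
    cols: dict[str, list[int]] = {name: [] for name in SLOPES}
    for d in dates:
        for name, a, e in zip(SLOPES, anchors, ends):
            cap = (e - a).days
            cols[name].append(min(max((d - a).days, 0), cap))
    design = pd.DataFrame(cols, index=pd.Index(dates, name="date"))
    return design


@dataclass(frozen=True)
class LRTResult:
    """Likelihood-ratio test between nested random-effect structures."""

    chisq: float
    df: int
    p: float


@dataclass
class MLMFit:
    """A fitted mixed model: fixed effects, variance components, fit stats."""

    model: str
    outcome: str
    fixed: pd.DataFrame          # term, estimate, se, p (reporting order)
    random_terms: tuple[str, ...]
    random_sd: pd.Series         # SD per random term
    random_corr: pd.DataFrame    # correlations between random terms
    cov_re: pd.DataFrame         # random-effect covariance (variance scale)
    residual_sd: float
    minus2ll: float
    n_obs: int
    n_users: int
    converged: bool
    singular: bool
    icc: Optional[float] = None
    warnings: list = field(default_factory=list)

    @property
    def n_cov_params(self) -> int:
        q = len(self.random_terms)
        return q * (q + 1) // 2


def _fit_mixedlm(model: MixedLM):
    """REML fit with an optimizer fallback chain.

    lbfgs is fastest but its line search can step through a singular
    covariance; fall back to more conservative optimizers when it does.
    """
    result = None
    for method in ("lbfgs", "cg", "powell"):
        try:
            result = model.fit(reml=True, method=method, maxiter=500)
        except np.linalg.LinAlgError:
            continue
        if np.isfinite(result.llf):
            return result
    try:
        fallback = model.fit(reml=True, maxiter=500)
        if np.isfinite(fallback.llf):
            return fallback
    except np.linalg.LinAlgError:
        pass
    if result is None:
        raise ModelError("mixed-model optimization failed under every optimizer")
    return result


def _check_fit_inputs(person_days: pd.DataFrame, outcome: str) -> None:
    if outcome not in person_days.columns:
        raise ModelError(f"outcome {outcome!r} not in person-day table")
    per_user = person_days.groupby("user_id").size()
    if (per_user >= 2).sum() < 2:
        raise ModelError("need at least 2 users with at least 2 observations each")


def filter_min_users_per_day(
    person_days: pd.DataFrame, min_users: int
) -> pd.DataFrame:
    """Drop dates observed by fewer than ``min_users`` distinct users."""
    per_day = person_days.groupby("date")["user_id"].nunique()
    keep = per_day[per_day >= min_users].index
    return person_days[person_days["date"].isin(keep)].reset_index(drop=True)


def _collect_fit(
    model_name: str,
    outcome: str,
    terms: Sequence[str],
    random_terms: Sequence[str],
    result,
    n_obs: int,
    n_users: int,
    caught: list,
) -> MLMFit:
    fixed = pd.DataFrame(
        {
            "term": list(terms),
            "estimate": np.asarray(result.fe_params, dtype=float),
            "se": np.asarray(result.bse_fe, dtype=float),
            "p": np.asarray(result.pvalues[: len(terms)], dtype=float),
        }
    )
    cov = pd.DataFrame(
        np.atleast_2d(np.asarray(result.cov_re, dtype=float)),
        index=list(random_terms),
        columns=list(random_terms),
    )
    sd = pd.Series(np.sqrt(np.diag(cov.values)), index=cov.index, name="sd")
    denom = np.outer(sd.values, sd.values)
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = pd.DataFrame(
            np.where(denom > 0, cov.values / denom, np.nan),
            index=cov.index,
            columns=cov.columns,
        )
    eigvals = np.linalg.eigvalsh(cov.values)
    singular = bool(eigvals.min() < 1e-10 * max(eigvals.max(), 1.0))
    return MLMFit(
        model=model_name,
        outcome=outcome,
        fixed=fixed,
        random_terms=tuple(random_terms),
        random_sd=sd,
        random_corr=corr,
        cov_re=cov,
        residual_sd=float(np.sqrt(result.scale)),
        minus2ll=float(-2.0 * result.llf),
        n_obs=n_obs,
        n_users=n_users,
        converged=bool(result.converged),
        singular=singular,
        warnings=[str(w.message) for w in caught],
    )


def fit_empty_model(person_days: pd.DataFrame, outcome: str = "valence") -> MLMFit:
    """Random-intercept-only ("empty") model, with the ICC.

    The intraclass correlation coefficient is the between-person
    variance over the total variance, i.e. the share of outcome variance
    attributable to stable person differences.
    """
    _check_fit_inputs(person_days, outcome)
    y = person_days[outcome].to_numpy(dtype=float)
    X = np.ones((len(y), 1))
    groups = person_days["user_id"].to_numpy()
    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always")
        result = _fit_mixedlm(MixedLM(y, X, groups=groups))
    fit = _collect_fit(
        "empty", outcome, ("intercept",), ("intercept",), result,
        len(y), person_days["user_id"].nunique(), list(caught),
    )
    between = float(fit.cov_re.iloc[0, 0])
    within = fit.residual_sd**2
    fit.icc = between / (between + within)
    return fit


def _null_reml_minus2ll(y: np.ndarray, X: np.ndarray) -> float:
    """REML -2 log-likelihood of the fixed-effects-only model.

    Matches the statsmodels MixedLM REML convention so that the value is
    comparable with ``MLMFit.minus2ll`` of a model fitted on the same
    data:  -2ll = (n-p) log(2 pi) + (n-p) log(s2) + log|X'X| + rss/s2
    with s2 = rss / (n - p).
    """
    n, p = X.shape
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    rss = float(resid @ resid)
    s2 = rss / (n - p)
    _, logdet = np.linalg.slogdet(X.T @ X)
    return float(
        (n - p) * math.log(2 * math.pi) + (n - p) * math.log(s2) + logdet + rss / s2
    )


def empty_model_lrt(person_days: pd.DataFrame, outcome: str = "valence",
                    fit: Optional[MLMFit] = None) -> LRTResult:
    """LRT of the random intercept against a no-random-effect model.

    One variance parameter is dropped, so df = 1 by the parameter
    counting rule used throughout (the reference distribution is the
    nominal chi-square; boundary conservatism is noted, not corrected).
    """
    if fit is None:
        fit = fit_empty_model(person_days, outcome)
    y = person_days[outcome].to_numpy(dtype=float)
    X = np.ones((len(y), 1))
    null_m2ll = _null_reml_minus2ll(y, X)
    chisq = max(0.0, null_m2ll - fit.minus2ll)
    return LRTResult(chisq=chisq, df=1, p=float(stats.chi2.sf(chisq, 1)))


def _design_matrix(frame: pd.DataFrame, terms: Sequence[str]) -> np.ndarray:
    cols = []
    for term in terms:
        if term == "intercept":
            cols.append(np.ones(len(frame)))
        elif ":" in term:
            a, b = term.split(":")
            cols.append(frame[a].to_numpy(float) * frame[b].to_numpy(float))
        else:
            cols.append(frame[term].to_numpy(float))
    return np.column_stack(cols)


def attach_design(person_days: pd.DataFrame, design: pd.DataFrame) -> pd.DataFrame:
    """Merge slope codes onto a person-day table by date.

    Rows whose date is outside the design table (e.g. before the fitting
    window) are dropped.
    """
    frame = person_days.copy()
    frame["date"] = pd.to_datetime(frame["date"]).dt.date
    d = design.reset_index()
    d["date"] = pd.to_datetime(d["date"]).dt.date
    merged = frame.merge(d, on="date", how="inner")
    return merged


def fit_model(
    person_days: pd.DataFrame,
    outcome: str = "valence",
    model: str = "model1",
    design: Optional[pd.DataFrame] = None,
    random_terms: Optional[Sequence[str]] = None,
    min_users_per_day: Optional[int] = None,
) -> MLMFit:
    """Fit piecewise growth model 1 or 2 by REML.

    The person-day table must carry a 0/1 ``location`` column (1 =
    locked-down group) and either the slope columns or a ``design``
    table to merge in.  ``random_terms`` overrides the model's default
    random structure (used for the nested fits behind the random-effect
    LRTs).  ``min_users_per_day`` optionally drops thin days first.
    """
    if model not in MODEL_FIXED:
        raise ModelError(f"unknown model {model!r}; expected model1 or model2")
    frame = person_days
    if design is not None:
        frame = attach_design(frame, design)
    missing = [c for c in (*SLOPES, "location") if c not in frame.columns]
    if missing:
        raise ModelError(f"person-day table lacks columns {missing}")
    if min_users_per_day:
        frame = filter_min_users_per_day(frame, min_users_per_day)
    _check_fit_inputs(frame, outcome)
    if not set(np.unique(frame["location"])) <= {0, 1}:
        raise ModelError("location must be coded 0/1")

    terms = MODEL_FIXED[model]
    random_terms = tuple(random_terms if random_terms is not None else MODEL_RANDOM[model])
    X = _design_matrix(frame, terms)
    Z = _design_matrix(frame, random_terms)
    y = frame[outcome].to_numpy(dtype=float)
    groups = frame["user_id"].to_numpy()
    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always")
        result = _fit_mixedlm(MixedLM(y, X, groups=groups, exog_re=Z))
    return _collect_fit(
        model, outcome, terms, random_terms, result,
        len(y), frame["user_id"].nunique(), list(caught),
    )


def lrt_random_effect(full: MLMFit, reduced: MLMFit) -> LRTResult:
    """LRT comparing nested random structures at identical fixed effects.

    chisq is the difference in REML -2 log-likelihoods (floored at 0);
    df counts the variance/covariance parameters dropped — removing one
    correlated random term from a structure with q terms drops q
    parameters (1 variance + q-1 covariances).
    """
    if list(full.fixed["term"]) != list(reduced.fixed["term"]):
        raise ModelError("LRT requires identical fixed effects")
    if not set(reduced.random_terms) <= set(full.random_terms):
        raise ModelError(
            f"random structure {reduced.random_terms} does not nest "
            f"in {full.random_terms}"
        )
    df = full.n_cov_params - reduced.n_cov_params
    chisq = max(0.0, reduced.minus2ll - full.minus2ll)
    p = float(stats.chi2.sf(chisq, df)) if df > 0 else 1.0
    return LRTResult(chisq=chisq, df=df, p=p)


def random_effect_lrt_table(
    person_days: pd.DataFrame,
    outcome: str = "valence",
    model: str = "model1",
    design: Optional[pd.DataFrame] = None,
    full: Optional[MLMFit] = None,
    min_users_per_day: Optional[int] = None,
) -> pd.DataFrame:
    """LRT of each random term in a model, dropped one at a time.

    Reproduces the reporting convention of the results tables: for every
    random term, the chi-square is the -2LL difference between the full
    model and the model without that term (the other random terms
    retained), with df equal to the parameters dropped.
    """
    if full is None:
        full = fit_model(person_days, outcome, model, design=design,
                         min_users_per_day=min_users_per_day)
    rows = []
    for term in full.random_terms:
        reduced_terms = tuple(t for t in full.random_terms if t != term)
        reduced = fit_model(
            person_days, outcome, model, design=design,
            random_terms=reduced_terms, min_users_per_day=min_users_per_day,
        )
        res = lrt_random_effect(full, reduced)
        rows.append(
            {
                "term": term,
                "sd": float(full.random_sd[term]),
                "chisq": res.chisq,
                "df": res.df,
                "p": res.p,
            }
        )
    return pd.DataFrame(rows)
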