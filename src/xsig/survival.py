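"""Survival stratification by signature call.

Survival tables are pandas DataFrames indexed by sample id with, per
endpoint e in {os, rfs, sar}, columns ``{e}_time`` (months) and
``{e}_event`` (0/1), plus arbitrary covariate columns. SAR (survival after
relapse) is defined only for relapsed subjects — its columns are NaN
elsewhere and those subjects are excluded from SAR fits.

Kaplan-Meier estimation and Cox proportional-hazards fits delegate to
lifelines (Efron handling of tied event times); analyses truncate follow-up
at 84 months by administrative censoring before fitting.
"""

from __future__ import annotations

import logging
import warnings

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.exceptions import ConvergenceError
from scipy import stats

log = logging.getLogger(__name__)

ENDPOINTS = ("os", "rfs", "sar")
DEFAULT_CUTOFF = 84.0


def truncate_survival(table: pd.DataFrame, cutoff: float = DEFAULT_CUTOFF,
                      endpoints=ENDPOINTS) -> pd.DataFrame:
    """Administrative censoring at ``cutoff`` months.

    Any time exceeding the cutoff is set to the cutoff with its event
    indicator cleared; times at or below the cutoff are unchanged.
    Idempotent; never increases any time or event count.
    """
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    out = table.copy()
    for e in endpoints:
        tcol, ecol = f"{e}_time", f"{e}_event"
        if tcol not in out.columns:
            continue
        t = out[tcol]
        if (t.dropna() < 0).any():
            raise ValueError(f"negative times in {tcol}")
        over = t > cutoff
        out.loc[over, tcol] = cutoff
        out.loc[over, ecol] = 0
    return out


def km_estimate(times, events, groups=None) -> dict[str, pd.DataFrame]:
    """Product-limit survival estimates, one step function per group.

    Returns, per group, a DataFrame indexed by event time with columns
    ``survival``, ``at_risk``, ``observed`` and ``censored``. At tied
    times, events are processed before censorings (standard convention).
    """
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    if len(times) == 0:
        raise ValueError("empty cohort")
    if events.sum() < 1:
        log.warning("km_estimate: no events observed; survival stays at 1")
    if groups is None:
        groups = np.repeat("all", len(times))
    groups = np.asarray(groups)
    out: dict[str, pd.DataFrame] = {}
    for g in pd.unique(groups):
        mask = groups == g
        if mask.sum() == 0:
            raise ValueError(f"empty group {g!r}")
        kmf = KaplanMeierFitter()
        kmf.fit(times[mask], events[mask], label=str(g))
        et = kmf.event_table
        surv = kmf.survival_function_.iloc[:, 0]
        df = pd.DataFrame({
            "survival": surv,
            "at_risk": et["at_risk"],
            "observed": et["observed"],
            "censored": et["censored"],
        })
        df.index.name = "time"
        out[str(g)] = df
    return out


def cox_fit(table: pd.DataFrame, endpoint: str, covariates: list[str],
            reference_levels: dict[str, str] | None = None) -> pd.DataFrame:
    """Cox proportional-hazards fit for one endpoint.

    Categorical covariates are dummy-coded against their reference level
    (first sorted level unless given in ``reference_levels``). Returns one
    row per model term: ``coef, se, hr, ci_low, ci_high, p`` plus the model
    log-likelihood and sample/event counts in ``attrs``.
    """
    tcol, ecol = f"{endpoint}_time", f"{endpoint}_event"
    sub = table[[tcol, ecol, *covariates]].dropna()
    if sub.empty or sub[ecol].sum() < 1:
        raise ValueError(f"no usable events for endpoint {endpoint!r}")
    refs = reference_levels or {}
    cols = {}
    for c in covariates:
        v = sub[c]
        if v.dtype == bool:
            cols[c] = v.astype(float)
        elif np.issubdtype(v.dtype, np.number):
            cols[c] = v.astype(float)
        else:
            levels = sorted(v.astype(str).unique())
            ref = refs.get(c, levels[0])
            for lev in levels:
                if lev != ref:
                    cols[f"{c}[{lev}]"] = (v.astype(str) == lev).astype(float)
    x = pd.DataFrame(cols, index=sub.index)
    flat = [c for c in x.columns if x[c].nunique() < 2]
    if flat:
        raise ValueError(f"covariate(s) without variation: {flat}")
    df = pd.concat([sub[[tcol, ecol]], x], axis=1)
    cph = CoxPHFitter()
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            cph.fit(df, duration_col=tcol, event_col=ecol,
                    fit_options={"precision": 1e-9})
    except ConvergenceError as err:
        raise ValueError(
            f"Cox fit failed to converge for endpoint {endpoint!r} "
            f"(possible separation): {err}") from err
    s = cph.summary
    out = pd.DataFrame({
        "coef": s["coef"],
        "se": s["se(coef)"],
        "hr": s["exp(coef)"],
        "ci_low": s["exp(coef) lower 95%"],
        "ci_high": s["exp(coef) upper 95%"],
        "p": s["p"],
    })
    out.attrs["log_likelihood"] = float(cph.log_likelihood_)
    out.attrs["n"] = int(len(df))
    out.attrs["n_events"] = int(df[ecol].sum())
    return out


def endpoint_suite(table: pd.DataFrame, call: pd.Series,
                   cutoff: float = DEFAULT_CUTOFF) -> pd.DataFrame:
    """Univariable allele-like vs non-allele-like Cox fits for OS/RFS/SAR.

    Follow-up is truncated at ``cutoff`` months first; SAR is restricted to
    relapsed subjects (non-null SAR columns). Endpoints without usable
    events are skipped with a warning row omitted.
    """
    df = table.copy()
    df["call"] = call.reindex(df.index).astype(float)
    if df["call"].isna().any():
        raise ValueError("classification call missing for some samples")
    df = truncate_survival(df, cutoff)
    rows = []
    for e in ENDPOINTS:
        if f"{e}_time" not in df.columns:
            continue
        try:
            fit = cox_fit(df, e, ["call"])
        except ValueError as err:
            log.warning("endpoint %s skipped: %s", e, err)
            continue
        r = fit.loc["call"]
        rows.append({"endpoint": e.upper(), "n": fit.attrs["n"],
                     "events": fit.attrs["n_events"], "hr": r["hr"],
                     "ci_low": r["ci_low"], "ci_high": r["ci_high"],
                     "p": r["p"]})
    return pd.DataFrame(rows).set_index("endpoint")


def clinical_enrichment(call: pd.Series, covariates: pd.DataFrame) -> pd.DataFrame:
    """Association of the signature call with categorical covariates.

    Per covariate, a 2 x k contingency table of call vs levels with a
    two-sided Fisher exact test (k = 2) or chi-square test (k > 2).
    Degenerate tables (a dimension with < 2 informative levels) get p = 1
    with a warning.
    """
    rows = []
    for c in covariates.columns:
        v = covariates[c].reindex(call.index)
        tab = pd.crosstab(call, v)
        if tab.shape[0] < 2 or tab.shape[1] < 2:
            log.warning("clinical_enrichment: degenerate table for %r", c)
            rows.append({"covariate": c, "test": "degenerate", "p": 1.0})
            continue
        if tab.shape[1] == 2:
            _, p = stats.fisher_exact(tab.values)
            test = "fisher"
        else:
            _, p, _, _ = stats.chi2_contingency(tab.values)
            test = "chi2"
        rows.append({"covariate": c, "test": test, "p": float(p)})
    return pd.DataFrame(rows).set_index("covariate")


def plot_km(km: dict[str, pd.DataFrame], path: str, title: str = "") -> None:
    """Write step-function KM curves for each group to SVG/PNG."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 4))
    for g, df in km.items():
        ax.step(df.index, df["survival"], where="post", label=g)
    ax.set_xlabel("months")
    ax.set_ylabel("survival probability")
    ax.set_ylim(0, 1.02)
    if title:
        ax.set_title(title)
    ax.legend()
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)
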