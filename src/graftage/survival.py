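"""Left-truncated survival analysis of CLAD-or-death.

Subjects enter observation only at their airway brush (roughly one year
post-transplant), so the time origin is transplant but risk sets are
restricted to subjects with ``entry_time < t <= event_time`` — left
truncation with delayed entry.  This module wraps Cox
proportional-hazards fitting (Efron ties), tertile coding of methylation
age, truncation-aware Kaplan-Meier curves, and the simulation-based power
procedure: simulate predictor draws under a grid of hazard ratios against
the observed baseline hazard and censoring pattern, record significance,
and read power off a fitted logistic curve.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter, NelsonAalenFitter
from lifelines.exceptions import ConvergenceError as _LLConvergenceError

from .errors import ConvergenceError, DegenerateDataError, ValidationError
from .io import SampleTable

__all__ = [
    "CoxFit",
    "PowerCurve",
    "fit_cox",
    "tertile_assign",
    "km_curve",
    "power_by_simulation",
]

_FIT_OPTIONS = {"precision": 1e-10}


@dataclass
class CoxFit:
    """A fitted Cox model: log-hazards, hazard ratios, Wald CIs."""

    coefs: pd.Series
    hr: pd.Series
    hr_ci: pd.DataFrame             # columns "lower", "upper"
    pvalues: pd.Series
    n: int
    n_events: int
    ties: str = "efron"

    def __post_init__(self) -> None:
        if not np.allclose(self.hr, np.exp(self.coefs)):
            raise ValidationError("HR != exp(coefficient)")
        lo, hi = self.hr_ci["lower"], self.hr_ci["upper"]
        if not ((lo <= self.hr + 1e-9) & (self.hr <= hi + 1e-9)).all():
            raise ValidationError("CI does not bracket HR")


@dataclass
class PowerCurve:
    """Simulation-based power curve over a hazard-ratio grid."""

    hr_grid: np.ndarray
    rejection_fraction: np.ndarray
    logistic_params: tuple[float, float]   # (intercept, slope on HR)
    power_at_query: float
    query_hr: float
    n_sims: int
    alpha: float
    seed: int

    def __post_init__(self) -> None:
        rf = np.asarray(self.rejection_fraction, dtype=float)
        if np.any((rf < 0) | (rf > 1)):
            raise ValidationError("rejection fractions outside [0, 1]")

    def power(self, hr: float) -> float:
        """Fitted rejection probability at an arbitrary hazard ratio."""
        b0, b1 = self.logistic_params
        return float(1.0 / (1.0 + np.exp(-(b0 + b1 * hr))))


def _survival_frame(table: SampleTable) -> pd.DataFrame:
    df = table.data
    return pd.DataFrame({
        "entry": df["entry_time"].to_numpy(float),
        "time": df["event_time"].to_numpy(float),
        "event": df["event"].to_numpy(bool),
    })


def fit_cox(
    table: SampleTable,
    predictor,
    *,
    name: str = "predictor",
    adjust_batch: bool = True,
    extra: pd.DataFrame | None = None,
) -> CoxFit:
    """Left-truncated Cox proportional-hazards fit.

    ``predictor`` may be a numeric vector (e.g. methylation age), a
    categorical/tertile coding, or a DataFrame of several columns.  Batch is
    added as a covariate unless ``adjust_batch=False``.  Ties are handled by
    the Efron approximation; CIs are Wald intervals.  A predictor with no
    variation returns the null fit (HR 1, p 1) rather than failing; a
    monotone likelihood (perfect separation) raises
    :class:`~graftage.errors.ConvergenceError` with the diverging direction.
    """
    df = _survival_frame(table)
    if not df["event"].any():
        raise DegenerateDataError("no events observed; cannot fit Cox model")
    if isinstance(predictor, pd.DataFrame):
        pred = predictor.reset_index(drop=True)
    else:
        arr = np.asarray(predictor)
        pred = pd.DataFrame({name: arr})
    if len(pred) != len(df):
        raise ValidationError("predictor length does not match sample table")

    X = _encode(pred)
    if adjust_batch and table.data["batch"].nunique() > 1:
        X = pd.concat(
            [X, _encode(table.data[["batch"]]).reset_index(drop=True)], axis=1)
    if extra is not None:
        X = pd.concat([X, _encode(extra).reset_index(drop=True)], axis=1)

    # drop constant columns; a zero-variance predictor is the null model
    constant = [c for c in X.columns if np.ptp(X[c].to_numpy(float)) == 0]
    dropped_predictor = [c for c in constant if not c.startswith("batch")]
    X = X.drop(columns=constant)
    if X.shape[1] == 0 or (dropped_predictor and X.shape[1] == 0):
        idx = pd.Index(dropped_predictor or [name])
        ones = pd.Series(1.0, index=idx)
        return CoxFit(
            coefs=pd.Series(0.0, index=idx),
            hr=ones,
            hr_ci=pd.DataFrame({"lower": ones, "upper": ones}),
            pvalues=pd.Series(1.0, index=idx),
            n=len(df), n_events=int(df["event"].sum()),
        )

    data = pd.concat([df, X], axis=1)
    cph = CoxPHFitter()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            cph.fit(data, duration_col="time", event_col="event",
                    entry_col="entry", fit_options=_FIT_OPTIONS)
        except _LLConvergenceError as exc:
            direction = None
            try:
                direction = float(np.sign(cph.params_.iloc[0]))
            except Exception:
                pass
            raise ConvergenceError(
                f"Cox partial likelihood did not converge (possible "
                f"monotone likelihood / perfect separation): {exc}",
                direction=direction,
            ) from exc

    ci = np.exp(cph.confidence_intervals_)
    ci.columns = ["lower", "upper"]
    ci.index = cph.params_.index
    fit = CoxFit(
        coefs=cph.params_,
        hr=np.exp(cph.params_),
        hr_ci=ci,
        pvalues=cph.summary["p"],
        n=len(df),
        n_events=int(df["event"].sum()),
    )
    if dropped_predictor:
        # re-attach null rows for zero-variance predictor columns
        for c in dropped_predictor:
            fit.coefs.loc[c] = 0.0
            fit.hr.loc[c] = 1.0
            fit.hr_ci.loc[c] = [1.0, 1.0]
            fit.pvalues.loc[c] = 1.0
    return fit


def _encode(design: pd.DataFrame) -> pd.DataFrame:
    from .associations import _encode_design
    return _encode_design(design.reset_index(drop=True))


def tertile_assign(values) -> np.ndarray:
    """Tertile codes {1, 2, 3} from youngest to oldest.

    Cutpoints are the 33 1/3 and 66 2/3 percentiles (linear-interpolation
    quantiles); values at a cutpoint go to the lower tertile.  With fewer
    than 3 distinct values the split is degenerate and a warning is issued.
    """
    v = np.asarray(values, dtype=float)
    if v.size < 3:
        raise ValidationError("need n >= 3 for tertiles")
    if np.unique(v).size < 3:
        warnings.warn("fewer than 3 distinct values; tertiles degenerate",
                      stacklevel=2)
    q1, q2 = np.percentile(v, [100 / 3, 200 / 3])
    return np.where(v <= q1, 1, np.where(v <= q2, 2, 3)).astype(int)


def km_curve(
    table: SampleTable,
    strata=None,
) -> dict[str, pd.DataFrame]:
    """Truncation-aware Kaplan-Meier estimates, one table per stratum.

    Each value is a DataFrame with columns ``time``, ``survival``,
    ``at_risk`` suitable for step plotting.  Empty strata are omitted with
    a warning.
    """
    df = _survival_frame(table)
    if strata is None:
        labels = np.array(["all"] * len(df))
    else:
        labels = np.asarray(strata).astype(str)
        if labels.size != len(df):
            raise ValidationError("strata length does not match table")
    out: dict[str, pd.DataFrame] = {}
    for lev in sorted(np.unique(labels)):
        mask = labels == lev
        if not mask.any():
            warnings.warn(f"stratum {lev!r} is empty; omitted", stacklevel=2)
            continue
        kmf = KaplanMeierFitter()
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            kmf.fit(df.loc[mask, "time"], df.loc[mask, "event"],
                    entry=df.loc[mask, "entry"])
        sf = kmf.survival_function_
        ev = kmf.event_table
        out[lev] = pd.DataFrame({
            "time": sf.index.to_numpy(float),
            "survival": sf.iloc[:, 0].to_numpy(float),
            "at_risk": ev["at_risk"].reindex(sf.index).to_numpy(float),
        }).reset_index(drop=True)
    return out


def power_by_simulation(
    table: SampleTable,
    predictor,
    *,
    hr_grid=(1.0, 1.5, 2.0, 2.5, 3.0),
    n_sims: int = 200,
    alpha: float = 0.05,
    query_hr: float = 1.05,
    seed: int = 0,
) -> PowerCurve:
    """Estimate power for a Cox predictor effect by simulation.

    For each hazard ratio ``h`` on the grid, ``n_sims`` replicates draw a
    predictor vector from Normal(observed mean, observed SD), simulate
    event times from a proportional-hazards model whose baseline cumulative
    hazard is the Nelson-Aalen estimate of the observed data and whose
    per-unit log hazard is ``ln h`` (predictor centered), keep the observed
    entry times and administrative censoring at each subject's observed
    follow-up, fit the Cox model, and record whether p < ``alpha``.  A
    logistic regression of rejection on ``h`` over all pooled replicates
    gives the smoothed power curve, evaluated at ``query_hr``.

    Only predictor values are redrawn; the observed survival-time scaffold
    (baseline hazard, entry, censoring) is held fixed.
    """
    from scipy.optimize import minimize

    df = _survival_frame(table)
    if not df["event"].any():
        raise DegenerateDataError(
            "no events in observed data; cannot estimate baseline hazard")
    x_obs = np.asarray(predictor, dtype=float)
    if x_obs.size != len(df):
        raise ValidationError("predictor length does not match table")
    hr_grid = np.asarray(sorted(hr_grid), dtype=float)
    if hr_grid.size < 2:
        raise ValidationError("hr_grid needs >= 2 points")
    mu, sd = float(x_obs.mean()), float(x_obs.std(ddof=1))

    naf = NelsonAalenFitter(nelson_aalen_smoothing=False)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        naf.fit(df["time"], df["event"], entry=df["entry"])
    ch = naf.cumulative_hazard_.iloc[:, 0]
    ch = ch[ch.index > 0]
    grid_t = ch.index.to_numpy(float)
    grid_H = ch.to_numpy(float)
    H_max = grid_H[-1]

    entry = df["entry"].to_numpy(float)
    followup = df["time"].to_numpy(float)
    n = len(df)
    rng = np.random.default_rng(seed)

    rejections = np.zeros(hr_grid.size)
    for gi, h in enumerate(hr_grid):
        beta = np.log(h)
        n_rej = 0
        for _ in range(n_sims):
            x = rng.normal(mu, sd, size=n)
            rel = np.exp(beta * (x - mu))
            # inverse-transform sampling on the step cumulative hazard,
            # started from each subject's entry time
            H_entry = np.interp(entry, grid_t, grid_H, left=0.0)
            target = H_entry + rng.exponential(1.0, size=n) / rel
            t_event = np.where(
                target > H_max, np.inf,
                grid_t[np.searchsorted(grid_H, target, side="left")
                       .clip(0, grid_t.size - 1)],
            )
            t_event = np.maximum(t_event, entry + 1e-6)
            event = t_event <= followup
            time = np.where(event, t_event, followup)
            sim = pd.DataFrame({"entry": entry, "time": time,
                                "event": event, "x": x})
            if not event.any():
                continue
            cph = CoxPHFitter()
            try:
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    cph.fit(sim, duration_col="time", event_col="event",
                            entry_col="entry")
                if float(cph.summary.loc["x", "p"]) < alpha:
                    n_rej += 1
            except Exception:
                continue
        rejections[gi] = n_rej / n_sims

    b0, b1 = _fit_logistic(np.repeat(hr_grid, n_sims),
                           _expand(rejections, n_sims))
    power_q = float(1.0 / (1.0 + np.exp(-(b0 + b1 * query_hr))))
    return PowerCurve(
        hr_grid=hr_grid,
        rejection_fraction=rejections,
        logistic_params=(b0, b1),
        power_at_query=power_q,
        query_hr=float(query_hr),
        n_sims=int(n_sims),
        alpha=float(alpha),
        seed=int(seed),
    )


def _expand(fracs: np.ndarray, n_sims: int) -> np.ndarray:
    """Rebuild pooled 0/1 outcomes from per-grid rejection counts."""
    out = []
    for f in fracs:
        k = int(round(f * n_sims))
        out.append(np.concatenate([np.ones(k), np.zeros(n_sims - k)]))
    return np.concatenate(out)


def _fit_logistic(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    import statsmodels.api as sm

    X = sm.add_constant(x)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            res = sm.GLM(y, X, family=sm.families.Binomial()).fit()
            return float(res.params[0]), float(res.params[1])
        except Exception:
            # all-0 or all-1 outcomes: flat curve at the observed mean
            p = float(np.clip(y.mean(), 1e-10, 1 - 1e-10))
            return float(np.log(p / (1 - p))), 0.0
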