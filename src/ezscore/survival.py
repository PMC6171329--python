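"""Survival-analysis primitives.

Kaplan–Meier estimation, two-group log-rank testing and univariate Cox
fitting wrap lifelines; maximally selected rank statistics (maxstat) —
the cutpoint-discovery machinery behind every signature gene and behind
the score threshold — is implemented here directly.

The maxstat statistic at a candidate split ``x > c`` is the standardized
log-rank statistic (O - E) / sqrt(V) with the usual hypergeometric
variance, so its square equals the ordinary log-rank chi-square at that
split.  The cutpoint maximizing the absolute standardized statistic is
reported together with a p-value corrected for the multiplicity of
candidate cutpoints (improved-Bonferroni approximation of Miller &
Siegmund / Lausen & Schumacher, or a permutation estimate).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.exceptions import ConvergenceError
from lifelines.statistics import logrank_test as _ll_logrank
from scipy import stats

__all__ = [
    "SurvivalData",
    "KMCurve",
    "CoxFit",
    "MaxstatResult",
    "kaplan_meier",
    "logrank_test",
    "fit_cox_univariate",
    "maxstat_cutpoint",
]


@dataclass(frozen=True)
class SurvivalData:
    """Right-censored survival records: time in months, event 1 = observed."""

    time: np.ndarray
    event: np.ndarray
    sample_id: np.ndarray

    def __post_init__(self):
        t = np.asarray(self.time, dtype=float)
        e = np.asarray(self.event, dtype=int)
        sid = np.asarray(self.sample_id)
        if t.size == 0:
            raise ValueError("survival data must contain at least one record")
        if t.shape != e.shape or t.shape != sid.shape:
            raise ValueError("time, event and sample_id must have equal length")
        if np.any(t < 0) or np.any(~np.isfinite(t)):
            raise ValueError("times must be finite and nonnegative")
        if not np.isin(e, (0, 1)).all():
            raise ValueError("event indicator must be 0 or 1")
        if len(np.unique(sid)) != sid.size:
            raise ValueError("sample_ids must be unique")
        object.__setattr__(self, "time", t)
        object.__setattr__(self, "event", e)
        object.__setattr__(self, "sample_id", sid)

    def __len__(self) -> int:
        return self.time.size

    @property
    def n_events(self) -> int:
        return int(self.event.sum())

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "SurvivalData":
        return cls(
            time=df["time"].to_numpy(),
            event=df["event"].to_numpy(),
            sample_id=df["sample_id"].to_numpy(),
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"sample_id": self.sample_id, "time": self.time, "event": self.event}
        )


@dataclass(frozen=True)
class KMCurve:
    """Product-limit estimate evaluated at the distinct event times."""

    event_times: np.ndarray
    survival_prob: np.ndarray
    n_at_risk: np.ndarray
    n_events: np.ndarray

    def survival_at(self, t: float) -> float:
        """S(t); step function, right-continuous, S = 1 before the first event."""
        idx = np.searchsorted(self.event_times, t, side="right") - 1
        return 1.0 if idx < 0 else float(self.survival_prob[idx])


@dataclass(frozen=True)
class CoxFit:
    """Univariate Cox proportional-hazards fit (Efron tie handling)."""

    beta: float
    se: float
    hazard_ratio: float
    p_value: float
    n: int
    n_events: int
    converged: bool


@dataclass(frozen=True)
class MaxstatResult:
    """Best cutpoint by maximally selected standardized log-rank statistics."""

    cutpoint: float
    max_statistic: float
    p_value: float
    n_low: int
    n_high: int
    cutpoints: np.ndarray = field(default=None, repr=False)
    statistics: np.ndarray = field(default=None, repr=False)

    @property
    def chisq(self) -> float:
        """Squared standardized statistic: the log-rank chi-square at the cut."""
        return self.max_statistic**2


def kaplan_meier(surv: SurvivalData) -> KMCurve:
    """Product-limit survival estimate.

    With no observed events the estimate is the constant curve S(t) = 1
    (an empty product) and ``event_times`` is empty.
    """
    if surv.n_events == 0:
        z = np.array([])
        return KMCurve(event_times=z, survival_prob=z, n_at_risk=z, n_events=z)
    kmf = KaplanMeierFitter()
    kmf.fit(surv.time, surv.event)
    ev = surv.time[surv.event == 1]
    times = np.unique(ev)
    s = np.array([float(kmf.survival_function_at_times(t).iloc[0]) for t in times])
    tab = kmf.event_table
    at_risk = tab.loc[times, "at_risk"].to_numpy(dtype=float)
    d = tab.loc[times, "observed"].to_numpy(dtype=float)
    return KMCurve(event_times=times, survival_prob=s, n_at_risk=at_risk, n_events=d)


def logrank_test(surv: SurvivalData, group) -> tuple[float, float]:
    """Two-group log-rank test; returns (chi-square on 1 df, p-value)."""
    g = np.asarray(group)
    labels = np.unique(g)
    if labels.size != 2:
        raise ValueError("log-rank test requires exactly two non-empty groups")
    if surv.n_events == 0:
        raise ValueError("log-rank test requires at least one observed event")
    mask = g == labels[0]
    res = _ll_logrank(
        surv.time[mask], surv.time[~mask], surv.event[mask], surv.event[~mask]
    )
    return float(res.test_statistic), float(res.p_value)


def fit_cox_univariate(x, surv: SurvivalData) -> CoxFit:
    """Cox proportional-hazards fit for a single covariate.

    Ties are handled by the Efron approximation (lifelines default).
    Non-convergence (e.g. monotone likelihood under perfect separation)
    is reported via ``converged=False`` rather than raised.
    """
    x = np.asarray(x, dtype=float)
    if x.shape != surv.time.shape:
        raise ValueError("covariate length must match survival data")
    if np.unique(x).size < 2:
        raise ValueError("covariate is constant; Cox model is unidentified")
    if surv.n_events == 0:
        raise ValueError("Cox model requires at least one observed event")
    df = pd.DataFrame({"x": x, "time": surv.time, "event": surv.event})
    cph = CoxPHFitter()
    converged = True
    with warnings.catch_warnings():
        warnings.simplefilter("error", category=UserWarning)
        try:
            cph.fit(df, duration_col="time", event_col="event")
        except (ConvergenceError, UserWarning, Warning):
            converged = False
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                try:
                    cph.fit(df, duration_col="time", event_col="event")
                except ConvergenceError as err:  # no usable estimate at all
                    raise ValueError(f"Cox fit failed: {err}") from err
    beta = float(cph.params_["x"])
    se = float(cph.standard_errors_["x"])
    return CoxFit(
        beta=beta,
        se=se,
        hazard_ratio=float(np.exp(beta)),
        p_value=float(cph.summary.loc["x", "p"]),
        n=len(surv),
        n_events=surv.n_events,
        converged=converged,
    )


def _logrank_all_splits(x, time, event, min_prop):
    """Standardized log-rank statistic at every admissible split ``x > c``.

    Candidate cutpoints are midpoints between consecutive distinct sorted
    x values; a split is admissible when both groups contain at least
    ``min_prop`` of the samples.  Returns (cutpoints, z, n_high) where
    z[i] = (O - E)/sqrt(V) for the high group of split i.
    """
    x = np.asarray(x, dtype=float)
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    n = x.size

    order = np.argsort(-x, kind="stable")  # descending x: top-k = high group
    xs = x[order]
    ts = time[order]
    es = event[order]

    # distinct event times and per-time death counts
    ev_times = np.unique(time[event == 1])
    if ev_times.size == 0:
        raise ValueError("maxstat requires at least one observed event")
    # at-risk indicator matrix: R[t_idx, i] = sample i at risk at ev_times[t_idx]
    R = ts[None, :] >= ev_times[:, None]
    D = (ts[None, :] == ev_times[:, None]) & (es[None, :] == 1)
    n_at_risk = R.sum(axis=1).astype(float)
    d = D.sum(axis=1).astype(float)

    # cumulative over the x-descending order: column k-1 -> high group = top-k
    n1 = np.cumsum(R, axis=1).astype(float)  # at risk in high group, per split
    o1 = np.cumsum(D, axis=1).astype(float)  # events in high group, per split

    with np.errstate(divide="ignore", invalid="ignore"):
        frac = n1 / n_at_risk[:, None]
        E = d[:, None] * frac
        corr = np.where(n_at_risk > 1, (n_at_risk - d) / (n_at_risk - 1), 0.0)
        V = d[:, None] * frac * (1.0 - frac) * corr[:, None]
    O = o1.sum(axis=0)
    Es = E.sum(axis=0)
    Vs = V.sum(axis=0)

    # admissible splits fall at boundaries between distinct x values
    k = np.arange(1, n + 1)
    distinct_boundary = np.empty(n, dtype=bool)
    distinct_boundary[:-1] = xs[:-1] > xs[1:]
    distinct_boundary[-1] = False  # splitting off nobody is not a split
    lo = int(np.ceil(min_prop * n))
    admissible = distinct_boundary & (k >= lo) & (n - k >= lo)
    idx = np.where(admissible)[0]
    if idx.size == 0:
        raise ValueError("no admissible cutpoint under the min_prop restriction")

    cutpoints = (xs[idx] + xs[idx + 1]) / 2.0
    with np.errstate(divide="ignore", invalid="ignore"):
        z = (O[idx] - Es[idx]) / np.sqrt(Vs[idx])
    z = np.where(np.isfinite(z), z, 0.0)
    return cutpoints[::-1], z[::-1], (idx + 1)[::-1]  # ascending cutpoint order


def _miller_siegmund_p(b: float, eps_lo: float, eps_hi: float) -> float:
    """Improved-Bonferroni tail bound for the maximally selected statistic.

    Approximates P(max |Z(eps)| >= b) for a standardized Brownian-bridge
    process restricted to quantiles [eps_lo, eps_hi].
    """
    if b <= 0:
        return 1.0
    phi = stats.norm.pdf(b)
    log_term = np.log((eps_hi * (1.0 - eps_lo)) / (eps_lo * (1.0 - eps_hi)))
    p = 4.0 * phi / b + phi * (b - 1.0 / b) * log_term
    return float(min(1.0, max(p, 2.0 * stats.norm.sf(b))))


def maxstat_cutpoint(
    x,
    surv: SurvivalData,
    min_prop: float = 0.10,
    p_method: str = "approx",
    n_perm: int = 10_000,
    seed: int | None = None,
) -> MaxstatResult:
    """Maximally selected rank statistics for a survival cutpoint.

    Evaluates the standardized log-rank statistic at every admissible
    split ``x > c`` (both groups at least ``min_prop`` of the samples)
    and returns the cutpoint with the maximal absolute statistic.

    Parameters
    ----------
    p_method : "approx" (improved Bonferroni, default) or "permutation"
        (label-shuffle estimate of P(max statistic >= observed), needs
        ``seed`` for reproducibility).
    """
    x = np.asarray(x, dtype=float)
    if not 0 < min_prop < 0.5:
        raise ValueError("min_prop must be in (0, 0.5)")
    if x.shape != surv.time.shape:
        raise ValueError("covariate length must match survival data")
    cutpoints, z, n_high = _logrank_all_splits(x, surv.time, surv.event, min_prop)
    best = int(np.argmax(np.abs(z)))
    b = float(np.abs(z[best]))
    n = len(surv)
    nh = int(n_high[best])

    if p_method == "approx":
        p = _miller_siegmund_p(b, min_prop, 1.0 - min_prop)
    elif p_method == "permutation":
        rng = np.random.default_rng(seed)
        exceed = 0
        for _ in range(n_perm):
            xp = rng.permutation(x)
            _, zp, _ = _logrank_all_splits(xp, surv.time, surv.event, min_prop)
            if np.max(np.abs(zp)) >= b:
                exceed += 1
        p = (exceed + 1) / (n_perm + 1)
    else:
        raise ValueError(f"unknown p_method: {p_method!r}")

    return MaxstatResult(
        cutpoint=float(cutpoints[best]),
        max_statistic=b,
        p_value=float(p),
        n_low=n - nh,
        n_high=nh,
        cutpoints=cutpoints,
        statistics=z,
    )
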