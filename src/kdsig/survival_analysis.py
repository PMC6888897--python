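"""Kaplan–Meier estimation, two-group log-rank testing and cutoff scanning.

The product-limit estimator, the log-rank test with hypergeometric variance,
and an O/E-ratio hazard-ratio approximation are implemented natively on
numpy arrays. Ties between events and censorings at the same time follow the
standard convention: events precede censorings, so a sample censored at an
event time is still in the risk set for that event.

``best_cutoff`` emulates the "auto select best cutoff" style of KM-plotting
tools: it scans candidate score thresholds between two quantiles, picks the
one minimizing the nominal log-rank p, and reports a permutation-adjusted p
that accounts for the minimum-p selection (nominal minimum p-values are
anti-conservative).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .exceptions import DegenerateTestError, ParameterError, ValidationError


@dataclass
class KMCurve:
    """Product-limit survival estimate evaluated at distinct event times."""

    event_times: np.ndarray  # increasing distinct times with >=1 event
    survival: np.ndarray  # S(t) just after each event time
    at_risk: np.ndarray  # risk-set size just before each event time
    n_events: np.ndarray  # events at each event time
    n_total: int  # samples entering the curve
    max_time: float = np.inf  # last observed time (event or censoring)

    def survival_at(self, times: float | np.ndarray) -> np.ndarray | float:
        """Step-function evaluation: S(t) = 1 before the first event."""
        times = np.asarray(times, dtype=float)
        if self.event_times.size == 0:
            out = np.ones_like(times)
        else:
            idx = np.searchsorted(self.event_times, times, side="right") - 1
            out = np.where(idx >= 0, self.survival[np.clip(idx, 0, None)], 1.0)
        return float(out) if out.ndim == 0 else out


@dataclass
class LogRankResult:
    chi_square: float
    df: int
    p_value: float
    observed: dict[str, float]
    expected: dict[str, float]
    hr_estimate: float | None  # (O1/E1)/(O2/E2); None when undefined
    groups: tuple[str, str]


@dataclass
class BestCutoffResult:
    cutoff: float
    p_nominal: float
    p_adjusted: float
    n_candidates: int
    group_sizes: tuple[int, int]


def km_estimate(time, event) -> KMCurve:
    """Kaplan–Meier product-limit estimator.

    S(t) = prod over event times t_i <= t of (1 - d_i / n_i); censored
    observations leave the risk set without contributing events.
    """
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    if time.size == 0:
        raise ValidationError("empty group: Kaplan-Meier estimate undefined")
    if not np.isfinite(time).all():
        raise ValidationError("non-finite follow-up times")
    order = np.argsort(time, kind="mergesort")
    t, e = time[order], event[order]
    n = t.size

    first = np.flatnonzero(np.r_[True, t[1:] > t[:-1]])
    d = np.add.reduceat(e, first)
    at_risk = n - first
    has_event = d > 0
    times_ev = t[first][has_event]
    d_ev = d[has_event]
    n_ev = at_risk[has_event]
    surv = np.cumprod(1.0 - d_ev / n_ev)
    return KMCurve(
        event_times=times_ev,
        survival=surv,
        at_risk=n_ev,
        n_events=d_ev,
        n_total=n,
        max_time=float(t[-1]),
    )


def _logrank_terms(t_sorted, e_sorted, first, at_risk, mask_sorted):
    """O1, E1, V, total events for group-1 membership mask (time-sorted)."""
    # group-1 members still at risk just before each distinct time
    sfx = np.cumsum(mask_sorted[::-1])[::-1]
    n1 = sfx[first]
    d = np.add.reduceat(e_sorted, first)
    d1 = np.add.reduceat(e_sorted & mask_sorted, first)
    ev = d > 0
    n_t, n1_t, d_t, d1_t = at_risk[ev], n1[ev], d[ev], d1[ev]
    o1 = float(d1_t.sum())
    e1 = float((d_t * n1_t / n_t).sum())
    with np.errstate(invalid="ignore", divide="ignore"):
        v_terms = d_t * (n1_t / n_t) * (1.0 - n1_t / n_t) * (n_t - d_t) / (n_t - 1.0)
    v = float(np.where(n_t > 1, v_terms, 0.0).sum())
    return o1, e1, v, float(d_t.sum())


def _presort(time, event):
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=bool)
    order = np.argsort(time, kind="mergesort")
    t, e = time[order], event[order]
    first = np.flatnonzero(np.r_[True, t[1:] > t[:-1]])
    at_risk = t.size - first
    return order, t, e, first, at_risk


def logrank_test(time, event, group) -> LogRankResult:
    """Two-group log-rank test with chi-square (df=1) reference distribution.

    Group 1 is the lexicographically first of the two labels. The hazard
    ratio is approximated by (O1/E1)/(O2/E2) and reported only when all four
    terms are positive. Raises :class:`DegenerateTestError` when the
    log-rank variance is zero (no information to compare groups).
    """
    group = np.asarray(group)
    labels = sorted(map(str, np.unique(group.astype(str))))
    if len(labels) != 2:
        raise ParameterError(f"log-rank test needs exactly 2 groups, got {labels}")
    g1 = labels[0]
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    if event.sum() < 1:
        raise DegenerateTestError("no events observed; log-rank test undefined")

    order, t, e, first, at_risk = _presort(time, event)
    mask = (group.astype(str) == g1)[order]
    o1, e1, v, d_tot = _logrank_terms(t, e, first, at_risk, mask)
    if v <= 0:
        raise DegenerateTestError("log-rank variance is zero; test undefined")
    chi2 = (o1 - e1) ** 2 / v
    p = float(stats.chi2.sf(chi2, df=1))
    o2, e2 = d_tot - o1, d_tot - e1
    hr = (o1 / e1) / (o2 / e2) if min(o1, e1, o2, e2) > 0 else None
    return LogRankResult(
        chi_square=float(chi2),
        df=1,
        p_value=p,
        observed={labels[0]: o1, labels[1]: o2},
        expected={labels[0]: e1, labels[1]: e2},
        hr_estimate=hr,
        groups=(labels[0], labels[1]),
    )


def _scan_min_p(scores_sorted, t, e, first, at_risk, candidates):
    """Minimum nominal log-rank p over threshold candidates (low = score <= c)."""
    best_p, best_c = np.inf, None
    for c in candidates:
        mask = scores_sorted <= c
        if not mask.any() or mask.all():
            continue
        o1, e1, v, _ = _logrank_terms(t, e, first, at_risk, mask)
        if v <= 0:
            continue
        p = stats.chi2.sf((o1 - e1) ** 2 / v, df=1)
        if p < best_p:
            best_p, best_c = p, c
    return best_p, best_c


def best_cutoff(
    scores,
    time,
    event,
    q_lo: float = 0.1,
    q_hi: float = 0.9,
    n_perm: int = 1000,
    seed: int = 0,
) -> BestCutoffResult:
    """Best score threshold by minimum log-rank p, with permutation correction.

    All distinct score values between the ``q_lo`` and ``q_hi`` quantiles
    are tried as thresholds (low group = score <= threshold). The adjusted p
    is the fraction of score-permuted datasets whose *minimum* nominal p is
    at least as small as the observed one (with add-one correction), i.e. a
    Westfall–Young-style correction for the threshold scan.
    """
    scores = np.asarray(scores, dtype=float)
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    if scores.size < 10:
        raise ParameterError("best_cutoff needs at least 10 samples")
    if scores.size != time.size or time.size != event.size:
        raise ParameterError("scores, time and event must be aligned")
    lo, hi = np.quantile(scores, [q_lo, q_hi])
    candidates = np.unique(scores[(scores >= lo) & (scores <= hi)])
    # a threshold at the maximum would leave the high group empty
    candidates = candidates[candidates < scores.max()]
    if candidates.size < 2:
        raise ParameterError("fewer than 2 candidate cutoffs in the quantile window")

    order, t, e, first, at_risk = _presort(time, event)
    s_sorted = scores[order]
    p_obs, c_obs = _scan_min_p(s_sorted, t, e, first, at_risk, candidates)
    if c_obs is None:
        raise DegenerateTestError("no candidate cutoff yields a defined log-rank test")

    rng = np.random.default_rng([404, int(seed)])
    hits = 0
    for _ in range(n_perm):
        sp = rng.permutation(s_sorted)
        p_min, _ = _scan_min_p(sp, t, e, first, at_risk, candidates)
        if p_min <= p_obs:
            hits += 1
    p_adj = (1 + hits) / (1 + n_perm)
    n_low = int((scores <= c_obs).sum())
    return BestCutoffResult(
        cutoff=float(c_obs),
        p_nominal=float(p_obs),
        p_adjusted=float(p_adj),
        n_candidates=int(candidates.size),
        group_sizes=(n_low, scores.size - n_low),
    )


def km_dominates(better: KMCurve, worse: KMCurve, tol: float = 1e-12) -> bool:
    """True if ``better`` lies on or above ``worse`` wherever both are informative.

    Curves are compared at every distinct event time inside the window where
    both estimates carry information: from the first time at which *both*
    groups have entered the event process (before a group's first event its
    estimate is the uninformative constant 1) up to the earlier of the two
    groups' last observed follow-up times (a KM curve is not extrapolated
    beyond its group's last observation).
    """
    times = np.union1d(better.event_times, worse.event_times)
    if better.event_times.size == 0 or worse.event_times.size == 0:
        return True
    start = max(better.event_times[0], worse.event_times[0])
    end = min(better.max_time, worse.max_time)
    times = times[(times >= start) & (times <= end)]
    return bool(np.all(better.survival_at(times) >= worse.survival_at(times) - tol))
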