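"""Call rates, silence, bout structure and inter-individual exchange timing.

Bout analysis follows the classic two-process view of behavioural timing:
inter-call intervals (ICIs, start-to-start within one individual) mix a
fast Poisson process (calls inside a bout, rate ``lambda_fast``) with a
slow one (gaps between bouts, rate ``lambda_slow``).  The mixture

    f(t) = p * lf * exp(-lf t) + (1 - p) * ls * exp(-ls t)

is fitted by maximum likelihood (EM on the raw intervals, initialized from
a broken-stick fit to the log-frequency histogram of log-transformed
intervals).  The bout-end criterion (BEC) is the interval at which the two
weighted component densities cross,

    bec = ln(p lf / ((1 - p) ls)) / (lf - ls),

and runs of >=2 calls whose successive ICIs all fall below the BEC are
bouts.  Exchange timing between individuals is summarized by the density
of cross-individual ICIs integrated over [0, horizon] seconds.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.stats import gaussian_kde

__all__ = [
    "AnalysisPeriod",
    "BoutModel",
    "Bout",
    "call_rate",
    "silence_stats",
    "ici_series",
    "fit_bout_model",
    "bout_end_criterion",
    "segment_bouts",
    "inter_individual_icis",
    "exchange_auc",
    "InsufficientDataError",
    "DegenerateMixtureError",
    "InvalidPeriodError",
]


class InvalidPeriodError(ValueError):
    """Analysis period has non-positive duration."""


class InsufficientDataError(ValueError):
    """Too few intervals / vocal individuals for the statistic."""


class DegenerateMixtureError(RuntimeError):
    """The two exponential processes are not separable."""


@dataclass(frozen=True)
class AnalysisPeriod:
    """The shared window over which a group's tags are analysed."""

    group_id: str
    t_start: float
    t_end: float
    whales: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if not self.t_end > self.t_start:
            raise InvalidPeriodError(
                f"period [{self.t_start}, {self.t_end}] has non-positive duration"
            )

    @property
    def duration_s(self) -> float:
        return self.t_end - self.t_start

    @property
    def duration_h(self) -> float:
        return self.duration_s / 3600.0


def call_rate(n_focal: int, period: AnalysisPeriod) -> float:
    """Raw call rate in calls per hour, rounded to 1 decimal for reporting."""
    if n_focal < 0:
        raise ValueError("n_focal must be non-negative")
    return round(n_focal / period.duration_h, 1)


def silence_stats(
    spans: Sequence[tuple[float, float]], period: AnalysisPeriod
) -> tuple[float, float]:
    """Proportion of the period with no detection on any tag, and longest gap.

    ``spans`` are (t_start, t_end) detection spans pooled over all tags;
    silence is the complement within the period of their union (touching
    spans merge).
    """
    t0, t1 = period.t_start, period.t_end
    clipped = sorted(
        (max(s, t0), min(e, t1)) for s, e in spans if min(e, t1) > max(s, t0)
    )
    gaps: list[float] = []
    occupied = 0.0
    cursor = t0
    for s, e in clipped:
        if s > cursor:
            gaps.append(s - cursor)
        occupied += max(0.0, e - max(s, cursor))
        cursor = max(cursor, e)
    if cursor < t1:
        gaps.append(t1 - cursor)
    silence = period.duration_s - occupied
    longest = max(gaps) if gaps else 0.0
    return silence / period.duration_s, longest


def ici_series(times: Sequence[float]) -> np.ndarray:
    """Start-to-start inter-call intervals for one individual.

    ``times`` must be sorted; n calls yield n-1 intervals (none for n <= 1).
    Zero intervals (duplicate start times) are dropped.
    """
    t = np.asarray(times, dtype=float)
    if t.size <= 1:
        return np.empty(0)
    if np.any(np.diff(t) < 0):
        raise ValueError("call start times must be sorted")
    icis = np.diff(t)
    return icis[icis > 0]


def bout_end_criterion(p: float, lambda_fast: float, lambda_slow: float) -> float:
    """Crossing point of the two weighted exponential densities."""
    return float(
        np.log(p * lambda_fast / ((1.0 - p) * lambda_slow)) / (lambda_fast - lambda_slow)
    )


@dataclass
class BoutModel:
    """Fitted two-process exponential mixture and its derived BEC."""

    p: float
    lambda_fast: float
    lambda_slow: float
    bec: float
    loglik: float
    n: int
    converged: bool = True
    n_iter: int = 0

    def density(self, t: np.ndarray) -> np.ndarray:
        t = np.asarray(t, dtype=float)
        return self.p * self.lambda_fast * np.exp(-self.lambda_fast * t) + (
            1.0 - self.p
        ) * self.lambda_slow * np.exp(-self.lambda_slow * t)


def _broken_stick_threshold(t: np.ndarray) -> float:
    """Breakpoint of a two-segment linear fit to the log-frequency histogram
    of log intervals; used only to initialize the MLE."""
    x = np.log(t)
    nbins = int(np.clip(np.sqrt(t.size), 8, 40))
    counts, edges = np.histogram(x, bins=nbins)
    centers = 0.5 * (edges[:-1] + edges[1:])
    mask = counts > 0
    c, y = centers[mask], np.log(counts[mask].astype(float))
    if c.size < 4:
        return float(np.median(t))
    best_sse, best_k = np.inf, None
    for k in range(1, c.size - 1):
        sse = 0.0
        for cs, ys in ((c[: k + 1], y[: k + 1]), (c[k:], y[k:])):
            coef = np.polyfit(cs, ys, 1)
            resid = ys - np.polyval(coef, cs)
            sse += float(resid @ resid)
        if sse < best_sse:
            best_sse, best_k = sse, k
    return float(np.exp(c[best_k]))


def fit_bout_model(
    icis: Sequence[float],
    min_n: int = 30,
    max_iter: int = 10_000,
    tol: float = 1e-8,
) -> BoutModel:
    """Maximum-likelihood fit of the two-process exponential mixture.

    EM on the raw intervals; the log transform enters only through the
    broken-stick histogram initialization.  Raises
    :class:`InsufficientDataError` below ``min_n`` intervals and
    :class:`DegenerateMixtureError` when the fitted rates are not separable
    (ratio < 1.5, an extreme mixture weight, or a non-positive BEC).
    """
    t = np.asarray(icis, dtype=float)
    t = t[np.isfinite(t) & (t > 0)]
    if t.size < min_n:
        raise InsufficientDataError(f"need >= {min_n} positive intervals, got {t.size}")

    thr = _broken_stick_threshold(t)
    fast, slow = t[t < thr], t[t >= thr]
    if fast.size < 2 or slow.size < 2:
        thr = float(np.median(t))
        fast, slow = t[t < thr], t[t >= thr]
    if fast.size < 2 or slow.size < 2:
        raise DegenerateMixtureError("cannot split intervals into two regimes")
    p = fast.size / t.size
    lf = 1.0 / float(fast.mean())
    ls = 1.0 / float(slow.mean())
    if lf < ls:
        lf, ls, p = ls, lf, 1.0 - p

    prev_ll = -np.inf
    ll = -np.inf
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        f1 = p * lf * np.exp(-lf * t)
        f2 = (1.0 - p) * ls * np.exp(-ls * t)
        tot = f1 + f2
        tot = np.where(tot > 0, tot, np.finfo(float).tiny)
        ll = float(np.sum(np.log(tot)))
        r = f1 / tot
        p = float(np.clip(r.mean(), 1e-9, 1 - 1e-9))
        lf = float(r.sum() / max(r @ t, np.finfo(float).tiny))
        ls = float((1.0 - r).sum() / max((1.0 - r) @ t, np.finfo(float).tiny))
        if lf < ls:
            lf, ls, p = ls, lf, 1.0 - p
        if np.isfinite(prev_ll) and abs(ll - prev_ll) <= tol * abs(prev_ll):
            converged = True
            break
        prev_ll = ll

    if lf / ls < 1.5 or p < 1e-4 or p > 1 - 1e-4:
        raise DegenerateMixtureError(
            f"fast/slow rates not separable (lf={lf:.4g}, ls={ls:.4g}, p={p:.4g})"
        )
    bec = bout_end_criterion(p, lf, ls)
    if not np.isfinite(bec) or bec <= 0:
        raise DegenerateMixtureError(f"non-positive BEC ({bec})")
    return BoutModel(
        p=p, lambda_fast=lf, lambda_slow=ls, bec=bec, loglik=ll, n=int(t.size),
        converged=converged, n_iter=it,
    )


@dataclass
class Bout:
    """A maximal run of >=2 calls with successive ICIs below the BEC."""

    whale_id: str
    call_indices: tuple[int, ...]
    t_start: float
    t_end: float

    @property
    def n_calls(self) -> int:
        return len(self.call_indices)


def segment_bouts(
    times_by_whale: Mapping[str, Sequence[float]],
    bec: float,
    period: Optional[AnalysisPeriod] = None,
) -> tuple[list[Bout], pd.DataFrame]:
    """Classify calls into bouts and summarize per whale.

    A bout is a maximal run of >=2 consecutive calls, each separated from
    the previous by a start-to-start ICI strictly below ``bec``.  The
    summary gives, per whale: call and bout counts, bout rate (bouts/hour,
    1 decimal, when a period is supplied), mean calls per bout (over bouts
    only) and the fraction of calls produced inside bouts.
    """
    if bec <= 0:
        raise ValueError("bec must be positive")
    bouts: list[Bout] = []
    rows = []
    for whale_id in sorted(times_by_whale):
        times = np.asarray(sorted(times_by_whale[whale_id]), dtype=float)
        n = times.size
        whale_bouts: list[Bout] = []
        run = [0]
        for i in range(1, n):
            if times[i] - times[i - 1] < bec:
                run.append(i)
            else:
                if len(run) >= 2:
                    whale_bouts.append(
                        Bout(whale_id, tuple(run), float(times[run[0]]), float(times[run[-1]]))
                    )
                run = [i]
        if len(run) >= 2:
            whale_bouts.append(
                Bout(whale_id, tuple(run), float(times[run[0]]), float(times[run[-1]]))
            )
        bouts.extend(whale_bouts)
        n_in_bouts = sum(b.n_calls for b in whale_bouts)
        n_bouts = len(whale_bouts)
        rows.append(
            {
                "whale_id": whale_id,
                "n_calls": n,
                "n_bouts": n_bouts,
                "bout_rate": round(n_bouts / period.duration_h, 1) if period else float("nan"),
                "mean_calls_per_bout": n_in_bouts / n_bouts if n_bouts else 0.0,
                "frac_in_bouts": n_in_bouts / n if n else 0.0,
            }
        )
    return bouts, pd.DataFrame(rows)


def inter_individual_icis(times_by_whale: Mapping[str, Sequence[float]]) -> np.ndarray:
    """Interval from each call to the next-later call by a *different* whale.

    One interval per call when such a successor exists.  Requires at least
    two individuals with calls.
    """
    events: list[tuple[float, str]] = []
    vocal = 0
    for whale_id, times in times_by_whale.items():
        ts = list(times)
        if ts:
            vocal += 1
        events.extend((float(t), whale_id) for t in ts)
    if vocal < 2:
        raise InsufficientDataError("need >= 2 individuals with calls")
    events.sort()
    out: list[float] = []
    n = len(events)
    for i, (t, w) in enumerate(events):
        for j in range(i + 1, n):
            if events[j][1] != w:
                out.append(events[j][0] - t)
                break
    return np.asarray(out, dtype=float)


def exchange_auc(
    cross_icis: Sequence[float], horizon: float = 100.0, min_n: int = 10
) -> tuple[float, float]:
    """Probability a conspecific answers within ``horizon`` seconds.

    Returns ``(auc_kde, proportion_empirical)``: the integral over
    [0, horizon] of a Gaussian KDE (Silverman bandwidth, reflected at zero
    to correct the boundary bias of non-negative intervals) and the plain
    fraction of intervals <= horizon.
    """
    x = np.asarray(cross_icis, dtype=float)
    x = x[np.isfinite(x)]
    if x.size < min_n:
        raise InsufficientDataError(f"need >= {min_n} intervals, got {x.size}")
    prop = float(np.mean(x <= horizon))
    if np.ptp(x) == 0:
        # degenerate sample: the density is a point mass
        return (1.0 if x[0] <= horizon else 0.0), prop
    kde = gaussian_kde(x, bw_method="silverman")
    grid = np.linspace(0.0, horizon, 2049)
    dens = kde(grid) + kde(-grid)  # reflection at zero
    auc = float(np.trapezoid(dens, grid))
    return auc, prop
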