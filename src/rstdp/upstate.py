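"""Light-evoked up-state latency analysis.

Under anesthesia, SPN membrane potential alternates between a hyperpolarized
down state and a depolarized up state.  A reward-conditioned light flash
delivered during a down state can advance the next up-state transition.  The
analysis quantifies that effect:

1. per light event, state thresholds are set from the distribution of
   membrane potentials in a 2 s window around the event — down level at the
   20th percentile, up level at the 80th, transition level at the mean of
   the two;
2. for every light event that lands in the down state, the latency to the
   first upward crossing of the transition level is measured, together with
   a control latency from a random point drawn in the same down state;
3. latency samples are fitted by maximum likelihood in a set of
   positive-support families ranked by BIC (log-logistic for light-evoked,
   Weibull for random latencies, in practice);
4. the fitted CDFs give the excess probability of an up state in the 60 to
   140 ms post-light window, and Kuiper's test compares the empirical
   light-evoked latencies with the fitted random-latency CDF.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence, Tuple

import numpy as np
from scipy import stats

from .distributions import FAMILIES, FIT_FAMILIES, N_FREE_PARAMS, frozen

__all__ = [
    "StateThresholds",
    "LatencyDataset",
    "DistributionFit",
    "estimate_thresholds",
    "extract_latencies",
    "fit_distribution",
    "select_distribution",
    "excess_probability",
]


@dataclass
class StateThresholds:
    """Percentile-based membrane-state levels for one light event."""

    down_level_mv: float
    up_level_mv: float
    transition_level_mv: float
    window_s: float = 2.0

    def __post_init__(self):
        if not (self.down_level_mv < self.transition_level_mv < self.up_level_mv):
            raise ValueError("thresholds must satisfy down < transition < up")


@dataclass
class LatencyDataset:
    """Paired light-evoked and random-control latencies (seconds)."""

    light_latencies_s: np.ndarray
    random_latencies_s: np.ndarray
    paired: bool = True
    n_light_events_seen: Optional[int] = None

    def __post_init__(self):
        self.light_latencies_s = np.asarray(self.light_latencies_s, dtype=float)
        self.random_latencies_s = np.asarray(self.random_latencies_s, dtype=float)
        if np.any(self.light_latencies_s <= 0) or np.any(self.random_latencies_s <= 0):
            raise ValueError("latencies must be positive")
        if self.paired and len(self.light_latencies_s) != len(self.random_latencies_s):
            raise ValueError("paired dataset requires equal light/random counts")

    @property
    def n_light(self) -> int:
        return len(self.light_latencies_s)

    @property
    def n_random(self) -> int:
        return len(self.random_latencies_s)

    @property
    def empty(self) -> bool:
        return self.n_light == 0


def estimate_thresholds(segment_vm, window_s: float = 2.0) -> StateThresholds:
    """Thresholds from the membrane-potential histogram of one 2 s window.

    Down level is the 20th percentile of the segment, up level the 80th, and
    the transition level the arithmetic mean of the two.  A degenerate
    (effectively constant) segment raises, since no state structure exists.
    """
    vm = np.asarray(segment_vm, dtype=float)
    if not np.all(np.isfinite(vm)):
        raise ValueError("segment contains non-finite values")
    down = float(np.percentile(vm, 20))
    up = float(np.percentile(vm, 80))
    if up - down < 1e-9:
        raise ValueError("degenerate segment: no up/down structure in window")
    return StateThresholds(down_level_mv=down, up_level_mv=up,
                           transition_level_mv=0.5 * (down + up), window_s=window_s)


def _smooth(vm: np.ndarray, fs: float, smooth_ms: float) -> np.ndarray:
    w = max(1, int(round(smooth_ms / 1000.0 * fs)))
    if w <= 1:
        return vm
    kernel = np.ones(w) / w
    return np.convolve(vm, kernel, mode="same")


def extract_latencies(recording, window_s: float = 2.0, max_latency_s: float = 1.0,
                      seed: int = 0, smooth_ms: float = 5.0) -> LatencyDataset:
    """Measure light-evoked and random-control latencies to the up state.

    Per light event: thresholds come from that event's ``window_s`` window;
    the event qualifies only if the (lightly smoothed) membrane potential at
    event time is on the down side of the transition level.  (The 20th
    percentile itself sits below the down-state mean whenever down-state
    occupancy exceeds 20%, so it cannot serve as a membership test; the
    transition level is the boundary that separates the states.)  The
    event's latency is the time to the
    first upward crossing of the transition level.  A random control point
    is drawn uniformly (seeded) in the portion of the same down state that
    precedes the light, and its latency to the next crossing is recorded.
    Events without a crossing within ``max_latency_s``, for either member of
    the pair, are dropped from both lists.

    Returns an empty (flagged) dataset if no light event qualifies.
    """
    fs = recording.sampling_rate_hz
    vm = recording.vm_mv
    n = len(vm)
    sm = _smooth(vm, fs, smooth_ms)
    rng = np.random.default_rng(seed)
    half = int(round(window_s / 2 * fs))

    light, rand = [], []
    light_times = recording.event_times("light")
    for t_ev in light_times:
        i_ev = int(round(t_ev * fs))
        if i_ev <= 0 or i_ev >= n - 1:
            continue
        lo, hi = max(0, i_ev - half), min(n, i_ev + half)
        try:
            thr = estimate_thresholds(vm[lo:hi], window_s=window_s)
        except ValueError:
            continue
        if sm[i_ev] >= thr.transition_level_mv:
            continue  # light fell outside the down state

        below = sm < thr.transition_level_mv
        i_max = min(n, i_ev + int(round(max_latency_s * fs)) + 1)
        cross = np.nonzero(~below[i_ev:i_max])[0]
        if cross.size == 0:
            continue  # no up transition within the cap
        lat_light = cross[0] / fs
        if lat_light <= 0:
            continue

        # preceding down state: contiguous sub-transition-level run ending at the light
        j = i_ev
        while j > 0 and below[j - 1]:
            j -= 1
        i_rand = int(rng.integers(j, i_ev + 1))
        cross_r = np.nonzero(~below[i_rand:i_rand + int(round(max_latency_s * fs)) + 1])[0]
        if cross_r.size == 0 or cross_r[0] == 0:
            continue
        lat_rand = cross_r[0] / fs

        light.append(lat_light)
        rand.append(lat_rand)

    return LatencyDataset(light_latencies_s=np.array(light),
                          random_latencies_s=np.array(rand),
                          paired=True, n_light_events_seen=len(light_times))


@dataclass
class DistributionFit:
    """Maximum-likelihood fit of one positive-support family."""

    family: str
    params: dict
    loglik: float
    bic: float
    n: int
    converged: bool = True
    message: str = ""

    def __post_init__(self):
        if self.converged:
            k = N_FREE_PARAMS[self.family]
            expected = k * np.log(self.n) - 2.0 * self.loglik
            if not np.isclose(self.bic, expected, rtol=1e-9, atol=1e-6):
                raise ValueError("bic inconsistent with k*ln(n) - 2*loglik")

    def frozen(self):
        return frozen(self.family, self.params)

    def cdf(self, x):
        return self.frozen().cdf(x)


def fit_distribution(latencies, family: str) -> DistributionFit:
    """ML fit of one family to positive latencies, with BIC.

    The location parameter is pinned at zero (latencies are measured from
    the event, so the support starts at 0).  Non-convergence returns a
    flagged fit rather than raising, so ranking can skip it.
    """
    x = np.asarray(latencies, dtype=float)
    if x.size < 5:
        raise ValueError("need at least 5 latencies to fit")
    if np.any(x <= 0):
        raise ValueError("latencies must be positive")
    dist, pnames = FAMILIES[family]
    try:
        fitted = dist.fit(x, floc=0)
        fr = dist(*fitted[:-2], loc=0.0, scale=fitted[-1])
        loglik = float(np.sum(fr.logpdf(x)))
        if not np.isfinite(loglik):
            raise RuntimeError("non-finite log-likelihood")
    except Exception as exc:  # flagged, excluded from ranking
        return DistributionFit(family=family, params={}, loglik=np.nan, bic=np.inf,
                               n=x.size, converged=False, message=str(exc))
    params = {}
    if "shape" in pnames:
        params["shape"] = float(fitted[0])
    params["scale"] = float(fitted[-1])
    k = N_FREE_PARAMS[family]
    bic = k * np.log(x.size) - 2.0 * loglik
    return DistributionFit(family=family, params=params, loglik=loglik,
                           bic=float(bic), n=x.size)


def select_distribution(latencies, families: Sequence[str] = FIT_FAMILIES):
    """Fit candidate families and rank them by ascending BIC.

    Ties break toward fewer free parameters, then the fixed candidate
    order.  Non-converged fits are excluded from the ranking but returned
    (flagged) at the end of the list.
    """
    fits = [fit_distribution(latencies, f) for f in families]
    order = {f: i for i, f in enumerate(families)}
    good = [f for f in fits if f.converged]
    bad = [f for f in fits if not f.converged]
    good.sort(key=lambda f: (f.bic, N_FREE_PARAMS[f.family], order[f.family]))
    return good + bad


def excess_probability(light_fit, random_fit,
                       window: Tuple[float, float] = (0.060, 0.140)) -> float:
    """Excess probability of an up state in the post-light window.

    [F_light(w1) - F_light(w0)] - [F_random(w1) - F_random(w0)] from the two
    fitted CDFs; +0.13-magnitude values indicate light events substantially
    above chance at initiating an up state in the expected 60-140 ms
    interval.
    """
    w0, w1 = window
    if not (0 <= w0 < w1):
        raise ValueError("window must satisfy 0 <= w0 < w1 (positive support)")
    fl = light_fit.frozen() if hasattr(light_fit, "frozen") else light_fit
    fr = random_fit.frozen() if hasattr(random_fit, "frozen") else random_fit
    p_light = float(fl.cdf(w1) - fl.cdf(w0))
    p_rand = float(fr.cdf(w1) - fr.cdf(w0))
    return p_light - p_rand
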