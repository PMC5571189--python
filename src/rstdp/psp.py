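"""PSP slope plasticity quantification.

Corticostriatal efficacy is indexed by the maximal initial slope of the
cortically evoked postsynaptic potential (PSP).  The pipeline mirrors the
standard in vivo workflow:

* **trace exclusion** — sweeps whose membrane potential deviates from the
  group mean by more than 1.5 SD at either of two standardized checkpoints
  (one pre-stimulus, one late post-stimulus when the potential should have
  returned to baseline) are discarded as contaminated by spontaneous
  fluctuations;
* **slope measurement** — a least-squares line is fitted in a 1 ms window
  slid over the initial depolarizing phase (restricted to the first,
  putatively monosynaptic, component) and the maximal slope is recorded;
* **normalization and binning** — slopes are expressed as percent change
  from the baseline-phase mean and averaged in 5 min bins of the test
  period;
* **cell-health QC** — down-state potential below -75 mV, spike amplitude
  above 50 mV, input resistance stable within 10%, baseline PSP of at
  least 5 mV.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy.signal import find_peaks

__all__ = [
    "QcCriteria",
    "PspSlopeResult",
    "checkpoint_stats",
    "exclude_outlier_traces",
    "psp_slope",
    "measure_trial_slopes",
    "normalize_and_bin",
    "qc_cell_health",
]


@dataclass
class QcCriteria:
    """Cell-health inclusion thresholds."""

    down_state_max_mv: float = -75.0
    ap_min_amp_mv: float = 50.0
    input_resistance_tolerance: float = 0.10
    psp_min_amp_mv: float = 5.0

    def __post_init__(self):
        for name in ("down_state_max_mv", "ap_min_amp_mv",
                     "input_resistance_tolerance", "psp_min_amp_mv"):
            if not np.isfinite(getattr(self, name)):
                raise ValueError(f"{name} must be finite")


def checkpoint_stats(traces, time_s, checkpoints) -> list:
    """Single-pass group mean/SD of the sweeps at each checkpoint time."""
    traces = np.asarray(traces, dtype=float)
    time_s = np.asarray(time_s, dtype=float)
    out = []
    for cp in checkpoints:
        if not (time_s[0] <= cp <= time_s[-1]):
            raise ValueError(f"checkpoint {cp} s outside trace extent")
        col = traces[:, int(np.argmin(np.abs(time_s - cp)))]
        out.append((float(col.mean()), float(col.std(ddof=0))))
    return out


def exclude_outlier_traces(traces, time_s, checkpoint_pre_s: float,
                           checkpoint_post_s: float, k_sd: float = 1.5,
                           stats=None) -> Tuple[np.ndarray, float]:
    """Flag sweeps deviating > ``k_sd`` group SDs at either checkpoint.

    The group mean and SD at each checkpoint are computed once over *all*
    trials (single pass, order-independent); a trial is excluded iff its
    potential deviates by more than ``k_sd`` standard deviations at either
    the pre-stimulus or the late post-stimulus checkpoint.  A zero group SD
    with any deviation retains the trial (degenerate case: identical sweeps
    cannot be outliers of themselves).  Pass frozen ``stats`` (the output of
    :func:`checkpoint_stats` from a previous run) to re-apply the rule with
    unchanged statistics, under which exclusion is idempotent.

    Returns ``(included, fraction_excluded)`` where ``included`` is a boolean
    mask over trials.
    """
    traces = np.asarray(traces, dtype=float)
    time_s = np.asarray(time_s, dtype=float)
    if traces.ndim != 2 or traces.shape[0] < 3:
        raise ValueError("need a 2-D trial array with at least 3 trials")
    checkpoints = (checkpoint_pre_s, checkpoint_post_s)
    if stats is None:
        stats = checkpoint_stats(traces, time_s, checkpoints)
    included = np.ones(traces.shape[0], dtype=bool)
    for cp, (mu, sd) in zip(checkpoints, stats):
        if not (time_s[0] <= cp <= time_s[-1]):
            raise ValueError(f"checkpoint {cp} s outside trace extent")
        col = traces[:, int(np.argmin(np.abs(time_s - cp)))]
        if sd > 0:
            included &= np.abs(col - mu) <= k_sd * sd
    return included, float(1.0 - included.mean())


@dataclass
class PspSlopeResult:
    """Maximal 1 ms-window slope of one PSP (mV/ms)."""

    slope_mv_per_ms: float
    window_start_s: float
    ok: bool = True
    message: str = ""


def _sliding_slopes(vm: np.ndarray, fs: float, i0: int, i1: int, win: int) -> np.ndarray:
    """Least-squares slope (mV/ms) for every window start in [i0, i1-win]."""
    x = np.arange(win) / fs * 1000.0  # ms
    xc = x - x.mean()
    w = xc / np.sum(xc**2)
    seg = vm[i0:i1]
    if len(seg) < win:
        return np.array([])
    # correlate: slope at window start j = sum_k w[k]*seg[j+k]
    return np.correlate(seg, w, mode="valid")


def psp_slope(vm, time_s_or_fs, stim_time_s: float, window_ms: float = 1.0,
              search_limit_ms: float = 20.0, blank_ms: float = 1.0,
              smooth_ms: float = 0.5) -> PspSlopeResult:
    """Maximal initial slope of the PSP following one stimulus.

    A 1 ms window slides over the depolarizing phase starting after a
    ``blank_ms`` stimulus-artifact blank; the search stops at the first
    local maximum of the (lightly smoothed) potential — the end of the
    first, most likely monosynaptic, component — or at ``search_limit_ms``,
    whichever is earlier.  The maximum least-squares slope over window
    positions is returned with its window position.

    If no depolarization rises above the pre-stimulus noise floor the
    result is flagged (``ok=False``, slope NaN).
    """
    vm = np.asarray(vm, dtype=float)
    fs = float(time_s_or_fs if np.isscalar(time_s_or_fs)
               else 1.0 / np.median(np.diff(time_s_or_fs)))
    if window_ms <= 0:
        raise ValueError("window_ms must be positive")
    i_stim = int(round(stim_time_s * fs))
    i_start = i_stim + int(round(blank_ms / 1000.0 * fs))
    i_limit = i_stim + int(round(search_limit_ms / 1000.0 * fs))
    if i_start >= len(vm) or i_limit > len(vm):
        raise ValueError("trace does not cover the slope search window")
    win = max(2, int(round(window_ms / 1000.0 * fs)))

    # noise floor from the pre-stimulus baseline
    base = vm[max(0, i_stim - int(0.010 * fs)): i_stim] if i_stim > 2 else vm[:2]
    noise_sd = float(np.std(base)) if base.size else 0.0
    floor = max(4.0 * noise_sd, 0.25)

    w_sm = max(1, int(round(smooth_ms / 1000.0 * fs)))
    sm = np.convolve(vm, np.ones(w_sm) / w_sm, mode="same") if w_sm > 1 else vm

    seg = sm[i_start:i_limit]
    if seg.size == 0 or np.max(seg) - sm[i_start] < floor:
        return PspSlopeResult(np.nan, np.nan, ok=False, message="no PSP above noise floor")

    # truncate at the first local maximum (end of the first component)
    peaks, _ = find_peaks(seg, prominence=floor / 2.0)
    i_end = i_start + (int(peaks[0]) + 1 if peaks.size else seg.size)

    # slopes measured on the lightly smoothed trace: interior ramp slopes are
    # unchanged while the max-over-windows selection bias under noise shrinks
    slopes = _sliding_slopes(sm, fs, i_start, i_end, win)
    if slopes.size == 0:
        # first component shorter than one window: fit it whole
        j1 = max(i_start + 3, i_end)
        x = (np.arange(i_start, j1) - i_start) / fs * 1000.0
        slope = float(np.polyfit(x, sm[i_start:j1], 1)[0])
        return PspSlopeResult(slope, i_start / fs)
    j = int(np.argmax(slopes))
    return PspSlopeResult(float(slopes[j]), (i_start + j) / fs)


def measure_trial_slopes(trial_set, **slope_kwargs) -> np.ndarray:
    """Apply :func:`psp_slope` to every sweep of a trial set."""
    return np.array([
        psp_slope(trial_set.traces[k], trial_set.time_s,
                  trial_set.stim_time_s, **slope_kwargs).slope_mv_per_ms
        for k in range(trial_set.n_trials)
    ])


def normalize_and_bin(series: pd.DataFrame, bin_width_s: float = 300.0) -> pd.DataFrame:
    """Percent-change normalization and 5 min binning of the test phase.

    ``series`` is a tidy per-trial table with columns ``trial_time_s``,
    ``slope_mv_per_ms``, ``included`` (bool), ``phase`` in
    {baseline, pairing, test} and optionally ``cell_id``.  Percent change is
    100 * (slope - baseline_mean) / baseline_mean, with the baseline mean
    taken over included baseline trials of the same cell.  Test-phase trials
    are averaged in consecutive bins starting at the first test trial.

    Returns a tidy table (cell_id, bin_start_s, mean, sem, n).
    """
    df = series.copy()
    if "cell_id" not in df.columns:
        df["cell_id"] = "cell0"
    rows = []
    for cell, g in df.groupby("cell_id"):
        g = g[g["included"]]
        base = g.loc[g["phase"] == "baseline", "slope_mv_per_ms"]
        if base.empty:
            raise ValueError(f"empty baseline for cell {cell!r}")
        base_mean = base.mean()
        test = g[g["phase"] == "test"].copy()
        if test.empty:
            continue
        test["percent_change"] = 100.0 * (test["slope_mv_per_ms"] - base_mean) / base_mean
        t0 = test["trial_time_s"].min()
        test["bin_start_s"] = t0 + np.floor(
            (test["trial_time_s"] - t0) / bin_width_s) * bin_width_s
        for b, gb in test.groupby("bin_start_s"):
            pc = gb["percent_change"].to_numpy()
            rows.append({
                "cell_id": cell, "bin_start_s": float(b),
                "mean": float(pc.mean()),
                "sem": float(pc.std(ddof=1) / np.sqrt(len(pc))) if len(pc) > 1 else 0.0,
                "n": int(len(pc)),
            })
    return pd.DataFrame(rows, columns=["cell_id", "bin_start_s", "mean", "sem", "n"])


def _down_state_mean(recording) -> float:
    vm = recording.vm_mv
    return float(vm[vm <= np.percentile(vm, 20)].mean())


def qc_cell_health(recording, criteria: QcCriteria = QcCriteria(),
                   input_resistance: Optional[Sequence[float]] = None) -> dict:
    """Evaluate the cell-health inclusion criteria on one recording.

    Returns a report dict with one entry per criterion, each ``"pass"``,
    ``"fail"`` or ``"not_evaluable"`` (a criterion whose required
    annotation is missing is reported, never silently passed), plus
    ``overall`` which is True only if every evaluable criterion passed and
    none was unevaluable.
    """
    fs = recording.sampling_rate_hz
    vm = recording.vm_mv
    report = {}

    report["down_state"] = (
        "pass" if _down_state_mean(recording) < criteria.down_state_max_mv else "fail")

    spikes = recording.event_times("spike")
    if spikes.size == 0:
        report["action_potential"] = "not_evaluable"
    else:
        amps = []
        for t in spikes:
            i = int(round(t * fs))
            lo, hi = max(0, i - int(0.002 * fs)), min(len(vm), i + int(0.002 * fs) + 1)
            b0 = max(0, i - int(0.020 * fs))
            baseline = np.median(vm[b0:lo]) if lo > b0 else vm[lo]
            amps.append(np.max(vm[lo:hi]) - baseline)
        report["action_potential"] = (
            "pass" if np.max(amps) > criteria.ap_min_amp_mv else "fail")

    if input_resistance is None or len(np.atleast_1d(input_resistance)) == 0:
        report["input_resistance"] = "not_evaluable"
    else:
        ir = np.asarray(input_resistance, dtype=float)
        rel = np.abs(ir - ir[0]) / np.abs(ir[0])
        report["input_resistance"] = (
            "pass" if np.max(rel) <= criteria.input_resistance_tolerance else "fail")

    stims = recording.event_times("cortical_stim")
    if stims.size == 0:
        report["baseline_psp"] = "not_evaluable"
    else:
        amps = []
        for t in stims:
            i = int(round(t * fs))
            pre = vm[max(0, i - int(0.010 * fs)): max(1, i)]
            post = vm[i: min(len(vm), i + int(0.050 * fs))]
            if post.size:
                amps.append(np.max(post) - np.mean(pre))
        report["baseline_psp"] = (
            "pass" if amps and np.mean(amps) >= criteria.psp_min_amp_mv else "fail")

    report["overall"] = all(v == "pass" for k, v in report.items() if k != "overall")
    return report
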