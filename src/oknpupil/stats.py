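"""Group-level analysis: correct-trial filtering, per-participant condition
averages, pointwise t-tests with Benjamini-Hochberg FDR control, latency
comparisons and Pearson correlations.

Trace comparisons are paired across participants (every factor is within
subject); the OKN-vs-pupil latency comparison is an independent pooled-
variance t-test, matching a design where the two latency samples are treated
as separate groups.  Pointwise p-values are corrected per panel with the BH
step-up procedure at q = 0.05, and the largest surviving p is reported as the
panel's significance threshold.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Hashable, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from . import okn as okn_mod
from . import preprocess as pp
from .latency import LatencyEstimate, estimate_latency
from .session import StimulusSpec, TrialRecording

__all__ = [
    "ConditionAverage",
    "PointwiseTestResult",
    "CorrelationResult",
    "LatencyComparison",
    "filter_correct",
    "condition_average",
    "bh_threshold",
    "pointwise_ttest",
    "compare_latencies",
    "correlate",
    "analysis_report",
]

logger = logging.getLogger(__name__)

FDR_Q = 0.05


@dataclass(frozen=True)
class ConditionAverage:
    """Per-participant mean trace over the trials of one condition cell."""

    participant_id: str
    condition: Hashable
    mean_trace: np.ndarray
    n_trials: int
    n_per_sample: np.ndarray  # non-missing trial count per timepoint

    def __post_init__(self) -> None:
        if self.n_trials < 1:
            raise ValueError("a condition average needs at least one trial")


@dataclass(frozen=True)
class PointwiseTestResult:
    """Per-timepoint paired/independent t-tests with BH-FDR thresholding."""

    t: np.ndarray
    p: np.ndarray
    p_thresh: float  # largest BH-significant p; 0.0 when nothing survives
    sig_mask: np.ndarray
    q: float = FDR_Q


@dataclass(frozen=True)
class CorrelationResult:
    r: float
    p: float
    n: int

    def __post_init__(self) -> None:
        if not -1.0 - 1e-12 <= self.r <= 1.0 + 1e-12:
            raise ValueError("Pearson r outside [-1, 1]")


@dataclass(frozen=True)
class LatencyComparison:
    t: float
    df: int
    p: float


def filter_correct(trials: Sequence[TrialRecording]) -> list[TrialRecording]:
    """Keep only trials where both target numerals were identified correctly."""
    kept = [tr for tr in trials if tr.meta is not None and tr.meta.both_correct]
    by_cond: dict[str, list[int]] = {}
    for tr in trials:
        if tr.meta is None:
            continue
        by_cond.setdefault(tr.meta.condition, []).append(int(tr.meta.both_correct))
    for cond, flags in sorted(by_cond.items()):
        logger.info("filter_correct: %s retained %d/%d trials (%.4f)",
                    cond, sum(flags), len(flags),
                    sum(flags) / len(flags) if flags else float("nan"))
    return kept


def condition_average(
    traces: Sequence[np.ndarray],
    labels: Sequence[Hashable],
    participants: Sequence[str],
) -> list[ConditionAverage]:
    """Timepoint-wise mean per (participant, label), ignoring missing samples."""
    if not (len(traces) == len(labels) == len(participants)):
        raise ValueError("traces, labels and participants must align")
    groups: dict[tuple[str, Hashable], list[np.ndarray]] = {}
    for trace, label, pid in zip(traces, labels, participants):
        groups.setdefault((pid, label), []).append(np.asarray(trace, dtype=float))
    out = []
    for (pid, label), members in sorted(groups.items(), key=lambda kv: repr(kv[0])):
        stack = np.vstack(members)
        counts = np.sum(np.isfinite(stack), axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            mean = np.where(counts > 0, np.nansum(stack, axis=0) / counts, np.nan)
        out.append(ConditionAverage(
            participant_id=pid,
            condition=label,
            mean_trace=mean,
            n_trials=stack.shape[0],
            n_per_sample=counts,
        ))
    return out


def bh_threshold(p: np.ndarray, q: float = FDR_Q) -> tuple[float, np.ndarray]:
    """Benjamini-Hochberg step-up over all m p-values.

    Returns ``(p_thresh, mask)`` where ``p_thresh`` is the largest p(k) with
    p(k) <= (k/m) q (0.0, with an all-False mask, if none), and ``mask`` flags
    every p <= p_thresh.
    """
    p = np.asarray(p, dtype=float)
    m = p.size
    if m == 0:
        return 0.0, np.zeros(0, dtype=bool)
    order = np.sort(p)
    crit = (np.arange(1, m + 1) / m) * q
    passing = np.flatnonzero(order <= crit)
    if passing.size == 0:
        return 0.0, np.zeros(m, dtype=bool)
    p_thresh = float(order[passing[-1]])
    return p_thresh, p <= p_thresh


def _paired_t(a: np.ndarray, b: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized paired two-sided t-test per column; zero-difference columns
    give t = 0, p = 1 instead of NaN."""
    d = a - b
    n = d.shape[0]
    md = d.mean(axis=0)
    sd = d.std(axis=0, ddof=1)
    t = np.zeros(d.shape[1])
    p = np.ones(d.shape[1])
    nonzero = sd > 0
    t[nonzero] = md[nonzero] / (sd[nonzero] / np.sqrt(n))
    p[nonzero] = 2.0 * sps.t.sf(np.abs(t[nonzero]), df=n - 1)
    degenerate = (~nonzero) & (md != 0)
    t[degenerate] = np.sign(md[degenerate]) * np.inf
    p[degenerate] = 0.0
    return t, p


def _independent_t(a: np.ndarray, b: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    res = sps.ttest_ind(a, b, axis=0, equal_var=True)
    t = np.nan_to_num(np.asarray(res.statistic), nan=0.0)
    p = np.where(np.isnan(res.pvalue), 1.0, res.pvalue)
    return t, np.asarray(p)


def pointwise_ttest(
    group_a: np.ndarray,
    group_b: np.ndarray,
    paired: bool = True,
    q: float = FDR_Q,
) -> PointwiseTestResult:
    """Two-sided t-test at every timepoint, BH-corrected over all timepoints.

    ``group_a``/``group_b`` are (participants x timepoints); paired tests
    require matched participant rows.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.ndim != 2 or b.ndim != 2 or a.shape[1] != b.shape[1]:
        raise ValueError("groups must be 2-D with equal trace lengths")
    if paired and a.shape[0] != b.shape[0]:
        raise ValueError("paired tests require matched participants")
    if min(a.shape[0], b.shape[0]) < 3:
        raise ValueError("pointwise tests need at least 3 participants per group")
    t, p = _paired_t(a, b) if paired else _independent_t(a, b)
    p_thresh, mask = bh_threshold(p, q)
    return PointwiseTestResult(t=t, p=p, p_thresh=p_thresh, sig_mask=mask, q=q)


def compare_latencies(
    okn_latencies: Sequence[float], pupil_latencies: Sequence[float]
) -> LatencyComparison:
    """Pooled-variance two-sample two-sided t-test (df = n1 + n2 - 2)."""
    x = np.asarray(okn_latencies, dtype=float)
    y = np.asarray(pupil_latencies, dtype=float)
    x = x[np.isfinite(x)]
    y = y[np.isfinite(y)]
    if x.size < 2 or y.size < 2:
        raise ValueError("latency comparison needs >= 2 values per group")
    res = sps.ttest_ind(x, y, equal_var=True)
    return LatencyComparison(t=float(res.statistic), df=x.size + y.size - 2,
                             p=float(res.pvalue))


def correlate(x: Sequence[float], y: Sequence[float]) -> CorrelationResult:
    """Pearson correlation with two-sided p; pairs with any invalid member
    are dropped."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise ValueError("x and y must pair up")
    ok = np.isfinite(x) & np.isfinite(y)
    x, y = x[ok], y[ok]
    if x.size < 3:
        raise ValueError("correlation needs at least 3 valid pairs")
    r, p = sps.pearsonr(x, y)
    return CorrelationResult(r=float(r), p=float(p), n=int(x.size))


# ---------------------------------------------------------------------------
# full-session analysis
# ---------------------------------------------------------------------------


def _spv_trace(rec: TrialRecording, spec: StimulusSpec) -> np.ndarray:
    pos = pp.mark_invalid_samples(rec.x, spec.sampling_rate, "deg")
    return okn_mod.slow_phase_velocity(pos).velocity


def _pupil_trace(rec: TrialRecording, spec: StimulusSpec) -> np.ndarray | None:
    raw = pp.mark_invalid_samples(rec.pupil, spec.sampling_rate, "pixels")
    smoothed = pp.gaussian_smooth(raw, 100)
    try:
        z = pp.zscore_trial(smoothed, (0.0, spec.trial_duration))
    except pp.DegenerateTrialError:
        logger.warning("degenerate pupil trial excluded from averaging")
        return None
    return z.values


def _align_average(
    traces: Sequence[np.ndarray],
    event_times: Sequence[float],
    ref_time: float,
    sampling_rate: float,
) -> np.ndarray:
    """Average traces after shifting each so its event lands at ``ref_time``;
    residual missing samples are bridged by linear interpolation."""
    n = traces[0].size
    stack = np.full((len(traces), n), np.nan)
    for row, (trace, ev) in enumerate(zip(traces, event_times)):
        shift = int(round((ref_time - ev) * sampling_rate))
        src_lo, src_hi = max(0, -shift), min(n, n - shift)
        stack[row, src_lo + shift : src_hi + shift] = trace[src_lo:src_hi]
    counts = np.sum(np.isfinite(stack), axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        mean = np.where(counts > 0, np.nansum(stack, axis=0) / counts, np.nan)
    finite = np.flatnonzero(np.isfinite(mean))
    if finite.size == 0:
        raise ValueError("aligned average is empty")
    return np.interp(np.arange(n), finite, mean[finite])


def participant_latencies(
    trials: Sequence[TrialRecording],
    spec: StimulusSpec,
    condition: str,
    *,
    brightness_first: str = "black",
    cue_relation: str = "opposite",
    search_halfwidth: float = 1.5,
) -> pd.DataFrame:
    """Per-participant OKN and pupil latencies relative to the second cue.

    Follows the headline analysis: restrict to the black-to-white opposite-cue
    trials of one condition, average each participant's traces aligned to the
    second cue (OKN traces are sign-aligned so the pre-switch slow phase is
    positive), then locate the deepest acceleration valley.  Rows hold NaN
    where no valley fell inside the search window.
    """
    sel = [tr for tr in trials
           if tr.meta is not None
           and tr.meta.condition == condition
           and tr.meta.cue_relation == cue_relation
           and tr.meta.brightness_first == brightness_first]
    ref_time = spec.motion_onset + 3.1  # nominal second-cue time
    rows = []
    by_pid: dict[str, list[TrialRecording]] = {}
    for tr in sel:
        by_pid.setdefault(tr.meta.participant_id, []).append(tr)
    for pid in sorted(by_pid):
        recs = by_pid[pid]
        cue2s = [tr.meta.cue2_time for tr in recs]
        signs = [1.0 if tr.meta.motion_dir_first == "right" else -1.0 for tr in recs]
        okn_traces = [s * _spv_trace(tr, spec) for s, tr in zip(signs, recs)]
        okn_avg = _align_average(okn_traces, cue2s, ref_time, spec.sampling_rate)
        okn_est = estimate_latency(okn_avg, ref_time, spec.sampling_rate,
                                   search_halfwidth=search_halfwidth, diff_order=1)
        pupil_pairs = [(zt, tr.meta.cue2_time) for tr, zt in
                       ((tr, _pupil_trace(tr, spec)) for tr in recs)
                       if zt is not None]
        if pupil_pairs:
            pupil_avg = _align_average([p[0] for p in pupil_pairs],
                                       [p[1] for p in pupil_pairs],
                                       ref_time, spec.sampling_rate)
            pupil_est = estimate_latency(pupil_avg, ref_time, spec.sampling_rate,
                                         search_halfwidth=search_halfwidth,
                                         diff_order=2)
        else:
            pupil_est = LatencyEstimate(np.nan, np.nan, False)
        rows.append({
            "participant": pid,
            "condition": condition,
            "n_trials": len(recs),
            "okn_latency_s": okn_est.latency if okn_est.valid else np.nan,
            "okn_valid": okn_est.valid,
            "pupil_latency_s": pupil_est.latency if pupil_est.valid else np.nan,
            "pupil_valid": pupil_est.valid,
        })
    return pd.DataFrame(rows)


def analysis_report(
    trials: Sequence[TrialRecording],
    spec: StimulusSpec | None = None,
    out_dir: str | Path | None = None,
    q: float = FDR_Q,
    paired: bool = True,
) -> dict:
    """Run the full group pipeline on a session and (optionally) write outputs.

    Steps: correct-trial filter -> per-trial slow-phase velocity and z-scored
    pupil -> per-participant averages per condition panel (condition x cue
    relation, traces split by the second cue's motion direction for OKN and
    brightness for pupil) -> BH-corrected pointwise t-tests per panel ->
    per-participant latencies on the black-to-white opposite-cue trials ->
    OKN-vs-pupil latency t-tests and the latency correlations.

    Returns a dict with keys ``averages``, ``pointwise``, ``latencies``,
    ``comparisons``, ``correlations``; when ``out_dir`` is given, also writes
    ``averages.csv``, ``pointwise_tests.csv``, ``latencies.csv``,
    ``comparisons.json`` and ``correlations.json`` there.
    """
    spec = spec or StimulusSpec()
    kept = filter_correct(trials)
    if not kept:
        raise ValueError("no correct trials to analyze")

    spv = {id(tr): _spv_trace(tr, spec) for tr in kept}
    pupil = {id(tr): _pupil_trace(tr, spec) for tr in kept}

    averages: list[ConditionAverage] = []
    pointwise_rows = []
    pointwise_meta = {}
    for signal, split_field, values_by_id in (
        ("okn", "motion_dir_second", spv),
        ("pupil", "brightness_second", pupil),
    ):
        split_levels = (("left", "right") if split_field == "motion_dir_second"
                        else ("white", "black"))
        for condition in ("gaze", "attention"):
            for relation in ("opposite", "same"):
                panel = [tr for tr in kept
                         if tr.meta.condition == condition
                         and tr.meta.cue_relation == relation
                         and values_by_id[id(tr)] is not None]
                if not panel:
                    continue
                traces = [values_by_id[id(tr)] for tr in panel]
                labels = [(signal, condition, relation,
                           getattr(tr.meta, split_field)) for tr in panel]
                pids = [tr.meta.participant_id for tr in panel]
                cell_avgs = condition_average(traces, labels, pids)
                averages.extend(cell_avgs)
                groups = {lvl: {} for lvl in split_levels}
                for avg in cell_avgs:
                    groups[avg.condition[3]][avg.participant_id] = avg.mean_trace
                common = sorted(set(groups[split_levels[0]])
                                & set(groups[split_levels[1]]))
                if len(common) >= 3:
                    a = np.vstack([groups[split_levels[0]][pid] for pid in common])
                    b = np.vstack([groups[split_levels[1]][pid] for pid in common])
                    res = pointwise_ttest(a, b, paired=paired, q=q)
                    key = (signal, condition, relation)
                    pointwise_meta[key] = res
                    times = np.arange(res.t.size) / spec.sampling_rate
                    pointwise_rows.append(pd.DataFrame({
                        "signal": signal, "condition": condition,
                        "cue_relation": relation, "time_s": times,
                        "t": res.t, "p": res.p, "sig": res.sig_mask,
                        "p_thresh": res.p_thresh,
                    }))

    lat_frames = [participant_latencies(kept, spec, cond)
                  for cond in ("gaze", "attention")]
    latencies = pd.concat(lat_frames, ignore_index=True)

    comparisons = {}
    for cond in ("gaze", "attention"):
        sub = latencies[latencies.condition == cond]
        okn_l = sub.okn_latency_s.to_numpy()
        pup_l = sub.pupil_latency_s.to_numpy()
        if np.isfinite(okn_l).sum() >= 2 and np.isfinite(pup_l).sum() >= 2:
            cmp_res = compare_latencies(okn_l[np.isfinite(okn_l)],
                                        pup_l[np.isfinite(pup_l)])
            comparisons[cond] = dataclasses.asdict(cmp_res)

    correlations = {}
    wide = latencies.pivot(index="participant", columns="condition",
                           values=["okn_latency_s", "pupil_latency_s"])
    pairs = {
        "okn_vs_pupil_gaze": (("okn_latency_s", "gaze"), ("pupil_latency_s", "gaze")),
        "okn_vs_pupil_attention": (("okn_latency_s", "attention"),
                                   ("pupil_latency_s", "attention")),
        "okn_gaze_vs_attention": (("okn_latency_s", "gaze"),
                                  ("okn_latency_s", "attention")),
        "pupil_gaze_vs_attention": (("pupil_latency_s", "gaze"),
                                    ("pupil_latency_s", "attention")),
    }
    for name, (cx, cy) in pairs.items():
        if cx in wide.columns and cy in wide.columns:
            try:
                correlations[name] = dataclasses.asdict(
                    correlate(wide[cx].to_numpy(), wide[cy].to_numpy()))
            except ValueError:
                logger.info("correlation %s skipped: too few valid pairs", name)

    results = {
        "averages": averages,
        "pointwise": pointwise_meta,
        "latencies": latencies,
        "comparisons": comparisons,
        "correlations": correlations,
    }

    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        avg_rows = []
        for avg in averages:
            signal, condition, relation, level = avg.condition
            avg_rows.append(pd.DataFrame({
                "participant": avg.participant_id, "signal": signal,
                "condition": condition, "cue_relation": relation,
                "level": level, "n_trials": avg.n_trials,
                "sample_index": np.arange(avg.mean_trace.size),
                "mean": avg.mean_trace,
            }))
        pd.concat(avg_rows, ignore_index=True).to_csv(out / "averages.csv", index=False)
        if pointwise_rows:
            pd.concat(pointwise_rows, ignore_index=True).to_csv(
                out / "pointwise_tests.csv", index=False)
        latencies.to_csv(out / "latencies.csv", index=False)
        (out / "comparisons.json").write_text(json.dumps(comparisons, indent=2))
        (out / "correlations.json").write_text(json.dumps(correlations, indent=2))
    return results
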