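"""Head-up-tilt (HUT) protocol analysis of oximetry time series.

The protocol is 10 min supine baseline (0 deg), 30 min head-up tilt
(70 deg, reached over ~5 s), and 10 min supine recovery.  This module
segments concentration-change series by that protocol and computes the
quantities used to compare POTS patients with healthy controls:

* segment averages (mean +/- SE during the tilt),
* rates of change over the first 10 min after each posture change,
* area under the curve (uM*min) over the 30-min tilt,
* equal-variance two-tailed Student t-tests between groups (alpha = 0.01),
* cross-device correlation (R^2) against a reference oximeter trace,
* the orthostatic-tachycardia heart-rate criterion (>40 bpm rise for
  children, >30 bpm for adults, within the tilt).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import pandas as pd
from scipy import stats

from .exceptions import NumericalError, ValidationError
from .mbll import SIGNALS, ConcentrationSeries


@dataclass(frozen=True)
class ProtocolSegment:
    label: str
    angle_deg: float
    duration_min: float


@dataclass(frozen=True)
class ProtocolDefinition:
    """Ordered posture segments of the tilt-table protocol.

    The default is the 10/30/10-min 0/70/0-degree protocol.  The ~5 s
    posture transition is assigned to the segment it leads into, so segment
    windows are exact half-open intervals.
    """

    segments: tuple[ProtocolSegment, ...] = (
        ProtocolSegment("baseline", 0.0, 10.0),
        ProtocolSegment("tilt", 70.0, 30.0),
        ProtocolSegment("recovery", 0.0, 10.0),
    )
    transition_s: float = 5.0

    def __post_init__(self) -> None:
        labels = [s.label for s in self.segments]
        if len(set(labels)) != len(labels):
            raise ValidationError("segment labels must be unique")
        if any(s.duration_min <= 0 for s in self.segments):
            raise ValidationError("segment durations must be positive")

    @property
    def total_s(self) -> float:
        return 60.0 * sum(s.duration_min for s in self.segments)

    def boundaries_s(self) -> list[tuple[str, float, float]]:
        """(label, t_start, t_end) in seconds, half-open [t_start, t_end)."""
        out, t = [], 0.0
        for s in self.segments:
            out.append((s.label, t, t + 60.0 * s.duration_min))
            t += 60.0 * s.duration_min
        return out


@dataclass(frozen=True)
class SubjectRecord:
    """Per-subject metadata and heart-rate summaries."""

    id: str
    group: str
    age: float
    sex: str = ""
    height_cm: float = float("nan")
    weight_kg: float = float("nan")
    hr_baseline_max: float = float("nan")
    hr_tilt_max: float = float("nan")

    def __post_init__(self) -> None:
        if self.group not in ("POTS", "control"):
            raise ValidationError(f"group must be POTS or control, got {self.group!r}")
        for v in (self.hr_baseline_max, self.hr_tilt_max):
            if np.isfinite(v) and not (30.0 <= v <= 250.0):
                raise ValidationError(f"heart rate {v} bpm outside physiological range")


@dataclass
class Segmentation:
    """Protocol-labelled sub-series with their half-open index windows."""

    windows: dict[str, tuple[int, int]]
    series: dict[str, ConcentrationSeries]

    def __getitem__(self, label: str) -> ConcentrationSeries:
        return self.series[label]


def segment(conc: ConcentrationSeries, proto: ProtocolDefinition | None = None) -> Segmentation:
    """Split a concentration series into protocol segments.

    Windows are half-open sample-index intervals covering [0, total
    duration); the posture transition belongs to the following segment.
    A recording shorter than the protocol is rejected, naming the missing
    number of samples.
    """
    proto = proto or ProtocolDefinition()
    fs = 1.0 / float(np.median(np.diff(conc.time)))
    n_needed = int(round(proto.total_s * fs))
    n = conc.time.size
    if n < n_needed:
        raise ValidationError(
            f"recording shorter than protocol: {n_needed - n} samples missing "
            f"({(n_needed - n) / fs:.0f} s)")
    t0 = conc.time[0]
    windows, series = {}, {}
    for label, ts, te in proto.boundaries_s():
        i0 = int(np.searchsorted(conc.time, t0 + ts, side="left"))
        i1 = int(np.searchsorted(conc.time, t0 + te, side="left"))
        windows[label] = (i0, i1)
        series[label] = conc.slice(i0, i1)
    return Segmentation(windows=windows, series=series)


def segment_average(sub: ConcentrationSeries, signals=SIGNALS) -> pd.DataFrame:
    """Mean +/- standard error of each signal over a segment's time samples."""
    if sub.time.size < 2:
        raise ValidationError("segment must contain at least 2 samples")
    rows = []
    for name in signals:
        y = sub.signal(name)
        rows.append({"signal": name, "mean": float(np.mean(y)),
                     "se": float(np.std(y, ddof=1) / np.sqrt(y.size))})
    return pd.DataFrame(rows).set_index("signal")


def rate_of_change(sub: ConcentrationSeries, window_min: float = 10.0,
                   signals=SIGNALS) -> pd.Series:
    """OLS slope (uM/min) of each signal over the first ``window_min``
    minutes of a segment (half-open window from the segment start)."""
    t_min = (sub.time - sub.time[0]) / 60.0
    mask = t_min < window_min
    if mask.sum() < 3:
        raise ValidationError("need at least 3 samples in the slope window")
    t = t_min[mask]
    if np.ptp(t) == 0:
        raise NumericalError("degenerate time axis: zero span in slope window")
    out = {}
    for name in signals:
        y = sub.signal(name)[mask]
        out[name] = float(np.polyfit(t, y, 1)[0])
    return pd.Series(out)


def auc_tilt(sub: ConcentrationSeries, signals=SIGNALS) -> pd.Series:
    """Trapezoidal area under each signal over the tilt segment (uM*min)."""
    if sub.time.size < 2:
        raise ValidationError("AUC needs at least 2 samples")
    t_min = sub.time / 60.0
    return pd.Series({name: float(np.trapezoid(sub.signal(name), t_min))
                      for name in signals})


@dataclass(frozen=True)
class GroupTestResult:
    t: float
    p: float
    significant: bool
    degenerate: bool = False


def group_test(values_a, values_b, alpha: float = 0.01,
               equal_var: bool = True) -> GroupTestResult:
    """Two-sample two-tailed Student t-test (equal variance by default).

    Degenerate zero-variance cases follow the conventions: equal means give
    p = 1, distinct means give p = 0 (flagged degenerate).
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValidationError("need at least 2 subjects per group")
    if np.var(a, ddof=1) == 0 and np.var(b, ddof=1) == 0:
        if np.mean(a) == np.mean(b):
            return GroupTestResult(0.0, 1.0, False, degenerate=True)
        return GroupTestResult(np.inf if np.mean(a) > np.mean(b) else -np.inf,
                               0.0, True, degenerate=True)
    t, p = stats.ttest_ind(a, b, equal_var=equal_var)
    return GroupTestResult(float(t), float(p), bool(p < alpha))


@dataclass(frozen=True)
class CorrelationResult:
    r2: float
    slope: float
    intercept: float
    n: int
    degenerate: bool = False


def device_correlation(device_time, device_oxy, ref_time, ref_values,
                       window_s: tuple[float, float] = (600.0, 2400.0),
                       smooth_s: float = 10.0) -> CorrelationResult:
    """R^2 between the probe dOxy trace and a reference-oximeter trace.

    The reference is resampled onto the probe's time grid by linear
    interpolation over the tilt window; both series are then smoothed with
    a centred moving average of ``smooth_s`` seconds (mirroring the slow
    display update of clinical reference oximeters) and the reference is
    regressed on the probe signal by OLS.  The unit mismatch (% vs uM) only
    affects the slope, not R^2.
    """
    device_time = np.asarray(device_time, float)
    device_oxy = np.asarray(device_oxy, float)
    mask = (device_time >= window_s[0]) & (device_time < window_s[1])
    t = device_time[mask]
    if t.size < 3:
        raise ValidationError("need at least 3 overlapping samples")
    x = device_oxy[mask]
    y = np.interp(t, np.asarray(ref_time, float), np.asarray(ref_values, float))
    if smooth_s > 0:
        fs = 1.0 / float(np.median(np.diff(t)))
        k = max(1, int(round(smooth_s * fs)))
        if k > 1:
            kernel = np.ones(k) / k
            x = np.convolve(x, kernel, mode="valid")
            y = np.convolve(y, kernel, mode="valid")
    if np.std(x) == 0 or np.std(y) == 0:
        return CorrelationResult(float("nan"), float("nan"), float("nan"),
                                 int(x.size), degenerate=True)
    res = stats.linregress(x, y)
    return CorrelationResult(float(res.rvalue ** 2), float(res.slope),
                             float(res.intercept), int(x.size))


def pots_criterion(subj: SubjectRecord) -> bool:
    """Orthostatic-tachycardia heart-rate criterion.

    True iff the tilt heart-rate rise strictly exceeds 40 bpm for children
    (age < 18) or 30 bpm for adults.
    """
    if not (np.isfinite(subj.hr_baseline_max) and np.isfinite(subj.hr_tilt_max)):
        raise ValidationError(f"subject {subj.id}: heart-rate fields missing")
    delta = subj.hr_tilt_max - subj.hr_baseline_max
    threshold = 40.0 if subj.age < 18 else 30.0
    return bool(delta > threshold)


def load_printed_subjects() -> list[SubjectRecord]:
    """The packaged 6 POTS + 6 control subject metadata with the printed
    group-level heart-rate summaries attached to each member."""
    base = resources.files("nirsox.data")
    with resources.as_file(base / "subjects.csv") as p:
        subjects = pd.read_csv(p)
    with resources.as_file(base / "heart_rate_summary.csv") as p:
        hr = pd.read_csv(p).set_index("group")
    out = []
    for _, row in subjects.iterrows():
        g = row["group"]
        out.append(SubjectRecord(
            id=row["subject"], group=g, age=float(row["age"]), sex=row["sex"],
            height_cm=float(row["height_cm"]), weight_kg=float(row["weight_kg"]),
            hr_baseline_max=float(hr.loc[g, "hr_baseline_max"]),
            hr_tilt_max=float(hr.loc[g, "hr_tilt_max"])))
    return out


@dataclass
class CohortResult:
    """Cohort-level summary: per-subject statistics, group means +/- SE,
    group t-tests, optional per-subject device correlations, and the AUC of
    the group-mean curve (the subject-wise mean AUC lives in ``groups``)."""

    subjects: pd.DataFrame
    groups: pd.DataFrame
    tests: pd.DataFrame
    alpha: float
    correlations: pd.DataFrame | None = None
    group_mean_curve_auc: pd.DataFrame | None = None


def analyze_cohort(cohort, proto: ProtocolDefinition | None = None,
                   alpha: float = 0.01) -> CohortResult:
    """Run the full HUT statistics over a processed cohort.

    ``cohort`` is an iterable of (SubjectRecord, ConcentrationSeries,
    reference) triples; ``reference`` is None or a (time_s, values) tuple
    from the reference oximeter.
    """
    proto = proto or ProtocolDefinition()
    rows, corr_rows = [], []
    tilt_curves: dict[str, list[ConcentrationSeries]] = {"POTS": [], "control": []}
    for rec, conc, reference in cohort:
        seg = segment(conc, proto)
        tilt = seg["tilt"]
        tilt_curves[rec.group].append(tilt)
        means = segment_average(tilt)
        slopes_tilt = rate_of_change(tilt)
        slopes_rec = rate_of_change(seg["recovery"])
        aucs = auc_tilt(tilt)
        for name in SIGNALS:
            rows.append({
                "subject": rec.id, "group": rec.group, "signal": name,
                "tilt_mean_um": means.loc[name, "mean"],
                "tilt_auc_um_min": aucs[name],
                "slope_tilt_um_per_min": slopes_tilt[name],
                "slope_recovery_um_per_min": slopes_rec[name],
                "pots_criterion": pots_criterion(rec),
            })
        if reference is not None:
            c = device_correlation(conc.time, conc.d_oxy, reference[0], reference[1])
            corr_rows.append({"subject": rec.id, "group": rec.group,
                              "r2": c.r2, "slope": c.slope, "n": c.n})
    subjects = pd.DataFrame(rows)
    groups = (subjects
              .groupby(["group", "signal"])
              .agg(tilt_mean_um=("tilt_mean_um", "mean"),
                   tilt_mean_se=("tilt_mean_um", "sem"),
                   tilt_auc_um_min=("tilt_auc_um_min", "mean"),
                   tilt_auc_se=("tilt_auc_um_min", "sem"),
                   slope_tilt_um_per_min=("slope_tilt_um_per_min", "mean"),
                   slope_recovery_um_per_min=("slope_recovery_um_per_min", "mean"))
              .reset_index())
    test_rows = []
    for name in SIGNALS:
        pots = subjects.query("group == 'POTS' and signal == @name")["tilt_mean_um"]
        ctrl = subjects.query("group == 'control' and signal == @name")["tilt_mean_um"]
        res = group_test(pots, ctrl, alpha=alpha)
        test_rows.append({"signal": name, "statistic": "tilt_mean",
                          "t": res.t, "p": res.p, "significant": res.significant})
        pots_s = subjects.query("group == 'POTS' and signal == @name")["slope_tilt_um_per_min"]
        ctrl_s = subjects.query("group == 'control' and signal == @name")["slope_tilt_um_per_min"]
        res_s = group_test(pots_s, ctrl_s, alpha=alpha)
        test_rows.append({"signal": name, "statistic": "slope_tilt",
                          "t": res_s.t, "p": res_s.p, "significant": res_s.significant})
    tests = pd.DataFrame(test_rows)
    # AUC of the group-mean curve (alternative AUC reading)
    gm_rows = []
    for g, curves in tilt_curves.items():
        if not curves:
            continue
        for name in SIGNALS:
            stack = np.vstack([c.signal(name) for c in curves])
            mean_curve = ConcentrationSeries(
                time=curves[0].time, dc_hb=stack.mean(axis=0), dc_hbo2=stack.mean(axis=0))
            t_min = mean_curve.time / 60.0
            gm_rows.append({"group": g, "signal": name,
                            "auc_um_min": float(np.trapezoid(stack.mean(axis=0), t_min))})
    return CohortResult(
        subjects=subjects, groups=groups, tests=tests, alpha=alpha,
        correlations=pd.DataFrame(corr_rows) if corr_rows else None,
        group_mean_curve_auc=pd.DataFrame(gm_rows) if gm_rows else None)
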