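"""Synthetic POTS / control cohorts for the head-up-tilt pipeline.

No recordings are distributed with the study this package models, so this
module generates raw three-wavelength intensity recordings (two
detectors), heart-rate summaries and a reference-oximeter trace for a
6 + 6 cohort under the 10/30/10-min tilt protocol.  The generator is the
exact forward model of the analysis chain: piecewise-linear
concentration-change trajectories are pushed through the modified
Beer-Lambert law to attenuations and then to intensities
``I = I_o * 10**(-dA)``, with multiplicative measurement noise.

Trajectory templates encode the group-distinct hemodynamics of the study:
a rise-to-plateau ramp during the tilt whose rise time differs by group
(controls stop accumulating Hb after ~4 min, POTS patients keep
accumulating for the whole 30 min; HbO2 rises within ~2 min in controls
vs ~10 min in POTS) and an exponential relaxation back to baseline during
recovery, slower in POTS.  Ramp amplitudes are not free parameters: they
are solved in closed form from the published tilt areas under the curve,
AUC = A * (T_tilt - r/2) for rise time r and plateau A.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .exceptions import ValidationError
from .hut import ProtocolDefinition, SubjectRecord, load_printed_subjects
from .mbll import (DEVICE_WAVELENGTHS, ConcentrationSeries, ExtinctionTable,
                   PathlengthSpec, RawRecording)

#: Published tilt AUC targets (uM*min) that calibrate the template amplitudes.
DEFAULT_AUC_TARGETS: dict[tuple[str, str], float] = {
    ("POTS", "hb"): 113.0,
    ("control", "hb"): 52.0,
    ("POTS", "hbo2"): 42.0,
    ("control", "hbo2"): 41.0,
}

#: Rise times (min) of the tilt ramp, from the narrative time courses.
DEFAULT_RISE_MIN: dict[tuple[str, str], float] = {
    ("POTS", "hb"): 30.0,
    ("control", "hb"): 4.0,
    ("POTS", "hbo2"): 10.0,
    ("control", "hbo2"): 2.0,
}

#: Recovery relaxation time constants (min); slower recovery in POTS.
DEFAULT_RECOVERY_TAU_MIN: dict[str, float] = {"POTS": 6.0, "control": 2.0}

#: Heart-rate summary centres (bpm): (baseline max, tilt max) per group.
DEFAULT_HR_CENTERS: dict[str, tuple[float, float]] = {
    "POTS": (76.0, 123.0),
    "control": (66.0, 85.0),
}


@dataclass(frozen=True)
class TrajectoryTemplate:
    """Group/signal concentration-change trajectory (uM vs protocol time).

    Baseline is identically zero; during the tilt the signal ramps
    linearly to ``amplitude_um`` over ``rise_min`` minutes and stays
    there; during recovery it relaxes exponentially toward zero with
    ``recovery_tau_min``.
    """

    signal: str              # "hb" | "hbo2"
    group: str               # "POTS" | "control"
    amplitude_um: float
    rise_min: float
    recovery_tau_min: float

    def __post_init__(self) -> None:
        if self.rise_min <= 0:
            raise ValidationError("rise time must be positive")
        if self.recovery_tau_min <= 0:
            raise ValidationError("recovery time constant must be positive")

    def evaluate(self, time_s: np.ndarray,
                 proto: ProtocolDefinition | None = None) -> np.ndarray:
        proto = proto or ProtocolDefinition()
        (_, b0, b1), (_, t0, t1), (_, r0, r1) = proto.boundaries_s()
        t = np.asarray(time_s, float)
        out = np.zeros_like(t)
        tilt = (t >= t0) & (t < r0)
        rise_s = self.rise_min * 60.0
        out[tilt] = self.amplitude_um * np.minimum((t[tilt] - t0) / rise_s, 1.0)
        rec = t >= r0
        value_at_end = self.amplitude_um * min((r0 - t0) / rise_s, 1.0)
        tau_s = self.recovery_tau_min * 60.0
        out[rec] = value_at_end * np.exp(-(t[rec] - r0) / tau_s)
        return out


def calibrate_templates(auc_targets: dict | None = None,
                        rise_min: dict | None = None,
                        recovery_tau_min: dict | None = None,
                        tilt_duration_min: float = 30.0,
                        ) -> dict[tuple[str, str], TrajectoryTemplate]:
    """Solve template amplitudes from tilt AUC targets.

    A ramp with rise time r reaching plateau A over a tilt of length T has
    AUC = A * (T - r/2), hence A = AUC / (T - r/2).  A rise time equal to
    the tilt duration gives the triangle area A*T/2.
    """
    auc_targets = dict(DEFAULT_AUC_TARGETS if auc_targets is None else auc_targets)
    rise_min = dict(DEFAULT_RISE_MIN if rise_min is None else rise_min)
    recovery_tau_min = dict(DEFAULT_RECOVERY_TAU_MIN if recovery_tau_min is None
                            else recovery_tau_min)
    templates = {}
    for (group, signal), auc in auc_targets.items():
        r = rise_min[(group, signal)]
        if r >= 2.0 * tilt_duration_min:
            raise ValidationError("rise time must be shorter than twice the tilt")
        denom = tilt_duration_min - r / 2.0
        amplitude = auc / denom
        if auc != 0 and amplitude <= 0:
            raise ValidationError(
                f"non-positive implied amplitude for {group}/{signal}")
        templates[(group, signal)] = TrajectoryTemplate(
            signal=signal, group=group, amplitude_um=amplitude, rise_min=r,
            recovery_tau_min=recovery_tau_min[group])
    return templates


@dataclass(frozen=True)
class NoiseModel:
    """Measurement / between-subject dispersion of the generator.

    The study reports no noise model; these are artifact choices.
    ``intensity_cv`` is the multiplicative Gaussian coefficient of
    variation of the detected intensity; ``amplitude_sigma`` the lognormal
    sigma of the per-subject, per-signal trajectory scale factor;
    ``reference_sigma_pct`` the additive Gaussian noise (in % units) of
    the reference oximeter trace; ``hr_sigma_bpm`` the spread of the
    heart-rate summaries about their group centres.
    """

    intensity_cv: float = 0.005
    amplitude_sigma: float = 0.10
    reference_sigma_pct: float = 0.2
    hr_sigma_bpm: float = 2.0

    def __post_init__(self) -> None:
        for v in (self.intensity_cv, self.amplitude_sigma,
                  self.reference_sigma_pct, self.hr_sigma_bpm):
            if v < 0:
                raise ValidationError("noise dispersions must be >= 0")

    @classmethod
    def noiseless(cls) -> "NoiseModel":
        return cls(0.0, 0.0, 0.0, 0.0)


@dataclass(frozen=True)
class CohortSpec:
    """Everything needed to generate a cohort deterministically."""

    n_per_group: int = 6
    sample_rate_hz: float = 1.0
    seed: int = 42
    templates: dict = None
    noise: NoiseModel = NoiseModel()
    protocol: ProtocolDefinition = ProtocolDefinition()
    path: PathlengthSpec = PathlengthSpec()
    hr_centers: dict = None
    reference_scale_pct_per_um: float = 2.0
    reference_offset_pct: float = 0.0

    def __post_init__(self) -> None:
        if self.n_per_group < 2:
            raise ValidationError("need at least 2 subjects per group")
        if self.templates is None:
            object.__setattr__(self, "templates", calibrate_templates())
        if self.hr_centers is None:
            object.__setattr__(self, "hr_centers", dict(DEFAULT_HR_CENTERS))

    def extinction(self) -> ExtinctionTable:
        return ExtinctionTable.default()


@dataclass
class SyntheticSubject:
    """One generated subject: raw recording, metadata, reference trace and
    the noise-free ground-truth trajectories."""

    record: SubjectRecord
    recording: RawRecording
    reference_time_s: np.ndarray
    reference_pct: np.ndarray
    truth: ConcentrationSeries
    seed_key: tuple[int, ...]


def _subject_rng(spec: CohortSpec, group: str, index: int) -> tuple[np.random.Generator, tuple]:
    key = (int(spec.seed), 0 if group == "POTS" else 1, int(index))
    return np.random.default_rng(np.random.SeedSequence(key)), key


def generate_subject(spec: CohortSpec, group: str, index: int) -> SyntheticSubject:
    """Generate one subject's raw data deterministically.

    The forward model: true dC trajectories = template x per-subject
    lognormal amplitude factor; dA via the Beer-Lambert design with the
    spec's extinction table and pathlengths; intensities
    I = I_o * 10**(-dA) with multiplicative Gaussian noise, independently
    for the two detectors.  The reference trace is an affine map of the
    true dOxy plus additive noise.  Heart-rate summaries are drawn around
    the group centres.
    """
    if group not in ("POTS", "control"):
        raise ValidationError(f"unknown group {group!r}")
    rng, key = _subject_rng(spec, group, index)
    proto = spec.protocol
    dt = 1.0 / spec.sample_rate_hz
    time = np.arange(0.0, proto.total_s, dt)
    noise = spec.noise

    amp_hb = float(np.exp(rng.normal(0.0, noise.amplitude_sigma))) if noise.amplitude_sigma else 1.0
    amp_hbo2 = float(np.exp(rng.normal(0.0, noise.amplitude_sigma))) if noise.amplitude_sigma else 1.0
    hb = spec.templates[(group, "hb")].evaluate(time, proto) * amp_hb
    hbo2 = spec.templates[(group, "hbo2")].evaluate(time, proto) * amp_hbo2
    truth = ConcentrationSeries(time=time, dc_hb=hb, dc_hbo2=hbo2,
                                d_oxy=hbo2 - hb, d_bv=hbo2 + hb)

    eps = spec.extinction()
    L = np.array([spec.path.path_cm(w) for w in DEVICE_WAVELENGTHS])
    design = eps.design_matrix() * L[:, None] * 1e-3  # OD per uM
    delta_a = design @ np.vstack([hb, hbo2])          # (3, n)

    i_o = np.array([1.0, 0.9, 1.1])  # arbitrary per-wavelength lamp/gain levels
    clean = i_o[:, None] * 10.0 ** (-delta_a)
    intensity = np.empty((2, 3, time.size))
    for d in range(2):
        factor = (1.0 + rng.normal(0.0, noise.intensity_cv, size=clean.shape)
                  if noise.intensity_cv else 1.0)
        intensity[d] = clean * factor
    baseline = proto.boundaries_s()[0][1:]
    recording = RawRecording(time=time, intensity=intensity,
                             wavelengths=DEVICE_WAVELENGTHS,
                             baseline_window=baseline)

    b0, d0 = spec.hr_centers[group]
    hr_base = float(b0 + rng.normal(0.0, noise.hr_sigma_bpm)) if noise.hr_sigma_bpm else b0
    hr_tilt = float(d0 + rng.normal(0.0, noise.hr_sigma_bpm)) if noise.hr_sigma_bpm else d0
    meta = _printed_metadata(group, index)
    record = SubjectRecord(
        id=f"{'P' if group == 'POTS' else 'C'}{index + 1:02d}", group=group,
        age=meta["age"], sex=meta["sex"], height_cm=meta["height_cm"],
        weight_kg=meta["weight_kg"], hr_baseline_max=hr_base, hr_tilt_max=hr_tilt)

    ref = (spec.reference_scale_pct_per_um * truth.d_oxy
           + spec.reference_offset_pct)
    if noise.reference_sigma_pct:
        ref = ref + rng.normal(0.0, noise.reference_sigma_pct, size=ref.size)
    return SyntheticSubject(record=record, recording=recording,
                            reference_time_s=time.copy(), reference_pct=ref,
                            truth=truth, seed_key=key)


def _printed_metadata(group: str, index: int) -> dict:
    """Cycle biometrics from the packaged subject tables."""
    members = [s for s in load_printed_subjects() if s.group == group]
    s = members[index % len(members)]
    return {"age": s.age, "sex": s.sex, "height_cm": s.height_cm,
            "weight_kg": s.weight_kg}


@dataclass
class Cohort:
    spec: CohortSpec
    subjects: list[SyntheticSubject]

    def by_group(self, group: str) -> list[SyntheticSubject]:
        return [s for s in self.subjects if s.record.group == group]


def generate_cohort(spec: CohortSpec | None = None,
                    out_dir: str | Path | None = None) -> Cohort:
    """Generate the full two-group cohort; optionally write per-subject
    files and a manifest to ``out_dir``.

    Per-subject seeds derive deterministically from the master seed, so a
    fixed master seed reproduces every file bit for bit.
    """
    spec = spec or CohortSpec()
    subjects = [generate_subject(spec, group, i)
                for group in ("POTS", "control")
                for i in range(spec.n_per_group)]
    cohort = Cohort(spec=spec, subjects=subjects)
    if out_dir is not None:
        write_cohort(cohort, out_dir)
    return cohort


def write_cohort(cohort: Cohort, out_dir: str | Path) -> Path:
    """Write recordings, reference traces, subject metadata and a manifest."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    meta_rows = []
    file_hashes = {}
    for s in cohort.subjects:
        rec_path = out / f"{s.record.id}_recording.tsv"
        if rec_path.exists():
            raise OSError(f"output collision: {rec_path} already exists")
        df = s.recording.to_frame()
        df.to_csv(rec_path, sep="\t", index=False, float_format="%.9g")
        ref_path = out / f"{s.record.id}_reference.tsv"
        pd.DataFrame({"time_s": s.reference_time_s,
                      "d_oxy_pct": s.reference_pct}).to_csv(
            ref_path, sep="\t", index=False, float_format="%.9g")
        for p in (rec_path, ref_path):
            file_hashes[p.name] = hashlib.sha256(p.read_bytes()).hexdigest()
        meta_rows.append({
            "subject": s.record.id, "group": s.record.group, "age": s.record.age,
            "sex": s.record.sex, "height_cm": s.record.height_cm,
            "weight_kg": s.record.weight_kg,
            "hr_baseline_max": s.record.hr_baseline_max,
            "hr_tilt_max": s.record.hr_tilt_max,
            "seed_key": "-".join(map(str, s.seed_key))})
    meta = pd.DataFrame(meta_rows)
    meta.to_csv(out / "subjects.csv", index=False)
    file_hashes["subjects.csv"] = hashlib.sha256(
        (out / "subjects.csv").read_bytes()).hexdigest()
    noise = cohort.spec.noise
    manifest = {
        "master_seed": cohort.spec.seed,
        "n_per_group": cohort.spec.n_per_group,
        "sample_rate_hz": cohort.spec.sample_rate_hz,
        "noise": {"intensity_cv": noise.intensity_cv,
                  "amplitude_sigma": noise.amplitude_sigma,
                  "reference_sigma_pct": noise.reference_sigma_pct,
                  "hr_sigma_bpm": noise.hr_sigma_bpm},
        "templates": {f"{g}/{sig}": {"amplitude_um": t.amplitude_um,
                                     "rise_min": t.rise_min,
                                     "recovery_tau_min": t.recovery_tau_min}
                      for (g, sig), t in cohort.spec.templates.items()},
        "template_version": "auc-calibrated-v1",
        "subject_seeds": [list(s.seed_key) for s in cohort.subjects],
        "files": file_hashes,
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return out
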