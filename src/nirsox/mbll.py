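"""Modified Beer-Lambert inversion for three-wavelength reflectance oximetry.

A continuous-wave reflectance probe measures detected intensity ``I(t)`` at
735, 805 and 850 nm.  The change in optical attenuation relative to a
baseline window,

    dA(lambda, t) = -log10( I(lambda, t) / I_o(lambda) ),

is linear in the changes of chromophore concentration (modified
Beer-Lambert law):

    dA(lambda, t) = L(lambda) * [ eps_Hb(lambda) dC_Hb(t)
                                  + eps_HbO2(lambda) dC_HbO2(t) ],

with ``L`` the mean optical path length (differential pathlength factor
times source-detector separation) and ``eps`` the molar extinction
coefficients.  Three wavelengths and two chromophores give an
over-determined linear system per time point, solved by ordinary least
squares.  Derived signals are the oxygenation change
``dOxy = dC_HbO2 - dC_Hb`` and the blood-volume surrogate
``dBV = dC_HbO2 + dC_Hb``.

All attenuations are decadic (optical-density convention), paired with
decadic extinction coefficients, so the log base cancels out of the
recovered concentrations.  Concentrations are reported in uM.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from importlib import resources

import numpy as np
import pandas as pd

from .exceptions import DataError, NumericalError, ValidationError

#: The three wavelengths of the probe: Hb absorption peak region, the
#: Hb/HbO2 isosbestic point, and the HbO2-dominated band.
DEVICE_WAVELENGTHS: tuple[float, ...] = (735.0, 805.0, 850.0)

#: Signal column names used throughout the package.
SIGNALS: tuple[str, ...] = ("dc_hb", "dc_hbo2", "d_oxy", "d_bv")


@dataclass(frozen=True)
class ExtinctionTable:
    """Molar extinction coefficients of Hb and HbO2 versus wavelength.

    Units are cm^-1 mM^-1 (decadic).  The table must cover the three device
    wavelengths, and 805 nm must be the near-isosbestic one: the absolute
    Hb/HbO2 difference there must be the smallest of the three.
    """

    wavelengths: np.ndarray
    eps_hb: np.ndarray
    eps_hbo2: np.ndarray

    def __post_init__(self) -> None:
        wl = np.asarray(self.wavelengths, dtype=float)
        hb = np.asarray(self.eps_hb, dtype=float)
        hbo2 = np.asarray(self.eps_hbo2, dtype=float)
        object.__setattr__(self, "wavelengths", wl)
        object.__setattr__(self, "eps_hb", hb)
        object.__setattr__(self, "eps_hbo2", hbo2)
        if wl.shape != hb.shape or wl.shape != hbo2.shape:
            raise ValidationError("wavelengths and coefficient arrays must align")
        if np.any(hb <= 0) or np.any(hbo2 <= 0):
            raise ValidationError("extinction coefficients must be positive")
        missing = [w for w in DEVICE_WAVELENGTHS if w not in wl]
        if missing:
            raise ValidationError(f"extinction table missing device wavelengths: {missing}")
        diffs = {w: abs(self.eps_at(w)[0] - self.eps_at(w)[1]) for w in DEVICE_WAVELENGTHS}
        if min(diffs, key=diffs.get) != 805.0:
            raise ValidationError(
                "805 nm must be the near-isosbestic wavelength (smallest |eps_Hb - eps_HbO2|)"
            )

    def eps_at(self, wavelength: float) -> tuple[float, float]:
        """Return ``(eps_Hb, eps_HbO2)`` at an exact tabulated wavelength."""
        idx = np.nonzero(self.wavelengths == wavelength)[0]
        if idx.size == 0:
            raise ValidationError(f"wavelength {wavelength} nm not in extinction table")
        i = int(idx[0])
        return float(self.eps_hb[i]), float(self.eps_hbo2[i])

    def design_matrix(self, wavelengths=DEVICE_WAVELENGTHS) -> np.ndarray:
        """(n_wavelengths, 2) matrix of [eps_Hb, eps_HbO2] rows."""
        rows = [self.eps_at(w) for w in wavelengths]
        return np.asarray(rows, dtype=float)

    @classmethod
    def from_tsv(cls, path) -> "ExtinctionTable":
        df = pd.read_csv(path, sep="\t", comment="#")
        return cls(
            wavelengths=df["wavelength_nm"].to_numpy(float),
            eps_hb=df["eps_hb"].to_numpy(float),
            eps_hbo2=df["eps_hbo2"].to_numpy(float),
        )

    @classmethod
    def default(cls) -> "ExtinctionTable":
        """The packaged hemoglobin extinction table."""
        ref = resources.files("nirsox.data") / "extinction_hemoglobin.tsv"
        with resources.as_file(ref) as path:
            return cls.from_tsv(path)


@dataclass(frozen=True)
class PathlengthSpec:
    """Effective optical path length L = DPF x source-detector separation.

    ``dpf`` may be a scalar (shared across wavelengths, the default 4.0 is a
    literature value for muscle) or a mapping wavelength -> DPF, e.g. from a
    Monte Carlo pathlength estimate.
    """

    separation_cm: float = 2.0
    dpf: float | dict[float, float] = 4.0

    def path_cm(self, wavelength: float) -> float:
        dpf = self.dpf[wavelength] if isinstance(self.dpf, dict) else self.dpf
        L = dpf * self.separation_cm
        if L <= 0:
            raise ValidationError(f"non-positive optical path length at {wavelength} nm")
        return L


@dataclass
class RawRecording:
    """Raw detected-intensity time series for one subject.

    ``intensity`` has shape (n_detectors, n_wavelengths, n_samples) in
    arbitrary linear units; wavelength order follows ``wavelengths``.
    ``baseline_window`` is the (t_start, t_end) interval in seconds whose
    mean intensity defines the incident reference I_o.
    """

    time: np.ndarray
    intensity: np.ndarray
    wavelengths: tuple[float, ...] = DEVICE_WAVELENGTHS
    detectors: tuple[str, ...] = ("D1", "D2")
    baseline_window: tuple[float, float] = (0.0, 600.0)

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.intensity.ndim == 2:  # single detector convenience
            self.intensity = self.intensity[None, :, :]
        nd, nw, nt = self.intensity.shape
        if nt != self.time.size:
            raise ValidationError("intensity and time lengths differ")
        if nw != len(self.wavelengths):
            raise ValidationError("intensity wavelength axis does not match wavelengths")
        if np.any(np.diff(self.time) <= 0):
            raise ValidationError("time must be strictly increasing")
        for w in DEVICE_WAVELENGTHS:
            if w not in self.wavelengths:
                raise ValidationError(f"recording missing {w} nm channel")

    @property
    def sample_rate(self) -> float:
        return 1.0 / float(np.median(np.diff(self.time)))

    def to_frame(self) -> pd.DataFrame:
        """Tidy long-format view (time_s, detector, wavelength_nm, intensity)."""
        nd, nw, nt = self.intensity.shape
        frames = []
        for d in range(nd):
            for w in range(nw):
                frames.append(pd.DataFrame({
                    "time_s": self.time,
                    "detector": self.detectors[d],
                    "wavelength_nm": self.wavelengths[w],
                    "intensity": self.intensity[d, w],
                }))
        return pd.concat(frames, ignore_index=True)

    @classmethod
    def from_frame(cls, df: pd.DataFrame, baseline_window=(0.0, 600.0)) -> "RawRecording":
        detectors = tuple(sorted(df["detector"].unique()))
        wavelengths = tuple(sorted(df["wavelength_nm"].unique()))
        time = np.sort(df["time_s"].unique())
        inten = np.empty((len(detectors), len(wavelengths), time.size))
        for i, d in enumerate(detectors):
            for j, w in enumerate(wavelengths):
                sub = df[(df["detector"] == d) & (df["wavelength_nm"] == w)]
                sub = sub.sort_values("time_s")
                if len(sub) != time.size:
                    raise DataError(f"ragged channel: detector {d}, {w} nm")
                inten[i, j] = sub["intensity"].to_numpy(float)
        return cls(time=time, intensity=inten, wavelengths=wavelengths,
                   detectors=detectors, baseline_window=baseline_window)


@dataclass
class AttenuationSeries:
    """Change in attenuation dA(t) per wavelength (decadic optical density)."""

    time: np.ndarray
    delta_a: np.ndarray  # shape (n_wavelengths, n_samples)
    wavelengths: tuple[float, ...] = DEVICE_WAVELENGTHS


@dataclass
class ConcentrationSeries:
    """Chromophore concentration-change time series in uM.

    ``d_oxy``/``d_bv`` are populated by :func:`derive_oxy_bv`; ``residual``
    is the per-time-point least-squares residual norm (OD units), a data
    quality indicator.
    """

    time: np.ndarray
    dc_hb: np.ndarray
    dc_hbo2: np.ndarray
    d_oxy: np.ndarray | None = None
    d_bv: np.ndarray | None = None
    residual: np.ndarray | None = None

    def signal(self, name: str) -> np.ndarray:
        arr = getattr(self, name)
        if arr is None:
            raise ValidationError(f"signal {name!r} not populated")
        return arr

    def slice(self, start: int, stop: int) -> "ConcentrationSeries":
        pick = lambda a: None if a is None else a[start:stop]
        return ConcentrationSeries(
            time=self.time[start:stop], dc_hb=self.dc_hb[start:stop],
            dc_hbo2=self.dc_hbo2[start:stop], d_oxy=pick(self.d_oxy),
            d_bv=pick(self.d_bv), residual=pick(self.residual))

    def to_frame(self) -> pd.DataFrame:
        cols = {"time_s": self.time, "dc_hb_um": self.dc_hb, "dc_hbo2_um": self.dc_hbo2}
        if self.d_oxy is not None:
            cols["d_oxy_um"] = self.d_oxy
        if self.d_bv is not None:
            cols["d_bv_um"] = self.d_bv
        if self.residual is not None:
            cols["residual_od"] = self.residual
        return pd.DataFrame(cols)


def delta_attenuation(rec: RawRecording, detector: str = "mean") -> AttenuationSeries:
    """Convert raw intensities to attenuation changes dA = -log10(I/I_o).

    I_o is the mean intensity over the recording's baseline window, per
    detector and wavelength.  ``detector`` selects a named detector or
    ``"mean"`` to average the attenuation of all detectors (log domain, so
    multiplicative gain differences between detectors cancel).
    """
    t0, t1 = rec.baseline_window
    mask = (rec.time >= t0) & (rec.time < t1)
    if mask.sum() < 2:
        raise ValidationError("baseline window must contain at least 2 samples")
    if np.any(rec.intensity <= 0):
        bad = int(np.argwhere(rec.intensity <= 0)[0][-1])
        raise DataError(f"non-positive intensity at sample index {bad}")
    i_o = rec.intensity[:, :, mask].mean(axis=2)  # (n_det, n_wl)
    da = -np.log10(rec.intensity / i_o[:, :, None])
    if detector == "mean":
        da = da.mean(axis=0)
    else:
        if detector not in rec.detectors:
            raise ValidationError(f"unknown detector {detector!r}")
        da = da[rec.detectors.index(detector)]
    # restrict to the device wavelengths, in canonical order
    order = [rec.wavelengths.index(w) for w in DEVICE_WAVELENGTHS]
    return AttenuationSeries(time=rec.time, delta_a=da[order],
                             wavelengths=DEVICE_WAVELENGTHS)


def solve_concentrations(att: AttenuationSeries, eps: ExtinctionTable,
                         path: PathlengthSpec) -> ConcentrationSeries:
    """Invert the three-wavelength attenuation system for (dC_Hb, dC_HbO2).

    Per time point the system  dA_i = L_i (eps_Hb,i dC_Hb + eps_HbO2,i dC_HbO2)
    (three equations, two unknowns) is solved by ordinary least squares;
    the residual 2-norm per time point is reported.  Output is in uM
    (extinction in cm^-1 mM^-1, L in cm, hence a factor 1e-3 in the design).
    """
    if tuple(att.wavelengths) != DEVICE_WAVELENGTHS:
        raise ValidationError("attenuation series must carry the three device wavelengths")
    L = np.array([path.path_cm(w) for w in DEVICE_WAVELENGTHS])
    design = eps.design_matrix() * L[:, None] * 1e-3  # OD per uM
    cond = np.linalg.cond(design)
    if not np.isfinite(cond) or cond > 1e8:
        raise NumericalError(f"extinction design matrix is rank deficient (cond={cond:.3g})")
    # one pseudo-inverse applied to every time point
    sol, *_ = np.linalg.lstsq(design, att.delta_a, rcond=None)
    resid = np.linalg.norm(design @ sol - att.delta_a, axis=0)
    return ConcentrationSeries(time=att.time, dc_hb=sol[0], dc_hbo2=sol[1],
                               residual=resid)


def derive_oxy_bv(conc: ConcentrationSeries) -> ConcentrationSeries:
    """Fill the oxygenation change dOxy = dC_HbO2 - dC_Hb and blood-volume
    surrogate dBV = dC_HbO2 + dC_Hb (both uM).

    Negative dOxy means oxygen is consumed faster than it is supplied.
    """
    return replace(conc, d_oxy=conc.dc_hbo2 - conc.dc_hb,
                   d_bv=conc.dc_hbo2 + conc.dc_hb)


def process_recording(rec: RawRecording, eps: ExtinctionTable | None = None,
                      path: PathlengthSpec | None = None,
                      detector: str = "mean") -> ConcentrationSeries:
    """Full single-subject chain: attenuation -> concentrations -> dOxy/dBV."""
    eps = eps or ExtinctionTable.default()
    path = path or PathlengthSpec()
    att = delta_attenuation(rec, detector=detector)
    return derive_oxy_bv(solve_concentrations(att, eps, path))
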