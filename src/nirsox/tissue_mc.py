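"""Weighted Monte Carlo photon transport in layered tissue.

Standard hop-drop-spin transport for a collimated pencil beam normally
incident on a stack of plane-parallel layers (the last one semi-infinite):
exponential step sampling on the total interaction coefficient, fractional
weight deposition mu_a/mu_t per interaction, Henyey-Greenstein scattering,
unpolarised Fresnel reflection/refraction at every refractive-index
boundary, and Russian-roulette termination of low-weight photons.  Beyond
the textbook estimator the kernel records, for every photon that escapes
through the surface into a detector aperture, its survival weight, exit
radius, maximum depth reached, and geometric path length per layer - the
quantities needed to choose a source-detector separation (penetration
depth vs signal) and to estimate the differential pathlength factor used
by the Beer-Lambert inversion.

Geometry: z = 0 at the tissue surface, increasing downward (mm
internally); detectors are circular apertures on the surface centred at
the given separations from the source.  Because the problem is
rotationally symmetric about the source axis, detection uses exact
azimuthal averaging: an escaping photon at exit radius rho contributes to
a detector the fraction of the circle of radius rho that falls inside the
aperture.  This is the expectation of the Bernoulli hit variable and
lowers variance by roughly (2 pi d / 2a) without bias.

The Russian-roulette weight ledger is exact per run: weight removed by a
kill, and the (negative) weight injected by a survival boost, are both
booked against the absorbed total, so

    reflected + transmitted + absorbed = launched

holds to floating-point accumulation error for every seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from numba import njit

from .exceptions import InsufficientStatisticsError, ValidationError

#: Russian-roulette parameters: threshold weight and survival probability.
ROULETTE_THRESHOLD = 1e-4
ROULETTE_SURVIVE = 0.1

#: Depth (mm) at which photons in the semi-infinite layer are scored as
#: transmitted; far below any depth that can return to a surface detector.
DEFAULT_KILL_DEPTH_MM = 200.0


@dataclass(frozen=True)
class OpticalLayer:
    """One plane-parallel tissue layer.

    ``mu_a``/``mu_s`` (mm^-1) may be scalars or mappings wavelength(nm) ->
    value.  ``thickness_mm`` of None marks the semi-infinite final layer.
    """

    mu_a: float | dict[float, float]
    mu_s: float | dict[float, float]
    g: float
    n: float
    thickness_mm: float | None = None
    name: str = ""

    def __post_init__(self) -> None:
        if not (-1.0 < self.g < 1.0):
            raise ValidationError(f"anisotropy g={self.g} outside (-1, 1)")
        if self.n < 1.0:
            raise ValidationError(f"refractive index n={self.n} below 1")
        if self.thickness_mm is not None and self.thickness_mm <= 0:
            raise ValidationError("layer thickness must be positive")

    @property
    def semi_infinite(self) -> bool:
        return self.thickness_mm is None

    def _resolve(self, coeff, wavelength: float, what: str) -> float:
        if isinstance(coeff, dict):
            if wavelength not in coeff:
                raise ValidationError(
                    f"{what} undefined at {wavelength} nm for layer {self.name!r}")
            v = float(coeff[wavelength])
        else:
            v = float(coeff)
        if v < 0:
            raise ValidationError(f"negative {what} in layer {self.name!r}")
        return v

    def properties_at(self, wavelength: float) -> tuple[float, float]:
        return (self._resolve(self.mu_a, wavelength, "mu_a"),
                self._resolve(self.mu_s, wavelength, "mu_s"))


@dataclass(frozen=True)
class TissueModel:
    """Ordered stack of layers from the surface downward."""

    layers: tuple[OpticalLayer, ...]
    n_ambient: float = 1.0

    def __post_init__(self) -> None:
        if len(self.layers) < 1:
            raise ValidationError("model needs at least one layer")
        for lay in self.layers[:-1]:
            if lay.semi_infinite:
                raise ValidationError("only the last layer may be semi-infinite")
        if not self.layers[-1].semi_infinite:
            raise ValidationError("last layer must be semi-infinite")

    def arrays_at(self, wavelength: float, kill_depth_mm: float):
        """Per-layer (lower boundary z, mu_a, mu_s, g, n) arrays in mm."""
        n_lay = len(self.layers)
        zb = np.empty(n_lay)
        mua = np.empty(n_lay)
        mus = np.empty(n_lay)
        g = np.empty(n_lay)
        nidx = np.empty(n_lay)
        z = 0.0
        for i, lay in enumerate(self.layers):
            mua[i], mus[i] = lay.properties_at(wavelength)
            if mua[i] + mus[i] <= 0:
                raise ValidationError(
                    f"zero total interaction coefficient in layer {lay.name!r}")
            g[i], nidx[i] = lay.g, lay.n
            z = kill_depth_mm if lay.semi_infinite else z + lay.thickness_mm
            zb[i] = z
        return zb, mua, mus, g, nidx


@dataclass(frozen=True)
class ProbeGeometry:
    """Surface source and detector apertures.

    The source is a collimated pencil beam at the origin, normal to the
    surface; detectors are circular apertures of ``detector_radius_mm``
    centred at ``detector_separations_cm`` from the source (centre to
    centre on the surface), accepting all exit angles.
    """

    detector_separations_cm: tuple[float, ...] = (2.0,)
    detector_radius_mm: float = 1.5

    def __post_init__(self) -> None:
        seps = tuple(float(s) for s in self.detector_separations_cm)
        object.__setattr__(self, "detector_separations_cm", seps)
        if len(seps) < 1:
            raise ValidationError("at least one detector separation required")
        if self.detector_radius_mm <= 0:
            raise ValidationError("detector radius must be positive")
        a = self.detector_radius_mm
        for s in seps:
            if s * 10.0 <= a:
                raise ValidationError(
                    f"detector at {s} cm overlaps the source (radius {a} mm)")
        for i, si in enumerate(seps):
            for sj in seps[i + 1:]:
                d = abs(si - sj) * 10.0
                if 0.0 < d < 2.0 * a:
                    raise ValidationError(
                        f"detector apertures at {si} and {sj} cm overlap")


@dataclass
class DetectorHits:
    """Per-detector record of escaped photons (cm for radii/depths, mm for
    paths; weights are azimuthally averaged survival weights)."""

    separation_cm: float
    exit_weight: np.ndarray
    exit_radius_cm: np.ndarray
    max_depth_cm: np.ndarray
    partial_path_mm: np.ndarray  # (n_detected, n_layers)

    @property
    def n_detected(self) -> int:
        return int(self.exit_weight.size)

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame({
            "exit_weight": self.exit_weight,
            "exit_radius_cm": self.exit_radius_cm,
            "max_depth_cm": self.max_depth_cm,
        })
        for j in range(self.partial_path_mm.shape[1]):
            df[f"path_layer{j}_mm"] = self.partial_path_mm[:, j]
        return df


@dataclass
class MCSummary:
    """Outcome of one simulation run."""

    n_launched: int
    seed: int
    wavelength: float
    total_reflected: float
    total_transmitted: float
    total_absorbed: float
    detected: list[DetectorHits]
    fluence_grid: np.ndarray          # (n_r, n_z) deposited weight
    grid_dr_mm: float
    grid_dz_mm: float
    reflectance_r_mm: np.ndarray      # annulus centres
    reflectance_per_mm2: np.ndarray   # escaping weight / area / photon
    geometry: ProbeGeometry | None = None

    @property
    def conservation_error(self) -> float:
        total = self.total_reflected + self.total_transmitted + self.total_absorbed
        return abs(total - self.n_launched) / self.n_launched


@njit(cache=True)
def _fresnel(n1, n2, cos_i):
    """Unpolarised Fresnel reflectance for incidence cosine cos_i (n1 -> n2)."""
    if n1 == n2:
        return 0.0
    sin_i2 = 1.0 - cos_i * cos_i
    sin_t2 = (n1 / n2) * (n1 / n2) * sin_i2
    if sin_t2 >= 1.0:
        return 1.0
    cos_t = math.sqrt(1.0 - sin_t2)
    rs = (n1 * cos_i - n2 * cos_t) / (n1 * cos_i + n2 * cos_t)
    rp = (n1 * cos_t - n2 * cos_i) / (n1 * cos_t + n2 * cos_i)
    return 0.5 * (rs * rs + rp * rp)


@njit(cache=True)
def _arc_fraction(rho, d, a):
    """Fraction of the circle of radius rho (about the source) lying inside
    a circular aperture of radius a centred at distance d."""
    if rho <= 0.0:
        return 1.0 if d <= a else 0.0
    if rho + d <= a:
        return 1.0
    if abs(rho - d) >= a:
        return 0.0
    c = (rho * rho + d * d - a * a) / (2.0 * rho * d)
    if c > 1.0:
        c = 1.0
    elif c < -1.0:
        c = -1.0
    return math.acos(c) / math.pi


@njit(cache=True)
def _transport(n_photons, seed, zb, mua, mus, g_arr, n_arr, n_ambient,
               det_sep_mm, det_rad_mm, fluence, dr, dz,
               refl_prof, refl_dr,
               det_w, det_rho, det_zmax, det_paths, det_count):
    np.random.seed(seed)
    n_lay = mua.shape[0]
    n_det = det_sep_mm.shape[0]
    n_r = fluence.shape[0]
    n_z = fluence.shape[1]
    n_refl = refl_prof.shape[0]
    total_refl = 0.0
    total_trans = 0.0
    total_abs = 0.0
    paths = np.zeros(n_lay)
    for _ in range(n_photons):
        # launch: specular loss at the ambient/first-layer interface
        r_sp = _fresnel(n_ambient, n_arr[0], 1.0)
        w = 1.0 - r_sp
        total_refl += r_sp
        x = 0.0
        y = 0.0
        z = 0.0
        ux = 0.0
        uy = 0.0
        uz = 1.0
        layer = 0
        zmax = 0.0
        for j in range(n_lay):
            paths[j] = 0.0
        alive = True
        while alive:
            s_left = -math.log(np.random.random())
            while s_left > 0.0 and alive:
                mut = mua[layer] + mus[layer]
                step = s_left / mut
                # distance to the layer boundary along the flight direction
                if uz > 0.0:
                    db = (zb[layer] - z) / uz
                elif uz < 0.0:
                    z_up = zb[layer - 1] if layer > 0 else 0.0
                    db = (z_up - z) / uz
                else:
                    db = 1.0e30
                if step < db:
                    # hop ends inside the layer: drop + spin
                    x += ux * step
                    y += uy * step
                    z += uz * step
                    paths[layer] += step
                    if z > zmax:
                        zmax = z
                    s_left = 0.0
                    dw = w * mua[layer] / mut
                    w -= dw
                    total_abs += dw
                    ir = int(math.sqrt(x * x + y * y) / dr)
                    iz = int(z / dz)
                    if ir < n_r and 0 <= iz < n_z:
                        fluence[ir, iz] += dw
                    # spin: Henyey-Greenstein polar angle, uniform azimuth
                    g = g_arr[layer]
                    if g != 0.0:
                        tmp = (1.0 - g * g) / (1.0 - g + 2.0 * g * np.random.random())
                        cos_t = (1.0 + g * g - tmp * tmp) / (2.0 * g)
                        if cos_t > 1.0:
                            cos_t = 1.0
                        elif cos_t < -1.0:
                            cos_t = -1.0
                    else:
                        cos_t = 2.0 * np.random.random() - 1.0
                    sin_t = math.sqrt(1.0 - cos_t * cos_t)
                    phi = 2.0 * math.pi * np.random.random()
                    cos_p = math.cos(phi)
                    sin_p = math.sin(phi)
                    if abs(uz) > 0.99999:
                        ux = sin_t * cos_p
                        uy = sin_t * sin_p
                        uz = cos_t if uz > 0.0 else -cos_t
                    else:
                        den = math.sqrt(1.0 - uz * uz)
                        ux_n = sin_t * (ux * uz * cos_p - uy * sin_p) / den + ux * cos_t
                        uy_n = sin_t * (uy * uz * cos_p + ux * sin_p) / den + uy * cos_t
                        uz_n = -sin_t * cos_p * den + uz * cos_t
                        ux, uy, uz = ux_n, uy_n, uz_n
                    norm = math.sqrt(ux * ux + uy * uy + uz * uz)
                    ux /= norm
                    uy /= norm
                    uz /= norm
                    # Russian roulette (exact weight ledger)
                    if w < ROULETTE_THRESHOLD:
                        if np.random.random() < ROULETTE_SURVIVE:
                            boosted = w / ROULETTE_SURVIVE
                            total_abs -= boosted - w
                            w = boosted
                        else:
                            total_abs += w
                            alive = False
                else:
                    # hop hits a boundary
                    x += ux * db
                    y += uy * db
                    z += uz * db
                    paths[layer] += db
                    if z > zmax:
                        zmax = z
                    s_left -= db * mut
                    if uz > 0.0:
                        if layer == n_lay - 1:
                            # deep-kill plane of the semi-infinite layer
                            total_trans += w
                            alive = False
                        else:
                            n1 = n_arr[layer]
                            n2 = n_arr[layer + 1]
                            if np.random.random() < _fresnel(n1, n2, uz):
                                uz = -uz
                            else:
                                if n1 != n2:
                                    sin_t2 = (n1 / n2) * (n1 / n2) * (1.0 - uz * uz)
                                    cos_t = math.sqrt(1.0 - sin_t2)
                                    scale = n1 / n2
                                    ux *= scale
                                    uy *= scale
                                    uz = cos_t
                                layer += 1
                    else:
                        n1 = n_arr[layer]
                        n2 = n_ambient if layer == 0 else n_arr[layer - 1]
                        cos_i = -uz
                        if np.random.random() < _fresnel(n1, n2, cos_i):
                            uz = -uz
                        else:
                            if layer == 0:
                                # escapes through the surface
                                total_refl += w
                                rho = math.sqrt(x * x + y * y)
                                ib = int(rho / refl_dr)
                                if ib < n_refl:
                                    refl_prof[ib] += w
                                for d in range(n_det):
                                    frac = _arc_fraction(rho, det_sep_mm[d],
                                                         det_rad_mm)
                                    if frac > 0.0:
                                        k = det_count[d]
                                        if k < det_w.shape[1]:
                                            det_w[d, k] = w * frac
                                            det_rho[d, k] = rho
                                            det_zmax[d, k] = zmax
                                            for j in range(n_lay):
                                                det_paths[d, k, j] = paths[j]
                                            det_count[d] = k + 1
                                alive = False
                            else:
                                if n1 != n2:
                                    sin_t2 = (n1 / n2) * (n1 / n2) * (1.0 - uz * uz)
                                    cos_t = math.sqrt(1.0 - sin_t2)
                                    scale = n1 / n2
                                    ux *= scale
                                    uy *= scale
                                    uz = -cos_t
                                layer -= 1
    return total_refl, total_trans, total_abs


def simulate(model: TissueModel, geometry: ProbeGeometry | None = None,
             n_photons: int = 1_000_000, wavelength: float = 805.0,
             seed: int = 0, *, grid_dr_mm: float = 0.1, grid_dz_mm: float = 0.1,
             grid_r_max_mm: float = 40.0, grid_z_max_mm: float = 20.0,
             refl_bin_mm: float = 0.5, refl_r_max_mm: float = 40.0,
             kill_depth_mm: float = DEFAULT_KILL_DEPTH_MM) -> MCSummary:
    """Run the photon transport and score detectors, fluence and the radial
    diffuse-reflectance profile.

    Identical inputs and seed give bit-identical output (single-threaded,
    sequential photon stream).
    """
    geometry = geometry or ProbeGeometry()
    if n_photons < 1:
        raise ValidationError("n_photons must be >= 1")
    zb, mua, mus, g_arr, n_arr = model.arrays_at(wavelength, kill_depth_mm)
    det_sep_mm = np.asarray(geometry.detector_separations_cm, float) * 10.0
    n_det = det_sep_mm.size
    n_r = int(round(grid_r_max_mm / grid_dr_mm))
    n_z = int(round(grid_z_max_mm / grid_dz_mm))
    fluence = np.zeros((n_r, n_z))
    n_refl = int(round(refl_r_max_mm / refl_bin_mm))
    refl_prof = np.zeros(n_refl)
    cap = n_photons
    det_w = np.zeros((n_det, cap))
    det_rho = np.zeros((n_det, cap))
    det_zmax = np.zeros((n_det, cap))
    det_paths = np.zeros((n_det, cap, len(model.layers)))
    det_count = np.zeros(n_det, dtype=np.int64)
    total_refl, total_trans, total_abs = _transport(
        n_photons, seed, zb, mua, mus, g_arr, n_arr, model.n_ambient,
        det_sep_mm, geometry.detector_radius_mm, fluence,
        grid_dr_mm, grid_dz_mm, refl_prof, refl_bin_mm,
        det_w, det_rho, det_zmax, det_paths, det_count)
    detected = []
    for d in range(n_det):
        k = int(det_count[d])
        detected.append(DetectorHits(
            separation_cm=float(geometry.detector_separations_cm[d]),
            exit_weight=det_w[d, :k].copy(),
            exit_radius_cm=det_rho[d, :k].copy() / 10.0,
            max_depth_cm=det_zmax[d, :k].copy() / 10.0,
            partial_path_mm=det_paths[d, :k, :].copy()))
    r_edges = np.arange(n_refl + 1) * refl_bin_mm
    areas = np.pi * (r_edges[1:] ** 2 - r_edges[:-1] ** 2)
    return MCSummary(
        n_launched=n_photons, seed=seed, wavelength=wavelength,
        total_reflected=total_refl, total_transmitted=total_trans,
        total_absorbed=total_abs, detected=detected, fluence_grid=fluence,
        grid_dr_mm=grid_dr_mm, grid_dz_mm=grid_dz_mm,
        reflectance_r_mm=0.5 * (r_edges[:-1] + r_edges[1:]),
        reflectance_per_mm2=refl_prof / areas / n_photons,
        geometry=geometry)


@dataclass(frozen=True)
class DepthStats:
    median_cm: float
    mean_cm: float
    p95_cm: float
    n_detected: int
    total_weight: float


def _weighted_quantile(values: np.ndarray, weights: np.ndarray, q: float) -> float:
    order = np.argsort(values)
    v = values[order]
    cw = np.cumsum(weights[order])
    return float(np.interp(q * cw[-1], cw, v))


def _require_hits(summary: MCSummary, detector_index: int,
                  minimum: int = 100) -> DetectorHits:
    hits = summary.detected[detector_index]
    if hits.n_detected < minimum:
        raise InsufficientStatisticsError(
            f"detector {detector_index}: only {hits.n_detected} detected photons "
            f"(need >= {minimum})")
    return hits


def penetration_stats(summary: MCSummary, detector_index: int = 0,
                      min_detected: int = 100) -> DepthStats:
    """Exit-weight-weighted statistics of the maximum depth (cm) reached by
    photons detected at one aperture."""
    hits = _require_hits(summary, detector_index, minimum=min_detected)
    w = hits.exit_weight
    depth = hits.max_depth_cm
    return DepthStats(
        median_cm=_weighted_quantile(depth, w, 0.5),
        mean_cm=float(np.average(depth, weights=w)),
        p95_cm=_weighted_quantile(depth, w, 0.95),
        n_detected=hits.n_detected,
        total_weight=float(w.sum()))


@dataclass(frozen=True)
class PathlengthStats:
    total_mm: float
    per_layer_mm: np.ndarray
    dpf: float


def mean_pathlength(summary: MCSummary, detector_index: int = 0,
                    min_detected: int = 100) -> PathlengthStats:
    """Weight-averaged optical path length of detected photons, per layer
    and total, plus the differential pathlength factor
    DPF = mean path / source-detector separation."""
    hits = _require_hits(summary, detector_index, minimum=min_detected)
    w = hits.exit_weight
    per_layer = np.average(hits.partial_path_mm, axis=0, weights=w)
    total = float(per_layer.sum())
    return PathlengthStats(total_mm=total, per_layer_mm=per_layer,
                           dpf=total / (hits.separation_cm * 10.0))


def separation_scan(model: TissueModel, separations_cm, n_photons: int = 1_000_000,
                    seed: int = 0, wavelength: float = 805.0,
                    detector_radius_mm: float = 1.5, **kwargs) -> pd.DataFrame:
    """Score several source-detector separations in a single run.

    One photon stream is shared by all apertures (detection does not absorb
    photons), so results for matching geometry and seed are identical to a
    dedicated single-detector run.
    """
    separations_cm = tuple(float(s) for s in separations_cm)
    if len(separations_cm) < 2:
        raise ValidationError("scan needs at least 2 separations")
    geometry = ProbeGeometry(detector_separations_cm=separations_cm,
                             detector_radius_mm=detector_radius_mm)
    summary = simulate(model, geometry, n_photons=n_photons,
                       wavelength=wavelength, seed=seed, **kwargs)
    rows = []
    for d, sep in enumerate(separations_cm):
        hits = summary.detected[d]
        row = {"separation_cm": sep, "n_detected": hits.n_detected,
               "detected_weight": float(hits.exit_weight.sum())}
        try:
            row["median_depth_cm"] = penetration_stats(summary, d).median_cm
            row["dpf"] = mean_pathlength(summary, d).dpf
        except InsufficientStatisticsError:
            row["median_depth_cm"] = float("nan")
            row["dpf"] = float("nan")
        rows.append(row)
    return pd.DataFrame(rows)


def default_tissue_model(path=None) -> TissueModel:
    """The packaged three-layer calf model (dermis / subdermis / muscle)."""
    from .io import load_tissue_model
    return load_tissue_model(path)
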