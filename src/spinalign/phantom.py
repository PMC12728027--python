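"""Synthetic patients with known ground truth.

Emulates the study acquisition: a standing patient wearing nine
radiopaque skin markers undergoes biplanar radiography, then replicates
the posture in a different room for a 3D back-surface scan.  Each
phantom therefore consists of

* an internal spinal line (ISL) from L5 (y = 0) up to C7
  (y = spine length) with a parametric frontal scoliotic curve (sine or
  single circular arc) and a physiological sagittal double curve with
  prescribed kyphotic and lordotic Cobb angles,
* a spinous process line (SPL) on the skin: the ISL displaced
  posteriorly, with damped frontal amplitude plus a smooth transverse
  skin shift, so the two lines correlate strongly but not perfectly,
* nine named markers on the back surface,
* pixel annotations of markers and ISL in calibrated frontal/lateral
  radiograph frames, and
* a scan bundle (surface point cloud, markers, SPL) expressed in the
  scanner frame, i.e. moved by the inverse of the ground-truth postural
  transform, with Gaussian marker/surface noise.

All Cobb angles of the construction have closed-form values: the
sagittal profile is built from its tangent-angle function, the frontal
sine/arc from its analytic derivative.  A seed fully determines every
stochastic output.
"""

from __future__ import annotations

import datetime
from dataclasses import dataclass, field, replace

import numpy as np
import numpy.typing as npt
from scipy.spatial.transform import Rotation
from scipy.stats import truncnorm

from . import biplanar
from .curves import procrustes_align
from .types import Annotation2D, RadiographFrame, RigidTransform, SpinalignError, View

__all__ = [
    "PhantomSpec",
    "PhantomTruth",
    "ScanBundle",
    "PhantomBundle",
    "generate_phantom",
    "generate_cohort",
    "DEFAULT_COHORT_RANGES",
]

MARKER_NAMES = (
    "C7",
    "L5",
    "PSIS_L",
    "PSIS_R",
    "T7",
    "SCAP_L",
    "SCAP_R",
    "FLANK_L",
    "FLANK_R",
)

_PIXEL_SPACING = (0.2, 0.2)  # mm/px, typical of biplanar slot-scanner output
_MARGIN_MM = 25.0


@dataclass(frozen=True)
class PhantomSpec:
    """Parameters of one synthetic patient.

    ``frontal_amplitude_mm`` is the sine amplitude (``curve_mode="sine"``)
    or the arc sagitta (``curve_mode="arc"``).  The sagittal profile is
    defined by its target kyphotic/lordotic Cobb angles and the
    fractional height of the thoracolumbar junction.  ``spl_offset_mm``
    is the skin-to-spine depth, ``spl_damping`` the transverse
    amplitude ratio of skin over spine, and ``skin_shift_coef`` the
    fraction of the frontal amplitude added as a low-frequency lateral
    skin shift (this is what keeps the frontal SPL-ISL correlation
    below 1).  The postural transform maps scanner -> radiograph frame.
    """

    frontal_amplitude_mm: float = 16.5
    frontal_wavelength_mm: float = 400.0
    curve_mode: str = "sine"  # "sine" | "arc"
    kyphosis_angle_deg: float = 41.0
    lordosis_angle_deg: float = 40.0
    spine_length_mm: float = 450.0
    junction_fraction: float = 0.4
    spl_offset_mm: float = 35.0
    spl_damping: float = 0.55
    skin_shift_coef: float = 0.2
    marker_noise_sd_mm: float = 0.0
    surface_noise_sd_mm: float = 0.0
    postural_transform: RigidTransform = field(default_factory=RigidTransform.identity)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.spine_length_mm <= 0:
            raise SpinalignError("spine_length_mm must be positive")
        for name in (
            "frontal_amplitude_mm",
            "frontal_wavelength_mm",
            "kyphosis_angle_deg",
            "lordosis_angle_deg",
            "marker_noise_sd_mm",
            "surface_noise_sd_mm",
        ):
            if getattr(self, name) < 0:
                raise SpinalignError(f"{name} must be >= 0")
        if self.curve_mode not in ("sine", "arc"):
            raise SpinalignError(f"unknown curve_mode {self.curve_mode!r}")
        if not 0.1 <= self.junction_fraction <= 0.9:
            raise SpinalignError("junction_fraction must lie in [0.1, 0.9]")


@dataclass
class ScanBundle:
    """Back-surface scan content, in the scanner coordinate frame."""

    cloud: npt.NDArray[np.float64]  # (n, 3)
    markers: dict[str, np.ndarray]
    spl_polyline: npt.NDArray[np.float64]  # (m, 3)


@dataclass
class PhantomTruth:
    """Exact ground truth of a phantom, in the radiographic (EOS) frame."""

    isl: npt.NDArray[np.float64]  # dense noiseless ISL polyline
    spl: npt.NDArray[np.float64]  # dense noiseless SPL polyline
    markers_eos: dict[str, np.ndarray]
    markers_scanner: dict[str, np.ndarray]  # noiseless, scanner frame
    cobb_frontal_deg: float
    cobb_kyphotic_deg: float
    cobb_lordotic_deg: float
    pcc_frontal: float | None
    pcc_sagittal: float | None
    postural_transform: RigidTransform


@dataclass
class PhantomBundle:
    spec: PhantomSpec
    truth: PhantomTruth
    frames: dict[View, RadiographFrame]
    annotations: dict[View, Annotation2D]
    scan: ScanBundle


# ---------------------------------------------------------------- curves


class _FrontalCurve:
    """Analytic frontal deviation x(y) with exact derivative."""

    def __init__(self, spec: PhantomSpec):
        self.mode = spec.curve_mode
        self.A = spec.frontal_amplitude_mm
        self.S = spec.spine_length_mm
        if self.mode == "sine":
            self.k = 2 * np.pi / spec.frontal_wavelength_mm
        elif self.A > 0:
            # circular arc of sagitta A over chord S: x = R cos(phi) - R cos(beta)
            self.R = (self.A**2 + (self.S / 2) ** 2) / (2 * self.A)
            self.beta = float(np.arcsin((self.S / 2) / self.R))

    def x(self, y: np.ndarray) -> np.ndarray:
        y = np.asarray(y, dtype=float)
        if self.A == 0:
            return np.zeros_like(y)
        if self.mode == "sine":
            return self.A * np.sin(self.k * y)
        h = y - self.S / 2
        return np.sqrt(self.R**2 - h**2) - self.R * np.cos(self.beta)

    def dx(self, y: np.ndarray) -> np.ndarray:
        y = np.asarray(y, dtype=float)
        if self.A == 0:
            return np.zeros_like(y)
        if self.mode == "sine":
            return self.A * self.k * np.cos(self.k * y)
        h = y - self.S / 2
        return -h / np.sqrt(self.R**2 - h**2)

    def cobb_deg(self) -> float:
        """Largest Cobb angle between consecutive inflection/boundary tangents."""
        if self.A == 0:
            return 0.0
        if self.mode == "arc":
            return float(np.degrees(2 * self.beta))
        half = np.pi / self.k  # half wavelength
        interior = np.arange(1, int(self.S / half) + 1) * half
        interior = interior[(interior > 0) & (interior < self.S)]
        breaks = np.concatenate([[0.0], interior, [self.S]])
        ang = np.degrees(np.arctan(self.dx(breaks)))
        return float(np.max(np.abs(np.diff(ang))))


class _SagittalCurve:
    """Analytic sagittal profile z(y): a C2 double curve.

    Built from its tangent-angle function: the slope runs from
    ``s_L5`` at the bottom through an extremum ``s_T`` at the
    thoracolumbar junction to ``s_C7`` at the top, blended by sin^2
    ramps, so z'' changes sign exactly once (at the junction) and the
    kyphotic/lordotic Cobb angles are exactly the prescribed
    tangent-angle differences.  z points posteriorly; the cranial
    (kyphotic) segment has z'' < 0.
    """

    def __init__(self, spec: PhantomSpec):
        self.S = spec.spine_length_mm
        self.yT = spec.junction_fraction * self.S
        th_k = np.radians(spec.kyphosis_angle_deg)
        th_l = np.radians(spec.lordosis_angle_deg)
        self.flat = spec.kyphosis_angle_deg == 0 and spec.lordosis_angle_deg == 0
        phi_T = th_k / 2  # tangent angle at the junction
        self.s_T = np.tan(phi_T)
        self.s_C7 = np.tan(phi_T - th_k)
        self.s_L5 = np.tan(phi_T - th_l)
        self.a_k = np.pi / (2 * (self.S - self.yT))
        self.a_c = np.pi / (2 * self.yT)

    def z(self, y: np.ndarray) -> np.ndarray:
        y = np.asarray(y, dtype=float)
        if self.flat:
            return np.zeros_like(y)
        out = np.empty_like(y)
        up = y >= self.yT
        u = y[up] - self.yT
        dk = self.s_C7 - self.s_T
        out[up] = self.s_T * u + dk * (u / 2 - np.sin(2 * self.a_k * u) / (4 * self.a_k))
        u = self.yT - y[~up]
        dl = self.s_L5 - self.s_T
        out[~up] = -(self.s_T * u + dl * (u / 2 - np.sin(2 * self.a_c * u) / (4 * self.a_c)))
        return out

    def dz(self, y: np.ndarray) -> np.ndarray:
        y = np.asarray(y, dtype=float)
        if self.flat:
            return np.zeros_like(y)
        out = np.empty_like(y)
        up = y >= self.yT
        out[up] = self.s_T + (self.s_C7 - self.s_T) * np.sin(self.a_k * (y[up] - self.yT)) ** 2
        out[~up] = self.s_T + (self.s_L5 - self.s_T) * np.sin(self.a_c * (self.yT - y[~up])) ** 2
        return out


def _spl_from_isl(spec: PhantomSpec, fc: _FrontalCurve, sc: _SagittalCurve, y: np.ndarray):
    """Skin line: damped frontal copy + low-frequency shift, depth offset."""
    x = spec.spl_damping * fc.x(y) + spec.skin_shift_coef * spec.frontal_amplitude_mm * np.sin(
        np.pi * y / spec.spine_length_mm
    )
    z = sc.z(y) + spec.spl_offset_mm
    return np.column_stack([x, y, z])


def _marker_positions(spec: PhantomSpec, fc: _FrontalCurve, sc: _SagittalCurve) -> dict[str, np.ndarray]:
    S = spec.spine_length_mm

    def on_skin(frac_y: float, dx: float = 0.0, dz: float = 0.0, y_abs: float | None = None):
        y = frac_y * S if y_abs is None else y_abs
        spl = _spl_from_isl(spec, fc, sc, np.array([min(max(y, 0.0), S)]))[0]
        return np.array([spl[0] + dx, y, spl[2] + dz])

    return {
        "C7": on_skin(1.0),
        "L5": on_skin(0.0),
        "PSIS_L": on_skin(0.0, dx=-45.0, dz=-10.0, y_abs=-60.0),
        "PSIS_R": on_skin(0.0, dx=45.0, dz=-10.0, y_abs=-60.0),
        "T7": on_skin(0.55, dz=5.0),
        "SCAP_L": on_skin(0.72, dx=-80.0, dz=-12.0),
        "SCAP_R": on_skin(0.72, dx=80.0, dz=-12.0),
        "FLANK_L": on_skin(0.25, dx=-100.0, dz=-18.0),
        "FLANK_R": on_skin(0.25, dx=100.0, dz=-18.0),
    }


def _build_frames(content: np.ndarray) -> dict[View, RadiographFrame]:
    """Calibrated frames large enough to contain all projected content."""
    lo = content.min(axis=0) - _MARGIN_MM
    hi = content.max(axis=0) + _MARGIN_MM
    s_row, s_col = _PIXEL_SPACING

    def frame(view: View, u_axis: int) -> RadiographFrame:
        cols = int(np.ceil((hi[u_axis] - lo[u_axis]) / s_col)) + 1
        rows = int(np.ceil((hi[1] - lo[1]) / s_row)) + 1
        origin = [0.0, lo[1], 0.0]
        origin[u_axis] = lo[u_axis]
        return RadiographFrame(
            view=view,
            pixel_spacing=_PIXEL_SPACING,
            origin_mm=tuple(origin),
            image_size_px=(rows, cols),
            frame_id=view.value,
        )

    return {View.FRONTAL: frame(View.FRONTAL, 0), View.LATERAL: frame(View.LATERAL, 2)}


def _surface_cloud(spec: PhantomSpec, fc: _FrontalCurve, sc: _SagittalCurve) -> np.ndarray:
    """Back-surface sheet around the SPL: 120 mm wide, flanks curving
    anteriorly, sampled at roughly 5 points/cm^2."""
    half_w = 60.0
    n_y = 108
    n_s = 25
    y = np.linspace(0.0, spec.spine_length_mm, n_y)
    s = np.linspace(-half_w, half_w, n_s)
    spl = _spl_from_isl(spec, fc, sc, y)
    Y, Sg = np.meshgrid(y, s, indexing="ij")
    X = spl[:, 0][:, None] + Sg
    Z = spl[:, 2][:, None] - 18.0 * (Sg / half_w) ** 2
    return np.column_stack([X.ravel(), Y.ravel(), Z.ravel()])


def _truth_pcc(isl: np.ndarray, spl: np.ndarray) -> tuple[float | None, float | None]:
    """Shape correlation of the noiseless construction, per plane.

    Rotation+translation Procrustes of the ISL onto the SPL, then the
    plain Pearson correlation of each plane's coordinate sequences;
    None when exactly one sequence is flat, 1.0 when both are (two
    straight lines agree perfectly in shape).
    """
    aligned, _, _ = procrustes_align(spl, isl)
    out = []
    for idx in (0, 2):
        a, b = spl[:, idx], aligned[:, idx]
        if a.std() < 1e-12 and b.std() < 1e-12:
            out.append(1.0)
        elif a.std() < 1e-12 or b.std() < 1e-12:
            out.append(None)
        else:
            out.append(float(np.corrcoef(a, b)[0, 1]))
    return out[0], out[1]


def generate_phantom(spec: PhantomSpec) -> PhantomBundle:
    """Build one synthetic patient with exact ground truth.

    All randomness (marker and surface noise) is drawn from
    ``spec.seed``; the same spec reproduces identical output bitwise.
    """
    rng = np.random.default_rng(spec.seed)
    fc = _FrontalCurve(spec)
    sc = _SagittalCurve(spec)
    S = spec.spine_length_mm

    y_dense = np.linspace(0.0, S, 200)
    isl = np.column_stack([fc.x(y_dense), y_dense, sc.z(y_dense)])
    spl = _spl_from_isl(spec, fc, sc, y_dense)
    markers = _marker_positions(spec, fc, sc)

    T = spec.postural_transform
    Tinv = T.inverse()
    pcc_f, pcc_s = _truth_pcc(isl, spl)
    truth = PhantomTruth(
        isl=isl,
        spl=spl,
        markers_eos={k: v.copy() for k, v in markers.items()},
        markers_scanner={k: Tinv.apply(v) for k, v in markers.items()},
        cobb_frontal_deg=fc.cobb_deg(),
        cobb_kyphotic_deg=float(spec.kyphosis_angle_deg),
        cobb_lordotic_deg=float(spec.lordosis_angle_deg),
        pcc_frontal=pcc_f,
        pcc_sagittal=pcc_s,
        postural_transform=T,
    )

    # --- radiograph side: frames + pixel annotations -------------------
    marker_mat = np.vstack(list(markers.values()))
    content = np.vstack([isl, marker_mat])
    frames = _build_frames(content)
    y_ann = np.linspace(0.0, S, 41)
    isl_ann = np.column_stack([fc.x(y_ann), y_ann, sc.z(y_ann)])
    stamp = datetime.datetime.fromtimestamp(spec.seed, datetime.timezone.utc).isoformat()
    annotations: dict[View, Annotation2D] = {}
    for view in (View.FRONTAL, View.LATERAL):
        frame = frames[view]
        proj_f, proj_l = biplanar.project_to_views(isl_ann)
        proj = proj_f if view is View.FRONTAL else proj_l
        poly_px = biplanar.mm_to_pixel(proj, frame)
        mk_px = {}
        for name, p in markers.items():
            mf, ml = biplanar.project_to_views(p)
            px = biplanar.mm_to_pixel(mf if view is View.FRONTAL else ml, frame)
            mk_px[name] = (float(px[0]), float(px[1]))
        annotations[view] = Annotation2D(
            frame_id=frame.frame_id, markers=mk_px, isl_polyline=poly_px, timestamp=stamp
        )
        annotations[view].validate_against(frame)

    # --- scanner side: inverse postural transform + noise --------------
    y_spl = np.linspace(0.0, S, 80)
    spl_scan = Tinv.apply(_spl_from_isl(spec, fc, sc, y_spl))
    scan_markers = {}
    for name in MARKER_NAMES:
        noise = rng.normal(0.0, spec.marker_noise_sd_mm, 3) if spec.marker_noise_sd_mm else 0.0
        scan_markers[name] = Tinv.apply(markers[name]) + noise
    cloud = Tinv.apply(_surface_cloud(spec, fc, sc))
    if spec.surface_noise_sd_mm:
        cloud = cloud + rng.normal(0.0, spec.surface_noise_sd_mm, cloud.shape)
    scan = ScanBundle(cloud=cloud, markers=scan_markers, spl_polyline=spl_scan)

    return PhantomBundle(spec=spec, truth=truth, frames=frames, annotations=annotations, scan=scan)


# ---------------------------------------------------------------- cohort

#: Sampling ranges emulating the study population: primary frontal Cobb
#: median ~29 deg spanning roughly 9-54 deg, kyphosis ~41 deg,
#: lordosis ~40 deg.
DEFAULT_COHORT_RANGES: dict = {
    "frontal_cobb_deg": (29.0, 12.0, 9.0, 54.0),  # mean, sd, lo, hi (truncated normal)
    "kyphosis_deg": (41.0, 10.0, 20.0, 65.0),
    "lordosis_deg": (40.0, 8.0, 20.0, 60.0),
    "wavelength_mm": (360.0, 440.0),  # uniform
    "postural_rotation_deg": (0.0, 10.0),  # uniform magnitude, random axis
    "postural_translation_mm": (-100.0, 100.0),  # uniform per axis
}


def _trunc_normal(rng: np.random.Generator, mean, sd, lo, hi) -> float:
    a, b = (lo - mean) / sd, (hi - mean) / sd
    return float(truncnorm.rvs(a, b, loc=mean, scale=sd, random_state=rng))


def random_postural_transform(
    rng: np.random.Generator,
    rotation_deg: tuple[float, float] = (0.0, 10.0),
    translation_mm: tuple[float, float] = (-100.0, 100.0),
) -> RigidTransform:
    """Random rigid offset emulating imperfect posture replication."""
    axis = rng.normal(size=3)
    axis /= np.linalg.norm(axis)
    angle = np.radians(rng.uniform(*rotation_deg))
    R = Rotation.from_rotvec(angle * axis).as_matrix()
    t = rng.uniform(*translation_mm, size=3)
    return RigidTransform(R, t)


def sample_spec(
    rng: np.random.Generator,
    ranges: dict | None = None,
    marker_noise_sd_mm: float = 2.0,
    surface_noise_sd_mm: float = 0.5,
) -> PhantomSpec:
    """Draw one patient spec from the cohort distribution."""
    r = {**DEFAULT_COHORT_RANGES, **(ranges or {})}
    cobb = _trunc_normal(rng, *r["frontal_cobb_deg"])
    wavelength = rng.uniform(*r["wavelength_mm"])
    # invert cobb = 2 atan(2 pi A / wavelength) for the sine amplitude
    amplitude = wavelength * np.tan(np.radians(cobb) / 2) / (2 * np.pi)
    return PhantomSpec(
        frontal_amplitude_mm=float(amplitude),
        frontal_wavelength_mm=float(wavelength),
        kyphosis_angle_deg=_trunc_normal(rng, *r["kyphosis_deg"]),
        lordosis_angle_deg=_trunc_normal(rng, *r["lordosis_deg"]),
        marker_noise_sd_mm=marker_noise_sd_mm,
        surface_noise_sd_mm=surface_noise_sd_mm,
        postural_transform=random_postural_transform(
            rng, r["postural_rotation_deg"], r["postural_translation_mm"]
        ),
        seed=int(rng.integers(2**31)),
    )


def generate_cohort(
    n: int,
    seed: int,
    ranges: dict | None = None,
    marker_noise_sd_mm: float = 2.0,
    surface_noise_sd_mm: float = 0.5,
) -> list[PhantomBundle]:
    """Generate ``n`` phantoms sampled from the cohort distribution.

    Fully deterministic under ``seed``; different seeds change both
    the sampled specs and the noise realisations.
    """
    if n < 1:
        raise SpinalignError("cohort size must be >= 1")
    rng = np.random.default_rng(seed)
    return [
        generate_phantom(
            sample_spec(rng, ranges, marker_noise_sd_mm, surface_noise_sd_mm)
        )
        for _ in range(n)
    ]
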