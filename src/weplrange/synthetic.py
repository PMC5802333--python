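"""Ground-truthed digital phantom courses.

The generator emulates, in 2D, the inter-fraction changes that drive proton
range error on serial on-couch CT: per-fraction rigid setup displacement
with a recorded IGRT correction (leaving a residual), motion of high-density
structures (femoral-head surrogates) relative to the CTV, body-contour
erosion (weight loss), and density fluctuations in regions the beam
crosses (filling-type variation).  Every stochastic element is Gaussian
with a stated SD, so the population parameters the analysis pipeline should
recover — the overall mean m*, the SD of per-fraction means Σ*, and the
within-fraction per-pixel SD σ_w* — are analytic for the density-driven
mechanisms.

Fraction 1 is always the unperturbed reference.  A course is a pure
function of (phantom spec, motion model, n_fractions, seed).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from importlib import resources
from pathlib import Path
from typing import Dict, List, NamedTuple, Optional, Sequence, Tuple, Union

import numpy as np

from .fraction import FractionRecord
from .raytrace import SPImage

__all__ = [
    "PhantomInsert", "PhantomSpec", "DensityFluctuation", "MotionModel",
    "SyntheticCourse", "GroundTruth", "make_phantom", "simulate_course",
    "ground_truth_stats", "recovery_course_inputs",
]

_CARDINAL = (0.0, 90.0, 180.0, 270.0)


class PhantomSpecError(ValueError):
    """Inconsistent phantom geometry."""


class UnsupportedTruthError(ValueError):
    """Analytic ground truth is not defined for this motion model/angle."""


@dataclass(frozen=True)
class PhantomInsert:
    """A disc or axis-aligned slab of uniform stopping power.

    ``size`` is the radius (mm) for a disc, or (width_x, height_y) mm for a
    slab.  Inserts are clipped to the body contour.
    """

    shape: str
    center: Tuple[float, float]
    size: Union[float, Tuple[float, float]]
    sp: float

    def __post_init__(self) -> None:
        if self.shape not in ("disc", "slab"):
            raise PhantomSpecError(f"unknown insert shape {self.shape!r}")
        if self.sp < 0:
            raise PhantomSpecError("insert stopping power must be >= 0")

    def mask(self, X: np.ndarray, Y: np.ndarray,
             shift: Tuple[float, float] = (0.0, 0.0)) -> np.ndarray:
        cx, cy = self.center[0] + shift[0], self.center[1] + shift[1]
        if self.shape == "disc":
            return (X - cx) ** 2 + (Y - cy) ** 2 <= float(self.size) ** 2
        w, h = self.size
        return (np.abs(X - cx) <= w / 2.0) & (np.abs(Y - cy) <= h / 2.0)


@dataclass(frozen=True)
class PhantomSpec:
    """Geometry of the digital phantom (all lengths in mm).

    The grid uses the package coordinate convention (+y anterior, +x
    patient left, pixel (0,0) top-left) and is centred on the isocenter
    (0, 0).
    """

    grid_shape: Tuple[int, int]
    pixel_spacing: Tuple[float, float] = (1.0, 1.0)
    body_center: Tuple[float, float] = (0.0, 0.0)
    body_semiaxes: Tuple[float, float] = (150.0, 110.0)  # (a_x, b_y)
    background_sp: float = 1.0
    inserts: Tuple[PhantomInsert, ...] = ()
    ctv_center: Tuple[float, float] = (0.0, 0.0)
    ctv_radius: float = 20.0

    def __post_init__(self) -> None:
        if self.background_sp < 0:
            raise PhantomSpecError("background_sp must be >= 0")
        a, b = self.body_semiaxes
        cx, cy = self.body_center
        # CTV (with its radius) inside the body ellipse
        for phi in np.linspace(0, 2 * math.pi, 16, endpoint=False):
            px = self.ctv_center[0] + self.ctv_radius * math.cos(phi)
            py = self.ctv_center[1] + self.ctv_radius * math.sin(phi)
            if ((px - cx) / a) ** 2 + ((py - cy) / b) ** 2 > 1.0:
                raise PhantomSpecError("CTV extends outside the body ellipse")
        nrows, ncols = self.grid_shape
        sy, sx = self.pixel_spacing
        half_w, half_h = ncols * sx / 2.0, nrows * sy / 2.0
        if abs(cx) + a > half_w or abs(cy) + b > half_h:
            raise PhantomSpecError("grid does not cover the body ellipse")

    @classmethod
    def from_json(cls, path: Union[str, Path]) -> "PhantomSpec":
        with open(path) as fh:
            raw = json.load(fh)
        inserts = tuple(
            PhantomInsert(shape=i["shape"], center=tuple(i["center"]),
                          size=(tuple(i["size"]) if isinstance(i["size"], list)
                                else float(i["size"])), sp=i["sp"])
            for i in raw.get("inserts", ()))
        return cls(grid_shape=tuple(raw["grid_shape"]),
                   pixel_spacing=tuple(raw.get("pixel_spacing", (1.0, 1.0))),
                   body_center=tuple(raw["body"]["center"]),
                   body_semiaxes=tuple(raw["body"]["semiaxes"]),
                   background_sp=raw.get("background_sp", 1.0),
                   inserts=inserts,
                   ctv_center=tuple(raw["ctv"]["center"]),
                   ctv_radius=float(raw["ctv"]["radius"]))

    @classmethod
    def _from_package_data(cls, name: str) -> "PhantomSpec":
        ref = resources.files("weplrange.data").joinpath(name)
        with resources.as_file(ref) as path:
            return cls.from_json(path)

    @classmethod
    def prostate_like(cls) -> "PhantomSpec":
        """Pelvis-like section: wide ellipse, two lateral femoral-head discs."""
        return cls._from_package_data("prostate_like.json")

    @classmethod
    def head_neck_like(cls) -> "PhantomSpec":
        """Head-and-neck-like section: smaller ellipse with an air cavity."""
        return cls._from_package_data("head_neck_like.json")


@dataclass(frozen=True)
class DensityFluctuation:
    """Per-fraction stopping-power change in an axis-aligned slab region.

    ``scalar`` mode draws one N(mean, sd) offset per fraction for the whole
    region (filling-type change — shifts every downstream WEPL equally);
    ``per_pixel`` mode draws an independent N(mean, sd) offset per region
    pixel per fraction (local heterogeneity — pixel-level range noise).
    The region is anchored to the anatomy (it moves with the setup
    displacement).
    """

    center: Tuple[float, float]
    size: Tuple[float, float]  # (width_x, height_y) mm
    sd: float
    mean: float = 0.0
    per_pixel: bool = False

    def __post_init__(self) -> None:
        if self.sd < 0:
            raise PhantomSpecError("fluctuation sd must be >= 0")

    def _region(self) -> PhantomInsert:
        return PhantomInsert("slab", self.center, self.size, sp=0.0)


@dataclass(frozen=True)
class MotionModel:
    """Inter-fraction change model; all SDs in mm, Gaussian, per axis."""

    setup_sd: float = 0.0
    residual_after_igrt_sd: float = 0.0
    relative_insert_motion_sd: float = 0.0
    erosion_rate: float = 0.0  # mm of body-contour shrink per fraction
    density_fluctuations: Tuple[DensityFluctuation, ...] = ()

    def __post_init__(self) -> None:
        for name in ("setup_sd", "residual_after_igrt_sd",
                     "relative_insert_motion_sd", "erosion_rate"):
            if getattr(self, name) < 0:
                raise PhantomSpecError(f"{name} must be >= 0")

    @classmethod
    def from_json(cls, path: Union[str, Path]) -> "MotionModel":
        with open(path) as fh:
            raw = json.load(fh)
        flucts = tuple(
            DensityFluctuation(center=tuple(f["center"]), size=tuple(f["size"]),
                               sd=float(f["sd"]), mean=float(f.get("mean", 0.0)),
                               per_pixel=bool(f.get("per_pixel", False)))
            for f in raw.get("density_fluctuations", ()))
        return cls(setup_sd=raw.get("setup_sd", 0.0),
                   residual_after_igrt_sd=raw.get("residual_after_igrt_sd", 0.0),
                   relative_insert_motion_sd=raw.get("relative_insert_motion_sd", 0.0),
                   erosion_rate=raw.get("erosion_rate", 0.0),
                   density_fluctuations=flucts)


class GroundTruth(NamedTuple):
    """Analytic population parameters of a simulated course at one angle."""

    mean: float           # m*, mm
    sigma_systematic: float  # Σ*, mm
    sigma_within: float   # σ_w*, mm (per-pixel, per-fraction-mean removed)


@dataclass
class SyntheticCourse:
    """A simulated course plus everything needed to check the pipeline."""

    phantom: PhantomSpec
    motion: MotionModel
    seed: int
    angles: Tuple[float, ...]
    fractions: List[FractionRecord]     # fractions[0] is the reference
    ctv_mask: np.ndarray                # 2D planning CTV mask
    body_mask: np.ndarray               # 2D planning body mask
    expected_mean: Dict[float, np.ndarray]  # per angle, per fraction, mm

    @property
    def reference(self) -> FractionRecord:
        return self.fractions[0]


def make_phantom(spec: PhantomSpec,
                 body_shift: Tuple[float, float] = (0.0, 0.0),
                 insert_shifts: Optional[Sequence[Tuple[float, float]]] = None,
                 erosion: float = 0.0,
                 fluctuation_fields: Optional[Sequence[np.ndarray]] = None,
                 motion: Optional[MotionModel] = None,
                 ) -> Tuple[SPImage, np.ndarray, np.ndarray]:
    """Rasterize the phantom (pixel-centre rule), optionally perturbed.

    Returns (sp image, ctv mask, body mask).  The masks describe the
    *planning* (unshifted) CTV and the rasterized (possibly shifted/eroded)
    body.  ``fluctuation_fields`` are full-grid additive stopping-power
    fields, one per fluctuation of ``motion``, applied inside their regions
    (shifted with the anatomy) and clipped so no pixel goes negative.
    """
    nrows, ncols = spec.grid_shape
    img0 = SPImage(values=np.zeros(spec.grid_shape),
                   pixel_spacing=spec.pixel_spacing)
    X, Y = img0.pixel_centers()
    a = spec.body_semiaxes[0] - erosion
    b = spec.body_semiaxes[1] - erosion
    if a <= 0 or b <= 0:
        raise PhantomSpecError("erosion consumed the whole body")
    cx = spec.body_center[0] + body_shift[0]
    cy = spec.body_center[1] + body_shift[1]
    body = ((X - cx) / a) ** 2 + ((Y - cy) / b) ** 2 <= 1.0
    sp = np.where(body, spec.background_sp, 0.0)
    shifts = insert_shifts or [(0.0, 0.0)] * len(spec.inserts)
    for insert, extra in zip(spec.inserts, shifts):
        total = (body_shift[0] + extra[0], body_shift[1] + extra[1])
        m = insert.mask(X, Y, total) & body
        sp[m] = insert.sp
    if fluctuation_fields is not None:
        if motion is None:
            raise PhantomSpecError("fluctuation fields require the motion model")
        for fluct, fieldvals in zip(motion.density_fluctuations,
                                    fluctuation_fields):
            region = fluct._region().mask(X, Y, body_shift) & body
            sp[region] += np.broadcast_to(fieldvals, sp.shape)[region]
    sp = np.maximum(sp, 0.0)
    ctv = (X - spec.ctv_center[0]) ** 2 + (Y - spec.ctv_center[1]) ** 2 \
        <= spec.ctv_radius ** 2
    image = SPImage(values=sp, pixel_spacing=spec.pixel_spacing)
    return image, ctv, body


def _region_layers(spec: PhantomSpec, fluct: DensityFluctuation,
                   angle: float) -> int:
    """Number of rasterized pixel layers of a slab region along a beam."""
    img = SPImage(values=np.zeros(spec.grid_shape),
                  pixel_spacing=spec.pixel_spacing)
    X, Y = img.pixel_centers()
    m = fluct._region().mask(X, Y)
    if not m.any():
        return 0
    if angle % 180.0 == 0.0:
        return int(m.any(axis=1).sum())
    return int(m.any(axis=0).sum())


def _spacing_along(spec: PhantomSpec, angle: float) -> float:
    return spec.pixel_spacing[0] if angle % 180.0 == 0.0 else spec.pixel_spacing[1]


def _erosion_mean_delta(spec: PhantomSpec, ctv: np.ndarray, erosion: float,
                        angle: float) -> float:
    """Analytic mean ΔWEPL over CTV pixel centres from contour erosion.

    For a cardinal parallel beam through a uniform body of stopping power
    ``background_sp``, shrinking the ellipse changes only the entry-surface
    position, so ΔWEPL at a pixel is background_sp times the change in the
    entry coordinate along its ray.
    """
    if erosion == 0.0:
        return 0.0
    img = SPImage(values=np.zeros(spec.grid_shape),
                  pixel_spacing=spec.pixel_spacing)
    X, Y = img.pixel_centers()
    a0, b0 = spec.body_semiaxes
    a1, b1 = a0 - erosion, b0 - erosion
    cx, cy = spec.body_center
    if angle % 180.0 == 0.0:   # anterior/posterior: entry along y
        u = (X[ctv] - cx)
        ref = b0 * np.sqrt(np.maximum(1 - (u / a0) ** 2, 0.0))
        ero = b1 * np.sqrt(np.maximum(1 - (u / a1) ** 2, 0.0))
    else:                       # lateral: entry along x
        u = (Y[ctv] - cy)
        ref = a0 * np.sqrt(np.maximum(1 - (u / b0) ** 2, 0.0))
        ero = a1 * np.sqrt(np.maximum(1 - (u / b1) ** 2, 0.0))
    return float(spec.background_sp * np.mean(ero - ref))


def simulate_course(spec: PhantomSpec, motion: MotionModel, n_fractions: int,
                    seed: int, angles: Sequence[float] = (0.0,),
                    ) -> SyntheticCourse:
    """Generate a course of per-fraction stopping-power images.

    Fraction 1 is the unperturbed reference with zero recorded shift.  For
    each later fraction the sampled setup displacement d is applied to the
    whole anatomy; the recorded IGRT correction c = r − d is stored in the
    fraction record so that applying it leaves the residual displacement r
    (SD ``residual_after_igrt_sd`` per axis).  Inserts move by an extra
    independent displacement, the body contour shrinks by
    ``erosion_rate``·(fraction−1) mm, and density-fluctuation regions are
    re-drawn.  Identical seeds reproduce the course bit for bit.

    ``expected_mean[angle][k]`` is the expected CTV-mean ΔWEPL of fraction
    k given its sampled scalar fluctuations and erosion state (cardinal
    parallel beams; per-pixel noise and displacement mechanisms have zero
    expectation and contribute spread, not mean).
    """
    if n_fractions < 1:
        raise PhantomSpecError("n_fractions must be >= 1")
    rng = np.random.default_rng(seed)
    ref_image, ctv, body = make_phantom(spec)
    spacing3 = (1.0, *spec.pixel_spacing)
    fractions = [FractionRecord(fraction_index=1, image=ref_image.values[None],
                                spacing=spacing3, is_sp=True)]
    thickness = {
        angle: [(_region_layers(spec, f, angle) * _spacing_along(spec, angle))
                for f in motion.density_fluctuations]
        for angle in angles if angle % 90.0 == 0.0}
    expected: Dict[float, List[float]] = {a: [0.0] for a in thickness}

    for k in range(2, n_fractions + 1):
        d = rng.normal(0.0, motion.setup_sd, size=2) \
            if motion.setup_sd > 0 else np.zeros(2)
        r = rng.normal(0.0, motion.residual_after_igrt_sd, size=2) \
            if motion.residual_after_igrt_sd > 0 else np.zeros(2)
        recorded = r - d
        insert_shifts = [tuple(rng.normal(0.0, motion.relative_insert_motion_sd,
                                          size=2))
                         if motion.relative_insert_motion_sd > 0 else (0.0, 0.0)
                         for _ in spec.inserts]
        scalar_deltas: List[float] = []
        fields: List[np.ndarray] = []
        for fluct in motion.density_fluctuations:
            if fluct.per_pixel:
                fields.append(rng.normal(fluct.mean, fluct.sd,
                                         size=spec.grid_shape))
                scalar_deltas.append(0.0)  # zero-mean per construction
            else:
                delta = float(rng.normal(fluct.mean, fluct.sd))
                fields.append(np.full(spec.grid_shape, delta))
                scalar_deltas.append(delta)
        erosion = motion.erosion_rate * (k - 1)
        image, _, _ = make_phantom(spec, body_shift=tuple(d),
                                   insert_shifts=insert_shifts,
                                   erosion=erosion, fluctuation_fields=fields,
                                   motion=motion)
        fractions.append(FractionRecord(
            fraction_index=k, image=image.values[None], spacing=spacing3,
            is_sp=True, shift=(float(recorded[0]), float(recorded[1]))))
        for angle in expected:
            mu = sum(dv * t for dv, t in zip(scalar_deltas, thickness[angle]))
            mu += _erosion_mean_delta(spec, ctv, erosion, angle)
            expected[angle].append(mu)

    return SyntheticCourse(
        phantom=spec, motion=motion, seed=seed, angles=tuple(angles),
        fractions=fractions, ctv_mask=ctv, body_mask=body,
        expected_mean={a: np.asarray(v) for a, v in expected.items()})


def ground_truth_stats(course: SyntheticCourse, angle: float) -> GroundTruth:
    """Analytic (m*, Σ*, σ_w*) of the motion model at a cardinal angle.

    Defined for density-driven models (scalar and per-pixel fluctuations,
    erosion): the per-fraction mean is the sum of scalar-fluctuation WEPL
    offsets plus the deterministic erosion trend, and the per-pixel spread
    comes from the per-pixel fluctuation layers.  Displacement mechanisms
    (setup residual, insert motion) have geometry-dependent distributions
    without a closed form; requesting truth for them raises
    :class:`UnsupportedTruthError`.
    """
    if angle not in course.expected_mean:
        raise UnsupportedTruthError(
            f"angle {angle} was not simulated (cardinal angles only)")
    motion = course.motion
    if motion.setup_sd > 0 or motion.residual_after_igrt_sd > 0 \
            or motion.relative_insert_motion_sd > 0:
        raise UnsupportedTruthError(
            "analytic truth is only defined for density-driven motion models")
    spec = course.phantom
    n_later = len(course.fractions) - 1
    var_sys = 0.0
    var_within = 0.0
    m = 0.0
    for fluct in motion.density_fluctuations:
        t = _region_layers(spec, fluct, angle) * _spacing_along(spec, angle)
        layers = _region_layers(spec, fluct, angle)
        s_along = _spacing_along(spec, angle)
        if fluct.per_pixel:
            var_within += layers * (s_along * fluct.sd) ** 2
        else:
            m += fluct.mean * t
            var_sys += (fluct.sd * t) ** 2
    if motion.erosion_rate > 0 and n_later >= 1:
        trend = np.array([
            _erosion_mean_delta(spec, course.ctv_mask,
                                motion.erosion_rate * k, angle)
            for k in range(1, n_later + 1)])
        m += float(trend.mean())
        if n_later >= 2:
            var_sys += float(np.var(trend, ddof=1))
    return GroundTruth(mean=m, sigma_systematic=math.sqrt(var_sys),
                       sigma_within=math.sqrt(var_within))


def recovery_course_inputs(mean: float = -1.8, sigma_systematic: float = 3.4,
                           sigma_within: float = 3.3,
                           ) -> Tuple[PhantomSpec, MotionModel]:
    """Phantom and motion model for population parameter recovery.

    The phantom carries a ~500-pixel CTV disc irradiated from anterior
    (gantry 0°).  A 20 mm slab upstream of the CTV takes a scalar density
    offset per fraction, calibrated so the per-fraction CTV-mean ΔWEPL is
    N(mean, sigma_systematic²).  A 30-layer slab of dense material (SP 3,
    so the Gaussian noise never clips at zero) between it and the CTV takes
    independent per-pixel offsets calibrated so every CTV pixel's ΔWEPL
    carries an extra SD of ``sigma_within``.  Both slabs span all CTV ray
    columns, which makes the ground truth exact rather than approximate.
    """
    t_mean = 20.0   # mm, rasterizes to exactly 20 unit layers
    n_noise_layers = 30
    spec = PhantomSpec(
        grid_shape=(122, 162), pixel_spacing=(1.0, 1.0),
        body_center=(0.0, 0.0), body_semiaxes=(80.0, 60.0),
        background_sp=1.0,
        inserts=(PhantomInsert("slab", (0.0, 5.0), (40.0, 30.0), sp=3.0),),
        ctv_center=(0.0, -25.0), ctv_radius=12.65)
    motion = MotionModel(density_fluctuations=(
        DensityFluctuation(center=(0.0, 35.0), size=(40.0, 20.0),
                           mean=mean / t_mean, sd=sigma_systematic / t_mean),
        DensityFluctuation(center=(0.0, 5.0), size=(40.0, 30.0),
                           sd=sigma_within / math.sqrt(n_noise_layers),
                           per_pixel=True),
    ))
    return spec, motion
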