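"""Per-fraction processing: registration, truncation correction, ΔWEPL.

A treatment course is a reference fraction plus a sequence of daily
fractions, each a volumetric image with the rigid couch shift that was
applied clinically.  Every usable fraction is converted to relative
stopping power, resampled into the reference frame with its recorded rigid
shift, truncation-corrected against the scanning circle where requested,
and ray traced.  The per-pixel WEPL difference to the reference fraction
inside the CTV is the atom of all downstream statistics:

    delta_wepl > 0  : WEPL increased vs. reference (risk of undershoot)
    delta_wepl < 0  : WEPL decreased (risk of overshoot, e.g. weight loss)

Pixel correspondence across fractions is by grid index after rigid
registration; no deformable matching is attempted.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from scipy import ndimage

from .calibration import CalibrationTable, hu_to_sp
from .raytrace import BeamGeometry, SPImage, WEPLMap, wepl_map

__all__ = [
    "FractionRecord", "ScanningCircle", "RangeErrorSample", "FractionSummary",
    "CourseOptions", "apply_rigid_shift", "truncation_correct",
    "fraction_range_error", "summarize_fraction", "run_course",
]

logger = logging.getLogger(__name__)


class PipelineError(ValueError):
    """Invalid input to the fraction pipeline."""


@dataclass
class FractionRecord:
    """One treatment fraction.

    image : (n_slices, n_rows, n_cols) array, HU by default or relative
        stopping power when ``is_sp`` is set.
    shift : in-plane rigid couch correction (dx, dy) in mm that registers
        the fraction anatomy onto the reference frame (applied by
        translating the image content by (dx, dy)).
    dz : through-plane shift component, mm; resolved by nearest-slice
        matching.
    """

    fraction_index: int
    image: np.ndarray
    spacing: Tuple[float, float, float] = (1.0, 1.0, 1.0)  # (slice,row,col) mm
    is_sp: bool = False
    shift: Tuple[float, float] = (0.0, 0.0)
    dz: float = 0.0
    rotation: float = 0.0
    usable: bool = True
    excluded_slices: Tuple[int, ...] = ()

    def __post_init__(self) -> None:
        self.image = np.asarray(self.image, dtype=float)
        if self.image.ndim == 2:
            self.image = self.image[None]
        if self.image.ndim != 3:
            raise PipelineError("fraction image must be 2D or 3D")
        if not all(math.isfinite(v) for v in (*self.shift, self.dz, self.rotation)):
            raise PipelineError("shifts must be finite")


@dataclass(frozen=True)
class ScanningCircle:
    """Field-of-view circle of the on-couch imager (default diameter 386 mm)."""

    center: Tuple[float, float] = (0.0, 0.0)
    diameter: float = 386.0

    def __post_init__(self) -> None:
        if self.diameter <= 0:
            raise PipelineError("scanning-circle diameter must be > 0")


@dataclass
class RangeErrorSample:
    """Per-CTV-pixel ΔWEPL of one (patient, fraction, angle) triple."""

    patient_id: str
    fraction_index: int
    gantry_angle: float
    delta_wepl: np.ndarray

    def __post_init__(self) -> None:
        self.delta_wepl = np.asarray(self.delta_wepl, dtype=float).ravel()
        if not np.all(np.isfinite(self.delta_wepl)):
            raise PipelineError("delta_wepl contains non-finite values")

    @property
    def n_pixels(self) -> int:
        return int(self.delta_wepl.size)


@dataclass
class FractionSummary:
    """Mean/SD and percent-volume histogram of one fraction's ΔWEPL."""

    patient_id: str
    fraction_index: int
    gantry_angle: float
    mean: float
    sd: float          # NaN when n_pixels < 2
    bin_edges: np.ndarray
    percent_volume: np.ndarray
    n_pixels: int


@dataclass
class CourseOptions:
    """Knobs of :func:`run_course` that are not per-fraction data."""

    patient_id: str = "anon"
    bin_width: float = 1.0
    fill_sp: float = 1.0
    isocenter: Tuple[float, float] = (0.0, 0.0)
    fast_raytrace: bool = True


def apply_rigid_shift(image: SPImage, shift: Tuple[float, float],
                      rotation: float = 0.0,
                      center: Tuple[float, float] = (0.0, 0.0)) -> SPImage:
    """Translate (and optionally rotate about ``center``) the image content.

    The content is moved by ``shift`` = (dx, dy) mm in physical coordinates
    after rotating by ``rotation`` degrees (counter-clockwise in the x–y
    plane) about ``center``; the result is resampled onto the unchanged
    grid with bilinear interpolation, filling exposed pixels with 0.  A
    zero transform returns the input unchanged (no resampling).
    """
    dx, dy = shift
    if not (math.isfinite(dx) and math.isfinite(dy) and math.isfinite(rotation)):
        raise PipelineError("rigid shift must be finite")
    if dx == 0.0 and dy == 0.0 and rotation == 0.0:
        return image
    nrows, ncols = image.shape
    sy, sx = image.pixel_spacing
    x0, y0 = image.origin
    cols, rows = np.meshgrid(np.arange(ncols), np.arange(nrows))
    x = x0 + cols * sx
    y = y0 - rows * sy
    # output(q) = input(T^-1 q) with T p = R (p - center) + center + shift
    qx = x - dx - center[0]
    qy = y - dy - center[1]
    if rotation != 0.0:
        th = math.radians(rotation)
        ct, st = math.cos(th), math.sin(th)
        px = ct * qx + st * qy + center[0]
        py = -st * qx + ct * qy + center[1]
    else:
        px = qx + center[0]
        py = qy + center[1]
    src_cols = (px - x0) / sx
    src_rows = (y0 - py) / sy
    resampled = ndimage.map_coordinates(
        image.values, [src_rows, src_cols], order=1, mode="constant", cval=0.0)
    return replace(image, values=np.maximum(resampled, 0.0))


def truncation_correct(mvct: SPImage, circle: ScanningCircle,
                       body_mask: np.ndarray, fill_sp: float = 1.0) -> SPImage:
    """Fill anatomy truncated by the imaging field of view.

    Pixels inside the scanning circle keep their measured value; pixels
    outside the circle but inside the (shifted planning) body contour are
    assigned ``fill_sp`` — a uniform soft-tissue surrogate, water by
    default; pixels outside both are set to 0.
    """
    body_mask = np.asarray(body_mask, dtype=bool)
    if body_mask.shape != mvct.shape:
        raise PipelineError("body mask grid does not match the image grid")
    X, Y = mvct.pixel_centers()
    cx, cy = circle.center
    inside = (X - cx) ** 2 + (Y - cy) ** 2 <= (circle.diameter / 2.0) ** 2
    out = np.where(inside, mvct.values,
                   np.where(body_mask, float(fill_sp), 0.0))
    return replace(mvct, values=out)


def fraction_range_error(ref_wepl: WEPLMap, frac_wepl: WEPLMap,
                         ctv_mask: np.ndarray, patient_id: str = "anon",
                         fraction_index: int = 0,
                         gantry_angle: float = 0.0) -> RangeErrorSample:
    """Per-CTV-pixel WEPL difference, fraction minus reference."""
    ctv_mask = np.asarray(ctv_mask, dtype=bool)
    if ref_wepl.values.shape != frac_wepl.values.shape:
        raise PipelineError("WEPL maps are on different grids")
    if ctv_mask.shape != ref_wepl.values.shape:
        raise PipelineError("CTV mask grid does not match the WEPL maps")
    if not np.all(ref_wepl.valid_mask[ctv_mask]) or \
            not np.all(frac_wepl.valid_mask[ctv_mask]):
        raise PipelineError("CTV mask extends outside the valid WEPL region")
    delta = frac_wepl.values[ctv_mask] - ref_wepl.values[ctv_mask]
    return RangeErrorSample(patient_id=patient_id,
                            fraction_index=fraction_index,
                            gantry_angle=gantry_angle, delta_wepl=delta)


def summarize_fraction(sample: RangeErrorSample,
                       bin_width: float = 1.0) -> FractionSummary:
    """Mean, sample SD and percent-volume histogram of one fraction.

    Bins of ``bin_width`` mm cover the full data range (no display
    truncation: every pixel keeps its histogram mass).  With fewer than two
    pixels the SD is NaN but the mean is still reported.
    """
    if bin_width <= 0:
        raise PipelineError("bin_width must be > 0")
    d = sample.delta_wepl
    if d.size == 0:
        raise PipelineError("cannot summarize an empty sample")
    mean = float(np.mean(d))
    sd = float(np.std(d, ddof=1)) if d.size >= 2 else float("nan")
    lo = bin_width * math.floor(float(d.min()) / bin_width)
    hi = bin_width * math.ceil(float(d.max()) / bin_width)
    if hi <= lo:
        hi = lo + bin_width
    n_bins = int(round((hi - lo) / bin_width))
    edges = lo + bin_width * np.arange(n_bins + 1)
    counts, edges = np.histogram(d, bins=edges)
    return FractionSummary(
        patient_id=sample.patient_id, fraction_index=sample.fraction_index,
        gantry_angle=sample.gantry_angle, mean=mean, sd=sd,
        bin_edges=edges, percent_volume=100.0 * counts / d.size,
        n_pixels=d.size)


def _slices_to_sp(record: FractionRecord,
                  calibration: Optional[CalibrationTable],
                  circle: Optional[ScanningCircle],
                  body_mask: Optional[np.ndarray],
                  options: CourseOptions) -> Dict[int, SPImage]:
    """Convert, register and truncation-correct each non-excluded slice."""
    n_slices = record.image.shape[0]
    n_nan = int(np.isnan(record.image).sum())
    if n_nan:
        logger.warning("fraction %d: %d NaN voxels clamped via calibration",
                       record.fraction_index, n_nan)
    out: Dict[int, SPImage] = {}
    for s in range(n_slices):
        if s in record.excluded_slices:
            continue
        plane = record.image[s]
        if record.is_sp:
            sp_plane = np.maximum(np.nan_to_num(plane, nan=0.0), 0.0)
        else:
            if calibration is None:
                raise PipelineError("HU input requires a calibration table")
            sp_plane = hu_to_sp(plane, calibration)
        img = SPImage(values=sp_plane,
                      pixel_spacing=(record.spacing[1], record.spacing[2]),
                      slice_position=s * record.spacing[0])
        img = apply_rigid_shift(img, record.shift, record.rotation,
                                center=options.isocenter)
        if circle is not None:
            if body_mask is None:
                raise PipelineError("truncation correction needs a body mask")
            img = truncation_correct(img, circle, body_mask[s], options.fill_sp)
        out[s] = img
    return out


def run_course(reference: FractionRecord,
               fractions: Sequence[FractionRecord],
               ctv_mask: np.ndarray,
               body_mask: Optional[np.ndarray],
               beams: Sequence[BeamGeometry],
               calibration: Optional[CalibrationTable] = None,
               circle: Optional[ScanningCircle] = None,
               options: Optional[CourseOptions] = None,
               ) -> Tuple[List[RangeErrorSample], List[FractionSummary]]:
    """Run the full per-fraction ΔWEPL pipeline for a course.

    For each usable fraction and each beam: HU→SP conversion, rigid-shift
    registration into the reference frame, optional field-of-view
    truncation correction, WEPL maps for reference and fraction over the
    CTV, a :class:`RangeErrorSample` and its :class:`FractionSummary`.
    Slices excluded on the reference or on a fraction, and unusable
    fractions, are skipped and logged.  A fraction's ``dz`` relocates slice
    correspondence by the nearest whole slice.
    """
    if options is None:
        options = CourseOptions()
    if not reference.usable:
        raise PipelineError("reference fraction is not usable")
    if not beams:
        raise PipelineError("at least one beam is required")
    usable = [f for f in fractions if f.usable]
    for f in fractions:
        if not f.usable:
            logger.info("fraction %d unusable, skipped", f.fraction_index)
    if not usable:
        raise PipelineError("no usable fractions in the course")
    ctv_mask = np.asarray(ctv_mask, dtype=bool)
    if ctv_mask.ndim == 2:
        ctv_mask = ctv_mask[None]
    if body_mask is not None:
        body_mask = np.asarray(body_mask, dtype=bool)
        if body_mask.ndim == 2:
            body_mask = body_mask[None]

    ref_slices = _slices_to_sp(reference, calibration, circle, body_mask,
                               options)
    ctv_slices = [s for s in ref_slices
                  if s < ctv_mask.shape[0] and ctv_mask[s].any()]
    if not ctv_slices:
        raise PipelineError("CTV mask is empty on all non-excluded slices")
    ref_wepl = {(s, b.gantry_angle): wepl_map(ref_slices[s], ctv_mask[s], b,
                                              fast=options.fast_raytrace)
                for s in ctv_slices for b in beams}

    samples: List[RangeErrorSample] = []
    summaries: List[FractionSummary] = []
    slice_spacing = reference.spacing[0]
    for frac in usable:
        frac_slices = _slices_to_sp(frac, calibration, circle, body_mask,
                                    options)
        offset = int(round(frac.dz / slice_spacing)) if frac.dz else 0
        for beam in beams:
            deltas = []
            for s in ctv_slices:
                s_frac = s + offset
                if s_frac not in frac_slices:
                    logger.info("fraction %d: slice %d unavailable, skipped",
                                frac.fraction_index, s_frac)
                    continue
                fw = wepl_map(frac_slices[s_frac], ctv_mask[s], beam,
                              fast=options.fast_raytrace)
                deltas.append(fw.values[ctv_mask[s]]
                              - ref_wepl[(s, beam.gantry_angle)].values[ctv_mask[s]])
            if not deltas:
                logger.warning("fraction %d angle %g: no analysable slices",
                               frac.fraction_index, beam.gantry_angle)
                continue
            sample = RangeErrorSample(
                patient_id=options.patient_id,
                fraction_index=frac.fraction_index,
                gantry_angle=beam.gantry_angle,
                delta_wepl=np.concatenate(deltas))
            samples.append(sample)
            summaries.append(summarize_fraction(sample, options.bin_width))
    return samples, summaries
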