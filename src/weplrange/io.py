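"""Readers, writers, configuration and the end-to-end analysis driver.

Volumes are interchanged as NIfTI.  In memory every volume is an
(n_slices, n_rows, n_cols) array — 0-based, slice-major — with spacing in
mm per axis in the same order; on disk the NIfTI data axes are
(col, row, slice), the conventional (i, j, k) order, so round trips are
loss-free.  CSV outputs use fixed headers and 4-decimal mm precision so
re-runs are bit-reproducible.
"""

from __future__ import annotations

import csv
import dataclasses
import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd

from . import __version__
from .calibration import CalibrationTable
from .fraction import (CourseOptions, FractionRecord, FractionSummary,
                       RangeErrorSample, ScanningCircle, run_course)
from .popstats import PopulationStats, population_table
from .raytrace import BeamGeometry

__all__ = [
    "Volume", "ShiftRecord", "AnalysisConfig", "read_volume", "write_volume",
    "read_shift_table", "write_shift_table", "run_analysis",
    "write_summary_csv", "write_histogram_csv", "write_samples_csv",
    "write_population_csv", "read_summary_csv", "read_samples_csv",
]

logger = logging.getLogger(__name__)


class VolumeIOError(IOError):
    """A volume could not be read or lacks required metadata."""


@dataclass
class Volume:
    """A CT volume (HU) or mask with its grid metadata.

    values  : (n_slices, n_rows, n_cols)
    spacing : (slice, row, col) mm
    origin  : physical position of voxel (0, 0, 0), mm (bookkeeping)
    """

    values: np.ndarray
    spacing: Tuple[float, float, float]
    origin: Tuple[float, float, float] = (0.0, 0.0, 0.0)


def read_volume(path: Union[str, Path]) -> Volume:
    """Load a NIfTI volume into (slice, row, col) order."""
    import nibabel as nib
    path = Path(path)
    try:
        img = nib.load(str(path))
        data = np.asarray(img.dataobj, dtype=float)
    except Exception as exc:  # missing or corrupt file
        raise VolumeIOError(f"cannot read NIfTI volume {path}: {exc}") from exc
    if data.ndim == 2:
        data = data[..., None]
    if data.ndim != 3:
        raise VolumeIOError(f"{path}: expected a 2D/3D volume, got {data.ndim}D")
    zooms = img.header.get_zooms()[:3]
    if any(z <= 0 or not math.isfinite(z) for z in zooms):
        raise VolumeIOError(f"{path}: missing or invalid voxel spacing {zooms}")
    origin = tuple(float(v) for v in img.affine[:3, 3][::-1])
    return Volume(values=np.transpose(data, (2, 1, 0)),
                  spacing=(float(zooms[2]), float(zooms[1]), float(zooms[0])),
                  origin=origin)


def write_volume(path: Union[str, Path], values: np.ndarray,
                 spacing: Tuple[float, float, float],
                 origin: Tuple[float, float, float] = (0.0, 0.0, 0.0)) -> None:
    """Write an (slice, row, col) array as NIfTI with the given mm spacing."""
    import nibabel as nib
    values = np.asarray(values, dtype=np.float64)
    if values.ndim == 2:
        values = values[None]
    affine = np.diag([spacing[2], spacing[1], spacing[0], 1.0])
    affine[:3, 3] = origin[::-1]
    img = nib.Nifti1Image(np.transpose(values, (2, 1, 0)), affine)
    img.header.set_zooms((spacing[2], spacing[1], spacing[0]))
    nib.save(img, str(path))


@dataclass
class ShiftRecord:
    """One row of the per-fraction rigid-shift table."""

    fraction: int
    dx_mm: float = 0.0
    dy_mm: float = 0.0
    dz_mm: float = 0.0
    rotation_deg: float = 0.0
    usable: bool = True


SHIFT_HEADER = ["fraction", "dx_mm", "dy_mm", "dz_mm", "rotation_deg", "usable"]


def read_shift_table(path: Union[str, Path],
                     n_fractions: Optional[int] = None) -> List[ShiftRecord]:
    """Read the shift CSV; gaps in fraction numbering become unusable records.

    The expected header is ``fraction,dx_mm,dy_mm,dz_mm,rotation_deg,usable``.
    When ``n_fractions`` is given, missing fractions in 1..n_fractions are
    filled in as unusable and logged.
    """
    path = Path(path)
    records: Dict[int, ShiftRecord] = {}
    with open(path, newline="") as fh:
        reader = csv.reader(fh)
        rows = [r for r in reader if r and not r[0].lstrip().startswith("#")]
    if not rows or [c.strip() for c in rows[0]] != SHIFT_HEADER:
        raise VolumeIOError(
            f"{path}: expected header {','.join(SHIFT_HEADER)}")
    for lineno, row in enumerate(rows[1:], start=2):
        try:
            rec = ShiftRecord(fraction=int(row[0]), dx_mm=float(row[1]),
                              dy_mm=float(row[2]), dz_mm=float(row[3]),
                              rotation_deg=float(row[4]),
                              usable=bool(int(row[5])))
        except (ValueError, IndexError) as exc:
            raise VolumeIOError(f"{path}:{lineno}: malformed row {row!r}: "
                                f"{exc}") from exc
        records[rec.fraction] = rec
    top = n_fractions if n_fractions is not None else \
        (max(records) if records else 0)
    out: List[ShiftRecord] = []
    for k in range(1, top + 1):
        if k in records:
            out.append(records[k])
        else:
            logger.warning("%s: fraction %d missing from shift table, "
                           "marked unusable", path, k)
            out.append(ShiftRecord(fraction=k, usable=False))
    return out


def write_shift_table(path: Union[str, Path],
                      records: Sequence[ShiftRecord]) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(SHIFT_HEADER)
        for r in records:
            writer.writerow([r.fraction, f"{r.dx_mm:.4f}", f"{r.dy_mm:.4f}",
                             f"{r.dz_mm:.4f}", f"{r.rotation_deg:.4f}",
                             int(r.usable)])


@dataclass
class AnalysisConfig:
    """Everything needed to run one patient's course end to end."""

    patient_id: str
    fraction_images: List[str]          # fraction 1..N, in order
    shift_csv: str
    ctv_mask: str
    body_mask: Optional[str] = None
    calibration_csv: Optional[str] = None   # None -> packaged default curve
    angles: List[float] = field(default_factory=lambda: [0.0])
    sad: Optional[float] = 2000.0           # None -> parallel beam
    circle_diameter: Optional[float] = None  # None -> no truncation correction
    circle_center: Tuple[float, float] = (0.0, 0.0)
    bin_width: float = 1.0
    fill_sp: float = 1.0
    reference_fraction: Optional[int] = None  # None -> first usable
    sigma_method: str = "pooled"
    excluded_slices: List[int] = field(default_factory=list)
    sp_input: bool = False
    output_dir: str = "weplrange_out"
    make_figures: bool = True
    write_samples: bool = True

    def __post_init__(self) -> None:
        if not self.angles:
            raise ValueError("config needs at least one beam angle")

    @classmethod
    def from_json(cls, path: Union[str, Path]) -> "AnalysisConfig":
        with open(path) as fh:
            raw = json.load(fh)
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "AnalysisConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        kwargs = {k: v for k, v in raw.items() if k in known}
        if "circle_center" in kwargs:
            kwargs["circle_center"] = tuple(kwargs["circle_center"])
        return cls(**kwargs)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["circle_center"] = list(self.circle_center)
        return d


def _fmt(value: float) -> str:
    return "nan" if not math.isfinite(value) else f"{value:.4f}"


def write_summary_csv(path: Union[str, Path],
                      summaries: Sequence[FractionSummary]) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["patient", "fraction", "angle", "n_pixels",
                         "mean_mm", "sd_mm"])
        for s in summaries:
            writer.writerow([s.patient_id, s.fraction_index,
                             f"{s.gantry_angle:g}", s.n_pixels,
                             _fmt(s.mean), _fmt(s.sd)])


def read_summary_csv(path: Union[str, Path]) -> List[FractionSummary]:
    df = pd.read_csv(path)
    out = []
    for _, row in df.iterrows():
        out.append(FractionSummary(
            patient_id=str(row["patient"]), fraction_index=int(row["fraction"]),
            gantry_angle=float(row["angle"]), mean=float(row["mean_mm"]),
            sd=float(row["sd_mm"]), bin_edges=np.array([]),
            percent_volume=np.array([]), n_pixels=int(row["n_pixels"])))
    return out


def write_histogram_csv(path: Union[str, Path],
                        summaries: Sequence[FractionSummary]) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["patient", "fraction", "angle", "bin_low",
                         "bin_high", "percent_volume"])
        for s in summaries:
            for lo, hi, pv in zip(s.bin_edges[:-1], s.bin_edges[1:],
                                  s.percent_volume):
                writer.writerow([s.patient_id, s.fraction_index,
                                 f"{s.gantry_angle:g}", _fmt(lo), _fmt(hi),
                                 _fmt(pv)])


def write_samples_csv(path: Union[str, Path],
                      samples: Sequence[RangeErrorSample]) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["patient", "fraction", "angle", "delta_mm"])
        for s in samples:
            for v in s.delta_wepl:
                writer.writerow([s.patient_id, s.fraction_index,
                                 f"{s.gantry_angle:g}", _fmt(v)])


def read_samples_csv(path: Union[str, Path]) -> List[RangeErrorSample]:
    df = pd.read_csv(path)
    out = []
    for (patient, fraction, angle), grp in df.groupby(
            ["patient", "fraction", "angle"], sort=True):
        out.append(RangeErrorSample(
            patient_id=str(patient), fraction_index=int(fraction),
            gantry_angle=float(angle),
            delta_wepl=grp["delta_mm"].to_numpy(dtype=float)))
    return out


def write_population_csv(path: Union[str, Path],
                         rows: Sequence[PopulationStats]) -> None:
    """Population table: per-angle rows then the pooled 'All' row.

    ``sigma_mm`` is the systematic Σ, ``sd_mm`` the random σ.
    """
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["angle", "mean_mm", "sigma_mm", "sd_mm",
                         "n_fractions", "n_pixels"])
        for r in rows:
            label = r.gantry_angle if isinstance(r.gantry_angle, str) \
                else f"{r.gantry_angle:g}"
            writer.writerow([label, _fmt(r.mean), _fmt(r.sigma_systematic),
                             _fmt(r.sigma_random), r.n_fractions, r.n_pixels])


def _heatmap_figure(summaries: Sequence[FractionSummary], angle: float,
                    path: Path, display_range: float = 15.0,
                    bin_width: float = 1.0) -> None:
    """Fraction (x) vs ΔWEPL (y) percent-volume heat map for one angle."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    group = sorted((s for s in summaries if s.gantry_angle == angle),
                   key=lambda s: s.fraction_index)
    if not group:
        return
    edges = np.arange(-display_range, display_range + bin_width, bin_width)
    grid = np.zeros((len(edges) - 1, len(group)))
    for j, s in enumerate(group):
        centers = (s.bin_edges[:-1] + s.bin_edges[1:]) / 2.0
        idx = np.clip(np.digitize(centers, edges) - 1, 0, len(edges) - 2)
        np.add.at(grid[:, j], idx, s.percent_volume)
    fig, ax = plt.subplots(figsize=(8, 4))
    fracs = np.asarray([s.fraction_index for s in group], dtype=float)
    x_edges = np.append(fracs - 0.5, fracs[-1] + 0.5)
    mesh = ax.pcolormesh(x_edges, edges, grid, cmap="Greys", shading="flat")
    ax.axhline(0.0, color="tab:red", lw=0.8)
    ax.set_xlabel("fraction")
    ax.set_ylabel("range change (mm)")
    ax.set_title(f"{group[0].patient_id} — gantry {angle:g}°")
    fig.colorbar(mesh, ax=ax, label="% CTV volume")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def run_analysis(config: AnalysisConfig) -> Path:
    """Run the full per-patient workflow and write the artifact directory.

    Outputs: ``summaries.csv``, ``histograms.csv``, ``population.csv``,
    optional ``samples.csv`` and per-angle heat maps, and ``run_log.json``
    recording inputs, decisions and skipped fractions — enough to replay
    the analysis verbatim.
    """
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    calibration = (CalibrationTable.from_csv(config.calibration_csv)
                   if config.calibration_csv else CalibrationTable.default())
    shifts = read_shift_table(config.shift_csv,
                              n_fractions=len(config.fraction_images))
    ctv = read_volume(config.ctv_mask).values > 0.5
    body = read_volume(config.body_mask).values > 0.5 \
        if config.body_mask else None
    records: List[FractionRecord] = []
    for idx, image_path in enumerate(config.fraction_images):
        rec = shifts[idx]
        vol = read_volume(image_path)
        records.append(FractionRecord(
            fraction_index=rec.fraction, image=vol.values, spacing=vol.spacing,
            is_sp=config.sp_input, shift=(rec.dx_mm, rec.dy_mm), dz=rec.dz_mm,
            rotation=rec.rotation_deg, usable=rec.usable,
            excluded_slices=tuple(config.excluded_slices)))
    usable = [r for r in records if r.usable]
    if not usable:
        raise VolumeIOError("no usable fractions in the course")
    if config.reference_fraction is not None:
        reference = next((r for r in records
                          if r.fraction_index == config.reference_fraction), None)
        if reference is None or not reference.usable:
            raise VolumeIOError(
                f"reference fraction {config.reference_fraction} not usable")
    else:
        reference = usable[0]
    beams = [BeamGeometry(gantry_angle=a, source_axis_distance=config.sad)
             for a in config.angles]
    circle = (ScanningCircle(center=config.circle_center,
                             diameter=config.circle_diameter)
              if config.circle_diameter else None)
    options = CourseOptions(patient_id=config.patient_id,
                            bin_width=config.bin_width,
                            fill_sp=config.fill_sp)
    samples, summaries = run_course(
        reference, records, ctv, body, beams, calibration=calibration,
        circle=circle, options=options)
    table = population_table(samples, summaries,
                             sigma_method=config.sigma_method)

    write_summary_csv(outdir / "summaries.csv", summaries)
    write_histogram_csv(outdir / "histograms.csv", summaries)
    write_population_csv(outdir / "population.csv", table)
    artifacts = ["summaries.csv", "histograms.csv", "population.csv"]
    if config.write_samples:
        write_samples_csv(outdir / "samples.csv", samples)
        artifacts.append("samples.csv")
    if config.make_figures:
        for angle in config.angles:
            name = f"heatmap_{config.patient_id}_{angle:g}.png"
            _heatmap_figure(summaries, angle, outdir / name,
                            bin_width=config.bin_width)
            artifacts.append(name)
    log = {
        "software": {"name": "weplrange", "version": __version__},
        "config": config.to_dict(),
        "reference_fraction": reference.fraction_index,
        "skipped_fractions": [r.fraction_index for r in records
                              if not r.usable],
        "excluded_slices": list(config.excluded_slices),
        "n_samples": len(samples),
        "outputs": artifacts,
    }
    with open(outdir / "run_log.json", "w") as fh:
        json.dump(log, fh, indent=2, sort_keys=True)
    return outdir
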