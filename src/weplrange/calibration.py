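"""HU → relative proton stopping power calibration.

A megavoltage CT number is mapped to relative proton stopping power in two
stages.  First, the electron density of each calibration insert (relative to
water, rho_e/rho_ew) is converted to a stopping power relative to water with
the Bethe–Bloch ratio

    S_rel = (rho_e / rho_ew)
            * [ln(2 m_e c^2 beta^2 / (I (1 - beta^2))) - beta^2]
            / [ln(2 m_e c^2 beta^2 / (I_w (1 - beta^2))) - beta^2]

where I and I_w are the mean excitation energies of the material and of
water (I_w = 75 eV by default) and beta = v/c of the proton.  The ratio is
very nearly energy independent over therapeutic energies, which is what
makes a single HU→SP curve usable: for the worst-case insert (cortical
bone) the difference between 90 and 310 MeV is below 0.6 %.  Second, the
(measured HU, S_rel) pairs form a piecewise-linear calibration curve that is
evaluated per pixel.

The shipped default curve is a helical megavoltage-CT calibration measured
with a density-plug phantom; its knots are available as
:data:`DEFAULT_KNOTS` and via :meth:`CalibrationTable.default`.
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Sequence, Union

import numpy as np

__all__ = [
    "PhysicalConstants",
    "InsertSpec",
    "CalibrationTable",
    "RangeEnergyParams",
    "DEFAULT_CONSTANTS",
    "DEFAULT_KNOTS",
    "CORTICAL_BONE_I_EV",
    "CORTICAL_BONE_RHO_E",
    "beta_squared",
    "relative_stopping_power",
    "range_from_energy",
    "energy_independence_check",
    "build_calibration",
    "hu_to_sp",
    "load_inserts",
    "default_inserts",
]


class CalibrationError(ValueError):
    """Invalid input to a calibration computation."""


class NumericDomainError(CalibrationError):
    """A logarithm argument in the stopping-power ratio became non-positive."""


@dataclass(frozen=True)
class PhysicalConstants:
    """Rest energies and the water mean excitation energy.

    electron_rest_energy : MeV (m_e c^2)
    proton_rest_energy   : MeV (m_p c^2); converts kinetic energy to beta
    water_ionisation_potential : eV (I_w); 75 eV by convention, configurable
    """

    electron_rest_energy: float = 0.511
    proton_rest_energy: float = 938.272
    water_ionisation_potential: float = 75.0

    def __post_init__(self) -> None:
        for name in ("electron_rest_energy", "proton_rest_energy",
                     "water_ionisation_potential"):
            if getattr(self, name) <= 0:
                raise CalibrationError(f"{name} must be strictly positive")


DEFAULT_CONSTANTS = PhysicalConstants()

#: Manufacturer-typical mean excitation energy (eV) of the cortical-bone
#: substitute, used by the energy-independence check.
CORTICAL_BONE_I_EV = 87.0
#: Relative electron density of the cortical-bone substitute.
CORTICAL_BONE_RHO_E = 1.69


@dataclass(frozen=True)
class InsertSpec:
    """One calibration phantom insert.

    ``relative_electron_density`` is rho_e/rho_ew; ``ionisation_potential``
    is the mean excitation energy I in eV; ``measured_hu`` is the CT number
    measured for the insert on the scanner being calibrated.
    """

    name: str
    physical_density: float
    relative_electron_density: float
    ionisation_potential: float
    measured_hu: float

    def __post_init__(self) -> None:
        if self.relative_electron_density < 0:
            raise CalibrationError(
                f"insert {self.name!r}: relative_electron_density must be >= 0")
        if self.relative_electron_density > 0 and self.ionisation_potential <= 0:
            raise CalibrationError(
                f"insert {self.name!r}: ionisation_potential must be > 0")


#: Default calibration knots (HU, relative stopping power): air, lung,
#: water, inner bone, bone mineral, 30 % CaCO3, 50 % CaCO3, cortical bone.
DEFAULT_KNOTS: tuple[tuple[float, float], ...] = (
    (-970.0, 0.0),
    (-479.0, 0.481),
    (9.5, 1.00),
    (118.0, 1.081),
    (127.0, 1.091),
    (292.0, 1.258),
    (474.0, 1.431),
    (673.0, 1.622),
)


@dataclass(frozen=True)
class CalibrationTable:
    """Ordered (HU, relative stopping power) knots of a piecewise-linear curve."""

    knots: tuple[tuple[float, float], ...]

    def __post_init__(self) -> None:
        if len(self.knots) < 2:
            raise CalibrationError("calibration table needs at least 2 knots")
        hu = np.asarray([k[0] for k in self.knots], dtype=float)
        sp = np.asarray([k[1] for k in self.knots], dtype=float)
        if np.any(np.diff(hu) <= 0):
            raise CalibrationError("knot HU values must be strictly increasing")
        if np.any(sp < 0):
            raise CalibrationError("knot stopping powers must be non-negative")

    @property
    def hu(self) -> np.ndarray:
        return np.asarray([k[0] for k in self.knots], dtype=float)

    @property
    def sp(self) -> np.ndarray:
        return np.asarray([k[1] for k in self.knots], dtype=float)

    @classmethod
    def default(cls) -> "CalibrationTable":
        return cls(DEFAULT_KNOTS)

    @classmethod
    def from_csv(cls, path: Union[str, Path]) -> "CalibrationTable":
        """Read a ``hu,sp`` CSV (lines starting with ``#`` are comments)."""
        knots = []
        with open(path, newline="") as fh:
            rows = [r for r in csv.reader(fh)
                    if r and not r[0].lstrip().startswith("#")]
        if not rows or [c.strip().lower() for c in rows[0]] != ["hu", "sp"]:
            raise CalibrationError(f"{path}: expected header 'hu,sp'")
        for row in rows[1:]:
            knots.append((float(row[0]), float(row[1])))
        return cls(tuple(knots))

    def to_csv(self, path: Union[str, Path]) -> None:
        with open(path, "w", newline="") as fh:
            writer = csv.writer(fh)
            writer.writerow(["hu", "sp"])
            for hu, sp in self.knots:
                writer.writerow([f"{hu:g}", f"{sp:g}"])


@dataclass(frozen=True)
class RangeEnergyParams:
    """Power-law range–energy relation R = alpha * E**p (R in cm, E in MeV)."""

    alpha: float = 0.0022
    p: float = 1.77

    def __post_init__(self) -> None:
        if self.alpha <= 0 or self.p <= 0:
            raise CalibrationError("alpha and p must be strictly positive")


def beta_squared(energy: float,
                 constants: PhysicalConstants = DEFAULT_CONSTANTS) -> float:
    """beta^2 = 1 - (m_p c^2 / (m_p c^2 + E))^2 for kinetic energy E in MeV."""
    if energy < 0:
        raise CalibrationError(f"kinetic energy must be >= 0, got {energy}")
    ratio = constants.proton_rest_energy / (constants.proton_rest_energy + energy)
    return 1.0 - ratio * ratio


def _bracket(energy: float, ionisation_potential_ev: float,
             constants: PhysicalConstants) -> float:
    """ln(2 m_e c^2 beta^2 / (I (1-beta^2))) - beta^2, with I in eV."""
    b2 = beta_squared(energy, constants)
    if b2 <= 0.0:
        raise NumericDomainError(
            "beta^2 = 0: the stopping-power logarithm diverges at zero energy")
    mec2_ev = constants.electron_rest_energy * 1e6
    arg = 2.0 * mec2_ev * b2 / (ionisation_potential_ev * (1.0 - b2))
    log_term = math.log(arg)
    value = log_term - b2
    if value <= 0.0:
        raise NumericDomainError(
            f"non-positive stopping-power bracket ln({arg:g}) - beta^2 = "
            f"{value:g} (I = {ionisation_potential_ev} eV, E = {energy} MeV)")
    return value


def relative_stopping_power(rho_e_rel: float, ionisation_potential: float,
                            energy: float,
                            constants: PhysicalConstants = DEFAULT_CONSTANTS,
                            ) -> float:
    """Stopping power relative to water via the Bethe–Bloch ratio.

    Parameters
    ----------
    rho_e_rel : electron density relative to water (rho_e / rho_ew), >= 0.
    ionisation_potential : mean excitation energy I of the material, eV.
    energy : proton kinetic energy, MeV.

    Vanishes identically for rho_e_rel = 0 (e.g. air), without evaluating
    the material bracket.
    """
    if rho_e_rel < 0:
        raise CalibrationError("rho_e_rel must be >= 0")
    if rho_e_rel == 0.0:
        return 0.0
    if ionisation_potential <= 0:
        raise CalibrationError("ionisation_potential must be > 0")
    num = _bracket(energy, ionisation_potential, constants)
    den = _bracket(energy, constants.water_ionisation_potential, constants)
    return rho_e_rel * num / den


def range_from_energy(energy: float,
                      params: RangeEnergyParams = RangeEnergyParams()) -> float:
    """Proton range in water, cm, from the power law R = alpha * E**p."""
    if energy < 0:
        raise CalibrationError(f"kinetic energy must be >= 0, got {energy}")
    return params.alpha * energy ** params.p


def energy_independence_check(rho_e_rel: float, ionisation_potential: float,
                              energy_low: float, energy_high: float,
                              constants: PhysicalConstants = DEFAULT_CONSTANTS,
                              ) -> float:
    """Percent difference of S_rel between two energies.

    Returns 100 * |S_rel(E_low) - S_rel(E_high)| / S_rel(E_low).  Exactly
    zero when I equals I_w, since the ratio is then 1 at every energy.
    """
    s_low = relative_stopping_power(rho_e_rel, ionisation_potential,
                                    energy_low, constants)
    s_high = relative_stopping_power(rho_e_rel, ionisation_potential,
                                     energy_high, constants)
    if s_low == 0.0:
        return 0.0
    return 100.0 * abs(s_low - s_high) / s_low


def build_calibration(inserts: Sequence[InsertSpec], energy: float = 150.0,
                      constants: PhysicalConstants = DEFAULT_CONSTANTS,
                      ) -> CalibrationTable:
    """Build a calibration curve from phantom inserts at a reference energy.

    The reference energy defaults to 150 MeV (mid treatment range); by the
    energy-independence property the choice shifts the curve by well under
    a percent.
    """
    if len(inserts) < 2:
        raise CalibrationError("need at least 2 inserts")
    hus = [ins.measured_hu for ins in inserts]
    if len(set(hus)) != len(hus):
        raise CalibrationError("duplicate measured HU values among inserts")
    knots = sorted(
        (ins.measured_hu,
         relative_stopping_power(ins.relative_electron_density,
                                 ins.ionisation_potential
                                 if ins.relative_electron_density > 0 else
                                 constants.water_ionisation_potential,
                                 energy, constants))
        for ins in inserts)
    return CalibrationTable(tuple(knots))


def hu_to_sp(hu, table: CalibrationTable):
    """Piecewise-linear evaluation of the calibration curve.

    Below the lowest knot the value is clamped to 0; above the highest knot
    the last segment is extrapolated linearly (metal-bright pixels).  The
    result is clipped at 0 so no pixel acquires a negative stopping power.
    Accepts scalars or arrays; NaN inputs map to 0 with the count available
    to callers via ``np.isnan`` beforehand.
    """
    hu_arr = np.asarray(hu, dtype=float)
    knot_hu, knot_sp = table.hu, table.sp
    out = np.interp(hu_arr, knot_hu, knot_sp)
    # linear extrapolation above the top knot from the last segment
    slope = (knot_sp[-1] - knot_sp[-2]) / (knot_hu[-1] - knot_hu[-2])
    above = hu_arr > knot_hu[-1]
    if np.any(above):
        out = np.where(above, knot_sp[-1] + slope * (hu_arr - knot_hu[-1]), out)
    out = np.where(hu_arr < knot_hu[0], 0.0, out)
    out = np.where(np.isnan(hu_arr), 0.0, np.maximum(out, 0.0))
    if np.isscalar(hu) or np.ndim(hu) == 0:
        return float(out)
    return out


def load_inserts(path: Union[str, Path]) -> tuple[InsertSpec, ...]:
    """Read an insert CSV: ``name,density,rel_electron_density,ionisation_ev,hu``.

    Lines starting with ``#`` are comments.
    """
    with open(path, newline="") as fh:
        rows = [r for r in csv.reader(fh)
                if r and not r[0].lstrip().startswith("#")]
    expected = ["name", "density", "rel_electron_density", "ionisation_ev", "hu"]
    if not rows or [c.strip().lower() for c in rows[0]] != expected:
        raise CalibrationError(f"{path}: expected header {','.join(expected)}")
    return tuple(
        InsertSpec(name=r[0], physical_density=float(r[1]),
                   relative_electron_density=float(r[2]),
                   ionisation_potential=float(r[3]), measured_hu=float(r[4]))
        for r in rows[1:])


def default_inserts() -> tuple[InsertSpec, ...]:
    """The shipped density-plug insert set (see ``data/mvct_inserts.csv``)."""
    ref = resources.files("weplrange.data").joinpath("mvct_inserts.csv")
    with resources.as_file(ref) as path:
        return load_inserts(path)
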