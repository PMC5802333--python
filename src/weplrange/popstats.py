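"""Population range-error statistics: overall mean, systematic Σ, random σ.

The systematic component Σ is the standard deviation of the per-fraction
*mean* range changes pooled across patients (and, for the overall row,
across beam angles): the part of the error that shifts a whole fraction.
The random component σ is the spread of the individual per-pixel range
changes: weighting is therefore by number of data points, not by number of
images.  Both the pooled definition of σ (about the grand mean, so it
includes between-fraction mean variation) and a within-fraction definition
(per-fraction means removed) are provided; the pooled one is the default.

All estimators use the sample (n−1) standard deviation.  Means and Σ weight
each analysed image once — image-count weighting, not patient-count
weighting.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import List, Optional, Sequence, Union

import numpy as np

from .fraction import FractionSummary, RangeErrorSample

__all__ = ["PopulationStats", "UndefinedStatisticError", "overall_mean",
           "systematic_sigma", "random_sigma", "population_table"]


class UndefinedStatisticError(ValueError):
    """Too few data to define the requested statistic."""


@dataclass
class PopulationStats:
    """One row of the population table: a beam angle or the pooled 'All'."""

    gantry_angle: Union[float, str]
    mean: float
    sigma_systematic: float   # Σ, mm
    sigma_random: float       # σ, mm
    n_fractions: int
    n_pixels: int
    error: Optional[str] = None


def overall_mean(summaries: Sequence[FractionSummary]) -> float:
    """Image-weighted overall mean: each analysed fraction image counts once."""
    if not summaries:
        raise UndefinedStatisticError("no summaries: overall mean undefined")
    return float(np.mean([s.mean for s in summaries]))


def systematic_sigma(summaries: Sequence[FractionSummary]) -> float:
    """Σ: sample SD of the per-fraction mean range changes in the group."""
    if len(summaries) < 2:
        raise UndefinedStatisticError(
            "systematic sigma needs at least 2 fraction summaries")
    return float(np.std([s.mean for s in summaries], ddof=1))


def random_sigma(samples: Sequence[RangeErrorSample],
                 method: str = "pooled") -> float:
    """σ: spread of the per-pixel range changes, point-count weighted.

    method='pooled'  : sample SD of all per-pixel deltas concatenated,
                       about the pooled grand mean (includes
                       between-fraction mean variation).
    method='within'  : sqrt of the pixel-weighted mean of within-fraction
                       variances (per-fraction means removed).
    """
    if method not in ("pooled", "within"):
        raise ValueError(f"unknown sigma method {method!r}")
    arrays = [s.delta_wepl for s in samples if s.n_pixels > 0]
    total = sum(a.size for a in arrays)
    if total < 2:
        raise UndefinedStatisticError(
            "random sigma needs at least 2 pixel values")
    if method == "pooled":
        return float(np.std(np.concatenate(arrays), ddof=1))
    # within: sum of squared residuals about each fraction's own mean,
    # divided by (N - n_fractions) so each pixel keeps unit weight
    ss = sum(float(np.sum((a - a.mean()) ** 2)) for a in arrays)
    dof = total - len(arrays)
    if dof < 1:
        raise UndefinedStatisticError("within-fraction sigma needs >1 pixel "
                                      "in at least one fraction")
    return math.sqrt(ss / dof)


def population_table(samples: Sequence[RangeErrorSample],
                     summaries: Sequence[FractionSummary],
                     group_by_angle: bool = True,
                     sigma_method: str = "pooled") -> List[PopulationStats]:
    """Rows per gantry angle plus a terminal pooled 'All' row.

    A group whose statistics are undefined (too few fractions or pixels) is
    reported with NaN entries and the error message, leaving other rows
    intact.
    """
    if not summaries:
        raise UndefinedStatisticError("no summaries to tabulate")
    angles = sorted({s.gantry_angle for s in summaries}) if group_by_angle else []
    rows: List[PopulationStats] = []
    groups = [(a, [s for s in samples if s.gantry_angle == a],
               [s for s in summaries if s.gantry_angle == a]) for a in angles]
    groups.append(("All", list(samples), list(summaries)))
    for label, g_samples, g_summaries in groups:
        n_pixels = sum(s.n_pixels for s in g_samples)
        try:
            rows.append(PopulationStats(
                gantry_angle=label,
                mean=overall_mean(g_summaries),
                sigma_systematic=systematic_sigma(g_summaries),
                sigma_random=random_sigma(g_samples, method=sigma_method),
                n_fractions=len(g_summaries), n_pixels=n_pixels))
        except UndefinedStatisticError as exc:
            rows.append(PopulationStats(
                gantry_angle=label, mean=float("nan"),
                sigma_systematic=float("nan"), sigma_random=float("nan"),
                n_fractions=len(g_summaries), n_pixels=n_pixels,
                error=str(exc)))
    return rows
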