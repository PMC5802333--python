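"""Independent brute-force oracles used by the test suite.

These deliberately avoid the package's exact-traversal code path: the WEPL
oracle integrates by fine fixed-step sampling of the stopping-power grid
along the ray, so agreement with the analytic grid walk is a genuine
cross-check, not a tautology.
"""

import math

import numpy as np

from weplrange.raytrace import BeamGeometry, SPImage, ray_direction


def fine_step_wepl(image: SPImage, target_pixel, beam: BeamGeometry,
                   step_divisor: float = 1000.0) -> float:
    """Midpoint-rule WEPL with step = min(pixel spacing) / step_divisor."""
    r, c = target_pixel
    px, py = image.pixel_center(r, c)
    dx, dy = ray_direction((px, py), beam)
    xmin, xmax, ymin, ymax = image.bounds
    t_entry = -math.inf
    if dx > 0:
        t_entry = max(t_entry, (xmin - px) / dx)
    elif dx < 0:
        t_entry = max(t_entry, (xmax - px) / dx)
    if dy > 0:
        t_entry = max(t_entry, (ymin - py) / dy)
    elif dy < 0:
        t_entry = max(t_entry, (ymax - py) / dy)
    t_entry = min(t_entry, 0.0)
    step = min(image.pixel_spacing) / step_divisor
    n = max(1, int(math.ceil(-t_entry / step)))
    edges = np.linspace(t_entry, 0.0, n + 1)
    mids = (edges[:-1] + edges[1:]) / 2.0
    seg = np.diff(edges)
    xs = px + mids * dx
    ys = py + mids * dy
    sy, sx = image.pixel_spacing
    nrows, ncols = image.shape
    cols = np.floor((xs - xmin) / sx).astype(int)
    rows = np.floor((ymax - ys) / sy).astype(int)
    inside = (rows >= 0) & (rows < nrows) & (cols >= 0) & (cols < ncols)
    vals = np.zeros_like(mids)
    vals[inside] = image.values[rows[inside], cols[inside]]
    return float(np.sum(vals * seg))
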