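"""Pairwise plant-spacing simulation: pixel-area loss from overlapping shoots.

Two silhouettes recorded in isolation are composed at a chosen
centre-to-centre spacing, as if the plants stood that far apart on the same
bench: the pixel sets are aligned on their base rows (both plants stand at
bench level) and on their pot-centre reference columns.  The union is what
the LC would record for the pair; any shortfall of the union against the sum
of the individual areas is the *underestimation* caused by overlap.  The
*overlap width* is the maximum horizontal extent of the shared pixels.

The sweep enumerates all 18 x 18 view-angle combinations of the two plants
at each spacing (default 20 cm down to 0 cm in 4 cm steps), mirroring how a
real pair could face the sensor in any orientation combination.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import CompositionError
from .lc_io import VIEW_ANGLES, Silhouette

DEFAULT_DISTANCES_CM = (20.0, 16.0, 12.0, 8.0, 4.0, 0.0)


@dataclass(frozen=True)
class SpacingSimResult:
    """One composition: a pair of view angles at one spacing distance."""

    spacing_cm: float
    angle_a: int
    angle_b: int
    area_a: int
    area_b: int
    union_area: int
    underestimation: float  # percent of the summed individual areas
    overlap_width_cm: float


def _normalized(sil: Silhouette, col_shift: int = 0):
    """Pixels re-based so base_row -> 0 and ref_col -> col_shift."""
    return {(r - sil.base_row, c - sil.ref_col + col_shift) for r, c in sil.pixels}


def compose_pair(a: Silhouette, b: Silhouette, spacing_cm: float):
    """Union and intersection pixel sets of two silhouettes at a spacing.

    ``b`` is translated so the two pot-centre reference columns are
    ``spacing_cm`` apart (rounded to the nearest column); rows are aligned
    on each silhouette's base row.
    """
    if not (
        math.isclose(a.v_pitch, b.v_pitch, rel_tol=1e-9)
        and math.isclose(a.h_pitch, b.h_pitch, rel_tol=1e-9)
    ):
        raise CompositionError(
            f"pitch mismatch: ({a.v_pitch}, {a.h_pitch}) vs ({b.v_pitch}, {b.h_pitch})"
        )
    shift = int(round(spacing_cm * 10.0 / a.h_pitch))
    pa = _normalized(a)
    pb = _normalized(b, shift)
    return pa | pb, pa & pb


def overlap_width(intersection, h_pitch: float) -> float:
    """Maximum horizontal extent of the shared pixels, in cm (0 if empty)."""
    if not intersection:
        return 0.0
    cols = [c for _, c in intersection]
    return (max(cols) - min(cols) + 1) * h_pitch / 10.0


def underestimation(a: Silhouette, b: Silhouette, spacing_cm: float) -> float:
    """Percent by which the composed pixel area falls short of the summed areas."""
    return simulate_pair(a, b, 0, 0, spacing_cm).underestimation


def simulate_pair(
    a: Silhouette, b: Silhouette, angle_a: int, angle_b: int, spacing_cm: float
) -> SpacingSimResult:
    union, inter = compose_pair(a, b, spacing_cm)
    na, nb = len(a.pixels), len(b.pixels)
    total = na + nb
    under = 100.0 * (total - len(union)) / total if total else 0.0
    return SpacingSimResult(
        spacing_cm=float(spacing_cm),
        angle_a=int(angle_a),
        angle_b=int(angle_b),
        area_a=na,
        area_b=nb,
        union_area=len(union),
        underestimation=under,
        overlap_width_cm=overlap_width(inter, a.h_pitch),
    )


def sweep_spacing(stack_a, stack_b, distances_cm=DEFAULT_DISTANCES_CM):
    """Compose every 18 x 18 view-angle combination at each spacing.

    Returns ``(table, aggregates)``: a long-format DataFrame with one row
    per (spacing, angle_a, angle_b) — 324 rows per distance — and a
    per-distance aggregate DataFrame (mean/max underestimation, mean/max
    overlap width).
    """
    stack_a.require_complete()
    stack_b.require_complete()
    rows = []
    for d in distances_cm:
        for ang_a in VIEW_ANGLES:
            for ang_b in VIEW_ANGLES:
                res = simulate_pair(
                    stack_a.views[ang_a], stack_b.views[ang_b], ang_a, ang_b, d
                )
                rows.append(res.__dict__)
    table = pd.DataFrame(rows)
    agg = (
        table.groupby("spacing_cm")
        .agg(
            mean_underestimation=("underestimation", "mean"),
            max_underestimation=("underestimation", "max"),
            mean_overlap_width_cm=("overlap_width_cm", "mean"),
            max_overlap_width_cm=("overlap_width_cm", "max"),
            n=("underestimation", "size"),
        )
        .reset_index()
    )
    return table, agg


def spacing_study(
    n_pairs: int = 10,
    seed: int = 1,
    spacing_cm: float = 12.0,
    speed: float = 0.9,
    canopy_diameter_mm=(150.0, 250.0),
    area_cm2=(60.0, 350.0),
):
    """Seeded dicot-pair spacing experiment at one distance.

    Generates ``n_pairs`` pairs of synthetic rosette plants with canopy
    diameters and true leaf areas in the given ranges, builds their 18-view
    stacks, runs the 18 x 18 angle-combination composition at ``spacing_cm``
    and returns ``(mean_underestimation_pct, mean_overlap_width_cm, n)``
    where n counts all compositions across pairs.
    """
    from .synthetic import DICOT_ROSETTE, make_plant, make_view_stack
    from dataclasses import replace

    params = replace(
        DICOT_ROSETTE, canopy_diameter_mm=tuple(canopy_diameter_mm), area_cm2=tuple(area_cm2)
    )
    rng = np.random.default_rng(seed)
    seeds = rng.integers(0, 2**31 - 1, size=2 * n_pairs)
    unders, widths = [], []
    for k in range(n_pairs):
        pa = make_plant("dicot_rosette", params, int(seeds[2 * k]))
        pb = make_plant("dicot_rosette", params, int(seeds[2 * k + 1]))
        sa = make_view_stack(pa, speed=speed)
        sb = make_view_stack(pb, speed=speed)
        table, _ = sweep_spacing(sa, sb, distances_cm=[spacing_cm])
        unders.extend(table["underestimation"].tolist())
        widths.extend(table["overlap_width_cm"].tolist())
    return float(np.mean(unders)), float(np.mean(widths)), len(unders)
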