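"""Ground-truthed synthetic plants and their light-curtain renders.

No raw scans from the original experiments are available, so every stage of
the pipeline is exercised against parametric plants with exactly known leaf
area and height.  Two architectural archetypes are modelled:

* ``dicot_rosette`` — planophile: broad elliptical blades on petioles
  radiating from a short stem at low elevation (rapeseed/tomato habit);
* ``monocot`` — erectophile: long narrow tapering blades rising steeply
  from a short culm and arching over (maize/barley habit).

Blades are planar strips with an elliptical width profile, so the true
blade area is exactly pi * L * W / 4; a plant's ``true_leaf_area`` is the
sum over blades.  ``true_max_height`` is the highest point of the geometric
model above the plant base (the upper pot edge).

The render model is the physical core of the method: LC beams are parallel,
so the projection is orthographic.  A plant rotated by the view angle about
its vertical axis is projected onto the travel-height plane; a grid cell is
foreground iff a shape covers its centre *and* the local occlusion
thickness (chord length of the beam through the tissue) meets a threshold
(default 1 mm) — very thin tissue does not interrupt a beam, which is what
truncates the fine tips of erect monocot leaves.  Self-occlusion within a
plant is automatic: a pixel is either interrupted or not.

The horizontal pixel pitch scales with scanning speed (fixed temporal
sampling), reproducing the inverse proportionality of raw pixel area to
speed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .errors import GenerationError, LayoutError, ValidationError
from .lc_io import (
    H_REF,
    POT_HEIGHT_DEFAULT,
    POT_WIDTH_DEFAULT,
    SPEED_REF,
    V_PITCH_DEFAULT,
    VIEW_ANGLES,
    ScanMatrix,
    Silhouette,
    h_pitch_for_speed,
)
from .segmentation import DEFAULT_POT_EDGE_THRESHOLD, DEFAULT_RADIUS, segment_scan
from .traits import ViewStack

#: default occlusion-thickness threshold, mm (beam diameter is not published)
THICKNESS_THRESHOLD_DEFAULT = 1.0
#: cap on the beam chord length through a single shape, mm
_CHORD_CAP = 30.0
#: blade strip count along the midrib
_N_STRIPS = 12


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Leaf:
    """One blade: midrib from ``base`` at ``azimuth``/``elevation``.

    ``arch`` is the total downward bend of the midrib elevation from base to
    tip (deg; 0 for a flat dicot blade).  ``shape`` selects the width
    profile: ``'ellipse'`` (widest mid-blade) or ``'taper'`` (widest at the
    base, tapering to the tip).  ``thickness``/``tip_thickness`` give the
    tissue thickness (mm) on the inner 80% of the blade and at the very tip.
    """

    base: tuple
    azimuth: float
    elevation: float
    length: float
    width: float
    petiole: float = 0.0
    arch: float = 0.0
    shape: str = "ellipse"
    thickness: float = 2.0
    tip_thickness: float = 0.2

    @property
    def blade_area_mm2(self) -> float:
        return math.pi * self.length * self.width / 4.0


@dataclass(frozen=True)
class ArchetypeParams:
    """Sampling ranges for one architectural archetype (all mm / deg / cm^2)."""

    leaf_count: tuple
    elevation_deg: tuple
    arch_deg: tuple
    canopy_diameter_mm: tuple
    stem_height_mm: tuple
    height_mm: tuple
    area_cm2: tuple
    petiole_frac: tuple
    width_ratio: tuple      # admissible blade width/length interval
    stem_diameter_mm: float = 8.0
    blade_thickness_mm: float = 2.0
    tip_thickness_mm: float = 0.2

    def __post_init__(self):
        for name in (
            "leaf_count", "elevation_deg", "arch_deg", "canopy_diameter_mm",
            "stem_height_mm", "height_mm", "area_cm2", "petiole_frac", "width_ratio",
        ):
            lo, hi = getattr(self, name)
            if not (lo <= hi):
                raise ValidationError(f"{name} range must be ordered, got ({lo}, {hi})")
            if name != "arch_deg" and lo < 0:
                raise ValidationError(f"{name} range must be positive")


DICOT_ROSETTE = ArchetypeParams(
    leaf_count=(4, 14),
    elevation_deg=(15.0, 40.0),
    arch_deg=(0.0, 0.0),
    canopy_diameter_mm=(100.0, 280.0),
    stem_height_mm=(20.0, 60.0),
    height_mm=(25.0, 220.0),
    area_cm2=(12.0, 350.0),
    petiole_frac=(0.35, 0.6),
    width_ratio=(0.25, 0.9),
)

MONOCOT = ArchetypeParams(
    leaf_count=(3, 9),
    elevation_deg=(60.0, 80.0),
    arch_deg=(30.0, 70.0),
    canopy_diameter_mm=(50.0, 900.0),
    stem_height_mm=(20.0, 80.0),
    height_mm=(70.0, 680.0),
    area_cm2=(7.0, 317.0),
    petiole_frac=(0.0, 0.0),
    width_ratio=(0.008, 0.25),
    stem_diameter_mm=10.0,
    blade_thickness_mm=2.0,
    tip_thickness_mm=0.15,
)

_ARCHETYPE_DEFAULTS = {"dicot_rosette": DICOT_ROSETTE, "monocot": MONOCOT}


@dataclass(frozen=True)
class SyntheticPlant:
    """A parametric plant with exact ground truth.

    Coordinates are mm in the plant frame: origin at the stem base (upper
    pot edge level), z up.  ``true_leaf_area`` (cm^2) is the analytic sum of
    blade areas; ``true_max_height`` (mm) is the highest model point.
    """

    archetype: str
    leaves: tuple
    stem_height: float
    stem_diameter: float
    true_leaf_area: float
    true_max_height: float
    rng_seed: int | None = None

    def __post_init__(self):
        if self.archetype not in _ARCHETYPE_DEFAULTS:
            raise ValidationError(f"unknown archetype {self.archetype!r}")
        if self.true_leaf_area < 0 or self.true_max_height < self.stem_height - 1e-9:
            raise ValidationError("inconsistent ground-truth fields")
        object.__setattr__(self, "leaves", tuple(self.leaves))


# ---------------------------------------------------------------------------
# geometry: primitives, projection, rasterization
# ---------------------------------------------------------------------------

def _unit(v):
    n = np.linalg.norm(v)
    return v / n if n > 0 else v


def _blade_nodes(leaf: Leaf):
    """Midrib nodes, edge offsets and per-strip thickness for one blade."""
    phi = math.radians(leaf.azimuth)
    cross = np.array([-math.sin(phi), math.cos(phi), 0.0])
    u = np.linspace(0.0, 1.0, _N_STRIPS + 1)
    beta = np.radians(leaf.elevation - leaf.arch * u)
    start_dir = np.array(
        [math.cos(beta[0]) * math.cos(phi), math.cos(beta[0]) * math.sin(phi), math.sin(beta[0])]
    )
    p = np.asarray(leaf.base, dtype=float) + leaf.petiole * start_dir
    pts = [p]
    seg = leaf.length / _N_STRIPS
    for k in range(_N_STRIPS):
        bmid = (beta[k] + beta[k + 1]) / 2.0
        d = np.array(
            [math.cos(bmid) * math.cos(phi), math.cos(bmid) * math.sin(phi), math.sin(bmid)]
        )
        p = p + seg * d
        pts.append(p)
    pts = np.array(pts)
    if leaf.shape == "ellipse":
        w = 0.5 * leaf.width * np.sqrt(np.clip(1.0 - (2.0 * u - 1.0) ** 2, 0.0, None))
    elif leaf.shape == "taper":
        w = 0.5 * leaf.width * np.sqrt(np.clip(1.0 - u**2, 0.0, None))
    else:
        raise ValidationError(f"unknown blade shape {leaf.shape!r}")
    umid = (u[:-1] + u[1:]) / 2.0
    t = np.where(
        umid < 0.8,
        leaf.thickness,
        leaf.thickness + (umid - 0.8) / 0.2 * (leaf.tip_thickness - leaf.thickness),
    )
    return pts, w, cross, t


def _plant_primitives(plant: SyntheticPlant):
    """3-D primitives: ('quad', verts(4,3), t) and ('rod', p0, p1, d, t)."""
    prims = []
    top = np.array([0.0, 0.0, plant.stem_height])
    prims.append(("rod", np.zeros(3), top, plant.stem_diameter, plant.stem_diameter))
    for leaf in plant.leaves:
        pts, w, cross, t = _blade_nodes(leaf)
        if leaf.petiole > 0:
            d = 4.0
            prims.append(("rod", np.asarray(leaf.base, float), pts[0], d, d))
        for k in range(_N_STRIPS):
            quad = np.array(
                [
                    pts[k] - w[k] * cross,
                    pts[k] + w[k] * cross,
                    pts[k + 1] + w[k + 1] * cross,
                    pts[k + 1] - w[k + 1] * cross,
                ]
            )
            prims.append(("quad", quad, float(t[k])))
            # midrib rod: keeps edge-on blades visible, shares the taper
            prims.append(("rod", pts[k], pts[k + 1], max(leaf.thickness, 1.5), float(t[k])))
    return prims


def _plant_extent(plant: SyntheticPlant):
    """(horizontal reach, model height) in mm from the primitive vertices."""
    reach = height = 0.0
    for prim in _plant_primitives(plant):
        verts = prim[1] if prim[0] == "quad" else np.array([prim[1], prim[2]])
        reach = max(reach, float(np.hypot(verts[:, 0], verts[:, 1]).max()))
        height = max(height, float(verts[:, 2].max()))
    return reach, height


def project(plant: SyntheticPlant, view_angle: float):
    """Orthographic projection of the plant rotated by ``view_angle``.

    Rotates the model about its vertical axis, projects onto the
    (travel, height) plane and returns a list of shapes, one per solid
    primitive: ``(triangles(k, 3, 2), occlusion_thickness_mm)``.  The
    thickness is the beam chord through the tissue: ``t / |n . beam|`` for
    blade strips (long for edge-on blades, the bare tissue thickness
    face-on), capped at 30 mm; it accumulates across shapes but counts once
    per shape however many of its triangles cover a point.
    """
    return _project_prims(_plant_primitives(plant), view_angle)


def _project_prims(prims, view_angle: float):
    th = math.radians(view_angle)
    rot = np.array(
        [[math.cos(th), -math.sin(th), 0.0], [math.sin(th), math.cos(th), 0.0], [0.0, 0.0, 1.0]]
    )
    beam = np.array([0.0, 1.0, 0.0])
    shapes = []
    for prim in prims:
        if prim[0] == "quad":
            _, quad, t = prim
            q = quad @ rot.T
            n = _unit(np.cross(q[1] - q[0], q[3] - q[0]))
            denom = max(abs(float(n @ beam)), t / _CHORD_CAP if t > 0 else 1e-6)
            chord = t / denom if t > 0 else 0.0
            flat = q[:, [0, 2]]
            shapes.append((np.stack([flat[[0, 1, 2]], flat[[0, 2, 3]]]), chord))
        else:
            _, p0, p1, d, t = prim
            a, b = p0 @ rot.T, p1 @ rot.T
            l3 = float(np.linalg.norm(b - a))
            s = (b - a)[[0, 2]]
            lp = float(np.linalg.norm(s))
            chord = min(t * (l3 / max(lp, 1e-9)), _CHORD_CAP) if t > 0 else 0.0
            if lp < 1e-6:
                cx, cz = a[0], a[2]
                h = d / 2.0
                tri1 = np.array([[cx - h, cz - h], [cx + h, cz - h], [cx + h, cz + h]])
                tri2 = np.array([[cx - h, cz - h], [cx + h, cz + h], [cx - h, cz + h]])
            else:
                u = s / lp
                perp = np.array([-u[1], u[0]]) * (d / 2.0)
                a2, b2 = a[[0, 2]], b[[0, 2]]
                tri1 = np.array([a2 - perp, a2 + perp, b2 + perp])
                tri2 = np.array([a2 - perp, b2 + perp, b2 - perp])
            shapes.append((np.stack([tri1, tri2]), chord))
    return shapes


def _shape_cell_bounds(shapes, v_pitch, h_pitch):
    for tris, t in shapes:
        tris = np.asarray(tris, dtype=float)
        if tris.ndim == 2:  # a bare triangle
            tris = tris[None, :, :]
        xs = tris[:, :, 0]
        zs = tris[:, :, 1]
        c0 = math.ceil(xs.min() / h_pitch - 0.5)
        c1 = math.floor(xs.max() / h_pitch - 0.5)
        r0 = math.ceil(zs.min() / v_pitch - 0.5)
        r1 = math.floor(zs.max() / v_pitch - 0.5)
        if c1 >= c0 and r1 >= r0:
            yield tris, t, r0, r1, c0, c1


def _raster_accumulate(shapes, v_pitch: float, h_pitch: float):
    """Occlusion-thickness sum and coverage over cell centres hit by shapes.

    A shape is a set of triangles forming one solid primitive: its thickness
    counts once per shape (triangles of one primitive share edges), while
    thickness accumulates across shapes (a beam crossing several leaves).
    Returns ``(thickness, covered, row_offset, col_offset)`` arrays spanning
    the joint bounding box: absolute cell (r, c) maps to index
    ``(r - row_offset, c - col_offset)``.
    """
    items = list(_shape_cell_bounds(shapes, v_pitch, h_pitch))
    if not items:
        z = np.zeros((0, 0))
        return z, z.astype(bool), 0, 0
    gr0 = min(it[2] for it in items)
    gr1 = max(it[3] for it in items)
    gc0 = min(it[4] for it in items)
    gc1 = max(it[5] for it in items)
    thick = np.zeros((gr1 - gr0 + 1, gc1 - gc0 + 1))
    covered = np.zeros_like(thick, dtype=bool)
    for tris, t, r0, r1, c0, c1 in items:
        cc, rr = np.meshgrid(np.arange(c0, c1 + 1), np.arange(r0, r1 + 1))
        px = (cc + 0.5) * h_pitch
        pz = (rr + 0.5) * v_pitch
        inside = np.zeros(px.shape, dtype=bool)
        for tri in tris:
            d = []
            for i in range(3):
                ax, az = tri[i]
                bx, bz = tri[(i + 1) % 3]
                d.append((bx - ax) * (pz - az) - (bz - az) * (px - ax))
            inside |= ((d[0] >= 0) & (d[1] >= 0) & (d[2] >= 0)) | (
                (d[0] <= 0) & (d[1] <= 0) & (d[2] <= 0)
            )
        win_t = thick[r0 - gr0: r1 - gr0 + 1, c0 - gc0: c1 - gc0 + 1]
        win_c = covered[r0 - gr0: r1 - gr0 + 1, c0 - gc0: c1 - gc0 + 1]
        win_t[inside] += t
        win_c[inside] = True
    return thick, covered, gr0, gc0


def rasterize(
    shapes,
    v_pitch: float = V_PITCH_DEFAULT,
    h_pitch: float = H_REF,
    thickness_threshold: float = THICKNESS_THRESHOLD_DEFAULT,
) -> Silhouette:
    """Rasterize projected shapes onto the LC grid.

    A cell is foreground iff a shape covers its centre (at
    ``((c + 0.5) h_pitch, (r + 0.5) v_pitch)``) and the summed occlusion
    thickness there is at least ``thickness_threshold`` (0 disables the
    beam-interruption model).  Rows/cols may be negative; row 0 starts at
    the plant base.
    """
    if v_pitch <= 0 or h_pitch <= 0:
        raise ValidationError("pitches must be > 0")
    thick, covered, r_off, c_off = _raster_accumulate(shapes, v_pitch, h_pitch)
    mask = covered & (thick >= thickness_threshold) if thickness_threshold > 0 else covered
    rr, cc = np.nonzero(mask)
    pixels = frozenset((int(r) + r_off, int(c) + c_off) for r, c in zip(rr, cc))
    base_row = min(0, min((r for r, _ in pixels), default=0))
    return Silhouette(pixels=pixels, v_pitch=v_pitch, h_pitch=h_pitch, base_row=base_row)


# ---------------------------------------------------------------------------
# plant sampling
# ---------------------------------------------------------------------------

_MAX_TRIES = 50


def make_plant(
    archetype: str,
    params: ArchetypeParams | None = None,
    seed: int = 0,
    target_area_cm2: float | None = None,
) -> SyntheticPlant:
    """Sample one plant; deterministic given (archetype, params, seed).

    The true leaf area is hit exactly: blade lengths follow from the sampled
    canopy/height geometry, the target area (uniform over ``params.area_cm2``
    unless given) is distributed over blades in proportion to length
    squared, and widths are solved from the elliptical-blade area formula.
    Draws whose blade aspect ratios or model height leave the admissible
    ranges are rejected and resampled; failure after 50 tries raises
    :class:`GenerationError`.
    """
    if archetype not in _ARCHETYPE_DEFAULTS:
        raise ValidationError(f"unknown archetype {archetype!r}")
    params = params or _ARCHETYPE_DEFAULTS[archetype]
    rng = np.random.default_rng(seed)
    for _ in range(_MAX_TRIES):
        plant = (
            _sample_dicot(params, rng, target_area_cm2, seed)
            if archetype == "dicot_rosette"
            else _sample_monocot(params, rng, target_area_cm2, seed)
        )
        if plant is None:
            continue
        lo, hi = params.height_mm
        if lo <= plant.true_max_height <= hi:
            return plant
    raise GenerationError(
        f"could not satisfy {archetype} ranges (area target {target_area_cm2}) "
        f"after {_MAX_TRIES} tries"
    )


def _leaf_count_for_area(area_cm2: float, params: ArchetypeParams, rng) -> int:
    lo, hi = params.leaf_count
    n = int(round(3 + area_cm2 / 32.0)) + int(rng.integers(-1, 2))
    return int(min(max(n, lo), hi))


def _sample_elevations(params: ArchetypeParams, n: int, rng):
    """Hierarchical leaf inclinations: a canalized plant-level habit angle
    (central part of the admissible range) plus leaf-level jitter.  Leaf
    inclination distributions are species-characteristic, so between-plant
    spread is much smaller than the full range."""
    lo, hi = params.elevation_deg
    span = hi - lo
    habit = rng.uniform(lo + 0.4 * span, lo + 0.6 * span)
    return np.clip(habit + rng.uniform(-0.15, 0.15, size=n) * span, lo, hi)


def _finish(archetype, params, leaves, stem_h, area_cm2, seed):
    plant = SyntheticPlant(
        archetype=archetype,
        leaves=tuple(leaves),
        stem_height=stem_h,
        stem_diameter=params.stem_diameter_mm,
        true_leaf_area=area_cm2,
        true_max_height=stem_h,  # placeholder, replaced below
        rng_seed=seed,
    )
    _, height = _plant_extent(plant)
    return replace(plant, true_max_height=height)


def _sample_dicot(params, rng, target_area_cm2, seed):
    area = target_area_cm2 if target_area_cm2 is not None else rng.uniform(*params.area_cm2)
    # canopy diameter scales with sqrt(leaf area): rosette compactness is
    # canalized within a species, so diameter is not an independent draw
    a_lo, a_hi = params.area_cm2
    d_lo, d_hi = params.canopy_diameter_mm
    frac = math.sqrt(max(area - a_lo, 0.0) / max(a_hi - a_lo, 1e-9))
    diam = (d_lo + (d_hi - d_lo) * frac) * rng.uniform(0.95, 1.05)
    diam = min(max(diam, d_lo), d_hi)
    radius = diam / 2.0
    stem_h = rng.uniform(*params.stem_height_mm)
    # shape is canalized within a cultivar: plant-level habits (inclination,
    # petiole fraction, blade aspect ratio) from the central part of each
    # admissible range with small leaf-level jitter; size does the varying
    e_lo, e_hi = params.elevation_deg
    span = e_hi - e_lo
    habit_elev = rng.uniform(e_lo + 0.45 * span, e_lo + 0.55 * span)
    pf_lo, pf_hi = params.petiole_frac
    pf_habit = rng.uniform(pf_lo + 0.4 * (pf_hi - pf_lo), pf_lo + 0.6 * (pf_hi - pf_lo))
    r_lo, r_hi = params.width_ratio
    aspect_habit = rng.uniform(r_lo + 0.45 * (r_hi - r_lo), r_lo + 0.55 * (r_hi - r_lo))
    # leaf count chosen so the solved blade widths land near the aspect habit
    mean_len = 0.9 * radius / (pf_habit + math.cos(math.radians(habit_elev)))
    n_lo, n_hi = params.leaf_count
    n = int(round(4.0 * area * 100.0 / (math.pi * mean_len**2 * aspect_habit)))
    n = int(min(max(n, n_lo), n_hi))
    elev = np.clip(habit_elev + rng.uniform(-0.15, 0.15, size=n) * span, e_lo, e_hi)
    azim = rng.uniform(0.0, 360.0, size=n)
    arch = rng.uniform(*params.arch_deg, size=n)
    pfrac = np.clip(pf_habit + rng.uniform(-0.03, 0.03, size=n), pf_lo, pf_hi)
    reach = radius * rng.uniform(0.85, 0.95, size=n)
    length = reach / (pfrac + np.cos(np.radians(elev)))
    weights = length**2
    area_mm2 = area * 100.0 * weights / weights.sum()
    width = 4.0 * area_mm2 / (math.pi * length)
    ratio = width / length
    lo, hi = params.width_ratio
    if (ratio < lo).any() or (ratio > hi).any():
        return None
    base = (0.0, 0.0, stem_h)
    leaves = [
        Leaf(
            base=base,
            azimuth=float(azim[i]),
            elevation=float(elev[i]),
            length=float(length[i]),
            width=float(width[i]),
            petiole=float(pfrac[i] * length[i]),
            arch=float(arch[i]),
            shape="ellipse",
            thickness=params.blade_thickness_mm,
            tip_thickness=params.tip_thickness_mm,
        )
        for i in range(n)
    ]
    return _finish("dicot_rosette", params, leaves, stem_h, area, seed)


def _sample_monocot(params, rng, target_area_cm2, seed):
    a_lo, a_hi = params.area_cm2
    h_lo, h_hi = params.height_mm
    s = rng.uniform()
    area = target_area_cm2 if target_area_cm2 is not None else a_lo * (a_hi / a_lo) ** s
    if target_area_cm2 is not None:
        s = math.log(area / a_lo) / math.log(a_hi / a_lo)
    h_target = (h_lo + s * (h_hi - h_lo)) * rng.uniform(0.85, 1.15)
    h_target = min(max(h_target, h_lo), h_hi)
    stem_h = min(max(h_target * rng.uniform(0.2, 0.4), params.stem_height_mm[0]),
                 params.stem_height_mm[1])
    n = _leaf_count_for_area(area, params, rng)
    elev = _sample_elevations(params, n, rng)
    arch = rng.uniform(*params.arch_deg, size=n)
    azim = rng.uniform(0.0, 360.0, size=n)
    # rise of a unit-length arched midrib (peaks where the tangent turns horizontal)
    a0 = np.radians(elev)
    d = np.radians(arch)
    beta_low = np.maximum(a0 - d, 0.0)
    rise = (np.cos(beta_low) - np.cos(a0)) / d
    l_max = (h_target - stem_h) / rise.max()
    length = l_max * rng.uniform(0.75, 1.0, size=n)
    length[int(np.argmax(rise))] = l_max  # tallest leaf hits the target height
    weights = length**2
    area_mm2 = area * 100.0 * weights / weights.sum()
    width = 4.0 * area_mm2 / (math.pi * length)
    ratio = width / length
    lo, hi = params.width_ratio
    if (ratio < lo).any() or (ratio > hi).any():
        return None
    base = (0.0, 0.0, stem_h)
    leaves = [
        Leaf(
            base=base,
            azimuth=float(azim[i]),
            elevation=float(elev[i]),
            length=float(length[i]),
            width=float(width[i]),
            petiole=0.0,
            arch=float(arch[i]),
            shape="taper",
            thickness=params.blade_thickness_mm,
            tip_thickness=params.tip_thickness_mm,
        )
        for i in range(n)
    ]
    return _finish("monocot", params, leaves, stem_h, area, seed)


def make_population(
    archetype: str,
    n: int,
    seed: int = 0,
    params: ArchetypeParams | None = None,
) -> list[SyntheticPlant]:
    """``n`` seeded plants with true areas stratified across the area range."""
    params = params or _ARCHETYPE_DEFAULTS[archetype]
    rng = np.random.default_rng(seed)
    lo, hi = params.area_cm2
    targets = lo + (hi - lo) * (np.arange(n) + rng.uniform(size=n)) / n
    seeds = rng.integers(0, 2**31 - 1, size=n)
    return [
        make_plant(archetype, params, int(seeds[i]), target_area_cm2=float(targets[i]))
        for i in range(n)
    ]


# ---------------------------------------------------------------------------
# scan rendering
# ---------------------------------------------------------------------------

def render_scan(
    plants,
    pot_spacing: float = 300.0,
    speed: float = SPEED_REF,
    view_angles=None,
    v_pitch: float = V_PITCH_DEFAULT,
    pot_height: float = POT_HEIGHT_DEFAULT,
    pot_width: float = POT_WIDTH_DEFAULT,
    with_pots: bool = True,
    plant_z_offset: float | None = None,
    thickness_threshold: float = THICKNESS_THRESHOLD_DEFAULT,
    margin_mm: float | None = None,
    phase_mm: float = 0.0,
):
    """Render a row of potted plants to a ScanMatrix plus a ground-truth table.

    Plants sit at ``pot_spacing`` intervals on pots rendered as opaque
    filled rectangles (height 130 mm by default); ``h_pitch`` follows the
    scanning speed.  ``phase_mm`` shifts the whole bench relative to the
    sampling grid: the instrument's temporal sampling phase is arbitrary
    per run, and a bench aligned exactly to cell boundaries is a degenerate
    configuration.  Pot-centre metadata carries the phase, so downstream
    seeding is unaffected.  Returns ``(ScanMatrix, DataFrame)`` where the
    table lists each plant's id, pot centre, view angle, true leaf area
    (cm^2) and true model height (mm).
    """
    plants = list(plants)
    if view_angles is None:
        view_angles = [0.0] * len(plants)
    if len(view_angles) != len(plants):
        raise ValidationError("view_angles must match plants")
    if with_pots and pot_spacing < pot_width and len(plants) > 1:
        raise LayoutError(
            f"pot rectangles overlap: spacing {pot_spacing} < pot width {pot_width}"
        )
    z_off = plant_z_offset if plant_z_offset is not None else (pot_height if with_pots else 0.0)
    h_pitch = h_pitch_for_speed(speed)
    extents = [_plant_extent(p) for p in plants]
    reach = max((r for r, _ in extents), default=0.0)
    height = max((h for _, h in extents), default=0.0)
    if margin_mm is None:
        margin_mm = max(pot_spacing / 2.0, reach + 50.0)
    length = 2 * margin_mm + pot_spacing * max(len(plants) - 1, 0) + abs(phase_mm)
    n_cols = max(int(math.ceil(length / h_pitch)), 1)
    n_rows = max(int(math.ceil((z_off + height + 30.0) / v_pitch)), 1)

    shapes = []
    centers = []
    records = []
    for i, (plant, angle) in enumerate(zip(plants, view_angles)):
        cx = margin_mm + i * pot_spacing + phase_mm
        centers.append(cx)
        for tri, t in _project_prims(_plant_primitives(plant), angle):
            shapes.append((tri + np.array([cx, z_off]), t))
        if with_pots:
            w2 = pot_width / 2.0
            corners = np.array(
                [[cx - w2, 0.0], [cx + w2, 0.0], [cx + w2, pot_height], [cx - w2, pot_height]]
            )
            shapes.append((np.stack([corners[[0, 1, 2]], corners[[0, 2, 3]]]), 1e3))
        records.append(
            dict(
                plant_id=f"plant_{i}",
                pot_center_mm=cx,
                view_angle=float(angle),
                speed=speed,
                true_leaf_area_cm2=plant.true_leaf_area,
                true_max_height_mm=plant.true_max_height,
            )
        )

    thick, covered, r_off, c_off = _raster_accumulate(shapes, v_pitch, h_pitch)
    mask = covered & (thick >= thickness_threshold) if thickness_threshold > 0 else covered
    grid = np.zeros((n_rows, n_cols), dtype=np.uint8)
    rr, cc = np.nonzero(mask)
    rr = rr + r_off
    cc = cc + c_off
    keep = (rr >= 0) & (rr < n_rows) & (cc >= 0) & (cc < n_cols)
    grid[rr[keep], cc[keep]] = 1
    scan = ScanMatrix(
        grid=grid,
        v_pitch=v_pitch,
        h_pitch=h_pitch,
        speed=speed,
        pot_centers=tuple(centers),
        pot_height=pot_height,
        pot_width=pot_width,
    )
    return scan, pd.DataFrame(records)


#: golden-ratio fraction used to spread per-run sampling phases
_PHASE_STEP = (math.sqrt(5.0) - 1.0) / 2.0


def make_view_stack(
    plant: SyntheticPlant,
    speed: float = SPEED_REF,
    plant_id: str = "plant_0",
    radius: int = DEFAULT_RADIUS,
    pot_edge_threshold: float = DEFAULT_POT_EDGE_THRESHOLD,
    thickness_threshold: float = THICKNESS_THRESHOLD_DEFAULT,
    with_pots: bool = True,
    spread_phase: bool = True,
) -> ViewStack:
    """Render and segment the plant at all 18 view angles (10° steps).

    Each view is an independent scanning run, so each gets its own sampling
    phase (deterministic golden-ratio sequence over the pixel pitch) unless
    ``spread_phase`` is disabled.  With ``with_pots=False`` the raw plant
    raster is used directly (no pot, no segmentation) — the rendering-only
    path used e.g. for scanning-speed comparisons.
    """
    views = {}
    h_pitch = h_pitch_for_speed(speed)
    for k, angle in enumerate(VIEW_ANGLES):
        phase = ((k * _PHASE_STEP) % 1.0) * h_pitch if spread_phase else 0.0
        scan, _ = render_scan(
            [plant],
            speed=speed,
            view_angles=[angle],
            thickness_threshold=thickness_threshold,
            with_pots=with_pots,
            phase_mm=phase,
        )
        if with_pots:
            sil = segment_scan(scan, radius=radius, pot_edge_threshold=pot_edge_threshold)[0]
        else:
            rr, cc = np.nonzero(scan.grid)
            sil = Silhouette(
                pixels=frozenset(zip(rr.tolist(), cc.tolist())),
                v_pitch=scan.v_pitch,
                h_pitch=scan.h_pitch,
                base_row=0,
                ref_col=int(round(scan.pot_centers[0] / scan.h_pitch)),
            )
        views[angle] = replace(sil, plant_id=plant_id)
    return ViewStack(plant_id=plant_id, views=views, speed=speed)
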