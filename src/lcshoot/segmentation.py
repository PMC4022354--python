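"""Single-shoot silhouette extraction from a multi-plant LC scan.

The pipeline, applied once per pot position:

1. seed at the bottom centre of the pot (nearest foreground pixel);
2. radial growth: repeatedly add every foreground pixel within a Euclidean
   radius (default 25 px) of the current set, to its fixed point — this
   captures stems and petioles that are not 8-connected to the main body;
3. detect the upper pot edge as the first upward row-to-row pixel-count drop
   of more than 80%, and remove everything below it.

Distances are measured in pixel units (not mm): the growth radius is a
property of the sensor resolution, and the anisotropy of the pitches is
deliberately ignored.

Pixels reachable from several seeds are claimed by the plant whose pot
centre is horizontally nearest (ties go to the lower pot index), so the
output silhouettes partition the foreground deterministically.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage

from .errors import MetadataError, PotEdgeNotFoundError
from .lc_io import ScanMatrix, Silhouette

DEFAULT_RADIUS = 25
DEFAULT_POT_EDGE_THRESHOLD = 0.8


def locate_seed(scan: ScanMatrix, pot_center: float, radius: int = DEFAULT_RADIUS):
    """Foreground pixel nearest to (row 0, col = pot_center/h_pitch).

    Returns ``None`` (empty-plant condition) if no foreground pixel lies
    within ``radius`` of the bottom-centre point.  Ties are broken by the
    lower row, then the lower column.
    """
    rows, cols = scan.shape
    c0 = int(round(pot_center / scan.h_pitch))
    c0 = min(max(c0, 0), cols - 1)
    r_hi = min(radius, rows - 1)
    c_lo, c_hi = max(c0 - radius, 0), min(c0 + radius, cols - 1)
    window = scan.grid[: r_hi + 1, c_lo: c_hi + 1]
    rr, cc = np.nonzero(window)
    if rr.size == 0:
        return None
    d2 = rr.astype(np.int64) ** 2 + (cc + c_lo - c0).astype(np.int64) ** 2
    order = np.lexsort((cc, rr, d2))
    best = order[0]
    if d2[best] > radius * radius:
        return None
    return int(rr[best]), int(cc[best] + c_lo)


def grow_silhouette(scan: ScanMatrix, seed, radius: int = DEFAULT_RADIUS) -> set:
    """Transitive radial closure of the foreground around ``seed``.

    Returns the smallest superset S of {seed} such that every foreground
    pixel within Euclidean distance ``radius`` (pixel units) of a member of
    S belongs to S.

    Implementation: since any pixel within ``radius`` of the set drags in
    its whole 8-connected component (8-neighbours are at distance <= sqrt(2)
    <= radius), the closure is a union of connected components; components
    are merged while the minimum gap between the current set and another
    component is <= radius, measured with a Euclidean distance transform.
    """
    fg = scan.grid > 0
    seed = (int(seed[0]), int(seed[1]))
    if not fg[seed]:
        raise ValueError(f"seed {seed} is not a foreground pixel")
    if radius < 1:
        return {seed}
    # 8-connectivity is only valid when the radius covers the diagonal step
    structure = np.ones((3, 3), dtype=bool) if radius >= np.sqrt(2) else None
    labels, _ = ndimage.label(fg, structure=structure)
    in_set = {int(labels[seed])}
    while True:
        mask = np.isin(labels, sorted(in_set))
        dist = ndimage.distance_transform_edt(~mask)
        near = set(np.unique(labels[fg & (dist <= radius)]).tolist()) - {0}
        if near <= in_set:
            break
        in_set |= near
    mask = np.isin(labels, sorted(in_set))
    rr, cc = np.nonzero(mask)
    return {(int(r), int(c)) for r, c in zip(rr, cc)}


def detect_pot_edge(pixels, threshold: float = DEFAULT_POT_EDGE_THRESHOLD) -> int:
    """Row index of the plant base (one above the upper pot edge).

    Scanning upward from the bottom of the pixel set, with n_r the pixel
    count of row r, the pot edge is the smallest r with n_r > 0 and
    (n_r - n_{r+1}) / n_r > threshold; the returned base row is r + 1.
    The denominator is the lower row's count: the pot silhouette is wide
    and the stem narrow, so an upward drop marks the pot rim.
    """
    if not pixels:
        raise PotEdgeNotFoundError("empty pixel set")
    counts = {}
    for r, _ in pixels:
        counts[r] = counts.get(r, 0) + 1
    for r in range(min(counts), max(counts) + 1):
        n = counts.get(r, 0)
        if n > 0 and (n - counts.get(r + 1, 0)) / n > threshold:
            return r + 1
    raise PotEdgeNotFoundError(
        f"no consecutive-row drop exceeds {threshold:.0%}"
    )


def strip_pot(pixels, base_row: int) -> set:
    """Retain only pixels at or above ``base_row`` (may be empty)."""
    return {p for p in pixels if p[0] >= base_row}


def segment_scan(
    scan: ScanMatrix,
    radius: int = DEFAULT_RADIUS,
    pot_edge_threshold: float = DEFAULT_POT_EDGE_THRESHOLD,
    remove_pot: bool = True,
) -> list[Silhouette]:
    """Extract one silhouette per pot, in pot order.

    Empty pots produce empty-flagged silhouettes rather than errors, so
    batch runs continue.  A pixel reachable from several seeds is assigned
    to the nearest pot centre (tie: lower pot index).
    """
    if not scan.pot_centers:
        raise MetadataError("segment_scan requires pot_centers metadata")
    grown: list[set | None] = []
    closure_cache: dict[tuple, set] = {}
    for center in scan.pot_centers:
        seed = locate_seed(scan, center, radius)
        if seed is None:
            grown.append(None)
        elif seed in closure_cache:
            grown.append(closure_cache[seed])
        else:
            s = grow_silhouette(scan, seed, radius)
            for p in s:
                closure_cache[p] = s
            grown.append(s)

    # resolve pixels claimed by more than one plant
    claims: dict[tuple, list[int]] = {}
    for i, s in enumerate(grown):
        if s is None:
            continue
        for p in s:
            claims.setdefault(p, []).append(i)
    owned: list[set] = [set() for _ in scan.pot_centers]
    for p, owners in claims.items():
        if len(owners) == 1:
            owned[owners[0]].add(p)
        else:
            x = (p[1] + 0.5) * scan.h_pitch
            best = min(owners, key=lambda i: (abs(x - scan.pot_centers[i]), i))
            owned[best].add(p)

    out = []
    for i, (center, px) in enumerate(zip(scan.pot_centers, owned)):
        base_row = 0
        if px and remove_pot:
            base_row = detect_pot_edge(px, pot_edge_threshold)
            px = strip_pot(px, base_row)
        out.append(
            Silhouette(
                pixels=frozenset(px),
                v_pitch=scan.v_pitch,
                h_pitch=scan.h_pitch,
                base_row=base_row,
                ref_col=int(round(center / scan.h_pitch)),
                plant_id=f"plant_{i}",
            )
        )
    return out
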