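"""Reading and writing light-curtain scans, sidecar metadata and trait tables.

A light curtain array (LC) is a travelling pair of vertical poles carrying
infrared light barriers at a fixed vertical pitch (2.5 mm for the INFRASCAN
geometry modelled here).  A scan is a binary occlusion matrix: entry 1 means
the beam at that height was interrupted at that travel position.  The matrix
is stored bottom-up: row 0 is bench level, rows increase upward, column 0 is
the scan start.  Pixel (r, c) covers the physical half-open cell
``[c*h_pitch, (c+1)*h_pitch) x [r*v_pitch, (r+1)*v_pitch)`` in mm.

The horizontal pitch is a property of the travel speed: the sensor samples at
a fixed temporal rate, so ``h_pitch = H_REF * speed / SPEED_REF``.  This is
what makes raw pixel area inversely proportional to scanning speed while
leaving height estimates untouched.

Scan files are portable netpbm images (P1/P2 ASCII or P5 binary) or CSV of
0/1; metadata travels in a JSON sidecar.  The netpbm codec here is
deliberately literal: any stored value > 0 means "beam interrupted" (the
usual PBM photometric inversion, where 1 means black, would silently flip
the occlusion semantics, so a library image reader is not used).
"""

from __future__ import annotations

import json
import math
import re
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import FormatError, MetadataError, ValidationError

#: vertical distance between neighbouring light barriers, mm
V_PITCH_DEFAULT = 2.5
#: horizontal pitch at the reference speed, mm
H_REF = 2.5
#: reference scanning speed, m min^-1
SPEED_REF = 0.9
#: pot height (bench to upper pot edge), mm
POT_HEIGHT_DEFAULT = 130.0
#: pot top diameter, mm (not printed in the source protocol; 2 L pot)
POT_WIDTH_DEFAULT = 150.0

VIEW_ANGLES = tuple(range(0, 180, 10))


def h_pitch_for_speed(speed: float, h_ref: float = H_REF, speed_ref: float = SPEED_REF) -> float:
    """Horizontal pixel pitch (mm) implied by a scanning speed (m min^-1)."""
    return h_ref * speed / speed_ref


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ScanMatrix:
    """A binary LC occlusion matrix plus its physical metadata.

    Attributes
    ----------
    grid : ndarray of uint8, shape (rows, cols)
        1 = beam interrupted.  Row 0 is bench level (bottom).
    v_pitch, h_pitch : float
        Pixel pitches in mm.
    speed : float
        Scanning speed in m min^-1.
    pot_centers : tuple of float
        Pot centre positions in mm along the travel direction, strictly
        increasing.
    pot_height, pot_width : float
        Pot geometry in mm.
    """

    grid: np.ndarray
    v_pitch: float
    h_pitch: float
    speed: float
    pot_centers: tuple = ()
    pot_height: float = POT_HEIGHT_DEFAULT
    pot_width: float = POT_WIDTH_DEFAULT

    def __post_init__(self):
        g = np.asarray(self.grid, dtype=np.uint8)
        if g.ndim != 2 or g.shape[0] < 1 or g.shape[1] < 1:
            raise ValidationError(f"grid must be 2-D with >=1 rows/cols, got shape {g.shape}")
        if not np.isin(g, (0, 1)).all():
            raise ValidationError("grid values must be 0 or 1")
        object.__setattr__(self, "grid", g)
        for name in ("v_pitch", "h_pitch", "speed"):
            if not getattr(self, name) > 0:
                raise ValidationError(f"{name} must be > 0")
        centers = tuple(float(c) for c in self.pot_centers)
        object.__setattr__(self, "pot_centers", centers)
        if any(b <= a for a, b in zip(centers, centers[1:])):
            raise ValidationError("pot_centers must be strictly increasing")
        extent = self.grid.shape[1] * self.h_pitch
        if any(not (0 <= c <= extent) for c in centers):
            raise ValidationError("pot_centers must lie within the scan extent")

    @property
    def shape(self):
        return self.grid.shape

    def __eq__(self, other):
        if not isinstance(other, ScanMatrix):
            return NotImplemented
        meta_close = all(
            math.isclose(getattr(self, k), getattr(other, k), rel_tol=1e-9)
            for k in ("v_pitch", "h_pitch", "speed", "pot_height", "pot_width")
        )
        centers_close = len(self.pot_centers) == len(other.pot_centers) and all(
            math.isclose(a, b, rel_tol=1e-9, abs_tol=1e-9)
            for a, b in zip(self.pot_centers, other.pot_centers)
        )
        return meta_close and centers_close and np.array_equal(self.grid, other.grid)

    __hash__ = None


@dataclass(frozen=True)
class Silhouette:
    """One plant's pixel set after pot removal.

    ``pixels`` are (row, col) pairs in the source scan's coordinate frame;
    all rows are >= ``base_row`` (the former upper pot edge).  ``ref_col``
    is the pot-centre column, used as the horizontal reference when
    silhouettes are composed in the spacing simulation.
    """

    pixels: frozenset
    v_pitch: float
    h_pitch: float
    base_row: int = 0
    ref_col: int = 0
    plant_id: str | None = None

    def __post_init__(self):
        object.__setattr__(self, "pixels", frozenset((int(r), int(c)) for r, c in self.pixels))
        if any(r < self.base_row for r, _ in self.pixels):
            raise ValidationError("all silhouette rows must be >= base_row")

    @property
    def is_empty(self) -> bool:
        return len(self.pixels) == 0


# ---------------------------------------------------------------------------
# netpbm codec (P1/P2 ASCII, P5 binary; literal value semantics)
# ---------------------------------------------------------------------------

def _pnm_tokens(data: bytes):
    """Yield whitespace-separated tokens, skipping '#' comments."""
    for line in data.split(b"\n"):
        line = line.split(b"#", 1)[0]
        yield from line.split()


def read_pnm(path) -> np.ndarray:
    """Read a P1/P2/P5 netpbm file into a 0/1 array (top row first)."""
    data = Path(path).read_bytes()
    if not data or data[:1] != b"P":
        raise FormatError(f"{path}: not a netpbm file")
    magic = data[:2].decode("ascii", "replace")
    if magic == "P5":
        # header: magic, width, height, maxval, single whitespace, raster
        m = re.match(
            rb"P5\s+(?:#[^\n]*\n\s*)*(\d+)\s+(?:#[^\n]*\n\s*)*(\d+)\s+(?:#[^\n]*\n\s*)*(\d+)\s",
            data,
        )
        if not m:
            raise FormatError(f"{path}: malformed P5 header")
        w, h, maxval = (int(g) for g in m.groups())
        if maxval > 255:
            raise FormatError(f"{path}: 16-bit P5 not supported")
        raster = data[m.end():]
        if len(raster) < w * h:
            raise FormatError(f"{path}: truncated P5 raster")
        arr = np.frombuffer(raster[: w * h], dtype=np.uint8).reshape(h, w)
        return (arr > 0).astype(np.uint8)
    if magic in ("P1", "P2"):
        toks = _pnm_tokens(data)
        next(toks)  # magic
        try:
            w, h = int(next(toks)), int(next(toks))
            if magic == "P2":
                int(next(toks))  # maxval
            vals = [int(next(toks)) for _ in range(w * h)]
        except (StopIteration, ValueError) as exc:
            raise FormatError(f"{path}: malformed {magic} file") from exc
        arr = np.array(vals).reshape(h, w)
        if (arr < 0).any():
            raise FormatError(f"{path}: negative sample values")
        return (arr > 0).astype(np.uint8)
    raise FormatError(f"{path}: unsupported netpbm magic {magic!r}")


def write_pnm(arr: np.ndarray, path, fmt: str = "P5") -> None:
    """Write a 0/1 array (top row first) as P1 ASCII or P5 binary."""
    arr = np.asarray(arr, dtype=np.uint8)
    h, w = arr.shape
    path = Path(path)
    if fmt == "P1":
        body = "\n".join(" ".join(str(v) for v in row) for row in arr)
        path.write_text(f"P1\n{w} {h}\n{body}\n")
    elif fmt == "P5":
        with open(path, "wb") as fh:
            fh.write(f"P5\n{w} {h}\n255\n".encode())
            fh.write((arr * 255).astype(np.uint8).tobytes())
    else:
        raise ValueError(f"unsupported output format {fmt!r}")


# ---------------------------------------------------------------------------
# scan + sidecar IO
# ---------------------------------------------------------------------------

_MANDATORY_KEYS = ("speed_m_per_min",)


def _sidecar_to_meta(doc: dict) -> dict:
    for key in _MANDATORY_KEYS:
        if key not in doc:
            raise MetadataError(f"sidecar is missing mandatory key {key!r}")
    speed = float(doc["speed_m_per_min"])
    return dict(
        v_pitch=float(doc.get("v_pitch_mm", V_PITCH_DEFAULT)),
        h_pitch=float(doc.get("h_pitch_mm", h_pitch_for_speed(speed))),
        speed=speed,
        pot_centers=tuple(float(c) for c in doc.get("pot_centers_mm", ())),
        pot_height=float(doc.get("pot_height_mm", POT_HEIGHT_DEFAULT)),
        pot_width=float(doc.get("pot_width_mm", POT_WIDTH_DEFAULT)),
    )


def read_scan(path, meta_path) -> ScanMatrix:
    """Read a scan file (PGM P1/P2/P5 or CSV of 0/1) plus its JSON sidecar.

    File rows follow image convention (top row first); the returned grid is
    flipped so that row 0 is bench level.
    """
    path = Path(path)
    try:
        doc = json.loads(Path(meta_path).read_text())
    except json.JSONDecodeError as exc:
        raise MetadataError(f"{meta_path}: invalid JSON sidecar") from exc
    meta = _sidecar_to_meta(doc)
    if path.suffix.lower() == ".csv":
        try:
            arr = np.loadtxt(path, delimiter=",", ndmin=2)
        except ValueError as exc:
            raise FormatError(f"{path}: malformed CSV scan") from exc
        if (arr < 0).any() or not np.isin(arr, np.floor(arr)).all():
            raise FormatError(f"{path}: non-binary values in CSV scan")
        grid_top = (arr > 0).astype(np.uint8)
    else:
        grid_top = read_pnm(path)
    return ScanMatrix(grid=np.flipud(grid_top), **meta)


def write_scan(scan: ScanMatrix, path, meta_path, fmt: str | None = None) -> None:
    """Write a ScanMatrix as PGM (P1/P5) or CSV plus a JSON sidecar.

    Round-trips bit-exactly through :func:`read_scan`.
    """
    path = Path(path)
    grid_top = np.flipud(scan.grid)
    if fmt is None:
        fmt = "csv" if path.suffix.lower() == ".csv" else "P5"
    if fmt == "csv":
        np.savetxt(path, grid_top, fmt="%d", delimiter=",")
    else:
        write_pnm(grid_top, path, fmt=fmt)
    sidecar = dict(
        v_pitch_mm=scan.v_pitch,
        h_pitch_mm=scan.h_pitch,
        speed_m_per_min=scan.speed,
        pot_centers_mm=list(scan.pot_centers),
        pot_height_mm=scan.pot_height,
        pot_width_mm=scan.pot_width,
    )
    Path(meta_path).write_text(json.dumps(sidecar, indent=1))


# ---------------------------------------------------------------------------
# silhouette IO (bounding-box PGM + JSON sidecar)
# ---------------------------------------------------------------------------

def write_silhouette(sil: Silhouette, path, meta_path, fmt: str = "P5") -> None:
    """Persist a silhouette as a bounding-box PGM plus offsets in a sidecar."""
    if sil.is_empty:
        bbox = np.zeros((1, 1), dtype=np.uint8)
        r0 = c0 = 0
    else:
        rows = [r for r, _ in sil.pixels]
        cols = [c for _, c in sil.pixels]
        r0, c0 = min(rows), min(cols)
        bbox = np.zeros((max(rows) - r0 + 1, max(cols) - c0 + 1), dtype=np.uint8)
        for r, c in sil.pixels:
            bbox[r - r0, c - c0] = 1
    write_pnm(np.flipud(bbox), path, fmt=fmt)
    meta = dict(
        v_pitch_mm=sil.v_pitch,
        h_pitch_mm=sil.h_pitch,
        base_row=sil.base_row,
        ref_col=sil.ref_col,
        row_offset=r0,
        col_offset=c0,
        plant_id=sil.plant_id,
        empty=sil.is_empty,
    )
    Path(meta_path).write_text(json.dumps(meta, indent=1))


def read_silhouette(path, meta_path) -> Silhouette:
    meta = json.loads(Path(meta_path).read_text())
    if meta.get("empty"):
        pixels = frozenset()
    else:
        bbox = np.flipud(read_pnm(path))
        rr, cc = np.nonzero(bbox)
        pixels = frozenset(
            (int(r) + meta["row_offset"], int(c) + meta["col_offset"]) for r, c in zip(rr, cc)
        )
    return Silhouette(
        pixels=pixels,
        v_pitch=meta["v_pitch_mm"],
        h_pitch=meta["h_pitch_mm"],
        base_row=meta["base_row"],
        ref_col=meta["ref_col"],
        plant_id=meta.get("plant_id"),
    )


# ---------------------------------------------------------------------------
# trait tables
# ---------------------------------------------------------------------------

TRAIT_COLUMNS = (
    "plant_id", "species", "species_group", "view_angle", "speed",
    "pixel_area", "max_height",
)
OPTIONAL_TRAIT_COLUMNS = ("measured_leaf_area", "measured_height", "dry_weight")


def validate_trait_table(df: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in TRAIT_COLUMNS if c not in df.columns]
    if missing:
        raise ValidationError(f"trait table is missing columns {missing}")
    angles = pd.to_numeric(df["view_angle"])
    bad = ~angles.isin(VIEW_ANGLES)
    if bad.any():
        raise ValidationError(
            f"view_angle must be a multiple of 10 in [0, 170]; offending values "
            f"{sorted(angles[bad].unique().tolist())}"
        )
    groups = set(df["species_group"].unique())
    if not groups <= {"monocot", "dicot"}:
        raise ValidationError(f"species_group must be monocot/dicot, got {groups}")
    if (pd.to_numeric(df["pixel_area"]) < 0).any():
        raise ValidationError("pixel_area must be >= 0")
    if (pd.to_numeric(df["max_height"]) < 0).any():
        raise ValidationError("max_height must be >= 0")
    return df


def read_trait_table(path) -> pd.DataFrame:
    """Read and validate a trait CSV; unknown columns are preserved."""
    df = pd.read_csv(path)
    return validate_trait_table(df)


def write_trait_table(df: pd.DataFrame, path) -> None:
    validate_trait_table(df)
    df.to_csv(path, index=False)
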