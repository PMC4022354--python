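"""Trait extraction and calibration for LC silhouettes.

Pixel area is the silhouette's foreground pixel count — the LC proxy for
leaf area.  Maximum height is the vertical distance from the plant base
(former upper pot edge) to the highest silhouette pixel.

Because a single profile hides self-overlapping plant parts, traits are
averaged over a *view stack*: the 18 silhouettes recorded at 10° rotation
steps over 0–170° (180° repeats the 0° profile, so angles wrap modulo 180).
The *maximum deviation to the mean* (MDM) quantifies the worst-case
percentage error of a subset-averaged trait relative to a reference mean —
the error bound incurred by recording only a few views.

Raw pixel area depends on scanning speed (fixed temporal sampling makes the
horizontal pitch proportional to speed), so areas are comparable across
speeds only after multiplying by ``speed / ref_speed``.  Calibration from
pixel area to leaf area (or dry weight) is an ordinary least-squares line,
fitted per species group at a single speed and only valid at that speed.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import statsmodels.api as sm

from .errors import (
    CalibrationMisuseError,
    FitError,
    IncompleteStackError,
    UndefinedStatisticError,
    ValidationError,
)
from .lc_io import SPEED_REF, VIEW_ANGLES, Silhouette


# ---------------------------------------------------------------------------
# single-silhouette traits
# ---------------------------------------------------------------------------

def pixel_area(sil: Silhouette) -> int:
    """Number of pixels in the silhouette (0 for empty-flagged plants)."""
    return len(sil.pixels)


def max_height(sil: Silhouette) -> float:
    """Height in mm from the plant base to the top silhouette pixel.

    The top pixel's cell extends to ``(row + 1) * v_pitch``, so a single
    pixel at the base row has height one pitch.
    """
    if sil.is_empty:
        return 0.0
    top = max(r for r, _ in sil.pixels)
    return (top - sil.base_row + 1) * sil.v_pitch


_METRICS = {"area": pixel_area, "height": max_height}


def _resolve_metric(metric):
    if callable(metric):
        return metric
    try:
        return _METRICS[metric]
    except KeyError:
        raise ValidationError(f"unknown metric {metric!r}; use 'area' or 'height'") from None


# ---------------------------------------------------------------------------
# view stacks
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ViewStack:
    """The silhouettes of one plant at 10° view-angle increments."""

    plant_id: str
    views: dict  # view_angle (deg) -> Silhouette
    speed: float = SPEED_REF

    def __post_init__(self):
        views = {int(a): s for a, s in self.views.items()}
        bad = [a for a in views if a not in VIEW_ANGLES]
        if bad:
            raise ValidationError(f"view angles must be in {{0,10,...,170}}, got {bad}")
        pitches = {(s.v_pitch, s.h_pitch) for s in views.values()}
        if len(pitches) > 1:
            raise ValidationError("all views of a stack must share pitches")
        object.__setattr__(self, "views", views)

    @property
    def is_complete(self) -> bool:
        return set(self.views) == set(VIEW_ANGLES)

    def require_complete(self):
        if not self.is_complete:
            missing = sorted(set(VIEW_ANGLES) - set(self.views))
            raise IncompleteStackError(f"stack {self.plant_id} is missing views {missing}")


def subset_mean(
    stack: ViewStack,
    n: int,
    step_deg: int = 10,
    start_deg: int = 0,
    metric="area",
) -> float:
    """Mean trait over ``n`` views spaced ``step_deg`` apart from ``start_deg``.

    Angles wrap modulo 180 (a view at θ and θ+180 is the same silhouette),
    so every start position is valid for any (n, step) combination.
    """
    if not 1 <= n <= len(VIEW_ANGLES):
        raise ValidationError(f"n must be in [1, 18], got {n}")
    if step_deg % 10 or not 10 <= step_deg <= 170:
        raise ValidationError(f"step_deg must be a multiple of 10 in [10, 170], got {step_deg}")
    fn = _resolve_metric(metric)
    vals = []
    for i in range(n):
        angle = (start_deg + i * step_deg) % 180
        if angle not in stack.views:
            raise IncompleteStackError(f"stack {stack.plant_id} has no view at {angle} deg")
        vals.append(fn(stack.views[angle]))
    return float(np.mean(vals))


def max_deviation_to_mean(
    stack: ViewStack,
    n: int,
    step_deg: int = 10,
    metric="area",
    reference: str = "all18",
) -> float:
    """Worst-case percentage deviation of a subset mean from the reference.

    With R the reference mean, returns
    ``max over the 18 starts of |subset_mean(n, step, start) - R| / R * 100``.

    ``reference='all18'`` uses the mean over all 18 views; ``'window16'``
    uses, for each start, the mean of the 16 consecutive 10°-spaced views
    beginning at that start (the windowed reference used when plotting
    overlapping 16-view means).
    """
    stack.require_complete()
    if reference not in ("all18", "window16"):
        raise ValidationError(f"reference must be 'all18' or 'window16', got {reference!r}")
    devs = []
    r_all = subset_mean(stack, 18, 10, 0, metric) if reference == "all18" else None
    for start in VIEW_ANGLES:
        ref = r_all if r_all is not None else subset_mean(stack, 16, 10, start, metric)
        if ref == 0:
            raise UndefinedStatisticError("reference mean is zero")
        devs.append(abs(subset_mean(stack, n, step_deg, start, metric) - ref) / ref * 100.0)
    return float(max(devs))


def stack_mean(stack: ViewStack, metric="area") -> float:
    """Mean trait over all 18 views (the standard reporting quantity)."""
    return subset_mean(stack, 18, 10, 0, metric)


# ---------------------------------------------------------------------------
# speed normalization and calibration
# ---------------------------------------------------------------------------

def normalize_for_speed(area: float, speed: float, ref_speed: float = SPEED_REF) -> float:
    """Convert a pixel area recorded at ``speed`` to its ``ref_speed`` equivalent.

    Pixel area is inversely proportional to scanning speed (the horizontal
    pitch scales with speed at fixed temporal sampling), so the equivalent
    count at the reference speed is ``area * speed / ref_speed``.
    """
    if speed <= 0 or ref_speed <= 0:
        raise ValidationError("speeds must be > 0")
    return area * speed / ref_speed


@dataclass(frozen=True)
class CalibrationModel:
    """Linear map from pixel area to a measured response at one speed."""

    slope: float          # response units (cm^2 or g) per pixel
    intercept: float
    r_squared: float
    speed: float          # m min^-1 the model was fitted at
    species_group: str
    response: str = "leaf_area"
    n_points: int = 0

    def __post_init__(self):
        if not 0 <= self.r_squared <= 1 + 1e-12:
            raise ValidationError("r_squared must be in [0, 1]")
        if self.species_group not in ("monocot", "dicot"):
            raise ValidationError("species_group must be 'monocot' or 'dicot'")
        if self.response not in ("leaf_area", "dry_weight"):
            raise ValidationError("response must be 'leaf_area' or 'dry_weight'")

    def to_json(self, path=None) -> str:
        doc = json.dumps(self.__dict__, indent=1)
        if path is not None:
            Path(path).write_text(doc)
        return doc

    @classmethod
    def from_json(cls, doc: str) -> "CalibrationModel":
        return cls(**json.loads(doc))


def fit_calibration(
    pixel_areas,
    responses,
    speed: float,
    species_group: str,
    response: str = "leaf_area",
) -> CalibrationModel:
    """OLS fit of a measured response on pixel area, with intercept.

    All points must come from scans at one speed; R^2 is the squared
    Pearson correlation.
    """
    x = np.asarray(pixel_areas, dtype=float)
    y = np.asarray(responses, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise FitError("pixel_areas and responses must be 1-D and equally long")
    if x.size < 3:
        raise FitError(f"need at least 3 points, got {x.size}")
    if np.ptp(x) == 0:
        raise FitError("pixel areas have zero variance")
    res = sm.OLS(y, sm.add_constant(x)).fit()
    return CalibrationModel(
        slope=float(res.params[1]),
        intercept=float(res.params[0]),
        r_squared=float(res.rsquared),
        speed=float(speed),
        species_group=species_group,
        response=response,
        n_points=int(x.size),
    )


def predict_leaf_area(model: CalibrationModel, area: float, speed: float) -> float:
    """Apply a calibration model to a pixel area recorded at ``speed``.

    The model is only valid at the speed it was fitted for; normalize the
    area first (``normalize_for_speed``) to use it across speeds.
    """
    if not math.isclose(speed, model.speed, rel_tol=1e-6):
        raise CalibrationMisuseError(
            f"model fitted at {model.speed} m/min applied at {speed} m/min; "
            "normalize the pixel area to the model speed first"
        )
    return model.slope * area + model.intercept
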