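"""Shared fixtures: small seeded synthetic plants and helper builders."""

import numpy as np
import pytest

import lcshoot as lc
from lcshoot.lc_io import Silhouette


def silhouette_from_areas(area_by_angle, v_pitch=2.5, h_pitch=2.5):
    """ViewStack whose view at angle a has exactly area_by_angle[a] pixels."""
    views = {
        a: Silhouette(
            pixels=frozenset((0, i) for i in range(int(n))),
            v_pitch=v_pitch,
            h_pitch=h_pitch,
        )
        for a, n in area_by_angle.items()
    }
    return lc.ViewStack(plant_id="fake", views=views)


@pytest.fixture(scope="session")
def small_dicot():
    return lc.make_plant("dicot_rosette", seed=11, target_area_cm2=80.0)


@pytest.fixture(scope="session")
def small_dicot_stack(small_dicot):
    return lc.make_view_stack(small_dicot)


@pytest.fixture(scope="session")
def second_dicot_stack():
    plant = lc.make_plant("dicot_rosette", seed=12, target_area_cm2=70.0)
    return lc.make_view_stack(plant)


@pytest.fixture(scope="session")
def small_monocot():
    return lc.make_plant("monocot", seed=13, target_area_cm2=40.0)


def brute_force_closure(fg_points, seed, radius):
    """Reference radial-growth oracle: repeated pairwise-distance unioning.

    Grows the set by adding every foreground point within `radius`
    (Euclidean) of any current member, until nothing changes.
    """
    pts = np.array(sorted(fg_points))
    d2 = ((pts[:, None, :] - pts[None, :, :]) ** 2).sum(axis=2)
    adj = d2 <= radius * radius
    idx = {tuple(p): i for i, p in enumerate(pts)}
    in_set = np.zeros(len(pts), dtype=bool)
    in_set[idx[tuple(seed)]] = True
    while True:
        new = adj[in_set].any(axis=0)
        if (new == in_set).all():
            break
        in_set = new
    return {tuple(p) for p in pts[in_set]}
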