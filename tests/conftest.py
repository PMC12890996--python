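"""Shared fixtures: programmatically built skeleton shapes and images."""

from __future__ import annotations

import numpy as np
import pytest
from skimage import draw


def _canvas(*segments, size=(32, 32)):
    """Boolean canvas with 1-px 8-connected line segments drawn on it."""
    img = np.zeros(size, dtype=bool)
    for r0, c0, r1, c1 in segments:
        rr, cc = draw.line(r0, c0, r1, c1)
        img[rr, cc] = True
    return img


def _diamond_loop(center=(16, 16), radius=6, size=(32, 32)):
    """Closed diamond ring: every pixel has exactly two (diagonal) neighbors."""
    img = np.zeros(size, dtype=bool)
    r0, c0 = center
    for dr in range(-radius, radius + 1):
        dc = radius - abs(dr)
        img[r0 + dr, c0 + dc] = True
        img[r0 + dr, c0 - dc] = True
    return img


def skeleton_shape_battery() -> list[tuple[str, np.ndarray]]:
    """>= 20 thin shapes on canvases <= 64x64: lines, crosses, T/H/Y shapes,
    loops, combs, and seeded random polylines."""
    shapes: list[tuple[str, np.ndarray]] = [
        ("h_line", _canvas((10, 5, 10, 14))),
        ("v_line", _canvas((3, 8, 20, 8))),
        ("diag_line", _canvas((2, 2, 13, 13))),
        ("anti_diag", _canvas((18, 4, 6, 16))),
        ("plus_cross", _canvas((16, 12, 16, 20), (12, 16, 20, 16))),
        ("x_cross", _canvas((8, 8, 20, 20), (20, 8, 8, 20))),
        ("t_shape", _canvas((5, 5, 5, 20), (5, 12, 18, 12))),
        ("h_shape", _canvas((4, 6, 20, 6), (4, 18, 20, 18), (12, 6, 12, 18))),
        ("y_shape", _canvas((4, 4, 12, 12), (4, 20, 12, 12), (12, 12, 24, 12))),
        ("l_path", _canvas((4, 4, 18, 4), (18, 4, 18, 16))),
        ("z_path", _canvas((4, 4, 4, 14), (4, 14, 14, 4), (14, 4, 14, 14))),
        ("diamond_loop", _diamond_loop()),
        ("lollipop", _diamond_loop(center=(12, 12), radius=5)
         | _canvas((17, 12, 28, 12))),
        ("two_lines", _canvas((5, 5, 5, 15), (20, 5, 20, 15))),
        ("single_pixel", _canvas((7, 7, 7, 7))),
        ("two_pixels", _canvas((7, 7, 7, 8))),
        ("rect_outline", _canvas((4, 4, 4, 14), (10, 4, 10, 14),
                                 (4, 4, 10, 4), (4, 14, 10, 14))),
        ("comb", _canvas((6, 4, 6, 24), (6, 8, 14, 8), (6, 14, 14, 14),
                         (6, 20, 14, 20))),
        ("double_cross", _canvas((10, 4, 10, 26), (4, 9, 16, 9), (4, 21, 16, 21))),
        ("circle", None),  # filled below
        ("staircase", _canvas((4, 4, 8, 8), (8, 8, 8, 14), (8, 14, 14, 20))),
    ]
    circle = np.zeros((40, 40), dtype=bool)
    rr, cc = draw.circle_perimeter(20, 20, 10)
    circle[rr, cc] = True
    shapes[[n for n, _ in shapes].index("circle")] = ("circle", circle)
    rng = np.random.default_rng(42)
    for k in range(4):
        segs = []
        for _ in range(4):
            r0, c0, r1, c1 = rng.integers(2, 62, size=4)
            segs.append((int(r0), int(c0), int(r1), int(c1)))
        shapes.append((f"random_{k}", _canvas(*segs, size=(64, 64))))
    return shapes


@pytest.fixture(scope="session")
def shape_battery():
    return skeleton_shape_battery()


@pytest.fixture()
def l_shape_image():
    """10x10 bright square with its 5x5 corner removed, on a dark canvas."""
    img = np.zeros((20, 20), dtype=float)
    img[0:10, 0:10] = 10.0
    img[5:10, 5:10] = 0.0
    return img
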