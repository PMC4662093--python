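"""Independent numeric oracles for dual-route checks.

These deliberately avoid the code paths they verify: distances via dense
point sampling along lines, areas via Monte-Carlo point sampling, road
lengths via fine sampling of the segments. Keep them dumb.
"""

from __future__ import annotations

import math

import numpy as np
import shapely


def densify_line(coords: np.ndarray, step: float) -> np.ndarray:
    """Points along a polyline at ~step spacing, endpoints included."""
    pts = [coords[0]]
    for a, b in zip(coords[:-1], coords[1:]):
        a, b = np.asarray(a, float), np.asarray(b, float)
        seg_len = float(np.hypot(*(b - a)))
        n = max(1, math.ceil(seg_len / step))
        t = np.linspace(0.0, 1.0, n + 1)[1:]
        pts.extend(a + t[:, None] * (b - a))
    return np.asarray(pts)


def densified_min_distance(x: float, y: float, lines, step: float = 0.01) -> float:
    """Brute-force min distance from (x, y) to densified line vertices."""
    best = math.inf
    for line in lines:
        pts = densify_line(np.asarray(line.coords), step)
        d = np.hypot(pts[:, 0] - x, pts[:, 1] - y).min()
        best = min(best, float(d))
    return best


def mc_areal_sum(
    rng: np.random.Generator,
    x: float,
    y: float,
    radius: float,
    zones,
    attribute: str,
    n: int = 10**6,
) -> tuple[float, float]:
    """Monte-Carlo estimate (and its sigma) of the areal-weighted sum.

    Samples n points uniformly in the exact disc; the integrand at a
    point is the local density sum attr_j/area_j over polygons covering
    it. Returns (estimate, standard error), both on the sum scale.
    """
    u = rng.random(n)
    theta = rng.uniform(0.0, 2.0 * math.pi, n)
    r = radius * np.sqrt(u)
    px = x + r * np.cos(theta)
    py = y + r * np.sin(theta)
    dens = np.zeros(n)
    for f in zones:
        value = f.attributes[attribute]
        if value is None:
            continue
        inside = shapely.contains_xy(f.geometry, px, py)
        dens[inside] += float(value) / f.geometry.area
    disc_area = math.pi * radius**2
    est = disc_area * float(dens.mean())
    sigma = disc_area * float(dens.std(ddof=1)) / math.sqrt(n)
    return est, sigma


def mc_class_area_fraction(
    rng: np.random.Generator,
    x: float,
    y: float,
    radius: float,
    landcover,
    class_code: str,
    class_attribute: str = "class_code",
    n: int = 10**6,
) -> tuple[float, float]:
    """Monte-Carlo (fraction, standard error) of one class within the disc."""
    u = rng.random(n)
    theta = rng.uniform(0.0, 2.0 * math.pi, n)
    r = radius * np.sqrt(u)
    px = x + r * np.cos(theta)
    py = y + r * np.sin(theta)
    hit = np.zeros(n, dtype=bool)
    for f in landcover:
        if f.attributes.get(class_attribute) != class_code:
            continue
        hit |= shapely.contains_xy(f.geometry, px, py)
    p = float(hit.mean())
    sigma = math.sqrt(max(p * (1.0 - p), 1e-12) / n)
    return p, sigma


def sampled_road_length(
    x: float, y: float, radius: float, segments, step: float = 0.1
) -> float:
    """Clipped road length estimated by fine sampling along segments:
    midpoint of every `step` sub-segment tested against the exact disc."""
    total = 0.0
    r2 = radius * radius
    for seg in segments:
        coords = np.asarray(seg.geometry.coords, float)
        for a, b in zip(coords[:-1], coords[1:]):
            seg_len = float(np.hypot(*(b - a)))
            n = max(1, math.ceil(seg_len / step))
            t = (np.arange(n) + 0.5) / n
            mids = a + t[:, None] * (b - a)
            inside = (mids[:, 0] - x) ** 2 + (mids[:, 1] - y) ** 2 <= r2
            total += inside.sum() * (seg_len / n)
    return total
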