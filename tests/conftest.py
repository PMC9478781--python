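"""Shared fixtures: small synthetic systems and independent oracles."""

from __future__ import annotations

import numpy as np
import pytest
from shapely.geometry import Polygon

from trrlink import (GeographyConfig, RunConfig, WaitlistConfig,
                     aligned_config, generate_geography, generate_waitlist,
                     run_pipeline)


def star_polygon(rng: np.random.Generator, n_vertices: int = 8,
                 radius: float = 1.0) -> Polygon:
    """Random simple (star-shaped) polygon around the origin."""
    angles = np.sort(rng.uniform(0.0, 2.0 * np.pi, n_vertices))
    radii = rng.uniform(0.3 * radius, radius, n_vertices)
    pts = [(r * np.cos(a), r * np.sin(a)) for r, a in zip(radii, angles)]
    return Polygon(pts)


def shoelace_area(poly: Polygon) -> float:
    """Independent area oracle: the shoelace formula on the exterior ring
    minus the holes."""
    def ring_area(coords):
        xs = np.asarray([c[0] for c in coords])
        ys = np.asarray([c[1] for c in coords])
        return 0.5 * abs(np.sum(xs[:-1] * ys[1:] - xs[1:] * ys[:-1]))
    total = ring_area(list(poly.exterior.coords))
    for hole in poly.interiors:
        total -= ring_area(list(hole.coords))
    return float(total)


def monte_carlo_area(geom, n_samples: int = 1_000_000, seed: int = 0) -> float:
    """Point-sampling area oracle over the geometry's bounding box."""
    import shapely
    rng = np.random.default_rng(seed)
    minx, miny, maxx, maxy = geom.bounds
    xs = rng.uniform(minx, maxx, n_samples)
    ys = rng.uniform(miny, maxy, n_samples)
    inside = shapely.contains_xy(geom, xs, ys)
    return float(inside.mean() * (maxx - minx) * (maxy - miny))


def exact_wilcoxon_oracle(d: np.ndarray) -> tuple[float, float]:
    """Brute-force Wilcoxon oracle: mean ranks, then the exact two-sided
    p as 2*min(tail probabilities) over all 2^n sign patterns."""
    from itertools import product
    from scipy.stats import rankdata
    d = np.asarray(d, float)
    d = d[d != 0]
    ranks = rankdata(np.abs(d))
    w_obs = ranks[d > 0].sum()
    ws = np.array([np.dot(s, ranks) for s in product((0, 1), repeat=len(d))])
    lo = np.mean(ws <= w_obs + 1e-12)
    hi = np.mean(ws >= w_obs - 1e-12)
    return float(w_obs), float(min(1.0, 2.0 * min(lo, hi)))


@pytest.fixture(scope="session")
def misaligned_system():
    """Small misaligned system: 16 tracts, 144 block groups, 4 HRRs,
    offset 4x4 zip grid, 4 centers."""
    cfg = GeographyConfig(side=60.0, n=12, k=3, h=4, m=4, delta=0.3,
                          c=4, cluster_prob=0.3, seed=7)
    system = generate_geography(cfg)
    system.waitlist = generate_waitlist(
        system, WaitlistConfig(n_patients=600, seed=7))
    return system


@pytest.fixture(scope="session")
def aligned_system():
    cfg = aligned_config(seed=5)
    system = generate_geography(cfg)
    system.waitlist = generate_waitlist(
        system, WaitlistConfig(n_patients=300, seed=5))
    return system


@pytest.fixture(scope="session")
def misaligned_run(tmp_path_factory, misaligned_system):
    """Full pipeline result on the misaligned fixture system."""
    cfg = RunConfig(
        geography=misaligned_system.config,
        waitlist=WaitlistConfig(n_patients=600, seed=7),
    )
    out = tmp_path_factory.mktemp("misrun")
    return run_pipeline(cfg, out, system=misaligned_system), out


@pytest.fixture(scope="session")
def aligned_run(tmp_path_factory, aligned_system):
    cfg = RunConfig(
        geography=aligned_system.config,
        waitlist=WaitlistConfig(n_patients=300, seed=5),
    )
    out = tmp_path_factory.mktemp("alignedrun")
    return run_pipeline(cfg, out, system=aligned_system), out
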