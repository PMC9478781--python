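"""Seeded generator of a synthetic study system.

Emulates the layered geography the analysis assumes: square census block
groups partitioning a square region, tracts as k x k blocks of block
groups, hospital referral regions (HRRs) as Voronoi cells misaligned to
census lines, zip polygons as a grid offset from the census grid, plus
crosswalks derived from true polygon overlap, transplant-center points,
and patient waitlist records.

The coordinate unit is abstract; distances behave like miles in the
sense that the 10-unit center-merging threshold plays the role of the
10-mile rule. Defaults describe a mid-sized study system: a 100 x 100
region, 900 block groups in 100 tracts, 8 HRRs, a 10 x 10 zip grid
offset by 0.3 of a cell, 6 centers, and 2000 waitlisted patients over
an 11-year study period.
"""

from __future__ import annotations

from dataclasses import dataclass
from datetime import date, timedelta
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from shapely import STRtree
from shapely.geometry import MultiPoint, Point, Polygon, box
from shapely.ops import voronoi_diagram

from . import geometry
from .geoio import Layer, read_layer, write_layer


@dataclass(frozen=True)
class GeographyConfig:
    """Parameters of the synthetic layered geography."""

    side: float = 100.0            # region side length (abstract units)
    n: int = 30                    # block-group grid is n x n
    k: int = 3                     # each tract is k x k block groups
    h: int = 8                     # number of HRRs (Voronoi cells)
    m: int = 10                    # zip grid is m x m before offsetting
    delta: float = 0.3             # zip offset, fraction of a zip cell
    c: int = 6                     # number of transplant centers
    cluster_prob: float = 0.3      # P(center spawns within 10 units of another)
    seed: int = 0
    hrr_seeds: Optional[Sequence[tuple[float, float]]] = None

    def validate(self) -> None:
        if self.side <= 0:
            raise ValueError("side must be positive")
        if self.n % self.k != 0:
            raise ValueError("n must be divisible by k (tracts tile block groups)")
        if self.n % self.m != 0:
            raise ValueError("n must be divisible by m (delta=0 must align zip "
                             "and block-group boundaries)")
        if self.h < 2:
            raise ValueError("need at least 2 HRRs")
        if self.c < 2:
            raise ValueError("need at least 2 centers")
        if not (0.0 <= self.delta < 1.0):
            raise ValueError("delta must lie in [0, 1)")
        if self.hrr_seeds is not None and len(self.hrr_seeds) != self.h:
            raise ValueError("hrr_seeds must supply exactly h points")


@dataclass(frozen=True)
class WaitlistConfig:
    """Parameters of the synthetic waitlist."""

    n_patients: int = 2000
    multi_center_prob: float = 0.15   # second listing at another center
    repeat_entry_prob: float = 0.10   # second entry at the same center
    missing_end_prob: float = 0.20
    minor_overlap_prob: float = 0.05  # 18th birthday inside the interval
    alias_fraction: float = 0.20      # entries filed under a pre-merge alias id
    retired_center_prob: float = 0.02 # entries at a center absent from the
                                      # active-center table (dropped downstream)
    study_start: date = date(2008, 1, 1)
    study_end: date = date(2018, 12, 31)
    choice_scale: float = 5.0         # distance-decay scale of center choice
    seed: int = 0

    def validate(self) -> None:
        for name in ("multi_center_prob", "repeat_entry_prob", "missing_end_prob",
                     "minor_overlap_prob", "alias_fraction", "retired_center_prob"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must lie in [0, 1]")
        if self.study_start >= self.study_end:
            raise ValueError("study_start must precede study_end")
        if self.n_patients < 1:
            raise ValueError("need at least one patient")


#: Alias/canonical ids of the synthetic retired center: present in the
#: facility crosswalk but absent from the active-center table.
RETIRED_ALIAS = "FRET"
RETIRED_CANONICAL = "CRET"


@dataclass
class SyntheticSystem:
    """All layers, crosswalks and tables of one synthetic study system."""

    config: GeographyConfig
    blockgroups: Layer
    tracts: Layer
    hrrs: Layer
    zips: Layer
    zip_hrr: pd.DataFrame          # columns zip, hrr
    zip_tract: pd.DataFrame        # columns zip, tract
    facility_xwalk: pd.DataFrame   # columns alias_id, canonical_id
    centers: pd.DataFrame          # columns id, x, y
    waitlist: Optional[pd.DataFrame] = None

    def region(self) -> Polygon:
        return box(0.0, 0.0, self.config.side, self.config.side)

    def write(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        write_layer(self.blockgroups, outdir / "blockgroups.geojson")
        write_layer(self.tracts, outdir / "tracts.geojson")
        write_layer(self.hrrs, outdir / "hrrs.geojson")
        write_layer(self.zips, outdir / "zips.geojson")
        self.zip_hrr.to_csv(outdir / "zip_hrr.csv", index=False)
        self.zip_tract.to_csv(outdir / "zip_tract.csv", index=False)
        self.facility_xwalk.to_csv(outdir / "facility_xwalk.csv", index=False)
        self.centers.to_csv(outdir / "centers.csv", index=False)
        if self.waitlist is not None:
            self.waitlist.to_csv(outdir / "waitlist.csv", index=False)


def read_system(indir: str | Path,
                config: GeographyConfig | None = None) -> SyntheticSystem:
    """Load a system previously written with :meth:`SyntheticSystem.write`."""
    indir = Path(indir)
    waitlist_path = indir / "waitlist.csv"
    return SyntheticSystem(
        config=config or GeographyConfig(),
        blockgroups=read_layer(indir / "blockgroups.geojson"),
        tracts=read_layer(indir / "tracts.geojson"),
        hrrs=read_layer(indir / "hrrs.geojson"),
        zips=read_layer(indir / "zips.geojson"),
        zip_hrr=pd.read_csv(indir / "zip_hrr.csv", dtype=str),
        zip_tract=pd.read_csv(indir / "zip_tract.csv", dtype=str),
        facility_xwalk=pd.read_csv(indir / "facility_xwalk.csv", dtype=str),
        centers=pd.read_csv(indir / "centers.csv",
                            dtype={"id": str, "x": float, "y": float}),
        waitlist=(pd.read_csv(waitlist_path, dtype=str, keep_default_na=False)
                  if waitlist_path.exists() else None),
    )


def _rng(seed: int, stream: int) -> np.random.Generator:
    # per-layer streams: adding a layer never perturbs earlier ones
    return np.random.default_rng([int(seed), stream])


def _census_layers(cfg: GeographyConfig) -> tuple[Layer, Layer]:
    cell = cfg.side / cfg.n
    nt = cfg.n // cfg.k
    tracts = Layer()
    blockgroups = Layer()
    for tr in range(nt):
        for tc in range(nt):
            tid = f"T{tr + 1:02d}{tc + 1:02d}"
            x0, y0 = tc * cfg.k * cell, tr * cfg.k * cell
            side_t = cfg.k * cell
            tracts.add(tid, box(x0, y0, x0 + side_t, y0 + side_t))
            for i in range(cfg.k):
                for j in range(cfg.k):
                    bid = f"{tid}B{i * cfg.k + j + 1}"
                    bx, by = x0 + j * cell, y0 + i * cell
                    blockgroups.add(bid, box(bx, by, bx + cell, by + cell),
                                    tract=tid)
    return blockgroups, tracts


def _hrr_layer(cfg: GeographyConfig, region: Polygon) -> Layer:
    if cfg.hrr_seeds is not None:
        pts = [Point(p) for p in cfg.hrr_seeds]
    else:
        rng = _rng(cfg.seed, 1)
        # rejection-sample seeds with a minimum separation so cells have
        # non-degenerate size
        min_sep = cfg.side / (2.0 * np.sqrt(cfg.h))
        pts: list[Point] = []
        while len(pts) < cfg.h:
            cand = Point(rng.uniform(0, cfg.side), rng.uniform(0, cfg.side))
            if all(cand.distance(p) >= min_sep for p in pts):
                pts.append(cand)
    cells = voronoi_diagram(MultiPoint(pts), envelope=region)
    layer = Layer()
    clipped = [cell.intersection(region) for cell in cells.geoms]
    # voronoi_diagram does not preserve seed order; match cells to seeds
    for idx, pt in enumerate(pts):
        owner = next(g for g in clipped if g.covers(pt))
        layer.add(f"H{idx + 1}", owner)
    return layer


def _zip_layer(cfg: GeographyConfig, region: Polygon) -> Layer:
    cell = cfg.side / cfg.m
    shift = cfg.delta * cell
    layer = Layer()
    ncell = cfg.m + (1 if cfg.delta > 0 else 0)
    for r in range(ncell):
        for col in range(ncell):
            x0, y0 = col * cell - shift, r * cell - shift
            poly = box(x0, y0, x0 + cell, y0 + cell).intersection(region)
            if poly.is_empty or poly.area <= 0:
                continue
            layer.add(f"Z{r + 1:02d}{col + 1:02d}", poly)
    return layer


def _overlap_pairs(left: Layer, right: Layer,
                   left_col: str, right_col: str) -> pd.DataFrame:
    """Crosswalk rows for every pair of features with positive-area overlap."""
    right_ids = list(right)
    tree = STRtree([right[i] for i in right_ids])
    rows = []
    for lid, lgeom in left.items():
        for j in tree.query(lgeom):
            rid = right_ids[j]
            if geometry.overlap_area(lgeom, right[rid]) > 0.0:
                rows.append((lid, rid))
    rows.sort()
    return pd.DataFrame(rows, columns=[left_col, right_col])


def _center_table(cfg: GeographyConfig) -> pd.DataFrame:
    rng = _rng(cfg.seed, 2)
    pts: list[tuple[float, float]] = []
    margin = 0.05 * cfg.side
    while len(pts) < cfg.c:
        if pts and rng.random() < cfg.cluster_prob:
            cx, cy = pts[rng.integers(len(pts))]
            ang = rng.uniform(0, 2 * np.pi)
            rad = rng.uniform(0, 10.0)
            x, y = cx + rad * np.cos(ang), cy + rad * np.sin(ang)
            if not (0 <= x <= cfg.side and 0 <= y <= cfg.side):
                continue
        else:
            x = rng.uniform(margin, cfg.side - margin)
            y = rng.uniform(margin, cfg.side - margin)
        pts.append((float(x), float(y)))
    return pd.DataFrame(
        {"id": [f"C{i + 1}" for i in range(cfg.c)],
         "x": [p[0] for p in pts],
         "y": [p[1] for p in pts]}
    )


def generate_geography(cfg: GeographyConfig) -> SyntheticSystem:
    """Build all polygon layers, crosswalks and the center table.

    Deterministic for a fixed seed. The zip->HRR crosswalk lists every
    HRR a zip genuinely overlaps, so any offset (delta > 0) against
    non-grid HRR boundaries produces zips split across HRRs — the source
    of the crosswalk method's error downstream.
    """
    cfg.validate()
    region = box(0.0, 0.0, cfg.side, cfg.side)
    blockgroups, tracts = _census_layers(cfg)
    hrrs = _hrr_layer(cfg, region)
    zips = _zip_layer(cfg, region)
    zip_hrr = _overlap_pairs(zips, hrrs, "zip", "hrr")
    zip_tract = _overlap_pairs(zips, tracts, "zip", "tract")
    centers = _center_table(cfg)
    aliases = [(f"F{cid}A", cid) for cid in centers["id"]]
    aliases.append((RETIRED_ALIAS, RETIRED_CANONICAL))
    facility_xwalk = pd.DataFrame(aliases, columns=["alias_id", "canonical_id"])
    return SyntheticSystem(
        config=cfg, blockgroups=blockgroups, tracts=tracts, hrrs=hrrs,
        zips=zips, zip_hrr=zip_hrr, zip_tract=zip_tract,
        facility_xwalk=facility_xwalk, centers=centers,
    )


def _draw_dates(rng: np.random.Generator, cfg: WaitlistConfig
                ) -> tuple[date, Optional[date]]:
    # listing windows extend one year past each end of the study period so
    # downstream trimming and exclusion rules are all exercised
    lo = cfg.study_start - timedelta(days=365)
    hi = cfg.study_end + timedelta(days=365)
    span = (hi - lo).days
    start = lo + timedelta(days=int(rng.integers(0, span + 1)))
    end: Optional[date] = None
    if rng.random() >= cfg.missing_end_prob:
        end = start + timedelta(days=int(rng.integers(30, 2001)))
    return start, end


def _draw_birth(rng: np.random.Generator, cfg: WaitlistConfig,
                start: date, end: Optional[date]) -> date:
    eff_end = end if end is not None else cfg.study_end
    if eff_end > start and rng.random() < cfg.minor_overlap_prob:
        # 18th birthday strictly inside the listing interval
        offset = int(rng.integers(1, (eff_end - start).days + 1))
        eighteenth = start + timedelta(days=offset)
        try:
            return eighteenth.replace(year=eighteenth.year - 18)
        except ValueError:  # Feb 29
            return eighteenth.replace(year=eighteenth.year - 18, day=28)
    age_days = int(rng.integers(int(20 * 365.25), int(75 * 365.25)))
    return start - timedelta(days=age_days)


def generate_waitlist(system: SyntheticSystem,
                      cfg: WaitlistConfig) -> pd.DataFrame:
    """Generate waitlist records for the system's centers and zips.

    Each patient has a home zip (uniform over zips) and lives at its
    centroid; centers are chosen with probability proportional to
    exp(-distance / choice_scale), so with strong decay each zip's
    patients concentrate at the nearest center. Dates are ISO-8601;
    missing end dates are empty strings.
    """
    cfg.validate()
    if len(system.centers) == 0:
        raise RuntimeError("cannot generate a waitlist without centers")
    rng = _rng(cfg.seed, 10)
    zip_ids = list(system.zips)
    zip_centroids = {z: system.zips[z].centroid for z in zip_ids}
    cxy = system.centers[["x", "y"]].to_numpy(float)
    cids = list(system.centers["id"])
    alias_of = dict(zip(system.facility_xwalk["canonical_id"],
                        system.facility_xwalk["alias_id"]))

    rows = []

    def emit(pid: str, center: str, zid: str, birth: date,
             start: date, end: Optional[date]) -> None:
        fid = center
        if rng.random() < cfg.retired_center_prob:
            fid = RETIRED_ALIAS
        elif rng.random() < cfg.alias_fraction and center in alias_of:
            fid = alias_of[center]
        rows.append((pid, fid, zid, birth.isoformat(), start.isoformat(),
                     end.isoformat() if end is not None else ""))

    for p in range(cfg.n_patients):
        pid = f"P{p + 1:06d}"
        zid = zip_ids[rng.integers(len(zip_ids))]
        cen = zip_centroids[zid]
        d = np.hypot(cxy[:, 0] - cen.x, cxy[:, 1] - cen.y)
        w = np.exp(-d / cfg.choice_scale)
        w /= w.sum()
        ci = int(rng.choice(len(cids), p=w))
        start, end = _draw_dates(rng, cfg)
        birth = _draw_birth(rng, cfg, start, end)
        emit(pid, cids[ci], zid, birth, start, end)
        if rng.random() < cfg.repeat_entry_prob:
            s2, e2 = _draw_dates(rng, cfg)
            emit(pid, cids[ci], zid, birth, s2, e2)
        if len(cids) > 1 and rng.random() < cfg.multi_center_prob:
            w2 = w.copy()
            w2[ci] = 0.0
            w2 /= w2.sum()
            cj = int(rng.choice(len(cids), p=w2))
            s3, e3 = _draw_dates(rng, cfg)
            emit(pid, cids[cj], zid, birth, s3, e3)

    return pd.DataFrame(
        rows, columns=["patient_id", "facility_id", "zip",
                       "birth_date", "start_date", "end_date"]
    )


def aligned_config(n: int = 4, k: int = 2, m: int = 2, side: float = 100.0,
                   seed: int = 0) -> GeographyConfig:
    """A fully aligned two-HRR configuration (delta=0, HRR boundary on a
    tract line): the limit in which both linkage methods must agree with
    zero misassigned area."""
    return GeographyConfig(
        side=side, n=n, k=k, h=2, m=m, delta=0.0, c=2, cluster_prob=0.0,
        seed=seed,
        hrr_seeds=[(side * 0.25, side * 0.5), (side * 0.75, side * 0.5)],
    )
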