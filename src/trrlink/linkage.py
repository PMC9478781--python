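"""Census-unit -> TRR linkage by two competing methods.

Zip-crosswalk method: a tract reaches every TRR connected to it through
any tract->zip->HRR->TRR chain (the many-to-many crosswalks are
preserved end-to-end, which is exactly what produces multiplets); block
groups inherit their parent tract's TRR set.

Spatial method: each (coverage-clipped) unit goes to the single TRR
with the largest area of intersection. Exact area ties are broken by
smallest TRR id and logged. Intersection areas below the sliver
tolerance are treated as zero so shared boundaries never create
spurious candidates.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd
from shapely import STRtree

from . import geometry
from .cohort import DataError
from .geoio import Layer
from .trr import HrrAssignment


@dataclass
class AssignmentSet:
    """All unit->TRR assignments for one method at one scale."""

    method: str                      # "zip" | "spatial"
    scale: str                       # "tract" | "blockgroup"
    trrs_of: dict[str, frozenset[str]]   # unit id -> TRR ids (non-empty)
    unassigned: list[str]
    ties: list[str]                  # spatial method only

    def to_frame(self) -> pd.DataFrame:
        rows = [(u, t) for u, ts in sorted(self.trrs_of.items())
                for t in sorted(ts)]
        return pd.DataFrame(rows, columns=["unit_id", "trr_id"])

    def units_of(self, trr_id: str) -> list[str]:
        return sorted(u for u, ts in self.trrs_of.items() if trr_id in ts)


def clip_units_to_coverage(units: Layer, hrr_layer: Layer
                           ) -> tuple[Layer, list[str]]:
    """Clip every unit to the dissolved HRR coverage.

    Mirrors the exclusion of coastline and other territory outside every
    HRR. Units left with no area are dropped and listed.
    """
    if not hrr_layer:
        raise ValueError("empty HRR layer")
    coverage = geometry.dissolve(list(hrr_layer.values()))
    clipped = Layer()
    dropped: list[str] = []
    for uid, geom in units.items():
        inter = geom.intersection(coverage)
        if inter.is_empty or inter.area <= geometry.SLIVER_REL_TOL * geom.area:
            dropped.append(uid)
            continue
        clipped.add(uid, inter, **units.properties.get(uid, {}))
    return clipped, dropped


def link_zip_method(
    tracts: Layer,
    blockgroups: Layer,
    zip_tract: pd.DataFrame,
    zip_hrr: pd.DataFrame,
    hrr_assignments: list[HrrAssignment],
) -> tuple[AssignmentSet, AssignmentSet]:
    """Crosswalk-join linkage at both scales.

    Joins zip->tract with zip->HRR on zip, then HRR->TRR; a tract's TRR
    set is everything reachable through any chain. Block groups take the
    parent tract's set unchanged.
    """
    trr_of_hrr = {a.hrr_id: a.group_id for a in hrr_assignments}
    zt = zip_tract.astype(str)
    zh = zip_hrr.astype(str)
    chains = zt.merge(zh, on="zip", how="inner")
    chains["trr_id"] = chains["hrr"].map(trr_of_hrr)
    chains = chains.dropna(subset=["trr_id"])
    tract_sets: dict[str, set[str]] = {}
    for tract_id, trr_id in zip(chains["tract"], chains["trr_id"]):
        tract_sets.setdefault(tract_id, set()).add(trr_id)

    tract_assign: dict[str, frozenset[str]] = {}
    tract_unassigned: list[str] = []
    for tid in tracts:
        ts = tract_sets.get(tid)
        if ts:
            tract_assign[tid] = frozenset(ts)
        else:
            tract_unassigned.append(tid)

    bg_assign: dict[str, frozenset[str]] = {}
    bg_unassigned: list[str] = []
    for bid in blockgroups:
        parent = blockgroups.properties[bid].get("tract")
        if parent is None or parent not in tracts:
            raise DataError(f"block group {bid!r} has unknown parent tract "
                            f"{parent!r}")
        ts = tract_assign.get(parent)
        if ts:
            bg_assign[bid] = ts
        else:
            bg_unassigned.append(bid)

    return (
        AssignmentSet("zip", "tract", tract_assign, sorted(tract_unassigned), []),
        AssignmentSet("zip", "blockgroup", bg_assign, sorted(bg_unassigned), []),
    )


def link_spatial_method(units: Layer, trr_layer: Layer, scale: str
                        ) -> AssignmentSet:
    """Largest-area-of-intersection linkage for one unit scale.

    Units must already be clipped to HRR coverage. Every unit receives
    exactly one TRR (or none, if it overlaps no TRR).
    """
    trr_ids = sorted(trr_layer)
    tree = STRtree([trr_layer[t] for t in trr_ids])
    assign: dict[str, frozenset[str]] = {}
    unassigned: list[str] = []
    ties: list[str] = []
    for uid, geom in units.items():
        best_area = 0.0
        best: list[str] = []
        for j in sorted(tree.query(geom)):
            tid = trr_ids[j]
            a = geometry.overlap_area(geom, trr_layer[tid])
            if a <= 0.0:
                continue
            if not best or a > best_area * (1.0 + 1e-12):
                best_area, best = a, [tid]
            elif a >= best_area * (1.0 - 1e-12):
                best.append(tid)
        if not best:
            unassigned.append(uid)
            continue
        if len(best) > 1:
            ties.append(uid)
        assign[uid] = frozenset([min(best)])
    return AssignmentSet("spatial", scale, assign, unassigned, ties)
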