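"""Transplant referral region (TRR) derivation.

Centers within 10 straight-line distance units of each other (directly
or through a chain of intermediate centers) are merged into one group;
cohort entries are fanned out to every HRR their home zip overlaps; each
HRR goes to the center group with the most distinct waitlisted patients;
and a group's TRR is the dissolve of the HRRs it won.

"Majority" is implemented as plurality (argmax over distinct-patient
counts): with more than two groups an absolute majority need not exist.
Ties are broken deterministically — the group whose member-center
centroid is nearest the HRR centroid wins, then the lexicographically
smallest group id — and every tie is recorded in the run log.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import geometry
from .cohort import DataError
from .geoio import Layer


@dataclass(frozen=True)
class CenterGroup:
    group_id: str
    members: tuple[str, ...]
    centroid: tuple[float, float]


@dataclass
class HrrAssignment:
    hrr_id: str
    group_id: str
    winning_count: int
    runner_up_count: int
    tie: bool = False


@dataclass
class Trr:
    trr_id: str
    geometry: object
    member_hrrs: tuple[str, ...]
    member_centers: tuple[str, ...]


def group_centers(centers: pd.DataFrame, threshold: float = 10.0
                  ) -> list[CenterGroup]:
    """Merge centers into connected components of the <=threshold graph.

    Group ids are ``G<i>`` numbered by the smallest member center id, so
    the grouping is invariant to input row order.
    """
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    ids = list(centers["id"].astype(str))
    if len(ids) != len(set(ids)):
        raise DataError("duplicate center ids")
    if not ids:
        raise ValueError("need at least one center")
    xy = {i: (float(x), float(y))
          for i, x, y in zip(ids, centers["x"], centers["y"])}
    # union-find over pairwise-close centers
    parent = {i: i for i in ids}

    def find(a: str) -> str:
        while parent[a] != a:
            parent[a] = parent[parent[a]]
            a = parent[a]
        return a

    for i, a in enumerate(ids):
        for b in ids[i + 1:]:
            if geometry.distance(xy[a], xy[b]) <= threshold:
                parent[find(a)] = find(b)
    comps: dict[str, list[str]] = {}
    for i in ids:
        comps.setdefault(find(i), []).append(i)
    groups = sorted((sorted(members) for members in comps.values()),
                    key=lambda ms: ms[0])
    out = []
    for gi, members in enumerate(groups):
        pts = np.array([xy[m] for m in members], dtype=float)
        out.append(CenterGroup(
            group_id=f"G{gi + 1}",
            members=tuple(members),
            centroid=(float(pts[:, 0].mean()), float(pts[:, 1].mean())),
        ))
    return out


def allocate_entries_to_hrrs(cohort: pd.DataFrame, zip_hrr: pd.DataFrame
                             ) -> tuple[pd.DataFrame, dict]:
    """Fan each cohort entry out to every HRR its home zip maps to.

    Entries whose zip is absent from the crosswalk are dropped and
    tallied (the analogue of listings whose zip the crosswalk does not
    cover, e.g. territories with no HRR defined).
    """
    xw = zip_hrr.astype(str)
    known = set(xw["zip"])
    zips = cohort["zip"].astype(str)
    matched = cohort[zips.isin(known)]
    log = {"unmatched_zip_entries": int(len(cohort) - len(matched))}
    pairs = matched.merge(xw, on="zip", how="inner")
    return pairs, log


def count_patients(pairs: pd.DataFrame, groups: list[CenterGroup]
                   ) -> pd.DataFrame:
    """Distinct-patient counts per (HRR, center group).

    A patient contributes at most once to a group within an HRR however
    many entries they hold at that group's centers; a patient listed at
    centers in two groups contributes once to each.
    """
    group_of = {m: g.group_id for g in groups for m in g.members}
    df = pairs.copy()
    df["group_id"] = df["center_id"].astype(str).map(group_of)
    if df["group_id"].isna().any():
        missing = sorted(df.loc[df["group_id"].isna(), "center_id"].unique())
        raise DataError(f"centers not in any group: {missing}")
    counts = (
        df.drop_duplicates(["hrr", "group_id", "patient_id"])
        .groupby(["hrr", "group_id"], as_index=False)
        .size()
        .rename(columns={"size": "patients", "hrr": "hrr_id"})
    )
    return counts


def assign_hrrs(counts: pd.DataFrame, groups: list[CenterGroup],
                hrr_layer: Layer) -> tuple[list[HrrAssignment], dict]:
    """Assign each HRR with >=1 patient to the plurality center group."""
    centroid_of = {g.group_id: g.centroid for g in groups}
    assignments: list[HrrAssignment] = []
    ties = 0
    for hrr_id, sub in counts.groupby("hrr_id"):
        sub = sub[sub["patients"] > 0]
        if sub.empty:
            continue
        best = int(sub["patients"].max())
        leaders = sorted(sub.loc[sub["patients"] == best, "group_id"])
        tie = len(leaders) > 1
        if tie:
            ties += 1
            hc = hrr_layer[str(hrr_id)].centroid
            leaders.sort(key=lambda g: (
                geometry.distance((hc.x, hc.y), centroid_of[g]), g))
        others = sub.loc[sub["group_id"] != leaders[0], "patients"]
        assignments.append(HrrAssignment(
            hrr_id=str(hrr_id), group_id=leaders[0], winning_count=best,
            runner_up_count=int(others.max()) if len(others) else 0,
            tie=tie,
        ))
    assigned_ids = {a.hrr_id for a in assignments}
    unassigned = sorted(set(hrr_layer) - assigned_ids)
    log = {"hrr_ties": ties, "unassigned_hrrs": unassigned}
    return assignments, log


def build_trrs(assignments: list[HrrAssignment], hrr_layer: Layer,
               groups: list[CenterGroup]) -> list[Trr]:
    """Dissolve each winning group's HRRs into its TRR polygon."""
    members_of = {g.group_id: g.members for g in groups}
    by_group: dict[str, list[str]] = {}
    for a in assignments:
        if a.hrr_id not in hrr_layer:
            raise DataError(f"assignment references unknown HRR {a.hrr_id!r}")
        by_group.setdefault(a.group_id, []).append(a.hrr_id)
    trrs = []
    for gid in sorted(by_group):
        hrr_ids = sorted(by_group[gid])
        geom = geometry.dissolve([hrr_layer[h] for h in hrr_ids])
        trrs.append(Trr(
            trr_id=gid, geometry=geom, member_hrrs=tuple(hrr_ids),
            member_centers=tuple(members_of.get(gid, ())),
        ))
    return trrs


def trr_layer(trrs: list[Trr]) -> Layer:
    layer = Layer()
    for t in trrs:
        layer.add(t.trr_id, t.geometry,
                  member_hrrs=list(t.member_hrrs),
                  member_centers=list(t.member_centers))
    return layer


def derive_trrs(cohort: pd.DataFrame, centers: pd.DataFrame,
                zip_hrr: pd.DataFrame, hrr_layer: Layer,
                threshold: float = 10.0
                ) -> tuple[list[Trr], list[HrrAssignment],
                           list[CenterGroup], dict]:
    """Full derivation: group centers, allocate, count, assign, dissolve."""
    groups = group_centers(centers, threshold)
    pairs, alog = allocate_entries_to_hrrs(cohort, zip_hrr)
    counts = count_patients(pairs, groups)
    assignments, hlog = assign_hrrs(counts, groups, hrr_layer)
    trrs = build_trrs(assignments, hrr_layer, groups)
    log = {**alog, **hlog, "n_groups": len(groups), "n_trrs": len(trrs)}
    return trrs, assignments, groups, log
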