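"""Linkage-error metrics.

Two error notions, mirroring the two failure modes of areal crosswalks:

* **Multiplets** — census units assigned to more than one TRR, whose
  data would be aggregated multiply. Counted per method and scale,
  together with the double-assigned area and its share of the total
  TRR-covered area.

* **Misassigned area** — per TRR, the symmetric difference between the
  TRR polygon and the union of the census units assigned to it,
  decomposed into the assigned-but-outside portion and the uncovered
  portion. The percentage is taken relative to the TRR's own area and
  is deliberately unclamped (nothing bounds it above 100).

Methods are compared per TRR with a paired Wilcoxon signed-rank test
(exact sign enumeration up to n = 12; normal approximation with tie and
continuity corrections beyond). Zero differences are dropped, the
standard Wilcoxon convention; the count dropped is reported.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import product

import numpy as np

from . import geometry
from .geoio import Layer
from .linkage import AssignmentSet
from .trr import Trr

EXACT_ENUMERATION_LIMIT = 12


@dataclass
class MultipletReport:
    method: str
    scale: str
    n_multiplets: int
    double_assigned_area: float
    pct_of_total_trr_area: float


@dataclass
class MisassignmentRecord:
    method: str
    scale: str
    trr_id: str
    area_outside: float
    area_uncovered: float
    total_misassigned: float
    pct_misassigned: float


def count_multiplets(assignments: AssignmentSet, units: Layer,
                     trrs: list[Trr]) -> MultipletReport:
    """Count units assigned to >1 TRR and their (clipped) area."""
    multi = [u for u, ts in assignments.trrs_of.items() if len(ts) > 1]
    area_multi = float(sum(units[u].area for u in multi if u in units))
    total = float(sum(t.geometry.area for t in trrs))
    pct = 100.0 * area_multi / total if total > 0 else 0.0
    return MultipletReport(
        method=assignments.method, scale=assignments.scale,
        n_multiplets=len(multi), double_assigned_area=area_multi,
        pct_of_total_trr_area=pct,
    )


def misassigned_area(trr: Trr, assigned_units: list, method: str,
                     scale: str) -> MisassignmentRecord:
    """Per-TRR error decomposition against the assigned units' union.

    outside   = area(union(units) - TRR)
    uncovered = area(TRR - union(units))
    total     = outside + uncovered
              = symmetric difference of the TRR and the union.
    """
    trr_area = trr.geometry.area
    if trr_area <= 0:
        raise ValueError(f"TRR {trr.trr_id!r} has zero area")
    if assigned_units:
        union = geometry.dissolve(assigned_units)
        outside = float(union.difference(trr.geometry).area)
        uncovered = float(trr.geometry.difference(union).area)
    else:
        outside, uncovered = 0.0, float(trr_area)
    total = outside + uncovered
    return MisassignmentRecord(
        method=method, scale=scale, trr_id=trr.trr_id,
        area_outside=outside, area_uncovered=uncovered,
        total_misassigned=total,
        pct_misassigned=100.0 * total / trr_area,
    )


def misassignment_records(trrs: list[Trr], assignments: AssignmentSet,
                          units: Layer) -> list[MisassignmentRecord]:
    """Misassignment for every TRR under one method/scale.

    A multiplet unit's geometry enters the computation of every TRR it
    is assigned to.
    """
    records = []
    for trr in trrs:
        geoms = [units[u] for u in assignments.units_of(trr.trr_id)
                 if u in units]
        records.append(misassigned_area(trr, geoms, assignments.method,
                                        assignments.scale))
    return records


@dataclass
class SummaryRow:
    method: str
    scale: str
    n: int
    mean_pct: float
    sd_pct: float
    median_pct: float
    min_pct: float
    max_pct: float
    mean_area: float
    sd_area: float
    median_area: float
    min_area: float
    max_area: float
    sd_undefined: bool = False
    p_value_pct: float | None = None
    p_value_area: float | None = None


def _stats(values: np.ndarray) -> tuple[float, float, float, float, float, bool]:
    mean = float(values.mean())
    flag = len(values) < 2
    sd = 0.0 if flag else float(values.std(ddof=1))
    return (mean, sd, float(np.median(values)), float(values.min()),
            float(values.max()), flag)


def summarize(records: list[MisassignmentRecord]) -> SummaryRow:
    """Mean (SD), median (range) of percent and absolute misassigned."""
    if not records:
        raise ValueError("summarize requires at least one record")
    pct = np.array([r.pct_misassigned for r in records], dtype=float)
    ar = np.array([r.total_misassigned for r in records], dtype=float)
    mp, sp, medp, lop, hip, flag = _stats(pct)
    ma, sa, meda, loa, hia, _ = _stats(ar)
    return SummaryRow(
        method=records[0].method, scale=records[0].scale, n=len(records),
        mean_pct=mp, sd_pct=sp, median_pct=medp, min_pct=lop, max_pct=hip,
        mean_area=ma, sd_area=sa, median_area=meda, min_area=loa,
        max_area=hia, sd_undefined=flag,
    )


@dataclass
class WilcoxonResult:
    w_plus: float
    p_value: float
    n_used: int
    n_zeros_dropped: int
    exact: bool


def _signed_ranks(d: np.ndarray) -> np.ndarray:
    """Mean ranks of |d| (ties share their average rank)."""
    a = np.abs(d)
    order = np.argsort(a, kind="stable")
    ranks = np.empty(len(a), dtype=float)
    i = 0
    while i < len(a):
        j = i
        while j + 1 < len(a) and a[order[j + 1]] == a[order[i]]:
            j += 1
        ranks[order[i:j + 1]] = (i + j) / 2.0 + 1.0
        i = j + 1
    return ranks


def wilcoxon_signed_rank(differences) -> WilcoxonResult:
    """Paired Wilcoxon signed-rank test on a vector of differences.

    Exact zeros are dropped. W+ is the sum of ranks of the positive
    differences, with mean ranks for tied magnitudes. The two-sided p
    is exact — full enumeration of all 2^n sign patterns over the
    observed rank magnitudes — for n <= 12, and a normal approximation
    with tie correction and a 0.5 continuity correction otherwise.
    """
    d = np.asarray(differences, dtype=float)
    if d.ndim != 1:
        raise ValueError("differences must be one-dimensional")
    nz = d[d != 0.0]
    dropped = int(len(d) - len(nz))
    n = len(nz)
    if n == 0:
        raise ValueError("all differences are zero: test degenerate")
    ranks = _signed_ranks(nz)
    w_plus = float(ranks[nz > 0].sum())
    if n <= EXACT_ENUMERATION_LIMIT:
        # distribution of W+ under H0: each rank positive with prob 1/2
        stats = []
        for signs in product((0.0, 1.0), repeat=n):
            stats.append(float(np.dot(signs, ranks)))
        stats = np.array(stats)
        mean = stats.mean()
        dev = abs(w_plus - mean)
        p = float(np.mean(np.abs(stats - mean) >= dev - 1e-12))
        return WilcoxonResult(w_plus, min(p, 1.0), n, dropped, True)
    mean = n * (n + 1) / 4.0
    # tie correction subtracts sum(t^3 - t)/48 from the null variance
    _, counts = np.unique(np.abs(nz)[np.argsort(np.abs(nz))],
                          return_counts=True)
    var = n * (n + 1) * (2 * n + 1) / 24.0 - float(
        ((counts.astype(float) ** 3 - counts).sum()) / 48.0)
    dev = abs(w_plus - mean)
    z = max(dev - 0.5, 0.0) / math.sqrt(var)
    p = float(min(1.0, 2.0 * (1.0 - _norm_cdf(z))))
    return WilcoxonResult(w_plus, p, n, dropped, False)


def _norm_cdf(z: float) -> float:
    return 0.5 * (1.0 + math.erf(z / math.sqrt(2.0)))


def compare_methods(records_a: list[MisassignmentRecord],
                    records_b: list[MisassignmentRecord]
                    ) -> dict[str, WilcoxonResult]:
    """Paired per-TRR comparison of two methods at one scale.

    Pairs on TRR id; tests both percent and absolute misassigned area.
    Differences are method-a minus method-b.
    """
    a = {r.trr_id: r for r in records_a}
    b = {r.trr_id: r for r in records_b}
    common = sorted(set(a) & set(b))
    if not common:
        raise ValueError("no TRRs in common between the two record sets")
    d_pct = np.array([a[t].pct_misassigned - b[t].pct_misassigned
                      for t in common])
    d_area = np.array([a[t].total_misassigned - b[t].total_misassigned
                       for t in common])
    return {"pct": wilcoxon_signed_rank(d_pct),
            "area": wilcoxon_signed_rank(d_area)}
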