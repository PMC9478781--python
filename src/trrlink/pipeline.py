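"""End-to-end orchestration: simulate -> cohort -> derive -> link ->
evaluate -> report.

Every stage reads and writes plain files (GeoJSON / CSV / JSON) inside
one run directory, so stages are independently runnable and testable;
identical config + seed yields byte-identical artifacts.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from datetime import date
from pathlib import Path

import pandas as pd

from . import __version__
from .cohort import StudyPeriod, build_cohort
from .geoio import Layer, read_layer, write_json, write_layer
from .linkage import (AssignmentSet, clip_units_to_coverage,
                      link_spatial_method, link_zip_method)
from .metrics import (compare_methods, count_multiplets,
                      misassignment_records, summarize)
from .synthetic import (GeographyConfig, SyntheticSystem, WaitlistConfig,
                        generate_geography, generate_waitlist, read_system)
from .trr import HrrAssignment, Trr, derive_trrs, trr_layer

SCALES = ("tract", "blockgroup")
METHODS = ("zip", "spatial")


@dataclass(frozen=True)
class RunConfig:
    geography: GeographyConfig = GeographyConfig()
    waitlist: WaitlistConfig = WaitlistConfig()
    threshold: float = 10.0
    scales: tuple[str, ...] = SCALES
    seed: int | None = None   # overrides both sub-config seeds

    def __post_init__(self) -> None:
        if self.threshold <= 0:
            raise ValueError("threshold must be positive")
        bad = set(self.scales) - set(SCALES)
        if bad:
            raise ValueError(f"unknown scales: {sorted(bad)}")

    def resolved(self) -> "RunConfig":
        if self.seed is None:
            return self
        return dataclasses.replace(
            self,
            geography=dataclasses.replace(self.geography, seed=self.seed),
            waitlist=dataclasses.replace(self.waitlist, seed=self.seed),
        )

    @staticmethod
    def from_dict(doc: dict) -> "RunConfig":
        geo = GeographyConfig(**doc.get("geography", {}))
        wl = dict(doc.get("waitlist", {}))
        for key in ("study_start", "study_end"):
            if key in wl and isinstance(wl[key], str):
                wl[key] = date.fromisoformat(wl[key])
        return RunConfig(
            geography=geo, waitlist=WaitlistConfig(**wl),
            threshold=float(doc.get("threshold", 10.0)),
            scales=tuple(doc.get("scales", SCALES)),
            seed=doc.get("seed"),
        )

    def to_dict(self) -> dict:
        doc = dataclasses.asdict(self)
        for key in ("study_start", "study_end"):
            doc["waitlist"][key] = doc["waitlist"][key].isoformat()
        if doc["geography"]["hrr_seeds"] is not None:
            doc["geography"]["hrr_seeds"] = [
                list(p) for p in doc["geography"]["hrr_seeds"]]
        doc["scales"] = list(doc["scales"])
        return doc


def stage_simulate(cfg: RunConfig, outdir: Path) -> SyntheticSystem:
    cfg = cfg.resolved()
    system = generate_geography(cfg.geography)
    system.waitlist = generate_waitlist(system, cfg.waitlist)
    system.write(outdir)
    return system


def stage_cohort(cfg: RunConfig, outdir: Path,
                 system: SyntheticSystem) -> tuple[pd.DataFrame, dict]:
    period = StudyPeriod(cfg.waitlist.study_start, cfg.waitlist.study_end)
    cohort_df, tally = build_cohort(
        system.waitlist, system.facility_xwalk, system.centers, period)
    cohort_df.to_csv(outdir / "cohort.csv", index=False)
    write_json(tally, outdir / "exclusions.json")
    return cohort_df, tally


def stage_derive(cfg: RunConfig, outdir: Path, system: SyntheticSystem,
                 cohort_df: pd.DataFrame
                 ) -> tuple[list[Trr], list[HrrAssignment], dict]:
    trrs, assignments, groups, log = derive_trrs(
        cohort_df, system.centers, system.zip_hrr, system.hrrs,
        threshold=cfg.threshold)
    write_layer(trr_layer(trrs), outdir / "trrs.geojson")
    pd.DataFrame(
        [(a.hrr_id, a.group_id, a.winning_count, a.runner_up_count,
          int(a.tie)) for a in assignments],
        columns=["hrr_id", "trr_id", "winning_count", "runner_up_count",
                 "tie_flag"],
    ).to_csv(outdir / "hrr_assignments.csv", index=False)
    return trrs, assignments, log


def stage_link(cfg: RunConfig, outdir: Path, system: SyntheticSystem,
               assignments: list[HrrAssignment]
               ) -> tuple[dict[tuple[str, str], AssignmentSet],
                          dict[str, Layer], dict]:
    """Clip units and run both linkage methods at the requested scales."""
    clipped: dict[str, Layer] = {}
    log: dict = {}
    for scale, layer in (("tract", system.tracts),
                         ("blockgroup", system.blockgroups)):
        clipped[scale], dropped = clip_units_to_coverage(layer, system.hrrs)
        log[f"clip_dropped_{scale}"] = len(dropped)
    zt, zb = link_zip_method(clipped["tract"], clipped["blockgroup"],
                             system.zip_tract, system.zip_hrr, assignments)
    trrs_layer = read_layer(outdir / "trrs.geojson")
    out: dict[tuple[str, str], AssignmentSet] = {}
    for aset in (zt, zb):
        if aset.scale in cfg.scales:
            out[("zip", aset.scale)] = aset
    for scale in cfg.scales:
        out[("spatial", scale)] = link_spatial_method(
            clipped[scale], trrs_layer, scale)
    for (method, scale), aset in sorted(out.items()):
        aset.to_frame().to_csv(
            outdir / f"assignments_{method}_{scale}.csv", index=False)
        pd.DataFrame({"unit_id": aset.unassigned}).to_csv(
            outdir / f"unassigned_{method}_{scale}.csv", index=False)
        log[f"unassigned_{method}_{scale}"] = len(aset.unassigned)
        if method == "spatial":
            log[f"area_ties_{method}_{scale}"] = len(aset.ties)
    return out, clipped, log


def stage_evaluate(cfg: RunConfig, outdir: Path, trrs: list[Trr],
                   linked: dict[tuple[str, str], AssignmentSet],
                   clipped: dict[str, Layer]) -> dict:
    table1_rows = []
    records = {}
    for (method, scale), aset in sorted(linked.items()):
        rep = count_multiplets(aset, clipped[scale], trrs)
        table1_rows.append((rep.method, rep.scale, rep.n_multiplets,
                            rep.double_assigned_area,
                            rep.pct_of_total_trr_area))
        recs = misassignment_records(trrs, aset, clipped[scale])
        records[(method, scale)] = recs
        pd.DataFrame(
            [(r.trr_id, r.area_outside, r.area_uncovered,
              r.total_misassigned, r.pct_misassigned) for r in recs],
            columns=["trr_id", "area_outside", "area_uncovered",
                     "total_misassigned", "pct_misassigned"],
        ).to_csv(outdir / f"misassignment_{method}_{scale}.csv", index=False)
    pd.DataFrame(
        table1_rows,
        columns=["method", "scale", "n_double_assigned",
                 "area_double_assigned", "pct_of_total_trr_area"],
    ).to_csv(outdir / "table1.csv", index=False)

    table2_rows = []
    tests = {}
    for scale in cfg.scales:
        try:
            comp = compare_methods(records[("zip", scale)],
                                   records[("spatial", scale)])
        except ValueError:
            # aligned limit: methods agree on every TRR, no test possible
            comp = {}
        tests[scale] = comp
        for method in METHODS:
            s = summarize(records[(method, scale)])
            table2_rows.append((
                method, scale, s.n, s.mean_pct, s.sd_pct, s.median_pct,
                s.min_pct, s.max_pct, s.mean_area, s.sd_area,
                s.median_area, s.min_area, s.max_area,
                comp["pct"].p_value if comp else float("nan"),
                comp["area"].p_value if comp else float("nan")))
    pd.DataFrame(
        table2_rows,
        columns=["method", "scale", "n", "mean_pct", "sd_pct",
                 "median_pct", "min_pct", "max_pct", "mean_area",
                 "sd_area", "median_area", "min_area", "max_area",
                 "p_value", "p_value_area"],
    ).to_csv(outdir / "table2.csv", index=False)
    return {
        "records": records,
        "tests": {
            scale: {k: dataclasses.asdict(v) for k, v in comp.items()}
            for scale, comp in tests.items()
        },
    }


def run_pipeline(cfg: RunConfig, outdir: str | Path,
                 system: SyntheticSystem | None = None) -> dict:
    """Run every stage; return the manifest (also written to disk).

    If ``system`` is supplied (e.g. user-provided layers read from
    disk), simulation is skipped and the given layers are used; they
    must provide a waitlist table.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    cfg = cfg.resolved()
    if system is None:
        system = stage_simulate(cfg, outdir)
    elif system.waitlist is None:
        raise ValueError("supplied system has no waitlist table")
    cohort_df, tally = stage_cohort(cfg, outdir, system)
    trrs, assignments, derive_log = stage_derive(cfg, outdir, system,
                                                 cohort_df)
    linked, clipped, link_log = stage_link(cfg, outdir, system, assignments)
    evaluation = stage_evaluate(cfg, outdir, trrs, linked, clipped)
    manifest = {
        "tool": "trrlink",
        "version": __version__,
        "config": cfg.to_dict(),
        "cohort": tally,
        "derivation": derive_log,
        "linkage": link_log,
        "tests": evaluation["tests"],
    }
    write_json(manifest, outdir / "manifest.json")
    return {
        "manifest": manifest,
        "system": system,
        "cohort": cohort_df,
        "trrs": trrs,
        "assignments": assignments,
        "linked": linked,
        "clipped": clipped,
        "records": evaluation["records"],
    }
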