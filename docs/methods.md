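# Methods

## Study system and model

The pipeline reproduces, on synthetic data, the full chain of a
catchment-area linkage study for organ transplant:

1. **Cohort.** Waitlist entries carry a patient id, facility id, home zip,
   birth date and a listing interval. Facility aliases are collapsed to
   canonical center ids through a many-to-one crosswalk; entries at centers
   absent from the active-center table are dropped and counted. Inclusion
   rules then run in a fixed order: (i) drop entries with a missing start
   date or a start after the recorded end; (ii) administratively censor
   open entries (missing end) at the last study day; (iii) trim each
   interval to the adult portion inside the study period (start to
   max(start, 18th birthday, study start); end to min(end, study end));
   (iv) drop entries whose trimmed interval is empty. "At least one day"
   uses inclusive endpoints, matching censoring *on* the last study day,
   and the under-18 rule trims rather than excludes because only the
   portion of a listing at age ≥ 18 counts. The rule order is a
   convention: it only affects which tally a doubly-bad row lands in,
   never the final cohort. A missing birth date is surfaced as a data
   error rather than silently kept or dropped.

2. **TRR derivation.** Centers within the merge threshold (default 10
   distance units, the analogue of 10 straight-line miles) are grouped by
   connected components, so two distant centers linked by a third close to
   both merge. Entries fan out to *every* HRR their zip overlaps. Within
   an HRR, distinct patients are counted per center group — repeat
   entries at one group count once; listings at two groups count for
   both; overlapping and non-overlapping entries are treated alike, since
   only the distinct-patient relation matters. Each HRR with at least one
   patient goes to the plurality group ("majority" is implemented as
   argmax: with more than two groups an absolute majority need not
   exist). Ties break to the group whose member-centroid is nearest the
   HRR centroid, then to the smallest group id; every tie is flagged in
   `hrr_assignments.csv`. Zero-patient HRRs join no TRR and are listed in
   the manifest.

3. **Linkage.** Units are first clipped to the dissolved union of all
   HRRs (dropping, e.g., coastline-only units). The zip method preserves
   the many-to-many crosswalks end to end — no deduplication to a
   dominant chain — because duplicate assignment is precisely the failure
   mode being measured; block groups inherit the parent tract's TRR set.
   The spatial method assigns each unit to the TRR of largest
   intersection; intersection areas below 1e-9 of the smaller operand are
   zeroed first so shared boundaries never create candidates, and exact
   ties break to the smallest TRR id (logged).

4. **Error metrics.** Multiplets are units with ≥ 2 TRRs; their clipped
   area is reported absolutely and as a share of total TRR area. Per-TRR
   misassignment decomposes the symmetric difference between the TRR and
   the union of its assigned units into assigned-but-outside and
   uncovered components; the percentage (relative to TRR area) is
   deliberately unclamped — nothing bounds it above 100. A multiplet
   unit's geometry enters every TRR it is assigned to. Summaries report
   mean, sample SD (n−1; zero with a flag when n = 1), median and range.

## Statistics

The paired Wilcoxon signed-rank test is implemented in-package: exact
zeros are dropped (standard convention; the count is reported), tied
magnitudes receive mean ranks, W⁺ is the sum of positive-difference
ranks, and the two-sided p is exact by full 2ⁿ enumeration of sign
patterns for n ≤ 12 — the null distribution is enumerated over the
*observed* (possibly tied) rank vector, so ties are handled exactly —
and a normal approximation with the tie-corrected variance
n(n+1)(2n+1)/24 − Σ(t³−t)/48 and a 0.5 continuity correction beyond.
Tests cross-check this against an independent brute-force enumerator and
against scipy's implementation in the regimes where scipy's conventions
coincide. Methods are paired per TRR at the same scale, on both percent
and absolute misassigned area.

## Synthetic geography

The generator emulates the structural relationships the analysis
depends on, not US geography itself:

* Block groups: an n×n square grid on a side-`side` region; tracts:
  k×k blocks of block groups (n divisible by k). Both partition the
  region exactly.
* HRRs: Voronoi cells of h seed points clipped to the region — convex,
  boundary lines misaligned to the census grid, partitioning the region.
  Seeds are random with a minimum-separation rejection rule, or caller
  supplied (the aligned fixtures place two seeds symmetric about a tract
  line so the Voronoi boundary coincides with it).
* Zips: an m×m grid offset by δ·(cell size) in both axes (0 ≤ δ < 1),
  clipped to the region; δ = 0 reproduces an aligned grid. n must be
  divisible by m so that the δ = 0 limit makes zip lines a subset of
  block-group lines. Zips are polygons and the zip↔HRR and zip↔tract
  crosswalks are derived from true positive-area overlap, mirroring how
  real ZCTA crosswalks are constructed, so the zip method's error is
  geometrically attributable.
* Centers: c points; each new center clusters within 10 units of an
  existing one with probability `cluster_prob`, exercising the
  center-merging rule.
* Waitlist: patients live at their home-zip centroid (the lowest spatial
  resolution the data model grants patients) and choose centers with
  probability ∝ exp(−distance/`choice_scale`); listing windows extend
  one year past each end of the study period so every trimming and
  exclusion rule fires; configurable fractions of repeat entries,
  second-center listings, missing end dates, minors aging in
  mid-listing, alias facility ids, and listings at a retired center
  absent from the active table.

Defaults — 100×100 region, n = 30, k = 3, h = 8, m = 10, δ = 0.3, c = 6,
2000 patients, study period 2008-01-01 to 2018-12-31 — give a system
where every HRR is practically always won by some group (so TRRs tile
the region) while zips straddle HRR boundaries freely. These sizes are
the package's desk-scale study conditions; a full-country system is
three orders of magnitude larger but adds no new structure.

One global seed fans out to per-layer substreams, so adding a layer
never perturbs earlier ones; identical config + seed yields
byte-identical artifacts (sorted-key JSON, stable float repr).

**What passing synthetic runs do not show:** grid census units and
convex Voronoi HRRs are far tamer than TIGER polygons (no coastlines,
slivers, holes or topology defects beyond what the validity checks
catch); zip polygons here tile the region exactly, whereas real ZCTAs
have gaps; and patient geography is uniform rather than
population-weighted, so absolute error magnitudes are not comparable to
real-data values — only the structural guarantees (zero spatial-method
multiplets, spatial ≤ zip total misassignment under partition, exact
agreement in the aligned limit) transfer.

## Numerical choices

* All geometry is planar and delegates to shapely/GEOS; validity is
  checked and self-intersecting rings raise an error naming the feature.
  No spherical geometry: the projected-planar and spherical routes are
  equivalent for this analysis, and a haversine great-circle mode (miles)
  exists only for lon/lat center distances behind an explicit flag.
* Sliver tolerance 1e-9 (relative) throughout — crosswalk derivation,
  clipping, spatial argmax: synthetic tessellations share exact vertices,
  so anything smaller than that is a floating-point artifact, not data.
* Dominance of the spatial method (total misassigned area ≤ zip method's)
  is guaranteed only where clipped units partition the TRR-covered
  region; a unit partially outside every TRR but zip-unassigned can
  reverse the inequality, which is why the guarantee — and the test — is
  conditioned on the partition property.
* With few TRRs the exact two-sided Wilcoxon p is floored at 2/2ⁿ
  (0.25 at n = 3): reported as computed, never extrapolated.

## Known limitations

Areal interpolation (splitting units across TRRs with area or population
weights) and population-weighted error measures are out of scope, as is
ingestion of real USRDS/HRSA/Dartmouth/TIGER sources. Units left
unassigned by a method are excluded from that method's error metrics but
reported in the unassigned logs.
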