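# Methods

This note documents the models, numerical choices and synthetic study
conditions behind `driftsource`, and what the tests do and do not establish.

## Surface transport model

Particles are surface-restricted (2-D) and move under

* **Advection**: classical 4-stage Runge–Kutta on the interpolated current
  field. Velocities are converted to angular rates with 111,195 m per degree
  of latitude and a cos(lat) factor for longitude (latitude clipped at
  ±89.5° to keep the metric factor finite). Backtracking negates the
  velocities and runs the clock in reverse.
* **Diffusion**: independent zero-mean Gaussian kicks per horizontal axis
  with variance 2·K·Δt m² per internal step, converted to degrees at the
  particle's latitude. K = 0 is exactly the identity. The random walk in a
  backtracked run is a fresh stochastic realisation, not an "undoing" of
  forward noise — the usual choice in Lagrangian backtracking, since the
  sub-grid history of a particle is unknowable.

Defaults: K = 10 m²/s (the value favoured by drifter calibration),
internal step 3,600 s, output/settlement interval 86,400 s. RK4 at hourly
steps on mesoscale-smooth fields gives deterministic forward–backward
round-trip errors far below 1 km over 30 days (the suite checks < 1 km).

Field sampling is bilinear in lon/lat — wrap-aware across the 0/360 seam,
the internal longitude convention everywhere — and linear in time between
daily snapshots. Masked (land) nodes contribute zero velocity, which keeps
coastal interpolation finite; what a particle does at the coast is decided
in transport: a sub-step that would end on a land node resamples its
diffusion kick up to 10 times and otherwise stays put for that sub-step
(prevents beaching artifacts). Particles whose latitude leaves the grid — or
longitude, for a regional (non-global) domain — are flagged `escaped` and
removed, mirroring open-boundary particle tracking in a regional model
domain. Particles still adrift at the field's time boundary or a configured
maximum duration are `expired`.

Randomness is order-invariant: one master seed spawns an independent
substream per particle keyed by particle id, so a particle's path is
identical regardless of ensemble size or execution order (tested).

## Settlement geometry

Settlement cells are pointy-top hexagons of 1° horizontal edge-to-edge
width, laid out in planar lon/lat coordinates. "1°" is interpreted as the
horizontal width because the size semantics of a GIS hex grid over a
territorial-sea shapefile are conventionally planar; results at this scale
are robust to the convention but not bit-identical to any particular
shapefile-derived grid. A cell is active iff it intersects ≥ 1 habitat
polygon and no exclusion polygon (exclusion is cell-level — whole hexagons
are removed, as when the Hawaiian archipelago is excluded to forbid
self-recruitment). Point-in-cell queries resolve shared edges to the lowest
cell id, making the tessellation an exact partition for scoring. Landing is
tested at the daily output step only, matching daily-resolved transport;
sub-daily first-contact is deliberately not modelled.

## Landing statistics

Percentages are counts over the *total released* (not total landed),
rounded half-up to one decimal for display (banker's rounding would bias
printed tables). Region aggregation assigns each cell to the box containing
its centroid (inclusive lower bounds, exclusive upper), with disjointness
validated and a residual "other" bucket so counts always conserve. Pairwise
group comparisons use the Wilcoxon–Mann–Whitney rank-sum test: exact
enumeration of all C(n+m, n) assignments with midrank ties when both groups
have ≤ 8 observations, the tie-corrected normal approximation otherwise;
families are Bonferroni-adjusted. ENSO/season association uses unpaired
rank-sum on monthly landing counts (months without landings count as zero);
a paired signed-rank variant is provided but requires equal-length groups,
because the pairing unit of a "paired rank sum" across unequal phase-month
counts is undefined.

## Diffusivity calibration

For each candidate K ∈ {0.5, 5, 10, 20, 50} m²/s, n particles (default
1,000) are backtracked from a drifter's final fix; each particle's score is
its minimum passing distance — the smallest haversine distance (sphere
radius 6,371 km) between any logged daily position and the known origin
point. The K with the smallest mean is selected; every candidate whose
pairwise Bonferroni-adjusted p versus the winner is ≥ 0.05 is reported as
statistically indistinguishable. Only the final fix seeds the ensemble and
only the origin anchors the metric; the intermediate drifter track is not
assimilated. `pool_calibrations` concatenates per-K samples across several
drifters before selection, as a study with multiple tagged objects does.

A structural property of this score worth knowing: when the deterministic
(K→0) backtrack happens to pass close to the origin, added diffusion is pure
noise and the smallest K wins; when it misses badly, exploration pays and
the largest K wins. The score therefore identifies K only weakly — in the
original field application the 5–50 m²/s arms were statistically
indistinguishable — and a decisive synthetic test must pool drifters whose
unresolved forcing spans both regimes (see below).

## Pooled eDNA screening

Cq is the first threshold crossing of the fluorescence trace, linearly
interpolated between bracketing cycles. The standard curve is the
least-squares line of Cq on log10 copies (≥ 3 distinct dilution levels);
efficiency = 10^(−1/slope) − 1, so slope −3.3219 is 100%. Quantification
inverts the fitted line exactly; an uncalled Cq is zero copies. "Positive
starting quantity" is operationalised as: Cq called and quantified copies
> 0. The plate threshold is an input (instruments compute their own); a
documented fallback (baseline mean + 10 SD over cycles 3–15) is provided.
The region decision table: any NTC/EB amplification ⇒ contaminated; else a
positive (spiked) pool with no amplifying replicate ⇒ invalid_spike_fail;
else ≥ 1 positive sample-pool replicate ⇒ detected; else presumed_negative.
The reliability rule smooths the mean replicate trace with a centred moving
average (window 3 cycles) and requires the smoothed consensus to exceed the
mean threshold — a dependency-free stand-in for the visual smoother-based
criterion, chosen so the rule is deterministic and testable; a single-cycle
spike in one replicate is correctly suppressed. Pools are capped at 20
members so a single positive diluted m-fold stays above the assay floor.

## Barcode identity

Pairwise global alignment is Needleman–Wunsch with match +1 / mismatch −1 /
gap −2 and a deterministic traceback tie order (diagonal, then up), verified
against an independent aligner's optimal score. Percent identity is
100 × matching columns / columns where both rows carry a base, with
terminal-gap columns stripped — ragged amplicon ends do not penalise,
internal indels simply drop out of the denominator. Identities are reported
exactly and displayed half-up to one decimal. Confirmation requires rbcL,
COI and SSU each strictly > 99% identity *and* an eDNA detection
(provisional without the detection, rejected otherwise). Multiple-sequence
alignment construction is out of scope; pre-aligned FASTA rows are consumed
as-is.

## Synthetic study conditions

The generators define the conditions under which the pipeline is tested:

* **uniform / solid_body** fields carry closed-form trajectories (straight
  lines; exact circles in degree space) used as integrator oracles.
* **double_gyre** is the classic two-gyre streamfunction on planar
  equirectangular metres, divergence-free by construction, optionally with
  an oscillating separatrix (chaotic advection).
* **convergent_sink** is the designated known-source fixture: linear radial
  flow about an island, oriented so the *backtracked* flow converges on it,
  making source recovery decidable (≥ 95% of backtracked particles should
  land in the island's cells; the suite observes 100% at K = 10).
* **Drifters** are forward-simulated with the transport module itself at a
  known K_true (4-h fix cadence; 61 fixes over 10 days, endpoints
  inclusive), optionally with a constant *windage* slip — unresolved forcing
  the drifter feels but the model field does not contain, which is what
  makes real tagged-debris tracks deviate systematically from deterministic
  model trajectories.
* **qPCR curves** are logistic sigmoids positioned so the threshold crossing
  solves to Cq = intercept + slope·log10(copies) (steepness 0.4/cycle,
  plateau 1000 RFU): linear-interpolated Cq calling then recovers the
  analytic root within 0.05 cycles and quantification round-trips within
  10% over 10–10⁶ copies.
* **Sequence families** mutate a reference at per-site probability d with a
  uniformly chosen different base, so expected identity is 100(1−d)%.

The calibration test condition uses eight drifters (K_true = 10 m²/s,
60-day tracks, windage 0.012/0.009 m/s) on the steady double gyre, each
backtracked for 150 days with 125 particles per arm and the arms pooled
before selection. The windage magnitude is deliberate: it places the
deterministic-backtrack miss in the crossover band where neither the
near-deterministic (K = 0.5) arm — stranded at the systematic miss — nor
heavily over-dispersed (K = 50) arms — paying exploration losses with no
remaining gains — can win, so the selected K falls at or adjacent to K_true
and the 0.5 arm is significantly worse: the qualitative structure the field
calibration reported. Because selection among the 5–50 m²/s arms is weakly
identified (their score distributions overlap broadly), the outcome remains
stochastic at the margins; pooling several drifters is what makes it
decisive in practice. Problem sizes (hundreds of particles, 150-day
windows, 0.5° grids) are chosen as the smallest at which these contrasts
are decisive.

What the synthetic conditions do *not* emulate: mesoscale realism of
reanalysis currents (western-boundary currents, ENSO-dependent circulation),
3-D motion, windage/Stokes classes of drifting objects, observational gaps
in drifter records, and qPCR inhibition or probe chemistry beyond a clean
sigmoid. Passing tests therefore demonstrate correctness of the machinery
and decision rules under controlled transport and assay physics, not skill
of any particular reanalysis product.

## Known limitations

* Geometry is planar in lon/lat; hexagon areas shrink poleward and no
  equal-area grid is offered.
* Settlement at daily resolution can skip a cell a particle crossed
  sub-daily.
* The rank-sum exact branch enumerates combinations and is exponential;
  it is restricted to n, m ≤ 8 by design.
* Minimum-passing-distance calibration identifies K only weakly (see
  above); its selected value should always be read together with the
  indistinguishable set.
* ESRI shapefile input is not supported; polygons are GeoJSON.
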