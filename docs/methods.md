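# Methods

## Simulation model

The virtual instrument executes one scan at a time from a request queue
that starts with a single MS1 survey scan. Completing an MS1 scan hands it
to the controller, which returns zero or more MS2 requests; the instrument
queues them as one duty cycle — MS2 scans, then the next MS1 — and advances
a deterministic clock. Per-scan durations are constants that fold the
controller's processing time into the MS1 duration, the same way wall-clock
gaps between scan start times behave on a real instrument. Defaults (s):
full-scan 0.54, TopN 0.56, WeightedDEW 0.61, SmartROI 0.68 for MS1,
matching measured inter-scan gaps for these controller classes on an
Orbitrap-type instrument; MS2 defaults to 0.20 s, chosen consistent with
MS2 scans being acquired at much lower resolution than MS1 (7 500 vs
120 000) and configurable since per-scan MS2 timings are not separately
published. There is no stochastic scan-time jitter: runs are exactly
reproducible, which the determinism contracts and the controller
equivalence tests rely on.

**Shifted scheduling.** With shift k, a cycle's plan becomes
`(n−k) MS2, MS1, k MS2`: the trailing k scans (still derived from the
triggering survey scan) execute after the next MS1, so on hardware the
controller's processing would overlap acquisition. A shift larger than the
number of requests is clamped (all MS2 scans deferred). In this simulator,
whose durations already include processing, shifting mainly reorders
execution; the throughput gain it buys on hardware is represented by the
shift variants being run with the same folded timings.

## Chemicals, chromatograms and ground truth

Each analyte is one charged species: an m/z, a Gaussian elution profile
`I(t) = I_max · exp(−(t − rt_apex)² / 2σ²)`, and no isotopes, adducts or
fragment spectra content (MS2 scans carry precursor identity only; neither
coverage nor efficiency inspects fragments). A Gaussian was chosen because
the true bounding box then has a closed form — RT bounds where the profile
crosses the detection floor, `rt_apex ± σ·sqrt(2·ln(I_max/floor))` — making
every downstream stage testable against exact expectations; any unimodal
shape would serve, and the intensity-function contract keeps it pluggable.

Generator defaults define the study conditions: m/z uniform over
70–1000 Th (positive-mode metabolomics window), apex RT uniform over the
run, σ uniform on 3–10 s (chromatographic peaks a few tens of seconds
wide), apex intensities log-uniform on 1e4–1e7 to emulate the wide dynamic
range of complex extracts, all above the 5e3 fragmentation floor so that
the box count equals the analyte count and coverage deficits are
attributable to scheduling, not detectability. The trend study uses 1000
analytes in a 300 s run — roughly 100 species coeluting at any instant,
far more than the ~10 MS2 slots per duty cycle can serve — to reproduce
the regime where prioritisation strategy matters. Box m/z half-width is
0.01 Th; the detection floor for boxes equals the controllers' minimum
fragmentation intensity (5e3) so that a box exists exactly when its
analyte is ever eligible for fragmentation.

What the generator does **not** emulate: isotope envelopes and adducts
(several boxes per compound in real data), intensity noise between runs,
peak tailing, background/contaminant ions, and centroiding artefacts.
Passing tests therefore demonstrate correctness of the scheduling,
exclusion, ROI and matching logic under known ground truth — not
performance on real extracts, where peak picking itself is imperfect.

## Controllers

**TopN + DEW.** Peaks at or above the intensity floor and not excluded are
ranked by intensity; the top N are fragmented. An m/z is excluded while
`t − t_f ≤ t0` for a dynamic-exclusion record within 10 ppm (tolerance
configurable; the most recent matching record wins, and re-fragmentation
overwrites the record rather than appending). Defaults N = 10, t0 = 15 s.

**WeightedDEW.** Priority is intensity × weight, the weight ramping
linearly from 0 at t0 to 1 at t1 after fragmentation; never-fragmented
ions have weight 1, and only strictly positive priorities are requestable.
Defaults t0 = 15 s, t1 = 120 s (grid-search optima); t1 = t0 reduces the
controller to TopN exactly, a scan-by-scan equivalence asserted in the
tests.

**SmartROI.** Regions of interest are grown across survey scans: each peak
extends the active ROI with the nearest last-point m/z within 10 ppm (one
peak per ROI per scan, ties toward lower m/z, greedy nearest-first
assignment); unmatched peaks above the creation threshold (default: the
fragmentation floor) start new ROIs; ROIs not extended by a scan are
retired immediately, since fragmentation decisions are live and a retired
ROI can no longer be targeted. Availability rules: (1) at or above the
intensity floor in the latest scan, else unavailable regardless of
history; (2) available if never fragmented; (3) else available if current
intensity ≥ α × intensity at last fragmentation, or ≤ β × the maximum
since last fragmentation. "Dropped by a factor β" is implemented as
current ≤ β·max (β = 0.1: fallen to 10 % of the running maximum); the
running maximum resets to the current intensity at each fragmentation.
Defaults α = 1000, β = 0.1 (grid-search optima). With α = +∞, β = 0 every
ROI is fragmented at most once — the degenerate regime used as a property
test. α ≤ 1 or β ≥ 1 make a rule vacuously true and trigger a warning,
not an error.

Selection ties (equal priority) break toward higher m/z, then earlier peak
index, fixing the otherwise arbitrary order so runs are byte-reproducible.

## The coverage optimum

The offline bound schedules a fixed grid of duty cycles (one MS1 followed
by N MS2 slots at the mean scan durations), then builds a bipartite graph:
slot—box edges require the slot time inside the box's RT extent, the
immediately preceding MS1 scan's time inside it too (a controller can only
target what a survey scan showed while the peak was live), and the box's
intensity at that MS1 scan at or above the fragmentation floor. All RT
comparisons are inclusive at both endpoints; a missing intensity value
counts as below the floor. The maximum matching — computed by an in-package
Hopcroft–Karp with deterministic node ordering, verified in tests against
exhaustive enumeration and an independent library implementation — is the
largest number of boxes fragmentable at least once. The same edge rules
applied to a *realized* simulated schedule give a per-run bound that no
controller's coverage exceeds (asserted across the test matrix). For
synthetic inputs the per-box intensity lookup evaluates the analyte's
chromatogram; for full-scan data it takes the most intense centroid within
the box's m/z range in the nearest MS1 scan.

## Evaluation conventions

An MS2 event belongs to a box when its precursor m/z and its own scan
start time fall inside the rectangle (inclusive); using the source MS1
time instead is available behind a flag, as box membership at the survey
versus the fragmentation instant is a genuine convention choice. An event
inside k overlapping boxes credits all k by default — so efficiency is not
strictly capped at 1 in pathological overlaps — with a single-credit mode
(nearest box centre, ties by id) behind a switch. Efficiency's denominator
counts every MS2 scan, including those that hit no box; reported tables
round to two decimals but the raw ratio is always carried. The grid search
runs one deterministic simulation per parameter combination, sequentially,
and breaks score ties toward the earlier grid point.

## Problem sizes and numerical choices

The test suite and the acceptance script run entirely on synthetic data
generated at call time: unit fixtures use 60–250 analytes over 120–200 s;
the headline comparison uses 1000 analytes over 300 s (about 1100–1300
scans per run, ~2 s wall clock); matching-oracle property tests use graphs
up to 8+8 nodes against an exhaustive subset dynamic programme. CSV
serialisation writes floats with `%.17g` and reads with round-trip
precision so that fixed-seed outputs are byte-identical across runs. mzML
reading extracts only ms level and scan start time (converting
minute-based times to seconds) to estimate mean per-level scan durations
for schedule construction.

## Known limitations

* No instrument-queue concurrency: processing time is folded into scan
  durations, so shifted scheduling cannot show its real-hardware
  throughput benefit, only its correctness.
* Precursor selection is noiseless and m/z-exact; chimeric isolation
  (multiple species in one 0.7 Th window) is not modelled.
* ROI tracking matches at most one peak per ROI per scan and does not
  split or smooth ROIs; no prediction of whether an ROI contains a peak.
* The optimum is a fixed-grid (or realized-schedule) matching; it does not
  consider schedules that skip unused MS2 slots to fit more duty cycles.
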