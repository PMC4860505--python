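# Methods

`fiberglow` models and quantifies a single-molecule DNA fiber assay for
psoralen adducts. Cells uniformly prelabeled with CldU are treated with a
digoxigenin-tagged trimethylpsoralen (Dig-TMP) and photoactivated with
long-wave UV — either a lamp exposing the whole population or a laser
confined to a nuclear region of interest (ROI) — then pulse-labeled with
IdU for 1 h. Spread DNA fibers are imaged in three channels: the CldU
prelabel delineates each molecule end to end, immuno-quantum dots mark
individual Dig-TMP adducts, and IdU marks replication tracts synthesized
after treatment. The package simulates this experiment with full ground
truth, renders realistic fields, re-analyzes them blind, and computes the
assay's statistics.

## Ground-truth generator

**Adduct placement.** Adducts on a fiber of length $L$ kb follow a
piecewise-constant-rate Poisson process. The nominal rate $\lambda$ is
expressed in adducts per $10^3$ kb. Chromatin-accessibility heterogeneity
is modeled with two zones: a contiguous accessible segment covering a
fraction $f$ of the fiber (uniform random location) reacts at $r$ times the
base rate; the base rate is scaled so the length-weighted mean is exactly
$\lambda$:

$$\lambda_\text{inaccessible} = \frac{\lambda}{f r + (1-f)}, \qquad
  \lambda_\text{accessible} = r\,\lambda_\text{inaccessible}.$$

Defaults $f = 0.3$, $r = 4$ produce visible clustering of adducts without
point hotspots; $r = 1$ (or $f \in \{0, 1\}$) recovers a homogeneous
process with exponential inter-adduct gaps of mean $10^3/\lambda$ kb.
Each adduct is independently an interstrand crosslink (ICL) with
probability $10/11$, otherwise a monoadduct — the measured 10:1 product
ratio of the compound. The imaging tag cannot distinguish the two, so the
pipeline counts "signals"; the kind is retained in ground truth for
validation only.

**Calibration constants.** $\lambda = 2.69$ per $10^3$ kb represents the
5 µM treatment and $4.48$ the 20 µM treatment (their reported group
means); no dose–response model is implemented. Arc positions map to the
image through the spread-fiber stretching constant 2.59 kb/µm and the
camera sampling 0.16 µm/px (≈ 0.414 kb per pixel). The stretching constant
is a convention for spread fibers, not a measured property of these data,
so it is configurable and recorded in every output header.

**Fiber lengths.** No length distribution is published for these spreads.
The default is lognormal with arithmetic mean 210 kb ($\sigma_{\log} =
0.45$), truncated to 50–500 kb. The mean is implied by the reported
per-experiment tallies (e.g. 44 signals on 78 fibers at 2.69 per $10^3$ kb
gives ≈ 210 kb per fiber); truncation keeps every fiber renderable within
one field and removes debris-scale fragments. All statistics per kb are
insensitive to this choice; it is exposed in the config.

**Replication events.** Each adduct independently receives an adjacent
replication event with probability `encounter_fraction` (default 0.7 — in
an asynchronous 1-h pulse most adducts in replicating regions are
encountered). The event is single-sided with probability 0.15 (one IdU
tract abutting the adduct, side chosen at random), else double-sided
(tracts flanking both sides) — the reported 15%/85% split. Tract lengths
are lognormal, mean 30 kb (5–120 kb), consistent with ~0.5 kb/min fork
progression over a 1-h pulse. A tract unlinked to any adduct is added per
fiber with probability 0.3, kept ≥ 10 kb from every adduct. Double-sided
requests at a fiber end degrade to single-sided and are flagged.

When adducts sit close together their tracts can collide. Free tract ends
are trimmed at the overlap midpoint; ends pinned to an adduct never move;
a tract squeezed to nothing is dropped. After resolution the per-adduct
event labels are **recomputed from the realized geometry** (a neighbour's
tract may now span an adduct — genuinely replication on both sides — or an
adduct may have lost its tract). Ground truth therefore always describes
what is actually on the fiber, which is what a blind re-analysis can
recover.

**Treatment modes.** Lamp mode exposes every fiber to the adduct process.
Laser mode models harvesting cells near the scribed mark: only a fraction
`roi_fiber_fraction` (default 0.7) of fibers derive from exposed nuclei
and carry adducts; the per-fiber adduct law is identical. This encodes the
hypothesis the assay was used to test — that lesion density and spacing do
not depend on the light source — so the two modes should differ only in
the fraction of signal-bearing fibers.

## Rendering

Fibers are drawn as smooth curves of exact arc length: the heading
performs a clamped random walk (SD 0.015 rad/px, |heading| ≤ 0.3 rad) with
a restoring pull toward the lane center, so curvature stays bounded and
fibers remain in disjoint horizontal lanes (16 px tall, ≥ 30 px gaps). A
population that does not fit one 1024×2048 field spills into further
fields; a fiber longer than the usable field width raises an error rather
than wrapping. Intensity is deposited bilinearly along the path (CldU over
the whole arc, IdU over tract arcs, quantum dots as points), blurred with
a Gaussian PSF (σ = 1.2 px), offset by a constant background (100
counts), and degraded with Poisson shot noise plus Gaussian read noise
(SD 2). Channel gains give a fiber plateau of ≈ 200 counts over background
and quantum-dot peaks of ≈ 1300 (SNR ≈ 35, appropriate for quantum dots).
Noise-free renders (`shot_noise=false`, `read_noise_sd=0`) support
validation. Ground-truth pixel paths and spot coordinates are emitted with
every field.

## Image analysis

**Tracing.** Background and noise are estimated robustly (median, MAD) on
the lightly smoothed CldU channel. Connected components above a seed
threshold are re-thresholded at the half-maximum of their plateau — for a
PSF-blurred uniform line this places the boundary at the true fiber ends —
then skeletonized. Spurs shorter than 10 px ending at junctions are
pruned; any component still containing a branch point is a fiber crossing
and is discarded whole and counted (conservative, as in manual scoring).
The ordered skeleton is Gaussian-smoothed (σ = 2 px) to remove chain-code
quantization, which otherwise inflates the length of slanted lines by up
to 8%, and each end is extended by (ridge width / 2 − 0.5) px to undo
skeleton endpoint retreat; both corrections were fixed once against
noise-free renders and zero the mean length bias (residual per-fiber error
≲ 1.5%). Traces shorter than 30 kb are rejected as debris; traces touching
the field edge are flagged and excluded (their length is truncated by the
field of view). Intensity profiles of all channels are sampled every
0.5 kb along the arc.

**Spot detection and assignment.** Quantum-dot spots are local maxima of
the smoothed qdot channel above background + 5 robust SDs, ≥ 3 px apart,
with sub-pixel intensity-weighted centroids. Each spot is assigned to the
trace minimizing perpendicular distance if that distance is ≤ 3 px;
farther spots, and spots exactly equidistant between traces, stay
unassigned (ties counted). Arc positions come from orthogonal projection.
Because a traced polyline has no intrinsic orientation, positional
comparisons against ground truth use the better of the two orientations;
the achieved accuracy is ≤ 2 px-equivalents worst-case, median below one
pixel.

**Tract segmentation.** IdU profiles are thresholded (default: Otsu on the
per-fiber profile, guarded by a contrast test — the above-threshold mean
must exceed the below-threshold mean by 4 below-threshold SDs — so
tract-free noise profiles yield nothing; an absolute threshold can be
supplied instead). Supra-threshold runs separated by gaps < 2 kb merge;
merged runs shorter than 1 kb are dropped. A run of $n$ samples maps to a
half-open interval of width $n \times$ step, which makes segmentation
idempotent on its own output.

## Classification

Per signal at arc position $s$ with adjacency window $a$ (default 2 kb,
≈ 5 px — "immediately adjacent" was a visual judgment in the original
scoring): a tract is left-adjacent if its end lies within $a$ of $s$ (and
starts left of $s$), right-adjacent symmetrically, and a signal buried
deeper than $a$ inside one tract counts as replicated on both sides (a
double-sided encounter appears as one continuous tract across the adduct
after gap closing). Both sides → DOUBLE_SIDED; one → SINGLE_SIDED; tracts
present but none adjacent → TRACT_DISTANT. A fiber's category is the most
advanced state over its signals (DOUBLE > SINGLE > DISTANT); fibers with
signals but no tracts are SIGNAL_NO_TRACT, fibers without signals
NO_SIGNAL. Signals within $a$ of a fiber end can never show a flanking
tract and are flagged end-censored; they are excluded from encounter
proportions by default. Proportions can be counted over fibers (rolled-up
categories) or over signals; the signal level is the unit in which the
15%/85% split is defined and reported.

## Statistics

- 2×2 chi-squared, $\chi^2 = N(ad-bc)^2 / [(a+b)(c+d)(a+c)(b+d)]$, df = 1,
  no continuity correction, for fiber-with-signal counts between groups.
- Pooled-variance Student t from summary statistics (mean, SD, n). With
  the published density summaries (2.69, 0.095, 3) vs (4.48, 0.285, 3)
  pooled gives p ≈ 5×10⁻⁴, consistent with the reported bound p < 0.001,
  whereas Welch gives ≈ 6×10⁻³; the bound selects pooled.
- One-sample z of the double-sided proportion against 0.5: single- and
  double-sided are complementary outcomes of one sample, so the
  "two-proportion" comparison reduces to $z = (\hat p - 0.5)/\sqrt{0.25/N}$.
  A classical two-independent-sample variant is provided separately.
- Two-sample Kolmogorov–Smirnov for spacing distributions (scipy), with
  quartile/mean summaries of both samples.

Two published values are documented as not reproducible: the chi-squared
p = 0.114 for the signal-fraction comparison (no pooling of the printed
counts yields it, with or without continuity correction; the uncorrected
pooled table gives χ² ≈ 1.89, p ≈ 0.169, which the pipeline reports), and
the third decimal of the 0.138/0.862 proportions (pooled counts give
0.1387/0.8613, per-experiment averaging 0.1362/0.8638; pooled values are
reported).

## What the synthetic data does and does not emulate

Emulated: uniform CldU prelabel, Poisson adduct statistics with two-zone
accessibility, the 10:1 ICL:monoadduct ratio, abutting/flanking IdU
tracts with the 15/85 split, diffraction-limited quantum-dot spots at the
stated pixel scale, background/shot/read noise, fiber crossings only as an
opt-in (`overlap` is avoided by lane layout so ground truth stays
unambiguous). Not emulated: fiber fragmentation and debris, variable
stretching along one molecule, antibody labeling gaps in CldU, quantum-dot
blinking or multiple dots per adduct, spectral bleed-through, uneven
illumination. Passing tests therefore demonstrate correctness of the
measurement pipeline under known geometry and noise, not robustness to
every artifact of real spreads; the detection thresholds are deliberately
expressed in robust background units so they transfer to real images.

## Problem sizes and numerical choices

Validation runs use populations of 60–1200 fibers (one to eight
1024×2048 fields); the headline parameter-recovery check uses 1200 fibers
at λ = 2.69 so that Poisson sampling error (~4%) sits well inside the 10%
agreement band, and the adduct-type ratio check uses ≥ 10⁵ adducts (ratio
SD ≈ 1%). All randomness flows from one integer seed per run
(`numpy.random.default_rng`); rendering uses a child stream spawned from
the same seed, and fixed seeds give bit-identical ground-truth tables and
CSV outputs. Half-open intervals in kb, 0-based from the fiber start, are
used throughout; kb values are written to 3 decimals with the calibration
constants in every file header.

## Known limitations

- The tracer discards crossing fibers instead of untangling them; at high
  fiber densities this biases the retained population toward shorter
  fibers (the simulator's lane layout avoids crossings by default).
- Arc positions inherit trace-endpoint uncertainty (≈ 1 px), so adjacency
  calls within ~0.5 kb of the window edge can differ from ground truth
  when another tract boundary happens to fall inside the window.
- The laser ROI is modeled only as a subpopulation fraction; nuclear
  geometry of the stripe, UVA dose, and photochemistry kinetics are out of
  scope.
- Densities well above ~20 adducts per 10³ kb make spot merging below the
  3 px separation limit non-negligible; the assay's reported regimes (2.69
  and 4.48) are far from that limit.
- The published per-fiber tallies are mutually in tension under a Poisson
  model: the density tallies imply a mean fiber length near 210 kb, while
  the ~11% with-signal fraction at the same adduct rate implies fibers
  several-fold shorter (plausibly because that count included many short
  fragments). The default length distribution follows the density tallies,
  so simulated with-signal fractions (~0.4) are higher than the published
  fraction; the published fraction is reproduced from its own counts, not
  from simulation.
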