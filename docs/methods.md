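# Methods

## Model and procedure

A bisulfite sequencing read is treated as an *epiallele*: the ordered binary
methylation states of the CpGs it covers, taken as one cell's local
methylation configuration. The caller asks, region by region, what fraction
of the underlying cell population carries the *fully methylated* epiallele.

**Windows.** For one chromosome, let the distinct covered CpG coordinates be
sorted; every run of `window_w` consecutive CpGs whose adjacent gaps are all
≤ `max_gap` bp is a candidate window (step one CpG). The *common reads* of a
window are the reads covering every window CpG — a read that skips a CpG
inside its span (ambiguous call) is not common for windows containing that
CpG. With `n_common ≥ min_depth`,

    f = #(common reads methylated at all window CpGs) / n_common,

otherwise `f` is undefined. `f` is bounded above by each window CpG's
common-read methylation level, so it never exceeds the weakest site.

**Hot spots and extension.** Windows that are maxima of `f` (ties to the
leftmost) among defined-`f` windows within ± `max_gap` bp of their anchor,
with `f > 0`, seed regions in descending-`f` order. A region grows over
adjacent windows on both sides and stops, per side, when the next window has
`f = 0`, has undefined `f`, lies more than `max_gap` bp away
(anchor-to-anchor), or already belongs to a previously grown region (each
window joins at most one region, so regions never double-count reads).

**Quantification.** With window anchors `p_1 < … < p_k` and scores
`f_1 … f_k`, the trapezoidal integral `I = ∫ f dp` over `[p_1, p_k]` gives

    CM = I / (p_k − p_1),

the integral mean of `f`; by the mean value theorem `min f ≤ CM ≤ max f`
(asserted as a test invariant on every called region). A single-window
region takes `CM = f`, the degenerate limit. A region's `avg_meth` is the
mean per-CpG pileup methylation (all covering reads) over its CpGs — the
quantity a site-level analysis would report.

The window anchor is the midpoint of the window's first and last CpG. Any
monotone anchor choice shifts `I` negligibly; the midpoint makes trapezoids
symmetric and is fixed for determinism.

## Parameters

| parameter | default | units | meaning |
|---|---|---|---|
| `window_w` | 5 | CpGs | sliding-window length; below 5 the all-methylated event is too likely under independence, blurring the two patterns |
| `min_depth` | 10 | reads | minimum *common* reads (not per-site depth) for a defined `f` |
| `max_gap` | 100 | bp | maximum adjacent-CpG and adjacent-window distance; matches the read length, beyond which no read links neighbours |
| `read_length` | 100 | bp | read span; bounds the epiread span and the simulator geometry |
| coverage (evaluation) | 50 | fold | depth of the benchmark simulation |

## Simulator

The generator scans the CpG map 5'→3' holding a pool of active reads; each
read covers the current CpG at a uniform offset in [1, read_length]. A read's
first covered CpG draws Bernoulli(site level); at later CpGs a
*random*-pattern read draws independently from that CpG's level while a
*concordant*-pattern read copies its own previous state. When the pool
covering a CpG drops below the coverage, new reads are created and
back-filled at every already-passed CpG they cover by the same rule (for the
concordant pattern the back-fill draws at the earliest covered CpG and copies
forward). A CpG more than one read length past its predecessor starts a
fresh segment. Consequences: per-CpG depth is exactly the configured
coverage at assignment time (back-fill then raises realized pileup depth
above it); both patterns reproduce the map's per-site marginals and differ
only within reads; seeded runs are exactly reproducible.

Evaluation regions draw their CpG count uniformly from {6,…,20} and
inter-CpG gaps uniformly from 2–20 bp — chosen once so that every region
admits 5-CpG windows with common reads at 100 bp read length; the geometry
sensitivity of the headline numbers is reported by
`evaluate.geometry_sensitivity`. θ is sampled continuously from U(0.1, 0.9).
The synthetic genome map (`synthetic_cpg_map`) emulates an RRBS methylome:
CpG clusters of 10–30 sites with 2–20 bp gaps, separated by >100 bp, cluster
mean levels from a bimodal Beta mixture (0.4 low Beta(1.5,8), 0.4 high
Beta(8,1.5), 0.2 uniform) with 0.05 SD site jitter.

What the simulator does *not* model: sequencing error, bisulfite
non-conversion, fragment-end bias, PCR duplicates, strand asymmetries, or
partially concordant multi-pattern mixtures. Passing benchmarks therefore
show that the caller recovers read-level concordance under clean sampling
noise, not that it is robust to platform artifacts.

## Evaluation and diagnostics

Each benchmark region pair (one concordant, one random) shares θ, so the
average-methylation score carries no class information by construction
(AUC ≈ 0.5); the CM score separates the patterns because the probability of
an all-methylated window under independence is ≈ θ^w. A simulated region's
score is the maximum CM fraction among called regions overlapping it, 0 when
nothing is called. AUC is the rank (Mann–Whitney) statistic with ties at
0.5; R² comes from ordinary least squares of predicted CM on θ over the
positive set.

Distribution-shape diagnostics for the window-size sweep are computed over
windows with defined `f > 0` (zero-`f` windows are the non-signal background
the caller never integrates): the Kolmogorov–Smirnov distance to U(0, 1)
(< 0.2 counts as near-uniform; genuinely uniform samples sit well below 0.1)
and Sarle's bimodality coefficient (uniform gives 5/9 ≈ 0.56; > 0.65 flags
bimodality). On the bimodal-methylome map, random-pattern `f` (a product of
~w local levels, smeared by binomial sampling) is near-uniform while
concordant-pattern `f` inherits the bimodal level distribution.

## Numerical and design choices

- Coordinates are 0-based half-open everywhere, BED-compatible; reverse-strand
  CpG calls are collapsed to the forward-strand C (the Bismark adapter does
  the shift), treating a CpG as one unit.
- Undefined-`f` windows stop extension exactly like `f = 0`: integrating over
  unmeasured space would fabricate signal.
- Equal-`f` local maxima seed leftmost-first; all tie-breaks are fixed so
  identical input yields byte-identical BED output.
- Adjacent regions never merge across an `f = 0` window.
- Differential calling re-quantifies the *union* of both samples' CMRs on
  fixed coordinates (overlapping intervals merged); a sample with windows but
  none passing depth scores CM = 0 ("no detection"), while a sample with no
  pileup at all marks the region not assessable. Thresholds are inclusive
  (|Δ| ≥ 0.2), making the classification exactly antisymmetric under sample
  swap.
- Occupancy attributes a region's full length to the track containing its
  midpoint, so rates can exceed 1 for short tracks (CpG islands); strict
  intersection is available behind `mode="intersection"`.

## Problem sizes

The default test run uses 1000 region pairs per seed for the benchmark
(five seeds), 1000 random epiread matrices for the exact window oracle, and
three replicate sweeps over a 150-cluster (~3000 CpG) synthetic map for the
distribution diagnostics — about 40 s in total; `scripts/acceptance.py`
completes in a few seconds.

## Known limitations

- The estimator's variance is low: a region's CM pools all windows of the
  extended region (~150 distinct reads at 50×), so predicted-vs-true R² on
  positives reaches ~0.95 at the benchmark settings.
- At 10× coverage the `min_depth = 10` common-read filter is near the
  feasibility boundary (common reads of a 5-CpG window are strictly fewer
  than the per-CpG depth), so many windows are undefined and called regions
  fragment: CpGs per region drop by roughly half relative to 20–100×, while
  region counts and mean CM stay comparatively stable. Analyses at 10×
  should expect shorter regions, or relax `min_depth` deliberately.
- CMR boundaries are window-granular (CpG positions of the outermost
  windows), not base-precise.
- Only the fully methylated epiallele is modelled; fully *un*methylated
  concordance and phased multi-pattern decomposition are out of scope.
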