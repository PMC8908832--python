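# Methods

## The system being modelled

Laying hens in a pen with outdoor access move along a linear chain of
four areas, IN–WG–SY–FR, connected by single gates. Antennas on both
sides of each gate register passing hens, so a complete passage produces
two reads: exit side first, entry side about a second later. The
analysis window is the pop-hole open period (default 08:00–17:00, nine
hours); all event times are integer seconds from pop-hole opening.

## Synthetic flock generator

`flocknet.synthetic.simulate_flock` is an event-driven continuous-time
simulation with three planted layers of structure:

* **Ranging types.** Each hen carries a type defining per-area exit
  hazards (s⁻¹) and neighbour preference weights; on leaving an area the
  destination is drawn among chain neighbours proportionally to
  preference. The default four types (`DEFAULT_TYPES`) span the spectrum
  seen in commercial flocks — hens that essentially never leave the
  barn, wintergarden-centred hens, stone-yard users, and free-rangers —
  and give stable, individually distinct daily occupancy profiles.
* **Affiliation graph.** A planted partition into `n_groups` contiguous
  groups; within-group dyads are affiliation edges with probability
  `p_in` (default 0.7), between-group with `p_out` (default 0.05).
* **Social following.** When a hen makes a spontaneous transition, every
  affiliate currently in the origin area follows with probability `s`
  after a uniform 1–10 s delay (`follow_window = 10`). Followed moves do
  not recruit further followers; this bounds cascade depth while still
  producing multi-hen bursts, because the leader recruits all its
  affiliates in one step. Following is the single dial that creates both
  gate co-occurrence within 5 s windows and day-scale alignment of
  occupancy patterns.

Defaults emulate the study system the package targets: 105 hens per
pen, 72 tracking days, a nine-hour open window, and i.i.d. registration
dropout `p_miss = 0.15`. At pop-hole closing all hens still outside are
stepped back to IN; these shoo-in transitions are flagged `forced` in
the ground-truth log and are not emitted as registrations (the event
CSV schema has no flag column, and they fall outside the analysis
window by construction). Identical config and seed reproduce the event
log byte for byte.

**A deliberate design point: the exchangeable flock.** Hens that use
the same gates meet more often *by chance*, so with heterogeneous
ranging types the association matrix correlates with movement
similarity even at `s = 0` (Mantel r near −0.6 in our conditions).
This chance-co-location confound is real — it is the very artefact the
time-shift control exists to probe — but it makes a heterogeneous flock
unsuitable for measuring recovery of the *social* coupling parameter.
Coupling-recovery experiments therefore use the single-type preset
`UNIFORM_TYPES`, under which hens are statistically exchangeable, the
`s = 0` Mantel correlation is null-calibrated, and the mean pooled
AI–DTW Mantel r decreases strictly with s (measured ladder ≈ −0.05,
−0.21, −0.44, −0.72 at s = 0, 0.3, 0.6, 0.9). Likewise, at `s = 0` a
heterogeneous flock's detected communities genuinely reflect ranging
types, so the cluster-versus-community independence calibration is run
where independence actually holds: movement clusters against *planted*
affiliation groups drawn independently of type.

What the generator does **not** emulate: weather-driven day effects,
within-barn behaviour (nests, perches, tiers), rearing-phase dynamics,
diurnal rate variation within the open window, antenna clock drift, and
burst-correlated (non-i.i.d.) detection failures. Passing tests
demonstrate internal consistency of the estimators under a known
data-generating process, not that real flocks satisfy these
assumptions.

## Event curation

* **Pairing.** Two reads at the same gate on opposite sides within 5 s
  collapse to one transition, timestamped at the entry-side read (the
  moment of arrival in the new area). A single surviving read still
  identifies a passage; its direction is resolved from the hen's
  tracked current area, approaching via the nearer gate side when the
  hen was last located elsewhere.
* **Interpolation.** When consecutive located areas are non-adjacent,
  the m missing transitions are placed at the evenly spaced interior
  points (fractions 1/(m+1) … m/(m+1)) of the bracketing known times —
  the midpoint for a single gap — and flagged `interpolated`. This is
  the natural multi-gap extension of the half-way rule for single
  missing passages.
* **Sojourns** are emitted only when both the entry and the exit read
  of a stay were recorded with no undetected passage in between;
  incomplete stays are tallied, not guessed.
* **Daily series.** Step function of area codes sampled every `bin`
  seconds; a change takes effect at the first bin boundary at or after
  the transition. The library default `bin = 60 s` resolves transitions
  (median sojourns are many minutes) at ~540 points per nine-hour day.
* **Descriptors.** Per hen: time-budget fractions per area, days with
  any outdoor excursion, transition count, leading index (fraction of
  gate passages where the gap to the hen ahead exceeds the gap to the
  hen behind, computed within day × gate × direction; undefined without
  both neighbours), mean rank of the first morning WG→SY exit and of
  the last SY→WG return, and sample entropy. SampEn(m = 2,
  r = 0.2·SD of the hen's concatenated series) is computed per day and
  averaged; a constant series has SampEn 0, and +inf is returned when
  no (m+1)-template pair matches. Per-day computation keeps the O(n²)
  template count tractable and treats each day as one realization of
  the daily routine.
* **Gap-time coordination.** For each day × gate × direction with k ≥ 2
  transitions at times spanning [a, b], the null of uncoordinated
  movement pools gaps from `n_draws` uniform samples of k points on
  [a, b]; a two-sample KS test compares observed gaps against the pool.
  Bursty following yields an excess of short gaps.

## DTW stage

Classic dynamic programming with local cost |u−v|, steps
match/insert/delete without slope weights and no global window; the
value is the raw cumulative cost (dimensionless, no normalization; a
path-length-normalized variant exists behind a flag for unequal
windows). The numba kernel is checked exactly against an independent
pure-Python top-down recursion over all warping moves, and against
literal enumeration of every monotone warping path for short series.
Equal-length series are the normal case since the sampling window is
fixed.

The hypermatrix M₄ holds all hen-day pair distances; the summed matrix
keeps same-day pairs only, A<sub>ik</sub> = Σ<sub>d</sub>
dd<sub>i,d,k,d</sub>. Within/between contrasts take each hen's median
over its own day pairs versus its median over all cross-hen hen-day
pairs, compared by a one-sided Wilcoxon signed-rank test; an all-zero
difference vector is reported as degenerate rather than tested.

Clustering of A uses Diana (divisive analysis with Macnaughton-Smith
splintering: repeatedly split the largest-diameter cluster, seeding the
splinter with the object of maximal average dissimilarity), ties broken
towards the lowest hen index so results are deterministic; agglomerative
complete linkage is available as an alternative. With `k = None` the
cut is chosen by silhouette score over k ∈ 2…6, reflecting the four-to-
five ranging clusters typical of such flocks. The long-term trend of
daily mean cross-hen dissimilarity is summarized by an OLS line (slope,
F, p, adjusted R²) — deliberately simpler than a smoother, since the
question is only whether a systematic drift exists.

## Association networks

A transition is one registration at its entry-side antenna (gate +
direction). Two hens co-occur when registered at the same antenna on
the same day within a closed 5 s window; cross-side and cross-direction
matches do not count. Within each dyad, events pair one-to-one by
greedy time-ordered matching so that AB ≤ min(A, B) and AI = AB/(A+B−AB)
stays in [0, 1]; a single registration may still co-occur with several
different partners, and a burst at 0, 4, 8, 12 s yields exactly the
chain pairs (0,4), (4,8), (8,12). A and B count gate passages
(transitions), keeping numerator and denominator on the same footing.
Pooled AI is computed from summed counts, which is not the mean of
daily AIs.

Null models are label permutations: the strength CDF reallocates hen
labels across all registrations (preserving each hen's total count and
every event time/antenna); the temporal autocorrelation null permutes
hen labels of one matrix in each day pair. Autocorrelation at lag τ is
the mean Pearson correlation of vectorized upper triangles over all day
pairs (d, d+τ) with a t-interval over pairs. Communities come from
Girvan–Newman edge-betweenness removal (betweenness computed on
distances 1/AI), cut at maximal weighted modularity, with the initial
connected-components partition included as a candidate; by-community
assortativity is the weighted mixing-matrix coefficient
(tr e − Σe²)/(1 − Σe²). PageRank uses damping 0.85 on AI weights.
Down-sampling robustness subsamples hens without replacement and tracks
density, mean AI, modularity and the PageRank correlation of retained
hens against the full sample.

## Coupling statistics

Matrix correlation is Pearson over strict upper triangles. The Mantel
test jointly permutes rows and columns of the DTW matrix while the AI
matrix stays fixed (10 000 permutations by default); reported are the
empirical two-sided p = (count(|r_null| ≥ |r_obs|)+1)/(n_perm+1), the
2.5–97.5% null interval, and σ = (r_obs − mean_null)/sd_null. The daily
coupling trend regresses |daily matrix correlation| on day number.
Fisher's method combines per-pen p-values as X² = −2Σln p with 2k df —
the four published per-pen regression p-values (0.027, 0.071, 0.0003,
8.7 × 10⁻⁷) combine to X² = 56.65 at df 8, which the test suite pins.
The likelihood-ratio G-test of cluster × community tables delegates to
the standard log-likelihood contingency machinery after dropping empty
rows/columns.

The time-shift control samples dyad-days, adds 60 s to one member's
transition times, and recomputes both dyadic measures. A one-bin
displacement barely moves a day-long warping cost (DTW correlation
≈ 0.996–0.999 at bin = 60 s) but destroys 5 s co-occurrence windows, so
the AI correlation collapses — the signature that the AI–DTW coupling
is not an artefact of deriving both measures from the same
registrations. When a correlation is undefined because one side is
constant (e.g. all shifted AIs zero), it is reported as 0 by documented
convention; identical inputs return exactly 1.

## Numerical and engineering choices

* Analysis-scale experiments in the test suite and acceptance script
  use 20–30 hens, 5–20 days and `bin = 300 s` (108 samples/day), sizes
  at which every planted effect is comfortably detectable; the library
  default remains `bin = 60 s`.
* Permutation counts: 999 for calibration experiments, 10 000 for the
  flagship Mantel test, ≥100 for null envelopes.
* All randomness flows through `numpy.random.default_rng` seeds carried
  in configs; pipeline stage seeds are derived from one root seed and
  recorded in the report.
* Transitions in the final five minutes before pop-hole closing are
  retained by default (they are a negligible fraction of passages); a
  flag in the curation layer can exclude them.
* Degenerate inputs have defined behaviour throughout: empty graphs
  give uniform PageRank and singleton communities; all-equal distance
  matrices split into deterministic contiguous blocks; k < 2
  transitions skip the gap-time test with a notice.

## Known limitations

* The curation state machine can mis-direct a passage when both reads
  of one passage *and* a read of the next are lost in sequence; such
  cascades are quadratic-order rare at realistic dropout and are
  re-synchronized by the next paired passage.
* Girvan–Newman is quadratic-ish in edges per removal; it is intended
  for per-pen networks (~100 hens), not thousands of nodes.
* The G-test's asymptotic p-value is rough on sparse cluster × community
  tables (tens of hens); the calibration experiment bounds its
  rejection rate with a binomial interval rather than expecting exact
  nominal behaviour.
* Fisher's method assumes independent pens; pens sharing weather or
  management violate this silently.
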