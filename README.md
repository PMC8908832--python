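# flocknet

Movement patterns and social association networks of RFID-tracked laying
hens.

Commercial laying hens housed with outdoor access move through a linear
chain of four areas — barn interior (IN), covered wintergarden (WG),
stone yard (SY) and free-range pasture (FR) — passing gate antennas that
register every crossing. Two questions drive the analysis this package
implements for movement ecologists and poultry scientists working with
such gate-registration streams:

1. **Do individual hens have persistent daily movement styles?**
   Each hen-day becomes an ordinal area-occupancy series
   *ts*<sub>i,j</sub> (codes 1–4 sampled on a fixed grid); dynamic time
   warping (DTW, local cost |u−v|, symmetric step pattern) gives a
   dissimilarity *dd*(*ts*<sub>i,j</sub>, *ts*<sub>k,l</sub>) for every
   pair of hen-days, collected in the a×b×a×b hypermatrix M₄. Persistent
   styles show up as within-hen medians below between-hen medians
   (one-sided Wilcoxon signed-rank across hens), and the summed same-day
   matrix A<sub>ik</sub> = Σ<sub>d</sub> dd<sub>i,d,k,d</sub> supports
   divisive (Diana) clustering into ranging types.

2. **Is social association coupled to movement similarity?** Two hens
   registered at the same antenna within 5 s co-occur; counts combine
   into the association index AI(AB) = AB / (A + B − AB) ∈ [0, 1] per
   day and pooled. Coupling is the Mantel matrix-permutation correlation
   between the pooled AI matrix and A (10 000 joint row/column
   permutations by default), backed by: dyadic-strength null CDFs,
   Newman–Girvan communities with weighted modularity and by-community
   assortativity, weighted PageRank, temporal autocorrelation of daily
   networks against a permutation band, gap-time coordination tests
   against a uniform U(a, b) null, Fisher's combined probability across
   pens, a G-test of movement-cluster × social-community agreement, and
   a +60 s time-shift control that separates genuine coupling from
   shared-registration artefacts.

Because raw tracking data of this kind are rarely public, the package
ships an agent-based simulator (`flocknet.synthetic`) producing
RFID-like event logs with known ground truth: per-hen ranging types
(continuous-time Markov movement on the chain), a planted affiliation
graph, social following with probability *s*, and registration dropout.
Every downstream stage is validated against this ground truth.

## Worked example

Simulate one pen of 28 hens over 15 days in which four affiliation
cliques coincide with four ranging types and social following is strong
(*s* = 0.9), then run the full pipeline:

```sh
flocknet run-all --config demo.yaml --out demo_run
```

with `demo.yaml`:

```yaml
sim:
  n_hens: 28
  n_days: 15
  s: 0.9
  seed: 7
  n_groups: 4
  p_in: 1.0
  p_out: 0.0
  types_align_groups: true
bin: 300
n_perm_mantel: 999
k_clusters: 4
```

The command prints

```
pen1: mantel r = -0.621 (null 95% -0.117..0.063, p = 0.001, sigma = -13.23)
```

and `demo_run/report.json` contains, among others:

* `curate`: 74 108 transitions curated from the raw registrations, 1 572
  of them interpolated across missed detections;
* `dtw.within_between`: V = 0, p = 1.8 × 10⁻⁶ — every hen's daily series
  resemble each other more than they resemble other hens' days;
* `network`: 4 Newman–Girvan communities, modularity 0.72, assortativity
  0.95 — the four planted cliques, recovered from gate co-occurrence
  alone;
* `couple.mantel`: r = −0.62 far outside the permutation null (σ =
  −13.2) — closely associated hens move more similarly;
* `couple.g_test`: G = 77.6, p = 4.8 × 10⁻¹³ — movement clusters and
  social communities coincide;
* `couple.timeshift`: shifting one dyad member by 60 s leaves dyadic DTW
  almost untouched (r = 0.996) while the association correlation
  collapses (r = 0.21) — the coupling is not a registration artefact.

The negative Mantel sign is the expected direction: high association
(large AI) pairs with low DTW dissimilarity.

Library use mirrors the CLI: `simulate_flock(SimConfig(...))`,
`pair_registrations`, `build_series_array`, `daily_distance_matrices`,
`association_matrix(detect_cooccurrences(...))`, `mantel_test`, … — see
`docs/methods.md` for the statistical conventions behind each step.

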