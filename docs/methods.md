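# Methods

## Weighted networks

Expression is assumed gene-level and pre-normalized; duplicate gene rows
are an error rather than silently aggregated (probe-to-gene reduction is
upstream of this package and hiding it behind a mean would mask
mistakes). Each interaction whose two genes are both measured receives
the cohort's Pearson correlation ρ and distance d = 1 − |ρ|; interactions
with an unmeasured gene are dropped and counted. A zero-variance gene
makes ρ undefined; such links are **kept** with d = 1 and category
"none", which leaves the graph intact while making the link maximally
unattractive to the shortest-path search. Whether the original analysis
kept or removed such links is not documented anywhere we know of; this
convention is the package's own choice.

Correlation categories on |ρ|: [0, 0.3) none, [0.3, 0.5] low, (0.5, 1]
high. Both boundaries close into "low" so that ties are deterministic
("high" is read strictly as *above* 0.5).

## Pathways and the signaling network

One minimum-distance path per ordered (receptor, TF) pair, Dijkstra on
the link distances. Ties among equal-distance optima are resolved by
fewer hops, then the lexicographically smallest node sequence; the choice
is arbitrary but must be fixed, because frequencies and motif counts
depend on which optimum is kept. The implementation runs Dijkstra with
the composite key (distance, hops, node sequence), under which every
prefix of an optimal path is optimal, so the first settled label per node
is the unique tie-ruled optimum.

The signaling network is the union of pathway links restricted to its
largest connected component (size ties break toward the component
holding the smallest node label). Link and node frequencies are counted
**after** that restriction, endpoints included; pathways in discarded
components are dropped. Consequently Σ_links f = Σ_pathways hops.

## Feature panel

* *Path length* is the hop count of the distance-optimal pathway, and
  the *diameter* is the mean hop distance over reachable node pairs —
  hop metrics, not summed distances. The source analysis does not state
  which it used; the magnitudes of its reported values (≈ 4–9) are only
  consistent with hops, and the hub-removal robustness literature the
  diameter follows uses hops.
* Unreachable node pairs are excluded from the diameter mean (after hub
  removal the network may fragment; penalizing unreachable pairs would
  need an arbitrary constant).
* *Hub removal* deletes max(1, ⌊0.10 · n⌋) nodes of highest node
  frequency (ties: frequency, then name) and reports
  diameter_after/diameter_before on the surviving largest component.
* *Clustering* is C = 2L/(k(k−1)) (0 for k < 2), i.e. 1 for a fully
  connected neighborhood — the printed formula in the source omits the
  factor 2 that its own prose ("fully connected ⇒ 1") requires.
* *Power-law exponent*: continuous MLE α = 1 + n [Σ ln(f_i/f_min)]⁻¹
  (the cumulative-distribution estimator), f_min = smallest observed
  frequency unless overridden; a `discrete=True` flag applies the
  half-step offset f_min − 0.5 for integer data. A least-squares log-log
  fit is provided for plotting only. At least 10 values, not all equal.
* *Entropy* I = −Σ p_i log₂ p_i with p_i = f_i/Σf over links.

## Motifs

Triangles are enumerated around each selected hub and kept only when all
three links exist in both cohorts' signaling networks (comparability of
the two columns). A triangle with hubs at two corners yields one record
per hub role. Hub selection intersects a cancer-mutated gene list with
the nodes present in both cohorts, ranks by node frequency per cohort
(ties lexicographic), takes the top k = 50 per cohort and unites them;
passing no mutation list disables the intersection filter.

The maintenance count is attributed to the cohort in which the hub is
DE-correlated (hub links high in the *other* cohort, none here, with the
neighbour–neighbour category unchanged), so detached tumor hubs raise
the tumor column.

The comparative motif is restricted to receptor pairs converging on the
same TF; "share" means a common undirected link, a shared node does not
count. The counter scans receptor pairs per TF with an early disjointness
exit, which is exact and fast at the package's problem sizes; a
brute-force enumerator backs it in the tests.

## Paired statistics

Wilcoxon signed-rank on per-dataset (normal, tumor) pairs: differences
tumor − normal, zeros dropped, midranks on |d|, W⁺ = Σ ranks of positive
d. `exact` computes the two-sided tail of W⁺ by a dynamic-programming
convolution over integer ranks — identical to enumerating all 2ⁿ sign
assignments, proved against that enumeration in the tests — with rank
ties broken by input order (well defined whenever tied |d| do not mix
signs). `approx` is the Gaussian tail with continuity correction 0.5 and
variance n(n+1)(2n+1)/24 − Σ(t³−t)/48. `auto` picks exact without ties,
approx with. Two-sided p = min(1, 2·min(tails)). No multiple-testing
correction (raw p against the conventional 0.05).

For the shipped published table the per-feature route is fixed
(`published_table_comparison`): the two motif-count columns carry
genuine ties and use the approximation; all other features are
continuous at source, so ties in their printed, rounded values are
rounding artifacts and the exact tail applies. Three published p-values
are not recoverable from the rounded columns at all (the α column's
factor-two discrepancy comes from one pair rounding to equality; the
path-length p matches one of the three mutually inconsistent published
variants; the diameter-ratio and per-node-clustering columns round too
coarsely) — the recomputed values are reported as computed, not adjusted.

Fisher enrichment is the one-sided (greater) hypergeometric tail on the
2×2 membership table, with the sample odds ratio.

## Synthetic cohorts

The generator emulates the study conditions, not microarray physics: a
preferential-attachment (Barabási–Albert) interaction network, uniformly
sampled disjoint receptor/TF sets, and Gaussian expression propagated
along a deterministic BFS spanning tree (root = smallest label): child =
ρ·parent + √(1−ρ²)·noise, so tree-edge population correlations equal
their targets exactly; non-tree-edge correlations are emergent and only
measured. Targets are imposed on the tree because an arbitrary edge-wise
correlation assignment on a cyclic graph need not be positive definite.
The default target law is uniform |ρ| ∈ [0.35, 0.95] (mean 0.65,
matching realistic normal-tissue co-regulation of interacting proteins);
the tumor regime multiplies every target by λ (default 0.3), which keeps
targets in [0, 1] by construction, rather than adding noise.

Defaults — 300 nodes, attachment 2, 20 receptors, 15 TFs, 200 samples
per cohort, λ = 0.3 — are the package's reference recovery condition: at
these settings the analyzed pair reproduces the qualitative tumor/normal
contrast (higher mean link distance, higher entropy, lower maximal link
frequency, shorter pathways in the attenuated cohort). What passing this
shows is that the *pipeline* transduces a correlation-attenuation
contrast into the expected feature signature; it does not validate the
biological claim on real data, and the generator has no batch effects,
no heteroscedastic noise, no negative correlations and no realistic
dynamic range.

The simulated matrices at the reference condition are a few hundred
kilobytes and are regenerated from the seed rather than stored
(`analysis/01_simulate_cohorts.py` writes them under
`scratch/synthetic_inputs/`). The synthetic cancer-gene list written by
the `simulate` command is a random 10 % node subset — a labelled
synthetic stand-in for a curated mutation list so the motif stage runs
end to end.

## Numerical choices

* Correlations are clamped to [−1, 1] against floating-point overshoot;
  |ρ| beyond 1 by more than 1e-9 is an error.
* Path-distance comparisons use raw floats; both the implementation and
  the test oracles accumulate sums left-to-right along the path, so
  tie decisions are reproducible.
* All randomness flows through `numpy.random.default_rng` seeds;
  compound runs derive child seeds with `SeedSequence` (kept < 2³¹).

## Limitations

Undirected signaling only (no direction, no sign on the path level); one
pathway per pair (no k-shortest alternatives); the power-law fit has no
goodness-of-fit test; the comparative-motif same-TF restriction and the
maintenance-column attribution are interpretive choices documented
above; absolute per-dataset values for real cohorts depend on the
interaction database and arrays used and are not reproduced here — only
the cross-dataset statistics over the published per-dataset table are.
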