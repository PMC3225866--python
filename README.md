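# corsignet

Correlation-weighted signaling-network analysis of paired tumor/normal
expression cohorts.

Cancer cells rewire signal transduction. One way to see this on a global
scale is to weight a protein–protein interaction network with the
co-regulation of each interacting gene pair in a cohort of expression
profiles, trace the most co-regulated routes from receptors to
transcription factors, and compare how tumors and matched normal tissues
organize that traffic. `corsignet` implements this analysis end to end
for anyone studying condition-specific network regulation: systems
biologists with paired cohort expression data, or method developers who
want a fully synthetic, seeded test bed.

## The model

For each cohort, every interaction (x, y) gets a link distance

d_xy = 1 − |ρ_xy|,

where ρ_xy is the Pearson correlation of the two genes' expression over
the cohort's samples (absolute value, so induction and inhibition count
alike). For every (receptor, transcription factor) pair the single
minimum-distance path is computed with Dijkstra's algorithm —
deterministic ties: fewer hops, then lexicographically smallest node
sequence — and the union of these pathways, restricted to its largest
connected component, is the cohort's **signaling network**. On it the
package computes:

* **link/node frequency** — the number of receptor→TF pathways through a
  link or node (a role-restricted betweenness), and the exponent α of
  the power law P(f) ∼ f^−α fitted to the link-frequency distribution
  with the continuous MLE α = 1 + n [Σ ln(f_i/f_min)]⁻¹;
* **information entropy** I = −Σ p_i log₂ p_i with p_i proportional to
  link traffic;
* **clustering coefficient** C = 2L/(k(k−1)), mean pathway hop length,
  mean-shortest-path diameter, and the diameter increase after deleting
  the top 10 % of hubs;
* three **regulation motifs** contrasting the two cohorts: hub-centred
  triangles that are fully highly correlated (*integration*), triangles
  whose hub links decorrelate in one cohort while the neighbour link
  keeps its category (*maintenance*), and receptor pairs converging on a
  TF whose pathways share a link in exactly one cohort (*comparative*);
* paired cross-dataset **Wilcoxon signed-rank** statistics (exact
  2ⁿ-enumeration tail or tie-corrected Gaussian approximation) and
  Fisher-exact gene-set enrichment.

Correlation categories use |ρ| < 0.3 → none, 0.3 ≤ |ρ| ≤ 0.5 → low,
|ρ| > 0.5 → high.

A synthetic-data module generates scale-free interaction networks,
role assignments and Gaussian expression cohorts whose edge-wise
correlations follow configurable targets, with a "tumor" regime obtained
by attenuating all targets by a factor λ — so the entire pipeline runs,
seeded and offline, without any external data.

## Worked example

The numbered scripts under `analysis/` run the whole study on synthetic
data. `analysis/01_simulate_cohorts.py` simulates a 300-gene scale-free
network with 20 receptors, 15 TFs and 200 samples per cohort (tumor
correlations attenuated to λ = 0.3) and prints

```
simulated 596 links, 300 genes, 200 samples/cohort (seed 2026)
mean |rho| over links  normal: 0.421   tumor: 0.125
```

`analysis/02_run_pipeline.py` then runs the full pipeline on that pair:

```
signaling networks   normal: 75 nodes / 113 links   tumor: 91 nodes / 163 links
feature                    normal     tumor
mean link distance           0.579     0.875
mean pathway hops            3.773     3.393
entropy (bits)               6.114     6.821
mean link frequency         10.018     6.245
power-law exponent           1.617     1.704
% nodes used                25.000    30.333
comparative motif (normal, tumor): (845, 108)
```

Read: the attenuated ("tumor") cohort spreads its signaling over more of
the network (91 vs 75 nodes, higher entropy), reuses individual links
less (frequency 6.2 vs 10.0, steeper power law), reaches TFs in fewer
hops, and loses the shared-link structure of the normal cohort (the two
normal pathways of a receptor pair share a link 845 times where the
tumor pair shares none, against 108 in the opposite direction).

`analysis/03_published_table_stats.py` applies the same cross-dataset
comparison stage to the published per-dataset feature table for twenty
real tumor/normal cohort pairs that ships with the package
(`corsignet.load_published_cohort_features()`), e.g.:

```
            feature  normal_mean  tumor_mean tendency  p_two_sided        method
            n_links     1.68e+04    1.92e+04       Up     3.81e-06         exact
     link_frequency          226         121     Down     3.81e-06         exact
        path_length         5.45        4.55     Down     9.54e-06         exact
  integration_motif          432         104     Down     0.000553 normal_approx
  maintenance_motif         7.55        38.5       Up     0.000634 normal_approx
            entropy         11.4          12       Up      8.2e-05         exact
```

There is also a `corsignet` CLI (`simulate`, `build`, `features`,
`motifs`, `compare`, `run`) for driving the same stages from a shell; see
`corsignet --help`.

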