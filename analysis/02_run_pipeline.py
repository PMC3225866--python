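#!/usr/bin/env python
"""Run the full signaling-network analysis on the simulated cohort pair.

Consumes the files written by 01_simulate_cohorts.py, runs
stratification -> weighted networks -> pathway extraction -> pruning ->
feature panel -> motif counts, and writes features.tsv / motifs.tsv /
comparison.tsv / report.json under results/synthetic_run/.
"""

from pathlib import Path

from corsignet import io, pipeline

ROOT = Path(__file__).resolve().parents[1]
INPUTS = ROOT / "scratch" / "synthetic_inputs"
OUT = ROOT / "results" / "synthetic_run"

config = io.AnalysisConfig(
    interactions=INPUTS / "interactions.tsv",
    receptors=INPUTS / "receptors.txt",
    transcription_factors=INPUTS / "tfs.txt",
    cancer_genes=INPUTS / "cancer_genes.txt",
    datasets={
        "synthetic": {
            "normal": INPUTS / "expression_normal.tsv",
            "tumor": INPUTS / "expression_tumor.tsv",
        }
    },
    seed=2026,
    output_dir=OUT,
)

outcome = pipeline.run_full_analysis(config)
res = outcome["results"][0]
fn, ft = res.features_normal, res.features_tumor

print(f"signaling networks   normal: {fn.n_nodes} nodes / {fn.n_links} links   "
      f"tumor: {ft.n_nodes} nodes / {ft.n_links} links")
print("feature                    normal     tumor")
for label, attr in [
    ("mean link distance", "avg_link_distance"),
    ("mean pathway hops", "avg_path_length"),
    ("entropy (bits)", "entropy_bits"),
    ("mean link frequency", "avg_link_freq"),
    ("power-law exponent", "alpha"),
    ("% nodes used", "pct_used_nodes"),
]:
    print(f"{label:25s} {getattr(fn, attr):8.3f}  {getattr(ft, attr):8.3f}")
mc = res.motif_counts
print(f"comparative motif (normal, tumor): {mc.comparative}")
print(f"integration motif (normal, tumor): {mc.integration}")
print(f"maintenance motif (normal, tumor): {mc.maintenance}")
print("-> the attenuated cohort uses more of the network, shorter pathways,")
print("   more dispersed traffic (higher entropy), and loses the shared-link")
print("   (comparative-motif) structure of the normal cohort.")
print(f"tables written to {OUT}/")
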