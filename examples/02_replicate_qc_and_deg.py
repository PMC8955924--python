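"""Validate replicates, merge them, and call DEGs with the signed ratio.

The Pearson correlation of ln(RPKM) between biological replicates should be
near 1 for a clean experiment; replicates are then averaged and the
treatment/control ratio computed per transcript, with downregulation mapped
to -1/ratio so a 2-fold drop reads -2. |ratio| > 1.5 calls a DEG.
"""

from berrydeg import call_degs, compute_rpkm, merge_replicates, replicate_correlation, top_k
from berrydeg.deg_ratio import ratio_histogram
from berrydeg.simulate import SimulationConfig, simulate_counts

cfg = SimulationConfig(seed=42)
counts, annotation, design, truth = simulate_counts(cfg)
rpkm = compute_rpkm(counts, annotation, design)

qc = replicate_correlation(rpkm, design)
for _, row in qc.iterrows():
    print(f"{row['condition_id']}: r = {row['r']:.4f} over {row['n_pairs']} transcripts")
# r close to 1 means replicate differences are noise, not biology.

merged = merge_replicates(rpkm, design)
ratios = call_degs(merged, stage="V", cutoff=1.5)
n_sig = int(ratios["significant"].sum())
print(f"\nveraison RDI-vs-SDI: {n_sig} significant DEGs at |ratio| > 1.5")

planted = set(truth.index[(truth['label'].isin(['up', 'down'])) & (truth['stage'] == 'V')])
called = set(ratios.loc[ratios["significant"], "transcript_id"])
print(f"planted DEGs recovered: {len(called & planted)}/{len(planted)}")

hist = ratio_histogram(ratios)
central = hist.bins.set_index("label").loc["[-1.5, 1.5]", "count"]
print(f"unregulated transcripts in the central interval: {central}")

up, down = top_k(ratios, k=3)
print("\nmost upregulated:")
for _, r in up.iterrows():
    print(f"  {r['transcript_id']}: {r['ratio_signed']:+.2f}")
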