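"""Alpha/beta diversity and a study-adjusted PERMANOVA.

Computes Chao1/Shannon/Simpson per sample, Bray-Curtis and weighted UniFrac
distance matrices on the rarefied table, a PCoA, and a sequential PERMANOVA
with the study entered first so every host factor is study-adjusted.
"""

import coremicro as cm

spec = cm.SyntheticSpec(
    n_studies=8, samples_per_study=(15, 15), n_otus=150, n_core=20,
    n_subcore=3, seed=7,
)
table, meta, taxonomy, tree, truth = cm.generate_dataset(spec)

rarefied = cm.rarefy(table, depth=5000, seed=0)
alpha = cm.alpha_diversity(
    cm.CountTable(rarefied.otu_ids, rarefied.sample_ids, rarefied.values)
)
print("alpha diversity (mean over samples):")
print(alpha.mean().round(3).to_string())

bc = cm.bray_curtis(cm.tss(rarefied))
wuf = cm.weighted_unifrac(rarefied, tree)
print(f"\nmean Bray-Curtis {bc.condensed_form().mean():.3f}, "
      f"mean weighted UniFrac {wuf.condensed_form().mean():.3f}")

ord_res = cm.pcoa(bc, k=2)
print(f"PCoA axes 1+2 explain {100 * ord_res.proportion_explained[:2].sum():.1f}% "
      "of (positive-eigenvalue) variance")

kept = meta.set_index("sample_id").loc[list(bc.ids)].reset_index()
res = cm.permanova(bc, kept, ["study", "gender", "smoking"], n_perm=999, seed=1)
print("\nsequential PERMANOVA (study entered first = study-adjusted):")
print(res.round(4).to_string(index=False))
print("-> the study (batch) term dominates; host factors explain little,")
print("   mirroring the structure of pooled multi-study 16S collections.")
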