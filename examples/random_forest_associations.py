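"""Random-forest category association and rank-sum differential abundance.

Screens which metadata categories a random forest can classify (low
out-of-bag error = strong community association), selects the OTUs that
drive the strongest category via cross-validation, and runs the Wilcoxon
rank-sum differential-abundance screen with BH correction.
"""

import coremicro as cm

spec = cm.SyntheticSpec(
    n_studies=8, samples_per_study=(20, 20), n_otus=150, n_core=20,
    n_subcore=3,
    category_effects={"location": (40, 2.0), "smoking": (20, 1.2),
                      "gender": (6, 0.25)},
    seed=5,
)
table, meta, taxonomy, tree, truth = cm.generate_dataset(spec)

grid = cm.rf_grid(
    table, meta, taxonomy,
    categories=["location", "smoking", "gender"],
    levels=["otu", "genus"], normalisations=["TSS"], seed=0,
)
print("out-of-bag error per category x taxonomic level (lower = stronger):")
print(grid[["category", "taxonomic_level", "oob_error"]].round(3).to_string(index=False))

sel = cm.important_features(table, meta, "smoking", k_folds=5, repeats=2,
                            seed=1, n_estimators=200)
planted = set(truth.category_effects["smoking"]["otu_id"])
print(f"\nimportant OTUs for smoking: {len(sel['selected'])} selected, "
      f"{len(planted & set(sel['selected']))} of them truly planted")

diff = cm.differential_rank_sum(table, meta, "smoking", ("smoker", "non_smoker"))
hits = diff[diff["q_value"] < 0.05]
print(f"rank-sum screen: {len(hits)} taxa at q < 0.05 "
      f"(of which {len(planted & set(hits.index))} planted)")
print("-> the planted location effect gives near-zero OOB error while the")
print("   weak gender effect stays near chance; both screens find the")
print("   smoking-shifted taxa.")
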