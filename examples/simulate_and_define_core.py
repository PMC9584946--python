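"""Define a core microbiome three ways on a synthetic multi-study dataset.

Generates a pooled multi-study OTU table with a planted 24-taxon core,
applies the count-level inclusion filters, computes abundance-occupancy
statistics on the rarefied table, and defines the core by fixed thresholds,
by occupancy-ranked beta-diversity contribution (Bray-Curtis and weighted
UniFrac), and by their consensus.
"""

import coremicro as cm

spec = cm.SyntheticSpec(
    n_studies=10, samples_per_study=(20, 20), n_otus=200, n_core=24,
    n_subcore=4, subcore_mra_target=0.16, seed=42,
)
table, meta, taxonomy, tree, truth = cm.generate_dataset(spec)

table = cm.filter_samples_min_reads(table, floor=2000)
table = cm.filter_features(table, min_total=11, min_samples=2)
print(f"after filtering: {table.n_otus} OTUs x {table.n_samples} samples")

ao = cm.abundance_occupancy(table, meta, rarefy_depth=5000, seed=1)
threshold_core = cm.core_by_threshold(ao)  # MRA > 0.1%, occupancy > 75%

ranked = cm.rank_by_occupancy(ao)
rarefied = cm.rarefy(table, depth=5000, seed=1)
bc_core = cm.core_by_ranked_contribution(
    cm.contribution_curve(rarefied, ranked, "bray_curtis"), ranked
)
wuf_core = cm.core_by_ranked_contribution(
    cm.contribution_curve(rarefied, ranked, "weighted_unifrac", tree=tree), ranked
)
consensus = cm.consensus_core([threshold_core, bc_core, wuf_core])

print(f"threshold core:          {len(threshold_core)} OTUs")
print(f"ranked core (BC):        {len(bc_core)} OTUs")
print(f"ranked core (wUF):       {len(wuf_core)} OTUs")
print(f"consensus:               {len(consensus)} OTUs")

planted = set(truth.core_ids)
recovered = len(set(consensus.members) & planted)
print(f"planted core recovered:  {recovered}/{len(planted)}")
print("-> the three definitions agree on the planted high-occupancy taxa;")
print("   the ranked lists extend a little further into abundant-but-patchy taxa.")
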