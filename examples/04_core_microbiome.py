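"""Two-step core-microbiome identification and planted-pair recovery.

Step 1 scores each OTU's functional keystoneness (weighted betweenness
with emission-linked weights); step 2 ranks every linked pair by the core
reinforcement index B'_i * B'_j * C_ij (checkerboard variant) or
B'_i * B'_j * T_ij (togetherness variant). The top 15 between-group and
top 10 within-group pairs form the core microbiome.
"""

from corepair import generate_study
from corepair.pipeline import run_study

study = generate_study(seed=1)
result = run_study(study["table"], study["metadata"], study["fluxes"],
                   metric="potential", n_trees=200, seed=1)

top = result.core.top_pairs[("checker", "between")]
print("top between-group pairs (checker variant):")
print(top[["otu_i", "otu_j", "group_pair", "C", "T",
           "R_checker"]].head(10).to_string(index=False))

planted = {tuple(sorted(p[:2])) for p in study["structure"].core_pairs}
found = {tuple(sorted((r.otu_i, r.otu_j))) for r in top.itertuples()}
print(f"\nplanted pairs recovered in the top 15: "
      f"{len(planted & found)} / {len(planted)}")
print(f"core microbiome members: {len(result.core.members)} OTUs")

print("\ngroup-pair summary (sum of all pairwise effects / mean over "
      "core pairs):")
cols = ["group_pair", "interaction_type", "sum_checker",
        "core_mean_checker"]
print(result.core.summary[cols].to_string(index=False))
# High recovery means the reinforcement ranking finds the planted
# function-linked hub pairs among ~300 network edges.
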