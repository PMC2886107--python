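"""SOTA clustering of P-value profiles and the pathway-latitude regression.

Clusters significant proteins' 8-dimensional one-sided P-value profiles into
hard clusters with the self-organizing tree algorithm, then aggregates
population effects over a pathway and regresses the aggregate on absolute
breeder latitude with a quadratic model.
"""

import numpy as np

import beepop as bp

design = bp.generate_design(bp.enumerate_samples(bp.STUDY_ROSTER), seed=0)
truth = bp.make_ground_truth(design, n_proteins=120, seed=1,
                             frac_differential=0.25, effect_sd=0.5)
matrix = bp.simulate_ratio_matrix(design, truth, seed=2)
norm = bp.label_standardize(bp.block_center(matrix))
fits, _ = bp.fit_matrix(bp.filter_by_observation(norm), design)

res = bp.results_frame(fits)
profiles = res.loc[res.significant, [c for c in res.columns if c.startswith("p1_")]]
print(f"{len(profiles)} significant proteins, profiles = 8 one-sided P-values")

tree = bp.sota_cluster(profiles, max_cycles=7, max_diversity=0.8)
div = tree.diversities(profiles.to_numpy(float))
print(f"SOTA: {len(tree.leaves())} clusters after {tree.n_cycles} cycles; "
      "diversity = mean distance of members to the cluster centroid")
for k, (leaf, d) in enumerate(zip(tree.leaves(), div), start=1):
    print(f"  cluster {k}: {len(leaf.members)} proteins, diversity {d:.3f}")

pops = [c[len("p1_"):] for c in profiles.columns]
dend = bp.hierarchical_cluster(profiles, axis="columns")
print("\npopulation dendrogram (Euclidean, average linkage):")
print(" ", dend.to_newick())

# pathway aggregate vs absolute latitude of breeder origin
eff = res[[c for c in res.columns if c.startswith("effect_")]]
eff.columns = [c[len("effect_"):] for c in eff.columns]
pathway = {"planted_set": [f"P{i + 1:04d}"
                           for i in np.flatnonzero(np.abs(truth.population_effect).sum(axis=1) > 0)]}
prof = bp.pathway_profile(eff, pathway, stat="median")
lats = {p.name: p.latitude_deg for p in bp.STUDY_ROSTER}
fit = bp.latitude_regression(prof.iloc[0].to_numpy(),
                             [lats[p] for p in prof.columns])
print("\nquadratic fit of median pathway effect on |latitude| A:")
print(f"  Y = {fit.beta0:.4f} + {fit.beta1:.4f} A + {fit.beta2:.6f} A^2, "
      f"R^2 = {fit.r_squared:.3f}, r = {fit.pearson_r:.3f}")
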