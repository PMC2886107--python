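"""From a peptide-spectrum-match table to a protein x block ratio matrix.

Simulates PSMs with decoys and shared peptides, applies the ion-score filter,
estimates the decoy FDR, collapses proteins by parsimony and averages log2
channel intensities per protein and block.
"""

import beepop as bp

design = bp.generate_design(
    bp.enumerate_samples(bp.STUDY_ROSTER[:3]), seed=1
)
pmap = {
    "AVLPEPTIDEK": ["ACC1"],
    "SHAREDPEPK": ["ACC1", "ACC2"],
    "GWDISTINCTK": ["ACC2"],
    "LMNOPQRSTK": ["ACC3"],
}
psms = bp.simulate_psm_table(
    1995, 5, seed=2, peptide_map=pmap, block_ids=design.block_ids
)

print(f"PSMs: {len(psms)} simulated; decoy FDR before filtering: "
      f"{100 * bp.estimate_fdr(psms):.2f}% (reversed hits / all hits)")
kept = bp.filter_psms(psms, min_score=25)
print(f"{len(kept)} pass the ion-score >= 25 filter; decoy FDR at the "
      f"cut-off: {100 * bp.estimate_fdr(kept):.2f}%")

groups = bp.infer_protein_groups(kept)
print(f"protein groups after parsimony: {len(groups)}")
for g in groups:
    members = ", ".join(sorted(g.member_accessions)) or "-"
    print(f"  leader {g.leader_accession}: {len(g.supporting_peptides)} peptides,"
          f" members: {members}")

matrix = bp.aggregate_ratios(groups, kept, design)
print(f"\nratio matrix: {matrix.shape[0]} proteins x "
      f"{matrix.shape[1]} (block, channel) columns; "
      f"values are mean log2 intensities per protein and block")
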