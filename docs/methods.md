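# Methods

## Study structure

A *population* is the set of colonies descended from queens of one breeder
location; the packaged study roster has eight populations with colony counts
(4, 4, 4, 8, 8, 10, 11, 9) — 58 colonies, each sampled in triplicate, 174
sample units. A *block* is one triplex LC-MS/MS run combining three
differentially labelled samples (light/medium/heavy formaldehyde
isotopologues), so 174 units fill exactly 58 blocks. Roster latitudes are
the breeder towns' geographic latitudes; they feed only the
pathway-versus-latitude regression.

## Block design

The design must place every sample once, with three distinct labels per
block, three distinct populations per block (configurable to
distinct-colonies-only), and each colony's three replicates on three
different labels. Construction: a largest-remaining-first greedy partition
of colony slots into blocks (feasible whenever no population holds more
samples than there are blocks), followed by a proper 3-edge-coloring of the
colony×block incidence graph by alternating-chain recoloring, which always
succeeds on a bipartite graph of maximum degree three and yields the label
balance exactly.

Designs are scored by a Ds-type criterion: the log-determinant of the
information matrix of the sum-to-zero population contrasts after
residualizing against intercept, block and label columns. This is the
determinant analogue of the design goal — minimizing the standard errors of
the population effects. The optimizer is a seeded multi-restart exchange
search (random feasible start, greedy acceptance of criterion-improving
colony swaps between blocks, 6·n_blocks proposals per sweep). Ties are
never re-broken: the first best design encountered is kept, so the search is
deterministic for a fixed seed and the returned criterion is monotone
non-decreasing in the number of restarts. On rosters small enough to
enumerate (3 populations × 1 colony) the search attains the brute-force
optimum; on the full roster optimality is not claimed, only feasibility
plus improvement over the random starts.

## PSM assembly

PSMs are filtered at ion score ≥ 25 (boundary inclusive). The decoy FDR is
rev/(for+rev) over the filtered records. Protein inference is a greedy
minimal set cover: proteins ranked by distinct-peptide count (ties by
accession for determinism); a protein whose peptides are contained in an
accepted group joins it as a member; one explaining a new peptide founds a
group; one covered only jointly attaches to the group sharing most
peptides. Quantities are log2 channel intensities averaged per group and
block (log-then-average; zero intensities are treated as unquantified).
Peptides shared between non-nested groups count toward every group by
default (`shared="unique"` restricts to group-unique peptides) — with no
stated convention for shared-peptide ratio averaging, the inclusive default
maximizes per-block coverage and the option preserves the strict reading.

## Normalization

Two stages, both on the log2 scale:

1. **Block centering** — per protein and block, subtract the mean of the
   observed channels. Removes the arbitrary mixing ratio of each triplex;
   fully observed triples sum to zero afterwards.
2. **Label standardization** — per label channel, subtract the median and
   divide by the median absolute deviation, computed across all proteins
   pooled over blocks. The MAD is raw (no 1.4826 consistency constant);
   `consistency=` rescales if a normal-sd-comparable unit is wanted. A
   label with zero MAD raises an error naming the channel. Per-(block,
   label) standardization is available (`per_block=True`); pooling is the
   default because block effects are already removed by centering and
   re-adjusted in the mixed model.

Both stages are idempotent, and the pipeline output is invariant to adding
a constant to all channels of a block and to per-label affine changes.

## Per-protein mixed model

Fixed effects: population (sum-to-zero coding over the populations actually
observed for that protein), block and label dummies. Random intercept per
colony. Estimation by REML (statsmodels `MixedLM` on prebuilt design
matrices). The eighth effect and its SE are recovered from the coded seven
via the sum-to-zero constraint. Proteins observed in fewer than two blocks,
or with fewer than two populations, are reported as failures and excluded
from downstream sets.

**Factor test.** The overall population effect is tested with a Wald F-test
of the population contrasts, `W/(k-1)` against `F(k-1, n_obs - p_fixed)`.
A likelihood-ratio χ² with k−1 df was evaluated first and rejected: with
~67 fixed parameters for ~174 observations it rejected 28% of null
proteins in simulation. The residual-df F statistic measures 5.3% at
nominal 5% with uniform null P-values (Kolmogorov–Smirnov p = 0.62 at 500
proteins × 8 effects); a Bartlett-scaled LRT over-corrected to 1.3%.

**Degenerate and ill-conditioned fits.** When the data are exactly
noise-free (OLS residual sum of squares below 1e-12) the OLS solution is
exact and is used directly; when the mixed fit fails to converge or leaves
a non-positive-definite covariance (variance estimate on the boundary), the
fit falls back to OLS with an F-test, flagged via `LMEFit.method = "ols"`.

**P-value profile.** `p1 = Φ(effect/se)` per population (normal
approximation rather than t: the residual df of an unbalanced mixed fit is
not well defined, and at ≥100 residual df the difference is negligible);
`p2 = 1 − 2|p1 − 0.5|` exactly. Zero SE maps p1 to the step function at the
effect's sign.

**Observation filter.** A protein is kept when observed (any channel) in at
least `floor(0.25 · n_blocks)` blocks — the floor makes 14 of 58 blocks
sufficient. **Significance** is strict: factor P < α (default 0.05), with
direction from the sign of each population effect; exactly-zero effects
join neither direction.

## Overlap and enrichment

Representation factor `RF = o·N/(n_x·n_y)` over the quantified background
N; RF > 1 iff the overlap exceeds its expectation. Significance is the
exact upper tail `P(X ≥ o)`, `X ~ Hypergeom(N, n_x, n_y)` (scipy), verified
against explicit PMF summation to 1e-12 for every instance with N ≤ 60.
Population-pair overlap counts same-direction proteins by default (up in
both or down in both), since shared *expression patterns* are directional;
`direction="blind"` ignores sign. Term enrichment uses the same tail test
per term with Benjamini–Hochberg adjustment across tested terms; background
proteins without annotations still count in N. The background is always the
post-observation-filter quantified set, never the full identified list.

## SOTA clustering

Divisive growth: one cell holding all profiles; each cycle splits the leaf
with the greatest diversity (mean Euclidean distance of members to the
centroid) into two daughters — initialized at the parent centroid and at
the member farthest from it, for determinism — and runs adaptation epochs
in which each member of the split cell moves to its nearest daughter while
the winner, mother and sister centroids move by learning rates
(0.01, 0.005, 0.001), until the relative change of the summed
winner-distance error falls below 1e-6. Adaptation is restricted to the
split cell's members (restricted presentation), so the leaves partition the
input after every cycle. Growth stops at `max_cycles` splits (7 → at most 8
hard clusters) or when every leaf diversity ≤ `max_diversity` (0.8 on
P-value profiles). Reported centroids are member means; presentation order
is the input row order, so results are reproducible without randomness (the
`seed` argument exists for interface symmetry only). Learning rates and ε
are conventional SOTA-style defaults; the clustering source names none.

Dendrograms are scipy agglomerative clustering, Euclidean distance, average
linkage (UPGMA — the default of the named visualization tool; single and
complete available), exportable as Newick.

## Pathway–latitude regression

Pathway profile = median (default; mean optional — the two summaries are
both described by the source material, so both ship) of member-protein
effects per population; composite pathways are unions of member lists. The
aggregate is the response, absolute latitude A the regressor:
`Y = β0 + β1·A + β2·A²` by OLS, reporting coefficients with SEs, R² and the
Pearson correlation of fitted versus observed (R² equals its square, an OLS
identity checked numerically). At least three distinct |A| values are
required.

## Synthetic data

The generator emulates what the pipeline assumes, per protein and block:
channel value = population effect + block effect + label effect + colony
intercept + Normal(0, residual_sd), all on log2; whole protein×block cells
missing i.i.d. with `missing_prob` (channel-level dropout deliberately
off: quantitation is per block). Defaults — residual sd 0.25, colony sd
0.10, block effects N(0, 0.2), label effects N(0, 0.05), missingness 0.30,
planted effect sd 0.5 on a quarter of proteins, decoy fraction 0.01 — are
one-time calibration choices typical of dimethyl-labelling replicate
variability; no effect sizes are reported by the study being emulated, so
these are not reproductions. The PSM simulator draws target scores
N(45, 12) and decoy scores N(18, 6) floored at zero, and takes an explicit
peptide→proteins map to inject shared-peptide structure.

What the generator does *not* emulate: intensity-dependent missingness,
peptide-level variance heterogeneity, isotope-envelope interference,
retention-time structure, or correlated proteins. Passing recovery and
calibration tests therefore demonstrates correctness of the inference
machinery under the stated model, not robustness to those real-data
features.

Parameter-recovery tests compare estimates with truth on block-centered
(not label-standardized) data: standardization is a per-label affine map
that changes the units of the planted truth, while block centering leaves
population contrasts identified in the original log2 units (block dummies
absorb the centering offsets exactly).

## Problem sizes and numerical choices

Simulation-based checks run at 500 proteins (null calibration: rejection
rate 0.05 ± 0.02 and KS uniformity of p1 at α = .01), 200 proteins
(recovery: ≥95% of proteins with all eight effects within 3 SE of truth)
and 100 profiles (clustering oracle), all on the full 58-block design with
fixed seeds. Exactness checks enumerate every hypergeometric instance with
N ≤ 60 and every 3-population × 1-colony design. Criterion ties in the
design search are broken by first-found; parsimony ties by accession order;
SOTA assignment ties by the first daughter. Floating-point tolerances:
1e-9 for sum-to-zero and idempotence, 1e-12 for exact-test agreement.

## Known limitations

* The design optimizer is a local exchange search; global Ds-optimality is
  verified only at enumerable sizes.
* The factor test's residual-df F is an approximation (no
  Satterthwaite/Kenward–Roger adjustment); its calibration is demonstrated
  at the study's block structure, not in general.
* Protein grouping is the greedy set-cover heuristic, which can differ from
  a minimum cover on adversarial peptide-sharing patterns.
* Enrichment treats annotations as flat term sets (GO-slim style); there is
  no ontology-graph propagation.
* Replicating the published 578-protein and 172-protein counts requires the
  original protein×block spreadsheet, which is not redistributable here;
  the replication test fails explicitly in its absence rather than passing
  vacuously.
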