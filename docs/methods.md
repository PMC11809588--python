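# Methods

This note records the models implemented in `coalmorph`, the defaults and
why they were chosen, the numerical choices that affect results, and what
the synthetic data do and do not establish.

## Data containers and formats

Alignments are byte matrices over a declared alphabet (20 amino acids or 4
nucleotides) with `-` for gaps and `X`/`N` for unknowns; residues outside
the alphabet are remapped to unknown with a logged warning rather than
rejected, because transcriptome-derived proteins routinely contain
ambiguity codes.  Taxon ids are normalised (whitespace → `_`) at read time
for Newick/NEXUS interoperability.  Trees are stored as parent-pointer
arrays with per-edge lengths and a unit tag (`subst_per_site`,
`coalescent_units`, `Ma`, `none`); dendropy handles Newick/NEXUS parsing
and writing at the boundary, while the numerical code works on the arrays
directly (the D-statistic calibrations touch ~10⁵ simulated loci, where
per-locus object trees would dominate runtime).  Morphological matrices
keep the missing (`?`) / inapplicable (`-`) distinction in the cells;
ordered flags and weights round-trip through an `ASSUMPTIONS` block
(`TYPESET`/`WTSET`).  Supermatrices are concatenations with RAxML-style
1-based inclusive partition ranges; absent taxa are gap-filled per block,
and total scored-residue counts are conserved (a tested invariant).

## Synthetic data: what is emulated

The generator defines the study conditions used throughout the tests.

* **Species trees**: Yule (pure birth) trees via the reconstructed-process
  construction — the epoch with k lineages lasts `Exp(k·λ)` — so the root
  height has the closed-form mean `Σ_{k=2..n} 1/(kλ)` used as an oracle.
  Branch lengths are coalescent units; trees are exactly ultrametric.
* **Gene trees**: msprime with one population per species-tree branch,
  haploid samples and population size 1, so one time unit is one coalescent
  unit and triplet discordance obeys `(2/3)e^(−t)` (a binding test at
  t ∈ {0.5, 1, 2}).  One lineage is sampled per species, matching a
  one-transcriptome-per-species design.
* **Introgression**: a single instantaneous pulse — at the pulse time each
  recipient-population lineage moves to the donor population with
  probability γ (`msprime` mass migration, backwards in time).  This is the
  detection model the D statistics assume; continuous migration is out of
  scope.
* **Sequences**: i.i.d. sites under the symmetric k-state model
  (Jukes–Cantor for DNA, Poisson for amino acids), with `μ·length` expected
  substitutions per site per branch, checked against the
  `p = (k−1)/k·(1 − e^(−k·d/(k−1)))` closed form.  The LG model is
  supported for distance estimation but not simulation, keeping simulation
  oracles in closed form.
* **Morphology**: symmetric Mk per character with a per-character rate
  multiplier; true node states are recorded for recovery scoring.
* **Occupancy**: taxa are deleted from randomly chosen genes until each
  taxon's presence count equals its target exactly, reproducing the heavy
  occupancy skew of real transcriptome sets (some taxa present in <20 of
  thousands of genes).

What is *not* emulated: indels and alignment error, among-site rate
heterogeneity in simulated sequences, profile-mixture (C20/C60-style)
compositional site effects, recombination within loci, and correlated
character evolution.  Passing tests therefore demonstrate correctness of
the statistics under their own model assumptions, not robustness to those
real-data violations.

## Gene properties

Saturation is `1 − b` with `b` the least-squares through-origin slope of
uncorrected pairwise p-distances on patristic distances; the regression is
forced through the origin because both distances are zero for identical
sequences by construction.  p-distances ignore columns with a gap/unknown
in either sequence; pairs absent from tree or alignment are skipped with a
logged count.  "Substitution rate" is operationalised as total gene-tree
length, the convention of gene-sorting workflows.  RCFV is computed on the
declared alphabet only, `Σ_states Σ_taxa |f_st − f̄_s| / n_taxa`, with
frequencies over scored residues per taxon.  Ranking directions: occupancy
high-is-best; rate, saturation, RCFV, patristic low-is-best; ties break
lexicographically by gene id so subsets are deterministic and nested.

## D statistics

Sites enter the quartet counts only if all four residues are scored and
exactly two states occur; the outgroup state is taken as ancestral.  For
amino acids "biallelic" means exactly two amino-acid states, with no
similarity grouping — the simplest faithful extension of the SNP
definition.  The jackknife deletes contiguous column blocks (default 1,000
columns, trailing remainder merged into the last block; the method needs
≥ 2 blocks), `SE² = (n−1)/n · Σ(D_i − D̄)²`, `z = D/SE`, significance at
|z| ≥ 3 (configurable).  A deleted block that removes all informative sites
contributes the full-data D as its pseudovalue.

D_FOIL uses the published left/right pattern sets: D_FO and D_IL compare
P1 (resp. P2) against sites where P3 ≠ P4; D_FI and D_OL compare P3
(resp. P4) against sites where P1 ≠ P2.  Per-statistic significance is a
two-sided binomial test of left vs right totals (α = 0.01); results with
fewer than 100 informative sites (configurable) are flagged insufficient.
The signature → donor/recipient table was verified by simulation under the
pulse model itself (γ = 0.5 pulses in all eight terminal directions plus
the two ancestral cases, 8,000 loci each); each class has a distinct
signature, e.g. `P1⇒P3: (+,+,+,0)`, `P3⇒P1: (+,0,+,+)`, ancestral
exchange `(±,±,0,0)`.  A subtlety worth recording: singleton site patterns
(AAAB etc.) contribute to D_FO/D_IL, so a pulse that shortens a recipient's
pendant genealogy branches moves *both* statistics — intuition based only
on shared-derived patterns predicts the wrong zeros.

## Hemiplasy risk factor

The focal internal branch (length `t` CU) is modelled as a rooted triplet:
the two descendant lineages coalesce within the branch with probability
`1 − e^(−t)` (time truncated-Exp(1)); otherwise all three lineages join
uniformly above it (first interval Exp(3), second Exp(1)).  Pendant
branches default to 1.0 CU — summary-coalescent species trees carry no
terminal coalescent-unit lengths, so this is an explicit, exposed choice.
A binary trait mutates as Poisson(μ per CU) with parity toggling; a
*conflicting* pattern shares the derived state across the focal split; it
is *hemiplastic* if produced by exactly one mutation (necessarily on a
discordant genealogy's internal branch) and *homoplastic* with ≥ 2
mutations.  HRF = hemiplastic / conflicting.

Two estimators share the genealogy sampler.  The default integrates the
mutation layer out exactly per sampled genealogy (2⁴ branch-parity
enumeration gives P(conflict); `μ·L_int·e^(−μ·L_tot)` gives the
single-mutation term), which keeps HRF stable at μ = 10⁻⁴ where actual
conflicting draws are ~10⁻⁵ per replicate and a naive counter would return
noise; it also makes the μ-profile smooth at fixed seed, since one
genealogy sample serves the whole grid.  `method="scatter"` draws Poisson
counts explicitly and returns integer counts; the two agree within Monte
Carlo error (tested).  The SE of the default estimator is the delta-method
SE of the ratio of means.

## Mk engine

Likelihoods use Felsenstein pruning with per-node rescaling; uniform 1/k
root prior; missing and inapplicable tips are all-ones vectors.  Discrete
gamma uses equal-probability categories with category-mean rates
(normalised to mean 1), four categories by default.  The Lewis correction
is applied after category averaging: `L_v = L / (1 − Σ_s L_const(s))` with
constant patterns fully coded; likelihoods summed over all variable
patterns equal 1 on enumerable cases (tested), and a constant-pattern sum
≥ 1 raises a numerical error.  Parsimony is Sankoff DP — unit costs
reproduce Fitch counts, `|i−j|` costs handle ordered ladders — with
missing tips unconstrained.  Characters with different observed state
counts are grouped and evaluated under their own k.  Scalar optimisation
(pendant lengths, rates) is bounded Brent refined against the interval
endpoints; rate-like parameters are optimised in log space.

## Morphology toolkit

* **MORD**: ordered characters contribute `|a−b| / range` (range over the
  whole matrix), unordered an inequality indicator; the pair distance is
  the mean over comparable characters.  Inapplicable cells are excluded
  from comparability by default; `inapplicable="match"` alternatively
  scores two inapplicables as a comparable match, since the reference
  behaviour for inapplicables is genuinely underdetermined.
* **Implied weights**: `es = steps − (observed states − 1)` on the given
  tree, `f = k/(k+es)` with concavity k = 3 by default; calibration
  rescales fits to mean 1.  This measures homoplasy against an explicit
  topology rather than replicating any tool's internal calibration — the
  intent (downweight characters inconsistent with the reference
  hypothesis) is the same and the quantity is testable.
* **Partitioning**: 1-D k-means (25 restarts) for k = 1..10 on the
  per-character scores; the chosen k is the smallest achieving zero
  within-cluster SS, else the largest second difference of the SS curve
  (the elbow); an override is provided for fixing k externally.
* **Placement**: the query is attached at each edge midpoint with an
  optimised pendant length in [10⁻⁸, 10]; the edge score is
  `Σ_c w_c · lnL_c` under Mk + Γ4 + Lewis.  Midpoint attachment without
  within-edge optimisation keeps scoring O(edges × characters); discrete
  characters carry little signal for within-edge position.  Reference
  trees without lengths get unit lengths with a notice.  The assigned
  group is the unique group label of the clade below the best edge (None
  if mixed) — placements outside a group's clade therefore count as
  incorrect, matching how placement accuracy tables are scored.
* **Ancestral states**: marginal posteriors by up/down passes per gamma
  category, combined on the common likelihood scale; a node resolves only
  above the 0.69 threshold (a deliberately conservative convention kept
  configurable).  The Lewis normalisation cancels in the per-site
  posterior and is omitted there.
* **Rate shifts**: each scheme fits one rate multiplier per branch block
  (joint L-BFGS-B over log rates) or per character block (separable scalar
  fits); AIC = 2p − 2lnL and Akaike weights compare schemes.  Missing
  cells are uncertainty over all states; inapplicable cells are treated as
  missing.
* **Molecular distances**: pairwise ML distances maximise
  `Σ n_ab ln(π_a P_ab(t))` on the sites shared by each pair, under the
  Poisson model (uniform frequencies; agrees with the
  `−((k−1)/k)·ln(1−(k/(k−1))p)` closed form) or the LG model, whose
  published exchangeabilities and frequencies are embedded as constants.
  Gene selection by occupancy (`top_k`) mirrors "most complete genes
  first".

## Study conditions used by the binding tests

Fixed once, as the conditions the acceptance checks run under: quartet
species tree `(((P1,P2):1,P3):2,O)` with the focal internal branch 1.0 CU
and DNA loci of 200 sites at μ = 0.02/CU; null calibration with 100
replicate matrices of 2,000 loci; power with a γ = 0.3 P3→P2 pulse and
1,100 loci (≈5×10⁴ biallelic informative sites per matrix).  Placement
recovery uses a 20-taxon Yule tree with 100 binary characters at 0.25
changes per coalescent unit — the regime where characters change a
handful of times across the tree, as in empirical morphological matrices;
faster-evolving characters degrade placement accuracy noticeably.  The
HRF grid is the seven-value set 10⁻⁴…0.1 at 10⁵ replicates on a 0.5-CU
branch.  Mk-engine equivalence uses 200 random ≤5-leaf trees with k ∈
{2,3,4} and 20% missing data at 10⁻¹⁰ tolerance.  Rate-shift calibration
contrasts a single-rate scheme against a two-block scheme split at the
clade nearest half the taxa — splitting at the root can leave one block a
single long pendant edge on which binary characters are saturated and a
rate contrast is unidentifiable.

## Known limitations

Placement considers midpoint attachment only; D statistics here are
single-sequence (counts, not allele frequencies), so population sampling
and f4-ratio admixture proportions are out of scope; the HRF triplet model
ignores the subtree structure below the focal branch beyond its two
entering lineages; rate-shift schemes cannot mix branch and character
blocks in one scheme; NEXUS support covers CHARACTERS/DATA blocks (not
trees blocks) and the TYPESET/WTSET subset of ASSUMPTIONS.
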