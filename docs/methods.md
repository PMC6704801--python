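# Methods

This note records the models and procedures implemented in `fiberfam`, the
assumptions behind them, the defaults that matter, and what the synthetic
generators do and do not emulate.

## Scientific setting

Cultivated cotton comprises two allotetraploids — *G. hirsutum* (AD1, high
yield) and *G. barbadense* (AD2, superior fiber) — descended from diploid
progenitors carrying the A and D genomes (*G. arboreum* A2, *G. raimondii*
D5). R2R3-MYB transcription factors, defined by two tandem ~53-residue
DNA-binding repeats, regulate fiber initiation and elongation. The package
chains the analyses that connect this gene family to fiber-quality
variation: identify family members by repeat content, place them on a
phylogeny, classify post-polyploidy gene loss and selection pressure,
intersect family members with fiber-trait QTL hotspots, type
interspecific coding SNPs across multiple genome assemblies, and test those
SNP markers against fiber phenotypes and allele-specific expression in an
interspecific backcross inbred line (BIL) population.

## MYB repeat scanning (`mybscan`)

Repeats are detected with a log-odds position-specific scoring matrix
(PSSM) over a fixed repeat length L = 53, estimated from a seed alignment
with pseudocount 0.5·background:

    pssm[p][r] = log2((count[p][r] + 0.5·bg[r]) / (rows + 0.5) / bg[r])

Scoring is a plain sum of per-position bits over each window; insert and
delete states are not modelled — repeat length in this family is nearly
constant, and imperfect matches are absorbed by the log-odds scores.
Windows at or above `score_threshold` are kept greedily by descending score
(ties to the leftmost start) with overlap exclusion. Accepted repeats more
than `max_gap` (default 30 residues, configurable) apart split into
clusters and only the largest cluster defines the repeat count, so a stray
remote hit cannot inflate the subfamily call. The subfamily label is a pure
function of the count: 0 → none, 1 → 1R, 2 → R2R3, 3 → 3R, ≥4 → 4R.

The default threshold is half the consensus (maximum attainable) bit score.
With a typical seed (20 rows, ~10% divergence) the consensus scores ≈ 219
bits, planted repeats at 10% divergence ≈ 170–200 bits, and random windows
are deeply negative (mean ≈ −250), so the half-maximum rule separates the
two populations by a wide margin. `calibrate_threshold` offers the
alternative of an empirical shuffle-null quantile; note that per-window
tail probabilities multiply over the hundreds of windows in a protein, so a
null quantile intended to control per-protein false positives must be
chosen accordingly.

Conservation logos use per-column information content IC = log2(20) − H
with H the Shannon entropy of observed column frequencies, no small-sample
correction — the convention of standard logo drawers. The modal residue per
column is reported so repeat-specific substitutions (e.g. the R3 repeat's
first tryptophan being replaced by phenylalanine) are visible.

## Phylogeny (`phylo`)

Distances are uncorrected p-distances on a user-supplied domain alignment
(multiple alignment is out of scope), with gap/ambiguity columns excluded
pairwise. Trees are Saitou–Nei neighbor joining, delegated to
scikit-bio's implementation behind `nj_tree`; the two-taxon case splits the
single edge evenly, and negative branch-length estimates are clamped to
zero. On any additive matrix NJ recovers the generating topology and
leaf-to-leaf path lengths exactly; the test suite verifies this against a
brute-force oracle on random trees. Bootstrap support is not computed:
clade supports are not consumed by any downstream step.

Subgroup assignment transfers the label of the nearest annotated reference
(Arabidopsis S-categories such as S9/MIXTA and S15/GLABRA1) when its
p-distance is ≤ 0.6 (default), else calls the query lineage-specific
("G-S"); ties break on lexicographic reference id. The cutoff is a display
level convention, not a fitted parameter — clade boundaries in family-wide
trees are not defined by a reproducible rule.

## Loss scenarios and dN/dS (`evolution`)

An ortholog group records presence/absence across the six roles (A2, D5,
At/Dt of AD1, At/Dt of AD2). The scenario classifier is a fixed decision
table: full retention; loss of one tetraploid subgenome copy (progenitor
retained); loss of both subgenome copies of one species; loss of a diploid
progenitor copy with both tetraploid descendants retained; joint loss of a
subgenome copy and its progenitor; everything else OTHER. All 63 nonempty
patterns are covered, and an independently constructed pattern→label table
guards the mapping. Lost-pair counts per tetraploid count groups with at
least one absent subgenome slot (a both-subgenome loss counts once);
counting groups rather than genes is a deliberate choice where the
convention is ambiguous.

dN/dS is Nei–Gojobori (1986) counting rather than codon-model maximum
likelihood: synonymous sites per codon are the fraction of the nine
single-base mutants preserving the amino acid (mutants to stops count as
nonsynonymous), averaged over the two sequences; observed differences at
multi-hit codons are averaged over all minimal mutational pathways,
excluding pathways through stop codons (if all are blocked the raw
differences are charged as nonsynonymous); proportions are corrected with
Jukes–Cantor, d = −3/4·ln(1 − 4p/3), reported as NaN when saturated
(p ≥ 3/4). ω = dN/dS is undefined when dS = 0 or saturated; otherwise
ω < 1 is called purifying, ω > 1 positive, ω = 1 neutral. NG86 is
closed-form and exactly checkable against pathway enumeration; the
downstream inference used here (whether ω is below 1) does not depend on
the likelihood machinery it replaces. Significance testing of ω against 1
is out of scope.

## QTL hotspots and co-localization (`qtlcoloc`)

A hotspot is ≥ `min_count` (default 4) same-trait QTL within a `window`
(default 20 cM) region. Detection is windowing on QTL peak positions
(interval midpoints when only a support interval is given): per
(trait, chromosome), a candidate window [peak, peak + 20] is anchored at
every peak, windows holding ≥ 4 peaks are kept, overlapping kept windows
merge (a merged hotspot may exceed 20 cM), and the reported interval is the
[min, max] of member peaks. Different traits never merge, though their
physical intervals may overlap. Ids follow the `FL_Hotspot_c5` /
`MIC_Hotspot_c5_1` convention. An interval-based alternative (windowing on
whole support intervals) was considered and not implemented as the default
because the cluster rule is stated on positions.

Genetic→physical anchoring interpolates linearly between flanking markers
carrying both cM and bp positions, clamping outside the anchored range.
Anchors violating joint monotonicity (local map inversions) are dropped by
longest-increasing-subsequence filtering before interpolation. Gene
co-localization uses half-open interval overlap in bp — abutting intervals
do not overlap — and genes on chromosomes without anchored hotspots (e.g.
scaffold-placed genes) are reported unplaced rather than silently dropped.

## SNP typing, association, expression (`snpassoc`)

The multi-assembly classification rule, with species A = *G. hirsutum*
(parent CCRI 36; references TM-1 NAU and JGI) and species B =
*G. barbadense* (parent Hai 7124; own assembly ZJU; references Xinhai 21
and 3-79):

1. parents equal → unclassifiable;
2. parent A differing from **every** species-A reference → A-specific
   candidate;
3. parent B matching its own assembly **and** differing from every other
   species-B reference → B-specific candidate;
4. both → conflicting; 5. neither → interspecific.

The own-assembly confirmation in rule 3 is the key design choice: it
separates an accession-private allele from a genuine between-species
difference even when one reference assembly disagrees. The packaged 27-site
parental allele matrix reproduces its printed typing exactly under this
rule (20 interspecific / 3 A-specific / 4 B-specific), including the two
irregular rows where one reference assembly carries the other species'
allele.

Association is the point-biserial Pearson correlation between a 0/1
donor-allele genotype (1 = the *G. barbadense* parent's allele, so signs
read as the donor allele's effect) and a quantitative trait, per
environment, with p from t = r√(n−2)/√(1−r²), df = n−2, two-sided. Missing
values are excluded pairwise; line means per environment are the input
unit; a constant genotype or phenotype yields an undefined (not erroneous)
result. Stars are per-test: * for p < 0.05, ** for p < 0.01, and stability
counts the environments significant at the 0.05 level. No multiple-testing
correction is applied by default, matching the per-marker star convention
of correlation tables in this design; heterozygous BIL calls are treated as
missing (BC1F7 lines are near-fixed).

qPCR relative expression is 2^−ΔΔCt with technical/biological replicate
Cts averaged before differencing. Expression concordance asks whether the
allele-pair expression ordering matches the association sign in at least
one shared development stage (10/20/25 DPA in the motivating design); a
strict all-stages flag exists.

## Synthetic data (`synth`)

Each generator draws from a named substream (seed, crc32(name)), so
generators are mutually independent and byte-reproducible. Defaults encode
the study conditions the pipeline targets:

* proteome: 200 proteins, 30% repeat-family members, repeat counts
  dominated by 2 (R2R3), 10% per-position divergence from a fixed
  53-residue consensus carrying the family's spaced tryptophans;
* QTL map: 5 planted same-trait clusters (4–8 members within 15 cM) on
  5 chromosomes plus 50 scattered background QTL and monotone, jittered
  marker anchors (~1 Mb/cM);
* BIL: 180 lines, donor-allele frequency 0.25 (one backcross halves the
  donor share; selfing to BC1F7 fixes it), 4 environments with their own
  intercepts, residual sd 1, marker effects specified as target population
  correlations;
* allele matrix / ortholog groups: class mixtures allocated to exact
  integer counts by largest-remainder rounding, rows constructed to satisfy
  their intended class by rule.

Deliberate idealizations: background QTL of a trait are thinned to lie
> 1 window apart and ≥ 2 windows from same-trait planted clusters, so
planted clusters are exactly the detectable hotspots and recovery can be
scored without ambiguity; BIL markers are generated independently (no
linkage map or LD decay); phenotypes are Gaussian with purely additive
marker effects; proteome background is i.i.d. over residues. Passing the
planted-recovery and calibration tests therefore demonstrates correctness
of the decision rules and test statistics under their stated assumptions,
not robustness to real-data pathologies (correlated markers, repeat-length
variation, map errors, non-normal traits).

## Problem sizes and numerical choices

Test and acceptance runs use desk-scale sizes chosen to make planted-truth
and calibration checks sharp: 200-protein proteomes, 1,000-marker null
panels, 200-replicate power and ω simulations, 100-codon sequence pairs,
4–6-taxon trees against brute-force oracles. Tolerances: NJ path lengths
1e-9 (exact arithmetic up to float round-off); type-I error within
[0.035, 0.065] at α = 0.05 for 1,000 null tests (±2 binomial SD); all
rule-based classifiers exact. Tie-breaks are deterministic throughout
(leftmost window, lexicographic reference id, cM-then-id ordering).

## Known limitations

* The PSSM scanner has no insert/delete states; genuinely gapped repeats
  would be missed or truncated.
* E-value statistics are not computed; thresholds are bit scores.
* Scenario labels are declared, not inferred; patterns outside the seven
  named models fall into OTHER rather than being subdivided.
* NG86 assumes equal base frequencies and no transition/transversion bias;
  ω is a pairwise summary, not a branch- or site-level estimate.
* Hotspot detection depends on the declared trait vocabulary; synonymous
  trait names in merged QTL databases must be normalized upstream.
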