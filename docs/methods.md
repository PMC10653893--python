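# Methods

This note documents the models and procedures `magenes` implements, the
defaults that matter, what the synthetic generators do and do not emulate,
and the design choices made where the design was genuinely open.

## Translation and amber read-through

Translation uses the standard genetic code with plain codon semantics (no
start-codon remapping). TAA and TGA always terminate. TAG behaves per
`amber_mode`: `stop` terminates; `pyl` emits pyrrolysine ('O') and
continues. Codons containing N translate to 'X' rather than aborting,
because draft scaffolds contain Ns. Coordinates throughout are 0-based,
half-open, forward-strand; ORF spans include the terminating stop codon.

ORF calling scans all six frames. An ORF starts at a start codon (default
ATG/GTG/TTG) and ends at the first terminator; only the longest ORF per
(frame, terminator) is reported, matching common gene-caller behavior.
In read-through mode up to `max_readthroughs` in-frame TAGs are crossed
(default 1 — every characterized Pyl-containing MttB carries a single
pyrrolysine; a larger budget multiplies variants without biological
support). `mode="both"` reports the TAG-terminated call *and* its
read-through extension, deferring the interpretation to curation.
`min_aa` defaults to 100: MA genes are all several hundred residues, and
the threshold is exposed.

Truncated-gene recall (`recall_truncated`) re-calls a scaffold with
read-through and accepts the ORF covering the truncated span if its
protein reaches at least 80 % of the reference (anchor) protein's length
(`min_anchor_fraction`, configurable). The fraction guards against TAGs
immediately followed by genuine stops.

## Homology engine

Pairwise alignment is affine-gap dynamic programming (Biopython's
`PairwiseAligner`) with BLOSUM62, gap open −11 / extend −1 — the familiar
protein-search defaults. Raw scores map to bit scores via
`bits = (λ·S − ln K) / ln 2` with the standard gapped constants λ = 0.267,
K = 0.041. The homolog screen retains candidates scoring strictly above
60 bits against any validated seed. The engine is deterministic (first
optimal traceback), and its scores are verified in the test suite against
an independent brute-force Gotoh implementation.

Pyrrolysine is scored with lysine's matrix row by default (Pyl is a
lysine derivative); the row choice is configurable.

Two identity definitions are exposed, because different steps conventionally
use different ones: `pct_identity` = matches / aligned columns (used for
SSN edges and tree distances) and `identity_short` = matches / shorter
sequence length (the cd-hit convention, used for dereplication).

### Reference placement

The workflow this package automates selected "the branch containing the
sequences of interest" in an interactive tree viewer. Automating that
literally proved fragile: we first implemented *minimal clade containing
all positive references* on a neighbor-joining p-distance tree (both as a
midpoint-rooted LCA and as a minimal split side) and found that no
single-edge rule is reliable — NJ can attach a cherry of genuine
candidates anywhere along the reference span, and one edge cannot always
separate every inlier from every outlier. The shipped rule is
containment on the NJ tree: a candidate is placed with the positives when
its patristic distance to the nearest positive reference is at most the
positives' own patristic diameter *and* it is closer to a positive than
to any negative reference. This is rooting-free, deterministic, keeps
everything the references bracket, excludes outliers far outside their
span, and reduces to outgroup-aware branch selection when negatives are
provided. With fewer than two positive references the tree carries no
span information and candidates are judged by nearest-reference bit score
instead.

### Active residues

Residue profiles pin required anchor positions to allowed residue sets;
a candidate passes when every required position maps (via global
alignment) to an allowed residue — a gap fails. Shipped profiles are
config stubs the user should review against the biochemical literature
for their reference enzymes; the synthetic benchmark generates its own.

## Curation decision procedure

Each gene type is assessed separately: seed screen (> 60 bits) → reference
placement → per-type rule. For *cutC*, *cntA/yeaW*, *grdI*, *mtmB* and
*mtbB* the rule is the active-residue check. *cntA* and *yeaW* are one
pooled label: substrate specificity cannot be inferred from sequence.

The MTTB superfamily splits on pyrrolysine:

1. longer than 360 aa, no 'O', and the anchor's Pyl column maps to a
   standard residue → **mtxB** (non-Pyl, substrate unassigned);
2. carries 'O' mapping onto the Pyl column (recalled from the scaffold
   with read-through if the hit was TAG-truncated) → **mttB**;
3. truncated with no nucleotide context → rejected
   (`truncated_no_context`);
4. 'O' anywhere else → rejected (`amber_off_column`).

The 360 filter is interpreted as **360 amino acids, strictly greater**:
MttB-superfamily proteins run ~450–500 aa, so a 360-nucleotide (120 aa)
filter would exclude nothing, and the boundary follows the wording
"longer than". The Pyl column itself is defined by the annotated amber
position of the configured Pyl-containing anchor.

A candidate accepted under several type pipelines with the same final
label keeps it; conflicting labels reject it as `ambiguous`. Genomes are
classified from their curated inventory: any proatherogenic gene ⇒
`proatherogenic`, any non-TMA gene ⇒ `non_TMA`, one of each ⇒ `both`,
empty ⇒ `none`; copy number and order never change the status.

## Catalog

Dereplication is greedy incremental clustering: sequences sorted longest
first (ties by id), each joining the best-identity existing representative
at or above the threshold (default 0.99, `identity_short`), else founding
a cluster. The SSN collapses sequences at `collapse_min` (default 1.00 —
exact duplicates; the stricter of the two published descriptions, with
0.99 reachable by flag) into nodes and draws edges between representatives
at aligned-column identity strictly above `edge_min` (default 0.80).
Clusters are connected components, ordered by size then smallest member.

## Quantification

Per-gene abundance from per-base depths: covered fraction = share of
positions with depth ≥ 1; below 0.75 the gene is called absent (0);
otherwise the mean after trimming `floor(0.05·L)` positions from each
tail. The gate is applied before trimming; the 5 % per-tail default is
configurable (the upstream tool names only the mode, not the fraction).

geTMM: RPK = count/(length/1000); TMM factors are computed **on the RPK
matrix** (that is the "gene-length corrected" part); the normalized value
is RPK / (factor × ΣRPK) × 10⁶. TMM follows the canonical recipe —
reference sample by 75th-percentile count fraction closest to the mean,
M/A values on genes positive in both, double trim (30 % on M, 5 % on A,
rank-based), delta-method precision weights, factors rescaled to
geometric mean 1. During development the factors were checked against
edgeR's `calcNormFactors` and agree to 4 decimal places; the shipped test
suite instead verifies recovery of planted composition shifts within 2 %
(at sequencing depths where the estimator's own noise permits — at mean
counts near 20 both this implementation and edgeR deviate ~2.6 % from the
analytic factor; at counts in the hundreds both are below 1 %).

Accumulation curves recompute the dereplicated gene count on the growing
union of subjects; each step equals a from-scratch batch dereplication of
the first k subjects, and permuted orderings give a mean ± sd band.

## Cohort models

Features (variants 1–7): Shannon diversity per gene type + gender; blood
markers (triglyceride, LDL, HDL, mmol/L) + gender; abundance of
cutC + cntA/yeaW + gender; every gene's abundance + gender; abundance per
type + gender; abundance per TMA role + gender; variant 1 without gender.
Labels: 1 = disease, 0 = healthy; gender 1 = male, 0 = female. Shannon
diversity uses natural log with proportions renormalized within each
type; an all-zero type scores 0.

Classification is L2-penalized logistic regression (scikit-learn, lbfgs),
features z-scored on the training folds only. The default penalty is the
common inverse-strength-1.0 default of the original analysis environment;
a no-penalty mode is provided. Evaluation: stratified 10-fold CV from a
seeded shuffle; per-fold ROC curves vertically averaged on a 101-point
FPR grid; the reported AUC is the trapezoidal area under the mean curve
(per-fold AUCs are also returned — averaging them is the other published
convention, and both are emitted so the choice is visible). Model
comparison: McNemar's test on paired out-of-fold correctness at a 0.5
probability threshold — exact two-sided binomial when discordant pairs
b + c < 25, chi-square with continuity correction otherwise.

## Synthetic data: what it does and does not emulate

`plant_genes` reverse-translates proteins with random synonymous codons,
plants TAG at Pyl positions, alternates strands, and flanks each gene with
a short all-frame stop guard plus random intergenic spacers, so planted
coordinates are exactly recoverable and ORFs never run across gene
boundaries. `make_family` substitutes an exact number of positions for a
target identity, optionally protecting active-site columns. Decoys are
residue-shuffled proteins: composition preserved, homology destroyed.
The default curation benchmark plants 40 genes across all 7 types
(including 6 amber-containing *mttB*) on 8 scaffolds plus 40 decoys.

The cohort simulator draws negative-binomial counts (variance
μ + 0.3 μ²) with per-sample depth factors and plants the observed effect
directions: proatherogenic genes 2-fold enriched and *mttB* 2-fold
depleted in cases (log2 effects ±1 by default), with 218 cases and 187
controls matching the real cohort's class sizes. Blood markers shift
with the label; gender is drawn 50/50.

None of this mimics real evolution: families are star-shaped point-mutant
clouds, not phylogenies; scaffolds have uniform base composition and no
gene overlap; counts have no taxonomic covariance structure. Passing
tests therefore demonstrate the *machinery* — exact recovery, correct
thresholds, calibrated statistics — not performance on real metagenomes,
where reference choice and profile curation dominate.

Problem sizes in the tests (40-gene benchmark, 2,000-gene × 20-sample
normalization fixtures, 405-sample cohorts, 20 CV replicates) were chosen
as the smallest at which each property is statistically decidable.

## Numerical choices and limitations

- Alignment tie-breaks: first optimal traceback of the DP, deterministic.
- Dereplication ties: first (earliest-founded) representative wins.
- The reactor mass-balance helper uses dose-to-target-concentration
  semantics (a 1 mM dose into v mL adds v µmol); sampling 1 mL before the
  second and third dose gives 10 + 9 + 8 = 27 µmol on the published
  schedule. Priming doses at or below 0.04 mM are tallied separately.
- All generators and model evaluations are bit-reproducible under their
  seed parameters.
- Known limitations: no E-value statistics (bit-score gate only); no
  heuristic seeding, so all-vs-all alignment is quadratic and meant for
  curated candidate sets, not whole proteomes; selenocysteine (UGA)
  read-through is out of scope; depth rarefaction requires raw reads and
  is therefore consumed as pre-rarefied tables.
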