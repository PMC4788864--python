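# Methods

This note documents the models, conventions, numerical choices and known
limitations behind each pipeline stage, and what the synthetic-data
generators do and do not emulate.

## Coordinates and formats

All genomic coordinates are 1-based inclusive (GFF3 convention); promoter
positions are signed with −1 the base immediately 5′ of the translation
start codon, so a window of length L spans −L…−1. Chromosome names sort
in natural order ("Chr2" before "Chr10"). Tables are tab-separated UTF-8
with `#` comments; sequences are FASTA; trees are Newick. Parsers never
drop records silently: malformed input is a hard error naming the line.

## Family identification

Candidates are BLAST subjects with at least one hit at E ≤ the cutoff
(inclusive, default 10⁻⁷), intersected with proteins carrying at least
one hit of the diagnostic domain (default PF01554). The two filters
commute. Naming sorts members by (natural chromosome order, start,
gene_id) — the gene_id tie-break makes numbering deterministic when two
loci share a start, which real annotations occasionally do — and assigns
`prefix+1…prefix+N`. One representative protein per locus is assumed;
two proteins mapping to one locus is an error rather than a silent
collapse, because isoform handling is a data-preparation decision.
Unanchored scaffolds are not special-cased: they are named wherever
natural order places them, so the pipeline does not crash on draft
assemblies.

## Protein properties

Molecular weight is the sum of average (not monoisotopic) residue masses
plus one water. `X` is a hard error by default; with `allow_x=True` it
contributes the mean canonical residue mass (a documented approximation,
reported per run by the caller's flag, never silently).

The isoelectric point is the root of the net-charge function over the
termini and D, E, C, Y, H, K, R side chains. The function is strictly
decreasing in pH, so the root is unique and bisection on [0, 14] always
converges; iteration stops when |Q| < 10⁻⁴. Two pK sets are embedded:
the Bjellqvist set used by the ExPASy Compute pI/Mw tool (default,
including its residue-specific N-terminal pKs and the D/E C-terminal
adjustments) and the EMBOSS iep set for sensitivity analysis. pI values
are meaningful only relative to a stated pK set; the two sets typically
differ by a few tenths of a pH unit on real proteins.

The transmembrane-segment estimate is a Kyte–Doolittle sliding-window
count (window 19, threshold 1.6, runs separated by fewer than 5 window
positions merge). It is a hydropathy heuristic, not an HMM topology
predictor, and is excluded from any quantitative comparison with
HMM-based TM counts; it exists so a complete property table can be
produced from sequence alone.

## Duplication analysis

Protein similarity is the fraction of BLOSUM62-positive aligned pairs
over all columns of a global (end-to-end) alignment with affine gaps
(open 10, extend 0.5). Published tandem definitions rarely state whether
"similarity" means identity or positive-scoring similarity, or the
alignment length convention; both metrics are selectable and the default
is the positive-fraction reading, the most common one.

Tandem: two family genes on one chromosome with strictly fewer than 10
annotated loci between them (counted over all loci, exclusive of both;
a flag restricts counting to family loci) and similarity strictly above
50 %. Both thresholds are strict: a pair at exactly 10 intervening loci
or exactly 50 % similarity is not tandem.

Segmental duplicates come from simplified collinearity: anchors are
homologous pairs at E strictly below 10⁻⁵, keeping each query's top 5
matches; chains must be monotone in gene rank on both chromosomes
(increasing or decreasing — inverted blocks are detected and labelled),
with rank gaps ≤ 25 between adjacent anchors and ≥ 5 anchors per block;
each anchor joins at most one block. This deliberately omits the
statistical block E-value of MCScan-family tools — block significance is
controlled by the anchor-count and gap parameters instead — so
genome-wide duplicate counts from this module are not comparable
number-for-number with MCScan output. A gene is segmental when it
appears in a block anchor whose partner is also a family gene; genes in
both categories are labelled `both` and counted once in the
"present in duplications" total, giving the bookkeeping identity
tandem + segmental − both = duplicated.

## Promoter cis-elements

Extraction takes the `length` bases immediately 5′ of the start codon on
the gene's sense strand (reverse-complemented 3′ flank for − genes);
windows truncated by a chromosome edge are returned short and flagged,
not padded. Scanning is exhaustive and overlapping — adjacent degenerate
matches such as −944/−943 are distinct occurrences and both counted —
case-insensitive, and by default on the sense strand only, which matches
the magnitudes observed for GGNVS in plant promoters (≈5–15 per 1.5 kb);
a `both_strands` flag maps reverse-strand hits back to sense-strand
5′-most positions. The position convention (5′-most base, −1 adjacent to
ATG) is written into every output header. In the degenerate consensus
GGN(T/g/a/C)V(C/A/g)S(C/G), the parenthesised letters are frequency
annotations from the source characterization, not constraints; matching
uses the full IUPAC sets N/V/S, the only reading that defines a matcher.

The expected match count under an i.i.d. background is
(L − k + 1) · Π_j Σ_{b ∈ allowed_j} f_b; for GGNVS at uniform base
frequencies and L = 1500 this is 1496 · (1/4)² · 1 · (3/4) · (1/2) =
35.0625, a useful sanity scale for real scans.

The element catalog (ABRE, ARE, HSE, LTR, MBS, …) ships as an editable
TSV whose consensus strings are clearly marked placeholders: regulatory
databases define several variants per element, so per-element counts are
only as meaningful as the catalog supplied.

## Expression atlas

Genes with zero abundance in every tissue are removed first (on the
study-shaped 117 × 9 matrix this retains 113). Values then transform as
log₁₀(v + 1) — the pseudocount is configurable and recorded; the original
heat-map software's zero handling is undocumented, and +1 keeps zeros at
zero — and each gene row is mean-centred. Clustering is average-linkage
(UPGMA) on Euclidean row distances via scipy; rows are pre-sorted by gene
id so results are permutation-invariant, with scipy's
cluster-creation-order tie-break making equal-height merges
deterministic. Outputs are the row-reordered matrix and a Newick
dendrogram whose branch lengths derive from merge heights. Average
linkage is not guaranteed monotone under pathological ties, so merge
height monotonicity is asserted only on clean instances. Comparisons
against specific published heat maps are structural (retained counts,
invariants), not pixel-level: the original tool's exact zero and tie
handling is unknown.

## qPCR

Efficiency: OLS of Ct on x = log₁₀(1/dilution factor) over ≥ 3 distinct
levels; E = 10^(−1/slope) − 1, with slope ≥ 0 rejected as
"not amplifying". A slope of −3.3219 (3.32 cycles per 10-fold template)
gives E = 1, perfect doubling.

Relative expression uses group-mean ΔCt: ΔCt = mean Ct(target) − mean
Ct(reference) per group, ΔΔCt = ΔCt(treated) − ΔCt(control), fold =
2^(−ΔΔCt). Group means define the headline fold because the standard
2^(−ΔΔCt) reference formulation works on means; per-replicate folds
(treated replicates paired target-vs-reference by index, compared
against the control-group mean ΔCt) supply the spread and the t-test
inputs. Folds are invariant to any global Ct shift, since ΔΔ cancels it.
Efficiencies are reported but do not correct the fold by default (plain
2^(−ΔΔCt)); an efficiency-corrected base (1+E)^(−ΔΔCt) is optional.
Genotype comparisons use the equal-variance Student's t-test (Welch
optional) on per-replicate folds by default (ΔΔCt-scale testing is
selectable; which scale the original analyses used is typically not
stated). Marks: `**` for P < 0.01, `*` for P < 0.05, `nd` when fewer
than 2 replicates; two identical zero-variance samples get P = 1.

## Tree subgroups

Unrooted input trees are midpoint-rooted (missing branch lengths default
to 1) unless an outgroup leaf is supplied; pre-rooted trees are left
alone. A query leaf takes subgroup X when the smallest clade containing
it and any anchor holds anchors of only X; mixed clades fall back to the
nearest anchor by patristic distance, and exact cross-subgroup ties are
left `unassigned` rather than broken arbitrarily. Anchors always keep
their declared subgroup. The shipped anchor table lists characterized
plant MATE transporters by name (SbMATE, HvAACT1, OsFRDL4, AtTT12, …)
with their subgroups; it is a default to edit, since anchor choice
defines the classification.

## Synthetic data

One integer seed drives everything; each stage uses an independent
substream keyed by a stable hash of the stage name, so a stage can be
regenerated alone and byte-identically. Defaults mirror the study's
shapes: 20 chromosomes × 100 loci, 117 family genes, protein lengths
drawn from 80–593 aa, 1500 bp promoters at GC 0.35, a 9-tissue
expression matrix with 4 all-zero genes, and a 2-genotype × 2-treatment
× 3-timepoint × 3-replicate qPCR design with replicate noise sd 0.2 and
true efficiency 0.95; the simulated candidate gene's true folds
(127/274/335 tolerant vs 10/39/33 sensitive across 6/12/24 h) give it
the strong genotype contrast expected of an Al-tolerance transporter.

Planted structure is constructed to be unambiguous: tandem-cluster
members descend from a shared ancestor protein (5 % substitution), all
other family genes sit at least 10 intervening loci apart — the exact
exclusion boundary of the tandem rule — so planted-cluster recovery has
precision = recall = 1 by construction; collinear blocks place anchor
pairs at 11-rank steps (inside the chaining gap, outside tandem reach).
Motif planting intersects IUPAC base sets position-wise, raising an
error on incompatible overlaps, and truth tables are exhaustive: a
brute-force scan (independent of the production scanner) enumerates
every match including background collisions. In collision-free mode the
background is repaired/resampled until each pattern occurs exactly at
its planted positions; this is how the synthetic stand-ins for the eight
C4-3 promoters reproduce the published GGNVS count/position table
exactly.

What the generators do **not** emulate: real codon structure, repeats or
GC heterogeneity along chromosomes; homology decay with distance;
dye-saturation or pipetting structure in Ct values beyond i.i.d.
Gaussian noise; phylogenetic signal in protein sequences. Passing the
planted-recovery tests therefore demonstrates the correctness of the
algorithms and conventions, not calibration against real soybean data —
genome-wide duplicate percentages in particular depend on the input
proteome and anchor evidence, and published values for those are
documented here only as context.

## Problem sizes

Test and acceptance runs use the study-shaped defaults above (2 000 loci,
117 family genes, 8 reference promoters, 117 × 9 expression, 15-point
dilution series); the whole suite runs in a few seconds, with the
duplication stage dominated by the few within-cluster global alignments
its planted layout requires.
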