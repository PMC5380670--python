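# Methods

## Scope and model

`camfam` implements the desk-scale core of a calmodulin (CaM) /
calmodulin-like (CML) gene-family analysis for a plant genome: detecting
EF-hand Ca²⁺-binding motifs in protein sequences, quantifying relatedness
to a reference CaM, assigning family membership, relating gene structure
to the coding frame, and summarizing expression behaviour. Every stage is
driven either by user-supplied FASTA/TSV inputs or by the package's own
seeded generators, which carry machine-readable ground truth.

## EF-hand detection

An EF-hand is a helix-loop-helix motif whose 12-residue loop chelates
Ca²⁺ at positions 1 (+X), 3 (+Y), 5 (+Z), 7 (−Y), 9 (−X) and 12 (−Z).
The scanner encodes the conserved plant CaM/CML loop as a
position-specific grammar:

    pos 1 = D;  pos 3 ∈ {D,N,S};  pos 5 ∈ {D,N,S,T};  pos 6 = G;
    pos 9 ∈ {T,D,S,N,G,E,Q};  pos 12 ∈ {E,D}

`relaxed` mode drops the position-9 constraint; `canonical` is the
default used for family classification. Overlapping candidate windows are
resolved by keeping the leftmost match and resuming after its end — two
physical 12-residue loops cannot overlap, and the rule is deterministic.
This grammar deliberately excludes pseudo-loops lacking the position-1
aspartate; it stands in for profile-HMM domain scans and is exact on the
generator's outputs but will differ from HMM calls on strongly degenerate
natural loops.

Pairing is greedy left-to-right over adjacent loops whose linker
(`next.start − prev.end`) lies within `[MIN_LINKER, MAX_LINKER]` =
`[8, 30]` residues. In CaM the two loops of a pair sit ~24 residues apart
start-to-start (12-residue linker); the bounds bracket that with slack.
On a path of adjacent-loop candidates, greedy leftmost matching is a
maximum matching, which the tests verify by exhaustive search. A loop at
position 12 carrying aspartate instead of the canonical bidentate
glutamate is flagged: that substitution shifts the site's preference
toward Mg²⁺.

The loop frequency table tallies residues per loop position; the
consensus slot is the most frequent residue (ties alphabetical) with
alternative residues at frequency ≥ `alt_threshold` (default 0.15) in
brackets, and `x` where the top frequency is below both 0.5 and the
threshold. The 0.15 default reproduces "frequently found alternatives"
behaviour without biasing toward any one cohort; it is a free parameter.

## Percent identity

Relatedness is the number of identical residue pairs in a global
alignment divided by the length of the **shorter** unaligned sequence,
×100, reported at two decimals with half-up rounding (149-residue pair
with 2 substitutions → 98.66). Identical pairs are counted only where
both columns are non-gap. Alignment is Needleman–Wunsch with affine gaps
(Biopython `PairwiseAligner`; BLOSUM62, gap open −10, extend −0.5 —
conventional protein defaults; they matter only for gapped pairs).
Because co-optimal alignments can differ in identical-column count, the
symmetric entry point canonically orders the pair before aligning, making
`pid(a, b) == pid(b, a)` exact rather than merely expected.

## Classification

Proteins below 23.00% identity to the reference, or annotated with
non-EF-hand functional domains (via an optional external annotation
table), are excluded from the family. Retained proteins with four
EF-hands and identity ≥ `CAM_THRESHOLD` are CaM; the rest are CML.
`CAM_THRESHOLD` defaults to 60.00%: in the census this package mirrors,
the lowest CaM prints 79.19% and the highest CML 42.45%, so 60 sits in
the empirical gap. The original family split was made on tree topology;
the threshold is a documented, configurable stand-in. The retention cut
is inclusive at 23.00 because the census's lowest retained member sits at
23.91% and the family is defined as "at least 23% identical".

Annotation features: %Met (half-up, 2 dp); Cys27-equivalent = cysteine at
position 7 (−Y) of the first detected loop; Lys116-equivalent = lysine in
the column aligned to reference residue 116; N-myristoylation by a
PROSITE-style rule (initiator Met, Gly acceptor, then
`G-[^EDRKHPFYW]-x-x-[STAGCN]-[^P]`). The rule replaces neural-network
predictors and is advisory: it over-calls relative to them on some
N-termini and is labelled as putative in reports.

## Gene structure

A gene model is an exact decomposition of the genomic sequence into exons
that concatenate to the cDNA, separated by GT..AG introns (plus strand
only; callers orient inputs; minimum exon 10 nt by default). The
depth-first search tries intron end points left to right, so among
multiple valid chains the one with leftmost exon starts is returned.
There is no tolerance for substitutions or for non-GT..AG boundaries —
the intended inputs are same-assembly cDNA/genomic pairs — and an
unresolvable pair raises a structured error rather than a partial model.
An intron after `u` exonic nucleotides interrupts codon `u // 3 + 1` at
phase `u mod 3`; a CDS of `L` nucleotides encodes `L/3 − 1` residues
(terminal stop uncounted). Coordinates are 0-based half-open internally
and 1-based inclusive in GFF3 output.

## Expression

Atlas values are taken as given (EST-atlas style, normalized upstream).
A gene is organ-specific when its maximum over the chosen organ subset
falls in that organ; ties break by column order. No statistical test is
attached — the call mirrors how expression atlases are read qualitatively.

qPCR uses the ΔΔCt model: technical replicates are averaged per
biological replicate; ΔCt = Ct_target − Ct_reference per biological
replicate; ΔΔCt = mean ΔCt(treated) − mean ΔCt(control); fold = 2^−ΔΔCt.
Biological replicates are the statistical unit (standard ΔΔCt practice;
the aggregation order is otherwise underdetermined). Significance is an
optional two-sided Welch t-test on the per-replicate ΔCt sets, α = 0.05,
no multiple-testing correction — one target per experiment. The method
assumes perfect (2-fold per cycle) amplification efficiency for both
genes; efficiency correction is out of scope.

## Grouping

The distance between two proteins is 100 − percent identity, consistent
with the classification statistic. A neighbor-joining tree (scikit-bio)
is built over the full matrix; negative NJ branch lengths are clamped to
zero and lengths rounded to 6 decimals for stable Newick output. Groups
are obtained by deleting branches — internal branches longest-first, then
terminal ones — until the leaves fall into `k` non-empty components
(equivalently, all branches above a length threshold). Internal-first
ordering makes the first cut separate clades rather than split off the
single longest-branched leaf; ties break by the alphabetically first leaf
below the branch. This is a documented stand-in for likelihood/Bayesian
tree inference, which is out of scope: it reproduces the CaM/CML
two-group separation on synthetic cohorts but carries no support values.

## Synthetic data

The cohort generator emulates the census structure of a legume CaM/CML
family. The reference CaM is 149 residues with four canonical loops at
offsets 20/44/88/112 (pairs 1+2 and 3+4; inter-pair gap 32 exceeds the
linker bound, so pairing is unambiguous), Cys at loop-1 position 7, Lys
at residue 116, and 9 methionines (6.04%). CaM isoforms carry exact
substitution counts (2 → 98.66%) or one tail insertion plus 31
substitutions (150 aa, 118 identical aligned residues → 79.19%). The 19
CMLs follow the census row-by-row in loop count (total 55, including
lone hands, a two-separate-hands architecture and six −Z aspartate
loops), length (111–237) and planned identity (23.91–42.45%). Two CMLs
carry the myristoylation start. Decoys are background-only sequences
rejection-sampled below the 23% retention band.

Background residues are drawn from an alphabet without D, C, K or M:
since the grammar anchors on aspartate at position 1, no window outside
an implanted loop can match, making implanted-motif recovery exact at
every seed; the Cys27/Lys116/Met features likewise occur only where
placed. Conserved background positions (which tune identity toward the
planned value) exclude all reference loop regions, so no reference loop
can be re-created piecewise. Planned identities are realized as exact
identical-position counts under the intended gapless alignment; the
optimal alignment recovers a few additional coincidental matches, so
computed values run somewhat above plan (observed 24.8–51.1% over 30
seeds) while remaining strictly inside the (23, 60) band that separates
excluded, CML and CaM calls — family ground truth is unaffected.

Gene loci interleave GT..AG introns whose interiors are drawn from
{C, T} only, so no decoy GT/AG boundary can occur inside an intron. The
atlas generator plants organ-specific genes by multiplying one organ's
log-normal baseline by an effect size (default 10×). The qPCR generator
shifts the treated target Ct by −log₂(fold) and adds Gaussian noise per
technical replicate (default σ = 0.1, 3 biological × 3 technical
replicates, matching the emulated design).

What passing tests on these data do **not** show: robustness to
sequencing error, to degenerate natural loops that violate the grammar,
to spliced alignments with mismatches, or to qPCR efficiency differences.

## Problem sizes and numerical choices

Default test problem sizes: 100 seeded cohorts for motif recovery, 200
random loci for splice round-trips, 1000 qPCR simulations for fold
recovery, alignment-oracle cross-checks at lengths ≤ 12 (the memoized
Gotoh recursion is exponential-free but kept small so the oracle remains
visibly independent), NJ consistency on 4–8 leaf additive trees. All
percentages use decimal half-up rounding at two decimals, matching the
precision of the printed census this package mirrors. Degenerate inputs
(empty sequences, <12-residue proteins, single-replicate qPCR, k outside
[1, n]) raise or warn as documented per module rather than returning
sentinel values.
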