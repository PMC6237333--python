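# Methods

This note documents the models, conventions and numerical choices behind
mitochar, and what its synthetic-data validation does and does not show.

## Coordinate and annotation model

All coordinates are 1-based inclusive on the heavy (H) strand, the
convention of published mitogenome feature tables; GenBank's 0-based
half-open locations are converted at the I/O boundary. Light-strand (L)
features are stored with H-strand coordinates and reverse-complemented on
extraction, so every extracted gene reads 5'→3' in its own sense.
Origin-spanning (wrap-around) features are rejected: the canonical teleost
annotation places the control-region boundary at the origin, so none occur
in practice, and refusing them keeps gap arithmetic single-valued. Gene
names are normalized to lowercase symbols (nad1…nad6, nad4l, cox1–3, atp6,
atp8, cytb, trnX, rrnS, rrnL, OL, CR) via a synonym map covering common
GenBank spellings; duplicate serine/leucine tRNA labels are disambiguated
by coordinate order (first occurrence → 1), since printed tables do not
always carry anticodons.

## Architecture accounting

For consecutive features (sorted by start; last→first closed across the
origin when circular) the gap is `next.start − prev.end − 1`: negative
values are overlaps of |gap| bp, positive values spacers, zero abutting.
This pairwise rule assumes non-nested features; multi-way overlaps are
resolved by a per-position occupancy helper. Because the annotation marks
the light-strand replication origin (O_L) as a feature while the largest
"intergenic spacer" of a teleost mitogenome is exactly the trnN–trnC
interval that O_L occupies, the report always carries two views: O_L as a
feature (primary) and O_L excluded (under which trnN–trnC surfaces as a
38 bp spacer in the reference annotation).

## Composition and skew

AT skew = (A−T)/(A+T), GC skew = (G−C)/(G+C), computed on the H strand.
N bases are excluded from numerator and denominator; a zero denominator
yields an undefined (None) skew, never 0. Percentages are presented to
2 d.p. and skews to 4 d.p. (raw doubles are preserved in JSON). Codon
positions of the concatenated PCGs are assigned per codon within each gene
independently, so the 1–2 trailing nucleotides of an incomplete terminal
stop fall at positions 1(,2) and frames never leak across gene boundaries.

## Codon usage and RSCU

The vertebrate mitochondrial code (NCBI translation table 2) is taken from
Biopython: ATA→Met, TGA→Trp, AGA/AGG are stops, leaving 60 sense codons.
A CDS whose length is not a multiple of 3 ends in an incomplete stop (T or
TA, completed to TAA by transcript polyadenylation); those nucleotides are
classified as the stop, never as a codon. RSCU for codon c in a family of
k synonymous codons is k·n_c/Σn; families with zero total are reported
missing rather than 0 so absent amino acids cannot masquerade as avoided
codons. Initiation codons are excluded from the replication report's
counts by default (the convention of published mitogenome RSCU tables);
a flag includes them.

## Nei–Gojobori Ka/Ks

Classic NG86 with unweighted pathway averaging: no transition/transversion
weighting in the site or difference counts, because the analysis it
replicates names no weighting scheme. Site counting excludes stop-codon
neighbours from the per-position denominator, so s + n = 3 per codon
exactly. Difference counting averages over all orderings of the differing
positions, discarding orderings that pass through a stop; in the degenerate
case where every ordering is blocked, each position is classified
independently (logged). Codon columns containing gaps or ambiguity codes
are dropped pairwise. Jukes–Cantor correction is applied independently to
ps and pn; p ≥ 3/4 is reported as saturated, not clamped; Ks = 0 leaves
ω undefined, not infinite. ω estimates from the κ>1 simulations sit
slightly below their generating values — the known NG86 bias when
transitions (disproportionately synonymous) are accelerated — and the
recovery bands in the tests accommodate it.

## Control region and O_L

Motif scanning is Hamming-distance matching on both strands with
per-motif mismatch allowances. The shipped conserved-sequence-block
profile (CSB-F/E/D, CSB-1/2/3, TAS) contains conventional consensus motifs
from the comparative vertebrate control-region literature — it is a
user-replaceable default, not derived from any single genome, and block
calls should be read as candidate matches. The tandem-repeat finder
reports maximal exact arrays with primitive repeat units (copies ≥ 2,
fractional last copy allowed; nested reports suppressed, the longest
period kept on equal spans). It deliberately does not reproduce
alignment-scored repeat finders: the informative result for most
Beloniformes control regions is a clean negative, which an exact scanner
states exactly. The O_L check pairs the element's ends inward
(Watson–Crick + G·U, minimum loop 3 nt) and reports stem length, loop
length and paired fraction — a topology check, not thermodynamic folding.

## tRNA cloverleaf validation

Folding is an exhaustive search over the canonical cloverleaf layout only:
acceptor stem 6–9 bp (a few mitochondrial tRNAs extend to 9), DHU stem
0 or 3–4 bp (0 models the DHU-less serine tRNA of vertebrate
mitochondria), anticodon stem 4–6 bp with a fixed 7 nt loop, TΨC stem
4–5 bp, small inter-arm spacers and a 0–9 nt variable region. Every stem
position must pair (Watson–Crick or G·U on the DNA alphabet, U≡T); the
placement maximizing paired positions wins, ties broken by more acceptor
pairs, then fewer G·U pairs, then leftmost DHU arm. This is validation
against an architecture, not secondary-structure prediction; a sequence
whose true structure deviates from the grid (e.g. unusual loop sizes) will
either fold suboptimally or be reported unfoldable. One known asymmetry:
a G·U pair complements to A·C, so refolding a reverse-complemented gene is
not guaranteed to reproduce the paired count when wobbles are present.

## Phylogeny stage

The implemented inference is deliberately desk-scale: p, JC69
(d = −(3/4)ln(1−(4/3)p)) or K2P (d = −½ln((1−2P−Q)√(1−2Q))) distances with
pairwise deletion, Saitou–Nei neighbor joining (negative branch estimates
clamped to 0 and logged), and nonparametric bootstrap over alignment
columns (optionally stratified within gene partitions). Saturated distance
entries are flagged undefined and refuse NJ rather than being imputed;
saturated bootstrap replicates contribute no support. Heavier ML/Bayesian
inference is out of scope — the supermatrix can be exported as relaxed
PHYLIP or NEXUS (with a partition block) for external tools, and any
imported newick tree can be interrogated with the same monophyly
predicate. Concatenation uses the annotation-table gene order (recorded in
the partition map); the choice only relabels columns. Monophyly of a taxon
set is evaluated after rooting on a named outgroup; when false, the
predicate returns the intruding taxa inside the set's smallest containing
clade.

## Synthetic data: what it emulates

`generate_mitogenome` produces a circular, fully annotated genome in the
canonical vertebrate gene order with the canonical irregularities planted:
one GTG start (cox1), incomplete T stops on cox2/nad4/cytb, nad6 and eight
tRNAs on the light strand, one DHU-less serine tRNA, control-region motifs
at known offsets and an end-paired O_L hairpin. Feature lengths default to
the shipped reference annotation, so length bookkeeping mirrors a real
genome (≈16.5 kb, 39 features). Genome-wide skews are targeted by biased
base/codon sampling followed by A↔T / G↔C flips at free (rRNA, spacer,
non-motif CR) positions until both skews are within ±0.005 of target —
comfortably inside the ±0.01 recovery tolerance the tests assert. Codon
alignments evolve by exact per-codon Gillespie simulation with rate
multipliers κ on transitions and ω on nonsynonymous changes, stop states
forbidden, branch lengths in expected substitutions per codon at the
ancestor's neutral scale; matrix exponentiation is unnecessary at these
sizes and the event-level simulation is exact. All generators are
bit-reproducible under their seed.

What passing on synthetic data does **not** show: real mitogenomes have
rate heterogeneity across sites and genes, indels, compositional
non-stationarity across lineages, and annotation errors; the generators
produce none of these. Tests therefore certify the arithmetic and the
algorithms, not robustness to messy annotations.

## Problem sizes and defaults

Defaults used in the validation suite and acceptance script, chosen as
typical of the study system: 500-codon alignments with branch lengths 0.2
and κ = 2 for ω recovery (ω ∈ {0.05, 0.1, 0.5}); 50 random 5–10 taxon
additive matrices for NJ; 100 bootstrap replicates (the conventional
count); 200 bp strings for the tandem-scan oracle; ≤ 75 nt tRNAs for the
exhaustive folding oracle. Skew targets default to the reference genome's
values (AT +0.0307, GC −0.2899).

## Known limitations

* Wrap-around features and joined GenBank locations are unsupported.
* The CSB profile is heuristic; a real CSB call needs comparative
  alignment evidence.
* NG86 is a counting method: it underestimates ω under strong transition
  bias and saturates near p = 3/4; likelihood codon models are out of
  scope.
* NJ + bootstrap is a surrogate inference stage, not a replacement for
  model-based phylogenetics.
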