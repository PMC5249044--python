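# Methods

This note records how each statistic is defined, the conventions and
numerical choices behind the implementation, what the synthetic-data
generator does and does not emulate, and the design decisions taken where
more than one defensible convention exists.

## Coordinates and genome model

A genome is a (+)-strand DNA string over {A,C,G,T,N} plus an ordered list
of features. Internally all intervals are 0-based half-open; GenBank and
feature-table I/O use 1-based inclusive coordinates. Circularity is a
genome-level flag; a feature crossing the origin is stored with
`start > end` and normalized only at sequence extraction, so deposited
coordinates survive a read/write round trip unchanged. Gene labels are
canonicalized through a synonym dictionary (COI/CO1/COX1 → cox1, 12S →
rrnS, …); the two leucine and two serine tRNA isoacceptors are
disambiguated by anticodon (trnL1 = Leu-CUN/anticodon TAG, trnL2 =
Leu-UUR; trnS1 = Ser-AGN, trnS2 = Ser-UCN). Unknown labels are preserved
verbatim with a warning rather than rejected, since deposited annotations
vary. N bases (unsequenced stretches) are excluded from every count-based
statistic.

## Composition

AT-skew = (A−T)/(A+T) and GC-skew = (G−C)/(G+C); a skew whose denominator
is zero is reported as missing, not as 0. Per-gene and per-category skews
are computed on the coding-sense sequence, so mitochondrial strand
asymmetry appears as a sign flip between (+)- and (−)-strand genes; this
is a deliberate convention — computing on the (+) strand throughout would
hide the biologically interpretable flip. Sliding windows default to
100 b.p. at 10 b.p. steps; on circular sequences windows wrap the origin
so every start position is covered, on linear ones the last partial
window is dropped. Codon-position AT% pools position-1/2/3 bases over all
complete codons of a CDS set; the 1–2 trailing nucleotides of a
truncated-stop CDS lie outside any complete codon and are excluded.
Reported tables round skews to 3 decimals and percentages to 2 (the
conventional printed precision); JSON sidecars keep full precision.

## Codon usage and the effective number of codons

All codon statistics use the invertebrate mitochondrial code (translation
table 5: AGA/AGG = Ser, ATA = Met, TGA = Trp; stops TAA/TAG only). Usage
tables pool the complete in-frame codons of all CDS of a genome,
excluding stop codons and trailing partial codons. Start codons are
classified against the six observed mitochondrial initiators (ATA, ATG,
ATT, ATC, TTG, GTG); a CDS whose length is not a multiple of 3 is read as
ending in a truncated stop (T or TA), the post-transcriptionally
polyadenylated form.

Wright's Nc: per synonymous family with n codons and within-family
frequencies p̂, the homozygosity is F̂ = (nΣp̂² − 1)/(n − 1); Nc sums
N_k / mean(F̂) over degeneracy classes k. The family partition keeps Leu
(6 codons) and Ser (8 codons) whole — 12 two-fold, 6 four-fold, one
six-fold, one eight-fold family; 20 families, 62 sense codons — because
the whole-family reading of the code is self-consistent and makes the
one-codon-per-family limit exactly 20 and the uniform-usage limit exactly
62. The alternative 2+4 split of Leu/Ser used by some implementations is
available via `split_leu_ser=True`. Families with fewer than 2 codons
take the mean F̂ of their degeneracy class; a class with no measurable
family falls back to 1/k (its uniform-usage value); families with F̂ = 0
are treated as unmeasured (the standard guard against division blow-ups).
Nc is capped at 62. GC3s is the G+C fraction at third positions of codons
in synonymous families; under table 5 every amino-acid family is at least
two-fold, so the synonymous-only restriction (the default; an all-sites
option exists) only excludes stop codons.

## Nucleotide diversity

π is the plain mean over all C(n,2) sequence pairs of the per-site
difference fraction, after removing every column containing a gap or N in
any row (complete deletion). No (n/(n−1)) correction is applied. Both
choices follow the DnaSP π convention, the de facto standard for this
statistic; pairwise deletion is available as an option. The bundled
codon-aware aligner is a minimal star alignment (translate under table 5,
globally align each protein to the first sequence with match +1 /
mismatch −1 / gap −4, back-translate gaps as codon triplets); it is meant
for desk-scale homologous mitochondrial genes, and externally produced
alignments are first-class input.

## Gene order

A gene arrangement is reduced to a circular sequence of (label, strand)
pairs, linearized at an anchor (cox1) and reflected if necessary so the
anchor reads +; this makes the signature invariant under genome rotation
and whole-molecule reflection, the two symmetries of an unrooted circular
map. The reference is the pancrustacean ground pattern — the inferred
ancestral arrangement of the 37 genes plus control region — transcribed
once as a versioned constant (`GROUND_PATTERN_VERSION`).

Comparisons are restricted to the labels both arrangements share
(duplicated copies beyond the first, or genes missing from partial
genomes, are reported separately and excluded from the distance). The
breakpoint count is the number of signed circular adjacencies of one
arrangement absent from the other, with an adjacency a→b identified with
b̄→ā; with equal label sets this count is symmetric and satisfies the
triangle inequality. "Translocated" is operationalized as: both
strand-blind flanking adjacencies of the gene are absent from the
reference. This recovers exactly the moved gene for single-gene
translocations and deliberately excludes in-place inversions (which are
reported in the separate `inverted` set as sign flips). A gene inverted
at the anchor position is indistinguishable from "everything else
inverted" on a circular signed order, so the anchor is never a useful
inversion target; the synthetic generator avoids it.

## tRNA duplication and remolding

Pairwise identity comes from global (Needleman–Wunsch) alignment with
match +1, mismatch −1, linear gap −2, and a deterministic traceback
preferring diagonal, then a gap in the second sequence; identity =
matches / alignment columns, reported to 2 decimals. One property of this
scoring worth stating explicitly: for two equal-length sequences
differing by k substitutions, the identity equals (L−k)/L only while no
gapped alignment can out-score the ungapped one; at high divergence
(roughly below ~75% for 64-mers) the optimal gapped alignment can
legitimately report a somewhat higher identity. The exhaustive-enumeration
oracle in the test suite confirms the DP is exact either way.

Remolding calls: every copy of a duplicated tRNA label is aligned against
all other tRNA genes of the genome. If the best non-self donor reaches
65% identity the label is a remolding candidate (the duplicate's sequence
is better explained by a non-cognate isoacceptor); otherwise, if the
copies' mutual identity reaches 85% — or exceeds every donor identity —
the pair is a recent duplicate; anything else is ambiguous. The
donor-existence criterion, not the within-pair threshold alone, is what
separates the two calls: a 75%-identical pair with no qualifying donor is
still best explained by a single-gene origin. Both thresholds are
configurable.

## Control-region detection

Candidate regions are the maximal unannotated intervals between features
(circular closure included); regions the input annotates as CR are
reported alongside, flagged. Each region of ≥ 50 b.p. is scanned per
contiguous N-free block for four feature classes with these defaults:

| feature | default | rationale |
|---|---|---|
| poly-T run | ≥ 10 b.p., either strand | smallest run treated as diagnostic in invertebrate CRs |
| tandem repeat | seed 12 (capped at the period), period 10–200, ≥ 2.0 copies, ≥ 80% adjacent-copy match | separates real repeats from chance k-mer matches at CR scale |
| hairpin | perfect stem ≥ 6 b.p., loop 3–30 nt | shortest stem stable enough to matter, no thermodynamics implied |
| AT excess | ≥ 5 points over genome AT% | conservative cut for "AT-rich" against typical within-genome spread |

The score is the unweighted count of classes present (0–4): the relative
importance of the four features is not quantified anywhere we trust, so
transparency beats a fitted weighting; candidates sort by score, then
length. Overlapping tandem-repeat calls are merged keeping the call with
the most copies (then longest span, then smallest period): the 2× period
harmonic of a true repeat spans as long as the fundamental but has half
the copies, so a span-first rule would report harmonics. Hairpin
detection enumerates maximal perfect stems only; wobble pairs and folding
energies are out of scope.

## Synthetic-data generator

The generator emulates the statistical structure of an amphipod-like
mitogenome under controlled, recoverable conditions. Defaults are the
emulated study conditions: genome ≈ 15.5 kb, AT fraction 0.65, (+)-strand
AT-skew 0, GC-skew −0.30, codon-position AT targets (0.55, 0.62, 0.80)
(third positions most AT-rich), ground-pattern gene order, typical
per-gene lengths, 64 b.p. tRNAs, a 700 b.p. control region carrying a
13-T run, a 51-mer tandem repeat × 4 at 2% copy noise, an 8/6 hairpin and
+8 points AT excess, and 10 b.p. inter-gene spacers.

Base probabilities solve the targets exactly: for AT fraction f and skews
s_AT, s_GC, p_A = f(1+s_AT)/2, p_T = f(1−s_AT)/2, p_G = (1−f)(1+s_GC)/2,
p_C = (1−f)(1−s_GC)/2. Protein-coding genes are sampled codon-structured
on their coding sense (start codon uniform over the six initiators, stop
TAA/TAG, interior codons i.i.d. per position distribution), so the pooled
PCG coding-sense composition realizes the targets in expectation; the
exact expected counts — including the planted start/stop contributions —
are recorded in the ground truth as the reference for recovery checks.
Interior in-frame stop triplets are not resampled: any avoidance rule
measurably biases the planted composition (position-wise rejection
depresses position-1 AT by ≈ 2 points; third-base redraws depress AT-skew
by several SE), and downstream codon statistics exclude stops from counts
regardless. Synthetic CDS are therefore not translatable ORFs — a
documented departure from real coding sequence. All other elements
(tRNAs, rRNAs, spacers) are sampled directly on the (+) strand, so
(−)-strand PCGs reproduce the real flipped-skew strand structure while
non-PCG elements carry the genome-wide composition.

Duplicated tRNAs are copy-and-mutate products: substitutions (never
indels) are added one at a time until the package's own identity measure
reaches the target within ~1 point — the literal reading of "duplicate at
X% identity" under the gapped-identity definition above. A relabelled
duplicate (copy of trnX annotated as trnY) is the remolding scenario; the
planted copy always numbers after the original in `copy_index`.
Translocation edits move a gene to a stated index; the randomized spec
generator additionally guarantees the new neighbourhood shares no gene
with the old one, since an adjacent-slot "move" rearranges nothing.

Alignments are star trees: every taxon mutates independently from one
ancestor with per-site substitution probability q, each hit replaced
uniformly by another base. Two taxa then differ at a site with
probability 2q − (4/3)q², giving q = (3 − √(9 − 12p))/4 for a target
pairwise difference p ∈ [0, 0.75]. The star topology is deliberate: π is
a summary statistic whose estimator should be exercised without
phylogenetic correlation confounding the planted value. Consequences:
synthetic alignments carry no rate heterogeneity across sites or genes,
no indels, no codon-position rate structure, and no tree shape — recovery
of π here shows the estimator is correct, not that real aligned data meet
its assumptions.

Determinism: one `numpy` Generator seeded from the spec drives all
sampling; identical (spec, seed) gives byte-identical genomes, features
and ground truth.

## Problem sizes

The shipped test suite and acceptance script run on full-size genomes
(~15.5 kb, 38+ features): a 10-genome cohort for the cross-genome
statistics, 20 randomized genomes for ground-truth recovery, alignments
of 10 taxa at gene length (156–1536 b.p.), brute-force oracles at their
tractable scales (alignments ≤ 10×200 for π, signatures ≤ 12 genes for
breakpoints, sequences ≤ 8 nt for exhaustive alignment enumeration,
1 kb for hairpin enumeration). These sizes give every binomial check
standard errors an order of magnitude below the planted effects while the
whole suite runs in well under a minute.

## Known limitations

- Annotation is an input, never inferred: no ORF finding, no tRNA
  structure prediction, no de novo CR boundary calling (a candidate's
  extent is the unannotated interval, not a refined boundary).
- Breakpoint distance reports dissimilarity, not a rearrangement
  scenario; event inference (DCJ/HP sorting) is out of scope.
- The remolding call is sequence-level evidence only; it does not model
  anticodon positions or functional acceptance by the translation
  machinery.
- The sliding-window module does not infer replication origins from
  cumulative skew.
- The statistical recovery tolerances (±3 SE style checks) are per-target
  bands; across many simultaneous checks occasional boundary misses are
  expected by construction, and the suite surfaces them rather than
  correcting for multiplicity.
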