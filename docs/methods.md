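# Methods

This note documents the models, heuristics and numerical choices behind
arrestscan, what the synthetic data generator does and does not emulate,
and the known limitations.

## The screening model

Monitoring substrates share an architecture imposed by their mechanism: a
ribosome stalled near the 3' end of the ORF must still present the
N-terminal targeting signal outside the exit tunnel, and the arrest
sequence must be conserved wherever the regulatory circuit is conserved.
The screen operationalizes this as five testable criteria per upstream
ORF (c1 proximity, c2 size 80–200 aa, c3 topogenic signal, c4 exposed
domain ≥ 40 aa, c5 C-terminal conservation). All five are binary; the
screen deliberately performs no ranking or scoring beyond them, and no
multiple-testing machinery applies because each criterion is a
deterministic rule, not a statistic.

### Target-gene location (c1 context)

Targets are found by case-insensitive, token-based keyword matching
against gene names and `product=` annotation (yidC/oxaA/spoIIIJ; secDF;
secD; secF; secY; secE; secA; secG). A token matches a keyword exactly or
with a trailing paralog digit (`yidC2`), never as a substring, and when a
gene matches several classes the longest matched keyword wins, so a fused
`secDF` gene is reported once as class secDF rather than as secD and
secF. Genomes in which no target is found silently drop out of the
screen — incomplete annotation is expected and is not an error.

### Upstream ORF enumeration (c1, c2)

The finder scans the 1000-nt window 5' of the target start on the
target's strand. An ORF must begin with ATG/GTG/TTG (all translated as
Met, genetic code table 11), end with a stop codon inside the window, and
end within 500 nt of the target start. "No assigned function" is
approximated by "overlaps no annotated gene by more than 30 nt"; the
tolerance admits the small operonic overlaps real uORFs show.
Among nested ORFs sharing a stop codon, the longest one passing the size
and overlap filters is kept — internal initiation is not modelled.
Windows truncated by a contig edge are flagged, not rejected. The
implementation is verified against a brute-force six-frame enumerator
that applies the same filters independently.

For *reporting*, the screen enumerates with relaxed bounds (minimum 40
aa, window 3000 nt) and then grades c1/c2 against the screening bounds;
otherwise an ORF failing c1 or c2 could never appear in the results
table. The relaxed bounds affect only which failures are visible, never
which candidates pass.

### Topogenic-signal heuristic (c3)

TMHMM/SignalP-class predictors are replaced by a transparent hydropathy
rule, because the screen uses the prediction only as a binary gate plus a
boundary. Windowed Kyte–Doolittle means (defined only where the full
window fits) are thresholded:

* **TM**: a run of ≥ 15 residues with window-19 mean ≥ 1.6 whose first
  residue lies within the first 45 residues;
* **SS**: otherwise, ≥ 1 Lys/Arg in the first 5 residues (n-region) and a
  run of ≥ 7 residues with window-7 mean ≥ 2.0 (h-region) starting within
  the first 35 residues.

`signal_end`, the last residue of the detected run, anchors the exposure
computation; the TM/SS label itself is provenance only — both satisfy
c3. Thresholds follow common hydropathy-analysis practice and are
config-exposed (`topology:`). The run *start* is bounded by the search
limit; the run end may pass residue 45 (a long TM beginning at residue 35
is still an N-terminal signal). Cleavage-site prediction and membrane
topology orientation are out of scope: no criterion consumes them.

### Exposure (c4)

`exposed_len = len(protein) − signal_end`, pass iff ≥ 40 (the comparator
is config-exposed; the strict `>` reading is available). When c3 fails,
the whole chain counts as exposed — c4 then reflects only length, so a
"no signal" candidate fails c3 alone and per-criterion attribution stays
clean.

### Conservation (c5)

Candidates from the whole panel (optionally restricted to the same
target class) are clustered by single linkage: two candidates link when
the identity of their globally aligned C-terminal 30-mers is ≥ 0.35.
Alignment is Needleman–Wunsch with Gotoh affine gaps (match +2, mismatch
−1, gap −5 for the first residue and −1 for each further one;
deterministic diagonal > up > left traceback). Singleton clusters are
dropped: conservation is undefined for one member, so a panel of one
genome can never satisfy c5.

Each group is scored over the last 30 columns of a reference-anchored
alignment (members aligned to the longest member; insertions relative to
the reference dropped; short members padded with leading gaps). The
per-column statistic is the modal-residue fraction with gapped members in
the denominator — a missing C-terminus is evidence *against* conserved
arrest function — matching the completely/highly-conserved rendering
conventions of published alignments; a Shannon-entropy alternative is
available. An `anchor_motif` option right-justifies members on a motif
instead of aligning, reproducing manual motif-anchored alignments.

c5 passes when the group's mean conservation is ≥ 0.7 **and** the
member's own mean pairwise column agreement with the rest of the group is
≥ 0.7. The second condition exists because single linkage is fragile at
the identity threshold: a 2-member chance pair at identity ≈ 0.4 already
reaches a modal-fraction mean of 0.7 (mismatched columns still score
0.5), and an unrelated sequence chance-attached to a large conserved
family would otherwise inherit the family's high mean. Member agreement
is 1.0 within an identical family, ≈ (1 − divergence)² within a diverged
one, and ≈ raw identity for an attached outlier, so it separates exactly
the failure case. The 0.35/30-column/0.7 defaults are this package's
operationalization of "mutually conserved, judged by alignment" and are
config-exposed (`align:`).

## Arrest-site analyses

**Toeprint mapping.** Reverse transcriptase stops 15–17 nt downstream of
the first nucleotide of the P-site codon of a stalled ribosome. Because
that window equals the codon size, the mapper returns the full candidate
codon set — `{(stop − o − start) // 3 + 1, o ∈ 15..17}` — and declares a
consensus only for singletons, which occur exactly when the stop is 17 nt
from a codon's first nucleotide. Offsets reaching upstream of the ORF
start are clipped (only relevant for initiator-codon stalls); replicate
bands combine by set intersection, with an empty intersection an error
and a multi-codon intersection a warned "undefined". Whether the stop
nucleotide itself counts as +0 or +1 in trace reading cannot be audited
from published electropherograms; the convention `stop = first_nt +
offset` is fixed here and the window is config-exposed.

**Motif scan.** All (overlapping) occurrences of Arg-Ala-Pro-(Gly|Pro)
with 1-based inclusive coordinates. The motif's final residue is the
A-site residue of the stalled ribosome in the characterized peptides.

**Internal frameshift design.** Delete the first nucleotide of codon
*f*, insert one nucleotide (by default the deleted one; the choice is
config-exposed) after codon *l*: codons *f..l* are scrambled, everything
else — length, flanks, downstream frame — is untouched. Each shifted
codon reads the last two nucleotides of an original codon plus the first
nucleotide of the next (or the insert), so a shift-created stop is
repaired by a synonymous change to the codon contributing its first two
nucleotides, falling back to the following codon, choosing the synonym
with the fewest nucleotide changes (then lexicographically), and
re-checking from scratch. Some junctions are genuinely unfixable — an
ATG (no synonym) followed by a codon whose synonyms all begin with A
(Ile/Thr/Lys/Asn/Met) always shifts to TGA — and raise a `DesignError`
naming the codon; in practice one then chooses a different segment
boundary, which is how the test harness and acceptance script proceed.

**Synonymous block.** Every codon in the block is replaced by its
synonym of maximal nucleotide Hamming distance (ties broken
lexicographically); Met/Trp stay with a warning. Translation invariance
is by construction and property-tested.

**Reporter classification.** Fold = mutant/wildtype mean
β-galactosidase activity; ≥ 3-fold is arrest-deficient, ≤ 1/3 is flagged
arrest-enhanced. Means only: published values are mean ± SD with n = 3
and no hypothesis test, so the SD is carried for reporting but not
tested on.

## The synthetic panel generator

The generator emulates the statistical structure the screen assumes, not
bacterial genomes at large. Each genome is a concatenation of blocks
([spacer, in-frame stop insulator, ORF, gap, annotated 900-nt target
gene, spacer], plus filler genes and intergenic sequence at configurable
GC). Planted families share a hydrophilic 30-residue C-terminal tail
containing R-A-P-[G/P] (placed so the motif ends 3 or 5 residues before
the C-terminus, mirroring the 108/102–105 and 128/120–123 layouts of the
characterized peptides) and get per-member signals: TM = Met + 2 charged
+ 30 hydrophobic residues, SS = Met + 2 charged + 12 hydrophobic, drawn
from {L,I,V,F,A} weighted 35/25/20/10/10. Hydrophilic stretches come
from a 12-letter alphabet whose only positive-hydropathy residue (Ala)
is capped at runs of 4, which provably cannot reach either detector
threshold — so "no signal" decoys can never sprout accidental signals.
Proteins are reverse-translated with codons drawn uniformly over
synonyms *independently per genome*: homologous proteins are conserved
while their CDSs diverge at synonymous sites, which also decorrelates
reading-frame artifacts across genomes. One family is planted on the
forward and one on the reverse strand to exercise strand handling.

Six decoy classes each violate exactly one rule: `short` (60 codons),
`no_signal` (hydrophilic N-terminus), `short_exposure` (hydrophobic run
placed so the exposed tail is ≈ 30 residues), `scrambled_tail` (fresh
random tail per genome), `wrong_strand` (antisense placement, hence
never enumerated), `far_from_target` (stop 2 kb upstream). Decoy
families are planted across all genomes so they *pass* the conservation
criterion and fail only their own. A JSON truth manifest records every
planted coordinate, protein, signal span and motif position; generation
is byte-reproducible from the seed (numpy PCG64).

What passing on these panels shows: the pipeline implements its stated
rules exactly, with per-criterion attribution, on data satisfying the
screen's assumptions. What it does not show: performance on real
genomes, where annotation keywords are noisy, homolog divergence is
phylogenetically structured rather than i.i.d., hydropathy heuristics
disagree with HMM predictors near their thresholds, and conservation
judgements are confounded by alignment quality. The generator has no
phylogeny (i.i.d. substitutions only), no codon-usage realism, and no
mRNA secondary structure.

## Problem sizes and numerics

The shipped tests and the acceptance script use a 10-species panel with
2 planted families (5 members each) and all 6 decoy classes; 100 random
5-kb contigs for the ORF-finder/oracle comparison; codons 1–200 × offsets
15–17 for the toeprint round trip; and 1000 random CDSs for the design
invariants — sizes at which every check runs in seconds to tens of
seconds on one CPU while exercising all code paths. Alignment identity
is matches over alignment columns; all tie-breaks (alignment traceback,
modal residue, synonym choice, cluster roots, group ids) are
lexicographic so that results are order- and platform-independent, which
the permutation- and determinism tests assert. The in-house aligner's
optimal scores are cross-checked against Bio.Align.PairwiseAligner under
identical scoring in the test suite; the package itself never calls it.

## Known limitations

* Keyword-based target location inherits annotation quality; a
  sequence-similarity fallback is deliberately out of scope.
* The hydropathy heuristic has no positive-inside rule, no cleavage-site
  model, and fixed windows; borderline real signals will disagree with
  HMM-based predictors.
* Conservation is scored on a reference-anchored alignment, not a full
  MSA; for small, C-terminally anchored groups this is adequate, for
  deep families a dedicated MSA tool would be preferable.
* Internal translation initiation within candidate ORFs is not modelled;
  the longest-ORF-per-stop rule reports a single start per stop.
* The toeprint mapper does not model sequencing-ladder context, so
  two-codon ambiguity at offsets 15–16 is surfaced rather than resolved.
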