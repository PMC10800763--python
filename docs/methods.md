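# Methods

## Coordinate conventions

All sequences are stored on the sense strand, 5′→3′, with 0-based
half-open coordinates; transcript-style 1-based c. positions exist only in
documentation. For a sense C>T variant the editable adenine lies on the
antisense strand, and *downstream on the antisense strand* means
*decreasing* sense coordinate: a bystander *k* positions downstream of the
target maps to sense offset `variant_offset − k`. At the *PAH* locus this
yields the documented geometry — the +1 adenine is the synonymous CCT→CCC
position, +5 is the Ile406Thr position (ATA→ACA), and −6/−7 are the two
Phe410 adenines (TTC→CTC/TCC singly, TTC→CCC jointly).

Protospacers are numbered 1 at the 5′ (PAM-distal) end; the PAM occupies
positions 21–23 immediately 3′. Only the strand carrying the target
adenine is searched for protospacers, since ABE correction requires the
target A on the protospacer strand.

## The PAH locus fixture

The package ships a 45-nt sense slice covering codons 400–414 of the *PAH*
coding sequence with the reading frame anchored at codon 406. It is a
**synthetic reconstruction**, not a RefSeq extract, but it is pinned
almost everywhere by published facts: codons 406 (ATA), 407 (CCT), 408
(CGG, TGG in the patient) and 410 (TTC) are the published identities, and
the six published guide PAMs (AGC, GCA, CAA, AAA, AAG, AGT) sit at
consecutive antisense placements (target at protospacer positions 8 down
to 3), which determines sense c.1202–c.1210. The remaining codons are free
choices kept free of sense-strand T near the editing window so the locus
has exactly the four documented non-target antisense adenines at offsets
−7, −6, +1, +5. `build_pah_fixture` accepts any caller-supplied
codon-aligned slice instead, validates it against the published codons
(failing loudly and naming the codon on contradiction), and surfaces any
unexpected antisense adenine in codon 409 as a warning rather than
dropping it.

## Editor models

PAM profiles are ordered IUPAC 3-mer lists with activity tiers: SpCas9
{NGG preferred; NAG, NGA tolerated}, iSpyMac {NAA preferred}, SpG {NGN
preferred}, SpRY {NRN preferred, NYN tolerated}. SpRY is encoded with a
purine preference at position 2 rather than as literally patternless so
that tier reporting stays meaningful. Editing-window defaults are
ABE7.10 4–7, ABE8e 3–9, ABE8.20 3–9, ABE8.8 4–8. The published record
gives only a qualitative breadth ordering (ABE8e broadest, ABE8.8
narrowest); these numerals are configuration defaults chosen to respect
that ordering, overridable from the CLI (`--window-override`), and tests
avoid hard-coding window biology beyond the locus worked examples.

Note that on this locus SpCas9 has *tolerated*-tier (NAG) placements with
the target in the broad window; what the geometry excludes is any
NGG-adjacent placement, and the tests assert exactly that.

Ranking of candidates is deterministic and purely geometric: fewest
nonsynonymous in-window bystanders, then target centrality within the
window, then PAM tier, then lexicographic protospacer. No editing
efficiency is predicted; the score components are reported so users can
apply their own weighting.

Bystander consequences are single-edit codon changes evaluated on the
corrected background (the clinically relevant comparison once the target
is fixed). Joint multi-edit consequences are evaluated at classification
time, not design time.

## Read classification

Reads are aligned to the patient-allele amplicon with Biopython's
`PairwiseAligner` (match +2, mismatch −1, gap open −5, gap extend −1,
free end gaps on both sequences); both orientations are tried and the
better score kept, ties favouring the forward read. Of equal-scoring
alignments the first in Biopython's deterministic enumeration is used;
tests check score optimality against an independent affine-gap DP rather
than Biopython-internal tie order.

Classification priority: **discarded** (alignment identity < 0.6, window
not covered, or non-edit mismatches exceeding 30% of window positions) →
**indel** (any gap overlapping the quantification window) → corrective
categories → **bystander_only** → **unedited**. The quantification window
defaults to the protospacer footprint plus a 5-nt flank. An antisense A→G
edit presents as a sense T→C. *Correction only* is computed, not
hard-coded: a read whose joint in-window edits translate to the corrected
wild-type peptide is correction-only, which generalizes the
adjacent-synonymous-adenine exception to any locus. Proportions are
reported over retained (non-discarded) reads. Base-quality filtering is
off by default (the simulator emits constant Q37); thresholds are exposed
as flags.

The identity floor, window-mismatch fraction and flank width are declared
defaults in the spirit of CRISPResso-style amplicon quantification, not
values inferred from any particular dataset.

## Dose-response fit

`fit_dose_response` fits the four-parameter logistic
`y = floor + (ceiling − floor) / (1 + (EC50/x)^h)` by least squares on
log dose (scipy `curve_fit`, Levenberg–Marquardt, log-EC50
parameterisation so EC50 stays positive, iteration cap 20,000).
Initialization uses the response extremes and the dose bracketing the
half-maximal response interpolated on log dose. Degenerate input
(constant responses) and non-convergence return a diagnostic failure
object, never a silent result. Fits with `floor > ceiling` are normalized
by swapping asymptotes and negating the Hill slope (an equivalent
parameterisation).

## Off-target scanning

Admission rule: mismatches ≤ 2 with no bulges, or mismatches ≤ 1 with at
most 2 bulges, no PAM constraint (the 3′ trinucleotide is reported for
inspection only). Each bulge is a single-nucleotide gap — a DNA bulge is
an unpaired genomic base, an RNA bulge an unpaired spacer base; bulges are
counted, not measured; two bulges may be adjacent or split and may sit on
either molecule. Bulges are **interior-only**: the first and last spacer
bases must pair, since a terminal bulge is indistinguishable from a
shifted alignment. A spacer base opposite a gap is a bulge, never also a
mismatch. Mismatch counting excludes bulge positions.

The scanner enumerates every bulge placement ("shape": 723 placements at
≤2 bulges) and evaluates all genome windows per shape with vectorized
byte comparisons, on both strands; windows containing N are skipped and
counted. Overlapping admissible placements on the same strand are merged
keeping the best accounting (fewest total edits, then fewest bulges, then
leftmost). The independent oracle (`exhaustive_dp_ends`) is a layered
semi-global dynamic program stratified by gap count with the same
interior-bulge restriction; scanner and oracle are different algorithms
for the same admission rule and are required to agree exactly in tests.
Runtime is linear in genome length at fixed criteria (~0.2 s per 20-kb
strand pair per spacer).

Published off-target site *counts* for any particular guide are not
reproduced: they depend on the reference build and the semantics of the
external nomination tool.

## Synthetic data

The read simulator emulates amplicon sequencing of an edited cell
population: per read it samples a category (defaults 60% correction-only,
12% unwanted bystander, 5% bystander-only, 3% indel, 20% unedited),
builds the corresponding haplotype (corrective sense T→C; a synonymous
co-edit on half of corrective reads; one uniformly chosen nonsynonymous
protospacer bystander for unwanted/bystander-only; a 1–3-nt deletion
inside the protospacer for indels), overlays iid substitution error
(default 0.1%) and emits FASTQ at constant Q37, half of the reads
reverse-complemented. Truth tables are complete and the output is
byte-identical for a fixed seed. It does **not** model quality decay,
context-dependent error, indel sequencing errors, PCR duplicates or UMI
structure — so passing tests demonstrate correctness of the
classification logic under a clean error model, not robustness to every
real-world artifact.

The genome simulator plants spacer near-matches at stated
mismatch/bulge configurations into iid background sequence.
Negative-control sites (configurations outside the admission criteria)
are re-checked *in genomic context* (site plus 25-nt flanks, both
orientations) and resampled until no admissible alignment overlaps the
planted span; without this, a random substitution choice can accidentally
admit an alternative alignment and the control would not be a control.

## Problem sizes and numerical tolerances

The test suite and acceptance script use: 10,000-read mixtures for
classifier recovery (exact agreement at zero error; 3 binomial standard
errors at 0.1% error), five random spacers against 20-kb planted genomes
for scanner/oracle equivalence (exact), noiseless 4PL recovery to 1e-6
relative error and σ=2 noisy recovery within 10% (EC50 truth 750 on the
fg/cell dose scale; the acceptance script reports the mean EC50 over five
independent noisy experiments, the estimator a replicated bench
experiment would report), and exact floored-mean-difference net-editing
arithmetic (0.25% vs 0.14% arms → 0.11%). These sizes were chosen so the
whole suite runs in well under a minute on one CPU while leaving binomial
noise small relative to the tolerances.

## Known limitations

- Guide ranking is geometric; it does not model deaminase sequence
  preferences, chromatin state, or measured editing efficiencies.
- Single-exon, single-frame loci only; no HGVS parsing, no splice
  awareness.
- The bundled PAH slice is a constrained synthetic reconstruction; users
  wanting the exact RefSeq sequence should supply their own slice to
  `build_pah_fixture`, which will validate it.
- Off-target scanning supports at most two bulges (matching the admission
  rule it implements); aggregate risk scores (CFD/MIT) are out of scope.
- Paired-end merging, UMI handling and gRNA-independent deamination are
  out of scope.
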