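# Methods

## Sequence model

Coordinates are 0-based, half-open, plus-strand internally; residue numbers
are 1-based in every user-facing report. Plasmids are circular by default and
all slicing wraps modulo length; an ORF may span the origin. Ambiguity codes
are rejected on input (design on ambiguous bases is meaningless);
soft-masked FASTA is uppercased. The enzyme registry covers the two type-IIS
enzymes the workflow uses — BsaI (GGTCTC) and BsmBI (CGTCTC), both cutting
1 nt downstream of the recognition site with a 4-nt 5' overhang — and is
exportable as JSON; other enzymes can be added but are untested.

Silent codon swaps pick replacements from a shipped human codon-usage table
(descending usage; ties broken by GC content, then alphabetically). A swap is
accepted only if it removes every banned-motif match overlapping the codon in
its local context; single-codon residues (Met, Trp) fail loudly rather than
silently keeping a site.

## Melting temperatures and primer specificity

Duplex Tm is computed as ΔH/(ΔS + R·ln(C/x)) − 273.15 from nearest-neighbor
sums under two parameter sets shipped as versioned TSV data (a Sugimoto-style
table and a SantaLucia–Hicks-style unified table), with the entropic salt
correction 0.368·(N−1)·ln[Na+] applied to both. Default conditions are
500 nM total oligo and 50 mM monovalent salt; both are configurable and both
model estimates are always exported. Because the source workflow sets the
window "between 55 °C and 61 °C" from both calculations without saying how
they are combined, the accept/reject statistic here is the mean of the two
estimates — a single decidable rule.

Off-target annealing is modeled on what licenses spurious PCR extension: at
every register on both template strands (circular where applicable), the
longest contiguous exact match anchored at the primer's 3' end (minimum
6 nt) is scored as the Tm of that matched stretch; a primer is non-specific
if any such hit outside its intended footprint exceeds 35 °C (strictly).
Specificity contexts follow the amplification reactions: backbone primers
are scanned against the plasmid, subpool primers against the entire oligo
pool and the plasmid. Hairpins, primer dimers and divalent-cation
corrections are out of scope.

## Fragmentation and overhangs

The ORF is divided into K fragments, consecutive fragments sharing exactly
one codon, sized as evenly as possible to the nearest codon. The per-oligo
overhead is 62 nt (2×12 barcodes, 2×7 BsmBI sites including the frame base,
24-nt handle), leaving a 168-nt gene payload for 230-nt synthesis. Each
boundary overhang is the boundary codon plus the following wildtype base, so
one extension base rides inside the payload and the fragment cap is
⌊(168−1)/3⌋ = 55 codons. Overhangs must be pairwise distinct, distinct from
each other's reverse complements, and non-palindromic (palindromes
self-ligate). Clashes are resolved by moving boundaries whole codons, greedy
outward search (±1, ±2, …, ±10), leftmost boundary first; if the minimal
fragment count leaves no slack to move any boundary, the plan is re-made
with one more fragment and re-balanced. Gene ends cannot move; a clash there
(e.g. a homopolymeric gene) is an explicit infeasibility error naming the
boundary. Ligation-fidelity optimization against empirical ligase bias
tables is out of scope.

## Handle and oligo layout

The genetic handle is `linker5 | GAGACC | GGTCTC | linker3` — two
outward-facing BsaI sites whose cut windows land wholly inside the linker
codons, so the handle can be excised and replaced by any in-frame domain
while leaving the linkers as the only scars. Linker codons are chosen by
codon-usage rank subject to: exactly two BsaI sites, no BsmBI site, and
distinct, non-palindromic, non-complementary cut windows. With the default
Ser-Gly / Gly-Ser linkers the handle is exactly 24 nt and translates in
frame.

Each oligo reads `fwd barcode (12) | CGTCTC | frame base | payload | frame
base | GAGACG | rev barcode (12)` where the payload is the fragment sequence
plus one extension base with the handle inserted between two codons. The
frame base is the N1 spacer that puts the BsmBI cut window exactly on the
boundary overhang; it is 'A' unless that creates a banned motif, then 'T'.
Insertion positions run from after the fragment's second codon to before its
last codon — the first and last codons are the cloning cut sites — so a
fragment of L codons yields L−2 oligos and the junction after each shared
boundary codon is structurally unreachable (inserting there would destroy
the wildtype overhang). For a gene of N codons with K fragments the designed
set is therefore {2, …, N−1} minus the K−1 boundary junctions; this is the
designed-coverage analogue of the near-complete (not literally complete)
coverage such libraries show.

Backbone primers amplify the whole plasmid minus the fragment interior. The
5' end of each annealing region is pinned to the fragment overhang (the
non-annealing tail adds an inward-facing BsmBI site plus spacer); only the
3' length is tunable, searched from 12 to 35 nt, first length satisfying
both the Tm window and specificity wins. Twelve is deliberately below the
usual 18-nt PCR floor: with a pinned 5' end, a GC-rich boundary whose 18-mer
already exceeds 61 °C has no other remedy, and short primers are only ever
accepted when they still reach 55 °C (i.e. extreme-GC stretches). If no
length works, the fragmented site itself is shifted by whole codons
(bounded, never revisiting a tried position) and the neighbors are
redesigned. Subpool primers anneal across barcode + BsmBI + cut window with
the 3' end fixed at the window; the 5' end is tuned, and infeasibility is
resolved by swapping the barcode.

Barcodes are seeded rejection samples: 12-mers, GC-balanced (5-7), pairwise
Hamming distance ≥ 4, and free of BsaI/BsmBI motifs both alone and joined to
their constant oligo flanks. A user-supplied list is accepted in place of
generation and validated against the same invariants.

## Final quality control

The pool-level QC loop alternates two passes until a fixed point (bounded,
with every intervention recorded): (1) any BsaI/BsmBI site beyond the four
designed ones is removed — by a silent swap of a gene codon overlapping the
site (never a boundary-overhang codon, never the handle), by flipping the
frame base, or by replacing a barcode when the site spans a barcode
junction; unresolvable sites are reported as failures, never silently kept.
(2) every subpool primer is re-scanned against all oligos and the plasmid;
non-specific primers trigger a barcode replacement (deterministic: next
unused barcode) and the loop repeats. The design as a whole is a pure
function of (plasmid, configuration, barcode list/seed).

## Assembly simulation

Digestion fragments are represented on the top strand with both terminal
4-mers included, so a type-IIS cut leaves the overhang text on both product
fragments and ligation merges the shared 4-mer. Ligation requires exact 4/4
complementarity — this is a design-verification oracle, not a fidelity
model — and enumerates circular products of up to three distinct parts in
either orientation; products retaining an intact recognition site are
flagged re-cuttable, as in a real one-pot reaction. Pool verification runs
both cloning steps per oligo: BsmBI assembly of the digested oligo with the
simulated inverse-PCR amplicon must equal the target-with-handle (built from
the oligo's *designed* payload, so QC codon recoding is honored), and BsaI
replacement with a domain amplicon must give the in-frame domain insertion;
mismatches report the first divergent base after rotational alignment.

## Library statistics

Normalized insertions per residue are v_i = (r_i/t)·N, averaging exactly 1.
Bias is compared by the two-sample Kolmogorov–Smirnov statistic (SciPy,
asymptotic p; exact methods are unnecessary at library scale). Coverage
curves first rescale a gene to 300 reads/position by seeded multinomial
resampling (the mechanism is unstated in the source; multinomial resampling
is the minimal-assumption choice, and a table already at the target depth is
used as is), then report the fraction of positions at or above each depth
threshold. Frame/direction analysis partitions calls into six classes
(frames 0/+1/+2 × plus/minus); frequencies are class reads over total reads
and enrichment is the ratio to the pre-sort control, with zero-frequency
control classes reported as missing rather than infinite. 1-bp-deletion
frequency counts aligned reads whose CIGAR contains a length-1 deletion
(multi-deletion reads count once) over all aligned reads. Sequence-context
matrices count bases in a ±5-nt window (configurable) around insertion
points against an all-positions background; the frequency difference is the
two-sample-logo input. Replicate agreement is the mean pairwise Spearman
correlation with missing positions zero-filled — dropping them entirely
would discard exactly the sparser library's information.

## Permissibility

F(i) = r_SE(i)/t_SE − r_NSE(i)/t_NSE, defined only where both sorted
populations have reads; all other positions are NA and excluded downstream.
Profiles are z-scored with the sample (n−1) standard deviation — the source
says only "sample standard deviation"; n−1 is the convention its statistical
environment defaults to — and replicates are z-scored first, then averaged
per position (NA only where all replicates are NA). Averaging F first and
z-scoring after is the alternative; z-then-average matches per-dataset
z-scoring and makes replicates unit-comparable. The false-call comparison
uses the pooled two-proportion z-test with a two-sided normal p-value.

## Synthetic data

Generators are pure functions of a `SimulationConfig`; each operation draws
from its own stream derived from the master seed, so adding one call never
perturbs another. Plasmids embed a random ORF (ATG … stop, no internal
stops) in a random backbone, scrubbed of BsaI/BsmBI sites (or salted with a
stated number of BsmBI sites). Insertion counts are multinomial draws under
a uniform, hotspot (a random 10% of positions up-weighted 10×) or
trinucleotide-preference model (positions whose codon matches a chosen 3-mer
up-weighted) — the latter two emulate transposase-like bias. Sorted counts
split each position's reads binomially by a planted per-position
permissibility. Deletion alignments emit SAM reads of which a stated
fraction carries exactly one 1-nt deletion. What these generators do *not*
emulate: sequencing error beyond 1-nt deletions, FACS gating noise,
cell-level co-transfection mixing, and real-genome base composition — so
passing recovery tests demonstrates the estimators and the design logic, not
robustness to those real-data effects.

## Default parameters

| parameter | default | why |
|---|---|---|
| oligo_max | 230 nt | array synthesis limit |
| barcode length / min distance | 12 nt / Hamming 4 | subpool orthogonality |
| handle | 24 nt, SG/GS linkers | two BsaI sites + 2+2 linker codons |
| Tm window | 55–61 °C | stated primer design window |
| off-target threshold | 35 °C | stated specificity cutoff |
| oligo conc. / Na+ | 500 nM / 50 mM | typical PCR-like conditions (unstated in source) |
| primer length search | 12–35 nt | see backbone-primer rationale above |
| coverage normalization | 300 reads/position | stated comparison depth |
| context window | ±5 nt | unstated; covers the known trinucleotide bias motif |

## Known limitations

Ligation is all-or-none on 4/4 overhang matches; concatemers beyond three
parts are not enumerated. The off-target model ignores mismatched duplexes
that could still anneal (only exact 3'-anchored stretches score). Multi-gene
pool design is supported at the statistics level, but `design_library`
handles one target per call; cross-gene barcode orthogonality must be
enforced by supplying one shared barcode list. Fragment boundaries at the
gene ends cannot move, so a pathological GC context at the terminal codons
can make primer design infeasible; the error names the boundary.
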