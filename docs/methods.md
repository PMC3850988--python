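# Methods

## The splice-junction search space

`sasd` treats alternative splicing identification as a database problem:
rather than infer events from spectra, it enumerates every elementary
event a transcript's exon/intron structure permits and emits the peptide
each event would produce, so that a standard MS/MS search engine does the
identification. Two event families are covered: whole single features
(every exon, every intron), and all pairwise junctions — adjacent
exon–exon (normal splicing control), non-adjacent exon–exon (exon
skipping), exon–intron and intron–exon (the two retention boundaries).
Mutually exclusive exons and alternative donor/acceptor sites are not
enumerated as first-class types; they are recoverable as co-occurring
skip/retention calls, and making them explicit would square the event
count without adding identifiable sequence.

Events are enumerated within one transcript; exons of different
transcripts of the same gene are never joined. Duplicate peptides arising
from sibling transcripts are kept by default so that per-transcript
accounting is exact; `dedupe` collapses byte-identical peptides keeping
the lexicographically smallest entry id.

## Window assembly

A junction window takes the last `flank` nucleotides of the left feature
and the first `flank` of the right, in transcript orientation. The
default `flank = 120` nt (≈ 40 residues per side) comfortably covers the
length distribution of tryptic fragments, so any identifiable peptide
spanning the junction lies inside the 240-nt window. Flanks are drawn
only from the two joined features: extending a flank into the next
feature would silently change the event's meaning, so short features
truncate instead, and the `left_truncated`/`right_truncated` flags record
exactly that (a feature shorter than the flank ⇒ flag set).

Single-feature events emit the feature whole when it fits in `2·flank`;
longer features are tiled into `2·flank` windows stepping by `flank`
(the last window anchored at the feature end), so the whole feature is
covered with ≥ `flank` overlap and no junction-free peptide of tryptic
length can be lost at a window boundary. Tiles share the event's mode
string and are distinguished by a window index in the entry id.

All internal coordinates are 0-based half-open; GTF/GFF3's 1-based
inclusive convention is converted exactly once at the I/O boundary. Exon
ordinals are recomputed from coordinates (5'→3' in transcript order,
i.e. reversed genomic order on the minus strand); an `exon_number`
attribute is only cross-checked, since its dialect varies. Features whose
sequence exceeds 10 % ambiguity bases (N) are flagged and events touching
them dropped with a logged count — their translations would be
meaningless.

## Translation and frame selection

Translation uses the standard genetic code. When the annotation carries
the exon phase (GFF3 frame convention: phase *p* means *p* bases of the
exon's first codon came from the previous exon), pure-exon entries
(`EXON_NM`, `E_E_NM`) are translated directly in that frame; because a
window may start mid-exon (flank tail or tile), the phase is propagated
along the exon so the genomic reading frame is preserved. Intron-
containing events have no phase and are translated in all three frames.
Transcripts without phase information are routed entirely through
three-frame translation rather than excluded.

Per frame, the candidate peptide is the maximal stop-free codon run
covering the junction — at least one residue on each side, or, when a
codon straddles the junction, the shared residue plus at least one
neighbour. Among frames the longest junction-spanning candidate wins;
ties break to the lowest frame index, and only the selected frame is
stored (the frame index is recorded so the others are reproducible).
Single-feature events keep the longest stop-free run anywhere in the
window. Ambiguity codons translate to `X` and terminate a run like a
stop. Peptides shorter than 6 residues (configurable) are dropped as
unidentifiable by MS. Stops inside a window therefore shorten the emitted
segment rather than rejecting the entry.

The junction notation inserts `^` between residues when the splice site
falls on a codon boundary and wraps the residue in `()` when its codon
straddles the site; stripping both markers recovers the plain sequence,
which is what the FASTA carries.

## Post-identification analysis

Engine hits arrive as a TSV (`sample_id, peptide, entry_id, evalue
[, group]`). Defaults mirror common search practice: e-value ≤ 0.1, and a
peptide must appear in ≥ 2 distinct samples to be trusted (duplicate
spectra within a sample count once for that filter). Novelty is an exact
substring search of the peptide against the reference proteome restricted
to the source gene's proteins — a peptide may match another gene's
protein and still be a novel isoform of its own gene; a global scope and
an I/L-equivalence fold (MS cannot distinguish the two) are optional.

Differential presence compares per-sample spectral counts (absent = 0)
between two groups with a one-sided Wilcoxon rank-sum test, elevated in
the designated case group. For designs with ≤ 12 samples the p-value is
computed by exhaustive permutation of the group labels (all C(n, k)
reassignments, so ties are handled exactly); larger designs use the
tie-corrected normal approximation. The field's habit for this design is
sometimes described as a signed-rank test, but an unpaired two-group
comparison calls for the rank-sum form; the signed-rank variant is
available only with explicit positional pairing. Markers are called at
p < 0.05 without multiplicity adjustment by default — the conventional,
permissive choice for hypothesis generation — with Benjamini–Hochberg
available behind a flag because dozens of uncorrected tests inflate the
false-positive rate.

## Synthetic fixtures

The fixture generator plants gene structures with recorded coordinates
and sequences into a random genome, so every stage has a ground-truth
oracle without downloads. Defaults are one contig, 2 genes × 4 exons,
feature lengths 150–250 nt (the scale of typical internal exons), ≥ 500 nt
random spacer between genes so flanks can never cross gene boundaries,
and stop-free planting: sequences contain no `TA`/`TG` dinucleotide and
start with `C`, which provably excludes stop codons from every reading
frame and every junction, guaranteeing that translation succeeds for all
19 events of a 4-exon gene. Hit tables emulate engine output as Bernoulli
presence per sample with configurable per-group probabilities and
e-values uniform on (0, 0.05); the planted-marker scenario uses 5 + 5
samples, which the exact permutation test resolves at p = 1/252 ≈ 0.004.

What the fixtures do *not* emulate: real codon usage and splice-site
motifs, overlapping genes, sequencing-style ambiguity, engine score
distributions, or spectra at all. Passing tests therefore demonstrate the
combinatorics, coordinate handling, frame logic and statistics are
correct — not that any particular biological sample will yield novel
isoforms.

## Numerical and design notes

* Acceptance-style checks and the reproduction script use desk-scale
  problem sizes (200 random transcripts of 1–12 exons for enumeration,
  1 000 random windows for frame selection, 4-exon genes for end-to-end
  runs); all counts are exact, so scale only affects coverage, not
  tolerances.
* Determinism: a fixed seed makes fixtures, builds, views and manifests
  byte-identical; entry order is sorted by transcript id, then
  enumeration order.
* Entry ids (`transcript|mode|type|f<frame>[|w<window>]`) are a
  deterministic stand-in identifier scheme; the FASTA accession prefixes
  them with `SASD|` so engines report self-describing hits, and a
  `simple` header style replaces `|` for engines with strict accession
  parsing.
* Degenerate inputs: single-exon transcripts yield exactly one event;
  all-equal presence vectors return p = 1 with a degenerate flag; an
  empty gene-set intersection is a warned empty result, while an empty
  build is a hard error.

## Known limitations

Cross-transcript joins, PTM enumeration and in-silico digestion are out
of scope (the search engine digests). The gene-scope novelty call depends
on the reference proteome's header `gene=` attributes being complete; a
gene absent from the proteome makes its peptides trivially novel (logged).
The exact permutation branch is capped at 12 samples for cost; beyond
that the normal approximation is standard but approximate in the extreme
tails.
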