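# sasd

Synthetic alternative-splicing junction peptide databases for shotgun
proteomics.

Standard protein databases (UniProt, NCBI nr, Ensembl proteomes) contain
only annotated isoforms, so a tandem-MS search against them can never
identify a peptide arising from an unannotated splice event. `sasd` closes
that gap by *synthesising* the search space: from a genome FASTA and a
GTF/GFF3 gene annotation it exhaustively enumerates, per transcript, six
elementary splicing events —

| mode token | join | class |
|---|---|---|
| `EXON_NM` | single exon *k* | Normal Splicing |
| `E_E_NM` | exon *k* + exon *k*+1 | Normal Splicing |
| `E_E_AS` | exon *j* + exon *k*, *k* ≥ *j*+2 | Exon Skipping |
| `E_I_AS` | exon *k* + intron *k* | Intron Retention |
| `I_E_AS` | intron *k* + exon *k*+1 | Intron Retention |
| `INTRON_AS` | single intron *k* | Intron Retention |

For every junction the last 120 nt of the left feature and the first
120 nt of the right feature are joined into a 240-nt virtual transcript
(flanks truncate at short feature boundaries; long single features are
tiled). Each window is translated with the exon phase when the annotation
provides it, otherwise in all three reading frames, keeping the frame
whose stop-free peptide spans the junction with the most residues. The
junction is annotated `…E^V…` when it falls between codons, or `…T(A)S…`
when a codon straddles it. A transcript with *E* exons yields exactly
*E* + 4(*E*−1) + C(*E*,2) − (*E*−1) events.

The resulting FASTA can be searched by any MS/MS engine (OMSSA, Mascot,
Comet, …). `sasd` then consumes the engine's peptide hits and performs
the downstream analysis:

* **novelty calling** — a junction peptide is a novel isoform of its
  source gene when it is not a substring of any annotated protein of that
  gene;
* **reproducibility filtering** — peptides are trusted only when
  identified in ≥ 2 distinct samples (e-value cutoff 0.1 by default);
* **marker testing** — per peptide, a one-sided Wilcoxon rank-sum test of
  per-sample spectral counts between two groups (exact by exhaustive
  label permutation for designs with ≤ 12 samples), reporting per-group
  hit counts and p-values.

Context-specific builds (e.g. the splice space of a 15-gene cancer panel)
are supported through GMT/TSV gene sets with alias resolution.

## Worked example

Everything is testable offline: the `fixture` subcommand plants a
synthetic gene with known structure, then `build` runs the full pipeline.

```sh
$ sasd fixture --outdir demo --n-genes 1 --exons-per-gene 4 --seed 7
$ sasd build --genome demo/genome.fa --annotation demo/annotation.gtf \
             --out-prefix demo/db
INFO sasd: parsed 1 transcript model(s)
INFO sasd:   EXON_NM    4
INFO sasd:   E_E_NM     3
INFO sasd:   E_I_AS     3
INFO sasd:   I_E_AS     3
INFO sasd:   E_E_AS     3
INFO sasd:   INTRON_AS  3
INFO sasd: wrote 19 entries to demo/db.fasta
```

The 4-exon transcript yields 19 entries: 4 single-exon windows, 3 of each
junction-adjacent type, and C(4,2) − 3 = 3 exon-skipping joins. Headers
encode transcript, mode, event type and selected frame:

```
>SASD|TX001|E1|EXON_NM|f0 gene=GENE001 name=GENE001
PGRTRLFKFDRVLFVTFRRIFPKFPGGSHRAFSSEFSTPHSTSSSPHFTFSQSKVFPSSP
NPDDSL
```

Alongside the FASTA the build writes region/gene/transcript TSV views and
a manifest with the per-type accounting (`count_E_E_AS=3`, …). The
`markers` subcommand takes a hits TSV (`sample_id, peptide, entry_id,
evalue[, group]`), a region view and a reference proteome and reports
novel differentially present peptides with their p-values and per-group
sample counts.

As a library:

```python
from sasd import load_annotation, build_database, BuildConfig, write_fasta

models, genome = load_annotation("demo/annotation.gtf", "demo/genome.fa")
entries, manifest = build_database(models, genome, BuildConfig(flank=120))
write_fasta(entries, "db.fasta")
```

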