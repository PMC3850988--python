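"""Transcript models from genome FASTA + GTF/GFF3 annotation.

Coordinate conventions
----------------------
External files (GTF/GFF3) use 1-based inclusive coordinates; every
in-memory interval in this package is 0-based half-open.  The conversion
happens exactly once, at the I/O boundary in :func:`load_annotation`.

Exon ordinals are 1-based ranks in 5'->3' *transcript* order, i.e. on the
minus strand ordinal 1 is the genomically rightmost exon.  Intron ``i``
lies between exon ``i`` and exon ``i+1`` in transcript order.

Phase follows the GFF3 frame convention: phase ``p`` means ``p`` bases of
the exon's first codon were contributed by the preceding exon; ``None``
when the frame column is ``.``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import gffutils
from Bio.Seq import reverse_complement

logger = logging.getLogger(__name__)

# fraction of N above which a feature is flagged as ambiguous
N_FRACTION_FLAG = 0.10


class AnnotationError(ValueError):
    """Raised for unrecoverable genome/annotation inconsistencies."""


class Genome:
    """Set of contig sequences with strand-aware interval extraction.

    Lookups use 0-based half-open intervals; minus-strand lookups return
    the reverse complement of the plus-strand slice.
    """

    def __init__(self, contigs: Mapping[str, str]):
        if not contigs:
            raise AnnotationError("genome contains no contigs")
        for name, seq in contigs.items():
            if not seq:
                raise AnnotationError(f"contig {name!r} has empty sequence")
        self._contigs = {name: str(seq).upper() for name, seq in contigs.items()}

    @classmethod
    def from_fasta(cls, path: str | Path) -> "Genome":
        import pyfaidx

        fa = pyfaidx.Fasta(str(path), as_raw=True, rebuild=False)
        return cls({name: str(fa[name][:]) for name in fa.keys()})

    def __contains__(self, contig: str) -> bool:
        return contig in self._contigs

    def contig_length(self, contig: str) -> int:
        return len(self._contigs[contig])

    @property
    def contig_ids(self) -> list[str]:
        return list(self._contigs)

    def fetch(self, contig: str, start: int, end: int, strand: str = "+") -> str:
        if contig not in self._contigs:
            raise AnnotationError(f"contig {contig!r} not present in genome")
        seq = self._contigs[contig]
        if start < 0 or end > len(seq) or start >= end:
            raise AnnotationError(
                f"interval [{start}, {end}) outside contig {contig!r} "
                f"of length {len(seq)}"
            )
        sub = seq[start:end]
        return reverse_complement(sub) if strand == "-" else sub

    def reverse_complemented(self) -> "Genome":
        """Mirror image of the genome (used by strand-symmetry checks)."""
        return Genome({c: reverse_complement(s) for c, s in self._contigs.items()})


@dataclass(frozen=True)
class ExonRecord:
    transcript_id: str
    ordinal: int  # 1-based, transcript (5'->3') order
    contig: str
    start: int  # 0-based half-open
    end: int
    strand: str
    phase: int | None = None

    def __post_init__(self):
        if self.start >= self.end:
            raise AnnotationError(
                f"exon {self.transcript_id}:{self.ordinal} has start >= end"
            )
        if self.strand not in "+-":
            raise AnnotationError(f"bad strand {self.strand!r}")
        if self.phase is not None and self.phase not in (0, 1, 2):
            raise AnnotationError(f"bad phase {self.phase!r}")

    def __len__(self) -> int:
        return self.end - self.start

    def sequence(self, genome: Genome) -> str:
        return genome.fetch(self.contig, self.start, self.end, self.strand)


@dataclass(frozen=True)
class IntronRecord:
    transcript_id: str
    ordinal: int  # intron i lies between exon i and exon i+1
    contig: str
    start: int
    end: int
    strand: str

    def __len__(self) -> int:
        return self.end - self.start

    def sequence(self, genome: Genome) -> str:
        return genome.fetch(self.contig, self.start, self.end, self.strand)


@dataclass
class TranscriptModel:
    """Ordered exons of one transcript plus the derived introns."""

    transcript_id: str
    gene_id: str
    gene_name: str
    exons: list[ExonRecord]
    introns: list[IntronRecord] = field(default_factory=list)

    def __post_init__(self):
        if not self.exons:
            raise AnnotationError(f"transcript {self.transcript_id} has no exons")
        self.introns = derive_introns(self)

    @property
    def contig(self) -> str:
        return self.exons[0].contig

    @property
    def strand(self) -> str:
        return self.exons[0].strand

    @property
    def n_exons(self) -> int:
        return len(self.exons)

    def spliced_sequence(self, genome: Genome) -> str:
        return "".join(e.sequence(genome) for e in self.exons)


def derive_introns(model: TranscriptModel) -> list[IntronRecord]:
    """Gaps between consecutive exons, numbered in transcript order.

    A single-exon transcript has no introns.  In genomic orientation the
    intron occupies the half-open interval between the two exons; on the
    minus strand exon ordinal order runs right-to-left, so intron ``i``
    lies genomically *left* of exon ``i``.
    """
    exons = model.exons
    introns: list[IntronRecord] = []
    for left, right in zip(exons, exons[1:]):
        if left.strand == "+":
            start, end = left.end, right.start
        else:
            start, end = right.end, left.start
        if start >= end:
            raise AnnotationError(
                f"transcript {model.transcript_id}: exons {left.ordinal} and "
                f"{right.ordinal} are adjacent or overlapping; no intron exists"
            )
        introns.append(
            IntronRecord(
                transcript_id=model.transcript_id,
                ordinal=left.ordinal,
                contig=left.contig,
                start=start,
                end=end,
                strand=left.strand,
            )
        )
    return introns


def ambiguous_fraction(seq: str) -> float:
    return seq.count("N") / len(seq) if seq else 0.0


def feature_is_ambiguous(feature, genome: Genome) -> bool:
    """True when a feature's sequence carries >10% ambiguity (N) bases."""
    return ambiguous_fraction(feature.sequence(genome)) > N_FRACTION_FLAG


def _attr_first(feature, *keys: str) -> str | None:
    for key in keys:
        if key in feature.attributes:
            val = feature.attributes[key]
            if val:
                return val[0]
    return None


def _exon_transcript_id(feature) -> str | None:
    tid = _attr_first(feature, "transcript_id")
    if tid:
        return tid
    parent = _attr_first(feature, "Parent")
    if parent:
        # GFF3 Parent values may carry a "transcript:" prefix (Ensembl style)
        return parent.split(":", 1)[-1]
    return None


def load_annotation(
    annotation_path: str | Path,
    genome_path: str | Path | Genome,
) -> tuple[list[TranscriptModel], Genome]:
    """Parse a GTF/GFF3 + genome FASTA into transcript models.

    Transcripts with overlapping exons are rejected with a warning; an
    annotation referencing a contig absent from the FASTA, or yielding no
    transcripts at all, is a hard error.
    """
    genome = genome_path if isinstance(genome_path, Genome) else Genome.from_fasta(genome_path)

    db = gffutils.create_db(
        str(annotation_path),
        ":memory:",
        merge_strategy="create_unique",
        disable_infer_genes=True,
        disable_infer_transcripts=True,
        keep_order=True,
    )

    by_transcript: dict[str, list] = {}
    meta: dict[str, tuple[str, str]] = {}
    for feat in db.features_of_type("exon"):
        tid = _exon_transcript_id(feat)
        if tid is None:
            logger.warning("exon at %s:%s-%s lacks a transcript id; skipped",
                           feat.seqid, feat.start, feat.end)
            continue
        if feat.seqid not in genome:
            raise AnnotationError(
                f"annotation references contig {feat.seqid!r} absent from the genome FASTA"
            )
        by_transcript.setdefault(tid, []).append(feat)
        if tid not in meta:
            gid = _attr_first(feat, "gene_id") or "unknown_gene"
            gname = _attr_first(feat, "gene_name", "Name") or gid
            meta[tid] = (gid, gname)

    models: list[TranscriptModel] = []
    for tid in sorted(by_transcript):
        feats = by_transcript[tid]
        contigs = {f.seqid for f in feats}
        strands = {f.strand for f in feats}
        if len(contigs) > 1 or len(strands) > 1:
            logger.warning("transcript %s spans multiple contigs/strands; rejected", tid)
            continue
        strand = strands.pop()
        # genomic order first, then transcript order by strand
        feats.sort(key=lambda f: f.start)
        if any(a.end >= b.start for a, b in zip(feats, feats[1:])):
            logger.warning("transcript %s has overlapping exons; rejected", tid)
            continue
        if strand == "-":
            feats = feats[::-1]
        exons = []
        for ordinal, f in enumerate(feats, start=1):
            declared = _attr_first(f, "exon_number")
            if declared is not None and declared.isdigit() and int(declared) != ordinal:
                logger.warning(
                    "transcript %s: exon_number attribute %s disagrees with "
                    "coordinate-derived ordinal %d; using ordinal",
                    tid, declared, ordinal,
                )
            phase = None
            if f.frame is not None and f.frame in ("0", "1", "2"):
                phase = int(f.frame)
            exons.append(
                ExonRecord(
                    transcript_id=tid,
                    ordinal=ordinal,
                    contig=f.seqid,
                    start=f.start - 1,  # GTF 1-based inclusive -> 0-based half-open
                    end=f.end,
                    strand=strand,
                    phase=phase,
                )
            )
        gid, gname = meta[tid]
        models.append(TranscriptModel(tid, gid, gname, exons))

    if not models:
        raise AnnotationError(f"no transcripts parsed from {annotation_path}")
    return models, genome
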