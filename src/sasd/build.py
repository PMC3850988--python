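"""Three-step database build: transcript models -> events -> peptides.

The build enumerates every elementary splicing event of every transcript,
assembles the flanked artificial splicing transcripts, translates them
(phase-directed where the exon phase is known, three-frame otherwise) and
emits one database entry per surviving peptide.  Entries carry enough
metadata — gene, transcript, mode string, event type/class, frame,
genomic flank intervals — to reconstruct the event from a search-engine
accession alone.

Output is a search-ready protein FASTA plus gene/transcript/region TSV
views and a flat key=value manifest recording the configuration and the
per-type accounting, so two builds from identical inputs are
byte-identical.
"""

from __future__ import annotations

import hashlib
import logging
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from . import events as ev
from . import translate as tr
from .gene_models import Genome, TranscriptModel, feature_is_ambiguous

logger = logging.getLogger(__name__)

ALL_TYPES = tuple(t.value for t in ev.SpliceEventType)


@dataclass(frozen=True)
class BuildConfig:
    flank: int = ev.DEFAULT_FLANK
    min_peptide_length: int = tr.MIN_PEPTIDE_LENGTH
    dedupe: bool = False
    event_types: tuple[str, ...] = ALL_TYPES  # inclusion mask
    gene_set: frozenset[str] | None = None  # context restriction, pre-build
    header_style: str = "full"  # full | simple

    def __post_init__(self):
        unknown = set(self.event_types) - set(ALL_TYPES)
        if unknown:
            raise ValueError(f"unknown event types: {sorted(unknown)}")
        if self.header_style not in ("full", "simple"):
            raise ValueError(f"unknown header style {self.header_style!r}")


@dataclass(frozen=True)
class DatabaseEntry:
    entry_id: str
    gene_id: str
    gene_name: str
    transcript_id: str
    mode: str
    type: str
    splice_class: str
    peptide: str
    junction_notation: str
    frame: int
    phase_used: bool
    window_index: int | None
    contig: str
    strand: str
    intervals: tuple[tuple[str, int, int, str], ...]


def _entry_id(tid: str, mode: str, etype: str, frame: int, window: int | None) -> str:
    eid = f"{tid}|{mode}|{etype}|f{frame}"
    if window is not None:
        eid += f"|w{window}"
    return eid


def build_database(
    models: Sequence[TranscriptModel],
    genome: Genome,
    config: BuildConfig = BuildConfig(),
) -> tuple[list[DatabaseEntry], dict]:
    """Run the full build; returns (entries, manifest dict).

    The manifest counts entries per event type and records every drop
    reason (ambiguous feature, failed translation, peptide below the
    length floor).  An entirely empty build is an error.
    """
    mask = set(config.event_types)
    entries: list[DatabaseEntry] = []
    counts: Counter = Counter()
    drops: Counter = Counter()

    for model in sorted(models, key=lambda m: m.transcript_id):
        if config.gene_set is not None and not _gene_in_set(model, config.gene_set):
            drops["gene_not_in_context"] += 1
            continue
        ambiguous = {
            ("E", x.ordinal) for x in model.exons if feature_is_ambiguous(x, genome)
        } | {
            ("i", x.ordinal) for x in model.introns if feature_is_ambiguous(x, genome)
        }
        if ambiguous:
            logger.warning("transcript %s: %d ambiguous feature(s) flagged",
                           model.transcript_id, len(ambiguous))
        for event in ev.enumerate_events(model):
            if event.type.value not in mask:
                drops["masked"] += 1
                continue
            touched = [event.left] + ([event.right] if event.right else [])
            if any(f in ambiguous for f in touched):
                drops["ambiguous_feature"] += 1
                continue
            for ast in ev.assemble_ast(event, genome, model, flank=config.flank):
                pep = _translate_entry(ast, model, config)
                if pep is None:
                    drops["no_peptide"] += 1
                    continue
                e = _make_entry(model, ast, pep)
                entries.append(e)
                counts[e.type] += 1

    if config.dedupe:
        entries = dedupe_entries(entries)
        counts = Counter(e.type for e in entries)

    if not entries:
        raise ValueError("build produced no database entries")

    manifest = {
        "flank": config.flank,
        "min_peptide_length": config.min_peptide_length,
        "dedupe": config.dedupe,
        "event_types": ",".join(config.event_types),
        "n_transcripts": len({e.transcript_id for e in entries}),
        "n_genes": len({e.gene_id for e in entries}),
        "n_entries": len(entries),
    }
    for t in ALL_TYPES:
        manifest[f"count_{t}"] = counts.get(t, 0)
    for reason, n in sorted(drops.items()):
        manifest[f"dropped_{reason}"] = n
    return entries, manifest


def _gene_in_set(model: TranscriptModel, gene_set: frozenset[str]) -> bool:
    lowered = {g.lower() for g in gene_set}
    return model.gene_id.lower() in lowered or model.gene_name.lower() in lowered


def _translate_entry(ast, model, config: BuildConfig):
    """Phase-directed translation for pure-exon entries with known phase;
    three-frame selection everywhere else (introns carry no phase)."""
    etype = ast.event.type
    if etype in (ev.SpliceEventType.EXON_NM, ev.SpliceEventType.E_E_NM):
        lead = model.exons[ast.event.left[1] - 1]
        if lead.phase is not None:
            # the AST may start mid-exon (flank tail, or a tile window);
            # propagate the phase along the exon so the genomic reading
            # frame is preserved inside the window
            offset = ((3 - lead.phase) % 3 - _window_start(ast, lead)) % 3
            return tr.translate_in_frame(
                ast, offset, phase_used=True, min_length=config.min_peptide_length
            )
    return tr.translate_three_frames(ast, min_length=config.min_peptide_length)


def _window_start(ast, feat) -> int:
    """Offset of the AST's first nucleotide within its leading feature,
    in transcript orientation."""
    contig, s, e, strand = ast.genomic_intervals[0]
    return (s - feat.start) if strand == "+" else (feat.end - e)


def _make_entry(model: TranscriptModel, ast, pep) -> DatabaseEntry:
    event = ast.event
    return DatabaseEntry(
        entry_id=_entry_id(model.transcript_id, event.mode, event.type.value,
                           pep.frame, ast.window_index),
        gene_id=model.gene_id,
        gene_name=model.gene_name,
        transcript_id=model.transcript_id,
        mode=event.mode,
        type=event.type.value,
        splice_class=event.type.splice_class,
        peptide=pep.sequence,
        junction_notation=pep.junction_notation,
        frame=pep.frame,
        phase_used=pep.phase_used,
        window_index=ast.window_index,
        contig=model.contig,
        strand=model.strand,
        intervals=ast.genomic_intervals,
    )


def dedupe_entries(entries: Iterable[DatabaseEntry]) -> list[DatabaseEntry]:
    """Collapse byte-identical peptides, keeping the lexicographically
    smallest entry_id; output keeps the original order of the survivors."""
    best: dict[str, DatabaseEntry] = {}
    for e in entries:
        cur = best.get(e.peptide)
        if cur is None or e.entry_id < cur.entry_id:
            best[e.peptide] = e
    keep = {e.entry_id for e in best.values()}
    return [e for e in entries if e.entry_id in keep]


def filter_by_gene_set(
    entries: Sequence[DatabaseEntry], gene_set: Iterable[str]
) -> list[DatabaseEntry]:
    """Entries whose gene id or gene name is in the set (names matched
    case-insensitively); order preserved.  Empty intersections warn."""
    lowered = {g.lower() for g in gene_set}
    out = [e for e in entries
           if e.gene_id.lower() in lowered or e.gene_name.lower() in lowered]
    if lowered and not out:
        logger.warning("gene-set filter matched no entries")
    return out


def fasta_header(entry: DatabaseEntry, style: str = "full") -> tuple[str, str]:
    """(id, description) for one FASTA record.

    The full style packs transcript, mode, event type, frame and window
    into a single `|`-separated accession so search engines report a
    self-describing hit id.
    """
    if style == "simple":
        return entry.entry_id.replace("|", "_"), ""
    acc = f"SASD|{entry.entry_id}"
    return acc, f"gene={entry.gene_id} name={entry.gene_name}"


def write_fasta(entries: Sequence[DatabaseEntry], path: str | Path,
                style: str = "full") -> None:
    if not entries:
        raise ValueError("refusing to write an empty FASTA")
    records = []
    for e in entries:
        rid, desc = fasta_header(e, style)
        records.append(SeqRecord(Seq(e.peptide), id=rid, description=desc))
    with open(path, "w") as fh:
        SeqIO.write(records, fh, "fasta")


def entries_frame(entries: Sequence[DatabaseEntry]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "entry_id": e.entry_id, "gene_id": e.gene_id,
                "gene_name": e.gene_name, "transcript_id": e.transcript_id,
                "mode": e.mode, "type": e.type, "class": e.splice_class,
                "frame": e.frame, "phase_used": e.phase_used,
                "window": "" if e.window_index is None else e.window_index,
                "contig": e.contig, "strand": e.strand,
                "intervals": ";".join(f"{c}:{s}-{x}({st})" for c, s, x, st in e.intervals),
                "junction_notation": e.junction_notation,
                "peptide": e.peptide,
            }
            for e in entries
        ]
    )


def write_views(entries: Sequence[DatabaseEntry], path_prefix: str | Path) -> dict[str, Path]:
    """Write gene / transcript / region TSV views.

    The region view lists one row per entry with the genomic flank
    intervals, junction notation and peptide; the gene and transcript
    views aggregate per-type entry counts.
    """
    if not entries:
        raise ValueError("refusing to write views for an empty build")
    prefix = Path(path_prefix)
    df = entries_frame(entries)
    paths = {}

    region_path = prefix.with_name(prefix.name + "_region_view.tsv")
    df.to_csv(region_path, sep="\t", index=False)
    paths["region"] = region_path

    for level, key in (("gene", "gene_id"), ("transcript", "transcript_id")):
        pivot = (
            df.pivot_table(index=key, columns="type", values="entry_id",
                           aggfunc="count", fill_value=0)
            .reindex(columns=list(ALL_TYPES), fill_value=0)
            .astype(int)
        )
        pivot["total"] = pivot.sum(axis=1)
        out = prefix.with_name(f"{prefix.name}_{level}_view.tsv")
        pivot.sort_index().to_csv(out, sep="\t")
        paths[level] = out
    return paths


def write_manifest(manifest: dict, path: str | Path,
                   input_paths: Iterable[str | Path] = ()) -> None:
    """Flat key=value manifest; input files are checksummed for
    provenance."""
    lines = [f"{k}={v}" for k, v in manifest.items()]
    for p in input_paths:
        p = Path(p)
        digest = hashlib.sha256(p.read_bytes()).hexdigest()[:16]
        lines.append(f"sha256_{p.name}={digest}")
    Path(path).write_text("\n".join(lines) + "\n")
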