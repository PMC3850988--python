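"""Splice-junction event enumeration and artificial splicing transcripts.

Six elementary event types are enumerated exhaustively per transcript:

========  ==============================  =================
token     join                            class
========  ==============================  =================
EXON_NM   single exon k                   Normal Splicing
E_E_NM    exon k + exon k+1 (adjacent)    Normal Splicing
E_E_AS    exon j + exon k, k >= j+2       Exon Skipping
E_I_AS    exon k + intron k               Intron Retention
I_E_AS    intron k + exon k+1             Intron Retention
INTRON_AS single intron k                 Intron Retention
========  ==============================  =================

For a junction event the artificial splicing transcript (AST) is the last
``flank`` nt of the left feature joined to the first ``flank`` nt of the
right feature, in transcript orientation (default flank 120 nt, so 240 nt
when both features are long enough).  Flanks are drawn only from the two
joined features and truncate at the feature boundary — they never extend
into a neighbouring feature, which would change the event's meaning.

Single-feature events emit the whole feature; features longer than
``2 * flank`` are tiled into overlapping ``2 * flank`` windows (step =
``flank``) so long exons/introns are fully covered.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from enum import Enum
from itertools import combinations

from .gene_models import Genome, TranscriptModel

DEFAULT_FLANK = 120  # nt per side; matches typical tryptic-fragment span


class SpliceEventType(str, Enum):
    EXON_NM = "EXON_NM"
    E_E_NM = "E_E_NM"
    E_I_AS = "E_I_AS"
    I_E_AS = "I_E_AS"
    E_E_AS = "E_E_AS"
    INTRON_AS = "INTRON_AS"

    @property
    def splice_class(self) -> str:
        return _EVENT_CLASS[self]

    @property
    def is_junction(self) -> bool:
        """Two-feature events have a junction; single-feature events do not."""
        return self not in (SpliceEventType.EXON_NM, SpliceEventType.INTRON_AS)


_EVENT_CLASS = {
    SpliceEventType.EXON_NM: "Normal Splicing",
    SpliceEventType.E_E_NM: "Normal Splicing",
    SpliceEventType.E_E_AS: "Exon Skipping",
    SpliceEventType.E_I_AS: "Intron Retention",
    SpliceEventType.I_E_AS: "Intron Retention",
    SpliceEventType.INTRON_AS: "Intron Retention",
}

EVENT_TYPES = tuple(SpliceEventType)


@dataclass(frozen=True)
class JunctionEvent:
    """One elementary splicing event of a transcript.

    ``left``/``right`` are (feature_kind, ordinal) pairs with kind ``"E"``
    for exon and ``"i"`` for intron; ``right`` is ``None`` for the
    single-feature events EXON_NM and INTRON_AS.
    """

    transcript_id: str
    gene_id: str
    type: SpliceEventType
    left: tuple[str, int]
    right: tuple[str, int] | None = None

    def __post_init__(self):
        t = self.type
        lk, lo = self.left
        if t.is_junction:
            if self.right is None:
                raise ValueError(f"{t.value} requires a right feature")
            rk, ro = self.right
            ok = {
                SpliceEventType.E_E_NM: lk == "E" and rk == "E" and ro == lo + 1,
                SpliceEventType.E_E_AS: lk == "E" and rk == "E" and ro >= lo + 2,
                SpliceEventType.E_I_AS: lk == "E" and rk == "i" and ro == lo,
                SpliceEventType.I_E_AS: lk == "i" and rk == "E" and ro == lo + 1,
            }[t]
        else:
            ok = self.right is None and lk == ("E" if t is SpliceEventType.EXON_NM else "i")
        if not ok:
            raise ValueError(f"inconsistent {t.value} event: left={self.left} right={self.right}")

    @property
    def mode(self) -> str:
        return mode_string(self)


@dataclass(frozen=True)
class ArtificialSplicingTranscript:
    """Nucleotide window around a junction (or covering a single feature).

    ``junction_offset`` is the number of nt contributed by the left
    feature; ``None`` for single-feature events.  ``window_index`` numbers
    the tiles of a long single feature (``None`` when untiled).
    ``genomic_intervals`` records the contributing genomic slices as
    (contig, start, end, strand), 0-based half-open, in transcript order.
    """

    event: JunctionEvent
    sequence: str
    junction_offset: int | None
    left_truncated: bool = False
    right_truncated: bool = False
    window_index: int | None = None
    genomic_intervals: tuple[tuple[str, int, int, str], ...] = ()


def enumerate_events(model: TranscriptModel) -> list[JunctionEvent]:
    """All elementary events of one transcript, deterministically ordered.

    For E exons (and I = E-1 introns) the per-type counts are
    E, I, I, I, I and C(E,2) - (E-1).
    """
    E = model.n_exons
    tid, gid = model.transcript_id, model.gene_id
    ev: list[JunctionEvent] = []
    for k in range(1, E + 1):
        ev.append(JunctionEvent(tid, gid, SpliceEventType.EXON_NM, ("E", k)))
    for k in range(1, E):
        ev.append(JunctionEvent(tid, gid, SpliceEventType.INTRON_AS, ("i", k)))
    for k in range(1, E):
        ev.append(JunctionEvent(tid, gid, SpliceEventType.E_E_NM, ("E", k), ("E", k + 1)))
    for k in range(1, E):
        ev.append(JunctionEvent(tid, gid, SpliceEventType.E_I_AS, ("E", k), ("i", k)))
    for k in range(1, E):
        ev.append(JunctionEvent(tid, gid, SpliceEventType.I_E_AS, ("i", k), ("E", k + 1)))
    for j, k in combinations(range(1, E + 1), 2):
        if k >= j + 2:
            ev.append(JunctionEvent(tid, gid, SpliceEventType.E_E_AS, ("E", j), ("E", k)))
    return ev


def _resolve(model: TranscriptModel, feature: tuple[str, int]):
    kind, ordinal = feature
    pool = model.exons if kind == "E" else model.introns
    if not 1 <= ordinal <= len(pool):
        raise ValueError(
            f"{model.transcript_id}: no {'exon' if kind == 'E' else 'intron'} "
            f"with ordinal {ordinal}"
        )
    return pool[ordinal - 1]


def assemble_ast(
    event: JunctionEvent,
    genome: Genome,
    model: TranscriptModel,
    flank: int = DEFAULT_FLANK,
) -> list[ArtificialSplicingTranscript]:
    """Assemble the AST(s) for one event.

    Junction events yield exactly one AST; single-feature events yield one
    AST per tile window (one window when the feature fits in ``2*flank``).
    """
    if flank < 1:
        raise ValueError("flank must be >= 1")
    if event.transcript_id != model.transcript_id:
        raise ValueError("event does not belong to this transcript model")

    if event.type.is_junction:
        lf = _resolve(model, event.left)
        rf = _resolve(model, event.right)
        lseq, rseq = lf.sequence(genome), rf.sequence(genome)
        ltrunc, rtrunc = len(lseq) < flank, len(rseq) < flank
        ltake, rtake = min(flank, len(lseq)), min(flank, len(rseq))
        seq = lseq[-ltake:] + rseq[:rtake]
        ivals = (
            _tail_interval(lf, ltake),
            _head_interval(rf, rtake),
        )
        return [
            ArtificialSplicingTranscript(
                event=event,
                sequence=seq,
                junction_offset=ltake,
                left_truncated=ltrunc,
                right_truncated=rtrunc,
                genomic_intervals=ivals,
            )
        ]

    feat = _resolve(model, event.left)
    seq = feat.sequence(genome)
    width = 2 * flank
    if len(seq) <= width:
        return [
            ArtificialSplicingTranscript(
                event=event,
                sequence=seq,
                junction_offset=None,
                genomic_intervals=(_span_interval(feat, 0, len(seq)),),
            )
        ]
    # tile long features: full-width windows stepping by flank, last window
    # anchored at the feature end so coverage is complete
    starts = list(range(0, len(seq) - width, flank))
    starts.append(len(seq) - width)
    return [
        ArtificialSplicingTranscript(
            event=event,
            sequence=seq[s : s + width],
            junction_offset=None,
            window_index=w,
            genomic_intervals=(_span_interval(feat, s, s + width),),
        )
        for w, s in enumerate(starts, start=1)
    ]


def _tail_interval(feat, take: int):
    # last `take` nt in transcript orientation
    if feat.strand == "+":
        return (feat.contig, feat.end - take, feat.end, "+")
    return (feat.contig, feat.start, feat.start + take, "-")


def _head_interval(feat, take: int):
    if feat.strand == "+":
        return (feat.contig, feat.start, feat.start + take, "+")
    return (feat.contig, feat.end - take, feat.end, "-")


def _span_interval(feat, off: int, end: int):
    # transcript-orientation offsets [off, end) mapped to genomic coords
    if feat.strand == "+":
        return (feat.contig, feat.start + off, feat.start + end, "+")
    return (feat.contig, feat.end - end, feat.end - off, "-")


# --- mode-string grammar ---------------------------------------------------
#
# Canonical emission uses no separator: "E2", "i6", "E1E2", "E1i1", "i3E4",
# "E1E3".  The parser additionally accepts an optional underscore between
# the two feature tokens ("E7_E11" == "E7E11").  Digit runs are consumed
# greedily, so "E102E182" tokenizes as exons 102 and 182.

_MODE_RE = re.compile(r"^([Ei])(\d+)(?:_?([Ei])(\d+))?$")


def mode_string(event: JunctionEvent) -> str:
    lk, lo = event.left
    s = f"{lk}{lo}"
    if event.right is not None:
        rk, ro = event.right
        s += f"{rk}{ro}"
    return s


def parse_mode(s: str) -> tuple[SpliceEventType, tuple[str, int], tuple[str, int] | None]:
    """Parse a mode string into (type, left, right).

    Raises ``ValueError`` naming the offending token for strings outside
    the grammar (unknown feature letters, non-adjacent E_I/I_E ordinals,
    identical or reversed exon pairs).
    """
    m = _MODE_RE.match(s.strip())
    if not m:
        raise ValueError(f"unparseable mode string {s!r}")
    lk, lo, rk, ro = m.group(1), int(m.group(2)), m.group(3), m.group(4)
    if lo < 1 or (ro is not None and int(ro) < 1):
        raise ValueError(f"mode {s!r}: ordinals must be >= 1")
    left = (lk, lo)
    if rk is None:
        t = SpliceEventType.EXON_NM if lk == "E" else SpliceEventType.INTRON_AS
        return t, left, None
    ro = int(ro)
    right = (rk, ro)
    if lk == "E" and rk == "E":
        if ro == lo + 1:
            return SpliceEventType.E_E_NM, left, right
        if ro >= lo + 2:
            return SpliceEventType.E_E_AS, left, right
        raise ValueError(f"mode {s!r}: exon pair E{lo},E{ro} is not ascending")
    if lk == "E" and rk == "i":
        if ro != lo:
            raise ValueError(f"mode {s!r}: E_I join requires intron ordinal {lo}, got i{ro}")
        return SpliceEventType.E_I_AS, left, right
    if lk == "i" and rk == "E":
        if ro != lo + 1:
            raise ValueError(f"mode {s!r}: I_E join requires exon ordinal {lo + 1}, got E{ro}")
        return SpliceEventType.I_E_AS, left, right
    raise ValueError(f"mode {s!r}: intron-intron joins are not an event type")
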