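"""Translate artificial splicing transcripts into junction peptides.

Each AST is translated with the standard genetic code (table 1).  When the
reading frame is known from Ensembl-style exon phase it is used directly;
otherwise all three frames are tried and the frame whose stop-free peptide
spans the junction with the most residues wins (ties break to the lowest
frame index).  Introns carry no phase, so every intron-containing event is
three-frame translated.

A junction peptide must cover at least one residue on each side of the
splice site, or — when a codon straddles the site — the shared residue
plus at least one neighbour.  In the human-readable notation the splice
site is marked ``^`` between residues, or ``(X)`` around a residue whose
codon straddles the junction.
"""

from __future__ import annotations

from dataclasses import dataclass

from Bio.Seq import Seq

from .events import ArtificialSplicingTranscript

MIN_PEPTIDE_LENGTH = 6  # residues; shorter fragments are unidentifiable by MS

_STOPLIKE = frozenset("*X")  # X from ambiguity codons also breaks a segment


@dataclass(frozen=True)
class ASPeptide:
    """A stop-free translated peptide with its junction annotation.

    ``junction_residue_index`` is the peptide index of the residue right
    of the splice site (``junction_shared`` False) or of the residue whose
    codon straddles the site (``junction_shared`` True); ``None`` for
    single-feature events and peptides not covering the junction.
    """

    ast: ArtificialSplicingTranscript
    sequence: str
    frame: int
    phase_used: bool
    junction_residue_index: int | None = None
    junction_shared: bool = False

    @property
    def junction_notation(self) -> str:
        return annotate_junction(self)

    def __len__(self) -> int:
        return len(self.sequence)


def _translate_frame(nt: str, offset: int) -> str:
    """Amino-acid string of the frame starting at ``offset`` (trailing
    partial codon dropped); stops are '*', ambiguous codons 'X'."""
    sub = nt[offset:]
    sub = sub[: len(sub) - len(sub) % 3]
    if not sub:
        return ""
    return str(Seq(sub).translate(table=1))


def _stop_free_runs(aa: str):
    """Maximal runs of residues free of stops and ambiguity, as
    (start_codon_index, residues) pairs."""
    runs = []
    start = None
    for i, r in enumerate(aa):
        if r in _STOPLIKE:
            if start is not None:
                runs.append((start, aa[start:i]))
                start = None
        elif start is None:
            start = i
    if start is not None:
        runs.append((start, aa[start:]))
    return runs


def translate_in_frame(
    ast: ArtificialSplicingTranscript,
    offset: int,
    *,
    phase_used: bool = False,
    min_length: int = MIN_PEPTIDE_LENGTH,
) -> ASPeptide | None:
    """Candidate peptide for one frame offset, or ``None``.

    Junction events return the maximal stop-free segment covering the
    splice site; single-feature events return the longest stop-free
    segment.  Segments shorter than ``min_length`` are rejected.
    """
    if offset not in (0, 1, 2):
        raise ValueError(f"frame offset must be 0, 1 or 2, got {offset}")
    if len(ast.sequence) - offset < 3:
        return None
    aa = _translate_frame(ast.sequence, offset)
    runs = _stop_free_runs(aa)
    if not runs:
        return None

    if ast.junction_offset is None:
        start, pep = max(runs, key=lambda r: (len(r[1]), -r[0]))
        if len(pep) < min_length:
            return None
        return ASPeptide(ast, pep, offset, phase_used)

    rel = ast.junction_offset - offset
    if rel <= 0:
        return None  # no left-side nucleotides survive in this frame
    if rel % 3 == 0:
        # splice site falls between codons rel/3 - 1 and rel/3
        left_codon, right_codon = rel // 3 - 1, rel // 3
        shared = False
        needed = (left_codon, right_codon)
    else:
        # one codon straddles the site: its residue is shared
        shared_codon = rel // 3
        shared = True
        needed = (shared_codon,)
    for start, pep in runs:
        end = start + len(pep)
        if all(start <= c < end for c in needed):
            if shared and len(pep) < 2:
                return None  # shared residue needs >=1 neighbour
            if len(pep) < min_length:
                return None
            jidx = needed[-1] - start
            return ASPeptide(ast, pep, offset, phase_used,
                             junction_residue_index=jidx, junction_shared=shared)
    return None


def translate_with_phase(
    ast: ArtificialSplicingTranscript,
    phase: int,
    *,
    min_length: int = MIN_PEPTIDE_LENGTH,
) -> ASPeptide | None:
    """Phase-directed translation: phase ``p`` means ``p`` bases of the
    first codon came from the previous exon, so the first complete codon
    starts at offset ``(3 - p) % 3``."""
    if phase not in (0, 1, 2):
        raise ValueError(f"phase must be 0, 1 or 2, got {phase}")
    return translate_in_frame(ast, (3 - phase) % 3, phase_used=True,
                              min_length=min_length)


def frame_candidates(
    ast: ArtificialSplicingTranscript,
    *,
    min_length: int = MIN_PEPTIDE_LENGTH,
) -> list[ASPeptide | None]:
    """The three per-frame candidates considered before selection."""
    return [translate_in_frame(ast, f, min_length=min_length) for f in (0, 1, 2)]


def translate_three_frames(
    ast: ArtificialSplicingTranscript,
    *,
    min_length: int = MIN_PEPTIDE_LENGTH,
) -> ASPeptide | None:
    """Try frames 0..2 and keep the candidate with the longest
    junction-spanning peptide (longest peptide for single-feature
    events); ties break to the lowest frame."""
    best: ASPeptide | None = None
    for cand in frame_candidates(ast, min_length=min_length):
        if cand is None:
            continue
        score = junction_span_length(cand, ast) if ast.junction_offset is not None else len(cand)
        if score == 0:
            continue
        if best is None or score > _score_of(best, ast):
            best = cand
    return best


def _score_of(pep: ASPeptide, ast: ArtificialSplicingTranscript) -> int:
    return junction_span_length(pep, ast) if ast.junction_offset is not None else len(pep)


def junction_span_length(pep: ASPeptide, ast: ArtificialSplicingTranscript) -> int:
    """Residue count of a junction-covering peptide, else 0."""
    if pep.ast is not ast and pep.ast.sequence != ast.sequence:
        raise ValueError("peptide was not derived from this AST")
    if ast.junction_offset is None or pep.junction_residue_index is None:
        return 0
    return len(pep.sequence)


def annotate_junction(pep: ASPeptide) -> str:
    """Human-readable junction notation.

    ``^`` marks a splice site between residues, ``(X)`` a residue whose
    codon straddles the site.  Single-feature peptides are unmarked.
    Stripping the markers recovers the plain sequence.
    """
    seq, i = pep.sequence, pep.junction_residue_index
    if i is None:
        return seq
    if pep.junction_shared:
        return f"{seq[:i]}({seq[i]}){seq[i + 1:]}"
    return f"{seq[:i]}^{seq[i:]}"


def strip_markers(notation: str) -> str:
    return notation.replace("^", "").replace("(", "").replace(")", "")
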