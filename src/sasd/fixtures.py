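"""Synthetic genomes, annotations, proteomes and hit tables with known truth.

Every downstream stage of the pipeline is testable offline: this module
plants gene structures with recorded coordinates and sequences into a
random genome, writes them as standard FASTA/GTF, and emulates
search-engine output as per-sample peptide-hit tables.

Stop-free planting uses a dinucleotide constraint rather than rejection
sampling over whole features: a sequence containing no ``TA`` and no
``TG`` dinucleotide cannot contain a stop codon (TAA, TAG, TGA) in *any*
reading frame, and starting every feature with ``C`` keeps junctions
stop-free too.  This guarantees that every artificial splicing transcript
assembled from such features translates cleanly in all three frames.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from Bio.Seq import reverse_complement

SPACER_MIN = 500  # nt between genes, so flanks can never cross gene boundaries

_BASES = np.array(list("ACGT"))


@dataclass(frozen=True)
class FixtureSpec:
    """Parameters of one synthetic genome/annotation fixture."""

    n_genes: int = 2
    exons_per_gene: int | tuple[int, int] = 4
    exon_length_range: tuple[int, int] = (150, 250)
    intron_length_range: tuple[int, int] = (150, 250)
    strand_policy: str = "all_plus"  # all_plus | all_minus | mixed
    seed: int = 0
    plant_stop_free_frame: bool = True
    plant_phases: bool = False
    contig_id: str = "chrT"

    def __post_init__(self):
        if self.n_genes < 1:
            raise ValueError("n_genes must be >= 1")
        lo_e = self.exons_per_gene if isinstance(self.exons_per_gene, int) else self.exons_per_gene[0]
        if lo_e < 1:
            raise ValueError("exons_per_gene must be >= 1")
        for rng_ in (self.exon_length_range, self.intron_length_range):
            if rng_[0] < 3:
                raise ValueError("feature lengths must be >= 3")
        if self.strand_policy not in ("all_plus", "all_minus", "mixed"):
            raise ValueError(f"unknown strand_policy {self.strand_policy!r}")


@dataclass(frozen=True)
class TruthFeature:
    """Ground-truth record for one planted exon or intron.

    Coordinates are 0-based half-open genomic; ``sequence`` is in
    transcript orientation (reverse-complemented for minus-strand genes).
    """

    gene_id: str
    transcript_id: str
    kind: str  # "exon" | "intron"
    ordinal: int
    contig: str
    start: int
    end: int
    strand: str
    sequence: str
    phase: int | None = None


@dataclass
class Fixture:
    spec: FixtureSpec
    contig_sequence: str
    features: list[TruthFeature]
    genome_path: Path | None = None
    gtf_path: Path | None = None
    truth_path: Path | None = None

    def transcript_sequence(self, transcript_id: str) -> str:
        exons = sorted(
            (f for f in self.features if f.transcript_id == transcript_id and f.kind == "exon"),
            key=lambda f: f.ordinal,
        )
        return "".join(f.sequence for f in exons)


def _random_seq(rng: np.random.Generator, length: int) -> str:
    return "".join(_BASES[rng.integers(0, 4, size=length)])


def _stop_free_seq(rng: np.random.Generator, length: int) -> str:
    # first base C so a junction with any preceding feature cannot form a
    # stop; after T only C/T are allowed (never A/G), killing TAA/TAG/TGA
    # in every frame
    out = ["C"]
    for _ in range(length - 1):
        if out[-1] == "T":
            out.append("CT"[rng.integers(0, 2)])
        else:
            out.append(_BASES[rng.integers(0, 4)])
    return "".join(out)


def _feature_seq(rng, length, stop_free):
    return _stop_free_seq(rng, length) if stop_free else _random_seq(rng, length)


def _draw(rng: np.random.Generator, value: int | tuple[int, int]) -> int:
    if isinstance(value, int):
        return value
    return int(rng.integers(value[0], value[1] + 1))


def generate_fixture(spec: FixtureSpec, outdir: str | Path | None = None) -> Fixture:
    """Build a fixture; optionally write genome.fa / annotation.gtf /
    ground_truth.tsv under ``outdir``.  Same spec + seed => identical
    files, byte for byte."""
    rng = np.random.default_rng(spec.seed)
    contig_parts: list[str] = [_random_seq(rng, SPACER_MIN)]
    pos = SPACER_MIN
    features: list[TruthFeature] = []

    for g in range(1, spec.n_genes + 1):
        gene_id = f"GENE{g:03d}"
        tid = f"TX{g:03d}"
        n_exons = _draw(rng, spec.exons_per_gene)
        if spec.strand_policy == "all_plus":
            strand = "+"
        elif spec.strand_policy == "all_minus":
            strand = "-"
        else:
            strand = "+-"[rng.integers(0, 2)]

        # transcript-oriented feature sequences: E1, i1, E2, i2, ...
        seqs: list[tuple[str, int, str]] = []
        for k in range(1, n_exons + 1):
            seqs.append(("exon", k, _feature_seq(rng, _draw(rng, spec.exon_length_range),
                                                 spec.plant_stop_free_frame)))
            if k < n_exons:
                seqs.append(("intron", k, _feature_seq(rng, _draw(rng, spec.intron_length_range),
                                                       spec.plant_stop_free_frame)))

        phases = _phases_for(seqs) if spec.plant_phases else {}

        pre_mrna = "".join(s for _, _, s in seqs)
        genomic = pre_mrna if strand == "+" else reverse_complement(pre_mrna)
        # genomic coordinates: walk the pre-mRNA left-to-right for +,
        # right-to-left for -
        offset = 0
        for kind, ordinal, s in seqs:
            if strand == "+":
                start = pos + offset
                end = start + len(s)
            else:
                end = pos + len(genomic) - offset
                start = end - len(s)
            features.append(
                TruthFeature(gene_id, tid, kind, ordinal, spec.contig_id,
                             start, end, strand, s,
                             phase=phases.get((kind, ordinal)))
            )
            offset += len(s)
        contig_parts.append(genomic)
        pos += len(genomic)
        spacer = _random_seq(rng, SPACER_MIN)
        contig_parts.append(spacer)
        pos += SPACER_MIN

    fixture = Fixture(spec, "".join(contig_parts), features)
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        fixture.genome_path = outdir / "genome.fa"
        fixture.gtf_path = outdir / "annotation.gtf"
        fixture.truth_path = outdir / "ground_truth.tsv"
        write_genome_fasta(fixture, fixture.genome_path)
        write_gtf(fixture, fixture.gtf_path)
        write_truth_tsv(fixture, fixture.truth_path)
    return fixture


def _phases_for(seqs) -> dict[tuple[str, int], int]:
    """GFF3-convention phase per exon from cumulative coding length:
    phase = bases the previous exon contributed to the boundary codon."""
    phases = {}
    cum = 0
    for kind, ordinal, s in seqs:
        if kind != "exon":
            continue
        phases[("exon", ordinal)] = cum % 3
        cum += len(s)
    return phases


def write_genome_fasta(fixture: Fixture, path: str | Path, width: int = 60) -> None:
    seq = fixture.contig_sequence
    with open(path, "w") as fh:
        fh.write(f">{fixture.spec.contig_id}\n")
        for i in range(0, len(seq), width):
            fh.write(seq[i : i + width] + "\n")


def write_gtf(fixture: Fixture, path: str | Path) -> None:
    rows = []
    for f in fixture.features:
        if f.kind != "exon":
            continue
        frame = "." if f.phase is None else str(f.phase)
        attrs = (f'gene_id "{f.gene_id}"; transcript_id "{f.transcript_id}"; '
                 f'gene_name "{f.gene_id}"; exon_number "{f.ordinal}";')
        rows.append((f.contig, "fixture", "exon", f.start + 1, f.end, ".",
                     f.strand, frame, attrs))
    rows.sort(key=lambda r: (r[0], r[3], r[4]))
    with open(path, "w") as fh:
        for r in rows:
            fh.write("\t".join(str(x) for x in r) + "\n")


def write_truth_tsv(fixture: Fixture, path: str | Path) -> None:
    df = pd.DataFrame(
        [
            {
                "gene_id": f.gene_id, "transcript_id": f.transcript_id,
                "kind": f.kind, "ordinal": f.ordinal, "contig": f.contig,
                "start": f.start, "end": f.end, "strand": f.strand,
                "phase": "" if f.phase is None else f.phase,
                "sequence": f.sequence,
            }
            for f in fixture.features
        ]
    )
    df.to_csv(path, sep="\t", index=False)


def mirror_fixture_files(
    genome_in: str | Path, gtf_in: str | Path,
    genome_out: str | Path, gtf_out: str | Path,
) -> None:
    """Reverse-complement the genome and mirror the annotation coordinates.

    The mirrored pair describes the *same* transcripts on the opposite
    strand; extracted feature sequences are identical strings, which
    drives the strand-symmetry checks.
    """
    from pyfaidx import Fasta

    fa = Fasta(str(genome_in), as_raw=True, rebuild=False)
    lengths = {name: len(fa[name]) for name in fa.keys()}
    with open(genome_out, "w") as fh:
        for name in fa.keys():
            rc = reverse_complement(str(fa[name][:]))
            fh.write(f">{name}\n")
            for i in range(0, len(rc), 60):
                fh.write(rc[i : i + 60] + "\n")

    out_rows = []
    with open(gtf_in) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            f = line.rstrip("\n").split("\t")
            L = lengths[f[0]]
            start, end = int(f[3]), int(f[4])
            f[3], f[4] = str(L - end + 1), str(L - start + 1)
            f[6] = "-" if f[6] == "+" else "+"
            out_rows.append(f)
    out_rows.sort(key=lambda f: (f[0], int(f[3]), int(f[4])))
    with open(gtf_out, "w") as fh:
        for f in out_rows:
            fh.write("\t".join(f) + "\n")


def generate_hit_table(
    db_entries,
    n_samples_per_group: int,
    presence_probabilities,
    seed: int,
    group_labels: tuple[str, str] = ("control", "case"),
) -> pd.DataFrame:
    """Emulated search-engine output: per-sample Bernoulli presence.

    ``presence_probabilities`` maps entry_id -> (p_groupA, p_groupB); a
    single pair applies to every entry.  Present hits draw an e-value
    uniformly from (0, 0.05).
    """
    rng = np.random.default_rng(seed)
    if isinstance(presence_probabilities, tuple):
        probs = {e.entry_id: presence_probabilities for e in db_entries}
    else:
        probs = presence_probabilities
    rows = []
    for gi, glabel in enumerate(group_labels):
        for s in range(1, n_samples_per_group + 1):
            sample_id = f"{glabel}_{s:02d}"
            for entry in db_entries:
                pa, pb = probs.get(entry.entry_id, (0.0, 0.0))
                p = (pa, pb)[gi]
                if not 0.0 <= p <= 1.0:
                    raise ValueError("presence probabilities must lie in [0, 1]")
                if rng.random() < p:
                    rows.append(
                        {"sample_id": sample_id, "group": glabel,
                         "peptide": entry.peptide, "entry_id": entry.entry_id,
                         "evalue": float(rng.uniform(0.0, 0.05))}
                    )
    return pd.DataFrame(rows, columns=["sample_id", "group", "peptide", "entry_id", "evalue"])


def normal_proteome(fixture: Fixture) -> dict[str, tuple[str, str]]:
    """Frame-0 translations of the planted spliced (normal) transcripts,
    as protein_id -> (gene_id, sequence).  With stop-free planting these
    are clean full-length proteins; junction peptides from skipped exons
    or retained introns are never substrings of them."""
    from Bio.Seq import Seq

    out: dict[str, tuple[str, str]] = {}
    seen: dict[str, str] = {}
    for f in fixture.features:
        if f.kind == "exon" and f.transcript_id not in seen:
            seen[f.transcript_id] = f.gene_id
    for tid, gid in seen.items():
        mrna = fixture.transcript_sequence(tid)
        mrna = mrna[: len(mrna) - len(mrna) % 3]
        aa = str(Seq(mrna).translate(table=1)).split("*")[0]
        out[f"{tid}_P1"] = (gid, aa)
    return out


def write_reference_proteome(
    proteins: dict[str, tuple[str, str]], path: str | Path, width: int = 60
) -> None:
    """Write a protein FASTA whose headers carry ``gene=`` attributes.

    ``proteins`` maps protein_id -> (gene_id, sequence).
    """
    with open(path, "w") as fh:
        for pid in sorted(proteins):
            gid, seq = proteins[pid]
            fh.write(f">{pid} gene={gid}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")
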