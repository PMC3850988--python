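"""Post-identification analysis of search-engine hits.

After a mass-spectrometry engine has been run against the exported
junction-peptide FASTA, this module consumes its per-sample peptide hits
and performs the downstream calls:

* e-value filtering (engine significance threshold, default 0.1);
* cross-validation filtering: a peptide is trusted only when identified
  in at least ``n`` distinct samples (default 2);
* novelty calling: a junction peptide is a *novel isoform* of its source
  gene when it is not a substring of any annotated protein of that gene
  (gene scope; a global whole-proteome scope is optional);
* differential presence: per peptide, a one-sided rank test of
  per-sample spectral counts between two groups, exact by permutation
  for small designs, tie-corrected normal approximation otherwise.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

EVALUE_CUTOFF = 0.1
MIN_SAMPLES = 2
EXACT_MAX_SAMPLES = 12  # exhaustive permutation up to C(12,6) = 924 labelings

REQUIRED_HIT_COLUMNS = ("sample_id", "peptide", "entry_id", "evalue")


@dataclass(frozen=True)
class NoveltyCall:
    peptide: str
    source_gene_id: str
    gene_scope_hit: bool
    global_hit: bool | None
    novel: bool


@dataclass(frozen=True)
class MarkerTestResult:
    peptide: str
    entry_id: str
    h: int  # distinct control-group samples with the peptide
    c: int  # distinct case-group samples with the peptide
    p_value: float
    direction: str  # case_up | control_up | none
    degenerate: bool = False


# --- hit ingest ------------------------------------------------------------

def load_hits(path: str | Path, entries: Mapping[str, object] | None = None) -> pd.DataFrame:
    """Read the canonical hits TSV (sample_id, peptide, entry_id, evalue
    [, group]).  Rows with non-positive e-values, unknown entry ids or
    peptides that are not substrings of their entry are dropped with a
    log line; a missing required column is a hard error."""
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str, "peptide": str,
                                            "entry_id": str})
    missing = [c for c in REQUIRED_HIT_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"hits table {path} lacks required column(s): {missing}")
    bad_e = df["evalue"] <= 0
    if bad_e.any():
        logger.warning("%d hit(s) with non-positive e-value rejected", int(bad_e.sum()))
        df = df[~bad_e]
    if entries is not None:
        known = df["entry_id"].isin(entries.keys())
        if (~known).any():
            logger.warning("%d hit(s) referencing unknown entries excluded",
                           int((~known).sum()))
            df = df[known]
        ok = [
            pep in _entry_peptide(entries[eid])
            for pep, eid in zip(df["peptide"], df["entry_id"])
        ]
        if not all(ok):
            logger.warning("%d hit(s) whose peptide is not contained in the "
                           "referenced entry excluded", ok.count(False))
            df = df[ok]
    return df.reset_index(drop=True)


def _entry_peptide(entry) -> str:
    return entry if isinstance(entry, str) else entry.peptide


def filter_evalue(hits: pd.DataFrame, cutoff: float = EVALUE_CUTOFF) -> pd.DataFrame:
    return hits[hits["evalue"] <= cutoff].reset_index(drop=True)


def filter_min_samples(hits: pd.DataFrame, n: int = MIN_SAMPLES) -> set[str]:
    """Peptides identified in at least ``n`` distinct samples (duplicate
    hits within one sample count once)."""
    per_pep = hits.groupby("peptide")["sample_id"].nunique()
    return set(per_pep[per_pep >= n].index)


# --- novelty ---------------------------------------------------------------

class ReferenceProteome:
    """Known protein sequences indexed by gene id.

    FASTA headers must carry the gene in a ``gene=<id>`` attribute (the
    attribute key is configurable).
    """

    def __init__(self, by_gene: Mapping[str, Sequence[tuple[str, str]]]):
        self._by_gene = {g: list(ps) for g, ps in by_gene.items()}

    @classmethod
    def from_fasta(cls, path: str | Path, gene_attr: str = "gene") -> "ReferenceProteome":
        from Bio import SeqIO

        by_gene: dict[str, list[tuple[str, str]]] = {}
        n = 0
        for rec in SeqIO.parse(str(path), "fasta"):
            n += 1
            gene = None
            for tok in rec.description.split():
                if tok.startswith(f"{gene_attr}="):
                    gene = tok.split("=", 1)[1]
                    break
            if gene is None:
                logger.warning("protein %s lacks a %s= attribute; indexed under "
                               "its own id", rec.id, gene_attr)
                gene = rec.id
            by_gene.setdefault(gene, []).append((rec.id, str(rec.seq).upper()))
        if n == 0:
            raise ValueError(f"no protein records parsed from {path}")
        return cls(by_gene)

    def proteins_of(self, gene_id: str) -> list[tuple[str, str]]:
        return self._by_gene.get(gene_id, [])

    def all_proteins(self) -> Iterable[tuple[str, str]]:
        for ps in self._by_gene.values():
            yield from ps

    @property
    def gene_ids(self) -> set[str]:
        return set(self._by_gene)


def _fold_il(s: str) -> str:
    return s.replace("I", "L")


def check_novelty(
    peptide: str,
    source_gene_id: str,
    proteome: ReferenceProteome,
    scope: str = "gene",
    il_equivalent: bool = False,
) -> NoveltyCall:
    """Exact substring search of the peptide against known proteins.

    With the default gene scope the haystack is restricted to the source
    gene's proteins: a peptide may match proteins of *other* genes and
    still be a novel isoform of its own gene.  ``il_equivalent`` folds
    isoleucine onto leucine on both sides (indistinguishable by MS).
    """
    if scope not in ("gene", "global"):
        raise ValueError(f"unknown novelty scope {scope!r}")
    needle = _fold_il(peptide) if il_equivalent else peptide

    def _hit(prots) -> bool:
        for _, seq in prots:
            hay = _fold_il(seq) if il_equivalent else seq
            if needle in hay:
                return True
        return False

    gene_prots = proteome.proteins_of(source_gene_id)
    if not gene_prots:
        logger.warning("gene %s absent from the reference proteome; peptide "
                       "trivially novel in gene scope", source_gene_id)
    gene_hit = _hit(gene_prots)
    global_hit = _hit(proteome.all_proteins()) if scope == "global" else None
    novel = not (global_hit if scope == "global" else gene_hit)
    return NoveltyCall(peptide, source_gene_id, gene_hit, global_hit, novel)


# --- differential presence -------------------------------------------------

def presence_matrix(hits: pd.DataFrame, samples: Sequence[str]) -> pd.DataFrame:
    """Peptide x sample matrix of spectral counts (0 when absent)."""
    counts = (
        hits.groupby(["peptide", "sample_id"]).size().unstack(fill_value=0)
    )
    return counts.reindex(columns=list(samples), fill_value=0).fillna(0).astype(int)


def _ranksum_statistic(case: np.ndarray, control: np.ndarray) -> float:
    pooled = np.concatenate([case, control])
    ranks = stats.rankdata(pooled)
    return float(ranks[: len(case)].sum())


def rank_sum_presence_test(case: np.ndarray, control: np.ndarray) -> tuple[float, bool]:
    """One-sided (case elevated) Wilcoxon rank-sum p-value on per-sample
    counts.  Exhaustive permutation of group labels when the design has
    at most 12 samples; tie-corrected normal approximation otherwise.
    Returns (p, degenerate)."""
    case = np.asarray(case, dtype=float)
    control = np.asarray(control, dtype=float)
    if len(case) < 2 or len(control) < 2:
        raise ValueError("each group needs at least 2 samples")
    if np.ptp(np.concatenate([case, control])) == 0:
        return 1.0, True
    if len(case) + len(control) <= EXACT_MAX_SAMPLES:
        res = stats.permutation_test(
            (case, control),
            _ranksum_statistic,
            permutation_type="independent",
            alternative="greater",
            n_resamples=np.inf,
            vectorized=False,
        )
        return float(res.pvalue), False
    res = stats.mannwhitneyu(case, control, alternative="greater",
                             method="asymptotic")
    return float(res.pvalue), False


def signed_rank_presence_test(case: np.ndarray, control: np.ndarray) -> tuple[float, bool]:
    """One-sided Wilcoxon signed-rank test on *paired* samples; pairs are
    positional (case[i] with control[i])."""
    case = np.asarray(case, dtype=float)
    control = np.asarray(control, dtype=float)
    if len(case) != len(control):
        raise ValueError("signed-rank pairing requires equally sized groups")
    diffs = case - control
    if np.all(diffs == 0):
        return 1.0, True
    res = stats.wilcoxon(case, control, alternative="greater",
                         zero_method="wilcox")
    return float(res.pvalue), False


def differential_presence(
    hits: pd.DataFrame,
    group_assignment: Mapping[str, str],
    case_group: str,
    method: str = "rank_sum",
    peptides: Iterable[str] | None = None,
) -> list[MarkerTestResult]:
    """Per-peptide one-sided test for elevated presence in the case group.

    ``group_assignment`` maps sample_id -> group label; exactly two
    groups, each with >=2 samples.  Samples without any hit still count
    as zeros.  Results are sorted by ascending p-value (peptide as
    tie-break).
    """
    if method not in ("rank_sum", "signed_rank"):
        raise ValueError(f"unknown method {method!r}")
    groups = sorted(set(group_assignment.values()))
    if len(groups) != 2 or case_group not in groups:
        raise ValueError("need exactly two groups including the case group")
    control_group = next(g for g in groups if g != case_group)
    case_samples = sorted(s for s, g in group_assignment.items() if g == case_group)
    control_samples = sorted(s for s, g in group_assignment.items() if g == control_group)
    if len(case_samples) < 2 or len(control_samples) < 2:
        raise ValueError("each group needs at least 2 samples")

    all_samples = control_samples + case_samples
    mat = presence_matrix(hits, all_samples)
    if peptides is not None:
        mat = mat.loc[[p for p in mat.index if p in set(peptides)]]

    entry_of = (
        hits.drop_duplicates("peptide").set_index("peptide")["entry_id"].to_dict()
    )
    test = rank_sum_presence_test if method == "rank_sum" else signed_rank_presence_test

    results = []
    for pep, row in mat.iterrows():
        case_v = row[case_samples].to_numpy()
        ctrl_v = row[control_samples].to_numpy()
        p, degen = test(case_v, ctrl_v)
        if degen:
            direction = "none"
        else:
            direction = "case_up" if case_v.mean() > ctrl_v.mean() else (
                "control_up" if case_v.mean() < ctrl_v.mean() else "none")
        results.append(
            MarkerTestResult(
                peptide=pep,
                entry_id=entry_of.get(pep, ""),
                h=int((ctrl_v > 0).sum()),
                c=int((case_v > 0).sum()),
                p_value=p,
                direction=direction,
                degenerate=degen,
            )
        )
    results.sort(key=lambda r: (r.p_value, r.peptide))
    return results


def call_markers(
    results: Sequence[MarkerTestResult],
    alpha: float = 0.05,
    bh: bool = False,
) -> list[MarkerTestResult]:
    """Markers at ``p < alpha``; no multiplicity adjustment by default,
    Benjamini-Hochberg when ``bh`` is set."""
    if not results:
        return []
    if bh:
        from statsmodels.stats.multitest import multipletests

        reject, *_ = multipletests([r.p_value for r in results], alpha=alpha,
                                   method="fdr_bh")
        return [r for r, rej in zip(results, reject) if rej]
    return [r for r in results if r.p_value < alpha]


def marker_report(
    results: Sequence[MarkerTestResult],
    entries: Mapping[str, object] | None = None,
) -> pd.DataFrame:
    """Tabular marker report (sequence, gene, transcript, mode, type,
    pvalue, h, c)."""
    rows = []
    for r in results:
        row = {"peptide": r.peptide, "entry_id": r.entry_id,
               "pvalue": r.p_value, "h": r.h, "c": r.c,
               "direction": r.direction}
        if entries is not None and r.entry_id in entries:
            e = entries[r.entry_id]
            row.update(gene=e.gene_id, transcript=e.transcript_id,
                       mode=e.mode, type=e.type)
        rows.append(row)
    cols = ["peptide", "entry_id", "pvalue", "h", "c", "direction"]
    return pd.DataFrame(rows, columns=cols if not rows else None)
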