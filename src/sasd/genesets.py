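"""Context gene sets (pathway/disease/drug/organ/custom) and id mapping.

Contexts arrive as GMT files or long-format TSV; heterogeneous member ids
(symbols, transcript ids, protein ids) are mapped onto the build's
canonical gene ids through a user-supplied alias table.  Symbol matching
is case-insensitive; unresolved aliases are reported, never fatal.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable

CONTEXT_KINDS = ("pathway", "disease", "drug", "organ", "custom")

_ID_LIST_SPLIT = re.compile(r"[,;\s]+")


class GeneSetError(ValueError):
    pass


@dataclass(frozen=True)
class GeneSetContext:
    context_kind: str  # pathway | disease | drug | organ | custom
    context_id: str
    context_name: str
    members: frozenset[str]

    def __post_init__(self):
        if not self.members:
            raise GeneSetError(f"context {self.context_id!r} has no members")
        if self.context_kind not in CONTEXT_KINDS:
            raise GeneSetError(f"unknown context kind {self.context_kind!r}")


class IdMap:
    """Many-to-one alias -> canonical gene id mapping.

    Canonical ids always resolve to themselves, so resolution is
    idempotent.  Alias lookup is case-insensitive.
    """

    def __init__(self, alias_to_canonical: dict[str, str]):
        self._map = {a.lower(): c for a, c in alias_to_canonical.items()}
        for c in set(alias_to_canonical.values()):
            self._map.setdefault(c.lower(), c)

    @classmethod
    def from_tsv(cls, path: str | Path) -> "IdMap":
        """Two-column TSV: alias <tab> canonical_gene_id (header optional,
        detected by an 'alias' first field)."""
        mapping: dict[str, str] = {}
        with open(path) as fh:
            for lineno, line in enumerate(fh, 1):
                line = line.rstrip("\n")
                if not line or line.startswith("#"):
                    continue
                parts = line.split("\t")
                if len(parts) < 2:
                    raise GeneSetError(f"{path}:{lineno}: expected 2 columns")
                if lineno == 1 and parts[0].lower() in ("alias", "id"):
                    continue
                mapping[parts[0]] = parts[1]
        return cls(mapping)

    def get(self, raw_id: str) -> str | None:
        return self._map.get(raw_id.lower())


def identity_map(canonical_ids: Iterable[str]) -> IdMap:
    return IdMap({c: c for c in canonical_ids})


def parse_id_list(raw: str) -> list[str]:
    """Split a user id list on comma, semicolon, whitespace or newlines."""
    return [tok for tok in _ID_LIST_SPLIT.split(raw.strip()) if tok]


def load_gene_sets(path: str | Path, kind: str = "custom") -> list[GeneSetContext]:
    """Load contexts from GMT (`name<TAB>description<TAB>member...`) or
    long TSV (`set_id<TAB>member` or `set_id<TAB>kind<TAB>member`).
    Duplicate members collapse; malformed lines raise with the line
    number."""
    path = Path(path)
    if path.suffix.lower() == ".gmt":
        return _load_gmt(path, kind)
    return _load_long_tsv(path, kind)


def _load_gmt(path: Path, kind: str) -> list[GeneSetContext]:
    contexts = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise GeneSetError(
                    f"{path}:{lineno}: GMT line needs name, description and >=1 member"
                )
            name, desc, *members = parts
            members = [m for m in members if m]
            if not members:
                raise GeneSetError(f"{path}:{lineno}: context {name!r} has no members")
            contexts.append(GeneSetContext(kind, name, desc or name, frozenset(members)))
    return contexts


def _load_long_tsv(path: Path, default_kind: str) -> list[GeneSetContext]:
    grouped: dict[str, tuple[str, set[str]]] = {}
    order: list[str] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) == 2:
                cid, kind, member = parts[0], default_kind, parts[1]
            elif len(parts) >= 3:
                cid, kind, member = parts[0], parts[1], parts[2]
            else:
                raise GeneSetError(f"{path}:{lineno}: expected 2 or 3 columns")
            if lineno == 1 and member.lower() in ("member", "gene", "gene_id"):
                continue
            if cid not in grouped:
                grouped[cid] = (kind, set())
                order.append(cid)
            grouped[cid][1].add(member)
    out = []
    for cid in order:
        kind, members = grouped[cid]
        out.append(GeneSetContext(kind, cid, cid, frozenset(members)))
    return out


def resolve_ids(raw_ids: Iterable[str], id_map: IdMap) -> tuple[set[str], list[str]]:
    """Map raw ids onto canonical gene ids; returns (resolved set,
    unresolved list in input order)."""
    resolved: set[str] = set()
    unresolved: list[str] = []
    for rid in raw_ids:
        canon = id_map.get(rid)
        if canon is None:
            unresolved.append(rid)
        else:
            resolved.add(canon)
    return resolved, unresolved
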