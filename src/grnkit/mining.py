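"""Dictionary-based mining of disease-associated gene/TF symbols from an
abstract corpus, and GRN filtering by the mined lists."""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field

from .catalog import GENE, TF, Lexicon

__all__ = [
    "AbstractRecord",
    "AssociationLists",
    "parse_corpus",
    "mine_symbols",
    "filter_grns",
]

# whole tokens only; hyphen kept word-internal so miRNA-style names stay intact
_TOKEN = re.compile(r"[A-Za-z0-9][A-Za-z0-9-]*")


@dataclass(frozen=True)
class AbstractRecord:
    record_id: str
    text: str

    def __post_init__(self):
        if not self.text.strip():
            raise ValueError(f"abstract {self.record_id!r} has empty text")


@dataclass
class AssociationLists:
    genes: set[str] = field(default_factory=set)
    tfs: set[str] = field(default_factory=set)
    hit_counts: dict[str, int] = field(default_factory=dict)

    def __contains__(self, symbol: str) -> bool:
        return symbol in self.genes or symbol in self.tfs


def parse_corpus(text: str) -> list[AbstractRecord]:
    """Parse a plain-text corpus: records separated by blank lines, first
    line of each record is its id, the rest is the abstract text."""
    records = []
    for block in re.split(r"\n\s*\n", text.strip()):
        lines = block.strip().splitlines()
        if not lines:
            continue
        rid = lines[0].strip()
        body = " ".join(line.strip() for line in lines[1:])
        if not body:
            continue
        records.append(AbstractRecord(rid, body))
    return records


def mine_symbols(
    corpus: list[AbstractRecord], lexicon: Lexicon, min_hits: int = 1
) -> AssociationLists:
    """List every gene/TF symbol whose name (or an alias) occurs as a whole
    token, case-insensitively, in at least ``min_hits`` abstracts.

    miRNA symbols are not mined.  Hit counts are per-abstract (multiple
    mentions within one abstract count once).
    """
    if not corpus:
        warnings.warn("empty corpus: association lists are empty")
        return AssociationLists()

    token_to_symbol: dict[str, str] = {}
    for sym in lexicon.symbols:
        if lexicon.class_of(sym) in (GENE, TF):
            token_to_symbol[sym.upper()] = sym
    for alias, sym in lexicon.alias_map().items():
        if lexicon.class_of(sym) in (GENE, TF):
            token_to_symbol.setdefault(alias, sym)

    hits: dict[str, int] = {}
    for rec in corpus:
        seen = set()
        for tok in _TOKEN.findall(rec.text):
            sym = token_to_symbol.get(tok.upper())
            if sym is not None:
                seen.add(sym)
        for sym in seen:
            hits[sym] = hits.get(sym, 0) + 1

    out = AssociationLists()
    for sym, n in hits.items():
        if n < min_hits:
            continue
        out.hit_counts[sym] = n
        if lexicon.class_of(sym) == TF:
            out.tfs.add(sym)
        else:
            out.genes.add(sym)
    return out


def filter_grns(triples, assoc: AssociationLists, mode: str = "any"):
    """Keep trios containing mined symbols.

    ``mode="any"``: gene in mined genes OR tf in mined TFs;
    ``mode="both"``: both conditions.  Returns (kept, per-type counts).
    """
    if mode not in ("any", "both"):
        raise ValueError(f"unknown mode {mode!r}")
    kept = []
    counts: dict[str, int] = {}
    for tr in triples:
        gene_hit = tr.gene in assoc.genes
        tf_hit = tr.tf in assoc.tfs
        ok = (gene_hit and tf_hit) if mode == "both" else (gene_hit or tf_hit)
        if ok:
            kept.append(tr)
            counts[tr.motif_type] = counts.get(tr.motif_type, 0) + 1
    return kept, counts
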