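"""Interaction catalog: lexicon handling, symbol normalization, evidence
filtering and feed-forward / feedback tagging of regulatory edges.

Edges are directed and restricted to the four regulatory kinds
``TF->GENE`` (``TG``), ``TF->MIRNA`` (``TM``), ``MIRNA->TF`` (``MT``) and
``MIRNA->GENE`` (``MG``).  A TF appearing as the target of another TF is
treated in the gene role (kind ``TG``).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace

import pandas as pd

__all__ = [
    "TF",
    "GENE",
    "MIRNA",
    "ENTITY_CLASSES",
    "Lexicon",
    "Interaction",
    "InteractionCatalog",
    "load_lexicon",
    "load_edges",
    "normalize_symbols",
    "filter_evidence",
    "tag_fb_ff",
    "interactions_to_frame",
    "frame_to_interactions",
]

TF = "TF"
GENE = "GENE"
MIRNA = "MIRNA"
ENTITY_CLASSES = (TF, GENE, MIRNA)

# (source_class, target_class) -> edge-kind code
_EDGE_KINDS = {
    (TF, GENE): "TG",
    (TF, TF): "TG",  # TF targeted in the gene role
    (TF, MIRNA): "TM",
    (MIRNA, TF): "MT",
    (MIRNA, GENE): "MG",
}

EVIDENCE_FIELDS = ("tfbs_z", "mem_p", "cometa_score")


class Lexicon:
    """Official-symbol dictionary with entity classes and aliases.

    Symbol matching is case-insensitive; the canonical (file) spelling is
    preserved on output so that miRNA names keep their conventional casing.
    """

    def __init__(self, classes: dict[str, str], aliases: dict[str, str] | None = None):
        self._classes = dict(classes)
        self._canon = {sym.upper(): sym for sym in self._classes}
        if len(self._canon) != len(self._classes):
            raise ValueError("symbols not unique under case-insensitive matching")
        self._aliases: dict[str, str] = {}
        for alias, sym in (aliases or {}).items():
            key = alias.upper()
            if key in self._canon:
                warnings.warn(
                    f"alias {alias!r} collides with official symbol "
                    f"{self._canon[key]!r}; alias dropped"
                )
                continue
            self._aliases[key] = sym
        self.n_skipped = 0  # malformed rows skipped by load_lexicon

    def __len__(self) -> int:
        return len(self._classes)

    def __contains__(self, name: str) -> bool:
        return self.resolve(name) is not None

    @property
    def symbols(self) -> list[str]:
        return list(self._classes)

    def resolve(self, name: str) -> str | None:
        """Map a raw name (symbol or alias, any case) to its official symbol."""
        key = name.strip().upper()
        if key in self._canon:
            return self._canon[key]
        return self._aliases.get(key)

    def class_of(self, symbol: str) -> str:
        sym = self.resolve(symbol)
        if sym is None:
            raise KeyError(f"unknown symbol {symbol!r}")
        return self._classes[sym]

    def of_class(self, entity_class: str) -> set[str]:
        return {s for s, c in self._classes.items() if c == entity_class}

    def alias_map(self) -> dict[str, str]:
        """Uppercased alias -> official symbol (aliases only, not symbols)."""
        return dict(self._aliases)


@dataclass(frozen=True, slots=True)
class Interaction:
    """One directed regulatory edge with optional evidence scores."""

    source: str
    source_class: str
    target: str
    target_class: str
    tfbs_z: float | None = None
    mem_p: float | None = None
    cometa_score: float | None = None

    def __post_init__(self):
        if self.source == self.target:
            raise ValueError(f"self-edge {self.source!r}")
        if (self.source_class, self.target_class) not in _EDGE_KINDS:
            raise ValueError(
                f"unsupported edge kind {self.source_class}->{self.target_class} "
                f"({self.source}->{self.target})"
            )

    @property
    def kind(self) -> str:
        return _EDGE_KINDS[(self.source_class, self.target_class)]

    @property
    def key(self) -> tuple[str, str]:
        return (self.source, self.target)

    def evidence(self) -> dict[str, float]:
        out = {}
        for f in EVIDENCE_FIELDS:
            v = getattr(self, f)
            if v is not None:
                out[f] = v
        return out


@dataclass
class InteractionCatalog:
    """Evidence-filtered edges partitioned into feedback pairs and
    feed-forward edges."""

    interactions: set[Interaction] = field(default_factory=set)
    fb_pairs: set[tuple[str, str]] = field(default_factory=set)  # (tf, mirna)
    ff_edges: set[Interaction] = field(default_factory=set)


def load_lexicon(path) -> Lexicon:
    """Read a lexicon TSV (columns ``symbol``, ``class``, ``aliases``).

    Aliases are pipe-separated.  Malformed rows (blank symbol, unknown
    class) are skipped and counted on ``Lexicon.n_skipped``; a symbol
    listed twice with conflicting classes is a hard error.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    for col in ("symbol", "class"):
        if col not in df.columns:
            raise ValueError(f"lexicon file missing required column {col!r}")
    df = df.rename(columns={"class": "entity_class"})
    classes: dict[str, str] = {}
    aliases: dict[str, str] = {}
    skipped = 0
    for row in df.itertuples(index=False):
        sym = row.symbol.strip()
        cls = row.entity_class.strip().upper()
        if not sym or cls not in ENTITY_CLASSES:
            skipped += 1
            continue
        prev = classes.get(sym)
        if prev is not None and prev != cls:
            raise ValueError(f"symbol {sym!r} listed with conflicting classes {prev}/{cls}")
        classes[sym] = cls
        raw_aliases = getattr(row, "aliases", "") if "aliases" in df.columns else ""
        for alias in str(raw_aliases).split("|"):
            alias = alias.strip()
            if alias:
                aliases[alias] = sym
    if skipped:
        warnings.warn(f"skipped {skipped} malformed lexicon row(s)")
    lex = Lexicon(classes, aliases)
    lex.n_skipped = skipped
    return lex


def load_edges(path) -> pd.DataFrame:
    """Read an interaction TSV with columns source, source_class, target,
    target_class, tfbs_z, mem_p, cometa_score (empty cell = absent)."""
    df = pd.read_csv(path, sep="\t", dtype={"source": str, "target": str})
    required = {"source", "target"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"edge file missing required column(s) {sorted(missing)}")
    return df


def _best(field_name: str, a: float | None, b: float | None) -> float | None:
    """Strongest evidence wins on duplicate edges: max |Z|, min p, max score."""
    if a is None:
        return b
    if b is None:
        return a
    if field_name == "tfbs_z":
        return a if abs(a) >= abs(b) else b
    if field_name == "mem_p":
        return min(a, b)
    return max(a, b)


def normalize_symbols(
    raw_edges: pd.DataFrame, lexicon: Lexicon
) -> tuple[set[Interaction], int]:
    """Rewrite edge endpoints to official symbols and collapse duplicates.

    Returns the normalized interaction set and the number of rows dropped
    because an endpoint was absent from the lexicon (or the edge kind was
    unsupported).  Duplicate (source, target) edges are merged keeping the
    strongest value per evidence field.
    """
    merged: dict[tuple[str, str], Interaction] = {}
    dropped = 0
    has = {f: f in raw_edges.columns for f in EVIDENCE_FIELDS}
    for row in raw_edges.itertuples(index=False):
        src = lexicon.resolve(str(row.source))
        tgt = lexicon.resolve(str(row.target))
        if src is None or tgt is None or src == tgt:
            dropped += 1
            continue
        src_cls = lexicon.class_of(src)
        tgt_cls = lexicon.class_of(tgt)
        if (src_cls, tgt_cls) not in _EDGE_KINDS:
            dropped += 1
            continue
        ev = {}
        for f in EVIDENCE_FIELDS:
            if has[f]:
                v = getattr(row, f)
                ev[f] = None if v is None or (isinstance(v, float) and math.isnan(v)) else float(v)
            else:
                ev[f] = None
        edge = Interaction(src, src_cls, tgt, tgt_cls, **ev)
        prev = merged.get(edge.key)
        if prev is not None:
            edge = replace(
                edge,
                **{f: _best(f, getattr(prev, f), getattr(edge, f)) for f in EVIDENCE_FIELDS},
            )
        merged[edge.key] = edge
    if dropped:
        warnings.warn(f"dropped {dropped} edge row(s) with unresolvable endpoints")
    return set(merged.values()), dropped


def filter_evidence(
    interactions: set[Interaction],
    z_cut: float = 2.33,
    mem_cut: float = 0.05,
    cometa_cut: float = 4.0,
) -> set[Interaction]:
    """Retain an edge iff every evidence field that is present passes its
    inclusive threshold; edges carrying no evidence at all are dropped."""
    if not (0 < mem_cut <= 1):
        raise ValueError(f"mem_cut must lie in (0, 1], got {mem_cut}")
    if cometa_cut < 0:
        raise ValueError(f"cometa_cut must be non-negative, got {cometa_cut}")
    if not all(map(math.isfinite, (z_cut, mem_cut, cometa_cut))):
        raise ValueError("thresholds must be finite")

    kept = set()
    for e in interactions:
        ev = e.evidence()
        if not ev:
            continue
        ok = True
        if "tfbs_z" in ev and ev["tfbs_z"] < z_cut:
            ok = False
        if "mem_p" in ev and ev["mem_p"] > mem_cut:
            ok = False
        if "cometa_score" in ev and ev["cometa_score"] < cometa_cut:
            ok = False
        if ok:
            kept.add(e)
    return kept


def tag_fb_ff(interactions: set[Interaction]) -> InteractionCatalog:
    """Split edges into reciprocal TF<->miRNA feedback pairs and
    feed-forward edges.  TF->gene and miRNA->gene edges are always FF."""
    tm = {(e.source, e.target) for e in interactions if e.kind == "TM"}
    mt = {(e.target, e.source) for e in interactions if e.kind == "MT"}  # as (tf, mir)
    fb_pairs = tm & mt
    ff = set()
    for e in interactions:
        if e.kind == "TM" and (e.source, e.target) in fb_pairs:
            continue
        if e.kind == "MT" and (e.target, e.source) in fb_pairs:
            continue
        ff.add(e)
    return InteractionCatalog(interactions=set(interactions), fb_pairs=fb_pairs, ff_edges=ff)


def interactions_to_frame(interactions) -> pd.DataFrame:
    """Serialize interactions to the canonical TSV column layout."""
    rows = [
        {
            "source": e.source,
            "source_class": e.source_class,
            "target": e.target,
            "target_class": e.target_class,
            "tfbs_z": e.tfbs_z,
            "mem_p": e.mem_p,
            "cometa_score": e.cometa_score,
        }
        for e in interactions
    ]
    df = pd.DataFrame(
        rows,
        columns=["source", "source_class", "target", "target_class", *EVIDENCE_FIELDS],
    )
    return df.sort_values(["source", "target"], ignore_index=True)


def frame_to_interactions(df: pd.DataFrame) -> set[Interaction]:
    """Inverse of :func:`interactions_to_frame` for already-normalized tables."""
    out = set()
    has = {f: f in df.columns for f in EVIDENCE_FIELDS}
    for row in df.itertuples(index=False):
        ev = {}
        for f in EVIDENCE_FIELDS:
            if has[f]:
                v = getattr(row, f)
                ev[f] = None if v is None or (isinstance(v, float) and math.isnan(v)) else float(v)
        out.add(
            Interaction(
                str(row.source), str(row.source_class), str(row.target), str(row.target_class), **ev
            )
        )
    return out
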