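"""Enumeration and classification of (TF, gene, miRNA) regulatory motifs.

Edge codes within a trio: ``TG`` TF->gene, ``TM`` TF->miRNA, ``MT``
miRNA->TF, ``MG`` miRNA->gene.  Five motif classes partition the trios:

========  =============================================================
``CL1``   closed loop, reciprocal TF<->miRNA plus common gene target
``CL2``   common gene target with a single TF-miRNA edge (either way)
``G``     common gene target, regulators unconnected
``TFC``   common TF: TF regulates both the gene... (TF->gene, TF->miRNA)
``MIR``   common miRNA: miRNA regulates both TF and gene
========  =============================================================

Classification precedence CL1 > CL2 > G > TFC > MIR makes the assignment
a partition, so per-class counts always sum to the total.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass

import pandas as pd

__all__ = [
    "MOTIF_TYPES",
    "CENSUS_GROUPS",
    "GRNTriple",
    "classify_motif",
    "enumerate_triples",
    "motif_census",
    "census_total",
    "triples_to_frame",
]

MOTIF_TYPES = ("CL1", "CL2", "G", "TFC", "MIR")

#: reporting group per motif type (CL1 and CL2 are reported together as "cl")
CENSUS_GROUPS = {"CL1": "cl", "CL2": "cl", "G": "g", "TFC": "tf", "MIR": "mir"}


@dataclass(frozen=True, slots=True)
class GRNTriple:
    tf: str
    gene: str
    mirna: str
    edges: frozenset
    motif_type: str

    @property
    def grn_id(self) -> str:
        return f"{self.tf}_{self.gene}_{self.mirna}"


def classify_motif(edges) -> str | None:
    """Assign a motif class to a trio's induced edge set, or ``None``.

    ``edges`` is any iterable over edge codes TG/TM/MT/MG.
    """
    e = frozenset(edges)
    bad = e - {"TG", "TM", "MT", "MG"}
    if bad:
        raise ValueError(f"unknown edge code(s) {sorted(bad)}")
    has_tg, has_tm, has_mt, has_mg = ("TG" in e), ("TM" in e), ("MT" in e), ("MG" in e)
    if has_tg and has_mg:
        if has_tm and has_mt:
            return "CL1"
        if has_tm or has_mt:
            return "CL2"
        return "G"
    if has_tg and has_tm and not has_mg:
        return "TFC"
    if has_mt and has_mg and not has_tg:
        return "MIR"
    return None


def enumerate_triples(interactions) -> list[GRNTriple]:
    """Enumerate every (tf, gene, mirna) trio whose induced edges classify
    to a motif type; each qualifying trio appears exactly once.

    ``interactions`` is an iterable of edges exposing ``source``,
    ``target`` and ``kind`` (e.g. :class:`grnkit.catalog.Interaction` or
    :class:`grnkit.coexpression.CorrelationResult` unwrapped).
    """
    tg = defaultdict(set)  # tf -> genes
    tm = defaultdict(set)  # tf -> mirnas
    mt = defaultdict(set)  # mirna -> tfs
    mg = defaultdict(set)  # mirna -> genes
    for e in interactions:
        e = getattr(e, "interaction", e)  # accept CorrelationResult
        {"TG": tg, "TM": tm, "MT": mt, "MG": mg}[e.kind][e.source].add(e.target)

    mg_by_gene = defaultdict(set)
    for m, genes in mg.items():
        for g in genes:
            mg_by_gene[g].add(m)

    # every qualifying trio contains {TG,MG}, {TG,TM} or {MT,MG}
    candidates: set[tuple[str, str, str]] = set()
    for t, genes in tg.items():
        for g in genes:
            for m in mg_by_gene.get(g, ()):
                candidates.add((t, g, m))
            for m in tm.get(t, ()):
                candidates.add((t, g, m))
    for m, genes in mg.items():
        for g in genes:
            for t in mt.get(m, ()):
                candidates.add((t, g, m))

    triples = []
    for t, g, m in candidates:
        edges = set()
        if g in tg.get(t, ()):
            edges.add("TG")
        if m in tm.get(t, ()):
            edges.add("TM")
        if t in mt.get(m, ()):
            edges.add("MT")
        if g in mg.get(m, ()):
            edges.add("MG")
        mt_type = classify_motif(edges)
        if mt_type is not None:
            triples.append(GRNTriple(t, g, m, frozenset(edges), mt_type))
    triples.sort(key=lambda tr: tr.grn_id)
    return triples


def motif_census(triples) -> dict[str, int]:
    """Per-group counts (cl/g/tf/mir, plus cl1/cl2 split) and total.

    Raises if the per-type counts fail to partition the total.
    """
    counts = {t: 0 for t in MOTIF_TYPES}
    total = 0
    for tr in triples:
        counts[tr.motif_type] += 1
        total += 1
    census = {
        "cl": counts["CL1"] + counts["CL2"],
        "cl1": counts["CL1"],
        "cl2": counts["CL2"],
        "g": counts["G"],
        "tf": counts["TFC"],
        "mir": counts["MIR"],
        "total": total,
    }
    assert census["cl"] + census["g"] + census["tf"] + census["mir"] == total
    return census


def census_total(per_type: dict[str, int]) -> int:
    """Sum per-group motif counts, asserting the partition invariant if a
    ``total`` key is supplied."""
    groups = ("cl", "g", "tf", "mir")
    missing = [g for g in groups if g not in per_type]
    if missing:
        raise ValueError(f"missing count(s) for group(s) {missing}")
    if any(per_type[g] < 0 for g in groups):
        raise ValueError("counts must be non-negative")
    total = sum(per_type[g] for g in groups)
    if "total" in per_type and per_type["total"] != total:
        raise ValueError(
            f"per-type counts sum to {total}, not the stated total {per_type['total']}"
        )
    return total


def triples_to_frame(triples) -> pd.DataFrame:
    """GRN table: grn_id, tf, gene, mirna, edges (comma-joined), motif_type."""
    rows = [
        {
            "grn_id": tr.grn_id,
            "tf": tr.tf,
            "gene": tr.gene,
            "mirna": tr.mirna,
            "edges": ",".join(sorted(tr.edges)),
            "motif_type": tr.motif_type,
        }
        for tr in triples
    ]
    return pd.DataFrame(
        rows, columns=["grn_id", "tf", "gene", "mirna", "edges", "motif_type"]
    )
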