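"""Pathway assignment for GRNs and hypergeometric over-representation.

A GRN's pathways are the intersection of the pathway sets of its three
components; miRNAs are annotated through their target genes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import pandas as pd
from scipy import stats

from .catalog import GENE, MIRNA, TF

__all__ = [
    "GRNPathwayResult",
    "read_gmt",
    "write_gmt",
    "load_mirna_targets",
    "annotate_entity",
    "grn_pathways",
    "overrepresentation",
]


@dataclass
class GRNPathwayResult:
    grn_id: str
    per_entity: dict[str, set] = field(default_factory=dict)  # role -> pathway ids
    pathways: set = field(default_factory=set)  # intersection


def read_gmt(path) -> dict[str, set]:
    """Parse a GMT file into pathway_id -> member gene set.

    Standard layout: name <tab> description <tab> member genes.  Pathways
    repeated under the same name are deduplicated by exact-name identity
    (members unioned); empty member sets are rejected.
    """
    pathways: dict[str, set] = {}
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line.strip():
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"malformed GMT line: {line[:80]!r}")
            name, members = parts[0], {m for m in parts[2:] if m}
            if not members:
                raise ValueError(f"pathway {name!r} has no members")
            pathways.setdefault(name, set()).update(members)
    return pathways


def write_gmt(pathways: dict[str, set], path) -> None:
    with open(path, "w") as fh:
        for name in sorted(pathways):
            fh.write("\t".join([name, "na", *sorted(pathways[name])]) + "\n")


def load_mirna_targets(path) -> dict[str, set]:
    """miRNA -> target-gene set from a two-column TSV (mirna, target)."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    if not {"mirna", "target"} <= set(df.columns):
        raise ValueError("miRNA target file needs columns 'mirna' and 'target'")
    out: dict[str, set] = {}
    for row in df.itertuples(index=False):
        out.setdefault(row.mirna, set()).add(row.target)
    return out


def annotate_entity(
    symbol: str,
    role: str,
    annotations: dict[str, set],
    mirna_targets: dict[str, set] | None = None,
) -> set:
    """Pathways for one entity.

    TF/GENE: pathways whose member set contains the symbol.  MIRNA: union
    of pathways containing any of its target genes; an unknown miRNA gives
    an empty set with a warning.
    """
    if role in (TF, GENE):
        return {p for p, members in annotations.items() if symbol in members}
    if role == MIRNA:
        if mirna_targets is None:
            raise ValueError("mirna_targets map required for MIRNA role")
        targets = mirna_targets.get(symbol)
        if targets is None:
            warnings.warn(f"miRNA {symbol!r} absent from target map")
            return set()
        return {p for p, members in annotations.items() if members & targets}
    raise ValueError(f"unknown role {role!r}")


def grn_pathways(
    triple,
    annotations: dict[str, set],
    mirna_targets: dict[str, set],
) -> GRNPathwayResult:
    """Common pathways of a trio: intersection of TF, gene and miRNA sets."""
    per_entity = {
        TF: annotate_entity(triple.tf, TF, annotations),
        GENE: annotate_entity(triple.gene, GENE, annotations),
        MIRNA: annotate_entity(triple.mirna, MIRNA, annotations, mirna_targets),
    }
    common = per_entity[TF] & per_entity[GENE] & per_entity[MIRNA]
    return GRNPathwayResult(grn_id=triple.grn_id, per_entity=per_entity, pathways=common)


def overrepresentation(
    query_genes: set,
    annotations: dict[str, set],
    universe: set,
    p_cut: float = 0.05,
    correct: str | None = None,
) -> list[tuple[str, float]]:
    """One-sided hypergeometric over-representation per pathway.

    p = P(overlap >= observed) drawing |query| genes from |universe| with
    |pathway & universe| successes.  Retains p < p_cut, sorted by (p, id).
    ``correct="bh"`` applies Benjamini-Hochberg before the cut.
    """
    if not universe:
        raise ValueError("universe must be non-empty")
    if not query_genes <= universe:
        raise ValueError("query genes must be a subset of the universe")
    m_total = len(universe)
    n_query = len(query_genes)
    raw = []
    for name, members in annotations.items():
        k_path = len(members & universe)
        if k_path == 0:
            continue
        k_hit = len(members & query_genes)
        p = float(stats.hypergeom.sf(k_hit - 1, m_total, k_path, n_query))
        raw.append((name, min(p, 1.0)))
    if correct == "bh":
        raw = _benjamini_hochberg(raw)
    elif correct is not None:
        raise ValueError(f"unknown correction {correct!r}")
    hits = [(name, p) for name, p in raw if p < p_cut]
    hits.sort(key=lambda t: (t[1], t[0]))
    return hits


def _benjamini_hochberg(results: list[tuple[str, float]]) -> list[tuple[str, float]]:
    m = len(results)
    order = sorted(range(m), key=lambda i: results[i][1])
    adjusted = [0.0] * m
    running = 1.0
    for rank_from_end, idx in enumerate(reversed(order)):
        rank = m - rank_from_end
        running = min(running, results[idx][1] * m / rank)
        adjusted[idx] = running
    return [(results[i][0], adjusted[i]) for i in range(m)]
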