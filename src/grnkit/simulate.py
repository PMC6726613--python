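"""Seed-deterministic generators for every pipeline input, with ground
truth recorded alongside: interaction networks with planted motifs,
paired gene/miRNA expression with planted differential regulation, symbol
corpora, pathway annotations and qPCR Ct tables.

Cohort shape defaults mirror the reference microarray design (14 controls,
RRMS 7, SPMS 6, PPMS 6 with paired gene+miRNA profiles per individual)
and the qPCR cohort (30 controls, RRMS 14, PPMS 13, SPMS 12).
"""

from __future__ import annotations

import json
import zlib
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .catalog import GENE, MIRNA, TF, Lexicon
from .constants import CONDITIONS, CONTROL, CONTRASTS, MS_CONDITIONS, contrast_condition
from .motifs import GRNTriple

__all__ = [
    "GeneratorConfig",
    "SyntheticNetwork",
    "generate_network",
    "generate_expression",
    "generate_corpus",
    "generate_pathways",
    "generate_ct",
    "default_perturbation",
    "simulate_all",
]

_PLANT_KIND_EDGES = {
    "cl": frozenset({"TG", "TM", "MT", "MG"}),
    "g": frozenset({"TG", "MG"}),
    "tf": frozenset({"TG", "TM"}),
    "mir": frozenset({"MT", "MG"}),
}
_PLANT_KIND_TYPE = {"cl": "CL1", "g": "G", "tf": "TFC", "mir": "MIR"}

_FILLER_VOCAB = (
    "patients cohort demyelination lesion relapse axonal inflammation "
    "lymphocyte expression profiling signalling cascade pathway serum "
    "biomarker immune response chronic progressive onset severity outcome "
    "treatment therapy observed measured elevated reduced compared analysis"
).split()


@dataclass
class GeneratorConfig:
    """Knobs for all generators; a fixed seed yields identical outputs."""

    n_tf: int = 40
    n_gene: int = 80
    n_mirna: int = 40
    edge_probs: dict = field(
        default_factory=lambda: {"TG": 0.02, "TM": 0.02, "MT": 0.02, "MG": 0.02}
    )
    planted_motifs: dict = field(
        default_factory=lambda: {"cl": 5, "g": 5, "tf": 5, "mir": 5}
    )
    n_samples: dict = field(
        default_factory=lambda: {CONTROL: 14, "RRMS": 7, "SPMS": 6, "PPMS": 6}
    )
    effect_fold: float = 2.0
    noise_sd: float = 0.1  # log2 scale
    coexpr_strength: float = 0.8  # latent-factor loading within planted trios
    background_fail_fraction: float = 0.3  # background edges failing evidence cuts
    seed: int = 0

    def __post_init__(self):
        for kind, p in self.edge_probs.items():
            if not 0 <= p <= 1:
                raise ValueError(f"edge probability for {kind} outside [0, 1]")
        if any(v <= 0 for v in (self.n_tf, self.n_gene, self.n_mirna)):
            raise ValueError("entity counts must be positive")
        planted = sum(self.planted_motifs.values())
        if planted > min(self.n_tf, self.n_gene, self.n_mirna):
            raise ValueError(
                f"{planted} planted motifs need at least that many TFs, genes and "
                "miRNAs (planted trios are entity-disjoint)"
            )

    def rng(self, stream: str) -> np.random.Generator:
        # crc32 is stable across processes, unlike hash()
        return np.random.default_rng([self.seed, zlib.crc32(stream.encode())])


@dataclass
class SyntheticNetwork:
    lexicon: Lexicon
    edges: pd.DataFrame  # interaction TSV schema
    planted: list[GRNTriple]  # ground truth, entity-disjoint

    def planted_by_type(self) -> dict[str, list[GRNTriple]]:
        out: dict[str, list[GRNTriple]] = {}
        for tr in self.planted:
            out.setdefault(tr.motif_type, []).append(tr)
        return out


def _evidence_for(kind: str, rng, passing: bool) -> dict:
    ev = {"tfbs_z": None, "mem_p": None, "cometa_score": None}
    if kind == "TG":
        if passing:
            ev["tfbs_z"] = float(rng.uniform(2.33, 5.0))
            ev["mem_p"] = float(rng.uniform(1e-6, 0.05))
        else:  # fail exactly one of the two at random
            if rng.random() < 0.5:
                ev["tfbs_z"] = float(rng.uniform(0.0, 2.32))
                ev["mem_p"] = float(rng.uniform(1e-6, 0.05))
            else:
                ev["tfbs_z"] = float(rng.uniform(2.33, 5.0))
                ev["mem_p"] = float(rng.uniform(0.051, 0.5))
    else:
        ev["cometa_score"] = float(rng.uniform(4.0, 9.0) if passing else rng.uniform(0.0, 3.99))
    return ev


def generate_network(cfg: GeneratorConfig) -> SyntheticNetwork:
    """Random background edges plus entity-disjoint planted motifs.

    Planted edges always pass every evidence filter; a configurable
    fraction of background edges fails at least one.  Background edges are
    drawn only among non-planted entities so the planted motif patterns
    are exactly as constructed.
    """
    rng = cfg.rng("network")
    tfs = [f"TF{i:03d}" for i in range(1, cfg.n_tf + 1)]
    genes = [f"G{i:04d}" for i in range(1, cfg.n_gene + 1)]
    mirnas = [f"hsa-miR-{i}" for i in range(1, cfg.n_mirna + 1)]
    classes = {**{t: TF for t in tfs}, **{g: GENE for g in genes}, **{m: MIRNA for m in mirnas}}
    lexicon = Lexicon(classes)

    rows = []
    planted: list[GRNTriple] = []
    i_tf = i_gene = i_mir = 0
    for kind in ("cl", "g", "tf", "mir"):
        for _ in range(int(cfg.planted_motifs.get(kind, 0))):
            t, g, m = tfs[i_tf], genes[i_gene], mirnas[i_mir]
            i_tf, i_gene, i_mir = i_tf + 1, i_gene + 1, i_mir + 1
            edges = _PLANT_KIND_EDGES[kind]
            planted.append(GRNTriple(t, g, m, edges, _PLANT_KIND_TYPE[kind]))
            for code in sorted(edges):
                src, s_cls, tgt, t_cls = {
                    "TG": (t, TF, g, GENE),
                    "TM": (t, TF, m, MIRNA),
                    "MT": (m, MIRNA, t, TF),
                    "MG": (m, MIRNA, g, GENE),
                }[code]
                rows.append(
                    {
                        "source": src,
                        "source_class": s_cls,
                        "target": tgt,
                        "target_class": t_cls,
                        **_evidence_for(code, rng, passing=True),
                    }
                )

    bg_tfs, bg_genes, bg_mirs = tfs[i_tf:], genes[i_gene:], mirnas[i_mir:]
    kinds = {
        "TG": (bg_tfs, TF, bg_genes, GENE),
        "TM": (bg_tfs, TF, bg_mirs, MIRNA),
        "MT": (bg_mirs, MIRNA, bg_tfs, TF),
        "MG": (bg_mirs, MIRNA, bg_genes, GENE),
    }
    for code, (sources, s_cls, targets, t_cls) in kinds.items():
        p = cfg.edge_probs.get(code, 0.0)
        if p <= 0 or not sources or not targets:
            continue
        mask = rng.random((len(sources), len(targets))) < p
        for i, j in np.argwhere(mask):
            passing = rng.random() >= cfg.background_fail_fraction
            rows.append(
                {
                    "source": sources[i],
                    "source_class": s_cls,
                    "target": targets[j],
                    "target_class": t_cls,
                    **_evidence_for(code, rng, passing),
                }
            )
    edges = pd.DataFrame(
        rows,
        columns=["source", "source_class", "target", "target_class", "tfbs_z", "mem_p", "cometa_score"],
    )
    return SyntheticNetwork(lexicon=lexicon, edges=edges, planted=planted)


def default_perturbation(
    net: SyntheticNetwork, cfg: GeneratorConfig, n_up: int = 10, n_down: int = 10
) -> dict[str, dict[str, float]]:
    """Assign per-contrast folds to planted GRNs: within each motif type the
    first ``n_up`` trios go up (effect_fold) and the next ``n_down`` go down
    (1/effect_fold) in every MS condition."""
    perturb: dict[str, dict[str, float]] = {}
    for motif_type, trios in net.planted_by_type().items():
        if len(trios) < n_up + n_down:
            raise ValueError(
                f"motif type {motif_type}: {len(trios)} planted trios < "
                f"n_up + n_down = {n_up + n_down}"
            )
        for idx, tr in enumerate(trios[: n_up + n_down]):
            fold = cfg.effect_fold if idx < n_up else 1.0 / cfg.effect_fold
            perturb[tr.grn_id] = {cond: fold for cond in MS_CONDITIONS}
    return perturb


def generate_expression(
    cfg: GeneratorConfig,
    net: SyntheticNetwork,
    perturb: dict[str, dict[str, float]] | None = None,
):
    """Paired gene and miRNA expression matrices with planted effects.

    Baseline expression is log-normal; members of a planted trio share a
    per-sample latent factor so their control co-expression survives the
    Pearson filter.  ``perturb`` maps grn_id -> {condition or contrast:
    fold}; the fold multiplies all three components in that condition's
    samples.  Returns (gene_expr, mirna_expr) ExpressionMatrix objects.
    """
    from .coexpression import ExpressionMatrix

    rng = cfg.rng("expression")
    samples, conds = [], []
    i = 1
    for cond in CONDITIONS:
        for _ in range(int(cfg.n_samples.get(cond, 0))):
            samples.append(f"S{i:03d}")
            conds.append(cond)
            i += 1
    condition = pd.Series(conds, index=samples, name="condition")

    entities = net.lexicon.symbols
    base = rng.uniform(4.0, 10.0, size=len(entities))
    log2 = np.tile(base[:, None], (1, len(samples)))
    log2 = log2 + rng.normal(0.0, cfg.noise_sd, size=log2.shape)

    idx = {sym: k for k, sym in enumerate(entities)}
    cond_arr = np.asarray(conds)
    for tr in net.planted:
        latent = rng.normal(0.0, 1.0, size=len(samples))
        # center within each condition: co-expression without spurious
        # between-condition shifts in the condition summaries
        for cond in set(conds):
            sel = cond_arr == cond
            latent[sel] -= latent[sel].mean()
        for sym in (tr.tf, tr.gene, tr.mirna):
            log2[idx[sym]] += cfg.coexpr_strength * latent

    if perturb:
        by_id = {tr.grn_id: tr for tr in net.planted}
        col_of_cond = {
            c: [j for j, s in enumerate(samples) if condition[s] == c] for c in CONDITIONS
        }
        for grn_id, folds in perturb.items():
            tr = by_id.get(grn_id)
            if tr is None:
                raise ValueError(f"cannot perturb unknown GRN {grn_id!r}")
            for key, fold in folds.items():
                cond = contrast_condition(key) if key in CONTRASTS else key
                if cond not in CONDITIONS:
                    raise ValueError(f"unknown condition/contrast {key!r}")
                cols = col_of_cond[cond]
                for sym in (tr.tf, tr.gene, tr.mirna):
                    log2[idx[sym], cols] += np.log2(fold)

    values = pd.DataFrame(2.0 ** log2, index=entities, columns=samples)
    gene_rows = [s for s in entities if net.lexicon.class_of(s) in (TF, GENE)]
    mir_rows = [s for s in entities if net.lexicon.class_of(s) == MIRNA]
    return (
        ExpressionMatrix(values.loc[gene_rows], condition),
        ExpressionMatrix(values.loc[mir_rows], condition),
    )


def generate_corpus(
    cfg: GeneratorConfig,
    lexicon: Lexicon,
    planted_symbols,
    n_abstracts: int = 100,
    words_per_abstract: int = 40,
) -> tuple[str, set[str]]:
    """Filler-vocabulary abstracts with planted whole-token symbol mentions.

    Returns (corpus text, planted symbol set).  Filler words never collide
    with lexicon symbols, so mined hits equal the planted truth exactly.
    """
    rng = cfg.rng("corpus")
    known = {s.upper() for s in lexicon.symbols} | set(lexicon.alias_map())
    vocab = [w for w in _FILLER_VOCAB if w.upper() not in known]
    planted = [s for s in planted_symbols]
    unknown = [s for s in planted if lexicon.resolve(s) is None]
    if unknown:
        raise ValueError(f"planted symbols absent from lexicon: {unknown}")
    blocks = []
    for k in range(n_abstracts):
        words = list(rng.choice(vocab, size=words_per_abstract))
        blocks.append([f"PMID{k + 1:05d}", " ".join(words)])
    for sym in planted:
        k = int(rng.integers(0, n_abstracts))
        blocks[k][1] += f" {sym}"
    text = "\n\n".join(f"{rid}\n{body}" for rid, body in blocks)
    return text, set(planted)


def generate_pathways(
    cfg: GeneratorConfig, net: SyntheticNetwork, n_background: int = 10
) -> tuple[dict[str, set], dict[str, set]]:
    """Pathway annotations plus a miRNA target map.

    Every planted trio gets one dedicated pathway shared by its TF, its
    gene and (via the target map) its miRNA, so the common-pathway
    intersection is non-empty by construction.  Returns
    (pathways, mirna_targets).
    """
    rng = cfg.rng("pathways")
    pathways: dict[str, set] = {}
    mirna_targets: dict[str, set] = {}
    for k, tr in enumerate(net.planted, start=1):
        pathways[f"PW_PLANTED_{k:03d}"] = {tr.tf, tr.gene}
        mirna_targets.setdefault(tr.mirna, set()).add(tr.gene)
    symbols = np.array(net.lexicon.symbols)
    for k in range(1, n_background + 1):
        members = set(rng.choice(symbols, size=min(6, len(symbols)), replace=False))
        pathways[f"PW_BG_{k:03d}"] = members
    return pathways, mirna_targets


def generate_ct(
    cfg: GeneratorConfig,
    lexicon: Lexicon,
    targets,
    planted_shifts: dict[tuple[str, str], float] | None = None,
    group_sizes: dict[str, int] | None = None,
    ct_noise_sd: float = 0.15,
) -> pd.DataFrame:
    """Per-sample Ct table for the given targets across the qPCR cohort.

    Reference Ct (GAPDH for genes/TFs, U6 for miRNAs) is near-constant;
    ``planted_shifts`` maps (target, group) -> delta cycles ADDED to the
    target Ct: a shift of -1 doubles and +1 halves relative expression in
    expectation.
    """
    rng = cfg.rng("ct")
    sizes = group_sizes or {CONTROL: 30, "RRMS": 14, "PPMS": 13, "SPMS": 12}
    shifts = planted_shifts or {}
    rows = []
    base_delta = {t: float(rng.uniform(2.0, 8.0)) for t in targets}
    i = 1
    for group in CONDITIONS:
        for _ in range(int(sizes.get(group, 0))):
            sid = f"Q{i:03d}"
            i += 1
            for t in targets:
                ref = "U6" if lexicon.class_of(t) == MIRNA else "GAPDH"
                ct_ref = 20.0 + float(rng.normal(0.0, 0.05))
                ct_t = (
                    ct_ref
                    + base_delta[t]
                    + shifts.get((t, group), 0.0)
                    + float(rng.normal(0.0, ct_noise_sd))
                )
                rows.append(
                    {
                        "sample_id": sid,
                        "group": group,
                        "target": t,
                        "ct_target": round(ct_t, 4),
                        "ct_reference": round(ct_ref, 4),
                        "reference": ref,
                    }
                )
    return pd.DataFrame(rows)


def simulate_all(cfg: GeneratorConfig, out_dir) -> dict:
    """Write every pipeline input under ``out_dir`` plus a truth JSON.

    Files: lexicon.tsv, edges.tsv, gene_expr.tsv, mirna_expr.tsv,
    samples.tsv, abstracts.txt, pathways.gmt, mir_targets.tsv, ct.tsv,
    truth.json.  Returns the truth dict.
    """
    from .enrichment import write_gmt

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    net = generate_network(cfg)

    lex_rows = [
        {"symbol": s, "class": net.lexicon.class_of(s), "aliases": ""}
        for s in net.lexicon.symbols
    ]
    pd.DataFrame(lex_rows).to_csv(out / "lexicon.tsv", sep="\t", index=False)
    net.edges.to_csv(out / "edges.tsv", sep="\t", index=False)

    n_plantable = min(len(v) for v in net.planted_by_type().values()) if net.planted else 0
    n_dir = max(1, n_plantable // 2)
    perturb = default_perturbation(net, cfg, n_up=n_dir, n_down=n_plantable - n_dir) if net.planted else {}
    gene_expr, mir_expr = generate_expression(cfg, net, perturb)
    gene_expr.to_tsv(out / "gene_expr.tsv", out / "samples.tsv")
    mir_expr.to_tsv(out / "mirna_expr.tsv")

    assoc_truth = sorted({tr.tf for tr in net.planted} | {tr.gene for tr in net.planted})
    corpus, planted_syms = generate_corpus(cfg, net.lexicon, assoc_truth)
    (out / "abstracts.txt").write_text(corpus + "\n")

    pathways, mir_targets = generate_pathways(cfg, net)
    write_gmt(pathways, out / "pathways.gmt")
    pd.DataFrame(
        [{"mirna": m, "target": t} for m, ts in sorted(mir_targets.items()) for t in sorted(ts)]
    ).to_csv(out / "mir_targets.tsv", sep="\t", index=False)

    ct_targets = sorted(
        {tr.tf for tr in net.planted[:4]}
        | {tr.gene for tr in net.planted[:4]}
        | {tr.mirna for tr in net.planted[:4]}
    )
    ct = generate_ct(cfg, net.lexicon, ct_targets)
    ct.to_csv(out / "ct.tsv", sep="\t", index=False)

    truth = {
        "config": asdict(cfg),
        "planted_motifs": [
            {
                "grn_id": tr.grn_id,
                "motif_type": tr.motif_type,
                "edges": sorted(tr.edges),
            }
            for tr in net.planted
        ],
        "perturbation": perturb,
        "mined_symbols": sorted(planted_syms),
        "ct_targets": ct_targets,
    }
    (out / "truth.json").write_text(json.dumps(truth, indent=2) + "\n")
    return truth
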