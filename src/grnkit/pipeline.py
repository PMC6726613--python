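"""End-to-end convenience wrapper chaining the pipeline stages on a
synthetic input set; used by the acceptance harness and benchmarks."""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from . import catalog, coexpression, integrity, motifs
from .constants import CONTRASTS
from .simulate import GeneratorConfig, SyntheticNetwork, default_perturbation, generate_expression, generate_network

__all__ = ["PipelineResult", "run_synthetic_ranking"]


@dataclass
class PipelineResult:
    net: SyntheticNetwork
    perturbation: dict[str, dict[str, float]]
    triples: list
    records: pd.DataFrame
    selections: dict[str, pd.DataFrame] = field(default_factory=dict)

    @property
    def n_selected(self) -> int:
        return sum(len(df) for df in self.selections.values())

    def recovery_fraction(self) -> float:
        """Fraction of (planted GRN, contrast) cells found in the selected
        list of the planted direction."""
        n_hit = n_tot = 0
        for grn_id, folds in self.perturbation.items():
            for contrast, cond in CONTRASTS.items():
                fold = folds.get(cond, folds.get(contrast, 1.0))
                if fold == 1.0:
                    continue
                want = "UP" if fold > 1 else "DOWN"
                sel = self.selections[contrast]
                n_tot += 1
                n_hit += bool(
                    ((sel["grn_id"] == grn_id) & (sel["direction"] == want)).any()
                )
        return n_hit / n_tot if n_tot else float("nan")


def run_synthetic_ranking(
    cfg: GeneratorConfig,
    n_up: int = 10,
    n_down: int = 10,
    k_up: int = 10,
    k_down: int = 10,
) -> PipelineResult:
    """Generate a network + expression with ``n_up``/``n_down`` planted
    up/down GRNs per motif type, run evidence + Pearson filtering, motif
    enumeration, integrity scoring and top-k selection for all contrasts."""
    net = generate_network(cfg)
    edges, _ = catalog.normalize_symbols(net.edges, net.lexicon)
    kept = catalog.filter_evidence(edges)
    perturb = default_perturbation(net, cfg, n_up=n_up, n_down=n_down)
    gene_expr, mir_expr = generate_expression(cfg, net, perturb)
    expr = coexpression.ExpressionMatrix.concat(gene_expr, mir_expr)
    retained = coexpression.pearson_validate(kept, expr)
    triples = motifs.enumerate_triples(retained)
    summaries = coexpression.condition_summary(expr)
    records, _ = integrity.score_all(motifs.triples_to_frame(triples), summaries)
    result = PipelineResult(net=net, perturbation=perturb, triples=triples, records=records)
    for contrast in CONTRASTS:
        result.selections[contrast] = integrity.rank_and_select(
            records, contrast, k_up=k_up, k_down=k_down
        )
    return result
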