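"""Expression handling: normalization, Pearson confirmation of regulatory
edges on control samples, and per-condition expression summaries."""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .catalog import Interaction, InteractionCatalog
from .constants import CONDITIONS, CONTROL

__all__ = [
    "ExpressionMatrix",
    "CorrelationResult",
    "normalize_expression",
    "pearson_validate",
    "condition_summary",
]


class ExpressionMatrix:
    """Entities x samples expression values plus a per-sample condition label.

    ``values`` is a DataFrame indexed by entity symbol with sample columns;
    ``condition`` maps every sample to one of CONTROL/RRMS/PPMS/SPMS.
    """

    def __init__(self, values: pd.DataFrame, condition: pd.Series):
        if values.index.has_duplicates:
            dups = values.index[values.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicate entity ids: {dups}")
        condition = condition.astype(str)
        unlabeled = [s for s in values.columns if s not in condition.index]
        if unlabeled:
            raise ValueError(f"samples without condition label: {unlabeled}")
        bad = set(condition) - set(CONDITIONS)
        if bad:
            raise ValueError(f"unknown condition label(s): {sorted(bad)}")
        self.values = values
        self.condition = condition.loc[list(values.columns)]

    @property
    def entity_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    def samples_in(self, condition: str) -> list[str]:
        return [s for s in self.values.columns if self.condition[s] == condition]

    @classmethod
    def from_tsv(cls, values_path, samples_path) -> "ExpressionMatrix":
        values = pd.read_csv(values_path, sep="\t", index_col=0)
        samples = pd.read_csv(samples_path, sep="\t", index_col=0)
        return cls(values, samples.iloc[:, 0])

    def to_tsv(self, values_path, samples_path=None) -> None:
        self.values.to_csv(values_path, sep="\t", index_label="entity")
        if samples_path is not None:
            self.condition.rename("condition").to_csv(
                samples_path, sep="\t", index_label="sample"
            )

    @classmethod
    def concat(cls, *matrices: "ExpressionMatrix") -> "ExpressionMatrix":
        """Stack matrices (e.g. gene + miRNA) on their shared samples.

        Sample identity is the join key: profiles must come from the same
        individuals, so only samples present in every matrix are kept.
        """
        shared = list(matrices[0].values.columns)
        for m in matrices[1:]:
            shared = [s for s in shared if s in m.values.columns]
        if not shared:
            raise ValueError("no shared samples across matrices")
        values = pd.concat([m.values[shared] for m in matrices], axis=0)
        return cls(values, matrices[0].condition.loc[shared])


@dataclass(frozen=True)
class CorrelationResult:
    interaction: Interaction
    r: float
    p: float


def normalize_expression(expr: ExpressionMatrix, method: str = "quantile") -> ExpressionMatrix:
    """Normalize to strictly positive values.

    ``quantile`` aligns per-sample distributions by the rank-average
    construction (value at rank k becomes the mean over samples of their
    k-th order statistic, ties averaged); ``log2_shift`` applies
    log2(x + 1) and shifts the matrix minimum just above zero.
    """
    vals = expr.values
    if not np.isfinite(vals.to_numpy()).all():
        mask = ~np.isfinite(vals.to_numpy())
        i, j = np.argwhere(mask)[0]
        raise ValueError(
            f"non-finite expression for entity {vals.index[i]!r} sample {vals.columns[j]!r}"
        )
    arr = vals.to_numpy(dtype=float)
    if method == "quantile":
        n = arr.shape[0]
        mean_sorted = np.sort(arr, axis=0).mean(axis=1)
        ranks = pd.DataFrame(arr).rank(axis=0, method="average").to_numpy()
        # interpolate handles tied (fractional) ranks
        out = np.interp(ranks, np.arange(1, n + 1), mean_sorted)
    elif method == "log2_shift":
        shifted = arr - arr.min() if arr.min() < 0 else arr
        out = np.log2(shifted + 1.0)
    else:
        raise ValueError(f"unknown normalization method {method!r}")
    eps = np.finfo(float).eps
    lo = out.min()
    if lo <= 0:
        out = out + (eps - lo)
    return ExpressionMatrix(
        pd.DataFrame(out, index=vals.index, columns=vals.columns), expr.condition
    )


def _edges_of(catalog) -> set[Interaction]:
    if isinstance(catalog, InteractionCatalog):
        return catalog.interactions
    return set(catalog)


def pearson_validate(
    catalog,
    expr: ExpressionMatrix,
    p_cut: float = 0.05,
    require_sign: bool = False,
) -> list[CorrelationResult]:
    """Confirm edges by Pearson correlation on CONTROL samples.

    An edge is retained iff its two-sided correlation p-value is <= p_cut
    (and, with ``require_sign``, r < 0 for miRNA->target edges and r > 0
    otherwise).  Zero-variance profiles make r undefined; such edges are
    dropped with a warning, as are edges with a missing endpoint.
    """
    controls = expr.samples_in(CONTROL)
    if len(controls) < 3:
        raise ValueError(f"need >= 3 control samples, have {len(controls)}")
    sub = expr.values[controls]
    have = set(sub.index)
    retained: list[CorrelationResult] = []
    n_missing = n_novar = 0
    for e in sorted(_edges_of(catalog), key=lambda e: e.key):
        if e.source not in have or e.target not in have:
            n_missing += 1
            continue
        x = sub.loc[e.source].to_numpy(dtype=float)
        y = sub.loc[e.target].to_numpy(dtype=float)
        if np.ptp(x) == 0 or np.ptp(y) == 0:
            n_novar += 1
            continue
        r, p = stats.pearsonr(x, y)
        if p > p_cut:
            continue
        if require_sign:
            want_negative = e.source_class == "MIRNA"
            if want_negative and r >= 0:
                continue
            if not want_negative and r <= 0:
                continue
        retained.append(CorrelationResult(e, float(r), float(p)))
    if n_missing:
        warnings.warn(f"{n_missing} edge(s) skipped: endpoint absent from expression")
    if n_novar:
        warnings.warn(f"{n_novar} edge(s) dropped: zero-variance profile")
    return retained


def condition_summary(expr: ExpressionMatrix, statistic: str = "mean") -> pd.DataFrame:
    """One summary value per entity per condition (entities x conditions)."""
    if statistic not in ("mean", "median"):
        raise ValueError(f"unknown statistic {statistic!r}")
    cols = {}
    for cond in CONDITIONS:
        samples = expr.samples_in(cond)
        if not samples:
            continue
        block = expr.values[samples]
        cols[cond] = block.mean(axis=1) if statistic == "mean" else block.median(axis=1)
    return pd.DataFrame(cols)
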