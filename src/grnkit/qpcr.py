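"""qPCR validation: 2^-dCt relative expression, group comparison,
qPCR-based regulatory fold changes and concordance accuracy."""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .constants import CONTROL, CONTRASTS, contrast_condition
from .integrity import RegulatoryWeights, DEFAULT_WEIGHTS, direction_of, integrity_score

__all__ = [
    "CtRecord",
    "relative_expression",
    "load_ct_table",
    "relative_expression_table",
    "group_means",
    "group_compare",
    "qpcr_rfc",
    "concordance_accuracy",
]


@dataclass(frozen=True)
class CtRecord:
    """One qPCR measurement: target and reference cycle thresholds."""

    sample_id: str
    group: str
    target: str
    ct_target: float
    ct_reference: float

    def __post_init__(self):
        for name in ("ct_target", "ct_reference"):
            v = getattr(self, name)
            if v is None or not math.isfinite(v) or v <= 0:
                raise ValueError(f"{name} must be finite and positive, got {v!r}")


def relative_expression(rec_or_ct, ct_reference: float | None = None) -> float:
    """2^-(ct_target - ct_reference); accepts a CtRecord or two scalars."""
    if isinstance(rec_or_ct, CtRecord):
        ct_t, ct_r = rec_or_ct.ct_target, rec_or_ct.ct_reference
    else:
        if ct_reference is None:
            raise ValueError("reference Ct missing")
        ct_t, ct_r = float(rec_or_ct), float(ct_reference)
    return 2.0 ** (-(ct_t - ct_r))


def load_ct_table(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    required = {"sample_id", "group", "target", "ct_target", "ct_reference"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"Ct table missing column(s) {sorted(missing)}")
    return df


def relative_expression_table(ct: pd.DataFrame) -> pd.DataFrame:
    """Append a ``rel_expr`` column of per-row 2^-dCt values."""
    out = ct.copy()
    out["rel_expr"] = 2.0 ** (-(out["ct_target"] - out["ct_reference"]))
    return out


def group_means(ct: pd.DataFrame) -> dict[tuple[str, str], float]:
    """Mean per-sample relative expression keyed by (target, group)."""
    rel = relative_expression_table(ct)
    grouped = rel.groupby(["target", "group"])["rel_expr"].mean()
    return {(t, g): float(v) for (t, g), v in grouped.items()}


def group_compare(values_a, values_b, equal_var: bool = True):
    """Compare two groups of relative-expression values.

    Returns (fold_change, t, p) with fold_change = mean(b)/mean(a) and a
    two-sided Student's t-test (equal variances by default; Welch with
    ``equal_var=False``).  Two zero-variance groups with equal means give
    p = 1 by convention.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs at least two values")
    fold = float(b.mean() / a.mean())
    if a.std() == 0 and b.std() == 0:
        if a.mean() == b.mean():
            return fold, 0.0, 1.0
        return fold, math.inf if b.mean() > a.mean() else -math.inf, 0.0
    t, p = stats.ttest_ind(b, a, equal_var=equal_var)
    return fold, float(t), float(p)


def qpcr_rfc(
    rel_expr: dict[tuple[str, str], float],
    grn,
    w: RegulatoryWeights = DEFAULT_WEIGHTS,
) -> dict[str, tuple[float, str | None]]:
    """Integrity-score fold change per contrast from qPCR group means.

    ``rel_expr`` maps (entity, group) -> mean relative expression for all
    three GRN components in every group; returns contrast -> (rfc,
    direction).
    """
    def score(group: str) -> float:
        vals = {}
        for role, sym in (("tf", grn.tf), ("gene", grn.gene), ("mir", grn.mirna)):
            key = (sym, group)
            if key not in rel_expr:
                raise ValueError(f"missing qPCR measurement for {sym!r} in group {group!r}")
            vals[role] = rel_expr[key]
        return integrity_score(vals["tf"], vals["gene"], vals["mir"], w)

    n_control = score(CONTROL)
    out = {}
    for contrast in CONTRASTS:
        rfc = score(contrast_condition(contrast)) / n_control
        out[contrast] = (rfc, direction_of(rfc))
    return out


def concordance_accuracy(
    qpcr_dirs: dict[tuple[str, str], str],
    array_dirs: dict[tuple[str, str], str],
    failed: set[tuple[str, str]] = frozenset(),
) -> tuple[float, pd.DataFrame]:
    """Fraction of (GRN, contrast) cells where qPCR and array direction
    calls agree and the cell is not marked failed.

    Cells whose qPCR evidence lacks statistical significance go in
    ``failed`` and count as misclassified even if directions match.
    Returns (accuracy, grid) where grid has one row per cell with a
    CONCORDANT/DISCORDANT status.
    """
    if set(qpcr_dirs) != set(array_dirs):
        only_q = set(qpcr_dirs) - set(array_dirs)
        only_a = set(array_dirs) - set(qpcr_dirs)
        raise ValueError(f"key mismatch: qpcr-only {sorted(only_q)}, array-only {sorted(only_a)}")
    if not qpcr_dirs:
        raise ValueError("empty grids")
    rows = []
    n_concordant = 0
    for (grn_id, contrast) in sorted(qpcr_dirs):
        agree = (
            qpcr_dirs[(grn_id, contrast)] == array_dirs[(grn_id, contrast)]
            and (grn_id, contrast) not in failed
        )
        n_concordant += agree
        rows.append(
            {
                "grn_id": grn_id,
                "contrast": contrast,
                "qpcr": qpcr_dirs[(grn_id, contrast)],
                "array": array_dirs[(grn_id, contrast)],
                "status": "CONCORDANT" if agree else "DISCORDANT",
            }
        )
    accuracy = n_concordant / len(rows)
    return accuracy, pd.DataFrame(rows)
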