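"""Network integrity scoring and regulatory fold-change ranking.

The integrity score of a trio with component expressions (e_tf, e_gene,
e_mir) and regulatory weights (r_tf, r_gene, r_mir) is the sum of the
pairwise products of the weighted expressions::

    N = (r_tf*e_tf)(r_mir*e_mir) + (r_mir*e_mir)(r_gene*e_gene)
        + (r_gene*e_gene)(r_tf*e_tf)

N is homogeneous of degree 2: scaling all three expressions by c scales
N by c**2.  The regulatory fold change RFC = N_MS / N_control calls a GRN
up-regulated when RFC > 1 and down-regulated when RFC < 1; RFC == 1 is
excluded from ranking.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd

from .constants import CONDITIONS, CONTROL, CONTRASTS, contrast_condition

__all__ = [
    "RegulatoryWeights",
    "DEFAULT_WEIGHTS",
    "integrity_score",
    "score_all",
    "regulatory_fold_change",
    "direction_of",
    "rfc_table",
    "rank_and_select",
    "overlap_summary",
]

UP = "UP"
DOWN = "DOWN"


@dataclass(frozen=True)
class RegulatoryWeights:
    """Role weights: TF strongest, gene moderate, miRNA weakest."""

    r_tf: float = 1.0
    r_gene: float = 0.75
    r_mir: float = 0.5

    def __post_init__(self):
        for name in ("r_tf", "r_gene", "r_mir"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")


DEFAULT_WEIGHTS = RegulatoryWeights()


def integrity_score(e_tf, e_gene, e_mir, w: RegulatoryWeights = DEFAULT_WEIGHTS):
    """Integrity score N for one trio; accepts scalars or numpy arrays."""
    for role, val in (("tf", e_tf), ("gene", e_gene), ("mir", e_mir)):
        if np.any(np.asarray(val) <= 0) or not np.all(np.isfinite(np.asarray(val))):
            raise ValueError(f"expression for role {role!r} must be strictly positive and finite")
    wt, wg, wm = w.r_tf * np.asarray(e_tf), w.r_gene * np.asarray(e_gene), w.r_mir * np.asarray(e_mir)
    n = wt * wm + wm * wg + wg * wt
    return float(n) if np.isscalar(e_tf) or np.asarray(e_tf).ndim == 0 else n


def score_all(
    grns: pd.DataFrame,
    summaries: pd.DataFrame,
    w: RegulatoryWeights = DEFAULT_WEIGHTS,
) -> tuple[pd.DataFrame, int]:
    """Score every GRN in every condition.

    ``grns`` needs columns grn_id, tf, gene, mirna (motif_type carried
    through if present); ``summaries`` is entities x conditions from
    :func:`grnkit.coexpression.condition_summary`.  GRNs with any missing
    component summary are dropped and counted.  Returns (records, n_dropped)
    where records has exactly 4 rows per retained GRN.
    """
    conditions = [c for c in CONDITIONS if c in summaries.columns]
    frames = []
    mask_ok = (
        grns["tf"].isin(summaries.index)
        & grns["gene"].isin(summaries.index)
        & grns["mirna"].isin(summaries.index)
    )
    dropped = int((~mask_ok).sum())
    if dropped:
        warnings.warn(f"dropped {dropped} GRN(s) lacking a condition summary")
    kept = grns.loc[mask_ok]
    for cond in conditions:
        col = summaries[cond]
        e_tf = col.reindex(kept["tf"]).to_numpy()
        e_gene = col.reindex(kept["gene"]).to_numpy()
        e_mir = col.reindex(kept["mirna"]).to_numpy()
        n = integrity_score(e_tf, e_gene, e_mir, w)
        frame = pd.DataFrame(
            {
                "grn_id": kept["grn_id"].to_numpy(),
                "condition": cond,
                "e_tf": e_tf,
                "e_gene": e_gene,
                "e_mir": e_mir,
                "N": n,
            }
        )
        if "motif_type" in kept.columns:
            frame.insert(1, "motif_type", kept["motif_type"].to_numpy())
        frames.append(frame)
    records = pd.concat(frames, ignore_index=True) if frames else pd.DataFrame()
    return records, dropped


def regulatory_fold_change(n_ms: float, n_control: float) -> float:
    """RFC = N_MS / N_control (both strictly positive)."""
    if n_control <= 0:
        raise ValueError("N_control must be strictly positive")
    if n_ms <= 0:
        raise ValueError("N_MS must be strictly positive")
    return n_ms / n_control


def direction_of(rfc: float) -> str | None:
    """UP if RFC > 1, DOWN if RFC < 1, None at exactly 1."""
    if rfc > 1:
        return UP
    if rfc < 1:
        return DOWN
    return None


def rfc_table(records: pd.DataFrame, contrast: str) -> pd.DataFrame:
    """Per-GRN RFC for one contrast from a score_all record table."""
    ms_cond = contrast_condition(contrast)
    cols = ["grn_id", "N"] + (["motif_type"] if "motif_type" in records.columns else [])
    ctrl = records.loc[records["condition"] == CONTROL, cols].set_index("grn_id")
    ms = records.loc[records["condition"] == ms_cond, ["grn_id", "N"]].set_index("grn_id")
    joined = ctrl.join(ms, how="inner", lsuffix="_control", rsuffix="_ms")
    if (joined[["N_control", "N_ms"]] <= 0).any().any():
        raise ValueError("integrity scores must be strictly positive")
    out = pd.DataFrame(
        {
            "grn_id": joined.index,
            "contrast": contrast,
            "rfc": (joined["N_ms"] / joined["N_control"]).to_numpy(),
        }
    )
    if "motif_type" in records.columns:
        out["motif_type"] = joined["motif_type"].to_numpy()
    out["direction"] = [direction_of(x) for x in out["rfc"]]
    return out.reset_index(drop=True)


def rank_and_select(
    records: pd.DataFrame,
    contrast: str,
    k_up: int = 10,
    k_down: int = 10,
) -> pd.DataFrame:
    """Top-k up- and down-regulated GRNs per motif type for one contrast.

    UP candidates (RFC > 1) are ranked by RFC descending, DOWN candidates
    (RFC < 1) by RFC ascending — most extreme first; RFC == 1 never ranks.
    Ties break lexicographically on grn_id.  If a direction has fewer than
    k candidates all are returned with a warning.
    """
    table = rfc_table(records, contrast)
    if "motif_type" not in table.columns:
        table["motif_type"] = "ALL"
    selected = []
    for motif_type, group in table.groupby("motif_type", sort=True):
        for direction, k in ((UP, k_up), (DOWN, k_down)):
            cand = group[group["direction"] == direction]
            ascending = direction == DOWN
            cand = cand.sort_values(
                ["rfc", "grn_id"], ascending=[ascending, True], kind="mergesort"
            )
            if len(cand) < k:
                warnings.warn(
                    f"{motif_type}/{direction} in {contrast}: only {len(cand)} "
                    f"candidate(s) for k={k}"
                )
            top = cand.head(k).copy()
            top["rank"] = np.arange(1, len(top) + 1)
            selected.append(top)
    if not selected:
        return pd.DataFrame(
            columns=["grn_id", "motif_type", "contrast", "rfc", "direction", "rank"]
        )
    out = pd.concat(selected, ignore_index=True)
    return out[["grn_id", "motif_type", "contrast", "rfc", "direction", "rank"]]


def overlap_summary(selections: dict[str, pd.DataFrame]) -> dict[str, dict[str, set]]:
    """Venn regions of selected GRN ids across the three contrasts.

    ``selections`` maps contrast name -> rank_and_select output.  Returns,
    per motif type, the seven regions keyed e.g. ``"RRMS_only"``,
    ``"RRMS_PPMS"`` (pairwise, exclusive) and ``"ALL"``.
    """
    missing = set(CONTRASTS) - set(selections)
    if missing:
        raise ValueError(f"selections missing for contrast(s) {sorted(missing)}")
    conds = {c: contrast_condition(c) for c in CONTRASTS}
    motif_types = sorted(
        set().union(*(set(df["motif_type"]) for df in selections.values() if len(df)))
    )
    result: dict[str, dict[str, set]] = {}
    for mt in motif_types:
        ids = {
            conds[c]: set(df.loc[df["motif_type"] == mt, "grn_id"])
            for c, df in selections.items()
        }
        names = sorted(ids)
        regions: dict[str, set] = {}
        for r in (1, 2, 3):
            for combo in combinations(names, r):
                inside = set.intersection(*(ids[n] for n in combo))
                outside = set().union(*(ids[n] for n in names if n not in combo), set())
                region = inside - outside
                if r == 3:
                    regions["ALL"] = inside
                elif r == 2:
                    regions["_".join(combo)] = region
                else:
                    regions[f"{combo[0]}_only"] = region
        result[mt] = regions
    return result
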