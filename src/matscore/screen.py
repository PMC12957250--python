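"""Transcription-factor overexpression screen analytics.

Hit calling follows the screen's rule: within each experiment (±T3
condition) a TF is a hit on a channel (maturation score or Myom2-RFP %)
when its readout strictly exceeds mean + 1·SD of all non-control TF wells
of that condition; TFs are then categorized by whether they exceeded in
both conditions, one, or none. Confirmation uses the exact two-sided
Wilcoxon rank-sum test of a TF's replicate scores against pooled control
wells, and maturation-marker genes are flagged when p < 0.05 *and* the
linear-scale fold change versus control exceeds two-fold.
"""

from __future__ import annotations

import warnings
from typing import Mapping

import numpy as np
import pandas as pd
import scipy.stats

from .io_formats import ExpressionMatrix
from .normalize import NormalizationConfig, inverse_log_transform
from .score import MIN_GROUP_N, _rank_sum_p

__all__ = ["validate_screen_table", "call_hits", "confirm_hits", "marker_flags"]

CONDITIONS = ("T3", "no_T3")
CHANNEL_COLUMNS = {"score": "maturation_score", "rfp": "rfp_percent"}

#: hit threshold is mean + K_SD · SD of the non-control wells (K_SD = 1)
K_SD = 1.0
#: sample (n−1) SD convention for the screen threshold
SD_DDOF = 1


def validate_screen_table(table: pd.DataFrame) -> pd.DataFrame:
    """Check a screen well table against its invariants."""
    required = ("tf_id", "condition", "replicate", "maturation_score",
                "rfp_percent", "is_control")
    missing = [c for c in required if c not in table.columns]
    if missing:
        raise ValueError(f"screen table missing columns: {missing}")
    if table["tf_id"].astype(str).str.strip().eq("").any():
        raise ValueError("empty tf_id in screen table")
    bad = set(table["condition"]) - set(CONDITIONS)
    if bad:
        raise ValueError(f"unknown conditions {sorted(bad)}; expected {CONDITIONS}")
    rfp = table["rfp_percent"].to_numpy(dtype=float)
    if ((rfp < 0) | (rfp > 100)).any():
        raise ValueError("rfp_percent outside [0, 100]")
    return table


def call_hits(screen_table: pd.DataFrame, channel: str = "score") -> pd.DataFrame:
    """Per-TF hit categories for one readout channel.

    For each condition the threshold is mean + 1·SD (sample SD, n−1) of the
    channel metric over all non-control TF wells — controls are excluded
    from the threshold distribution. Exceedance is strict (>). Returns one
    row per TF with the per-condition metrics, thresholds, and the
    category ``both_conditions`` / ``one_condition`` / ``none``.
    """
    if channel not in CHANNEL_COLUMNS:
        raise ValueError(f"channel must be one of {tuple(CHANNEL_COLUMNS)}")
    metric = CHANNEL_COLUMNS[channel]
    validate_screen_table(screen_table)
    tf_wells = screen_table[~screen_table["is_control"]]

    exceeded: dict[str, pd.Series] = {}
    thresholds: dict[str, float] = {}
    for cond in CONDITIONS:
        wells = tf_wells[tf_wells["condition"] == cond]
        if len(wells) == 0:
            raise ValueError(f"condition {cond!r} has no non-control wells")
        if wells["tf_id"].nunique() < 3:
            raise ValueError(f"condition {cond!r} has fewer than 3 TFs")
        vals = wells[metric].to_numpy(dtype=float)
        thr = float(vals.mean() + K_SD * vals.std(ddof=SD_DDOF))
        thresholds[cond] = thr
        per_tf = wells.groupby("tf_id")[metric].mean()
        exceeded[cond] = per_tf > thr

    tf_ids = sorted(set(tf_wells["tf_id"]))
    rows = []
    for tf in tf_ids:
        hits = [bool(exceeded[c].get(tf, False)) for c in CONDITIONS]
        n_hit = sum(hits)
        category = ("both_conditions" if n_hit == 2
                    else "one_condition" if n_hit == 1 else "none")
        rows.append({
            "tf_id": tf,
            "channel": channel,
            "exceeds_T3": hits[0],
            "exceeds_no_T3": hits[1],
            "category": category,
        })
    out = pd.DataFrame(rows)
    out.attrs["thresholds"] = thresholds
    return out


def confirm_hits(screen_table: pd.DataFrame, channel: str = "score",
                 condition: str | None = None) -> pd.DataFrame:
    """Exact Wilcoxon rank-sum of each TF's replicates versus pooled controls.

    Controls (``is_control``) are pooled — in the screen these are the
    no-insert and GFP vector wells. TFs or control pools with fewer than 3
    wells yield NA (no statistics on n < 3). Significance is flagged at
    0.05 and 0.01.
    """
    metric = CHANNEL_COLUMNS[channel]
    validate_screen_table(screen_table)
    t = screen_table
    if condition is not None:
        t = t[t["condition"] == condition]
        if len(t) == 0:
            raise ValueError(f"no wells for condition {condition!r}")
    controls = t.loc[t["is_control"], metric].to_numpy(dtype=float)
    rows = []
    for tf, sub in t[~t["is_control"]].groupby("tf_id"):
        vals = sub[metric].to_numpy(dtype=float)
        if len(vals) < MIN_GROUP_N or len(controls) < MIN_GROUP_N:
            warnings.warn(
                f"no statistics for TF {tf!r}: fewer than {MIN_GROUP_N} "
                "replicates or controls", stacklevel=2)
            p = np.nan
        else:
            p = _rank_sum_p(vals, controls)
        rows.append({
            "tf_id": tf,
            "n_replicates": len(vals),
            "n_controls": len(controls),
            "mean_metric": float(vals.mean()),
            "control_mean": float(controls.mean()) if len(controls) else np.nan,
            "p_value": p,
            "significant_05": bool(p < 0.05) if np.isfinite(p) else False,
            "significant_01": bool(p < 0.01) if np.isfinite(p) else False,
        })
    return pd.DataFrame(rows)


def marker_flags(matrix: ExpressionMatrix,
                 groups: Mapping[str, str] | pd.Series,
                 control_group: str,
                 config: NormalizationConfig = NormalizationConfig(),
                 fold_change_min: float = 2.0,
                 alpha: float = 0.05) -> pd.DataFrame:
    """Flag maturation-marker genes changed versus a control group.

    A gene is flagged for a group when the two-sided Wilcoxon p-value
    against the control group is below ``alpha`` *and* the linear-TPM fold
    change (ratio of group means) exceeds ``fold_change_min`` in either
    direction. Input may be TPM or log-TPM (log values are back-transformed
    for the fold change; the rank test is scale-invariant). A zero-mean
    control gene leaves the fold change undefined → NA with a warning.
    """
    if matrix.unit == "log1p_tpm":
        tpm = inverse_log_transform(matrix, config)
    elif matrix.unit == "tpm":
        tpm = matrix
    else:
        raise ValueError(f"marker_flags expects tpm or log1p_tpm, got {matrix.unit!r}")
    g = pd.Series(dict(groups) if not isinstance(groups, pd.Series) else groups)
    if control_group not in set(g.values):
        raise ValueError(f"control group {control_group!r} not present")
    ctrl_ids = [s for s in g.index[g == control_group] if s in tpm.values.columns]
    if len(ctrl_ids) < MIN_GROUP_N:
        raise ValueError(f"control group needs >= {MIN_GROUP_N} samples")

    rows = []
    for group in (x for x in pd.unique(g.values) if x != control_group):
        ids = [s for s in g.index[g == group] if s in tpm.values.columns]
        if len(ids) < MIN_GROUP_N:
            warnings.warn(f"group {group!r} has n < {MIN_GROUP_N}; skipped",
                          stacklevel=2)
            continue
        for gene in tpm.gene_ids:
            x = tpm.values.loc[gene, ids].to_numpy(dtype=float)
            c = tpm.values.loc[gene, ctrl_ids].to_numpy(dtype=float)
            p = _rank_sum_p(x, c)
            if c.mean() == 0:
                warnings.warn(f"zero control mean for gene {gene!r}; "
                              "fold change undefined", stacklevel=2)
                fc, flagged, direction = np.nan, False, "na"
            else:
                fc = float(x.mean() / c.mean())
                big = fc > fold_change_min or fc < 1.0 / fold_change_min
                flagged = bool(p < alpha and big)
                direction = "up" if fc > 1 else "down"
            rows.append({"group": group, "gene_id": gene, "p_value": p,
                         "fold_change": fc, "direction": direction,
                         "flagged": flagged})
    return pd.DataFrame(rows)
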