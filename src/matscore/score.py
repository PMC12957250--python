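"""Project query samples onto a frozen atlas and compare score groups.

The PC1 value of a query sample is the centered projection
``Σᵢ ωᵢ (xᵢ − μᵢ)`` over the atlas gene set, where x is the sample's
log-TPM and μ the atlas reference means; genes the query lacks are imputed
at μ (contribute zero), capped at 5% of the total |ω| mass. The maturation
score is then the exact affine map ``scale × (offset + pc1)``.
"""

from __future__ import annotations

import itertools
import warnings
from typing import Mapping

import numpy as np
import pandas as pd
import scipy.stats

from .io_formats import ExpressionMatrix, MaturationAtlas

__all__ = ["project", "maturation_score", "compare_groups"]

#: queries missing more than this fraction of Σ|ω| are refused by default
MAX_MISSING_WEIGHT_FRACTION = 0.05

#: per-group size above which the rank-sum test switches to the normal
#: approximation (screen groups are tiny, so exactness is the common path)
EXACT_WILCOXON_MAX_N = 25

#: groups smaller than this yield NA instead of a p-value
MIN_GROUP_N = 3


def project(atlas: MaturationAtlas,
            sample: pd.Series,
            centered: bool = True,
            allow_missing: bool = False,
            ) -> tuple[float, int, float]:
    """Project one log-TPM sample onto the atlas PC1 axis.

    Parameters
    ----------
    sample
        log1p_tpm expression indexed by gene symbol.
    centered
        If True (default) returns Σω(x − μ); if False the uncentered
        Σω·x, which differs by the constant Σωμ (absorbable into the
        calibration offset).
    allow_missing
        Override the 5% missing-weight-mass cap.

    Returns
    -------
    (pc1_value, n_genes_matched, missing_weight_fraction)
    """
    w = atlas.weight_series()
    mu = atlas.mean_series()
    matched = w.index.intersection(sample.index)
    total_mass = float(np.abs(w).sum())
    missing_mass = float(np.abs(w.drop(matched)).sum())
    missing_frac = missing_mass / total_mass if total_mass > 0 else 0.0
    if missing_frac > MAX_MISSING_WEIGHT_FRACTION and not allow_missing:
        raise ValueError(
            f"query lacks {missing_frac:.1%} of the atlas |weight| mass "
            f"(cap {MAX_MISSING_WEIGHT_FRACTION:.0%}); pass allow_missing=True "
            "to score anyway"
        )
    x = sample.reindex(w.index)
    x = x.fillna(mu)  # absent genes imputed at the reference mean
    if centered:
        pc1 = float((w * (x - mu)).sum())
    else:
        pc1 = float((w * x).sum())
    return pc1, len(matched), missing_frac


def maturation_score(atlas: MaturationAtlas,
                     matrix: ExpressionMatrix,
                     allow_missing: bool = False) -> pd.DataFrame:
    """Score every sample of a log-TPM matrix against the atlas.

    Returns a table with one row per sample: ``sample_id``, ``pc1_value``,
    ``maturation_score`` (= scale × (offset + pc1)), ``n_genes_matched``
    and ``missing_weight_fraction``.
    """
    if matrix.unit != "log1p_tpm":
        raise ValueError(
            f"maturation_score expects log1p_tpm input, got {matrix.unit!r}"
        )
    cal = atlas.calibration
    rows = []
    for sid in matrix.sample_ids:
        pc1, n_matched, miss = project(atlas, matrix.values[sid],
                                       allow_missing=allow_missing)
        rows.append({
            "sample_id": sid,
            "pc1_value": pc1,
            "maturation_score": cal.scale * (cal.offset + pc1),
            "n_genes_matched": n_matched,
            "missing_weight_fraction": miss,
        })
    return pd.DataFrame(rows)


def _rank_sum_p(x: np.ndarray, y: np.ndarray) -> float:
    """Two-sided Wilcoxon rank-sum p; exact null for small groups."""
    method = "exact" if max(len(x), len(y)) <= EXACT_WILCOXON_MAX_N else "asymptotic"
    return float(scipy.stats.mannwhitneyu(x, y, alternative="two-sided",
                                          method=method).pvalue)


def compare_groups(score_table: pd.DataFrame,
                   groups: Mapping[str, str] | pd.Series,
                   method: str = "wilcoxon",
                   alpha: float = 0.05,
                   bh_column: bool = False) -> pd.DataFrame:
    """Pairwise group comparison of maturation scores.

    ``method="wilcoxon"`` runs the two-sided rank-sum test per pair (exact
    null up to n = 25 per group); ``method="tukey_hsd"`` runs Tukey's
    honestly-significant-difference procedure jointly over all groups of
    size ≥ 3. Pairs involving a group with fewer than 3 samples are
    reported as NA with a warning — no statistics on n < 3. P-values are
    flagged at ``alpha`` (0.05) without multiple-testing correction; set
    ``bh_column=True`` for an additional Benjamini–Hochberg column.
    """
    if method not in ("wilcoxon", "tukey_hsd"):
        raise ValueError(f"unknown method {method!r}")
    g = pd.Series(dict(groups) if not isinstance(groups, pd.Series) else groups)
    scores = score_table.set_index("sample_id")["maturation_score"]
    by_group: dict[str, np.ndarray] = {}
    for name in pd.unique(g.values):
        ids = g.index[g == name]
        vals = scores.reindex(ids).dropna().to_numpy()
        if len(vals) == 0:
            raise ValueError(f"group {name!r} has no scored samples")
        by_group[name] = vals
    names = list(by_group)
    if len(names) < 2:
        raise ValueError("need at least two groups to compare")

    eligible = [n for n in names if len(by_group[n]) >= MIN_GROUP_N]
    tukey_p: dict[tuple[str, str], float] = {}
    if method == "tukey_hsd" and len(eligible) >= 2:
        res = scipy.stats.tukey_hsd(*(by_group[n] for n in eligible))
        for i, j in itertools.combinations(range(len(eligible)), 2):
            tukey_p[(eligible[i], eligible[j])] = float(res.pvalue[i, j])

    rows = []
    for a, b in itertools.combinations(names, 2):
        na, nb = len(by_group[a]), len(by_group[b])
        if na < MIN_GROUP_N or nb < MIN_GROUP_N:
            warnings.warn(
                f"no statistics for pair ({a!r}, {b!r}): group size below "
                f"{MIN_GROUP_N}", stacklevel=2)
            p = np.nan
        elif method == "wilcoxon":
            p = _rank_sum_p(by_group[a], by_group[b])
        else:
            p = tukey_p[(a, b)]
        rows.append({"group1": a, "group2": b, "n1": na, "n2": nb,
                     "method": method, "p_value": p,
                     "significant": bool(p < alpha) if np.isfinite(p) else False})
    out = pd.DataFrame(rows)
    if bh_column:
        mask = out["p_value"].notna()
        adj = np.full(len(out), np.nan)
        if mask.any():
            adj[mask.to_numpy()] = scipy.stats.false_discovery_control(
                out.loc[mask, "p_value"].to_numpy())
        out["p_adj_bh"] = adj
    return out
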