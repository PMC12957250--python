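"""Build the developmental maturation atlas.

PCA is the SVD of the column-centered (per-gene mean removed) log-TPM
matrix with genes as variables and no unit-variance scaling, so loadings
weight high-dynamic-range maturation genes. The PC1 loading vector is
stored unit-norm, its sign oriented so older reference samples project
higher, and the PC1 range of reference *ventricles* anchors the affine
0–100 calibration.
"""

from __future__ import annotations

import logging
import warnings
from typing import Sequence

import numpy as np
import pandas as pd
import scipy.stats

from .io_formats import Calibration, ExpressionMatrix, MaturationAtlas, SampleMetadata
from .normalize import NormalizationConfig

__all__ = ["build_atlas", "calibrate", "select_weighted_genes", "write_gene_lists"]

logger = logging.getLogger(__name__)


def calibrate(pc1_values: Sequence[float],
              mode: str = "data_driven",
              offset: float | None = None,
              scale: float | None = None) -> Calibration:
    """Derive the affine PC1 → score calibration.

    ``data_driven`` maps the observed PC1 range exactly onto [0, 100]:
    offset = −min(PC1), scale = 100/(max − min). ``paper_constants`` stores
    the supplied (offset, scale) verbatim — e.g. the published mouse
    constants (32, 1.5) or humanized constants (27, 1.8).
    """
    if mode == "paper_constants":
        if offset is None or scale is None:
            raise ValueError("paper_constants mode requires explicit offset and scale")
        return Calibration(offset=float(offset), scale=float(scale), mode=mode)
    if mode != "data_driven":
        raise ValueError(f"unknown calibration mode {mode!r}")
    vals = np.asarray(list(pc1_values), dtype=float)
    if len(np.unique(vals)) < 2:
        raise ValueError("calibration needs at least 2 distinct PC1 values")
    lo, hi = float(vals.min()), float(vals.max())
    return Calibration(offset=-lo, scale=100.0 / (hi - lo), mode="data_driven")


def build_atlas(matrix: ExpressionMatrix,
                metadata: SampleMetadata,
                reference_selector: Sequence[str] | None = None,
                calibration_mode: str = "data_driven",
                manual_offset: float | None = None,
                manual_scale: float | None = None,
                config: NormalizationConfig = NormalizationConfig(),
                ) -> MaturationAtlas:
    """Fit the maturation atlas on reference log-TPM samples.

    Parameters
    ----------
    matrix
        log1p_tpm matrix already restricted to the filtered gene set.
    metadata
        Sample annotations; reference samples need numeric ``age_days``.
    reference_selector
        Sample ids to fit on; defaults to every metadata sample present in
        the matrix. At least 3 samples spanning ≥ 2 distinct ages.
    calibration_mode
        ``data_driven`` (reference ventricular PC1 range → [0, 100]) or
        ``paper_constants`` with ``manual_offset``/``manual_scale``.

    Notes
    -----
    Sign orientation: the loading is flipped so the Spearman correlation
    between reference PC1 scores and age is positive; an exact zero
    correlation falls back to making the largest-|ω| gene positive.
    """
    if matrix.unit != "log1p_tpm":
        raise ValueError(f"build_atlas expects log1p_tpm, got {matrix.unit!r}")
    if reference_selector is None:
        reference_selector = [s for s in metadata.sample_ids
                              if s in matrix.values.columns]
    ref_ids = list(reference_selector)
    if len(ref_ids) < 3:
        raise ValueError(f"need >= 3 reference samples, got {len(ref_ids)}")
    ref = matrix.subset_samples(ref_ids)
    ages = metadata.age_of().reindex(ref_ids)
    if ages.dropna().nunique() < 2:
        raise ValueError("reference samples must span >= 2 distinct age_days values")

    X = ref.values.to_numpy(dtype=float)            # genes × samples
    mu = X.mean(axis=1)
    Xc = (X - mu[:, None]).T                        # samples × genes, centered
    U, S, Vt = np.linalg.svd(Xc, full_matrices=False)
    if S[0] <= 1e-12 * max(Xc.shape):
        raise ValueError("reference matrix has no variance; cannot extract PC1")
    weights = Vt[0]                                 # unit-norm gene loadings
    scores = Xc @ weights                           # PC1 per reference sample

    sign = _orientation_sign(scores, ages.to_numpy(dtype=float), weights)
    weights = sign * weights
    scores = sign * scores

    oldest, youngest = ages.max(), ages.min()
    mean_old = scores[(ages == oldest).to_numpy()].mean()
    mean_young = scores[(ages == youngest).to_numpy()].mean()
    if not mean_old > mean_young:
        warnings.warn(
            "after orientation the oldest reference group does not outscore the "
            "youngest; the maturation axis may be weak in these data",
            stacklevel=2,
        )

    chambers = metadata.chamber_of().reindex(ref_ids)
    vent_mask = (chambers == "ventricle").to_numpy()
    if vent_mask.any():
        cal_scores = scores[vent_mask]
    else:
        warnings.warn("no ventricle samples among the reference; calibrating on all "
                      "reference samples", stacklevel=2)
        cal_scores = scores
    lo, hi = float(cal_scores.min()), float(cal_scores.max())
    if not lo < hi:
        raise ValueError("degenerate PC1 range over calibration samples (min == max)")

    calibration = calibrate(cal_scores, mode=calibration_mode,
                            offset=manual_offset, scale=manual_scale)

    provenance = {
        "log_base": config.log_base,
        "pseudocount": config.pseudocount,
        "low_expression_threshold": config.low_expression_threshold,
        "min_reads_per_sample": config.min_reads_per_sample,
        "n_reference_samples": len(ref_ids),
        "pca_scaling": "none",
        "projection": "centered",
    }
    return MaturationAtlas(
        gene_ids=ref.gene_ids,
        weights=weights,
        reference_means=mu,
        calibration=calibration,
        orientation_sign=int(sign),
        pc1_reference_range=(lo, hi),
        provenance=provenance,
    )


def _orientation_sign(scores: np.ndarray, ages: np.ndarray,
                      weights: np.ndarray) -> int:
    """+1/−1 so that PC1 increases with age (Spearman); tie → top gene positive."""
    ok = np.isfinite(ages)
    rho = 0.0
    if ok.sum() >= 2 and len(np.unique(ages[ok])) >= 2:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            rho = scipy.stats.spearmanr(scores[ok], ages[ok]).statistic
        if not np.isfinite(rho):
            rho = 0.0
    if rho > 0:
        return +1
    if rho < 0:
        return -1
    top = int(np.argmax(np.abs(weights)))
    return +1 if weights[top] >= 0 else -1


def select_weighted_genes(atlas: MaturationAtlas, k_sd: float = 2.0,
                          ) -> tuple[list[str], list[str]]:
    """Genes with extreme PC1 weights, for gene-ontology upload.

    Positive list: ω ≥ mean(ω) + k_sd·sd(ω); negative list:
    ω ≤ mean(ω) − k_sd·sd(ω). Both sorted by |ω| descending; disjoint
    whenever sd > 0. sd is taken over all atlas weights (population sd);
    when every weight is identical (sd = 0) both lists are empty.
    """
    if not k_sd > 0:
        raise ValueError("k_sd must be positive")
    w = atlas.weights
    m, s = float(w.mean()), float(w.std())
    if s == 0:
        return [], []
    hi, lo = m + k_sd * s, m - k_sd * s
    order = np.argsort(-np.abs(w), kind="stable")
    pos = [atlas.gene_ids[i] for i in order if w[i] >= hi]
    neg = [atlas.gene_ids[i] for i in order if w[i] <= lo]
    return pos, neg


def write_gene_lists(atlas: MaturationAtlas, positive_path, negative_path,
                     k_sd: float = 2.0) -> None:
    """Write the weighted-gene lists as one symbol per line (PANTHER-ready)."""
    pos, neg = select_weighted_genes(atlas, k_sd=k_sd)
    for path, genes in ((positive_path, pos), (negative_path, neg)):
        with open(path, "w") as fh:
            for g in genes:
                fh.write(g + "\n")
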