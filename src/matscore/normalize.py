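"""Sample QC, TPM normalization for 3′-tag counts, and gene filtering.

QuantSeq-style 3′ libraries yield one tag per transcript, so "TPM" here is
length-free counts-per-million: each column is scaled to sum to 1e6. The
log transform is log(ε + 1) in a configurable base (natural by default).
Thresholds follow strict inequalities: samples with *fewer than* the read
minimum are dropped, genes whose reference mean TPM is *less than* the
threshold are excluded.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .io_formats import LOG_BASES, ExpressionMatrix

__all__ = ["NormalizationConfig", "qc_filter_samples", "counts_to_tpm",
           "log_transform", "inverse_log_transform", "filter_low_expression"]

logger = logging.getLogger(__name__)

_LOG_FN = {"natural": np.log, "log2": np.log2, "log10": np.log10}
_EXP_FN = {"natural": np.exp, "log2": lambda x: np.exp2(x), "log10": lambda x: 10.0 ** x}


@dataclass(frozen=True)
class NormalizationConfig:
    """Normalization and filtering parameters.

    Attributes
    ----------
    min_reads_per_sample
        Samples with column sum strictly below this are dropped (default 1e6).
    low_expression_threshold
        Genes with reference-mean TPM strictly below this are excluded
        (default 1.0 TPM).
    log_base
        Base of the log(ε + 1) transform; "natural", "log2" or "log10".
    pseudocount
        The +1 inside the log; fixed at 1.0 by convention.
    """

    min_reads_per_sample: int = 1_000_000
    low_expression_threshold: float = 1.0
    log_base: str = "natural"
    pseudocount: float = 1.0

    def __post_init__(self) -> None:
        if self.min_reads_per_sample < 0:
            raise ValueError("min_reads_per_sample must be >= 0")
        if self.low_expression_threshold < 0:
            raise ValueError("low_expression_threshold must be >= 0")
        if self.log_base not in LOG_BASES:
            raise ValueError(f"log_base must be one of {LOG_BASES}")
        if not self.pseudocount > 0:
            raise ValueError("pseudocount must be > 0")


def qc_filter_samples(matrix: ExpressionMatrix,
                      config: NormalizationConfig = NormalizationConfig(),
                      ) -> ExpressionMatrix:
    """Drop samples with fewer than ``min_reads_per_sample`` total reads.

    The inequality is strict: a sample with exactly the minimum is kept.
    Sample order of the survivors is preserved. Raises if nothing survives.
    """
    if matrix.unit != "raw_counts":
        raise ValueError(f"QC operates on raw_counts, got unit={matrix.unit!r}")
    totals = matrix.values.sum(axis=0)
    keep = totals >= config.min_reads_per_sample
    removed = list(matrix.values.columns[~keep])
    if removed:
        logger.info("QC removed %d sample(s) below %d reads: %s",
                    len(removed), config.min_reads_per_sample, removed)
    if not keep.any():
        raise ValueError(
            f"all {matrix.shape[1]} samples fall below the "
            f"{config.min_reads_per_sample}-read QC minimum"
        )
    return ExpressionMatrix(matrix.values.loc[:, keep], "raw_counts")


def counts_to_tpm(matrix: ExpressionMatrix) -> ExpressionMatrix:
    """Scale each sample's counts to transcripts-per-million.

    For 3′-tag counts no transcript-length division is applied (one tag per
    transcript); each output column sums to exactly 1e6.
    """
    if matrix.unit != "raw_counts":
        raise ValueError(f"counts_to_tpm expects raw_counts, got {matrix.unit!r}")
    totals = matrix.values.sum(axis=0)
    zero = totals[totals <= 0]
    if len(zero):
        raise ValueError(f"zero-sum sample(s): {list(zero.index)}")
    tpm = matrix.values / totals * 1e6
    return ExpressionMatrix(tpm, "tpm")


def log_transform(matrix: ExpressionMatrix,
                  config: NormalizationConfig = NormalizationConfig(),
                  ) -> ExpressionMatrix:
    """Elementwise log(ε + pseudocount) in the configured base."""
    if matrix.unit != "tpm":
        raise ValueError(f"log_transform expects tpm, got {matrix.unit!r}")
    out = _LOG_FN[config.log_base](matrix.values + config.pseudocount)
    return ExpressionMatrix(out, "log1p_tpm")


def inverse_log_transform(matrix: ExpressionMatrix,
                          config: NormalizationConfig = NormalizationConfig(),
                          ) -> ExpressionMatrix:
    """Invert :func:`log_transform`; clips tiny negative round-off to zero."""
    if matrix.unit != "log1p_tpm":
        raise ValueError(f"expected log1p_tpm, got {matrix.unit!r}")
    out = _EXP_FN[config.log_base](matrix.values) - config.pseudocount
    return ExpressionMatrix(out.clip(lower=0.0), "tpm")


def filter_low_expression(matrix: ExpressionMatrix,
                          reference_sample_ids: Sequence[str],
                          config: NormalizationConfig = NormalizationConfig(),
                          ) -> list[str]:
    """Genes whose mean TPM over *reference* samples meets the threshold.

    The mean is taken over the reference (heart) samples only — query
    samples never change the atlas gene set. "Less than one" is strict, so
    a gene at exactly the threshold is retained. Returns gene ids in the
    matrix's original order.
    """
    if matrix.unit != "tpm":
        raise ValueError(f"filter_low_expression expects tpm, got {matrix.unit!r}")
    ref = list(reference_sample_ids)
    if not ref:
        raise ValueError("reference sample set is empty")
    missing = [s for s in ref if s not in matrix.values.columns]
    if missing:
        raise ValueError(f"reference samples absent from matrix: {missing[:5]}")
    means = matrix.values[ref].mean(axis=1)
    kept = list(matrix.values.index[means >= config.low_expression_threshold])
    if not kept:
        raise ValueError(
            f"no gene reaches mean TPM {config.low_expression_threshold} "
            f"over the {len(ref)} reference samples"
        )
    dropped = matrix.shape[0] - len(kept)
    if dropped:
        logger.info("low-expression filter removed %d of %d genes",
                    dropped, matrix.shape[0])
    return kept
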