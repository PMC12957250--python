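"""Cross-species harmonization by shared gene symbols.

Mouse and human gene symbols differ mainly in casing conventions
(mouse Title-case ``Ckmt2`` vs human UPPER-case ``CKMT2``), so the default
policy matches symbols case-insensitively; an explicit two-column table
overrides it. Matching is one-to-one: any symbol involved in a
many-to-many collision is dropped and logged. After restriction to the
shared gene space, TPM is recomputed so each sample re-sums to one
million — scoring requires compositional consistency within the reduced
space.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .atlas import build_atlas
from .io_formats import ExpressionMatrix, MaturationAtlas, SampleMetadata
from .normalize import NormalizationConfig, counts_to_tpm, log_transform

__all__ = ["OrthologMap", "build_ortholog_map", "read_ortholog_table",
           "harmonize", "build_humanized_atlas"]

logger = logging.getLogger(__name__)

#: harmonization refuses to proceed when the map covers less than this
#: fraction of an atlas's |weight| mass
MIN_ATLAS_WEIGHT_COVERAGE = 0.5


@dataclass
class OrthologMap:
    """One-to-one symbol pairs (species A ↔ species B)."""

    pairs: list[tuple[str, str]]
    match_policy: str = "case_insensitive_symbol"
    dropped_collisions: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for a, b in self.pairs:
            for s in (a, b):
                if s in seen:
                    raise ValueError(f"symbol {s!r} appears in more than one pair")
                seen.add(s)

    def __len__(self) -> int:
        return len(self.pairs)

    def target_by_key(self) -> dict[str, str]:
        """casefolded symbol (either species) → species-A symbol."""
        out: dict[str, str] = {}
        for a, b in self.pairs:
            out[a.casefold()] = a
            out[b.casefold()] = a
        return out


def build_ortholog_map(symbols_a: Sequence[str],
                       symbols_b: Sequence[str],
                       policy: str = "case_insensitive_symbol",
                       table: Sequence[tuple[str, str]] | None = None,
                       ) -> OrthologMap:
    """Match two symbol lists into one-to-one ortholog pairs.

    With the default policy, symbols pair when their casefolded forms are
    identical. Keys carried by more than one symbol on either side are
    collisions: every involved symbol is dropped and reported. An explicit
    ``table`` of (a, b) pairs bypasses matching (rows referencing symbols
    absent from the lists are ignored).
    """
    if policy == "explicit_table":
        if table is None:
            raise ValueError("explicit_table policy requires a table")
        set_a, set_b = set(symbols_a), set(symbols_b)
        pairs = [(a, b) for a, b in table if a in set_a and b in set_b]
        if not pairs:
            raise ValueError("ortholog table matches no genes in the two lists")
        return OrthologMap(pairs, match_policy="explicit_table")
    if policy != "case_insensitive_symbol":
        raise ValueError(f"unknown match policy {policy!r}")

    by_key_a: dict[str, list[str]] = {}
    by_key_b: dict[str, list[str]] = {}
    for s in symbols_a:
        by_key_a.setdefault(s.casefold(), []).append(s)
    for s in symbols_b:
        by_key_b.setdefault(s.casefold(), []).append(s)

    pairs, dropped = [], []
    for key in by_key_a:
        if key not in by_key_b:
            continue
        ca, cb = by_key_a[key], by_key_b[key]
        if len(ca) == 1 and len(cb) == 1:
            pairs.append((ca[0], cb[0]))
        else:
            dropped.extend(ca + cb)
    if dropped:
        logger.warning("dropped %d symbols in many-to-many collisions: %s%s",
                       len(dropped), dropped[:10],
                       " …" if len(dropped) > 10 else "")
    if not pairs:
        raise ValueError("no shared gene symbols between the two lists")
    return OrthologMap(pairs, dropped_collisions=dropped)


def read_ortholog_table(path) -> list[tuple[str, str]]:
    """Read a two-column TSV of (species A symbol, species B symbol)."""
    df = pd.read_csv(path, sep="\t", header=None, comment="#", dtype=str)
    if df.shape[1] < 2:
        raise ValueError(f"ortholog table {path} needs two columns")
    return list(df.iloc[:, :2].itertuples(index=False, name=None))


def harmonize(matrix: ExpressionMatrix,
              ortholog_map: OrthologMap,
              atlas: MaturationAtlas | None = None) -> ExpressionMatrix:
    """Restrict a matrix to mapped genes, renamed into species-A symbols.

    For TPM input the columns are renormalized to 1e6 on the reduced gene
    set. Idempotent: harmonizing an already harmonized matrix is a no-op.
    When an ``atlas`` is supplied, the call refuses maps covering less than
    half of the atlas's |weight| mass.
    """
    if matrix.unit not in ("raw_counts", "tpm"):
        raise ValueError(f"harmonize expects raw_counts or tpm, got {matrix.unit!r}")
    lookup = ortholog_map.target_by_key()
    keep_idx, new_names = [], []
    for gene in matrix.gene_ids:
        target = lookup.get(gene.casefold())
        if target is not None:
            keep_idx.append(gene)
            new_names.append(target)
    if not keep_idx:
        raise ValueError("ortholog map matches no gene in the matrix")
    if atlas is not None:
        w = atlas.weight_series()
        covered = w.index.intersection(new_names)
        coverage = float(np.abs(w.loc[covered]).sum() / np.abs(w).sum())
        if coverage < MIN_ATLAS_WEIGHT_COVERAGE:
            raise ValueError(
                f"ortholog map covers only {coverage:.1%} of the atlas |weight| "
                f"mass (minimum {MIN_ATLAS_WEIGHT_COVERAGE:.0%})"
            )
    sub = matrix.values.loc[keep_idx].copy()
    sub.index = new_names
    if matrix.unit == "tpm":
        sub = sub / sub.sum(axis=0) * 1e6
    return ExpressionMatrix(sub, matrix.unit)


def build_humanized_atlas(mouse_counts: ExpressionMatrix,
                          metadata: SampleMetadata,
                          ortholog_map: OrthologMap,
                          reference_selector: Sequence[str] | None = None,
                          calibration_mode: str = "data_driven",
                          manual_offset: float | None = None,
                          manual_scale: float | None = None,
                          config: NormalizationConfig = NormalizationConfig(),
                          ) -> MaturationAtlas:
    """Rebuild the maturation atlas on the shared-symbol gene space.

    Identical pipeline to :func:`matscore.atlas.build_atlas`, run after
    restricting the mouse reference counts to mapped genes and recomputing
    TPM on the reduced set. ``paper_constants`` mode with the published
    humanized values stores (offset 27, scale 1.8) verbatim.
    """
    if mouse_counts.unit != "raw_counts":
        raise ValueError("build_humanized_atlas expects raw counts")
    reduced = harmonize(mouse_counts, ortholog_map)
    logtpm = log_transform(counts_to_tpm(reduced), config)
    humanized = build_atlas(logtpm, metadata,
                            reference_selector=reference_selector,
                            calibration_mode=calibration_mode,
                            manual_offset=manual_offset,
                            manual_scale=manual_scale,
                            config=config)
    humanized.provenance["gene_space"] = "shared_orthologs"
    humanized.provenance["n_orthologs"] = len(ortholog_map)
    return humanized
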