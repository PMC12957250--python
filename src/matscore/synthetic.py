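"""Ground-truthed simulators for atlases, two-species data and TF screens.

The atlas generator emulates a chronological whole-heart reference: a
monotone maturation program (log-mean expression rising or falling
linearly in pseudotime, echoing energy-metabolism/sarcomere genes up and
cell-cycle genes down), a chamber program on a disjoint gene set (shifted
in atria, flat in time), and negative-binomial counts around
library-size-scaled means. Stage ages follow the nonuniform embryonic →
10-month design (dense early, sparse late); pseudotime is log-age rescaled
to [0, 1]. Every generator is a pure function of (spec, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .io_formats import ExpressionMatrix, SampleMetadata

__all__ = ["SyntheticAtlasSpec", "GroundTruth", "TwoSpeciesData",
           "simulate_atlas", "simulate_two_species", "simulate_screen"]

#: conception-anchored ages (days) for the default 8 reference stages
DEFAULT_STAGES: tuple[tuple[str, float], ...] = (
    ("E11", 11.0), ("E16", 16.0), ("P1", 22.0), ("P7", 28.0),
    ("P14", 35.0), ("P56", 77.0), ("5mo", 171.0), ("10mo", 321.0),
)


@dataclass(frozen=True)
class SyntheticAtlasSpec:
    """Parameters of the synthetic developmental atlas.

    Fractions partition genes into maturation-up, maturation-down,
    chamber-program and flat classes. Slopes are natural-log-units of
    change across the full pseudotime span; ``chamber_effect_size`` is the
    log-scale shift applied to chamber genes in atrial samples.
    """

    n_genes: int = 2000
    frac_up: float = 0.15
    frac_down: float = 0.10
    frac_chamber: float = 0.05
    stages: tuple[tuple[str, float], ...] = DEFAULT_STAGES
    replicates_per_stage: int = 4
    chambers: tuple[str, ...] = ("ventricle", "atrium")
    chamber_effect_size: float = 2.0
    slope_range: tuple[float, float] = (1.0, 3.0)
    baseline_log_mean: float = 3.0
    baseline_log_sd: float = 2.0
    nb_dispersion: float = 0.05
    library_size_mean: float = 4e6
    library_size_cv: float = 0.3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genes <= 0 or self.replicates_per_stage <= 0:
            raise ValueError("n_genes and replicates_per_stage must be positive")
        if min(self.frac_up, self.frac_down, self.frac_chamber) < 0:
            raise ValueError("gene-class fractions must be non-negative")
        if self.frac_up + self.frac_down + self.frac_chamber > 1:
            raise ValueError("gene-class fractions must sum to <= 1")
        if len(self.stages) < 2:
            raise ValueError("need at least 2 stages")
        if self.nb_dispersion < 0 or self.library_size_mean <= 0:
            raise ValueError("invalid noise parameters")

    def pseudotime(self) -> dict[str, float]:
        """Stage → true pseudotime in [0, 1] (log-age rescaled)."""
        ages = np.array([a for _, a in self.stages], dtype=float)
        la = np.log(ages)
        t = (la - la.min()) / (la.max() - la.min())
        return {name: float(ti) for (name, _), ti in zip(self.stages, t)}


@dataclass
class GroundTruth:
    """What the generator knows: per-sample pseudotime, per-gene class."""

    pseudotime: pd.Series          # sample_id → t ∈ [0, 1]
    gene_class: pd.Series          # gene_id → {up, down, flat, chamber}
    tf_effects: dict[str, float] | None = None


@dataclass
class TwoSpeciesData:
    """Paired species-A (Title-case) and species-B (UPPER-case) datasets."""

    matrix_a: ExpressionMatrix
    metadata_a: SampleMetadata
    truth_a: GroundTruth
    matrix_b: ExpressionMatrix
    metadata_b: SampleMetadata
    truth_b: GroundTruth
    shared_genes_a: list[str]      # species-A symbols of the shared genes


def _gene_params(spec: SyntheticAtlasSpec, rng: np.random.Generator):
    n = spec.n_genes
    n_up = int(round(spec.frac_up * n))
    n_down = int(round(spec.frac_down * n))
    n_cham = int(round(spec.frac_chamber * n))
    classes = np.array(["up"] * n_up + ["down"] * n_down +
                       ["chamber"] * n_cham + ["flat"] * (n - n_up - n_down - n_cham))
    genes = [f"Gene{i:05d}" for i in range(n)]
    baseline = rng.normal(spec.baseline_log_mean, spec.baseline_log_sd, size=n)
    lo, hi = spec.slope_range
    mag = rng.uniform(lo, hi, size=n)
    slope = np.where(classes == "up", mag, np.where(classes == "down", -mag, 0.0))
    cham_sign = rng.choice([-1.0, 1.0], size=n)
    cham_shift = np.where(classes == "chamber",
                          cham_sign * spec.chamber_effect_size, 0.0)
    return genes, classes, baseline, slope, cham_shift


def _nb_counts(mean: np.ndarray, dispersion: float,
               rng: np.random.Generator) -> np.ndarray:
    """Negative binomial via Gamma–Poisson; var = m + dispersion·m²."""
    if dispersion == 0:
        return rng.poisson(mean)
    lam = rng.gamma(shape=1.0 / dispersion, scale=mean * dispersion)
    return rng.poisson(lam)


def simulate_atlas(spec: SyntheticAtlasSpec = SyntheticAtlasSpec(),
                   seed: int | None = None,
                   ) -> tuple[ExpressionMatrix, SampleMetadata, GroundTruth]:
    """Simulate a raw-count developmental atlas with known ground truth.

    Deterministic per (spec, seed); ``seed=None`` uses ``spec.seed``.
    """
    rng = np.random.default_rng(spec.seed if seed is None else seed)
    genes, classes, baseline, slope, cham_shift = _gene_params(spec, rng)
    t_of = spec.pseudotime()

    sigma = np.sqrt(np.log1p(spec.library_size_cv ** 2))
    mu_lib = np.log(spec.library_size_mean) - sigma ** 2 / 2

    cols, meta_rows, pseudo = {}, [], {}
    for stage, age in spec.stages:
        t = t_of[stage]
        for chamber in spec.chambers:
            log_mean = baseline + slope * t
            if chamber == "atrium":
                log_mean = log_mean + cham_shift
            rel = np.exp(log_mean)
            p = rel / rel.sum()
            for rep in range(1, spec.replicates_per_stage + 1):
                lib = float(np.exp(rng.normal(mu_lib, sigma)))
                counts = _nb_counts(lib * p, spec.nb_dispersion, rng)
                sid = f"{stage}_{chamber[0].upper()}{rep}"
                cols[sid] = counts
                pseudo[sid] = t
                meta_rows.append({"sample_id": sid, "chamber": chamber,
                                  "stage_label": stage, "age_days": age,
                                  "group": "reference"})

    matrix = ExpressionMatrix(
        pd.DataFrame(cols, index=genes, dtype=float), "raw_counts")
    metadata = SampleMetadata(pd.DataFrame(meta_rows))
    truth = GroundTruth(pseudotime=pd.Series(pseudo, name="pseudotime"),
                        gene_class=pd.Series(classes, index=genes, name="class"))
    return matrix, metadata, truth


def simulate_two_species(spec: SyntheticAtlasSpec = SyntheticAtlasSpec(),
                         shared_fraction: float = 0.8,
                         n_private_b: int | None = None,
                         replicates_b: int = 2,
                         seed: int | None = None) -> TwoSpeciesData:
    """Simulate paired datasets with mouse-style and human-style symbols.

    Species A carries the full gene set with Title-case symbols; species B
    carries ``shared_fraction`` of those genes (identical ground truth,
    symbols upper-cased) plus private noise genes. Species-B samples are
    ventricle-style replicates over the same stages.
    """
    if not 0 < shared_fraction <= 1:
        raise ValueError("shared_fraction must lie in (0, 1]")
    base_seed = spec.seed if seed is None else seed
    matrix_a, metadata_a, truth_a = simulate_atlas(spec, seed=base_seed)

    rng = np.random.default_rng(base_seed + 1)
    genes, classes, baseline, slope, _ = _gene_params(
        spec, np.random.default_rng(spec.seed if seed is None else seed))
    n_shared = int(round(shared_fraction * spec.n_genes))
    shared_idx = np.sort(rng.choice(spec.n_genes, size=n_shared, replace=False))
    shared_a = [genes[i] for i in shared_idx]

    if n_private_b is None:
        n_private_b = spec.n_genes - n_shared
    private_b = [f"BONLY{i:05d}" for i in range(n_private_b)]
    b_genes = [g.upper() for g in shared_a] + private_b
    b_base = np.concatenate([baseline[shared_idx],
                             rng.normal(spec.baseline_log_mean,
                                        spec.baseline_log_sd, size=n_private_b)])
    b_slope = np.concatenate([slope[shared_idx], np.zeros(n_private_b)])

    sigma = np.sqrt(np.log1p(spec.library_size_cv ** 2))
    mu_lib = np.log(spec.library_size_mean) - sigma ** 2 / 2
    t_of = spec.pseudotime()

    cols, meta_rows, pseudo = {}, [], {}
    for stage, age in spec.stages:
        t = t_of[stage]
        rel = np.exp(b_base + b_slope * t)
        p = rel / rel.sum()
        for rep in range(1, replicates_b + 1):
            lib = float(np.exp(rng.normal(mu_lib, sigma)))
            counts = _nb_counts(lib * p, spec.nb_dispersion, rng)
            sid = f"B_{stage}_{rep}"
            cols[sid] = counts
            pseudo[sid] = t
            meta_rows.append({"sample_id": sid, "chamber": "in_vitro",
                              "stage_label": stage, "age_days": age,
                              "group": "species_b"})

    b_classes = np.concatenate([classes[shared_idx],
                                np.array(["flat"] * n_private_b)])
    matrix_b = ExpressionMatrix(
        pd.DataFrame(cols, index=b_genes, dtype=float), "raw_counts")
    metadata_b = SampleMetadata(pd.DataFrame(meta_rows))
    truth_b = GroundTruth(pseudotime=pd.Series(pseudo, name="pseudotime"),
                          gene_class=pd.Series(b_classes, index=b_genes,
                                               name="class"))
    return TwoSpeciesData(matrix_a, metadata_a, truth_a,
                          matrix_b, metadata_b, truth_b, shared_a)


def simulate_screen(n_tfs: int = 92,
                    planted: Sequence[str] = (),
                    effect_sizes: Sequence[float] = (),
                    planted_conditions: str = "both",
                    tf_sd: float = 3.0,
                    noise_sd: float = 0.5,
                    control_mean: float = 45.0,
                    t3_shift: float = 5.0,
                    rfp_base: float = 5.0,
                    rfp_sd: float = 2.0,
                    rfp_effect_ratio: float = 0.5,
                    n_controls: int = 4,
                    n_replicates: int = 1,
                    seed: int = 0) -> pd.DataFrame:
    """Simulate a TF overexpression screen well table.

    Null TF wells draw their maturation score from the screen's null
    spread (SD ``tf_sd``, redrawn independently per ±T3 condition,
    emulating between-well experimental variability); planted TFs carry a
    reproducible shift of ``effect × tf_sd`` measured with well-level
    noise ``noise_sd``. The reporter channel mirrors the score channel
    with a weaker effect (``rfp_effect_ratio``), emulating the observed
    discordance between the two readouts. T3 adds a uniform shift to
    every well, so within-condition hit thresholds are unaffected.

    ``planted_conditions`` is ``"both"``, ``"T3"`` or ``"no_T3"``.
    Returns a well table with ground-truth effects in ``attrs["planted"]``.
    """
    planted = list(planted)
    effect_sizes = list(effect_sizes)
    if len(planted) != len(effect_sizes):
        raise ValueError("planted and effect_sizes must have equal length")
    tf_ids = [f"TF{i:03d}" for i in range(1, n_tfs + 1)]
    unknown = [p for p in planted if p not in tf_ids]
    if unknown:
        raise ValueError(f"planted TFs not in the screen: {unknown}")
    if planted_conditions not in ("both", "T3", "no_T3"):
        raise ValueError("planted_conditions must be 'both', 'T3' or 'no_T3'")
    effect_of = dict(zip(planted, effect_sizes))

    rng = np.random.default_rng(seed)
    rows = []
    for condition in ("T3", "no_T3"):
        base = control_mean + (t3_shift if condition == "T3" else 0.0)
        active = planted_conditions in ("both", condition)
        for tf in tf_ids:
            eff = effect_of.get(tf, 0.0) if active else 0.0
            for rep in range(1, n_replicates + 1):
                if tf in effect_of:
                    score = base + eff * tf_sd + rng.normal(0.0, noise_sd)
                    rfp = (rfp_base + eff * rfp_effect_ratio * rfp_sd
                           + rng.normal(0.0, noise_sd))
                else:
                    score = (base + rng.normal(0.0, tf_sd)
                             + rng.normal(0.0, noise_sd))
                    rfp = rfp_base + rng.normal(0.0, rfp_sd)
                rows.append({"tf_id": tf, "condition": condition,
                             "replicate": rep, "maturation_score": score,
                             "rfp_percent": float(np.clip(rfp, 0.0, 100.0)),
                             "is_control": False})
        for c in range(1, n_controls + 1):
            score = base + rng.normal(0.0, noise_sd)
            rfp = rfp_base + rng.normal(0.0, rfp_sd)
            rows.append({"tf_id": f"control{c}", "condition": condition,
                         "replicate": 1, "maturation_score": score,
                         "rfp_percent": float(np.clip(rfp, 0.0, 100.0)),
                         "is_control": True})
    table = pd.DataFrame(rows)
    table.attrs["planted"] = effect_of
    return table
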