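import numpy as np
import pandas as pd
import pytest

import matscore as m


@pytest.fixture(scope="session")
def atlas_bundle():
    """Default synthetic atlas run end-to-end once, shared across tests."""
    spec = m.SyntheticAtlasSpec()
    counts, metadata, truth = m.simulate_atlas(spec, seed=1)
    counts = m.qc_filter_samples(counts)
    tpm = m.counts_to_tpm(counts)
    kept = m.filter_low_expression(tpm, tpm.sample_ids)
    logtpm = m.log_transform(tpm.subset_genes(kept))
    atlas = m.build_atlas(logtpm, metadata)
    scores = m.maturation_score(atlas, logtpm)
    return {"spec": spec, "counts": counts, "metadata": metadata,
            "truth": truth, "tpm": tpm, "logtpm": logtpm, "atlas": atlas,
            "scores": scores}


@pytest.fixture
def tiny_counts():
    """3 genes × 2 samples of integer counts."""
    df = pd.DataFrame({"s1": [250, 750, 0], "s2": [10, 20, 70]},
                      index=["Ckmt2", "Mb", "Tnni1"], dtype=float)
    return m.ExpressionMatrix(df, "raw_counts")


def random_reference(rng, n_genes=30, n_samples=10):
    """Random log-TPM matrix plus metadata with graded ages."""
    vals = rng.gamma(2.0, 2.0, size=(n_genes, n_samples))
    genes = [f"G{i}" for i in range(n_genes)]
    samples = [f"s{i}" for i in range(n_samples)]
    matrix = m.ExpressionMatrix(
        pd.DataFrame(vals, index=genes, columns=samples), "log1p_tpm")
    meta = m.SampleMetadata(pd.DataFrame({
        "sample_id": samples,
        "chamber": ["ventricle"] * n_samples,
        "stage_label": [f"d{i}" for i in range(n_samples)],
        "age_days": np.linspace(10, 300, n_samples),
        "group": ["reference"] * n_samples,
    }))
    return matrix, meta


def pc1_eig_oracle(values: np.ndarray):
    """Brute-force PC1 via eigendecomposition of the gene–gene covariance.

    Independent of the SVD path: forms the dense covariance of the
    centered genes × samples matrix and takes its leading eigenvector.
    Returns (loading, per-sample scores), sign unoriented.
    """
    mu = values.mean(axis=1, keepdims=True)
    Xc = values - mu
    cov = (Xc @ Xc.T) / max(values.shape[1] - 1, 1)
    evals, evecs = np.linalg.eigh(cov)
    v = evecs[:, -1]
    v = v / np.linalg.norm(v)
    return v, Xc.T @ v
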