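"""Tabular and atlas file I/O.

Canonical on-disk formats are plain text so every artifact diffs cleanly:

* expression matrices — TSV (CSV accepted by delimiter sniffing), gene
  symbols in the first column, sample ids in the header; optionally
  MatrixMarket triplet plus two id files for large matrices;
* sample metadata — TSV with columns ``sample_id``, ``chamber``,
  ``stage_label``, ``age_days``, ``group``;
* atlases — a self-describing ``key<TAB>value`` header followed by a
  per-gene weight table, checksummed so corruption is detected on read.
"""

from __future__ import annotations

import dataclasses
import datetime
import hashlib
import io
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse

__all__ = [
    "UNITS",
    "CHAMBERS",
    "ATLAS_FORMAT_VERSION",
    "ExpressionMatrix",
    "SampleMetadata",
    "Calibration",
    "MaturationAtlas",
    "MatrixFormatError",
    "AtlasFormatError",
    "read_matrix",
    "write_matrix",
    "read_matrix_mtx",
    "read_metadata",
    "write_metadata",
    "read_atlas",
    "write_atlas",
]

UNITS = ("raw_counts", "tpm", "log1p_tpm")
CHAMBERS = ("ventricle", "atrium", "in_vitro", "unknown")
LOG_BASES = ("natural", "log2", "log10")

ATLAS_FORMAT_VERSION = "1"


class MatrixFormatError(ValueError):
    """Malformed expression matrix or metadata table."""


class AtlasFormatError(ValueError):
    """Malformed or corrupted atlas file."""


# ---------------------------------------------------------------------------
# domain containers
# ---------------------------------------------------------------------------

@dataclass
class ExpressionMatrix:
    """A genes × samples expression table with a declared unit.

    Parameters
    ----------
    values
        DataFrame indexed by gene symbol, columns are sample ids. All
        entries must be finite and non-negative; for ``unit="raw_counts"``
        they must additionally be integral.
    unit
        One of ``raw_counts``, ``tpm`` or ``log1p_tpm``.
    """

    values: pd.DataFrame
    unit: str

    def __post_init__(self) -> None:
        if self.unit not in UNITS:
            raise ValueError(f"unknown unit {self.unit!r}; expected one of {UNITS}")
        if not isinstance(self.values, pd.DataFrame):
            self.values = pd.DataFrame(self.values)
        _check_ids("gene", self.values.index)
        _check_ids("sample", self.values.columns)
        self.values.index.name = None
        self.values.columns.name = None
        arr = self.values.to_numpy()
        if arr.size and not np.issubdtype(arr.dtype, np.number):
            raise MatrixFormatError("expression values must be numeric")
        if arr.size:
            if not np.all(np.isfinite(arr)):
                bad = np.argwhere(~np.isfinite(arr))[0]
                raise MatrixFormatError(
                    f"non-finite value at gene {self.values.index[bad[0]]!r}, "
                    f"sample {self.values.columns[bad[1]]!r}"
                )
            if (arr < 0).any():
                bad = np.argwhere(arr < 0)[0]
                raise MatrixFormatError(
                    f"negative value at gene {self.values.index[bad[0]]!r}, "
                    f"sample {self.values.columns[bad[1]]!r}"
                )
            if self.unit == "raw_counts" and not np.allclose(arr, np.round(arr)):
                bad = np.argwhere(~np.isclose(arr, np.round(arr)))[0]
                raise MatrixFormatError(
                    f"raw_counts matrix holds a non-integer value at gene "
                    f"{self.values.index[bad[0]]!r}, sample {self.values.columns[bad[1]]!r}"
                )

    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def subset_genes(self, genes: Sequence[str]) -> "ExpressionMatrix":
        missing = [g for g in genes if g not in self.values.index]
        if missing:
            raise KeyError(f"genes absent from matrix: {missing[:5]}")
        return ExpressionMatrix(self.values.loc[list(genes)], self.unit)

    def subset_samples(self, samples: Sequence[str]) -> "ExpressionMatrix":
        missing = [s for s in samples if s not in self.values.columns]
        if missing:
            raise KeyError(f"samples absent from matrix: {missing[:5]}")
        return ExpressionMatrix(self.values[list(samples)], self.unit)


@dataclass
class SampleMetadata:
    """Per-sample annotations: chamber, stage label, age, treatment group."""

    table: pd.DataFrame

    REQUIRED = ("sample_id", "chamber", "stage_label", "age_days", "group")

    def __post_init__(self) -> None:
        t = self.table
        missing = [c for c in self.REQUIRED if c not in t.columns]
        if missing:
            raise MatrixFormatError(f"metadata missing required columns: {missing}")
        _check_ids("sample", t["sample_id"])
        bad_chamber = set(t["chamber"]) - set(CHAMBERS)
        if bad_chamber:
            raise MatrixFormatError(
                f"unknown chamber values {sorted(bad_chamber)}; expected {CHAMBERS}"
            )
        ages = pd.to_numeric(t["age_days"], errors="coerce")
        in_tissue = t["chamber"].isin(("ventricle", "atrium"))
        if (in_tissue & ages.isna()).any():
            bad = t.loc[in_tissue & ages.isna(), "sample_id"].tolist()
            raise MatrixFormatError(
                f"age_days missing for tissue samples {bad[:5]}; only in_vitro/unknown "
                "samples may omit age"
            )
        if (ages.dropna() < 0).any():
            raise MatrixFormatError("age_days must be non-negative")
        self.table = t.assign(age_days=ages).reset_index(drop=True)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.table["sample_id"])

    def age_of(self) -> pd.Series:
        return self.table.set_index("sample_id")["age_days"]

    def chamber_of(self) -> pd.Series:
        return self.table.set_index("sample_id")["chamber"]

    def subset(self, sample_ids: Sequence[str]) -> "SampleMetadata":
        t = self.table.set_index("sample_id").loc[list(sample_ids)].reset_index()
        return SampleMetadata(t)


@dataclass
class Calibration:
    """Affine map from a PC1 projection to the 0–100 maturation scale.

    ``score = scale * (offset + pc1)``.  ``paper_constants`` stores
    published constants verbatim (mouse 32/1.5, humanized 27/1.8);
    ``data_driven`` pins the reference ventricular PC1 range exactly onto
    [0, 100].
    """

    offset: float
    scale: float
    mode: str = "data_driven"

    def __post_init__(self) -> None:
        if self.mode not in ("paper_constants", "data_driven"):
            raise ValueError(f"unknown calibration mode {self.mode!r}")
        if not self.scale > 0:
            raise ValueError("calibration scale must be positive")

    def apply(self, pc1) -> np.ndarray | float:
        return self.scale * (self.offset + np.asarray(pc1, dtype=float))


@dataclass
class MaturationAtlas:
    """Frozen maturation reference: gene set, PC1 weights, calibration.

    ``weights`` is the unit-norm PC1 loading vector (ω), oriented so older
    reference samples project higher; ``reference_means`` (μ) are per-gene
    mean log-TPM over the reference samples, used to center queries and to
    impute genes a query lacks.
    """

    gene_ids: list[str]
    weights: np.ndarray
    reference_means: np.ndarray
    calibration: Calibration
    orientation_sign: int
    pc1_reference_range: tuple[float, float]
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)
        self.reference_means = np.asarray(self.reference_means, dtype=float)
        n = len(self.gene_ids)
        if n == 0:
            raise ValueError("atlas must contain at least one gene")
        if len(set(self.gene_ids)) != n:
            raise ValueError("atlas gene ids contain duplicates")
        if self.weights.shape != (n,) or self.reference_means.shape != (n,):
            raise ValueError("weights/means length must match gene_ids")
        norm = float(np.linalg.norm(self.weights))
        if abs(norm - 1.0) > 1e-10:
            raise ValueError(f"PC1 weights must be unit-norm (got ‖ω‖₂ = {norm})")
        if self.orientation_sign not in (+1, -1):
            raise ValueError("orientation_sign must be +1 or -1")
        lo, hi = self.pc1_reference_range
        if not lo < hi:
            raise ValueError("pc1_reference_range must satisfy min < max")

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    def weight_series(self) -> pd.Series:
        return pd.Series(self.weights, index=self.gene_ids, name="weight")

    def mean_series(self) -> pd.Series:
        return pd.Series(self.reference_means, index=self.gene_ids, name="mean_log_tpm")


def _check_ids(kind: str, ids: Iterable) -> None:
    ids = list(ids)
    strs = [str(x) for x in ids]
    if any(s.strip() == "" for s in strs):
        raise MatrixFormatError(f"empty {kind} id")
    seen: dict[str, int] = {}
    dups = []
    for s in strs:
        seen[s] = seen.get(s, 0) + 1
        if seen[s] == 2:
            dups.append(s)
    if dups:
        raise MatrixFormatError(f"duplicate {kind} ids: {dups}")


# ---------------------------------------------------------------------------
# expression matrices
# ---------------------------------------------------------------------------

def read_matrix(path, unit: str) -> ExpressionMatrix:
    """Read a genes × samples TSV/CSV matrix (delimiter is sniffed).

    The first column holds gene symbols, the header holds sample ids.
    Duplicate ids, negative entries and non-numeric cells are hard errors
    that name the offending gene/sample.
    """
    path = Path(path)
    with open(path) as fh:
        head = fh.readline()
    sep = "\t" if head.count("\t") >= head.count(",") else ","
    raw = pd.read_csv(path, sep=sep, index_col=0, dtype=str)
    raw.index = raw.index.astype(str)
    _check_ids("gene", raw.index)
    _check_ids("sample", raw.columns)
    # Python float() round-trips repr output exactly; pd.to_numeric's fast
    # strtod can be off by one ulp, which would break lossless round-trips
    out = np.empty(raw.shape, dtype=float)
    for si, col in enumerate(raw.columns):
        for gi, cell in enumerate(raw[col]):
            try:
                out[gi, si] = float(cell)
            except (TypeError, ValueError):
                raise MatrixFormatError(
                    f"non-numeric cell {cell!r} at gene {raw.index[gi]!r}, "
                    f"sample {col!r} in {path}"
                ) from None
    numeric = pd.DataFrame(out, index=raw.index, columns=raw.columns)
    return ExpressionMatrix(numeric, unit)


def write_matrix(matrix: ExpressionMatrix, path) -> None:
    """Write a matrix as TSV at full double precision (round-trip safe)."""
    if matrix.shape[0] == 0 or matrix.shape[1] == 0:
        raise ValueError("refusing to write an empty expression matrix")
    df = matrix.values
    with open(path, "w") as fh:
        fh.write("gene_id\t" + "\t".join(map(str, df.columns)) + "\n")
        arr = df.to_numpy()
        for gene, row in zip(df.index, arr):
            fh.write(str(gene) + "\t" + "\t".join(repr(float(v)) for v in row) + "\n")


def read_matrix_mtx(mtx_path, gene_path, sample_path, unit: str) -> ExpressionMatrix:
    """Read a MatrixMarket triplet matrix plus one-id-per-line gene/sample files."""
    mat = scipy.io.mmread(mtx_path)
    genes = [ln.strip() for ln in open(gene_path) if ln.strip()]
    samples = [ln.strip() for ln in open(sample_path) if ln.strip()]
    dense = np.asarray(mat.todense() if scipy.sparse.issparse(mat) else mat, dtype=float)
    if dense.shape != (len(genes), len(samples)):
        raise MatrixFormatError(
            f"MTX shape {dense.shape} does not match {len(genes)} genes × "
            f"{len(samples)} samples"
        )
    return ExpressionMatrix(pd.DataFrame(dense, index=genes, columns=samples), unit)


def read_metadata(path) -> SampleMetadata:
    return SampleMetadata(pd.read_csv(path, sep="\t", dtype={"sample_id": str}))


def write_metadata(metadata: SampleMetadata, path) -> None:
    metadata.table.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# atlas serialization
# ---------------------------------------------------------------------------

_REQUIRED_PROVENANCE = (
    "log_base",
    "pseudocount",
    "low_expression_threshold",
    "min_reads_per_sample",
)


def write_atlas(atlas: MaturationAtlas, path, software_version: str = "0.1.0") -> None:
    """Serialize an atlas to a single reviewable text file.

    Layout: ``#`` comment line, ``key<TAB>value`` header (calibration,
    orientation, provenance, weight-table checksum), blank line, then a
    three-column gene table. Floats are written with ``repr`` so the
    round-trip is bit-exact.
    """
    missing = [k for k in _REQUIRED_PROVENANCE if k not in atlas.provenance]
    if missing:
        raise AtlasFormatError(f"atlas provenance missing fields: {missing}")
    table = io.StringIO()
    table.write("gene_id\tweight\tmean_log_tpm\n")
    for g, w, m in zip(atlas.gene_ids, atlas.weights, atlas.reference_means):
        table.write(f"{g}\t{float(w)!r}\t{float(m)!r}\n")
    table_text = table.getvalue()
    checksum = hashlib.sha256(table_text.encode()).hexdigest()

    header = {
        "format_version": ATLAS_FORMAT_VERSION,
        "software_version": software_version,
        "created": datetime.datetime.now(datetime.timezone.utc).isoformat(),
        "n_genes": str(atlas.n_genes),
        "calibration_mode": atlas.calibration.mode,
        "offset": repr(float(atlas.calibration.offset)),
        "scale": repr(float(atlas.calibration.scale)),
        "orientation_sign": str(atlas.orientation_sign),
        "pc1_ref_min": repr(float(atlas.pc1_reference_range[0])),
        "pc1_ref_max": repr(float(atlas.pc1_reference_range[1])),
        "table_sha256": checksum,
    }
    for k, v in atlas.provenance.items():
        header[f"prov_{k}"] = str(v)

    with open(path, "w") as fh:
        fh.write("# matscore maturation atlas\n")
        for k, v in header.items():
            fh.write(f"{k}\t{v}\n")
        fh.write("\n")
        fh.write(table_text)


def read_atlas(path) -> MaturationAtlas:
    """Read an atlas file; verifies checksum and required provenance."""
    header: dict[str, str] = {}
    table_lines: list[str] = []
    in_table = False
    with open(path) as fh:
        for line in fh:
            if line.startswith("#"):
                continue
            if not in_table and line.strip() == "":
                in_table = True
                continue
            if in_table:
                table_lines.append(line)
            else:
                key, _, value = line.rstrip("\n").partition("\t")
                header[key] = value

    for key in ("format_version", "offset", "scale", "calibration_mode",
                "orientation_sign", "pc1_ref_min", "pc1_ref_max", "table_sha256"):
        if key not in header:
            raise AtlasFormatError(f"atlas header missing field {key!r} in {path}")
    if header["format_version"] != ATLAS_FORMAT_VERSION:
        warnings.warn(
            f"atlas format version {header['format_version']} differs from "
            f"current {ATLAS_FORMAT_VERSION}",
            stacklevel=2,
        )
    table_text = "".join(table_lines)
    if hashlib.sha256(table_text.encode()).hexdigest() != header["table_sha256"]:
        raise AtlasFormatError(f"atlas weight-table checksum mismatch in {path}")

    provenance = {k[len("prov_"):]: v for k, v in header.items() if k.startswith("prov_")}
    missing = [k for k in _REQUIRED_PROVENANCE if k not in provenance]
    if missing:
        raise AtlasFormatError(f"atlas provenance missing fields: {missing}")

    genes, weights, means = [], [], []
    for line in table_lines:
        line = line.strip()
        if not line or line.startswith("gene_id"):
            continue
        g, w, m = line.split("\t")
        genes.append(g)
        weights.append(float(w))
        means.append(float(m))

    return MaturationAtlas(
        gene_ids=genes,
        weights=np.array(weights),
        reference_means=np.array(means),
        calibration=Calibration(
            offset=float(header["offset"]),
            scale=float(header["scale"]),
            mode=header["calibration_mode"],
        ),
        orientation_sign=int(header["orientation_sign"]),
        pc1_reference_range=(float(header["pc1_ref_min"]), float(header["pc1_ref_max"])),
        provenance=provenance,
    )
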