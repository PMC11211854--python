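"""Readers and writers for count matrices, coordinates, and results.

The model consumes raw integer UMI counts (no numerical transformation), so
non-integral expression values are rejected outright.  Depths are always
full-matrix row sums, computed at read time.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.io import mmread

from .lrdb import CountMatrix

__all__ = ["RunConfig", "read_expression", "read_coords", "config_hash"]


@dataclass
class RunConfig:
    """End-to-end pipeline configuration; see the CLI for flag mapping."""

    matrix_path: str
    coords_path: str
    lrdb_path: str
    matrix_format: str = "csv_dense"  # mtx_triplet | csv_dense | h5ad_container
    graph_layout: str = "hex"  # hex | rect | radius
    graph_spacing: float = 1.0  # spacing for grids, threshold for radius
    self_loops: bool = True
    celltype_pair: tuple[str, str] | None = None
    n_perm: int = 500
    seed: int = 0
    min_spots: int | None = None
    screen_mode: str = "default"
    fdr_threshold: float = 0.2  # report annotation, not a filter
    output_dir: str = "copulacci_out"
    extra: dict = field(default_factory=dict)

    @classmethod
    def from_json(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = json.load(fh)
        if "celltype_pair" in data and data["celltype_pair"] is not None:
            data["celltype_pair"] = tuple(data["celltype_pair"])
        return cls(**data)


def config_hash(cfg: RunConfig) -> str:
    payload = json.dumps(vars(cfg), sort_keys=True, default=str).encode()
    return hashlib.sha256(payload).hexdigest()[:12]


def _check_integral(values: np.ndarray, source: str) -> np.ndarray:
    if not np.allclose(values, np.round(values)):
        raise ValueError(
            f"{source}: non-integer expression values found; the model consumes "
            "raw UMI counts and applies no numerical transformation"
        )
    return np.round(values).astype(np.int64)


def read_expression(path, format: str = "csv_dense") -> CountMatrix:
    """Read a spot x gene UMI matrix into a :class:`CountMatrix`.

    ``csv_dense``: CSV/TSV with spot IDs as the index column and genes as
    columns.  ``mtx_triplet``: a directory with matrix.mtx plus
    features/genes and barcodes TSV lists (gene x spot orientation, as
    produced by common pipelines, is transposed automatically).
    ``h5ad_container``: AnnData-dialect file, obs = spots, var = genes.
    """
    path = Path(path)
    if format == "csv_dense":
        sep = "\t" if path.suffix in (".tsv", ".txt") else ","
        df = pd.read_csv(path, sep=sep, index_col=0)
        counts = _check_integral(df.to_numpy(dtype=float), str(path))
        return CountMatrix.from_counts(
            [str(s) for s in df.index], [str(g) for g in df.columns], counts
        )
    if format == "mtx_triplet":
        d = path
        mtx = d / "matrix.mtx"
        feats = d / "features.tsv"
        if not feats.exists():
            feats = d / "genes.tsv"
        barcodes = d / "barcodes.tsv"
        for f in (mtx, feats, barcodes):
            if not f.exists():
                raise FileNotFoundError(f"mtx_triplet input missing {f}")
        mat = mmread(mtx).toarray().astype(float)
        genes = pd.read_csv(feats, sep="\t", header=None)[0].astype(str).tolist()
        spots = pd.read_csv(barcodes, sep="\t", header=None)[0].astype(str).tolist()
        if mat.shape == (len(genes), len(spots)):
            mat = mat.T
        elif mat.shape != (len(spots), len(genes)):
            raise ValueError("matrix dimensions match neither orientation")
        counts = _check_integral(mat, str(mtx))
        return CountMatrix.from_counts(spots, genes, counts)
    if format == "h5ad_container":
        import anndata

        ad = anndata.read_h5ad(path)
        X = ad.X
        X = X.toarray() if hasattr(X, "toarray") else np.asarray(X)
        counts = _check_integral(np.asarray(X, dtype=float), str(path))
        return CountMatrix.from_counts(
            [str(s) for s in ad.obs_names], [str(g) for g in ad.var_names], counts
        )
    raise ValueError(f"unknown matrix format {format!r}")


def read_coords(path) -> pd.DataFrame:
    """Read spot coordinates: columns spot_id, x, y and optional cell_type."""
    path = Path(path)
    sep = "\t" if path.suffix in (".tsv", ".txt") else ","
    df = pd.read_csv(path, sep=sep)
    df.columns = [str(c).strip().lower() for c in df.columns]
    for col in ("spot_id", "x", "y"):
        if col not in df.columns:
            raise ValueError(f"coordinates file missing column {col!r}")
    df["spot_id"] = df["spot_id"].astype(str)
    return df


def align_coords(m: CountMatrix, coords: pd.DataFrame) -> pd.DataFrame:
    """Re-order the coordinate table to the matrix's spot order; spot-ID
    mismatches are a hard error listing the offenders."""
    coord_ids = set(coords["spot_id"])
    matrix_ids = set(m.spot_ids)
    missing = sorted(matrix_ids - coord_ids)
    extra = sorted(coord_ids - matrix_ids)
    if missing or extra:
        raise ValueError(
            "spot-ID mismatch between matrix and coordinates; "
            f"missing from coords: {missing[:10]}; not in matrix: {extra[:10]}"
        )
    return coords.set_index("spot_id").loc[m.spot_ids].reset_index()
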