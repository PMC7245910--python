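"""File formats, result serialization and run manifests.

Counts travel as TSV (first column = gene id, header = sample ids) or
MatrixMarket MTX (genes x samples) with ``<stem>.genes.txt`` /
``<stem>.samples.txt`` label sidecars.  Designs and coefficients are
headered TSV with a label column.  A thinning run is persisted as a
directory of plain-text files plus a JSON manifest that is sufficient to
replay the run bit-exactly.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from datetime import datetime, timezone
from pathlib import Path
from typing import Optional, Union

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse

from .types import (
    CountMatrix,
    Permutation,
    TargetCorrelation,
    ThinLogMatrix,
    ThinningResult,
)

__all__ = [
    "read_counts",
    "write_counts",
    "read_design",
    "write_design",
    "read_vector",
    "write_vector",
    "read_target_correlation",
    "RunManifest",
    "write_result",
    "read_result",
]

_log = logging.getLogger("countthin")

MANIFEST_NAME = "manifest.json"


# ---------------------------------------------------------------------------
# count matrices


def _mtx_sidecars(path: Path) -> tuple:
    stem = path.with_suffix("")
    return Path(f"{stem}.genes.txt"), Path(f"{stem}.samples.txt")


def _infer_format(path: Path, fmt: Optional[str]) -> str:
    if fmt is not None:
        if fmt not in ("tsv", "mtx"):
            raise ValueError(f"format must be 'tsv' or 'mtx', got {fmt!r}")
        return fmt
    return "mtx" if path.suffix.lower() == ".mtx" else "tsv"


def read_counts(path: Union[str, Path], fmt: Optional[str] = None) -> CountMatrix:
    """Read a genes x samples count matrix from TSV or MatrixMarket."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    fmt = _infer_format(path, fmt)
    if fmt == "tsv":
        df = pd.read_csv(path, sep="\t", index_col=0)
        if df.index.hasnans or df.columns.hasnans:
            raise ValueError(f"{path}: missing gene or sample labels")
        if df.isna().any().any():
            raise ValueError(f"{path}: count matrix contains missing values")
        return CountMatrix(
            df.to_numpy(), tuple(map(str, df.index)), tuple(map(str, df.columns))
        )
    mat = scipy.io.mmread(path)
    if scipy.sparse.issparse(mat):
        mat = mat.toarray()
    gene_file, sample_file = _mtx_sidecars(path)
    gene_ids = sample_ids = None
    if gene_file.exists():
        gene_ids = tuple(gene_file.read_text().split())
    if sample_file.exists():
        sample_ids = tuple(sample_file.read_text().split())
    cm = CountMatrix(np.asarray(mat), gene_ids, sample_ids)
    _log.info("read %d genes x %d samples from %s", cm.n_genes,
              cm.n_samples, path)
    return cm


def write_counts(cm: CountMatrix, path: Union[str, Path],
                 fmt: Optional[str] = None) -> Path:
    """Write a count matrix as TSV or MatrixMarket (+ label sidecars)."""
    path = Path(path)
    fmt = _infer_format(path, fmt)
    path.parent.mkdir(parents=True, exist_ok=True)
    if fmt == "tsv":
        pd.DataFrame(
            cm.values, index=list(cm.gene_ids), columns=list(cm.sample_ids)
        ).to_csv(path, sep="\t", index_label="gene")
    else:
        scipy.io.mmwrite(path, scipy.sparse.coo_matrix(cm.values))
        gene_file, sample_file = _mtx_sidecars(path)
        gene_file.write_text("\n".join(cm.gene_ids) + "\n")
        sample_file.write_text("\n".join(cm.sample_ids) + "\n")
    return path


# ---------------------------------------------------------------------------
# designs, coefficients, vectors


def read_design(path: Union[str, Path]) -> pd.DataFrame:
    """Headered TSV with a leading label column; rows are samples (designs)
    or genes (coefficients)."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    arr = df.to_numpy(dtype=float)
    if not np.all(np.isfinite(arr)):
        raise ValueError(f"{path}: non-finite entries")
    return df


def write_design(arr: np.ndarray, path: Union[str, Path], row_ids,
                 index_label: str = "id", prefix: str = "v") -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    arr = np.atleast_2d(np.asarray(arr, dtype=float))
    cols = [f"{prefix}{j + 1}" for j in range(arr.shape[1])]
    pd.DataFrame(arr, index=list(row_ids), columns=cols).to_csv(
        path, sep="\t", index_label=index_label
    )
    return path


def read_vector(path: Union[str, Path]) -> np.ndarray:
    """One float per line, no header."""
    vals = [float(tok) for tok in Path(path).read_text().split()]
    return np.asarray(vals, dtype=float)


def write_vector(vec: np.ndarray, path: Union[str, Path]) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text("\n".join(repr(float(v)) for v in np.ravel(vec)) + "\n")
    return path


def read_target_correlation(path: Union[str, Path]) -> TargetCorrelation:
    """Headered TSV: rows = permutable design columns, cols = factors."""
    return TargetCorrelation(read_design(path).to_numpy(dtype=float))


# ---------------------------------------------------------------------------
# run manifests


@dataclass
class RunManifest:
    """Everything needed to reproduce a CLI run exactly."""

    command: str
    params: dict
    seed: Optional[int]
    version: str
    created: str = ""
    outputs: list = field(default_factory=list)

    def save(self, path: Union[str, Path]) -> Path:
        path = Path(path)
        path.parent.mkdir(parents=True, exist_ok=True)
        path.write_text(json.dumps(asdict(self), indent=2, sort_keys=True) + "\n")
        return path

    @classmethod
    def load(cls, path: Union[str, Path]) -> "RunManifest":
        data = json.loads(Path(path).read_text())
        return cls(**data)


def _now() -> str:
    return datetime.now(timezone.utc).isoformat(timespec="seconds")


def new_manifest(command: str, params: dict, seed: Optional[int],
                 outputs=()) -> RunManifest:
    from . import __version__

    return RunManifest(
        command=command,
        params=dict(params),
        seed=seed,
        version=__version__,
        created=_now(),
        outputs=[str(p) for p in outputs],
    )


# ---------------------------------------------------------------------------
# thinning results


def write_result(result: ThinningResult, out_dir: Union[str, Path],
                 fmt: str = "tsv", command: str = "api",
                 params: Optional[dict] = None) -> Path:
    """Persist a thinning result directory; returns the manifest path."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cm = result.counts
    counts_name = "counts.mtx" if fmt == "mtx" else "counts.tsv"
    files = {"counts": counts_name}
    write_counts(cm, out / counts_name, fmt=fmt)
    write_vector(result.thin_log.e, out / "row_offsets.txt")
    files["row_offsets"] = "row_offsets.txt"
    (out / "permutation.txt").write_text(
        "\n".join(str(int(i)) for i in result.permutation.pi) + "\n"
    )
    files["permutation"] = "permutation.txt"
    pairs = [
        ("design_fixed", result.design_fixed, cm.sample_ids, "sample", "x"),
        ("coef_fixed", result.coef_fixed, cm.gene_ids, "gene", "b"),
        ("design_perm_applied", result.design_perm_applied, cm.sample_ids,
         "sample", "x"),
        ("coef_perm", result.coef_perm, cm.gene_ids, "gene", "b"),
    ]
    for name, arr, ids, label, prefix in pairs:
        if arr.shape[1] > 0:
            write_design(arr, out / f"{name}.tsv", ids, label, prefix)
            files[name] = f"{name}.tsv"
    seed = result.seed if isinstance(result.seed, (int, type(None))) else None
    manifest = new_manifest(
        command,
        dict(params or {}, files=files,
             permutation=[int(i) for i in result.permutation.pi]),
        seed,
        outputs=sorted(files.values()),
    )
    return manifest.save(out / MANIFEST_NAME)


def read_result(result_dir: Union[str, Path]) -> ThinningResult:
    """Load a thinning result directory written by :func:`write_result`."""
    out = Path(result_dir)
    manifest = RunManifest.load(out / MANIFEST_NAME)
    files = manifest.params["files"]
    cm = read_counts(out / files["counts"])
    e = read_vector(out / files["row_offsets"])
    pi = np.asarray(
        [int(t) for t in (out / files["permutation"]).read_text().split()],
        dtype=np.int64,
    )
    g, n = cm.shape

    def _load(name, rows):
        if name in files:
            return read_design(out / files[name]).to_numpy(dtype=float)
        return np.zeros((rows, 0))

    # q itself is not persisted (it is large and reproducible); a zero
    # matrix with the stored e keeps the shapes consistent for downstream
    # summaries that only need the provenance arrays.
    return ThinningResult(
        counts=cm,
        thin_log=ThinLogMatrix(q=np.zeros((g, n)), e=e),
        permutation=Permutation(pi),
        design_fixed=_load("design_fixed", n),
        coef_fixed=_load("coef_fixed", g),
        design_perm_applied=_load("design_perm_applied", n),
        coef_perm=_load("coef_perm", g),
        seed=manifest.seed,
    )
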