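"""Data containers and I/O for count matrices, responses and splits.

The central objects are :class:`CountDataset` (an N cells x G genes raw
count matrix with optional nuisance covariates such as batch one-hots or
log library size) and :class:`ResponseVector` (the per-cell response with
its likelihood family).  All downstream modules consume these; formats
(CSV/TSV, MatrixMarket, AnnData h5ad) are handled here and nowhere else.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse

from ._seeds import rng_for

FAMILIES = ("gaussian", "poisson", "bernoulli")


@dataclass
class CountDataset:
    """Raw UMI-like counts with identifiers and nuisance covariates.

    Parameters
    ----------
    counts
        N x G non-negative integer matrix (stored dense, float64 or int).
    gene_names, cell_ids
        Unique labels matching the matrix dimensions.
    nuisance
        N x T real matrix of observed nuisance factors (batch one-hots,
        log library size, ...). May have T = 0 columns. Categorical
        covariates must be pre-encoded.
    """

    counts: np.ndarray
    gene_names: list[str]
    cell_ids: list[str]
    nuisance: np.ndarray | None = None
    nuisance_names: list[str] = field(default_factory=list)

    def __post_init__(self):
        self.counts = np.asarray(self.counts)
        if scipy.sparse.issparse(self.counts):  # pragma: no cover - coerced above
            self.counts = self.counts.toarray()
        if self.counts.ndim != 2:
            raise ValueError("counts must be a 2-D matrix")
        if not np.all(np.isfinite(self.counts)):
            raise ValueError("counts contain non-finite entries")
        if np.any(self.counts < 0):
            raise ValueError("counts contain negative entries")
        if np.any(self.counts != np.round(self.counts)):
            raise ValueError("counts contain non-integer entries")
        n, g = self.counts.shape
        self.gene_names = [str(x) for x in self.gene_names]
        self.cell_ids = [str(x) for x in self.cell_ids]
        if len(self.gene_names) != g:
            raise ValueError(f"{len(self.gene_names)} gene names for {g} genes")
        if len(self.cell_ids) != n:
            raise ValueError(f"{len(self.cell_ids)} cell ids for {n} cells")
        if len(set(self.gene_names)) != g:
            raise ValueError("gene names are not unique")
        if len(set(self.cell_ids)) != n:
            raise ValueError("cell ids are not unique")
        if self.nuisance is None:
            self.nuisance = np.zeros((n, 0))
        self.nuisance = np.atleast_2d(np.asarray(self.nuisance, dtype=float))
        if self.nuisance.shape[0] != n:
            raise ValueError("nuisance rows do not match number of cells")
        if not np.all(np.isfinite(self.nuisance)):
            raise ValueError("nuisance matrix has missing/non-finite values")
        if len(self.nuisance_names) != self.nuisance.shape[1]:
            self.nuisance_names = [f"s{i}" for i in range(self.nuisance.shape[1])]

    @property
    def n_cells(self) -> int:
        return self.counts.shape[0]

    @property
    def n_genes(self) -> int:
        return self.counts.shape[1]

    @property
    def n_nuisance(self) -> int:
        return self.nuisance.shape[1]

    def subset(self, idx: np.ndarray) -> "CountDataset":
        idx = np.asarray(idx)
        return CountDataset(
            counts=self.counts[idx],
            gene_names=list(self.gene_names),
            cell_ids=[self.cell_ids[i] for i in idx],
            nuisance=self.nuisance[idx],
            nuisance_names=list(self.nuisance_names),
        )

    def with_log_library_size(self) -> "CountDataset":
        """Append log total count per cell as an extra nuisance column.

        Opt-in: the generative model also captures depth, so conditioning
        on it twice is a user decision, not a default.
        """
        lls = np.log(self.counts.sum(axis=1))
        return CountDataset(
            counts=self.counts,
            gene_names=list(self.gene_names),
            cell_ids=list(self.cell_ids),
            nuisance=np.column_stack([self.nuisance, lls]),
            nuisance_names=list(self.nuisance_names) + ["log_library_size"],
        )


@dataclass
class ResponseVector:
    """Per-cell response with its likelihood family."""

    values: np.ndarray
    family: str = "gaussian"
    name: str = "y"

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float).ravel()
        if self.family not in FAMILIES:
            raise ValueError(f"family must be one of {FAMILIES}, got {self.family!r}")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("response contains non-finite values")
        if self.family == "bernoulli" and not np.all(np.isin(self.values, (0.0, 1.0))):
            raise ValueError("bernoulli response must be in {0, 1}")
        if self.family == "poisson":
            if np.any(self.values < 0) or np.any(self.values != np.round(self.values)):
                raise ValueError("poisson response must be non-negative integers")

    def __len__(self) -> int:
        return len(self.values)

    def subset(self, idx: np.ndarray) -> "ResponseVector":
        return ResponseVector(self.values[np.asarray(idx)], self.family, self.name)


@dataclass(frozen=True)
class DataSplit:
    """Disjoint development/validation partition of cell indices."""

    dev_idx: np.ndarray
    val_idx: np.ndarray
    seed: int

    def __post_init__(self):
        dev = np.asarray(self.dev_idx)
        val = np.asarray(self.val_idx)
        if np.intersect1d(dev, val).size:
            raise ValueError("dev and val indices overlap")
        object.__setattr__(self, "dev_idx", dev)
        object.__setattr__(self, "val_idx", val)

    @property
    def n(self) -> int:
        return len(self.dev_idx) + len(self.val_idx)


def make_split(n_cells: int, dev_fraction: float = 0.7, seed: int = 0) -> DataSplit:
    """Uniformly random development/validation partition.

    The default 70-30 ratio follows the standard train-models-on-dev,
    test-on-val protocol of the CRT: generative model and importance score
    are fit on dev cells only, p-values are computed on val cells only.
    """
    if not 0.0 < dev_fraction < 1.0:
        raise ValueError("dev_fraction must be in (0, 1)")
    if n_cells < 2:
        raise ValueError("need at least 2 cells to split")
    n_dev = int(round(dev_fraction * n_cells))
    n_dev = min(max(n_dev, 1), n_cells - 1)
    perm = rng_for(seed, "split").permutation(n_cells)
    return DataSplit(dev_idx=np.sort(perm[:n_dev]), val_idx=np.sort(perm[n_dev:]), seed=seed)


def compute_log_cpm(counts: np.ndarray, pseudocount: float = 1.0) -> np.ndarray:
    """log(1e6 * count / cell_total + pseudocount), per cell.

    Not mean-centered; centering is a separate composable step
    (:func:`center_columns`). A cell with zero total has no defined CPM and
    raises.
    """
    counts = np.asarray(counts, dtype=float)
    totals = counts.sum(axis=1)
    bad = np.where(totals <= 0)[0]
    if bad.size:
        raise ValueError(f"cells with zero total count: {bad[:10].tolist()}")
    return np.log(1e6 * counts / totals[:, None] + pseudocount)


def center_columns(x: np.ndarray) -> np.ndarray:
    """Subtract the per-column (per-gene) mean."""
    x = np.asarray(x, dtype=float)
    return x - x.mean(axis=0, keepdims=True)


# ---------------------------------------------------------------------------
# File formats
# ---------------------------------------------------------------------------

def _one_hot(series: pd.Series, prefix: str) -> pd.DataFrame:
    return pd.get_dummies(series, prefix=prefix, dtype=float)


def load_dataset(
    path: str,
    format: str | None = None,
    nuisance_columns: list[str] | None = None,
    layer: str | None = None,
    add_log_library_size: bool = False,
) -> CountDataset:
    """Load a count matrix into a validated :class:`CountDataset`.

    Supported formats: ``csv`` (dense, header row = gene names, index
    column = cell ids; TSV accepted via extension), ``mtx`` (MatrixMarket
    cells x genes with `<stem>_genes.txt` / `<stem>_cells.txt` sidecars)
    and ``h5ad`` (counts in X or a named layer, covariates from .obs).
    Categorical covariates are one-hot encoded.
    """
    if format is None:
        ext = os.path.splitext(path)[1].lower().lstrip(".")
        format = {"tsv": "csv", "txt": "csv"}.get(ext, ext)
    if format not in ("csv", "mtx", "h5ad"):
        raise ValueError(f"unknown format {format!r}")

    nuisance = None
    nuisance_names: list[str] = []

    if format == "csv":
        sep = "\t" if path.endswith((".tsv", ".txt")) else ","
        try:
            df = pd.read_csv(path, sep=sep, index_col=0)
        except Exception as e:  # pragma: no cover - pandas message passthrough
            raise ValueError(f"failed to parse {path}: {e}") from e
        counts = df.to_numpy()
        genes = [str(c) for c in df.columns]
        cells = [str(i) for i in df.index]
        if nuisance_columns:
            raise ValueError("csv format carries no covariate columns; "
                             "supply nuisance separately")
    elif format == "mtx":
        mat = scipy.io.mmread(path)
        counts = np.asarray(mat.todense() if scipy.sparse.issparse(mat) else mat)
        stem = path[:-4] if path.endswith(".mtx") else path
        genes = _read_lines(stem + "_genes.txt")
        cells = _read_lines(stem + "_cells.txt")
        if nuisance_columns:
            raise ValueError("mtx format carries no covariate columns")
    else:  # h5ad
        import anndata

        adata = anndata.read_h5ad(path)
        x = adata.layers[layer] if layer else adata.X
        counts = np.asarray(x.todense() if scipy.sparse.issparse(x) else x)
        genes = [str(g) for g in adata.var_names]
        cells = [str(c) for c in adata.obs_names]
        if nuisance_columns:
            blocks = []
            for col in nuisance_columns:
                if col not in adata.obs.columns:
                    raise ValueError(f"covariate column {col!r} not found in .obs")
                s = adata.obs[col]
                if s.dtype.kind in "OUb" or isinstance(s.dtype, pd.CategoricalDtype):
                    blocks.append(_one_hot(s, col))
                else:
                    blocks.append(s.astype(float).to_frame(col))
            nf = pd.concat(blocks, axis=1)
            nuisance = nf.to_numpy(dtype=float)
            nuisance_names = [str(c) for c in nf.columns]

    ds = CountDataset(counts=counts, gene_names=genes, cell_ids=cells,
                      nuisance=nuisance, nuisance_names=nuisance_names)
    if add_log_library_size:
        ds = ds.with_log_library_size()
    return ds


def _read_lines(path: str) -> list[str]:
    if not os.path.exists(path):
        raise ValueError(f"missing sidecar name file: {path}")
    with open(path) as fh:
        return [line.strip() for line in fh if line.strip()]


def save_dataset(dataset: CountDataset, path: str, format: str = "csv") -> None:
    """Write a dataset back out; round-trips exactly through load_dataset."""
    if format == "csv":
        sep = "\t" if path.endswith((".tsv", ".txt")) else ","
        pd.DataFrame(dataset.counts.astype(int), index=dataset.cell_ids,
                     columns=dataset.gene_names).to_csv(path, sep=sep)
    elif format == "mtx":
        scipy.io.mmwrite(path, scipy.sparse.coo_matrix(dataset.counts.astype(int)))
        stem = path[:-4] if path.endswith(".mtx") else path
        _write_lines(stem + "_genes.txt", dataset.gene_names)
        _write_lines(stem + "_cells.txt", dataset.cell_ids)
    elif format == "h5ad":
        import anndata

        obs = pd.DataFrame(dataset.nuisance, index=dataset.cell_ids,
                           columns=dataset.nuisance_names)
        adata = anndata.AnnData(X=dataset.counts.astype(np.float64), obs=obs,
                                var=pd.DataFrame(index=dataset.gene_names))
        adata.write_h5ad(path)
    else:
        raise ValueError(f"unknown format {format!r}")


def _write_lines(path: str, lines: list[str]) -> None:
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")
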