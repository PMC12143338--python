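"""Count bundles: the universal in-memory container and its 10x-style disk format.

A :class:`CountBundle` holds a cells x genes sparse UMI count matrix, per-cell
total transcriptomic read counts (needed for the saturation statistic), an
optional antibody-derived-tag (ADT) matrix, and a per-cell metadata table.
On disk a bundle is a Matrix Market triplet (``matrix.mtx[.gz]`` +
``barcodes.tsv[.gz]`` + ``features.tsv[.gz]``, features x cells, 1-based
coordinates) plus a ``metadata.tsv`` with read totals — the layout emitted by
common droplet pipelines, with RNA and ADT features distinguished by the
``feature_type`` column (``Gene Expression`` / ``Antibody Capture``).
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import io as spio
from scipy import sparse

from .exceptions import FormatError, ValidationError

RNA_FEATURE_TYPE = "Gene Expression"
ADT_FEATURE_TYPE = "Antibody Capture"

META_COLUMNS = ["cell_id", "subject_id", "tissue", "lane", "rna_reads", "adt_reads"]


@dataclass
class CountBundle:
    """Sparse UMI counts plus read totals and per-cell metadata.

    Invariants (enforced at construction): unique cell and gene identifiers,
    metadata aligned 1:1 with cells, and per-cell read totals at least as large
    as per-cell UMI totals so the saturation statistic ``1 - UMIs/reads`` is
    well defined.
    """

    cell_ids: list[str]
    gene_ids: list[str]
    rna_counts: sparse.csr_matrix
    rna_reads_per_cell: np.ndarray
    meta: pd.DataFrame
    adt_ids: list[str] | None = None
    adt_counts: np.ndarray | None = None
    adt_reads_per_cell: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.rna_counts = sparse.csr_matrix(self.rna_counts)
        self.rna_reads_per_cell = np.asarray(self.rna_reads_per_cell, dtype=np.int64)
        self.validate()

    # -- invariants -------------------------------------------------------
    def validate(self) -> None:
        n, g = self.rna_counts.shape
        if len(self.cell_ids) != n:
            raise FormatError(
                f"matrix has {n} cells but {len(self.cell_ids)} barcodes"
            )
        if len(self.gene_ids) != g:
            raise FormatError(
                f"matrix has {g} genes but {len(self.gene_ids)} feature rows"
            )
        if len(set(self.cell_ids)) != n:
            raise ValidationError("duplicate cell barcodes")
        if len(set(self.gene_ids)) != g:
            raise ValidationError("duplicate gene identifiers")
        if self.rna_counts.nnz and self.rna_counts.data.min() < 0:
            raise ValidationError("negative RNA counts")
        if self.rna_reads_per_cell.shape != (n,):
            raise ValidationError("rna_reads_per_cell misaligned with cells")
        umis = self.umis_per_cell()
        if np.any(self.rna_reads_per_cell < umis):
            bad = int(np.argmax(self.rna_reads_per_cell < umis))
            raise ValidationError(
                f"cell {self.cell_ids[bad]!r} has more UMIs than reads"
            )
        if len(self.meta) != n:
            raise ValidationError("metadata rows do not align 1:1 with cells")
        if self.adt_counts is not None:
            self.adt_counts = np.asarray(self.adt_counts, dtype=np.int64)
            if self.adt_counts.shape[0] != n:
                raise ValidationError("ADT matrix misaligned with cells")
            if self.adt_ids is None or len(self.adt_ids) != self.adt_counts.shape[1]:
                raise FormatError("ADT tag names misaligned with ADT matrix")
            if self.adt_reads_per_cell is not None:
                self.adt_reads_per_cell = np.asarray(
                    self.adt_reads_per_cell, dtype=np.int64
                )
                if np.any(self.adt_reads_per_cell < self.adt_counts.sum(axis=1)):
                    raise ValidationError("ADT reads below ADT UMI totals")

    # -- conveniences -----------------------------------------------------
    @property
    def n_cells(self) -> int:
        return self.rna_counts.shape[0]

    @property
    def n_genes(self) -> int:
        return self.rna_counts.shape[1]

    def umis_per_cell(self) -> np.ndarray:
        return np.asarray(self.rna_counts.sum(axis=1)).ravel().astype(np.int64)

    def features_per_cell(self) -> np.ndarray:
        return np.diff(self.rna_counts.indptr).astype(np.int64)

    def subset_cells(self, mask: np.ndarray) -> "CountBundle":
        """Return a new bundle restricted to the cells where ``mask`` is True."""
        mask = np.asarray(mask)
        idx = np.flatnonzero(mask) if mask.dtype == bool else mask
        return CountBundle(
            cell_ids=[self.cell_ids[i] for i in idx],
            gene_ids=list(self.gene_ids),
            rna_counts=self.rna_counts[idx],
            rna_reads_per_cell=self.rna_reads_per_cell[idx],
            meta=self.meta.iloc[idx].reset_index(drop=True),
            adt_ids=list(self.adt_ids) if self.adt_ids is not None else None,
            adt_counts=self.adt_counts[idx] if self.adt_counts is not None else None,
            adt_reads_per_cell=(
                self.adt_reads_per_cell[idx]
                if self.adt_reads_per_cell is not None
                else None
            ),
        )


def _find(directory: Path, stem: str) -> Path:
    for name in (stem, stem + ".gz"):
        p = directory / name
        if p.exists():
            return p
    raise FormatError(f"missing {stem}[.gz] under {directory}")


def _open_text(path: Path):
    if path.suffix == ".gz":
        return gzip.open(path, "rt")
    return open(path, "rt")


def _read_mtx(path: Path) -> sparse.csr_matrix:
    if path.suffix == ".gz":
        with gzip.open(path, "rb") as fh:
            m = spio.mmread(fh)
    else:
        m = spio.mmread(path)
    return sparse.csr_matrix(m)


def read_count_bundle(directory: str | Path) -> CountBundle:
    """Read a 10x-style bundle (``matrix.mtx`` features x cells) from ``directory``.

    Gzip-compressed members are accepted. RNA and ADT features are split on the
    third column of ``features.tsv``. Raises :class:`FormatError` on dimension
    mismatches and :class:`ValidationError` on duplicate barcodes.
    """
    directory = Path(directory)
    mat = _read_mtx(_find(directory, "matrix.mtx"))
    with _open_text(_find(directory, "barcodes.tsv")) as fh:
        barcodes = [line.strip() for line in fh if line.strip()]
    feats = pd.read_csv(
        _find(directory, "features.tsv"),
        sep="\t",
        header=None,
        names=["gene_id", "gene_symbol", "feature_type"],
        dtype=str,
    )
    if mat.shape[0] != len(feats):
        raise FormatError(
            f"matrix declares {mat.shape[0]} features but features file has "
            f"{len(feats)} rows"
        )
    if mat.shape[1] != len(barcodes):
        raise FormatError(
            f"matrix declares {mat.shape[1]} cells but barcodes file has "
            f"{len(barcodes)}"
        )
    meta = pd.read_csv(_find(directory, "metadata.tsv"), sep="\t", dtype={"lane": str})
    missing = [c for c in META_COLUMNS[:4] if c not in meta.columns]
    if missing:
        raise FormatError(f"metadata.tsv lacks required columns: {missing}")
    if list(meta["cell_id"]) != barcodes:
        meta = meta.set_index("cell_id").reindex(barcodes).reset_index()
        if meta["subject_id"].isna().any():
            raise FormatError("metadata.tsv does not cover all barcodes")

    cells_x_feats = sparse.csr_matrix(mat.T)
    is_rna = (feats["feature_type"] == RNA_FEATURE_TYPE).to_numpy()
    is_adt = (feats["feature_type"] == ADT_FEATURE_TYPE).to_numpy()
    rna = cells_x_feats[:, np.flatnonzero(is_rna)]
    gene_ids = feats.loc[is_rna, "gene_symbol"].tolist()

    adt_ids = None
    adt_counts = None
    adt_reads = None
    if is_adt.any():
        adt_counts = np.asarray(
            cells_x_feats[:, np.flatnonzero(is_adt)].todense(), dtype=np.int64
        )
        adt_ids = feats.loc[is_adt, "gene_symbol"].tolist()
        if "adt_reads" in meta.columns and meta["adt_reads"].notna().all():
            adt_reads = meta["adt_reads"].to_numpy(dtype=np.int64)
    if "rna_reads" not in meta.columns:
        raise FormatError("metadata.tsv lacks the rna_reads column")
    rna_reads = meta["rna_reads"].to_numpy(dtype=np.int64)

    return CountBundle(
        cell_ids=barcodes,
        gene_ids=gene_ids,
        rna_counts=rna,
        rna_reads_per_cell=rna_reads,
        meta=meta,
        adt_ids=adt_ids,
        adt_counts=adt_counts,
        adt_reads_per_cell=adt_reads,
    )


def write_count_bundle(
    bundle: CountBundle, directory: str | Path, compress: bool = False
) -> None:
    """Write ``bundle`` to ``directory`` in the 10x-style triplet layout."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    suffix = ".gz" if compress else ""

    n_adt = len(bundle.adt_ids) if bundle.adt_ids is not None else 0
    feats = pd.DataFrame(
        {
            "gene_id": list(bundle.gene_ids) + list(bundle.adt_ids or []),
            "gene_symbol": list(bundle.gene_ids) + list(bundle.adt_ids or []),
            "feature_type": [RNA_FEATURE_TYPE] * bundle.n_genes
            + [ADT_FEATURE_TYPE] * n_adt,
        }
    )
    blocks = [sparse.csr_matrix(bundle.rna_counts)]
    if n_adt:
        blocks.append(sparse.csr_matrix(bundle.adt_counts))
    feats_x_cells = sparse.coo_matrix(sparse.hstack(blocks).T)

    mtx_path = directory / ("matrix.mtx" + suffix)
    if compress:
        with gzip.open(mtx_path, "wb") as fh:
            spio.mmwrite(fh, feats_x_cells, field="integer")
    else:
        spio.mmwrite(mtx_path, feats_x_cells, field="integer")

    opener = gzip.open if compress else open
    with opener(directory / ("barcodes.tsv" + suffix), "wt") as fh:
        fh.write("\n".join(bundle.cell_ids) + "\n")
    feats.to_csv(
        directory / ("features.tsv" + suffix), sep="\t", header=False, index=False
    )

    meta = bundle.meta.copy()
    meta["cell_id"] = bundle.cell_ids
    meta["rna_reads"] = bundle.rna_reads_per_cell
    if bundle.adt_reads_per_cell is not None:
        meta["adt_reads"] = bundle.adt_reads_per_cell
    cols = [c for c in META_COLUMNS if c in meta.columns]
    cols += [c for c in meta.columns if c not in cols]
    meta[cols].to_csv(directory / "metadata.tsv", sep="\t", index=False)
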