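"""Data model and readers/writers for count matrices, metadata and gene sets.

The pipeline's primary input is a gene x cell matrix of non-negative integer
read counts (Smart-seq2 style, no UMIs).  Matrices travel either as Matrix
Market coordinate triplets with ``genes.tsv`` / ``barcodes.tsv`` sidecars, or
as a dense TSV with gene rows and a cell-ID header.  Per-cell metadata
(sample, patient, optional sorted-population label) rides in ``metadata.tsv``.
Gene sets use the GMT exchange format.

Conventions: genes are rows, cells are columns, everywhere.  Gene identifiers
are HGNC symbols matched exactly and case-sensitively.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse

from .errors import FormatError, ValidationError

log = logging.getLogger(__name__)

META_COLUMNS = ["sample_id", "patient_id", "population_label"]


@dataclass
class CountMatrix:
    """Gene x cell non-negative integer counts with identifiers and metadata.

    ``cell_meta`` is indexed by cell_id with columns sample_id, patient_id and
    population_label (nullable).
    """

    counts: np.ndarray
    gene_ids: list[str]
    cell_ids: list[str]
    cell_meta: pd.DataFrame

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_cells(self) -> int:
        return len(self.cell_ids)

    def validate(self) -> "CountMatrix":
        if self.counts.shape != (len(self.gene_ids), len(self.cell_ids)):
            raise ValidationError(
                f"counts shape {self.counts.shape} does not match "
                f"({len(self.gene_ids)} genes, {len(self.cell_ids)} cells)"
            )
        if len(set(self.gene_ids)) != len(self.gene_ids):
            raise ValidationError("duplicate gene identifiers")
        if len(set(self.cell_ids)) != len(self.cell_ids):
            raise ValidationError("duplicate cell identifiers")
        if not np.issubdtype(self.counts.dtype, np.integer):
            frac, _ = np.modf(self.counts)
            bad = np.argwhere(frac != 0)
            if bad.size:
                g, c = bad[0]
                raise ValidationError(
                    f"non-integer count {self.counts[g, c]} at "
                    f"gene {self.gene_ids[g]!r}, cell {self.cell_ids[c]!r}"
                )
            self.counts = self.counts.astype(np.int64)
        if (self.counts < 0).any():
            g, c = np.argwhere(self.counts < 0)[0]
            raise ValidationError(
                f"negative count at gene {self.gene_ids[g]!r}, cell {self.cell_ids[c]!r}"
            )
        missing = set(self.cell_ids) - set(self.cell_meta.index)
        if missing:
            raise ValidationError(f"cells without metadata: {sorted(missing)[:5]}")
        self.cell_meta = self.cell_meta.loc[self.cell_ids]
        return self

    def subset_genes(self, keep: np.ndarray) -> "CountMatrix":
        """Return a new matrix keeping genes where ``keep`` (bool mask) is True."""
        idx = np.flatnonzero(keep)
        return CountMatrix(
            counts=self.counts[idx, :],
            gene_ids=[self.gene_ids[i] for i in idx],
            cell_ids=list(self.cell_ids),
            cell_meta=self.cell_meta.copy(),
        )

    def subset_cells(self, keep: np.ndarray) -> "CountMatrix":
        idx = np.flatnonzero(keep)
        cell_ids = [self.cell_ids[i] for i in idx]
        return CountMatrix(
            counts=self.counts[:, idx],
            gene_ids=list(self.gene_ids),
            cell_ids=cell_ids,
            cell_meta=self.cell_meta.loc[cell_ids].copy(),
        )


@dataclass
class ExpressionMatrix:
    """Log-normalized expression derived deterministically from counts.

    value[g, c] = ln(1 + scale_factor * count[g, c] / source_total[c]).
    Zero counts map to zero values and vice versa.
    """

    values: np.ndarray
    gene_ids: list[str]
    cell_ids: list[str]
    source_total: np.ndarray
    scale_factor: float

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_cells(self) -> int:
        return len(self.cell_ids)

    def gene_index(self) -> dict[str, int]:
        return {g: i for i, g in enumerate(self.gene_ids)}


def normalize(cm: CountMatrix, scale_factor: float = 1e4) -> ExpressionMatrix:
    """Counts-per-``scale_factor`` followed by natural log1p.

    Cells with zero total counts (allowed at load, removed at QC) get all-zero
    values rather than NaN.
    """
    if scale_factor <= 0:
        raise ValidationError("scale_factor must be positive")
    totals = cm.counts.sum(axis=0).astype(np.float64)
    safe = np.where(totals > 0, totals, 1.0)
    values = np.log1p(scale_factor * cm.counts / safe[None, :])
    return ExpressionMatrix(
        values=values,
        gene_ids=list(cm.gene_ids),
        cell_ids=list(cm.cell_ids),
        source_total=totals,
        scale_factor=scale_factor,
    )


@dataclass
class GeneSetLibrary:
    """Named, ordered gene lists with free-text provenance per set."""

    sets: dict[str, list[str]] = field(default_factory=dict)
    provenance: dict[str, str] = field(default_factory=dict)

    def __getitem__(self, name: str) -> list[str]:
        return self.sets[name]

    def __contains__(self, name: str) -> bool:
        return name in self.sets

    def names(self) -> list[str]:
        return list(self.sets)


# ---------------------------------------------------------------------------
# count matrix IO


def _read_id_column(path: Path, what: str) -> list[str]:
    ids = [line.rstrip("\n").split("\t")[0] for line in path.read_text().splitlines()]
    ids = [i for i in ids if i]
    if len(set(ids)) != len(ids):
        raise ValidationError(f"duplicate identifiers in {what} sidecar {path}")
    return ids


def _load_metadata(path: Path, cell_ids: list[str]) -> pd.DataFrame:
    if path.exists():
        meta = pd.read_csv(path, sep="\t", dtype=str)
        if "cell_id" not in meta.columns:
            raise FormatError(f"{path}: metadata TSV must have a cell_id column")
        meta = meta.set_index("cell_id")
        for col in META_COLUMNS:
            if col not in meta.columns:
                meta[col] = pd.NA
        return meta[META_COLUMNS]
    meta = pd.DataFrame(
        {"sample_id": "sample", "patient_id": "patient", "population_label": pd.NA},
        index=pd.Index(cell_ids, name="cell_id"),
    )
    return meta


def load_counts(path: str | Path, format: str = "mtx") -> CountMatrix:
    """Load a count matrix from an MTX triplet directory or a dense TSV.

    ``format='mtx'``: ``path`` is a directory holding matrix.mtx, genes.tsv,
    barcodes.tsv and optionally metadata.tsv.  ``format='tsv'``: ``path`` is a
    dense TSV (gene rows, header = cell IDs); a sibling metadata.tsv is picked
    up when present.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format == "mtx":
        mtx = path / "matrix.mtx"
        genes_f = path / "genes.tsv"
        cells_f = path / "barcodes.tsv"
        for f in (mtx, genes_f, cells_f):
            if not f.exists():
                raise FormatError(f"missing sidecar or matrix file: {f}")
        mat = scipy.io.mmread(mtx)
        dense = np.asarray(mat.todense() if scipy.sparse.issparse(mat) else mat)
        gene_ids = _read_id_column(genes_f, "gene")
        cell_ids = _read_id_column(cells_f, "cell")
        meta = _load_metadata(path / "metadata.tsv", cell_ids)
    elif format == "tsv":
        df = pd.read_csv(path, sep="\t", index_col=0)
        dense = df.to_numpy()
        gene_ids = [str(g) for g in df.index]
        cell_ids = [str(c) for c in df.columns]
        meta = _load_metadata(path.parent / "metadata.tsv", cell_ids)
    else:
        raise ValueError(f"unknown format {format!r}")
    cm = CountMatrix(counts=dense, gene_ids=gene_ids, cell_ids=cell_ids, cell_meta=meta)
    return cm.validate()


def write_counts(cm: CountMatrix, path: str | Path, format: str = "mtx") -> None:
    """Write a CountMatrix so that :func:`load_counts` round-trips it exactly."""
    cm.validate()
    path = Path(path)
    if format == "mtx":
        path.mkdir(parents=True, exist_ok=True)
        sparse = scipy.sparse.coo_matrix(cm.counts.astype(np.int64))
        scipy.io.mmwrite(path / "matrix.mtx", sparse, field="integer")
        (path / "genes.tsv").write_text("".join(f"{g}\n" for g in cm.gene_ids))
        (path / "barcodes.tsv").write_text("".join(f"{c}\n" for c in cm.cell_ids))
        meta = cm.cell_meta.reset_index()
        meta.columns = ["cell_id"] + list(cm.cell_meta.columns)
        meta.to_csv(path / "metadata.tsv", sep="\t", index=False)
    elif format == "tsv":
        path.parent.mkdir(parents=True, exist_ok=True)
        df = pd.DataFrame(cm.counts, index=cm.gene_ids, columns=cm.cell_ids)
        df.index.name = "gene_id"
        df.to_csv(path, sep="\t")
        meta = cm.cell_meta.reset_index()
        meta.columns = ["cell_id"] + list(cm.cell_meta.columns)
        meta.to_csv(path.parent / "metadata.tsv", sep="\t", index=False)
    else:
        raise ValueError(f"unknown format {format!r}")


# ---------------------------------------------------------------------------
# GMT


def load_gmt(path: str | Path) -> GeneSetLibrary:
    """Parse a GMT file: set_name TAB description TAB gene1 TAB gene2 ...

    Duplicate genes within a line are collapsed (first occurrence kept) with a
    logged warning; lines with fewer than three fields raise FormatError.
    """
    lib = GeneSetLibrary()
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if not line.strip():
            continue
        fields = line.rstrip("\n").split("\t")
        if len(fields) < 3:
            raise FormatError(f"{path}: line {lineno} has fewer than 3 fields")
        name, desc, genes = fields[0], fields[1], [g for g in fields[2:] if g]
        seen: dict[str, None] = {}
        dups = 0
        for g in genes:
            if g in seen:
                dups += 1
            else:
                seen[g] = None
        if dups:
            log.warning("%s: set %r had %d duplicate genes collapsed", path, name, dups)
        lib.sets[name] = list(seen)
        lib.provenance[name] = desc
    return lib


def write_gmt(lib: GeneSetLibrary, path: str | Path) -> None:
    lines = []
    for name, genes in lib.sets.items():
        desc = lib.provenance.get(name, "")
        lines.append("\t".join([name, desc] + list(genes)))
    Path(path).write_text("".join(line + "\n" for line in lines))


def match_genes(requested: list[str], universe: list[str], label: str = "set") -> list[str]:
    """Exact, case-sensitive intersection; unmatched genes dropped with a logged count."""
    present = set(universe)
    matched = [g for g in requested if g in present]
    n_missing = len(requested) - len(matched)
    if n_missing:
        log.info("%s: %d/%d genes absent from matrix universe, dropped", label, n_missing, len(requested))
    return matched
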