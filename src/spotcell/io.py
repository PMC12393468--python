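"""Shared data model and readers/writers for the standard file formats.

The pipeline speaks 10x Visium conventions on disk: a MatrixMarket count
matrix, ``barcodes.tsv`` / ``features.tsv``, and a ``tissue_positions.csv``
with full-resolution pixel coordinates.  In memory, a sample is a
:class:`SpotMatrix`; a labeled single-nucleus reference is collapsed into a
:class:`ReferencePanel` of per-type expression fractions; ligand-receptor
pairs live in a :class:`LRTable`.
"""

from __future__ import annotations

import os
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import io as spio
from scipy import sparse

GROUPS = ("AC", "PART", "AD")
#: Hippocampal subregions: soma layers, fiber layers and the vascular domain.
DOMAINS = ("SUB", "CA1", "CA2", "CA3", "CA4", "DG", "SR", "SO", "ML", "VAS")
UNASSIGNED = "UNASSIGNED"

POSITION_COLUMNS = [
    "barcode",
    "in_tissue",
    "array_row",
    "array_col",
    "pxl_row_in_fullres",
    "pxl_col_in_fullres",
]


@dataclass
class SpotMatrix:
    """One sample's spots x genes UMI counts with pixel coordinates.

    ``x`` is the full-resolution pixel column and ``y`` the pixel row
    (Visium convention); distances are Euclidean in px with 1 px ~ 1 um.
    """

    counts: np.ndarray
    spot_ids: np.ndarray
    gene_ids: np.ndarray
    x: np.ndarray
    y: np.ndarray
    sample_id: str = "sample"
    group: str = "AC"
    domain: np.ndarray | None = None
    is_vas: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.ndim != 2:
            raise ValueError("counts must be a 2-D spots x genes matrix")
        if np.issubdtype(self.counts.dtype, np.floating):
            if not np.allclose(self.counts, np.round(self.counts)):
                raise ValueError("counts must be integers")
            self.counts = self.counts.astype(np.int64)
        if self.counts.min(initial=0) < 0:
            raise ValueError("counts must be non-negative")
        self.spot_ids = np.asarray(self.spot_ids, dtype=object)
        self.gene_ids = np.asarray(self.gene_ids, dtype=object)
        if len(set(self.spot_ids)) != len(self.spot_ids):
            raise ValueError("spot_ids must be unique")
        dup = _duplicates(self.gene_ids)
        if dup:
            raise ValueError(f"duplicate gene ids: {sorted(dup)}")
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        if not (np.isfinite(self.x).all() and np.isfinite(self.y).all()):
            raise ValueError("coordinates must be finite")
        n, g = self.counts.shape
        if not (len(self.spot_ids) == len(self.x) == len(self.y) == n):
            raise ValueError("spot metadata length mismatch with counts rows")
        if len(self.gene_ids) != g:
            raise ValueError("gene_ids length mismatch with counts columns")
        if self.group not in GROUPS:
            raise ValueError(f"group must be one of {GROUPS}, got {self.group!r}")
        if self.is_vas is None:
            self.is_vas = np.zeros(n, dtype=bool)
        else:
            self.is_vas = np.asarray(self.is_vas, dtype=bool)
        if self.domain is not None:
            self.domain = np.asarray(self.domain, dtype=object)
            bad = self.is_vas & (self.domain != "VAS")
            if bad.any():
                raise ValueError(
                    "is_vas spots must carry domain VAS when domains are assigned"
                )

    @property
    def n_spots(self) -> int:
        return self.counts.shape[0]

    @property
    def n_genes(self) -> int:
        return self.counts.shape[1]


@dataclass
class ReferencePanel:
    """Cell-type expression fractions phi built from a labeled reference.

    ``phi[k, g]`` is the expected fraction of a type-``k`` cell's transcripts
    that come from gene ``g``; rows are strictly positive and sum to one.
    """

    cell_types: list[str]
    phi: np.ndarray
    gene_ids: np.ndarray
    n_cells_per_type: np.ndarray
    pseudocount: float

    def __post_init__(self) -> None:
        self.phi = np.asarray(self.phi, dtype=float)
        self.gene_ids = np.asarray(self.gene_ids, dtype=object)
        if len(self.cell_types) < 1:
            raise ValueError("at least one cell type required")
        if self.phi.shape != (len(self.cell_types), len(self.gene_ids)):
            raise ValueError("phi shape mismatch")
        if (self.phi <= 0).any():
            raise ValueError("phi entries must be strictly positive")
        if not np.allclose(self.phi.sum(axis=1), 1.0, atol=1e-9):
            raise ValueError("phi rows must sum to 1")

    @property
    def n_types(self) -> int:
        return len(self.cell_types)


@dataclass
class LREntry:
    pathway: str
    ligand: str
    receptor_subunits: list[str]
    pair_name: str


@dataclass
class LRTable:
    entries: list[LREntry] = field(default_factory=list)

    def __post_init__(self) -> None:
        names = [e.pair_name for e in self.entries]
        dup = _duplicates(names)
        if dup:
            raise ValueError(f"duplicate pair_name: {sorted(dup)}")
        for e in self.entries:
            if not e.receptor_subunits:
                raise ValueError(f"empty receptor subunit list for {e.pair_name}")

    def __len__(self) -> int:
        return len(self.entries)

    def genes(self) -> set[str]:
        out: set[str] = set()
        for e in self.entries:
            out.add(e.ligand)
            out.update(e.receptor_subunits)
        return out


def _duplicates(values) -> set:
    seen: set = set()
    dup: set = set()
    for v in values:
        if v in seen:
            dup.add(v)
        seen.add(v)
    return dup


# ---------------------------------------------------------------------------
# Readers
# ---------------------------------------------------------------------------

def read_spot_matrix(
    mtx_path,
    barcodes_path,
    features_path,
    positions_path,
    sample_id: str = "sample",
    group: str = "AC",
) -> SpotMatrix:
    """Read a Visium-convention file set into a :class:`SpotMatrix`.

    The MatrixMarket file may be stored genes x spots (10x convention) or
    spots x genes; orientation is auto-detected by matching a dimension to
    the number of barcodes.  Only ``in_tissue == 1`` spots are kept; spot
    order follows the barcodes file; ``x`` is ``pxl_col_in_fullres`` and
    ``y`` is ``pxl_row_in_fullres``.
    """
    barcodes = pd.read_csv(barcodes_path, header=None, sep="\t")[0].astype(str).tolist()
    features = pd.read_csv(features_path, header=None, sep="\t")[0].astype(str).tolist()
    mat = spio.mmread(os.fspath(mtx_path))
    if sparse.issparse(mat):
        mat = mat.toarray()
    mat = np.asarray(mat)
    nb, nf = len(barcodes), len(features)
    if mat.shape == (nb, nf):
        counts = mat
    elif mat.shape == (nf, nb):
        counts = mat.T
    else:
        raise ValueError(
            f"matrix shape {mat.shape} matches neither (spots={nb}, genes={nf}) "
            f"nor its transpose"
        )
    if not np.allclose(counts, np.round(counts)):
        raise ValueError("matrix contains non-integer values")
    counts = np.round(counts).astype(np.int64)
    dup = _duplicates(features)
    if dup:
        raise ValueError(f"duplicate gene ids: {sorted(dup)}")

    pos = pd.read_csv(positions_path)
    missing = [c for c in POSITION_COLUMNS if c not in pos.columns]
    if missing:
        raise ValueError(f"positions file missing columns: {missing}")
    pos = pos.set_index(pos["barcode"].astype(str))
    for bc in barcodes:
        if bc not in pos.index:
            raise ValueError(f"barcode {bc!r} present in matrix but absent from positions")
    pos = pos.loc[barcodes]
    keep = pos["in_tissue"].to_numpy() == 1
    return SpotMatrix(
        counts=counts[keep],
        spot_ids=np.asarray(barcodes, dtype=object)[keep],
        gene_ids=np.asarray(features, dtype=object),
        x=pos["pxl_col_in_fullres"].to_numpy(float)[keep],
        y=pos["pxl_row_in_fullres"].to_numpy(float)[keep],
        sample_id=sample_id,
        group=group,
    )


def write_spot_matrix(spots: SpotMatrix, out_dir) -> None:
    """Write a :class:`SpotMatrix` as the Visium-convention file set.

    Emits ``matrix.mtx`` (genes x spots, the 10x orientation), ``barcodes.tsv``,
    ``features.tsv`` and ``tissue_positions.csv`` under ``out_dir``.
    """
    os.makedirs(out_dir, exist_ok=True)
    spio.mmwrite(
        os.path.join(out_dir, "matrix.mtx"),
        sparse.coo_matrix(spots.counts.T),
        field="integer",
    )
    pd.Series(spots.spot_ids).to_csv(
        os.path.join(out_dir, "barcodes.tsv"), index=False, header=False, sep="\t"
    )
    pd.Series(spots.gene_ids).to_csv(
        os.path.join(out_dir, "features.tsv"), index=False, header=False, sep="\t"
    )
    pos = pd.DataFrame(
        {
            "barcode": spots.spot_ids,
            "in_tissue": 1,
            "array_row": np.zeros(spots.n_spots, dtype=int),
            "array_col": np.zeros(spots.n_spots, dtype=int),
            "pxl_row_in_fullres": spots.y,
            "pxl_col_in_fullres": spots.x,
        }
    )
    pos.to_csv(os.path.join(out_dir, "tissue_positions.csv"), index=False)


def build_reference(
    cell_counts,
    cell_labels,
    gene_ids,
    pseudocount: float = 0.5,
) -> ReferencePanel:
    """Collapse labeled reference cells into per-type expression fractions.

    phi[k, g] = (C[k, g] + eps) / sum_g (C[k, g] + eps) with C the summed
    counts of gene g over cells of type k.  The pseudocount is applied to the
    type-summed counts so every entry is strictly positive.
    """
    if pseudocount <= 0:
        raise ValueError("pseudocount must be > 0")
    cell_counts = np.asarray(cell_counts)
    cell_labels = np.asarray(cell_labels, dtype=object)
    if cell_counts.shape[0] != len(cell_labels):
        raise ValueError("cell_labels length mismatch with cell_counts rows")
    cell_types = sorted(set(cell_labels))
    rows = []
    n_cells = []
    for ct in cell_types:
        mask = cell_labels == ct
        if not mask.any():
            raise ValueError(f"cell type {ct!r} has zero cells")
        summed = cell_counts[mask].sum(axis=0).astype(float) + pseudocount
        rows.append(summed / summed.sum())
        n_cells.append(int(mask.sum()))
    return ReferencePanel(
        cell_types=list(cell_types),
        phi=np.vstack(rows),
        gene_ids=np.asarray(gene_ids, dtype=object),
        n_cells_per_type=np.asarray(n_cells),
        pseudocount=float(pseudocount),
    )


def read_lr_table(tsv_path) -> LRTable:
    """Parse a ligand-receptor pair TSV.

    Columns: ``pathway``, ``ligand``, ``receptors`` (';'-separated subunits)
    and optional ``pair_name``.  A multi-subunit pair defaults to the
    "LIG-(SUB1+SUB2)" naming; a single-subunit pair to "LIG-SUB".
    """
    df = pd.read_csv(tsv_path, sep="\t", dtype=str).fillna("")
    required = {"pathway", "ligand", "receptors"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"LR table missing columns: {sorted(missing)}")
    entries = []
    for _, row in df.iterrows():
        subunits = [s for s in str(row["receptors"]).split(";") if s]
        if not subunits:
            raise ValueError(
                f"empty receptors field for ligand {row['ligand']!r}"
            )
        name = row.get("pair_name", "") or default_pair_name(row["ligand"], subunits)
        entries.append(
            LREntry(
                pathway=row["pathway"],
                ligand=row["ligand"],
                receptor_subunits=subunits,
                pair_name=name,
            )
        )
    return LRTable(entries=entries)


def default_pair_name(ligand: str, subunits: list[str]) -> str:
    if len(subunits) == 1:
        return f"{ligand}-{subunits[0]}"
    return f"{ligand}-({'+'.join(subunits)})"


def write_lr_table(table: LRTable, tsv_path) -> None:
    rows = [
        {
            "pathway": e.pathway,
            "ligand": e.ligand,
            "receptors": ";".join(e.receptor_subunits),
            "pair_name": e.pair_name,
        }
        for e in table.entries
    ]
    pd.DataFrame(rows, columns=["pathway", "ligand", "receptors", "pair_name"]).to_csv(
        tsv_path, sep="\t", index=False
    )


# ---------------------------------------------------------------------------
# Report tables
# ---------------------------------------------------------------------------

def write_table(records, path, key_columns=None) -> None:
    """Write records as a deterministic TSV report.

    Rows are stable-sorted on ``key_columns`` (all columns if omitted), so the
    same records in any input order produce a byte-identical file.  Floats are
    serialized with 6 significant digits.
    """
    if isinstance(records, pd.DataFrame):
        df = records.copy()
    else:
        df = pd.DataFrame(list(records))
    if len(df) and key_columns is None:
        key_columns = list(df.columns)
    if len(df) and key_columns:
        bad = [c for c in key_columns if c not in df.columns]
        if bad:
            raise ValueError(f"unknown key columns: {bad}")
        df = df.sort_values(list(key_columns), kind="stable").reset_index(drop=True)
    df.to_csv(path, sep="\t", index=False, float_format="%.6g", encoding="utf-8")


def read_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
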