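"""Readers and writers for the standard formats the pipeline touches.

Expression matrices travel as MatrixMarket triplets (plus barcode and
feature TSVs), gene sets as GMT, ligand-receptor pairs and annotations as
CSV. Everything is validated into the package-wide conventions on load:
cells x genes orientation, unique cell and gene identifiers, integer
non-negative counts stored in ``adata.layers["counts"]``.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from pathlib import Path

import anndata as ad
import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp

__all__ = [
    "GeneSet",
    "InteractionPair",
    "FormatError",
    "read_counts_mtx",
    "write_counts_mtx",
    "read_gmt",
    "write_gmt",
    "read_interaction_csv",
    "write_interaction_csv",
    "read_annotation_csv",
    "write_annotation_csv",
    "validate_expression",
]

COUNTS_LAYER = "counts"
LOGNORM_LAYER = "lognorm"
DEFAULT_MITO_PREFIX = "mt-"


class FormatError(ValueError):
    """Raised when an input file violates its format contract."""


@dataclass(frozen=True)
class GeneSet:
    """A named, ordered list of gene symbols (no duplicates, non-empty)."""

    name: str
    genes: tuple[str, ...]

    def __post_init__(self):
        object.__setattr__(self, "genes", tuple(self.genes))
        if not self.name:
            raise ValueError("GeneSet name must be non-empty")
        if len(self.genes) == 0:
            raise ValueError(f"GeneSet {self.name!r} is empty")
        if len(set(self.genes)) != len(self.genes):
            raise ValueError(f"GeneSet {self.name!r} contains duplicate genes")

    def __len__(self) -> int:
        return len(self.genes)


@dataclass(frozen=True)
class InteractionPair:
    """A directional ligand->receptor pair; either side may be a multi-subunit complex."""

    name: str
    ligand_subunits: tuple[str, ...]
    receptor_subunits: tuple[str, ...]

    def __post_init__(self):
        object.__setattr__(self, "ligand_subunits", tuple(self.ligand_subunits))
        object.__setattr__(self, "receptor_subunits", tuple(self.receptor_subunits))
        for side, subs in (
            ("ligand", self.ligand_subunits),
            ("receptor", self.receptor_subunits),
        ):
            if len(subs) == 0 or any(not s for s in subs):
                raise ValueError(
                    f"InteractionPair {self.name!r}: {side} complex must have >=1 "
                    "non-empty subunit"
                )
            if len(set(subs)) != len(subs):
                raise ValueError(
                    f"InteractionPair {self.name!r}: duplicate subunit in {side} complex"
                )


def _dedup_symbols(symbols: list[str]) -> list[str]:
    """Make symbols unique by suffixing '.1', '.2', ... to repeats, in order."""
    seen: dict[str, int] = {}
    out = []
    for s in symbols:
        if s in seen:
            seen[s] += 1
            out.append(f"{s}.{seen[s]}")
        else:
            seen[s] = 0
            out.append(s)
    return out


def _read_tsv_column(path: Path) -> list[str]:
    rows = pd.read_csv(path, sep="\t", header=None, dtype=str)
    return rows.iloc[:, 0].tolist()


def validate_expression(adata: ad.AnnData) -> ad.AnnData:
    """Check the package invariants on an expression AnnData and return it.

    Counts must be present, non-negative and integral; identifiers unique;
    the lognorm layer, when present, non-negative and shape-matched.
    """
    if COUNTS_LAYER not in adata.layers:
        raise ValueError("expression matrix lacks a 'counts' layer")
    counts = adata.layers[COUNTS_LAYER]
    data = counts.data if sp.issparse(counts) else np.asarray(counts)
    if data.size and float(np.min(data)) < 0:
        raise ValueError("counts contain negative entries")
    if data.size and np.any(data != np.round(data)):
        raise ValueError("counts contain non-integer entries")
    if adata.obs_names.has_duplicates:
        raise ValueError("duplicate cell barcodes")
    if adata.var_names.has_duplicates:
        raise ValueError("duplicate gene symbols")
    if LOGNORM_LAYER in adata.layers:
        norm = adata.layers[LOGNORM_LAYER]
        if norm.shape != adata.shape:
            raise ValueError("lognorm layer shape does not match counts")
        nd = norm.data if sp.issparse(norm) else np.asarray(norm)
        if nd.size and float(np.min(nd)) < 0:
            raise ValueError("lognorm layer contains negative values")
    return adata


def read_counts_mtx(
    matrix_path: str | Path,
    barcodes_path: str | Path,
    features_path: str | Path,
    mito_prefix: str = DEFAULT_MITO_PREFIX,
) -> ad.AnnData:
    """Read a MatrixMarket count triplet into a cells x genes AnnData.

    The standard 10x layout stores the matrix as genes x cells; orientation
    is auto-detected by matching the header dimensions against the barcode
    and feature row counts, and the matrix is transposed to cells x genes
    when needed. Duplicate feature symbols are made unique by suffixing
    ``.1``, ``.2``, ...
    """
    matrix_path, barcodes_path, features_path = (
        Path(matrix_path),
        Path(barcodes_path),
        Path(features_path),
    )
    mat = scipy.io.mmread(str(matrix_path))
    mat = sp.csr_matrix(mat)
    barcodes = _read_tsv_column(barcodes_path)
    features = _read_tsv_column(features_path)
    n_rows, n_cols = mat.shape

    if (n_rows, n_cols) == (len(features), len(barcodes)):
        mat = sp.csr_matrix(mat.T)  # 10x genes x cells -> cells x genes
    elif (n_rows, n_cols) == (len(barcodes), len(features)):
        pass
    else:
        raise FormatError(
            f"matrix is {n_rows} x {n_cols} but there are {len(barcodes)} barcodes "
            f"and {len(features)} features; neither orientation matches"
        )

    data = mat.data
    if data.size and (float(data.min()) < 0 or np.any(data != np.round(data))):
        raise ValueError("count matrix has negative or non-integer entries")

    if len(set(barcodes)) != len(barcodes):
        raise FormatError("duplicate cell barcodes in barcodes file")
    features = _dedup_symbols(features)

    counts = sp.csr_matrix(mat.astype(np.int64))
    adata = ad.AnnData(
        X=counts.copy(),
        obs=pd.DataFrame(index=pd.Index(barcodes, name="cell_id")),
        var=pd.DataFrame(index=pd.Index(features, name="gene")),
        layers={COUNTS_LAYER: counts},
    )
    adata.uns["mito_prefix"] = mito_prefix
    return validate_expression(adata)


def write_counts_mtx(adata: ad.AnnData, out_dir: str | Path) -> None:
    """Write counts as ``matrix.mtx`` + ``barcodes.tsv`` + ``features.tsv`` (10x genes x cells)."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    counts = sp.coo_matrix(adata.layers[COUNTS_LAYER].T)  # genes x cells on disk
    scipy.io.mmwrite(str(out_dir / "matrix.mtx"), counts, field="integer")
    (out_dir / "barcodes.tsv").write_text("".join(f"{b}\n" for b in adata.obs_names))
    (out_dir / "features.tsv").write_text("".join(f"{g}\n" for g in adata.var_names))


def read_gmt(path: str | Path) -> list[GeneSet]:
    """Parse a GMT file: one tab-separated line per set (name, description, genes...).

    The description field is dropped; duplicate genes within a line are
    removed keeping the first occurrence.
    """
    sets = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(
                    f"{path}: line {lineno} has {len(fields)} fields, expected >=3 "
                    "(name, description, genes...)"
                )
            name, _desc, *genes = fields
            genes = [g for g in genes if g]
            deduped = list(dict.fromkeys(genes))
            sets.append(GeneSet(name=name, genes=tuple(deduped)))
    return sets


def write_gmt(sets: list[GeneSet], path: str | Path, description: str = "na") -> None:
    with open(path, "w") as fh:
        for s in sets:
            fh.write("\t".join([s.name, description, *s.genes]) + "\n")


def _split_complex(value: str) -> tuple[str, ...]:
    return tuple(s.strip() for s in value.split("+") if s.strip())


def read_interaction_csv(path: str | Path) -> list[InteractionPair]:
    """Read ligand-receptor pairs from a CSV with columns name, ligand, receptor.

    Multi-subunit complexes are written with ``+`` between subunits
    (e.g. ``Osmr+Il6st`` for the two-chain OSM receptor).
    """
    pairs = []
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh)
        required = {"name", "ligand", "receptor"}
        if reader.fieldnames is None or not required.issubset(reader.fieldnames):
            raise FormatError(f"{path}: header must contain columns {sorted(required)}")
        for rownum, row in enumerate(reader, start=2):
            lig = _split_complex(row["ligand"] or "")
            rec = _split_complex(row["receptor"] or "")
            if not lig or not rec:
                raise ValueError(
                    f"{path}: row {rownum} ({row.get('name', '?')!r}) has an empty "
                    "ligand or receptor field"
                )
            pairs.append(
                InteractionPair(
                    name=row["name"], ligand_subunits=lig, receptor_subunits=rec
                )
            )
    return pairs


def write_interaction_csv(pairs: list[InteractionPair], path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["name", "ligand", "receptor"])
        for p in pairs:
            writer.writerow(
                [p.name, "+".join(p.ligand_subunits), "+".join(p.receptor_subunits)]
            )


def read_annotation_csv(path: str | Path) -> pd.DataFrame:
    """Read a per-cell annotation CSV keyed by ``cell_id``."""
    df = pd.read_csv(path, dtype={"cell_id": str})
    if "cell_id" not in df.columns:
        raise FormatError(f"{path}: annotation CSV must have a 'cell_id' column")
    if df["cell_id"].duplicated().any():
        raise FormatError(f"{path}: duplicate cell_id rows")
    return df.set_index("cell_id")


def write_annotation_csv(ann: pd.DataFrame, path: str | Path) -> None:
    out = ann.copy()
    out.index.name = "cell_id"
    out.to_csv(path)
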