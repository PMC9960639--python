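"""Readers, writers and in-memory containers for every format the pipeline touches.

Coordinate conventions are explicit: files follow their standard's convention
(GFF3 is 1-based closed, bedGraph is 0-based half-open); the in-memory model
is 1-based closed everywhere. Every reader/writer pair round-trips losslessly
on valid inputs.
"""

from __future__ import annotations

import io as _io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
import scipy.io as spio
import scipy.sparse as sp

__all__ = [
    "GeneModelSet",
    "ReadPlacementTable",
    "ExpressionMatrix",
    "TFInteractionTable",
    "ParseError",
    "read_gff",
    "write_gff",
    "read_matrix",
    "write_matrix",
    "read_placements",
    "write_placements",
    "read_coverage_bedgraph",
    "write_coverage_bedgraph",
    "read_fasta",
    "write_fasta",
    "read_spikein_mix",
    "write_spikein_mix",
]

READ_CLASSES = ("biological", "spikein", "unmapped")
MATRIX_UNITS = ("counts", "CPM", "TPM", "log2TPM1")


class ParseError(ValueError):
    """Malformed input file; carries the 1-based line number where known."""

    def __init__(self, message: str, line: int | None = None):
        self.line = line
        if line is not None:
            message = f"line {line}: {message}"
        super().__init__(message)


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------

@dataclass
class GeneModelSet:
    """Gene models on one or more linear references, 1-based closed coordinates.

    ``genes`` has columns ``gene_id, ref, start, end, strand, length``; the
    effective length defaults to ``end - start + 1`` but an explicit value
    (e.g. a mature-transcript length) may be supplied.
    """

    genes: pd.DataFrame
    ref_lengths: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        g = self.genes
        required = ["gene_id", "ref", "start", "end", "strand"]
        missing = [c for c in required if c not in g.columns]
        if missing:
            raise ValueError(f"gene table missing columns {missing}")
        if "length" not in g.columns:
            g = g.assign(length=g["end"] - g["start"] + 1)
        if (g["start"] > g["end"]).any():
            bad = g.loc[g["start"] > g["end"], "gene_id"].iloc[0]
            raise ValueError(f"gene {bad!r} has start > end")
        if (g["start"] < 1).any():
            raise ValueError("coordinates are 1-based; start must be >= 1")
        if g["gene_id"].duplicated().any():
            dup = g.loc[g["gene_id"].duplicated(), "gene_id"].iloc[0]
            raise ValueError(f"duplicate gene_id {dup!r}")
        if not g["strand"].isin(["+", "-"]).all():
            raise ValueError("strand must be '+' or '-'")
        self.genes = g.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.genes)

    @property
    def gene_ids(self) -> list[str]:
        return self.genes["gene_id"].tolist()

    def lengths(self) -> pd.Series:
        return self.genes.set_index("gene_id")["length"]

    def equals(self, other: "GeneModelSet") -> bool:
        a = self.genes.sort_values("gene_id").reset_index(drop=True)
        b = other.genes.sort_values("gene_id").reset_index(drop=True)
        cols = ["gene_id", "ref", "start", "end", "strand", "length"]
        return a[cols].equals(b[cols])


@dataclass
class ReadPlacementTable:
    """Per-read mapped locations for one or more cells.

    Columns: ``cell_id, ref, start, length, strand, read_class`` with
    ``read_class`` in ``{biological, spikein, unmapped}``. Unmapped reads
    carry no coordinates (NA ref/start/length/strand).
    """

    reads: pd.DataFrame

    def __post_init__(self) -> None:
        r = self.reads
        required = ["cell_id", "ref", "start", "length", "strand", "read_class"]
        missing = [c for c in required if c not in r.columns]
        if missing:
            raise ValueError(f"read table missing columns {missing}")
        if not r["read_class"].isin(READ_CLASSES).all():
            raise ValueError(f"read_class must be one of {READ_CLASSES}")
        mapped = r["read_class"] != "unmapped"
        if mapped.any():
            m = r.loc[mapped]
            if m["start"].isna().any() or (m["start"] < 1).any():
                raise ValueError("mapped reads need 1-based start >= 1")
            if m["length"].isna().any() or (m["length"] < 1).any():
                raise ValueError("mapped reads need length >= 1")
        self.reads = r.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.reads)

    def for_cell(self, cell_id: str) -> "ReadPlacementTable":
        return ReadPlacementTable(self.reads[self.reads["cell_id"] == cell_id])

    def mapped(self, read_class: str | None = None) -> pd.DataFrame:
        r = self.reads[self.reads["read_class"] != "unmapped"]
        if read_class is not None:
            r = r[r["read_class"] == read_class]
        return r

    @property
    def cell_ids(self) -> list[str]:
        return sorted(self.reads["cell_id"].unique())


@dataclass
class ExpressionMatrix:
    """Genes × cells expression with a declared unit.

    ``values`` is a dense DataFrame indexed by gene id with cell-id columns.
    ``unit`` is one of ``counts | CPM | TPM | log2TPM1``. Optional per-gene
    lengths (bp) and per-cell metadata (condition, batch) ride along.
    """

    values: pd.DataFrame
    unit: str
    gene_lengths: pd.Series | None = None
    cell_meta: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        if self.unit not in MATRIX_UNITS:
            raise ValueError(f"unit must be one of {MATRIX_UNITS}, got {self.unit!r}")
        if (self.values.to_numpy() < 0).any():
            raise ValueError("expression values must be non-negative")
        if self.unit == "counts":
            v = self.values.to_numpy()
            if not np.allclose(v, np.round(v)):
                raise ValueError("counts must be integers")
        if self.gene_lengths is not None:
            self.gene_lengths = self.gene_lengths.reindex(self.values.index)
        if self.cell_meta is not None:
            if not self.cell_meta.index.equals(self.values.columns):
                self.cell_meta = self.cell_meta.reindex(self.values.columns)

    @property
    def gene_ids(self) -> list[str]:
        return self.values.index.tolist()

    @property
    def cell_ids(self) -> list[str]:
        return self.values.columns.tolist()

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def subset_genes(self, gene_ids: Iterable[str]) -> "ExpressionMatrix":
        ids = [g for g in gene_ids]
        lengths = self.gene_lengths.loc[ids] if self.gene_lengths is not None else None
        return ExpressionMatrix(self.values.loc[ids], self.unit, lengths, self.cell_meta)

    def subset_cells(self, cell_ids: Iterable[str]) -> "ExpressionMatrix":
        ids = [c for c in cell_ids]
        meta = self.cell_meta.loc[ids] if self.cell_meta is not None else None
        return ExpressionMatrix(self.values[ids], self.unit, self.gene_lengths, meta)


@dataclass
class TFInteractionTable:
    """TF → target-gene interactions with an evidence tag.

    Columns ``tf_id, target, evidence`` (plus optional ``motif_id, site_start,
    site_end``). Duplicate (tf, target, evidence) triples are rejected.
    """

    edges: pd.DataFrame

    def __post_init__(self) -> None:
        e = self.edges
        required = ["tf_id", "target", "evidence"]
        missing = [c for c in required if c not in e.columns]
        if missing:
            raise ValueError(f"interaction table missing columns {missing}")
        if e.duplicated(subset=required).any():
            raise ValueError("duplicate (tf, target, evidence) triples")
        self.edges = e.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.edges)

    def targets_of(self, tf_id: str) -> set[str]:
        return set(self.edges.loc[self.edges["tf_id"] == tf_id, "target"])

    @property
    def tf_ids(self) -> list[str]:
        return sorted(self.edges["tf_id"].unique())

    def target_sets(self) -> dict[str, set[str]]:
        return {tf: set(sub["target"]) for tf, sub in self.edges.groupby("tf_id")}


# ---------------------------------------------------------------------------
# GFF3
# ---------------------------------------------------------------------------

_GFF_COLS = ["seqid", "source", "type", "start", "end", "score", "strand", "phase", "attributes"]


def read_gff(path: str | Path) -> GeneModelSet:
    """Read gene models from a GFF3 file (``gene`` features only).

    Coordinates are kept 1-based closed, exactly as in the file. A
    ``region``/``chromosome`` feature or ``##sequence-region`` pragma, when
    present, supplies reference lengths. Raises :class:`ParseError` with the
    offending line number on malformed input.
    """
    records = []
    ref_lengths: dict[str, int] = {}
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if line.startswith("##sequence-region"):
                parts = line.split()
                if len(parts) >= 4:
                    ref_lengths[parts[1]] = int(parts[3])
                continue
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 9:
                raise ParseError(f"expected 9 tab-separated fields, got {len(fields)}", lineno)
            try:
                start, end = int(fields[3]), int(fields[4])
            except ValueError as exc:
                raise ParseError(f"non-integer coordinate: {exc}", lineno) from None
            if start > end:
                raise ParseError(f"start {start} > end {end}", lineno)
            ftype = fields[2]
            attrs = _parse_attributes(fields[8], lineno)
            if ftype in ("region", "chromosome"):
                ref_lengths[fields[0]] = end
                continue
            if ftype != "gene":
                continue
            gene_id = attrs.get("ID") or attrs.get("gene_id")
            if gene_id is None:
                raise ParseError("gene feature without ID attribute", lineno)
            length = int(attrs["effective_length"]) if "effective_length" in attrs else end - start + 1
            records.append(
                {"gene_id": gene_id, "ref": fields[0], "start": start, "end": end,
                 "strand": fields[6], "length": length}
            )
    genes = pd.DataFrame(records, columns=["gene_id", "ref", "start", "end", "strand", "length"])
    return GeneModelSet(genes, ref_lengths=ref_lengths)


def write_gff(models: GeneModelSet, path: str | Path) -> None:
    """Write gene models as GFF3 ``gene`` features (round-trips with read_gff)."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for ref, length in sorted(models.ref_lengths.items()):
            fh.write(f"##sequence-region {ref} 1 {length}\n")
        for row in models.genes.itertuples(index=False):
            attrs = f"ID={row.gene_id}"
            if row.length != row.end - row.start + 1:
                attrs += f";effective_length={row.length}"
            fh.write(
                f"{row.ref}\tscstress\tgene\t{row.start}\t{row.end}\t.\t{row.strand}\t.\t{attrs}\n"
            )


def _parse_attributes(text: str, lineno: int) -> dict[str, str]:
    attrs: dict[str, str] = {}
    if text in (".", ""):
        return attrs
    for item in text.rstrip(";").split(";"):
        if "=" not in item:
            raise ParseError(f"malformed attribute {item!r}", lineno)
        key, value = item.split("=", 1)
        attrs[key.strip()] = value.strip()
    return attrs


# ---------------------------------------------------------------------------
# expression matrices
# ---------------------------------------------------------------------------

def write_matrix(matrix: ExpressionMatrix, path: str | Path, fmt: str = "tsv") -> None:
    """Write an expression matrix as TSV or MatrixMarket MTX.

    TSV holds genes as rows, cells as columns, with the unit recorded in a
    ``#unit=`` header comment. MTX writes ``<stem>.mtx`` plus sidecar
    ``<stem>.genes.txt`` / ``<stem>.cells.txt`` id files.
    """
    path = Path(path)
    if fmt == "tsv":
        with open(path, "w") as fh:
            fh.write(f"#unit={matrix.unit}\n")
            matrix.values.to_csv(fh, sep="\t", index_label="gene_id", float_format="%.10g")
    elif fmt == "mtx":
        stem = path.with_suffix("") if path.suffix == ".mtx" else path
        sparse = sp.csr_matrix(matrix.values.to_numpy())
        comment = f"unit={matrix.unit}"
        spio.mmwrite(str(stem) + ".mtx", sparse, comment=comment)
        Path(str(stem) + ".genes.txt").write_text("\n".join(matrix.gene_ids) + "\n")
        Path(str(stem) + ".cells.txt").write_text("\n".join(matrix.cell_ids) + "\n")
    else:
        raise ValueError(f"unknown matrix format {fmt!r}")


def read_matrix(path: str | Path, fmt: str = "tsv", unit: str | None = None) -> ExpressionMatrix:
    """Read an expression matrix written by :func:`write_matrix`.

    Explicit zeros in MTX input are normalized away (implicit-zero canonical
    form); the unit comes from the file header unless overridden.
    """
    path = Path(path)
    if fmt == "tsv":
        with open(path) as fh:
            first = fh.readline()
            file_unit = None
            if first.startswith("#unit="):
                file_unit = first.strip().split("=", 1)[1]
            else:
                fh.seek(0)
            df = pd.read_csv(fh, sep="\t", index_col="gene_id")
        df.index = df.index.astype(str)
        df.columns = df.columns.astype(str)
        return ExpressionMatrix(df, unit or file_unit or "counts")
    if fmt == "mtx":
        stem = path.with_suffix("") if path.suffix == ".mtx" else path
        sparse = spio.mmread(str(stem) + ".mtx").tocsr()
        sparse.eliminate_zeros()
        genes = Path(str(stem) + ".genes.txt").read_text().splitlines()
        cells = Path(str(stem) + ".cells.txt").read_text().splitlines()
        if sparse.shape != (len(genes), len(cells)):
            raise ParseError(
                f"matrix shape {sparse.shape} inconsistent with sidecar ids "
                f"({len(genes)} genes, {len(cells)} cells)"
            )
        file_unit = None
        with open(str(stem) + ".mtx") as fh:
            for line in fh:
                if line.startswith("%") and "unit=" in line:
                    file_unit = line.strip().lstrip("%").strip().split("=", 1)[1]
                if not line.startswith("%"):
                    break
        df = pd.DataFrame(sparse.toarray(), index=genes, columns=cells)
        return ExpressionMatrix(df, unit or file_unit or "counts")
    raise ValueError(f"unknown matrix format {fmt!r}")


# ---------------------------------------------------------------------------
# read placements
# ---------------------------------------------------------------------------

def write_placements(table: ReadPlacementTable, path: str | Path) -> None:
    """Write a read-placement table as TSV (NA fields for unmapped reads)."""
    out = table.reads.copy()
    out.to_csv(path, sep="\t", index=False, na_rep="NA")


def read_placements(
    path: str | Path,
    spike_refs: set[str] | None = None,
    strict: bool = False,
    known_refs: set[str] | None = None,
) -> ReadPlacementTable:
    """Read a TSV read-placement table.

    If the file lacks a ``read_class`` column, the class is inferred from the
    reference name: members of ``spike_refs`` are ``spikein``, NA references
    are ``unmapped``, everything else ``biological``. With ``strict=True`` a
    mapped reference outside ``known_refs ∪ spike_refs`` raises.
    """
    df = pd.read_csv(path, sep="\t", na_values=["NA"], dtype={"cell_id": str})
    if "read_class" not in df.columns:
        spike_refs = spike_refs or set()
        cls = np.where(
            df["ref"].isna(), "unmapped",
            np.where(df["ref"].isin(spike_refs), "spikein", "biological"),
        )
        df["read_class"] = cls
    if strict:
        allowed = (known_refs or set()) | (spike_refs or set())
        mapped_refs = set(df.loc[df["read_class"] != "unmapped", "ref"].dropna().unique())
        unknown = mapped_refs - allowed
        if unknown:
            raise ParseError(f"unknown references in strict mode: {sorted(unknown)}")
    return ReadPlacementTable(df)


# ---------------------------------------------------------------------------
# bedGraph coverage
# ---------------------------------------------------------------------------

def read_coverage_bedgraph(
    path: str | Path, ref_lengths: Mapping[str, int]
) -> dict[str, np.ndarray]:
    """Expand a bedGraph file to per-base coverage arrays.

    bedGraph intervals are 0-based half-open; the returned arrays are indexed
    so that ``array[i]`` is the coverage of 1-based position ``i + 1``.
    Overlapping intervals are an error.
    """
    arrays = {ref: np.zeros(length) for ref, length in ref_lengths.items()}
    seen: dict[str, int] = {}
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) != 4:
                raise ParseError(f"expected 4 fields, got {len(parts)}", lineno)
            ref, start, end, value = parts[0], int(parts[1]), int(parts[2]), float(parts[3])
            if ref not in arrays:
                raise ParseError(f"unknown reference {ref!r}", lineno)
            if end > len(arrays[ref]) or start < 0 or start >= end:
                raise ParseError(f"interval [{start},{end}) out of bounds for {ref!r}", lineno)
            if ref in seen and start < seen[ref]:
                raise ParseError(f"overlapping or unsorted interval at {start}", lineno)
            if np.any(arrays[ref][start:end] != 0):
                raise ParseError(f"overlapping interval [{start},{end})", lineno)
            arrays[ref][start:end] = value
            seen[ref] = end
    return arrays


def write_coverage_bedgraph(coverage: Mapping[str, np.ndarray], path: str | Path) -> None:
    """Write per-base coverage as run-length-compressed bedGraph (zeros omitted)."""
    with open(path, "w") as fh:
        for ref in sorted(coverage):
            arr = np.asarray(coverage[ref], dtype=float)
            if arr.size == 0:
                continue
            change = np.flatnonzero(np.diff(arr) != 0) + 1
            starts = np.concatenate([[0], change])
            ends = np.concatenate([change, [arr.size]])
            for s, e in zip(starts, ends):
                if arr[s] != 0:
                    fh.write(f"{ref}\t{s}\t{e}\t{arr[s]:.10g}\n")


# ---------------------------------------------------------------------------
# FASTA and small tables
# ---------------------------------------------------------------------------

def read_fasta(path: str | Path) -> dict[str, str]:
    """Read a FASTA file into an {id: sequence} dict (Biopython-backed)."""
    from Bio import SeqIO

    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(sequences: Mapping[str, str], path: str | Path, width: int = 60) -> None:
    from Bio.Seq import Seq
    from Bio.SeqRecord import SeqRecord
    from Bio import SeqIO

    records = [SeqRecord(Seq(seq), id=name, description="") for name, seq in sequences.items()]
    SeqIO.write(records, str(path), "fasta")


def read_spikein_mix(path: str | Path) -> pd.DataFrame:
    """Read a spike-in mix table (columns ``spike_id, concentration``)."""
    df = pd.read_csv(path, sep="\t")
    if not {"spike_id", "concentration"} <= set(df.columns):
        raise ParseError("spike-in mix needs columns spike_id, concentration")
    return df


def write_spikein_mix(mix: pd.DataFrame, path: str | Path) -> None:
    mix.to_csv(path, sep="\t", index=False)
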