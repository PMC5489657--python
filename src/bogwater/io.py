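"""Readers and writers for the pipeline's plain-text formats.

On disk the OTU table is tab-delimited with OTUs as rows (the long axis)
and samples as columns; in memory :class:`~bogwater.model.OtuTable` is
samples x OTUs.  Metadata, distance matrices and taxonomy tables are
tab-delimited; sequences are FASTA; trees are Newick.
"""

from __future__ import annotations

import datetime as _dt
from pathlib import Path

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord
from skbio import TreeNode

from .model import (OtuTable, ReferenceDatabase, SampleMetadata,
                    TaxonomyAssignment)

__all__ = [
    "OtuTableFormatError",
    "read_otu_table", "write_otu_table",
    "read_metadata", "write_metadata",
    "read_fasta", "write_fasta",
    "read_tree", "write_tree",
    "read_reference_database", "write_reference_database",
    "read_distance_matrix", "write_distance_matrix",
    "write_assignments", "read_assignments",
]


class OtuTableFormatError(ValueError):
    """An on-disk OTU table violates the tab-delimited contract."""


def read_otu_table(path) -> OtuTable:
    """Read a tab-delimited OTU table (OTU rows x sample columns)."""
    path = Path(path)
    with path.open() as fh:
        header = fh.readline().rstrip("\n")
        if header == "":
            raise OtuTableFormatError(f"{path}: empty file")
        cols = header.split("\t")
        sample_ids = cols[1:]
        otu_ids: list[str] = []
        rows: list[list[int]] = []
        for lineno, line in enumerate(fh, start=2):
            fields = line.rstrip("\n").split("\t")
            if len(fields) != len(cols):
                raise OtuTableFormatError(
                    f"{path}:{lineno}: expected {len(cols)} columns, "
                    f"got {len(fields)}")
            otu_ids.append(fields[0])
            row = []
            for colno, cell in enumerate(fields[1:], start=2):
                try:
                    value = int(cell)
                except ValueError:
                    raise OtuTableFormatError(
                        f"{path}:{lineno} col {colno}: "
                        f"non-integer count {cell!r}") from None
                if value < 0:
                    raise OtuTableFormatError(
                        f"{path}:{lineno} col {colno}: negative count {value}")
                row.append(value)
            rows.append(row)
    counts = (np.array(rows, dtype=np.int64)
              if rows else np.zeros((0, len(sample_ids)), dtype=np.int64))
    try:
        # disk is OTUs x samples; memory is samples x OTUs
        return OtuTable(counts.T, sample_ids, otu_ids)
    except ValueError as exc:
        raise OtuTableFormatError(f"{path}: {exc}") from None


def write_otu_table(table: OtuTable, path) -> None:
    path = Path(path)
    with path.open("w") as fh:
        fh.write("#OTU ID\t" + "\t".join(table.sample_ids) + "\n")
        mat = table.counts.T  # OTUs as rows on disk
        for otu_id, row in zip(table.otu_ids, mat):
            fh.write(otu_id + "\t" + "\t".join(map(str, row)) + "\n")


_META_COLS = ["sample_id", "lake", "layer", "date", "year",
              "mixing_regime", "replicate"]


def read_metadata(path) -> list[SampleMetadata]:
    df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    out = []
    for _, row in df.iterrows():
        out.append(SampleMetadata(
            sample_id=row["sample_id"], lake=row["lake"], layer=row["layer"],
            date=_dt.date.fromisoformat(row["date"]),
            replicate=row.get("replicate", "")))
    return out


def write_metadata(metadata, path) -> None:
    df = pd.DataFrame([{
        "sample_id": m.sample_id, "lake": m.lake, "layer": m.layer,
        "date": m.date.isoformat(), "year": m.year,
        "mixing_regime": m.mixing_regime, "replicate": m.replicate,
    } for m in metadata], columns=_META_COLS)
    df.to_csv(path, sep="\t", index=False)


def read_fasta(path) -> list[tuple[str, str]]:
    return [(rec.id, str(rec.seq).upper())
            for rec in SeqIO.parse(str(path), "fasta")]


def write_fasta(records, path) -> None:
    SeqIO.write(
        (SeqRecord(Seq(seq), id=name, description="")
         for name, seq in records),
        str(path), "fasta")


def read_tree(path) -> TreeNode:
    return TreeNode.read(str(path), format="newick")


def write_tree(tree: TreeNode, path) -> None:
    tree.write(str(path), format="newick")


def read_reference_database(fasta_path, taxonomy_path,
                            rank_names) -> ReferenceDatabase:
    """Reference FASTA plus 2-column taxonomy file (id, semicolon path)."""
    seqs = dict(read_fasta(fasta_path))
    records = []
    with Path(taxonomy_path).open() as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            seq_id, path_str = line.split("\t")
            path = tuple(p for p in path_str.strip(";").split(";"))
            records.append((seq_id, seqs[seq_id], path))
    return ReferenceDatabase(records, rank_names)


def write_reference_database(db: ReferenceDatabase, fasta_path,
                             taxonomy_path) -> None:
    write_fasta([(sid, seq) for sid, seq, _ in db], fasta_path)
    with Path(taxonomy_path).open("w") as fh:
        for sid, _, path in db:
            fh.write(f"{sid}\t{';'.join(path)};\n")


def read_distance_matrix(path):
    df = pd.read_csv(path, sep="\t", index_col=0)
    return df.to_numpy(dtype=float), list(df.index)


def write_distance_matrix(d: np.ndarray, labels, path) -> None:
    pd.DataFrame(d, index=labels, columns=labels).to_csv(path, sep="\t")


def write_assignments(assignments, path) -> None:
    """Tab-delimited: otu_id, semicolon path of label(confidence), source."""
    with Path(path).open("w") as fh:
        fh.write("otu_id\ttaxonomy\tsource_db\n")
        for a in assignments:
            tax = ";".join(f"{label}({conf:.0f})"
                           for (_, label), conf in zip(a.ranks, a.confidences))
            fh.write(f"{a.otu_id}\t{tax}\t{a.source_db}\n")


def read_assignments(path, rank_names_by_source) -> list[TaxonomyAssignment]:
    """Inverse of :func:`write_assignments`.

    ``rank_names_by_source`` maps source_db -> ordered rank-name tuple.
    """
    out = []
    with Path(path).open() as fh:
        header = fh.readline()
        if not header.startswith("otu_id"):
            raise ValueError(f"{path}: missing assignment header")
        for line in fh:
            otu_id, tax, source = line.rstrip("\n").split("\t")
            rank_names = rank_names_by_source[source]
            labels, confs = [], []
            for token in tax.split(";"):
                label, conf = token.rsplit("(", 1)
                labels.append(label)
                confs.append(float(conf.rstrip(")")))
            out.append(TaxonomyAssignment(
                otu_id=otu_id,
                ranks=tuple(zip(rank_names, labels)),
                confidences=tuple(confs),
                source_db=source))
    return out
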