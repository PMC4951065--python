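"""Readers and writers for the plain-text formats the toolkit consumes.

FASTA via Biopython; expression matrices, peptide tables and sample sheets
as TSV; pathway membership as standard GMT.
"""

from __future__ import annotations

from pathlib import Path
from typing import Mapping

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from dielomix.datatypes import ExpressionMatrix, GeneSequenceRecord, PeptideTable


def write_fasta(path: str | Path, sequences: Mapping[str, str]) -> None:
    records = [
        SeqRecord(Seq(seq), id=name, description="") for name, seq in sequences.items()
    ]
    SeqIO.write(records, str(path), "fasta")


def read_fasta(path: str | Path) -> dict[str, str]:
    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}


def read_gene_records(
    cds_path: str | Path,
    utr5_path: str | Path | None = None,
    utr3_path: str | Path | None = None,
    protein_path: str | Path | None = None,
) -> list[GeneSequenceRecord]:
    """Assemble gene records from per-region FASTA files keyed by gene id."""
    cds = read_fasta(cds_path)
    utr5 = read_fasta(utr5_path) if utr5_path else {}
    utr3 = read_fasta(utr3_path) if utr3_path else {}
    prot = read_fasta(protein_path) if protein_path else {}
    records = []
    for gene, seq in cds.items():
        records.append(
            GeneSequenceRecord(
                gene_id=gene,
                cds=seq,
                utr5=utr5.get(gene, ""),
                utr3=utr3.get(gene, ""),
                protein=prot.get(gene, ""),
                utr5_complete=gene in utr5,
                utr3_complete=gene in utr3,
            )
        )
    return records


def write_expression_tsv(path: str | Path, expr: ExpressionMatrix) -> None:
    path = Path(path)
    expr.data.rename_axis("gene_id").to_csv(path, sep="\t")
    expr.samples.rename_axis("sample_id").to_csv(
        path.with_name(path.stem + "_samples.tsv"), sep="\t"
    )


def read_expression_tsv(
    path: str | Path, samples_path: str | Path | None = None
) -> ExpressionMatrix:
    path = Path(path)
    data = pd.read_csv(path, sep="\t", index_col=0)
    if samples_path is None:
        samples_path = path.with_name(path.stem + "_samples.tsv")
    samples = pd.read_csv(samples_path, sep="\t", index_col=0)
    return ExpressionMatrix(data, samples)


def write_peptides_tsv(
    path: str | Path, samples_path: str | Path, peptides: PeptideTable
) -> None:
    df = peptides.abundance.copy()
    df.insert(
        0, "protein_ids", peptides.mapping["protein_ids"].map(";".join)
    )
    df.rename_axis("peptide_id").to_csv(path, sep="\t")
    peptides.datasets.rename_axis("dataset_id").to_csv(samples_path, sep="\t")


def read_peptides_tsv(path: str | Path, samples_path: str | Path) -> PeptideTable:
    df = pd.read_csv(path, sep="\t", index_col=0)
    protein_ids = df.pop("protein_ids").map(lambda s: tuple(str(s).split(";")))
    mapping = pd.DataFrame(
        {"protein_ids": protein_ids, "unique": protein_ids.map(len) == 1}
    )
    datasets = pd.read_csv(samples_path, sep="\t", index_col=0)
    return PeptideTable(df, mapping, datasets)


def read_gmt(path: str | Path) -> dict[str, list[str]]:
    """Parse a GMT file: pathway_id <tab> description <tab> gene ids..."""
    pathways: dict[str, list[str]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(
                    f"malformed GMT line {lineno}: expected at least 3 tab-separated "
                    f"fields, got {len(parts)}"
                )
            pathways[parts[0]] = [g for g in parts[2:] if g]
    return pathways


def write_gmt(path: str | Path, pathways: Mapping[str, list[str]]) -> None:
    with open(path, "w") as fh:
        for name, genes in pathways.items():
            fh.write("\t".join([name, "na", *genes]) + "\n")
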