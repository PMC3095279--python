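"""Readers and writers for the plain-text formats the pipeline exchanges.

FASTA via Biopython; gene order from GFF3 gene features or a BED-like TSV;
homology maps, domain annotations and motif definitions as TSV.
"""

from __future__ import annotations

import csv
from pathlib import Path
from typing import Iterable

import pandas as pd
from Bio import SeqIO

from .duplication import GeneLocus, GeneOrder, HomologyMap
from .family import DomainAnnotation, FamilyAssignment
from .motifs import MotifDefinition
from .phylogeny import ProteinAlignment

__all__ = [
    "read_fasta",
    "read_alignment",
    "read_gene_order",
    "read_homology",
    "read_domains",
    "read_motif_defs",
    "write_assignments",
]


def read_fasta(path: str | Path) -> dict[str, str]:
    """FASTA file -> id -> sequence (uppercased)."""
    out: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in out:
            raise ValueError(f"duplicate FASTA id {rec.id!r} in {path}")
        out[rec.id] = str(rec.seq).upper()
    return out


def read_alignment(path: str | Path) -> ProteinAlignment:
    records = read_fasta(path)
    return ProteinAlignment(tuple(records), tuple(records.values()))


def _parse_gff3_loci(path: Path) -> list[GeneLocus]:
    loci = []
    with path.open() as fh:
        for line in fh:
            if line.startswith("#") or not line.strip():
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 9 or fields[2] != "gene":
                continue
            attrs = dict(
                kv.split("=", 1) for kv in fields[8].split(";") if "=" in kv
            )
            gene_id = attrs.get("ID") or attrs.get("Name")
            if gene_id is None:
                raise ValueError(f"gene feature without ID attribute in {path}")
            strand = fields[6] if fields[6] in "+-" else "+"
            loci.append(GeneLocus(gene_id, fields[0], int(fields[3]), int(fields[4]), strand))
    return loci


def _parse_tsv_loci(path: Path) -> list[GeneLocus]:
    df = pd.read_csv(path, sep="\t")
    required = {"gene_id", "chrom", "start", "end"}
    if not required <= set(df.columns):
        raise ValueError(f"gene table {path} must have columns {sorted(required)}")
    strands = df["strand"] if "strand" in df.columns else ["+"] * len(df)
    return [
        GeneLocus(str(g), str(c), int(s), int(e), str(st))
        for g, c, s, e, st in zip(df["gene_id"], df["chrom"], df["start"], df["end"], strands)
    ]


def read_gene_order(path: str | Path) -> GeneOrder:
    """Gene order from GFF3 (gene features) or a BED-like TSV."""
    path = Path(path)
    if path.suffix.lower() in {".gff", ".gff3"}:
        return GeneOrder(_parse_gff3_loci(path))
    return GeneOrder(_parse_tsv_loci(path))


def read_homology(path: str | Path) -> HomologyMap:
    hom = HomologyMap()
    with Path(path).open() as fh:
        reader = csv.reader(fh, delimiter="\t")
        for i, row in enumerate(reader):
            if not row or row[0].startswith("#"):
                continue
            if i == 0 and row[0].lower() in {"gene1", "gene_id", "gene_a"}:
                continue
            if len(row) < 2:
                raise ValueError(f"homology row {i + 1} has fewer than 2 columns")
            hom.add(row[0], row[1])
    return hom


def read_domains(path: str | Path) -> dict[str, list[DomainAnnotation]]:
    df = pd.read_csv(path, sep="\t")
    required = {"gene_id", "domain", "start", "end"}
    if not required <= set(df.columns):
        raise ValueError(f"domain table {path} must have columns {sorted(required)}")
    out: dict[str, list[DomainAnnotation]] = {}
    for row in df.itertuples(index=False):
        ann = DomainAnnotation(str(row.gene_id), str(row.domain), int(row.start), int(row.end))
        out.setdefault(ann.gene_id, []).append(ann)
    return out


def read_motif_defs(path: str | Path) -> list[MotifDefinition]:
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"motif_id", "pattern"}
    if not required <= set(df.columns):
        raise ValueError(f"motif table {path} must have columns {sorted(required)}")
    defs = [MotifDefinition(str(r.motif_id), str(r.pattern)) for r in df.itertuples(index=False)]
    for d in defs:
        d.compiled()  # fail fast on bad patterns
    return defs


def write_assignments(assignments: Iterable[FamilyAssignment], path: str | Path) -> None:
    with Path(path).open("w") as fh:
        fh.write("gene_id\tis_member\tsubfamily\thkd_hits\tpseudogene\n")
        for a in assignments:
            spans = ";".join(f"{s}-{e}" for s, e in a.hkd_hits)
            fh.write(f"{a.gene_id}\t{a.is_member}\t{a.subfamily}\t{spans}\t{a.pseudogene}\n")
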