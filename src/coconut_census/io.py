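"""Readers and writers for the formats the pipeline touches.

GFF3 is 1-based inclusive on disk and converted to the internal 0-based
half-open convention on read. Only CDS features are parsed; other feature
types are ignored because the census operates on protein-coding genes.
All readers reject malformed records rather than silently repairing them.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Optional, TextIO, Union

from Bio import SeqIO

from .core import (
    Contig,
    DomainHit,
    GeneRecord,
    HitSource,
    ProteinRecord,
    from_external_coords,
    to_external_coords,
)

PathLike = Union[str, Path]

GFF_SOURCE = "coconut_census"


class ParseError(ValueError):
    """A malformed record; the message names the offending line."""


@dataclass
class GenomeBundle:
    """Everything one analysis run consumes: gene tables, proteins, hits."""

    contigs: list[Contig]
    proteins: dict[str, ProteinRecord]
    hits: Optional[list[DomainHit]] = None

    def __post_init__(self) -> None:
        for contig in self.contigs:
            for g in contig.genes:
                if g.protein_id is not None and g.protein_id not in self.proteins:
                    raise ValueError(
                        f"gene {g.gene_id}: protein_id {g.protein_id} does not "
                        "resolve in the protein mapping"
                    )
        for h in self.hits or []:
            if h.protein_id not in self.proteins:
                raise ValueError(
                    f"domain hit {h.domain_name}: protein_id {h.protein_id} "
                    "does not resolve"
                )

    def all_genes(self) -> Iterable[GeneRecord]:
        for contig in self.contigs:
            yield from contig.genes


def _parse_attributes(raw: str, lineno: int) -> dict[str, str]:
    attrs: dict[str, str] = {}
    for chunk in raw.strip().split(";"):
        if not chunk:
            continue
        if "=" not in chunk:
            raise ParseError(f"line {lineno}: malformed attribute {chunk!r}")
        key, value = chunk.split("=", 1)
        attrs[key.strip()] = value.strip()
    return attrs


def read_gff3(path: PathLike) -> list[Contig]:
    """Read CDS features from a GFF3 file into sorted Contig objects.

    Contig lengths are taken from ``##sequence-region`` pragmas when
    present, otherwise from the rightmost feature end.
    """
    contig_lengths: dict[str, int] = {}
    genes_by_contig: dict[str, list[GeneRecord]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            if line.startswith("##sequence-region"):
                parts = line.split()
                if len(parts) != 4:
                    raise ParseError(f"line {lineno}: malformed sequence-region pragma")
                contig_lengths[parts[1]] = int(parts[3])
                genes_by_contig.setdefault(parts[1], [])
                continue
            if line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) != 9:
                raise ParseError(
                    f"line {lineno}: expected 9 tab-separated columns, got {len(cols)}"
                )
            seqid, _source, ftype, start_s, end_s, _score, strand, _phase, attr_s = cols
            if ftype != "CDS":
                continue
            try:
                start_1, end_incl = int(start_s), int(end_s)
            except ValueError as exc:
                raise ParseError(f"line {lineno}: non-integer coordinate") from exc
            if strand not in ("+", "-"):
                raise ParseError(f"line {lineno}: missing or invalid strand {strand!r}")
            attrs = _parse_attributes(attr_s, lineno)
            if "ID" not in attrs:
                raise ParseError(f"line {lineno}: CDS feature lacks an ID attribute")
            start, end = from_external_coords(start_1, end_incl)
            try:
                gene = GeneRecord(
                    gene_id=attrs["ID"],
                    contig_id=seqid,
                    start=start,
                    end=end,
                    strand=strand,
                    protein_id=attrs.get("protein_id"),
                    protein_length=int(attrs.get("protein_length", 0)),
                )
            except ValueError as exc:
                raise ParseError(f"line {lineno}: {exc}") from exc
            genes_by_contig.setdefault(seqid, []).append(gene)
    contigs = []
    for contig_id in genes_by_contig:
        genes = genes_by_contig[contig_id]
        length = contig_lengths.get(
            contig_id, max((g.end for g in genes), default=0)
        )
        contigs.append(Contig(contig_id=contig_id, genes=genes, length=length))
    return contigs


def write_gff3(contigs: Iterable[Contig], path: PathLike) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for contig in contigs:
            fh.write(f"##sequence-region {contig.contig_id} 1 {contig.length}\n")
            for g in contig.genes:
                start_1, end_incl = to_external_coords(g)
                attrs = [f"ID={g.gene_id}"]
                if g.protein_id is not None:
                    attrs.append(f"protein_id={g.protein_id}")
                    attrs.append(f"protein_length={g.protein_length}")
                fh.write(
                    "\t".join(
                        [
                            contig.contig_id,
                            GFF_SOURCE,
                            "CDS",
                            str(start_1),
                            str(end_incl),
                            ".",
                            g.strand,
                            "0",
                            ";".join(attrs),
                        ]
                    )
                    + "\n"
                )


def read_fasta(path: PathLike) -> dict[str, ProteinRecord]:
    """Read a protein FASTA; the first whitespace-delimited header token is
    the ID. Sequences are uppercased; duplicate IDs and empty sequences are
    rejected."""
    proteins: dict[str, ProteinRecord] = {}
    for record in SeqIO.parse(str(path), "fasta"):
        pid = record.id
        if pid in proteins:
            raise ParseError(f"duplicate FASTA ID {pid!r}")
        seq = str(record.seq).upper()
        if not seq:
            raise ParseError(f"FASTA record {pid!r} has an empty sequence")
        proteins[pid] = ProteinRecord(protein_id=pid, sequence=seq)
    return proteins


def write_fasta(proteins: dict[str, ProteinRecord], path: PathLike, width: int = 60) -> None:
    with open(path, "w") as fh:
        for pid in sorted(proteins):
            seq = proteins[pid].sequence
            fh.write(f">{pid}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def read_domain_hits(path: PathLike, evalue_threshold: float = 0.001) -> list[DomainHit]:
    """Read a tab-separated hit table (protein_id, domain_name, start_1based,
    end_inclusive, evalue, source). Hits with E-value above the threshold are
    dropped at read time; coordinates are converted to the internal
    convention. An E-value of ``.`` or ``NA`` means "not applicable" and the
    hit is retained."""
    hits: list[DomainHit] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) != 6:
                raise ParseError(
                    f"line {lineno}: expected 6 tab-separated columns, got {len(cols)}"
                )
            pid, name, start_s, end_s, evalue_s, source_s = cols
            start_1, end_incl = int(start_s), int(end_s)
            if start_1 < 1 or end_incl < 1:
                raise ParseError(f"line {lineno}: negative or zero 1-based coordinate")
            evalue = None if evalue_s in (".", "NA", "") else float(evalue_s)
            if evalue is not None and evalue < 0:
                raise ParseError(f"line {lineno}: negative E-value")
            if evalue is not None and evalue > evalue_threshold:
                continue
            start, end = from_external_coords(start_1, end_incl)
            try:
                hits.append(
                    DomainHit(
                        protein_id=pid,
                        domain_name=name,
                        start_aa=start,
                        end_aa=end,
                        evalue=evalue,
                        source=HitSource(source_s),
                    )
                )
            except ValueError as exc:
                raise ParseError(f"line {lineno}: {exc}") from exc
    return hits


def write_domain_hits(hits: Iterable[DomainHit], path: PathLike) -> None:
    with open(path, "w") as fh:
        for h in hits:
            evalue = "." if h.evalue is None else repr(h.evalue)
            fh.write(
                "\t".join(
                    [
                        h.protein_id,
                        h.domain_name,
                        str(h.start_aa + 1),
                        str(h.end_aa),
                        evalue,
                        h.source.value,
                    ]
                )
                + "\n"
            )


def write_newick(tree) -> str:
    """Serialize a (scikit-bio style) tree node to a Newick string with
    branch lengths, terminated by ';'. Raises on cyclic structures."""
    seen: set[int] = set()

    def render(node) -> str:
        if id(node) in seen:
            raise ValueError("cyclic tree structure")
        seen.add(id(node))
        label = node.name or ""
        length = "" if node.length is None else f":{float(node.length)}"
        children = list(node.children)
        if not children:
            return f"{label}{length}"
        inner = ",".join(render(c) for c in children)
        return f"({inner}){label}{length}"

    return render(tree) + ";"


def read_newick(text: str):
    import io as _io

    from skbio import TreeNode

    return TreeNode.read(_io.StringIO(text), format="newick")


def _normalize(value):
    if isinstance(value, Enum):
        return value.value
    if dataclasses.is_dataclass(value) and not isinstance(value, type):
        return {k: _normalize(v) for k, v in dataclasses.asdict(value).items()}
    if isinstance(value, dict):
        return {k: _normalize(v) for k, v in value.items()}
    if isinstance(value, (list, tuple)):
        return [_normalize(v) for v in value]
    return value


def _call_to_row(call) -> dict:
    if dataclasses.is_dataclass(call) and not isinstance(call, type):
        d = {
            f.name: _normalize(getattr(call, f.name))
            for f in dataclasses.fields(call)
        }
    else:
        d = _normalize(dict(call))
    components = d.get("components")
    if components is not None:
        d["roles"] = ";".join(
            f"{c['role']}:{c['gene']['gene_id']}" for c in components
        )
    return d


def _tsv_cell(row: dict, column: str) -> str:
    value = row.get(column, "")
    if column == "signature" and isinstance(value, dict):
        value = value.get("variant")
    if column == "carf_association" and isinstance(value, dict):
        value = value["carf_gene"]["gene_id"]
    return "" if value is None else str(value)


def write_report(
    calls: list,
    funnel,
    json_path: PathLike,
    tsv_path: PathLike,
    config: Optional[dict] = None,
    version: str = "0.1.0",
) -> None:
    """Write the census/classification report: a JSON document embedding the
    resolved configuration, the per-tier funnel counts, and one record per
    classified locus; plus a TSV with one row per call."""
    funnel_d = dataclasses.asdict(funnel) if dataclasses.is_dataclass(funnel) else dict(funnel)
    rows = [_call_to_row(c) for c in calls]
    doc = {
        "version": version,
        "config": config or {},
        "funnel": funnel_d,
        "calls": rows,
    }
    with open(json_path, "w") as fh:
        json.dump(doc, fh, indent=2, default=str)
        fh.write("\n")
    columns = ["locus_id", "contig_id", "label", "tier", "signature", "tery_p",
               "extended_IIIA", "carf_association", "roles"]
    with open(tsv_path, "w") as fh:
        fh.write("\t".join(columns) + "\n")
        for row in rows:
            fh.write("\t".join(_tsv_cell(row, c) for c in columns) + "\n")
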