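"""Readers and writers for the standard formats the toolkit speaks.

FASTA reading is a small validating reader so that malformed input is rejected
with the offending line number and residue case (masking) is preserved exactly.
Trees go through dendropy's Newick support.
"""

from __future__ import annotations

from typing import List

import dendropy

from .model import GAP_CHARS, IUPAC_NT, GeneAnnotation, SequenceRecord


class FastaParseError(ValueError):
    pass


def read_fasta(path, allow_gaps: bool = False) -> List[SequenceRecord]:
    """Parse a (multi-)FASTA file, preserving residue case and record order.

    Raises :class:`FastaParseError` naming the line number for residues outside
    the IUPAC nucleotide alphabet or for sequence data before the first header.
    An empty file yields an empty list.
    """
    allowed = IUPAC_NT | (GAP_CHARS if allow_gaps else set())
    records: List[SequenceRecord] = []
    header = None
    description = ""
    chunks: List[str] = []

    def flush(lineno: int) -> None:
        if header is None:
            return
        residues = "".join(chunks)
        if not residues:
            raise FastaParseError(f"line {lineno}: record {header!r} has no sequence")
        records.append(SequenceRecord(header, residues, description))

    with open(path) as fh:
        lineno = 0
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                continue
            if line.startswith(">"):
                flush(lineno)
                head = line[1:].strip()
                if not head:
                    raise FastaParseError(f"line {lineno}: empty FASTA header")
                parts = head.split(None, 1)
                header = parts[0]
                description = parts[1] if len(parts) > 1 else ""
                chunks = []
            else:
                if header is None:
                    raise FastaParseError(f"line {lineno}: sequence data before first '>' header")
                bad = set(line.upper()) - allowed
                if bad:
                    raise FastaParseError(
                        f"line {lineno}: illegal residue(s) {sorted(bad)} in record {header!r}"
                    )
                chunks.append(line)
        flush(lineno + 1)
    return records


def write_fasta(records, path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for rec in records:
            head = f">{rec.id}"
            if rec.description:
                head += f" {rec.description}"
            fh.write(head + "\n")
            for i in range(0, len(rec.residues), width):
                fh.write(rec.residues[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# GFF3


def _gff3_attributes(gene: GeneAnnotation) -> str:
    attrs = [f"ID={gene.name}", f"gene_type={gene.gene_type}", f"functionality={gene.functionality}"]
    if gene.subgroup:
        attrs.append(f"subgroup={gene.subgroup}")
    if gene.cassette:
        attrs.append(f"cassette={gene.cassette}")
    if gene.defects:
        attrs.append("defects=" + "|".join(gene.defects))
    if gene.rescued_by_cdna:
        attrs.append("rescued_by_cdna=true")
    return ";".join(attrs)


def write_gff3(annotations, path) -> None:
    """Write genes and their exons as GFF3 (1-based closed, native convention)."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for gene in annotations:
            span = gene.span
            fh.write(
                "\t".join(
                    [
                        span.seq_id,
                        "trgkit",
                        "gene",
                        str(span.start),
                        str(span.end),
                        ".",
                        span.strand,
                        ".",
                        _gff3_attributes(gene),
                    ]
                )
                + "\n"
            )
            for label, iv in gene.exons:
                fh.write(
                    "\t".join(
                        [
                            iv.seq_id,
                            "trgkit",
                            "exon",
                            str(iv.start),
                            str(iv.end),
                            ".",
                            iv.strand,
                            ".",
                            f"ID={gene.name}.{label};Parent={gene.name};exon_label={label}",
                        ]
                    )
                    + "\n"
                )


def read_gff3(path) -> List[GeneAnnotation]:
    """Read back annotations written by :func:`write_gff3`."""
    from .model import GenomicInterval

    genes: dict = {}
    order: List[str] = []
    with open(path) as fh:
        for raw in fh:
            if raw.startswith("#") or not raw.strip():
                continue
            cols = raw.rstrip("\n").split("\t")
            if len(cols) != 9:
                raise ValueError(f"malformed GFF3 line: {raw!r}")
            seq_id, _, ftype, start, end, _, strand, _, attr_str = cols
            attrs = dict(kv.split("=", 1) for kv in attr_str.split(";") if "=" in kv)
            iv = GenomicInterval(seq_id, int(start), int(end), strand)
            if ftype == "gene":
                g = GeneAnnotation(
                    name=attrs["ID"],
                    gene_type=attrs["gene_type"],
                    exons=[],
                    functionality=attrs.get("functionality", "F"),
                    defects=attrs.get("defects", "").split("|") if attrs.get("defects") else [],
                    rescued_by_cdna=attrs.get("rescued_by_cdna") == "true",
                    subgroup=attrs.get("subgroup"),
                    cassette=attrs.get("cassette"),
                )
                genes[g.name] = g
                order.append(g.name)
            elif ftype == "exon":
                parent = attrs["Parent"]
                genes[parent].exons.append((attrs.get("exon_label", "EXON"), iv))
    return [genes[name] for name in order]


# ---------------------------------------------------------------------------
# Newick

_BL_FORMAT = "%0.10f"


def read_newick(path) -> dendropy.Tree:
    return dendropy.Tree.get(path=str(path), schema="newick", preserve_underscores=True)


def write_newick(tree: dendropy.Tree, path) -> None:
    """Write Newick with branch lengths at fixed precision (round-trip stable)."""
    txt = tree.as_string(
        schema="newick",
        real_value_format_specifier=".10f",
        suppress_rooting=True,
        unquoted_underscores=True,
    )
    with open(path, "w") as fh:
        fh.write(txt)
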