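"""Rearranged cDNA analysis: V-J-C assignment, junctions, primers.

Each rearranged transcript is matched against the germline gene set: the best
local (infix) alignment per gene type assigns the V, J and C genes, the bases
strictly between the V and J matches form the junction, and cassette
membership of the assigned genes tests the intra-cassette rearrangement
preference and C-proximal splicing that characterize cassette-organized TRG
loci.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import edlib
import numpy as np
import pandas as pd

from .model import Cassette, GenomicInterval, MotifHit, SequenceRecord, reverse_complement

#: standard IUPAC nucleotide degeneracies
IUPAC_CODES: Dict[str, frozenset] = {
    "A": frozenset("A"), "C": frozenset("C"), "G": frozenset("G"), "T": frozenset("T"),
    "R": frozenset("AG"), "Y": frozenset("CT"), "S": frozenset("CG"), "W": frozenset("AT"),
    "K": frozenset("GT"), "M": frozenset("AC"), "B": frozenset("CGT"), "D": frozenset("AGT"),
    "H": frozenset("ACT"), "V": frozenset("ACG"), "N": frozenset("ACGT"),
}


@dataclass
class DegeneratePrimer:
    """A primer whose pattern may use degenerate codes.

    ``code_map`` defaults to IUPAC but can be overridden to honor a primer's
    own printed definition when it deviates (such definitions win over the
    standard table, because they describe what was actually synthesized).
    """

    name: str
    pattern: str
    code_map: Dict[str, frozenset] = field(default_factory=lambda: dict(IUPAC_CODES))

    def __post_init__(self) -> None:
        missing = [c for c in self.pattern.upper() if c not in self.code_map]
        if missing:
            raise ValueError(f"pattern characters without code_map entry: {missing}")


@dataclass
class GeneMatch:
    gene: str
    identity: float
    start: int  # 0-based half-open on the cDNA
    end: int
    mismatches: List[Tuple[int, str, str]] = field(default_factory=list)


@dataclass
class TranscriptAssignment:
    """One cDNA's V/J/C call with junction and cassette bookkeeping."""

    cdna_id: str
    v: Optional[GeneMatch] = None
    j: Optional[GeneMatch] = None
    c: Optional[GeneMatch] = None
    junction: str = ""
    intra_cassette: Optional[bool] = None
    c_is_j_proximal: Optional[bool] = None

    @property
    def mismatches(self) -> List[Tuple[str, int, str, str]]:
        out = []
        for m in (self.v, self.j, self.c):
            if m is not None:
                out.extend((m.gene, pos, g, o) for pos, g, o in m.mismatches)
        return out


def _best_infix(germline: str, cdna: str):
    """Best infix placement of a germline segment in a cDNA.

    Returns (identity, start, end0, mismatches) where identity is relative to
    the germline length and mismatches lists (germline position 1-based,
    germline base, observed base) for substitution columns.
    """
    res = edlib.align(germline, cdna, mode="HW", task="path")
    if res["editDistance"] < 0:
        return None
    identity = 1.0 - res["editDistance"] / len(germline)
    s, e = res["locations"][0]
    mismatches = []
    qpos = 0
    tpos = s
    import re as _re

    for n, op in _re.findall(r"(\d+)([=XID])", res["cigar"]):
        n = int(n)
        if op == "=":
            qpos += n
            tpos += n
        elif op == "X":
            for k in range(n):
                mismatches.append((qpos + k + 1, germline[qpos + k], cdna[tpos + k]))
            qpos += n
            tpos += n
        elif op == "D":  # gap in target: germline bases unmatched
            qpos += n
        else:  # I: extra target bases
            tpos += n
    return identity, s, e + 1, mismatches


def assign_transcript(
    cdna: SequenceRecord,
    germline: Dict[str, Dict[str, str]],
    cassettes: Sequence[Cassette] = (),
    gene_order: Sequence[str] = (),
    min_identity: float = 0.85,
    min_coverage: float = 0.80,
) -> TranscriptAssignment:
    """Assign a rearranged cDNA to germline V, J and C genes.

    ``germline`` maps gene type ('V'/'J'/'C') to {gene name: coding sequence}.
    The best-identity gene per type wins if it reaches ``min_identity`` over at
    least ``min_coverage`` of the germline segment (full-segment infix
    alignment pays for truncation beyond 1-coverage, which enforces this).
    The junction is the cDNA between the V and J matches; ``intra_cassette``
    says whether V and J share a cassette; ``c_is_j_proximal`` whether the
    assigned C is the first C downstream of the assigned J in genomic order.
    """
    for gtype in "VJC":
        if not germline.get(gtype):
            raise ValueError(f"germline set has no {gtype} genes")
    text = cdna.residues.upper()
    out = TranscriptAssignment(cdna.id)
    del min_coverage  # implied: the infix alignment spans the full segment
    for gtype, slot in (("V", "v"), ("J", "j"), ("C", "c")):
        best_gene, best_ident = None, -1.0
        for gene, seq in germline[gtype].items():
            res = edlib.align(seq.upper(), text, mode="HW", task="distance")
            if res["editDistance"] < 0:
                continue
            identity = 1.0 - res["editDistance"] / len(seq)
            if identity >= min_identity and identity > best_ident:
                best_gene, best_ident = gene, identity
        if best_gene is not None:
            identity, s, e, mm = _best_infix(germline[gtype][best_gene].upper(), text)
            setattr(out, slot, GeneMatch(best_gene, identity, s, e, mm))
    if out.v and out.j:
        out.junction = text[out.v.end : out.j.start] if out.j.start > out.v.end else ""
        cas_of = {}
        for cas in cassettes:
            for g in cas.genes:
                cas_of[g.name] = cas.name
        if out.v.gene in cas_of and out.j.gene in cas_of:
            out.intra_cassette = cas_of[out.v.gene] == cas_of[out.j.gene]
    if out.j and out.c and cassettes:
        names = list(gene_order) or [g.name for cas in cassettes for g in cas.genes]
        c_names = {cas.c_gene.name for cas in cassettes}
        if out.j.gene in names:
            downstream = names[names.index(out.j.gene) + 1 :]
            first_c = next((g for g in downstream if g in c_names), None)
            out.c_is_j_proximal = first_c == out.c.gene
    return out


def assign_repertoire(
    cdnas: Sequence[SequenceRecord],
    germline: Dict[str, Dict[str, str]],
    cassettes: Sequence[Cassette] = (),
    gene_order: Sequence[str] = (),
    min_identity: float = 0.85,
) -> List[TranscriptAssignment]:
    return [
        assign_transcript(c, germline, cassettes, gene_order, min_identity) for c in cdnas
    ]


def repertoire_summary(
    assignments: Sequence[TranscriptAssignment],
    sequences: Optional[Dict[str, str]] = None,
) -> Dict[str, object]:
    """Summarize a repertoire: V x J usage, cassette preference, redundancy.

    Returns a dict with a ``vj_counts`` DataFrame, the intra-cassette fraction
    with a normal-approximation 95% confidence interval, the C-proximal
    fraction, and the distinct-transcript count after exact-sequence
    deduplication (requires ``sequences``: cdna id -> sequence).
    """
    if not assignments:
        raise ValueError("no assignments to summarize")
    rows = [
        {
            "cdna": a.cdna_id,
            "v": a.v.gene if a.v else None,
            "j": a.j.gene if a.j else None,
            "c": a.c.gene if a.c else None,
            "intra": a.intra_cassette,
            "c_proximal": a.c_is_j_proximal,
        }
        for a in assignments
    ]
    df = pd.DataFrame(rows)
    vj = df.dropna(subset=["v", "j"]).groupby(["v", "j"]).size().rename("count").reset_index()
    flagged = df["intra"].dropna()
    n = len(flagged)
    frac = float(flagged.mean()) if n else float("nan")
    if n:
        se = float(np.sqrt(max(frac * (1 - frac), 0.0) / n))
        ci = (max(0.0, frac - 1.96 * se), min(1.0, frac + 1.96 * se))
    else:
        ci = (float("nan"), float("nan"))
    prox = df["c_proximal"].dropna()
    out: Dict[str, object] = {
        "n": len(df),
        "vj_counts": vj,
        "intra_cassette_fraction": frac,
        "intra_cassette_ci95": ci,
        "c_proximal_fraction": float(prox.mean()) if len(prox) else float("nan"),
    }
    if sequences is not None:
        out["distinct_transcripts"] = len({
            sequences[a.cdna_id].upper() for a in assignments if a.cdna_id in sequences
        })
    return out


def match_primer(
    seq: SequenceRecord,
    primer: DegeneratePrimer,
    max_mismatch: int = 0,
) -> List[MotifHit]:
    """All placements of a degenerate primer on both strands.

    A position matches when every pattern character admits the target base
    (per the primer's code_map), allowing at most ``max_mismatch`` exceptions.
    Reverse-strand hits are reported in forward coordinates with strand '-'.
    """
    pattern = primer.pattern.upper()
    if not pattern:
        raise ValueError("empty primer pattern")
    allowed = [primer.code_map[c] for c in pattern]
    L = len(pattern)
    hits: List[MotifHit] = []
    for strand in "+-":
        text = seq.residues.upper() if strand == "+" else reverse_complement(seq.residues).upper()
        for i in range(len(text) - L + 1):
            mism = 0
            for k in range(L):
                if text[i + k] not in allowed[k]:
                    mism += 1
                    if mism > max_mismatch:
                        break
            else:
                if strand == "+":
                    iv = GenomicInterval(seq.id, i + 1, i + L, "+")
                else:
                    iv = GenomicInterval(seq.id, len(text) - (i + L) + 1, len(text) - i, "-")
                hits.append(MotifHit(primer.pattern, iv, text[i : i + L]))
    return sorted(hits, key=lambda h: (h.interval.start, h.interval.strand))


# the published RACE primers for this locus family; GL2L's printed definition
# of Y (A or G) deviates from IUPAC and is honored as printed
GL1L = DegeneratePrimer("GL1L", "TCCAGAAGACAAAGGTATGTTCCA")
GL1LBIS = DegeneratePrimer("GL1Lbis", "TCAAGAAGACAAAGATGTGTCCCA")
GL2L = DegeneratePrimer(
    "GL2L",
    "TATYTCAGCAATYGAAGGAAG",
    code_map={**IUPAC_CODES, "Y": frozenset("AG")},
)
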