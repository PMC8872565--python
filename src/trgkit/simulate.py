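"""Synthetic TR-gamma-like loci with known truth.

The generator emulates the cassette organization of cetartiodactyl TRG loci:
tandem V-J-(J)-C units, each V with a leader exon (L-PART1) and a 3' 23-RS,
each J with a 5' 12-RS, a terminal FGXG motif and a 3' donor site, each C with
EX1 / 1-3 EX2 copies / EX3, plus a germline J promoter (PJ) upstream of the
C-distal J and an enhancer-like element (En) ~2 kb downstream of C, both
carrying a STAT consensus motif (TTCNNNGAA).

Divergence between cassette copies is truth-preserving: every copy derives
from a common ancestor by random substitution, but positions that define gene
identity (RS motifs, splice dinucleotides, initiation codon, J motif codons,
STAT cores, the terminator) are protected, and substitutions that would create
an in-frame stop codon in a coding exon, a decoy splice dinucleotide next to a
real one, or a consensus RS heptamer anywhere are vetoed. This encodes the
purifying selection that keeps real functional genes recognizable, and it is
what makes exact annotation recovery a well-defined expectation. Planted
defects are applied after divergence, so each defect is the only functional
lesion its gene carries.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .model import Cassette, GeneAnnotation, GenomicInterval, RSSignal, SequenceRecord

STOP_CODONS = {"TAA", "TAG", "TGA"}
HEPTAMER = "CACAGTG"
NONAMER = "ACAAAAACC"
BASES = "ACGT"

DEFECT_KINDS = {
    "stop_codon",
    "frameshift",
    "frameshift_leader",
    "rs_heptamer_core",
    "j_motif_second_position",
    "donor_site",
}

#: functionality implied by each planted defect kind (IMGT-style rules)
DEFECT_FUNCTIONALITY = {
    "stop_codon": "P",
    "frameshift": "P",
    "frameshift_leader": "P",
    "rs_heptamer_core": "ORF",
    "j_motif_second_position": "ORF",
    "donor_site": "ORF",
}


class SpecError(ValueError):
    pass


@dataclass
class LocusSpec:
    """Blueprint for one synthetic locus.

    Geometry defaults follow the stated J length range (51 nt is within the
    observed 49-60 bp) and typical TR gene sizes (45-nt leader, ~300-nt V
    exon); all are configurable.
    """

    n_cassettes: int = 4
    v_per_cassette: Sequence[int] = (5, 1, 1, 1)
    j_per_cassette: Sequence[int] = (2, 2, 1, 1)
    ex2_copies_per_cassette: Optional[Sequence[int]] = None
    divergence: float = 0.10
    indel_rate: float = 0.0
    defect_plan: Sequence[Tuple[str, str]] = ()
    intergenic_len: int = 2000
    seed: int = 0
    # geometry (nt)
    leader_len: int = 45
    v_exon_len: int = 300
    v_intron_len: int = 100
    j_len: int = 51
    c_ex1_len: int = 330
    c_ex2_len: int = 60
    c_ex3_len: int = 450
    c_intron_len: int = 120
    pj_len: int = 600
    en_len: int = 770
    en_offset: int = 2000
    # which V "family" (ancestral subgroup) each V slot derives from; default is
    # positional: slot i of every cassette shares family i, so zero-divergence
    # cassette copies are character-identical.
    v_family_plan: Optional[Sequence[Sequence[int]]] = None

    def __post_init__(self) -> None:
        if self.n_cassettes < 1:
            raise SpecError("n_cassettes must be >= 1")
        if len(self.v_per_cassette) != self.n_cassettes:
            raise SpecError("v_per_cassette length must equal n_cassettes")
        if len(self.j_per_cassette) != self.n_cassettes:
            raise SpecError("j_per_cassette length must equal n_cassettes")
        if any(j < 1 for j in self.j_per_cassette):
            raise SpecError("each cassette needs at least one J gene")
        if self.ex2_copies_per_cassette is None:
            self.ex2_copies_per_cassette = [1] + [3] * (self.n_cassettes - 1)
        if len(self.ex2_copies_per_cassette) != self.n_cassettes:
            raise SpecError("ex2_copies_per_cassette length must equal n_cassettes")
        if any(k not in (1, 2, 3) for k in self.ex2_copies_per_cassette):
            raise SpecError("EX2 copy numbers must be 1, 2 or 3")
        if not (0.0 <= self.divergence <= 0.5):
            raise SpecError("divergence must be in [0, 0.5]")
        if self.v_family_plan is None:
            self.v_family_plan = [list(range(nv)) for nv in self.v_per_cassette]
        for kind in (k for _, k in self.defect_plan):
            if kind not in DEFECT_KINDS:
                raise SpecError(f"unknown defect kind {kind!r}")
        for ln in (self.leader_len, self.v_exon_len, self.j_len, self.c_ex1_len,
                   self.c_ex2_len, self.c_ex3_len):
            if ln % 3 != 0:
                raise SpecError("coding segment lengths must be multiples of 3")

    def gene_names(self) -> List[str]:
        names = []
        for c in range(self.n_cassettes):
            names += [f"V{c + 1}-{i + 1}" for i in range(self.v_per_cassette[c])]
            names += [f"J{c + 1}-{i + 1}" for i in range(self.j_per_cassette[c])]
            names.append(f"C{c + 1}")
        return names


@dataclass
class TranscriptTruth:
    cdna_id: str
    v: str
    j: str
    c: str
    junction: str


@dataclass
class TruthSet:
    """Ground truth emitted alongside a synthetic locus."""

    genes: List[GeneAnnotation] = field(default_factory=list)
    cassettes: List[Cassette] = field(default_factory=list)
    regulatory: List[Tuple[str, GenomicInterval]] = field(default_factory=list)
    transcripts: List[TranscriptTruth] = field(default_factory=list)
    locus: Optional[SequenceRecord] = None
    c_exon_reference: List[SequenceRecord] = field(default_factory=list)
    pj_reference: Optional[SequenceRecord] = None
    en_reference: Optional[SequenceRecord] = None
    v_subgroups: Dict[str, str] = field(default_factory=dict)

    def gene(self, name: str) -> GeneAnnotation:
        for g in self.genes:
            if g.name == name:
                return g
        raise KeyError(name)

    def coding_sequence(self, name: str) -> str:
        return self.gene(name).coding_sequence(self.locus.residues)

    def cassette_of(self, gene_name: str) -> str:
        for cas in self.cassettes:
            if any(g.name == gene_name for g in cas.genes):
                return cas.name
        raise KeyError(gene_name)

    def subgroup_partition(self) -> List[List[str]]:
        """Planted V subgroup partition, ordered by genomic position."""
        order = [g.name for g in self.genes if g.gene_type == "V"]
        groups: Dict[str, List[str]] = {}
        for name in order:
            groups.setdefault(self.v_subgroups[name], []).append(name)
        return sorted(groups.values(), key=lambda ms: order.index(ms[0]))


# ---------------------------------------------------------------------------
# sequence parts


@dataclass
class _Part:
    kind: str
    seq: List[str]
    gene: Optional[str] = None
    exon_label: Optional[str] = None
    frame: Optional[int] = None  # codon frame offset; enables stop-codon vetoes
    protected: set = field(default_factory=set)
    forbidden: Tuple[str, ...] = ()
    allow_indels: bool = False
    cassette: Optional[int] = None

    def clone(self) -> "_Part":
        return _Part(
            self.kind, list(self.seq), self.gene, self.exon_label, self.frame,
            set(self.protected), self.forbidden, self.allow_indels, self.cassette,
        )

    def text(self) -> str:
        return "".join(self.seq)


# every background part must stay free of a consensus RS heptamer: a cryptic
# consensus signal inside the locus would be targeted by the recombination
# machinery (and would make the planted annotation ambiguous).
_GLOBAL_FORBIDDEN = (HEPTAMER,)


def _pattern_at(seq: List[str], pat: str, around: int) -> bool:
    lo = max(0, around - len(pat) + 1)
    hi = min(len(seq) - len(pat), around)
    window = "".join(seq[lo : hi + len(pat)])
    return pat in window


def _violates(part: _Part, i: int) -> bool:
    for pat in part.forbidden + _GLOBAL_FORBIDDEN:
        if _pattern_at(part.seq, pat, i):
            return True
    if part.frame is not None:
        ci = (i - part.frame) // 3
        start = part.frame + 3 * ci
        if 0 <= start and start + 3 <= len(part.seq):
            if "".join(part.seq[start : start + 3]) in STOP_CODONS:
                return True
    return False


def _scrub(part: _Part, rng: np.random.Generator) -> None:
    """Resample positions until the part satisfies its own constraints."""
    for _ in range(40):
        dirty = [i for i in range(len(part.seq)) if i not in part.protected and _violates(part, i)]
        if not dirty:
            return
        for i in dirty:
            part.seq[i] = BASES[rng.integers(4)]
    raise RuntimeError("could not scrub part; constraints too tight")


def _rand_part(rng, kind, n, *, forbidden=(), frame=None, allow_indels=False, **kw) -> _Part:
    seq = [BASES[b] for b in rng.integers(0, 4, size=n)]
    part = _Part(kind, seq, forbidden=tuple(forbidden), frame=frame, allow_indels=allow_indels, **kw)
    _scrub(part, rng)
    return part


def _coding_part(rng, kind, n, **kw) -> _Part:
    part = _rand_part(rng, kind, n, frame=0, **kw)
    return part


def _fixed_part(kind, text, *, protect_all=True, **kw) -> _Part:
    part = _Part(kind, list(text), **kw)
    if protect_all:
        part.protected = set(range(len(text)))
    return part


def _mutate(part: _Part, rng: np.random.Generator, sub_rate: float, indel_rate: float) -> None:
    n = len(part.seq)
    if sub_rate > 0:
        hits = np.nonzero(rng.random(n) < sub_rate)[0]
        for i in hits:
            i = int(i)
            if i in part.protected:
                continue
            old = part.seq[i]
            alt = [b for b in BASES if b != old]
            part.seq[i] = alt[rng.integers(3)]
            if _violates(part, i):
                part.seq[i] = old
    if indel_rate > 0 and part.allow_indels:
        out: List[str] = []
        for i, ch in enumerate(part.seq):
            if i in part.protected:
                out.append(ch)
                continue
            r = rng.random()
            if r < indel_rate / 2:
                continue  # deletion
            out.append(ch)
            if r >= indel_rate / 2 and r < indel_rate:
                out.append(BASES[rng.integers(4)])  # insertion
        probe = _Part(part.kind, out, forbidden=part.forbidden)
        _scrub(probe, rng)
        part.seq = probe.seq
        part.protected = set()  # indel parts carry no protected signal


# ---------------------------------------------------------------------------
# ancestor templates


def _ancestor_v_block(rng, spec: LocusSpec) -> List[_Part]:
    # the pad upstream of the leader is kept free of decoy ATG / GT so the
    # leader's initiation codon and donor are the unique solutions in range
    pad = _rand_part(rng, "pad", 80, forbidden=("ATG", "GT"))
    # the leader itself carries no decoy GT, so its donor is the unique one
    leader = _coding_part(rng, "leader", spec.leader_len, forbidden=("GT",))
    leader.seq[0:3] = list("ATG")
    leader.protected |= {0, 1, 2}
    _scrub(leader, rng)
    intron = _rand_part(rng, "intron", spec.v_intron_len - 14, forbidden=("AG", "GT"))
    tract = _fixed_part("tract", "TTCTTCCTTC")  # polypyrimidine tract
    donor = _fixed_part("donor", "GT")
    acceptor = _fixed_part("acceptor", "AG")
    vexon = _coding_part(rng, "vexon", spec.v_exon_len)
    spacer23 = _rand_part(rng, "rs_spacer", 23)
    rs = _Part(
        "rs23",
        list(HEPTAMER) + spacer23.seq + list(NONAMER),
        protected=set(range(7)) | set(range(30, 39)),
    )
    vsep = _rand_part(rng, "spacer", 150, allow_indels=True)
    parts = [pad, leader, donor, intron, tract, acceptor, vexon, rs, vsep]
    return parts


def _ancestor_j_block(rng, spec: LocusSpec) -> List[_Part]:
    spacer12 = _rand_part(rng, "rs_spacer", 12)
    rs = _Part(
        "rs12",
        list(HEPTAMER) + spacer12.seq + list(NONAMER),
        protected=set(range(7)) | set(range(19, 28)),
    )
    j = _coding_part(rng, "j", spec.j_len - 12)
    # canonical FGXG motif at the very 3' end (F G S G), followed by the donor
    motif = _Part("jmotif", list("TTTGGAAGCGGA"), frame=0, protected=set(range(12)))
    donor = _fixed_part("jdonor", "GT")
    # the donor neighborhood stays free of decoy GT so the donor is unambiguous
    jspacer = _rand_part(rng, "jspacer", 120, forbidden=("GT",), allow_indels=True)
    return [rs, j, motif, donor, jspacer]


def _c_intron(rng, spec: LocusSpec) -> List[_Part]:
    body = _rand_part(rng, "cintron", spec.c_intron_len - 4)
    return [_fixed_part("donor", "GT"), body, _fixed_part("acceptor", "AG")]


def _ancestor_c_block(rng, spec: LocusSpec) -> Dict[str, List[_Part]]:
    cpre = _rand_part(rng, "spacer", 150, allow_indels=True)
    ex1 = _coding_part(rng, "cexon", spec.c_ex1_len)
    ex1.exon_label = "EX1"
    ex2 = _coding_part(rng, "cexon", spec.c_ex2_len)
    ex2.exon_label = "EX2"
    ex3 = _coding_part(rng, "cexon", spec.c_ex3_len - 3)
    stop = _Part("cstop", list("TAA"), protected={0, 1, 2}, exon_label="EX3STOP")
    ex3.exon_label = "EX3"
    return {
        "cpre": [cpre],
        "EX1": [ex1],
        "EX2": [ex2],
        "EX3": [ex3, stop],
        "intron": _c_intron(rng, spec),
    }


def _ancestor_regulatory(rng, spec: LocusSpec):
    def with_stat(kind: str, n: int, core_at: int) -> _Part:
        p = _rand_part(rng, kind, n, allow_indels=True)
        stat = "TTC" + "".join(BASES[b] for b in rng.integers(0, 4, 3)) + "GAA"
        p.seq[core_at : core_at + 9] = list(stat)
        p.protected |= {core_at + k for k in (0, 1, 2, 6, 7, 8)}
        return p

    pj = with_stat("pj", spec.pj_len, spec.pj_len // 2)
    en = with_stat("en", spec.en_len, spec.en_len // 2)
    return pj, en


# ---------------------------------------------------------------------------
# defects


def _apply_defect(parts_by_gene: Dict[str, List[_Part]], gene: str, kind: str,
                  rng: np.random.Generator) -> None:
    parts = parts_by_gene.get(gene)
    if parts is None:
        raise SpecError(f"defect on nonexistent gene {gene!r}")
    by_kind: Dict[str, _Part] = {}
    for p in parts:
        by_kind.setdefault(p.kind, p)  # first occurrence (EX1 for C exons)

    def coding(kinds):
        for k in kinds:
            if k in by_kind:
                return by_kind[k]
        raise SpecError(f"gene {gene!r} has no coding part for defect {kind!r}")

    if kind == "stop_codon":
        part = coding(["vexon", "j", "cexon"])
        ci = min(20, len(part.seq) // 3 - 2)
        part.seq[3 * ci : 3 * ci + 3] = list("TAA")
    elif kind == "frameshift":
        part = coding(["vexon", "cexon", "j"])
        if part.kind == "cexon":
            del part.seq[min(113, len(part.seq) - 2)]
        else:
            # pick a deletion point whose shifted tail stays nearly stop-free,
            # as a frameshift surviving in a gene implies it arose recently
            for pos in range(len(part.seq) - 45, len(part.seq) - 5, 3):
                tail = "".join(part.seq[:pos] + part.seq[pos + 1 :])[pos:]
                stops = sum(
                    tail[i : i + 3] in STOP_CODONS for i in range(0, len(tail) - 2, 3)
                )
                if stops <= 2:
                    del part.seq[pos]
                    break
            else:
                del part.seq[len(part.seq) - 6]
        part.frame = None  # frame is broken by design now
    elif kind == "frameshift_leader":
        part = coding(["leader"])
        del part.seq[30]
        part.frame = None
    elif kind == "rs_heptamer_core":
        part = by_kind.get("rs23") or by_kind.get("rs12")
        if part is None:
            raise SpecError(f"gene {gene!r} has no RS for defect {kind!r}")
        part.seq[0] = "T"  # CAC... -> TAC...
    elif kind == "j_motif_second_position":
        part = by_kind.get("jmotif")
        if part is None:
            raise SpecError(f"defect {kind!r} requires a J gene, got {gene!r}")
        part.seq[3:6] = list("GCA")  # G -> A in the second motif position
    elif kind == "donor_site":
        part = by_kind.get("donor") or by_kind.get("jdonor")
        if part is None:
            raise SpecError(f"gene {gene!r} has no donor site for defect {kind!r}")
        part.seq[0:2] = list("GC")


# ---------------------------------------------------------------------------
# main generator


def generate_locus(spec: LocusSpec) -> Tuple[SequenceRecord, TruthSet]:
    """Emit a synthetic locus and its complete ground truth.

    Byte-identical output for identical (spec, seed); with ``divergence=0`` and
    ``indel_rate=0`` all cassette copies of equal composition are identical
    strings.
    """
    rng = np.random.default_rng(spec.seed)
    defect_map: Dict[str, List[str]] = {}
    known = set(spec.gene_names())
    for gene, kind in spec.defect_plan:
        if gene not in known:
            raise SpecError(f"defect on nonexistent gene {gene!r}")
        defect_map.setdefault(gene, []).append(kind)

    n_families = max((max(fams) for fams in spec.v_family_plan if fams), default=-1) + 1
    v_ancestors = [_ancestor_v_block(rng, spec) for _ in range(n_families)]
    j_ancestor = _ancestor_j_block(rng, spec)
    c_ancestor = _ancestor_c_block(rng, spec)
    pj_anc, en_anc = _ancestor_regulatory(rng, spec)
    pj_pre = _rand_part(rng, "spacer", 200, allow_indels=True)
    pj_post = _rand_part(rng, "spacer", 150, allow_indels=True)
    en_gap = _rand_part(rng, "spacer", spec.en_offset, allow_indels=True)
    tail = _rand_part(rng, "spacer", 200, allow_indels=True)

    def instantiate(template: List[_Part], gene=None, cassette=None) -> List[_Part]:
        out = []
        for p in template:
            q = p.clone()
            q.gene = gene
            q.cassette = cassette
            _mutate(q, rng, spec.divergence, spec.indel_rate)
            out.append(q)
        return out

    all_parts: List[_Part] = []
    parts_by_gene: Dict[str, List[_Part]] = {}
    all_parts += instantiate([_rand_part(rng, "spacer", spec.intergenic_len, allow_indels=True)])

    for c in range(spec.n_cassettes):
        for vi in range(spec.v_per_cassette[c]):
            name = f"V{c + 1}-{vi + 1}"
            fam = spec.v_family_plan[c][vi]
            block = instantiate(v_ancestors[fam], gene=name, cassette=c)
            parts_by_gene[name] = block
            all_parts += block
        all_parts += instantiate([pj_pre], cassette=c)
        pj_parts = instantiate([pj_anc], cassette=c)
        all_parts += pj_parts
        all_parts += instantiate([pj_post], cassette=c)
        for ji in range(spec.j_per_cassette[c]):
            name = f"J{c + 1}-{ji + 1}"
            block = instantiate(j_ancestor, gene=name, cassette=c)
            parts_by_gene[name] = block
            all_parts += block
        cname = f"C{c + 1}"
        cblock = instantiate(c_ancestor["cpre"], cassette=c)
        cblock += instantiate(c_ancestor["EX1"], gene=cname, cassette=c)
        n_ex2 = spec.ex2_copies_per_cassette[c]
        for k in range(n_ex2):
            cblock += instantiate(c_ancestor["intron"], gene=cname, cassette=c)
            ex2 = instantiate(c_ancestor["EX2"], gene=cname, cassette=c)
            ex2[0].exon_label = "EX2" + "ABC"[k]
            cblock += ex2
        cblock += instantiate(c_ancestor["intron"], gene=cname, cassette=c)
        cblock += instantiate(c_ancestor["EX3"], gene=cname, cassette=c)
        parts_by_gene[cname] = [p for p in cblock if p.gene == cname]
        all_parts += cblock
        all_parts += instantiate([en_gap], cassette=c)
        all_parts += instantiate([en_anc], cassette=c)
        all_parts += instantiate([tail], cassette=c)

    all_parts += instantiate([_rand_part(rng, "spacer", spec.intergenic_len, allow_indels=True)])

    for gene, kinds in defect_map.items():
        for kind in kinds:
            _apply_defect(parts_by_gene, gene, kind, rng)

    return _assemble(spec, all_parts, defect_map)


def _assemble(spec: LocusSpec, parts: List[_Part], defect_map) -> Tuple[SequenceRecord, TruthSet]:
    from .annotate import score_rs  # local import; annotate does not import simulate

    seq_id = "synthetic_locus"
    chunks: List[str] = []
    pos = 1  # next 1-based coordinate
    exon_ivs: Dict[str, List[Tuple[str, GenomicInterval]]] = {}
    rs_by_gene: Dict[str, RSSignal] = {}
    gene_order: List[str] = []
    gene_cassette: Dict[str, int] = {}
    regulatory: List[Tuple[str, GenomicInterval]] = []
    reg_by_cassette: Dict[int, Dict[str, GenomicInterval]] = {}

    for part in parts:
        text = part.text()
        iv = GenomicInterval(seq_id, pos, pos + len(text) - 1) if text else None
        chunks.append(text)
        pos += len(text)
        if part.gene and part.gene not in gene_order:
            gene_order.append(part.gene)
            gene_cassette[part.gene] = part.cassette
        if part.kind in ("rs23", "rs12") and part.gene:
            rs_by_gene[part.gene] = _rs_signal(part, iv, score_rs)
        if part.exon_label and part.gene:
            if part.exon_label == "EX3STOP":
                # extend the preceding EX3 interval to include the terminator
                lab, prev = exon_ivs[part.gene][-1]
                exon_ivs[part.gene][-1] = (
                    lab,
                    GenomicInterval(seq_id, prev.start, iv.end),
                )
            else:
                exon_ivs.setdefault(part.gene, []).append((part.exon_label, iv))
        elif part.kind == "leader" and part.gene:
            exon_ivs.setdefault(part.gene, []).append(("L-PART1", iv))
        elif part.kind == "vexon" and part.gene:
            exon_ivs.setdefault(part.gene, []).append(("V-EXON", iv))
        elif part.kind in ("j", "jmotif") and part.gene:
            prev = exon_ivs.setdefault(part.gene, [])
            if prev and prev[-1][0] == "J-REGION":
                lab, old = prev[-1]
                prev[-1] = (lab, GenomicInterval(seq_id, old.start, iv.end))
            else:
                prev.append(("J-REGION", iv))
        if part.kind in ("pj", "en") and iv is not None:
            kind = "PJ" if part.kind == "pj" else "En"
            regulatory.append((kind, iv))
            reg_by_cassette.setdefault(part.cassette, {})[kind] = iv

    residues = "".join(chunks)
    record = SequenceRecord(seq_id, residues, "synthetic TRG-like locus")

    truth = TruthSet(locus=record, regulatory=regulatory)
    genes_by_name: Dict[str, GeneAnnotation] = {}
    for name in gene_order:
        gtype = name[0]
        defects = list(defect_map.get(name, []))
        functionality = "F"
        for kind in defects:
            grade = DEFECT_FUNCTIONALITY[kind]
            if grade == "P" or functionality == "F":
                functionality = grade
        gene = GeneAnnotation(
            name=name,
            gene_type=gtype,
            exons=exon_ivs[name],
            rs=rs_by_gene.get(name),
            functionality=functionality,
            defects=defects,
            cassette=f"cas{gene_cassette[name] + 1}",
        )
        genes_by_name[name] = gene
        truth.genes.append(gene)

    for c in range(spec.n_cassettes):
        members = [g for g in truth.genes if gene_cassette[g.name] == c]
        regs = reg_by_cassette.get(c, {})
        truth.cassettes.append(
            Cassette(f"cas{c + 1}", members, pj=regs.get("PJ"), en=regs.get("En"))
        )

    for c, fams in enumerate(spec.v_family_plan):
        for vi, fam in enumerate(fams):
            truth.v_subgroups[f"V{c + 1}-{vi + 1}"] = f"SG{fam + 1}"

    truth.c_exon_reference = _reference_exons(spec, parts)
    truth.pj_reference, truth.en_reference = _reference_regulatory(parts)
    return record, truth


def _rs_signal(part: _Part, iv: GenomicInterval, score_rs) -> RSSignal:
    text = part.text()
    spacer_class = 23 if part.kind == "rs23" else 12
    heptamer, nonamer = text[:7], text[-9:]
    spacer_len = len(text) - 16
    score, motif_score, core = score_rs(heptamer, spacer_len, nonamer, spacer_class)
    return RSSignal(heptamer, spacer_len, nonamer, iv, score, core,
                    motif_score=motif_score, spacer_class=spacer_class)


def _reference_exons(spec: LocusSpec, parts: List[_Part]) -> List[SequenceRecord]:
    """First-cassette copies of the C exons, usable as a reference library."""
    refs: Dict[str, str] = {}
    stop = ""
    for part in parts:
        if part.cassette != 0 or not part.gene or not part.gene.startswith("C"):
            continue
        if part.exon_label == "EX3STOP":
            stop = part.text()
        elif part.exon_label:
            label = "EX2" if part.exon_label.startswith("EX2") else part.exon_label
            refs.setdefault(label, part.text())
    if "EX3" in refs:
        refs["EX3"] = refs["EX3"] + stop
    return [SequenceRecord(label, seq) for label, seq in sorted(refs.items())]


def _reference_regulatory(parts: List[_Part]):
    pj = en = None
    for part in parts:
        if part.cassette == 0 and part.kind == "pj" and pj is None:
            pj = SequenceRecord("PJ_ref", part.text())
        if part.cassette == 0 and part.kind == "en" and en is None:
            en = SequenceRecord("En_ref", part.text())
    return pj, en


# ---------------------------------------------------------------------------
# repertoire simulation


def generate_repertoire(
    truth: TruthSet,
    n: int,
    trans_cassette_rate: float = 0.25,
    junction_insert_max: int = 5,
    seed: int = 0,
    trim_max: int = 0,
) -> List[SequenceRecord]:
    """Simulate rearranged V-J-C transcripts constrained by cassette membership.

    Each transcript is the spliced V coding sequence, a junction of
    0..junction_insert_max random inserted bases, a J segment and the coding
    sequence of the C gene proximal to that J. With probability
    ``trans_cassette_rate`` the J (and therefore its C) come from a different
    cassette than the V. Only cassettes with at least one functional V, J and C
    contribute. Generating genes are recorded in ``truth.transcripts``.
    """
    if n < 0:
        raise SpecError("n must be >= 0")
    rng = np.random.default_rng(seed)
    locus = truth.locus.residues

    eligible = []
    for cas in truth.cassettes:
        vs = [g for g in cas.v_genes if g.functionality == "F"]
        js = [g for g in cas.j_genes if g.functionality == "F"]
        if vs and js and cas.c_gene.functionality == "F":
            eligible.append((cas, vs, js))
    if not eligible:
        raise SpecError("no cassette has a functional V, J and C gene")

    out: List[SequenceRecord] = []
    truth.transcripts = []
    for i in range(n):
        ci = int(rng.integers(len(eligible)))
        cas, vs, js = eligible[ci]
        v = vs[int(rng.integers(len(vs)))]
        trans = len(eligible) > 1 and rng.random() < trans_cassette_rate
        if trans:
            others = [k for k in range(len(eligible)) if k != ci]
            cas_j, _, js_j = eligible[others[int(rng.integers(len(others)))]]
        else:
            cas_j, js_j = cas, js
        j = js_j[int(rng.integers(len(js_j)))]
        c = cas_j.c_gene

        v_seq = v.coding_sequence(locus)
        j_seq = j.coding_sequence(locus)
        c_seq = c.coding_sequence(locus)
        if trim_max > 0:
            v_seq = v_seq[: len(v_seq) - int(rng.integers(trim_max + 1))]
            j_seq = j_seq[int(rng.integers(trim_max + 1)) :]
        ins_len = int(rng.integers(junction_insert_max + 1))
        junction = "".join(BASES[b] for b in rng.integers(0, 4, ins_len))
        cdna_id = f"tx{i + 1:05d}"
        out.append(SequenceRecord(cdna_id, v_seq + junction + j_seq + c_seq))
        truth.transcripts.append(TranscriptTruth(cdna_id, v.name, j.name, c.name, junction))
    return out
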