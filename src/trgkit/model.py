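"""Shared domain types for TRG-locus analysis.

Coordinates are 1-based, fully closed, following the NCBI convention. Loci on
the minus strand of an assembly are expected to be reverse-complemented once at
load time; every coordinate in this package then refers to the forward strand
of the working sequence.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Optional

import yaml

IUPAC_NT = set("ACGTRYSWKMBDHVN")
GAP_CHARS = set("-.")

COMPLEMENT = str.maketrans(
    "ACGTRYSWKMBDHVNacgtryswkmbdhvn",
    "TGCAYRSWMKVHDBNtgcayrswmkvhdbn",
)


def reverse_complement(seq: str) -> str:
    return seq.translate(COMPLEMENT)[::-1]


@dataclass
class SequenceRecord:
    """A named nucleotide sequence.

    Case is meaningful: uppercase residues are unmasked, lowercase residues are
    (repeat-)masked. Masking is an input property; it is respected by seed
    finders but ignored by coordinate arithmetic.
    """

    id: str
    residues: str
    description: str = ""

    def __post_init__(self) -> None:
        if not self.residues:
            raise ValueError(f"sequence {self.id!r} has no residues")

    def __len__(self) -> int:
        return len(self.residues)

    @property
    def upper(self) -> str:
        return self.residues.upper()

    def reverse_complement(self) -> "SequenceRecord":
        return SequenceRecord(self.id, reverse_complement(self.residues), self.description)


@dataclass(frozen=True)
class GenomicInterval:
    """1-based fully closed interval; ``end >= start`` always holds."""

    seq_id: str
    start: int
    end: int
    strand: str = "+"

    def __post_init__(self) -> None:
        if self.start < 1:
            raise ValueError(f"start must be >= 1, got {self.start}")
        if self.end < self.start:
            raise ValueError(f"end ({self.end}) < start ({self.start})")
        if self.strand not in {"+", "-"}:
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")

    @classmethod
    def from_endpoints(cls, seq_id: str, a: int, b: int, strand: str = "+") -> "GenomicInterval":
        """Build an interval from endpoints written in either order.

        Assembly coordinates of minus-strand features are conventionally printed
        high-to-low; this normalizes them.
        """
        return cls(seq_id, min(a, b), max(a, b), strand)

    @property
    def length(self) -> int:
        return self.end - self.start + 1

    def overlaps(self, other: "GenomicInterval") -> bool:
        return self.seq_id == other.seq_id and self.start <= other.end and other.start <= self.end

    def slice(self, seq: str) -> str:
        """Extract this interval from a 0-based python string."""
        return seq[self.start - 1 : self.end]


def interval_length(iv, b: Optional[int] = None) -> int:
    """Length of a closed interval; symmetric in its endpoints.

    Accepts a :class:`GenomicInterval`, an ``(a, b)`` pair, or two integers.
    """
    if b is not None:
        a = iv
        return abs(int(a) - int(b)) + 1
    if isinstance(iv, GenomicInterval):
        return iv.length
    a, b = iv
    return abs(int(a) - int(b)) + 1


@dataclass
class RSSignal:
    """A recombination signal: heptamer + 12/23-nt spacer + nonamer.

    ``score`` follows the contract 0.6*(heptamer matches/7) +
    0.4*(nonamer matches/9) - 0.05*|spacer deviation| and is additionally capped
    below the acceptance default whenever the crucial CAC heptamer core is
    broken. ``motif_score`` is the uncapped value, used when deciding whether a
    non-canonical RS is still credible enough to anchor a gene call.
    """

    heptamer: str
    spacer_length: int
    nonamer: str
    interval: GenomicInterval
    score: float
    core_intact: bool
    motif_score: float = 0.0
    spacer_class: int = 23


@dataclass
class GeneAnnotation:
    """One V, J or C gene with its exons, signals and functionality verdict."""

    name: str
    gene_type: str  # V | J | C
    exons: list  # list[(label, GenomicInterval)]
    rs: Optional[RSSignal] = None
    functionality: str = "F"  # F | ORF | P
    defects: list = field(default_factory=list)
    rescued_by_cdna: bool = False
    subgroup: Optional[str] = None
    cassette: Optional[str] = None
    corrected_sequence: Optional[str] = None

    def __post_init__(self) -> None:
        if self.gene_type not in {"V", "J", "C"}:
            raise ValueError(f"gene_type must be V, J or C, got {self.gene_type!r}")

    @property
    def span(self) -> GenomicInterval:
        ivs = [iv for _, iv in self.exons]
        if self.rs is not None:
            ivs.append(self.rs.interval)
        return GenomicInterval(ivs[0].seq_id, min(i.start for i in ivs), max(i.end for i in ivs))

    @property
    def coding_span(self) -> GenomicInterval:
        ivs = [iv for _, iv in self.exons]
        return GenomicInterval(ivs[0].seq_id, min(i.start for i in ivs), max(i.end for i in ivs))

    def exon(self, label: str) -> Optional[GenomicInterval]:
        for lab, iv in self.exons:
            if lab == label:
                return iv
        return None

    def coding_sequence(self, locus: str) -> str:
        """Spliced coding sequence (exons concatenated 5'->3')."""
        parts = [iv.slice(locus) for _, iv in sorted(self.exons, key=lambda e: e[1].start)]
        return "".join(parts).upper()


@dataclass
class Cassette:
    """An ordered V* J+ C duplication unit with its regulatory elements."""

    name: str
    genes: list  # ordered GeneAnnotation, ending with exactly one C
    pj: Optional[GenomicInterval] = None
    en: Optional[GenomicInterval] = None

    def __post_init__(self) -> None:
        c_genes = [g for g in self.genes if g.gene_type == "C"]
        if len(c_genes) != 1 or self.genes[-1].gene_type != "C":
            raise ValueError(f"cassette {self.name!r} must end with exactly one C gene")

    @property
    def v_genes(self) -> list:
        return [g for g in self.genes if g.gene_type == "V"]

    @property
    def j_genes(self) -> list:
        return [g for g in self.genes if g.gene_type == "J"]

    @property
    def c_gene(self) -> GeneAnnotation:
        return self.genes[-1]

    @property
    def span(self) -> GenomicInterval:
        ivs = [g.span for g in self.genes]
        for extra in (self.pj, self.en):
            if extra is not None:
                ivs.append(extra)
        return GenomicInterval(ivs[0].seq_id, min(i.start for i in ivs), max(i.end for i in ivs))


@dataclass(frozen=True)
class MotifHit:
    """A match of a sequence motif (e.g. the STAT consensus TTCNNNGAA)."""

    motif: str
    interval: GenomicInterval
    matched_text: str


@dataclass
class RunConfig:
    """Tunable parameters with documented defaults; YAML-serializable.

    rs_min_score          -- reporting threshold for RS scans (contract default)
    rs_call_score         -- uncapped motif-score floor an RS must reach to
                             anchor a gene call; near-consensus by default
    spacer_tolerance      -- allowed deviation from the nominal 12/23 spacer
    identity_threshold    -- V subgrouping threshold (strictly 'more than')
    bootstrap_replicates  -- NJ bootstrap resamplings
    calibration_ma        -- (min, max) age in Ma for the calibrated node
    seed                  -- master random seed
    """

    rs_min_score: float = 0.7
    rs_call_score: float = 0.9
    spacer_tolerance: int = 1
    identity_threshold: float = 0.75
    bootstrap_replicates: int = 100
    calibration_ma: tuple = (66.0, 68.0)
    seed: int = 0

    def to_yaml(self, path) -> None:
        data = dataclasses.asdict(self)
        data["calibration_ma"] = list(self.calibration_ma)
        with open(path, "w") as fh:
            yaml.safe_dump(data, fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config parameters: {sorted(unknown)}")
        if "calibration_ma" in data:
            data["calibration_ma"] = tuple(data["calibration_ma"])
        return cls(**data)
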