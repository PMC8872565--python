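"""V/J/C gene identification and IMGT-style functionality classification.

Genes are anchored on recombination signals (RS): a conserved heptamer, a 12-
or 23-nt spacer and a nonamer. V genes are reconstructed upstream of a 23-RS
(acceptor -> V-EXON, then donor + ATG -> L-PART1), J genes downstream of a
12-RS (J-REGION ending near the canonical FGXG motif, bounded by a GT donor),
and C genes by reference-exon alignment chained across GT..AG introns.

Classification follows the standard rules for germline TR genes: a gene with a
stop codon or frameshift in its coding region is a pseudogene (P); a gene with
an intact reading frame but a broken RS core, a non-canonical splice site or a
deviant conserved motif is ORF; everything else is functional (F). A P gene
whose coding region is matched at high identity by a productive cDNA is
rescued to F.
"""

from __future__ import annotations

from typing import Dict, List, Optional, Sequence

import edlib
import numpy as np
from Bio.Seq import Seq

from .model import (
    GeneAnnotation,
    GenomicInterval,
    RSSignal,
    RunConfig,
    SequenceRecord,
    reverse_complement,
)

HEPTAMER = "CACAGTG"
NONAMER = "ACAAAAACC"

#: score a core-broken RS can never exceed (keeps it below the 0.7 default)
CORE_BROKEN_CAP = 0.65


def score_rs(heptamer: str, spacer_length: int, nonamer: str, spacer_class: int):
    """Score an RS candidate.

    Returns ``(score, motif_score, core_intact)``. ``motif_score`` is
    0.6*(heptamer matches/7) + 0.4*(nonamer matches/9) - 0.05*|spacer
    deviation|; ``score`` equals it unless the crucial CAC core is broken, in
    which case it is capped at :data:`CORE_BROKEN_CAP`.
    """
    h = sum(a == b for a, b in zip(heptamer.upper(), HEPTAMER))
    n = sum(a == b for a, b in zip(nonamer.upper(), NONAMER))
    dev = abs(spacer_length - spacer_class)
    motif = 0.6 * h / 7 + 0.4 * n / 9 - 0.05 * dev
    core = heptamer[:3].upper() == "CAC"
    score = motif if core else min(motif, CORE_BROKEN_CAP)
    return score, motif, core


def _as_str(seq) -> str:
    return seq.residues if isinstance(seq, SequenceRecord) else str(seq)


def _seq_array(seq: str) -> np.ndarray:
    return np.frombuffer(seq.upper().encode("ascii"), dtype=np.uint8)


def _match_counts(arr: np.ndarray, motif: str, n_pos: int) -> np.ndarray:
    """Count motif matches starting at each of the first n_pos positions."""
    counts = np.zeros(n_pos, dtype=np.int16)
    mot = np.frombuffer(motif.encode("ascii"), dtype=np.uint8)
    for k, ch in enumerate(mot):
        counts += arr[k : k + n_pos] == ch
    return counts


def scan_rss(
    seq,
    spacer_class: int,
    min_score: float = 0.7,
    spacer_tolerance: int = 1,
    strand: str = "+",
    seq_id: str = "seq",
) -> List[RSSignal]:
    """Find heptamer-spacer-nonamer signals on one strand.

    Scanning is case-insensitive; coordinates are 1-based on the forward
    strand even when ``strand='-'`` (the reverse complement is scanned and
    hits are mapped back). At each start position only the best-scoring spacer
    length is kept (nominal spacer wins ties). Sites with a broken CAC core
    carry ``core_intact=False`` and a capped score, so they never pass the
    default 0.7 threshold; their uncapped ``motif_score`` is retained.
    """
    if isinstance(seq, SequenceRecord):
        seq_id, text = seq.id, seq.residues
    else:
        text = str(seq)
    if strand == "-":
        text = reverse_complement(text)
    L = len(text)
    arr = _seq_array(text)
    best: Dict[int, RSSignal] = {}
    for dev in range(-spacer_tolerance, spacer_tolerance + 1):
        spacer = spacer_class + dev
        span = 7 + spacer + 9
        n_pos = L - span + 1
        if n_pos <= 0:
            continue
        h = _match_counts(arr, HEPTAMER, n_pos)
        n = _match_counts(arr[7 + spacer :], NONAMER, n_pos)
        motif = 0.6 * h / 7 + 0.4 * n / 9 - 0.05 * abs(dev)
        core = (
            (arr[0:n_pos] == ord("C"))
            & (arr[1 : n_pos + 1] == ord("A"))
            & (arr[2 : n_pos + 2] == ord("C"))
        )
        score = np.where(core, motif, np.minimum(motif, CORE_BROKEN_CAP))
        # keep candidates that could pass either the reporting threshold or,
        # core-broken, the uncapped motif score
        for i in np.nonzero((score >= min_score) | ((~core) & (motif >= min_score)))[0]:
            i = int(i)
            if score[i] < min_score:
                continue
            hept = text[i : i + 7].upper()
            nona = text[i + 7 + spacer : i + 16 + spacer].upper()
            if strand == "+":
                iv = GenomicInterval(seq_id, i + 1, i + span, "+")
            else:
                iv = GenomicInterval(seq_id, L - (i + span) + 1, L - i, "-")
            sig = RSSignal(
                hept, spacer, nona, iv, float(score[i]), bool(core[i]),
                motif_score=float(motif[i]), spacer_class=spacer_class,
            )
            prev = best.get(i)
            if prev is None or sig.score > prev.score or (
                sig.score == prev.score and abs(dev) < abs(prev.spacer_length - spacer_class)
            ):
                best[i] = sig
    return [best[i] for i in sorted(best)]


def _translate(nt: str) -> str:
    nt = nt[: len(nt) - len(nt) % 3]
    if not nt:
        return ""
    return str(Seq(nt).translate())


def _count_stops(nt: str) -> int:
    return _translate(nt).count("*")


# ---------------------------------------------------------------------------
# J genes


def find_j_genes(
    seq,
    rss_hits: Sequence[RSSignal],
    window=(40, 75),
    default_len: int = 51,
    seq_id: str = "seq",
) -> List[GeneAnnotation]:
    """Call J genes downstream of 12-RS signals.

    For every 12-RS, GT donor candidates 40-75 nt downstream are translated in
    the donor-anchored frame; the candidate whose FGXG motif sits closest to
    the 3' end wins. A motif whose second position deviates (F-x-x-G) is still
    called, with a "J-motif" defect. If the donor itself is broken (no GT in
    the window) but the RS is credible, the modal J length is assumed and a
    splice defect recorded.
    """
    if isinstance(seq, SequenceRecord):
        seq_id, text = seq.id, seq.residues
    else:
        text = str(seq)
    text = text.upper()
    genes: List[GeneAnnotation] = []
    for hit in rss_hits:
        rs_end = hit.interval.end  # 1-based end of the RS
        best = None  # (not_full, dist, -L, defects)
        for L in range(window[0], window[1] + 1):
            if text[rs_end + L - 1 + 1 : rs_end + L + 2] != "GT":
                continue
            jseq = text[rs_end : rs_end + L]
            prot = _translate(jseq[L % 3 :])
            full_dist = _motif_dist(prot, strict=True)
            loose_dist = _motif_dist(prot, strict=False)
            if full_dist is not None and full_dist <= 3:
                cand = (0, full_dist, -L, [])
            elif loose_dist is not None and loose_dist <= 2:
                cand = (1, loose_dist, -L, ["J-motif"])
            else:
                continue
            if best is None or cand[:3] < best[:3]:
                best = cand
        defects: List[str] = []
        if best is None:
            # donor absent: fall back to the modal J length
            L = default_len
            jseq = text[rs_end : rs_end + L]
            prot = _translate(jseq[L % 3 :])
            if _motif_dist(prot, strict=False) is None:
                continue  # no motif either: not a J gene
            defects.append("splice(J-donor)")
            if _motif_dist(prot, strict=True) is None:
                defects.append("J-motif")
        else:
            _, _, negL, defects = best
            L = -negL
            jseq = text[rs_end : rs_end + L]
            defects = list(defects)
        if _count_stops(jseq[L % 3 :]) > 0:
            defects.append("stop_codon(J-REGION)")
        if not hit.core_intact:
            defects.append("rs-core(J-RS)")
        iv = GenomicInterval(seq_id, rs_end + 1, rs_end + L)
        genes.append(
            GeneAnnotation(
                name=f"J{len(genes) + 1}",
                gene_type="J",
                exons=[("J-REGION", iv)],
                rs=hit,
                defects=defects,
            )
        )
    return genes


def _motif_dist(prot: str, strict: bool) -> Optional[int]:
    """Distance (in codons) of the rightmost FGXG (or F..G) motif from the end."""
    best = None
    for i in range(len(prot) - 3):
        if prot[i] != "F" or prot[i + 3] != "G":
            continue
        if strict and prot[i + 1] != "G":
            continue
        best = len(prot) - (i + 4)
    return best


# ---------------------------------------------------------------------------
# V genes


def find_v_genes(
    seq,
    rss_hits: Sequence[RSSignal],
    exon_range=(200, 380),
    intron_range=(60, 150),
    leader_range=(30, 63),
    default_leader_len: int = 45,
    max_stops: int = 3,
    seq_id: str = "seq",
) -> List[GeneAnnotation]:
    """Call V genes upstream of 23-RS signals.

    The V-EXON is the longest exon in range opening at an AG acceptor and
    ending at the RS; L-PART1 is the longest ATG-initiated exon ending at a GT
    donor an intron-length upstream. When no donor is found, an ATG at a
    modal-leader-compatible position is still accepted, with a splice defect
    (the TRGV6-style non-canonical donor). Candidates whose exon cannot be
    read through in any frame with at most ``max_stops`` stops are rejected as
    non-genes.
    """
    if isinstance(seq, SequenceRecord):
        seq_id, text = seq.id, seq.residues
    else:
        text = str(seq)
    text = text.upper()
    genes: List[GeneAnnotation] = []
    for hit in rss_hits:
        rs_start = hit.interval.start
        exon_iv = None
        for d in range(exon_range[1], exon_range[0] - 1, -1):
            a = rs_start - d - 2  # 1-based start of the candidate acceptor AG
            if a < 1:
                continue
            if text[a - 1 : a + 1] == "AG":
                exon_iv = GenomicInterval(seq_id, rs_start - d, rs_start - 1)
                break
        if exon_iv is None:
            continue
        exon_seq = exon_iv.slice(text)

        leader_iv = None
        defects: List[str] = []
        best_len = -1
        for g in range(exon_iv.start - intron_range[1], exon_iv.start - intron_range[0] + 1):
            if g < 1 or text[g - 1 : g + 1] != "GT":
                continue
            for a in range(g - leader_range[1], g - leader_range[0] + 1):
                if a < 1 or text[a - 1 : a + 2] != "ATG":
                    continue
                if g - a > best_len:
                    best_len = g - a
                    leader_iv = GenomicInterval(seq_id, a, g - 1)
                break  # earliest ATG gives the longest leader for this donor
        if leader_iv is None:
            # donor may be non-canonical: look for an ATG at a position
            # compatible with a modal-length leader and an in-range intron
            lo = exon_iv.start - intron_range[1] - default_leader_len
            hi = exon_iv.start - intron_range[0] - default_leader_len
            for a in range(max(1, lo), hi + 1):
                if text[a - 1 : a + 2] == "ATG":
                    leader_iv = GenomicInterval(seq_id, a, a + default_leader_len - 1)
                    defects.append("splice(L-PART1-donor)")
                    break

        if leader_iv is not None:
            leader_seq = leader_iv.slice(text)
            combined = leader_seq + exon_seq
            if len(leader_seq) % 3 != 0:
                defects.append("frameshift(L-PART1)")
            elif len(combined) % 3 != 0:
                defects.append("frameshift(V-EXON)")
            if _count_stops(leader_seq) > 0:
                defects.append("stop_codon(L-PART1)")
            stops_exon = _count_stops(exon_seq)
            stops_combined = _count_stops(combined)
        else:
            defects.append("no-leader")
            stops_exon = _count_stops(exon_seq)
            stops_combined = stops_exon
        if min(stops_exon, stops_combined) > max_stops:
            continue  # unreadable in every natural frame: not a V gene
        if stops_exon > 0:
            defects.append("stop_codon(V-EXON)")
        if not hit.core_intact:
            defects.append("rs-core(V-RS)")

        exons = [("V-EXON", exon_iv)]
        if leader_iv is not None:
            exons.insert(0, ("L-PART1", leader_iv))
        genes.append(
            GeneAnnotation(
                name=f"V{len(genes) + 1}",
                gene_type="V",
                exons=exons,
                rs=hit,
                defects=defects,
            )
        )
    return genes


# ---------------------------------------------------------------------------
# C genes


def _glocal_aligner():
    """Full-query alignment with free target end gaps and affine internal gaps.

    The heavy gap-open cost means paralog copies that differ only by
    substitutions align gap-free (unit-cost edit paths tend to fabricate
    compensating indel pairs), while a genuine frameshift still pays for
    exactly one gap — so the net indel balance of the path is trustworthy.
    """
    from Bio import Align

    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = 1
    aligner.mismatch_score = -1
    aligner.open_internal_gap_score = -12
    aligner.extend_internal_gap_score = -3
    # target = the genomic window: its unaligned flanks are free
    for side in ("left", "right"):
        setattr(aligner, f"open_{side}_deletion_score", 0)
        setattr(aligner, f"extend_{side}_deletion_score", 0)
        # the reference exon (query) must be aligned end to end
        setattr(aligner, f"open_{side}_insertion_score", -1000)
        setattr(aligner, f"extend_{side}_insertion_score", -1000)
    return aligner


_GLOCAL = None


def _refine_hit(ref_seq: str, window: str):
    """Align the full reference exon into a window; return (s, e, matches)."""
    global _GLOCAL
    if _GLOCAL is None:
        _GLOCAL = _glocal_aligner()
    aln = _GLOCAL.align(window, ref_seq)[0]
    blocks = aln.aligned[0]  # aligned blocks on the target (window)
    s, e = int(blocks[0][0]), int(blocks[-1][1]) - 1
    matches = 0
    qblocks = aln.aligned[1]
    for (ts, te), (qs, _) in zip(blocks, qblocks):
        for k in range(te - ts):
            if window[ts + k].upper() == ref_seq[qs + k]:
                matches += 1
    if e - s + 1 != len(ref_seq):
        # a gap was opened; unless it buys a clear improvement over the
        # gap-free reading, treat it as alignment noise and snap to full span
        gap_free = window[s : s + len(ref_seq)]
        if len(gap_free) == len(ref_seq):
            ham_matches = sum(a.upper() == b for a, b in zip(gap_free, ref_seq))
            if matches - ham_matches <= 3:
                return s, s + len(ref_seq) - 1, ham_matches
    return s, e, matches


def _exon_hits(text: str, ref: SequenceRecord, min_identity: float) -> List[dict]:
    """Locate every diverged copy of one reference exon.

    Iterative semi-global search: edlib places the reference exon in the
    locus, the hit is masked out, and the search repeats until below the
    identity floor. Each accepted hit's boundaries are then refined with an
    affine-gap alignment so exon ends (and the indel balance that signals a
    frameshift) are exact.
    """
    ref_seq = ref.residues.upper()
    work = list(text)
    hits: List[dict] = []
    for _ in range(64):  # hard stop; real loci have a handful of copies
        res = edlib.align(ref_seq, "".join(work), mode="HW", task="locations")
        if res["editDistance"] < 0:
            break
        if 1.0 - res["editDistance"] / len(ref_seq) < min_identity:
            break
        s, e = res["locations"][0]
        w_lo = max(0, s - 20)
        w_hi = min(len(text), e + 21)
        rs, re_, matches = _refine_hit(ref_seq, text[w_lo:w_hi])
        identity = matches / len(ref_seq)
        if identity >= min_identity:
            hits.append(
                {
                    "label": ref.id,
                    "start": w_lo + rs + 1,
                    "end": w_lo + re_ + 1,
                    "identity": identity,
                    "ref_len": len(ref_seq),
                }
            )
        work[s : e + 1] = "X" * (e - s + 1)
    return hits


def find_c_genes(
    seq,
    reference_c: Sequence[SequenceRecord],
    min_identity: float = 0.6,
    min_coverage: float = 0.6,
    k: int = 12,
    max_intron: int = 2000,
    seq_id: str = "seq",
) -> List[GeneAnnotation]:
    """Call C genes by chaining reference-exon alignments across GT..AG introns.

    Reference record ids must name the exon class (EX1, EX2 or EX2A/B/C, EX3).
    Every hit covers its full reference exon at >= min_identity (semi-global
    alignment pays for truncation, which enforces the coverage requirement).
    EX2 copy number (1-3) is read off the chain and labelled EX2A/B/C in order.
    """
    if not reference_c:
        raise ValueError("reference C exon library is empty")
    if isinstance(seq, SequenceRecord):
        seq_id, text = seq.id, seq.residues
    else:
        text = str(seq)
    text = text.upper()
    del min_coverage, k  # coverage is implied by semi-global alignment of the ref
    hits = []
    for ref in reference_c:
        label = ref.id.upper()
        if label.startswith("EX2"):
            label = "EX2"
        if label not in {"EX1", "EX2", "EX3"}:
            raise ValueError(f"reference exon id {ref.id!r} must name EX1/EX2*/EX3")
        for h in _exon_hits(text, SequenceRecord(label, ref.residues), min_identity):
            hits.append(h)
    # near the identity floor, short exons can be matched by chance anywhere in
    # the locus; a borderline hit is believed only when it sits between
    # canonical splice dinucleotides appropriate for its class
    strong = 0.75

    def _credible(h) -> bool:
        if h["identity"] >= strong:
            return True
        donor_ok = text[h["end"] : h["end"] + 2] == "GT"
        acceptor_ok = text[h["start"] - 3 : h["start"] - 1] == "AG"
        if h["label"] == "EX1":
            return donor_ok
        if h["label"] == "EX3":
            return acceptor_ok
        return donor_ok and acceptor_ok

    hits = [h for h in hits if _credible(h)]
    # dedupe overlapping hits (any class), best identity wins
    hits.sort(key=lambda h: (-h["identity"], h["start"]))
    kept = []
    for h in hits:
        if any(not (h["end"] < o["start"] or o["end"] < h["start"]) for o in kept):
            continue
        kept.append(h)
    kept.sort(key=lambda h: h["start"])

    genes: List[GeneAnnotation] = []
    i = 0
    while i < len(kept):
        if kept[i]["label"] != "EX1":
            i += 1
            continue
        chain = [kept[i]]
        j = i + 1
        while (
            j < len(kept)
            and kept[j]["label"] == "EX2"
            and len(chain) < 4  # at most three EX2 copies per gene
            and kept[j]["start"] - chain[-1]["end"] <= max_intron
        ):
            chain.append(kept[j])
            j += 1
        if j < len(kept) and kept[j]["label"] == "EX3" and (
            kept[j]["start"] - chain[-1]["end"] <= max_intron
        ):
            chain.append(kept[j])
            j += 1
        if chain[-1]["label"] != "EX3" or len(chain) < 3:
            i += 1
            continue
        defects: List[str] = []
        exons = []
        n_ex2 = 0
        for h in chain:
            label = h["label"]
            if label == "EX2":
                label = "EX2" + "ABC"[n_ex2]
                n_ex2 += 1
            iv = GenomicInterval(seq_id, h["start"], h["end"])
            exons.append((label, iv))
            if (iv.length - h["ref_len"]) % 3 != 0:
                defects.append(f"frameshift({label})")
        for (l1, iv1), (l2, iv2) in zip(exons, exons[1:]):
            if text[iv1.end : iv1.end + 2] != "GT":
                defects.append(f"splice({l1}-donor)")
            if text[iv2.start - 3 : iv2.start - 1] != "AG":
                defects.append(f"splice({l2}-acceptor)")
        spliced = "".join(iv.slice(text) for _, iv in exons)
        coding = spliced[: len(spliced) - len(spliced) % 3]
        if _translate(coding[:-3]).count("*") > 0:  # internal stops only
            defects.append("stop_codon(C-REGION)")
        genes.append(
            GeneAnnotation(
                name=f"C{len(genes) + 1}",
                gene_type="C",
                exons=exons,
                defects=defects,
            )
        )
        i = j
    return genes


# ---------------------------------------------------------------------------
# functionality


_P_GRADE = ("stop_codon", "frameshift")
_ORF_GRADE = ("rs-core", "splice", "J-motif", "no-leader")


def classify_functionality(gene: GeneAnnotation) -> GeneAnnotation:
    """Set F/ORF/P from the recorded defects (pseudogene trumps ORF)."""
    if gene.rescued_by_cdna:
        gene.functionality = "F"
        return gene
    if any(d.startswith(_P_GRADE) for d in gene.defects):
        gene.functionality = "P"
    elif any(d.startswith(_ORF_GRADE) for d in gene.defects):
        gene.functionality = "ORF"
    else:
        gene.functionality = "F"
    return gene


def rescue_with_cdna(
    genes: Sequence[GeneAnnotation],
    locus,
    cdnas: Sequence[SequenceRecord],
    min_identity: float = 0.95,
) -> List[GeneAnnotation]:
    """Reclassify P genes matched by a productive cDNA segment.

    A pseudogene whose coding region aligns into some cDNA at
    >= min_identity, where the matched cDNA segment is stop-free in at least
    one frame, is considered functional in the expressed repertoire
    (sequencing/assembly error in the germline); the corrected sequence is the
    matched cDNA segment.
    """
    if not 0.9 <= min_identity <= 1.0:
        raise ValueError("min_identity must be in [0.9, 1]")
    text = _as_str(locus)
    for gene in genes:
        if gene.functionality != "P":
            continue
        coding = gene.coding_sequence(text)
        for cdna in cdnas:
            res = edlib.align(coding, cdna.residues.upper(), mode="HW", task="locations")
            if res["editDistance"] < 0:
                continue
            identity = 1.0 - res["editDistance"] / len(coding)
            if identity < min_identity:
                continue
            s, e = res["locations"][0]
            segment = cdna.residues.upper()[s : e + 1]
            if min(_count_stops(segment[o:]) for o in range(3)) == 0:
                gene.rescued_by_cdna = True
                gene.corrected_sequence = segment
                gene.functionality = "F"
                break
    return list(genes)


# ---------------------------------------------------------------------------
# pipeline


def annotate_locus(
    locus,
    reference_c: Sequence[SequenceRecord],
    cdnas: Optional[Sequence[SequenceRecord]] = None,
    config: Optional[RunConfig] = None,
) -> List[GeneAnnotation]:
    """Full annotation pass: RS scan, V/J/C calling, classification, rescue.

    Gene calling requires an uncapped RS motif score >= config.rs_call_score
    (default 0.9): real RS are near-consensus in the crucial positions, and
    core-broken but otherwise consensus RS (TRGJ6-1-style) are retained so the
    gene can be annotated as ORF.
    """
    config = config or RunConfig()
    if isinstance(locus, SequenceRecord):
        seq_id = locus.id
    else:
        seq_id = "seq"
    hits23 = [
        h
        for h in scan_rss(locus, 23, min_score=0.5, spacer_tolerance=config.spacer_tolerance)
        if h.motif_score >= config.rs_call_score
    ]
    hits12 = [
        h
        for h in scan_rss(locus, 12, min_score=0.5, spacer_tolerance=config.spacer_tolerance)
        if h.motif_score >= config.rs_call_score
    ]
    genes = find_v_genes(locus, hits23, seq_id=seq_id)
    genes += find_j_genes(locus, hits12, seq_id=seq_id)
    genes += find_c_genes(locus, reference_c, seq_id=seq_id)
    genes.sort(key=lambda g: g.span.start)

    # drop same-type overlaps (keep the stronger RS / higher identity call)
    kept: List[GeneAnnotation] = []
    for g in genes:
        clash = [o for o in kept if o.gene_type == g.gene_type and o.span.overlaps(g.span)]
        if clash:
            continue
        kept.append(g)
    counters = {"V": 0, "J": 0, "C": 0}
    for g in kept:
        counters[g.gene_type] += 1
        g.name = f"{g.gene_type}{counters[g.gene_type]}"
        classify_functionality(g)
    if cdnas:
        rescue_with_cdna(kept, locus, cdnas)
    return kept
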