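"""Re-annotation evidence and processing-site sequence motifs.

Re-annotation of a mature miRNA rests on three independent evidence
classes, combined per precursor:

1. *degradome* — a prominent degradome signal at the candidate's 5'
   processing site;
2. *duplex geometry* — Drosha/Dicer (animals) and DCL1 (plants) cropping
   leaves miRNA-5p:miRNA-3p duplexes with 2-nt 3' overhangs, so the
   candidate must form such a duplex with the partner arm on the hairpin's
   secondary structure (consumed as dot-bracket; folding is an input, not
   computed here);
3. *abundance* — the candidate must be the most abundant member of its
   arm's sRNA cluster.

Motif analysis collects the 20-nt windows around supported processing
sites (10 nt upstream, 10 nt downstream, the site nucleotide being the
11th) and summarizes them as count/frequency matrices with per-column
information content in bits, IC_j = 2 + sum_b f_bj log2 f_bj.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

from degratrack.sequencing_io import (
    DegradomeLibrary,
    MatureAnnotation,
    PrecursorRecord,
    validate_dotbracket,
)
from degratrack.signal_scan import ProminentSignal, TagAlignment, map_tags

logger = logging.getLogger(__name__)

BASES = ("A", "C", "G", "U")
WINDOW_LEN = 20
SITE_COLUMN = 11  # 1-based column index of the site nucleotide


# ---------------------------------------------------------------------------
# Secondary-structure pairing

@dataclass
class PairMap:
    """Base-pair partner table derived from dot-bracket (1-based positions).

    ``loop_midpoint`` is the floor-midpoint of the hairpin loop, i.e. of the
    longest unpaired run whose flanking positions pair with each other; it
    is None for structures without such a loop (non-hairpin).
    """

    partner: dict[int, int]
    loop_midpoint: int | None
    length: int

    def is_paired(self, pos: int) -> bool:
        return pos in self.partner


def pair_map_from_dotbracket(structure: str) -> PairMap:
    """Stack-parse a dot-bracket string into a `PairMap`."""
    validate_dotbracket(structure)
    partner: dict[int, int] = {}
    stack: list[int] = []
    for pos, ch in enumerate(structure, 1):
        if ch == "(":
            stack.append(pos)
        elif ch == ")":
            open_pos = stack.pop()
            partner[open_pos] = pos
            partner[pos] = open_pos

    # hairpin loop: longest unpaired run [a..b] with partner(a-1) == b+1
    best: tuple[int, int] | None = None
    run_start = None
    for pos in range(1, len(structure) + 2):
        unpaired = pos <= len(structure) and pos not in partner
        if unpaired and run_start is None:
            run_start = pos
        elif not unpaired and run_start is not None:
            a, b = run_start, pos - 1
            run_start = None
            if a > 1 and b < len(structure) and partner.get(a - 1) == b + 1:
                if best is None or (b - a) > (best[1] - best[0]):
                    best = (a, b)
    loop_midpoint = (best[0] + best[1]) // 2 if best else None
    return PairMap(partner=partner, loop_midpoint=loop_midpoint, length=len(structure))


# ---------------------------------------------------------------------------
# Duplex 2-nt 3'-overhang geometry

@dataclass
class DuplexCheck:
    arm5: tuple[int, int]
    arm3: tuple[int, int]
    overhang_at_3p_end_of_3p: int
    overhang_at_3p_end_of_5p: int

    @property
    def canonical(self) -> bool:
        return self.overhang_at_3p_end_of_3p == 2 and self.overhang_at_3p_end_of_5p == 2


def _first_paired_at_or_after(pair_map: PairMap, pos: int, limit: int) -> int | None:
    for p in range(pos, limit + 1):
        if pair_map.is_paired(p):
            return p
    return None


def duplex_overhangs(
    pair_map: PairMap, arm5: tuple[int, int], arm3: tuple[int, int]
) -> DuplexCheck:
    """Measure the two 3' overhangs of a putative miRNA duplex.

    For each arm, the partner of the arm's first paired position marks
    where the opposite strand of the duplex would end if blunt; the
    overhang is how far the other arm's 3' end extends past that partner.
    Both overhangs equal 2 for a canonical Dicer/DCL1 product.  Bulged
    stems are handled by using the nearest paired position at or 3'-ward
    of each arm start.
    """
    if pair_map.loop_midpoint is None:
        raise ValueError("structure has no hairpin loop; duplex undefined")
    if not (arm5[1] < pair_map.loop_midpoint < arm3[0]):
        raise ValueError(
            f"arms {arm5}/{arm3} do not flank the hairpin loop at {pair_map.loop_midpoint}"
        )
    q_pos = _first_paired_at_or_after(pair_map, arm5[0], arm5[1])
    r_pos = _first_paired_at_or_after(pair_map, arm3[0], arm3[1])
    if q_pos is None or r_pos is None:
        raise ValueError("an arm has no paired position; duplex undefined")
    return DuplexCheck(
        arm5=arm5,
        arm3=arm3,
        overhang_at_3p_end_of_3p=arm3[1] - pair_map.partner[q_pos],
        overhang_at_3p_end_of_5p=arm5[1] - pair_map.partner[r_pos],
    )


# ---------------------------------------------------------------------------
# sRNA clusters

@dataclass
class SrnaCluster:
    arm: str  # "5p" or "3p"
    members: list[TagAlignment] = field(default_factory=list)

    @property
    def top(self) -> TagAlignment | None:
        """Most abundant distinct member (ties broken by sequence)."""
        if not self.members:
            return None
        best: dict[str, TagAlignment] = {}
        for m in self.members:
            best.setdefault(m.tag_sequence, m)
        return max(best.values(), key=lambda m: (m.rpm, m.tag_sequence))


def srna_clusters(
    srna_alignments: Sequence[TagAlignment], pair_map: PairMap
) -> tuple[SrnaCluster, SrnaCluster]:
    """Partition sRNA alignments into 5'-arm and 3'-arm clusters.

    A tag belongs to the arm holding its midpoint relative to the hairpin
    loop midpoint; a tag centred exactly on the midpoint goes to the 5'
    arm.
    """
    if pair_map.loop_midpoint is None:
        raise ValueError("structure has no hairpin loop; clusters undefined")
    cluster5 = SrnaCluster(arm="5p")
    cluster3 = SrnaCluster(arm="3p")
    for a in srna_alignments:
        mid = a.five_prime_pos + (len(a.tag_sequence) - 1) / 2.0
        (cluster5 if mid <= pair_map.loop_midpoint else cluster3).members.append(a)
    return cluster5, cluster3


# ---------------------------------------------------------------------------
# Re-annotation

def five_prime_shift(annotated_seq: str, candidate_seq: str) -> int | None:
    """5' offset (nt) of a candidate mature relative to the annotation.

    Positive means the candidate starts downstream of (is shorter from) the
    annotated 5' end; negative means it extends further 5'.  Returns None
    when neither sequence contains the other.
    """
    if candidate_seq in annotated_seq:
        return annotated_seq.find(candidate_seq)
    if annotated_seq in candidate_seq:
        return -candidate_seq.find(annotated_seq)
    return None


@dataclass
class RecommendationReport:
    precursor_id: str
    recommendation: str  # SHIFT, NOVEL_ARM, PROMOTE, NONE
    arm: str | None = None
    shift_nt: int | None = None
    candidate_start: int | None = None
    candidate_end: int | None = None
    candidate_seq: str | None = None
    evidence_degradome: bool = False
    evidence_duplex: bool = False
    evidence_abundance: bool = False
    partial: bool = False  # True when no structure was available

    def as_row(self) -> dict:
        return {
            "precursor_id": self.precursor_id,
            "recommendation": self.recommendation,
            "arm": self.arm or "",
            "shift_nt": "" if self.shift_nt is None else self.shift_nt,
            "candidate_start": "" if self.candidate_start is None else self.candidate_start,
            "candidate_end": "" if self.candidate_end is None else self.candidate_end,
            "candidate_seq": self.candidate_seq or "",
            "evidence_degradome": self.evidence_degradome,
            "evidence_duplex": self.evidence_duplex,
            "evidence_abundance": self.evidence_abundance,
            "partial": self.partial,
        }


def _mature_seq(precursor: PrecursorRecord, ann: MatureAnnotation) -> str:
    return precursor.sequence[ann.start - 1 : ann.end]


def _duplex_canonical(
    pair_map: PairMap | None,
    arm5: tuple[int, int] | None,
    arm3: tuple[int, int] | None,
) -> bool | None:
    """True/False for a checkable duplex, None when it cannot be checked."""
    if pair_map is None or arm5 is None or arm3 is None:
        return None
    try:
        return duplex_overhangs(pair_map, arm5, arm3).canonical
    except ValueError:
        return None


def propose_reannotation(
    precursor: PrecursorRecord,
    annotations: Sequence[MatureAnnotation],
    prominent_signals: Sequence[ProminentSignal],
    srna_library: DegradomeLibrary,
    structure: str | None = None,
    min_srna_len: int = 15,
    max_shift: int = 5,
) -> RecommendationReport:
    """Combine degradome, duplex and sRNA-abundance evidence for one precursor.

    Emits SHIFT when an annotated mature's arm cluster is dominated by a
    shifted variant whose 5' end carries a prominent degradome signal;
    NOVEL_ARM when an unannotated arm shows a prominent signal plus an
    abundant cluster tag forming a canonical duplex with the annotated
    mature; PROMOTE when both annotated matures have zero-offset prominent
    signals, a canonical duplex, and top-of-cluster abundance but are not
    yet high-confidence; NONE otherwise.  Without a structure the duplex
    class cannot be evaluated and the report is flagged partial.
    """
    structure = structure if structure is not None else precursor.structure
    pair_map = None
    if structure is not None:
        pair_map = pair_map_from_dotbracket(structure)
        if pair_map.loop_midpoint is None:
            pair_map = None
    partial = pair_map is None

    anns = {a.arm: a for a in annotations if a.precursor_id == precursor.id}
    signal_positions = {s.position for s in prominent_signals if s.precursor_id == precursor.id}
    aligns = map_tags(srna_library, precursor, min_tag_len=min_srna_len)

    tops: dict[str, TagAlignment | None] = {"5p": None, "3p": None}
    if pair_map is not None:
        c5, c3 = srna_clusters(aligns, pair_map)
        tops["5p"], tops["3p"] = c5.top, c3.top
    else:
        # without structure, split clusters at the midpoint between the
        # annotated arms (or the precursor midpoint)
        if "5p" in anns and "3p" in anns:
            split = (anns["5p"].end + anns["3p"].start) / 2.0
        else:
            split = precursor.core_length / 2.0
        c5 = SrnaCluster(arm="5p")
        c3 = SrnaCluster(arm="3p")
        for a in aligns:
            mid = a.five_prime_pos + (len(a.tag_sequence) - 1) / 2.0
            (c5 if mid <= split else c3).members.append(a)
        tops["5p"], tops["3p"] = c5.top, c3.top

    def arm_coords(ann: MatureAnnotation) -> tuple[int, int]:
        return (ann.start, ann.end)

    # --- SHIFT: annotated arm whose top cluster tag is a shifted variant
    for arm in ("5p", "3p"):
        ann = anns.get(arm)
        top = tops.get(arm)
        if ann is None or top is None:
            continue
        if top.five_prime_pos == ann.start:
            continue
        ann_seq = _mature_seq(precursor, ann)
        shift = five_prime_shift(ann_seq, top.tag_sequence)
        if shift is None:
            shift = top.five_prime_pos - ann.start
        if not 1 <= abs(shift) <= max_shift:
            continue
        degradome = top.five_prime_pos in signal_positions
        if not degradome:
            continue
        cand = (top.five_prime_pos, top.five_prime_pos + len(top.tag_sequence) - 1)
        other = anns.get("3p" if arm == "5p" else "5p")
        if other is not None:
            pair = (arm_coords(other), cand) if arm == "3p" else (cand, arm_coords(other))
            duplex = _duplex_canonical(pair_map, pair[0], pair[1])
        else:
            duplex = None
        return RecommendationReport(
            precursor_id=precursor.id,
            recommendation="SHIFT",
            arm=arm,
            shift_nt=shift,
            candidate_start=cand[0],
            candidate_end=cand[1],
            candidate_seq=top.tag_sequence,
            evidence_degradome=True,
            evidence_duplex=bool(duplex),
            evidence_abundance=True,
            partial=partial or duplex is None,
        )

    # --- NOVEL_ARM: unannotated arm with signal + abundant duplex-forming tag
    if len(anns) == 1:
        known_arm, ann = next(iter(anns.items()))
        novel_arm = "3p" if known_arm == "5p" else "5p"
        top = tops.get(novel_arm)
        if top is not None and top.five_prime_pos in signal_positions:
            cand = (top.five_prime_pos, top.five_prime_pos + len(top.tag_sequence) - 1)
            if novel_arm == "3p":
                duplex = _duplex_canonical(pair_map, arm_coords(ann), cand)
            else:
                duplex = _duplex_canonical(pair_map, cand, arm_coords(ann))
            if duplex or (duplex is None and partial):
                return RecommendationReport(
                    precursor_id=precursor.id,
                    recommendation="NOVEL_ARM",
                    arm=novel_arm,
                    candidate_start=cand[0],
                    candidate_end=cand[1],
                    candidate_seq=top.tag_sequence,
                    evidence_degradome=True,
                    evidence_duplex=bool(duplex),
                    evidence_abundance=True,
                    partial=partial,
                )

    # --- PROMOTE: both arms confirmed but not yet high-confidence
    if len(anns) == 2:
        ann5, ann3 = anns["5p"], anns["3p"]
        both_signals = ann5.start in signal_positions and ann3.start in signal_positions
        top5, top3 = tops.get("5p"), tops.get("3p")
        abundance = (
            top5 is not None
            and top3 is not None
            and top5.five_prime_pos == ann5.start
            and top3.five_prime_pos == ann3.start
        )
        duplex = _duplex_canonical(pair_map, arm_coords(ann5), arm_coords(ann3))
        already_hc = ann5.confidence == "HC" and ann3.confidence == "HC"
        if both_signals and abundance and (duplex or (duplex is None and partial)) and not already_hc:
            return RecommendationReport(
                precursor_id=precursor.id,
                recommendation="PROMOTE",
                arm=None,
                evidence_degradome=True,
                evidence_duplex=bool(duplex),
                evidence_abundance=True,
                partial=partial,
            )

    return RecommendationReport(precursor_id=precursor.id, recommendation="NONE", partial=partial)


# ---------------------------------------------------------------------------
# Motifs

def motif_windows(
    sites: Iterable[tuple[str, int]],
    precursors: Mapping[str, PrecursorRecord] | Sequence[PrecursorRecord],
) -> list[str]:
    """Extract the 20-nt windows around processing-site positions.

    ``sites`` are (precursor_id, position) pairs; the window spans positions
    p-10 .. p+9 so the site nucleotide is the 11th.  Windows falling off
    either end of the (possibly extended) precursor are skipped and logged.
    """
    if not isinstance(precursors, Mapping):
        precursors = {p.id: p for p in precursors}
    windows = []
    skipped = 0
    for pid, pos in sites:
        pre = precursors[pid]
        lo = pos - (SITE_COLUMN - 1)
        hi = pos + (WINDOW_LEN - SITE_COLUMN)
        if lo < 1 or hi > len(pre):
            skipped += 1
            continue
        windows.append(pre.sequence[lo - 1 : hi])
    if skipped:
        logger.info("motif_windows: skipped %d sites too close to a precursor end", skipped)
    return windows


@dataclass
class MotifMatrix:
    """Per-column base counts, frequencies and information content (bits)."""

    counts: np.ndarray  # shape (4, window_len), rows ordered A,C,G,U
    frequencies: np.ndarray
    information_content: np.ndarray  # per column, in [0, 2]
    n_windows: int

    @property
    def window_len(self) -> int:
        return self.counts.shape[1]

    def max_letter(self, column: int) -> str:
        """Most frequent base in a 1-based column (ties -> alphabetical)."""
        return BASES[int(np.argmax(self.frequencies[:, column - 1]))]

    def as_rows(self) -> list[dict]:
        rows = []
        for j in range(self.window_len):
            row = {"position": j + 1}
            for i, b in enumerate(BASES):
                row[f"count_{b}"] = int(self.counts[i, j])
                row[f"freq_{b}"] = float(self.frequencies[i, j])
            row["ic_bits"] = float(self.information_content[j])
            row["max_letter"] = self.max_letter(j + 1)
            rows.append(row)
        return rows


def motif_matrix(windows: Sequence[str]) -> MotifMatrix:
    """Count/frequency matrix with uncorrected per-column IC in bits."""
    if not windows:
        raise ValueError("at least one window required")
    length = len(windows[0])
    if any(len(w) != length for w in windows):
        raise ValueError("windows have mixed lengths")
    counts = np.zeros((4, length), dtype=int)
    index = {b: i for i, b in enumerate(BASES)}
    for w in windows:
        for j, ch in enumerate(w):
            counts[index[ch], j] += 1
    totals = counts.sum(axis=0)
    frequencies = counts / totals
    with np.errstate(divide="ignore", invalid="ignore"):
        plogp = np.where(frequencies > 0, frequencies * np.log2(frequencies), 0.0)
    ic = 2.0 + plogp.sum(axis=0)
    ic = np.clip(ic, 0.0, 2.0)
    return MotifMatrix(
        counts=counts, frequencies=frequencies, information_content=ic, n_windows=len(windows)
    )


def class_sites(
    annotations: Sequence[MatureAnnotation], classes: Iterable[int] = (1, 2, 3, 4)
) -> list[tuple[str, int, int]]:
    """All annotated processing sites as (precursor_id, position, class)."""
    wanted = set(classes)
    out = []
    for a in annotations:
        if a.arm == "5p":
            pairs = ((1, a.start), (2, a.end + 1))
        else:
            pairs = ((3, a.start), (4, a.end + 1))
        for cls, pos in pairs:
            if cls in wanted:
                out.append((a.precursor_id, pos, cls))
    return out
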