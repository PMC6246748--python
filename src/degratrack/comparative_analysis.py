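"""Tissue comparisons: sample-specific support, sRNA accumulation, chi-square.

Links tissue- or cell-line-specific processing evidence (which samples'
degradome libraries support which miRNAs) to mature-miRNA accumulation in
matched sRNA libraries.  A mature is called highly accumulated in tissue A
when its level exceeds 1 RPM in A and is at least twice its level in B
(defaults configurable).  Sampling-diversity curves report prefix-union
support ratios, which are monotone non-decreasing because support across
samples is a union.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import scipy.stats

from degratrack.sequencing_io import DegradomeLibrary, MatureAnnotation, PrecursorRecord
from degratrack import processing_support, signal_scan


def sample_specific_sets(
    support_a: set[str], support_b: set[str]
) -> tuple[set[str], set[str], set[str]]:
    """Split two per-sample support sets into (only_A, only_B, both)."""
    return support_a - support_b, support_b - support_a, support_a & support_b


@dataclass
class AccumulationCall:
    mature_id: str
    level_a: float  # RPM
    level_b: float
    call: str  # "high_in_A", "high_in_B", or "neither"


def _library_level(
    library: DegradomeLibrary, mature_seq: str, isomir_window: int
) -> float:
    if isomir_window <= 0:
        return library.rpm(mature_seq)
    total = 0.0
    w = isomir_window
    for seq, rec in library.tags.items():
        if seq in mature_seq:
            i = mature_seq.find(seq)
            if i <= w and len(mature_seq) - (i + len(seq)) <= w:
                total += rec.rpm
        elif mature_seq in seq:
            i = seq.find(mature_seq)
            if i <= w and len(seq) - (i + len(mature_seq)) <= w:
                total += rec.rpm
    return total


def accumulation_call(
    srna_library_a: DegradomeLibrary,
    srna_library_b: DegradomeLibrary,
    mature_sequences: Mapping[str, str],
    min_rpm: float = 1.0,
    fold: float = 2.0,
    isomir_window: int = 0,
) -> list[AccumulationCall]:
    """Call tissue-biased accumulation for each mature miRNA.

    The mature level is the RPM of the exact annotated mature sequence in
    each library (0 if absent); ``isomir_window > 0`` additionally
    aggregates tags whose 5'/3' ends lie within that many nucleotides of
    the mature's ends.  One call is emitted per mature present in either
    library.
    """
    calls = []
    for mature_id in sorted(mature_sequences):
        seq = mature_sequences[mature_id]
        a = _library_level(srna_library_a, seq, isomir_window)
        b = _library_level(srna_library_b, seq, isomir_window)
        if a == 0.0 and b == 0.0:
            continue
        if a > min_rpm and a >= fold * b:
            call = "high_in_A"
        elif b > min_rpm and b >= fold * a:
            call = "high_in_B"
        else:
            call = "neither"
        calls.append(AccumulationCall(mature_id=mature_id, level_a=a, level_b=b, call=call))
    return calls


@dataclass
class ContingencyTable2x2:
    """Counts [[a, b], [c, d]]; rows are groups, columns supported/unsupported."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("contingency counts must be non-negative")
        if self.a + self.b + self.c + self.d == 0:
            raise ValueError("contingency table is empty")


def chi_square_2x2(table: ContingencyTable2x2) -> tuple[float, float]:
    """Pearson chi-square for a 2x2 table, df=1, no continuity correction."""
    row1 = table.a + table.b
    row2 = table.c + table.d
    col1 = table.a + table.c
    col2 = table.b + table.d
    if min(row1, row2, col1, col2) == 0:
        raise ValueError("chi-square undefined: zero marginal total")
    res = scipy.stats.chi2_contingency(
        [[table.a, table.b], [table.c, table.d]], correction=False
    )
    return float(res.statistic), float(res.pvalue)


def diversity_curve(
    libraries_in_order: Sequence[DegradomeLibrary],
    precursors: Sequence[PrecursorRecord],
    annotations: Sequence[MatureAnnotation],
    min_ratio: float = signal_scan.DEFAULT_MIN_RATIO,
    rank_k: int = signal_scan.DEFAULT_RANK_K,
    min_tag_len: int = signal_scan.DEFAULT_MIN_TAG_LEN,
) -> list[dict]:
    """Support ratios under growing prefix-unions of degradome libraries.

    Returns one row per (prefix length, confidence class) with the
    percentage of matures and of precursors supported by the union of the
    first n libraries.  Non-decreasing in n by the union rule.
    """
    if not libraries_in_order:
        raise ValueError("at least one library required")
    scans = [
        signal_scan.scan_library(
            lib, precursors, min_ratio=min_ratio, rank_k=rank_k, min_tag_len=min_tag_len
        )
        for lib in libraries_in_order
    ]

    mirna_conf = {a.mature_id: a.confidence for a in annotations}
    pre_conf: dict[str, str] = {p.id: "LC" for p in precursors}
    for a in annotations:
        if a.confidence == "HC":
            pre_conf[a.precursor_id] = "HC"
    totals = {
        conf: (
            sum(1 for c in mirna_conf.values() if c == conf),
            sum(1 for c in pre_conf.values() if c == conf),
        )
        for conf in ("HC", "LC")
    }

    rows: list[dict] = []
    for n in range(1, len(scans) + 1):
        signals_by_sample = {s.sample_id: s.signals for s in scans[:n]}
        support = processing_support.call_support(signals_by_sample, annotations)
        sup_mirnas = support.supported_mirnas()
        sup_pres = support.supported_precursors()
        for conf in ("HC", "LC"):
            m_total, p_total = totals[conf]
            m_sup = sum(1 for m in sup_mirnas if mirna_conf.get(m) == conf)
            p_sup = sum(1 for p in sup_pres if pre_conf.get(p) == conf)
            rows.append(
                {
                    "n_samples": n,
                    "confidence": conf,
                    "supported_mirna_ratio": 100.0 * m_sup / m_total if m_total else 0.0,
                    "supported_precursor_ratio": 100.0 * p_sup / p_total if p_total else 0.0,
                }
            )
    return rows
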