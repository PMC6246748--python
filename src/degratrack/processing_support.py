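"""Classification of prominent signals against mature-miRNA ends.

Each annotated mature miRNA defines two processing sites on its precursor:
the 5' site (the mature's first nucleotide) and the 3' site (one nucleotide
downstream of the mature's last nucleotide, because the cut that releases
the 3' end leaves the downstream fragment starting there).  A prominent
degradome signal is classified by its offset from the nearest site using 14
labels: ``5'`` and ``3'`` for exact hits, and ``5'_+k`` / ``5'_-k`` /
``3'_+k`` / ``3'_-k`` for signals 1-3 nt away.  Following the field's
labelling convention, ``+k`` means the signal lies k nt *upstream* of the
site (smaller coordinate) and ``-k`` k nt downstream.

A mature miRNA is degradome-supported when some sample shows a zero-offset
prominent signal at either of its sites; a precursor is supported when any
of its matures is.  Exact sites are further assigned to four position
classes: (1) 5' end of the 5p miRNA, (2) 3' end + 1 of the 5p, (3) 5' end
of the 3p, (4) 3' end + 1 of the 3p.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from degratrack.sequencing_io import MatureAnnotation, PrecursorRecord
from degratrack.signal_scan import ProminentSignal

FIVE_PRIME = "five_prime"
THREE_PRIME_PLUS1 = "three_prime_plus1"

MAX_OFFSET = 3

#: The 14 offset labels in display order (Figure-2-style histograms).
OFFSET_LABELS = (
    "5'_+3", "5'_+2", "5'_+1", "5'", "5'_-1", "5'_-2", "5'_-3",
    "3'_+3", "3'_+2", "3'_+1", "3'", "3'_-1", "3'_-2", "3'_-3",
)

_CLASS_MAP = {
    ("5p", FIVE_PRIME): 1,
    ("5p", THREE_PRIME_PLUS1): 2,
    ("3p", FIVE_PRIME): 3,
    ("3p", THREE_PRIME_PLUS1): 4,
}


def site_position(annotation: MatureAnnotation, end_kind: str) -> int:
    """Precursor coordinate of a processing site of one mature miRNA."""
    if end_kind == FIVE_PRIME:
        return annotation.start
    if end_kind == THREE_PRIME_PLUS1:
        return annotation.end + 1
    raise ValueError(f"unknown end_kind {end_kind!r}")


def classify_offset(
    signal_position: int, annotation: MatureAnnotation
) -> tuple[str, str] | None:
    """Classify a signal position against one mature's two processing sites.

    Returns ``(end_kind, offset_label)`` or None when the signal lies more
    than 3 nt from both sites.  When within 3 nt of both sites of one
    (pathologically short) mature, the nearer site wins; ties go to the 5'
    site.
    """
    candidates = []
    for end_kind in (FIVE_PRIME, THREE_PRIME_PLUS1):
        site = site_position(annotation, end_kind)
        offset = site - signal_position  # + means signal upstream of site
        if abs(offset) <= MAX_OFFSET:
            candidates.append((abs(offset), 0 if end_kind == FIVE_PRIME else 1, end_kind, offset))
    if not candidates:
        return None
    candidates.sort()
    _, _, end_kind, offset = candidates[0]
    prefix = "5'" if end_kind == FIVE_PRIME else "3'"
    if offset == 0:
        return end_kind, prefix
    sign = "+" if offset > 0 else "-"
    return end_kind, f"{prefix}_{sign}{abs(offset)}"


def assign_position_class(arm: str, end_kind: str, offset_label: str | None = None) -> int:
    """Map (arm, end_kind) of a zero-offset call to position class 1-4."""
    if offset_label is not None and offset_label not in {"5'", "3'"}:
        raise ValueError(f"position classes are defined only for zero-offset calls, got {offset_label!r}")
    try:
        return _CLASS_MAP[(arm, end_kind)]
    except KeyError:
        raise ValueError(f"invalid arm/end_kind combination ({arm!r}, {end_kind!r})") from None


@dataclass
class SiteCall:
    """One classified signal/annotation relationship, aggregated over samples."""

    precursor_id: str
    mature_id: str
    end_kind: str
    offset_label: str
    signal_position: int
    position_class: int | None = None  # defined only for zero-offset calls
    supporting_samples: set[str] = field(default_factory=set)

    @property
    def is_exact(self) -> bool:
        return self.offset_label in {"5'", "3'"}


@dataclass
class SupportResult:
    """Support calls for a cohort: per-site, per-miRNA and per-precursor."""

    site_calls: list[SiteCall] = field(default_factory=list)
    mirna_support: dict[str, set[str]] = field(default_factory=dict)  # mature -> samples
    precursor_support: dict[str, set[str]] = field(default_factory=dict)
    # prominent signals not within 3 nt of any annotated site of their
    # precursor; these may mark processing of unannotated arms and are
    # reported but never counted as support
    unassigned_signals: list[tuple[str, str, int]] = field(default_factory=list)  # (sample, pre, pos)

    def supported_mirnas(self) -> set[str]:
        return set(self.mirna_support)

    def supported_precursors(self) -> set[str]:
        return set(self.precursor_support)


def call_support(
    prominent_signals_by_sample: Mapping[str, Sequence[ProminentSignal]],
    annotations: Sequence[MatureAnnotation],
) -> SupportResult:
    """Classify per-sample prominent signals and call degradome support.

    Support across samples is a union: a mature is supported as soon as any
    sample yields a zero-offset prominent signal at either of its sites.
    Signals matching sites of two overlapping matures are assigned to both;
    each mature is evaluated independently.
    """
    ann_by_precursor: dict[str, list[MatureAnnotation]] = {}
    for ann in annotations:
        ann_by_precursor.setdefault(ann.precursor_id, []).append(ann)
    precursor_of_mature = {a.mature_id: a.precursor_id for a in annotations}

    result = SupportResult()
    calls: dict[tuple[str, str, str], SiteCall] = {}
    for sample_id in sorted(prominent_signals_by_sample):
        for sig in prominent_signals_by_sample[sample_id]:
            anns = ann_by_precursor.get(sig.precursor_id, [])
            matched = False
            for ann in anns:
                res = classify_offset(sig.position, ann)
                if res is None:
                    continue
                matched = True
                end_kind, label = res
                key = (ann.mature_id, end_kind, label)
                call = calls.get(key)
                if call is None:
                    call = SiteCall(
                        precursor_id=ann.precursor_id,
                        mature_id=ann.mature_id,
                        end_kind=end_kind,
                        offset_label=label,
                        signal_position=sig.position,
                        position_class=(
                            assign_position_class(ann.arm, end_kind) if label in {"5'", "3'"} else None
                        ),
                    )
                    calls[key] = call
                call.supporting_samples.add(sample_id)
                if call.is_exact:
                    result.mirna_support.setdefault(ann.mature_id, set()).add(sample_id)
                    result.precursor_support.setdefault(ann.precursor_id, set()).add(sample_id)
            if not matched:
                result.unassigned_signals.append((sample_id, sig.precursor_id, sig.position))
    for mature_id in result.mirna_support:
        if mature_id not in precursor_of_mature:
            raise ValueError(f"support call references unknown mature {mature_id!r}")
    result.site_calls = sorted(
        calls.values(), key=lambda c: (c.precursor_id, c.signal_position, c.mature_id)
    )
    return result


@dataclass
class SupportSummary:
    """Table-1-style cohort summary.

    A: precursors; B: precursors with >=1 perfectly mapped signature;
    C: precursors with >=1 prominent signal; D: precursors whose processing
    is degradome-supported.  D <= C <= B <= A by construction.  Ratios are
    percentages.  The HC/LC blocks count supported matures/precursors per
    miRBase confidence class; the offset histogram counts unique
    (precursor, signal position) pairs per offset label; class percentages
    are supported sites over annotated sites per position class.
    """

    A: int
    B: int
    C: int
    D: int
    ratio_DA: float
    ratio_DB: float
    ratio_DC: float
    mirna_counts: dict[str, tuple[int, int]]  # confidence -> (supported, total)
    precursor_counts: dict[str, tuple[int, int]]
    offset_histogram: dict[str, int]
    class_percentages: dict[int, float]
    class_counts: dict[int, tuple[int, int]]  # class -> (supported, annotated)

    def as_rows(self) -> list[dict]:
        """Long-format rows for the ``summary`` results schema."""
        rows = [
            {"metric": "A_precursors", "value": self.A},
            {"metric": "B_with_mapped_signatures", "value": self.B},
            {"metric": "C_with_prominent_signals", "value": self.C},
            {"metric": "D_supported", "value": self.D},
            {"metric": "ratio_D_A_pct", "value": self.ratio_DA},
            {"metric": "ratio_D_B_pct", "value": self.ratio_DB},
            {"metric": "ratio_D_C_pct", "value": self.ratio_DC},
        ]
        for conf in ("HC", "LC"):
            sup, tot = self.mirna_counts.get(conf, (0, 0))
            rows.append({"metric": f"mirnas_{conf}_supported", "value": sup})
            rows.append({"metric": f"mirnas_{conf}_total", "value": tot})
            sup, tot = self.precursor_counts.get(conf, (0, 0))
            rows.append({"metric": f"precursors_{conf}_supported", "value": sup})
            rows.append({"metric": f"precursors_{conf}_total", "value": tot})
        for label in OFFSET_LABELS:
            rows.append({"metric": f"offset[{label}]", "value": self.offset_histogram.get(label, 0)})
        for cls in (1, 2, 3, 4):
            rows.append({"metric": f"class_{cls}_supported_pct", "value": self.class_percentages.get(cls, 0.0)})
        return rows


def _pct(numerator: int, denominator: int) -> float:
    return 100.0 * numerator / denominator if denominator else 0.0


def summarize(
    precursors: Sequence[PrecursorRecord],
    annotations: Sequence[MatureAnnotation],
    support: SupportResult,
    mapped_precursors: Iterable[str] = (),
    precursors_with_signals: Iterable[str] = (),
) -> SupportSummary:
    """Build the cohort support summary.

    ``mapped_precursors`` / ``precursors_with_signals`` are the unions over
    samples of precursors with >=1 perfectly mapped signature and >=1
    prominent signal (from `degratrack.signal_scan.ScanResult`).
    """
    precursor_ids = {p.id for p in precursors}
    supported_pre = support.supported_precursors() & precursor_ids
    with_signals = (set(precursors_with_signals) & precursor_ids) | supported_pre
    mapped = (set(mapped_precursors) & precursor_ids) | with_signals

    A = len(precursor_ids)
    B = len(mapped)
    C = len(with_signals)
    D = len(supported_pre)

    mirna_conf = {a.mature_id: a.confidence for a in annotations}
    # a precursor is HC when any of its matures is HC
    pre_conf: dict[str, str] = {pid: "LC" for pid in precursor_ids}
    for a in annotations:
        if a.confidence == "HC":
            pre_conf[a.precursor_id] = "HC"

    supported_mirnas = support.supported_mirnas()
    mirna_counts = {}
    precursor_counts = {}
    for conf in ("HC", "LC"):
        m_tot = [m for m, c in mirna_conf.items() if c == conf]
        mirna_counts[conf] = (len([m for m in m_tot if m in supported_mirnas]), len(m_tot))
        p_tot = [p for p, c in pre_conf.items() if c == conf]
        precursor_counts[conf] = (len([p for p in p_tot if p in supported_pre]), len(p_tot))

    # offset histogram: unique (precursor, signal position) pairs per label
    per_label: dict[str, set[tuple[str, int]]] = {}
    for call in support.site_calls:
        per_label.setdefault(call.offset_label, set()).add(
            (call.precursor_id, call.signal_position)
        )
    offset_histogram = {label: len(per_label.get(label, ())) for label in OFFSET_LABELS}

    # class percentages: supported sites / annotated sites of that class
    ann_sites = {1: 0, 2: 0, 3: 0, 4: 0}
    for a in annotations:
        if a.arm == "5p":
            ann_sites[1] += 1
            ann_sites[2] += 1
        else:
            ann_sites[3] += 1
            ann_sites[4] += 1
    supported_sites = {1: set(), 2: set(), 3: set(), 4: set()}
    for call in support.site_calls:
        if call.is_exact and call.position_class is not None:
            supported_sites[call.position_class].add((call.mature_id, call.end_kind))
    class_counts = {c: (len(supported_sites[c]), ann_sites[c]) for c in (1, 2, 3, 4)}
    class_percentages = {c: _pct(*class_counts[c]) for c in (1, 2, 3, 4)}

    return SupportSummary(
        A=A,
        B=B,
        C=C,
        D=D,
        ratio_DA=_pct(D, A),
        ratio_DB=_pct(D, B),
        ratio_DC=_pct(D, C),
        mirna_counts=mirna_counts,
        precursor_counts=precursor_counts,
        offset_histogram=offset_histogram,
        class_percentages=class_percentages,
        class_counts=class_counts,
    )

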