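"""Prominent degradome-signal detection on miRNA precursors.

A degradome tag marks an uncapped 5' end.  For each precursor, tags are
mapped by exact substring match on the sense strand; positions are then
scored with two statistics:

* ``signal`` — the mean RPM of the distinct signatures whose 5' ends map at
  the candidate position;
* ``noise``  — the mean RPM of the distinct signatures mapped onto the
  precursor anywhere else.

A position is *prominent* when signal/noise >= ``min_ratio`` (default 5)
and the most abundant signature at that position ranks among the top
``rank_k`` (default 12) most abundant signatures on the precursor.  The
ratio criterion suppresses the uniform background left by random RNA decay;
the rank criterion guards against calling sites that are only locally
enriched in an otherwise busy profile.

Averaging is over distinct signature sequences (not raw reads): a tag that
maps at two positions of one precursor contributes one alignment per
position, each carrying the tag's full RPM.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from degratrack.sequencing_io import DegradomeLibrary, PrecursorRecord

DEFAULT_MIN_RATIO = 5.0
DEFAULT_RANK_K = 12
DEFAULT_MIN_TAG_LEN = 15


@dataclass(frozen=True)
class TagAlignment:
    """A perfect match of one tag on one precursor (1-based 5' position)."""

    tag_sequence: str
    precursor_id: str
    five_prime_pos: int
    rpm: float


@dataclass
class PositionProfile:
    """Per-position aggregation of the alignments on one precursor."""

    precursor_id: str
    length: int
    n_signatures: list[int] = field(default_factory=list)
    sum_rpm: list[float] = field(default_factory=list)
    max_signature_rpm: list[float] = field(default_factory=list)
    # tags_at[p-1] holds the distinct tag sequences whose 5' ends map at p
    tags_at: list[list[str]] = field(default_factory=list)


@dataclass
class ProminentSignal:
    precursor_id: str
    position: int
    signal: float
    noise: float
    ratio: float  # may be math.inf when noise == 0 and signal > 0
    top_rank: int
    passed: bool


def map_tags(
    library: DegradomeLibrary,
    precursor: PrecursorRecord,
    min_tag_len: int = DEFAULT_MIN_TAG_LEN,
) -> list[TagAlignment]:
    """Report every exact sense-strand occurrence of each library tag.

    Tags shorter than ``min_tag_len`` are skipped (short tags produce
    spurious exact matches).  A tag occurring at several positions yields
    one alignment per position, each with the tag's full RPM.
    """
    seq = precursor.sequence
    alignments: list[TagAlignment] = []
    for tag_seq in sorted(library.tags):
        if len(tag_seq) < min_tag_len:
            continue
        rpm = library.tags[tag_seq].rpm
        start = seq.find(tag_seq)
        while start != -1:
            alignments.append(
                TagAlignment(
                    tag_sequence=tag_seq,
                    precursor_id=precursor.id,
                    five_prime_pos=start + 1,
                    rpm=rpm,
                )
            )
            start = seq.find(tag_seq, start + 1)
    return alignments


def build_profile(alignments: Sequence[TagAlignment], precursor_length: int) -> PositionProfile:
    """Aggregate alignments of one precursor into a per-position profile."""
    if not alignments:
        pid = ""
    else:
        pids = {a.precursor_id for a in alignments}
        if len(pids) != 1:
            raise ValueError(f"alignments span multiple precursors: {sorted(pids)}")
        pid = alignments[0].precursor_id
    profile = PositionProfile(
        precursor_id=pid,
        length=precursor_length,
        n_signatures=[0] * precursor_length,
        sum_rpm=[0.0] * precursor_length,
        max_signature_rpm=[0.0] * precursor_length,
        tags_at=[[] for _ in range(precursor_length)],
    )
    seen: set[tuple[str, int]] = set()
    for a in alignments:
        if not 1 <= a.five_prime_pos <= precursor_length:
            raise ValueError(
                f"alignment position {a.five_prime_pos} outside 1..{precursor_length}"
            )
        key = (a.tag_sequence, a.five_prime_pos)
        if key in seen:  # duplicate alignment record; count once per position
            continue
        seen.add(key)
        i = a.five_prime_pos - 1
        profile.n_signatures[i] += 1
        profile.sum_rpm[i] += a.rpm
        profile.max_signature_rpm[i] = max(profile.max_signature_rpm[i], a.rpm)
        profile.tags_at[i].append(a.tag_sequence)
    return profile


def signal_noise(profile: PositionProfile, position: int) -> tuple[float, float, float]:
    """Signal, noise and their ratio at one precursor position.

    Returns ``(signal, noise, ratio)``; ratio is ``inf`` when there is
    signal but zero noise, and 0 when there is no signal.
    """
    if not 1 <= position <= profile.length:
        raise ValueError(f"position {position} outside 1..{profile.length}")
    i = position - 1
    n_here = profile.n_signatures[i]
    signal = profile.sum_rpm[i] / n_here if n_here else 0.0
    n_other = sum(profile.n_signatures) - n_here
    sum_other = sum(profile.sum_rpm) - profile.sum_rpm[i]
    noise = sum_other / n_other if n_other else 0.0
    if signal == 0.0:
        ratio = 0.0
    elif noise == 0.0:
        ratio = math.inf
    else:
        ratio = signal / noise
    return signal, noise, ratio


def find_prominent(
    library: DegradomeLibrary,
    precursor: PrecursorRecord,
    min_ratio: float = DEFAULT_MIN_RATIO,
    rank_k: int = DEFAULT_RANK_K,
    min_tag_len: int = DEFAULT_MIN_TAG_LEN,
) -> list[ProminentSignal]:
    """Detect the prominent degradome signals on one precursor.

    Every position with at least one mapped signature is evaluated; only
    positions passing both the ratio and the rank criteria are returned,
    sorted by position.
    """
    if min_ratio <= 0:
        raise ValueError("min_ratio must be > 0")
    if rank_k < 1:
        raise ValueError("rank_k must be >= 1")
    alignments = map_tags(library, precursor, min_tag_len=min_tag_len)
    return prominent_from_alignments(
        alignments, len(precursor), min_ratio=min_ratio, rank_k=rank_k
    )


def prominent_from_alignments(
    alignments: Sequence[TagAlignment],
    precursor_length: int,
    min_ratio: float = DEFAULT_MIN_RATIO,
    rank_k: int = DEFAULT_RANK_K,
) -> list[ProminentSignal]:
    """`find_prominent` on precomputed alignments (one precursor)."""
    if not alignments:
        return []
    profile = build_profile(alignments, precursor_length)
    rpm_by_tag = {a.tag_sequence: a.rpm for a in alignments}
    # rank of a signature = 1 + number of signatures with strictly larger rpm
    rpms = sorted(rpm_by_tag.values(), reverse=True)
    rank_of_rpm = {}
    for idx, value in enumerate(rpms):
        rank_of_rpm.setdefault(value, idx + 1)

    signals: list[ProminentSignal] = []
    for position in range(1, precursor_length + 1):
        i = position - 1
        if profile.n_signatures[i] == 0:
            continue
        sig, noise, ratio = signal_noise(profile, position)
        top_rank = rank_of_rpm[profile.max_signature_rpm[i]]
        passed = (ratio >= min_ratio) and (top_rank <= rank_k)
        if passed:
            signals.append(
                ProminentSignal(
                    precursor_id=profile.precursor_id,
                    position=position,
                    signal=sig,
                    noise=noise,
                    ratio=ratio,
                    top_rank=top_rank,
                    passed=True,
                )
            )
    signals.sort(key=lambda s: s.position)
    return signals


@dataclass
class ScanResult:
    """Prominent signals of one library across a precursor cohort."""

    sample_id: str
    signals: list[ProminentSignal] = field(default_factory=list)
    mapped_precursors: set[str] = field(default_factory=set)
    evaluated_positions: int = 0  # positions with >=1 mapped signature

    def signals_by_precursor(self) -> dict[str, list[ProminentSignal]]:
        out: dict[str, list[ProminentSignal]] = {}
        for s in self.signals:
            out.setdefault(s.precursor_id, []).append(s)
        return out


def scan_library(
    library: DegradomeLibrary,
    precursors: Iterable[PrecursorRecord],
    min_ratio: float = DEFAULT_MIN_RATIO,
    rank_k: int = DEFAULT_RANK_K,
    min_tag_len: int = DEFAULT_MIN_TAG_LEN,
) -> ScanResult:
    """Run `find_prominent` over a whole cohort for one library."""
    result = ScanResult(sample_id=library.sample_id)
    for pre in precursors:
        alignments = map_tags(library, pre, min_tag_len=min_tag_len)
        if not alignments:
            continue
        result.mapped_precursors.add(pre.id)
        result.evaluated_positions += len({a.five_prime_pos for a in alignments})
        result.signals.extend(
            prominent_from_alignments(alignments, len(pre), min_ratio=min_ratio, rank_k=rank_k)
        )
    return result
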