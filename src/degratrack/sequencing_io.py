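"""Input/output and pre-treatment of degradome-seq / sRNA-seq tag data.

Handles the standard inputs of the pipeline — hairpin precursor FASTA with
mature-miRNA coordinate annotations, collapsed tag libraries, genome FASTA
for 3' extensions, dot-bracket structures — plus the pre-treatment steps:
N-read filtering, collapsing of identical sequences, and RPM normalization
(raw count / post-filter library total x 10^6).

Conventions
-----------
* Coordinates are 1-based inclusive on the precursor sense strand, and 3'
  genomic extensions never shift existing coordinates.
* Sequences are normalized to the RNA alphabet {A,C,G,U} internally;
  DNA ``T`` and lowercase input are accepted on read.
* Precursor FASTA headers may carry a genomic locus in the form
  ``>id chrom:start-end(+)`` (1-based inclusive); headers without a locus
  yield precursors that simply cannot be extended.
"""

from __future__ import annotations

import logging
import math
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
from Bio import SeqIO

logger = logging.getLogger(__name__)

RNA_ALPHABET = frozenset("ACGU")

_COMPLEMENT = str.maketrans("ACGU", "UGCA")

_LOCUS_RE = re.compile(r"^(?P<chrom>[\w.\-]+):(?P<start>\d+)-(?P<end>\d+)\((?P<strand>[+-])\)$")


def to_rna(sequence: str) -> str:
    """Uppercase and convert T->U."""
    return sequence.strip().upper().replace("T", "U")


def reverse_complement(sequence: str) -> str:
    """Reverse complement of an RNA string."""
    return to_rna(sequence).translate(_COMPLEMENT)[::-1]


@dataclass
class GenomicLocus:
    chrom: str
    start: int  # 1-based inclusive
    end: int  # 1-based inclusive
    strand: str  # "+" or "-"

    def __post_init__(self) -> None:
        if self.strand not in {"+", "-"}:
            raise ValueError(f"invalid strand {self.strand!r}")
        if not 1 <= self.start <= self.end:
            raise ValueError(f"invalid locus coordinates {self.start}..{self.end}")


@dataclass
class PrecursorRecord:
    """A miRNA hairpin precursor, optionally 3'-extended from the genome.

    ``sequence`` includes any appended extension; ``extension_len`` records
    how many 3' nucleotides are genomic extension rather than annotated
    precursor.  ``core_length`` is the unextended length.
    """

    id: str
    sequence: str
    genomic_locus: GenomicLocus | None = None
    structure: str | None = None
    extension_len: int = 0

    def __post_init__(self) -> None:
        self.sequence = to_rna(self.sequence)
        if not self.sequence:
            raise ValueError(f"precursor {self.id}: empty sequence")
        bad = set(self.sequence) - RNA_ALPHABET
        if bad:
            raise ValueError(f"precursor {self.id}: non-ACGU characters {sorted(bad)}")
        if self.extension_len < 0 or self.extension_len >= len(self.sequence):
            raise ValueError(f"precursor {self.id}: invalid extension_len {self.extension_len}")
        if self.structure is not None:
            validate_dotbracket(self.structure)
            if len(self.structure) != self.core_length:
                raise ValueError(
                    f"precursor {self.id}: structure length {len(self.structure)} "
                    f"!= core sequence length {self.core_length}"
                )

    @property
    def core_length(self) -> int:
        return len(self.sequence) - self.extension_len

    def __len__(self) -> int:
        return len(self.sequence)


def validate_dotbracket(structure: str) -> None:
    depth = 0
    for ch in structure:
        if ch == "(":
            depth += 1
        elif ch == ")":
            depth -= 1
            if depth < 0:
                raise ValueError("unbalanced dot-bracket structure")
        elif ch != ".":
            raise ValueError(f"invalid dot-bracket character {ch!r}")
    if depth != 0:
        raise ValueError("unbalanced dot-bracket structure")


@dataclass
class MatureAnnotation:
    """Coordinates of one mature miRNA on its precursor.

    ``confidence`` mirrors the miRBase high-confidence flag; annotation
    sources without confidence information default to low-confidence (LC).
    """

    precursor_id: str
    mature_id: str
    start: int  # 1-based inclusive
    end: int  # 1-based inclusive
    arm: str  # "5p" or "3p"
    confidence: str = "LC"  # "HC" or "LC"

    def __post_init__(self) -> None:
        if self.arm not in {"5p", "3p"}:
            raise ValueError(f"annotation {self.mature_id}: arm must be 5p or 3p, got {self.arm!r}")
        if self.confidence not in {"HC", "LC"}:
            raise ValueError(f"annotation {self.mature_id}: confidence must be HC or LC")
        if not 1 <= self.start <= self.end:
            raise ValueError(f"annotation {self.mature_id}: invalid coordinates {self.start}..{self.end}")

    @property
    def length(self) -> int:
        return self.end - self.start + 1


@dataclass
class TagRecord:
    """One collapsed short-read sequence with raw and RPM-normalized counts."""

    sequence: str
    raw_count: int
    rpm: float = 0.0

    def __post_init__(self) -> None:
        if self.raw_count < 1:
            raise ValueError("raw_count must be >= 1")
        if "N" in self.sequence:
            raise ValueError("tag sequence contains N after filtering")


@dataclass
class DegradomeLibrary:
    """A collapsed tag library (degradome or sRNA) for one sample.

    ``tags`` is keyed by unique tag sequence; RPM values are computed from
    the post-N-filter raw total and sum to 10^6.
    """

    sample_id: str
    tags: dict[str, TagRecord] = field(default_factory=dict)
    total_raw: int = 0

    def rpm(self, sequence: str) -> float:
        rec = self.tags.get(sequence)
        return rec.rpm if rec is not None else 0.0

    def __len__(self) -> int:
        return len(self.tags)


def _parse_locus(description: str) -> GenomicLocus | None:
    # description is the FASTA header line minus ">"; locus is the second token
    parts = description.split()
    for token in parts[1:]:
        m = _LOCUS_RE.match(token)
        if m:
            return GenomicLocus(
                chrom=m.group("chrom"),
                start=int(m.group("start")),
                end=int(m.group("end")),
                strand=m.group("strand"),
            )
    return None


ANNOTATION_COLUMNS = ["precursor_id", "mature_id", "start", "end", "arm", "confidence"]


def read_precursors(
    fasta_path: str | Path,
    annotation_table_path: str | Path,
) -> tuple[list[PrecursorRecord], list[MatureAnnotation]]:
    """Read precursor FASTA plus the mature-annotation TSV.

    The annotation table is a TSV with header ``precursor_id, mature_id,
    start, end, arm, confidence``; the confidence column may be absent, in
    which case every annotation is treated as low-confidence.  Every
    annotation must reference an existing precursor and lie within its
    sequence; mature ids must be unique.
    """
    precursors: list[PrecursorRecord] = []
    for rec in SeqIO.parse(str(fasta_path), "fasta"):
        precursors.append(
            PrecursorRecord(
                id=rec.id,
                sequence=str(rec.seq),
                genomic_locus=_parse_locus(rec.description),
            )
        )
    by_id = {p.id: p for p in precursors}
    if len(by_id) != len(precursors):
        raise ValueError("duplicate precursor ids in FASTA")

    table = pd.read_csv(annotation_table_path, sep="\t", dtype=str)
    required = ["precursor_id", "mature_id", "start", "end", "arm"]
    missing = [c for c in required if c not in table.columns]
    if missing:
        raise ValueError(f"annotation table missing columns: {missing}")
    if "confidence" not in table.columns:
        table["confidence"] = "LC"
    table["confidence"] = table["confidence"].fillna("LC")

    annotations: list[MatureAnnotation] = []
    seen_mature: set[str] = set()
    arms_per_precursor: dict[str, set[str]] = {}
    for row in table.itertuples(index=False):
        ann = MatureAnnotation(
            precursor_id=row.precursor_id,
            mature_id=row.mature_id,
            start=int(row.start),
            end=int(row.end),
            arm=row.arm,
            confidence=row.confidence,
        )
        pre = by_id.get(ann.precursor_id)
        if pre is None:
            raise ValueError(f"annotation {ann.mature_id}: no such precursor {ann.precursor_id!r}")
        if ann.end > len(pre):
            raise ValueError(
                f"annotation {ann.mature_id}: end {ann.end} beyond precursor "
                f"{pre.id} length {len(pre)}"
            )
        if ann.mature_id in seen_mature:
            raise ValueError(f"duplicate mature_id {ann.mature_id!r}")
        seen_mature.add(ann.mature_id)
        arms = arms_per_precursor.setdefault(ann.precursor_id, set())
        if ann.arm in arms:
            raise ValueError(f"precursor {ann.precursor_id}: duplicate annotation on arm {ann.arm}")
        arms.add(ann.arm)
        annotations.append(ann)
    return precursors, annotations


def read_structures(
    path: str | Path,
    precursors: Sequence[PrecursorRecord] | None = None,
) -> dict[str, str]:
    """Read a dot-bracket table TSV (precursor_id, structure).

    When ``precursors`` is given the structures are attached in place and
    validated against the core sequence lengths.
    """
    table = pd.read_csv(path, sep="\t", dtype=str)
    if list(table.columns[:2]) != ["precursor_id", "structure"]:
        raise ValueError("structure table must have columns precursor_id, structure")
    structures = dict(zip(table["precursor_id"], table["structure"]))
    for s in structures.values():
        validate_dotbracket(s)
    if precursors is not None:
        for pre in precursors:
            s = structures.get(pre.id)
            if s is not None:
                if len(s) != pre.core_length:
                    raise ValueError(
                        f"precursor {pre.id}: structure length {len(s)} != "
                        f"core length {pre.core_length}"
                    )
                pre.structure = s
    return structures


def load_tag_library(path: str | Path, sample_id: str) -> DegradomeLibrary:
    """Load a collapsed tag library, filter N-reads, collapse, normalize.

    Two dialects are accepted: FASTA with headers ``>tagid_count`` (the raw
    count is the trailing integer after the last underscore) and 2-column
    TSV ``sequence<TAB>raw_count`` (an optional header row is tolerated).
    Reads containing N are dropped *before* the library total is computed,
    so RPM values are invariant to the presence of N-reads in the input.
    """
    path = Path(path)
    counts: dict[str, int] = {}
    dropped_n = 0

    def _add(seq: str, count: int) -> None:
        nonlocal dropped_n
        seq = to_rna(seq)
        if "N" in seq:
            dropped_n += count
            return
        counts[seq] = counts.get(seq, 0) + count

    with open(path) as fh:
        first = fh.read(1)
    if first == ">":
        for rec in SeqIO.parse(str(path), "fasta"):
            tail = rec.id.rsplit("_", 1)
            if len(tail) != 2 or not tail[1].isdigit():
                raise ValueError(f"{path}: FASTA header {rec.id!r} lacks trailing _count")
            _add(str(rec.seq), int(tail[1]))
    else:
        with open(path) as fh:
            for lineno, line in enumerate(fh, 1):
                line = line.strip()
                if not line:
                    continue
                fields = line.split("\t")
                if len(fields) != 2:
                    raise ValueError(f"{path}:{lineno}: expected 2 tab-separated fields")
                seq, count_str = fields
                if lineno == 1 and not count_str.strip().lstrip("-").isdigit():
                    continue  # header row
                try:
                    count = int(count_str)
                except ValueError as exc:
                    raise ValueError(f"{path}:{lineno}: non-integer count {count_str!r}") from exc
                if count < 1:
                    raise ValueError(f"{path}:{lineno}: count must be >= 1")
                _add(seq, count)

    total = sum(counts.values())
    if total == 0:
        raise ValueError(f"{path}: no reads survive N-filtering")
    if dropped_n:
        logger.info("%s: dropped %d reads containing N", path, dropped_n)
    library = DegradomeLibrary(sample_id=sample_id, total_raw=total)
    for seq in sorted(counts):
        raw = counts[seq]
        library.tags[seq] = TagRecord(sequence=seq, raw_count=raw, rpm=raw / total * 1e6)
    return library


def write_tag_library(library: DegradomeLibrary, path: str | Path) -> None:
    """Write a library back out in the 2-column TSV dialect (sorted by sequence)."""
    with open(path, "w") as fh:
        fh.write("sequence\traw_count\n")
        for seq in sorted(library.tags):
            fh.write(f"{seq}\t{library.tags[seq].raw_count}\n")


def extend_precursors(
    precursors: Iterable[PrecursorRecord],
    genome_fasta: str | Path | Mapping[str, str],
    n_ext: int = 50,
) -> list[PrecursorRecord]:
    """Append up to ``n_ext`` nt of 3' genomic sequence to each precursor.

    Degradome tags of ~20 nt starting at the 3' processing site of a 3'-arm
    miRNA often run past the annotated precursor end, so they only map once
    the precursor carries its downstream genomic context.  Positions on the
    extended precursor remain 1-based from the original 5' end.  Precursors
    without a genomic locus are returned unextended; extensions running off
    a chromosome end are truncated with a warning.
    """
    if n_ext < 0:
        raise ValueError("n_ext must be >= 0")
    if isinstance(genome_fasta, (str, Path)):
        genome = {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(genome_fasta), "fasta")}
    else:
        genome = {k: v.upper() for k, v in genome_fasta.items()}

    out: list[PrecursorRecord] = []
    for pre in precursors:
        if n_ext == 0 or pre.genomic_locus is None:
            if pre.genomic_locus is None and n_ext > 0:
                logger.warning("precursor %s has no genomic locus; left unextended", pre.id)
            out.append(pre)
            continue
        locus = pre.genomic_locus
        chrom = genome.get(locus.chrom)
        if chrom is None:
            raise ValueError(f"precursor {pre.id}: chromosome {locus.chrom!r} not in genome")
        if locus.strand == "+":
            lo = locus.end  # 0-based slice start == 1-based end position
            hi = min(locus.end + n_ext, len(chrom))
            ext = chrom[lo:hi]
        else:
            lo = max(locus.start - 1 - n_ext, 0)
            hi = locus.start - 1
            ext = reverse_complement(chrom[lo:hi])
        if len(ext) < n_ext:
            logger.warning(
                "precursor %s: extension truncated to %d nt at chromosome end", pre.id, len(ext)
            )
        out.append(
            PrecursorRecord(
                id=pre.id,
                sequence=pre.sequence + to_rna(ext),
                genomic_locus=pre.genomic_locus,
                structure=pre.structure,
                extension_len=pre.extension_len + len(ext),
            )
        )
    return out


# ---------------------------------------------------------------------------
# Results tables

_SCHEMAS: dict[str, dict] = {
    "prominent_signals": {
        "columns": [
            "sample_id", "precursor_id", "position", "signal", "noise", "ratio", "top_rank",
        ],
        "sort": ["precursor_id", "position", "sample_id"],
    },
    "support_calls": {
        "columns": [
            "precursor_id", "mature_id", "end_kind", "offset_label", "position_class",
            "signal_position", "supporting_samples",
        ],
        "sort": ["precursor_id", "signal_position", "mature_id"],
    },
    "summary": {
        "columns": [
            "metric", "value",
        ],
        "sort": [],
    },
    "motif_matrix": {
        "columns": [
            "position", "count_A", "count_C", "count_G", "count_U",
            "freq_A", "freq_C", "freq_G", "freq_U", "ic_bits", "max_letter",
        ],
        "sort": ["position"],
    },
    "recommendations": {
        "columns": [
            "precursor_id", "recommendation", "arm", "shift_nt",
            "candidate_start", "candidate_end", "candidate_seq",
            "evidence_degradome", "evidence_duplex", "evidence_abundance", "partial",
        ],
        "sort": ["precursor_id"],
    },
}


def write_results_table(records: Iterable[Mapping], path: str | Path, schema_name: str) -> None:
    """Write records as a TSV with fixed column order and deterministic sorting.

    Floats are written with 4 decimal places; rerunning on the same records
    yields a byte-identical file.
    """
    schema = _SCHEMAS.get(schema_name)
    if schema is None:
        raise ValueError(f"unknown results schema {schema_name!r}")
    columns = schema["columns"]
    rows = [dict(r) for r in records]
    for row in rows:
        unknown = set(row) - set(columns)
        if unknown:
            raise ValueError(f"schema {schema_name}: unexpected fields {sorted(unknown)}")
    df = pd.DataFrame(rows, columns=columns)
    if schema["sort"] and len(df):
        df = df.sort_values(schema["sort"], kind="mergesort").reset_index(drop=True)

    def _fmt(value) -> str:
        if value is None or (isinstance(value, float) and math.isnan(value)):
            return ""
        if isinstance(value, bool):
            return str(value)
        if isinstance(value, float):
            return "inf" if math.isinf(value) else f"{value:.4f}"
        return str(value)

    with open(path, "w") as fh:
        fh.write("\t".join(columns) + "\n")
        for _, row in df.iterrows():
            fh.write("\t".join(_fmt(row[c]) for c in columns) + "\n")
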