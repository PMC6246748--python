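"""Ground-truthed synthetic cohorts of miRNA hairpins and tag libraries.

The generator emulates the statistical structure the detector assumes:
hairpin precursors with two mature arms placed so that the true
miRNA-5p:miRNA-3p duplex carries 2-nt 3' overhangs, degradome libraries in
which tag 5' ends pile up at the true processing sites on top of a uniform
random-decay background at a configurable signal/noise, and per-tissue
sRNA libraries whose mature-miRNA abundances are biased toward the tissue
in which each precursor's processing signals are planted.  A machine-
readable truth table records every planted site and every true mature so
recovery, classification and re-annotation can be scored exactly.

Each hairpin is a perfect stem (exact reverse-complement pairing) with
single-stranded 5'/3' flanks, embedded in a synthetic chromosome with
ample flanking sequence on a random strand, so that 3' genomic extension
behaves exactly as with real annotations.  Degradome tags for the class-4
site (3' end + 1 of the 3p mature) necessarily run past the annotated
precursor end and are drawn from the genomic extension, so their detection
requires `degratrack.sequencing_io.extend_precursors` — mirroring why 3'
processing-site counts rise sharply once precursors are extended.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

from degratrack.sequencing_io import (
    DegradomeLibrary,
    GenomicLocus,
    MatureAnnotation,
    PrecursorRecord,
    TagRecord,
    extend_precursors,
    reverse_complement,
)

_BASES = np.array(list("ACGU"))


@dataclass
class CohortConfig:
    """Study conditions for one synthetic cohort.

    ``planted_classes`` maps position class (1-4) to the probability that
    the corresponding true site of a precursor receives a planted degradome
    signal; classes 1/3/4 default to 0.7 and class 2 to absent, matching
    the strong depletion of class-2 signals in real data while leaving
    unsupported same-class sites to serve as motif control sets.
    ``planted_snr`` is the signal/noise the planted tags aim for;
    ``tissue_bias`` the fold-increase of a mature's sRNA abundance in its
    precursor's assigned tissue.  ``shift3p_prob`` precursors carry a true
    3p mature 3 nt shorter (from the 5' end) than its annotation;
    ``unannotated_arm_prob`` precursors are annotated on the 5' arm only.
    """

    n_precursors: int = 50
    stem_len: int = 30
    loop_len: int = 12
    mature_len: int = 21
    flank5_len: int = 15
    flank3_len: int = 5
    planted_classes: dict[int, float] = field(
        default_factory=lambda: {1: 0.7, 3: 0.7, 4: 0.7}
    )
    planted_snr: float = 20.0
    background_tags_per_precursor: int = 25
    depth: int = 500_000
    isomir_jitter_prob: float = 0.1
    tissues: tuple[str, ...] = ("tissueA", "tissueB")
    tissue_bias: float = 4.0
    unannotated_arm_prob: float = 0.1
    shift3p_prob: float = 0.05
    shift3p_nt: int = 3
    class1_u_prob: float = 0.9
    hc_prob: float = 0.3
    seed: int = 7

    def __post_init__(self) -> None:
        if self.mature_len >= self.stem_len:
            raise ValueError("mature_len must be smaller than stem_len")
        if self.stem_len < self.mature_len + 4:
            raise ValueError("stem_len must be >= mature_len + 4")
        for cls, p in self.planted_classes.items():
            if cls not in {1, 2, 3, 4} or not 0.0 <= p <= 1.0:
                raise ValueError(f"invalid planted class/probability ({cls}, {p})")
        for p in (self.isomir_jitter_prob, self.unannotated_arm_prob,
                  self.shift3p_prob, self.class1_u_prob, self.hc_prob):
            if not 0.0 <= p <= 1.0:
                raise ValueError("probabilities must lie in [0, 1]")
        if self.n_precursors > 0 and self.depth < 10 * self.background_tags_per_precursor * self.n_precursors:
            raise ValueError("depth must be >= 10 x background_tags_per_precursor x n_precursors")

    @property
    def core_length(self) -> int:
        return self.flank5_len + 2 * self.stem_len + self.loop_len + self.flank3_len


@dataclass
class TruthSite:
    """One true processing site, with whether/where a signal was planted."""

    precursor_id: str
    position: int  # 1-based on the precursor
    position_class: int
    mature_id: str
    tissue: str
    planted: bool


@dataclass
class TruthMirna:
    mature_id: str
    precursor_id: str
    arm: str
    annotated: bool
    annotated_start: int
    annotated_end: int
    true_start: int
    true_end: int
    confidence: str
    tissue: str
    shifted: bool


@dataclass
class Cohort:
    config: CohortConfig
    precursors: list[PrecursorRecord]
    annotations: list[MatureAnnotation]
    genome: dict[str, str]  # DNA alphabet, as a genome FASTA would hold
    truth_sites: list[TruthSite]
    truth_mirnas: list[TruthMirna]

    def precursor(self, pid: str) -> PrecursorRecord:
        return next(p for p in self.precursors if p.id == pid)

    def extended_precursors(self, n_ext: int = 50) -> list[PrecursorRecord]:
        return extend_precursors(self.precursors, self.genome, n_ext=n_ext)


def _random_seq(rng: np.random.Generator, length: int) -> str:
    return "".join(_BASES[rng.integers(0, 4, size=length)])


def make_hairpin(
    rng: np.random.Generator, config: CohortConfig, index: int
) -> tuple[PrecursorRecord, list[MatureAnnotation], dict[str, str], list[TruthSite], list[TruthMirna]]:
    """Build one hairpin locus with truth annotations.

    Returns the precursor (with structure and genomic locus), its emitted
    annotations (what a miRBase-style table would carry, i.e. excluding
    unannotated arms and using the *annotated* coordinates for shifted
    3p matures), the genome contribution, and the truth rows.
    """
    cfg = config
    pid = f"synpre{index:03d}"
    f5, stem, loop, ml = cfg.flank5_len, cfg.stem_len, cfg.loop_len, cfg.mature_len

    # precursor category
    u = rng.random()
    shifted = u < cfg.shift3p_prob
    unannotated_3p = (not shifted) and u < cfg.shift3p_prob + cfg.unannotated_arm_prob

    # arm placement: 2-nt 3' overhangs on the true duplex by construction
    s5 = int(rng.integers(4, stem - ml + 1))  # start offset within the 5' stem
    arm5 = (f5 + s5, f5 + s5 + ml - 1)
    partner_of_start = f5 + 2 * stem + loop + 1 - s5
    arm3_end = partner_of_start + 2
    arm3 = (arm3_end - ml + 1, arm3_end)

    tissue = str(cfg.tissues[int(rng.integers(0, len(cfg.tissues)))]) if cfg.tissues else ""

    planted: dict[int, bool] = {}
    for cls in (1, 2, 3, 4):
        p = cfg.planted_classes.get(cls, 0.0)
        planted[cls] = bool(rng.random() < p) if p > 0 else False

    # sequence: the class-1 site nucleotide is biased to U when that site
    # carries a planted signal (processing-site motif)
    flank5 = _random_seq(rng, f5)
    stem5 = list(_random_seq(rng, stem))
    loop_seq = _random_seq(rng, loop)
    flank3 = _random_seq(rng, cfg.flank3_len)
    if planted[1] and rng.random() < cfg.class1_u_prob:
        stem5[s5 - 1] = "U"
    stem5_str = "".join(stem5)
    core = flank5 + stem5_str + loop_seq + reverse_complement(stem5_str) + flank3
    structure = "." * f5 + "(" * stem + "." * loop + ")" * stem + "." * cfg.flank3_len

    # genomic embedding with >=50 nt of flank on both sides, random strand
    chrom_name = f"chr{index:03d}"
    gflank5 = _random_seq(rng, 60)
    gflank3 = _random_seq(rng, 60)
    strand = "+" if rng.random() < 0.5 else "-"
    if strand == "+":
        chrom_rna = gflank5 + core + gflank3
    else:
        chrom_rna = gflank5 + reverse_complement(core) + gflank3
    locus = GenomicLocus(chrom=chrom_name, start=61, end=60 + len(core), strand=strand)
    genome = {chrom_name: chrom_rna.replace("U", "T")}

    precursor = PrecursorRecord(
        id=pid, sequence=core, genomic_locus=locus, structure=structure
    )

    # annotations and truth
    conf5 = "HC" if rng.random() < cfg.hc_prob else "LC"
    conf3 = "HC" if rng.random() < cfg.hc_prob else "LC"
    ann3_start = arm3[0] - cfg.shift3p_nt if shifted else arm3[0]

    annotations = [
        MatureAnnotation(pid, f"{pid}-5p", arm5[0], arm5[1], "5p", conf5)
    ]
    if not unannotated_3p:
        annotations.append(
            MatureAnnotation(pid, f"{pid}-3p", ann3_start, arm3[1], "3p", conf3)
        )

    truth_mirnas = [
        TruthMirna(f"{pid}-5p", pid, "5p", True, arm5[0], arm5[1], arm5[0], arm5[1],
                   conf5, tissue, False),
        TruthMirna(f"{pid}-3p", pid, "3p", not unannotated_3p, ann3_start, arm3[1],
                   arm3[0], arm3[1], conf3, tissue, shifted),
    ]

    site_pos = {1: arm5[0], 2: arm5[1] + 1, 3: arm3[0], 4: arm3[1] + 1}
    truth_sites = [
        TruthSite(pid, site_pos[cls], cls, f"{pid}-5p" if cls in (1, 2) else f"{pid}-3p",
                  tissue, planted[cls])
        for cls in (1, 2, 3, 4)
    ]
    return precursor, annotations, genome, truth_sites, truth_mirnas


def build_cohort(config: CohortConfig) -> Cohort:
    """Deterministically build a cohort from its config (seeded)."""
    rng = np.random.default_rng([config.seed, 0])
    precursors: list[PrecursorRecord] = []
    annotations: list[MatureAnnotation] = []
    genome: dict[str, str] = {}
    truth_sites: list[TruthSite] = []
    truth_mirnas: list[TruthMirna] = []
    for i in range(config.n_precursors):
        pre, anns, chrom, sites, mirnas = make_hairpin(rng, config, i)
        precursors.append(pre)
        annotations.extend(anns)
        genome.update(chrom)
        truth_sites.extend(sites)
        truth_mirnas.extend(mirnas)
    return Cohort(config, precursors, annotations, genome, truth_sites, truth_mirnas)


def _scale_counts(counts: dict[str, int], depth: int) -> dict[str, int]:
    total = sum(counts.values())
    if total == 0 or depth <= 0:
        return counts
    factor = depth / total
    return {seq: max(1, round(c * factor)) for seq, c in counts.items()}


def _library_from_counts(counts: Mapping[str, int], sample_id: str) -> DegradomeLibrary:
    total = sum(counts.values())
    lib = DegradomeLibrary(sample_id=sample_id, total_raw=total)
    for seq in sorted(counts):
        lib.tags[seq] = TagRecord(sequence=seq, raw_count=counts[seq], rpm=counts[seq] / total * 1e6)
    return lib


def simulate_degradome(
    cohort: Cohort, tissue: str | None = None, n_ext: int = 50
) -> DegradomeLibrary:
    """Simulate one degradome library over the cohort.

    ``tissue=None`` plants every truth-planted site (a pooled, saturated
    sample); a tissue name plants only the sites of precursors assigned to
    that tissue, giving tissue-specific processing evidence.  Background
    tags have 5' ends uniform over precursor positions that fit a full tag
    and are not themselves planted sites, with low-dispersion counts, so
    the random-decay floor is flat.  Planted tag counts are solved so that
    the realized signal/noise — which includes the other planted
    signatures of the same precursor in its noise mean — approaches the
    configured ``planted_snr`` (capped at 90% of the attainable maximum
    when several strong sites share one precursor).
    """
    cfg = cohort.config
    stream = 1 if tissue is None else 2 + list(cfg.tissues).index(tissue)
    rng = np.random.default_rng([cfg.seed, stream])
    extended = {p.id: p.sequence for p in cohort.extended_precursors(n_ext=n_ext)}
    sites_by_pre: dict[str, list[TruthSite]] = {}
    for s in cohort.truth_sites:
        sites_by_pre.setdefault(s.precursor_id, []).append(s)

    counts: dict[str, int] = {}

    def _add(seq: str, count: int) -> None:
        counts[seq] = counts.get(seq, 0) + count

    nb = cfg.background_tags_per_precursor
    for pre in cohort.precursors:
        seq_ext = extended[pre.id]
        core_len = pre.core_length
        planted_sites = [
            s for s in sites_by_pre.get(pre.id, [])
            if s.planted and (tissue is None or s.tissue == tissue)
        ]
        planted_positions = {s.position for s in planted_sites}

        # background: uniform random-decay floor
        allowed = [p for p in range(1, core_len - 25 + 1) if p not in planted_positions]
        bg_positions = rng.choice(allowed, size=nb, replace=True)
        bg_lengths = rng.integers(18, 26, size=nb)
        bg_counts = rng.integers(8, 13, size=nb)
        for p, ln, c in zip(bg_positions, bg_lengths, bg_counts):
            _add(seq_ext[p - 1 : p - 1 + ln], int(c))

        # isomiR-like neighbours at low abundance
        jitter: list[tuple[int, int]] = []
        b_mean = float(bg_counts.mean()) if nb else 10.0
        for s in planted_sites:
            if rng.random() < cfg.isomir_jitter_prob:
                delta = int(rng.choice([-3, -2, -1, 1, 2, 3]))
                jpos = s.position + delta
                if 1 <= jpos <= len(seq_ext) - 19 and jpos not in planted_positions:
                    jitter.append((jpos, max(1, round(2 * b_mean))))

        # planted signals calibrated to planted_snr
        k = len(planted_sites)
        if k:
            B = int(bg_counts.sum())
            jsum = sum(c for _, c in jitter)
            m = nb + len(jitter) + k - 1
            if k > 1:
                target = min(cfg.planted_snr, 0.9 * m / (k - 1))
            else:
                target = cfg.planted_snr
            c_planted = target * (B + jsum) / (m - target * (k - 1))
            c_planted = max(1, round(c_planted))
            for s in planted_sites:
                if s.position + 20 - 1 <= len(seq_ext):
                    _add(seq_ext[s.position - 1 : s.position - 1 + 20], c_planted)
        for jpos, jcount in jitter:
            _add(seq_ext[jpos - 1 : jpos - 1 + 20], jcount)

    counts = _scale_counts(counts, cfg.depth)
    sample_id = "pooled" if tissue is None else tissue
    return _library_from_counts(counts, sample_id)


def simulate_srna(cohort: Cohort, tissue: str) -> DegradomeLibrary:
    """Simulate one sRNA library with tissue-biased mature abundances.

    Every *true* mature (including unannotated arms) is emitted at a base
    abundance multiplied by ``tissue_bias`` in its precursor's assigned
    tissue, plus a 1-nt 3'-trimmed variant at 20% abundance.  For shifted
    3p matures the (incorrect) annotated sequence is emitted at one fifth
    of the true sequence's abundance, so the true variant dominates its
    arm's sRNA cluster.
    """
    cfg = cohort.config
    by_pre = {p.id: p for p in cohort.precursors}
    counts: dict[str, int] = {}

    def _add(seq: str, count: int) -> None:
        if count >= 1 and seq:
            counts[seq] = counts.get(seq, 0) + count

    base = 100
    for tm in cohort.truth_mirnas:
        pre = by_pre[tm.precursor_id]
        bias = cfg.tissue_bias if tm.tissue == tissue else 1.0
        true_seq = pre.sequence[tm.true_start - 1 : tm.true_end]
        _add(true_seq, round(base * bias))
        _add(true_seq[:-1], round(0.2 * base * bias))
        if tm.shifted:
            ann_seq = pre.sequence[tm.annotated_start - 1 : tm.annotated_end]
            _add(ann_seq, round(0.2 * base * bias))

    counts = _scale_counts(counts, cfg.depth)
    return _library_from_counts(counts, f"srna_{tissue}")


# ---------------------------------------------------------------------------
# Fixture directories

def _write_tsv(path: Path, header: Sequence[str], rows: Iterable[Sequence]) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(header) + "\n")
        for row in rows:
            fh.write("\t".join(str(x) for x in row) + "\n")


def generate_cohort(config: CohortConfig, out_dir: str | Path) -> Cohort:
    """Build a cohort and write it as a cross-consistent fixture directory.

    Emits precursor FASTA (with genomic loci in the headers), genome FASTA,
    annotation and structure TSVs, one degradome tag TSV per tissue plus a
    pooled one, one sRNA tag TSV per tissue, the truth tables, and a
    manifest recording config and seed.  Identical config+seed reproduce a
    byte-identical directory.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cohort = build_cohort(config)

    with open(out / "precursors.fa", "w") as fh:
        for p in cohort.precursors:
            loc = p.genomic_locus
            fh.write(f">{p.id} {loc.chrom}:{loc.start}-{loc.end}({loc.strand})\n{p.sequence}\n")
    with open(out / "genome.fa", "w") as fh:
        for chrom in sorted(cohort.genome):
            fh.write(f">{chrom}\n{cohort.genome[chrom]}\n")
    _write_tsv(
        out / "annotations.tsv",
        ["precursor_id", "mature_id", "start", "end", "arm", "confidence"],
        [(a.precursor_id, a.mature_id, a.start, a.end, a.arm, a.confidence)
         for a in cohort.annotations],
    )
    _write_tsv(
        out / "structures.tsv",
        ["precursor_id", "structure"],
        [(p.id, p.structure) for p in cohort.precursors],
    )
    _write_tsv(
        out / "truth_sites.tsv",
        ["precursor_id", "position", "position_class", "mature_id", "tissue", "planted"],
        [(s.precursor_id, s.position, s.position_class, s.mature_id, s.tissue, s.planted)
         for s in cohort.truth_sites],
    )
    _write_tsv(
        out / "truth_mirnas.tsv",
        ["mature_id", "precursor_id", "arm", "annotated", "annotated_start", "annotated_end",
         "true_start", "true_end", "confidence", "tissue", "shifted"],
        [(m.mature_id, m.precursor_id, m.arm, m.annotated, m.annotated_start, m.annotated_end,
          m.true_start, m.true_end, m.confidence, m.tissue, m.shifted)
         for m in cohort.truth_mirnas],
    )

    def _write_library(lib: DegradomeLibrary, path: Path) -> None:
        _write_tsv(path, ["sequence", "raw_count"],
                   [(seq, lib.tags[seq].raw_count) for seq in sorted(lib.tags)])

    if config.n_precursors > 0:
        _write_library(simulate_degradome(cohort, tissue=None), out / "degradome_pooled.tsv")
        for tissue in config.tissues:
            _write_library(simulate_degradome(cohort, tissue=tissue),
                           out / f"degradome_{tissue}.tsv")
            _write_library(simulate_srna(cohort, tissue), out / f"srna_{tissue}.tsv")
    else:
        _write_tsv(out / "degradome_pooled.tsv", ["sequence", "raw_count"], [])
        for tissue in config.tissues:
            _write_tsv(out / f"degradome_{tissue}.tsv", ["sequence", "raw_count"], [])
            _write_tsv(out / f"srna_{tissue}.tsv", ["sequence", "raw_count"], [])

    manifest = {"seed": config.seed, "config": asdict(config)}
    manifest["config"]["tissues"] = list(config.tissues)
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return cohort
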