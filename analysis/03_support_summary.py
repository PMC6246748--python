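"""Classify prominent signals against mature-miRNA ends and summarize support.

Reads the prominent-signals table, classifies each signal by its offset
from the annotated 5' and 3'+1 processing sites (14 labels), calls
degradome support for matures and precursors, and writes the site-call
table plus a Table-1-style summary with the A/B/C/D chain, HC/LC blocks,
the offset histogram and per-class supported percentages.
"""

import argparse
import math
from pathlib import Path

import pandas as pd

from degratrack import processing_support as ps
from degratrack import sequencing_io as sio
from degratrack.signal_scan import ProminentSignal, map_tags


def read_signals(path: Path) -> dict[str, list[ProminentSignal]]:
    df = pd.read_csv(path, sep="\t")
    out: dict[str, list[ProminentSignal]] = {}
    for r in df.itertuples():
        ratio = math.inf if str(r.ratio) == "inf" else float(r.ratio)
        out.setdefault(r.sample_id, []).append(
            ProminentSignal(
                precursor_id=r.precursor_id,
                position=int(r.position),
                signal=float(r.signal),
                noise=float(r.noise),
                ratio=ratio,
                top_rank=int(r.top_rank),
                passed=True,
            )
        )
    return out


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--cohort", type=Path, default=Path("scratch/cohort"))
    ap.add_argument("--signals", type=Path, default=Path("results/prominent_signals.tsv"))
    ap.add_argument("--out", type=Path, default=Path("results"))
    args = ap.parse_args()
    args.out.mkdir(parents=True, exist_ok=True)

    pres, anns = sio.read_precursors(args.cohort / "precursors.fa", args.cohort / "annotations.tsv")
    extended = sio.extend_precursors(pres, args.cohort / "genome.fa", 50)
    library = sio.load_tag_library(args.cohort / "degradome_pooled.tsv", "pooled")
    mapped = {p.id for p in extended if map_tags(library, p)}
    signals_by_sample = read_signals(args.signals)
    support = ps.call_support(signals_by_sample, anns)
    with_signals = {s.precursor_id for sigs in signals_by_sample.values() for s in sigs}
    summary = ps.summarize(
        pres, anns, support,
        mapped_precursors=mapped,
        precursors_with_signals=with_signals,
    )

    sio.write_results_table(
        [
            {
                "precursor_id": c.precursor_id,
                "mature_id": c.mature_id,
                "end_kind": c.end_kind,
                "offset_label": c.offset_label,
                "position_class": c.position_class,
                "signal_position": c.signal_position,
                "supporting_samples": ",".join(sorted(c.supporting_samples)),
            }
            for c in support.site_calls
        ],
        args.out / "support_calls.tsv",
        "support_calls",
    )
    sio.write_results_table(summary.as_rows(), args.out / "support_summary.tsv", "summary")

    print(f"A={summary.A}  B={summary.B}  C={summary.C}  D={summary.D}")
    print(f"D/A={summary.ratio_DA:.2f}%  D/B={summary.ratio_DB:.2f}%  D/C={summary.ratio_DC:.2f}%")
    print("class supported %:", {c: round(v, 1) for c, v in summary.class_percentages.items()})
    print("unassigned signals (possible unannotated arms):", len(support.unassigned_signals))
    print(f"tables: {args.out / 'support_calls.tsv'}, {args.out / 'support_summary.tsv'}")


if __name__ == "__main__":
    main()
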