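"""Processing-site sequence motifs: supported vs control windows.

Collects the 20-nt windows around class-1 processing sites (site nucleotide
at column 11), split into degradome-supported and same-class unsupported
control sets, and writes both count/frequency/IC matrices.
"""

import argparse
from pathlib import Path

import pandas as pd

from degratrack import annotation_and_motif as am
from degratrack import processing_support as ps
from degratrack import sequencing_io as sio
from degratrack import signal_scan as ss


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--cohort", type=Path, default=Path("scratch/cohort"))
    ap.add_argument("--out", type=Path, default=Path("results"))
    ap.add_argument("--position-class", type=int, default=1, choices=(1, 2, 3, 4))
    args = ap.parse_args()
    args.out.mkdir(parents=True, exist_ok=True)

    pres, anns = sio.read_precursors(args.cohort / "precursors.fa", args.cohort / "annotations.tsv")
    extended = sio.extend_precursors(pres, args.cohort / "genome.fa", 50)
    library = sio.load_tag_library(args.cohort / "degradome_pooled.tsv", "pooled")
    scan = ss.scan_library(library, extended)
    support = ps.call_support({scan.sample_id: scan.signals}, anns)

    supported_sites = {
        (c.precursor_id, c.signal_position)
        for c in support.site_calls
        if c.is_exact and c.position_class == args.position_class
    }
    all_sites = {
        (pid, pos) for pid, pos, _ in am.class_sites(anns, classes={args.position_class})
    }
    control_sites = all_sites - supported_sites

    ext_by_id = {p.id: p for p in extended}
    for name, sites in (("supported", supported_sites), ("control", control_sites)):
        windows = am.motif_windows(sorted(sites), ext_by_id)
        matrix = am.motif_matrix(windows)
        path = args.out / f"motif_class{args.position_class}_{name}.tsv"
        sio.write_results_table(matrix.as_rows(), path, "motif_matrix")
        ic11 = matrix.information_content[am.SITE_COLUMN - 1]
        print(
            f"{name}: {matrix.n_windows} windows, IC at column {am.SITE_COLUMN} = "
            f"{ic11:.3f} bits (max letter {matrix.max_letter(am.SITE_COLUMN)}) -> {path}"
        )


if __name__ == "__main__":
    main()
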