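# degratrack

Tracking microRNA processing signals on hairpin precursors with
degradome-seq (PARE/GMUCT) data.

## The problem

Degradome sequencing captures the uncapped 5′ ends of polyadenylated RNAs.
Because most miRNA genes are transcribed by RNA polymerase II into
polyadenylated primary transcripts, the intermediates left behind by the
two-step cropping of the hairpin precursor — by Drosha/Dicer in animals or
DCL1 in plants — appear in degradome libraries as tags whose 5′ ends sit
exactly at the processing sites.  `degratrack` is for researchers who want
to exploit this: it detects prominent degradome signals on annotated
precursors, asks whether they coincide with mature-miRNA ends, summarizes
degradome support per miRNA/precursor cohort, compares tissue-specific
processing against small-RNA accumulation, and turns degradome + structure
+ sRNA-cluster evidence into concrete re-annotation recommendations.

## The statistic

Tags are mapped to each precursor by exact sense-strand match.  For a
candidate position *p* on a precursor:

- **signal(p)** = mean RPM of the distinct tag signatures whose 5′ ends map
  at *p*;
- **noise(p)** = mean RPM of the distinct signatures mapped anywhere else
  on that precursor;

and *p* is called **prominent** when

```
signal(p) / noise(p) >= r        (default r = 5)
rank(top signature at p) <= k    (default k = 12, ranked by RPM over the precursor)
```

The ratio criterion suppresses the flat background left by random RNA
decay; the rank criterion requires the site to be driven by one of the
precursor's most abundant signatures.  A mature miRNA is
*degradome-supported* when a prominent signal falls exactly on its 5′ end
or on its 3′ end + 1 nt; exact sites are classed 1–4 (5′/3′ site of the
5p/3p arm), and near-miss signals at ±1–3 nt are reported with 14 offset
labels (isomiR-like evidence, never counted as support).

Re-annotation combines three evidence classes per precursor: a prominent
signal at the candidate 5′ site, a canonical miRNA duplex with 2-nt 3′
overhangs on the hairpin structure (dot-bracket input), and top-of-cluster
sRNA abundance.

## Worked example

The whole analysis runs on a ground-truthed synthetic cohort (50 hairpins,
two tissues, planted processing signals at signal/noise 20 over a uniform
decay background):

```
python analysis/01_generate_cohort.py       # writes scratch/cohort/
python analysis/02_scan_signals.py          # detector + recovery scoring
python analysis/03_support_summary.py       # offset calls + cohort summary
python analysis/04_tissue_comparison.py     # tissue specificity vs accumulation
python analysis/05_reannotation.py          # duplex/cluster evidence
python analysis/06_motifs.py                # processing-site motifs
```

prints, among other things:

```
planted recovered:   110/110 (100.0%)
false positives:     0/1142 evaluated positions
A=50  B=50  C=49  D=48
D/A=96.00%  D/B=96.00%  D/C=97.96%
tissueA-specific miRNAs: 100.0% high in tissueA, 0.0% high in tissueB
miR168a-3p worked example: candidate shifted 3 nt from the annotated 5' end
recommendations: {'NONE': 28, 'NOVEL_ARM': 3, 'PROMOTE': 18, 'SHIFT': 1}
supported: 38 windows, IC at column 11 = 1.650 bits (max letter U)
control: 12 windows, IC at column 11 = 0.445 bits (max letter G)
```

Reading this: every planted processing site is recovered at S/N ≥ 5 with
no spurious calls; 48 of 50 precursors end up degradome-supported (A–D are
the cohort, mapped, prominent-signal and supported precursor counts);
miRNAs whose processing is supported only in one tissue's degradome are
the ones highly accumulated in that tissue; the rice miR168a-3p case
reproduces its known 3-nt 5′ shift from the printed sequences; and the U
planted at supported 5p 5′-ends dominates column 11 of the motif matrix
while the unsupported control stays near background.

Tables land under `results/` in fixed, documented TSV schemas
(`prominent_signals`, `support_calls`, `summary`, `recommendations`,
`motif_matrix`).

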