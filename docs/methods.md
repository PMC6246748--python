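# Methods

## Model and assumptions

`degratrack` treats a degradome-seq library as a censused collection of
uncapped 5′ RNA ends.  On a miRNA precursor, three processes generate such
ends: the crops that excise the mature duplex (ends at the mature 5′ ends
and 1 nt downstream of the mature 3′ ends, because the downstream fragment
of each cut starts there), isomiR-producing imprecise crops at ±1–3 nt,
and random exonucleolytic/endonucleolytic decay, which is assumed to
spread 5′ ends broadly over the precursor with no positional preference.
The detector separates the first two from the third purely by positional
concentration of abundance; it does not model cleavage chemistry.

Assumptions worth stating explicitly:

- **Perfect sense-strand mapping.** Tags are matched exactly against the
  precursor (plus optional 3′ genomic extension).  No mismatches, no
  reverse-complement matching: degradome tags are fragments of the primary
  transcript itself.
- **Averaging over distinct signatures.** "Signal" and "noise" are means
  over distinct tag sequences, not over raw reads and not over positions:
  a position covered by one enormous signature and a position covered by
  three modest ones are compared by their mean signature abundance.  A tag
  occurring at several positions contributes one alignment per position,
  each carrying its full RPM (no fractional allocation).  Positions with
  no mapped signature never enter either mean.
- **Per-library prominence.** Signal/noise is computed within one library
  at a time; evidence across libraries is combined downstream as a union
  of support calls, so adding a library can only add support.
- **Zero-noise convention.** A precursor whose signatures all map to one
  position gets ratio +inf there, which passes any finite threshold.

## Parameters that matter

| parameter | default | meaning |
|---|---|---|
| `min_ratio` | 5 | signal/noise threshold; 3 is the permissive and 50 the stringent setting used in the comparative analyses |
| `rank_k` | 12 | the site's top signature must rank among the k most abundant signatures on the precursor |
| `min_tag_len` | 15 nt | tags shorter than this are not mapped (spurious exact matches) |
| `n_ext` | 50 nt | 3′ genomic extension; class-4 sites near the precursor end are undetectable without it because ~20-nt tags starting there overrun the annotated sequence |
| offset window | ±3 nt | near-site signals get one of 14 offset labels; upstream of a site is labelled "+k" (field convention), downstream "−k" |
| accumulation rule | >1 RPM and ≥2× | mature called highly accumulated in tissue A when above both thresholds against tissue B |

RPM normalization divides each tag's raw count by the post-N-filter
library total and multiplies by 10^6; N-containing reads are removed
before the total is computed, so RPM values do not depend on how many
N-reads a file happens to contain.

## Duplex geometry

Dicer/DCL1 products leave 2-nt 3′ overhangs on the miRNA-5p:miRNA-3p
duplex.  Given a dot-bracket structure, for each arm we take the partner
of the arm's first paired position (searching 3′-ward, which also handles
bulges by the nearest-paired-position rule) and measure how far the other
arm's 3′ end extends past it; the duplex is canonical when both overhangs
equal 2.  On perfect stems this reduces to pure coordinate arithmetic,
which the tests use as an independent oracle.  Structures are consumed,
never predicted: folding quality is the caller's responsibility.

## Motif matrices

Windows are the 20 nt around a processing site with the site nucleotide at
column 11 (10 nt upstream, 10 downstream); windows overrunning a precursor
end are skipped.  Information content per column is the uncorrected
IC_j = 2 + Σ_b f_bj log2 f_bj in bits.  No small-sample correction is
applied: the matrices are meant for comparison between a supported set and
a same-class unsupported control of similar size, where the shared
small-sample bias cancels in direction even though absolute IC values of
small sets are inflated (the bias is ≈ 3/(2·ln2·n) bits per column).

## The synthetic cohort

The generator emulates the study conditions the pipeline is built for, and
is itself first-class, tested code.

- **Hairpins.** A perfect stem (default 30 bp, exact reverse-complement
  pairing) with a 12-nt loop, flanked by single-stranded 15-nt 5′ and 5-nt
  3′ segments, as real pri-miRNA fragments are; the flanks also give
  class-1 sites enough upstream sequence for full motif windows.  Mature
  arms (21 nt) are placed so the true duplex has 2-nt 3′ overhangs by
  construction; the emitted dot-bracket matches the construction.  Each
  hairpin is embedded in its own synthetic chromosome with 60-nt flanks on
  a random strand, so 3′ extension exercises real coordinate arithmetic.
- **Degradome libraries.** Per precursor, 25 background tags (lengths
  18–25 nt) with 5′ ends drawn uniformly over positions that fit a whole
  tag and are not planted sites, with low-dispersion counts (8–12) —
  a deliberately flat random-decay floor.  Planted tags sit exactly at the
  true sites of classes 1/3/4 (each with probability 0.7 per site; class 2
  is never planted, matching its strong depletion in real data).  Planted
  counts are solved self-consistently so the *realized* signal/noise —
  whose noise mean includes the other planted signatures on the same
  precursor — approaches the configured target (default 20).  With three
  planted sites on one precursor the realized ratio has an asymptote of
  (n_bg + k − 1)/(k − 1) ≈ 13.5, so the solver caps the target at 90% of
  the asymptote; realized ratios then fall in roughly 12–20, inside the
  factor-two band around the target.  IsomiR-like neighbours at ±1–3 nt
  appear with probability 0.1 at about twice the background abundance.
  Class-4 tags necessarily extend into the genomic 3′ flank, so their
  detection requires the 50-nt extension.  Counts are rescaled to a total
  library depth of 500 000 reads.
- **Tissues.** Each precursor is assigned one tissue.  A tissue's
  degradome library plants only its own precursors' sites (`tissue=None`
  gives a pooled library planting everything).  Its sRNA library carries
  every true mature at a base abundance, multiplied by 4 in the assigned
  tissue, plus 1-nt trimmed variants at 20%; this couples
  tissue-specific processing evidence to tissue-biased accumulation.
- **Re-annotation patterns.** 5% of precursors carry a true 3p mature 3 nt
  shorter (5′) than its annotation, with the true variant dominating the
  3′ sRNA cluster and the degradome signal at the true 5′ site; 10% are
  annotated on the 5′ arm only while the 3′ arm still produces signals
  and sRNAs.  These drive the SHIFT and NOVEL_ARM recommendations.
- **Motif planting.** The class-1 site nucleotide is set to U with
  probability 0.9 when that site carries a planted signal, so the
  supported motif set shows the 5′-U preference while the unsupported
  control does not.

What the cohort does **not** emulate: sequencing errors and quality
artefacts, bulged or imperfect stems (the bulge path of the duplex rule is
tested on handcrafted structures instead), non-uniform decay landscapes,
multi-locus tag ambiguity, and expression dynamics beyond a single fold
bias.  Passing on this cohort therefore shows the machinery is correct
under its stated model, not that the thresholds are optimal for any
particular real library.

## Numerical and design choices

- Coordinates are 1-based inclusive on the precursor sense strand;
  extensions never shift existing coordinates.  DNA input is converted to
  RNA on read; case-insensitive.
- Rank ties share the better rank, so a site tied at the 12th abundance
  qualifies.
- Signals within 3 nt of the sites of two overlapping matures are
  assigned to both; within one mature, the nearer site wins and an exact
  tie goes to the 5′ site.
- Prominent signals more than 3 nt from every annotated site are reported
  separately (they may mark unannotated-arm processing) and never counted
  in support ratios.
- Chi-square is Pearson's with df = 1 and no continuity correction,
  computed via `scipy.stats.chi2_contingency`; the closed form
  N(ad−bc)²/((a+b)(c+d)(a+c)(b+d)) serves as an independent cross-check in
  the tests.  No multiple-testing correction is applied; raw p-values are
  reported.
- Mature sRNA levels default to exact-sequence RPM; an optional window
  aggregates 5′/3′ variants within ±k nt.
- Results tables have fixed column orders, 4-decimal floats and
  deterministic sort keys; reruns are byte-identical.
- Problem sizes in the shipped analyses (50 precursors, ~1 300 tags per
  library, two to five tissues) were chosen so the full pipeline and its
  cross-checks run in seconds while every per-precursor regime — zero, one
  or three planted sites — is well represented.

## Known limitations

- "Averaged read count" admits several readings (per read, per signature,
  per position); the per-distinct-signature reading used here changes
  absolute ratios relative to the alternatives, though not the ranking of
  strongly concentrated sites.
- Whether the abundance rank should be computed per precursor per library
  or pooled across libraries is a genuine choice; per precursor per
  library is used, matching per-dataset prominence.
- Duplex overhangs on heavily bulged stems depend on the
  nearest-paired-position convention and should be reviewed visually for
  borderline re-annotation calls.
- The re-annotation logic emits at most one recommendation per precursor,
  preferring SHIFT over NOVEL_ARM over PROMOTE; precursors with several
  competing stories surface only the strongest pattern.
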