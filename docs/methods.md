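# Methods notes

## Scoring model

A phenotype-microarray well reports a colorimetric signal over 72 h of
incubation; respiration on the well's sole nitrogen source reduces a
tetrazolium dye, so cumulative color is a proxy for substrate
consumption.  The pipeline reduces each curve to its area under the
curve (AUC) on the recorded time grid by the trapezoid rule — no
resampling, smoothing or curve-shape fitting, since the quantity of
interest is plain cumulative signal and the trapezoid integral is exact
for piecewise-linear signals on their own grid.  Replicates are averaged
at the AUC stage rather than the curve stage so that replicates with
unequal time grids remain comparable.

Each strain × plate pair carries its own negative-control and
L-glutamine positive-control wells.  The blanked, normalized consumption
of a well is

    p = 100 · max(AUC − AUC_neg, 0) / (AUC_gln − AUC_neg)

Blanking against the negative control is on by default (and can be
turned off via `blank=False` / `--no-blank`): the negative control
captures spontaneous dye reduction and inoculum carry-over, which would
otherwise inflate weak wells.  A plate whose glutamine AUC does not
exceed its negative control has no usable dynamic range and raises a
`DegeneratePlateError` naming the strain and plate rather than emitting
nonsense percentages.

Percentages are discretized into six levels with half-open bins
(20, 40], (40, 60], (60, 80], (80, 100], (100, ∞); p = 20.0 is level 0
because a substrate counts as utilized only *above* 20 % of the
glutamine control.  The printed-style "21–40 %" ranges are read as
continuous intervals, not integer percents.  Missing wells propagate as
missing values (`<NA>` in the level matrix), never as level 0, so an
absent measurement can never masquerade as a negative call.

## Comparative analyses

Set algebra uses the utilization rule (level ≥ 1, i.e. > 20 %) by
default; `min_level` tightens it, and `level_difference_set` provides
the level-aware contrast (combo level minus best single level ≥ d) used
to isolate strong-synergy substrates.  Positional composition reports
raw counts, within-set frequencies and fold enrichment over a background
set at the N-terminus, C-terminus or any position; no significance test
is attached to the fold ratios themselves, but a permutation p-value
(equal-size resamples from the background) is available as an explicitly
optional layer.

Clustering is agglomerative (scipy) on the integer level vectors with
Euclidean distance and average linkage by default; the metric and
linkage are exposed because nothing in the underlying experimental
design dictates them.  Missing levels are treated as 0 for distance
computation.  Leaf order is scipy's deterministic dendrogram order
without optimal leaf ordering, so merge-height ties resolve by input
index and repeated runs are identical.  Trees export to Newick with
branch lengths equal to merge-height differences.

## Promoter scanning

Windows are the 500 bp immediately upstream of a start codon (1-based
inclusive coordinates; truncated-and-flagged at contig edges; minus-
strand genes use the reverse complement of the downstream-in-contig
block).  PWMs are additive per-position scores over A/C/G/T; matrices
supplied as base frequencies are converted to log₂-odds against a
uniform background with pseudocount 0.01.  A window's relative score is
min–max rescaled, (s − s_min)/(s_max − s_min) ∈ [0, 1], and both strands
are scanned; hits must exceed the cutoff strictly (default 0.95).
Min–max rescaling was chosen over percent-of-raw-maximum because the
latter is ill-behaved for matrices with negative entries; the cutoff
comparison and convention are configurable.  Positions overlapping an N
are skipped rather than scored.

## qPCR quantification

The relative standard-curve method: per gene, a straight line
Ct = slope·log₁₀(q) + intercept is least-squares fitted to a genomic-DNA
dilution series (≥ 3 distinct dilutions required); efficiency is
10^(−1/slope) − 1, so perfect doubling gives slope −1/log₁₀2 ≈ −3.3219.
Unknown Ct values are interpolated to quantities and target genes are
divided by the SCR1 reference gene's quantity in the same sample, which
cancels the arbitrary unit of the standards (quantities are treated as
arbitrary units throughout, since dilution factors carry no absolute
calibration).  Replicate Ct values are averaged before interpolation by
default, following instrument-vendor convention; per-replicate
quantification with mean ± sd reporting is available.  Group comparisons
(one-way ANOVA plus Tukey HSD via statsmodels) are deliberately
off-the-shelf statistics layered on top of the quantification.

## Protein identity

Global alignment with BLOSUM62, gap open 10 / extend 0.5 (Biopython's
PairwiseAligner); percent identity is matches over alignment length
including gap columns, with matches-over-shorter-sequence as an option,
because both denominators are common and the choice matters at the
90–99 % identities typical of transporter paralogs.  The test suite
cross-checks optimal scores against an independently written Gotoh
affine-gap dynamic program on short sequences.

## Synthetic data

The simulators generate every input format the pipeline reads, always
paired with a truth table, and are deterministic given their seed.

Kinetic wells follow baseline + A·logistic((t − t₀)/τ) + N(0, σ),
clipped at zero, on 97 points over 72 h (15-min-to-hourly reader
cadences bracket this; 45-min spacing is a plausible middle).  Defaults:
baseline 50, glutamine amplitude 200 signal units, midpoint 24 h, shape
scale 4 h, two replicates (plates are typically run in duplicate).  The
amplitude for a planted level is chosen so the noiseless blanked,
normalized AUC lands at the *center* of the level's bin (30/50/70/90 %
for levels 1–4, 110 % for level 5): since baseline and the logistic
integral cancel in the normalization, the planted percent is exact at
zero noise and recovery is unambiguous; bin-edge behavior is exercised
separately with explicit edge values.  At σ = 5 % of the glutamine
amplitude with three replicates the AUC noise is far below a bin's 20-
point width, so level recovery remains essentially exact — the
acceptance suite asserts ≥ 95 % exact and ≥ 99.5 % within ±1.

The `paper_like` preset plants, on the default 284-substrate catalog, a
panel of 11 strains whose set relations encode the study design: a wild
type consuming 207 substrates (195 dipeptides, 12 tripeptides); two
Fot1–Fot2 strains at 191 and 189 differing only in Gly–Leu and Lys–Trp
at level 1; a 59-substrate synergy set consumed by the pair strains but
by neither single-transporter strain, 21 of them at level 4 versus 0,
and biased toward Gly/Trp at the termini and Glu/Pro/Asp at the
C-terminus; a 14-substrate fraction (12 dipeptides, 2 tripeptides, all
with N-terminal Gly) consumed only by strains retaining the non-Fot
transporters; single-transporter ranges of 152/110/99 with nested
overlap so the narrow-range strains cluster together; three weakly
consumed dipeptides (His–Pro, Thr–Ser, γ-Glu–Gly) shared by every
strain including the full knockout; and D-/β-modified peptides consumed
by no strain.  The printed per-strain counts are not mutually exact set
identities, so two additional wild-type-only substrates reconcile them;
unpinned consumed cells draw levels 1–5 from a seeded mildly
decreasing distribution.  The preset emulates set structure and
amplitude coding, not instrument artifacts (edge effects, drift,
plate-position covariance) — passing tests demonstrate correctness of
the analysis path, not calibration to any real reader's signal scale.

The promoter simulator plants motif consensus sequences at known
positions in i.i.d. background of configurable GC content; the qPCR
simulator generates standards and unknowns from known quantities and a
known efficiency.  Both are exact at zero noise.

## Default substrate catalog

The vendor's true well maps are proprietary, so the default catalog is
a generated stand-in honoring the published composition: 270 dipeptides
(258 unmodified, 12 D-/β-/γ-modified) and 14 tripeptides across four
96-well plates, each with negative and glutamine control wells at A1/A2.
All peptides named in the analyses, all 20 Gly-X dipeptides and the
modified set are pinned; the remaining dipeptides are a fixed-seed draw
from the unused residue pairs, so the catalog is identical across runs.
Real well maps can be supplied as a catalog TSV and override the
default everywhere.

## Numerical and interface choices

* Peptide names accept hyphen, en- or em-dashes and Greek or Latin
  modifier prefixes; canonical rendering uses three-letter codes,
  en-dashes and Greek prefixes (`γ-Glu–Gly`).
* The default residue classification (hydrophobic AVLIMFWGP; polar
  uncharged STCYNQ; charged DEKRH) places Gly, Pro and Trp with the
  hydrophobic panel, matching how peptide-preference panels group
  Gly-X/Pro-X/Trp-X substrates; it is a YAML-swappable scheme because
  the placement of these three residues is a judgment call.
* All tabular formats are TSV with a reader for every writer;
  write∘read∘write is byte-stable.
* Problem sizes in the test and acceptance runs — the full 284-substrate
  × 11-strain panel at 97 timepoints, 2–3 replicates — are the package's
  native working scale; a complete run takes a few seconds.

## Known limitations

* Consumption levels are AUC-based only; lag time and maximal rate are
  out of scope.
* The simulators do not model instrument drift, well-position effects
  or non-Gaussian noise.
* The identity module reports alignment identity under one scoring
  scheme; it does not attempt to reproduce values computed with other
  aligners or parameterizations.
* PWM scanning reports per-window hits without motif-enrichment
  statistics.
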