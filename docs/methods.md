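# Methods

`cerna_screen` implements an in silico screen for candidate ceRNA
(competing endogenous RNA) relationships: lncRNAs that may act as
miRNA sponges, detected as (lncRNA, miRNA) pairs that are both
sequence-predicted targets and significantly anti-correlated in
expression across a patient cohort. This note documents the models,
the defaults and why they are what they are, the synthetic benchmark,
and the known limitations.

## Probe re-annotation and summarization

Array probes are intersected with two exon annotations: a coding
("Ensembl-like") set and a lncRNA ("LNCipedia-like") set. A probe is
*univocally referable* to a lncRNA when it (a) overlaps at least one
lncRNA exon, (b) overlaps no coding transcript, and (c) every lncRNA
transcript it touches belongs to one gene. All other probes are
dropped with a reason code (`coding_overlap`, `no_hit`,
`ambiguous_gene`); the four outcomes partition the probe set. Overlap
requires a single base, is computed on exons (a `gene_body` flag
includes introns, since array designs differ on this point), and
ignores strand by default — arrays report probe strand inconsistently,
and strand-blind overlap is the conservative choice when the purpose
is to *discard* anything possibly coding. Probe-level expression of
surviving probes is summarized per lncRNA gene as the per-sample
median (even counts: mean of the central pair). Coordinates are
0-based half-open internally (BED convention); GFF3 is converted on
load and all reported site coordinates are 1-based inclusive.

## Feature selection

Two inclusion filters are combined by union, then an exclusion filter
is applied to lncRNAs:

1. **Permutation differential expression (SAM-style).** Per feature,
   `d = (mean_tumor − mean_normal) / (s + s0)` with `s` the pooled
   two-sample standard error and `s0` an exchangeability factor chosen
   on a grid of percentiles of `s` (plus 0) minimizing the coefficient
   of variation of the median absolute deviation of `d` across
   s-quantile bins. The null is built from label permutations — all
   distinct assignments when there are at most `n_permutations`
   (default 1000) of them, otherwise that many random shuffles. Each
   feature's q is the 90th percentile of null exceedance counts at its
   |d|, divided by the observed count, capped at 1 and made monotone
   non-increasing in |d|; a feature is selected when this q equals the
   threshold (default 0, i.e. the null stays entirely below the
   feature's |d| in at least 90% of permutations). The comparison uses
   the tumor and normal groups only.
2. **Variation filter.** Keep features whose IQR (or SD) across the
   comparison samples reaches the 0.75 across-feature quantile. The
   filter is label-free; it exists because disease cohorts with
   heterogeneous genetic backgrounds contain features that are highly
   variable without being uniformly shifted against normals.
3. **Immunoglobulin-region exclusion (lncRNAs only).** lncRNAs whose
   cytoband starts with `14q32`, `2p` or `22q` are removed: apparent
   expression at the immunoglobulin loci reflects the polyclonal
   antibody repertoire of plasma cells rather than a lncRNA. Matching
   is string-prefix based so band labels of mixed resolution compare
   correctly ("14q32.33" matches "14q32").

The SAM and variation filters are also exposed as scikit-learn
`SelectorMixin` estimators (`SamSelector`, `VariationFilter`) for use
in sklearn pipelines.

## Target prediction

Sites of a miRNA on a transcript are defined by four constraints, all
configurable with these defaults: seed of 7 bases (miRNA positions
2–8) pairing antiparallel with at most 1 mismatch and at most 1 G:U
wobble (a wobble counts as paired and consumes its own budget); at
least 12 paired bases (Watson-Crick or G:U) over the full miRNA length
after gapless extension of the seed register; and duplex free energy
at most −12 kcal/mol.

Free energy uses a Turner-style nearest-neighbor model embedded in
`thermo.py`: one duplex-initiation penalty (+4.09 kcal/mol), a stack
term for every step of two adjacent pairs (Xia et al. Watson-Crick
values; Turner-style wobble values), and a +0.45 terminal penalty per
helix end closed by A:U or G:U. Unpaired positions break stacking, so
a duplex with interior loops is scored as independent helices sharing
one initiation term. The table is symmetric under duplex reversal and
covers all 36 steps of the six pair types.

**Empirical significance.** Each site's ΔG is compared with the null
distribution of the best ΔG the same miRNA attains on
dinucleotide-preserving shuffles of the transcript (Altschul–Erickson
Euler-walk shuffle; candidate sites on shuffles satisfy the seed and
pairing constraints, with the energy itself serving as the test
statistic). `p = (1 + #{shuffles with ΔG_null ≤ ΔG_site}) / (1 +
n_shuffles)` — add-one corrected, never zero, deterministic given the
configured seed. The default is 500 shuffles: the achievable q after
Benjamini–Hochberg correction is bounded below by roughly
`m / (k (n_shuffles + 1))` for `m` tested sites of which `k` reach the
floor, and a typical run of this screen tests a few hundred sites, so
500 shuffles keep floor-level sites comfortably below the 5% FDR
working point while 200 would sit at its edge. Benjamini–Hochberg runs
over all tested sites of a batch.

**Alignment predictor.** A miRanda-like local alignment: affine-gap
Smith–Waterman on complementarity (+5 Watson-Crick, +1 G:U, −3
mismatch, −9/−4 gap open/extend, substitution scores ×4 at miRNA
positions 2–8), run with no score or energy cutoff; any
positive-scoring alignment is a hit. With unrestricted thresholds the
hit decision reduces exactly to "some miRNA base can pair with some
transcript base", which is evaluated in closed form; the full dynamic
program supplies scores for reported pairs and is cross-checked
against an independent implementation in the tests.

**Consensus.** A (miRNA, transcript) pair is retained when it has at
least one duplex-predictor site with q strictly below 0.05 *and* an
alignment-predictor hit. The per-pair best site (lowest q, ties by
lowest ΔG) is reported with 1-based inclusive transcript coordinates.
Prediction is per transcript; downstream correlation uses gene-level
expression with transcript-level site annotation.

## Correlation screen and replication

Consensus pairs are correlated (Pearson by default, on log2 values;
Spearman by flag) across the discovery-cohort samples (tumor samples
only by default). Two-sided p-values are BH-adjusted over all tested
pairs, and pairs with negative coefficient and q < 0.05 are the
candidates. Replication recomputes the correlation in an independent
cohort and flags candidates with negative coefficient at raw p < 0.05
— raw deliberately, because replication tests only the handful of
already-screened pairs. Zero-variance or missing features are
reported with a status, never as undefined coefficients. A two-sided
Wilcoxon rank-sum utility (exact for groups of ≤ 10 without ties,
tie-corrected normal approximation otherwise) is provided but is not
wired into the default funnel.

## Synthetic benchmark

The generator emulates the study design end to end: a toy genome with
two-exon lncRNA genes on four chromosomes, per-gene probes (3 by
default), decoy probes overlapping a coding annotation placed in host
introns (exactly `n_decoy_coding_overlaps` of them), lncRNAs on
immunoglobulin cytobands, transcript sequences of 400–800 nt
(LNCipedia-like median lengths) with a mildly AU-rich composition
(A/C/G/U = 0.3/0.2/0.2/0.3), and random 20–23-nt miRNAs.

A planted sponge pair embeds the exact reverse complement of miRNA
positions 1–16 in the host transcript; miRNAs are drawn with at least
6 G/C among those positions so the embedded duplex is always far below
the −12 kcal/mol threshold (a full Watson-Crick 16-mer with 6 strong
pairs is bounded below −17 kcal/mol under the stack table).
Expression couples each planted pair through a latent factor z,
standardized to zero mean and unit variance across samples so effect
sizes hold exactly per draw: the miRNA row gets +z, every probe of the
partner lncRNA gets −`sponge_strength`·z, plus N(0, noise_sd) noise on
a per-feature baseline drawn uniform on log2 scale [4, 10].
Differential features (10% of each side, disjoint from planted ones)
gain `de_effect` (default 2) in tumor groups. Defaults are the
benchmark conditions: 200 lncRNAs × 100 miRNAs, 20 planted pairs at
loading 0.9, noise SD 0.4, and groups MM:44, PCL:12, normal:4.
Annotations, sequences and expression use three RNG streams spawned
from the master seed, so artifacts regenerate independently and
byte-identically.

What the generator does *not* emulate: raw array intensities and
normalization, batch effects, correlated decoy structure (decoy
features are independent noise), genome-scale annotation complexity,
isoform diversity (one transcript per gene), and any mechanistic
titration model of sponging — the latent factor is the simplest
generator of the anti-correlation the screen is designed to detect.
Passing the recovery benchmark therefore demonstrates the pipeline's
internal consistency and statistical calibration, not performance on
real cohorts.

## Numerical and design choices

- Even-count medians take the mean of the central pair; quantiles use
  linear interpolation throughout.
- The q threshold in the consensus is a strict inequality (q < FDR);
  a site at exactly 0.05 is excluded.
- Seed origin is miRNA position 2 (canonical convention); extension is
  gapless because a paired-base count is well-defined only for an
  ungapped register, while the alignment predictor supplies gapped
  sensitivity.
- Correlation method defaults to Pearson on log2 intensities; the
  discovery screen uses BH q-values, replication uses raw p — the
  asymmetry mirrors how discovery and confirmation cohorts are
  treated.
- One master seed fans out to stage seeds at fixed offsets; every
  stochastic component (permutations, shuffles, generator) is seeded
  and reruns are byte-identical.
- Degenerate inputs: all-equal `s` gives s0 = 0; empty probe
  assignments, empty consensus sets and zero-variance features produce
  empty outputs or status flags with warnings, not errors.

## Problem sizes in the shipped checks

The automated checks run the benchmark at 200×100 features with 10
master seeds for the recovery suite and 3 for the reproduction script,
500-shuffle site nulls, and 500–1000 permutation SAM nulls; these
sizes keep each check's full-fidelity statistics while completing on a
single CPU in minutes.

## Known limitations

- The duplex-energy surrogate enforces the four stated constraints and
  an empirical shuffle significance; it does not reproduce any
  particular external predictor's pattern-discovery machinery, site
  boundaries or scores bit-for-bit.
- The permutation-FDR "90th-percentile = 0" selection rule keeps its
  intrinsic ~10% chance of calling at least one feature under a
  complete null (the observed labeling is exchangeable with the
  permutations); this is a property of the rule, not of the
  implementation.
- With few normal samples (the default has 4) the supervised contrast
  is weakly powered; the union with the variation filter is what makes
  the funnel robust.
- Cytoband exclusion is prefix-string based and only as good as the
  supplied band labels.
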