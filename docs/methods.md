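# Methods

## Segregation data model

A tetrad is stored as one 4 × M int8 matrix per chromosome over
{P1, P2, MISSING}; marker positions are 1-based base pairs, strictly
increasing. Each marker's segregation class is the counted P1:P2 ratio
(2:2, 3:1, 1:3, 4:0, 0:4), INCOMPLETE when any call is missing. For a
2:2 marker the *phase* is the unordered pair of spores carrying P1.
Event intervals are reported on breakpoint bounds: a crossover interval
spans the two flanking informative markers, a tract interval the first
and last converted markers.

Markers that segregate 4:0/0:4 in two or more tetrads of a batch are
treated as genotyping/marker artifacts and masked (set to MISSING) in
every tetrad before calling; a removal report lists them. Markers
aberrant in a single tetrad are retained — they are the only evidence
for genuine two-chromatid conversions and feed the E6 class. Masked
markers behave as neutral gaps downstream: they carry no phase, do not
break a phase comparison, and do not join two conversion runs (two
tracts separated only by a masked marker stay separate events).

## Event calling

Within one chromosome, conversion tracts are maximal runs of
consecutive non-2:2 markers. The converted strand(s) are the spores
whose calls deviate from their expected parental allele, with the
expectation taken from the nearest informative 2:2 marker on each side;
the union over the two sides is reported. When the two flanks agree
(SAME_PHASE) this pins the converted strand exactly. When they differ
(PHASE_CHANGE) the tract is crossover-associated and the conversion is
intrinsically two-fold ambiguous — the junction may sit at either tract
edge, so the deviation is a single strand against *either* flank — and
the tract deliberately reports the two-candidate set, which coincides
with the crossover's strand pair. At a chromosome end (EDGE) the single
available flank is used.

Crossovers are phase changes between consecutive informative 2:2
markers: a Hamming distance of 2 between P1-spore sets is one CO on the
two switching strands; distance 4 is a four-strand double CO (two
events, strands paired by sorted order). When conversion runs lie
between the two markers the CO is attached to the first run's interval;
one phase change yields exactly one attachment regardless of how many
runs sit in between. A chromosome with fewer than two informative 2:2
markers yields no calls (no phase is definable) and a warning.

Nearby events are merged by single-linkage clustering at a 5 kb gap,
measured between closest footprint endpoints; groups are maximal under
transitive closure and independent of input order.

## Classification

The decision order is total and exhaustive; every group gets exactly
one label:

1. no CO, one tract on one strand → **E1**;
2. no CO, ≥2 single-strand tracts all on one strand → **E4**;
3. one CO, no tract or a single run attached to it on its strands →
   **E2**;
4. one CO with additional/discontinuous conversion on its strands →
   **E3**;
5. two COs → **E5** (**E5A** when both involve the same strand pair);
6. no CO, conversion on ≥2 strands (including 4:0 tracts) → **E6**;
7. anything else (≥3 COs, or conversion on a non-CO strand) → **E7**.

E1–E4 and E5A follow their published definitions; the E5/E6/E7
boundaries are this package's documented reconstruction of the
remaining space (compatible with, but not guaranteed identical to, the
original groupEvents program, whose full rules are not public). An
enumeration oracle — every ≤2-event configuration on a six-marker
scaffold, labeled directly from the definitions with minimal-explanation
matching — agrees with the pipeline on all 5 238 enumerable cases.

Tract lengths are reported in three conventions: *min* spans the
converted markers, *max* the nearest flanking unconverted markers, and
*mid* their average — the default for medians, as it is unbiased
between the two bounds under uniform marker placement. Note that *mid*
inflates short tracts by about half the marker spacing, so simulated
medians are recovered within the marker resolution, not exactly. A CO
without conversion has a zero tract, excluded from "non-zero tract"
medians. Edge tracts (one flank missing) extend *max* on the flanked
side only and are flagged.

Per-tetrad summaries derive CO = E2+E3, NCO = E1, NCO_disc = E4 and
IH_total = Σ all classes (E5A counted within E5's family); they are
never stored independently.

## Simulator

One meiosis starts from four chromatids, spores (0,1) ≡ P1 and (2,3) ≡
P2. Crossover breakpoints follow a stationary gamma-renewal process per
chromosome: inter-arrival Gamma(shape, scale) with the scale set so the
expected genome-wide count equals `mean_co_per_meiosis` (90 by default)
apportioned by chromosome length; the first arrival uses the exact
equilibrium delay U·Gamma(shape+1), so the proportionality holds for
any shape. Shape 1 is a Poisson process (no interference; count exactly
Poisson); the default shape 2 gives the even spacing characteristic of
crossover interference in yeast.

Physically a crossover joins two non-sister chromatid backbones, and
earlier junctions determine which spore is travelling on which backbone.
The simulator therefore samples the *observable* switching spore pair
from the running 2:2 phase (one spore out of the current P1 set, one
in, uniformly) — distributionally identical to a uniform non-sister
backbone pair — which makes painting exact: crossovers are applied in
position order as reciprocal exchanges of the distal marker segment
between the two recorded spores, then conversion tracts flip the
recipient strand's calls inside their interval(s). Truth records carry
the switching spores, the tract interval(s) and the recipient strand.

Tract lengths are lognormal, parameterized by median (scale = ln median,
sigma = `tract_dispersion`); a CO-associated tract starts at the
breakpoint and extends to one side on one of the two exchanged strands,
side and strand uniform; NCO tracts are centred on a uniform position
on a strand chosen uniformly from four. With probability
`p_discontinuous` a tract is split into two sub-tracts around a
restored internal segment, emulating patchy heteroduplex repair.
Corruption is applied batch-wise: per-call allele flips at
`genotyping_error`, and with `shared_artifact_rate` per marker a forced
4:0 call in *every* tetrad — the artifact class the shared-aberrant
filter is designed to remove.

Defaults are the wild-type study conditions: 90 COs and 41
detectable-scale NCOs per meiosis, CO/NCO tract medians 1790/1460 bp,
16 chromosomes with real *S. cerevisiae* sizes (12.07 Mb total).
Values the source data do not pin down were fixed once at realistic
levels: `p_co_assoc_tract` = 0.9 (most crossovers carry a detectable
tract), `tract_dispersion` = 0.75 (heavy right tail, sub-kb tracts
common), `p_discontinuous` = 0.05 (discontinuous NCOs are a ~2% minority
of events), marker spacing 500 bp (a dense hybrid SNP map), and
genotyping error and artifact rates 0 by default because the assays the
pipeline emulates work from already-filtered genotypes; corruption is
opt-in for robustness experiments. The true (not detectable) NCO count
per meiosis is unidentifiable from marker data, so
`calibrate_detectable_nco` estimates the marker-visibility fraction by
Monte Carlo and inflates the generated mean to hit a target *called*
count when needed.

What the generator does not emulate: recombination hot/cold spots and
centromere/telomere suppression, post-meiotic segregation, non-uniform
SNP density, aneuploidy, and read-level genotyping noise. Passing
round-trip tests therefore shows the calling/classification machinery
is correct on data satisfying the model's assumptions, not that real
genomes are free of additional structure.

## Caller-vs-truth scoring

`truth_recall` compares called crossover counts with the truth per
tetrad and scores conversion-tract strand assignment. A tract enters
the strand-scoring denominator only if it is *identifiable in
principle*: it covers ≥1 marker, both flanking markers exist (a tract
clipped at a chromosome end has one flank and cannot be attributed),
and no other planted event intrudes into its flank window (two
conversions with no 2:2 marker between them, or a conversion abutting a
foreign junction, are not attributable by any caller from segregation
data alone — about 2% of tracts at study defaults). A match is the
exact recipient strand or, for a crossover tract, the two-candidate
pair. At study defaults with 1 kb markers and no error, 50 tetrads give
a mean called CO within sampling error of the configured 90 (a ≈1%
systematic shortfall comes from crossovers beyond the terminal markers
and end-clipped associated tracts) and 100% strand agreement on
identifiable tracts.

## Statistics

Count comparisons use Welch's unequal-variance two-sided t-test (group
sizes differ between genotypes; with zero variance in both groups and
equal means, t = 0 and p = 1 by convention). Tract-length comparisons
use the Mann-Whitney rank-sum test with midranks for ties and the
tie-corrected normal approximation without continuity correction
(identical samples give p = 1 exactly), or the two-sample
Kolmogorov-Smirnov test. Per-chromosome regressions are OLS of the
mean count per chromosome on chromosome length; against a reference
genotype each chromosome is tested by Welch's t and flagged at p < 0.05
with no multiple-testing correction by default (a Benjamini-Hochberg
option exists), matching the per-chromosome asterisk convention.
Chromosome size classes are small < 0.5 Mb, medium 0.5–0.9 Mb,
large > 0.9 Mb.

## Classical assays

Fluorescent tetrads with RFP/CFP in repulsion are typed PD {R,R,C,C},
TT {R,C,RC,–}, NPD {RC,RC,–,–}; any other pattern is aberrant. Because
the assay cannot distinguish NPDs from meiosis-I nondisjunction, NPD
patterns are excluded from the scored total by default (configurable).
Phenotypes against wild-type and null controls use 2×2 χ² (TT vs
non-TT) without continuity correction at p < 0.01 — at the assay's
n ≥ 250 the correction changes no call; a warning is issued when an
expected cell drops below 5.

Perkins distances use cM = 100·(TT/2 + 3·NPD)/n with the SE computed
from per-tetrad scores {0, 0.5, 3}: SE = 100·sd/√n, which matches a
resampling bootstrap within a few percent.

Spore-viability summaries report the 4/3/2/1/0-viable class
frequencies, %SV, and an MI-nondisjunction index (the fraction of
tetrads in the {4,2,0} classes, elevated when meiosis-I nondisjunction
kills spores in pairs); strain comparisons use 2×2 χ² on viable vs
inviable spores.

Fluctuation analysis uses the Lea-Coulson method of the median: the
median revertant count r̃ solves r̃ = m·(1.24 + ln m) (solved by Brent's
method on the increasing branch; r̃ = 1.24 ⇒ m = 1), and the rate is
m/N for N cells per culture. The 95% CI takes Dixon-Massey
order-statistic bounds on the median count (largest rank l with
P(Bin(n,½) < l) ≤ 0.025 and its mirror) and pushes each bound through
the same transform; an all-zero median is reported as below detection
with a half-count bound. The estimator choice among the classical
variants is deliberate and swappable; simulation at m = 10 recovers the
true rate within a few percent, well inside the method's documented
bias envelope. Rates are normalized to the wild-type median (fold
change) and phenotyped by CI overlap: wild-type-only overlap "+",
null-only "−", neither "±", both indeterminate (a case the overlap rule
alone cannot resolve).

## Pipeline and reproducibility

`run_pipeline` executes load/simulate → shared-4:0 filter → call →
group → classify → summarize → stats, writing every stage as TSV plus a
log with seed and parameters; a failing stage is named and partial
outputs retained. All randomness flows from one seeded generator, so a
fixed seed reproduces every output byte-identically, and re-running
from the written segregation TSV reproduces all downstream tables.
Problem sizes in the test-suite and acceptance runs (50-tetrad
round-trip batches, 10⁴ bootstrap resamples, 10³ calibration
replicates, 200 fluctuation replicates) were chosen to hold Monte-Carlo
error comfortably below the tolerances being checked.

## Known limitations

* E5/E6/E7 boundaries are a reconstruction (above); counts in those
  minority classes may differ from the original program on complex
  events.
* Two tracts separated by a single masked marker are not rejoined; the
  original program's behaviour in that case is unknown, so E4-type
  counts can differ on noisy data.
* The caller does not probabilistically smooth genotypes; it assumes
  upstream filtering removed read-level noise, as in the assays it
  models.
* Perkins SEs treat tetrad scores as i.i.d.; at very high NPD fractions
  the normal approximation degrades.
* Whether the per-chromosome reference tests should pool variances is
  undocumented in the source analyses; Welch is used throughout for
  consistency.
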