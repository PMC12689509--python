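# Methods

## Scanning model

A transcript is scanned with a fixed window (default 120 nt) and step
(default 1 nt). Each window is folded at a set temperature; a *full* run
additionally shuffles the window sequence (mononucleotide shuffling: a
uniform random permutation, preserving the base multiset exactly) a fixed
number of times (default 100), refolds every shuffle, and reports

* `z = (MFE_native − mean MFE_shuffled) / sd(MFE_shuffled)` with the
  sample (n−1) standard deviation;
* an empirical p-value, the fraction of shuffled MFEs ≤ the native MFE
  (ties count);
* ensemble diversity (ED), centroid structure, and pair probabilities
  from the partition function.

Windows shorter than the window size (whole short transcripts) are folded
once and flagged `short` rather than dropped; windows whose shuffled MFEs
are all identical (e.g. homopolymers) get z = 0 and a `degenerate_null`
flag. Flagged windows are excluded from ΔED aggregation and the exclusion
count is reported per gene.

Per-window shuffle streams are seeded by (master seed, window start), so
results are independent of evaluation order and parallel scheduling; a
fixed seed reproduces every output byte-for-byte (timestamps excluded —
output files carry no timestamps).

## Folding backends

**ViennaRNA** (production): nearest-neighbor thermodynamics at the
requested temperature; MFE and structure from the MFE fold, pair
probabilities/centroid from the partition function, ED as the engine's
mean base-pair distance of the ensemble. Engine name, version, and
settings (dangles 2, lonely pairs allowed — the engine defaults) are
recorded in every output header; published ScanFold-style datasets may
have used other option sets, so numeric agreement with any particular
database is engine-version-dependent.

**Toy model** (testing): additive per-pair energies GC/CG −3.0, AU/UA
−2.0, GU/UG −1.0 kcal/mol, minimum hairpin loop of 3, no stacking or loop
terms; N and ambiguity codes never pair; T is read as U. MFE, partition
function, pair probabilities (inside–outside), ED = Σ 2p(1−p), and the
centroid {(i,j): p > 0.5} are computed by exact dynamic programming
(numba kernels, O(n³)). An exhaustive enumeration oracle (guard: length
≤ 18) generates *all* nested structures; the test suite requires the
dynamic path to agree with enumeration to 1e−9. RT uses
0.0019872 kcal·mol⁻¹·K⁻¹ with T(K) = °C + 273.15.

Centroid pairs cannot cross for a >0.5 threshold under a single coherent
ensemble; should crossings ever arise (degenerate models), the dot-bracket
writer drops the lower-probability pair and logs it.

## Consensus and motifs

Each window's MFE pairs vote in transcript coordinates, accumulating the
z-scores of the windows that predicted them. Competition is resolved by
**mutual-best selection on mean z**: each position prefers its
lowest-mean-z candidate pair, and a pair enters the consensus only if both
endpoints prefer it; ties break by higher support count, then smaller
span, then smaller 5′ coordinate. This is a deterministic reading of
"pairs recurring across low-z windows"; it is not guaranteed to reproduce
any other implementation pair-for-pair.

Threshold filtering keeps pairs with mean z ≤ t (t ∈ {none, −1, −2} by
default), which is nested by construction. Motifs group surviving pairs
whose spans overlap or are separated by fewer than `min_gap` nucleotides
(default 10 — motif counts depend on this choice, so it is an explicit
parameter); each motif reports its hull, a nested dot-bracket (crossing
pairs, which can coexist in the consensus because they come from different
windows, are dropped lowest-|mean z| first at export), and the lowest
contributing window z. Trimming removes unpaired flanking nucleotides and
is idempotent. Consensus is computed per temperature from that
temperature's full scan only.

## ΔED screen and statistics

Two scan-only runs at a low and a high temperature (defaults 28 °C and
42 °C; the full z-scored run defaults to 37 °C) are aligned strictly by
window start; ΔED = ED(high) − ED(low), so positive values mean a larger
ensemble when heated. Per gene: mean, sd, and the extreme windows. Per
cohort: mean, sample sd, median, and quartiles (numpy linear
interpolation) over per-gene means; per-gene standard scores
(gene mean − cohort mean)/cohort sd; and a two-sided one-sample t-test
(scipy) of a gene family's means against a caller-supplied reference mean
(typically the cohort mean).

## Synthetic data

The generators define the conditions under which the package is tested:

* `random_sequence`: i.i.d. letters with P(G)=P(C)=gc/2.
* `plant_hairpin`: one perfect inverted repeat overwritten into a
  background; the default stable element is a 12-bp GC stem with a 4-nt
  loop — deep enough (−36 kcal/mol under the toy model) that background
  competition rarely displaces it, which is the low-z signal the
  consensus must recover.
* `thermometer_tandem`: a tandem array of one *marginal* AU-stem hairpin
  (14-bp stem, 4-nt C loop, 8-nt A/C spacer). The array is periodic so
  that every scan window contains a full marginal duplex (halves of
  adjacent identical units re-form the same hairpin across junctions);
  AU-only stems sit near their melting regime at 28–42 °C, giving a
  positive ΔED at essentially every window. This targets marginal
  stability rather than an exact melting temperature: rank and sign
  effects, not calibrated melting curves, are what the tests assert.
* `make_cohort`: labelled cohorts with toy two-exon gene models (5′UTR,
  intron, 3′UTR; both strands), written as per-gene FASTA plus one GFF3
  and a manifest of planted elements.

What the generators do **not** emulate: codon structure, real
composition heterogeneity, isoform diversity beyond one toy layout,
RNA modifications, and protein binding. Passing tests show the machinery
detects the signals it defines, at the sizes it uses — not that any
particular biological transcript contains such signals.

## Problem sizes

The statistical suites run at reduced scale chosen to keep the default
test run fast while leaving enough windows/genes for stable statistics:
window 40 with the toy backend; null calibration over ≥ 200 windows with
50 shuffles; planted-stem recovery over 20 fixtures; type-I calibration
on a 200-gene null cohort (79-nt genes, 40 windows each) with 500
resampled families of 25 genes; the real-engine directional check scans
50 random 500-nt transcripts at window 120, step 10, both temperatures.
Production defaults (window 120, step 1, 100 shuffles, full transcripts)
are unchanged by any of this.

## Numerical and interface choices

* Internal coordinates are 0-based half-open everywhere; every emitted
  file is 1-based inclusive (GFF3/wig/CT convention).
* Wig values anchor at the window *start* position (documented in the
  track header), making window arithmetic exactly invertible; minus-strand
  genes are emitted in ascending genomic order, and a gap in the window
  stream opens a new fixedStep block.
* The base-pair arc ("bp") format has no formal standard; the dialect is
  pinned in `thermoscan/io_tracks.py`: `color:<TAB>r,g,b<TAB>label` header
  lines declaring the z bins (z ≥ 0 gray, z < 0 yellow, z ≤ −1 green,
  z ≤ −2 blue), then one row per pair with 1-based single-nucleotide
  anchors and a color index.
* Scan TSVs carry a fixed header (column order is not assumed on read),
  `#`-prefixed run metadata, `NA` for absent null fields, and floats at 12
  significant digits so numeric round trips hold to 1e−9. `delta_g` is
  written as a synonym of the windowed MFE.
* Gene-model transcript coordinates run 5′→3′ along the gene's genomic
  span *including introns*, since scanning operates on unspliced gene
  sequence; introns are derived per isoform as gaps between exons.
* Per-gene seeds derive from the master seed plus a CRC32 of the gene id,
  keeping cohort runs reproducible and order-independent.

## Known limitations

* The toy energy model has temperature-independent energies (pure
  enthalpy), so its melting response is muted compared to real
  thermodynamics; it is a calibration instrument, not a predictor.
* The consensus competition rule is one deterministic choice among
  several defensible ones; motif counts additionally depend on `min_gap`.
* ED values are engine-defined; comparing ED or ΔED across engines or
  engine versions is not meaningful.
* No multiple-testing correction is applied across genes in the family
  screen, and pseudoknots are outside the structure model.
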