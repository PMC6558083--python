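# Methods

## Model

`mosaicf` treats a diploid genome as a mosaic of homozygous-by-descent
(HBD) and non-HBD segments. Segments belong to one of K HBD classes or a
single non-HBD class; a segment of class k has exponential length with
rate R_k per Morgan. Because roughly 2G recombination events separate the
two haplotypes of a segment inherited from a common ancestor G
generations back (R ≈ 2G), each class captures inbreeding of a
characteristic age: R = 4 means long segments from very recent ancestors,
R = 2048 means sub-cM fragments dating back near domestication for a
livestock genome. The default ladder is R ∈ {2, 4, 8, …, 2048} for the 11
HBD classes and 2048 for the non-HBD class. The ladder values are used
directly as the exponential rates; the R = 2G relation is how users
should map class k to an approximate generation count R_k/2. The rate
vector is fully configurable, so an analysis that prefers to read the
ladder as generation counts (rates 2G = 4…4096) only has to pass that
vector.

### Emissions

Genotypes are B-allele dosages at SNPs with population frequency p,
observed with error rate e (default 0.001, the usual array figure).
Inside an HBD segment both haplotypes carry one ancestral allele:

    P(AA | HBD) = (1-e)(1-p) + e(1-p)^2      P(AA | non-HBD) = (1-p)^2
    P(AB | HBD) = e * 2p(1-p)                P(AB | non-HBD) = 2p(1-p)
    P(BB | HBD) = (1-e)p + e p^2             P(BB | non-HBD) = p^2

Missing genotypes emit 1 in every state. Markers whose minor allele
frequency falls below the floor (default 0.01), or whose frequency is
undefined, are treated the same way — masked as uninformative rather than
deleted, so the coordinate system and hence ROH lengths and F
denominators are unaffected by the MAF floor.

### Transitions

Between adjacent markers separated by d Morgans (constant 1 cM/Mb by
default, configurable; physical gaps are floored at 1e-8 Morgans to
absorb duplicate positions) the chain either survives in its current
segment or the segment ends and a new class is drawn from the
per-individual mixing proportions pi:

    T[k, j] = exp(-R_k d) 1[k=j] + (1 - exp(-R_k d)) pi_j

Any class may follow any class. This mixture structure lets the forward,
backward and EM-count recursions run in O(K) per marker instead of
O(K^2); the inner loops are numba-compiled kernels, which is what makes
per-individual EM over ~50k-marker genomes cheap.

### Estimation

Rates are fixed; each individual's mixing proportions are estimated by
EM. The E-step is scaled forward–backward per chromosome chain (each
chain starts from pi); the M-step sets pi_k proportional to the expected
number of segment draws landing in class k — the expected change events
computed in O(K) per interval, plus the initial draw of each chain. The
log-likelihood is non-decreasing (property-tested); iteration stops at a
gain below 1e-6 log-likelihood units or 1,000 iterations, returning a
warning flag in the latter case.

F_G is the genome-wide mean of the per-marker total-HBD posterior;
averaging one class at a time partitions F_G by age, and the partition is
exactly additive. Note that for an unobserved chain the state marginal is
pi only at the first marker and then drifts toward the length-biased
occupancy (proportional to pi_k / R_k), which is the stationary
distribution of T — the mixing proportions weight segment *counts*, not
genome *fraction*.

## ROH calling

Two segment definitions are implemented:

* **posterior** (default): seed markers with total HBD posterior > 0.999
  are extended in both directions across markers > 0.99, stopping at the
  first marker below; overlapping extensions merge. No bridging across a
  sub-threshold marker.
* **viterbi**: maximal runs of HBD states in the MAP path (ties broken
  deterministically toward the lower class index).

Segment coordinates are 0-based half-open; start is the first included
marker's bp and end is one past the last. F_ROH divides summed segment
length by the mapped length (per chromosome, first marker to one past the
last marker), so a fully autozygous map gives exactly F_ROH = 1.
F_ROH>2Mb counts only segments strictly longer than 2 Mb. Each segment is
annotated with the modal Viterbi class of its markers.

The two definitions have different error profiles, measured on simulated
truth: the posterior rule is conservative — it waits for 99% confidence,
so boundaries sit ~10 markers inside the true segment — while Viterbi
change points are within ~1 marker interval of truth on average. Segment-
boundary benchmarks therefore use viterbi mode; F_ROH defaults to the
posterior rule. Boundary errors of 3+ markers occur for ~10–15% of
boundaries under any decoder because flanking non-HBD markers are
homozygous by chance with probability ≈ 1 − 2pq per marker; this is an
information limit of the data, not a decoder artefact.

## Copy-loss correction

Arrays type a hemizygous (copy-number-1) region as a run of homozygous
calls, so deletions masquerade as ROH. The correction: (1) intersect each
individual's ROH with their copy-loss CNV calls (CN 0/1 only; CNV
*detection* is out of scope — calls are consumed as input); (2) confirm
hemizygosity where the mean log R ratio over markers inside the
intersection is below −0.3 (regions with zero markers are reported but
never flagged); (3) merge flagged intervals per individual (no double
counting) and subtract their total length, divided by the mapped length,
from F_ROH, F_ROH>2Mb and F_G, clamping at zero. A subtracted *length*
must become a genome *fraction* to be commensurate with the F metrics;
that is the only dimensionally coherent reading and the one implemented.
For F_ROH>2Mb only flagged length inside ROH longer than 2 Mb is
subtracted. Mean LRR is computed per (individual, region), not pooled
across carriers of a shared region.

## Synthetic cohorts

The generator produces exactly the structure the model assumes, so every
stage is testable against known truth without any external download:

* **Mosaic**: chromosomes are tiled left to right with stationary class
  draws and exponential lengths (1 cM/Mb conversion). The first segment
  is drawn like any other; the missing stationarity correction biases
  only the first O(1/R) Morgans of each chromosome. The helper
  `mixing_for_autozygosity` inverts the renewal identity — expected HBD
  fraction = Σ_HBD pi_k/R_k over Σ_all pi_k/R_k — so cohorts can be
  simulated at a chosen expected autozygosity.
* **Genotypes**: Hardy–Weinberg draws outside HBD, a single ancestral
  allele (B with probability p) inside, error rate 0.001, optional
  missingness (default 0; QC tests override).
* **Deletions and intensities**: LRR ~ N(0, 0.15) at copy number 2 and
  N(−0.55, 0.20) inside deletions — magnitudes consistent with Illumina
  array behaviour and chosen here, since no published values fix them;
  BAF is dosage/2 plus N(0, 0.03) noise clipped to [0,1], which polarises
  to {0,1} inside deletions. Genotypes inside a deletion are recoded
  homozygous for a retained allele drawn per marker with B-probability p
  (haplotype-coherent retention is not modelled; downstream only sees
  homozygosity and LRR). Each injected deletion emits a matching CN1
  call, so simulated CNV input corresponds to a perfect upstream caller.
  By default deletions are placed in truly non-HBD genome — the scenario
  in which a deletion fabricates an ROH.

Defaults emulate a 50k-chip livestock cohort: ~30 autosomes of 100 Mb,
10 markers/Mb, uniform(0.01, 0.99) allele frequencies truncated to
[0.01, 0.99], and an expected autozygosity near 0.07 concentrated in
ancient classes. What the generator does *not* emulate: linkage
disequilibrium between markers beyond the HBD structure itself, realistic
site-frequency spectra, pedigree relationships between individuals, or X
chromosomes. Passing recovery tests therefore demonstrate correctness of
the inference machinery under the model's own assumptions, not robustness
to model misspecification in real data.

## QC conventions

"Call rate ≤ x%" filters are implemented as *missingness strictly greater
than x% removes*; markers are filtered before individuals, and individual
missingness is judged on the surviving markers. The Hardy–Weinberg filter
is an exact test (full enumeration of heterozygote counts conditional on
allele counts, no mid-p), pooled across the whole cohort; per-breed
testing is a reasonable alternative the API allows by subsetting.
Monomorphic markers get p = 1 and are handled by the MAF mask instead.
PED/MAP bp positions are 1-based and converted to the internal 0-based
half-open convention on ingest; all BED/TSV interval outputs are 0-based
half-open.

## Validation experiments (scripts/acceptance.py)

Problem sizes are the package's own desk-scale choices:

* **Oracle equivalence**: posteriors and Viterbi paths vs exhaustive
  path enumeration on 3-state chains of ≤ 8 markers (agreement to 1e-9).
* **F_G recovery**: four cohorts (50 individuals total, 30 × 100 Mb
  chromosomes, 10 markers/Mb) at expected autozygosity 0, 0.05, 0.10,
  0.25 in the R = 4 class; reported as per-stratum mean |F_G − truth| and
  the truth–estimate correlation.
* **ROH recovery**: truth segments ≥ 2 Mb at 25 markers/Mb; recall and
  mean boundary error in marker intervals (viterbi mode).
* **Copy-loss correction**: flag sensitivity over 1,000 injected 500 kb
  deletions with ≥ 10 markers; full-chain raw vs adjusted F_ROH error
  with 2.5 Mb deletions (long enough to be called as ROH — 1 Mb regions
  at this density hover just below the 0.999 seed); and the fraction of
  untouched individuals in a deletion-free cohort.

## Known limitations

* Rates are fixed, never estimated; only mixing proportions are fitted.
* Per-individual EM ignores relatedness and shares no information across
  animals except the pooled allele frequencies.
* The posterior ROH rule is intentionally conservative near boundaries;
  use viterbi mode when segment end points matter.
* Emissions are genotype-based; haplotype or sequence-level evidence is
  out of scope.
* The `GenotypeDataset` and posterior matrices are dense in memory; a
  608-animal, 50k-marker cohort fits comfortably, but posterior storage
  can be disabled (`store_posteriors=False`) for larger cohorts.
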