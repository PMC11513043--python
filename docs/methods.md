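# Methods

This note documents the models, the synthetic-data design, the numerical
choices, and the known limitations of `exocnv`. Tunable parameters are
given with their defaults and rationale; every empirical statement below is
computed by the test suite or by `scripts/acceptance.py`.

## The problem setting

Exome (targeted) sequencing measures DNA only on capture targets, so CNVs
must be inferred from depth of coverage (DoC): the read count on a target
scales, to first order, with the number of genomic copies of that target in
the sample. The signal is confounded by capture efficiency per probe, GC
bias per library, library size, and batch effects, all of which can dwarf
the 1.5× or 0.5× signal of a single-copy gain or loss. Cohort reanalysis
adds heterogeneity: many enrichment kits, many labs, a wide range of mean
depths. The package therefore (a) preprocesses coverage per kit, (b) runs
three callers with complementary detection philosophies, and (c) triages
pooled calls with cohort-frequency, gene-panel, class, and
disease-network-specific rules, since raw call sets are far too large for
clinical review.

## Synthetic cohorts

The generator is first-class, tested code: every downstream stage is
validated against its ground truth. The count model for sample *s*, target
*t* is negative binomial with

    mean = L_s · w_t · g_s(GC_t) · B_{b(s),t} · CN_{s,t} / 2,
    Var  = mean + α · mean²,

where `L_s` is the library-size factor (uniform over
`mean_depth_range = (100, 200)` reads per probe; roughly 125–250× base
coverage, the upper range of clinical exomes), `w_t` is a probe capture
efficiency (lognormal, σ = 0.7 — probe efficiencies genuinely span an
order of magnitude, and this spread is what makes reference-sample
correlations behave like real data), `g_s` is a per-library GC-bias curve
(Gaussian-shaped multiplicative curve; each sample draws its own optimum
and strength, the dominant smooth systematic in capture data),
`B_{b(s),t}` is a per-batch per-probe multiplicative imprint (lognormal,
σ = 0.40; batches are contiguous "plates" of samples, 4 per kit by
default), and `CN_{s,t}` is the true copy number (sex-adjusted ploidy as
baseline, overridden on spiked intervals; the X pseudo-autosomal stub keeps
ploidy 2 in both sexes, Y is absent in females). The dispersion default is
`α = 0.01`, technical overdispersion of a well-behaved library within a
homogeneous batch after GC effects are modelled separately.

Design choices worth stating explicitly:

* **Targets are 120 bp probes.** Coverage windows must be statistically
  independent observations for any likelihood over windows to be honest;
  apportioning one per-target count across several windows would create
  perfectly correlated windows and double-count evidence. Probe-level
  (120-mer) target definitions are the granularity of real capture
  manifests, and the 120 bp windowing step then maps one window per probe.
  Multi-window targets remain fully supported and tested in the
  preprocessing layer.
* **Exon-like probe spacing.** Probe gaps are a mixture of sub-kilobase
  intra-gene gaps and rare large intergenic jumps, so the genomic lengths
  of multi-probe events are realistic (kilobases within genes, megabases
  when spanning gene deserts). A uniform spread of 5000 probes over 3 Gb
  would make every 2-probe call longer than 500 kb and collapse the class
  system.
* **Spiked events.** Poisson(1.5) events per proband drawn from a length
  mixture (1 probe 20%, 2–3 probes 30%, 4–10 probes 40%, >500 kb 8%,
  whole gonosome 2%) and a copy-number mixture over {0, 1, 3, 4, 5, 6}.
  In trios, each proband event is de novo with probability 0.5, otherwise
  also planted in one parent. Common polymorphic loci (3 by default) are
  planted in 5% of samples each so the frequency filter has true positives;
  rare spikes are (up to trio inheritance) singletons.
* **Double-hit partners.** Half of the heterozygous autosomal truth
  deletions overlapping a recessive-inheritance gene receive a heterozygous
  pathogenic SNV partner in the same gene and sample, plus decoys (a
  pathogenic SNV in a dominant gene, a benign SNV in a recessive gene) that
  a correct matcher must ignore. The constructed pairing list is kept as
  ground truth.

What the generator does **not** emulate: read-level artefacts (mappability,
segmental duplications, reference errors), mosaicism, allele-balance
signal, relatedness beyond trios, and kit-to-kit target-set overlap.
Passing tests therefore demonstrate algorithmic correctness and the
expected operating characteristics under a faithful statistical model of
capture coverage — not performance on any particular real dataset.

## Preprocessing

Fixed order: GC-extreme target removal (GC > 0.80, strict) → per-sample
coverage QC (pass iff ≥70% of target bases at ≥10 reads; depth is
approximated from counts at an assumed 150 bp read length, since per-base
depth is alignment-level detail outside the package's inputs) → per-kit
cohort gate (<30 samples: calling not attempted) → 120 bp windowing →
GC/library correction → exclusion of systematically low windows → square
root. GC correction divides each sample by its median window coverage
(robust to CNVs) and then by per-GC-bin medians (bin width 0.05 in GC
fraction, bins merged leftward below 10 windows); output is normalised
coverage on a per-sample median-1 scale. A window is systematically low —
and excluded — when ≥90% of samples sit below 0.3 on that scale, i.e. the
probe captures under 30% of typical coverage in nearly everyone. The
square root stabilises Poisson-like variance to ≈ 1/4 independent of the
mean (delta method), verified by Monte Carlo in the tests.

## The likelihood-segmentation caller

Samples are clustered on their coverage profiles to neutralise batch
structure: windows in the top and bottom variance quintiles are dropped,
profiles are smoothed with a rolling median (window 11), embedded with
deterministic PCA, and density-clustered (DBSCAN) with a minimum subgroup
size of 15; the DBSCAN radius is the knee of the 15-nearest-neighbour
distance curve, and noise points join the nearest cluster centroid. The
embedding uses 3 components: k batch centroids span a rank-(k−1)
subspace, and 2-D projections can collide two batches (observed in
testing); the dimension is configurable. Each window is then divided by
its within-cluster median (same-sex medians on non-pseudo-autosomal X and
on Y, falling back to the cluster median below 5 samples of a sex), which
cancels the batch imprint exactly and puts every sample's baseline at 1.

Per window the Gaussian log-density of the observed value is evaluated
under copy-number states 0–6 with means √(max(c, 0.05)/ploidy) — the 0.05
floor keeps the homozygous-deletion state away from a degenerate zero —
and a noise level σ_w · f_s, where σ_w is the per-window scaled MAD across
the cluster-normalised cohort (floored at 1e-3) and f_s is a per-sample
noise factor (scaled MAD of the sample's standardised residuals, clipped
to [0.5, 2]): deeper, cleaner libraries get narrower likelihoods, as in
sample-specific variance models.

Segmentation per chromosome (split into constant-ploidy blocks, so X
separates into pseudo-autosomal and hemizygous parts): iteratively, the
(state, segment) pair with the highest summed log-likelihood ratio over the
baseline — jointly across alternative states — is found with a
maximum-subarray search; if the sum reaches the threshold (default 20) a
call is emitted and its windows masked. Ties break to the longer, then
leftmost segment, then the smaller state; the fast prefix-sum search is
property-tested against an exhaustive oracle (200 random instances), and
raising the threshold provably never adds calls (calls at a higher
threshold are a stopped prefix of the same greedy sequence).

Sample-level QC fits a Huber-weighted robust regression of the 75th
percentile of per-chromosome call counts (insensitive to one shattered
chromosome) on median depth, kit, and ancestry label (one-hot, collinear
columns dropped); a sample fails outside the central 99.5% prediction
interval from the robust scale. De novo annotation checks both parents'
mean normalised coverage over the call: consistent with baseline within
±0.15 in sqrt space (a CN=3 carrier parent deviates by √1.5 − 1 ≈ 0.22,
so the band must sit below that); a missing parent yields "unknown".

## The SVD-residual caller

RPKM per target and kit; per-target standardisation; removal of the
leading 3–15 singular components (start value: the elbow of the
singular-value curve, the automated analogue of scree-plot inspection,
clipped to [3, 15]); calls from maximal runs of residuals beyond ±1.75
with the extremal |z| as quality and no copy-number estimate. Two
behaviours of the original tool are included because they produce its
documented profile: probes with median RPKM below 20% of the cohort-typical
value are masked (they carry mostly shot noise), and the residual is
smoothed with a 3-target moving average before thresholding — which
dilutes 1–2-target signals to a third or two-thirds of their height and is
precisely why this caller family is blind to short CNVs while retaining
multi-target and chromosome-scale events. The batch QC loop accepts a
batch when every sample has <30 calls; otherwise, if the median is <10
calls, samples with >30 calls are discarded, else the number of removed
components is incremented and the batch rerun (capped at 15 with an
"unresolved" status). The X chromosome runs in sex-specific pools; Y is
not called by this strategy. SVD signs are fixed (largest-|loading|
element positive) for bit-reproducibility.

## The reference-matched beta-binomial caller

For each test sample, candidate references are ranked by Pearson
correlation of raw count profiles and added greedily while the
test-versus-aggregate correlation improves by more than 1e-4, up to 10
members; samples whose final correlation is below 0.97 fail QC and yield
no calls. Counts are modelled beta-binomially: given the combined
test+reference total n_t, the test count has expected share
p_c = (c/2 · p₀)/((c/2 · p₀) + (1 − p₀)) under copy number c, with p₀ the
overall test share and the intraclass correlation ρ estimated by method of
moments on presumed-diploid targets (binomial fallback with a warning if
the estimate is non-positive). Per-target maximum-likelihood states are
merged into runs of agreeing non-baseline states within a chromosome; the
segment's Bayes factor is log10 of its likelihood ratio against the
baseline, with calls kept above 15. Copy-number labels come from the
observed/expected read ratio through the diploid bins ([0, 0.10) → 0,
[0.10, 0.75) → 1, [0.75, 1.25) → 2, [1.25, 1.75) → 3, [1.75, 2.25) → 4,
[2.25, ∞) → OTHER; lower bounds inclusive — the printed bin boundaries
are open on both sides, so boundary membership is a package choice,
configurable in one place). Gonosomes are called as a separate problem
against a same-sex reference with their own p₀ and ρ, because mixing the
two shares in one moment estimate destroys both.

## Cohort filtering

The frequency filter discards a call when more than 1% of individuals
carry a same-type call covering at least half of its region. The carrier
test is asymmetric by design: a candidate nested inside another
individual's call marks that individual as a carrier (callers fragment the
same polymorphic locus with discordant boundaries), while a tiny unrelated
call inside a large candidate does not make the candidate's region common.
Note the rule is only meaningful for cohorts of ≥100 individuals — below
that, "more than 1%" is less than one individual and every call is
removed, as it would be under the published rule.

Classes are assigned with precedence LONG (>500 kb) > GONOSOMAL >
HOM_DEL > HIGH_CN (≥4 or OTHER) > DOUBLE_HIT > HET_AD, so the broadest
evidence class wins; calls fitting no class (e.g. an autosomal CN1 call in
a recessive-only gene without an SNV partner) are not returned for
interpretation. Calls from the SVD caller carry no copy number and class
as single-copy changes (DEL → 1, DUP → 3). Double hits require a
heterozygous deletion and a heterozygous pathogenic/high-impact SNV in the
same recessive-inheritance gene and sample; homozygous deletions are
excluded (already explanatory alone). ENCODE-blacklist, benign and low-QC
flags are input columns on the call table; producing those annotations is
out of scope. The four ERN strategies implement the published rule sets
(EURO-NMD's haploinsufficiency/pLI and log-likelihood cut-offs and
recessive-only discard; GENTURIS's multi-tool tier 1 and single-tool
thresholds; ITHACA's length minima with homozygous/de novo exceptions,
validity-score prioritisation, and ≥200 kb catch-all; RND's tool-specific
thresholds with multi-tool rescue).

## Reporting

CNV length is end − start under 0-based half-open coordinates, the
convention that reproduces the packaged catalog's printed lengths exactly.
HGVS-style names use GRCh37 RefSeq chromosome accessions with
uncertain-breakpoint syntax, `del`/`dup` suffixes for single-copy changes
and bracketed copy numbers for CN 0 and ≥4; whole-gonosome aneuploidies
print as `pter_qter[n]`. The packaged catalog was transcribed once from
the published record table and ships with the package; the transcription
normalises three typographic slips in printed nomenclature strings and two
swapped chromosome labels (the HGVS accessions and gene positions are
authoritative), and every CNV row's name regenerates from its fields.
Percentages round half-up (2 decimals in summary tables, 1 in yields),
matching the printed conventions.

## Problem sizes and determinism

The acceptance evaluation simulates one kit of 100 samples × 5000 probes —
large enough that the 1% frequency rule, the ≥30-cohort gate, the
minimum-15 clustering and the callers' operating points are all exercised
at realistic per-sample depth, while a full run of all three callers plus
filtering completes in well under a minute on one CPU. All randomness
flows from explicit seeds (`numpy.random.default_rng`); fixed seeds give
bit-identical cohorts, and the callers themselves are deterministic.

## Known limitations

* The likelihood caller's sensitivity floor is set by the threshold of 20:
  single-window events almost never reach it, and 3-window heterozygous
  deletions on weak probes (captured at a fraction of typical efficiency)
  can fall just short — measured overall recall for ≥3-window autosomal
  deletions is 91–100% across seeds at the default conditions.
* The beta-binomial caller's Bayes-factor threshold (15 in log10 units) is
  intentionally conservative; its recall of multi-window deletions is
  roughly half the likelihood caller's on identical input, while events
  the likelihood caller finds with very high evidence are essentially
  always confirmed.
* The frequency filter counts individuals, not families; in trio-rich
  small cohorts an inherited variant present in parent and child already
  reaches 2% of a 100-sample cohort and is removed. At the cohort sizes
  the rule was designed for this effect is negligible.
* Per-base coverage QC is approximated from per-target counts and an
  assumed read length; alignment-level depth extraction is out of scope.
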