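# Methods

This note records the models, rules and numerical choices behind `hlarray`,
and what the simulator does and does not emulate.

## Probe design

Every position of every catalog allele anchors one probe (a complete
overlapping set, shifted by one nucleotide). Starting from a 25-mer, the
probe is extended or shortened **at its 3′ end only** until its melting
temperature is as close as possible to the array hybridization target;
one-sided adjustment keeps the convention that a probe's signal is assigned
to its starting position. Tm uses the GC-count rule for long oligos,

    Tm = 64.9 + 41 · (nG + nC − 16.4) / L ,

lengths are clamped to 20–60 nt (the bound of in-situ synthesis platforms),
and ties in |Tm − 64.2| break toward the shorter probe (cheaper synthesis,
deterministic). Anchors with fewer than 20 nt remaining anchor no probe.
Identical probe sequences across alleles and loci collapse into unique
probes; the probe set retains the full probe → {(allele, start)} coverage
map, which is where probe masking (an absent allele's probe lighting up
because the same sequence occurs in a present allele) enters the calling
stages. Physical replicate spots are modeled as a per-probe replicate count,
not repeated entries.

## Signal model and processing

**Normalization.** Each array is mapped to a fixed scale with
`Sn = min(S − Rmin + F, F·20000)/F`. The cap makes F underdetermined in
closed form, so F is defined as the unique root of `mean(Sn(F)) = 1000`;
`mean(Sn)` is strictly decreasing in F wherever an uncapped above-minimum
signal exists, so Brent's method on a bracketing interval converges to
machine precision (achieved mean verified to 10⁻⁶ relative). When no signal
caps, the closed form `F = mean(S − Rmin)/999` is exact and used directly.
A constant raw vector admits no F and is rejected as degenerate, as is an
array whose capped mean cannot reach 1,000 (essentially all mass at the
minimum).

**Error correction.** Positive signals change smoothly along each allele's
overlapping-probe track while negative probes sit at background, so a probe
deviating from its rolling window median (window 5, both directions) by more
than a factor of 3 is an outlier and is replaced by that median (a discard
mode sets it to the scale minimum instead). Probes shared by several tracks
take the median of the per-track proposals. Passes repeat to a fixed point
(bounded at 10 iterations), making the operation idempotent. Tracks shorter
than the window are left untouched.

**Thresholds.** Positivity is `signal > threshold`, strict. Cold start uses
10% of the maximal signal; once knowledgebase templates exist, each probe's
template signals are split at the largest log-gap (gap factor 4) into a low
and a high mode and the threshold is the geometric midpoint of the gap.
Probes observed only at background across all templates are marked
never-positive with a threshold above all observations. For a single query
array with no knowledgebase, a per-probe 10%-of-own-signal rule would mark
every probe positive, so probes without a threshold fall back to 10% of the
**array-wide** maximum — on the normalized scale, positives sit near the
20,000 cap, so this fallback lands around 2,000, well above background.

**QC.** An array whose raw-scale mean falls below 1/3 of the cohort mean is
flagged degraded (the ratio observed in the one documented degraded sample);
it is still typed but marked unreliable. An array whose normalized maximum
stays below 5,000 cannot contain a genuinely positive probe (positives reach
the cap region once the mean is pinned at 1,000) and is reported as a
negative/no-call — this is how negative-control hybridizations are caught,
since normalization alone would otherwise inflate pure background to the
standard scale.

**Array correlation.** Whole-array comparisons use Pearson correlation of
the normalized signals. A log-scale variant exists behind a flag but is not
the default: the normalization's minimum subtraction stretches the
background tail on the log scale, adding noise exactly where no information
lives.

## Three-stage calling

**Stage 1 — serotype determination.** `Neg(x)` counts an allele's probe
placements whose unique probe is negative. Per allele group (the "serotype"
of array-based typing, e.g. A*02), the k = min(5, N) smallest `Neg(x)` are
averaged into `Neg(ST)`; groups are ranked ascending per locus (ties by
smaller minimum `Neg(x)`, then name). The published form of the k rule reads
"Max(5, N)", which would make the selection clause vacuous for N ≥ 5; the
min form — the five best-supported alleles — matches the described intent
and is the default, with the other form selectable. A locus is homozygous
when the runner-up trails the leader by ≥ 20 negative probes (inclusive);
then only the leader survives. Groups ranked behind second place are
eliminated when their margin over the leader exceeds `MaxDifference`
(default 30 when no empirical table exists); the top two are never
eliminated and configured never-distinguishable pairs are exempt, so a
present group essentially cannot be lost at this stage.

**Stage 2 — genotype determination.** Surviving groups are clustered by
serogroup (a configurable table; unlisted groups are singletons). Each
cluster yields a comparison vector: per allele, `AvgWins(x)` (the mean,
over opponents in scope, of the number of alignment positions where the two
alleles anchor different probes and x's probe is brighter) and `Neg(x)`,
in canonical allele order. With a knowledgebase, the vector is correlated
against stored same-scope template vectors and the present alleles of the
top five templates become candidates. Without (or when the lookup is
empty), the knowledge-based rule applies: `Weight(x) = AvgWins(x) − Neg(x)`
must strictly exceed `WeightThreshold(x)` (global default 0; per-allele
thresholds learned from templates as the midpoint between present and
absent Weight modes). Within each group, only alleles within 20 wins of the
group's best Weight are then kept — the allele comparison's "most likely
allele" selection. This tie window is what lets a fully masked decoy
(Weight indistinguishable from the true allele's) survive alongside it,
reproducing the documented masked-homozygote error, while absent siblings
(Weight below the leader by the cover of their discriminating probes) drop
out.

**Stage 3 — ambiguity removal.** When more than two candidates remain at a
locus (or more than six overall), all legal locus genotypes (pairs and
homozygotes) are enumerated and compared round-robin with the genotype
comparison rule: `Sig(G, p)` sums the covered probe signals of G's involved
alleles at position p, the larger sum wins the position, equal sums score
neither. A homozygous genotype involves one allele, counted once —
heterozygous candidates therefore genuinely outscore homozygotes wherever
the extra allele's probes are positive, which is the behaviour the original
error analysis shows (a masked homozygote reported as the heterozygote).
Every locus genotype within 20 wins of the locus maximum is reported, and
full genotypes are the cross-locus combinations of the survivors. The
round-robin is computed per locus because loci share no alignment columns,
so pairwise genotype wins decompose exactly into per-locus sums; applying
the margin per locus keeps the win scale comparable to the pairwise
definition no matter how many combinations the other loci contribute.
Enumeration is capped (default 10,000 genotypes) with an error instructing
threshold tightening. An optional allele-frequency table re-ranks reported
genotypes by the product of population frequencies (stable sort; unknown
alleles get a 10⁻⁶ floor), implementing the rare-pair implausibility
argument.

**Flags.** Homozygous calls and same-group pairs are always flagged for
confirmatory sequencing — exactly the two classes in which the assay's
errors concentrate. `ambiguous` marks results where more than one genotype
survived the margin or a locus entered ambiguity removal with more than two
candidates; `degraded` and `no-call` propagate from QC.

## Template knowledgebase

A template stores a confirmed typing: the normalized signal vector,
genotype, serotype composition, per-scope comparison vectors, and the
per-group `Neg(ST)` values. Matching computes Pearson r between the query
and every template: identity requires r > 0.975 **and** zero serotype
mismatches (the symmetric difference of locus-level group sets, summed over
loci); r > 0.95 with zero mismatches is a match; high correlation with
mismatching serotypes is rejected. Identity short-circuits the pipeline to
the template's genotype. Serotyping runs before matching because the match
rule consumes serotype mismatch counts. Templates are bound to a probe
design by a fingerprint (hash of the probe sequences and design
parameters); empirical tables (thresholds, weight thresholds, MaxNeg,
MaxDifference) regenerate deterministically from the stored templates, and
the JSON + TSV serialization round-trips bit-for-bit (17-significant-digit
floats, round-trip parsing).

## Simulator

The generator's defaults are the study conditions the rest of the package
is tested under.

**Catalogs.** All sequences descend from one random ancestor. Per-locus
roots diverge so that the pairwise identity between alleles of different
loci lands near `cross_locus_identity` (default 0.88, matching the >85%
cross-locus identity of real class I loci — this is what makes cross-locus
probe sharing, and hence masking, possible). Group founders differ from the
locus root at `between_serotype_divergence` random positions (default 18 on
360 nt, ~90% identity between groups). Within-group variation follows how
real class I polymorphism behaves: it concentrates at a small set of
hypervariable columns shared across groups. Each locus carries
`within_serotype_divergence` such columns (default 2, spaced at least a
probe length apart and away from the sequence ends), each group draws one
variant base per column, and its alleles are the founder with the variant
applied at distinct column subsets — so every group contains close allele
pairs (1–2 nt apart, >98% identity) with the same distance structure, which
is the property that makes the fixed homozygosity margin of 20 negative
probes meaningful. Each group additionally carries a distinct two-base
signature adjacent to each column (polymorphism clusters), so probe windows
spanning a column always differ between groups; without it, two groups
drawing the same variant base inside an otherwise identical window produce
accidental full cross-group masking at a rate real inter-group divergence
precludes. Related-group pairs (A*03/A*11-like) and their serogroup table
are available via `related_serotype_pairs`. No indels by default; per-locus
alignments are columnar by construction.

**Signals.** A unique probe is positive iff it occurs in at least one
present allele — shared placements included, so masking emerges rather than
being injected. Positive contributions are `positive_mean` (4,000 RFU)
times a smooth lognormal hybridization-efficiency profile along each allele
track (σ = 0.2, Gaussian correlation length 15 probes); background is
`negative_mean` (100 RFU). All probes carry multiplicative lognormal noise
(σ = 0.12) and a per-array scale factor (σ = 0.4). The profile belongs to
the *sample* (the labeled cRNA preparation): replicate arrays share it,
distinct samples do not — which is what separates replicate-pair
correlations (≈0.98) from distinct-sample correlations (≤0.55 even for
allele-disjoint genotypes sharing groups). The noise level was set so that
replicate arrays reproduce at r > 0.975, the reproducibility the assay
demonstrates; the profile spread was set so that smooth-profile dips do not
cross the positivity threshold, because in the real assay positive probes
reliably exceed thresholds and errors arise from masking, not signal
dropout. Degraded arrays multiply all signals by `degradation_factor`
(0.25, reproducing the one-third-of-cohort-mean degraded instance); mixed
samples sum two genotypes' material; negative controls contain background
only.

**The engineered masking fixture** (`build_masking_catalog`) reproduces the
classic homozygote ambiguity: a decoy sibling of A*01:01 differs at two
adjacent positions placed maximally far from every hypervariable column,
and the window around them is copied into the whole C*01 group (preserving
that group's own column variants). A sample homozygous for A*01:01 and
carrying a C*01 allele then lights every decoy probe: the decoy's
`Neg = 0` in noise-free simulation, and the pipeline reports either the
decoy/true-allele pair (close-alleles flag) or a homozygous call — the
outcomes probe signals genuinely cannot distinguish.

**What the simulator does not emulate:** hybridization thermodynamics and
cross-hybridization between near-identical (rather than identical) probes,
spatial slide artifacts, dye chemistry, indel-containing alignments, and
real IMGT catalog content with its uneven group sizes. Passing tests
demonstrate the computational method's behaviour under the stated
similarity and noise structure, not the wet-lab performance of a physical
array.

## Problem sizes and determinism

The test suite and the acceptance script run at desk scale: catalogs of
3 loci × 8 groups × 4 alleles over 360 nt (~13,000 unique probes from
~33,000 placements), cohorts of up to 200 samples, 20 replicate and 50
distinct array pairs, and 1,000 randomized oracle instances — sizes chosen
so the complete suite runs in well under a minute per component while every
rule is exercised against an independent brute-force implementation. All
randomness flows from explicit seeds (one generator per sample profile, one
per array); identical seeds reproduce catalogs, cohorts and typing results
byte-for-byte.

## Known limitations

- Real IMGT catalogs contain indels and unevenly sized groups; the package
  requires pre-aligned, equal-length sequences per locus and treats the
  probe anchor as the alignment column.
- The cold-start weight threshold (0) separates present alleles from absent
  siblings only because groups contain close alleles with symmetric distance
  structure; on catalogs with isolated, highly divergent alleles, per-allele
  empirical thresholds from a knowledgebase are needed.
- Mixed samples are reliably *flagged* but not deconvolved; two-sample
  mixtures usually surface as ambiguity or implausible homozygous collapse.
- Serotype-level no-calls via MaxNeg tables require an accumulated
  knowledgebase; cold-start negative detection relies on the array-wide
  signal ceiling.
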