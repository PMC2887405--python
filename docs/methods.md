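# Methods

## Data model

All statistics operate on per-locus multiple-sequence alignments over
{A, C, G, T, -, N} with a panel table assigning each accession to a
population (cultivated / wild / outgroup) and, for cultivated accessions,
a subgroup (indica / japonica).  Internally every coordinate is 0-based
half-open; report writers print 1-based positions.  Each FASTA record is
treated as one haplotype (cloned wild-rice PCR products are not collapsed
per accession — the panel gives no heterozygote structure to collapse on).
Sequences are stored on the precursor's plus strand; annotations are given
in the same orientation, so no reverse-complement handling occurs inside
the statistics.

**Core alignment.** '-' and 'N' are both missing data: a column containing
either in any retained sequence is excluded.  Statistics are computed on
the remaining core of length *L*, recomputed per accession subset, so *L*
may differ between subgroups at the same locus.  Maximal runs of
gap-containing columns are catalogued as one indel event each; indels
never contribute to *S*, π or θ (they appear only in the
functional-region mutation catalogue).

## Estimators

* π (k̂) is the unweighted mean count of differing core sites over all
  n(n−1)/2 unordered pairs — the sample version, no n/(n−1) correction.
  Per-site values divide by *L*; both are emitted since report conventions
  differ.
* θ̂\_W = S/a₁(n).  A multi-allelic column counts as one segregating site.
* Group means across loci are reported with the SEM (sd/√n\_loci); a
  single-locus group has SEM 0 so report tables stay total.
* S = 0 forces π = θ̂ = 0 and leaves Tajima's D undefined (NaN, never
  significant).  An empty core (L = 0) flags the whole statistic undefined.

## Tajima's D and its significance

D uses the 1989 coefficient set (checked against an exact-rational oracle
for n = 3..60).  Significance is by Hudson's fixed-S conditional null
rather than the beta approximation: a neutral genealogy is simulated, S
mutations are placed multinomially by branch length, and the two-tailed
p-value is (1 + #{|D\_sim| ≥ |D\_obs|}) / (n\_reps + 1).  Default 10,000
replicates; a master seed is mandatory and every stochastic operation
derives its own child stream, so reruns are bit-identical.  The
conditional null is centred close to, not exactly at, zero (the variance
normalisation is itself approximate); its lower 2.5% quantile at n ≈ 20,
S ≈ 10 sits near −1.7 to −1.8, consistent with which published D values
carry significance stars.  No recombination is modelled in the null —
conservative for ~600 bp fragments.

## HKA test

Reduced single-polymorphism form: within-ingroup polymorphism
(S\_i on core length L\_poly) plus mean pairwise divergence D\_i to the
outgroup (computed on columns shared with the outgroup, L\_div; the two
outgroup accessions are averaged by taking the mean over all
ingroup × outgroup pairs).  No Jukes–Cantor correction is applied — raw
differences, documented so divergence columns are comparable with the
input alignments.  With time in 2N units and equal ancestral size,

    E[S_i] = θ_i L_poly a1(n_i)         Var[S_i] = E[S_i] + (θ_i L_poly)² a2(n_i)
    E[D_i] = θ_i L_div (T + 1)          Var[D_i] = E[D_i] + (θ_i L_div)²

Estimation enforces the classical moment constraints (per-locus totals and
the divergence total equal their expectations), which reduce to a 1-D
fixed point in x = T + 1, iterated to 1e-10; the one-locus fit is solved
in closed form and is exactly saturated (X² = 0).  Significance is a
parametric bootstrap: (S\_i, D\_i) are simulated at the fitted parameters
with a joint coalescent (the outgroup lineage enters the ingroup genealogy
at T via the consistency construction, so shared branches induce the
correct S–D correlation), **each simulated dataset is refitted**, and
p = (1 + #{X²\_sim ≥ X²\_obs}) / (n\_sim + 1).  Each candidate locus is
tested with the reference loci only (one test per candidate), matching
one printed p-value per locus; loci may be excluded with a reason string
(e.g. clustered multi-copy families) rather than guessed at.

## Selection screen

Two independent lines of evidence, reported side by side with no
conjunction enforced:

* **Fold screen**: fold = π\_wild,site / π\_cult,site per candidate and
  subgroup, against a baseline equal to the *maximum* fold across the
  neutral reference loci (undefined folds skipped with a warning; zero
  cultivated diversity flags an infinite fold).  With ~600 bp loci and few
  reference genes the baseline is a heavy-tailed ratio statistic and can
  be large in small synthetic panels; it stabilises with longer loci or
  more reference genes.
* **Candidate status**: a positive-selection signal is a *significantly
  negative* Tajima's D or an HKA p < α (α = 0.05 throughout, no
  multiple-testing correction, both configurable).  A significantly
  positive D (balancing selection) is never a positive signal.  Status is
  Putative iff a cultivated subgroup shows a signal and the wild
  population (same two tests) does not; ND otherwise; NA when both
  cultivated subgroups lack usable tests or no wild contrast exists.
  Missing individual tests count as no-signal for that test only.

## Synthetic panels

msprime drives a four-population structured coalescent; time is in 2N
generations (pair-coalescence rate 1) with no calendar-year mapping.
Defaults, chosen once to emulate the targeted study design:

| parameter | default | rationale |
|---|---|---|
| locus length | 600 bp | typical amplified fragment (precursor + flanks) |
| θ per site | 0.005 | wild-rice-like nucleotide diversity |
| samples | 17 indica / 16 japonica / 15 wild / 2 outgroup | survey panel sizes |
| wild–cultivated split | 0.5 | domestication at an appreciable fraction of 2N generations |
| bottleneck | strength 0.1 for duration 0.18 after each split | gives ≈2.1–2.2-fold neutral cultivated diversity reduction, inside the <2.6-fold neutral-gene envelope |
| outgroup divergence T | 5 | divergence ≈ 10× diversity, congener-scale outgroup |
| region multipliers | mature 0.3, precursor 0.6, flanks 1.0 | purifying selection strongest on the mature sequence |

Mutations are finite-sites JC69 laid down with a per-region rate map;
the emitted FASTA/TSV bundle round-trips through the package's own
readers.  Indica and japonica are founded independently (separate
bottlenecks).  An optional indel rate adds gap events to exercise the
core-alignment logic; by default sequences are emitted already aligned
with no indels.

The null engines are hand-vectorised Kingman-coalescent code: all
replicates advance through the same merge schedule, so a batch of trees
costs ~n numpy operations on replicate-length vectors.  Infinite-sites
mutations are mapped to distinct sequence positions sampled without
replacement (unbiased for S and π; surplus beyond 10% of the sequence
length triggers a saturation warning).  Emitted carrier sets use tip
exchangeability (a branch with c descendants subtends a uniform c-subset);
this is exact for site-wise statistics, and linkage-sensitive statistics
are out of scope.

**Sweep proxy.** A selective sweep replaces the cultivated sequences at
one locus with copies of a single wild haplotype plus private mutations
accumulated over the sweep age (default: the split time) under the
locus's rate profile — a star genealogy producing reduced diversity and an
excess of rare variants (D ≈ −2.2) in the cultivated subgroups only.
Forward simulation with selection coefficients is deliberately out of
scope.

## Self-validation experiments (`srnapop.calibration`)

Problem sizes were fixed as a compromise between Monte-Carlo precision and
single-CPU runtime; all are driven by one master seed.

* Estimator calibration: 2,000 neutral replicates (n = 20, θ\_site = 0.01,
  L = 600) emitted as alignments and measured through the ordinary
  diversity path; the fixed-S test's type-I error uses 2,000-replicate
  nulls shared between replicates with equal S.
* HKA calibration: 800 joint-neutral 5-locus datasets (T = 5, n = 20),
  300 null simulations each; measured type-I ≈ 0.04 at α = 0.05.
* End-to-end sweep recovery: 100 replicates of a compact panel
  (4 neutral references + 1 swept + 1 neutral candidate).  An a-priori
  power analysis bounds the sole-Putative probability by
  P(no wild false veto) × P(sweep detected) × (1 − per-locus false-Putative
  rate)^K ≈ 0.93 × 0.97 × (1 − p\_fp)^K, which is why the panel carries a
  single neutral candidate: every additional neutral locus multiplies in
  another (1 − p\_fp).

## Known limitations

* **Demographic confounding of the HKA test.** Under the default
  domestication bottleneck the across-replicate distribution of cultivated
  S is overdispersed relative to the constant-size null the test simulates
  (genealogies either coalesce inside the bottleneck or escape it), which
  raises the cultivated-subgroup HKA false-positive rate to roughly
  0.08–0.10 at nominal 0.05 even though the matched-model calibration
  holds its size.  Consequently the end-to-end sole-Putative recovery rate
  plateaus near 0.75, and the fold screen and classifier cannot, by
  construction, distinguish direct selection from linked sweeps or
  demography alone.
* The fixed-S null and the HKA null assume no recombination and no
  population structure within each tested group.
* Synthetic panels emulate site-wise summary statistics, not haplotype
  structure or linkage disequilibrium; passing tests say nothing about
  LD-based inference on real data.
* Target scanning uses the standard plant-miRNA penalty weights
  (mismatch 1, G:U wobble 0.5, no bulges, cap 4); the weights are
  configurable because published scans rarely state them exactly.
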