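# Methods

This note describes the statistical procedures implemented by
`sapiens_catalog`, the assumptions behind them, the synthetic-data model used
to exercise them, and the numerical choices that a user or reviewer would want
stated explicitly. No number quoted here is asserted anywhere except where the
test suite or `scripts/acceptance.py` computes it at run time.

## Ancient-DNA genotype preparation

Low-coverage ancient genomes are represented by **pseudohaploid** calls: at
each biallelic site one sequencing read with base and mapping quality >= 30
(both configurable) is drawn uniformly at random among reads whose base
matches the site's ref or alt allele, and its allele becomes the individual's
hemizygous genotype. Reads matching neither allele are excluded before the
draw, consistent with the removal of sites showing more than two alleles.

Post-mortem cytosine deamination produces C→T (and, on the opposite strand,
G→A) errors, which mimic transitions. The preparation therefore applies
UDG-aware transition rules:

- individuals with only non-UDG libraries: all transition (A/G, C/T) sites
  are coded missing;
- individuals with both library types: at transition sites only UDG-library
  reads enter the draw; at transversion sites all passing reads do;
- UDG-treated (and modern) individuals: no restriction.

The panel-level routine consumes a single seeded RNG stream in canonical
(chrom, pos, individual, read) order, so output is byte-reproducible and
invariant to the input row order. Genetic sex is assigned from the
X/autosome coverage ratio with a deliberate gap between the bands
(XX if R >= 0.8, XY if R <= 0.6, otherwise unknown); the bands are
configurable because published ratio methods do not fix universal thresholds.

## Polarization

The ancestral state at each site is the consensus base among up to three
great-ape outgroup genomes (chimpanzee, gorilla, orangutan): at least one ape
must have data, all apes with data must agree, and the agreed base must equal
ref or alt. Heterozygous ape calls are treated as no-data — an ape polymorphic
at the site is uninformative about the ancestral state, and treating it as
such is the conservative reading. Sites with no ape data or ape disagreement
are `undetermined`; sites whose consensus matches neither allele are
`off_panel`; both are excluded and counted, so excluded + polarized always
equals the input site count. Derived dosages (0–2 for diploids, 0–1 for
pseudohaploids) are computed from allele-coded calls only after polarization;
stored genotypes are never rewritten.

## The HSS catalogue

A site is a ***Homo sapiens*-specific (HSS) variant** when (a) all four
archaic genomes (three Neandertals, one Denisovan) have calls, (b) their
derived dosage sum is zero, and (c) at least one derived allele is observed
among the *Homo sapiens* individuals. Sites failing the screen carry one
reason code (`archaic_missing`, `archaic_derived`, `no_human_derived`).

Group-level summaries use derived frequencies over called alleles
(complete-case per site):

- **present**: >= 1 derived allele observed;
- **fixed**: every called allele derived, with >= `min_called` alleles
  (default: the group's diploid size, i.e. half its allele count) to guard
  against single-genome artifacts;
- **variable**: derived observed but not fixed — so fixed/variable/absent
  partition the sites with data.

Spectra are computed at a projected allele count *m* either by
hypergeometric expectation (the exact distribution of the derived count in a
draw of *m* alleles without replacement, accumulated as fractional class
masses) or by a single seeded subsample per site; both modes are provided
because either reading of a fixed-sample-size spectrum is defensible. Sites
with fewer than *m* called alleles in the group are skipped and counted.

The Venn partition counts exact subset membership of per-group presence
sets; the **unique fraction** is 100 × unique/present with half-up rounding
to one decimal for display. The frequency-differential ranking restricts to
focal fixed-derived sites, sorts by focal minus comparison frequency
(descending, genome-order tie-break), and exports gene lists (unique symbols
with supporting-site counts) for external enrichment tools; enrichment itself
is out of scope, as is the production of functional annotations (a
SnpEff-compatible `ANN` field or a sidecar table is consumed, with
"amino acid-altering" = missense plus stop/start gain/loss).

## Population-genetic statistics

**Heterozygosity** is heterozygous genotype calls over total genotype calls
for a diploid individual. **Pairwise distances** average, over co-called
sites, the absolute difference of within-individual alt-allele fractions,
per chromosome, then combine chromosomes weighted by physical length
(weights renormalised over chromosomes with data, summing to 1). **UPGMA**
is standard average linkage with lexicographic tie-breaking; leaf heights are
equal by construction and newick branch lengths are emitted at full float
precision.

**FST** is the Weir–Cockerham (1984) two-population variance-component
estimator computed per site from individuals with full diploid calls; both the
"weighted" aggregate (ratio of summed components, the VCFtools convention)
and the mean of per-site ratios are reported, because published values rarely
say which was quoted. Sites monomorphic in the sample (zero denominator) are
excluded from both aggregates.

**f-statistics** use population allele-frequency products over complete-case
sites: f4(A,B;C,D) is the mean of (pA−pB)(pC−pD), and f3(T;A,B) the mean of
(pT−pA)(pT−pB) without normalisation ("vanilla"). No small-sample
heterozygosity correction is applied to the target term; the admixture
signals exercised here are far larger than the resulting O(1/n) bias, and the
identities f4(A,A;C,D)=0 and antisymmetry hold exactly. Ascertainment on
sites polymorphic between two archaic genomes (both called, derived allele
segregating among their alleles) is available to mirror archaic-polymorphism
ascertainment schemes.

**Uncertainty** comes from a weighted block jackknife over contiguous 5-Mb
windows anchored at position 1 per chromosome (the last partial window kept).
Block weights are informative-site counts, and the variance formula is the
Busing-style weighted delete-one form standard in the f-statistics
literature; with equal weights it reduces to the classic delete-one
jackknife, and two equal blocks give SE = |v1−v2|/2 exactly.

**Continuity.** The statistic conditions on sites heterozygous in an older
"anchor" diploid and reports the fraction of a more recent probe's called
alleles that are derived, with a block-jackknife CI. Probing the anchor with
itself gives exactly 1/2. Under pure drift the population frequency is a
martingale, and when the distribution of segregating frequencies is symmetric
about 1/2 the conditional expectation stays at 1/2 regardless of drift;
gene flow from a genetically differentiated source lowers it. Note the
symmetry caveat: under a skewed (e.g. neutral-like 1/f) spectrum the
conditional expectation sits below 1/2 even under continuity, so the
diagnostic signal is the *decrease* relative to an unadmixed baseline rather
than the absolute value — the tests assert both the exact self-anchored value
and strict monotonicity in the admixture fraction under paired seeds.

**Divergence times.** Two diploid genomes polarized by outgroups are
summarised as a 3×3 joint dosage spectrum (the two-by-two SFS) over sites
passing the scaffold filter (QUAL > 30, ancestral state assigned, per-individual
depth within its own 5th–95th coverage percentiles, supporting allele depth
>= 4). The split-time estimator implemented here is a **net-divergence moment
estimator**: with d_xy the probability that one allele from each individual
differs and H̄ the mean within-individual heterozygosity (both per callable
bp, read off the spectrum), T = (d_xy − H̄) / (2μ) generations. It is
unbiased when descendant and ancestral population sizes are equal — the
regime in which the recovery contract is tested — and is rescaled to years
with μ = 1.45 × 10⁻⁸ per bp per generation and a 29-year generation time
(both configurable). Confidence intervals are the weighted 5-Mb block
jackknife. The estimator is validated against coalescent simulations
(msprime) of two populations split τ generations ago (τ/2N ∈ {0.05, 0.2}
plus a zero-divergence null), with τ required to fall inside the 95% CI.

## The synthetic-data generator

The baseline generator is a **site-independent drift cascade**. Each site's
mutation is placed on one branch of a fixed population tree with probability
proportional to branch length × rate (an infinite-sites analogue: exactly one
origin branch per site), assigned a frequency at the end of its origin branch,
and propagated root-to-tip through Balding–Nichols beta steps
p_child ~ Beta(p(1−F)/F, (1−p)(1−F)/F) with per-branch drift F, a
martingale in the frequency. Admixture edges mix destination and source
frequencies linearly at the recent end of the destination branch. Genotypes
are binomial draws from terminal frequencies implemented as per-allele uniform
thresholds, so paired-seed runs differing only in an admixture fraction are
monotone in that fraction. Dedicated RNG substreams per branch and per
individual keep such paired runs comparable; identical configs are
byte-identical.

Great apes are fixed ancestral (polarization is exact unless an ape
missingness rate is switched on). Archaic genomes carry the derived allele
only where the origin branch is ancestral to them; frequencies drift inside
the archaic clade like any other population, which (i) leaves archaics
exactly ancestral at every human-side mutation — the property the HSS screen
needs — and (ii) makes archaic-polymorphism ascertainment select a non-empty
site set. An optional archaic error rate exercises the screen's reason codes.

The study preset emulates the analysed sample structure — 7 ancient southern
Africans, 7 northern San, 5 southern San, 7 pre-Neolithic Eurasians, 208
panel individuals (8 each from 26 populations: 4 western, 3 eastern, 19
non-African), 4 archaic genomes, 3 great apes — on a tree with a deep
southern split (10,000 generations), an east/west split (6,000), an
out-of-Africa bottleneck branch (high drift, F = 0.30) and round-number
branch lengths throughout: the real demography is not a simulation target,
and the preset is labelled as such. Sites are laid out uniformly on two
50-Mb chromosomes, giving 20 jackknife blocks at 5 Mb. Default origin
frequencies are log-uniform on (0.02, 0.98) — a rare-variant-heavy,
neutral-like law under which the bottlenecked group shows the expected
flatter spectrum and larger fixed-derived count; the single-population preset
used for continuity calibration instead draws uniform frequencies (the
symmetric regime discussed above). Effect classes are assigned at random
(missense-like 0.35, synonymous-like 0.25, other 0.35, unannotated 0.05) with
genes tiling consecutive sites; no codon model is simulated. Default problem
sizes (20,000 sites for catalogue-level runs, 50,000 for estimator
recovery, 10,000–12,000 for artifact and continuity runs) are chosen so each
Monte-Carlo check has comfortable power while a full run of the suite stays
light.

The aDNA artifact layer draws per-individual-site read counts from a Poisson
coverage model with extra dropout, copies read bases from the true alleles,
injects C→T/G→A errors on non-UDG reads at a configurable rate, assigns
libraries by UDG status (mixed individuals get half of each), and gives a
fraction of reads sub-threshold base quality to exercise the filters.

What passing tests do and do not show: the generator has no linkage
(sites are independent given the tree), no sequence context, no selection,
no archaic introgression into non-Africans, and a deliberately simple
coverage/damage model, so green tests demonstrate correctness of the
statistical machinery under the stated models — not that real-data values
(which depend on the full sequencing data) would be reproduced. The published
headline counts are therefore never asserted; the two published percentage
figures that are pure arithmetic on printed counts are recomputed exactly.

## Numerical choices and degenerate inputs

- Coordinates are 1-based inclusive throughout; block windows are
  [1, 5e6], (5e6, 1e7], … per chromosome.
- Group frequencies and FST components accumulate in float64; dosage storage
  is float32 with NaN for missing.
- Jackknife with fewer than two non-empty blocks, FST with no defined site,
  continuity without anchor-heterozygous overlap, and a two-by-two SFS with
  zero informative sites all raise typed errors rather than returning NaN.
- Reported percentages round half-up to one decimal; internal values are
  full precision.
- UPGMA merge ties resolve to the lexicographically smallest label pair;
  rank ties in the differential screen resolve to genome order.
- The CLI writes provenance comment lines (command, seed, version) on every
  TSV and one JSON manifest per pipeline directory; `manifest.json` and
  `run.log` are the only outputs that are not byte-stable across reruns.

## Known limitations

- The divergence estimator assumes equal ancestral and descendant population
  sizes; under strong size changes it inherits the usual net-divergence bias.
  The recovery contract is tested in the matched regime only.
- The continuity statistic's absolute level depends on the segregating
  frequency spectrum (see above); comparisons across probes with a shared
  anchor are the supported use.
- Pseudohaploid individuals contribute frequencies in {0, 1}; no further
  small-sample correction is applied to f-statistics.
- Dataset-assembly filters (missingness/HWE/MAF/LD pruning) are considered
  upstream of this package and are not reimplemented.
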