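# Methods

## Data model

Genotypes are diploid allele2-dosage codes (0/1/2, −1 for missing) in a
sample-major matrix, with a marker map sorted by (chromosome, bp) and a
sample table carrying breed, average litter size (ALS, lambs per lambing)
and a case/control label (high-yield vs low-yield tails of the ALS
distribution). On disk the package reads and writes the PLINK 1 binary
trio (`.bed` magic `6C 1B`, SNP-major mode `01`, 2-bit LSB-first fields:
`00` hom-allele1, `01` missing, `10` het, `11` hom-allele2) and diploid-GT
VCF. All internal coordinates are 1-based inclusive; region length is
end − start + 1, the convention under which array-region kb lengths
reproduce from their printed coordinates. BED I/O converts to 0-based
half-open.

## Quality control

Filters run in a fixed order so reports are reproducible: non-autosomal
markers → duplicate positions (keep first, warn) → sample call rate →
SNP call rate → minor-allele frequency → Hardy–Weinberg exact test. All
thresholds are caller-supplied; only the HWE default (p < 1e-6 removes)
is opinionated, the relaxed cutoff appropriate for livestock breeds whose
demographic history produces genuine HWE departures. The HWE test
conditions on observed allele counts and sums the probabilities of all
heterozygote counts no more probable than the observed one (two-sided,
probability-mass rule), computed in log space with a 1+1e-12 tie guard.

## ROH detection

A run of homozygosity must (i) span ≥ 1 Mb, (ii) contain ≥ 100 SNPs,
(iii) average ≥ 1 SNP per 50 kb, (iv) contain no inter-SNP gap > 1 Mb
(larger gaps split the run), and (v) show at most 1 heterozygous and 5
missing calls **per 50-SNP window**. The per-window reading of (v) is
deliberate: a 22 Mb ROH covers ~5000 array SNPs and would be rejected by
any total-count rule at realistic genotyping error rates, yet such runs
are exactly what highly inbred individuals exhibit. All eight parameters
(`ROHParams`) are configurable; defaults are the standard
genotype-counting settings for dense arrays.

Two detectors share the final-stage logic (gap split → trim ends to the
outermost homozygous call → criteria (i)–(iii)):

* **Windowed** (the production scanner): a 50-SNP window slides one SNP at
  a time; a window is a *hit* if it holds ≤ 1 het and ≤ 5 missing; a SNP
  is run-eligible when ≥ 5 % of the windows overlapping it are hits;
  maximal eligible stretches become candidates. Trimming before counting
  matters — a candidate may legitimately end on the heterozygote that
  terminated it.
* **Direct** (independent cross-check): enumerates, in one sweep, every
  maximal stretch in which no window violates allowance (v), then drops
  nested duplicates. Its enumeration is verified against an O(n²)
  brute-force oracle on random small arrays.

The two detectors agree exactly on fixtures whose planted runs carry at
most the window allowance of errors. The validation studies use 20-SNP
windows: at a het-flanked run boundary only two windows can certify the
edge SNP, so with 50-SNP windows and the 5 % threshold (which demands
three) the windowed scan starts one SNP inside the true edge —
a one-SNP bias that is invisible in production but would obscure an
exact-boundary comparison.

## Inbreeding and depression

F_ROH = Σ(segment lengths) / autosomal genome length (default
2655.71 Mb, the ovine HD array map; configurable). Segments partition
into half-open length classes [1,4), [4,8), [8,∞) Mb so the class
coefficients sum exactly to the total. Depression is estimated by
ordinary least squares of ALS on 100·F (per-1 % scale), one univariate
fit per measure (each class and the total), with a two-sided t test on
the slope (n−2 df). Degenerate inputs (n < 3, zero-variance F) raise
rather than return NaN. The OLS engine is statsmodels; tests verify it
against closed-form normal equations.

## Hotspots and association

Per-SNP carrier incidence (individuals counted once however many of
their segments overlap) is scanned for maximal runs with incidence ≥ 2
spanning ≥ 10 SNPs; runs never cross chromosomes, and IDs are assigned
in genome order ("S1", "S2", …). An individual *carries* a hotspot when
one of its ROH covers ≥ 50 % of the hotspot's SNPs. Majority coverage —
not full coverage — is the default because detected run endpoints jitter
by a few SNPs (the heterozygote budget lets a run extend into flanking
background homozygosity), making the maximal incidence run strictly
wider than any single member segment; under a full-coverage rule even
animals sharing an identical planted region would all count as
non-carriers. The fraction is configurable for users who want stricter
or looser consensus semantics.

Each hotspot's carrier counts against case/control labels form a 2×2
table tested with the two-sided Fisher exact test (probability-mass
definition, via scipy; verified against hypergeometric enumeration).
The Bonferroni threshold is α / (hotspots tested in the cohort), with
strict inequality for significance. Follow-up per-SNP tests inside a
candidate region use case-vs-control allele counts (missing excluded),
monomorphic SNPs reporting p = 1, with an in-region Bonferroni.

## Synthetic cohorts

The generator reproduces the statistical structure the analysis assumes,
at reduced marker density, and records full ground truth.

* **Map and background**: 26 autosomes × 2000 SNPs at ~10 kb mean spacing
  (jittered ±50 %), allele frequencies uniform on [0.05, 0.5], genotypes
  drawn under Hardy–Weinberg. LD is not simulated: none of the
  implemented statistics models LD, and planted segments supply all the
  spatial structure ROH detection needs.
* **Autozygosity**: per-individual segment counts are Poisson per length
  class (defaults 3.5 / 0.5 / 0.12 for 1–4 / 4–8 / >8 Mb), placed at one
  of 130 recurrent island loci (90 %, jittered ±0.4 Mb) or uniformly
  (10 %). Clustering is essential, not cosmetic: with uniform placement
  at realistic ROH loads the expected per-SNP incidence exceeds the
  sharing threshold almost everywhere and all consensus regions merge
  into a handful of chromosome-scale runs; real ROH cluster at islands.
  Within a planted interval genotypes become homozygous (allele drawn by
  frequency), then heterozygote errors (rate 0.002) and missing calls
  (rate 0.01) are injected. Realized F in the truth table is planted
  length over genome length, exactly.
* **Phenotypes**: ALS = β₀ + β₁·(100·F) + N(0, σ), floored at 1.0 lamb
  (litter size is at least one by definition). Defaults β₀ = 2.1,
  β₁ = −0.02, σ = 0.3 give a cohort mean ALS ≈ 1.9 at mean F ≈ 0.09.
* **Causal hotspot**: a reserved ~1.2 Mb region (no islands within 4 Mb,
  no background segments within 2 Mb) is planted as a homozygous segment
  in a Binomial(0.4) fraction of individuals; carriers' odds of the
  low-yield label are multiplied by 16 in a weighted without-replacement
  draw of the 13 controls (Gumbel-max sampling), the remaining animals
  splitting by ALS rank. The depressive direction — carriers enriched
  among low-yield ewes — is the one an autozygous region reducing litter
  size produces, and the only direction in which a 58-case/13-control
  design has any power: with carriers at 40 % frequency, even perfect
  case-enrichment bottoms out at p ≈ 1e-3, above a 0.05/100 Bonferroni
  bar, whereas full control-enrichment reaches p ≈ 6e-7.
* **F-only cohorts** (`simulate_froh_cohort`): for regression studies a
  Gamma-distributed total F (mean 0.093, SD 0.146, capped at 0.62 — the
  heavy-tailed profile of a highly inbred breed, where a minority of
  ewes carries most of the autozygosity) split across classes by a
  Dirichlet draw. This truth-level path decouples statistical
  calibration of the regression from genotype-level detection.

What passing tests on these cohorts do **not** show: robustness to LD
(background SNPs are independent), to array-specific genotyping artefacts
(error rates are uniform within segments), to cryptic relatedness or
population structure (individuals are exchangeable), or to real ROH
length distributions (class lengths are uniform within bins). The
statistical machinery is validated; transfer to a specific array and
breed still depends on those data properties.

## Problem sizes and numerics

The test suite and acceptance script run at desk scale, chosen so the
full suite completes in a few minutes on one CPU: 52k-SNP genomes for the
100-replicate end-to-end study (~0.7 s per cohort; ~85 hotspots tested
per cohort), 200 fixtures each for detector equivalence and boundary
recovery, 1000 truth-level cohorts for type-I calibration. Floating-point
choices: HWE and Fisher probabilities are computed in log space and
compared with small relative tie guards; class partitions and realized-F
identities are exact (no tolerance); regression checks use relative
tolerances ~1e-9 against closed forms. Ties at the Bonferroni threshold
are non-significant (strict inequality). Sub-1 Mb segments are a contract
violation in `classify_roh` and raise.

## Known limitations

* The windowed scanner can report a segment whose interior violates the
  per-window allowance when eligibility is carried by overlapping hit
  windows on either side (inherent to hit-fraction eligibility); the
  direct scanner never does.
* Carrier semantics ("presence" of a hotspot) have no single canonical
  definition in the field; the 0.5 default is a robustness choice, and
  conclusions sensitive to it should be re-run across a fraction sweep.
* No mixed-model or kinship correction in the association scan;
  population structure will inflate it on real data.
* VCF input accepts only bi-allelic diploid GT records; split
  multi-allelics upstream (`bcftools norm`).
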