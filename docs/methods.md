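# Methods

## The problem

Genotype panels assembled from nominally unrelated individuals routinely
contain cryptic relatives, mislabeled pedigrees and inbred offspring, and
downstream association or population-genetic analyses are biased when
those go unnoticed.  `ibdkit` audits a cohort of biallelic autosomal SNP
genotypes for relatedness using only unphased genotype calls: no
haplotype reference, no likelihood model, just identity-by-state (IBS)
composition analysed along the genome.

## Pairwise IBS and informative sites

For a pair of samples each marker is one of IBS0 (opposite homozygotes),
IBS1 (hom/het), IBS2\* (het/het), IBS2-hom (concordant homozygotes) or
missing.  Concordant homozygotes are discarded as uninformative.  Useful
closed forms under Hardy–Weinberg genotypes at B-allele frequency *q*
(*p* = 1 − *q*):

| state | unrelated | IBD1 region | IBD2 region |
|---|---|---|---|
| IBS0 | 2p²q² | 0 | 0 |
| IBS1 | 4pq(p²+q²) | 2pq | 0 |
| IBS2\* | 4p²q² | pq | 2pq |

Three consequences drive the design:

* **IBS2\*_ratio** = IBS2\*/(IBS0+IBS2\*) = 2/3 for unrelated pairs at
  *every* frequency, rising toward 1 with relatedness — a calibration
  point the test suite checks by Monte Carlo against the closed form.
* Within an IBD1 region the IBS1 share among informative sites is
  exactly 2/3, again frequency-free.
* Informative-site density per marker is 2p²q²+4pq(p²+q²)+4p²q²
  (≈0.656 under Uniform(0.05,0.95) frequencies) for IBD0 regions,
  3pq (≈0.5475) for IBD1 and 2pq (≈0.365) for IBD2.

## Windowed IBD classification and Cotterman coefficients

Informative sites are cut into windows of 500 sites per chromosome (a
trailing remainder of at least half a window stands alone, otherwise it
merges backward).  Each window is classified:

* IBD ≥ 1 iff the window's IBS0 fraction ≤ `window_ibs0_frac_tol`
  (default 0.06);
* IBD2 iff additionally its IBS1 fraction ≤ `window_ibs1_frac_tol`
  (default 0.40);
* IBD0 otherwise.

The defaults sit at *bp-majority midpoints* derived from the table
above.  An IBD0 region shows ≈0.11 IBS0 among informative sites, so
0.06 assigns a window straddling an IBD0/IBD1 breakpoint to whichever
state covers the majority of it.  For the IBD1/IBD2 boundary the IBS1
fraction of a window that is a fraction *u* IBD2 by bp is
(2/3)(1−u)·1.5 / ((1−u)·1.5 + u), using the exact 3pq:2pq = 1.5
informative-density ratio; setting the threshold to 0.40 makes the
decision flip exactly at u = 1/2.  Midpoint thresholds keep the
genome-wide estimates unbiased in the presence of recombination
breakpoints and tolerate several percent genotype error (an error site
contributes IBS0/IBS1 at rates far below the thresholds).

K0/K1/K2 are the **bp-span-weighted** fractions of windows in each
state.  The weighting matters because informative density falls as IBD
rises: equal-site windows span ~1.8× more bp in IBD2 than IBD0 regions,
so site- or window-count weighting would deflate K2 by roughly 30%
relative for a sib pair (measured against simulator truth); bp weighting
recovers truth to ±0.002 at the default density.  Conservation
K0+K1+K2 = 1 is enforced exactly.  Adjacent same-state windows merge
into IBD segments; a relationship call requires at least one IBD1/IBD2
segment of ≥ 10 Mb (the IBS0-free confirmation), otherwise an elevated
K1 is attributed to conserved-haplotype background and flagged
`UNCONFIRMED_K1`.

Relationship categories: identical (K2 ≥ 0.95); parent-child (K1 ≥ 0.95,
K2 < 0.05); full-sibling (K1 ∈ [0.38, 0.62], K2 ≥ 0.05); second-degree
(K1 ∈ [0.35, 0.70], K2 < 0.05); then half-open K1 bins
[0.30,0.35), [0.20,0.30), [0.10,0.20), [0.025,0.10); unrelated below
0.025.  Anomaly flags mark IBD2 ≥ 0.001 against a parent-child or
second-degree annotation (bilineal relatedness) and IBD0 ≥ 0.001 against
parent-child (chromosomal abnormality or systematic genotype error, e.g.
a hemizygous deletion miscalled as homozygous — reproduced as a
direction-only simulation test).  The relatedness coefficient is
r = K2 + K1/2.

## Runs of homozygosity and trio autozygosity

A ROH is a maximal marker run with no heterozygous call, trimmed to its
first/last homozygous SNP, split where consecutive homozygous SNPs are
more than 1 Mb apart, and reported when ≥ 2 Mb *and* ≥ 400 SNPs.
Missing calls neither break runs nor count toward the SNP tally; one
heterozygous call breaks a run (a configurable tolerance can merge
across isolated hets, default 0).  Without intensity data a ROH may be
autozygosity or a hemizygous deletion; the discriminator is the trio
test: a child ROH overlapping (≥ 1 Mb) a region where the parents are
IBD1 with each other is called autozygous, and IBD2 between child and a
parent corroborates parental relatedness.  Verdicts: `inbred` iff a
qualifying overlap exists or (child-parent IBD2 and the child has ROH);
`unknown` for single-parent trios; `not_inbred` otherwise — related
parents alone never make a child inbred.

## Triad reconstruction

Pairwise K cannot separate half-sib from avuncular from
grandparent-grandchild (all r = 1/4).  Three tracks on one shared
window grid can:

* **Opposite inheritance**: ≥ 3 consecutive windows where the two
  putative siblings are IBD0 with each other while the candidate is
  IBD1 with both.  An aunt/uncle carries both grandparental haplotypes
  and can satisfy this; a single grandparent cannot (wherever the sibs
  disagree about the shared parent's transmission, exactly one of them
  carries the grandparent's allele).  The impossibility is verified
  against 100 error-free simulated grandparent triads.
* **Nested sharing**: every candidate-grandchild segment must pass
  through the intermediate parent, so with a known parent-child pair
  pinned, a candidate whose parent track is parent-child-grade and
  whose child-track IBD1 windows are ≥ 95% contained in the
  candidate-parent IBD1/IBD2 windows is labeled grandparent.

Scenario labels follow the second-degree decision table: 1 — avuncular
to two half-sibs (opposite inheritance, sib pair second-degree without
IBD2; also labels the pair half-siblings, scenario 3); 2 — avuncular to
a pinned full-sib pair; 4 — two second-degree links plus one distant
link without opposite inheritance (reported as an indistinguishable
pedigree set); 5 — rule-outs (IBD2 between second-degree relatives
excludes unilineal half-sib/grandparent explanations; sub-threshold
nested sharing excludes grandparent).  Windows where a pair has < 25 of
its own informative sites inherit that pair's previous state.

## The simulator

Gene dropping over explicit pedigrees: founder haplotypes drawn under
HWE from Uniform(0.05, 0.95) per-marker frequencies, transmissions with
Haldane (Poisson, no-interference) crossovers on a sex-averaged linear
map, founder-allele labels retained so exact IBD states, segments and
autozygosity are emitted as truth.  Genotype error (uniform re-draw of
the call) and missingness are applied after truth extraction.

Genome defaults: the 22 human autosome lengths (2,878 Mb total) at
1.25 cM/Mb (3,597 cM) with 1,000,000 evenly spaced markers.  The marker
count is chosen so an unrelated pair retains ≈ 650k informative sites —
the regime of the genome-wide SNP panels this method was designed for
(several hundred thousand informative sites per pair, so a 500-site
window spans ≈ 2–3 Mb).  Far
sparser panels make the 500-site windows span tens of cM, coarser than
second-degree IBD segments (25–50 cM), and the windowed estimator is
then no longer meaningful for sibs and second-degree pairs — this is a
genuine limitation of fixed-count windowing on sparse data, not of the
implementation.

What the simulator does *not* emulate: linkage disequilibrium, allele-
frequency spectra of real populations, batch/platform artifacts,
crossover interference, sex-specific maps, and population structure.
Passing tests therefore demonstrate correctness of the estimators under
the model's assumptions, not robustness to every property of real data
(conserved long haplotypes, for instance, are exactly why the ≥ 10 Mb
segment confirmation exists and are not simulated here).

## Replicated experiments and problem sizes

Validation experiments (in `ibdkit.experiments`, reused by
`scripts/acceptance.py`): duplicate-sample K2 and parent-child K1
(exact 100% recovery); 200 independent full-sib pairs (mean K ≈
(0.25, 0.50, 0.25), per-pair K1 within the published 0.38–0.62 span);
200 second-degree pairs cycling half-sib, grandparent and avuncular
templates (K1 within 0.3–0.7); 50 children of first-cousin parents
(mean detected-ROH genome fraction within 3 Monte-Carlo SE of
F = 1/16 — the reporting thresholds forfeit only ~2% of autozygous bp
because autozygous segments average ~16.7 cM); 100 grandparent triads
(zero opposite-inheritance regions).  Replicate *i* of an experiment
seeds its generator with `SeedSequence([base_seed, i])`.  The test
suite runs the same experiments, with the opposite-inheritance
replicates at 200k markers and structural checks at 20k–60k markers
where window granularity is immaterial to the property under test.

## Numerical and degenerate-input choices

* Coordinates are 1-based inclusive bp (PLINK map convention); segment
  sizes are (end − start + 1)/10⁶ Mb.
* The per-marker A allele is the lexicographically smaller observed
  non-zero allele; every IBS state is invariant to the designation
  (property-tested), and any allele containing `0` makes the call NC.
* Truth segments tile chromosomes exactly, with boundaries at midpoints
  between markers of different state.
* IBS2\*_ratio with a zero denominator is `None`, not an error.
* A pair with no informative sites raises; an all-concordant-homozygote
  window grid cannot be classified.
* Ties at K1 bin edges: bins are half-open [lo, hi).

## Known limitations

* Fixed-count windows on sparse panels (≲ 100k markers genome-wide)
  are too coarse for sib/second-degree K recovery; use denser data or
  smaller windows.
* ROH thresholds (≥ 2 Mb, ≥ 400 SNPs) presuppose panel densities of
  ≥ ~200 SNPs/Mb.
* Triad logic assumes the three individuals' relationships run through
  at most one shared lineage; heavily endogamous cohorts can fire
  scenario-5 rule-outs instead of positive labels.
* Parent-child orientation (which member is the parent) is outside the
  genetic evidence available to these methods.
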