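# Methods

## Marker models and in-silico digestion

Each locus is an amplicon plus a restriction map.  Fragment coordinates are
1-based lengths in bp, cut positions measured from the 5′ end; digestion
returns the multiset of inter-cut distances including both terminal fragments
(fragments always sum to the amplicon length).  Only fragment multisets are
compared — gels cannot observe fragment order.

Where the literature prints fragment pairs for a known amplicon (Me15-16:
180/168 bp uncut alleles, 126 bp allele cut at 77 bp by *Aci*I in
*galloprovincialis* only; COI: 233 bp cut at 134 bp by *Xba*I in *chilensis*),
alleles are defined by cut position.  Where only fragment sizes are printed
(ITS *Hha*I, the four described 16S triple-digest haplotypes), alleles are
defined directly by their fragment pattern.  Two further 16S haplotypes are
known only by which restriction sites they gain or lose; they are registered
as site-presence descriptors with no committed sizes and no diagnostic
species, so they participate only in frequency-based assignment.

Pattern matching requires the same fragment count and pairs fragments after
sorting both patterns descending, accepting a match when every pair differs by
at most the tolerance.  Default tolerances reflect the scoring platform:
±4 bp for gel-scored markers (Me15-16, COI, 16S), ±2 bp for fragment-analyzer
scored markers (ITS, mac-1), both configurable per call.  Fragments under a
20 bp detection floor are flagged as potentially unobservable on gels but
still matched.  mac-1 has no diagnostic table at all — it is an open size
registry (164–494 bp observed range) and unrecognized sizes are auto-registered,
as are new 16S patterns.  An observed pattern matching two registered alleles
raises an ambiguity error naming both.

## Preprocessing

Mussels show doubly uniparental mitochondrial inheritance: males can carry
both the maternal and paternal mitochondrial genome, so one individual can
show two haplotypes at a mitochondrial marker.  Any individual with two
*distinct* haplotypes at any mitochondrial marker is excluded whole (not just
at that marker) before every frequency-based analysis; a per-marker mode is
not offered because the exclusion count feeds every downstream denominator.
Remaining single haplotypes are encoded as homozygous diploid genotypes
(2 gene copies per individual) so they can enter the diploid likelihood and
diploid allele-frequency denominators.  Individuals missing a marker
(amplification failure) are dropped only from computations involving that
marker.

## Assignment

The reference label is the rule-based *Me15-16 Aci*I call: homospecific
genotypes map through the diagnostic table, heterospecific allele pairs are F1
hybrid calls and are excluded from baselines and confusion matrices.  ITS
resolves *trossulus* versus the edulis/galloprovincialis/chilensis group
("E/G/Ch") and detects F1s as one-of-each heterozygotes; COI resolves
*chilensis* versus "T/E/G".

Frequency-based assignment uses the Rannala–Mountain Dirichlet
posterior-predictive genotype probability (per-allele prior mass 1/k, k = the
number of distinct alleles observed across all baselines at the locus,
configurable), multiplied across loci in log space.  Baselines are
species-level pools of the reference-labelled individuals.  Re-allocation is
leave-one-out: the focal individual's two gene copies per locus are removed
from its own species' baseline before scoring against every baseline.  Scores
are normalized across baselines (log-sum-exp); the individual is assigned to
the arg-max species, with ties broken in the fixed order trossulus, edulis,
galloprovincialis, chilensis (warned, deterministic), and flagged unassigned
when the top normalized score is below the threshold (default 0.05).  The
threshold is implemented as a rank rule on the normalized score; a Monte-Carlo
exclusion test (scoring against simulated genotypes) is deliberately out of
scope.  Mono-locus mode scores raw mac-1/16S alleles directly — no pooling of
similar-sized alleles into "synthetic" compound alleles.

Mito-nuclear introgression is flagged when a species-level nuclear call and a
species-level mitochondrial call disagree; group calls are uninformative and
never flagged.

## Diagnostics

Confusion matrices cross-tabulate reference species against assigned category
(four species, any group/hybrid categories, unassigned).  Group-aware mode
counts a group call containing the reference species on the diagonal — used
for ITS/COI correct-exclusion bookkeeping — and is off for mac-1/16S and the
panels, which make species-level calls.  Unassigned individuals count as
incorrect (a drop-unassigned mode exists).  Concordance is 100·trace/total,
reported to one decimal.  Sensitivity and specificity use the standard
one-vs-rest counts; LR+ is computed from S and E after adding 0.5 to TP, FN,
FP and TN, which keeps it finite when E = 1.  95% CIs are exact
(Clopper–Pearson) binomial for S and E — the CI method behind the published
intervals is not stated, so the exact method is a documented, swappable
choice — and the log-method interval on corrected counts for LR+.

The Wilcoxon signed-rank test drops zero differences (all-ties input returns
p = 1.0) and computes the exact permutation distribution of W⁺ by dynamic
programming over doubled (tie-averaged) ranks for up to 25 nonzero pairs,
falling back to the normal approximation beyond that.  Two-sided p is
2·min(P(W⁺ ≤ w), P(W⁺ ≥ w)) capped at 1.

### Packaged confusion fixtures

The fixtures under `mytilus_id/data/confusion/` encode the reported
re-assignment tallies (253 individuals for mono-locus mac-1/16S after the 40
DUI exclusions and 5 amplification failures; 258 for ITS/COI and the panels).
The published row totals are mutually inconsistent for mac-1 (50+50+65+92 =
257 ≠ 253); the fixtures resolve this by placing 4 of the 5 mac-1 failures in
the *trossulus* sample (n = 46, giving the printed sensitivity 0.76 = 35/46
and the printed overall 144/253 = 56.9% exactly).  Cells not individually
reported — the destinations of the 11 trossulus and 21 galloprovincialis
mac-1 errors, and one edulis plus one chilensis error placed to match the
printed 0.99 specificity for galloprovincialis — are reconstructed fill-in,
not observations, and are documented in `load_confusion_fixture`.

## Ordination

Genotypes are coded as an individuals × alleles indicator matrix of allele
copy counts (0/1/2; a 0/0.5/1 frequency mode exists), mitochondrial haplotypes
diploid-encoded — the standard coding for genotype FCA; the original analysis
names its software but not its coding, so counts coding is our documented
default.  Correspondence analysis decomposes the standardized residuals of the
relative-frequency table under independence; row principal coordinates are
returned and total inertia equals χ²/N.  CA drops individuals with any missing
marker; PCA (SVD of the column-centered matrix, largest-magnitude loading
positive per axis for determinism) imputes missing markers by per-column
means.  95% inertia ellipses use a 2.45-sigma radius (χ²₂ 95% quantile) on the
per-group coordinate covariance.

## Synthetic data

The generator emulates the survey structure the analysis assumes: four species
profiles at five loci, Hardy–Weinberg diploid draws at nuclear loci and one
maternal mitochondrial lineage per individual (COI and 16S drawn from the same
lineage, mirroring their linkage), F1 hybrids (one gamete per parental
profile, maternal mito), mito-nuclear introgressed individuals (nuclear from
the resident species, mito from the donor), DUI individuals (a second, distinct
haplotype from the same species' pool, falling back to the pooled
across-species haplotype frequencies when the species pool is monomorphic —
true paternal-lineage frequencies are unknown), and per-marker amplification
failure (default 2% at mac-1 and 16S, matching the observed failure rate; DUI
genotypes are exempt since their double haplotype was by definition amplified).
Counts per population are `round(fraction·n)`, so the 7/30/3 DUI fixture
yields exactly 40 exclusions.  Reported frequencies are encoded as printed
(16S edulis haplotype 0.980 in edulis, 0.957 in northern galloprovincialis
with the private haplotype at 0.043; mac-1 328 bp at 0.220 southern / 0.021
northern with 303 bp reversed; chilensis 16S haplotype fixed; trossulus novel
16S haplotype at 0.022; ≤3 mac-1 alleles — 255/266/298 — in edulis and
chilensis; shared 255/266 everywhere; high-frequency 487/494 plus low-frequency
private alleles in trossulus).  All remaining frequencies are plausible
fill-in chosen once: edulis and chilensis mac-1 profiles share the same three
alleles at similar frequencies, which is what makes mac-1 confuse those two
species — the generator's central qualitative feature.

What the generator does *not* emulate: within-species population structure
(HWE and linkage equilibrium are assumed — the assignment model's own
assumptions), backcrossed hybrids, genotyping error, or allele-size calibration
noise between scoring platforms.  Passing tests therefore demonstrate the
machinery and the direction of the mono- vs multi-locus contrast, not the
exact full-data percentages.

## Problem sizes and determinism

Analyses and tests use the survey-sized simulation (298 individuals, six
sites) or smaller; frequency-convergence checks use 5 000 individuals for one
species; the Monte-Carlo Dirichlet oracle uses 2·10⁵ draws.  Every random
draw flows from a single `numpy` Generator seeded from the run's `--seed`;
identical seeds give byte-identical datasets and reports.

## Known limitations

- The published LR+ of 63.63 for mac-1/galloprovincialis cannot be reproduced:
  it requires FP/TN cells available only in unpublished supplementary tables,
  and no continuity-correction convention we could verify yields it from the
  printed counts.  Our fixture gives ≈51 with the +0.5 rule.
- The 4-marker full-data percentages (96% edulis, 65% galloprovincialis) and
  the 27-allele mac-1 inventory likewise require the raw data; the synthetic
  suite covers them qualitatively only.
- The two novel 16S haplotypes have no committed fragment sizes, so they can
  be carried in datasets by label but never produced by pattern matching.
- The 0.05 assignment threshold is a rank rule on normalized scores; whether
  the original analysis used that rule or a simulation-based exclusion test is
  not determinable from the text.
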