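# Methods

## Data model and conventions

All coordinates are 0-based half-open internally; VCF (1-based) and GFF3
(1-based inclusive) are converted at the file boundary, BED passes through.
Haplotypes are rows of a 0/1 matrix per chromosome, two rows per diploid
sample, with a population label per row. Multi-allelic, unphased and
missing-genotype sites are excluded at load (counted per reason) rather
than imputed: the pipeline assumes statistically phased, complete input.
Allele 0/1 follows VCF REF/ALT without ancestral polarization; the
haplotype statistic is invariant to polarity and the frequency model is
symmetric enough that polarity only flips the sign of frequency
differences, not window ranks.

## XP-EHH

EHH at a (core, target) pair is the identical-pair fraction of haplotypes
grouped by identity over the inclusive span — so EHH at zero distance is
the core-site homozygosity, not 1. This makes EHH a pure function of the
span, lets a brute-force pairwise oracle check it exactly, and adds the
same core-site factor to both populations.

iHH integrates EHH against physical distance (bp; no genetic map, with an
optional per-bp scaling constant) in both directions from the core. The
integration span is decided once, from the *pooled* two-population EHH
dropping below a cutoff (default 0.05), so both populations integrate over
a common span and neither gets an asymmetric window. Integration also
stops at a chromosome edge or at an inter-site gap above `max_gap`
(default 200 kb, guarding against assembly gaps); such SNPs are kept but
edge-flagged, since dropping them is a policy choice the data may not
warrant. If the pooled EHH is below the cutoff at the core itself, iHH is
0.

Raw scores ln(iHH_focal/iHH_ref) are standardized over all defined scores
of the run (all chromosomes jointly). Sites where either iHH is 0 are
reported but excluded from standardization.

The scan exploits the fact that haplotype-identity grouping does not
depend on population labels: one incremental grouping pass over the pooled
panel yields pooled, focal and reference EHH at each extension step. The
inner loop is compiled with numba when available; a pure-numpy
implementation of the same algorithm is retained and cross-checked in the
tests (the two paths agree to 1e-6 bp on random panels).

## Composite-likelihood scan

The neutral model for the focal pre-sampling frequency q given the
reference frequency p is Gaussian drift, q ~ N(p, ω·p(1−p)), with the mass
outside (0,1) placed as atoms at 0 and 1 (fixation/loss absorption). ω is
the method-of-moments mean of (p̂_focal − p)²/(p(1−p)) over sites with
0.05 < p < 0.95 (at least 100 required). Note the estimator contains the
binomial sampling variance of p̂_focal (≈ 1/n_focal), so it converges to
the drift scale only for reasonably deep sampling; it is also inflated by
sweep-distorted regions, which is acceptable for scanning (conservative)
but means ω should be estimated genome-wide, not from a candidate region.

The sweep model transforms a neutral q by the two-branch hitchhiking law
with escape probability c = 1 − exp(−r·d·t_s), t_s = ln(2Ns)/s; s-grid
values with 2Ns ≤ 1 are skipped. The site likelihood integrates the
binomial sampling density against this law by fixed-grid quadrature:
512 equal cells on (0,1) by default, each cell contributing its *exact*
Gaussian mass (CDF difference) at its midpoint node, plus the two boundary
atoms. Cell masses sum to 1 by construction; a guard still aborts if the
weight sum deviates by more than 1e-6. The log-likelihood is assembled
with logsumexp throughout. Quadrature self-convergence was verified from
512 to 32,768 cells (differences < 2e-4 in log-likelihood) including
tail-dominated instances, where plain Monte-Carlo integration — used as
the cross-check oracle on generative instances — is itself unreliable.

The scan evaluates a grid of candidate sweep positions (default spacing
2.5 kb); sites within `window_radius` (default 12.5 kb) contribute.
CLR = 2(max_s ℓ_sweep − ℓ_neutral) is floored at 0 (grid-resolution
artifacts can otherwise produce small negative values); argmax ties over s
resolve toward the smaller s. Sites fixed in the reference population are
excluded from the scan: the drift law has zero variance there. Unlike the
original composite-likelihood method, correlated sites are *not*
down-weighted by LD — each site contributes independently; CLR values are
therefore comparable within a dataset but not across methods.

For localization experiments the window radius is set to 100 kb: at
s = 0.05 and r = 1e-8 the sweep's recombination footprint 1/(r·t_s) is
about 1.3 Mb, and within the default 12.5-kb radius the escape probability
is nearly constant, so the likelihood surface carries position information
only through sites at larger distances. Even so, localization precision is
physically limited to roughly ±1 window (25 kb) at these parameters; the
recovery experiments score the argmax as correct when it lands in the true
window or an adjacent one.

## Windows and significance

Windows tile each chromosome as [0, 25 kb), [25 kb, 50 kb), …; a window's
statistic is the maximum over the scored positions inside, and windows
with no scored positions are dropped (a max cannot be ranked). SNP-count
bins are 1–200, 201–400, 401–600 and >600 (upper edges inclusive).
Empirical p within a bin of B windows is rank/B with rank 1 for the
largest; tied windows all take the worst rank of the tied set
(conservative). Selection is strict (p < 0.01), so a bin needs more than
100 windows before anything can be flagged — empirical significance is
meaningful only against a genome-scale background. The CLR threshold is
the empirical (1 − 0.01) order statistic of the window maxima without
interpolation, flagged by ≥.

## Enrichment

Tests count haplotypes (two per individual; per-individual dominant coding
is available as an option). In amino-acid mode, k is the number of
categories *observed* at the site across all breeds; each of the three
breeds is tested as focal in turn. The one-sided p is the hypergeometric
upper tail P(X ≥ a) with the table's margins (scipy's survival function;
tests cross-check an exact-rational enumeration oracle to 1e-12). Zero-cell
odds ratios are reported as +inf when a·d > 0 with b·c = 0. Bonferroni
scope defaults to the gene (m = all tests emitted for that gene); a global
scope is available. Profile tables carry both the nominal 0.05 line and
the Bonferroni cutoff line for plotting.

## Synthetic data

`simulate_two_pop_sweep` is a forward Wright–Fisher model: an ancestral
pool of 2N haplotypes with M sites uniform on [0, L) and derived counts
from the neutral SFS shape (∝ 1/i), copied into two populations at the
split, each reproducing for T generations with Poisson(r·L) crossovers per
meiosis. Selection is additive on one site (pinned to the requested sweep
position); under hard-sweep conditioning (default) the selected allele
starts as a single copy, so one ancestral haplotype hitchhikes — the
classic hard-sweep geometry. Runs losing the allele restart the focal
population from the split on a fresh sub-stream (count recorded, at most
1000); the reference population evolves on its own stream and is never
perturbed by restarts. There is no new mutation after the split: both
populations segregate subsets of one ancestral site set, as a jointly
called variant panel does. Defaults (N = 500, T = 200, s = 0.1,
L = 2.5 Mb, M = 2000, r = 1e-8/bp ≈ 1 cM/Mb) give a strongly drifted pair
of populations with a completed sweep, in under a second per replicate.

What this emulates: drift-driven divergence, recombination-generated LD,
hitchhiking, and a shared site set. What it does not: new mutation on the
swept background (real swept haplotypes re-diversify), variable
recombination and mutation rates, demography beyond a clean split,
sequencing error and imputation noise. Consequently the synthetic swept
chromosome is *cleaner* than real data — passing power tests bound what
the method can do under ideal conditions, not what it will find in a real
panel.

`simulate_gene_sites` draws each null site's shared category distribution
once per site: P(Indel present) ~ Beta(1, 4) in Y/N mode (a present Indel
is a derived variant; derived-variant frequencies are skewed low), and
Dirichlet(1,…,1) over k ≥ 3 amino-acid categories (no canonical ancestral
label). Enriched sites multiply the focal breed's odds of the focal
category by the requested factor.

## Validation experiment design

End-to-end sweep detection scans each sweep replicate jointly with a fixed
panel of 40 neutral background chromosomes simulated under identical
conditions (≈ 4,100 ranked windows): the empirical-p rule cannot flag
anything against fewer than ~100 windows, and a real scan ranks a sweep
against a whole genome (tens of thousands of windows). The background is
simulated once and shared across replicates to keep runtime near
4 minutes; scores are standardized jointly per replicate. Detection means
the specific 25-kb window containing the selected site is flagged at
p < 0.01 — a deliberately strict criterion given that neighbouring windows
within the sweep's footprint are nearly exchangeable with it.

Monte-Carlo cross-checks of the site likelihood draw (p, ω, c) at random
and k from the model's own generative law, so the checked integral is
never tail-dominated; tail cases are covered by quadrature
self-convergence instead. Drift-variance recovery uses 1000 sampled focal
chromosomes per site so the moment estimator's 1/n sampling bias (~0.001)
is negligible against the ±0.01 tolerance.

Problem sizes throughout (replicate counts, site counts, background size,
quadrature density in experiments) are the package's own choices balancing
statistical resolution against single-CPU runtimes of a few minutes.

## Known limitations

- No LD down-weighting in the composite likelihood (correlated sites
  overcount evidence; CLR magnitudes are dataset-internal).
- Physical distance only; a genetic map can only enter through the
  constant per-bp recombination rate.
- The EHH truncation level (0.05) and edge policy are conventional
  defaults, both configurable; edge-flagged SNPs are kept.
- Localization of the CLR argmax is limited to roughly ±25–50 kb at
  s ≈ 0.05 with r = 1e-8 regardless of sample size.
- X-chromosome or non-autosomal contigs are processed like autosomes if
  present in the VCF; flagging them is the caller's responsibility.
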