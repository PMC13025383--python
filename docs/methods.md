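# Methods

`snpkin` implements pairwise relationship inference for very low-coverage
SNP hybridization-capture data — the regime of degraded skeletal samples
compared against family reference samples on a ~95K SNP panel — together
with the surrounding quality-control and ancestry machinery and a
synthetic-data generator that inverts the inference model exactly.

## Genotype likelihoods and the damage model

At ~1X coverage genotypes cannot be called reliably, so each covered site
keeps a likelihood triple over the alt-allele dosage g ∈ {0, 1, 2}.  For a
read with observed base *b*, Phred error probability *e*, and distances
*d5*/*d3* from the original 5'/3' read ends, the substitution model is

    P(b | t) = 1 − e_tot                            if b == t
    P(T | C) = δ5(d5) + (1 − δ5(d5))·e/3            (5' C→T deamination)
    P(A | G) = δ3(d3) + (1 − δ3(d3))·e/3            (3' G→A deamination)
    P(b | t) = e/3                                   otherwise,

an additive-hazard combination of sequencing error (split uniformly over
the three wrong bases, the conventional substitution-agnostic choice) and
postmortem cytosine deamination in the double-stranded-library convention
(C→T keyed to the 5' distance, G→A to the 3' distance).  The four
probabilities sum to one by construction.  The damage term follows the
*true* template base, which reproduces the C/T-site and G/A-site formulas
without needing the site's allele pair as an input.  Per dosage the
per-read contribution is the strand mixture ½P(b|a1) + ½P(b|a2) over the
unordered allele pair; reads multiply and triples are max-normalised
(the normalisation cancels in every ratio downstream).

Damage rates are estimated empirically: δ5[d] is the fraction of reads
over reference-C positions at 5'-distance d that read T, for d below a
window K (default 15, after which terminal deamination has decayed in
typical degraded material), with the pooled interior rate as baseline and
as fallback for empty distances.  Damage is applied only to skeletal
profiles; reference (saliva/buccal) profiles use a zero damage profile.
Estimation at the panel's own polymorphic sites slightly inflates rates
when a true T allele segregates at a C/T site; the simulation round-trip
tests therefore use homozygous-reference genotypes.  A base-quality floor
of Q2 is applied; "N" bases are dropped and counted, not errors.

## Relationship likelihoods

Seven fixed hypotheses are evaluated, each an IBD-proportion vector
k = (k0, k1, k2): self (0,0,1), parent–child (0,1,0), full sibling
(¼,½,¼), 2nd degree (½,½,0), 3rd degree (¾,¼,0), 4th degree (⅞,⅛,0),
unrelated (1,0,0) — the standard 2^(1−d) expected-IBD1 ladder for the
named degrees.  For alt frequency p the joint genotype table is the
k-mixture of the IBD0 (independent Hardy–Weinberg), IBD1 (one shared
allele) and IBD2 (copied genotype) tables.  Per site the two GL triples
are summed against this 3×3 table; log10 likelihoods accumulate over
sites (per-site 9-term sums in linear space are safe; accumulation is in
log space).  Each hypothesis is reported with a log10 LR versus unrelated
and a posterior probability under equal priors over all seven hypotheses,
computed with max-subtraction.  Equal priors are the default and
hard-coded into the reported PP; the argmax breaks exact ties toward the
more distant category, the conservative direction for a forensic claim.
Inbreeding and genetic linkage are not modelled.

Allele frequencies are clamped to [0.001, 0.999] so that genotyping error
can never zero out a hypothesis; for the common SNPs this panel targets
the clamp is inert.

Decision thresholds: a call is *conclusive* when the most likely
category's posterior reaches the PP threshold (0.9999 by default; 0.95
selectable) and — for any category other than unrelated — its log10 LR
versus unrelated is at least 4.  An unrelated call is judged on its
posterior alone.

## Dynamic LD pruning

Marker independence is enforced per comparison: LD (squared Pearson
correlation of dosages, pairwise-complete over missing data, 0 for
monomorphic columns) is precomputed from a reference dosage panel for all
pairs within a 1000-SNP index window at r² ≥ 0.2 (plink `--r2
--ld-window-r2` semantics; stored and pruning thresholds coincide).  For
each sample pair, starting from the sites present in both profiles, every
stored pair with both members still retained loses the member with the
lower coverage score — the *sum* of the two samples' depths at the site,
a symmetric, comparison-specific choice; ties retain the earlier site in
panel order.  Pairs are processed in ascending panel order, which together
with the tie-break makes pruning deterministic, idempotent and symmetric
in the sample labels; tests assert that no stored pair survives intact.

## Ancestry estimation and frequency-file selection

Global ancestry proportions q over African, Native American, East Asian,
Central/South Asian and European references maximise
Π_sites Σ_g GL(g)·Binom(g; 2, f(q)) with f(q) = Σ_k q_k·p_k, by
supervised-admixture EM on genotype likelihoods (population frequencies
fixed, allele-level responsibilities, uniform initialisation, stop at
max|Δq| < 1e-6 or 300 iterations).  The EM is monotone in the likelihood
and keeps q on the simplex; with identical frequency columns the
likelihood is flat and the uniform initial vector is returned (documented
degenerate case).  Estimates from fewer than 100 usable sites carry a
low-confidence warning.

A sample is *admixed* when max(q) < 0.90.  Kinship allele-frequency file
selection: non-admixed → majority population; admixed with both African
and European components present (component present at ≥ 0.10) → African
American; Native American plus European → Latino; when both rules could
fire the larger of the African and Native American proportions decides;
any other admixture falls back to the majority population with a warning.

## Quality control

SNP recovery counts panel sites at ≥1X/≥5X/≥10X against the 94,752-SNP
panel.  The analytical threshold for distinguishing authentic signal from
background is mean + 10·SD (sample SD, n−1) of the 1X SNP counts of clean
control blanks, reported raw and rounded up to the nearest 100 for
presentation.  Pass/fail boundaries follow the validated, deliberately
asymmetric conventions: references pass at ≥ 1000 SNPs (1X), skeletal
samples fail at ≤ 300.  A blank above its threshold is screened by
running the kinship comparison against every co-processed sample; a
most-likely call of *self* identifies the contaminating source.

## Synthetic data

The generator is the model's exact inverse, which is the point of the
parameter-recovery tests: IBD states are drawn i.i.d. per site from k (no
linkage or recombination map, matching the inference model's independence
assumption), genotypes from the same conditional tables the likelihood
uses, and read bases from the same substitution matrix the GL computation
inverts.  Population structure uses the Balding–Nichols model: per-site
ancestral frequency Uniform(0.05, 0.5) (a stand-in for the panel's
common-SNP frequency spectrum; configurable), per-population frequency
Beta(p(1−F)/F, (1−p)(1−F)/F).

Default conditions emulate the validated capture workflow at desk scale:
Poisson depth with mean 4, base error 0.01 (Q20), fragment lengths
uniform on 40–120 bp for skeletal material and 200–500 bp for references
(affecting only where in a read a site falls, hence the damage-position
draws).  Control blanks cover each panel site independently at a small
sporadic rate, depth 1, with bases drawn from the population frequency —
background signal with no single-source genome behind it.

What the generator does **not** emulate — and hence what passing tests do
not show about real data: genetic linkage along chromosomes, reference
bias and mapping artefacts, microbial co-extraction, index cross-talk,
mixture contributions, population misspecification between the sample and
the frequency file (the admixture false-positive mechanism observed with
real casework data), and USER-repair residual damage heterogeneity.

## Problem sizes and numerical choices

Stochastic suites run at desk scale, chosen to finish in minutes on one
CPU: typically 5–40 seeded replicates per condition and 1k–60k simulated
sites per pair.  Operating-point checks use the study conditions (depth
4, error 0.01, matched frequencies): related pairs at 20,000 SNPs for the
posterior claim, 2nd-degree pairs at 2,400 SNPs for the LR ≥ 4 claim,
unrelated pairs at 60,000 SNPs for the unrelated-posterior claim, and 60
related pairs (4th degree at 30,000 SNPs, others at 2,400) for the
no-false-negative claim.  Per-site likelihood sums are floored at 1e-300
before taking logs; GL triples are max-normalised; the EM tolerance is
1e-6 on max|Δq|.

At matched site counts and low coverage the parent–child and full-sibling
true-category LR distributions are statistically indistinguishable (the
full-sibling IBD2 cells compensate for parent–child's absent IBD0), so
the ordering property asserted in tests is strict decrease across
*degrees* (full sibling > 2nd > 3rd > 4th, and parent–child > 2nd).

## Known limitations

Fourth-degree versus third-degree/unrelated confusion at low site counts
is expected and tracked rather than asserted; conclusive 4th-degree calls
need tens of thousands of overlapping SNPs.  The Beagle-GL profile format
is an exchange stand-in (with a depth sidecar, since Beagle text carries
no depth), not a claim about any platform's internal format.  BAM/CRAM
pileup extraction, FASTQ handling, alignment, mitochondrial QC and
mixture interpretation are out of scope; single-source status is an input
flag.
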