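# Methods

## Matching model

`sketchid` scores each database candidate independently as a binary
hypothesis test: x_i = Y ("the sketch and candidate i are the same
individual") against x_i = N ("the sketch comes from an unrelated member
of the population"). Posteriors are deliberately not normalized across
the database — the evidence for one candidate says nothing about another,
and the same sketch may in principle match several entries (e.g.
duplicated reference files), which the scanner detects and reports.

Observations are assumed independent across markers. This is justified by
the sketching regime itself: coverage is far below 1x, so each marker is
seen by at most one read, and the extraction stage enforces a
first-observation-only policy when a later read does cover an
already-observed marker. Linkage disequilibrium between panel markers is
ignored; for the ~10²–10³ widely spaced common SNPs a sketch touches,
inter-marker correlation is negligible at the scale of the log-odds sums
involved.

The match likelihood is a genotype-conditional symmetric error matrix:
a homozygote emits its allele with probability 1 − ε and the other allele
with probability ε; a heterozygote emits either allele with probability
0.5 (a single read samples one chromosome uniformly, and the symmetric
error leaves the half-half mixture unchanged). The no-match likelihood is
the probability of drawing the observed allele from a random person:
(1 − ε)·f + ε·(1 − f), with f the observed allele's population frequency.
Markers with extreme frequencies are therefore the strong evidence
carriers in both directions: observing a rare allele that the candidate
carries multiplies the odds by up to ~0.98/0.07 ≈ 14, while an
observation inconsistent with a homozygous candidate divides them by
~ε/0.5.

## Decision thresholds

All accumulation is in natural-log odds (`scipy.special.logit/expit` at
the boundaries); linear-space products of hundreds of likelihoods against
priors down to 10⁻¹⁵ would underflow. Defaults:

| parameter | default | meaning |
|---|---|---|
| prior | 10⁻⁵ | prior match probability per candidate |
| match_threshold | 0.999 | posterior declaring a match |
| reject_threshold | 10⁻⁹ | posterior below which a candidate is abandoned |
| stop_snps | 300 | intersected-SNP budget before a no-match verdict |
| max_data_seconds | 3600 | sequencing data consumed per decision |

Early rejection uses "drops below" semantics: it is active only when the
prior lies above the rejection bound. With an extreme prior such as
10⁻¹⁵ the posterior *starts* below 10⁻⁹, and a literal reading would
reject every candidate at the first observation; disabling rejection in
that regime preserves the intended behaviour (the verdict is unchanged
for any prior between 10⁻¹⁵ and 10⁻², only the number of SNPs needed to
reach 99.9% grows as the prior shrinks). Rejected candidates report a
posterior of 0 — a truncated report, not a literal zero.

A matched candidate keeps consuming the stream (its posterior typically
saturates at ~1), so simultaneous matches are detected; ranking ties are
broken lexicographically by sample id. The per-candidate scan is
implemented as a vectorized cumulative sum over (candidates ×
observations) with threshold crossings resolved in stream order; the unit
tests verify it is exactly equivalent to the scalar sequential update and
to naive linear-space Bayes evaluation.

## Sketch extraction

Reads with mean Phred quality ≤ 9 or with multiple alignments
(secondary/supplementary records, or any repeated query name) are
discarded. Only aligned match/mismatch CIGAR columns yield bases; indels
and clips never do. A base at a panel position that is neither of the
marker's two alleles is counted as a sequencing error and dropped — at
nanopore error rates a third allele is overwhelmingly more likely to be a
miscall than a true tri-allelic variant. Every base landing on a panel
position is accounted for in exactly one counter (observation, error
discard, duplicate discard), and the run report surfaces the error
fraction.

Per-observation ε defaults to the Phred-implied error rate of the read's
mean quality, clamped to [0.001, 0.30] to keep the likelihood matrix
well-conditioned; a global override is available for calibrated
chemistry-wide rates (≈0.089 for R7 and ≈0.02 for R9 flow cells). The
clamp floor matters: ε = 0 turns a single inconsistent observation into
log 0.

## Synthetic study conditions

The simulators define the conditions under which the method is tested:

- **Panel**: 5,000 bi-allelic autosomal markers by default, allele-A
  frequency Uniform(0.05, 0.95). The real common-SNP spectrum is U-shaped
  rather than uniform; uniform over the panel's support is a conservative,
  documented stand-in since extreme-frequency markers are the strongest
  evidence carriers in both directions.
- **Individuals**: Hardy-Weinberg genotypes (f², 2f(1−f), (1−f)²),
  markers independent — no population structure, no LD, no genotyping
  error in reference files.
- **Relatives**: Mendelian transmission (one uniformly drawn allele per
  parent), giving exact expected sharing of 1 allele per locus for
  parent–child and 50% for grandparent–grandchild.
- **Sketching**: n distinct markers drawn without replacement; the
  transmitted allele is the homozygous allele or a fair coin for
  heterozygotes; a symmetric flip with probability ε produces the
  observation. ε = 0.02 is the default (R9 regime). Timestamps advance at
  `snps_per_minute` (default 30 at 250 bases/sec), scaled by the
  translocation-speed regime (70 bases/sec for R7), so wall-clock-based
  comparisons reflect chemistry speed.
- **Mixtures**: a contaminated sketch pools round(N·fraction) contaminant
  observations with the complement from the host, keeps marker sets
  disjoint (each locus is covered by at most one read at sketch
  coverage), shuffles, and re-times. The standard grid is 3,000
  observations at fractions {0, 0.1, 0.25, 0.5, 0.75} with five
  replicates each.

Because the generator omits real-data complications (reference-panel
frequency misestimation, alignment bias, per-read quality variation,
somatic instability of cell lines), passing simulations demonstrate the
statistical engine's calibration under its own assumptions, not
end-to-end accuracy on real flow-cell data.

## The relatives experiment

Relative discrimination is evaluated under the method's operating
protocol: the matcher is sequential and sketching stops once a match is
declared, so child and grandchild references are assessed on the
observations consumed up to the focal individual's own match (or the full
300-SNP budget when no match arrives). Under the default conditions the
focal individual matches at a median of ~75 intersected SNPs and neither
relative ever reaches the threshold by then.

A known limitation, worth stating plainly: if one keeps sketching far
past the decision point, a first-degree relative's posterior performs a
heavy-tailed random walk (driven by runs of shared rare alleles) and
transiently crosses 99.9% in roughly 1% of 300-SNP streams at ε = 0.02.
The negative expected drift (≈ −0.1 log-odds per observation) guarantees
eventual rejection, but the sequential threshold rule is not immune to
early stopping on a lucky burst if the true individual's reference is
absent and the budget is long. Second-degree relatives show no such
crossings at these settings.

## Growth model

Culture overgrowth is modelled as deterministic exponential (log-phase)
competition: N(t) = N₀·2^(t/T) per line, with the contaminant fraction
N_c/(N_c + N_h) and the closed-form 50% crossover
t* = log₂(N_h0/N_c0)/(1/T_c − 1/T_h) when the contaminant doubles faster.
Computations run on log₂ cell counts to avoid overflow over long
horizons. Doubling times are exposed as parameters (defaults 24 h host,
20 h contaminant, 10 cells vs 10⁶): note that with ~24 h doubling times a
2–4 h advantage needs ~2–3 months to overtake, so two-week overgrowth
scenarios imply substantially faster-cycling lines (e.g. 4 h vs 8 h); no
carrying capacity is modelled.

## Problem sizes

The test suite and `scripts/acceptance.py` use 1,000-run ensembles
against a 100-entry database, 100-run worst-case and relative
experiments, and 3,000-observation mixtures on a 5,000-marker panel —
sizes at which the binomial noise on the reported fractions is well below
the margins being checked, while a full run completes in seconds thanks
to the vectorized scan.
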