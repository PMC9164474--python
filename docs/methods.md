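# Methods

## Data model

A *phosphosite* is one quantified mono-phosphopeptide: a protein position
carrying S, T or Y, a 13-mer sequence window (positions −6…+6, the
phosphoacceptor at 0, `J` padding where the window runs past a protein
terminus), and a time course of log2(treated/vehicle) ratios at 1, 2, 5
and 15 min with three replicates per time point, each replicate paired
with an independent vehicle control. Windows are extracted with
`centralize_site` (1-based protein coordinates, closed windows); records
whose reported residue disagrees with the window center are dropped with
a warning rather than failing the run, since such rows are annotation
errors rather than malformed input.

## Regulation filter

Per-time-point p-values come from a two-sided one-sample t-test of the
replicate log2 ratios against 0. The paired treated/vehicle design makes
the per-replicate ratio the natural unit of observation; a two-sample
variant can be selected in `SignificanceConfig`. The empirical range is
±`ci_multiplier` × max_t SD_t, where SD_t is the across-site sample SD of
the mean ratios at time t and the multiplier defaults to 2 (with
reference SDs 0.104/0.104/0.128/0.148, 2 × 0.148 rounds to the 0.30
half-width; 1.96 would not). A site is regulated if both criteria hold at
the same time point, for at least one time point. The reported FDR is the
product of the two criterion levels, 0.05 × 0.05 = 0.0025, and no
across-site multiple-testing correction is applied.

**Caveat — the product FDR is optimistic.** Both criteria are functions
of the same sample mean, so their null rates do not multiply: with three
replicates the measured per-time joint null rate is ≈ 0.012, and the
union over four time points brings the per-site null call rate to
≈ 0.022 (measured by `scripts/acceptance.py` as
`null_regulated_fraction`). The filter keeps the classical dual-criteria
definition; the 0.0025 figure should be read as a lower bound on the
FDR, not an estimate of it.

## Clustering

The residue-class alphabet is Φ = AFILMVW (non-polar), Δ = STY
(phosphorylatable polar), Θ = DE (acidic), Ψ = RKH (basic), Σ = CNQ
(non-phosphorylatable polar), P, G. First-level partition, in precedence
order: P at +1 → Group I; Ψ at −3 → Group II; Δ at −3 and/or −2 →
Group III; else Group IV. The function is total: every valid window maps
to exactly one group.

Subclustering is a deterministic decision tree over three descriptors:

- *direction*: sign of the 15-min mean ratio (an exact 0 excludes the
  site from direction-based subclustering, with a warning);
- *speed*: first time the absolute ratio reaches half its maximum —
  fast (≤ 1 min), slow (≥ 5 min), intermediate otherwise;
- *pattern*: from the signs of successive differences d1 = x(1)−0,
  d2 = x(2)−x(1), d3 = x(5)−x(2): monotonic (d1,d2,d3 ≤ 0),
  dip-then-rise-at-5 (d1<0, d2≤0, d3>0), dip-then-rise-by-2 (d1<0,
  d2>0), rise-dip-rise (d1>0, d2<0, d3>0), otherwise *other*.

The tree: Group I splits by direction (I.B increased); I.A with Ψ at
both +5 and +6 → I.A.1, otherwise by pattern into I.A.2.a (monotonic),
I.A.2.b (dip-then-rise-at-5), I.A.2.c (dip-then-rise-by-2), else
unassigned. Group II splits on Ψ at −2 (II.A) — increased sites then
split by speed into II.A.1.a (slow) and II.A.1.b (fast) — and II.B,
where increases go to II.B.2 and decreases split by pattern into
II.B.1.a (rise-dip-rise) and II.B.1.b (either dip-then-rise form).
Group III splits by direction, with decreased sites split on Ψ at −1
(III.B.2) versus not (III.B.1); Group IV splits by direction only.
Sites the rules cannot cleanly place carry an `unassigned` flag and a
decision trail recording every rule applied. Speed, not glycine at −1,
separates II.A.1.a from II.A.1.b; the glycine enrichment of the fast
cluster is a descriptive feature, testable with `enrichment_chisq` (2×2
chi-square, no continuity correction by default; a Yates flag exists).

Frequency matrices exclude `J` positions from denominators so terminal
padding does not dilute the statistics.

## Bayesian engine

The engine is a sequential application of Bayes' Rule over a length-N
kinase vector (N = 521 reference, configurable), starting from the
uniform prior. Because each update multiplies the running posterior by a
likelihood vector and renormalizes, the result is invariant to step
order and equals the single-pass product form — a property the test
suite asserts against a brute-force oracle to 1e−12.

Evidence-to-likelihood transform: cMBF(z*) = 1 − exp(−z*²/2) with
z* = score/pivot. Pivots:

- steps 1–3 (transcript and two protein abundance tables): configured
  per dataset; when unspecified, the median of the dataset's positive
  values is used as the detection-noise scale. The median is robust to
  the right-skew of abundance data and leaves roughly half the detected
  kinases below z* = 1 (likelihood < cMBF(1) ≈ 0.39, hence floored),
  which matches the intent of "expressed at all" evidence.
- step 4 (S/T/Y acceptor preference, dot product of frequency triples):
  pivot 1/9, which makes any appreciable S/T overlap saturate while
  leaving pure tyrosine kinases at the floor.
- steps 5 and 7 (colocalization and motif dot products): pivot = the
  Poisson maximum-likelihood rate (sample mean) of the non-negative
  scores, estimated per cluster.

Likelihoods are floored at 0.5 after every continuous step (1–5, 7), so
a kinase with no evidence anywhere retains the all-0.5 path and is never
eliminated. Step 6 (curated activity direction vs. the cluster's 15-min
direction, taken as the majority over member sites) assigns discrete
likelihoods 0.9/0.1/0.7/0.5 and is *not* floored — flooring would erase
the deliberate 0.1 mismatch penalty.

Step 7 details: information content IC(a,i) = P(a,i)·log2(P(a,i)/Pref(a))
with zero frequencies contributing zero; cluster and kinase IC matrices
are dotted over the cluster's signature positions (+1 for Group I, −3/−2
for II.A, −3 for II.B, −3/−2 for III, −2/−1 for IV; overridable).
Negative per-cell products are clipped at 0 before the cMBF: the cMBF is
sign-symmetric, so without clipping a kinase *depleted* of the cluster's
signature residues would be scored as if enriched. Kinases missing from
the preference data inherit the score of their nearest kinome-tree
neighbor, walking chains of missing neighbors; an unscored cycle falls
back to 0 (hence the 0.5 floor). Rankings sort by descending posterior
with an alphabetical tie-break, and report probability ratio =
posterior × N.

## Synthetic data

The generator plants a configurable set of kinases (default five,
covering the four sequence groups and five distinct leaf clusters) in a
background of null sites. Conditions: 500 sites, 40 regulated, three
replicates, replicate noise SDs 0.104/0.104/0.128/0.148 at 1/2/5/15 min,
effect size 0.4 log2 units, 20-kinase registry, 10% evidence dropout,
six subcellular fractions. Windows of regulated sites are drawn from the
planted kinase's motif (signature positions deterministic, so first-level
group recovery is exact); temporal shapes are mean multipliers at the
four times chosen to satisfy the pattern-class sign definitions exactly
in the noise-free limit. Evidence tables are generated consistently:
planted kinases get high expression, matching acceptor triples, a shared
fractionation "home" with their substrates, and the correct activity
label. Ground-truth cluster labels are not hard-coded — each planted
kinase's expected leaf is computed by classifying its noise-free shape
and modal window, so the truth table can never drift from the
classifier. A single seed expands through `numpy.random.SeedSequence`
into independent child streams for sites and evidence.

What the generator does *not* emulate: missing-value mechanisms of
LC–MS/MS, TMT ratio compression, correlated replicate noise, biological
site-to-site variance beyond the planted effects, and realistic
kinase-family motif overlap (e.g. PKA vs. PKG near-identity). Passing
recovery tests therefore show the pipeline is correct and well
calibrated under its own assumptions, not that real-data performance
will match.

Measured operating characteristics at the default conditions (recomputed
by `scripts/acceptance.py`): planted-kinase top-5 recovery ≈ 98% of
cluster–kinase pairs over 50 seeds; dual-criteria power on planted sites
≈ 0.88 (the pooled SD includes the planted effects, inflating the
half-width to ≈ 0.26–0.27, which costs a few percentage points of
power); null site call rate ≈ 0.022 (see the filter caveat above).
Under the stated noise, shape fidelity is limited for the monotonic
class: the three successive differences of a 0 → −0.4 monotonic course
are at most ≈ 0.133 while their noise SD is √2·0.104/√3 ≈ 0.085, so at
most ≈ 83% of such sites can classify monotonic; misclassified members
fall to sibling leaves or the unassigned pool without affecting kinase
recovery.

## Numerical choices and degenerate inputs

- Zero replicate variance: p = 1 when the mean is also 0, p = 0 with a
  warning otherwise.
- Half-widths are rounded to two decimals (matching how such ranges are
  reported); comparisons use strict inequality, so a boundary value does
  not count as outside the range.
- The substrate-record filter uses strict localization P > 0.75.
- `cmbf` uses `expm1` for small-z accuracy and rejects non-finite input.
- All-zero likelihood×prior products raise rather than renormalize.
- Cluster ranking requires ≥ 3 member sites by default; smaller leaves
  are skipped with a log message.

## Known limitations

The engine treats the seven evidence layers as independent given the
true kinase, which is optimistic where datasets share provenance (two of
the three expression layers are proteomic). The leaf decision tree
operationalizes descriptive cluster characterizations; alternative
operationalizations (e.g. treating glycine at −1 as a rule) would move a
minority of sites between sibling leaves. The FDR product understates
the realized false discovery rate, as quantified above.
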