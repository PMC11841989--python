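# Methods

This note documents the statistical models, the synthetic-data generator,
the numerical choices, and the known limitations of `salexpr`.

## Study design and scales

The analyses assume a two-environment (normal / saline) common-garden design
on highly inbred diploid accessions, each grown with `r` replicates assigned
to blocks, with plant-level expression on the non-negative
log2(normalized count + 1) scale, per-plant fecundity as a filled-grain
count, and biallelic SNP dosages in {0, 1, 2} (heterozygotes rare and capped
at 5% by the hard filters). Genomic coordinates are 1-based inclusive
everywhere (VCF convention).

## Variance partitioning and heritability

Per trait, a two-way mixed ANOVA with environment fixed and genotype and
genotype×environment random. Sums of squares come from unweighted cell
means (Type I on balanced data; mild imbalance uses the harmonic-mean cell
count; a genotype missing an entire cell is an error for that trait).
F denominators follow the classical unrestricted mixed model: both main
effects over MS(G×E), the interaction over MS(error) — a choice that is
configurable because authorities differ on the denominator for the fixed
main effect. Components are method-of-moments: σ²err = MS(err),
σ²GE = (MS(G×E) − MS(err))/r, σ²G = (MS(G) − MS(G×E))/(e·r). Broad-sense
heritability is H² = σ²G/(σ²G + σ²GE/e + σ²err/(r·e)) with negative
component estimates clamped to zero first; the "environment" variance in the
denominator is interpreted as the *residual* error variance — the fixed
environment shift does not enter — which is the standard across-environment
H² and reproduces the formula's worked value 1/(1+0.25+0.25) = 0.667 for
σ²G=1, σ²GE=0.5, σ²err=1.5, e=2, r=3.

The environment contrast on fecundity uses accession means: a two-tailed
paired t-test and a one-sample proportion test of the count of accessions
with lower saline fecundity against 0.5. The proportion test is the
chi-square **without** continuity correction (z = (p̂−½)/√(¼/n)); this is
the variant that reproduces the test statistic printed for the 94-of-130
worked example (p = 3.639×10⁻⁷).

## Selection analysis

Relative fitness w is fecundity over mean fecundity among plants with
non-zero fecundity; zero-fecundity plants are excluded. Per transcript and
environment, expression values more than 3 SD from the mean are removed
(single pass), and a transcript must be expressed (>0) in ≥20 retained
plants. S is the slope of w on raw expression with block as a fixed
covariate; C is twice the quadratic coefficient of the model adding the
squared term (S is always reported from the linear model). Block enters as a
fixed covariate: with a balanced block design this is equivalent to the
random-block fit for the slope and keeps the estimator closed-form.
p-values are two-sided Wald t tests on the focal coefficient; Bonferroni
runs over the transcripts tested in that environment. Variance- and
mean-standardized forms are S·σ, S·μ (and C·σ², C·μ²).

Trade-off classes: AP requires p<0.05 in both environments with opposite
signs of S (checked first); same-sign significant pairs are "concordant";
CN uses the deliberately stricter asymmetric rule p<0.025 / p>0.05 to offset
the detection-bias asymmetry between CN and AP.

PCA is centered but not rescaled (expression shares the log2 scale);
components explaining >0.5% of variance are retained. Gradients β and γ come
from joint linear and quadratic regressions of w on the retained scores.
A PC's direction is assigned by majority sign agreement between its top-1%
|loading| transcripts and their univariate S; exact ties stay unresolved.
Organismal traits are greedily pruned until all pairwise |r|<0.6 (dropping
the trait with the largest mean |r| first), then z-scored.

GO-term selection strength is the median |S| of member transcripts (terms
with <20 members excluded); significance requires the percentile-bootstrap
95% CI lower bound to exceed the transcriptome-wide median |S|. The CI
method is a package choice (seeded percentile bootstrap, 1000 draws).

## Response to selection

The GRM is the cross-product of per-SNP dosages standardized to unit
variance (population SD, so the mean diagonal is exactly 1), over
polymorphic SNPs. The additive (co)variance matrix G of accession-mean PC
scores is estimated by Haseman–Elston regression: score cross-products
(symmetrized for off-diagonals) regressed on off-diagonal GRM entries.
An external REML tool is deliberately not used; HE is closed-form, unbiased
under the simulation model, and adequate at desk scale. Its sampling SD for
a single trait at n=150 is ≈0.3 — limited by the effective rank of the
relatedness variation, not by the estimator — so recovery checks average
over the diagonal of a multi-trait G. Any negative eigenvalues of the
assembled G are clipped to zero (flagged). The breeder's equation Δz = Gβ is
split into direct (G_ii·β_i) and indirect (off-diagonal) parts; "constraint"
flags mark components where the two oppose. This diagonal/off-diagonal
reading of direct vs indirect response is the standard one but is a design
choice. PCA (and hence G and Δz) is computed per environment.

## Decoherence

For the transcripts passing the entry filter (|S| above a threshold in at
least one environment and detected in ≥50% of plants), covariates are
regressed out, residuals are z-scored **within** environment (population
SD), and each pair's per-plant product is tested for an environment effect.
With within-environment z-scoring the environment-wise mean product equals
the within-environment Pearson correlation, so the test isolates correlation
change; the global-standardization variant of the reference method is
available behind a flag. The per-pair linear-model test reduces exactly to
the pooled-variance two-sample t, computed for all pairs at once via matrix
cross-products. BH controls the FDR at 5%. Hubs are transcripts with
strictly more significant pairs than the median count among transcripts
with ≥1 significant pair. Accession structure is ignored by the default
linear model (the mode of the reference method used at this design's scale).
The entry threshold is parameterized: |S| is on the raw scale and shrinks
with transcript SD, so the default study uses 0.04 where the source setting
on its own normalization used 0.1.

## eQTL mapping and architecture

Association uses accession replicate means per environment (replicate
variance enters only through the mean), an intercept, and the top-5 kinship
PCs. The full SNP×gene scan is computed by QR-residualizing expression and
dosage on the covariates and forming cross-products; this reproduces
per-pair OLS t statistics to 1e-8 and is tested against a brute-force
regression oracle. BH runs across all tested pairs within an environment
(global FDR 0.001; G×eQTL on the normal−saline difference at FDR 0.05).
cis = same chromosome and <100 kb from the gene body (distance 0 inside the
gene, else the gap to the nearest edge); trans = different chromosome or
≥1 Mb; the 100 kb–1 Mb gap is unclassified and excluded from cis/trans
contrasts. Lead SNPs minimize p per gene within non-overlapping 100-kb bins
anchored at position 1 of each chromosome (ties break to the smaller
coordinate). Hotspots are bins whose lead trans-eQTLs regulate >30 unique
genes (strict).

Cis-trans mode: per individual, the cis push is β_cis·(x−x̄) for the lead
cis-eQTL and the trans push averages β_t·(x−x̄) over lead trans-eQTLs; the
configuration is "same" when the product is positive. A gene is reinforcing
(compensating) when ≥60% of informative individuals are same (opposite).
The per-individual "allelic configuration" is operationalized as this push
product's sign — the quantity is named but not defined in the source
literature, and the classification is invariant to global allele
relabeling. The reinforcing-vs-compensating excess uses the two-sample
proportion z-test **with** continuity correction (the combination without/
with correction for the one-/two-sample tests is exactly what reproduces
both printed worked examples). Mode-wise inter-varietal variance uses a
one-sided Mann-Whitney test (reinforcing > compensating).

The LD permutation test compares the observed mean dosage-r² of cis-trans
pairs with 1000 null draws matching the pair count and the distance profile:
cross-chromosome pairs draw random cross-chromosome pairs; same-chromosome
pairs draw pairs within ±10% of the observed separation, with the tolerance
doubling (warned) when a stratum cannot be matched. The two-tailed p applies
the +1 permutation correction to each tail and caps at 1.

MAF is min(p, 1−p) of the dosage allele frequency; inbred accessions count
as single haploid-equivalents (heterozygotes count half), so per-site
diversity is π = 2p(1−p)·n/(n−1) with n the non-missing accession count.
π contrasts average over variant sites in 50-kb flanks around cis-eQTLs
versus 100-kb genome tiles excluding those windows; empty windows are
excluded with a reported count. Welch t-tests compare MAF sets and π means.
The background SNP set excludes eQTL SNPs.

## Synthetic-data generator

One master seed spawns an independent named substream per stage, so adding
or rerunning a stage never perturbs another and identical configs are
byte-identical. Defaults are the study conditions: 2 environments ×
3 replicates in 3 blocks; inbreeding 0.99 (selfing copies the second
haplotype with that probability, so `inbreeding=1` forces {0,2});
MAF spectrum uniform(0.05, 0.5); local LD from a shared block-level uniform
per haplotype over 50-kb windows; optional Balding–Nichols subpopulation
structure (the default study uses 3 subpopulations at Fst 0.25 — the
structured-panel feature that gives kinship PCs something to correct and
creates the long-range LD on which cis-trans mode calls depend).
Variance-component means (σ²G 0.8, σ²GE 0.7, σ²err 1.8, gamma-distributed
across transcripts with shape 4) put the median H² near 0.55 for the 2×3
design, matching a largely heritable field transcriptome; the environment
shift is N(0, 0.3) per transcript so only a minority of transcripts show a
marked genotype-independent response.

The planted architecture assigns genes to cis-only / dual / trans-only /
null modes; cis SNPs lie within 100 kb of the gene start (genes without a
candidate demote to trans-only with a warning), trans SNPs are ≥1 Mb away or
on another chromosome. A dual gene's trans partner is the eligible distant
SNP most *positively* correlated with its cis SNP — the genetic-fixation
(cis-trans LD) mechanism that makes per-individual mode calls informative —
and dual effects share their sign with probability `reinforce_fraction`
(default 0.6), keeping truth labels consistent with effect signs. Ordinary
effects are |β| ~ uniform(0.6, 1.4) on the log2 scale (matching mean effect
sizes near 1); the master-regulator hotspot wires one SNP to exactly
`n_targets` genes with |β| ~ uniform(1.2, 1.8) — master regulators are
modeled as strong so that their targets survive a transcriptome-wide FDR of
0.001 — and is saline-specific in the default study. Half of ordinary trans
effects are environment-specific, which produces the expected cis-vs-trans
sharing asymmetry and gives the G×eQTL scan true positives.

Fecundity is built from relative fitness w = 1 + Σ S·z + Σ (C/2)(z²−1) +
noise on within-environment standardized expression (the quadratic term is
centered so planted coefficients sit on the relative-fitness scale), scaled
by a per-environment base count (150 normal / 100 saline, so salinity
reduces fecundity), rounded, floored at 0, with an extra `zero_rate`
fraction (default 5%) of plants set to zero. Planted selection is therefore
recovered on the variance-standardized scale (S_s). Two deliberate
properties of this construction matter for interpretation: the zero floor
truncates the fitness surface, so loading one simulation with many strongly
selected transcripts (or planting |S| large under high noise) attenuates
every recovered coefficient by a few percent — recovery checks plant one
transcript per fitness realization at noise where the floor is inactive;
and the default study plants no opposite-sign selection, so observed AP
calls are pure false positives.

What the generator does **not** emulate: read-level sequencing noise,
normalization artifacts, realistic recombination maps or multi-allelic
sites, transcript-transcript regulatory networks beyond the planted shared
regulators, and selection on organismal traits (the trait table is
structured noise). Passing tests therefore demonstrate estimator
correctness under the assumed generating model, not robustness to every
feature of real field data.

## Numerical choices and degenerate inputs

OLS throughout uses explicit normal equations with rank checks; singular
designs skip the transcript (with a reason code) rather than erroring the
scan. Constant transcripts or SNPs are skipped per pair; transcripts
constant within an environment are dropped from CILP (tolerance 1e-10 on the
SD). BH q-values are computed with the standard step-up cummin. Bootstrap,
thinning, permutation, and generator randomness are all seeded. Expression
values are floored at 0 after noise (log2(x+1) scale). Eigenvector signs in
kinship PCs are fixed by the largest-magnitude component for deterministic
output.

## Default problem sizes

The default synthetic study runs 150 accessions × 2 environments ×
3 replicates, 1000 transcripts, and 3000 SNPs on five 30-Mb chromosomes —
sizes at which every stage's statistical behavior (FDR control, recovery,
hotspot power) is already stable and a full `run_all` completes in seconds.
Recovery simulations in the test-suite and acceptance script use 130–150
accessions, matching the emulated panel.

## Known limitations

- HE regression ignores the correlation between products sharing an
  individual, so its reported SEs are approximate (slightly optimistic);
  an EM-REML refinement is not implemented.
- The fixed-block, fixed-covariate selection regressions are equivalences
  for balanced designs; strongly unbalanced blocks would call for the
  mixed-model fit.
- Global BH across all SNP×gene pairs is conservative for genes with strong
  signals relative to per-gene FDR (offered as an option).
- The decoherence linear model ignores accession replication; an
  accession-mean aggregation is available but not default.
- The permutation test's distance matching widens its tolerance rather than
  failing when a stratum is unmatched, trading exactness for robustness on
  sparse maps.
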