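# Methods

`ctlong` implements a longitudinal circulating-tumour-DNA (ctDNA) analysis:
patient-specific filtering of plasma variant calls against matched tumour,
germline and benign-control samples, detection of localized hypermutation
(kataegis), refitting of trinucleotide mutational signatures, copy-number and
tumour-fraction estimation from binned read depth, and clonal deconvolution
across serial plasma draws. A synthetic serial-plasma generator with full
ground truth provides the validation substrate; this note records the models,
the defaults and why, and what the synthetic experiments do and do not show.

## The generative model (simdata)

Each synthetic patient carries a random rooted clone tree. Clone prevalences
are drawn top-down per timepoint: the founding clone receives a cellular
prevalence U(0.6, 0.95), and the children of each clone split a
uniform-Dirichlet share of their parent's prevalence, the remainder staying
private to the parent. This satisfies the phylogenetic sum condition — a
parent's prevalence is at least the sum of its children's — exactly by
construction. Prevalence draws are rejected (up to 500 times) until every
pair of clones differs by at least `min_clone_separation` (default 0.25)
somewhere along the time course: clones with coincident trajectories are
unresolvable at any sequencing depth, and a benchmark that scores inference
against an unidentifiable truth measures noise, not method quality.

A heterozygous copy-neutral somatic variant private to clone c is expected in
plasma at allele fraction `v = 0.5 * t_j * P_{c,j}`, where `t_j` is the
tumour fraction of cell-free DNA at timepoint j and `P_{c,j}` the clone's
cellular prevalence. Alt read counts are Binomial(depth, v) with a fair
strand split; depths are Poisson around the per-sample target (1000x plasma,
200x tumour, 50x germline); alt base qualities are Normal(35, 3) truncated to
[2, 60]. The matched tumour uses the pathology cellularity (default 0.7) in
place of `t_j`; the germline shows zero alt reads at somatic loci. Default
sizes — 5 clones with 20 mutations each, five plasma draws with tumour
fractions (0.25, 0.05, 0.08, 0.12, 0.10) — mirror a resected patient sampled
before and after surgery and through follow-up; per-clone mutation counts
follow the observed candidate loads of serial-plasma exome studies
(hundreds of candidates over ~10 clones).

On top of the clean signal the generator injects, at configurable rates
(default 0.1 of the somatic burden each), every artifact class the filtering
cascade removes: germline-leaked variants (alt reads in the matched
germline at >=20x), variants shared with chronic-pancreatitis (CP) control
plasma (the CP artifact loci are drawn once per run and shared by all CP
samples, emulating recurrent technical artifacts), fully strand-biased
calls (half of which are given matched-tumour support so they are rescued
past the call stage and must fall to the Fisher test), variants inside
blacklist intervals, multi-allelic loci, dbSNP-only annotations, low
base-quality calls, and synonymous/unknown classifications. Kataegis
clusters of configurable size and spacing (optionally pure T>G) and a
fragment-length mixture — weight 1-d on Normal(167, 10), d = 0.15 on
Normal(334, 20), truncated at 50 bp — complete the patient. Every injected
object is labelled in truth tables.

What the generator does **not** emulate: sequencing error beyond the explicit
artifact channels, CHIP-structured somatic copy-number noise in plasma
(bin noise is independent Poisson), copy-number-aware VAFs (the clonal model
is deliberately copy-neutral, matching the analysis), mappability structure,
and read-level data. Passing tests therefore demonstrate correctness of the
algorithms under their stated model, not robustness to every failure mode of
real plasma exomes.

## Filtering cascade

Stages run in a fixed order: (1) plasma calling — at least 3 alt-supporting
reads with one on each strand, or at least 1 read when the matched tumour
carries >=3 alt reads at the same variant; (2) drop variants absent from
COSMIC but holding a dbSNP identifier; (3) drop synonymous/unknown exonic
function (missing annotations count as unknown but are reported separately);
(4) drop mean alt base quality < 25; (5) keep only loci covered >=20x in the
matched germline with zero alt reads — under-covered loci are dropped as
unverifiable (config `germline_undercovered: keep|drop`, default drop, since
keeping unverifiable loci admits germline leakage); (6) drop loci with any
alt read in CP control plasma; (7) drop all alleles at loci showing more
than one alternate allele across the patient's serial plasma; (8) drop
positions inside blacklist intervals (BED half-open intervals converted to
1-based at the boundary); (9) strand bias — two-sided Fisher exact on the
per-strand ref/alt table, dropping only when p < 0.01 **and** the minor alt
strand carries under 10% of alt reads, so low-depth variants are spared;
(10) flag (never drop by default) variants with any population allele
frequency above zero.

Stages 2–9 are per-variant predicates over fixed context, so permuting them
cannot change the surviving set. This requires one care: the multi-allelic
rule is evaluated against the patient's *called* plasma universe, not the
current survivor set — otherwise dropping one allele of a pair at an earlier
stage would rescue the other and the cascade would become order-dependent.
"Minimum coverage of 3 reads" is read as 3 variant-supporting reads, the
reading consistent with the strand clause attaching to the same reads; it is
config-switchable. The strand-bias stage is a self-contained reimplementation
of the FPfilter idea with explicit, configurable thresholds.

## Kataegis

Consecutive SNVs on a chromosome are grouped greedily while the
inter-mutational distance (IMD) stays within 10^4 bp (log10 IMD <= 4); a
closed group is a kataegis event when it has >=6 members and mean IMD
<= 1000 bp. No member trimming is performed. Detection defaults to the
patient's combined all-timepoint plasma candidate set (duplicate variant keys
across timepoints are collapsed), with per-sample mode available. The
hypermutation score of a window is the observed/expected mutation-rate ratio
H against the sample-wide background rate, with a binomial upper-tail test;
windows are flagged at H >= 5 and p < 0.05. The exact score formula of
window-based kataegis callers is not standardised; the rate-ratio definition
used here is stated in full and config-exposed. Substitution spectra are
pyrimidine-referenced six-class counts; ties for the dominant class are
reported as ties.

## Mutational signatures

Spectra are 96-channel pyrimidine-referenced trinucleotide counts; contexts
come from a table column (or per-record metadata) so that no reference genome
needs to be bundled; purine-reference sites are reverse-complemented
including flanks. Exposures are refit by forward selection: starting from an
empty set, the signature whose inclusion most reduces the SSE — weights
re-solved by non-negative least squares, capped at total weight 1 — is added
until the relative SSE improvement falls below 1e-3; weights below the
discard threshold 0.06 (the refitting convention of the deconstructSigs
family) are zeroed and the survivors re-solved. Spectra are normalized to
proportions, making exposures scale-invariant. Genomic-instability labels
map post-discard weights to DSBR (signature 3), MMR (signatures 6, 15, 20,
21, 26) and POLN (signature 9); missing catalogue columns leave the label
undetermined rather than silently negative.

## Copy number and tumour fraction

Read counts in 1 Mb bins are corrected by dividing by a LOESS fit of count
against GC (fit on autosomal usable bins), sample and matched normal
separately; the ratio is median-centred and log2-transformed. Bins with
mappability < 0.9 or zero counts are masked. Segmentation is a 6-state
(HOMD, HETD, NEUT, GAIN, AMP, HLAMP = copy 0..5+) Viterbi pass with Gaussian
emissions centred on the purity model
`E[log2 r | c, t] = log2((t*c + 2(1-t))/2)`, emission sigma estimated by the
scaled median absolute deviation of the log-ratios, self-transition 0.99,
and a mild diploid-favouring per-bin state prior
(0.001, 0.05, 0.85, 0.05, 0.02, 0.01). The prior is load-bearing: without
it, a single-copy loss at tumour fraction t fits exactly as well as a
homozygous loss at t/2 (and a gain at t as an amplification at t/2), making
the purity likelihood aliased. The tumour fraction maximizes the Viterbi
path likelihood over the candidate grid 1 − {0.2, 0.35, 0.5, 0.65, 0.8,
0.9, 0.99} (the published normal-contamination initialization set), refined
by golden-section search between the best grid point's neighbours. The model
is clonal-only — one aberrant population, no subclonal fraction. Pathology
cellularity, when given for tumour samples, fixes t. A result whose Viterbi
path is entirely neutral is flagged `no_evidence` rather than trusted as an
estimate. State labels above GAIN follow the common convention AMP = copy 4,
HLAMP >= 5, config-exposed, since the labels have no universal numeric
definition.

## Clonal inference

Variants × timepoints alt/depth matrices are clustered with an absence-aware
binomial mixture: each variant contributes a Binomial(depth, phi_{k,j})
likelihood at every timepoint, so zero alt reads is evidence of absence at
that timepoint rather than missing data. Variants never detected anywhere
are excluded and reported. EM runs 20 seeded k-means++ restarts per
candidate k (per-iteration likelihood monotonicity is asserted); k is chosen
by BIC with k*T + (k−1) parameters. Clusters are ordered by descending mean
VAF for determinism.

Cluster VAFs become cellular prevalences U = clip(2*phi, 0, 1) under the
heterozygous copy-neutral model; loci inside non-neutral copy segments are
excluded from clustering when segments are supplied. The clone tree is found
by exhaustive enumeration of all rooted spanning forests under a virtual
germline root (feasible to ~8 clusters; hard cap `max_exhaustive_clones`,
default 10). Three modelling choices matter here:

- **Germline capacity.** The germline root's capacity at each timepoint is
  the total tumour-derived fraction, estimated by the largest clone
  prevalence, not 1. Plasma prevalences are scaled by the tumour fraction
  (U = t*P << 1), so a capacity of 1 never binds and star-like trees would
  always be feasible regardless of the data.
- **Noise-aware feasibility.** Violations of the sum condition are compared
  at a tolerance of about three standard errors of a cluster prevalence
  (derived from cluster sizes and depths); a tree whose violation is within
  noise of zero is treated as feasible as an exactly-feasible tree. With
  noise-free prevalences the tolerance is negligible and a zero-violation
  tree is returned whenever one exists; under sampling noise the guarantee
  holds at the noise resolution, which is the strongest version of it the
  data can support.
- **Likelihood tie-break.** Trees tied at the noise resolution are ranked by
  the likelihood of their parent-child splits under a neutral
  uniform-Dirichlet model (the density of m children under parent p is
  m!/U_p^m per timepoint, so clones attach to the smallest feasible parent),
  then by summed parent-child trajectory correlation, then lexicographically.

Clonal proportions are child-subtracted prevalences floored at zero. The
stem clone is the cluster with the highest mean prevalence (ties to the
smallest index, flagged). Dynamics labels use a detection floor of 0.005
prevalence: emergent = undetectable at baseline, detected later; declining =
a >=50% relative drop between consecutive draws (restricted to intervals
spanning a treatment day when treatment dates are given); stable otherwise.

## Tracking

Mean mutant allele fraction (MAF) per timepoint averages over the union of
the patient's detected candidate loci, counting covered-but-undetected loci
as 0 (keeping the series sensitive to clearance; configurable to drop them).
Tumour–plasma concordance reports the overlap of the tumour call set with
baseline plasma and with the union of all timepoints; the combined fraction
is a superset statistic and can never fall below baseline. Pathway
enrichment is a hypergeometric upper tail with Benjamini–Hochberg adjustment
across pathways (the correction is unstated in comparable analyses; BH is
the field default for exploratory enrichment). Fragment-size modes are
1 bp-resolution histogram argmaxes with ties resolved to the smallest
length. CA19-9 values join plasma draws by nearest day within ±14 days.
Actionability annotation uses a bundled toy gene catalogue (drivers, RAS
family, DDR biomarkers with therapy hints, DDR pathway members); a variant
detected in >=2 serial plasma samples is flagged trackable.

## Numerical and testing notes

- All randomness flows through `numpy.random.Generator` objects seeded from
  configs or explicit arguments; the end-to-end pipeline is bitwise
  reproducible for a fixed seed.
- Resolving a 1 bp histogram mode on a peak with a 10 bp standard deviation
  requires ~4e7 fragments (the per-fragment probability gap between 167 and
  its neighbours is ~2e-4); fragment-mode checks therefore use 4e7 draws,
  and the wider dinucleosome peak is only checked to a small neighbourhood.
- Multinomial spectrum checks bound the total L1 distance at three times its
  expected value rather than testing each channel, since rare channels
  individually violate per-channel Gaussian bounds.
- Benchmark problem sizes used by the test-suite and the acceptance script:
  kataegis, 100 (tests) / 60 (script) replicates on a 100 Mb contig at
  1 SNV/Mb; signatures, 50/30 refits of n=2000 spectra over 10 signatures;
  copy number, 30/9 genome-wide profiles at ~1665 reads per bin (log-ratio
  noise ~0.05); clonal inference, 200/60 replicates of 5 clones × 20
  mutations at 1000x over 4 timepoints.

## Known limitations

- Indels are parsed but flagged unsupported and excluded from all
  SNV-defined analyses (contexts, IMD, clustering).
- The clonal model ignores copy number and mutation multiplicity; prevalence
  estimates at CN-altered loci are biased unless those loci are excluded via
  supplied segments.
- Exhaustive tree search grows as (k+1)^(k-1); beyond ~8 clusters it is
  impractical and the cap should be lowered rather than raised.
- The copy-number emission model is Gaussian with a single global sigma;
  heavy-tailed bins (e.g. residual mappability artifacts) are not
  down-weighted as a Student-t emission would.
- Placement of clones whose prevalence sits at the detection floor
  (~0.005) is reported but carries little evidence; topology-recovery
  failures in validation are concentrated in exactly these clones.
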