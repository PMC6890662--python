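# Methods

## The problem

Bulk tumor expression profiles mix malignant cells with the tumor
microenvironment (TME): immune and stromal cells whose fraction (1 − purity)
varies from patient to patient.  A transcription factor (TF) such as STAT3 can
be active in both compartments, so a single activity estimate inferred from
target-gene expression confounds three things: tumor-cell activity,
TME activity, and the purity of the biopsy itself.  `basecomp` infers three
per-sample scores — General (G), Tumor (T) and Environmental (E) activity —
designed so that T and E track the latent compartment activities rather than
the cell-type composition of the sample.

## Rank-based activity scoring (BASE)

For one sample, genes are sorted by relative expression in descending order
(ties broken by gene identifier, making scores bit-reproducible).  Two
cumulative distributions are accumulated down the ranking,

    f(i) = Σ_{k≤i} |g_k · w_k|        / Σ_{k≤n} |g_k · w_k|
    b(i) = Σ_{k≤i} |g_k · (1 − w_k)|  / Σ_{k≤n} |g_k · (1 − w_k)|

where g_k is the (median-centered, log-scale) expression at rank k and
w_k ∈ [0, 1] the gene's binding-affinity weight (0 for genes outside the
profile).  The preliminary score is the signed deviation of largest
magnitude, d(i*) with d = f − b and i* = argmax |d(i)| (first index on ties).
It lies in [−1, 1]; it is positive when high-weight genes concentrate at the
top of the ranking, negative when they sink to the bottom, and exactly 0 for
constant weights (the weight cancels algebraically, and the implementation
computes both distributions from one shared cumulative sum in that case).

The preliminary score has no absolute scale, so it is normalized against a
permutation null: the gene-to-expression assignment within the scoring
universe is shuffled with the weights fixed to genes (implemented as
shuffling the weight-to-rank alignment, which is the same operation and
vectorizes over permutations), the statistic recomputed `n_perm` times
(default 1000), and the observation expressed either as a z-score
(`(obs − mean_null)/sd_null`, default) or a sign-stratified enrichment ratio
(`nes`: positive observations divided by the mean positive null, negative by
the mean |negative null|).  Per-sample permutation streams derive
deterministically from `(seed, sample index)`, so results do not depend on
evaluation order or parallelism.

Scores are only computed on per-gene median-centered input (the `normalized`
flag is enforced).  Centering matters because the statistic weights ranks by
|g|: adding a constant to a sample would leave the ranking unchanged but
silently reweight it.

The statistic is *not* strictly monotone in foreground expression: raising a
high-weight gene's magnitude also inflates the foreground normalizer, which
can lower f(i) at ranks before that gene, where the maximal deviation may
sit.  Small score decreases after increasing a target's expression are
therefore genuine behavior of the definition (the test suite pins one such
case against a brute-force oracle); the *mean* response across random
instances is positive.

## Compartment profiles

Profile construction happens once on a training cohort and the profile is
then applied frozen to other cohorts.

1. **Affinity weights.**  ChIP-seq binding p-values map to weights as
   w = min(1, −log10(p)/10), anchoring w = 0.5 at p = 1e−5 and saturating at
   p ≤ 1e−10.  Genes with w ≥ 0.5 (configurable) are the TF's high-affinity
   targets and carry their w into scoring.
2. **Purity association.**  Per-gene Spearman correlation (SCC) with tumor
   purity is computed over shared samples (≥ 10 required; constant rows are
   flagged and set to 0).  A gene counts as *purity-associated* when
   |SCC| exceeds the cutoff (default 0.1) **and** its Benjamini–Hochberg-
   adjusted Spearman p-value is below `ref_fdr` (default 0.05).  The
   significance condition exists because a raw magnitude cutoff admits a
   non-trivial fraction of genuinely uncorrelated genes at genome scale
   (about 8% of null genes exceed |SCC| = 0.1 at n = 200); such chance
   entrants dilute the purity signal the reference background must carry,
   and the purity confounder leaks back into the compartment scores.  The
   same single definition is applied to target partitioning and reference
   selection — using a stricter rule for references alone makes the
   reference pool *over*-track purity relative to the targets and biases the
   T score the other way.  Setting `ref_fdr=None` restores the magnitude-only
   rule.
3. **Partition.**  Purity-associated targets with SCC > 0 are tumor-specific,
   with SCC < 0 environment-specific; the rest (including targets absent
   from the expression matrix) are nonspecific.  The three sets exactly
   partition the target list.
4. **Reference genes.**  Purity-associated genes that are *not* targets and
   whose affinity stays below the target threshold form the positive
   (SCC > 0) and negative (SCC < 0) reference pools.  References are disjoint
   from all target sets by construction.

## Purity-adjusted scoring

- **G** scores all targets (tumor + env + nonspecific, with their weights)
  against the full gene universe.  It is intentionally purity-agnostic.
- **T** restricts the scoring universe to tumor targets plus positive
  references; references enter with w = 0, so they shape only the background
  distribution b(i).
- **E** mirrors T with environment targets and negative references.

The adjustment works by construction: both the foreground (targets) and the
background (references) rise and fall with purity together, so composition
shifts cancel and only activity-driven displacement of targets *relative to*
the references moves the score.  T and E universes are disjoint, so the two
scores are structurally independent — permuting environment-target expression
leaves T scores bit-identical.

Per-branch seeds derive from `(seed, branch index)`; coverage of each target
and reference set in the scored cohort is logged, and scoring aborts if less
than half of a set is present.

## TF screen

Two indirect comparisons locate where a TF is expressed: (1) Spearman
correlation of its expression with tumor purity across tumor samples, and
(2) a two-sample t-test on its within-sample expression *ranks* in tumors
versus cancer cell lines (pure tumor material).  Ranks are computed over the
gene universe shared by both matrices so the scales are comparable across
platforms; Welch's unequal-variance statistic is the default because the two
cohorts differ in size and technology (a flag restores the pooled form).
A TF is called TME-specific when SCC ≤ −0.5, t > 0 and p < 0.001;
tumor-specific by the mirror rule; otherwise unclassified.  Both cutoffs are
exposed; no multiple-testing correction is applied across TFs, matching the
raw-cutoff convention of this kind of screen.

## Genomic burden

CNV burden = Σ_i |log2(C_i/2) · s_i| / N over a sample's copy-number
segments (C_i copy number, s_i = end − start + 1 in bp, 1-based inclusive
SEG coordinates), N the genome size (default: sum of hg19 chromosome
lengths, 3,095,677,412 bp; hg38 available; overridable).  Copy number 0
makes the log undefined and is clamped to 0.25 (log2 ratio −3,
configurable).  Overlapping segments are summed as given with a warning.
The statistic is invariant to subdividing segments and additive in log2
units: doubling every C_i ≥ 2 adds exactly (Σ s_i)/N.  TMB is the count of
non-silent mutations per sample; the default non-silent set is
{Missense, Nonsense, Nonstop, Frame_Shift_Del/Ins, In_Frame_Del/Ins,
Splice_Site, Translation_Start_Site}.

## Downstream statistics

Patients stratify at activity 0 (High: score > 0; a score exactly 0 is Low —
the strict-inequality definitions leave 0 unassigned, so the tie rule is
declared rather than implied).  The four-group labeling is the cross of the
T and E stratifications.  Survival comparison uses Kaplan–Meier estimates and
the (k−1)-df log-rank test; proportional-hazards fits are a thin wrapper
over lifelines (routine statistics, not this package's contribution).
First-order partial Spearman correlation rank-transforms x, y, z, computes
the partial Pearson correlation of the x/y ranks given the z ranks, and takes
p from the t approximation with n − 3 degrees of freedom; it is cross-checked
against `pingouin.partial_corr` in the test suite.

## The synthetic cohort generator

The generator emulates a mixed-compartment bulk cohort.  Per gene, a baseline
mu_g ~ Normal(0, 1); per sample, purity p ~ Uniform(0.3, 0.9) and latent
activities a_T, a_E ~ Normal(0, 1).  Compartment log2 expression:

    x_T = mu + delta·[tumor-compartment gene] + effect·a_T·w·[T-responsive]
    x_E = mu + delta·[env-compartment gene]   + effect·a_E·w·[E-responsive]

with delta_g ~ Uniform(0.5, 1.5) the compartment-restricted baseline
elevation carried by tumor targets and positive background genes (tumor
side), environment targets and negative background genes (TME side), and
nonspecific targets (both sides).  Giving *targets* a compartment baseline —
not only an activity response — is essential: compartment-specific targets
are, by definition, genes expressed in one compartment, which is exactly why
they correlate with purity and why purity-matched references can cancel that
correlation.  Without it no partition by purity correlation could recover
the planted classes and the reference adjustment would have nothing to
cancel.  The observation is a linear-scale mixture re-logged,
y = log2(p·2^x_T + (1−p)·2^x_E) + Normal(0, noise_sd): bulk expression mixes
transcripts, not log values.  Target weights w ~ Uniform(0.5, 1) are emitted
as a binding table with p = 10^(−10w) — the exact preimage of the affinity
map — plus 300 decoy genes with sub-threshold affinities.

Defaults (the conditions under which the recovery and decoupling claims are
tested): 200 samples, 5000 genes, 120/170/90 tumor/env/nonspecific targets,
400/400 positive/negative background genes, effect size 1.0 log2 per unit
activity, noise SD 0.5, purity in [0.3, 0.9], activity SD 1.0.  The screen
generator plants TME-restricted TFs (elevated by the effect size in x_E
only) and tumor TFs (in x_T only) among neutral genes; its default effect is
3 log2 units (8-fold) around the same 0.5 noise floor, reflecting that genes
truly restricted to TME cell types (immune/stromal markers) show multi-fold
tissue-versus-cell-line contrasts; cell lines are drawn at purity 1.
CNV segments are constructed by tiling the genome into 22 chromosome-sized
pieces, each assigned 2·2^b (gain) or 2·2^(−b) (loss, only while above the
clamp floor), so the analytic burden equals the requested target exactly.

What the generator does **not** emulate: batch effects, probe-level
artifacts, copy-number-driven expression coupling, discrete cell
subpopulations, or TFs sharing targets.  Passing recovery tests therefore
demonstrates that the inference machinery is correct under the stated model,
not that real cohorts satisfy the model.

All generators are pure functions of (config, seed).

## Numerical and design choices

- RNA-seq log transform uses log10(x + 1); the pseudocount makes the
  transform defined at zero counts.
- One-channel probe collapsing keeps the probeset with the highest mean raw
  intensity across samples (ties: probe identifier); two-channel collapsing
  averages probesets on the log-ratio scale.
- Duplicate genes in binding tables keep the smallest p-value (logged).
- SEG values may be absolute copy numbers or log2 ratios (r → C = 2·2^r),
  declared by a flag.
- Expression ties rank by gene identifier; `argmax` ties resolve to the
  smallest rank index.
- The zscore permutation normalization is the default; `nes` is provided for
  compatibility with enrichment-ratio conventions.  An observed score of
  exactly 0 normalizes to 0 under `nes`.
- Problem sizes in the test suite: unit tests run on 40-sample/400-gene
  cohorts (structure checks), the end-to-end recovery and decoupling checks
  on the full 200 × 5000 default with n_perm = 1000, and the pipeline
  determinism check on the 40 × 400 cohort with n_perm = 200.
- Reference-gene SCCs are frozen at profile construction; profiles applied
  to a new cohort reuse the training-cohort gene sets (coverage logged).

## Known limitations

- The compartment partition needs cohorts large enough for the purity
  correlation to reach BH significance; below roughly 40 samples the screen
  may empty a compartment, in which case profile construction aborts with a
  clear message rather than producing an unadjustable profile.
- TFs with heavily shared target sets will receive correlated activity
  estimates; the framework scores one weight profile at a time.
- The unrestricted-background variant of T/E scoring is deliberately exposed
  only through the generic scoring API; the compartment API always adjusts.
- Activity scores are relative within a cohort (rank-based, permutation-
  normalized); they are not comparable in absolute value across cohorts
  scored with different universes.
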