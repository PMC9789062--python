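# Methods

`polycross` analyzes gene expression in the seeds of reciprocal crosses
between wheats of different ploidy (e.g. hexaploid AABBDD × tetraploid AABB,
whose F1 embryos are pentaploid AABBD). Three questions drive the design:
how the A, B and D homoeologs of a triad share expression; which genes are
expressed in a parent-of-origin-specific way (imprinting); and which
transcript isoforms change their inclusion between cross directions
(differential splicing). Each analysis is implemented as a pure function
over validated tables, with a synthetic-data generator that plants known
truth so the whole pipeline can be benchmarked end to end.

## Triad expression-bias classification

For a triad with per-homoeolog TPMs $(t_A, t_B, t_D)$ in one sample, the
composition $f_i = t_i / \sum_j t_j$ is assigned to the bias category whose
reference composition (centroid) is nearest in Euclidean distance. The seven
centroids are balanced $(1/3,1/3,1/3)$, A/B/D dominant (the corresponding
unit vectors) and A/B/D suppressed (mass split equally over the other two
subgenomes). Choices:

- **Exact thirds.** The balanced centroid uses $1/3$, not the conventional
  rounded $0.33$ (which does not sum to 1). On the simplex the two differ by
  a distance < 0.006 and never change which category is nearest at the
  resolutions that matter, but exactness keeps the fixed-point property
  (each centroid classifies as itself) strict.
- **Expression floor.** A triad is *defined* in a sample only when its total
  TPM ≥ 0.5 (configurable `--floor`). Compositions of unexpressed triads are
  noise; they are excluded from category percentages and tallied separately
  in transition tables.
- **Tie-breaking.** Exact distance ties (measure-zero but reachable on exact
  inputs such as $(0.75, 0.25, 0)$, equidistant from A-dominant and
  D-suppressed) go to the earliest category in the canonical order
  (balanced, A/B/D dominant, A/B/D suppressed).
- **Replicates.** Compositions are computed per replicate and then averaged
  (and renormalized) across replicates of the same cross × stage before
  classification; a per-replicate mode (`--per-replicate`) classifies each
  replicate separately. Averaging compositions rather than TPMs keeps
  high-expression replicates from dominating.
- **Two-genome mode.** Tetraploid (A/B only) crosses use centroids balanced
  $(1/2,1/2)$, A dominant $(1,0)$, B dominant $(0,1)$.

Category transitions between two call sets (reciprocal crosses, or stages)
are counted over triads classified in both; a triad undefined in either set
contributes to an `undefined` row/column instead of being dropped silently.

## Imprinting (MEG/PEG) calling

Input is a table of per-gene maternal/paternal SNP-read counts per cross
direction, stage and replicate. For one stage/tissue of a reciprocal pair:

1. Replicates are pooled within each cross direction. Pooling is the
   simplest reading of requiring support from both replicates; a stricter
   mode (`require_each_replicate`) additionally demands that every
   individual replicate pass the ratio threshold.
2. Genes with fewer than 10 pooled reads in either direction are
   `insufficient_data`.
3. Each direction's (maternal, paternal) counts are tested by a Pearson
   χ² goodness-of-fit (1 df, no continuity correction by default) against
   the tissue dosage expectation: maternal fraction 0.5 in embryo,
   2/3 in endosperm (two maternal : one paternal genome copy).
4. p-values are BH-adjusted in one family over all (gene × direction) tests
   of the stage/tissue. A call requires **both** directions to pass
   FDR < 0.01; the reported per-gene `q` is the larger of the two.
5. MEG: both maternal fractions ≥ 0.7 (embryo) / 0.85 (endosperm).
   PEG: both paternal fractions ≥ 0.7 (embryo) / 0.6 (endosperm).
   The asymmetric endosperm bars reflect the 2:1 dosage: an unimprinted
   endosperm gene already shows ~67% maternal reads.

Requiring both directions to pass makes direction concordance implicit: a
maternally biased gene in one direction that is paternally biased in the
other can never satisfy both thresholds. Known caveat: the endosperm
expectation uses 2/3 for every gene, including D-subgenome genes of
pentaploid endosperm whose true dosage differs (AAABBBDD vs AAABBBD); this
mirrors the single 67% reference convention and slightly inflates the χ²
statistic for those genes.

## Isoform PSI and differential splicing

PSI of an isoform in a sample is its TPM share of the gene's total isoform
TPM; genes below 1 TPM total (configurable) have undefined PSI, excluded
(never zero-filled) from all downstream means and distribution comparisons.
Isoforms with 0.05 ≤ PSI ≤ 0.95 (inclusive) are flagged *alternative*.
ΔPSI between groups is the difference of group-mean PSIs.

Significance is empirical: within-group between-replicate |PSI differences|
estimate the ΔPSI magnitude expected under no differential splicing. These
null values are pooled across isoforms within gene-abundance bins (3
quantile bins of log10 mean gene TPM, since PSI estimates of weakly
expressed genes are noisier), and each isoform's p-value is the add-one
smoothed exceedance fraction of `n_null` = 1000 values resampled from its
bin's pool: $p = (1 + \#\{d_{null} \ge |\Delta|\}) / (n_{null} + 1)$. The
construction is conservative under the null (p stochastically ≥ uniform at
the smoothing resolution) and deterministic given a seed. It requires at
least two replicates per group. A DAS call needs |ΔPSI| **strictly** > 0.1
and BH-adjusted q < 0.05. Distribution-level shifts between groups are
tested with the two-sample Kolmogorov–Smirnov statistic on pooled defined
PSIs (asymptotic p-value; the pooled sets contain thousands of values, where
exact small-sample corrections are irrelevant).

## Synthetic data

The generator reproduces the experiment's structure: a reciprocal cross
pair, two biological replicates per sample, embryo (E1–E7) and endosperm
(E8–E9) stages. Defaults (all `SimulationConfig` fields):

| parameter | default | rationale |
|---|---|---|
| `n_triads` | 2000 | enough for stable category percentages, fast |
| `category_proportions` | balanced 0.5, D-suppressed 0.3, A-dominant 0.2 | pentaploid-embryo-like mixture |
| `triad_total_tpm_mean` | 300 TPM | typical expressed-triad total |
| `gamma_shape` | 2 | right-skewed expression levels (CV ≈ 0.7) |
| `nb_dispersion` | 0.05 | typical bulk RNA-seq overdispersion (var = μ + αμ²) |
| `library_size` | 1e8 | deep sequencing; sets the Poisson (shot-noise) floor |
| `n_replicates` | 2 | two biological replicates per sample |
| `n_genes_ase` / `ase_depth_mean` | 5000 / 100 | allele-informative genes and SNP-read depth |
| `frac_meg` = `frac_peg` | 0.01 | 50 MEGs + 50 PEGs planted |
| `imprint_strength` | 0.95 | maternal fraction of a planted MEG (paternal for PEG) |
| `n_isoform_genes` | 667 | 2–4 isoforms/gene ⇒ ≈ 2000 isoforms |
| `n_das_isoforms` / `delta_psi_planted` | 100 / 0.3 | planted differential splicing |
| `psi_noise_sigma` | 0.15 | lognormal multiplicative TPM noise |
| `splicing_gene_tpm_mean` | 50 TPM | keeps most genes above the PSI floor |

Triad counts are drawn as negative binomial around
`total × centroid × library_size/ΣTPM`, then column-normalized back to TPM;
drawing in count space makes shot noise shrink with depth so the
dispersion → 0 limit is genuinely noise-free. Allele counts are
Binomial(total ~ Poisson(depth), p) with p the dosage expectation for
unimprinted genes and the imprint strength for planted MEGs/PEGs — defined
relative to the maternal allele, hence consistent across both cross
directions. Isoform PSIs start from a symmetric Dirichlet(1.5); a planted
shift moves the gene's least-included isoform up by `delta_psi_planted`
(renormalizing the rest; shifts that would exceed 1 are clipped with a
warning and the realized shift recorded in the truth labels).

One seed drives everything; each generator uses an independent child stream
(fixed offsets 1–3 of a `SeedSequence`), so changing one simulation's size
never perturbs another's draws.

**What the generator does not emulate:** developmental-stage trajectories
(stages are exchangeable), between-gene correlation, mapping/SNP-calling
artifacts in allele assignment, positional/coverage bias in isoform
quantification, and triads whose members respond differently to ploidy.
Recovery rates measured on these simulations therefore demonstrate
correctness of the statistical machinery under its own assumptions, not
expected sensitivity on real tissue.

## Numerical choices and degenerate inputs

- All-zero count vectors give all-zero TPM (documented, not an error);
  a zero-expression triad is undefined rather than erroneous.
- χ² requires total ≥ 1 read and an expected fraction strictly inside
  (0, 1); the ≥ 10-read filter is the caller's responsibility.
- BH adjustment validates p ∈ [0, 1] and unique test ids.
- Compositions must sum to 1 within 1e-6; per-gene defined PSIs sum to 1
  within 1e-6 by construction.
- Table round trips preserve values to 1e-9 (TSV, full float precision).

## Problem sizes

Tests and the acceptance script run the simulations at their default sizes
(2,000 triads, 5,000 allele-informative genes, ≈ 2,000 isoforms with
n_null = 1000), chosen so the full benchmark completes in seconds while
keeping Monte-Carlo error on recovery rates near or below one percentage
point.

## Known limitations

- The empirical splicing null is a desk-scale realization of the
  replicate-noise idea, not a reimplementation of any specific tool's
  windowing rules; its binning (3 bins) and `n_null` are configurable.
- The imprinting FDR family is per stage × tissue; pooling across stages
  would change q-values (the appropriate family depends on how many stages
  are screened).
- KS p-values are asymptotic; do not use them on fewer than ~20 PSI values
  per group.
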