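# Methods

## The placement model

`lode` treats SNP placement as an evidence problem over pairwise linkage
disequilibrium. For a query SNP and a panel of map-anchored SNPs, every
query–anchor pair yields an r² estimate; the per-chromosome summaries
`r²_max` and `n_0.1` feed a deliberately conservative decision rule (two
independent rankings must agree, thin evidence is excluded, low-MAF calls
face an extra runner-up check). The output position is always an existing
anchor's position: the method orders loci relative to a map, it does not
interpolate new coordinates. Its resolution is therefore bounded by local
anchor spacing and by the distance over which LD decays in the study
population.

Assumptions worth stating explicitly:

* individuals are treated as unrelated members of one population; strong
  family structure inflates long-range LD and will loosen placement.
  r² estimates are considered reliable only from ~75 individuals upward,
  and the library warns below that size.
* genotypes are unphased diploid dosages in {0, 1, 2}; phase is never
  required. X-chromosome loci are assumed to come from an all-male
  (hemizygous) cohort: heterozygous calls there are set to missing and the
  remaining calls treated as ordinary homozygotes.
* coordinates are 1-based bp; intervals closed.

## Haplotype-frequency EM and r²

For one pair of loci the data are a 3×3 genotype table. Under
random union of gametes the likelihood depends on the four haplotype
frequencies, of which — given that the observed allele frequencies are the
ML marginals — only `p_AB` is free. All cells are phase-known except the
double heterozygote, which splits between coupling (AB/ab) and repulsion
(Ab/aB) with posterior weight `w = p_AB·p_ab / (p_AB·p_ab + p_Ab·p_aB)`;
the M-step is `p_AB ← (known AB count + w·n₁₁) / 2n`.

The one-dimensional likelihood can have up to three stationary points, so
a single EM run can land on a minor mode. EM is therefore run from three
deterministic starts — the linkage-equilibrium product and points just
inside both ends of the feasible interval
`[max(0, p_A+p_B−1), min(p_A, p_B)]` — and the fixed point with the
highest log-likelihood is kept. This retains bit-reproducibility (no
random restarts) while matching an exhaustive grid search in every test.
Convergence: |Δp_AB| < 1e-8, at most 1000 iterations. The rare
non-converged pair falls back to the squared Pearson correlation of
dosage vectors and is flagged. Monomorphic pairs (in the shared-called
subset) are skipped, not fatal. r² is clipped to [0, 1] against
floating-point overshoot.

Significance uses the large-sample allelic-association statistic
χ² = n·r² on 1 df; "n observations" counts individuals with both calls
present (the conservative of the two possible conventions — counting
chromosomes would double it at the threshold).

## Decision-rule parameters

| parameter | default | meaning |
|---|---|---|
| `alpha` | 0.01 | significance level of the pair quality filter |
| `min_obs` | 100 | minimum shared-called individuals per pair |
| `r2_window` | 0.1 | r² threshold (strict >) defining `n_0.1` |
| `n01_floor` | 3 | chromosomes with fewer supporting anchors are dropped from the `n_0.1` ranking |
| `second_chrom_frac` | 2/3 | runner-up `r²_max` fraction that vetoes a low-MAF call (strict >, reading "exceed" literally) |
| `maf_floor` | 0.01 | queries at or below this MAF are not placed |
| `maf_safeguard` | 0.05 | MAF band (≤) in which the runner-up veto applies |

Design choices where the rule is genuinely open:

* the `n_0.1 < 3` exclusion applies to the `n_0.1` ranking only; a
  chromosome below the floor still competes in the `r²_max` ranking, so a
  spuriously strong single anchor produces a rank conflict (SNP left
  unplaced) rather than an assignment — conservative by construction.
* the runner-up in the 2/3 veto is the best `r²_max` among *all* other
  chromosomes with any quality-passing estimate, with no `n_0.1` exclusion:
  the veto is about the existence of competing LD, not about its breadth.
* exact ties (two chromosomes sharing top `r²_max` or top `n_0.1`) yield
  `unassigned(tie)`; ties essentially only arise in degenerate inputs.
  Two anchors tying for `r²_max` on the winning chromosome resolve to the
  smaller bp, keeping output deterministic.
* raising `min_obs` or lowering `alpha` can only shrink the
  quality-passing set, so efficiency is monotone in both (tested).

## The synthetic panel generator

The generator emulates the one property the method feeds on —
distance-decaying LD — with a two-layer haplotype-copying model:

1. per chromosome, a pool of `n_founder_haplotypes` (default 100) founder
   haplotypes whose alleles come from a latent Gaussian AR(1) copula:
   target allele frequencies are drawn from a three-class MAF spectrum
   (common (0.05, 0.5], low (0.01, 0.05], rare (0.001, 0.01]; default
   weights 0.75/0.15/0.10) and the latent correlation decays as
   `exp(−d / founder_corr_length_bp)` (default 1.5 Mb), standing in for
   ancestral recombination;
2. each gamete copies founder templates, switching to a uniformly chosen
   template at breakpoints (Poisson, `recomb_rate_per_bp`, default 1e-8),
   adding decay on top. Diploids are two independent gametes; an optional
   all-male X uses one gamete doubled.

The founder-level correlation exists because template switching alone
cannot deliver both strong local LD and a fine-grained MAF spectrum: with
independent founder alleles the background r² of nearby loci is ~1/K for a
pool of K founders, and a pool large enough to express MAF ≈ 0.01 (K ≥
100) would cap local r² near 0.01. The copula decouples the two: pool size
controls frequency resolution, the correlation length controls LD decay.

Default scale is 5 chromosomes × 400 SNPs × 300 diploids over 25 Mb per
chromosome (~62 kb marker spacing), with 2% missing calls, 8% of SNPs
emitted without map data, and a third of those grouped into scaffolds
(contiguous runs of 1–5 SNPs, random orientation). These sizes keep a full
every-10th audit of the default panel to about a minute while leaving
several hundred SNPs per MAF class for stable rates; the `seed` fully
determines every output byte.

What the generator does *not* model — and what passing tests therefore do
not establish about real data: demographic structure and relatedness,
genotyping batch effects, assembly-correlated error (real "unpositioned"
SNPs are enriched for repeats and segmental duplications), and realistic
chromosome counts/lengths. The audit numbers on synthetic panels
characterise the implementation, not any particular genome project.
Constructed fixtures are explicitly synthetic: the perfect-proxy panel
(every SNP duplicated in four identical copies, which forces an exactly
perfect audit), the cross-chromosome duplicated segment (confounder for
the 2/3 safeguard) and the relabelled translocation block (discordant-
block detection).

## Audit conventions

* "every 10th" masking is taken in bp order within chromosome — the only
  order defined for mapped SNPs; the k batches partition the panel, so
  every mapped SNP is tested exactly once per audit.
* precision is the mean ± standard error (not SD) of |known − assigned|
  in kb over same-chromosome assignments only.
* discordant blocks: maximal runs of ≥ `min_run` (default 3, matching the
  3–6-SNP runs such scans flag in practice) bp-consecutive tested SNPs
  reassigned to one common other chromosome; concordant *and* unassigned
  SNPs both break a run.
* the Oxford grid labels an X chromosome "30" in figures, after the bovine
  plotting convention.

## Numerical and degenerate-input notes

* MAF and call counts are always recomputed from the dosage matrix at load
  time; input metadata is not trusted.
* an all-missing column has undefined MAF and is an error at the MAF
  level; monomorphic columns are fine (MAF 0) and simply unplaceable.
* PLINK ped files carry no canonical dosage orientation, so monomorphic
  columns cannot round-trip exactly (the reader counts the
  alphabetically-first observed allele and reads single-allele columns as
  dosage 0). The dosage-TSV format round-trips exactly; every downstream
  statistic is invariant to the allele-label swap.
* scaffold placement uses the median of members' assigned positions as the
  scaffold's point estimate (robust to a single bad anchor) and Spearman
  rank correlation for orientation (robust to the anchor-granularity of
  assigned positions).

## Known limitations

* placement precision cannot beat anchor spacing; on sparse maps the
  reported positions are correspondingly coarse.
* the procedure is blind to intra-chromosomal misplacement of a query's
  best anchor: it validates chromosome-level structure far better than
  fine ordering.
* rare SNPs (MAF ≤ 0.01) are excluded by default for good reason — their
  LD signal is weak and placements unreliable; the floor can be lowered
  but a warning is emitted.
* batches are assigned independently; no joint/multipoint placement of
  several queries, and no splitting of conflicting scaffolds into
  separately placed segments.
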