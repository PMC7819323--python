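# Methods

## The problem being modeled

Amplicon sequencing profiles all amplifiable 16S rRNA gene copies in a
sample, whether they come from viable cells or from relic DNA (dead
cells, free DNA). PMA-seq attempts to restrict the profile to viable
organisms: propidium monoazide enters membrane-compromised cells,
photoactivation crosslinks it to the DNA, and that DNA no longer
amplifies. The package models the whole measurement chain — community →
PMA action → amplicon library + qPCR total — so that the analysis
statistics can be validated against known ground truth.

## Generative model

A community is a list of `(taxon, live/dead, cell fraction)` components
with per-taxon 16S copy numbers and an absolute cell total
(`CommunityDesign`).

**PMA action** is per-component binomial thinning. A dead cell's DNA is
removed with probability `p_dead_removed[taxon] × matrix_attenuation`, a
live cell's with `p_live_removed[taxon]`. The attenuation factor (default
1.0, i.e. none) stands in for matrix effects — soil particles and host
DNA competitively binding the dye — for which no quantitative literature
values exist; it is a free parameter deliberately left at identity.
Component cell counts are rounded to integers before thinning, so
deterministic limits (p = 0 or 1) are exact. If nothing survives, the
design becomes empty (`total_cells = 0`), which downstream produces a
below-detection qPCR entry and a library filled purely by contamination.

**Sequencing** draws a fixed `depth` of reads multinomially with taxon
weights ∝ cell mass × 16S copy number. Copy-number weighting is always
applied on the stochastic path; the *deterministic expectation* path
defaults to plain cell fractions (see below). Each read is independently
replaced by a draw from a contaminant pool with probability
`contamination_rate` — a per-read bleed-through model chosen because a
single parameter reproduces the salient behavior of near-empty
libraries: an all-dead community under effective PMA yields a library
composed entirely of contaminant reads. Default depth is 50,000 reads,
matching the order of a typical MiSeq 16S run (median ≈ 48k).

**qPCR** reports `log10(Σ mass × copy_number)` plus Gaussian noise on
the log scale (`qpcr_sigma_log10`, default 0 in unit tests, 0.1 in
simulation scenarios — roughly the replicate scatter of a SYBR assay).
Zero-copy samples are flagged below detection rather than carrying −∞.

**Backgrounds** for spike-in scenarios are Fisher log-series
compositions (`logser(θ)`, default θ = 0.995), the classic
species-abundance model for environmental communities, with a global
live fraction (default 0.8) split per taxon and integer copy numbers
drawn uniformly from 1–10. Presets follow the two biomass regimes of the
bench design: low-biomass surface-like backgrounds (50 taxa, 10³ cells,
paired with ~500 spike cells) and high-biomass soil/saliva-like
backgrounds (500 taxa, 10⁷ cells, paired with 10⁶ spike cells). These
emulate richness and biomass only; they make no claim about which real
taxa are present.

All stochastic operations accept either an integer seed or a shared
`numpy.random.Generator`; a fixed seed reproduces every table bit-exactly.

## Deterministic expectations

`expected_post_pma` computes the ideal-treatment limit: all dead
removed, all live kept, live fractions renormalized. The default is
cell-fraction arithmetic, because the declared expectations for the
two-strain mixtures (67%/33% etc.) are cell-based; `copy_weighted=True`
gives the amplicon-eye view (weights × copy number), which for the mixed
groups yields 77.8%/22.2% with the default copy numbers 7 (*E. coli*)
and 4 (*S. sanguinis*) — literature operon counts, used only where copy
weighting is explicitly requested. The expected signal reduction of the
half-dead mixed groups is reported both ways (0.25 cell-based; 0.18
copy-weighted for the 50/25/25 design) since the measurement basis of a
"~30%" DNA-yield reduction is ambiguous; neither value is privileged.

## The efficacy statistic

`efficacy = 1 − (D − B)/(C − A)` over the four arms of the spike-in
factorial, with each arm's signal = mean(reference relative abundance)
× mean(log₁₀ 16S copies) — means of the two factors over the arm's
replicates, not means of per-sample products. The reference is matched
by case-insensitive substring against lineage strings (default
`Enterobacteriaceae`, aggregating the whole family), summing all
matching taxa per sample.

If background signal is unchanged across arms and the spike is split 1:1
live:dead with removal probabilities p_d (dead) and p_l (live), the
expected statistic is (p_d + p_l)/2: the surviving spike share is
½(1−p_d) + ½(1−p_l), and one minus it is the removed share. The log₁₀
copy factor makes the signal only approximately proportional to absolute
reference amount; the approximation is good when the background dominates
total biomass (the log factor is then nearly constant across arms), which
is the regime of the high-biomass spike design. Simulation at a 10⁷-cell
background with a 10⁶-cell spike, depth 10⁵ and 4 replicates/arm recovers
(p_d + p_l)/2 within ±0.05 across the incomplete (0.35), ideal (0.5) and
fully toxic (1.0) regimes; these problem sizes are what the recovery test
and the README example use. A `copies_scale="linear"` option multiplies
by mean 10^copies instead — physically cleaner, but non-default because
the log-scale product is the established form of the statistic.

Classification uses a ±0.05 band around 0.5 for "ideal"; the value
itself is never clamped (toxicity can push it above 1). `C ≤ A` — spike
not detected above background — raises an explicit error from
`pma_efficacy` and is reported as `undefined` per type by
`efficacy_by_type`.

## Differential response

Per taxon and sample type, arm abundances are arithmetic means of
relative abundances over all of the type's samples in the PMA-free and
PMA-treated arms. The normalized change is `(free − pma)/max(free,
floor)`; the fold ratio is `max(free, floor)/max(pma, floor)` or its
reciprocal, whichever ≥ 1. The floor (default 10⁻⁶) sits one order of
magnitude below the smallest relative abundance resolvable at typical
depths (~10⁻⁵), so "appears from undetectable to 10⁻⁵" maps to change
−10 and ratio 10 rather than a division by zero; censoring flags
(`undetectable_before/after`) preserve the semantics. The >100-fold
highlight uses a strict inequality on the floored ratio.

Rankings average |change| per taxon over the sample types where the
taxon is detected in at least one arm (averaging over detected types,
not all types — the alternative would penalize taxa absent from some
environments). Only taxa scored in ≥ `min_types` (default 2) types are
eligible; responsive = top-n descending, resilient = top-n ascending
drawn from the remainder so the lists cannot overlap; ties break
lexicographically, making reruns deterministic.

Note an intrinsic compositional caveat: relative-abundance change
reflects a taxon's viability *relative to the community's overall
survival*. A fully live taxon in a community where much else dies shows
a large positive shift; the ranking therefore recovers true viability
ordering only when overall survival is high or comparable across taxa.
The ranking test constructs its communities accordingly (a dominant live
matrix taxon), and users should interpret field rankings with the same
caution.

## Compositional statistics

* **Genus collapsing** merges OTUs by genus; genus-unassigned OTUs are
  summed at their terminal assigned rank and keep a Greengenes-style
  rank prefix (`f__`, `o__`, …). Per-sample totals are conserved
  exactly.
* **Filtering** keeps taxa strictly above 0.01% relative abundance in at
  least `ceil(0.10 × n_samples)` samples ("at least 10%" read
  inclusively, the abundance bound strictly). Counts are converted
  per-sample before testing. Filtered tables are *not* renormalized by
  default — whether renormalization preceded downstream distances is
  genuinely ambiguous in common practice, so a flag is provided and the
  conservative default keeps raw fractions (Bray–Curtis is computed on
  the retained mass either way).
* **Bray–Curtis** `1 − 2Σmin/(Σx+Σy)` via `scipy.spatial.distance`; the
  undefined empty-vs-empty pair is set to 0 with a warning (two "no
  signal" samples are operationally identical).
* **PCoA** is classical scaling implemented directly (double-center
  −½D², `eigh`, scale by √λ): the implementation is a few lines and
  gives explicit control over the treatment of negative eigenvalues
  (excluded from axes and from the proportion-explained denominator).
  It is cross-checked against scikit-bio's `pcoa` in the tests, and
  round-trips Euclidean distance matrices to 1e-9.
* **PERMANOVA** is likewise implemented from its sums-of-squares
  definition (SS over squared distances, pseudo-F with (a−1, n−a)
  degrees of freedom) because the result object needs R² =
  SS_between/SS_total, bit-reproducible seeded permutation p-values of
  the form (1 + #{F_perm ≥ F_obs})/(1 + n_permutations), and an
  exact-enumeration mode for small designs (all distinct label
  assignments; used as its own oracle check at n = 6). The pseudo-F is
  cross-checked against scikit-bio's `permanova`. Multiple metadata
  factors are tested marginally (one-way per factor) with
  Benjamini–Hochberg adjustment across factors; sequential partitioning
  is not attempted since factor order would be arbitrary.

The default permutation count is 9999; the test suite uses 99–999 to
keep runtimes in seconds.

## Degenerate inputs and numerical choices

Relative-mode tables require rows to sum to ≤ 1 (within 1e-9): exactly 1
for full profiles, less after non-renormalized filtering, 0 for
"no signal" samples (kept as zeros, never NaN). Mixture fraction sums
are validated to 1e-9 and snapped exactly after renormalization to
avoid float drift compounding through pipelines. TSV round-trips are
bit-exact for counts and `repr`-exact for floats. BIOM 1.0 JSON tables
are read (dense or sparse) with the standard library JSON parser.

## What the simulator does not capture

No PCR/primer bias, chimeras or sequencing error; no read-level FASTQ;
no DNA degradation during heat killing; contamination is per-read, not
batch-structured; backgrounds are log-series caricatures of real
communities. Passing tests therefore demonstrate that the *statistics*
behave as designed under their stated assumptions — not that PMA-seq is
quantitatively accurate on real samples, where matrix effects,
amplification bias and taxon-specific membrane properties add exactly
the distortions the efficacy statistic is designed to expose.
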