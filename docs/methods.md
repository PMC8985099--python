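# Methods

This note documents the models, assumptions, parameter choices and known
limitations of the `ssp_ams` pipeline.  It states no empirical result that
the test suite or `scripts/acceptance.py` does not itself compute.

## Consensus SSP calling

A small secreted protein (SSP) is operationally defined as a complete ORF
of 50–250 amino acids (both bounds inclusive; the range is stated as a
closed interval and the boundary behaviour is pinned by tests) predicted to
be secreted by either of two routes:

* **conventional** — N-terminal signal sequence (NSS) supported by at least
  2 of 3 NSS tools *and* no transmembrane helix predicted by *any* of 3 TM
  tools.  The any-tool veto reflects that membrane proteins frequently
  carry signal sequences: a single TM call is treated as sufficient
  evidence against secretion via this route.
* **unconventional** — extracellular localization supported by at least 2
  of 3 localization tools.  By default the TM veto does **not** apply here
  (the veto belongs to the NSS branch of the decision flow); a
  `tm_vetoes_extracellular` flag makes the caller stricter.

The nine votes are treated as independent inputs even though in practice
one tool (a Phobius-like predictor) can feed both the NSS and TM panels; no
de-duplication rule is applied.  Tunables live in `CallerThresholds`
(`min_len=50`, `max_len=250`, `nss_min_votes=2`, `tm_exclusion_votes=1`,
`extra_min_votes=2`).

The three-set partition (NSS-only / Extracellular-only /
NSS-and-extracellular) is a disjoint cover of the SSP union; the report
writer asserts `|union| = |list1| + |list2| − |intersection|` on every run.

## Ortholog-group association with AMS

Let `n_AMS` be the number of AMS-capable species in the metadata.

* **AMS-specific**: members (SSP or not) from at least
  `ceil(0.30 · n_AMS)` distinct AMS species, zero members from non-AMS
  species, and at least one SSP member.  The ceiling is used because "at
  least 30% of species" bounds an integer count from below (39 AMS species
  → 12).  A `span_on_ssp_members` flag restricts the span count to SSP
  members for users who prefer the stricter reading.
* **AMS-preferential**: testable only for groups whose SSPs come from both
  host classes.  Per-species SSP counts are assembled over *all* species
  (zeros for species absent from the group — otherwise a group with a
  single non-AMS member would be untestable; `include_absent_species=False`
  switches to present-species-only) and compared with a one-sided Wilcoxon
  rank-sum test (AMS > non-AMS), preferential iff p ≤ 0.05.  P-values are
  reported raw; a Benjamini–Hochberg option is deliberately not applied by
  default because the preferentiality decision is defined on the raw
  threshold.
* **Genome level**: per-species SSP count and SSP ratio
  (count / `n_proteins_annotated`) are compared two-sided between host
  classes, overall and per lineage stratum; strata with fewer than two
  species on either side are reported as skipped rather than tested.

The one-sided choice for preferentiality ("more SSPs in AMS species") and
the two-sided choice for genome-level comparisons ("a difference in either
direction") mirror the scientific claims each test supports.

**Rank-sum implementation.**  `wilcoxon_rank_sum` delegates to
`scipy.stats.mannwhitneyu`: exact enumeration when both samples have ≤ 10
observations and no ties, otherwise the normal approximation with tie and
continuity corrections.  Tests validate the exact branch against a
complete-enumeration oracle for every size pair up to 8, and the asymptotic
branch against enumeration at sizes just beyond the exact cutoff (observed
agreement within 0.02 there; at very small sizes, e.g. 4 vs 4, the normal
approximation can err by ~0.03 mid-distribution, which is why the exact
branch exists).

## Differential expression and convergence

The built-in engine is intentionally simple and transparent:

1. **Normalization**: DESeq-style median-of-ratios size factors (median
   over everywhere-expressed genes of count / geometric row mean).  Plain
   total-count scaling is available (`normalization="libsize"`) but is not
   the default: with strongly asymmetric regulation the regulated genes
   inflate treatment library totals, total-count scaling then shifts every
   null gene in the opposite direction, and spurious "convergent"
   down-regulated groups appear.  This failure was observed directly on
   synthetic data with planted log2FC = 5 up-regulation.
2. **Effect size**: `log2FC = log2((mean_trt + 1)/(mean_ctl + 1))` on
   normalized counts (pseudocount 1).
3. **Inference**: Welch's t-test per gene on `log2(normalized + 1)`,
   Benjamini–Hochberg adjustment (statsmodels step-up).
4. **Calls**: `up` iff log2FC > 1 (strict) and padj ≤ 0.05 (inclusive);
   `down` symmetric; otherwise `ns`.  All-zero genes get padj = 1.

This engine substitutes for a dedicated count-model package; it is not an
empirical-Bayes method and has lower power at 2–3 replicates.  Any
externally produced DE table with the documented columns can be supplied
instead, which isolates the substitution from the downstream convergence
logic.

**Convergence**: per ortholog group and direction, the set of species with
≥ 1 significant DE SSP member of that direction; a result is emitted when
that set has ≥ 2 species (`min_species` configurable).  Contrasts are kept
separate per species; a group may converge in both directions.  The
displayed per-species effect is the mean log2FC of that group's DE SSP
members in that species (an aggregation choice; the underlying records are
all retained in `de.tsv`).

## Co-expression and SSP ranks

Pearson correlation with the exact two-sided p from
`t = r · sqrt((n−2)/(1−r²))`, vectorized through the equivalent beta-tail
form (numerically stable as |r| → 1 and identical to `scipy.stats.pearsonr`).
Edges require |r| ≥ 0.95 and p ≤ 0.05, both raw (a BH option exists for the
p-values but the operating definition is the raw threshold).  Computation
is seed-vs-all by default — the intended use is a few hundred SSP seeds
against a genome-wide atlas, where all-vs-all is a quadratic waste —
with `all_vs_all=True` available.  Constant-expression genes cannot be
correlated and never form edges; atlases with fewer than 3 samples are
rejected because the p-value is undefined.  The atlas is used as given,
with an optional `log2(x+1)` transform flag in the CLI.

Ranks summarize evidence tiers: **rank1** = SSPs in groups that are both
AMS-preferential and convergent; **rank2** = SSPs in the union of
AMS-specific, AMS-preferential and convergent groups, minus rank1 (the
union is read inclusively).  rank1 ∩ rank2 = ∅ by construction and both are
subsets of the SSP set.

## Synthetic data: what it emulates, and what it does not

The generator reproduces the *statistical shape* of a 60-genome, 5-contrast
comparative study at roughly 60-fold reduced proteome scale, with every
planted structure recorded in a ground-truth object.

Stated-world defaults (one seeded generator; per-stage substreams with
fixed offsets so each stage is reproducible in isolation):

| parameter | default | rationale |
|---|---|---|
| `n_species`, `frac_ams` | 60, 0.65 | 39 AMS / 21 non-AMS split of the emulated study |
| lineage mix | 33/15/12 per 60 | dicot / monocot / other proportions |
| `proteins_per_species` | 400–600 | ~60× scale-down of ~32k-protein proteomes |
| `frac_true_ssp` | 0.08 | above the study-wide ~3% so each species carries enough true SSPs to fill planted groups at this scale (a feasibility choice made once) |
| length model | log-normal, median 130 aa, truncated to [20, 600] | exercises the 50–250 gate on both sides (~12% fall outside) |
| `tool_sensitivity` / `tool_specificity` | 0.90 / 0.95 | stipulated: per-tool agreement rates are not published, only that disagreement is substantial |
| `n_orthogroups` | 1000 | preserves the ~31 proteins-per-group density |
| `n_planted_specific` / `n_planted_preferential` | 3 / 3 | the counts reported by the emulated study |
| `preferential_effect` | 5 | mean extra SSPs per AMS species in preferential groups |
| `n_de_species`, control | 4 + 1 | four AMS contrast species plus one non-AMS control (which receives background DE genes but no DE SSPs) |
| `n_replicates`, `de_log2fc`, `nb_dispersion` | 3, 3.0, 0.1 | typical RNA-seq design; NB2 counts |
| convergent planting | 3 up / 3 down | 27/34 of the study scaled by the ~60× group scale-down |
| `n_atlas_samples`, `planted_module_size`, `module_pcc` | 20, 5, 0.98 | modules share a latent factor: profile = √ρ·f + √(1−ρ)·ε, so pairwise correlation expectation is ρ |

Latent protein statuses are conventional-secreted, unconventional-secreted,
membrane (15%), or other; each tool class fires with its sensitivity on its
relevant statuses and with 1 − specificity elsewhere.  Membrane proteins
are NSS-relevant (they carry signal sequences) so the TM veto is exercised
even with perfect tools.  TM errors are drawn independently of NSS errors
even for the shared-tool case — a simplification that ignores the
correlation a real shared predictor would induce.

Planted AMS-specific groups force-include the contrast species in their
AMS span so convergent-DE planting always has an eligible pool; extra
per-species DE SSPs are planted only in groups that cannot produce
accidental cross-species same-direction convergence.  Background SSPs are
scattered sparsely (~1.6 per background group), which keeps chance
preferentiality below the radar of the rank-sum test — as in the real data,
where per-group per-species SSP counts are small and tie-heavy.

**Not emulated**: sequence-level realism (FASTA output is random residues
— no signal-peptide motifs, annotated as synthetic), correlated tool
errors, genome-level AMS vs non-AMS differences in SSP content (the
generator gives every species the same SSP rate, so the genome-level tests
are expected to be null on synthetic data), multiple time points per
contrast, and orthology inference errors.  A green planted-recovery test
therefore establishes that the *pipeline logic* recovers known structure —
not that the biological effect sizes of any real study are re-derivable.

**Strong-effect configuration** (`strong_effect_config()`): perfect tools,
log2FC = 5, five replicates, module ρ = 0.995.  Under these settings every
planted structure is identifiable, and end-to-end recovery at
precision = recall = 1 is asserted by the acceptance tests.  At the default
noisy settings, recovery is intentionally imperfect (tool noise bounds
SSP-call precision; 3-replicate Welch tests can miss planted DE), and the
run report quantifies it.

## Numerical and degenerate-input choices

* Thresholds on p-values are inclusive (≤ 0.05); the fold-change threshold
  is strict (> 1).  Both boundaries are unit-tested.
* Welch t-tests returning NaN (zero variance in both groups) are treated
  as no evidence (p = 1).
* Correlations are clipped to [−1, 1] before the p transform; edge lists
  are canonically ordered (gene_a < gene_b) and sorted, so networks are a
  deterministic function of matrix and thresholds.
* Identical rank-sum samples give p = 1; empty samples raise.
* All writers sort rows by id and serialize JSON with sorted keys, so
  reruns with the same seed are byte-identical.
* Seeds: `numpy.random.default_rng([seed, stage_offset])`; the CLI `--seed`
  flows to every stage.

## Known limitations

* The DE engine is a transparency-first substitute, under-powered relative
  to count-model packages at few replicates; import external DE tables for
  real analyses.
* Preferentiality p-values are raw across hundreds of groups by
  definition of the decision rule; users scanning many groups should
  consider the provided BH option.
* The completeness heuristic for FASTA input (starts with Met, no internal
  stop) is a fallback when no annotation flag is available.
* Raw tool-output converters (SignalP 5 short, TMHMM short, Phobius short)
  are best-effort; the unified prediction TSV is the contract.
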