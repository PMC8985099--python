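# ssp-ams

Comparative analysis of plant **small secreted proteins (SSPs)** in relation
to **arbuscular mycorrhizal symbiosis (AMS)** — consensus secretome calling,
ortholog-group association testing, cross-species AMF-responsive expression
convergence, and co-expression subnetwork extraction, exercisable end to end
on synthetic data with known ground truth.

Arbuscular mycorrhizal fungi (AMF, e.g. *Rhizophagus irregularis*) form
nutrient-exchanging root symbioses with most land plants, and small secreted
proteins are prime candidates for the molecular dialogue that establishes
them. Given per-species secretion-tool predictions, OrthoFinder-style
ortholog groups, AMS host status per species, AMF-vs-control expression
contrasts and an expression atlas, this package asks: which ortholog groups
of SSPs track the ability to form the symbiosis, and do they respond to the
fungus convergently across independent plant lineages?  It is written for
comparative genomicists who already have tool outputs and orthology tables
in hand — the external predictors, aligners and orthology inference are
never run here.

## The method

**Consensus SSP calling (majority decision).**  A protein is a candidate
when it is a complete ORF of 50–250 aa (closed bounds).  Nine binary tool
votes in three classes decide the rest. With N-terminal signal sequence
(NSS) votes `s_1..s_3`, transmembrane votes `t_1..t_3` and extracellular
localization votes `e_1..e_3`:

```
list1 (conventional route):   Σ s_i ≥ 2  and  Σ t_i = 0
list2 (unconventional route): Σ e_i ≥ 2
SSP set = list1 ∪ list2,  partitioned into
  NSS-only, Extracellular-only, NSS-and-extracellular (= list1 ∩ list2)
```

A single transmembrane prediction by any tool vetoes the conventional route
(membrane proteins often carry signal sequences); by default it does not
veto the extracellular route.

**Ortholog-group association.**  With `n_AMS` AMS species, a group is
*AMS-specific* when it has members from ≥ `ceil(0.30 · n_AMS)` distinct AMS
species, no members from any non-AMS species, and ≥ 1 SSP.  A group whose
SSPs come from both host classes is *AMS-preferential* when the per-species
SSP counts (zeros included for absent species) are higher in AMS species by
a one-sided Wilcoxon rank-sum test at P ≤ 0.05.  Genome-level comparisons
contrast per-species SSP counts and SSP ratios (count / proteome size)
between host classes, two-sided, overall and per lineage.

**Expression convergence.**  A gene is differentially expressed when
|log2FC| > 1 (strict) and BH-adjusted p ≤ 0.05.  The built-in engine uses
median-of-ratios normalization, Welch's t-test on log2(normalized + 1) and
BH correction; externally produced DE tables are accepted interchangeably.
An ortholog group is *convergent* in a direction when ≥ 2 species each
contribute ≥ 1 DE SSP member with that direction.

**Co-expression.**  Edges connect genes with |Pearson r| ≥ 0.95 at
two-sided p ≤ 0.05 (t transform of r), seed-vs-all around SSP seeds.
SSP *rank1* = SSPs in groups that are AMS-preferential **and** convergent;
*rank2* = SSPs in the union of AMS-specific, AMS-preferential and
convergent groups, minus rank1.

## Worked example

Run the whole pipeline on a synthetic 60-species world (39 AMS / 21
non-AMS, ~31k proteins, 1000 ortholog groups, four AMS RNA-seq contrasts
plus one non-AMS control, one atlas species):

```sh
$ ssp-ams run-all --seed 1 --out demo
report written to demo/report.json
SSP union 2293 = list1 1090 + list2 2137 - intersection 934
```

The consensus caller found 2293 non-redundant SSPs: 1090 via the
signal-sequence route, 2137 via the extracellular route, 934 by both (the
union identity is checked by the report writer).  `demo/report.json` then
records, among others:

```
"classify_groups": { "by_ssp_source": { "AMS_ONLY": 235, "NONAMS_ONLY": 274,
                                        "BOTH": 260, "NO_SSP": 231 },
                     "n_ams_specific": 3, "n_ams_preferential": 3 }
"converge":        { "n_up_groups": 3, "n_down_groups": 0 }
"coexpress":       { "n_seeds": 41, "n_edges": 8, "n_rank1": 744, "n_rank2": 50 }
```

Of the 769 SSP-containing groups, 235 draw their SSPs from AMS species
only, 274 from non-AMS only and 260 from both; exactly the three planted
AMS-specific and three planted AMS-preferential groups are flagged, and
three groups show convergent up-regulation under AMF treatment (at these
default, noisy-tool settings one planted convergent group per direction can
fall below DE power — the `recovery` block of the report quantifies this
against the generated ground truth).  Stage artifacts (`calls.tsv`,
`groups.tsv`, `de.tsv`, `convergence.tsv`, `edges.tsv`/`edges.sif`,
`ranks.tsv`, `genome_tests.json`) are plain TSV/JSON so any stage can be
re-run or replaced independently; each stage also has its own subcommand
(`simulate`, `call`, `classify-groups`, `de`, `converge`, `coexpress`).

## File dialects

* **Unified predictions** (`predictions.tsv`): columns `protein_id,
  species_id, length_aa, complete_orf, nss_signalp, nss_phobius,
  nss_targetp, tm_tmhmm, tm_memsat, tm_phobius, loc_apoplastp, loc_deeploc,
  loc_msubp`; booleans strictly `0`/`1`.
* **Orthogroups** (`Orthogroups.tsv`): OrthoFinder dialect — first column
  group id, one column per species, cells are comma-space-separated gene
  lists, empty cell = no members.
* **Species metadata**: `species_id, ams_status (AMS|non-AMS),
  lineage (dicot|monocot|other), n_proteins_annotated`.
* **DE tables**: `gene_id, species_id, contrast_id, log2fc, padj,
  direction (up|down|ns)`.
* **Count/atlas matrices**: genes × samples TSV, first column gene id.

Readers are strict (malformed booleans, missing columns, NaNs and duplicate
ids raise); writers emit sorted, deterministic output.

## Acceptance script

```sh
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

re-runs the complete default-configuration pipeline from scratch with the
given seed (all stage artifacts land in `results/acceptance_run/`) and
writes the acceptance JSON to `--out`.

See `docs/methods.md` for model assumptions, the synthetic-data design and
numerical choices.
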