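"""End-to-end orchestration: simulate/ingest -> call -> classify -> DE ->
convergence -> co-expression -> ranks, with a machine-readable run report.

The report records every stage's bookkeeping (list sizes, partition counts,
group-class counts, DE counts per contrast, convergent group counts, network
sizes) and checks the partition identities it implies.  When the inputs come
from the synthetic generator the report also carries planted-structure
recovery (precision/recall per planted structure class).
"""

from __future__ import annotations

import dataclasses
import glob
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__, io_formats
from .ams_orthology import (
    SSPSource,
    annotate_ssp_members,
    classify_groups,
    genome_level_tests,
)
from .coexpression import assign_ranks, build_network, seed_degrees, Rank
from .expression import (
    convergence_matrix,
    de_ssp_intersect,
    detect_convergence,
    simple_de,
)
from .ssp_caller import CallerThresholds, call_all, partition_counts
from .synthetic_data import (
    GroundTruth,
    SimConfig,
    SyntheticDataset,
    generate_all,
    write_dataset,
)
from .types import Direction


class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class RunConfig:
    """Paths, thresholds and the seed for one end-to-end run.

    With ``simulate=True`` all inputs are generated under ``out_dir/data``
    using ``sim``; otherwise the ``*_path`` fields must point at existing
    files (counts/design files are discovered as ``counts_*.tsv`` /
    ``design_*.tsv`` in ``input_dir``).
    """

    out_dir: str = "ssp_ams_run"
    simulate: bool = True
    sim: SimConfig = field(default_factory=SimConfig)
    input_dir: str | None = None
    atlas_species: str | None = None
    caller: CallerThresholds = field(default_factory=CallerThresholds)
    min_ams_fraction: float = 0.30
    group_alpha: float = 0.05
    de_alpha: float = 0.05
    min_abs_log2fc: float = 1.0
    min_species: int = 2
    pcc_min: float = 0.95
    pcc_alpha: float = 0.05
    all_vs_all: bool = False
    write_fasta: bool = False
    rng_seed: int = 0

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        sim = SimConfig(**raw.pop("sim", {}))
        caller = CallerThresholds(**raw.pop("caller", {}))
        cfg = cls(sim=sim, caller=caller, **raw)
        cfg.sim.rng_seed = raw.get("rng_seed", cfg.rng_seed)
        return cfg


def _recovery(planted: set, found: set) -> dict:
    tp = len(planted & found)
    precision = tp / len(found) if found else (1.0 if not planted else 0.0)
    recall = tp / len(planted) if planted else 1.0
    return {
        "n_planted": len(planted),
        "n_found": len(found),
        "n_recovered": tp,
        "precision": precision,
        "recall": recall,
    }


def run_all(cfg: RunConfig) -> dict:
    """Execute every stage; write artifacts and ``report.json`` under out_dir."""
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report: dict = {
        "version": __version__,
        "seed": cfg.rng_seed,
        "config": _config_echo(cfg),
        "stages": {},
    }

    # --- inputs ------------------------------------------------------------
    truth: GroundTruth | None = None
    try:
        if cfg.simulate:
            cfg.sim.rng_seed = cfg.rng_seed
            ds: SyntheticDataset = generate_all(cfg.sim)
            data_dir = out / "data"
            write_dataset(ds, data_dir, write_fasta=cfg.write_fasta)
            truth = ds.truth
        else:
            if cfg.input_dir is None:
                raise ValueError("input_dir is required when simulate=False")
            data_dir = Path(cfg.input_dir)
        species = io_formats.read_species(data_dir / "species.tsv")
        predictions = io_formats.read_unified_predictions(data_dir / "predictions.tsv")
        orthogroups = io_formats.read_orthogroups(
            data_dir / "Orthogroups.tsv",
            known_species=[s.species_id for s in species],
        )
        truth_path = data_dir / "ground_truth.json"
        if truth is None and truth_path.exists():
            import json

            truth = GroundTruth.from_json_dict(
                json.loads(truth_path.read_text())
            )
    except Exception as e:  # noqa: BLE001 - stage attribution
        raise StageError("inputs", e) from e
    report["stages"]["inputs"] = {
        "n_species": len(species),
        "n_ams": sum(1 for s in species if s.is_ams),
        "n_non_ams": sum(1 for s in species if not s.is_ams),
        "n_proteins": len(predictions),
        "n_orthogroups": len(orthogroups),
    }

    # --- consensus SSP calling --------------------------------------------
    try:
        calls = call_all(predictions, cfg.caller)
        io_formats.write_calls(calls, out / "calls.tsv")
        part = partition_counts(calls)
        part.check_identities()
    except Exception as e:
        raise StageError("call", e) from e
    report["stages"]["call"] = {
        "list1_size": part.list1_size,
        "list2_size": part.list2_size,
        "intersection": part.intersection_size,
        "union": part.union_size,
        "n_nss_only": part.n_nss_only,
        "n_extra_only": part.n_extra_only,
        "n_nss_and_extra": part.n_nss_and_extra,
    }

    # --- genome-level comparisons -----------------------------------------
    try:
        genome = genome_level_tests(calls, species, alpha=cfg.group_alpha)
        io_formats.write_json(
            io_formats.genome_comparisons_to_dict(genome),
            out / "genome_tests.json",
        )
    except Exception as e:
        raise StageError("genome_tests", e) from e

    # --- group classification ---------------------------------------------
    try:
        annotate_ssp_members(orthogroups, calls)
        classifications = classify_groups(
            orthogroups,
            species,
            min_frac=cfg.min_ams_fraction,
            alpha=cfg.group_alpha,
        )
        io_formats.write_classifications(classifications, out / "groups.tsv")
    except Exception as e:
        raise StageError("classify_groups", e) from e
    by_source = {s.value: 0 for s in SSPSource}
    for c in classifications:
        by_source[c.ssp_source.value] += 1
    n_ssp_groups = sum(
        v for k, v in by_source.items() if k != SSPSource.NO_SSP.value
    )
    assert n_ssp_groups == (
        by_source["AMS_ONLY"] + by_source["NONAMS_ONLY"] + by_source["BOTH"]
    )
    report["stages"]["classify_groups"] = {
        "by_ssp_source": by_source,
        "n_ssp_groups": n_ssp_groups,
        "n_ams_specific": sum(c.ams_specific for c in classifications),
        "n_ams_preferential": sum(c.ams_preferential for c in classifications),
    }

    # --- differential expression ------------------------------------------
    try:
        de_records = []
        de_stage = {}
        for counts_path in sorted(glob.glob(str(data_dir / "counts_*.tsv"))):
            sp_id = Path(counts_path).stem.removeprefix("counts_")
            design = pd.read_csv(
                data_dir / f"design_{sp_id}.tsv", sep="\t", dtype=str
            )
            counts = io_formats.read_matrix(counts_path)
            conditions = (
                design.set_index("sample").loc[counts.columns, "condition"].tolist()
            )
            recs = simple_de(
                counts,
                conditions,
                species_id=sp_id,
                contrast_id=f"{sp_id}:amf_vs_ctl",
                alpha=cfg.de_alpha,
                min_abs_log2fc=cfg.min_abs_log2fc,
            )
            de_records.extend(recs)
            n_deg = sum(r.direction is not Direction.NS for r in recs)
            de_stage[sp_id] = {"n_genes": len(recs), "n_deg": n_deg}
        io_formats.write_de_table(de_records, out / "de.tsv")
        de_ssp = de_ssp_intersect(de_records, calls)
        for sp_id in de_stage:
            de_stage[sp_id]["n_de_ssp"] = sum(
                1
                for r in de_ssp
                if r.species_id == sp_id and r.direction is not Direction.NS
            )
    except Exception as e:
        raise StageError("de", e) from e
    report["stages"]["de"] = de_stage

    # --- convergence -------------------------------------------------------
    try:
        convergent = detect_convergence(
            de_ssp, orthogroups, min_species=cfg.min_species
        )
        mat = convergence_matrix(convergent)
        mat.to_csv(out / "convergence_matrix.tsv", sep="\t")
        rows = [
            {
                "group_id": r.group_id,
                "direction": r.direction.value,
                "n_species": r.n_species,
                "species": ";".join(sorted(r.species_with_signal)),
                "n_ssp_degs": r.n_ssp_degs,
            }
            for r in convergent
        ]
        pd.DataFrame(
            rows,
            columns=["group_id", "direction", "n_species", "species", "n_ssp_degs"],
        ).to_csv(out / "convergence.tsv", sep="\t", index=False)
    except Exception as e:
        raise StageError("converge", e) from e
    report["stages"]["converge"] = {
        "n_up_groups": sum(r.direction is Direction.UP for r in convergent),
        "n_down_groups": sum(r.direction is Direction.DOWN for r in convergent),
    }

    # --- co-expression and ranks ------------------------------------------
    try:
        atlas = io_formats.read_matrix(data_dir / "atlas.tsv")
        atlas_sp = cfg.atlas_species or (truth.atlas_species if truth else None)
        if atlas_sp is None:
            raise ValueError("atlas_species is unknown; set it in the config")
        seeds = sorted(
            c.protein_id
            for c in calls
            if c.is_ssp and c.species_id == atlas_sp and c.protein_id in atlas.index
        )
        edges = build_network(
            atlas,
            seeds,
            pcc_min=cfg.pcc_min,
            alpha=cfg.pcc_alpha,
            all_vs_all=cfg.all_vs_all,
        )
        io_formats.write_edges(edges, out / "edges.tsv")
        io_formats.write_sif(edges, out / "edges.sif")
        ranks = assign_ranks(calls, classifications, convergent, orthogroups)
        io_formats.write_ranks(ranks, out / "ranks.tsv")
        degrees = seed_degrees(edges, seeds)
    except Exception as e:
        raise StageError("coexpress", e) from e
    report["stages"]["coexpress"] = {
        "atlas_species": atlas_sp,
        "n_seeds": len(seeds),
        "n_edges": len(edges),
        "n_connected_seeds": sum(1 for d in degrees.values() if d > 0),
        "n_rank1": sum(r.rank is Rank.RANK1 for r in ranks),
        "n_rank2": sum(r.rank is Rank.RANK2 for r in ranks),
    }

    # --- planted-structure recovery ---------------------------------------
    if truth is not None:
        ssp_found = {
            (c.species_id, c.protein_id) for c in calls if c.is_ssp
        }
        found_specific = {c.group_id for c in classifications if c.ams_specific}
        found_pref = {c.group_id for c in classifications if c.ams_preferential}
        found_up = {
            r.group_id for r in convergent if r.direction is Direction.UP
        }
        found_down = {
            r.group_id for r in convergent if r.direction is Direction.DOWN
        }
        # seed-vs-all networks can only see module edges incident to a seed
        seed_set = set(seeds)
        module_edges = set()
        for mod in truth.planted_coexpr_modules:
            mod = sorted(mod)
            for i, a in enumerate(mod):
                for b in mod[i + 1 :]:
                    if cfg.all_vs_all or a in seed_set or b in seed_set:
                        module_edges.add((a, b))
        edge_pairs = {(e.gene_a, e.gene_b) for e in edges}
        seed_adjacent = edge_pairs & module_edges
        report["recovery"] = {
            "n_offmodule_edges": len(edge_pairs - module_edges),
            "ssp": _recovery(truth.true_ssp_ids, ssp_found),
            "ams_specific": _recovery(truth.planted_specific_groups, found_specific),
            "ams_preferential": _recovery(
                truth.planted_preferential_groups, found_pref
            ),
            "convergent_up": _recovery(truth.planted_convergent["up"], found_up),
            "convergent_down": _recovery(
                truth.planted_convergent["down"], found_down
            ),
            "coexpr_module_edges": _recovery(module_edges, seed_adjacent),
        }

    io_formats.write_json(report, out / "report.json")
    return report


def _config_echo(cfg: RunConfig) -> dict:
    d = dataclasses.asdict(cfg)
    d["sim"] = dataclasses.asdict(cfg.sim)
    d["caller"] = dataclasses.asdict(cfg.caller)
    return d
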