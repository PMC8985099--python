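"""Synthetic benchmark generator with known ground truth.

Emulates, at reduced proteome scale, the statistical structure of a
60-genome comparative SSP study: 39 of 60 species are hosts of arbuscular
mycorrhizal fungi (AMS species), nine secretion-prediction tools vote with
configurable sensitivity/specificity around a latent per-protein secretion
status, ortholog groups carry planted AMS-specific and AMS-preferential
structure, four AMS species plus one non-AMS control get AMF-vs-control
count matrices with planted direction-consistent differentially expressed
SSPs, and one AMS species gets an expression atlas with planted correlated
modules around SSP seed genes.

Simulation is label-level only: tool calls are Bernoulli draws conditioned
on the latent status, and FASTA sequences are random residues — there are no
real signal-peptide motifs.  All randomness flows through one integer seed;
each stage draws from its own fixed substream so stages are reproducible in
isolation.
"""

from __future__ import annotations

import dataclasses
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import io_formats
from .ssp_caller import CallerThresholds
from .types import (
    AmsStatus,
    Lineage,
    OrthologGroup,
    ProteinPrediction,
    SpeciesRecord,
)

_AA = np.array(list("ACDEFGHIKLNPQRSTVWY"))  # no M, no *; M added explicitly

# fixed substream offsets per stage (reproducibility of each stage alone)
_STREAMS = {
    "species": 1,
    "predictions": 2,
    "orthogroups": 3,
    "counts": 4,
    "atlas": 5,
    "fasta": 6,
}


class SimConfigError(ValueError):
    """A simulation parameter is out of its documented range."""


@dataclass
class SimConfig:
    """All knobs of the generator.

    Defaults mirror the emulated study design: 60 species with a 39/21
    AMS/non-AMS split, three planted AMS-specific and three AMS-preferential
    ortholog groups, four AMS RNA-seq species plus one non-AMS control, and
    an ~31 proteins-per-orthogroup density.  Proteome sizes and group counts
    are scaled down ~60-fold so the full pipeline runs in seconds.
    """

    n_species: int = 60
    frac_ams: float = 0.65
    proteins_per_species: tuple[int, int] = (400, 600)
    frac_true_ssp: float = 0.08
    frac_membrane: float = 0.15
    frac_incomplete_orf: float = 0.05
    tool_sensitivity: float | dict = 0.90
    tool_specificity: float | dict = 0.95
    n_orthogroups: int = 1000
    frac_in_orthogroups: float = 0.92
    n_planted_specific: int = 3
    n_planted_preferential: int = 3
    preferential_effect: float = 5.0
    n_de_species: int = 4
    n_replicates: int = 3
    de_log2fc: float = 3.0
    nb_dispersion: float = 0.1
    frac_de_genes: float = 0.05
    n_extra_ssp_de: int = 5
    n_planted_convergent_up: int = 3
    n_planted_convergent_down: int = 3
    n_atlas_samples: int = 20
    planted_module_size: int = 5
    n_planted_modules: int = 2
    module_pcc: float = 0.98
    rng_seed: int = 0

    def validate(self) -> None:
        counts = {
            "n_species": self.n_species,
            "n_orthogroups": self.n_orthogroups,
            "n_replicates": self.n_replicates,
            "n_atlas_samples": self.n_atlas_samples,
            "planted_module_size": self.planted_module_size,
        }
        for name, v in counts.items():
            if int(v) != v or v < 1:
                raise SimConfigError(f"{name} must be a positive integer")
        fractions = {
            "frac_ams": self.frac_ams,
            "frac_true_ssp": self.frac_true_ssp,
            "frac_membrane": self.frac_membrane,
            "frac_incomplete_orf": self.frac_incomplete_orf,
            "frac_de_genes": self.frac_de_genes,
            "frac_in_orthogroups": self.frac_in_orthogroups,
            "module_pcc": self.module_pcc,
        }
        for name, v in fractions.items():
            if not 0.0 <= v <= 1.0:
                raise SimConfigError(f"{name} must lie in [0, 1]")
        if self.frac_true_ssp + self.frac_membrane > 1.0:
            raise SimConfigError("frac_true_ssp + frac_membrane must be <= 1")
        for name in ("tool_sensitivity", "tool_specificity"):
            for v in _per_class(getattr(self, name)).values():
                if not 0.0 <= v <= 1.0:
                    raise SimConfigError(f"{name} must lie in [0, 1]")
        lo, hi = self.proteins_per_species
        if lo < 1 or hi < lo:
            raise SimConfigError("proteins_per_species must be a valid count range")
        if self.nb_dispersion <= 0:
            raise SimConfigError("nb_dispersion must be > 0")
        for name in (
            "n_planted_specific",
            "n_planted_preferential",
            "n_de_species",
            "n_planted_convergent_up",
            "n_planted_convergent_down",
            "n_planted_modules",
            "n_extra_ssp_de",
        ):
            if getattr(self, name) < 0:
                raise SimConfigError(f"{name} must be >= 0")
        if self.n_atlas_samples < 3:
            raise SimConfigError(
                "n_atlas_samples must be >= 3 (correlation p undefined below)"
            )
        if self.planted_module_size < 2:
            raise SimConfigError("planted_module_size must be >= 2")


@dataclass
class GroundTruth:
    """Everything planted by the generator, for downstream recovery checks."""

    true_ssp_ids: set[tuple[str, str]] = field(default_factory=set)
    planted_specific_groups: set[str] = field(default_factory=set)
    planted_preferential_groups: set[str] = field(default_factory=set)
    planted_de: dict[str, set[tuple[str, str]]] = field(default_factory=dict)
    planted_coexpr_modules: list[set[str]] = field(default_factory=list)
    planted_convergent: dict[str, set[str]] = field(
        default_factory=lambda: {"up": set(), "down": set()}
    )
    atlas_species: str | None = None

    def to_json_dict(self) -> dict:
        return {
            "true_ssp_ids": sorted(map(list, self.true_ssp_ids)),
            "planted_specific_groups": sorted(self.planted_specific_groups),
            "planted_preferential_groups": sorted(self.planted_preferential_groups),
            "planted_de": {
                k: sorted(map(list, v)) for k, v in sorted(self.planted_de.items())
            },
            "planted_coexpr_modules": [
                sorted(m) for m in self.planted_coexpr_modules
            ],
            "planted_convergent": {
                k: sorted(v) for k, v in sorted(self.planted_convergent.items())
            },
            "atlas_species": self.atlas_species,
        }

    @classmethod
    def from_json_dict(cls, d: dict) -> "GroundTruth":
        return cls(
            true_ssp_ids={tuple(x) for x in d["true_ssp_ids"]},
            planted_specific_groups=set(d["planted_specific_groups"]),
            planted_preferential_groups=set(d["planted_preferential_groups"]),
            planted_de={
                k: {tuple(x) for x in v} for k, v in d["planted_de"].items()
            },
            planted_coexpr_modules=[set(m) for m in d["planted_coexpr_modules"]],
            planted_convergent={
                k: set(v) for k, v in d["planted_convergent"].items()
            },
            atlas_species=d["atlas_species"],
        )


def _per_class(value) -> dict[str, float]:
    """Expand a scalar sensitivity/specificity into the three tool classes."""
    if isinstance(value, dict):
        out = {"nss": 0.9, "tm": 0.9, "loc": 0.9}
        out.update(value)
        return out
    return {"nss": float(value), "tm": float(value), "loc": float(value)}


def _rng(cfg: SimConfig, stage: str) -> np.random.Generator:
    return np.random.default_rng([int(cfg.rng_seed), _STREAMS[stage]])


def generate_species(cfg: SimConfig) -> list[SpeciesRecord]:
    """Species records with a round(n_species * frac_ams) AMS split."""
    cfg.validate()
    rng = _rng(cfg, "species")
    n_ams = round(cfg.n_species * cfg.frac_ams)
    status = [AmsStatus.AMS] * n_ams + [AmsStatus.NON_AMS] * (cfg.n_species - n_ams)
    status = [status[i] for i in rng.permutation(cfg.n_species)]
    # lineage proportions follow a 33/15/12-of-60 dicot/monocot/other mix
    lineage_draw = rng.choice(3, size=cfg.n_species, p=[33 / 60, 15 / 60, 12 / 60])
    lineage_values = [Lineage.DICOT, Lineage.MONOCOT, Lineage.OTHER]
    lineages = [lineage_values[i] for i in lineage_draw]
    lo, hi = cfg.proteins_per_species
    sizes = rng.integers(lo, hi + 1, size=cfg.n_species)
    width = max(3, len(str(cfg.n_species)))
    return [
        SpeciesRecord(
            species_id=f"sp{i + 1:0{width}d}",
            ams_status=status[i],
            lineage=lineages[i],
            n_proteins_annotated=int(sizes[i]),
        )
        for i in range(cfg.n_species)
    ]


# latent status codes
_NSS, _UNCONV, _MEMBRANE, _OTHER = 0, 1, 2, 3
_RELEVANT = {
    "nss": (_NSS, _MEMBRANE),  # membrane proteins often carry signal sequences
    "tm": (_MEMBRANE,),
    "loc": (_NSS, _UNCONV),
}


def _draw_lengths(rng: np.random.Generator, n: int) -> np.ndarray:
    """Log-normal lengths truncated to [20, 600] aa (median ~130)."""
    out = np.empty(n)
    todo = np.arange(n)
    while todo.size:
        draw = rng.lognormal(mean=np.log(130.0), sigma=0.5, size=todo.size)
        ok = (draw >= 20) & (draw <= 600)
        out[todo[ok]] = draw[ok]
        todo = todo[~ok]
    return np.round(out).astype(int)


def generate_predictions(
    cfg: SimConfig, species: list[SpeciesRecord]
) -> tuple[list[ProteinPrediction], GroundTruth]:
    """Per-protein tool votes drawn around a latent secretion status.

    Each tool's call is Bernoulli: P(positive | relevant status) equals the
    class sensitivity, P(positive | otherwise) equals 1 - specificity.  The
    ground-truth SSP set holds proteins with a secreted latent status that
    also pass the default length/completeness gate.
    """
    cfg.validate()
    if not species:
        raise SimConfigError("n_species: species list is empty")
    rng = _rng(cfg, "predictions")
    sens = _per_class(cfg.tool_sensitivity)
    spec = _per_class(cfg.tool_specificity)
    gate = CallerThresholds()

    f = cfg.frac_true_ssp
    probs = [0.6 * f, 0.4 * f, cfg.frac_membrane, 1 - f - cfg.frac_membrane]

    predictions: list[ProteinPrediction] = []
    truth = GroundTruth()
    for sp in species:
        n = sp.n_proteins_annotated
        status = rng.choice(4, size=n, p=probs)
        lengths = _draw_lengths(rng, n)
        complete = rng.random(n) >= cfg.frac_incomplete_orf
        votes = {}
        for cls in ("nss", "tm", "loc"):
            relevant = np.isin(status, _RELEVANT[cls])
            p_pos = np.where(relevant, sens[cls], 1.0 - spec[cls])
            votes[cls] = rng.random((n, 3)) < p_pos[:, None]
        for i in range(n):
            pid = f"{sp.species_id}_g{i + 1:05d}"
            pred = ProteinPrediction(
                protein_id=pid,
                species_id=sp.species_id,
                length_aa=int(lengths[i]),
                complete_orf=bool(complete[i]),
                nss_votes=tuple(bool(v) for v in votes["nss"][i]),
                tm_votes=tuple(bool(v) for v in votes["tm"][i]),
                loc_votes=tuple(bool(v) for v in votes["loc"][i]),
            )
            predictions.append(pred)
            if status[i] in (_NSS, _UNCONV) and complete[i] and (
                gate.min_len <= lengths[i] <= gate.max_len
            ):
                truth.true_ssp_ids.add((sp.species_id, pid))
    return predictions, truth


def de_species_ids(cfg: SimConfig, species: list[SpeciesRecord]) -> list[str]:
    """The AMS species carrying AMF-vs-control contrasts (first n, sorted)."""
    ams = sorted(s.species_id for s in species if s.is_ams)
    if cfg.n_de_species > len(ams):
        raise SimConfigError("n_de_species exceeds the number of AMS species")
    return ams[: cfg.n_de_species]


def control_species_id(species: list[SpeciesRecord]) -> str | None:
    non = sorted(s.species_id for s in species if not s.is_ams)
    return non[0] if non else None


def generate_orthogroups(
    cfg: SimConfig,
    species: list[SpeciesRecord],
    predictions: list[ProteinPrediction],
    truth: GroundTruth,
) -> list[OrthologGroup]:
    """Ortholog groups with planted AMS-specific and AMS-preferential structure.

    Planted specific groups: one true SSP from each of >= ceil(0.3 * n_AMS)
    AMS species, zero non-AMS members.  Planted preferential groups: every
    AMS species contributes 1 + Poisson(preferential_effect) true SSPs, each
    non-AMS species contributes one with probability 1/2 (at least one is
    forced so both host classes are represented).  All remaining proteins
    are assigned uniformly to background groups.
    """
    cfg.validate()
    rng = _rng(cfg, "orthogroups")
    ams = sorted(s.species_id for s in species if s.is_ams)
    non = sorted(s.species_id for s in species if not s.is_ams)
    if cfg.n_planted_specific > 0 or cfg.n_planted_preferential > 0:
        if not ams:
            raise SimConfigError("frac_ams: planting requires >= 1 AMS species")
        if cfg.n_planted_preferential > 0 and not non:
            raise SimConfigError(
                "frac_ams: preferential planting requires >= 1 non-AMS species"
            )

    # per-species shuffled pools of unassigned true-SSP proteins
    ssp_pool: dict[str, list[str]] = {s.species_id: [] for s in species}
    for sp_id, pid in sorted(truth.true_ssp_ids):
        ssp_pool[sp_id].append(pid)
    for pool in ssp_pool.values():
        rng.shuffle(pool)

    n_planted = cfg.n_planted_specific + cfg.n_planted_preferential
    if n_planted > cfg.n_orthogroups:
        raise SimConfigError("n_orthogroups is smaller than the planted count")
    width = max(7, len(str(cfg.n_orthogroups)))
    gids = [f"OG{i:0{width}d}" for i in range(cfg.n_orthogroups)]
    order = rng.permutation(cfg.n_orthogroups)
    planted_ids = [gids[i] for i in order[:n_planted]]
    groups: list[OrthologGroup] = []

    def take_ssp(sp_id: str, k: int = 1) -> list[str]:
        pool = ssp_pool[sp_id]
        if len(pool) < k:
            raise SimConfigError(
                "frac_true_ssp: not enough true SSPs in "
                f"{sp_id} to fill planted groups"
            )
        taken, ssp_pool[sp_id] = pool[:k], pool[k:]
        return taken

    need = int(np.ceil(0.3 * len(ams))) if ams else 0
    forced = [s for s in de_species_ids(cfg, species) if s in ams]
    for j in range(cfg.n_planted_specific):
        gid = planted_ids[j]
        span_size = int(rng.integers(need, min(len(ams), need + 8) + 1))
        span = list(dict.fromkeys(forced))[:span_size]
        others = [s for s in ams if s not in span]
        extra = rng.choice(others, size=span_size - len(span), replace=False)
        span = sorted(span + [str(s) for s in extra])
        members = {(sp_id, take_ssp(sp_id, 1)[0]) for sp_id in span}
        groups.append(OrthologGroup(group_id=gid, members=members))
        truth.planted_specific_groups.add(gid)

    for j in range(cfg.n_planted_preferential):
        gid = planted_ids[cfg.n_planted_specific + j]
        members = set()
        for sp_id in ams:
            k = 1 + int(rng.poisson(cfg.preferential_effect))
            k = min(k, len(ssp_pool[sp_id]))
            if k == 0:
                raise SimConfigError(
                    f"frac_true_ssp: no true SSPs left in {sp_id} for planting"
                )
            members |= {(sp_id, pid) for pid in take_ssp(sp_id, k)}
        contributed = [sp_id for sp_id in non if rng.random() < 0.5]
        if not contributed:
            contributed = [non[0]]
        for sp_id in contributed:
            if ssp_pool[sp_id]:
                members.add((sp_id, take_ssp(sp_id, 1)[0]))
        if not any(sp in non for sp, _ in members):
            raise SimConfigError(
                "frac_true_ssp: no non-AMS true SSP available for "
                "preferential planting"
            )
        groups.append(OrthologGroup(group_id=gid, members=members))
        truth.planted_preferential_groups.add(gid)

    planted_members = {m for g in groups for m in g.members}
    background_ids = [gids[i] for i in order[n_planted:]]
    remaining = [
        (p.species_id, p.protein_id)
        for p in predictions
        if (p.species_id, p.protein_id) not in planted_members
    ]
    keep = rng.random(len(remaining)) < cfg.frac_in_orthogroups
    assignment = rng.integers(0, len(background_ids), size=len(remaining))
    background: dict[str, set] = {gid: set() for gid in background_ids}
    for m, k, a in zip(remaining, keep, assignment):
        if k:
            background[background_ids[a]].add(m)
    for gid in background_ids:
        if background[gid]:
            groups.append(OrthologGroup(group_id=gid, members=background[gid]))
    return sorted(groups, key=lambda g: g.group_id)


def _nb_draw(
    rng: np.random.Generator, mu: np.ndarray, dispersion: float, n_samples: int
) -> np.ndarray:
    """Negative-binomial counts with mean mu and NB2 dispersion."""
    r = 1.0 / dispersion
    p = r / (r + mu)
    return rng.negative_binomial(r, p[:, None], size=(mu.size, n_samples))


def generate_counts(
    cfg: SimConfig,
    species: list[SpeciesRecord],
    predictions: list[ProteinPrediction],
    orthogroups: list[OrthologGroup],
    truth: GroundTruth,
) -> dict[str, tuple[pd.DataFrame, list[str]]]:
    """AMF-vs-control count matrices with planted differential expression.

    Contrasts are generated for the first ``n_de_species`` AMS species plus
    one non-AMS control.  Planted DE genes shift the treatment mean by a
    factor ``2**(+-de_log2fc)``.  Convergent structure: same-direction DE is
    planted on the SSP members of chosen ortholog groups shared by >= 2
    contrast species (preferential groups first); additional per-species DE
    SSPs are planted only in groups that cannot create accidental
    cross-species convergence.  The non-AMS control receives a few non-SSP
    DE genes and no DE SSPs.
    """
    cfg.validate()
    rng = _rng(cfg, "counts")
    de_sp = de_species_ids(cfg, species)
    ctl_sp = control_species_id(species)
    genes_by_sp: dict[str, list[str]] = {}
    for p in predictions:
        genes_by_sp.setdefault(p.species_id, []).append(p.protein_id)
    true_ssp = truth.true_ssp_ids

    # --- choose convergent groups -----------------------------------------
    plant_effects: dict[str, dict[str, float]] = {sp: {} for sp in de_sp}
    if ctl_sp is not None:
        plant_effects[ctl_sp] = {}
    used_groups: set[str] = set()
    if cfg.de_log2fc != 0:
        group_de_ssps: dict[str, dict[str, list[str]]] = {}
        for g in orthogroups:
            per_sp = {}
            for sp_id, gene in sorted(g.members):
                if sp_id in de_sp and (sp_id, gene) in true_ssp:
                    per_sp.setdefault(sp_id, []).append(gene)
            if len(per_sp) >= 2:
                group_de_ssps[g.group_id] = per_sp
        pref = sorted(truth.planted_preferential_groups & set(group_de_ssps))
        spec_g = sorted(truth.planted_specific_groups & set(group_de_ssps))
        rest = sorted(set(group_de_ssps) - set(pref) - set(spec_g))
        pool = pref + spec_g + rest
        n_up, n_down = cfg.n_planted_convergent_up, cfg.n_planted_convergent_down
        if len(pool) < n_up + n_down:
            warnings.warn(
                f"only {len(pool)} groups eligible for convergent planting; "
                f"requested {n_up + n_down}"
            )
        chosen_up = pool[:n_up]
        chosen_down = pool[n_up : n_up + n_down]
        for direction, chosen in (("up", chosen_up), ("down", chosen_down)):
            sign = 1.0 if direction == "up" else -1.0
            for gid in chosen:
                used_groups.add(gid)
                truth.planted_convergent[direction].add(gid)
                for sp_id, genes in group_de_ssps[gid].items():
                    for gene in genes:
                        plant_effects[sp_id][gene] = sign * cfg.de_log2fc

        # --- per-species extra DE SSPs (convergence-safe) ------------------
        gene_groups: dict[tuple[str, str], set[str]] = {}
        group_other_de_ssp: dict[str, bool] = {}
        for g in orthogroups:
            n_de_sp_with_ssp = len(
                {sp for sp, gene in g.members if sp in de_sp and (sp, gene) in true_ssp}
            )
            group_other_de_ssp[g.group_id] = n_de_sp_with_ssp >= 2
            for m in g.members:
                gene_groups.setdefault(m, set()).add(g.group_id)
        for sp_id in de_sp:
            candidates = sorted(
                gene
                for gene in genes_by_sp[sp_id]
                if (sp_id, gene) in true_ssp
                and gene not in plant_effects[sp_id]
                and not any(
                    gid in used_groups or group_other_de_ssp[gid]
                    for gid in gene_groups.get((sp_id, gene), ())
                )
            )
            rng.shuffle(candidates)
            for gene in candidates[: cfg.n_extra_ssp_de]:
                sign = 1.0 if rng.random() < 0.5 else -1.0
                plant_effects[sp_id][gene] = sign * cfg.de_log2fc

        # --- background non-SSP DE ----------------------------------------
        for sp_id in de_sp + ([ctl_sp] if ctl_sp else []):
            non_ssp = [
                g for g in genes_by_sp[sp_id] if (sp_id, g) not in true_ssp
            ]
            frac = cfg.frac_de_genes if sp_id in de_sp else 0.01
            n_pick = int(round(frac * len(non_ssp)))
            picked = rng.choice(non_ssp, size=n_pick, replace=False)
            for gene in picked:
                sign = 1.0 if rng.random() < 0.5 else -1.0
                plant_effects[sp_id][str(gene)] = sign * cfg.de_log2fc

    # --- draw counts -------------------------------------------------------
    out: dict[str, tuple[pd.DataFrame, list[str]]] = {}
    for sp_id in de_sp + ([ctl_sp] if ctl_sp else []):
        genes = sorted(genes_by_sp[sp_id])
        mu = rng.lognormal(mean=np.log(50.0), sigma=1.0, size=len(genes))
        fold = np.array(
            [2.0 ** plant_effects[sp_id].get(g, 0.0) for g in genes]
        )
        ctl = _nb_draw(rng, mu, cfg.nb_dispersion, cfg.n_replicates)
        trt = _nb_draw(rng, mu * fold, cfg.nb_dispersion, cfg.n_replicates)
        cols = [f"ctl_{i + 1}" for i in range(cfg.n_replicates)] + [
            f"amf_{i + 1}" for i in range(cfg.n_replicates)
        ]
        df = pd.DataFrame(
            np.hstack([ctl, trt]), index=genes, columns=cols
        )
        conditions = ["control"] * cfg.n_replicates + ["treatment"] * cfg.n_replicates
        contrast = f"{sp_id}:amf_vs_ctl"
        truth.planted_de[contrast] = {
            (g, "up" if e > 0 else "down")
            for g, e in plant_effects[sp_id].items()
        }
        out[sp_id] = (df, conditions)
    return out


def atlas_species_id(cfg: SimConfig, species: list[SpeciesRecord]) -> str:
    """The atlas host: first AMS species without an AMF contrast."""
    de_sp = set(de_species_ids(cfg, species))
    ams = sorted(s.species_id for s in species if s.is_ams)
    if not ams:
        raise SimConfigError("frac_ams: atlas generation requires an AMS species")
    for sp_id in ams:
        if sp_id not in de_sp:
            return sp_id
    return ams[0]


def generate_atlas(
    cfg: SimConfig,
    species: list[SpeciesRecord],
    predictions: list[ProteinPrediction],
    orthogroups: list[OrthologGroup],
    truth: GroundTruth,
) -> pd.DataFrame:
    """Expression atlas with planted correlated modules around SSP seeds.

    Module genes share a latent factor: each profile is
    ``sqrt(rho) * f + sqrt(1-rho) * eps`` so every within-module pair has
    correlation expectation ``rho = module_pcc``.  Background genes are
    independent Gaussian profiles.  Each module is seeded on a true SSP of
    the atlas species, preferentially one sitting in a planted
    AMS-preferential group (the use case: SSP-seeded subnetworks).
    """
    cfg.validate()
    rng = _rng(cfg, "atlas")
    sp_id = atlas_species_id(cfg, species)
    truth.atlas_species = sp_id
    genes = sorted(p.protein_id for p in predictions if p.species_id == sp_id)
    n, s = len(genes), cfg.n_atlas_samples

    X = rng.normal(size=(n, s))
    pos = {g: i for i, g in enumerate(genes)}

    pref_members = {
        gene
        for g in orthogroups
        if g.group_id in truth.planted_preferential_groups
        for sp, gene in g.members
        if sp == sp_id
    }
    sp_ssps = sorted(g for s2, g in truth.true_ssp_ids if s2 == sp_id)
    seed_candidates = sorted(pref_members & set(sp_ssps)) + [
        g for g in sp_ssps if g not in pref_members
    ]
    if cfg.n_planted_modules > 0 and not seed_candidates:
        raise SimConfigError(
            "frac_true_ssp: no SSP seed available in the atlas species"
        )

    used: set[str] = set()
    non_ssp = [g for g in genes if g not in set(sp_ssps)]
    rho = cfg.module_pcc
    for m in range(cfg.n_planted_modules):
        seeds_left = [g for g in seed_candidates if g not in used]
        if not seeds_left:
            raise SimConfigError(
                "n_planted_modules: ran out of SSP seed genes in the atlas species"
            )
        module = [seeds_left[0]]
        pool = [g for g in non_ssp if g not in used]
        extra = rng.choice(pool, size=cfg.planted_module_size - 1, replace=False)
        module += [str(g) for g in extra]
        used |= set(module)
        f = rng.normal(size=s)
        for g in module:
            X[pos[g]] = np.sqrt(rho) * f + np.sqrt(1.0 - rho) * rng.normal(size=s)
        truth.planted_coexpr_modules.append(set(module))

    cols = [f"atlas_{i + 1:02d}" for i in range(s)]
    return pd.DataFrame(X, index=genes, columns=cols)


# ---------------------------------------------------------------------------
# One-call dataset assembly and on-disk layout
# ---------------------------------------------------------------------------

def strong_effect_config(rng_seed: int = 0) -> SimConfig:
    """The noiseless-identifiability operating point.

    Perfect tools, large expression effects, five replicates and near-unit
    module correlation: with these settings every downstream classifier is
    expected to recover its planted structure exactly, so the configuration
    anchors end-to-end recovery checks.
    """
    return SimConfig(
        tool_sensitivity=1.0,
        tool_specificity=1.0,
        frac_incomplete_orf=0.0,
        n_replicates=5,
        de_log2fc=5.0,
        module_pcc=0.995,
        rng_seed=rng_seed,
    )


@dataclass
class SyntheticDataset:
    config: SimConfig
    species: list[SpeciesRecord]
    predictions: list[ProteinPrediction]
    orthogroups: list[OrthologGroup]
    counts: dict[str, tuple[pd.DataFrame, list[str]]]
    atlas: pd.DataFrame
    truth: GroundTruth


def generate_all(cfg: SimConfig) -> SyntheticDataset:
    """Run every generator stage with the config's seed."""
    cfg.validate()
    species = generate_species(cfg)
    predictions, truth = generate_predictions(cfg, species)
    orthogroups = generate_orthogroups(cfg, species, predictions, truth)
    counts = generate_counts(cfg, species, predictions, orthogroups, truth)
    atlas = generate_atlas(cfg, species, predictions, orthogroups, truth)
    return SyntheticDataset(
        config=cfg,
        species=species,
        predictions=predictions,
        orthogroups=orthogroups,
        counts=counts,
        atlas=atlas,
        truth=truth,
    )


def _random_sequences(
    cfg: SimConfig, predictions: list[ProteinPrediction]
) -> dict[str, dict[str, str]]:
    """Random residue strings per species (synthetic, no real motifs)."""
    rng = _rng(cfg, "fasta")
    by_species: dict[str, dict[str, str]] = {}
    for p in predictions:
        body = "".join(rng.choice(_AA, size=p.length_aa - 1))
        first = "M" if p.complete_orf else str(rng.choice(_AA))
        by_species.setdefault(p.species_id, {})[p.protein_id] = first + body
    return by_species


def write_dataset(ds: SyntheticDataset, outdir, write_fasta: bool = True) -> None:
    """Write every pipeline input plus the ground-truth JSON to a directory."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    io_formats.write_species(ds.species, out / "species.tsv")
    io_formats.write_unified_predictions(ds.predictions, out / "predictions.tsv")
    species_ids = sorted(s.species_id for s in ds.species)
    io_formats.write_orthogroups(
        ds.orthogroups, species_ids, out / "Orthogroups.tsv"
    )
    for sp_id, (df, conditions) in sorted(ds.counts.items()):
        io_formats.write_matrix(df, out / f"counts_{sp_id}.tsv")
        pd.DataFrame(
            {"sample": df.columns, "condition": conditions}
        ).to_csv(out / f"design_{sp_id}.tsv", sep="\t", index=False)
    io_formats.write_matrix(ds.atlas, out / "atlas.tsv")
    io_formats.write_json(ds.truth.to_json_dict(), out / "ground_truth.json")
    io_formats.write_json(
        dataclasses.asdict(ds.config), out / "sim_config.json"
    )
    if write_fasta:
        fasta_dir = out / "fasta"
        fasta_dir.mkdir(exist_ok=True)
        for sp_id, seqs in sorted(_random_sequences(ds.config, ds.predictions).items()):
            io_formats.write_protein_fasta(seqs, fasta_dir / f"{sp_id}.faa")
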