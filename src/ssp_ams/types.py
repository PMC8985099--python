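"""Core data containers shared across the pipeline stages.

The pipeline reasons about four kinds of objects: species (with their
arbuscular-mycorrhizal-symbiosis status), per-protein secretion-tool
predictions, ortholog groups, and per-gene differential-expression results.
Everything else (consensus calls, group classifications, network edges) is
derived from these and lives next to the code that produces it.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field


class AmsStatus(str, enum.Enum):
    """Whether a plant species can form arbuscular mycorrhizal symbiosis."""

    AMS = "AMS"
    NON_AMS = "non-AMS"


class Lineage(str, enum.Enum):
    DICOT = "dicot"
    MONOCOT = "monocot"
    OTHER = "other"


@dataclass(frozen=True)
class SpeciesRecord:
    """One plant species; the unit of every cross-species comparison.

    Parameters
    ----------
    species_id
        Short unique label, e.g. ``"sp007"`` or ``"Ptrichocarpa"``.
    ams_status
        Host status for arbuscular mycorrhizal fungi.
    lineage
        Coarse phylogenetic stratum used for stratified genome-level tests.
    n_proteins_annotated
        Total number of annotated proteins in the genome; denominator of the
        per-species SSP ratio.
    """

    species_id: str
    ams_status: AmsStatus
    lineage: Lineage
    n_proteins_annotated: int

    def __post_init__(self) -> None:
        if self.n_proteins_annotated < 0:
            raise ValueError("n_proteins_annotated must be >= 0")

    @property
    def is_ams(self) -> bool:
        return self.ams_status is AmsStatus.AMS


@dataclass(frozen=True)
class ProteinPrediction:
    """Per-tool secretion predictions for one protein.

    Three tool classes, three tools each, mirroring a typical secretome
    workflow: N-terminal signal sequence (SignalP-, Phobius-, TargetP-like),
    transmembrane domains (TMHMM-, MEMSAT-, Phobius-like) and extracellular
    localization (ApoplastP-, DeepLoc-, Plant-mSubP-like).  Votes are plain
    booleans; the caller never sees tool scores.
    """

    protein_id: str
    species_id: str
    length_aa: int
    complete_orf: bool
    nss_votes: tuple[bool, bool, bool]
    tm_votes: tuple[bool, bool, bool]
    loc_votes: tuple[bool, bool, bool]

    def __post_init__(self) -> None:
        if self.length_aa < 1:
            raise ValueError("length_aa must be >= 1")
        for name in ("nss_votes", "tm_votes", "loc_votes"):
            v = getattr(self, name)
            if len(v) != 3:
                raise ValueError(f"{name} must hold exactly three votes")


@dataclass
class OrthologGroup:
    """A named set of (species, gene) members inferred to be orthologous.

    ``ssp_members`` is filled in downstream once consensus SSP calls exist;
    it is always a subset of ``members``.
    """

    group_id: str
    members: set[tuple[str, str]] = field(default_factory=set)
    ssp_members: set[tuple[str, str]] = field(default_factory=set)

    def species_present(self) -> set[str]:
        return {sp for sp, _ in self.members}

    def ssp_species(self) -> set[str]:
        return {sp for sp, _ in self.ssp_members}

    def validate(self) -> None:
        if not self.ssp_members <= self.members:
            raise ValueError(
                f"group {self.group_id}: ssp_members is not a subset of members"
            )


class Direction(str, enum.Enum):
    UP = "up"
    DOWN = "down"
    NS = "ns"


@dataclass(frozen=True)
class DERecord:
    """One gene's differential-expression result in one species/contrast.

    ``direction`` encodes the significance call: ``up`` requires
    log2fc > min_abs_log2fc and padj <= alpha (strict on the fold-change,
    inclusive on the adjusted p), ``down`` the mirror image, else ``ns``.
    """

    gene_id: str
    species_id: str
    contrast_id: str
    log2fc: float
    padj: float
    direction: Direction

    def __post_init__(self) -> None:
        if math.isnan(self.log2fc) or math.isnan(self.padj):
            raise ValueError("log2fc/padj must not be NaN")
        if not 0.0 <= self.padj <= 1.0:
            raise ValueError("padj must lie in [0, 1]")


def species_index(species: list[SpeciesRecord]) -> dict[str, SpeciesRecord]:
    """Index species by id, rejecting duplicates."""
    idx: dict[str, SpeciesRecord] = {}
    for sp in species:
        if sp.species_id in idx:
            raise ValueError(f"duplicate species_id {sp.species_id!r}")
        idx[sp.species_id] = sp
    return idx
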