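"""Ortholog-group AMS association and genome-level AMS comparisons.

Three questions are asked of each ortholog group, given per-species host
status for arbuscular mycorrhizal symbiosis (AMS):

* which host class contributes its SSP members (AMS only / non-AMS only /
  both / none);
* is it *AMS-specific* — members from at least 30% of the AMS species,
  none from any non-AMS species, and at least one SSP;
* is it *AMS-preferential* — SSPs from both classes, with AMS species
  carrying significantly more SSPs per species (one-sided Wilcoxon
  rank-sum, P <= 0.05).

Genome-level comparisons contrast per-species SSP counts and SSP ratios
(count / proteome size) between AMS and non-AMS species, overall and per
lineage, with a two-sided rank-sum test.
"""

from __future__ import annotations

import enum
import math
from collections import Counter
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .ssp_caller import SSPCall
from .types import OrthologGroup, SpeciesRecord, species_index

DEFAULT_MIN_AMS_FRACTION = 0.30
DEFAULT_ALPHA = 0.05


class SSPSource(str, enum.Enum):
    AMS_ONLY = "AMS_ONLY"
    NONAMS_ONLY = "NONAMS_ONLY"
    BOTH = "BOTH"
    NO_SSP = "NO_SSP"


@dataclass(frozen=True)
class GroupClassification:
    group_id: str
    ssp_source: SSPSource
    ams_specific: bool
    ams_preferential: bool
    wilcoxon_p: float | None
    ams_species_fraction: float


@dataclass(frozen=True)
class GenomeComparison:
    """One AMS-vs-non-AMS comparison of a per-species SSP metric."""

    metric: str  # "SSP_COUNT" | "SSP_RATIO"
    stratum: str  # "all" | lineage value
    p_value: float | None
    direction: str  # "AMS>non-AMS" | "non-AMS>AMS" | "none" | "skipped"
    n_ams: int
    n_non_ams: int
    skipped_reason: str | None = None


def wilcoxon_rank_sum(
    x: list[float] | np.ndarray,
    y: list[float] | np.ndarray,
    alternative: str = "two-sided",
) -> float:
    """Wilcoxon rank-sum (Mann-Whitney U) p-value.

    Exact by complete enumeration when both samples are small (max size 10)
    and tie-free; otherwise the normal approximation with tie and continuity
    corrections.  ``alternative='greater'`` tests whether ``x`` tends larger
    than ``y``.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("wilcoxon_rank_sum requires non-empty samples")
    pooled = np.concatenate([x, y])
    has_ties = np.unique(pooled).size < pooled.size
    method = "exact" if (max(x.size, y.size) <= 10 and not has_ties) else "asymptotic"
    res = stats.mannwhitneyu(x, y, alternative=alternative, method=method)
    return float(min(res.pvalue, 1.0))


def classify_ssp_source(
    g: OrthologGroup, species: list[SpeciesRecord] | dict[str, SpeciesRecord]
) -> SSPSource:
    """Classify a group by the host class of the species contributing SSPs."""
    idx = species if isinstance(species, dict) else species_index(species)
    for sp, _ in g.members:
        if sp not in idx:
            raise KeyError(f"group {g.group_id}: unknown species {sp!r}")
    ssp_sp = g.ssp_species()
    if not ssp_sp:
        return SSPSource.NO_SSP
    any_ams = any(idx[sp].is_ams for sp in ssp_sp)
    any_non = any(not idx[sp].is_ams for sp in ssp_sp)
    if any_ams and any_non:
        return SSPSource.BOTH
    return SSPSource.AMS_ONLY if any_ams else SSPSource.NONAMS_ONLY


def min_ams_species(n_ams: int, min_frac: float = DEFAULT_MIN_AMS_FRACTION) -> int:
    """Smallest integer species count satisfying 'at least min_frac of n_ams'."""
    return math.ceil(min_frac * n_ams)


def is_ams_specific(
    g: OrthologGroup,
    species: list[SpeciesRecord] | dict[str, SpeciesRecord],
    min_frac: float = DEFAULT_MIN_AMS_FRACTION,
    span_on_ssp_members: bool = False,
) -> bool:
    """True iff the group is AMS-specific.

    Requires (i) no members — SSP or not — from any non-AMS species,
    (ii) members from at least ``ceil(min_frac * n_AMS)`` distinct AMS
    species, and (iii) at least one SSP member.  With
    ``span_on_ssp_members=True`` the species span in (ii) is counted over SSP
    members only instead of all members.
    """
    idx = species if isinstance(species, dict) else species_index(species)
    n_ams = sum(1 for sp in idx.values() if sp.is_ams)
    if n_ams == 0:
        raise ValueError("is_ams_specific: no AMS species in the metadata")
    member_sp = g.ssp_species() if span_on_ssp_members else g.species_present()
    for sp in g.species_present():
        if sp not in idx:
            raise KeyError(f"group {g.group_id}: unknown species {sp!r}")
        if not idx[sp].is_ams:
            return False
    if not g.ssp_members:
        return False
    ams_span = sum(1 for sp in member_sp if idx[sp].is_ams)
    return ams_span >= min_ams_species(n_ams, min_frac)


def per_species_ssp_counts(
    g: OrthologGroup, idx: dict[str, SpeciesRecord], include_absent: bool = True
) -> tuple[np.ndarray, np.ndarray]:
    """Per-species SSP-member counts, split into (AMS, non-AMS) vectors.

    With ``include_absent`` (default) every species in the metadata
    contributes an entry, zero when it has no SSP member in the group.
    """
    counts = Counter(sp for sp, _ in g.ssp_members)
    ams, non = [], []
    for sid, rec in sorted(idx.items()):
        c = counts.get(sid, 0)
        if not include_absent and c == 0:
            continue
        (ams if rec.is_ams else non).append(c)
    return np.asarray(ams, dtype=float), np.asarray(non, dtype=float)


def is_ams_preferential(
    g: OrthologGroup,
    species: list[SpeciesRecord] | dict[str, SpeciesRecord],
    alpha: float = DEFAULT_ALPHA,
    include_absent_species: bool = True,
) -> tuple[bool, float | None]:
    """Test whether AMS species carry significantly more SSPs in this group.

    Only groups whose SSPs come from both host classes are testable; for any
    other group the result is ``(False, None)``.  The test is a one-sided
    Wilcoxon rank-sum on per-species SSP counts (AMS > non-AMS), with zero
    counts included for species absent from the group unless
    ``include_absent_species=False``.
    """
    idx = species if isinstance(species, dict) else species_index(species)
    if classify_ssp_source(g, idx) is not SSPSource.BOTH:
        return False, None
    ams, non = per_species_ssp_counts(g, idx, include_absent=include_absent_species)
    p = wilcoxon_rank_sum(ams, non, alternative="greater")
    return p <= alpha, p


def classify_groups(
    groups: list[OrthologGroup],
    species: list[SpeciesRecord],
    min_frac: float = DEFAULT_MIN_AMS_FRACTION,
    alpha: float = DEFAULT_ALPHA,
    span_on_ssp_members: bool = False,
    include_absent_species: bool = True,
) -> list[GroupClassification]:
    """Run source/specific/preferential classification over all groups."""
    idx = species_index(species)
    n_ams = sum(1 for sp in idx.values() if sp.is_ams)
    out = []
    for g in sorted(groups, key=lambda g: g.group_id):
        g.validate()
        source = classify_ssp_source(g, idx)
        specific = (
            is_ams_specific(g, idx, min_frac, span_on_ssp_members)
            if source is SSPSource.AMS_ONLY
            else False
        )
        preferential, p = is_ams_preferential(
            g, idx, alpha, include_absent_species
        )
        ams_span = sum(1 for sp in g.species_present() if idx[sp].is_ams)
        out.append(
            GroupClassification(
                group_id=g.group_id,
                ssp_source=source,
                ams_specific=specific,
                ams_preferential=preferential,
                wilcoxon_p=p,
                ams_species_fraction=ams_span / n_ams if n_ams else 0.0,
            )
        )
    return out


def annotate_ssp_members(
    groups: list[OrthologGroup], calls: list[SSPCall]
) -> None:
    """Fill ``ssp_members`` of each group in place from consensus calls."""
    ssp = {(c.species_id, c.protein_id) for c in calls if c.is_ssp}
    for g in groups:
        g.ssp_members = {m for m in g.members if m in ssp}


def genome_level_tests(
    calls: list[SSPCall],
    species: list[SpeciesRecord],
    alpha: float = DEFAULT_ALPHA,
) -> list[GenomeComparison]:
    """AMS vs non-AMS rank-sum tests on per-species SSP count and ratio.

    Runs two-sided comparisons overall and stratified by lineage; a stratum
    with fewer than two species on either side is reported as skipped.
    """
    idx = species_index(species)
    counts = Counter(c.species_id for c in calls if c.is_ssp)
    per_species = {}
    for sid, rec in idx.items():
        n = counts.get(sid, 0)
        if rec.n_proteins_annotated <= 0:
            raise ValueError(f"species {sid}: n_proteins_annotated must be > 0")
        per_species[sid] = (n, n / rec.n_proteins_annotated)

    strata = ["all"] + sorted({rec.lineage.value for rec in idx.values()})
    out = []
    for stratum in strata:
        members = [
            sid
            for sid, rec in sorted(idx.items())
            if stratum == "all" or rec.lineage.value == stratum
        ]
        ams = [s for s in members if idx[s].is_ams]
        non = [s for s in members if not idx[s].is_ams]
        for mi, metric in enumerate(("SSP_COUNT", "SSP_RATIO")):
            if len(ams) < 2 or len(non) < 2:
                out.append(
                    GenomeComparison(
                        metric=metric,
                        stratum=stratum,
                        p_value=None,
                        direction="skipped",
                        n_ams=len(ams),
                        n_non_ams=len(non),
                        skipped_reason="fewer than 2 species on one side",
                    )
                )
                continue
            x = np.array([per_species[s][mi] for s in ams], dtype=float)
            y = np.array([per_species[s][mi] for s in non], dtype=float)
            p = wilcoxon_rank_sum(x, y, alternative="two-sided")
            if p <= alpha:
                direction = (
                    "AMS>non-AMS" if np.median(x) >= np.median(y) else "non-AMS>AMS"
                )
            else:
                direction = "none"
            out.append(
                GenomeComparison(
                    metric=metric,
                    stratum=stratum,
                    p_value=p,
                    direction=direction,
                    n_ams=len(ams),
                    n_non_ams=len(non),
                )
            )
    return out
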