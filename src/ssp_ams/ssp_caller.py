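"""Consensus small-secreted-protein (SSP) calling.

An SSP is a small protein (complete ORF, 50-250 aa) predicted to be secreted
either conventionally (N-terminal signal sequence, NSS) or unconventionally
(extracellular localization).  Each protein carries nine binary tool votes in
three classes; a majority-decision rule accepts a property when at least two
of the three tools in a class agree, while a single transmembrane prediction
by any tool vetoes the NSS route (membrane proteins often carry signal
sequences but are not secreted).

Two candidate lists result:

* list 1 (NSS route): length gate AND >=2/3 NSS votes AND no TM vote;
* list 2 (extracellular route): length gate AND >=2/3 localization votes.

Their union is the non-redundant SSP set, partitioned into three categories:
NSS-only, Extracellular-only, and NSS-and-extracellular.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass

from .types import ProteinPrediction


class SSPCategory(str, enum.Enum):
    NSS_ONLY = "NSS_ONLY"
    EXTRA_ONLY = "EXTRA_ONLY"
    NSS_AND_EXTRA = "NSS_AND_EXTRA"
    NOT_SSP = "NOT_SSP"


@dataclass(frozen=True)
class CallerThresholds:
    """Tunable thresholds of the consensus caller.

    Defaults are the standard operating point: a closed 50-250 aa length
    window, 2-of-3 majorities for NSS and extracellular consensus, and a
    1-of-3 (any-tool) transmembrane exclusion.  ``tm_vetoes_extracellular``
    extends the TM veto to the extracellular route; by default the veto
    applies only to the NSS branch.
    """

    min_len: int = 50
    max_len: int = 250
    nss_min_votes: int = 2
    tm_exclusion_votes: int = 1
    extra_min_votes: int = 2
    tm_vetoes_extracellular: bool = False

    def __post_init__(self) -> None:
        if self.min_len > self.max_len:
            raise ValueError("min_len must be <= max_len")
        for name in ("nss_min_votes", "tm_exclusion_votes", "extra_min_votes"):
            v = getattr(self, name)
            if not 1 <= v <= 3:
                raise ValueError(f"{name} must lie in 1..3")


@dataclass(frozen=True)
class SSPCall:
    """Consensus verdict for one protein."""

    protein_id: str
    species_id: str
    is_ssp: bool
    category: SSPCategory
    nss_consensus: bool
    tm_any: bool
    extra_consensus: bool


@dataclass(frozen=True)
class SetPartitionReport:
    """Bookkeeping of the two candidate lists and their three-set partition.

    Satisfies ``union = list1 + list2 - intersection`` and
    ``intersection = n_nss_and_extra`` by construction.
    """

    n_nss_only: int
    n_extra_only: int
    n_nss_and_extra: int
    n_not_ssp: int

    @property
    def list1_size(self) -> int:
        """Size of the NSS-route candidate list."""
        return self.n_nss_only + self.n_nss_and_extra

    @property
    def list2_size(self) -> int:
        """Size of the extracellular-route candidate list."""
        return self.n_extra_only + self.n_nss_and_extra

    @property
    def intersection_size(self) -> int:
        return self.n_nss_and_extra

    @property
    def union_size(self) -> int:
        return self.n_nss_only + self.n_extra_only + self.n_nss_and_extra

    def check_identities(self) -> None:
        assert self.union_size == (
            self.list1_size + self.list2_size - self.intersection_size
        )


def passes_length_gate(p: ProteinPrediction, t: CallerThresholds) -> bool:
    """True iff the protein is a complete ORF within the closed length window."""
    return p.complete_orf and t.min_len <= p.length_aa <= t.max_len


def call_ssp(p: ProteinPrediction, t: CallerThresholds | None = None) -> SSPCall:
    """Apply the majority-vote consensus rule to one protein.

    Returns an :class:`SSPCall` whose category follows list membership:
    list-1-only -> ``NSS_ONLY``, list-2-only -> ``EXTRA_ONLY``, both ->
    ``NSS_AND_EXTRA``, neither -> ``NOT_SSP``.
    """
    t = t or CallerThresholds()
    gate = passes_length_gate(p, t)
    nss_consensus = sum(p.nss_votes) >= t.nss_min_votes
    tm_any = sum(p.tm_votes) >= t.tm_exclusion_votes
    extra_consensus = sum(p.loc_votes) >= t.extra_min_votes

    in_list1 = gate and nss_consensus and not tm_any
    in_list2 = gate and extra_consensus
    if t.tm_vetoes_extracellular:
        in_list2 = in_list2 and not tm_any

    if in_list1 and in_list2:
        category = SSPCategory.NSS_AND_EXTRA
    elif in_list1:
        category = SSPCategory.NSS_ONLY
    elif in_list2:
        category = SSPCategory.EXTRA_ONLY
    else:
        category = SSPCategory.NOT_SSP

    return SSPCall(
        protein_id=p.protein_id,
        species_id=p.species_id,
        is_ssp=category is not SSPCategory.NOT_SSP,
        category=category,
        nss_consensus=nss_consensus,
        tm_any=tm_any,
        extra_consensus=extra_consensus,
    )


def call_all(
    predictions: list[ProteinPrediction], t: CallerThresholds | None = None
) -> list[SSPCall]:
    t = t or CallerThresholds()
    return [call_ssp(p, t) for p in predictions]


def partition_counts(calls: list[SSPCall]) -> SetPartitionReport:
    """Count the three-set partition over a list of calls."""
    counts = {c: 0 for c in SSPCategory}
    for call in calls:
        counts[call.category] += 1
    report = SetPartitionReport(
        n_nss_only=counts[SSPCategory.NSS_ONLY],
        n_extra_only=counts[SSPCategory.EXTRA_ONLY],
        n_nss_and_extra=counts[SSPCategory.NSS_AND_EXTRA],
        n_not_ssp=counts[SSPCategory.NOT_SSP],
    )
    report.check_identities()
    return report


def ssp_gene_set(calls: list[SSPCall]) -> set[tuple[str, str]]:
    """The (species_id, protein_id) pairs called as SSPs."""
    return {(c.species_id, c.protein_id) for c in calls if c.is_ssp}
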