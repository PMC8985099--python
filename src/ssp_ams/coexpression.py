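"""Thresholded Pearson co-expression networks and SSP rank labels.

Edges connect gene pairs whose expression profiles across an atlas correlate
with |PCC| >= 0.95 at two-sided p <= 0.05 (p from the exact t transform of r
under bivariate normality).  By default correlations are computed seed-vs-all
— the intended use is a modest set of SSP seed genes against a whole-genome
atlas — with an all-vs-all option.

SSP ranks summarize the evidence tiers for network display: rank1 SSPs sit
in ortholog groups that are both AMS-preferential and convergently
AMF-responsive; rank2 SSPs sit in at least one of the AMS-specific,
AMS-preferential, or convergent-DE groups (rank1 excluded).
"""

from __future__ import annotations

import enum
import warnings
from collections import Counter
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .ams_orthology import GroupClassification
from .expression import ConvergenceResult
from .ssp_caller import SSPCall
from .types import OrthologGroup

DEFAULT_PCC_MIN = 0.95
DEFAULT_PCC_ALPHA = 0.05


@dataclass(frozen=True)
class CoexpressionEdge:
    """An undirected co-expression edge; gene_a < gene_b lexicographically."""

    gene_a: str
    gene_b: str
    pcc: float
    p_value: float


class Rank(str, enum.Enum):
    RANK1 = "rank1"
    RANK2 = "rank2"
    NONE = "none"


@dataclass(frozen=True)
class SSPRank:
    gene_id: str
    species_id: str
    rank: Rank


def pcc_with_p(x, y) -> tuple[float, float]:
    """Pearson correlation and its two-sided p-value.

    p is derived from ``t = r * sqrt((n-2) / (1-r^2))`` with n-2 degrees of
    freedom.  Requires n >= 3 and non-constant vectors.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise ValueError("vectors must have equal length")
    if x.size < 3:
        raise ValueError("correlation p-value requires n >= 3")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("correlation is undefined for a constant vector")
    r, p = stats.pearsonr(x, y)
    return float(r), float(p)


def _pvalues_from_r(r: np.ndarray, n: int) -> np.ndarray:
    # two-sided p via the beta distribution of |r| under the null,
    # identical to the t transform but stable at |r| -> 1
    ab = n / 2.0 - 1.0
    return 2.0 * stats.beta.cdf(-np.abs(r), ab, ab, loc=-1.0, scale=2.0)


def build_network(
    atlas: pd.DataFrame,
    seeds: set[str] | list[str],
    pcc_min: float = DEFAULT_PCC_MIN,
    alpha: float = DEFAULT_PCC_ALPHA,
    all_vs_all: bool = False,
    log_transform: bool = False,
) -> list[CoexpressionEdge]:
    """Thresholded co-expression edge list from a genes x samples atlas.

    Edges are kept when ``|PCC| >= pcc_min`` and ``p <= alpha``.  Seed genes
    absent from the atlas are ignored with a warning; constant-expression
    genes cannot be correlated and never form edges.  The edge list is
    deterministic: canonically ordered pairs, sorted.
    """
    n = atlas.shape[1]
    if n < 3:
        raise ValueError("co-expression requires at least 3 atlas samples")
    seeds = sorted(set(seeds))
    missing = [s for s in seeds if s not in atlas.index]
    if missing:
        warnings.warn(f"{len(missing)} seed gene(s) absent from the atlas")
        seeds = [s for s in seeds if s in atlas.index]
    if not seeds and not all_vs_all:
        warnings.warn("empty seed set: returning an empty network")
        return []

    X = atlas.to_numpy(dtype=float)
    genes = atlas.index.to_numpy()
    sd = X.std(axis=1)
    ok = sd > 0
    Z = np.zeros_like(X)
    Z[ok] = (X[ok] - X[ok].mean(axis=1, keepdims=True)) / (
        sd[ok][:, None] * np.sqrt(n)
    )

    if all_vs_all:
        rows = np.arange(len(genes))
    else:
        pos = {g: i for i, g in enumerate(genes)}
        rows = np.array([pos[s] for s in seeds], dtype=int)

    R = Z[rows] @ Z.T  # correlations; zero rows for constant genes
    np.clip(R, -1.0, 1.0, out=R)
    P = _pvalues_from_r(R, n)

    edges: dict[tuple[str, str], CoexpressionEdge] = {}
    for i, ri in enumerate(rows):
        keep = (np.abs(R[i]) >= pcc_min) & (P[i] <= alpha) & ok & ok[ri]
        keep[ri] = False  # no self-loops
        for j in np.nonzero(keep)[0]:
            a, b = str(genes[ri]), str(genes[j])
            key = (a, b) if a < b else (b, a)
            if key not in edges:
                edges[key] = CoexpressionEdge(
                    gene_a=key[0],
                    gene_b=key[1],
                    pcc=float(R[i, j]),
                    p_value=float(P[i, j]),
                )
    return [edges[k] for k in sorted(edges)]


def seed_degrees(
    edges: list[CoexpressionEdge], seeds: set[str] | list[str]
) -> dict[str, int]:
    """Number of partners per seed gene; isolated seeds report degree 0."""
    deg = Counter()
    for e in edges:
        deg[e.gene_a] += 1
        deg[e.gene_b] += 1
    return {s: deg.get(s, 0) for s in sorted(set(seeds))}


def partners_of(edges: list[CoexpressionEdge], gene: str) -> list[str]:
    out = set()
    for e in edges:
        if e.gene_a == gene:
            out.add(e.gene_b)
        elif e.gene_b == gene:
            out.add(e.gene_a)
    return sorted(out)


def assign_ranks(
    calls: list[SSPCall],
    classifications: list[GroupClassification],
    convergence: list[ConvergenceResult],
    orthogroups: list[OrthologGroup],
) -> list[SSPRank]:
    """Assign evidence-tier ranks to every SSP gene.

    rank1: SSPs in groups that are AMS-preferential AND contain convergent
    DE SSPs.  rank2: SSPs in the union of AMS-specific, AMS-preferential and
    convergent-DE groups, minus rank1.  Non-SSP genes and SSPs outside these
    groups get ``none``.
    """
    specific = {c.group_id for c in classifications if c.ams_specific}
    preferential = {c.group_id for c in classifications if c.ams_preferential}
    convergent = {r.group_id for r in convergence}

    rank1_groups = preferential & convergent
    union_groups = specific | preferential | convergent

    member_groups: dict[tuple[str, str], set[str]] = {}
    for g in orthogroups:
        for m in g.members:
            member_groups.setdefault(m, set()).add(g.group_id)

    out = []
    for c in sorted(calls, key=lambda c: (c.species_id, c.protein_id)):
        if not c.is_ssp:
            out.append(SSPRank(c.protein_id, c.species_id, Rank.NONE))
            continue
        gids = member_groups.get((c.species_id, c.protein_id), set())
        if gids & rank1_groups:
            rank = Rank.RANK1
        elif gids & union_groups:
            rank = Rank.RANK2
        else:
            rank = Rank.NONE
        out.append(SSPRank(c.protein_id, c.species_id, rank))
    return out


def annotate_functions(
    edges: list[CoexpressionEdge],
    seeds: set[str] | list[str],
    annotation: dict[str, str],
) -> dict[str, dict[str, int]]:
    """Per-seed counts of partner genes by functional category.

    Partners missing from the annotation table are counted as ``"unknown"``.
    """
    out = {}
    for seed in sorted(set(seeds)):
        cats = Counter(
            annotation.get(p, "unknown") for p in partners_of(edges, seed)
        )
        out[seed] = dict(sorted(cats.items()))
    return out
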