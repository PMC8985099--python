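"""Differential expression and cross-species AMF-response convergence.

The built-in DE engine is deliberately simple: library-size normalization to
the median library, log2(x+1) transform, Welch t-test per gene, and
Benjamini-Hochberg FDR control.  A gene is called differentially expressed
when |log2 fold change| > 1 (strict) and adjusted p <= 0.05.  Externally
produced DE tables with the same columns are accepted interchangeably.

Convergence detection asks which ortholog groups contain SSPs that respond
to arbuscular mycorrhizal fungus in the same direction in at least two
species — the signature of convergent AMF-responsive expression.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .ssp_caller import SSPCall, ssp_gene_set
from .types import DERecord, Direction, OrthologGroup

DEFAULT_DE_ALPHA = 0.05
DEFAULT_MIN_ABS_LOG2FC = 1.0


@dataclass(frozen=True)
class ConvergenceResult:
    """One ortholog group with same-direction DE SSPs in >= min_species species."""

    group_id: str
    direction: Direction
    species_with_signal: frozenset[str]
    n_species: int
    per_species_mean_log2fc: dict[str, float]
    n_ssp_degs: int


def benjamini_hochberg(pvals) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (monotone, in [0, 1])."""
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any(np.isnan(p)) or np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def assign_direction(
    log2fc: float,
    padj: float,
    alpha: float = DEFAULT_DE_ALPHA,
    min_abs_log2fc: float = DEFAULT_MIN_ABS_LOG2FC,
) -> Direction:
    """Direction call: strict on |log2fc|, inclusive on the adjusted p."""
    if padj <= alpha and log2fc > min_abs_log2fc:
        return Direction.UP
    if padj <= alpha and log2fc < -min_abs_log2fc:
        return Direction.DOWN
    return Direction.NS


def normalize_libsize(counts: pd.DataFrame) -> pd.DataFrame:
    """Scale each sample to the median library size.

    Sensitive to composition bias when strong DE is direction-asymmetric;
    :func:`normalize_median_of_ratios` is the default for that reason.
    """
    lib = counts.sum(axis=0)
    if (lib == 0).any():
        # all-zero samples cannot be rescaled; leave them as zeros
        scale = np.where(lib > 0, np.median(lib[lib > 0]) / lib.replace(0, 1), 1.0)
    else:
        scale = np.median(lib) / lib
    return counts * scale


def normalize_median_of_ratios(counts: pd.DataFrame) -> pd.DataFrame:
    """Median-of-ratios size-factor normalization.

    Per-sample size factor = median over genes of count / geometric row
    mean, using only genes expressed in every sample — robust to a minority
    of strongly regulated genes distorting library totals.  Falls back to
    library-size scaling when no gene is expressed everywhere.
    """
    positive = (counts > 0).all(axis=1)
    if not positive.any():
        return normalize_libsize(counts)
    logc = np.log(counts.loc[positive])
    log_geo = logc.mean(axis=1)
    log_sf = (logc.sub(log_geo, axis=0)).median(axis=0)
    return counts / np.exp(log_sf)


def simple_de(
    counts: pd.DataFrame,
    conditions: list[str] | pd.Series,
    species_id: str,
    contrast_id: str,
    treatment: str = "treatment",
    control: str = "control",
    alpha: float = DEFAULT_DE_ALPHA,
    min_abs_log2fc: float = DEFAULT_MIN_ABS_LOG2FC,
    normalization: str = "median_of_ratios",
) -> list[DERecord]:
    """Two-condition differential expression on a genes x samples count matrix.

    Parameters
    ----------
    counts
        Raw counts, genes in rows, samples in columns.
    conditions
        Condition label per column, containing ``treatment`` and ``control``;
        at least two replicates of each.
    normalization
        ``"median_of_ratios"`` (default) or ``"libsize"``.

    Returns one :class:`DERecord` per gene.  log2fc is computed as
    ``log2((mean_trt + 1) / (mean_ctl + 1))`` on normalized counts; p-values
    come from Welch's t-test on log2(normalized + 1) and are BH-adjusted.
    """
    cond = np.asarray(conditions)
    if cond.size != counts.shape[1]:
        raise ValueError("conditions must match the number of sample columns")
    trt_mask = cond == treatment
    ctl_mask = cond == control
    if trt_mask.sum() < 2 or ctl_mask.sum() < 2:
        raise ValueError("simple_de requires >= 2 replicates per condition")

    if normalization == "median_of_ratios":
        norm = normalize_median_of_ratios(counts.astype(float))
    elif normalization == "libsize":
        norm = normalize_libsize(counts.astype(float))
    else:
        raise ValueError(f"unknown normalization {normalization!r}")
    logn = np.log2(norm + 1.0)
    trt = logn.loc[:, trt_mask.tolist()].to_numpy()
    ctl = logn.loc[:, ctl_mask.tolist()].to_numpy()

    mean_trt = norm.loc[:, trt_mask.tolist()].mean(axis=1).to_numpy()
    mean_ctl = norm.loc[:, ctl_mask.tolist()].mean(axis=1).to_numpy()
    log2fc = np.log2((mean_trt + 1.0) / (mean_ctl + 1.0))

    with np.errstate(divide="ignore", invalid="ignore"):
        pvals = stats.ttest_ind(trt, ctl, axis=1, equal_var=False).pvalue
    # zero variance in both groups (e.g. all-zero genes) -> NaN; no evidence
    pvals = np.where(np.isnan(pvals), 1.0, pvals)
    padj = benjamini_hochberg(pvals)

    records = []
    for gene, fc, q in zip(counts.index, log2fc, padj):
        records.append(
            DERecord(
                gene_id=str(gene),
                species_id=species_id,
                contrast_id=contrast_id,
                log2fc=float(fc),
                padj=float(q),
                direction=assign_direction(float(fc), float(q), alpha, min_abs_log2fc),
            )
        )
    return records


def de_ssp_intersect(
    de: list[DERecord], calls: list[SSPCall]
) -> list[DERecord]:
    """Restrict DE records to genes called as SSPs in the same species."""
    ssp = ssp_gene_set(calls)
    return [r for r in de if (r.species_id, r.gene_id) in ssp]


def detect_convergence(
    de_ssp: list[DERecord],
    orthogroups: list[OrthologGroup],
    min_species: int = 2,
) -> list[ConvergenceResult]:
    """Find ortholog groups with same-direction DE SSPs in >= min_species species.

    Only significant records (direction up/down) participate.  A group may
    appear once per direction.  Output order is deterministic (group id,
    then direction).
    """
    member_to_groups: dict[tuple[str, str], list[str]] = {}
    group_by_id = {}
    for g in orthogroups:
        group_by_id[g.group_id] = g
        for m in g.members:
            member_to_groups.setdefault(m, []).append(g.group_id)

    # (group, direction) -> species -> list of log2fc of DE SSP members
    signal: dict[tuple[str, Direction], dict[str, list[float]]] = {}
    for r in de_ssp:
        if r.direction is Direction.NS:
            continue
        for gid in member_to_groups.get((r.species_id, r.gene_id), ()):
            signal.setdefault((gid, r.direction), {}).setdefault(
                r.species_id, []
            ).append(r.log2fc)

    results = []
    for (gid, direction), per_sp in sorted(
        signal.items(), key=lambda kv: (kv[0][0], kv[0][1].value)
    ):
        if len(per_sp) < min_species:
            continue
        results.append(
            ConvergenceResult(
                group_id=gid,
                direction=direction,
                species_with_signal=frozenset(per_sp),
                n_species=len(per_sp),
                per_species_mean_log2fc={
                    sp: float(np.mean(v)) for sp, v in sorted(per_sp.items())
                },
                n_ssp_degs=sum(len(v) for v in per_sp.values()),
            )
        )
    return results


def convergence_matrix(results: list[ConvergenceResult]) -> pd.DataFrame:
    """Groups x species matrix of per-species mean log2fc (NaN where absent).

    Row index is ``group_id:direction`` so a group convergent in both
    directions keeps both rows.
    """
    rows = {}
    for r in results:
        rows[f"{r.group_id}:{r.direction.value}"] = r.per_species_mean_log2fc
    return pd.DataFrame.from_dict(rows, orient="index").sort_index()
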