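"""DE engine, BH adjustment, SSP intersection and convergence detection."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from ssp_ams.expression import (
    assign_direction,
    benjamini_hochberg,
    convergence_matrix,
    de_ssp_intersect,
    detect_convergence,
    normalize_median_of_ratios,
    simple_de,
)
from ssp_ams.ssp_caller import SSPCall, SSPCategory
from ssp_ams.types import DERecord, Direction, OrthologGroup


def _de(gene, sp, log2fc, padj=0.01, contrast=None):
    return DERecord(
        gene_id=gene,
        species_id=sp,
        contrast_id=contrast or f"{sp}:amf_vs_ctl",
        log2fc=log2fc,
        padj=padj,
        direction=assign_direction(log2fc, padj),
    )


def _ssp_call(gene, sp, is_ssp=True):
    cat = SSPCategory.NSS_ONLY if is_ssp else SSPCategory.NOT_SSP
    return SSPCall(gene, sp, is_ssp, cat, is_ssp, False, False)


# --- direction thresholds --------------------------------------------------

@pytest.mark.parametrize(
    "log2fc,padj,expected",
    [
        (1.0, 0.01, Direction.NS),      # strict > 1 on the fold change
        (-1.0, 0.01, Direction.NS),
        (1.01, 0.05, Direction.UP),     # inclusive <= 0.05 on padj
        (-2.0, 0.05, Direction.DOWN),
        (3.0, 0.051, Direction.NS),
        (0.0, 0.0001, Direction.NS),
    ],
)
def test_direction_boundaries(log2fc, padj, expected):
    assert assign_direction(log2fc, padj) is expected


# --- BH --------------------------------------------------------------------

def test_bh_worked_example():
    """Step-up: adj_i = min over k>=i of p_k * m / k."""
    adj = benjamini_hochberg([0.01, 0.02, 0.03, 0.04])
    assert np.allclose(adj, [0.04, 0.04, 0.04, 0.04])


def test_bh_edge_cases():
    assert benjamini_hochberg([0.3]) == pytest.approx([0.3])
    assert np.allclose(benjamini_hochberg([1.0, 1.0, 1.0]), 1.0)
    with pytest.raises(ValueError):
        benjamini_hochberg([0.5, 1.5])


@given(st.lists(st.floats(min_value=0, max_value=1), min_size=1, max_size=30))
def test_bh_preserves_order_and_range(pvals):
    adj = benjamini_hochberg(pvals)
    assert np.all((adj >= 0) & (adj <= 1))
    assert np.all(adj >= np.asarray(pvals) - 1e-12)
    order = np.argsort(pvals, kind="stable")
    assert np.all(np.diff(adj[order]) >= -1e-12)


# --- simple_de -------------------------------------------------------------

def test_identical_counts_are_ns():
    counts = pd.DataFrame(
        {"c1": [10, 0], "c2": [10, 0], "t1": [10, 0], "t2": [10, 0]},
        index=["g1", "g_zero"],
    )
    recs = simple_de(counts, ["control", "control", "treatment", "treatment"],
                     "spA", "spA:c")
    by_gene = {r.gene_id: r for r in recs}
    assert by_gene["g1"].log2fc == pytest.approx(0.0)
    assert by_gene["g1"].direction is Direction.NS
    assert by_gene["g_zero"].padj == pytest.approx(1.0)  # all-zero gene
    assert by_gene["g_zero"].direction is Direction.NS


def test_simple_de_requires_replicates():
    counts = pd.DataFrame({"c1": [1], "t1": [2]}, index=["g"])
    with pytest.raises(ValueError):
        simple_de(counts, ["control", "treatment"], "spA", "c")


def test_median_of_ratios_removes_composition_bias():
    """A few huge up-regulated genes must not drag null genes down."""
    rng = np.random.default_rng(0)
    base = rng.poisson(100, size=(50, 6)).astype(float)
    counts = pd.DataFrame(base, index=[f"g{i}" for i in range(50)],
                          columns=list("abcdef"))
    counts.iloc[:5, 3:] *= 40  # strong asymmetric DE
    norm = normalize_median_of_ratios(counts)
    null_means = norm.iloc[5:]
    ratio = null_means.iloc[:, 3:].to_numpy().mean() / null_means.iloc[:, :3].to_numpy().mean()
    assert ratio == pytest.approx(1.0, abs=0.05)


def test_planted_de_recall_and_fdr():
    """log2fc=3, 5 replicates, dispersion 0.1: recall >= 0.9, FDR <= 0.1."""
    rng = np.random.default_rng(202)
    n_genes, n_de, n_rep = 1000, 100, 5
    mu = rng.lognormal(np.log(50), 1.0, size=n_genes)
    fold = np.ones(n_genes)
    signs = np.where(rng.random(n_de) < 0.5, 1.0, -1.0)
    fold[:n_de] = 2.0 ** (3.0 * signs)
    r = 1 / 0.1
    ctl = rng.negative_binomial(r, r / (r + mu[:, None]), size=(n_genes, n_rep))
    mu_t = mu * fold
    trt = rng.negative_binomial(r, r / (r + mu_t[:, None]), size=(n_genes, n_rep))
    counts = pd.DataFrame(
        np.hstack([ctl, trt]),
        index=[f"g{i}" for i in range(n_genes)],
        columns=[f"s{i}" for i in range(2 * n_rep)],
    )
    recs = simple_de(counts, ["control"] * n_rep + ["treatment"] * n_rep, "sp", "c")
    called = {r.gene_id for r in recs if r.direction is not Direction.NS}
    truth = {f"g{i}" for i in range(n_de)}
    recall = len(called & truth) / n_de
    fdr = len(called - truth) / max(len(called), 1)
    assert recall >= 0.9
    assert fdr <= 0.1


# --- SSP intersection ------------------------------------------------------

def test_de_ssp_intersect():
    de = [_de("g1", "spA", 2.5), _de("g2", "spA", 3.0), _de("g1", "spB", 2.0)]
    calls = [_ssp_call("g1", "spA"), _ssp_call("g2", "spA", is_ssp=False)]
    kept = de_ssp_intersect(de, calls)
    assert [(r.species_id, r.gene_id) for r in kept] == [("spA", "g1")]


# --- convergence -----------------------------------------------------------

def _group(gid, pairs):
    return OrthologGroup(gid, members=set(pairs), ssp_members=set(pairs))


def test_convergence_two_species_same_direction():
    groups = [_group("OG1", [("spA", "g1"), ("spB", "g2")])]
    de = [_de("g1", "spA", 2.5), _de("g2", "spB", 3.5)]
    res = detect_convergence(de, groups, min_species=2)
    assert len(res) == 1
    r = res[0]
    assert r.direction is Direction.UP and r.n_species == 2
    assert r.per_species_mean_log2fc == {"spA": 2.5, "spB": 3.5}


def test_no_convergence_with_opposite_directions():
    groups = [_group("OG1", [("spA", "g1"), ("spB", "g2")])]
    de = [_de("g1", "spA", 2.5), _de("g2", "spB", -3.5)]
    assert detect_convergence(de, groups, min_species=2) == []


def test_group_can_converge_in_both_directions():
    groups = [_group("OG1", [("spA", "g1"), ("spB", "g2"),
                             ("spA", "g3"), ("spB", "g4")])]
    de = [_de("g1", "spA", 2.5), _de("g2", "spB", 3.5),
          _de("g3", "spA", -2.5), _de("g4", "spB", -3.5)]
    res = detect_convergence(de, groups, min_species=2)
    assert [r.direction for r in res] == [Direction.DOWN, Direction.UP]


def test_convergence_invariant_to_input_order():
    groups = [_group("OG1", [("spA", "g1"), ("spB", "g2")]),
              _group("OG2", [("spA", "g3"), ("spB", "g4")])]
    de = [_de("g1", "spA", 2.5), _de("g2", "spB", 3.5),
          _de("g3", "spA", -2.0), _de("g4", "spB", -2.0)]
    forward = detect_convergence(de, groups, min_species=2)
    backward = detect_convergence(de[::-1], groups[::-1], min_species=2)
    assert forward == backward


def test_convergence_matrix_layout():
    groups = [_group("OG1", [("spA", "g1"), ("spB", "g2")])]
    de = [_de("g1", "spA", 2.5), _de("g2", "spB", 3.5)]
    mat = convergence_matrix(detect_convergence(de, groups, min_species=2))
    assert mat.loc["OG1:up", "spA"] == pytest.approx(2.5)
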