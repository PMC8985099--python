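"""Group classification, rank-sum testing, genome-level comparisons."""

import itertools

import numpy as np
import pytest

from ssp_ams.ams_orthology import (
    SSPSource,
    classify_ssp_source,
    genome_level_tests,
    is_ams_preferential,
    is_ams_specific,
    min_ams_species,
    wilcoxon_rank_sum,
)
from ssp_ams.ssp_caller import SSPCall, SSPCategory
from ssp_ams.types import AmsStatus, Lineage, OrthologGroup, SpeciesRecord


def make_species(n_ams, n_non, lineage=Lineage.DICOT, proteome=1000):
    out = []
    for i in range(n_ams):
        out.append(SpeciesRecord(f"ams{i:02d}", AmsStatus.AMS, lineage, proteome))
    for i in range(n_non):
        out.append(SpeciesRecord(f"non{i:02d}", AmsStatus.NON_AMS, lineage, proteome))
    return out


def group_from(ssp_pairs, extra_members=()):
    members = set(ssp_pairs) | set(extra_members)
    return OrthologGroup("OG1", members=members, ssp_members=set(ssp_pairs))


# --- exact rank-sum oracle -------------------------------------------------

def enumerate_rank_sum_p(x, y, alternative):
    """Complete enumeration over all C(n1+n2, n1) assignments (no ties)."""
    pooled = sorted(list(x) + list(y))
    assert len(set(pooled)) == len(pooled), "oracle requires tie-free data"
    n1 = len(x)
    u_obs = sum(1 for xi in x for yj in y if xi > yj)
    us = []
    for subset in itertools.combinations(range(len(pooled)), n1):
        xs = [pooled[i] for i in subset]
        ys = [pooled[i] for i in range(len(pooled)) if i not in set(subset)]
        us.append(sum(1 for xi in xs for yj in ys if xi > yj))
    us = np.array(us)
    p_less = np.mean(us <= u_obs)
    p_greater = np.mean(us >= u_obs)
    if alternative == "less":
        return p_less
    if alternative == "greater":
        return p_greater
    return min(1.0, 2.0 * min(p_less, p_greater))


def test_rank_sum_textbook_example():
    """Fully separated samples of 3: one assignment in 20 is as extreme."""
    assert wilcoxon_rank_sum([1, 2, 3], [4, 5, 6], "less") == pytest.approx(1 / 20)


def test_rank_sum_identical_samples_two_sided():
    assert wilcoxon_rank_sum([1, 2, 3], [1, 2, 3], "two-sided") == pytest.approx(1.0)


def test_rank_sum_empty_sample_rejected():
    with pytest.raises(ValueError):
        wilcoxon_rank_sum([], [1.0])


@pytest.mark.parametrize("n1,n2", [(11, 3), (12, 4), (11, 5)])
def test_asymptotic_branch_close_to_exact(n1, n2):
    """Beyond the exact cutoff (max sample > 10) the continuity-corrected
    normal approximation stays within 0.02 of complete enumeration."""
    rng = np.random.default_rng(5)
    for _ in range(10):
        pool = rng.permutation(100)[: n1 + n2].astype(float)
        x, y = pool[:n1], pool[n1:]
        for alt in ("less", "greater", "two-sided"):
            p_exact = enumerate_rank_sum_p(x, y, alt)
            p_approx = wilcoxon_rank_sum(x, y, alt)  # asymptotic path
            assert abs(p_approx - p_exact) <= 0.02


# --- ssp_source ------------------------------------------------------------

def test_classify_ssp_source_cases():
    sp = make_species(2, 2)
    both = group_from([("ams00", "g1"), ("non00", "g2")])
    assert classify_ssp_source(both, sp) is SSPSource.BOTH
    ams_only = group_from([("ams00", "g1"), ("ams01", "g2")])
    assert classify_ssp_source(ams_only, sp) is SSPSource.AMS_ONLY
    no_ssp = OrthologGroup("OG1", members={("ams00", "g1")})
    assert classify_ssp_source(no_ssp, sp) is SSPSource.NO_SSP
    with pytest.raises(KeyError):
        classify_ssp_source(group_from([("mystery", "g1")]), sp)


# --- AMS specificity -------------------------------------------------------

def test_min_ams_species_is_ceiling():
    assert min_ams_species(39) == 12
    assert min_ams_species(10) == 3
    assert min_ams_species(6) == 2


@pytest.mark.parametrize("span,expected", [(12, True), (11, False)])
def test_specificity_threshold_on_39_ams_species(span, expected):
    sp = make_species(39, 21)
    pairs = [(f"ams{i:02d}", f"g{i}") for i in range(span)]
    assert is_ams_specific(group_from(pairs), sp) is expected


def test_single_non_ams_member_disqualifies():
    sp = make_species(39, 21)
    pairs = [(f"ams{i:02d}", f"g{i}") for i in range(39)]
    g = group_from(pairs, extra_members=[("non00", "gx")])
    assert is_ams_specific(g, sp) is False


def test_specificity_requires_an_ssp():
    sp = make_species(10, 5)
    g = OrthologGroup("OG1", members={(f"ams{i:02d}", f"g{i}") for i in range(10)})
    assert is_ams_specific(g, sp) is False


def test_specificity_monotone_in_membership():
    sp = make_species(10, 5)
    pairs = [(f"ams{i:02d}", f"g{i}") for i in range(2)]
    g = group_from(pairs)
    assert is_ams_specific(g, sp) is False  # ceil(0.3*10)=3 > 2
    g.members.add(("ams05", "gz"))
    assert is_ams_specific(g, sp) is True
    g.members.add(("non00", "gq"))
    assert is_ams_specific(g, sp) is False


def test_specificity_errors_without_ams_species():
    sp = make_species(0, 5)
    with pytest.raises(ValueError):
        is_ams_specific(group_from([("non00", "g")]), sp)


# --- AMS preferentiality ---------------------------------------------------

def test_preferential_maximal_separation():
    sp = make_species(5, 5)
    pairs = [(f"ams{i:02d}", f"g{i}_{j}") for i in range(5) for j in range(5)]
    pairs += [("non00", "gn")]  # SSPs from both classes required
    flag, p = is_ams_preferential(group_from(pairs), sp)
    assert flag and p <= 0.05


def test_preferential_untestable_without_both_classes():
    sp = make_species(5, 5)
    flag, p = is_ams_preferential(group_from([("ams00", "g")]), sp)
    assert flag is False and p is None


def test_preferential_absent_species_counted_as_zero():
    sp = make_species(6, 6)
    pairs = [(f"ams{i:02d}", f"g{i}") for i in range(6)] + [("non00", "gn")]
    g = group_from(pairs)
    _, p_all = is_ams_preferential(g, sp, include_absent_species=True)
    _, p_present = is_ams_preferential(g, sp, include_absent_species=False)
    assert p_all != p_present  # zeros for absent species change the test


# --- genome-level tests ----------------------------------------------------

def _calls_for(species, counts):
    calls = []
    for sp, n in zip(species, counts):
        for i in range(n):
            calls.append(
                SSPCall(f"{sp.species_id}_p{i}", sp.species_id, True,
                        SSPCategory.NSS_ONLY, True, False, False)
            )
    return calls


def test_genome_tests_detect_extreme_difference():
    sp = make_species(5, 5)
    calls = _calls_for(sp, [100] * 5 + [1] * 5)
    results = genome_level_tests(calls, sp)
    overall = {(r.metric, r.stratum): r for r in results}
    count_all = overall[("SSP_COUNT", "all")]
    assert count_all.p_value < 0.05
    assert count_all.direction == "AMS>non-AMS"


def test_ratio_equals_count_for_equal_proteomes():
    sp = make_species(4, 4, proteome=5000)
    rng = np.random.default_rng(3)
    calls = _calls_for(sp, list(rng.integers(10, 200, size=8)))
    res = {(r.metric, r.stratum): r for r in genome_level_tests(calls, sp)}
    assert res[("SSP_COUNT", "all")].p_value == pytest.approx(
        res[("SSP_RATIO", "all")].p_value
    )


def test_small_stratum_is_skipped_with_reason():
    sp = make_species(3, 1)
    res = genome_level_tests(_calls_for(sp, [5, 5, 5, 5]), sp)
    skipped = [r for r in res if r.direction == "skipped"]
    assert skipped and all(r.skipped_reason for r in skipped)


def test_null_rarely_significant():
    """Identical count distributions: no finding in >= 90% of replicates."""
    rng = np.random.default_rng(11)
    sp = make_species(10, 10)
    hits = 0
    n_rep = 50
    for _ in range(n_rep):
        counts = list(rng.poisson(100, size=20))
        res = {(r.metric, r.stratum): r for r in genome_level_tests(_calls_for(sp, counts), sp)}
        if res[("SSP_COUNT", "all")].p_value <= 0.05:
            hits += 1
    assert hits <= 0.10 * n_rep
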