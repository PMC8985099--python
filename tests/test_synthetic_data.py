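"""Generator: determinism, planted-structure consistency, noiseless recovery."""

import numpy as np
import pytest

from conftest import small_sim_config
from ssp_ams.ams_orthology import min_ams_species
from ssp_ams.ssp_caller import call_all
from ssp_ams.synthetic_data import (
    GroundTruth,
    SimConfig,
    SimConfigError,
    de_species_ids,
    generate_all,
    generate_predictions,
    generate_species,
)
from ssp_ams.types import AmsStatus


def test_species_split_round():
    cfg = small_sim_config(n_species=10, frac_ams=0.5)
    species = generate_species(cfg)
    assert sum(s.is_ams for s in species) == 5
    assert len(species) == 10


def test_species_split_study_scale():
    cfg = SimConfig(n_species=60, frac_ams=0.65)
    species = generate_species(cfg)
    assert sum(s.is_ams for s in species) == 39
    assert sum(not s.is_ams for s in species) == 21


def test_determinism_same_seed():
    cfg = small_sim_config(rng_seed=33)
    a = generate_all(cfg)
    b = generate_all(small_sim_config(rng_seed=33))
    assert a.species == b.species
    assert a.predictions == b.predictions
    assert [(g.group_id, sorted(g.members)) for g in a.orthogroups] == [
        (g.group_id, sorted(g.members)) for g in b.orthogroups
    ]
    assert a.atlas.equals(b.atlas)
    for sp in a.counts:
        assert a.counts[sp][0].equals(b.counts[sp][0])
    assert a.truth.to_json_dict() == b.truth.to_json_dict()


def test_different_seed_differs():
    a = generate_all(small_sim_config(rng_seed=1))
    b = generate_all(small_sim_config(rng_seed=2))
    assert not a.atlas.equals(b.atlas)


def test_no_true_ssps_when_fraction_zero():
    cfg = small_sim_config(
        frac_true_ssp=0.0, n_planted_specific=0, n_planted_preferential=0,
        n_planted_convergent_up=0, n_planted_convergent_down=0,
        n_planted_modules=0,
    )
    species = generate_species(cfg)
    _, truth = generate_predictions(cfg, species)
    assert truth.true_ssp_ids == set()


@pytest.mark.parametrize(
    "field,value",
    [("frac_ams", 1.5), ("n_species", 0), ("nb_dispersion", 0.0),
     ("proteins_per_species", (10, 5)), ("n_atlas_samples", 2),
     ("planted_module_size", 1)],
)
def test_invalid_config_names_offending_field(field, value):
    cfg = small_sim_config(**{field: value})
    with pytest.raises(SimConfigError) as err:
        cfg.validate()
    assert field in str(err.value)


def test_planting_infeasible_without_ams_species():
    cfg = small_sim_config(frac_ams=0.0)
    with pytest.raises(SimConfigError):
        generate_all(cfg)


def test_planted_specific_predicate_by_direct_recount(strong_small_dataset):
    """Each planted specific group satisfies its defining predicate."""
    ds = strong_small_dataset
    idx = {s.species_id: s for s in ds.species}
    n_ams = sum(1 for s in ds.species if s.is_ams)
    need = min_ams_species(n_ams)
    by_id = {g.group_id: g for g in ds.orthogroups}
    assert ds.truth.planted_specific_groups
    for gid in ds.truth.planted_specific_groups:
        g = by_id[gid]
        assert all(idx[sp].is_ams for sp, _ in g.members)
        assert all(m in ds.truth.true_ssp_ids for m in g.members)
        assert len({sp for sp, _ in g.members}) >= need


def test_planted_preferential_predicate_by_direct_recount(strong_small_dataset):
    ds = strong_small_dataset
    idx = {s.species_id: s for s in ds.species}
    by_id = {g.group_id: g for g in ds.orthogroups}
    assert ds.truth.planted_preferential_groups
    for gid in ds.truth.planted_preferential_groups:
        g = by_id[gid]
        ssp_sp = {sp for m in g.members if m in ds.truth.true_ssp_ids
                  for sp in [m[0]]}
        assert any(idx[sp].is_ams for sp in ssp_sp)
        assert any(not idx[sp].is_ams for sp in ssp_sp)
        # every AMS species contributes at least one member
        assert {s.species_id for s in ds.species if s.is_ams} <= {
            sp for sp, _ in g.members
        }


def test_planted_convergent_groups_span_two_contrast_species(strong_small_dataset):
    ds = strong_small_dataset
    de_sp = set(de_species_ids(ds.config, ds.species))
    by_id = {g.group_id: g for g in ds.orthogroups}
    planted = ds.truth.planted_convergent
    assert planted["up"] and planted["down"]
    for direction, gids in planted.items():
        for gid in gids:
            members = by_id[gid].members
            sp_with_signal = set()
            for contrast, pairs in ds.truth.planted_de.items():
                sp = contrast.split(":")[0]
                if any(d == direction and (sp, gene) in members for gene, d in pairs):
                    sp_with_signal.add(sp)
            assert len(sp_with_signal & de_sp) >= 2


def test_noiseless_caller_recovers_truth_exactly(strong_small_dataset):
    """Perfect tools: consensus calls equal the latent SSP set."""
    ds = strong_small_dataset
    calls = call_all(ds.predictions)
    called = {(c.species_id, c.protein_id) for c in calls if c.is_ssp}
    assert called == ds.truth.true_ssp_ids


def test_noisy_recovery_f1_matches_independent_oracle(small_dataset):
    """F1 vs truth computed through an independently coded consensus."""
    from test_ssp_caller import flowchart_oracle
    from ssp_ams.ssp_caller import SSPCategory

    ds = small_dataset
    calls = call_all(ds.predictions)
    called = {(c.species_id, c.protein_id) for c in calls if c.is_ssp}
    oracle_called = {
        (p.species_id, p.protein_id)
        for p in ds.predictions
        if flowchart_oracle(p) is not SSPCategory.NOT_SSP
    }
    assert called == oracle_called

    def f1(found):
        tp = len(found & ds.truth.true_ssp_ids)
        prec = tp / len(found)
        rec = tp / len(ds.truth.true_ssp_ids)
        return 2 * prec * rec / (prec + rec)

    assert f1(called) == pytest.approx(f1(oracle_called))
    assert f1(called) > 0.8  # 0.9/0.95 tools remain informative


def test_background_correlation_tail_matches_analytic_null(small_dataset):
    """Background atlas pairs: P(|r| >= c) matches the beta-tail estimate."""
    from scipy import stats

    ds = small_dataset
    module_genes = set().union(*ds.truth.planted_coexpr_modules)
    bg = ds.atlas.loc[[g for g in ds.atlas.index if g not in module_genes]]
    X = bg.to_numpy()
    n = X.shape[1]
    Z = (X - X.mean(1, keepdims=True)) / (X.std(1, keepdims=True) * np.sqrt(n))
    rng = np.random.default_rng(4)
    idx = rng.permutation(len(Z))
    half = len(idx) // 2
    r = np.sum(Z[idx[:half]] * Z[idx[half : 2 * half]], axis=1)
    c = 0.5
    ab = n / 2 - 1
    p_true = 2 * stats.beta.cdf(-c, ab, ab, loc=-1, scale=2)
    obs = np.mean(np.abs(r) >= c)
    se = np.sqrt(p_true * (1 - p_true) / half)
    assert abs(obs - p_true) <= 4 * se + 1e-9


def test_atlas_samples_gate():
    with pytest.raises(SimConfigError):
        small_sim_config(n_atlas_samples=2).validate()


def test_ground_truth_json_round_trip(small_dataset):
    d = small_dataset.truth.to_json_dict()
    back = GroundTruth.from_json_dict(d)
    assert back.to_json_dict() == d
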