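"""Synthetic-data generator: reproducibility, structure, ground truth."""

import numpy as np
import pandas as pd
import pytest

from extirpa.records import CodingRules, SpeciesFlags, parse_records, summarize_by_period
from extirpa.status import census
from extirpa.synth import (CommunityConfig, assign_families,
                           simulate_community_records, simulate_cryptic_accumulation,
                           simulate_extinction, simulate_phylogeny,
                           simulate_trait_suite)


class TestPhylogenySim:
    def test_tip_count_and_labels(self):
        t = simulate_phylogeny(12, seed=1)
        assert t.n_tips == 12
        assert len(set(t.tip_labels)) == 12

    def test_three_tips_minimal_tree(self):
        t = simulate_phylogeny(3, seed=2)
        assert t.n_tips == 3 and t.is_bifurcating

    def test_same_seed_identical_newick(self):
        a = simulate_phylogeny(20, seed=5).to_newick()
        b = simulate_phylogeny(20, seed=5).to_newick()
        assert a == b

    def test_depth_rescaled_to_age(self):
        t = simulate_phylogeny(30, seed=6, age=75.0)
        depth = max(lf.distance_from_root() for lf in t._tree.leaf_node_iter())
        # terminal branches are floored at 0.005*age, so the depth may
        # exceed the target by at most that much
        assert 75.0 <= depth <= 75.0 * 1.005 + 1e-9

    def test_invalid_rates_error(self):
        with pytest.raises(ValueError):
            simulate_phylogeny(10, model="birth-death", birth_rate=1.0,
                               death_rate=2.0, seed=1)
        with pytest.raises(ValueError):
            simulate_phylogeny(2, seed=1)

    def test_yule_lineage_accumulation_roughly_exponential(self):
        # log lineage-through-time approximately linear in time for pure birth
        t = simulate_phylogeny(200, seed=7, age=100.0)
        times = sorted(nd.distance_from_root()
                       for nd in t._tree.preorder_internal_node_iter())
        k = np.arange(2, len(times) + 2)
        slope = np.polyfit(times, np.log(k), 1)[0]
        assert slope > 0
        r2 = np.corrcoef(times, np.log(k))[0, 1] ** 2
        assert r2 > 0.9


class TestTraitSim:
    def test_zero_change_rate_constant_traits(self):
        t = simulate_phylogeny(40, seed=8)
        traits = simulate_trait_suite(t, seed=9, change_rate=0.0)
        for col in ("host_specificity", "growth_form", "geographic_range",
                    "color_category"):
            assert traits[col].nunique() == 1

    def test_levels_within_declared_ranges(self):
        t = simulate_phylogeny(60, seed=10)
        traits = simulate_trait_suite(t, seed=11)
        assert traits["host_specificity"].between(1, 3).all()
        assert traits["growth_form"].between(1, 4).all()
        assert traits["color_category"].between(1, 9).all()
        assert (traits["wing_size"] > 0).all()

    def test_wing_size_divergence_grows_with_patristic_distance(self):
        t = simulate_phylogeny(80, seed=12)
        traits = simulate_trait_suite(t, seed=13)
        d = t.patristic_matrix()
        logs = np.log(traits["wing_size"])
        iu = np.triu_indices(80, 1)
        sq = (logs.to_numpy()[:, None] - logs.to_numpy()[None, :]) ** 2
        slope = np.polyfit(d.to_numpy()[iu], sq[iu], 1)[0]
        assert slope > 0

    def test_reproducible(self):
        t = simulate_phylogeny(25, seed=14)
        a = simulate_trait_suite(t, seed=15)
        b = simulate_trait_suite(t, seed=15)
        pd.testing.assert_frame_equal(a, b)


class TestExtinctionSim:
    def test_reproducible_and_nondegenerate(self):
        t = simulate_phylogeny(100, seed=16)
        traits = simulate_trait_suite(t, seed=17)
        a = simulate_extinction(t, traits, seed=18)
        b = simulate_extinction(t, traits, seed=18)
        assert a.equals(b)
        assert 0 < a.sum() < len(a)

    def test_strong_size_effect_selects_small_species(self):
        t = simulate_phylogeny(300, seed=19)
        traits = simulate_trait_suite(t, seed=20)
        flags = simulate_extinction(
            t, traits, beta={"wing_size": -0.4}, intercept=-1.0, seed=21)
        extinct_size = traits.loc[flags == 1, "wing_size"].mean()
        extant_size = traits.loc[flags == 0, "wing_size"].mean()
        assert extinct_size < extant_size


@pytest.fixture(scope="module")
def community():
    tree = simulate_phylogeny(200, seed=22)
    traits = simulate_trait_suite(tree, seed=23)
    flags = simulate_extinction(tree, traits, seed=24)
    cfg = CommunityConfig(n_species=200, effort_old=700, effort_recent=3600,
                          effort_between=200)
    records, truth = simulate_community_records(tree, flags, cfg, seed=25)
    return tree, flags, cfg, records, truth


class TestCommunityRecords:
    def test_extinct_species_never_recorded_recently(self, community):
        _, flags, _, records, truth = community
        recent = records[records["dataset"] == "monitoring"]
        extinct = set(flags[flags == 1].index)
        assert set(recent["species_id"]) & extinct == set()
        assert (truth.n_recent[list(extinct)] == 0).all()

    def test_reproducible(self, community):
        tree, flags, cfg, records, _ = community
        again, _ = simulate_community_records(tree, flags, cfg, seed=25)
        pd.testing.assert_frame_equal(records, again)

    def test_effort_totals_without_text_coding(self):
        tree = simulate_phylogeny(120, seed=26)
        traits = simulate_trait_suite(tree, seed=27)
        flags = simulate_extinction(tree, traits, seed=28)
        cfg = CommunityConfig(n_species=120, effort_old=500, effort_recent=2500,
                              effort_between=100, abundance_text_fraction=0.0)
        _, truth = simulate_community_records(tree, flags, cfg, seed=29)
        assert int(truth.n_old.sum()) == 500
        assert int(truth.n_recent.sum()) == 2500
        assert int(truth.n_between.sum()) == 100

    def test_classifier_recovers_ground_truth_categories(self, community):
        _, _, _, records, truth = community
        rules = CodingRules(fixed_years={"smallcoll": 1974})
        parsed = parse_records(records, rules)
        assert parsed.n_rejected == 0
        sf = {s: SpeciesFlags(is_cryptic=truth.roles[s] == "cryptic",
                              described_after_1943=truth.roles[s] == "recently_described")
              for s in truth.roles.index if truth.true_category[s] != 0}
        cen = census(summarize_by_period(parsed.records, species_flags=sf))
        for sid, cat in cen.assignments.items():
            assert int(cat) == truth.true_category[sid], sid

    def test_designed_extinct_species_recovered(self, community):
        _, flags, _, records, truth = community
        rules = CodingRules(fixed_years={"smallcoll": 1974})
        cen = census(summarize_by_period(parse_records(records, rules).records))
        designed = [s for s in flags[flags == 1].index if truth.n_old[s] >= 10]
        recovered = set(cen.species_in(9))
        assert set(designed) <= recovered


class TestCrypticAccumulation:
    def test_monotone_and_bounded(self):
        x, y = simulate_cryptic_accumulation(27, 800, seed=30)
        assert np.all(np.diff(y) >= 0)
        assert y[-1] <= 27
        assert len(x) == 800 and x[-1] == 800

    def test_plateaus_at_total_for_many_draws(self):
        _, y = simulate_cryptic_accumulation(10, 60000, seed=31, logseries_p=0.5)
        assert y[-1] == 10

    def test_same_seed_identical(self):
        a = simulate_cryptic_accumulation(15, 300, seed=32)
        b = simulate_cryptic_accumulation(15, 300, seed=32)
        assert np.array_equal(a[1], b[1])

    def test_zero_draws_error(self):
        with pytest.raises(ValueError):
            simulate_cryptic_accumulation(10, 0, seed=1)


def test_assign_families_covers_all_tips():
    tree = simulate_phylogeny(90, seed=33)
    fam = assign_families(tree, n_families=6)
    assert set(fam.index) == set(tree.tip_labels)
    assert fam.str.startswith("fam").all()
    assert 2 <= fam.nunique() <= 6
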