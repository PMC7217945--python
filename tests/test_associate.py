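"""Representative selection, category assignment, networks, R maps."""

import numpy as np
import pytest

from faupa import (
    CATEGORIES,
    build_networks,
    classify_faupas,
    correlation_map,
    select_representatives,
)
from faupa.detect import FAUPA


def _faupa_from_ideal(fid, ideal, scale=1.0, noise=None):
    ts = scale * ideal.values.copy()
    if noise is not None:
        ts = ts + noise
    return FAUPA(id=fid, voxels=((fid, 0, 0),), mean_ts=ts, homogeneity=1.0)


@pytest.fixture(scope="module")
def ideal_faupas(ideals):
    """One FAUPA per category whose series equals that category's ideal."""
    return [
        _faupa_from_ideal(i + 1, ideals[cat]) for i, cat in enumerate(CATEGORIES)
    ]


class TestSelectRepresentatives:
    def test_exact_matches_selected_with_r_one(self, ideal_faupas, ideals):
        reps = select_representatives(ideal_faupas, ideals)
        for i, cat in enumerate(CATEGORIES):
            assert reps[cat].faupa_id == i + 1
            assert reps[cat].r_to_ideal == pytest.approx(1.0, abs=1e-12)
            assert not reps[cat].below_validation

    def test_noise_faupas_selected_but_flagged(self, ideals):
        rng = np.random.default_rng(0)
        faupas = [
            FAUPA(id=i, voxels=((i, 0, 0),),
                  mean_ts=rng.standard_normal(288), homogeneity=1.0)
            for i in range(1, 4)
        ]
        with pytest.warns(UserWarning, match="matches its ideal"):
            reps = select_representatives(faupas, ideals)
        assert all(reps[cat].below_validation for cat in CATEGORIES)

    def test_empty_faupa_list_rejected(self, ideals):
        with pytest.raises(ValueError):
            select_representatives([], ideals)


class TestClassify:
    def test_noiseless_cohort_fully_recovered(self, ideal_faupas, ideals):
        reps = select_representatives(ideal_faupas, ideals)
        assignments = classify_faupas(ideal_faupas, reps, ideal_responses=ideals)
        for a, cat in zip(assignments, CATEGORIES):
            assert a.category == cat
            assert a.r_to_representative == pytest.approx(1.0, abs=1e-12)

    def test_scaled_copy_joins_its_representative(self, ideal_faupas, ideals):
        """Correlation is scale-invariant, so a half-amplitude copy of the FT
        response is still an FT FAUPA."""
        reps = select_representatives(ideal_faupas, ideals)
        copy = _faupa_from_ideal(99, ideals[("FT",)], scale=0.5)
        (a,) = classify_faupas([copy], reps)
        assert a.category == ("FT",)
        assert a.r_to_representative == pytest.approx(1.0, abs=1e-12)

    def test_white_noise_faupa_unassigned(self, ideal_faupas, ideals):
        rng = np.random.default_rng(1)
        reps = select_representatives(ideal_faupas, ideals)
        noise = FAUPA(id=50, voxels=((5, 5, 5),),
                      mean_ts=rng.standard_normal(288), homogeneity=1.0)
        (a,) = classify_faupas([noise], reps)
        assert a.category is None
        assert abs(a.r_to_representative) < 0.8

    def test_threshold_exclusivity_of_category_regressors(self, ideal_faupas, ideals):
        """The maximum inter-category ideal correlation (~0.774) is below the
        0.8 threshold, so an exact category regressor is never captured by a
        different category's representative."""
        reps = select_representatives(ideal_faupas, ideals)
        for cat in CATEGORIES:
            probe = _faupa_from_ideal(60, ideals[cat])
            (a,) = classify_faupas([probe], reps)
            assert a.category == cat

    def test_multi_assign_mode_returns_per_category_rows(self, ideal_faupas, ideals):
        reps = select_representatives(ideal_faupas, ideals)
        probe = _faupa_from_ideal(70, ideals[("WR", "PV", "FT")])
        rows = classify_faupas([probe], reps, r_threshold=0.7, multi_assign=True)
        cats = {r.category for r in rows}
        # above 0.7 the triple correlates with all three pairs (~0.77)
        assert ("WR", "PV", "FT") in cats
        assert len(cats) >= 3


class TestNetworks:
    def test_each_network_collects_four_categories(self, ideal_faupas, ideals):
        reps = select_representatives(ideal_faupas, ideals)
        assignments = classify_faupas(ideal_faupas, reps)
        nets = build_networks(assignments)
        for task in ("WR", "PV", "FT"):
            assert len(nets[task].members) == 4
            assert nets[task].size == 4
            for cat in nets[task].members:
                assert task in cat

    def test_only_triple_assignments_make_identical_networks(self, ideal_faupas,
                                                             ideals):
        reps = select_representatives(ideal_faupas, ideals)
        triple = [f for f, c in zip(ideal_faupas, CATEGORIES)
                  if c == ("WR", "PV", "FT")]
        nets = build_networks(classify_faupas(triple, reps))
        ids = [nets[t].faupa_ids for t in ("WR", "PV", "FT")]
        assert ids[0] == ids[1] == ids[2] != []

    def test_no_assignments_give_empty_networks(self):
        nets = build_networks([])
        assert all(net.size == 0 for net in nets.values())


class TestCorrelationMap:
    def test_planted_region_survives_threshold(self, three_region_pct,
                                               three_region_noiseless, ideals):
        """With an FT ideal reference on noiseless data, exactly the planted
        FT voxels exceed R > 0.45."""
        ft_region = three_region_noiseless.truth[0]
        assert ft_region.category == ("FT",)
        rmap, act = correlation_map(three_region_pct, ideals[("FT",)].values)
        got = {tuple(v) for v in np.argwhere(act)}
        assert got == set(ft_region.voxels)
        for v in ft_region.voxels:
            assert rmap[v] > 0.9

    def test_self_reference_gives_r_one(self, three_region_pct):
        v = (2, 2, 2)
        rmap, act = correlation_map(three_region_pct, three_region_pct.data[v])
        assert rmap[v] == pytest.approx(1.0, abs=1e-10)
        assert act[v]

    def test_faupa_and_ideal_references_agree_on_noiseless_data(
        self, three_region_pct, three_region_noiseless, ideals
    ):
        """The empirical-reference map and the model-reference map select
        the same voxels when the data contain no noise."""
        ft_region = three_region_noiseless.truth[0]
        ft_ts = three_region_pct.data[ft_region.voxels[0]]
        _, act_faupa = correlation_map(three_region_pct, ft_ts)
        _, act_ideal = correlation_map(three_region_pct, ideals[("FT",)].values)
        inter = np.logical_and(act_faupa, act_ideal).sum()
        union = np.logical_or(act_faupa, act_ideal).sum()
        assert inter / union >= 0.9

    def test_zero_variance_reference_rejected(self, three_region_pct):
        with pytest.raises(ValueError):
            correlation_map(three_region_pct, np.ones(288))
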