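"""Group partitioning, feedback-model fits, and AIC/BIC selection."""

import math

import numpy as np
import pytest

from toh_feedback import (
    AgentSpec,
    FeatureMap,
    generate_irl_dataset,
    partition_groups,
)
from toh_feedback.models import (
    ModelFit,
    fit_all_models,
    fit_model,
    group_feedback,
    modified_policy,
    select_model,
)
from toh_feedback.trajectories import Trajectory


@pytest.fixture(scope="module")
def group_data(graph4):
    spec = AgentSpec(
        model_id=2, k_true=1.0, beta0=3.0, eta=0.0,
        theta_override=(("0012", 0.75), ("1110", 1.0), ("1112", 1.25), ("2212", 0.75)),
    )
    trajs = generate_irl_dataset(graph4, "1112", 20, seed=21, spec=spec, condition=2)
    return trajs, partition_groups(trajs, graph4)


class TestPartition:
    def test_groups_are_keyed_by_target_subtriangle(self, group_data, graph4):
        trajs, part = group_data
        assert set(part.groups) <= {
            (t, i) for t in ("T2", "T3") for i in (1, 2, 3)
        }
        grp = part.groups[("T2", 3)]
        assert grp.designated_target == "1112"
        assert grp.n_trajectories + grp.n_dropped == len(trajs)

    def test_truncation_stops_at_first_entry(self, group_data, graph4):
        from toh_feedback import subtriangle_of

        _, part = group_data
        for grp in part.groups.values():
            for path in grp.paths:
                assert subtriangle_of(path[-1]) == grp.key
                assert all(subtriangle_of(s) != grp.key for s in path[:-1])

    def test_truncation_length_rule(self, graph4):
        # path enters the target sub-triangle at its 4th state
        traj = Trajectory(
            participant_id="p", condition=2, task="train4", trial=1,
            target="0022", path=["0000", "2000", "2100", "2122", "0122"],
            feedback=[None] * 4, success=False,
        )
        part = partition_groups([traj], graph4)
        (grp,) = part.groups.values()
        assert grp.paths == [["0000", "2000", "2100", "2122"]]

    def test_start_triangle_target_rejected(self, graph4):
        bad = Trajectory(
            participant_id="p", condition=1, task="train4", trial=1,
            target="1100", path=["0000"], feedback=[], success=False,
        )
        with pytest.raises(ValueError):
            partition_groups([bad], graph4)

    def test_never_entering_trajectories_are_dropped_and_counted(self, graph4):
        stay = Trajectory(
            participant_id="p", condition=1, task="train4", trial=1,
            target="0022", path=["0000", "1000", "0000"],
            feedback=[None] * 2, success=False,
        )
        part = partition_groups([stay], graph4)
        assert part.n_dropped == 1
        assert part.groups[("T2", 2)].paths == []


class TestModelFits:
    def test_parameter_counts_per_feature_family(self, group_data, sparse8, graph4):
        _, part = group_data
        grp = part.groups[("T2", 3)]
        fits = fit_all_models(grp, sparse8, lambda_grid=(0.2,))
        assert [f.p for f in fits] == [8, 9, 9, 1]
        all_states = FeatureMap.all_states(graph4)
        f1 = fit_model(grp, 1, all_states, lambda_grid=(0.2,))
        assert f1.p == 81

    def test_information_criteria_reproduce_from_stored_fields(self, group_data, sparse8):
        _, part = group_data
        grp = part.groups[("T2", 3)]
        f = fit_model(grp, 2, sparse8, lambda_grid=(0.2,))
        obj = f.to_json_obj()
        assert obj["AIC"] == (2 * obj["p"] - 2 * obj["logL"]) / obj["o"]
        assert obj["BIC"] == (obj["p"] * math.log(obj["o"]) - 2 * obj["logL"]) / obj["o"]
        assert f.o == grp.n_obs

    def test_nested_model_2_dominates_model_1(self, group_data, sparse8):
        _, part = group_data
        grp = part.groups[("T2", 3)]
        fits = fit_all_models(grp, sparse8, lambda_grid=(0.2,))
        assert fits[1].logL >= fits[0].logL - 1e-9

    def test_cv_over_model_grid_runs(self, group_data, sparse8):
        _, part = group_data
        grp = part.groups[("T2", 3)]
        f = fit_model(grp, 4, sparse8, lambda_grid=(0.0, 0.5), folds=5)
        assert len(f.cv_table) == 2
        assert f.best_lambda in (0.0, 0.5)

    def test_empty_group_rejected(self, sparse8, graph4):
        from toh_feedback.models import Group

        empty = Group(triangle="T2", index=1, designated_target="1102")
        with pytest.raises(ValueError):
            fit_model(empty, 1, sparse8, lambda_grid=(0.2,))


class TestModifiedPolicy:
    def test_zero_gain_matches_reward_only_policy(self, graph4, sparse8):
        H = group_feedback(
            type("G", (), {"designated_target": "1112", "key": ("T2", 3)})(), graph4
        )
        theta = np.array([0.2, 0.0, 0.9, 0.0, 0.5, 0.1, 0.0, 0.0])
        p1 = modified_policy(1, graph4, sparse8, theta, 0.0, H)
        p2 = modified_policy(2, graph4, sparse8, theta, 0.0, H)
        assert np.allclose(p1, p2, atol=1e-8)

    def test_rows_are_distributions(self, graph4, sparse8):
        H = group_feedback(
            type("G", (), {"designated_target": "2221", "key": ("T3", 3)})(), graph4
        )
        pol = modified_policy(3, graph4, sparse8, np.ones(8) * 0.3, 0.8, H)
        assert np.allclose(pol.sum(axis=1), 1.0, atol=1e-10)


class TestSelection:
    def _fit(self, mid, logL, p, key=("T2", 3)):
        return ModelFit(
            model_id=mid, group_key=key, theta=np.zeros(0), k=None,
            logL=logL, p=p, o=100, best_lambda=0.0,
        )

    def test_equal_likelihood_prefers_fewer_parameters(self):
        fits = [self._fit(1, -50.0, 8), self._fit(4, -50.0, 1)]
        sel = select_model(fits)
        assert sel["aic_winner"] == 4 and sel["bic_winner"] == 4

    def test_fixed_p_orderings_agree(self):
        fits = [self._fit(2, -40.0, 9), self._fit(3, -45.0, 9)]
        sel = select_model(fits)
        assert sel["aic_ranking"] == sel["bic_ranking"] == [2, 3]
        assert sel["criteria_agree"]

    def test_mixed_groups_rejected(self):
        with pytest.raises(ValueError):
            select_model([self._fit(1, -50.0, 8), self._fit(2, -40.0, 9, key=("T3", 1))])

    def test_single_fit_rejected(self):
        with pytest.raises(ValueError):
            select_model([self._fit(1, -50.0, 8)])
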