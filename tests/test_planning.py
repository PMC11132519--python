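"""Optimal values, evaluative feedback, and the scoring formulas."""

import numpy as np
import pytest

from toh_feedback.planning import (
    InconsistentRecordError,
    ScoreRecord,
    TaskMdp,
    feedback_array,
    feedback_for_move,
    move_budget,
    percent_score,
    score,
    score_trajectory,
    solve,
)
from toh_feedback.trajectories import Trajectory


class TestValueIteration:
    def test_matches_closed_form_at_half_discount(self, graph4):
        vt = solve(TaskMdp(graph=graph4, target="2201", gamma=0.5))
        for s in graph4.states:
            assert vt.V[s] == pytest.approx(0.5 ** vt.dist[s] / 0.5, abs=1e-9)
        # distance 2 from the target: V = gamma^2/(1-gamma) = 0.5
        two_away = next(s for s in graph4.states if vt.dist[s] == 2)
        assert vt.V[two_away] == pytest.approx(0.5)

    def test_target_value_is_the_unique_maximum(self, graph4):
        vt = solve(TaskMdp(graph=graph4, target="0012"))
        assert max(vt.V, key=vt.V.get) == "0012"

    @pytest.mark.parametrize("n,targets", [(3, ["221", "012"]), (4, ["1122", "0021"])])
    def test_value_ordering_reverses_distance_ordering(self, n, targets):
        from toh_feedback import build_graph

        g = build_graph(n)
        for target in targets:
            vt = solve(TaskMdp(graph=g, target=target))
            by_v = sorted(g.states, key=lambda s: -vt.V[s])
            dists = [vt.dist[s] for s in by_v]
            assert dists == sorted(dists)

    def test_greedy_policy_is_optimal(self, graph4):
        rng = np.random.default_rng(7)
        non_start = [s for s in graph4.states if s != "0000"]
        for target in rng.choice(non_start, size=5, replace=False):
            vt = solve(TaskMdp(graph=graph4, target=str(target)))
            s, steps = "0000", 0
            while s != target and steps < 100:
                s = max(graph4.neighbors(s), key=lambda t: vt.V[t])
                steps += 1
            assert steps == vt.dist["0000"]

    def test_bad_tolerance_rejected(self, graph4):
        with pytest.raises(ValueError):
            solve(TaskMdp(graph=graph4, target="0012"), tol=0.0)


class TestFeedback:
    def test_shortest_path_moves_are_all_good(self, graph4):
        import networkx as nx

        vt = solve(TaskMdp(graph=graph4, target="2212"))
        path = nx.shortest_path(graph4.nx_graph, "0000", "2212")
        for a, b in zip(path, path[1:]):
            assert feedback_for_move(vt, a, b) == 1

    def test_bridge_crossing_toward_t2_target_is_good(self, graph4):
        vt = solve(TaskMdp(graph=graph4, target="0012"))
        assert feedback_for_move(vt, "1110", "1112") == 1

    def test_equidistant_neighbours_exist_and_score_bad(self, graph4):
        vt = solve(TaskMdp(graph=graph4, target="0012"))
        ties = [
            (a, b)
            for a, b in graph4.nx_graph.edges
            if vt.dist[a] == vt.dist[b]
        ]
        assert ties, "odd cycles guarantee equidistant adjacent pairs"
        a, b = ties[0]
        assert feedback_for_move(vt, a, b) == -1
        assert feedback_for_move(vt, b, a) == -1

    def test_non_adjacent_pair_rejected(self, graph4):
        vt = solve(TaskMdp(graph=graph4, target="0012"))
        with pytest.raises(ValueError):
            feedback_for_move(vt, "0000", "0012")

    def test_feedback_array_matches_pairwise_signs(self, graph4, arrays4):
        vt = solve(TaskMdp(graph=graph4, target="1121"))
        H = feedback_array(vt)
        for i, s in enumerate(arrays4.states[::7]):
            si = arrays4.index[s]
            for a in range(3):
                if arrays4.mask[si, a]:
                    nxt = arrays4.states[arrays4.nbr[si, a]]
                    assert H[si, a] == feedback_for_move(vt, s, nxt)


class TestScoring:
    @pytest.mark.parametrize("m_min,budget", [(15, 23), (2, 3), (4, 6), (1, 2)])
    def test_move_budget(self, m_min, budget):
        assert move_budget(m_min) == budget

    def test_move_budget_rejects_nonpositive(self):
        for bad in [0, -3, 1.5]:
            with pytest.raises(ValueError):
                move_budget(bad)

    def _record(self, **kw):
        base = dict(
            participant="p", condition=1, task="train4", trial=1,
            m_min=15, m_allowed=23, m_used=15, success=True,
        )
        base.update(kw)
        return ScoreRecord(**base)

    def test_condition_formulas_match_worked_substitutions(self):
        r = self._record(m_good=10, m_bad=2, s_subgoal=1)
        assert score(1, r) == 90.0
        assert score(2, r) == 106.0
        assert score(5, r) == 111.0
        assert score(3, self._record(f_optional=4)) == 86.0
        assert score(4, self._record(s_subgoal=1)) == 95.0

    def test_unsolved_scores_zero_and_unknown_condition_rejected(self):
        r = self._record(success=False, m_used=24)
        assert score(2, r) == 0.0
        with pytest.raises(ValueError):
            score(6, self._record())

    def test_percent_score_extremes(self):
        assert percent_score(self._record(m_used=15)) == 100.0
        assert percent_score(self._record(success=False, m_used=24)) == 0.0
        assert percent_score(self._record(m_used=23)) == pytest.approx(100.0 / 9)

    def test_inconsistent_solved_record_rejected(self):
        with pytest.raises(InconsistentRecordError):
            percent_score(self._record(m_used=24))

    def test_score_trajectory_hand_count(self, graph4):
        # the unique 8-move optimal path to 1112 with one backtrack inserted
        vt = solve(TaskMdp(graph=graph4, target="1112"))
        path = [
            "0000", "1000", "1200", "1000", "1200", "2200",
            "2210", "0210", "0110", "1110", "1112",
        ]
        traj = Trajectory(
            participant_id="p", condition=2, task="train4", trial=1,
            target="1112", path=path, feedback=[1, 1, -1, 1, 1, 1, 1, 1, 1, 1],
            success=True,
        )
        rec = score_trajectory(traj, vt)
        assert (rec.m_min, rec.m_allowed, rec.m_used) == (8, 12, 10)
        assert (rec.m_good, rec.m_bad) == (9, 1)
        assert rec.s_subgoal == 1  # the path crosses the 1110 gate
        assert rec.S == 10 * (12 - 10 + 1) + 2 * (9 - 1)
        assert rec.pct == pytest.approx(60.0)
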