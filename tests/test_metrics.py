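import math

import numpy as np
import pytest

from roomwalk.agents import TerminationRule, run_agent
from roomwalk.environment import EnvironmentGraph, Room
from roomwalk.metrics import (
    BRANCHING,
    ROOM_TWO_DOOR_HIDDEN,
    ROOM_TWO_DOOR_VISIBLE,
    SIMPLE_CORNER,
    SIMPLE_CORRIDOR,
    STAIRCASE,
    VisitProfile,
    branch_revisit_profile,
    classify_rooms,
    degree_stationary_profile,
    floor_normalized_visit_ratio,
    normalized_visits,
    pooled_profile,
    radius_of_gyration,
    random_walk_baseline,
    reversal_rates,
    visit_ratio,
)
from roomwalk.trajectories import TrajectoryCorpus, build_movement_graph
from .conftest import make_traj


class TestNormalizedVisits:
    def test_share_arithmetic(self):
        prof = normalized_visits({"A": 10, "B": 30, "C": 60})
        assert prof.shares == {"A": 0.1, "B": 0.3, "C": 0.6}

    def test_single_room(self):
        mg = build_movement_graph(make_traj("p", "A"))
        assert normalized_visits(mg).shares == {"A": 1.0}

    def test_profiles_sum_to_one(self):
        mg = build_movement_graph(make_traj("p", "ABCBDBE"))
        assert sum(normalized_visits(mg).shares.values()) == pytest.approx(1.0)

    def test_empty_counts_rejected(self):
        with pytest.raises(ValueError, match="no visits"):
            normalized_visits({})

    def test_invalid_profile_rejected(self):
        with pytest.raises(ValueError, match="sum"):
            VisitProfile({"A": 0.5, "B": 0.4})


class TestVisitRatio:
    def test_ratio_arithmetic(self):
        p = VisitProfile({"A": 0.1, "B": 0.9})
        b = VisitProfile({"A": 0.05, "B": 0.95})
        assert visit_ratio(p, b)["A"] == pytest.approx(2.0)

    def test_identical_profiles_give_unity(self):
        p = VisitProfile({"A": 0.25, "B": 0.75})
        r = visit_ratio(p, p)
        assert all(v == pytest.approx(1.0) for v in r.values.values())

    def test_zero_baseline_flagged_not_scored(self):
        p = VisitProfile({"A": 0.5, "B": 0.5})
        b = VisitProfile({"A": 1.0})
        r = visit_ratio(p, b)
        assert "B" not in r.values
        assert r.flagged == ("B",)

    def test_highlight_bands(self):
        p = VisitProfile({"A": 0.4, "B": 0.35, "C": 0.25})
        b = VisitProfile({"A": 0.3, "B": 0.35, "C": 0.35})
        h = visit_ratio(p, b).highlights()
        assert h["over"] == ("A",) and h["under"] == ("C",)

    def test_long_walk_ensemble_matches_degree_law(self, palace44):
        """Pooled random walks reproduce the degree/(2|E|) stationary
        shares, so the walker-vs-stationary visit ratio sits in the
        5 % parity band for every room."""
        prof = random_walk_baseline(palace44, hops=200_000, n_walks=10, seed=0)
        ratios = visit_ratio(prof, degree_stationary_profile(palace44))
        assert not ratios.flagged
        assert all(0.95 <= y <= 1.05 for y in ratios.values.values())


class TestFloorNormalizedRatio:
    def test_single_floor_equals_plain_ratio(self, fig3):
        p = VisitProfile({"A": 0.3, "B": 0.7})
        b = VisitProfile({"A": 0.4, "B": 0.6})
        plain = visit_ratio(p, b)
        floored = floor_normalized_visit_ratio(p, b, fig3)
        for room, y in plain.values.items():
            assert floored[room] == pytest.approx(y)

    def test_between_floor_mass_cancels(self, palace44):
        """Uniform-within-floor profiles with different between-floor
        masses give floor-normalized ratios of exactly 1."""
        rooms_by_floor = {
            f: [r for r in palace44.room_ids() if palace44.floor_of(r) == f]
            for f in palace44.floors()
        }
        p_shares, b_shares = {}, {}
        for f, rooms in rooms_by_floor.items():
            p_mass = [0.7, 0.2, 0.1][f]
            b_mass = [0.2, 0.3, 0.5][f]
            for r in rooms:
                p_shares[r] = p_mass / len(rooms)
                b_shares[r] = b_mass / len(rooms)
        result = floor_normalized_visit_ratio(
            VisitProfile(p_shares), VisitProfile(b_shares), palace44
        )
        assert all(y == pytest.approx(1.0) for y in result.values.values())

    def test_staircase_aversion_shows_only_in_unnormalized_ratio(self, palace44):
        """A floor-averse cohort undervisits whole floors; renormalizing
        per floor removes most of that signal at staircase-adjacent
        rooms, so the two ratio maps must genuinely differ."""
        from roomwalk.synthetic_players import SyntheticCohortParams, generate_cohort

        cohort = generate_cohort(
            SyntheticCohortParams(n_players=20, floor_aversion=0.3, master_seed=4),
            palace44,
        )
        prof = pooled_profile(cohort.trajectories)
        base = random_walk_baseline(palace44, hops=100_000, n_walks=4, seed=5)
        plain = visit_ratio(prof, base)
        floored = floor_normalized_visit_ratio(prof, base, palace44)
        landing_rooms = [
            r for r in palace44.room_ids()
            if palace44.rooms[r].category == "staircase_landing" and r in plain.values
        ]
        diffs = [abs(plain[r] - floored[r]) for r in landing_rooms]
        assert max(diffs) > 0.05


class TestClassifyRooms:
    def test_degree_one_rooms_excluded(self, fig3):
        assert "A" not in classify_rooms(fig3)

    def test_palace_classes(self, palace44):
        classes = classify_rooms(palace44)
        assert classes["A_C1"] == BRANCHING          # dorm-corridor junction
        assert classes["G_S1"] == STAIRCASE
        assert classes["DB2"] == ROOM_TWO_DOOR_HIDDEN
        assert classes["LOUNGE"] == ROOM_TWO_DOOR_VISIBLE
        assert classes["G_CN1"] == SIMPLE_CORNER
        assert classes["G_C4"] == SIMPLE_CORRIDOR

    def test_unannotated_two_door_room_defaults_visible_with_warning(self):
        env = EnvironmentGraph(
            [Room("A", "A", 0, 0.0, 0.0, "room"),
             Room("B", "B", 0, 4.0, 0.0, "room"),
             Room("C", "C", 0, 8.0, 0.0, "room")],
            [("A", "B", "door"), ("B", "C", "door")],
        )
        with pytest.warns(UserWarning, match="door_visibility"):
            classes = classify_rooms(env)
        assert classes["B"] == ROOM_TWO_DOOR_VISIBLE


class TestReversalRates:
    def test_out_and_back_counts_reversal(self, fig3):
        corpus = TrajectoryCorpus([make_traj("p", "ABA")], fig3)
        stats = reversal_rates(corpus, fig3)
        # B is the only classified node (branching, degree 4)
        assert stats[BRANCHING].reversals == 1
        assert stats[BRANCHING].traversals == 1

    def test_forward_walk_has_zero_rate(self, palace44):
        corpus = TrajectoryCorpus(
            [make_traj("p", ["G_ENT", "G_C1", "G_C2", "G_CN1", "G_C3", "G_C4"])],
            palace44,
        )
        stats = reversal_rates(corpus, palace44)
        for st in stats.values():
            assert st.rate == 0.0

    def test_unvisited_classes_absent(self, fig3):
        corpus = TrajectoryCorpus([make_traj("p", "AB")], fig3)
        assert reversal_rates(corpus, fig3) == {}


class TestRadiusOfGyration:
    def test_single_room_is_zero(self, fig3):
        assert radius_of_gyration(make_traj("p", "A"), fig3) == 0.0

    def test_two_equal_weight_positions_two_metres_apart(self):
        env = EnvironmentGraph(
            [Room("P", "P", 0, 0.0, 0.0, "room"), Room("Q", "Q", 0, 2.0, 0.0, "room")],
            [("P", "Q", "door")],
        )
        assert radius_of_gyration(make_traj("p", "PQ"), env) == pytest.approx(1.0)

    def test_translation_invariance(self):
        def env_at(dx, dy):
            return EnvironmentGraph(
                [Room("P", "P", 0, dx, dy, "room"),
                 Room("Q", "Q", 0, dx + 3.0, dy + 4.0, "room")],
                [("P", "Q", "door")],
            )

        t = make_traj("p", "PQPQ")
        assert radius_of_gyration(t, env_at(0, 0)) == pytest.approx(
            radius_of_gyration(t, env_at(100.0, -40.0))
        )

    def test_vertical_component_counts_in_3d_only(self, palace44):
        t = make_traj("p", ["G_S1", "A_S1"] * 4)
        rg3 = radius_of_gyration(t, palace44, use_3d=True)
        rg2 = radius_of_gyration(t, palace44, use_3d=False)
        # the two landings share planar coordinates, one floor apart
        assert rg2 == pytest.approx(0.0)
        assert rg3 == pytest.approx(palace44.floor_height / 2)

    def test_long_walk_matches_stationary_closed_form(self, fig3):
        """For a long random walk, occupancy converges to the degree law
        and the radius of gyration to the closed form computed from
        stationary shares and fixture coordinates."""
        stat = degree_stationary_profile(fig3)
        pos = np.array([fig3.position3d(r) for r in fig3.room_ids()])
        w = np.array([stat[r] for r in fig3.room_ids()])
        centroid = (w[:, None] * pos).sum(axis=0)
        expected = math.sqrt((w * ((pos - centroid) ** 2).sum(axis=1)).sum())
        t = run_agent("random", fig3,
                      TerminationRule("fixed_hops", 200_000, cap=200_000), 11)
        assert radius_of_gyration(t, fig3) == pytest.approx(expected, rel=0.02)


class TestBranchRevisitProfile:
    BRANCH = ["DORM_C", "D1", "D2"]

    def test_corpus_that_never_enters(self, palace44):
        corpus = TrajectoryCorpus(
            [make_traj("p", ["A_S1", "A_C1", "A_R1", "A_C1", "A_C2"])], palace44
        )
        prof = branch_revisit_profile(corpus, "A_C1", self.BRANCH, palace44)
        assert (prof.entries == 0).all()
        assert prof.arrivals.iloc[0] == 1

    def test_junction_must_adjoin_branch(self, palace44):
        corpus = TrajectoryCorpus([make_traj("p", ["A_S1", "A_C1"])], palace44)
        with pytest.raises(ValueError, match="not adjacent"):
            branch_revisit_profile(corpus, "B_C1", self.BRANCH, palace44)

    def test_leaky_branch_rejected(self, palace44):
        corpus = TrajectoryCorpus([make_traj("p", ["A_S1", "A_C1"])], palace44)
        with pytest.raises(ValueError, match="dead-end"):
            branch_revisit_profile(corpus, "A_C1", ["DORM_C", "D1"], palace44)

    def test_perfect_memory_first_entry_sweeps_branch(self, palace44):
        """A walker whose window still holds the whole pocket explores
        D1 and D2 in a single visit before returning to the junction."""
        branch = set(self.BRANCH)
        for i in range(60):
            t = run_agent("memory", palace44, TerminationRule("full_coverage"),
                          (9, i), m=palace44.n_rooms)
            for j in range(t.n_steps - 1):
                if t.rooms[j] == "A_C1" and t.rooms[j + 1] in branch:
                    k, seen = j + 1, set()
                    while k < t.n_steps and t.rooms[k] in branch:
                        seen.add(t.rooms[k])
                        k += 1
                    assert seen == branch
                    break
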