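"""Breeding restrictions, mate allocation and their population-level effects."""

import numpy as np
import pytest
from scipy import stats

from herdkeeper.management import (
    ManagementPolicy,
    cap_selected_sons,
    eligible_parents,
    optimal_contributions_allocate,
    optimal_contributions_bruteforce,
    pick_sire,
)
from herdkeeper.sim_core import (
    SimConfig,
    SubpopSpec,
    init_founders,
    make_litters,
    newborn_f_trajectories,
    run_simulation,
)


def founder_state(males=5, females=10, policy=None, **kw):
    cfg = SimConfig(
        years=5, subpops=[SubpopSpec(males, females)], litters_per_year=5,
        litter_size_dist={2: 1.0}, policy=policy or ManagementPolicy(), **kw,
    )
    return init_founders(cfg, np.random.default_rng(0)), cfg


class TestEligibility:
    def test_sire_at_yearly_cap_excluded_then_eligible_again(self):
        policy = ManagementPolicy(max_litters_per_sire_year=2)
        state, _ = founder_state(policy=policy)
        males = np.nonzero(state.sex == 0)[0]
        state.litters_year[males[0]] = 2
        eligible = eligible_parents(state, policy, "male")
        assert males[0] not in eligible
        state.litters_year[males[0]] = 0  # next year: counter reset
        assert males[0] in eligible_parents(state, policy, "male")

    def test_inbreeding_threshold_excludes(self):
        policy = ManagementPolicy(max_inbreeding_offspring=0.1)
        state, _ = founder_state(policy=policy)
        males = np.nonzero(state.sex == 0)[0]
        state.K[males[0], males[0]] = (1 + 0.15) / 2  # F = 0.15
        eligible = eligible_parents(state, policy, "male")
        assert males[0] not in eligible

    def test_mean_kinship_exclusion_keeps_ties(self):
        policy = ManagementPolicy(mean_kinship_exclusion=True)
        state, _ = founder_state(policy=policy)
        # founders all have identical mean kinship: nobody may be excluded
        eligible = eligible_parents(state, policy, "female")
        assert len(eligible) == 10

    def test_mean_kinship_exclusion_removes_overrepresented(self):
        policy = ManagementPolicy(mean_kinship_exclusion=True)
        state, _ = founder_state(policy=policy)
        females = np.nonzero(state.sex == 1)[0]
        # make one female related to everybody
        state.K[females[0], :] += 0.2
        state.K[:, females[0]] += 0.2
        eligible = eligible_parents(state, policy, "female")
        assert females[0] not in eligible


class TestPickSire:
    def test_minimize_kinship_prefers_unrelated(self):
        policy = ManagementPolicy(minimize_kinship_mating=True)
        state, _ = founder_state(policy=policy)
        males = np.nonzero(state.sex == 0)[0]
        dam = int(np.nonzero(state.sex == 1)[0][0])
        state.K[dam, males[:-1]] = 0.25
        state.K[males[:-1], dam] = 0.25
        chosen = pick_sire(state, dam, males, policy, np.random.default_rng(0))
        assert chosen == males[-1]

    def test_kinship_threshold_skips_litter(self):
        policy = ManagementPolicy(max_parent_kinship=0.0625)
        state, _ = founder_state(males=1)
        males = np.nonzero(state.sex == 0)[0]
        dam = int(np.nonzero(state.sex == 1)[0][0])
        state.K[dam, males[0]] = state.K[males[0], dam] = 0.25  # full sibs
        assert pick_sire(state, dam, males, policy,
                         np.random.default_rng(0)) is None

    def test_uniform_choice_over_equal_candidates(self):
        state, _ = founder_state(males=5)
        males = np.nonzero(state.sex == 0)[0]
        dam = int(np.nonzero(state.sex == 1)[0][0])
        rng = np.random.default_rng(1)
        policy = ManagementPolicy()
        draws = np.array(
            [pick_sire(state, dam, males, policy, rng) for _ in range(10000)]
        )
        counts = np.array([(draws == m).sum() for m in males])
        chi2 = ((counts - 2000.0) ** 2 / 2000.0).sum()
        assert chi2 < stats.chi2.ppf(0.999, df=4)


class TestOptimalContributions:
    def test_two_unrelated_sires_split_evenly(self):
        state, _ = founder_state(males=2, females=4)
        males = np.nonzero(state.sex == 0)[0]
        dams = np.nonzero(state.sex == 1)[0][:2]
        alloc = optimal_contributions_allocate(state, males, dams, 2)
        assert alloc.tolist() == [1, 1]

    def test_unrelated_sire_dominates_related_one(self):
        state, _ = founder_state(males=2, females=4)
        males = np.nonzero(state.sex == 0)[0]
        dams = np.nonzero(state.sex == 1)[0][:4]
        # first male strongly related to every dam; the gain from avoiding
        # him then outweighs the diversity cost of concentrating on one sire
        for d in dams:
            state.K[males[0], d] = state.K[d, males[0]] = 0.4
        alloc = optimal_contributions_allocate(state, males, dams, 4)
        assert alloc.tolist() == [0, 4]
        brute = optimal_contributions_bruteforce(state, males, dams, 4)
        assert brute.tolist() == [0, 4]

    def test_small_instance_matches_exhaustive_search(self):
        rng = np.random.default_rng(7)
        for trial in range(10):
            state, _ = founder_state(males=3, females=4)
            n = state.n
            # random but valid kinship structure via a random pedigree-free
            # positive-definite perturbation
            B = rng.random((n, n)) * 0.1
            K = state.K + 0.5 * (B + B.T)
            np.fill_diagonal(K, 0.5)
            state.K = K
            males = np.nonzero(state.sex == 0)[0]
            dams = np.nonzero(state.sex == 1)[0]
            greedy = optimal_contributions_allocate(state, males, dams, 4)
            brute = optimal_contributions_bruteforce(state, males, dams, 4)

            def score(x):
                c = np.zeros(n)
                c[males] += x / 8.0
                c[dams] += 1.0 / (2 * len(dams))
                return c @ state.K @ c

            assert score(greedy) <= score(brute) + 1e-12


class TestCapSelectedSons:
    def test_cap_one_limits_single_sires_sons(self):
        rng = np.random.default_rng(0)
        policy = ManagementPolicy(max_sons_per_sire=1)
        newborns = list(range(8))
        sires = [100] * 5 + [200, 300, 400]
        chosen = cap_selected_sons(newborns, sires, 3, policy, rng)
        assert len(chosen) == 3
        chosen_sires = [sires[newborns.index(c)] for c in chosen]
        assert sum(s == 100 for s in chosen_sires) <= 1

    def test_cap_above_demand_unconstrained(self):
        rng = np.random.default_rng(0)
        policy = ManagementPolicy(max_sons_per_sire=10)
        chosen = cap_selected_sons(list(range(5)), [1] * 5, 3, policy, rng)
        assert len(chosen) == 3

    def test_cap_never_exceeded_across_seeds(self):
        policy = ManagementPolicy(max_sons_per_sire=2)
        sires = [1, 1, 1, 2, 2, 3, 3, 3, 3, 4]
        for seed in range(200):
            rng = np.random.default_rng(seed)
            lifetime: dict[int, int] = {}
            for _ in range(3):  # successive years share the lifetime counts
                chosen = cap_selected_sons(
                    list(range(10)), sires, 4, policy, rng,
                    sons_already=lifetime,
                )
                assert len(chosen) <= 4
            assert all(v <= 2 for v in lifetime.values())


class TestPolicyEffects:
    def test_null_policy_identical_to_plain_run(self):
        base = dict(
            years=15, runs=2, subpops=[SubpopSpec(4, 12)], litters_per_year=8,
            litter_size_dist={2: 1.0}, male_age_dist=(0.5, 0.5),
            female_age_dist=(0.5, 0.5),
        )
        plain = run_simulation(SimConfig(**base), seed=11)
        null = run_simulation(
            SimConfig(**base, policy=ManagementPolicy()), seed=11
        )
        for a, b in zip(plain, null):
            assert a.years.equals(b.years)

    @pytest.mark.parametrize(
        "policy",
        [
            ManagementPolicy(minimize_kinship_mating=True),
            ManagementPolicy(optimal_contributions=True),
        ],
        ids=["minimize_kinship", "optimal_contributions"],
    )
    def test_managed_mating_does_not_increase_kinship(self, policy):
        base = dict(
            years=30, runs=50, subpops=[SubpopSpec(5, 15)], litters_per_year=9,
            litter_size_dist={2: 0.5, 3: 0.5}, male_age_dist=(0.5, 0.5),
            female_age_dist=(0.5, 0.3, 0.2),
        )
        random_runs = run_simulation(SimConfig(**base), seed=21)
        managed_runs = run_simulation(SimConfig(**base, policy=policy), seed=21)
        f_random = np.nanmean(
            [r.years.mean_f_newborn_incl_self.iloc[-1] for r in random_runs]
        )
        f_managed = np.nanmean(
            [r.years.mean_f_newborn_incl_self.iloc[-1] for r in managed_runs]
        )
        assert f_managed <= f_random + 1e-6
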