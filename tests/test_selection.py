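import numpy as np
import pytest
from hypothesis import given, strategies as st

from conftest import brute_force_select
from edsim import (
    Cohort,
    ReplicateError,
    assign_mates,
    build_matings,
    compute_index,
    founder_cache,
    produce_generation,
    select_matings_for_editing,
    truncation_select,
)


def _cohort(ebv, g, sex, ids=None):
    ebv = np.asarray(ebv, dtype=float)
    n = ebv.size
    ids = np.arange(1, n + 1, dtype=np.int64) if ids is None else np.asarray(ids)
    return Cohort(
        generation=0,
        ids=ids,
        sire_ids=np.zeros(n, dtype=np.int64),
        dam_ids=np.zeros(n, dtype=np.int64),
        sex=np.asarray(sex, dtype=np.int8),
        tbv=ebv.copy(),
        ebv=ebv,
        g=np.asarray(g, dtype=np.int8),
        f=np.zeros(n),
        edited=np.zeros(n, dtype=bool),
    )


class TestComputeIndex:
    @pytest.mark.parametrize(
        "ebv,g,b1,b2,expected",
        [(1.2, 0, 1, 0.5, 1.2), (1.2, 2, 1, 0.5, 2.2), (0.0, 1, 1, 1000, 1000.0)],
    )
    def test_linear_combination(self, ebv, g, b1, b2, expected):
        assert compute_index(ebv, g, b1, b2) == pytest.approx(expected)

    @given(st.floats(-499.9, 499.9), st.floats(-499.9, 499.9))
    def test_maximal_weight_ranks_any_carrier_above_any_noncarrier(self, e0, e1):
        assert compute_index(e1, 1, 1, 1000) > compute_index(e0, 0, 1, 1000)


class TestTruncationSelect:
    def test_top_indices_selected(self):
        # 4 males with indices (3,1,2,0): ranks 1 and 3 win the two slots
        cohort = _cohort([3.0, 1.0, 2.0, 0.0, 0.0], [0] * 5, [1, 1, 1, 1, 0])
        sires, dams = truncation_select(cohort, 2, 1, 1.0, 0.0)
        assert list(sires) == [0, 2]

    def test_ties_broken_by_lower_id(self):
        cohort = _cohort([1.0] * 6, [0] * 6, [1, 1, 1, 0, 0, 0], ids=[10, 3, 7, 2, 9, 5])
        sires, dams = truncation_select(cohort, 2, 2, 1.0, 0.0)
        assert sorted(cohort.ids[sires]) == [3, 7]
        assert sorted(cohort.ids[dams]) == [2, 5]

    def test_zero_weight_reduces_to_ebv_ranking(self, rng):
        n = 60
        cohort = _cohort(rng.standard_normal(n), rng.integers(0, 3, n), rng.integers(0, 2, n))
        sires, dams = truncation_select(cohort, 5, 8, 1.0, 0.0)
        o_sires, o_dams = brute_force_select(
            cohort.ebv, np.zeros(n), cohort.sex, cohort.ids, 5, 8, 1.0, 0.0
        )
        assert set(sires) == set(o_sires) and set(dams) == set(o_dams)

    @given(st.integers(0, 2**31 - 1))
    def test_matches_brute_force_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(10, 40))
        # coarse values make index ties common, exercising the tie rule
        ebv = rng.integers(-2, 3, n).astype(float)
        g = rng.integers(0, 3, n)
        sex = rng.integers(0, 2, n)
        n_sires = min(3, int(np.sum(sex == 1)))
        n_dams = min(4, int(np.sum(sex == 0)))
        if n_sires == 0 or n_dams == 0:
            return
        cohort = _cohort(ebv, g, sex)
        b2 = float(rng.choice([0.0, 0.5, 1000.0]))
        sires, dams = truncation_select(cohort, n_sires, n_dams, 1.0, b2)
        o_sires, o_dams = brute_force_select(ebv, g, sex, cohort.ids, n_sires, n_dams, 1.0, b2)
        assert list(sires) == o_sires and list(dams) == o_dams

    def test_maximal_weight_prefers_carriers_over_any_ebv(self, rng):
        n = 30
        g = np.zeros(n, dtype=int)
        g[:4] = 1
        cohort = _cohort(rng.normal(0, 100, n), g, np.ones(n, dtype=int))
        sires, _ = truncation_select(cohort, 4, 0, 1.0, 1000.0)
        assert set(sires) == set(range(4))

    def test_insufficient_candidates_raises(self):
        cohort = _cohort([1.0, 2.0], [0, 0], [1, 1])
        with pytest.raises(ReplicateError):
            truncation_select(cohort, 1, 1, 1.0, 0.0)


class TestAssignMates:
    def test_single_sire_serves_all_dams(self, rng):
        assert np.all(assign_mates(1, 3, rng) == 0)

    def test_uniform_with_replacement_is_multinomial(self, rng):
        from scipy import stats

        n_sires, n_dams = 20, 4000
        counts = np.bincount(assign_mates(n_sires, n_dams, rng), minlength=n_sires)
        res = stats.chisquare(counts)
        assert res.pvalue > 1e-4  # uniform sire usage

    def test_balanced_assignment_is_even(self, rng):
        counts = np.bincount(assign_mates(10, 95, rng, balanced=True), minlength=10)
        assert counts.max() - counts.min() <= 1


def _founder_state_and_matings(spec, rng, b2=0.0):
    from edsim import init_founders

    state = init_founders(spec, rng)
    sires, dams = truncation_select(state.cohort, spec.n_sires, spec.n_dams, spec.b1, b2)
    cache = founder_cache(state.cohort.ids[np.concatenate([sires, dams])])
    choice = assign_mates(spec.n_sires, spec.n_dams, rng)
    matings = build_matings(state.cohort, sires, dams, choice, spec.b1, b2)
    return state, cache, matings


class TestProduceGeneration:
    def test_full_cohort_without_editing(self, small_spec, rng):
        state, cache, matings = _founder_state_and_matings(small_spec, rng)
        new_state, counters = produce_generation(
            matings, small_spec, None, rng, cache, 1, state.next_id
        )
        assert new_state.cohort.size == small_spec.n_candidates
        assert counters["n_subjected"] == 0

    def test_full_survival_keeps_cohort_size(self, small_spec, rng):
        spec = small_spec.replace(use_editing=True, edit_fraction=0.5, edit_survival_s=1.0)
        state, cache, matings = _founder_state_and_matings(spec, rng)
        plan = select_matings_for_editing(
            matings.parental_allele_count, matings.parent_avg_index, matings.dam_ids, 0.5
        )
        new_state, counters = produce_generation(matings, spec, plan, rng, cache, 1, state.next_id)
        assert new_state.cohort.size == spec.n_candidates
        assert counters["n_subjected"] == plan.n_flagged * spec.n_off_per_mating

    def test_zero_survival_removes_edited_families(self, small_spec, rng):
        spec = small_spec.replace(use_editing=True, edit_fraction=0.5, edit_survival_s=0.0)
        state, cache, matings = _founder_state_and_matings(spec, rng)
        plan = select_matings_for_editing(
            matings.parental_allele_count, matings.parent_avg_index, matings.dam_ids, 0.5
        )
        new_state, counters = produce_generation(matings, spec, plan, rng, cache, 1, state.next_id)
        expected_dead = plan.n_flagged * spec.n_off_per_mating
        assert new_state.cohort.size == spec.n_candidates - expected_dead
        assert counters["n_survived_editing"] == 0
        # surviving families are exactly the unflagged ones
        flagged_dams = set(matings.dam_ids[plan.flagged])
        assert flagged_dams.isdisjoint(new_state.cohort.dam_ids)

    def test_offspring_ids_exceed_parent_ids(self, small_spec, rng):
        state, cache, matings = _founder_state_and_matings(small_spec, rng)
        new_state, _ = produce_generation(matings, small_spec, None, rng, cache, 1, state.next_id)
        c = new_state.cohort
        assert np.all(c.ids > c.sire_ids) and np.all(c.ids > c.dam_ids)
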