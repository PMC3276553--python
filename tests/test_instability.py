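import numpy as np
import pandas as pd
import pytest

from epinstab.instability import (
    combined_demi,
    discretize,
    epi_indices,
    find_stable,
    hypo_frequency,
    indices_for_cohort,
    transitions,
)
from epinstab.locus_sets import LocusSet
from conftest import make_bm


def oracle_transition(beta, stable_state, normal_mean, buffer=0.10):
    """Straight-line reimplementation of the two calling rules."""
    if np.isnan(beta):
        return None
    state = 0 if beta < 0.25 else (1 if beta <= 0.7 else 2)
    if state == stable_state or abs(beta - normal_mean) < buffer:
        return ""
    if stable_state == 0:
        return "0->1/2"
    if stable_state == 1:
        return "1->2" if state == 2 else "1->0"
    return "2->0/1"


def stable_frame(states, means):
    return pd.DataFrame(
        {
            "stable_state": states,
            "normal_mean_beta": means,
            "n_normals": 3,
        },
        index=[f"cg{i:04d}" for i in range(len(states))],
    )


class TestDiscretize:
    @pytest.mark.parametrize(
        "beta, state",
        [(0.10, 0), (0.249, 0), (0.25, 1), (0.5, 1), (0.70, 1), (0.701, 2), (0.95, 2)],
    )
    def test_thresholds_with_inclusive_middle(self, beta, state):
        assert discretize(beta) == state

    def test_nan_propagates(self):
        assert np.isnan(discretize(np.nan))


class TestFindStable:
    def test_hand_examples(self):
        bm = make_bm(
            [
                [0.80, 0.90, 0.75],   # states 2,2,2 -> stable
                [0.80, 0.69, 0.90],   # states 2,1,2 -> not stable
                [0.10, 0.20, 0.24],   # states 0,0,0 -> stable
            ]
        )
        st = find_stable(bm)
        assert list(st.index) == ["cg0000", "cg0002"]
        assert st.loc["cg0000", "stable_state"] == 2
        assert st.loc["cg0000", "normal_mean_beta"] == pytest.approx(0.8167, abs=1e-4)
        assert st.loc["cg0002", "stable_state"] == 0

    def test_missing_normals_assessed_on_remainder(self):
        bm = make_bm([[0.8, np.nan, 0.9], [0.8, np.nan, np.nan]])
        st = find_stable(bm)
        assert list(st.index) == ["cg0000"]  # one observation is not stability
        assert st.loc["cg0000", "n_normals"] == 2

    def test_fewer_than_two_normals_is_an_error(self):
        with pytest.raises(ValueError, match=">= 2"):
            find_stable(make_bm([[0.5]]))

    def test_invariant_to_sample_order(self):
        rng = np.random.default_rng(0)
        vals = rng.random((50, 5))
        bm = make_bm(vals)
        st1 = find_stable(bm)
        st2 = find_stable(bm.subset_samples(list(bm.values.columns)[::-1]))
        pd.testing.assert_frame_equal(st1, st2)


class TestTransitions:
    def test_buffer_and_state_rules(self):
        st = stable_frame([2, 2, 2], [0.80, 0.75, 0.80])
        beta = pd.Series([0.68, 0.69, 0.73], index=st.index)
        lab = transitions(beta, st)
        assert lab.tolist() == ["2->0/1", "", ""]
        # 0.68: state 1, |delta| = 0.12 -> called
        # 0.69 vs 0.75: state 1 but |delta| = 0.06 < buffer -> blocked
        # 0.73: still state 2 -> never called

    def test_missing_beta_dropped(self):
        st = stable_frame([2, 2], [0.8, 0.8])
        lab = transitions(pd.Series([np.nan, 0.1], index=st.index), st)
        assert list(lab.index) == ["cg0001"]

    def test_agrees_with_oracle_on_beta_grid(self):
        grid = np.round(np.arange(0, 1.001, 0.01), 2)
        for state, mean in [(0, 0.10), (0, 0.22), (1, 0.40), (1, 0.68), (2, 0.75), (2, 0.90)]:
            st = stable_frame([state] * len(grid), [mean] * len(grid))
            lab = transitions(pd.Series(grid, index=st.index), st)
            expected = [oracle_transition(b, state, mean) for b in grid]
            assert lab.tolist() == expected, (state, mean)

    def test_monotone_in_buffer(self):
        rng = np.random.default_rng(1)
        states = rng.integers(0, 3, 200)
        means = np.where(states == 0, 0.1, np.where(states == 1, 0.5, 0.85))
        st = stable_frame(states, means)
        beta = pd.Series(rng.random(200), index=st.index)
        called_prev = None
        for buf in (0.0, 0.05, 0.10, 0.20, 0.5):
            called = set((transitions(beta, st, buffer=buf) != "").loc[lambda s: s].index)
            if called_prev is not None:
                assert called <= called_prev
            called_prev = called


class TestEpiIndices:
    def test_demi_worked_example(self):
        # 4 stable fully-methylated MESC probes; two qualify for 2->0/1
        st = stable_frame([2, 2, 2, 2], [0.80, 0.85, 0.90, 0.75])
        beta = pd.Series([0.68, 0.73, 0.20, 0.69], index=st.index)
        mesc = LocusSet("MESC", set(st.index))
        si = epi_indices(beta, st, mesc)
        assert si.demi == pytest.approx(0.5)
        assert si.denominators["f_2_loss"] == 4

    def test_identity_sample_all_zero(self):
        st = stable_frame([0, 1, 2, 2], [0.1, 0.5, 0.8, 0.9])
        beta = pd.Series(st["normal_mean_beta"].to_numpy(), index=st.index)
        si = epi_indices(beta, st)
        assert all(v == 0 for v in si.fractions.values())

    def test_zero_denominator_is_nan_not_zero(self):
        st = stable_frame([2, 2], [0.8, 0.8])  # no stable state-0 probes
        si = epi_indices(pd.Series([0.8, 0.8], index=st.index), st)
        assert np.isnan(si.fractions["f_0_gain"])
        assert si.denominators["f_0_gain"] == 0

    def test_missing_beta_shrinks_denominator(self):
        st = stable_frame([2, 2, 2], [0.8, 0.8, 0.8])
        beta = pd.Series([0.1, np.nan, 0.85], index=st.index)
        si = epi_indices(beta, st)
        assert si.denominators["f_2_loss"] == 2
        assert si.demi == pytest.approx(0.5)

    def test_shared_state1_denominator_bounds(self):
        st = stable_frame([1, 1, 1, 1], [0.5, 0.5, 0.5, 0.5])
        beta = pd.Series([0.9, 0.05, 0.9, 0.05], index=st.index)
        si = epi_indices(beta, st)
        assert si.fractions["f_1_gain"] + si.fractions["f_1_loss"] <= 1

    def test_probe_order_invariance(self):
        rng = np.random.default_rng(2)
        st = stable_frame(rng.integers(0, 3, 100),
                          rng.choice([0.1, 0.5, 0.85], 100))
        beta = pd.Series(rng.random(100), index=st.index)
        a = epi_indices(beta, st)
        perm = rng.permutation(100)
        b = epi_indices(beta.iloc[perm], st.iloc[perm])
        assert a.fractions == b.fractions


class TestCombinedDemi:
    def test_pooled_worked_example(self):
        # 2 stable hemi probes (one 1->0) + 4 stable methylated (two 2->0/1)
        st = stable_frame([1, 1, 2, 2, 2, 2], [0.50, 0.50, 0.80, 0.80, 0.85, 0.90])
        beta = pd.Series([0.10, 0.50, 0.10, 0.20, 0.80, 0.88], index=st.index)
        mesc = LocusSet("MESC", set(st.index))
        assert combined_demi(beta, st, mesc) == pytest.approx(3 / 6)

    def test_bounds(self):
        st = stable_frame([2, 2], [0.8, 0.9])
        mesc = LocusSet("MESC", set(st.index))
        quiet = pd.Series([0.8, 0.9], index=st.index)
        assert combined_demi(quiet, st, mesc) == 0.0
        wiped = pd.Series([0.05, 0.05], index=st.index)
        assert combined_demi(wiped, st, mesc) == 1.0

    def test_empty_pool_is_nan(self):
        st = stable_frame([0, 0], [0.1, 0.1])
        mesc = LocusSet("MESC", set(st.index))
        assert np.isnan(combined_demi(pd.Series([0.1, 0.1], index=st.index), st, mesc))


class TestHypoFrequency:
    def test_counting(self):
        st = stable_frame([2, 2], [0.85, 0.85])
        mesc = LocusSet("MESC", set(st.index))
        # probe cg0000 demethylated in 3 of 10 tumours, cg0001 never
        vals = np.full((2, 10), 0.85)
        vals[0, :3] = 0.05
        bm = make_bm(vals, groups="cancer")
        freq = hypo_frequency(bm, st, mesc)
        assert freq["cg0000"] == pytest.approx(0.3)
        assert freq["cg0001"] == 0.0
        assert list(freq.index) == ["cg0000", "cg0001"]  # never-demethylated ranks last

    def test_planted_frequency_recovered(self):
        rng = np.random.default_rng(11)
        n_probes, n_tumours, q = 200, 200, 0.4
        st = stable_frame([2] * n_probes, [0.85] * n_probes)
        mesc = LocusSet("MESC", set(st.index))
        flips = rng.random((n_probes, n_tumours)) < q
        vals = np.where(flips, 0.05, 0.85)
        bm = make_bm(vals, groups="cancer",
                     sample_ids=[f"t{i:03d}" for i in range(n_tumours)])
        freq = hypo_frequency(bm, st, mesc)
        # 99% binomial bounds for one probe's observed frequency
        lo, hi = 0.4 - 2.58 * np.sqrt(0.24 / n_tumours), 0.4 + 2.58 * np.sqrt(0.24 / n_tumours)
        within = ((freq >= lo) & (freq <= hi)).mean()
        assert within > 0.95
        assert freq.mean() == pytest.approx(q, abs=0.02)


class TestCohortIndices:
    def test_recovers_planted_truth_per_sample(self, sim_cfg, sim_manifest, cancer_cohort):
        manifest, sets = sim_manifest
        bm = cancer_cohort.bm
        stable = find_stable(bm.by_group("normal"))
        tumours = bm.by_group("cancer")
        idx = indices_for_cohort(tumours, stable, mesc=sets["mesc"])
        truth = cancer_cohort.truth
        # per-sample planted demethylation fraction among stable MESC probes
        stable_mesc2 = set(stable.index[(stable["stable_state"] == 2)
                                        & stable.index.isin(sets["mesc"].members)])
        for sid in list(tumours.values.columns)[:10]:
            planted = truth[(truth.sample_id == sid) & (truth.transition == "2->0/1")
                            & truth.probe_id.isin(stable_mesc2)]
            expected = len(planted) / len(stable_mesc2)
            assert idx.loc[sid, "mesc_demi"] == pytest.approx(expected, abs=0.02)
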