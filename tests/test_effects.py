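import numpy as np
import pandas as pd
import pytest

from lexcontext.effects import (
    compute_all_slowdowns,
    compute_diffs,
    fit_per_participant,
    freq_surp_diff,
    group_compare,
    paired_compare,
    participant_slowdown,
)
from lexcontext.gam import linear_partial_stub
from lexcontext.synth import (
    GenerativeEffectSpec,
    generate_participants,
    sample_modeling_frame,
)


@pytest.fixture(scope="module")
def corpus_10k():
    rng = np.random.default_rng(77)
    return pd.DataFrame(
        {
            "surp": rng.gamma(4.0, 2.0, 10_000),
            "freq": rng.gamma(5.0, 1.8, 10_000),
            "len": rng.integers(1, 14, 10_000).astype(float),
        }
    )


class TestSlowdown:
    def test_worked_example_5ms_per_bit_at_6_bits(self):
        stub = linear_partial_stub("surp", 5.0)
        contribution = stub.partial_effect("surp", 6.0, anchor="zero")
        assert contribution[0] == pytest.approx(30.0, abs=1e-9)

    def test_linear_closed_form_equals_brute_force(self, corpus_10k):
        stub = linear_partial_stub("surp", 5.0, x_range=(0.0, 25.0))
        eff = participant_slowdown(stub, corpus_10k, "surp")
        closed = 5.0 * corpus_10k["surp"].mean()
        brute = np.mean([
            stub.partial_effect("surp", v, anchor="zero")[0]
            for v in corpus_10k["surp"].to_numpy()[:200]
        ])
        assert eff.slowdown == pytest.approx(closed, rel=1e-10)
        assert brute == pytest.approx(
            5.0 * corpus_10k["surp"].to_numpy()[:200].mean(), rel=1e-10
        )

    def test_zero_partial_effect_gives_zero_slowdown(self, corpus_10k):
        stub = linear_partial_stub("freq", 0.0)
        assert participant_slowdown(stub, corpus_10k, "freq").slowdown == 0.0

    def test_out_of_range_words_counted_and_extended_linearly(self, corpus_10k):
        stub = linear_partial_stub("surp", 5.0, x_range=(2.0, 6.0))
        eff = participant_slowdown(stub, corpus_10k, "surp")
        assert eff.n_out_of_range > 0
        # linear extension keeps the closed form exact even out of range
        assert eff.slowdown == pytest.approx(5.0 * corpus_10k["surp"].mean(), rel=1e-10)


class TestDiff:
    def test_identical_partial_effects_cancel(self, corpus_10k):
        same = corpus_10k.copy()
        same["freq"] = same["surp"]
        f1 = linear_partial_stub("freq", 4.0)
        f2 = linear_partial_stub("surp", 4.0)
        d = freq_surp_diff(f1, f2, same)
        assert d.diff == pytest.approx(0.0, abs=1e-12)

    def test_swapping_effects_flips_sign(self, corpus_10k):
        f_freq = linear_partial_stub("freq", 3.0)
        f_surp = linear_partial_stub("surp", 5.0)
        d1 = freq_surp_diff(f_freq, f_surp, corpus_10k)
        swapped = corpus_10k.rename(columns={"freq": "surp", "surp": "freq"})
        d2 = freq_surp_diff(
            linear_partial_stub("freq", 5.0), linear_partial_stub("surp", 3.0), swapped
        )
        assert d1.diff == pytest.approx(-d2.diff, rel=1e-10)

    def test_closed_form(self, corpus_10k):
        d = freq_surp_diff(
            linear_partial_stub("freq", 3.0), linear_partial_stub("surp", 5.0), corpus_10k
        )
        expected = 3.0 * corpus_10k["freq"].mean() - 5.0 * corpus_10k["surp"].mean()
        assert d.diff == pytest.approx(expected, rel=1e-10)

    def test_diff_table_is_exact_row_difference(self):
        slow = pd.DataFrame(
            {
                "participant_id": ["a", "a", "b", "b"],
                "measure": ["tf"] * 4,
                "property": ["freq", "surp", "freq", "surp"],
                "slowdown": [20.0, 15.0, 31.0, 40.0],
            }
        )
        diffs = compute_diffs(slow).set_index("participant_id")
        assert diffs.loc["a", "diff"] == 5.0
        assert diffs.loc["b", "diff"] == -9.0


class TestPerParticipantFits:
    def test_two_participants_with_different_slopes_separated(self, small_annotations):
        eff_a = GenerativeEffectSpec(
            effects={"surp": (3.0,), "freq": (0.0,), "len": (0.0,)},
            spillover={}, noise_sd=15.0,
        )
        eff_b = GenerativeEffectSpec(
            effects={"surp": (8.0,), "freq": (0.0,), "len": (0.0,)},
            spillover={}, noise_sd=15.0,
        )
        prof = generate_participants(0, 1, random_effect_sds={}, seed=1)
        da = sample_modeling_frame(small_annotations, prof, 3000, eff_a, seed=2)
        db = sample_modeling_frame(small_annotations, prof, 3000, eff_b, seed=3)
        corpus = pd.concat([da, db], ignore_index=True)
        for df, true_slope in ((da, 3.0), (db, 8.0)):
            fits = fit_per_participant(df, "tf", which="frequency", min_rows=200)
            sl = participant_slowdown(fits["frequency"], corpus, "surp")
            assert sl.slowdown / corpus["surp"].mean() == pytest.approx(true_slope, rel=0.1)

    def test_participant_below_minimum_rows_skipped(self, small_annotations, small_profiles, caplog):
        eff = GenerativeEffectSpec()
        df = sample_modeling_frame(small_annotations, small_profiles[:1], 100, eff, seed=4)
        with caplog.at_level("INFO", logger="lexcontext.effects"):
            out = fit_per_participant(df, "tf", min_rows=200)
        assert out is None
        assert "skipping participant" in caplog.text

    def test_flat_participant_has_flat_partial_effects(self, small_annotations):
        eff = GenerativeEffectSpec(effects={}, spillover={}, noise_sd=10.0)
        prof = generate_participants(0, 1, random_effect_sds={}, seed=5)
        df = sample_modeling_frame(small_annotations, prof, 3000, eff, seed=6)
        fits = fit_per_participant(df, "tf", which="frequency", min_rows=200)
        grid = np.linspace(df["surp"].quantile(0.1), df["surp"].quantile(0.9), 9)
        pe = fits["frequency"].partial_effect("surp", grid)
        assert np.ptp(pe) < 2.0  # well within the 10 ms noise scale


class TestGroupComparisons:
    def test_identical_groups_give_t_zero(self):
        x = np.arange(10.0)
        c = group_compare(x, x.copy())
        assert c.t == pytest.approx(0.0, abs=1e-12)
        assert c.stars == "(.)"

    def test_group_size_below_two_rejected(self):
        with pytest.raises(ValueError, match="at least 2"):
            group_compare([1.0], [1.0, 2.0])

    def test_type_i_error_calibrated(self):
        rng = np.random.default_rng(8)
        rej = 0
        n_sim = 400
        for _ in range(n_sim):
            a = rng.normal(10, 3, 30)
            b = rng.normal(10, 3, 60)
            if group_compare(a, b).p_value < 0.05:
                rej += 1
        assert 0.03 <= rej / n_sim <= 0.08

    def test_power_for_doubled_l2_amplitude(self):
        # L2 mean effect twice the L1 mean at n = 40 + 40
        rng = np.random.default_rng(9)
        detected = 0
        n_sim = 60
        for _ in range(n_sim):
            l1 = rng.normal(10, 4, 40)
            l2 = rng.normal(20, 4, 40)
            if group_compare(l1, l2).p_value < 0.01:
                detected += 1
        assert detected / n_sim >= 0.9

    def test_paired_identical_columns_t_zero(self):
        x = np.arange(8.0)
        t, p = paired_compare(x, x.copy())
        assert t == pytest.approx(0.0, abs=1e-12)

    def test_paired_swap_negates_t(self):
        rng = np.random.default_rng(10)
        a, b = rng.normal(10, 2, 20), rng.normal(12, 2, 20)
        t1, _ = paired_compare(a, b)
        t2, _ = paired_compare(b, a)
        assert t1 == pytest.approx(-t2, rel=1e-12)

    def test_paired_power_when_surprisal_exceeds_frequency(self):
        rng = np.random.default_rng(11)
        detected = 0
        for _ in range(50):
            freq = rng.normal(15, 3, 40)
            surp = freq + rng.normal(3, 2, 40)
            t, p = paired_compare(freq, surp)
            if p < 0.05 and t > 0:
                detected += 1
        assert detected / 50 >= 0.9


class TestPipelineSlowdowns:
    def test_slowdown_table_covers_all_cells(self, small_retained):
        slow = compute_all_slowdowns(
            small_retained, measures=("tf",), min_rows=100, surprisal_from="frequency_model"
        )
        assert set(slow["property"]) == {"freq", "surp", "len"}
        per_participant = slow.groupby("participant_id").size()
        assert (per_participant == 3).all()

    def test_generative_ordering_preserved(self, small_annotations):
        # L2 amplitudes 2x L1: pipeline group means must preserve the ordering
        prof_l1 = generate_participants(6, 0, random_effect_sds={}, seed=12)
        prof_l2 = generate_participants(0, 6, random_effect_sds={}, seed=13)
        eff_l1 = GenerativeEffectSpec(
            effects={"surp": (4.0,), "freq": (2.0,), "len": (1.0,)}, noise_sd=25.0
        )
        eff_l2 = GenerativeEffectSpec(
            effects={"surp": (8.0,), "freq": (4.0,), "len": (2.0,)}, noise_sd=25.0
        )
        frames = []
        for profs, eff, seed in ((prof_l1, eff_l1, 14), (prof_l2, eff_l2, 15)):
            for i, p in enumerate(profs):
                df = sample_modeling_frame(small_annotations, [p], 700, eff, seed=seed * 100 + i)
                df["group"] = p.group
                frames.append(df)
        data = pd.concat(frames, ignore_index=True)
        slow = compute_all_slowdowns(
            data, measures=("tf",), min_rows=200, surprisal_from="frequency_model"
        )
        for prop in ("surp", "freq"):
            g = slow[slow["property"] == prop]
            m_l1 = g.loc[g["group"] == "L1", "slowdown"].mean()
            m_l2 = g.loc[g["group"] == "L2", "slowdown"].mean()
            assert m_l2 > m_l1
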