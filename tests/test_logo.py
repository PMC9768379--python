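"""Pause-site calling, PWMs, JS divergence, permutation significance."""

import itertools

import numpy as np
import pytest
from scipy.spatial.distance import jensenshannon

import poliseq as pq
from poliseq.logo import _encode_contexts, _jsd_rows


class TestCallPauseSites:
    def test_top_fraction_count(self, default_template):
        # spacers total 1690 positions; q=2.5 -> ceil(42.25) = 43
        rng = np.random.default_rng(0)
        med = rng.random(default_template.length)
        sites = pq.call_pause_sites(med, 2.5, default_template)
        assert len(sites) == int(np.ceil(0.025 * 1690))

    def test_q100_returns_all_region_positions(self, default_template):
        med = np.zeros(default_template.length)
        sites = pq.call_pause_sites(med, 100, default_template)
        assert np.array_equal(sites, default_template.positions_of_class("spacer"))

    def test_planted_spikes_recovered(self, default_template):
        rng = np.random.default_rng(1)
        spacer = default_template.positions_of_class("spacer")
        spikes = np.sort(rng.choice(spacer, size=25, replace=False))
        med = np.zeros(default_template.length)
        med[spikes] = 100 + rng.random(25)
        q = 25 / len(spacer) * 100
        sites = pq.call_pause_sites(med, q, default_template)
        assert np.array_equal(sites, spikes)

    def test_ties_broken_by_lower_coordinate(self, small_template):
        med = np.ones(small_template.length)
        sites = pq.call_pause_sites(med, 10, small_template, region_names=["ETS1"])
        assert np.array_equal(sites, np.arange(4))  # ceil(0.1*40)=4 lowest coords

    def test_restricted_to_named_regions(self, default_template):
        med = np.zeros(default_template.length)
        r18s = default_template.region_by_name("18S")
        med[r18s.start : r18s.end] = 100.0  # mature spike must be ignored
        sites = pq.call_pause_sites(med, 2.5, default_template)
        assert all(
            pq.region_of(default_template, int(p)).cls == "spacer" for p in sites
        )


class TestContexts:
    def test_single_offset_window_returns_bases(self, small_template):
        contexts, dropped = pq.extract_contexts(small_template, [0, 5, 99], window=(0,))
        assert contexts == [small_template.sequence[i] for i in (0, 5, 99)]
        assert dropped == 0

    def test_position_near_edge_dropped(self, small_template):
        contexts, dropped = pq.extract_contexts(
            small_template, [2], window=tuple(range(-5, 1))
        )
        assert contexts == []
        assert dropped == 1

    def test_matches_substring_oracle(self, default_template):
        rng = np.random.default_rng(2)
        window = tuple(range(-10, 6))
        positions = rng.integers(20, default_template.length - 20, size=100)
        contexts, dropped = pq.extract_contexts(default_template, positions, window)
        assert dropped == 0
        for p, ctx in zip(positions, contexts):
            assert ctx == default_template.sequence[p - 10 : p + 6]

    def test_window_must_include_zero(self, small_template):
        with pytest.raises(ValueError, match="offset 0"):
            pq.extract_contexts(small_template, [5], window=(1, 2))


class TestPWM:
    def test_pure_a_column_without_pseudocount(self):
        pwm = pq.pwm_from_contexts(["A", "A", "A"], pseudocount=0)
        assert np.array_equal(pwm.probs[0], [1, 0, 0, 0])

    def test_pseudocount_arithmetic(self):
        pwm = pq.pwm_from_contexts(["A"], pseudocount=1)
        assert np.allclose(pwm.probs[0], [2 / 5, 1 / 5, 1 / 5, 1 / 5])

    def test_rows_sum_to_one(self):
        rng = np.random.default_rng(3)
        contexts = ["".join(rng.choice(list("ACGT"), size=8)) for _ in range(50)]
        pwm = pq.pwm_from_contexts(contexts)
        assert np.allclose(pwm.probs.sum(axis=1), 1.0)
        assert pwm.n_contexts == 50

    def test_empty_and_ragged_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            pq.pwm_from_contexts([])
        with pytest.raises(ValueError, match="unequal"):
            pq.pwm_from_contexts(["AA", "A"])

    def test_counts_match_counter_oracle(self):
        from collections import Counter

        rng = np.random.default_rng(4)
        contexts = ["".join(rng.choice(list("ACGT"), size=5)) for _ in range(200)]
        pwm = pq.pwm_from_contexts(contexts, pseudocount=0)
        for j in range(5):
            counter = Counter(c[j] for c in contexts)
            oracle = np.array([counter[b] for b in "ACGT"]) / 200
            assert np.allclose(pwm.probs[j], oracle)


class TestJSDivergence:
    def test_identity_zero(self):
        assert pq.js_divergence([0.1, 0.2, 0.3, 0.4], [0.1, 0.2, 0.3, 0.4]) == 0.0

    def test_disjoint_supports_attain_one_bit(self):
        assert pq.js_divergence([1, 0, 0, 0], [0, 1, 0, 0]) == pytest.approx(1.0)

    def test_against_scipy_oracle(self):
        p = [0.5, 0.5, 0.0, 0.0]
        q = [0.25, 0.25, 0.25, 0.25]
        oracle = jensenshannon(p, q, base=2) ** 2
        assert pq.js_divergence(p, q) == pytest.approx(oracle, abs=1e-12)

    def test_symmetry_and_bounds_on_random_pairs(self):
        rng = np.random.default_rng(5)
        for _ in range(1000):
            p = rng.dirichlet(np.ones(4) * rng.uniform(0.2, 3))
            q = rng.dirichlet(np.ones(4) * rng.uniform(0.2, 3))
            d = pq.js_divergence(p, q)
            assert 0.0 <= d <= 1.0
            assert d == pytest.approx(pq.js_divergence(q, p), abs=1e-12)
            assert d == pytest.approx(jensenshannon(p, q, base=2) ** 2, abs=1e-9)

    def test_unnormalized_rejected(self):
        with pytest.raises(ValueError):
            pq.js_divergence([0.5, 0.5, 0.5, 0.0], [0.25, 0.25, 0.25, 0.25])


class TestDiffLogo:
    def rand_pwm(self, rng, width=6):
        probs = rng.dirichlet(np.ones(4), size=width)
        return pq.PWM(offsets=tuple(range(width)), probs=probs, n_contexts=10)

    def test_identical_pwms_all_zero(self):
        rng = np.random.default_rng(6)
        pwm = self.rand_pwm(rng)
        res = pq.diff_logo(pwm, pwm)
        assert np.allclose(res.jsd, 0.0)
        assert np.allclose(res.letter_deltas, 0.0)

    def test_single_offset_difference_localized(self):
        base = np.tile([0.25, 0.25, 0.25, 0.25], (4, 1))
        other = base.copy()
        other[2] = [0.7, 0.1, 0.1, 0.1]
        a = pq.PWM(tuple(range(4)), base, 5)
        b = pq.PWM(tuple(range(4)), other, 5)
        res = pq.diff_logo(a, b)
        assert res.jsd[2] > 0
        assert np.allclose(np.delete(res.jsd, 2), 0.0)

    def test_composition_matches_offsetwise_js(self):
        rng = np.random.default_rng(7)
        a, b = self.rand_pwm(rng), self.rand_pwm(rng)
        res = pq.diff_logo(a, b)
        for j in range(6):
            assert res.jsd[j] == pytest.approx(
                pq.js_divergence(a.probs[j], b.probs[j]), abs=1e-12
            )
        # signed deltas sum to zero per offset
        assert np.allclose(res.letter_deltas.sum(axis=1), 0.0)

    def test_window_mismatch_rejected(self):
        rng = np.random.default_rng(8)
        a = self.rand_pwm(rng, width=4)
        b = pq.PWM(tuple(range(1, 5)), rng.dirichlet(np.ones(4), size=4), 5)
        with pytest.raises(ValueError, match="windows"):
            pq.diff_logo(a, b)


class TestPermutation:
    def test_identical_multisets_give_p_one(self):
        contexts = ["AC", "GT", "AC", "TT"]
        p = pq.permutation_test(contexts, list(contexts), n_perm=199, seed=0)
        assert np.all(p == 1.0)

    def test_perfect_separation_attains_minimum_p(self):
        p = pq.permutation_test(["A"] * 50, ["C"] * 50, n_perm=999, seed=1)
        assert p[0] == pytest.approx(1 / 1000)

    def test_pvalues_in_unit_interval(self):
        rng = np.random.default_rng(9)
        ca = ["".join(rng.choice(list("ACGT"), size=3)) for _ in range(20)]
        cb = ["".join(rng.choice(list("ACGT"), size=3)) for _ in range(20)]
        p = pq.permutation_test(ca, cb, n_perm=99, seed=2)
        assert np.all((p > 0) & (p <= 1))

    def test_matches_exhaustive_enumeration_on_toy(self):
        # 4+4 contexts: exact p = fraction of all C(8,4) label splits with
        # permuted JSD >= observed; the sampled p must approach it
        ca, cb = ["A", "A", "A", "C"], ["C", "C", "G", "T"]
        coded = _encode_contexts(ca + cb)
        pc = 0.5

        def probs(rows):
            counts = np.bincount(rows[:, 0], minlength=4)
            return (counts + pc) / (len(rows) + 4 * pc)

        observed = _jsd_rows(probs(coded[:4]), probs(coded[4:]))[()]
        exceed = total = 0
        for combo in itertools.combinations(range(8), 4):
            mask = np.zeros(8, dtype=bool)
            mask[list(combo)] = True
            stat = _jsd_rows(probs(coded[mask]), probs(coded[~mask]))[()]
            exceed += stat >= observed - 1e-12
            total += 1
        exact = exceed / total
        p_hat = pq.permutation_test(ca, cb, n_perm=4999, seed=3)[0]
        assert p_hat == pytest.approx(exact, abs=0.05)

    def test_empty_set_rejected(self):
        with pytest.raises(ValueError, match="nonempty"):
            pq.permutation_test([], ["A"], n_perm=99)
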