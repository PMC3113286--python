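import itertools

import numpy as np
import pytest

from ephyskit import ParameterError
from ephyskit.epochs import EpochSet
from ephyskit.stats import (StatResult, baseline_emergence, bonferroni,
                            duration_criterion, fdr_bh, kruskal_wallis,
                            pvalues_to_evoked, pvalues_to_tf, quade,
                            randomization_test, t_test_paired,
                            wilcoxon_paired)


class TestWilcoxon:
    def test_all_positive_differences_exact_p(self):
        a = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        b = np.zeros(5)
        two = wilcoxon_paired(a[:, None], b[:, None]).p[0]
        one = wilcoxon_paired(a[:, None], b[:, None],
                              alternative="greater").p[0]
        assert one == pytest.approx(1 / 32)
        assert two == pytest.approx(1 / 16)

    def test_identical_inputs_p_one(self):
        a = np.random.default_rng(0).normal(size=(8, 3))
        res = wilcoxon_paired(a, a)
        assert np.all(res.p == 1.0)

    def test_exact_matches_sign_enumeration(self):
        """n = 12: exact p equals brute-force enumeration of all 2^12 sign
        assignments of the rank statistic."""
        rng = np.random.default_rng(5)
        for _ in range(5):
            d = rng.normal(size=12)
            a = d[:, None]
            b = np.zeros_like(a)
            got = wilcoxon_paired(a, b).p[0]
            ranks = np.argsort(np.argsort(np.abs(d))) + 1
            w_obs = ranks[d > 0].sum()
            n = 12
            stats = []
            for pat in range(2 ** n):
                signs = [(pat >> i) & 1 for i in range(n)]
                stats.append(sum(r for r, s in zip(ranks, signs) if s))
            stats = np.asarray(stats)
            mean_w = n * (n + 1) / 4
            p_exact = np.mean(np.abs(stats - mean_w) >= abs(w_obs - mean_w) - 1e-9)
            assert got == pytest.approx(p_exact, abs=1e-12)

    def test_too_few_pairs(self):
        with pytest.raises(ParameterError):
            wilcoxon_paired(np.zeros((4, 1)), np.ones((4, 1)))


class TestTTest:
    def test_matches_textbook_formula(self):
        rng = np.random.default_rng(1)
        a = rng.normal(size=(10, 4))
        b = rng.normal(size=(10, 4))
        res = t_test_paired(a, b)
        d = a - b
        t = d.mean(0) / (d.std(0, ddof=1) / np.sqrt(10))
        from scipy.stats import t as tdist
        p = 2 * tdist.sf(np.abs(t), 9)
        assert np.allclose(res.statistic, t, atol=1e-12)
        assert np.allclose(res.p, p, atol=1e-12)

    def test_identical_inputs(self):
        a = np.ones((6, 2))
        res = t_test_paired(a, a.copy())
        assert np.all(res.statistic == 0.0)
        assert np.all(res.p == 1.0)

    def test_degenerate_constant_difference(self):
        a = np.ones((6, 1))
        res = t_test_paired(a + 1.0, a)
        assert res.extra["degenerate"][0]
        assert 0 < res.p[0] <= np.finfo(float).tiny


class TestKruskalWallis:
    def test_identical_groups(self):
        g = np.ones((5, 2))
        res = kruskal_wallis([g, g.copy(), g.copy()])
        assert np.all(res.statistic == 0.0)
        assert np.all(res.p == 1.0)

    def test_hand_computed_h(self):
        groups = [np.array([1.0, 2, 3])[:, None],
                  np.array([4.0, 5, 6])[:, None],
                  np.array([7.0, 8, 9])[:, None]]
        res = kruskal_wallis(groups)
        # ranks 1..9, perfectly separated: H = 12/(9*10) * 3*((2-5)^2+0+3^2) * 3 ... = 7.2
        assert res.statistic[0] == pytest.approx(7.2)

    def test_invariant_under_monotone_transform(self):
        rng = np.random.default_rng(2)
        groups = [rng.normal(size=(6, 3)) for _ in range(3)]
        r1 = kruskal_wallis(groups)
        r2 = kruskal_wallis([np.exp(g) for g in groups])
        assert np.allclose(r1.statistic, r2.statistic, atol=1e-12)


class TestQuade:
    def test_all_identical_degenerate(self):
        table = np.ones((5, 3))
        res = quade(table)
        assert np.all(res.p == 1.0)

    def test_conover_textbook_example(self):
        """Store-sales style example checked against an independent
        from-scratch rank computation (Conover's classic 7-block, 3-brand
        layout)."""
        table = np.array([
            [5.0, 4.0, 7.0],
            [1.0, 3.0, 1.0],
            [16.0, 12.0, 22.0],
            [5.0, 4.0, 3.0],
            [10.0, 9.0, 7.0],
            [19.0, 18.0, 28.0],
            [10.0, 7.0, 6.0],
        ])
        res = quade(table)
        # independent implementation of the rank algebra
        from scipy.stats import rankdata

        b, k = table.shape
        r = np.vstack([rankdata(row) for row in table])
        q = rankdata(table.max(1) - table.min(1))
        s = q[:, None] * (r - (k + 1) / 2)
        A = (s ** 2).sum()
        B = (s.sum(0) ** 2).sum() / b
        F = (b - 1) * B / (A - B)
        assert res.statistic == pytest.approx(F)
        from scipy.stats import f as fdist
        assert res.p == pytest.approx(fdist.sf(F, k - 1, (b - 1) * (k - 1)))

    def test_two_treatments_agree_with_wilcoxon_direction(self):
        """k = 2: the Quade decision tracks the signed-rank decision."""
        rng = np.random.default_rng(3)
        agree = 0
        for _ in range(100):
            a = rng.normal(size=12)
            b = a + rng.normal(scale=1.0, size=12) + rng.uniform(-0.5, 1.0)
            tq = quade(np.column_stack([a, b]))
            tw = wilcoxon_paired(a[:, None], b[:, None])
            # compare at a fixed alpha
            agree += (tq.p[()] < 0.05) == (tw.p[0] < 0.05)
        assert agree >= 85

    def test_perfect_concordance_permutation_fallback(self):
        table = np.array([[1.0, 2.0], [3.0, 4.0], [5.0, 6.0], [7.0, 8.0]])
        res = quade(table)
        assert 0 < res.p[()] < 0.2  # extreme table, small permutation p


class TestRandomization:
    def test_identical_pairs_p_one(self):
        a = np.random.default_rng(0).normal(size=(8, 3))
        res = randomization_test((a, a.copy()), "paired_signflip",
                                 n_perm=200, seed=0)
        assert np.all(res.p == 1.0)

    def test_exhaustive_signflip_matches_enumeration(self):
        rng = np.random.default_rng(4)
        d = rng.normal(size=8)
        a = d[:, None]
        b = np.zeros_like(a)
        res = randomization_test((a, b), "paired_signflip", n_perm=100,
                                 seed=0)
        assert res.extra["exhaustive"]
        stats = []
        for signs in itertools.product([-1.0, 1.0], repeat=8):
            stats.append(np.mean(d * np.asarray(signs)))
        stats = np.abs(np.asarray(stats))
        p_expect = np.mean(stats >= abs(d.mean()) - 1e-15)
        assert res.p[0] == pytest.approx(p_expect, abs=1e-12)

    def test_twosample_exhaustive_matches_enumeration(self):
        rng = np.random.default_rng(5)
        a = rng.normal(size=(4, 1))
        b = rng.normal(size=(4, 1)) + 1.0
        res = randomization_test((a, b), "twosample_shuffle", n_perm=100,
                                 seed=0)
        pooled = np.concatenate([a, b])[:, 0]
        obs = abs(a.mean() - b.mean())
        vals = []
        for sel in itertools.combinations(range(8), 4):
            rest = [i for i in range(8) if i not in sel]
            vals.append(abs(pooled[list(sel)].mean() - pooled[rest].mean()))
        p_expect = np.mean(np.asarray(vals) >= obs - 1e-15)
        assert res.p[0] == pytest.approx(p_expect, abs=1e-12)

    def test_maxstat_subset_of_uncorrected(self):
        rng = np.random.default_rng(6)
        a = rng.normal(size=(12, 20))
        b = a + rng.normal(scale=0.5, size=(12, 20)) + 0.4
        plain = randomization_test((a, b), "paired_signflip", n_perm=300,
                                   seed=1)
        maxs = randomization_test((a, b), "paired_signflip", n_perm=300,
                                  seed=1, correction="maxstat")
        alpha = 0.05
        assert np.all((maxs.p < alpha) <= (plain.p < alpha))

    def test_additive_model_detects_interaction(self):
        rng = np.random.default_rng(7)
        n = 30
        A = rng.normal(1.0, 1.0, size=(n, 1))
        V = rng.normal(2.0, 1.0, size=(n, 1))
        AV = rng.normal(3.0 + 1.5, 1.0, size=(n, 1))  # super-additive
        res = randomization_test((A, V, AV), "multisensory_additive",
                                 n_perm=499, seed=2)
        assert res.p[0] < 0.01
        assert res.statistic[0] == pytest.approx(
            AV.mean() - A.mean() - V.mean())

    def test_additive_model_null_calibration(self):
        """AV distributed as A + V: rejection rate stays at the 5% level."""
        rng = np.random.default_rng(17)
        rej = 0
        n_runs = 300
        for s in range(n_runs):
            A = rng.normal(1.0, 1.0, size=(10, 1))
            V = rng.normal(2.0, 1.0, size=(10, 1))
            AV = rng.normal(3.0, np.sqrt(2.0), size=(10, 1))
            res = randomization_test((A, V, AV), "multisensory_additive",
                                     n_perm=199, seed=s)
            rej += res.p[0] < 0.05
        rate = rej / n_runs
        ci = 2.576 * np.sqrt(0.05 * 0.95 / n_runs)
        assert abs(rate - 0.05) < ci + 0.01

    def test_seed_reproducibility(self):
        rng = np.random.default_rng(8)
        a = rng.normal(size=(30, 2))
        b = rng.normal(size=(30, 2))
        r1 = randomization_test((a, b), "paired_signflip", n_perm=200, seed=3)
        r2 = randomization_test((a, b), "paired_signflip", n_perm=200, seed=3)
        assert np.array_equal(r1.p, r2.p)


class TestCorrections:
    def test_bonferroni_single_point(self):
        assert bonferroni(np.array([0.04]), 0.05)[0]

    def test_bonferroni_strict_at_boundary(self):
        p = np.full(10, 0.005)  # == alpha / M exactly
        assert not bonferroni(p, 0.05).any()

    def test_bonferroni_subset_of_uncorrected(self):
        rng = np.random.default_rng(9)
        p = rng.uniform(size=(5, 40))
        mask = bonferroni(p, 0.05)
        assert np.all(mask <= (p < 0.05))

    def test_fdr_all_small(self):
        p = np.full(100, 0.001)
        mask, thr = fdr_bh(p, 0.05)
        assert mask.all()
        assert thr == pytest.approx(0.001)

    def test_fdr_matches_brute_force(self):
        rng = np.random.default_rng(10)
        for _ in range(20):
            p = rng.uniform(size=60) ** rng.uniform(0.5, 2.0)
            mask, _ = fdr_bh(p, 0.05)
            # brute-force step-up: largest k with p_(k) <= k q / M
            srt = np.sort(p)
            M = p.size
            ks = np.nonzero(srt <= (np.arange(1, M + 1) * 0.05 / M))[0]
            if ks.size:
                expect = p <= srt[ks[-1]]
            else:
                expect = np.zeros(M, dtype=bool)
            assert np.array_equal(mask, expect)

    def test_fdr_controls_rate_on_mixed_maps(self):
        """Average false-rejection proportion stays below q."""
        rng = np.random.default_rng(11)
        q, fdps = 0.05, []
        for _ in range(400):
            p_null = rng.uniform(size=80)
            p_sig = rng.uniform(size=20) * 1e-4
            p = np.concatenate([p_null, p_sig])
            mask, _ = fdr_bh(p, q)
            n_rej = mask.sum()
            if n_rej:
                fdps.append(mask[:80].sum() / n_rej)
            else:
                fdps.append(0.0)
        assert np.mean(fdps) <= q * 1.2

    @pytest.mark.parametrize("L,run,expect", [
        (5, 4, 0), (5, 5, 5), (3, 7, 7), (1, 1, 1),
    ])
    def test_duration_run_lengths(self, L, run, expect):
        p = np.ones(30)
        p[10:10 + run] = 0.01
        mask = duration_criterion(p[None, :], 0.05, L)
        assert mask.sum() == expect

    def test_duration_matches_scan_oracle(self):
        rng = np.random.default_rng(12)
        for _ in range(20):
            p = rng.uniform(size=(3, 50))
            L = int(rng.integers(1, 6))
            mask = duration_criterion(p, 0.3, L)
            expect = np.zeros_like(mask)
            for c in range(3):
                below = p[c] < 0.3
                run = 0
                for i in range(50):
                    run = run + 1 if below[i] else 0
                    if below[i] and run >= L:
                        expect[c, i - run + 1:i + 1] = True
            assert np.array_equal(mask, expect)


class TestBaselineEmergence:
    def make_epochs(self, data, fs=100.0, t0=-0.2):
        n_tr, n_ch, _ = data.shape
        return EpochSet(data, fs, t0, 1, np.arange(n_tr), np.zeros(n_tr),
                        [f"c{i}" for i in range(n_ch)], ["uV"] * n_ch)

    def test_large_component_minimal_p_at_latency(self):
        rng = np.random.default_rng(13)
        n_tr, n_s = 20, 60
        data = rng.normal(scale=0.3, size=(n_tr, 1, n_s))
        data[:, 0, 40:50] += 5.0
        e = self.make_epochs(data)
        res = baseline_emergence(e, (-0.2, 0.0))
        assert res.p[0, 40:50].max() < 0.01
        assert np.median(res.p[0, :20]) > 0.2  # baseline region at chance

    def test_format_closure_to_containers(self):
        rng = np.random.default_rng(14)
        e = self.make_epochs(rng.normal(size=(12, 2, 30)))
        res = baseline_emergence(e, (-0.2, -0.1))
        evk = pvalues_to_evoked(res, e.fs, e.t0, e.event_code,
                                e.channel_names)
        assert evk.data.shape == (2, 30)
        tfr = pvalues_to_tf(
            StatResult(res.statistic[:, None, :], res.p[:, None, :],
                       res.test, res.n),
            [10.0], e.fs, e.t0, e.event_code, e.channel_names)
        assert tfr.quantity == "pvalue"
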