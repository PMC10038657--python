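"""Local-ancestry HMM: site selection, kernels vs enumeration oracles,
pulse-time estimation, tract calling, admixture proportion."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import admixclock as ac
from admixclock import hmm
from admixclock.hmm import (
    AncestryPulseModel,
    HMMParams,
    bootstrap_pulse_time,
    call_tracts,
    emission_probs,
    estimate_alpha,
    estimate_pulse_time,
    forward_backward,
    select_informative_sites,
    transition_matrix,
    viterbi,
)


def make_panel(pos, pA, pB, chrom="1", morgans_per_bp=1e-8, nA=20, nB=20):
    pos = np.asarray(pos)
    return ac.PanelPair(
        sites=pd.DataFrame(
            {
                "chrom": chrom,
                "pos": pos,
                "genetic_pos": pos * morgans_per_bp,
                "pA": pA,
                "pB": pB,
                "nA": nA,
                "nB": nB,
            }
        )
    )


# ---------------------------------------------------------------------------
# independent oracle: enumerate over pairs of haploid ancestry paths


def hap_trans(d, T, alpha):
    x = np.exp(-d * T)
    # rows/cols: (generalist, specialist)
    return np.array(
        [
            [x + (1 - x) * (1 - alpha), (1 - x) * alpha],
            [(1 - x) * (1 - alpha), x + (1 - x) * alpha],
        ]
    )


def brute_force_likelihood(genotypes, pos_m, params, pA, pB):
    """Sum over all pairs of haploid ancestry paths (2^n x 2^n)."""
    n = len(genotypes)
    d = np.diff(pos_m)
    pi = np.array([1 - params.alpha, params.alpha])
    total = 0.0
    for h1 in itertools.product((0, 1), repeat=n):
        for h2 in itertools.product((0, 1), repeat=n):
            p = pi[h1[0]] * pi[h2[0]]
            for t in range(1, n):
                A = hap_trans(d[t - 1], params.T, params.alpha)
                p *= A[h1[t - 1], h1[t]] * A[h2[t - 1], h2[t]]
            for t in range(n):
                k = h1[t] + h2[t]
                p *= emission_probs(genotypes[t], k, pA[t], pB[t], params.error_rate)
            total += p
    return np.log(total)


def brute_force_viterbi(genotypes, pos_m, params, pA, pB):
    """Argmax over all 3^n dosage paths using independently built diploid
    transitions (haploid enumeration), ties to the lexicographically smallest
    (lowest-dosage-first) path."""
    n = len(genotypes)
    d = np.diff(pos_m)
    pi = np.array([1 - params.alpha, params.alpha])
    start = np.array([pi[0] ** 2, 2 * pi[0] * pi[1], pi[1] ** 2])

    def diploid(dd):
        # from dosage j via a representative unordered haplotype pair
        A = hap_trans(dd, params.T, params.alpha)
        out = np.zeros((3, 3))
        reps = {0: (0, 0), 1: (0, 1), 2: (1, 1)}
        for j, (a1, a2) in reps.items():
            for b1 in (0, 1):
                for b2 in (0, 1):
                    out[j, b1 + b2] += A[a1, b1] * A[a2, b2]
        return out

    best_p, best_path = -np.inf, None
    # product() is lexicographic, so strict > keeps the lowest-dosage tie
    for path in itertools.product((0, 1, 2), repeat=n):
        p = start[path[0]] * emission_probs(
            genotypes[0], path[0], pA[0], pB[0], params.error_rate
        )
        for t in range(1, n):
            p *= diploid(d[t - 1])[path[t - 1], path[t]]
            p *= emission_probs(genotypes[t], path[t], pA[t], pB[t], params.error_rate)
        if p > best_p:
            best_p, best_path = p, path
    return np.array(best_path), np.log(best_p)


class TestSiteSelection:
    def test_filters_and_boundary(self):
        panel = make_panel(
            pos=[10_000, 40_000, 80_000, 120_000],
            pA=[0.9, 0.3, 0.9, 0.9],
            pB=[0.5, 0.0, 0.5, 0.5],
            nA=[20, 20, 5, 20],
            nB=20,
        )
        kept = select_informative_sites(panel)
        # site 0 passes (|diff|=0.4); site 1 dropped (=0.3 exactly, strict);
        # site 2 dropped (nA=5 < 10); site 3 passes
        assert list(kept.sites["pos"]) == [10_000, 120_000]

    def test_dense_grid_thins_to_exact_spacing(self):
        pos = np.arange(1, 101) * 1000
        panel = make_panel(pos=pos, pA=0.8, pB=0.3)
        kept = select_informative_sites(panel)
        gaps = np.diff(kept.sites["pos"])
        assert np.all(gaps == 10_000)

    def test_zero_survivors_raises_with_counts(self):
        panel = make_panel(pos=[1000, 2000], pA=0.5, pB=0.5)
        with pytest.raises(ValueError, match="freq-diff filter 0"):
            select_informative_sites(panel)


class TestTransitionMatrix:
    def test_zero_distance_is_identity(self):
        A = transition_matrix(0.0, HMMParams(T=450, alpha=0.3))
        np.testing.assert_allclose(A, np.eye(3), atol=1e-15)

    def test_infinite_distance_reaches_stationary(self):
        params = HMMParams(T=450, alpha=0.3)
        A = transition_matrix(1e3, params)
        for row in A:
            np.testing.assert_allclose(row, params.stationary, atol=1e-12)

    def test_haploid_closed_form(self):
        # P(specialist -> specialist) over d=0.01 at T=450, alpha=0.3
        x = np.exp(-4.5)
        expected = x + (1 - x) * 0.3
        A = hap_trans(0.01, 450.0, 0.3)
        assert A[1, 1] == pytest.approx(expected, abs=1e-12)
        assert expected == pytest.approx(0.3078, abs=1e-4)
        # and the diploid hom->hom entry is its square
        D = transition_matrix(0.01, HMMParams(T=450, alpha=0.3))
        assert D[2, 2] == pytest.approx(expected**2, abs=1e-12)

    def test_rows_sum_to_one_and_chapman_kolmogorov(self):
        rng = np.random.default_rng(5)
        for _ in range(20):
            T = rng.uniform(10, 2000)
            alpha = rng.uniform(0.05, 0.95)
            d1, d2 = rng.uniform(0, 0.05, 2)
            params = HMMParams(T=T, alpha=alpha)
            A1, A2 = transition_matrix(d1, params), transition_matrix(d2, params)
            np.testing.assert_allclose(A1.sum(axis=1), 1.0, atol=1e-12)
            np.testing.assert_allclose(
                transition_matrix(d1 + d2, params), A1 @ A2, atol=1e-12
            )

    def test_negative_distance_rejected(self):
        with pytest.raises(ValueError):
            transition_matrix(-0.1, HMMParams(T=10, alpha=0.5))

    @settings(deadline=None, derandomize=True, max_examples=60)
    @given(
        T=st.floats(1.0, 9000.0),
        alpha=st.floats(0.01, 0.99),
        d1=st.floats(0.0, 0.2),
        d2=st.floats(0.0, 0.2),
    )
    def test_semigroup_property_holds_everywhere(self, T, alpha, d1, d2):
        # the haploid family exp(-dT)I + (1-exp(-dT))Pi is semigroup-closed,
        # so the collapsed diploid chain must satisfy Chapman-Kolmogorov too
        params = HMMParams(T=T, alpha=alpha)
        lhs = transition_matrix(d1 + d2, params)
        rhs = transition_matrix(d1, params) @ transition_matrix(d2, params)
        assert np.max(np.abs(lhs - rhs)) < 1e-12
        assert np.max(np.abs(lhs.sum(axis=1) - 1.0)) < 1e-12


class TestEmissions:
    def test_deterministic_cases(self):
        assert emission_probs(2, 2, pA=1.0, pB=0.2, eps=0.0) == 1.0
        assert emission_probs(1, 1, pA=1.0, pB=0.0, eps=0.0) == 1.0
        assert emission_probs(0, 1, pA=1.0, pB=0.0, eps=0.0) == 0.0

    def test_binomial_expansion_for_dosage_zero(self):
        probs = [emission_probs(g, 0, pA=0.9, pB=0.5, eps=0.0) for g in (0, 1, 2)]
        np.testing.assert_allclose(probs, [0.25, 0.5, 0.25])

    def test_missing_scores_one_everywhere(self):
        for k in (0, 1, 2):
            assert emission_probs(None, k, 0.5, 0.5, 0.01) == 1.0
            assert emission_probs(-1, k, 0.5, 0.5, 0.01) == 1.0

    def test_invalid_genotype_rejected(self):
        with pytest.raises(ValueError, match="genotype"):
            emission_probs(3, 0, 0.5, 0.5, 0.01)


class TestForwardBackwardAndViterbi:
    @pytest.fixture
    def toy(self):
        panel = make_panel(
            pos=[10_000, 1_010_000, 2_510_000], pA=[0.9, 0.8, 0.95], pB=[0.2, 0.4, 0.1]
        )
        params = HMMParams(T=300.0, alpha=0.35, error_rate=0.02)
        genotypes = np.array([2, 1, 0], dtype=np.int8)
        return panel, params, genotypes

    def test_likelihood_matches_haploid_path_enumeration(self, toy):
        panel, params, genotypes = toy
        _, ll = forward_backward(genotypes, panel, params)
        ll_brute = brute_force_likelihood(
            genotypes,
            panel.sites["genetic_pos"].to_numpy(),
            params,
            panel.sites["pA"].to_numpy(),
            panel.sites["pB"].to_numpy(),
        )
        assert ll == pytest.approx(ll_brute, abs=1e-10)

    def test_log_space_engine_agrees_with_scaled(self, toy):
        panel, params, genotypes = toy
        post_s, ll_s = forward_backward(genotypes, panel, params)
        post_l, ll_l = forward_backward(genotypes, panel, params, use_log=True)
        assert ll_s == pytest.approx(ll_l, abs=1e-9)
        np.testing.assert_allclose(post_s, post_l, atol=1e-9)

    def test_posteriors_normalized_and_stationary_when_missing(self, toy):
        panel, params, _ = toy
        post, _ = forward_backward(np.full(3, -1, dtype=np.int8), panel, params)
        np.testing.assert_allclose(post.sum(axis=1), 1.0, atol=1e-9)
        np.testing.assert_allclose(post, np.tile(params.stationary, (3, 1)), atol=1e-9)

    def test_viterbi_matches_enumeration(self, toy):
        panel, params, genotypes = toy
        path = viterbi(genotypes, panel, params)
        expected, _ = brute_force_viterbi(
            genotypes,
            panel.sites["genetic_pos"].to_numpy(),
            params,
            panel.sites["pA"].to_numpy(),
            panel.sites["pB"].to_numpy(),
        )
        np.testing.assert_array_equal(path, expected)

    def test_uninformative_data_gives_modal_stationary_path(self):
        panel = make_panel(pos=[10_000, 20_000, 30_000], pA=0.8, pB=0.3)
        params = HMMParams(T=100.0, alpha=0.2)  # modal stationary state: dosage 0
        path = viterbi(np.full(3, -1, dtype=np.int8), panel, params)
        np.testing.assert_array_equal(path, 0)

    def test_diagnostic_run_flips_path_to_homozygous(self):
        pos = np.arange(1, 41) * 50_000
        panel = make_panel(pos=pos, pA=0.95, pB=0.05)
        params = HMMParams(T=100.0, alpha=0.2)
        geno = np.zeros(40, dtype=np.int8)
        geno[15:25] = 2  # long specialist-diagnostic stretch
        path = viterbi(geno, panel, params)
        assert np.all(path[16:24] == 2)
        assert np.all(path[:10] == 0) and np.all(path[-10:] == 0)


class TestPulseTimeEstimation:
    def test_recovery_within_15_percent(self, informative_sites, admixed_dataset):
        geno, truth = admixed_dataset
        est = estimate_pulse_time(geno, informative_sites, alpha=0.3)
        assert est.T_hat == pytest.approx(truth.T_true, rel=0.15)

    def test_monotone_separation_in_T(self, informative_sites, recomb_map):
        hats = []
        for T in (100.0, 1000.0):
            geno, _ = ac.simulate_admixed_genomes(
                informative_sites, T=T, alpha=0.3, n_ind=5, seed=33, recomb_map=recomb_map
            )
            hats.append(estimate_pulse_time(geno, informative_sites, alpha=0.3).T_hat)
        assert hats[0] < hats[1]

    def test_doubling_distances_halves_T_hat(self, informative_sites, admixed_dataset):
        geno, _ = admixed_dataset
        base = estimate_pulse_time(geno, informative_sites, alpha=0.3).T_hat
        stretched = informative_sites.sites.copy()
        stretched["genetic_pos"] = 2 * stretched["genetic_pos"]
        est2 = estimate_pulse_time(geno, ac.PanelPair(sites=stretched), alpha=0.3)
        assert est2.T_hat == pytest.approx(base / 2, rel=0.02)

    def test_flat_likelihood_flagged(self, informative_sites):
        geno = np.full((2, informative_sites.n_sites), -1, dtype=np.int8)
        with pytest.warns(UserWarning, match="flat"):
            est = estimate_pulse_time(geno, informative_sites, alpha=0.3)
        assert est.flat

    def test_mask_excludes_sites_from_timing(self, informative_sites, admixed_dataset):
        geno, _ = admixed_dataset
        mask = pd.DataFrame({"chrom": ["1"], "start": [0], "end": [100_000_000]})
        est = estimate_pulse_time(geno, informative_sites, alpha=0.3, mask=mask)
        per_chrom = informative_sites.chrom_slices()
        expected = informative_sites.n_sites - (per_chrom["1"].stop - per_chrom["1"].start)
        assert est.n_sites == expected


class TestBootstrap:
    def test_ci_brackets_estimate_and_shrinks_with_more_sites(
        self, informative_sites, recomb_map
    ):
        geno, _ = ac.simulate_admixed_genomes(
            informative_sites, T=450, alpha=0.3, n_ind=10, seed=41, recomb_map=recomb_map
        )
        quarter = ac.PanelPair(
            sites=informative_sites.sites.groupby("chrom", sort=False)
            .head(250)
            .reset_index(drop=True)
        )
        idx = np.concatenate(
            [np.arange(sl.start, sl.start + 250) for sl in informative_sites.chrom_slices().values()]
        )
        small = bootstrap_pulse_time(
            geno[:, idx], quarter, alpha=0.3, block_sites=100, seed=7
        )
        full = bootstrap_pulse_time(
            geno, informative_sites, alpha=0.3, block_sites=100, seed=7
        )
        assert small.ci_low <= small.T_hat <= small.ci_high
        assert (full.ci_high - full.ci_low) < (small.ci_high - small.ci_low)

    def test_single_block_resample_reproduces_block_estimate(self, informative_sites, admixed_dataset):
        geno, _ = admixed_dataset
        # a "bootstrap" with one block per chromosome and all replicates drawing
        # the same multiset collapses the CI onto a single value
        est = bootstrap_pulse_time(
            geno, informative_sites, alpha=0.3, block_sites=10_000, n_bootstrap=5, seed=1
        )
        assert est.ci_high - est.ci_low < 0.25 * est.T_hat

    def test_too_few_blocks_rejected(self, informative_sites, admixed_dataset):
        geno, _ = admixed_dataset
        sl = informative_sites.chrom_slices()["1"]
        one_chrom = ac.PanelPair(
            sites=informative_sites.sites.iloc[sl].reset_index(drop=True)
        )
        with pytest.raises(ValueError, match="blocks"):
            bootstrap_pulse_time(
                geno[:, sl], one_chrom, alpha=0.3, block_sites=10 * one_chrom.n_sites
            )


class TestTractCalling:
    def test_midpoint_convention_by_hand(self):
        panel = make_panel(pos=[10_000, 20_000, 30_000, 40_000, 50_000], pA=0.9, pB=0.1)
        tracts = call_tracts(np.array([0, 0, 1, 1, 0]), panel)
        assert len(tracts) == 1
        t = tracts[0]
        assert (t.start_bp, t.end_bp, t.dosage_class) == (25_000, 45_000, "heterozygous")

    def test_all_zero_path_gives_no_tracts(self):
        panel = make_panel(pos=[10_000, 20_000, 30_000], pA=0.9, pB=0.1)
        assert call_tracts(np.zeros(3, dtype=int), panel) == []

    def test_all_homozygous_covers_chromosome_span(self):
        panel = make_panel(pos=[10_000, 20_000, 30_000], pA=0.9, pB=0.1)
        tracts = call_tracts(
            np.full(3, 2), panel, chrom_lengths={"1": 1_000_000}
        )
        spans = {(t.start_bp, t.end_bp, t.dosage_class) for t in tracts}
        assert (0, 1_000_000, "homozygous") in spans
        assert (0, 1_000_000, "heterozygous") in spans

    def test_min_sites_suppresses_singletons(self):
        panel = make_panel(pos=[10_000, 20_000, 30_000], pA=0.9, pB=0.1)
        assert call_tracts(np.array([0, 2, 0]), panel, min_sites=2) == []
        assert len(call_tracts(np.array([0, 2, 0]), panel, min_sites=1)) == 2


class TestEstimateAlpha:
    def test_recovers_simulated_alpha(self, informative_sites, admixed_dataset):
        geno, truth = admixed_dataset
        alpha_hat, T_hat, _ = estimate_alpha(geno, informative_sites)
        assert alpha_hat == pytest.approx(truth.alpha_true, abs=0.03)

    def test_unadmixed_data_gives_near_zero(self, informative_sites, recomb_map):
        geno, _ = ac.simulate_admixed_genomes(
            informative_sites, T=100, alpha=0.0, n_ind=5, seed=55, recomb_map=recomb_map
        )
        alpha_hat, _, _ = estimate_alpha(geno, informative_sites)
        assert alpha_hat < 0.02

    def test_invariant_to_order_reversal(self, informative_sites, admixed_dataset):
        # the stationary chain is reversible, so flipping every chromosome
        # (preserving inter-site distances) leaves the likelihood unchanged
        geno, _ = admixed_dataset
        a1, _, _ = estimate_alpha(geno[:4], informative_sites)
        rev_idx = np.concatenate(
            [np.arange(sl.stop - 1, sl.start - 1, -1) for sl in informative_sites.chrom_slices().values()]
        )
        df = informative_sites.sites.iloc[rev_idx].reset_index(drop=True)
        for chrom, sl in informative_sites.chrom_slices().items():
            n = sl.stop - sl.start
            sub = df.iloc[sl]
            gp = sub["genetic_pos"].to_numpy()
            df.loc[sub.index, "genetic_pos"] = gp[0] - gp  # re-ascending distances
            df.loc[sub.index, "pos"] = np.arange(n) * 10_000 + 1
        a2, _, _ = estimate_alpha(geno[:4][:, rev_idx], ac.PanelPair(sites=df))
        assert a1 == pytest.approx(a2, abs=1e-6)


class TestModelResults:
    def test_fit_summary_and_tracts(self, informative_sites, admixed_dataset):
        geno, truth = admixed_dataset
        model = AncestryPulseModel(geno, informative_sites, alpha=0.3)
        res = model.fit(block_sites=200, n_bootstrap=20, seed=3)
        assert set(res.estimates["chrom"]) == {"1", "2", "3"}
        for e in res.chrom_estimates:
            assert e.ci_low <= e.T_hat <= e.ci_high
        assert res.mean_T == pytest.approx(truth.T_true, rel=0.25)
        assert "mean pulse age" in res.summary()
        prof = res.ancestry_profile()
        assert prof.shape == (informative_sites.n_sites,)
        # Viterbi decoding shrinks toward the modal state, so allow a small bias
        assert abs(prof.mean() - truth.alpha_true) < 0.08
        tracts = res.tracts()
        assert len(tracts) > 0
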