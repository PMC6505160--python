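"""EM haplotype frequencies, r², windowed LD, Hill–Weir decay, local LD."""

import numpy as np
import pandas as pd
import pytest
from scipy import optimize

import radpop as rp
from radpop.ld import (
    default_sample_chromosomes, hill_weir_expected_r2,
)


def grid_oracle_r2(g1, g2, xatol=1e-12):
    """Independent 1-D maximization of the observed-data likelihood over
    the coupling-haplotype frequency pAB (pA, pB fixed by allele counts)."""
    g1, g2 = np.asarray(g1), np.asarray(g2)
    m = (g1 != rp.MISSING) & (g2 != rp.MISSING)
    a, b = g1[m], g2[m]
    n = len(a)
    pA, pB = a.sum() / (2 * n), b.sum() / (2 * n)
    if pA in (0, 1) or pB in (0, 1):
        return np.nan
    counts = np.zeros((3, 3))
    for x, y in zip(a, b):
        counts[x, y] += 1

    def negll(pAB):
        h = [[1 - pA - pB + pAB, pB - pAB], [pA - pAB, pAB]]
        tot = 0.0
        for i in range(3):
            for j in range(3):
                if counts[i, j] == 0:
                    continue
                prob = 0.0
                for x1 in (0, 1):
                    for y1 in (0, 1):
                        x2, y2 = i - x1, j - y1
                        if x2 in (0, 1) and y2 in (0, 1):
                            prob += h[x1][y1] * h[x2][y2]
                tot += counts[i, j] * np.log(max(prob, 1e-300))
        return -tot

    lo, hi = max(0.0, pA + pB - 1), min(pA, pB)
    res = optimize.minimize_scalar(
        negll, bounds=(lo, hi), method="bounded", options={"xatol": xatol}
    )
    d = res.x - pA * pB
    return d * d / (pA * (1 - pA) * pB * (1 - pB))


def sample_pair(rng, n=20):
    """Genotypes at two loci drawn from random haplotype frequencies."""
    pa, pb = rng.uniform(0.2, 0.8, 2)
    lo, hi = max(0, pa + pb - 1), min(pa, pb)
    pAB = rng.uniform(lo + 0.02, hi - 0.02) if hi - lo > 0.04 else pa * pb
    h = np.array([pAB, pa - pAB, pb - pAB, 1 - pa - pb + pAB])
    hap = rng.choice(4, size=(n, 2), p=h)
    g1 = (hap < 2).sum(axis=1)  # haplotypes 0 (AB) and 1 (Ab) carry A
    g2 = ((hap == 0) | (hap == 2)).sum(axis=1)
    return g1.astype(np.int8), g2.astype(np.int8)


class TestEmHaplotypes:
    def test_unambiguous_identity(self):
        f = rp.em_haplotype_freqs([0, 2, 0, 2], [0, 2, 0, 2])
        assert (f.pAB, f.pAb, f.paB, f.pab) == pytest.approx((0.5, 0, 0, 0.5))

    def test_perfect_repulsion(self):
        f = rp.em_haplotype_freqs([0, 0, 2, 2], [2, 2, 0, 0])
        assert (f.pAb, f.paB) == pytest.approx((0.5, 0.5))
        assert f.pAB == pytest.approx(0.0)

    def test_monomorphic_returns_none(self):
        assert rp.em_haplotype_freqs([0, 0, 0], [0, 1, 2]) is None
        # monomorphic only after missing-data restriction
        assert rp.em_haplotype_freqs([1, 0, 0], [rp.MISSING, 1, 2]) is None

    def test_frequencies_sum_to_one(self):
        rng = np.random.default_rng(1)
        for _ in range(20):
            f = rp.em_haplotype_freqs(*sample_pair(rng))
            if f is not None:
                assert f.pAB + f.pAb + f.paB + f.pab == pytest.approx(1.0)

    def test_loglik_monotone_over_iterations(self):
        """EM property: observed-data log-likelihood never decreases."""
        rng = np.random.default_rng(3)
        checked = 0
        while checked < 25:
            out = rp.em_haplotype_freqs(*sample_pair(rng), return_trace=True)
            if out is None:
                continue
            _, trace = out
            assert all(b >= a - 1e-9 for a, b in zip(trace, trace[1:]))
            checked += 1


class TestR2Pair:
    def test_identical_columns(self):
        assert rp.r2_pair([0, 2, 0, 2, 1], [0, 2, 0, 2, 1]) == pytest.approx(1.0)

    def test_orthogonal_columns(self):
        assert rp.r2_pair([0, 0, 2, 2], [0, 2, 0, 2]) == pytest.approx(0.0)

    def test_matches_grid_oracle(self):
        rng = np.random.default_rng(5)
        for _ in range(30):
            g1, g2 = sample_pair(rng, n=25)
            r2 = rp.r2_pair(g1, g2)
            oracle = grid_oracle_r2(g1, g2)
            if np.isnan(oracle):
                assert np.isnan(r2)
            else:
                assert r2 == pytest.approx(oracle, abs=1e-6)

    def test_symmetry_and_allele_relabeling(self):
        rng = np.random.default_rng(8)
        for _ in range(15):
            g1, g2 = sample_pair(rng)
            base = rp.r2_pair(g1, g2)
            assert rp.r2_pair(g2, g1) == pytest.approx(base, abs=1e-9)
            assert rp.r2_pair(2 - g1, g2) == pytest.approx(base, abs=1e-9)
            assert rp.r2_pair(g1, 2 - g2) == pytest.approx(base, abs=1e-9)

    def test_composite_mode(self):
        g1 = np.array([0, 1, 2, 0, 1, 2], dtype=np.int8)
        assert rp.r2_pair(g1, g1, method="composite") == pytest.approx(1.0)
        assert np.isnan(rp.r2_pair(g1, np.zeros(6, np.int8), method="composite"))


class TestWindowedLd:
    def _gm(self, positions, dosage_cols, chrom="c1"):
        markers = [rp.MarkerInfo(chrom, p, "A", "C") for p in positions]
        return rp.GenotypeMatrix(
            [f"s{i}" for i in range(len(dosage_cols[0]))],
            markers,
            np.array(dosage_cols, dtype=np.int8).T,
        )

    def test_window_rule(self):
        col = [0, 1, 2, 0, 1, 2, 0, 1]
        gm = self._gm([1, 500_000, 1_200_000], [col, col, col])
        pairs = rp.windowed_ld(gm, window_bp=1_000_000)
        assert sorted(zip(pairs.pos_i, pairs.pos_j)) == [
            (1, 500_000), (500_000, 1_200_000),
        ]

    def test_single_marker_chromosome(self):
        gm = self._gm([100], [[0, 1, 2, 1]])
        assert len(rp.windowed_ld(gm)) == 0

    def test_matches_brute_force_enumeration(self):
        rng = np.random.default_rng(11)
        pos = np.sort(rng.choice(np.arange(1, 40_000), 25, replace=False))
        cols = [rng.integers(0, 3, 12).tolist() for _ in pos]
        gm = self._gm(pos.tolist(), cols)
        window = 10_000
        pairs = rp.windowed_ld(gm, window_bp=window)
        expected = []
        for a in range(len(pos)):
            for b in range(len(pos)):
                d = pos[b] - pos[a]
                if 0 < d <= window:
                    r2 = rp.r2_pair(gm.dosage[:, a], gm.dosage[:, b])
                    if not np.isnan(r2):
                        expected.append((int(pos[a]), int(pos[b]), r2))
        got = list(zip(pairs.pos_i, pairs.pos_j, pairs.r2))
        assert sorted(got) == pytest.approx(sorted(expected))


class TestDecayFit:
    def test_analytic_limits(self):
        """C = 0 gives (10/22)(1 + 36/(22n)) -> 5/11 as n grows; the large-
        distance asymptote is 1/n."""
        n = 50
        assert hill_weir_expected_r2(0.0, 1e-4, n) == pytest.approx(
            (10 / 22) * (1 + 36 / (22 * n))
        )
        assert hill_weir_expected_r2(0.0, 1e-4, 10**9) == pytest.approx(
            5 / 11, rel=1e-6
        )
        assert hill_weir_expected_r2(1e12, 1e-4, n) == pytest.approx(
            1 / n, rel=1e-3
        )

    def test_curve_monotone_decreasing(self):
        d = np.linspace(0, 500_000, 2000)
        y = hill_weir_expected_r2(d, 5e-4, 100)
        assert (np.diff(y) < 0).all()

    def test_rho_recovery_from_noisy_curve(self):
        rng = np.random.default_rng(30)
        rho, n = 5e-4, 100
        d = rng.uniform(1, 100_000, 2000)
        y = hill_weir_expected_r2(d, rho, n) + rng.normal(0, 0.02, 2000)
        fit = rp.fit_decay(pd.DataFrame({"distance_bp": d, "r2": y}), n=n)
        assert fit.rho == pytest.approx(rho, rel=0.1)
        # fitted decay distance is where the curve crosses the baseline
        assert hill_weir_expected_r2(
            fit.decay_distance_bp, fit.rho, n
        ) == pytest.approx(0.1, abs=1e-3)

    def test_decay_distance_decreases_with_rho(self):
        dists = []
        d = np.linspace(1, 200_000, 500)
        for rho in (1e-4, 5e-4, 2e-3):
            y = hill_weir_expected_r2(d, rho, 100)
            fit = rp.fit_decay(pd.DataFrame({"distance_bp": d, "r2": y}), n=100)
            dists.append(fit.decay_distance_bp)
        assert dists == sorted(dists, reverse=True)

    def test_baseline_never_reached(self):
        d = np.linspace(1, 100, 50)
        y = hill_weir_expected_r2(d, 1e-9, 100)
        fit = rp.fit_decay(pd.DataFrame({"distance_bp": d, "r2": y}), n=100)
        assert fit.decay_distance_bp is None

    def test_binned_mode_close_to_raw(self):
        rng = np.random.default_rng(31)
        d = rng.uniform(1, 50_000, 3000)
        y = hill_weir_expected_r2(d, 1e-3, 80) + rng.normal(0, 0.01, 3000)
        raw = rp.fit_decay(pd.DataFrame({"distance_bp": d, "r2": y}), n=80)
        binned = rp.fit_decay(
            pd.DataFrame({"distance_bp": d, "r2": y}), n=80, binned=True
        )
        assert binned.rho == pytest.approx(raw.rho, rel=0.15)

    def test_input_guards(self):
        df = pd.DataFrame({"distance_bp": [1] * 5, "r2": [0.5] * 5})
        with pytest.raises(ValueError):
            rp.fit_decay(df, n=10)
        df10 = pd.DataFrame({"distance_bp": range(1, 11), "r2": [0.5] * 10})
        with pytest.raises(ValueError):
            rp.fit_decay(df10, n=1)


class TestSimulatedDecay:
    def test_binned_r2_decreases_with_distance(self):
        """Founder-mosaic genotypes: mean r² per distance bin falls
        monotonically (Spearman < 0 over >= 5 bins)."""
        from scipy.stats import spearmanr

        gm = rp.simulate_ld_genotypes(
            rp.SimParams(seed=21, K=1, n_per_pop=60, n_loci=300,
                         founder_haplotypes=8, switch_rate_per_bp=5e-5,
                         marker_spacing_bp=1000, missing_rate=0.0)
        )
        pairs = rp.windowed_ld(gm, window_bp=60_000)
        bins = pairs.assign(b=pairs.distance_bp // 10_000).groupby("b").r2.mean()
        assert len(bins) >= 5
        rho, _ = spearmanr(bins.index, bins.to_numpy())
        assert rho < 0

    def test_decay_distance_shrinks_with_switch_rate(self):
        dists = []
        for c in (2e-6, 2e-5, 2e-4):
            gm = rp.simulate_ld_genotypes(
                rp.SimParams(seed=22, K=1, n_per_pop=50, n_loci=250,
                             founder_haplotypes=8, switch_rate_per_bp=c,
                             marker_spacing_bp=1000, missing_rate=0.0)
            )
            pairs = rp.windowed_ld(gm, window_bp=80_000)
            fit = rp.fit_decay(pairs, n=default_sample_chromosomes(pairs))
            dists.append(fit.decay_distance_bp if fit.decay_distance_bp else np.inf)
        assert dists[0] > dists[1] > dists[2]

    def test_high_switch_rate_kills_local_ld(self):
        """c -> large: adjacent-marker LD collapses to the finite-pool
        background, far below the tight-linkage level."""
        def adjacent_mean(c):
            gm = rp.simulate_ld_genotypes(
                rp.SimParams(seed=23, K=1, n_per_pop=50, n_loci=150,
                             founder_haplotypes=8, switch_rate_per_bp=c,
                             marker_spacing_bp=500, missing_rate=0.0)
            )
            vals = [
                rp.r2_pair(gm.dosage[:, j], gm.dosage[:, j + 1])
                for j in range(gm.n_markers - 1)
            ]
            return np.nanmean(vals)

        # tight linkage sits near the finite-pool level (~1/M for M=8);
        # complete switching leaves only sampling noise (~1/n)
        assert adjacent_mean(1.0) < 0.05 < adjacent_mean(1e-6)

    def test_two_founders_tight_linkage_near_perfect_ld(self):
        gm = rp.simulate_ld_genotypes(
            rp.SimParams(seed=24, K=1, n_per_pop=50, n_loci=100,
                         founder_haplotypes=2, switch_rate_per_bp=1e-7,
                         marker_spacing_bp=200, missing_rate=0.0)
        )
        vals = [
            rp.r2_pair(gm.dosage[:, j], gm.dosage[:, j + 1])
            for j in range(gm.n_markers - 1)
        ]
        assert np.nanmean(vals) > 0.8


class TestLocalLdProfile:
    def _setup(self, col_pairs):
        """Units at 1 kb spacing, each holding the given dosage columns."""
        markers, cols, units = [], [], []
        for uid, unit_cols in enumerate(col_pairs):
            cut = 1000 * (uid + 1)
            units.append(
                rp.SequencingUnit(uid, "c1", rp.CutSite("c1", cut),
                                  (cut - 93, cut + 93), [])
            )
            for k, col in enumerate(unit_cols):
                units[-1].snp_indices.append(len(markers))
                markers.append(rp.MarkerInfo("c1", cut + k, "A", "C", unit_id=uid))
                cols.append(col)
        gm = rp.GenotypeMatrix(
            [f"s{i}" for i in range(len(cols[0]))],
            markers,
            np.array(cols, dtype=np.int8).T,
        )
        return gm, units

    def test_identical_single_snps(self):
        col = [0, 1, 2, 0, 1, 2]
        gm, units = self._setup([[col], [col]])
        profile = rp.local_ld_profile(gm, units)
        assert profile.records.iloc[0]["mean_r2"] == pytest.approx(1.0)
        assert profile.records.iloc[0]["left_cut_pos"] == 1000
        total = profile.tallies.set_index("chrom").loc["Total"]
        assert (total["n_ge_baseline"], total["n_lt_baseline"]) == (1, 0)

    def test_single_unit_chromosome_no_pairs(self):
        gm, units = self._setup([[[0, 1, 2, 0]]])
        profile = rp.local_ld_profile(gm, units)
        assert profile.records.empty

    def test_tallies_sum_and_mean_over_cross_pairs(self):
        c1 = [0, 1, 2, 0, 1, 2, 0, 2]
        c2 = [2, 1, 0, 2, 1, 0, 2, 0]
        c3 = [0, 0, 2, 2, 0, 2, 1, 1]
        gm, units = self._setup([[c1, c2], [c3]])
        profile = rp.local_ld_profile(gm, units)
        rec = profile.records.iloc[0]
        expect = np.mean([
            rp.r2_pair(np.array(c1), np.array(c3)),
            rp.r2_pair(np.array(c2), np.array(c3)),
        ])
        assert rec["mean_r2"] == pytest.approx(expect)
        assert rec["n_snp_pairs"] == 2
        t = profile.tallies.set_index("chrom")
        assert (
            t.loc["Total", "n_ge_baseline"] + t.loc["Total", "n_lt_baseline"]
            == len(profile.records)
        )
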