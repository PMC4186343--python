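"""Diversity and differentiation estimators against independent oracles."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from hlag.pipeline import UTR3_WEIGHTS
from hlag.popgen import (
    FrequencyTable, WeightScheme, amova, bonferroni, classical_mds,
    exact_differentiation_test, gene_diversity, haplotype_diversity,
    hwe_exact_test, nucleotide_diversity, nucleotide_diversity_from_pool,
    pairwise_fst, private_haplotypes, reynolds_distance,
    unbiased_heterozygosity,
)


def utr3_site_freqs(ref):
    return {int(r["gene_pos"]): list(r["freqs"])
            for _, r in ref.panel.table.iterrows() if r["region"] == "utr3"}


class TestDiversity:
    def test_single_haplotype_zero(self):
        assert haplotype_diversity([1.0], 100) == 0.0

    def test_published_utr_haplotype_diversity(self, ref):
        h = haplotype_diversity(ref.utr3.frequencies.values(), 2152)
        assert h == pytest.approx(0.8223, abs=0.001)

    def test_published_whole_gene_haplotype_diversity(self, ref):
        freqs = ref.extended.table["global_freq"]
        h = haplotype_diversity(freqs, 2152)
        assert h == pytest.approx(0.9068, abs=0.001)

    def test_gene_diversity_closed_forms(self):
        assert gene_diversity([[1.0], [1.0]], 1000) == (0.0, 0.0)
        mean, _ = gene_diversity([[0.5, 0.5]], 10**6)
        assert mean == pytest.approx(0.5, abs=1e-4)

    def test_triallelic_site_heterozygosity(self):
        h = unbiased_heterozygosity([0.8550, 0.0953, 0.0497], 2152)
        assert h == pytest.approx(0.2576, abs=0.0005)

    def test_utr_mean_pairwise_differences_with_indel_weight(self, ref):
        k, pi = nucleotide_diversity(utr3_site_freqs(ref), 2152, UTR3_WEIGHTS)
        assert k == pytest.approx(8.19, abs=0.005)
        assert pi == pytest.approx(2.864, abs=0.002)

    def test_unit_weight_at_indel_lowers_k(self, ref):
        k, _ = nucleotide_diversity(utr3_site_freqs(ref), 2152,
                                    WeightScheme(region_length=286.0))
        assert k == pytest.approx(2.80, abs=0.02)

    def test_two_equifrequent_haplotypes_one_site(self):
        k, _ = nucleotide_diversity({1: [0.5, 0.5]}, 10**6)
        assert k == pytest.approx(0.5, abs=1e-4)

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(st.integers(0, 10**6), st.integers(2, 5), st.integers(2, 6))
    def test_frequency_form_matches_pairwise_oracle(self, seed, n_hap, n_site):
        rng = np.random.default_rng(seed)
        vectors = {}
        while len(vectors) < n_hap:
            vectors[f"h{len(vectors)}"] = tuple(
                rng.choice(["A", "C", "G"]) for _ in range(n_site))
        p = rng.dirichlet(np.ones(n_hap))
        freqs = dict(zip(vectors, p))
        sites = list(range(n_site))
        w = WeightScheme(weights={0: 14.0}, region_length=100.0)
        # frequency form needs per-site allele frequencies
        site_freqs = {}
        for i, s in enumerate(sites):
            tally = {}
            for name, vec in vectors.items():
                tally[vec[i]] = tally.get(vec[i], 0.0) + freqs[name]
            site_freqs[s] = list(tally.values())
        k1, _ = nucleotide_diversity(site_freqs, 2000, w)
        k2, _ = nucleotide_diversity_from_pool(freqs, vectors, sites, 2000, w)
        assert k1 == pytest.approx(k2, abs=1e-10)


class TestPrivateHaplotypes:
    def test_counting_rules(self):
        t = FrequencyTable(pd.DataFrame(
            {"A": [3, 2, 0], "B": [0, 1, 4]}, index=["x", "y", "z"]))
        out = private_haplotypes(t)
        assert out["A"] == 1 and out["B"] == 1  # y is shared, x/z private

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(st.integers(0, 10**6))
    def test_matches_brute_force_scan(self, seed):
        rng = np.random.default_rng(seed)
        counts = rng.integers(0, 5, size=(6, 4))
        counts[0, :] = counts[0, :] + 1  # keep columns non-empty
        df = pd.DataFrame(counts, index=[f"h{i}" for i in range(6)],
                          columns=list("ABCD"))
        out = private_haplotypes(FrequencyTable(df))
        for pop in df.columns:
            brute = sum(
                1 for h in df.index
                if df.loc[h, pop] > 0 and all(df.loc[h, q] == 0
                                              for q in df.columns if q != pop))
            assert out[pop] == brute


def levene_exact_biallelic(n11, n12, n22):
    """Full-enumeration exact HWE p-value for two alleles."""
    n = n11 + n12 + n22
    m1, m2 = 2 * n11 + n12, 2 * n22 + n12
    lf = [0.0]
    for i in range(1, 2 * n + 1):
        lf.append(lf[-1] + math.log(i))

    def logp(h):
        a, b = (m1 - h) // 2, (m2 - h) // 2
        return (lf[n] + lf[m1] + lf[m2] - lf[2 * n]
                + h * math.log(2) - lf[a] - lf[h] - lf[b])

    obs = logp(n12)
    tot = mass = 0.0
    for h in range(m1 % 2, min(m1, m2) + 1, 2):
        p = math.exp(logp(h))
        tot += p
        if logp(h) <= obs + 1e-9:
            mass += p
    return mass / tot


class TestHWE:
    @pytest.mark.parametrize("n11,n12,n22", [(3, 5, 12), (10, 2, 8), (6, 1, 6)])
    def test_chain_matches_enumeration_oracle(self, n11, n12, n22):
        exact = levene_exact_biallelic(n11, n12, n22)
        p, se = hwe_exact_test({(0, 0): n11, (0, 1): n12, (1, 1): n22},
                               chain_length=60_000, dememorization=5_000, seed=7)
        assert abs(p - exact) < 3 * max(se, 1e-4)

    def test_hwe_proportioned_counts_give_p_one(self):
        p, _ = hwe_exact_test({(0, 0): 25, (0, 1): 50, (1, 1): 25},
                              chain_length=20_000, dememorization=2_000, seed=1)
        assert p == pytest.approx(1.0, abs=1e-9)

    def test_all_heterozygote_extreme_is_significant(self):
        exact = levene_exact_biallelic(0, 50, 0)
        p, se = hwe_exact_test({(0, 1): 50}, chain_length=40_000,
                               dememorization=4_000, seed=2)
        assert p < 0.01
        assert abs(p - exact) < 3 * max(se, 1e-4)

    def test_monomorphic_flagged_p_one(self):
        with pytest.warns(UserWarning):
            p, se = hwe_exact_test({(0, 0): 30})
        assert (p, se) == (1.0, 0.0)

    def test_multiallelic_runs_and_is_seed_reproducible(self):
        counts = {(0, 0): 5, (0, 1): 8, (1, 1): 4, (0, 2): 3, (1, 2): 2, (2, 2): 1}
        p1 = hwe_exact_test(counts, chain_length=20_000, seed=3)
        p2 = hwe_exact_test(counts, chain_length=20_000, seed=3)
        assert p1 == p2


def fst_oracle(c1, c2):
    """Direct sum-of-squares variance decomposition for two populations."""
    n1, n2 = c1.sum(), c2.sum()
    n = n1 + n2
    # haplotype identity distance: SSD via pair counting
    def ssd(counts):
        m = counts.sum()
        same = sum(c * (c - 1) for c in counts) / 2
        pairs = m * (m - 1) / 2
        return (pairs - same) / m  # mean squared deviation form: SS/(2m) * 2
    ssd_total = ssd(c1 + c2)
    ssd_within = ssd(c1) + ssd(c2)
    msd_among = (ssd_total - ssd_within) / 1
    sigma_w = ssd_within / (n - 2)
    nc = n - (n1 ** 2 + n2 ** 2) / n
    sigma_a = (msd_among - sigma_w) / nc
    return sigma_a / (sigma_a + sigma_w)


class TestFst:
    def test_identical_populations_theta_zero_p_one(self):
        t = FrequencyTable(pd.DataFrame({"A": [20, 20], "B": [20, 20]},
                                        index=["h1", "h2"]))
        fst = pairwise_fst(t, permutations=199, seed=1)
        assert fst.values.iloc[0, 1] <= 0.0
        assert fst.pvalues.iloc[0, 1] > 0.5

    def test_fixed_populations_theta_one(self):
        t = FrequencyTable(pd.DataFrame({"A": [10, 0], "B": [0, 10]},
                                        index=["h1", "h2"]))
        fst = pairwise_fst(t, permutations=99, seed=1)
        assert fst.values.iloc[0, 1] == pytest.approx(1.0)
        assert fst.pvalues.iloc[0, 1] < 0.05

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(st.integers(0, 10**6))
    def test_matches_hand_variance_decomposition(self, seed):
        rng = np.random.default_rng(seed)
        c1 = rng.integers(0, 8, size=3) + np.array([1, 1, 0])
        c2 = rng.integers(0, 8, size=3) + np.array([0, 1, 1])
        t = FrequencyTable(pd.DataFrame({"A": c1, "B": c2},
                                        index=["x", "y", "z"]))
        got = pairwise_fst(t, permutations=0).values.iloc[0, 1]
        assert got == pytest.approx(fst_oracle(c1, c2), abs=1e-10)

    def test_permutation_pvalues_seed_reproducible(self):
        t = FrequencyTable(pd.DataFrame({"A": [8, 2], "B": [3, 7]},
                                        index=["h1", "h2"]))
        a = pairwise_fst(t, permutations=200, seed=5).pvalues.iloc[0, 1]
        b = pairwise_fst(t, permutations=200, seed=5).pvalues.iloc[0, 1]
        assert a == b


class TestReynolds:
    def test_closed_forms_and_symmetry(self):
        t = FrequencyTable(pd.DataFrame({"A": [5, 5], "B": [5, 5]},
                                        index=["h1", "h2"]))
        d = reynolds_distance(t)
        assert d.values.iloc[0, 1] == pytest.approx(0.0)
        # theta = 0.5 corresponds to distance ln 2
        assert -np.log(1 - 0.5) == pytest.approx(np.log(2))
        rng = np.random.default_rng(0)
        counts = pd.DataFrame(rng.integers(1, 10, size=(4, 3)),
                              index=list("wxyz"), columns=list("ABC"))
        d2 = reynolds_distance(FrequencyTable(counts))
        v = d2.values.to_numpy()
        assert np.allclose(v, v.T)
        assert np.allclose(np.diag(v), 0.0)


class TestExactDifferentiation:
    @pytest.mark.parametrize("table", [
        [[8, 2], [1, 9]],
        [[5, 5], [5, 5]],
        [[12, 0], [0, 3]],
        [[3, 7], [6, 1]],
    ])
    def test_two_by_two_matches_fisher_probability_mass(self, table):
        from scipy.stats import fisher_exact
        p, se = exact_differentiation_test(np.array(table))
        assert se == 0.0  # enumerated exactly
        assert p == pytest.approx(fisher_exact(np.array(table))[1], abs=1e-9)

    def test_identical_columns_not_differentiated(self):
        p, _ = exact_differentiation_test(np.array([[10, 10], [5, 5], [3, 3]]))
        assert p > 0.5

    def test_disjoint_supports_near_zero(self):
        p, _ = exact_differentiation_test(np.array([[9, 0], [0, 9]]))
        assert p < 1e-3

    def test_degenerate_margins_p_one(self):
        with pytest.warns(UserWarning):
            p, _ = exact_differentiation_test(np.array([[5, 0], [3, 0]]))
        assert p == 1.0

    def test_chain_agrees_with_enumeration(self):
        tab = np.array([[6, 2, 1], [1, 5, 4], [2, 2, 6]])
        exact_p, _ = exact_differentiation_test(tab)
        mc_p, se = exact_differentiation_test(
            tab, enumeration_limit=1, chain_length=60_000,
            dememorization=5_000, seed=11)
        assert abs(mc_p - exact_p) < 3 * max(se, 1e-3)


def amova_oracle(counts, gidx):
    """First-principles AMOVA decomposition on haplotype identity distance."""
    # build the chromosome-level distance matrix explicitly
    labels = []
    for j in range(counts.shape[1]):
        for h in range(counts.shape[0]):
            labels += [(j, h)] * counts[h, j]
    n = len(labels)
    pops = sorted({l[0] for l in labels})
    d2 = np.array([[0.0 if a[1] == b[1] else 1.0 for b in labels] for a in labels])
    def ssd(idx):
        if not idx:
            return 0.0
        sub = d2[np.ix_(idx, idx)]
        return sub.sum() / (2 * len(idx))
    all_idx = list(range(n))
    ssd_total = ssd(all_idx)
    pop_idx = {p: [i for i, l in enumerate(labels) if l[0] == p] for p in pops}
    ssd_wp = sum(ssd(pop_idx[p]) for p in pops)
    groups = sorted(set(gidx.values()))
    grp_idx = {g: [i for i, l in enumerate(labels) if gidx[l[0]] == g]
               for g in groups}
    ssd_groups = sum(ssd(grp_idx[g]) for g in groups)
    ssd_ag = ssd_total - ssd_groups
    ssd_apwg = ssd_groups - ssd_wp
    sizes = {p: len(pop_idx[p]) for p in pops}
    gsizes = np.array([len(grp_idx[g]) for g in groups], dtype=float)
    k, g = len(pops), len(groups)
    sigma_c = ssd_wp / (n - k)
    s_n2_ng = 0.0
    for gg in groups:
        members = [p for p in pops if gidx[p] == gg]
        ng = sum(sizes[p] for p in members)
        s_n2_ng += sum(sizes[p] ** 2 for p in members) / ng
    n1 = (n - s_n2_ng) / (k - g)
    sigma_b = (ssd_apwg / (k - g) - sigma_c) / n1
    sizes_arr = np.array([sizes[p] for p in pops], dtype=float)
    n2c = (s_n2_ng - (sizes_arr ** 2).sum() / n) / (g - 1)
    n3 = (n - (gsizes ** 2).sum() / n) / (g - 1)
    sigma_a = (ssd_ag / (g - 1) - sigma_c - n2c * sigma_b) / n3
    return sigma_a, sigma_b, sigma_c


class TestAmova:
    def test_identical_populations_all_variance_within(self):
        df = pd.DataFrame({"A": [10, 10], "B": [10, 10], "C": [10, 10],
                           "D": [10, 10]}, index=["h1", "h2"])
        res = amova(FrequencyTable(df), {"A": "g1", "B": "g1", "C": "g2", "D": "g2"},
                    permutations=0)
        # among components go (slightly negative) to zero; essentially all
        # variance sits within populations
        assert res.pct_within >= 99.0
        assert abs(res.f_ct) < 0.1
        assert abs(res.f_st) < 0.1

    def test_fixed_groups_all_variance_among(self):
        df = pd.DataFrame({"A": [10, 0], "B": [10, 0], "C": [0, 10],
                           "D": [0, 10]}, index=["h1", "h2"])
        res = amova(FrequencyTable(df), {"A": "g1", "B": "g1", "C": "g2", "D": "g2"},
                    permutations=0)
        assert res.pct_among_groups == pytest.approx(100.0, abs=1.0)
        assert res.f_ct == pytest.approx(1.0, abs=0.01)

    def test_components_match_first_principles_oracle(self):
        rng = np.random.default_rng(42)
        counts = rng.integers(0, 6, size=(4, 4)) + 1
        df = pd.DataFrame(counts, index=[f"h{i}" for i in range(4)],
                          columns=list("ABCD"))
        grouping = {"A": "g1", "B": "g1", "C": "g2", "D": "g2"}
        res = amova(FrequencyTable(df), grouping, permutations=0)
        gidx = {j: ("g1" if c in "AB" else "g2") for j, c in enumerate("ABCD")}
        sa, sb, sc = amova_oracle(counts, gidx)
        assert res.sigma_among_groups == pytest.approx(sa, abs=1e-10)
        assert res.sigma_among_pops == pytest.approx(sb, abs=1e-10)
        assert res.sigma_within == pytest.approx(sc, abs=1e-10)

    def test_percentages_sum_to_hundred(self):
        rng = np.random.default_rng(3)
        df = pd.DataFrame(rng.integers(0, 9, size=(5, 6)) + 1,
                          index=[f"h{i}" for i in range(5)],
                          columns=list("ABCDEF"))
        res = amova(FrequencyTable(df),
                    {"A": "g1", "B": "g1", "C": "g2", "D": "g2", "E": "g3", "F": "g3"},
                    permutations=50, seed=1)
        total = res.pct_among_groups + res.pct_among_pops + res.pct_within
        assert total == pytest.approx(100.0, abs=1e-6)
        for p in (res.p_f_ct, res.p_f_sc, res.p_f_st):
            assert 0.0 <= p <= 1.0

    def test_two_population_amova_equals_pairwise_fst(self):
        df = pd.DataFrame({"A": [8, 2, 0], "B": [1, 6, 3]}, index=list("xyz"))
        t = FrequencyTable(df)
        res = amova(t, permutations=0)
        theta = pairwise_fst(t, permutations=0).values.iloc[0, 1]
        assert res.f_st == pytest.approx(theta, abs=1e-12)
        assert res.sigma_among_groups is None


class TestBonferroniAndMds:
    def test_bonferroni_values(self):
        out = bonferroni(0.05, 91)
        assert out["raw"] == pytest.approx(0.05 / 91)
        assert out["reported"] == 0.0005
        assert bonferroni(0.05, 1)["raw"] == 0.05
        assert math.comb(14, 2) == 91  # 14 populations -> 91 comparisons

    def test_planar_configuration_recovered(self):
        rng = np.random.default_rng(8)
        pts = rng.normal(size=(7, 2))
        d = np.sqrt(((pts[:, None, :] - pts[None, :, :]) ** 2).sum(-1))
        coords = classical_mds(d).to_numpy()
        d2 = np.sqrt(((coords[:, None, :] - coords[None, :, :]) ** 2).sum(-1))
        assert np.abs(d - d2).max() < 1e-8  # distances invariant under rotation

    def test_degenerate_inputs(self):
        coords = classical_mds(np.zeros((4, 4)))
        assert np.allclose(coords.to_numpy(), 0.0)
        two = classical_mds(np.array([[0.0, 2.0], [2.0, 0.0]]))
        assert sorted(two["dim1"].tolist()) == pytest.approx([-1.0, 1.0])
        with pytest.raises(ValueError):
            classical_mds(np.array([[0.0, 1.0], [2.0, 0.0]]))

    def test_mds_of_reynolds_matrix_has_expected_shape(self):
        rng = np.random.default_rng(1)
        counts = pd.DataFrame(rng.integers(1, 15, size=(6, 5)),
                              index=[f"h{i}" for i in range(6)],
                              columns=list("ABCDE"))
        rey = reynolds_distance(FrequencyTable(counts))
        coords = classical_mds(rey.values)
        assert coords.shape == (5, 2)
        assert np.allclose(coords.mean(axis=0), 0.0, atol=1e-10)
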