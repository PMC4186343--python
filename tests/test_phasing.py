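"""EM haplotype-frequency estimation, partition-ligation and imputation."""

import itertools

import numpy as np
import pytest

from hlag.nomenclature import build_extended_vectors
from hlag.phase import (
    EMPhasingModel, em_frequencies, extract_region, phasing_summary,
    DiplotypeAssignment, HaplotypePool,
)
from hlag.refine import MISSING, GenotypeCall, GenotypeMatrix, refine_matrix
from hlag.simulate import (
    SimulationConfig, freqset_from_reference_table, sample_diplotypes,
    simulate_depths,
)

hom = lambda a: GenotypeCall("hom", a, a)
het = lambda a, b: GenotypeCall("het", *sorted((a, b)))
half = lambda a: GenotypeCall("half", a, MISSING)


def matrix_from_rows(sites, rows):
    samples = tuple(f"s{i}" for i in range(len(rows)))
    calls = {s: dict(zip(sites, row)) for s, row in zip(samples, rows)}
    return GenotypeMatrix(sites=tuple(sites), samples=samples, calls=calls)


def grid_likelihood_optimum(samples_pairs, haps, step=0.02):
    """Exhaustive likelihood maximisation on the frequency simplex."""
    best, best_ll = None, -np.inf
    ticks = np.arange(0.0, 1.0 + step / 2, step)
    for combo in itertools.product(ticks, repeat=len(haps) - 1):
        last = 1.0 - sum(combo)
        if last < -1e-9:
            continue
        f = dict(zip(haps, list(combo) + [max(last, 0.0)]))
        ll = 0.0
        for pairs in samples_pairs:
            tot = sum(f[a] * f[b] * (2 if a != b else 1) for a, b in pairs)
            if tot <= 0:
                ll = -np.inf
                break
            ll += np.log(tot)
        if ll > best_ll:
            best, best_ll = f, ll
    return best, best_ll


class TestEM:
    def test_all_homozygous_recovers_observed_proportions(self):
        rows = [[hom("A"), hom("C")]] * 3 + [[hom("G"), hom("T")]]
        m = matrix_from_rows([1, 2], rows)
        pool = em_frequencies(m, prune_floor=0.0)
        assert pool.frequencies[("A", "C")] == pytest.approx(0.75, abs=1e-9)
        assert pool.frequencies[("G", "T")] == pytest.approx(0.25, abs=1e-9)

    def test_two_site_toy_matches_exhaustive_likelihood(self):
        # 4 double-homozygotes AB/AB and 2 double-heterozygotes
        rows = [[hom("A"), hom("B")]] * 4 + [[het("A", "G"), het("B", "T")]] * 2
        m = matrix_from_rows([1, 2], rows)
        pool = em_frequencies(m, prune_floor=0.0, tol=1e-12)
        haps = [("A", "B"), ("A", "T"), ("G", "B"), ("G", "T")]
        pairs = [[(("A", "B"), ("A", "B"))]] * 4 + [
            [(("A", "B"), ("G", "T")), (("A", "T"), ("G", "B"))]] * 2
        grid_f, grid_ll = grid_likelihood_optimum(pairs, haps)
        assert pool.loglike >= grid_ll - 1e-6
        for h in haps:
            assert pool.frequencies.get(h, 0.0) == pytest.approx(
                grid_f[h], abs=0.03)

    def test_random_and_uniform_starts_agree_on_toy(self):
        rows = [[hom("A"), hom("B")]] * 4 + [[het("A", "G"), het("B", "T")]] * 2
        m = matrix_from_rows([1, 2], rows)
        p_uniform = em_frequencies(m, prune_floor=0.0, tol=1e-12)
        p_multi = em_frequencies(m, prune_floor=0.0, tol=1e-12, seed=5, restarts=4)
        assert p_multi.loglike == pytest.approx(p_uniform.loglike, abs=1e-6)

    def test_loglikelihood_monotone_every_iteration(self):
        # assert_monotone raises inside the EM loop if the likelihood dips
        rows = ([[het("A", "G"), het("B", "T"), hom("C")]] * 3
                + [[hom("A"), half("B"), het("C", "T")]] * 3
                + [[hom("G"), hom("T"), hom("C")]] * 2)
        m = matrix_from_rows([1, 2, 3], rows)
        pool = em_frequencies(m, assert_monotone=True, tol=1e-10)
        assert pool.converged

    def test_frequencies_sum_to_one_after_pruning(self):
        rows = [[het("A", "G"), het("B", "T")]] * 5 + [[hom("A"), hom("B")]] * 2
        m = matrix_from_rows([1, 2], rows)
        pool = em_frequencies(m)  # default prune floor
        assert sum(pool.frequencies.values()) == pytest.approx(1.0, abs=1e-9)


class TestPartitionLigation:
    def test_unambiguous_matrix_passes_through(self):
        rows = [[hom("A"), hom("B"), hom("C"), hom("D")]] * 4 + \
               [[hom("G"), hom("T"), hom("C"), hom("D")]] * 4
        m = matrix_from_rows([1, 2, 3, 4], rows)
        res = EMPhasingModel(m, window_size=2, restarts=1).fit()
        assert all(a.posterior == pytest.approx(1.0) for a in res.assignments.values())
        assert set(res.pool.frequencies) == {("A", "B", "C", "D"), ("G", "T", "C", "D")}

    def test_single_window_equals_ligated_windows_on_small_panel(self):
        # unambiguous double-het toy: the four-haplotype resolution is
        # identifiable, so splitting the panel must not change the optimum
        rows = ([[hom("A"), hom("B"), hom("C"), hom("D")]] * 5
                + [[hom("G"), hom("T"), hom("C"), hom("D")]] * 3
                + [[het("A", "G"), het("B", "T"), hom("C"), hom("D")]] * 2
                + [[hom("A"), hom("B"), het("C", "T"), het("D", "A")]] * 2)
        m = matrix_from_rows([1, 2, 3, 4], rows)
        single = EMPhasingModel(m, window_size=4, restarts=1, seed=0).fit()
        split = EMPhasingModel(m, window_size=2, restarts=1, seed=0).fit()
        assert split.loglike == pytest.approx(single.loglike, abs=1e-6)
        for h, f in single.pool.frequencies.items():
            assert split.pool.frequencies.get(h, 0.0) == pytest.approx(f, abs=1e-4)

    def test_window_equal_to_panel_matches_plain_em(self, ref):
        fs = freqset_from_reference_table(ref.utr3, seed=2)
        truth = sample_diplotypes(fs, 60, seed=21)
        recs = simulate_depths(truth, SimulationConfig(
            mean_depth=30, error_rate=0.0, mismap_rate=0.0, seed=21))
        m = refine_matrix(recs, truth.sites, truth.samples,
                          site_alleles=truth.site_alleles)
        res = EMPhasingModel(m, window_size=len(m.sites), restarts=1, seed=0).fit()
        plain = em_frequencies(m, restarts=1)
        assert res.loglike == pytest.approx(plain.loglike, abs=1e-4)

    def test_parameter_recovery_from_synthetic_cohort(self, ref):
        # 1000 chromosomes at high depth, no error: RMSE of estimated
        # haplotype frequencies below 0.01 and switch error below 5%
        fs = freqset_from_reference_table(ref.utr3, seed=2)
        truth = sample_diplotypes(fs, 500, seed=23)
        recs = simulate_depths(truth, SimulationConfig(
            mean_depth=30, error_rate=0.0, mismap_rate=0.0, seed=23))
        m = refine_matrix(recs, truth.sites, truth.samples,
                          populations=truth.populations,
                          site_alleles=truth.site_alleles)
        res = EMPhasingModel(m, window_size=5, restarts=2, seed=1).fit()
        true_counts = {}
        for s in truth.samples:
            for h in truth.hap_vectors[s]:
                true_counts[h] = true_counts.get(h, 0) + 1
        n = sum(true_counts.values())
        sq = [(res.pool.frequencies.get(h, 0.0) - c / n) ** 2
              for h, c in true_counts.items()]
        assert np.sqrt(np.mean(sq)) < 0.01
        for name in fs.names:
            if name.startswith("unnamed"):
                continue
            h = fs.vectors[name]
            p = fs.frequencies[name]
            se = np.sqrt(p * (1 - p) / n)
            assert abs(res.pool.frequencies.get(h, 0.0) - p) < 3 * se + 0.01
        from hlag.simulate import evaluate_calls
        phased = {s: res.assignments[s].haplotypes for s in m.samples}
        assert evaluate_calls(truth, m, phased=phased)["switch_error"] < 0.05

    def test_mean_posterior_increases_with_depth(self, ref):
        fs = freqset_from_reference_table(ref.utr3, seed=2)
        truth = sample_diplotypes(fs, 60, seed=25)
        posts = []
        for lam in (2.0, 30.0):
            recs = simulate_depths(truth, SimulationConfig(
                mean_depth=lam, error_rate=0.0, mismap_rate=0.0, seed=25))
            m = refine_matrix(recs, truth.sites, truth.samples,
                              site_alleles=truth.site_alleles)
            res = EMPhasingModel(m, window_size=5, restarts=1, seed=2).fit()
            posts.append(res.phasing_summary()[0])
        assert posts[1] > posts[0]


class TestSummariesAndRegions:
    def test_summary_arithmetic(self):
        mk = lambda s, p: DiplotypeAssignment(s, (("A",), ("A",)), p, ())
        mean, frac, _ = phasing_summary({"a": mk("a", 0.8), "b": mk("b", 1.0)})
        assert (mean, frac) == (pytest.approx(0.9), 0.5)
        mean, frac, _ = phasing_summary({"a": mk("a", 1.0)})
        assert (mean, frac) == (1.0, 1.0)

    def test_projection_identity_and_merging(self):
        pool = HaplotypePool(sites=(1, 2, 3), frequencies={
            ("A", "B", "C"): 0.5, ("A", "B", "T"): 0.3, ("G", "B", "C"): 0.2})
        ident = extract_region(pool, [1, 2, 3])
        assert ident.frequencies == pool.frequencies
        merged = extract_region(pool, [1, 2])
        assert merged.frequencies[("A", "B")] == pytest.approx(0.8)
        with pytest.raises(KeyError):
            extract_region(pool, [9])

    def test_extended_haplotypes_project_onto_utr_reference_rows(self, ref):
        ext = build_extended_vectors(ref)
        pos_index = {p: i for i, p in enumerate(ref.panel.gene_positions)}
        idx = [pos_index[p] for p in ref.utr3.sites]
        for _, row in ext.iterrows():
            utr_name = row["label"].split("/")[-1]
            if utr_name in ref.utr3.names:
                proj = tuple(row["vector"][i] for i in idx)
                assert proj == ref.utr3.vector(utr_name), row["label"]
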