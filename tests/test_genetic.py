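"""Genetic operators, generation composition, evolution loop, provenance."""

import numpy as np
import pytest

import pronyfit as pf
from pronyfit.genetic import (GAConfig, decode, encode, gaussian_mutation,
                              k_point_crossover, load_records, next_generation,
                              repair, resume, run, single_point_crossover)
from pronyfit.seeding import random_start


def chrom(g, tau):
    return encode(pf.PronySeries(g=np.asarray(g, float),
                                 tau=np.asarray(tau, float)))


@pytest.fixture()
def parents():
    return (chrom([0.1, 0.2], [0.01, 0.1]), chrom([0.3, 0.4], [1.0, 10.0]))


class TestCodecAndRepair:
    def test_round_trip(self):
        p = pf.PronySeries(g=[0.25, 0.3], tau=[0.02, 0.7])
        q = decode(encode(p))
        np.testing.assert_allclose(q.g, p.g)
        np.testing.assert_allclose(q.tau, p.tau)
        assert q.g_inf == pytest.approx(p.g_inf)

    def test_repair_restores_simplex_and_ordering(self):
        v = np.array([0.0, 1.4, -0.2, 5.0, 0.3])  # bad g's, unsorted tau
        r = repair(v)
        p = decode(r)
        assert pf.viability_check(p)
        assert np.all(np.diff(p.tau) >= 0)

    def test_repair_is_idempotent(self):
        v = np.array([0.0, 0.9, 0.8, 5.0, 0.3])
        r1 = repair(v)
        np.testing.assert_allclose(repair(r1), r1)


class TestCrossover:
    def test_identical_parents_give_identical_children(self, parents):
        p1, _ = parents
        rng = np.random.default_rng(0)
        c1, c2 = single_point_crossover(p1, p1.copy(), rng)
        np.testing.assert_allclose(c1, p1)
        np.testing.assert_allclose(c2, p1)

    def test_splice_bookkeeping_matches_cut_draw(self, parents):
        """Children are the verifiable prefix/suffix splice of the parents."""
        p1, p2 = parents
        rng = np.random.default_rng(3)
        cut = int(np.random.default_rng(3).integers(1, p1.size + 1))
        c1, c2 = single_point_crossover(p1, p2, rng)
        expected1 = repair(np.concatenate([p1[:cut], p2[cut:]]))
        expected2 = repair(np.concatenate([p2[:cut], p1[cut:]]))
        np.testing.assert_allclose(c1, expected1)
        np.testing.assert_allclose(c2, expected2)

    def test_cut_at_full_length_copies_parents(self, parents):
        p1, p2 = parents
        # find a seed whose first draw is the boundary cut 2N+1
        for s in range(200):
            if int(np.random.default_rng(s).integers(1, p1.size + 1)) == p1.size:
                c1, c2 = single_point_crossover(p1, p2, np.random.default_rng(s))
                np.testing.assert_allclose(c1, repair(p1))
                np.testing.assert_allclose(c2, repair(p2))
                return
        pytest.fail("no seed produced the boundary cut")

    def test_k_point_segment_membership(self, parents):
        """Every child gene traces to the correct parent for a fixed seed."""
        p1, p2 = parents
        seed = 17
        cuts = np.sort(np.random.default_rng(seed).choice(
            np.arange(1, p1.size), size=2, replace=False))
        c1, c2 = k_point_crossover(p1, p2, 2, np.random.default_rng(seed))
        raw1, raw2 = p1.copy(), p2.copy()
        take_second = False
        prev = 0
        for cut in list(cuts) + [p1.size]:
            if take_second:
                raw1[prev:cut], raw2[prev:cut] = p2[prev:cut], p1[prev:cut]
            take_second = not take_second
            prev = cut
        np.testing.assert_allclose(c1, repair(raw1))
        np.testing.assert_allclose(c2, repair(raw2))

    def test_children_always_viable(self, parents):
        p1, p2 = parents
        rng = np.random.default_rng(9)
        for _ in range(100):
            for c in single_point_crossover(p1, p2, rng):
                assert pf.viability_check(decode(c))
            for c in k_point_crossover(p1, p2, 3, rng):
                assert pf.viability_check(decode(c))


class TestMutation:
    def test_zero_sigma_is_identity(self):
        c = chrom([0.2, 0.3], [0.01, 1.0])
        out = gaussian_mutation(c, 0.0, np.random.default_rng(0))
        np.testing.assert_allclose(out, repair(c))

    def test_output_always_viable(self):
        c = chrom([0.2, 0.3], [0.01, 1.0])
        rng = np.random.default_rng(1)
        for sigma in (0.01, 0.1, 0.5):
            for _ in range(50):
                assert pf.viability_check(decode(gaussian_mutation(c, sigma, rng)))

    def test_empirical_spread_matches_sigma(self):
        """Monte-Carlo moment check on an interior gene (no repair clipping)."""
        c = chrom([0.3, 0.35], [0.01, 1.0])
        sigma = 0.02
        rng = np.random.default_rng(2)
        draws = np.array([gaussian_mutation(c, sigma, rng) for _ in range(10_000)])
        # additive spread on g_1 (index 1); multiplicative on tau_2 (index 4)
        assert np.std(draws[:, 1] - c[1]) == pytest.approx(sigma, rel=0.05)
        assert np.std(np.log(draws[:, 4] / c[4])) == pytest.approx(sigma, rel=0.05)


class TestNextGeneration:
    def _reports(self, pop, data):
        return [pf.FitnessReport(equation_error=pf.equation_objective(decode(c), data))
                for c in pop]

    def test_composition_thirds_and_elitism(self, data_n1):
        rng = np.random.default_rng(4)
        cfg = GAConfig(order=1, population_size=33, num_in_gen=1, elite_count=3)
        pop = [encode(random_start(1, rng)) for _ in range(33)]
        reports = self._reports(pop, data_n1)
        new, tags = next_generation(pop, reports, cfg, rng, return_tags=True)
        assert len(new) == 33
        assert tags.count("elite") == 3
        assert tags.count("crossover") == 10
        assert tags.count("mutation") == 10
        assert tags.count("random") == 10
        # elites are exact copies of the best-ranked members
        order = sorted(range(33), key=lambda i: reports[i].rank_key)
        for k in range(3):
            np.testing.assert_allclose(new[k], pop[order[k]])

    def test_every_member_viable(self, data_n1):
        rng = np.random.default_rng(6)
        cfg = GAConfig(order=2, population_size=33, num_in_gen=1)
        pop = [encode(random_start(2, rng)) for _ in range(33)]
        new = next_generation(pop, self._reports(pop, data_n1), cfg, rng)
        assert all(pf.viability_check(decode(c)) for c in new)

    def test_config_validation(self):
        with pytest.raises(ValueError):
            GAConfig(order=1, population_size=100)  # not divisible by 3
        with pytest.raises(ValueError):
            GAConfig(order=1, population_size=99, num_in_gen=100)
        with pytest.raises(ValueError):
            GAConfig(order=1, population_size=99, num_in_gen=1, k_points=5)


@pytest.fixture(scope="module")
def small_run(truth_n1_mod, data_n1_mod, curves_n1_mod, sim_mod, tmp_path_factory):
    backup = tmp_path_factory.mktemp("run") / "backup.jsonl"
    cfg = GAConfig(order=1, num_iteration=5, num_in_gen=6, population_size=33,
                   rng_seed=11, seed_restarts=4, elite_count=3)
    records = run(data_n1_mod, curves_n1_mod, cfg, sim_mod, backup_path=backup)
    return records, backup, cfg


# module-scoped copies of the session fixtures (run() is expensive)
@pytest.fixture(scope="module")
def truth_n1_mod():
    return pf.GroundTruth(prony=pf.PronySeries(g=[0.4], tau=[0.1]))


@pytest.fixture(scope="module")
def data_n1_mod(truth_n1_mod):
    return pf.make_dma_dataset(truth_n1_mod, rng=np.random.default_rng(0))


@pytest.fixture(scope="module")
def curves_n1_mod(truth_n1_mod):
    ramps, loop = pf.make_validation_series(truth_n1_mod,
                                            rng=np.random.default_rng(2))
    return pf.build_validation_curves(ramps, loop)


@pytest.fixture(scope="module")
def sim_mod():
    return pf.SimulationSettings(ogden=pf.DEFAULT_OGDEN)


class TestRun:
    def test_zero_iterations_returns_seeded_generation(
            self, data_n1_mod, curves_n1_mod, sim_mod):
        cfg = GAConfig(order=1, num_iteration=0, num_in_gen=3,
                       population_size=33, rng_seed=5, seed_restarts=2)
        records = run(data_n1_mod, curves_n1_mod, cfg, sim_mod)
        assert len(records) == 1
        assert records[0].generation_index == 0

    def test_best_mean_error_monotone_non_increasing(self, small_run):
        records, _, _ = small_run
        means = [r.best_so_far["mean_error_pct"] for r in records]
        assert all(b <= a + 1e-12 for a, b in zip(means, means[1:]))

    def test_all_recorded_individuals_viable(self, small_run):
        records, _, _ = small_run
        for rec in records:
            for c in rec.population:
                assert pf.viability_check(decode(np.asarray(c)))

    def test_backup_round_trips(self, small_run):
        records, backup, _ = small_run
        loaded = load_records(backup)
        assert len(loaded) == len(records)
        for a, b in zip(records, loaded):
            assert a.generation_index == b.generation_index
            np.testing.assert_allclose(np.asarray(a.population),
                                       np.asarray(b.population))
            assert a.best_so_far == b.best_so_far

    def test_identical_seeds_give_identical_records(
            self, small_run, data_n1_mod, curves_n1_mod, sim_mod):
        records, _, cfg = small_run
        again = run(data_n1_mod, curves_n1_mod, cfg, sim_mod)
        assert len(again) == len(records)
        for a, b in zip(records, again):
            np.testing.assert_array_equal(np.asarray(a.population),
                                          np.asarray(b.population))
            assert a.best_so_far == b.best_so_far
            assert a.rng_state == b.rng_state

    def test_recovery_of_generating_parameters(self, small_run):
        records, _, _ = small_run
        best = decode(np.asarray(records[-1].best_so_far["chromosome"]))
        assert records[-1].best_so_far["equation_error"] < 1e-4
        assert best.g[0] == pytest.approx(0.4, rel=0.05)
        assert best.tau[0] == pytest.approx(0.1, rel=0.05)

    def test_resume_continues_from_backup(self, small_run, data_n1_mod,
                                          curves_n1_mod, sim_mod, tmp_path):
        records, backup, cfg = small_run
        # copy the first 3 records into a fresh backup, then resume to 5
        partial = tmp_path / "partial.jsonl"
        lines = backup.read_text().strip().splitlines()
        partial.write_text("\n".join(lines[:3]) + "\n")
        resumed = resume(data_n1_mod, curves_n1_mod, cfg, sim_mod, partial)
        assert len(resumed) == len(records)
        np.testing.assert_array_equal(
            np.asarray(resumed[-1].population),
            np.asarray(records[-1].population))
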