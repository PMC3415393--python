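import numpy as np
import pandas as pd
import pytest

from badgerqc import engine, eqtl, simulate
from badgerqc.eqtl import ClassDensity, EQTLPair
from badgerqc.simulate import AlienError, SimulationConfig

from conftest import random_mixture_density


def _pair_with(densities):
    p = EQTLPair("probe", "snp", 20.0)
    p.densities = densities
    return p


class TestPosteriorPrediction:
    def test_brute_force_oracle(self):
        # posterior and expectation must equal a direct density-ratio
        # evaluation (plain pdf arithmetic, no log-space) on random
        # mixtures and expression levels
        rng = np.random.default_rng(42)
        for _ in range(100):
            densities = {
                c: random_mixture_density(rng)
                for c in (0, 1, 2)
                if rng.random() > 0.15
            }
            if not densities:
                densities = {1: random_mixture_density(rng)}
            e = float(rng.uniform(-3, 5))
            p, post = engine.predict_b_allele(_pair_with(densities), e)

            def naive_pdf(d, x):
                z = (x - d.points) / d.bandwidth
                return float(
                    np.mean(np.exp(-0.5 * z * z) / (d.bandwidth * np.sqrt(2 * np.pi)))
                )

            f = {c: naive_pdf(d, e) for c, d in densities.items()}
            total = sum(f.values())
            expected_post = {c: v / total for c, v in f.items()}
            expected_p = sum(c * q for c, q in expected_post.items())
            assert p == pytest.approx(expected_p, abs=1e-10)
            for c in densities:
                assert post[c] == pytest.approx(expected_post[c], abs=1e-10)

    def test_uninformative_expression_tends_to_heterozygote(self):
        d = ClassDensity(np.array([0.0]), 1.0)
        p, post = engine.predict_b_allele(
            _pair_with({0: d, 1: d, 2: d}), 0.0
        )
        assert p == pytest.approx(1.0)
        assert post == pytest.approx({0: 1 / 3, 1: 1 / 3, 2: 1 / 3})

    def test_well_separated_classes(self):
        dens = {
            c: ClassDensity(np.array([float(c)]), 0.2) for c in (0, 1, 2)
        }
        p, _ = engine.predict_b_allele(_pair_with(dens), 0.0)
        assert p < 0.01

    def test_two_available_classes_symmetric_point(self):
        dens = {0: ClassDensity(np.array([0.0]), 0.3), 2: ClassDensity(np.array([2.0]), 0.3)}
        p, post = engine.predict_b_allele(_pair_with(dens), 1.0)
        assert p == pytest.approx(1.0)
        assert set(post) == {0, 2}

    def test_missing_expression_gives_missing_prediction(self):
        p, post = engine.predict_b_allele(
            _pair_with({1: ClassDensity(np.array([1.0]), 0.3)}), float("nan")
        )
        assert np.isnan(p) and post is None


def _frame(arr, index, columns):
    return pd.DataFrame(np.asarray(arr, dtype=float), index=index, columns=columns)


class TestScoreMatrix:
    def test_printed_example(self):
        P = _frame([[0.1, 1.9]], ["E1"], ["q1", "q2"])
        O = _frame([[0.0], [2.0]], ["q1", "q2"], ["G1"])
        sm = engine.score_matrix(P, O)
        assert sm.scores.loc["E1", "G1"] == pytest.approx(0.02)

    def test_perfect_match_scores_zero(self):
        P = _frame([[0.0, 1.0, 2.0]], ["E1"], list("abc"))
        O = _frame([[0.0], [1.0], [2.0]], list("abc"), ["G1"])
        assert engine.score_matrix(P, O).scores.loc["E1", "G1"] == 0.0

    def test_fully_missing_column_is_missing(self):
        P = _frame([[0.1, 1.9]], ["E1"], ["q1", "q2"])
        O = _frame([[np.nan, 0.0], [np.nan, 2.0]], ["q1", "q2"], ["G0", "G1"])
        sm = engine.score_matrix(P, O)
        assert np.isnan(sm.scores.loc["E1", "G0"])
        assert sm.n_eqtls_used.loc["E1", "G0"] == 0

    def test_missing_rescaled_sum_matches_bruteforce(self):
        rng = np.random.default_rng(7)
        P = rng.uniform(0, 2, size=(5, 8))
        O = rng.integers(0, 3, size=(8, 6)).astype(float)
        P[rng.random(P.shape) < 0.2] = np.nan
        O[rng.random(O.shape) < 0.2] = np.nan
        Pf = _frame(P, [f"E{i}" for i in range(5)], [f"q{i}" for i in range(8)])
        Of = _frame(O, [f"q{i}" for i in range(8)], [f"G{i}" for i in range(6)])
        sm = engine.score_matrix(Pf, Of)
        for j in range(5):
            for k in range(6):
                terms = [
                    (P[j, i] - O[i, k]) ** 2
                    for i in range(8)
                    if not (np.isnan(P[j, i]) or np.isnan(O[i, k]))
                ]
                if terms:
                    expected = 8 / len(terms) * sum(terms)
                    assert sm.scores.iloc[j, k] == pytest.approx(expected, rel=1e-12)
                else:
                    assert np.isnan(sm.scores.iloc[j, k])

    def test_column_permutation_equivariance(self):
        rng = np.random.default_rng(8)
        P = _frame(rng.uniform(0, 2, (4, 6)), list("wxyz"), [f"q{i}" for i in range(6)])
        O = _frame(rng.integers(0, 3, (6, 5)).astype(float),
                   [f"q{i}" for i in range(6)], [f"G{i}" for i in range(5)])
        base = engine.score_matrix(P, O).scores
        perm = ["G3", "G0", "G4", "G2", "G1"]
        permuted = engine.score_matrix(P, O[perm]).scores
        assert permuted.equals(base[perm])


class TestRanks:
    def test_row_ranking(self):
        sm = engine.score_matrix(
            _frame([[0.5]], ["E1"], ["q"]), _frame([[0.0]], ["q"], ["G1"])
        )
        sm.scores = _frame([[0.5, 0.1, 0.9]], ["E1"], ["G1", "G2", "G3"])
        rm = engine.rank_matrix(sm)
        assert rm.ranks.loc["E1"].tolist() == [2.0, 1.0, 3.0]

    def test_ties_share_minimum_rank(self):
        sm = engine.score_matrix(
            _frame([[0.5]], ["E1"], ["q"]), _frame([[0.0]], ["q"], ["G1"])
        )
        sm.scores = _frame([[0.2, 0.2, 0.9]], ["E1"], ["G1", "G2", "G3"])
        rm = engine.rank_matrix(sm)
        assert rm.ranks.loc["E1"].tolist() == [1.0, 1.0, 3.0]


class TestDeltaStatistic:
    def test_simple_gap(self):
        row = pd.Series([0.1, 5.0, 6.0], index=list("abc"), name="E1")
        d = engine.delta_statistic(row, g=1)
        assert d.gap == pytest.approx(4.9)
        assert d.min_score == pytest.approx(0.1)
        assert d.best_genotype_array == "a"

    def test_replicate_aware_gap(self):
        # with a duplicated genotype array, the gap skips the replicate
        row = pd.Series([0.1, 0.12, 6.0, 7.0], index=list("abcd"), name="E1")
        assert engine.delta_statistic(row, g=1).gap == pytest.approx(0.02)
        assert engine.delta_statistic(row, g=2).gap == pytest.approx(5.9)

    def test_needs_more_scores_than_replicates(self):
        row = pd.Series([0.1, 0.2], index=list("ab"))
        with pytest.raises(ValueError):
            engine.delta_statistic(row, g=2)

    def test_mismatch_never_raises_delta(self):
        # destroying an array's partner (alien) can only shrink its gap;
        # compared under the same fitted densities, seed by seed
        violations = 0
        for seed in range(100):
            base = SimulationConfig(seed=seed + 500, n_samples=48, n_snps=40,
                                    n_probes=123, n_excluded=1,
                                    excluded_positions=(49,))
            clean = simulate.simulate_cohort(base)
            corrupted = simulate.simulate_cohort(
                SimulationConfig(**{**base.__dict__, "error_spec": (AlienError("genotype"),)})
            )
            (corr,) = corrupted.truth_corrections
            e_arr = next(m.expression_array for m in corr.moves if m.expression_array)
            pairs = eqtl.fit_eqtl_set(
                eqtl.scan_cis_associations(clean.expr, clean.geno, clean.smap),
                clean.expr, clean.geno, clean.smap)
            P = engine.predict_matrix(pairs, clean.expr)
            d_clean = engine.delta_statistics(engine.score_matrix(
                P, engine.observed_matrix(pairs, clean.geno)))[e_arr]
            d_bad = engine.delta_statistics(engine.score_matrix(
                P, engine.observed_matrix(pairs, corrupted.geno)))[e_arr]
            if d_bad.gap > d_clean.gap + 1e-9:
                violations += 1
        assert violations == 0


class TestDiscrepancyAndRefinement:
    def test_perfect_predictions_zero_discrepancy(self):
        P = _frame([[0.0, 1.0], [2.0, 1.0]], ["E1", "E2"], ["q1", "q2"])
        O = _frame([[0.0, 2.0], [1.0, 1.0]], ["q1", "q2"], ["G1", "G2"])
        d = engine.eqtl_discrepancy(P, O, [("E1", "G1"), ("E2", "G2")])
        assert (d == 0.0).all()

    def test_constant_heterozygote_prediction(self):
        # p = 1 against balanced genotypes 1/4, 1/2, 1/4 gives d = 0.5
        o = np.array([0.0] * 25 + [1.0] * 50 + [2.0] * 25)
        P = _frame(np.ones((100, 1)), [f"E{i}" for i in range(100)], ["q"])
        O = _frame(o[None, :].T.reshape(1, -1), ["q"], [f"G{i}" for i in range(100)])
        d = engine.eqtl_discrepancy(P, O, [(f"E{i}", f"G{i}") for i in range(100)])
        assert d.iloc[0] == pytest.approx(0.5)

    def test_true_eqtls_beat_null_eqtls(self):
        worse = 0
        for seed in range(20):
            c = simulate.simulate_cohort(
                SimulationConfig(seed=seed + 700, n_samples=48, n_snps=30, n_probes=60)
            )
            true = eqtl.fit_eqtl_set(
                eqtl.scan_cis_associations(c.expr, c.geno, c.smap), c.expr, c.geno, c.smap
            )
            true_probes = {p.probe_id for p in true}
            null_probe = next(
                p for p in c.expr.probe_ids
                if p not in true_probes
                and c.expr.probe_annotation.loc[p, "quality_tier"] == "perfect"
            )
            null = eqtl.fit_eqtl_set(
                [eqtl.EQTLPair(null_probe, true[0].snp_id, 0.0)], c.expr, c.geno, c.smap
            )
            pairs = true + null
            P = engine.predict_matrix(pairs, c.expr)
            O = engine.observed_matrix(pairs, c.geno)
            d = engine.eqtl_discrepancy(
                P, O, [(e, g) for _s, e, g in c.smap.matched_pairs()]
            )
            if d[null[0].key] > d[[p.key for p in true]].mean():
                worse += 1
        assert worse >= 19

    def test_infinite_cutoff_is_noop(self, fitted_clean):
        c, pairs, P, O = fitted_clean
        d = engine.eqtl_discrepancy(P, O, [(e, g) for _s, e, g in c.smap.matched_pairs()])
        retained, removed = engine.refine_eqtl_set(list(pairs), d, float("inf"))
        assert len(retained) == len(pairs) and removed == []

    def test_rescore_equals_full_recomputation_exactly(self, fitted_clean):
        c, pairs, P, O = fitted_clean
        keep = pairs[: len(pairs) // 2]
        direct = engine.score_matrix(
            P.loc[:, [p.key for p in keep]], O.loc[[p.key for p in keep]]
        )
        rescored = engine.rescore(P, O, keep)
        assert rescored.scores.equals(direct.scores)
        assert rescored.n_eqtls_used.equals(direct.n_eqtls_used)

    def test_auto_cutoff_never_splits_homogeneous_set(self):
        rng = np.random.default_rng(9)
        d = pd.Series(rng.uniform(0.02, 0.2, size=50))
        assert not np.isfinite(engine.auto_discrepancy_cutoff(d))

    def test_auto_cutoff_separates_two_clusters(self):
        rng = np.random.default_rng(10)
        d = pd.Series(
            np.concatenate([rng.uniform(0.02, 0.15, 50), rng.uniform(0.4, 0.7, 50)])
        )
        cutoff = engine.auto_discrepancy_cutoff(d)
        assert 0.15 < cutoff < 0.4


class TestDuplicateDetection:
    def test_exact_duplicate_columns_grouped(self, clean_cohort):
        geno = clean_cohort.geno
        dup = geno.values.copy()
        dup["G_dup"] = dup[geno.array_ids[0]]
        g2 = simulate.GenotypeMatrix(dup, geno.snp_annotation)
        groups = engine.find_duplicate_genotype_arrays(g2)
        assert [set(g) for g in groups] == [{geno.array_ids[0], "G_dup"}]
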