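import numpy as np
import pytest

from badgerqc import simulate
from badgerqc.core import apply_corrections
from badgerqc.simulate import (
    AlienError,
    CycleError,
    NeighbourSwap,
    PlateRotationError,
    PopulationGroup,
    SimulationConfig,
    SlippageError,
    TumourSpec,
)


class TestPopulation:
    def test_hardy_weinberg_at_zero_drift(self):
        cfg = SimulationConfig(seed=1, n_samples=600, n_snps=80)
        geno, groups, _ = simulate.simulate_population(cfg)
        g = geno.values.to_numpy()
        # observed allele frequency tracks the generating frequency; with
        # F=0 all samples share it, so the per-SNP genotype mean has
        # binomial sampling error only
        freqs = g.mean(axis=1) / 2.0
        counts = np.stack([(g == k).mean(axis=1) for k in (0, 1, 2)])
        expected = np.stack([(1 - freqs) ** 2, 2 * freqs * (1 - freqs), freqs**2])
        assert np.abs(counts - expected).max() < 0.08

    def test_mendelian_trios(self):
        cfg = SimulationConfig(seed=2, n_samples=60, n_snps=50, n_trios=5)
        geno, _, trios = simulate.simulate_population(cfg)
        assert len(trios) == 5
        for fa, mo, ch in trios:
            f = geno.values[fa].to_numpy()
            m = geno.values[mo].to_numpy()
            c = geno.values[ch].to_numpy()
            lower = (f == 2).astype(int) + (m == 2).astype(int)
            upper = 2 - (f == 0).astype(int) - (m == 0).astype(int)
            assert ((c >= lower) & (c <= upper)).all()

    def test_balding_nichols_drift_variance(self):
        # moment check: Var(p_group - p) = p(1-p) F under the Beta drift
        f = 0.2
        cfg = SimulationConfig(
            seed=3, n_samples=2000, n_snps=400, maf_range=(0.3, 0.3),
            population_spec=(PopulationGroup("g", 1.0, f, True),),
        )
        geno, _, _ = simulate.simulate_population(cfg)
        phat = geno.values.to_numpy().mean(axis=1) / 2.0
        var = np.var(phat - 0.3)
        expected = 0.3 * 0.7 * f  # sampling noise ~ p(1-p)/2n is negligible
        assert abs(var - expected) / expected < 0.25


class TestExpression:
    def test_noiseless_limit_is_exact(self):
        cfg = SimulationConfig(seed=4, n_samples=40, noise_sd=0.0, effect_size=1.0)
        geno, groups, _ = simulate.simulate_population(cfg)
        expr, truth = simulate.simulate_expression(geno, cfg, groups)
        for row in truth.itertuples():
            e = expr.values.loc[row.probe_id].to_numpy()
            g = geno.values.loc[row.snp_id].to_numpy()
            slope, intercept = np.polyfit(g, e, 1)
            assert slope == pytest.approx(1.0, abs=1e-9)
            assert np.abs(e - (intercept + slope * g)).max() < 1e-9

    def test_effect_recovery_and_inactive_group(self):
        cfg = SimulationConfig(
            seed=5, n_samples=400, noise_sd=0.3, effect_size=1.0,
            population_spec=(
                PopulationGroup("eu", 0.7, 0.0, True),
                PopulationGroup("af", 0.3, 0.1, False),
            ),
        )
        geno, groups, _ = simulate.simulate_population(cfg)
        expr, truth = simulate.simulate_expression(geno, cfg, groups)
        active = (groups == "eu").to_numpy()
        slopes_a, slopes_i = [], []
        for row in truth.itertuples():
            e = expr.values.loc[row.probe_id].to_numpy()
            g = geno.values.loc[row.snp_id].to_numpy()
            for mask, acc in ((active, slopes_a), (~active, slopes_i)):
                if np.std(g[mask]) > 0:
                    b, v = np.polyfit(g[mask], e[mask], 1, cov=True)[0][0], None
                    acc.append(b)
        # fitted slope recovers the unit effect in the active group and
        # vanishes in the group whose eQTLs are switched off
        assert abs(np.mean(slopes_a) - 1.0) < 3 * np.std(slopes_a) / np.sqrt(len(slopes_a)) + 0.02
        assert abs(np.mean(slopes_i)) < 0.05


class TestTumourDistortion:
    def _geno(self, seed=6):
        cfg = SimulationConfig(seed=seed, n_samples=300, n_snps=100)
        geno, _, _ = simulate.simulate_population(cfg)
        return geno

    def test_zero_rate_is_identity(self):
        geno = self._geno()
        out, _ = simulate.apply_tumour_distortion(
            geno, TumourSpec(loh_rate=0.0), np.random.default_rng(0)
        )
        assert out.values.equals(geno.values)

    def test_full_loh_pure_tumour_removes_all_hets(self):
        geno = self._geno()
        out, _ = simulate.apply_tumour_distortion(
            geno, TumourSpec(loh_rate=1.0), np.random.default_rng(0), cellularity=1.0
        )
        assert not (out.values.to_numpy() == 1.0).any()
        # homozygous calls untouched
        hom = geno.values.to_numpy() != 1.0
        assert (out.values.to_numpy()[hom] == geno.values.to_numpy()[hom]).all()

    def test_collapse_fraction_matches_rate_times_cellularity(self):
        geno = self._geno(7)
        out, _ = simulate.apply_tumour_distortion(
            geno, TumourSpec(loh_rate=0.5), np.random.default_rng(1), cellularity=0.4
        )
        het = geno.values.to_numpy() == 1.0
        collapsed = (out.values.to_numpy() != 1.0) & het
        frac = collapsed.sum() / het.sum()
        p = 0.5 * 0.4
        se = np.sqrt(p * (1 - p) / het.sum())
        assert abs(frac - p) < 4 * se


class TestErrorInjection:
    def test_empty_spec_is_identity(self):
        c = simulate.simulate_cohort(SimulationConfig(seed=8, n_samples=24))
        assert c.truth_corrections == []
        assert c.truth_map.assignment_signature() == c.smap.assignment_signature()

    def test_neighbour_swap_truth_is_one_two_cycle(self):
        c = simulate.simulate_cohort(
            SimulationConfig(seed=9, n_samples=24, error_spec=(NeighbourSwap("genotype"),))
        )
        (corr,) = c.truth_corrections
        assert corr.kind == "swap" and len(corr.moves) == 2
        s1, s2 = [m.sample_id for m in corr.moves]
        g1 = c.smap.record_of(s1).genotype_array
        g2 = c.smap.record_of(s2).genotype_array
        assert {m.genotype_array for m in corr.moves} == {g1, g2}

    def test_slippage_reproduces_orphan_alien_signature(self):
        # window of six included samples with space-holders after the third
        # and sixth: two orphans per platform, four shifted matches
        cfg = SimulationConfig(
            seed=10, n_samples=96, n_excluded=2, excluded_positions=(52, 56),
            error_spec=(SlippageError(start=49, length=8),),
        )
        c = simulate.simulate_cohort(cfg)
        (corr,) = c.truth_corrections
        assert corr.kind == "slippage"
        orphans = [m.sample_id for m in corr.moves if m.genotype_array is None]
        aliens = [m.sample_id for m in corr.moves if m.expression_array is None]
        shifted = [m for m in corr.moves if m.expression_array and m.genotype_array]
        assert len(orphans) == 2 and len(aliens) == 2 and len(shifted) == 4
        assert set(aliens) == {"S052", "S056"}  # the excluded space-holders

    def test_truth_corrections_reconstruct_truth_map(self):
        errors = (
            NeighbourSwap("genotype"),
            CycleError(3, "genotype"),
            SlippageError(start=40, length=6),
            AlienError("genotype"),
        )
        cfg = SimulationConfig(
            seed=11, n_samples=96, n_excluded=4, excluded_positions=(20, 45, 70, 90),
            error_spec=errors,
        )
        c = simulate.simulate_cohort(cfg)
        rebuilt = apply_corrections(c.smap, c.truth_corrections, strict=False)
        assert rebuilt.assignment_signature() == c.truth_map.assignment_signature()

    def test_rotation_requires_full_plate(self):
        cfg = SimulationConfig(
            seed=12, n_samples=40, error_spec=(PlateRotationError("genotype", "GP1"),)
        )
        with pytest.raises(ValueError, match="fully occupied"):
            simulate.simulate_cohort(cfg)


class TestDeterminism:
    def test_same_seed_bit_identical(self):
        cfg = dict(seed=13, n_samples=24, error_spec=(NeighbourSwap("genotype"),))
        a = simulate.simulate_cohort(SimulationConfig(**cfg))
        b = simulate.simulate_cohort(SimulationConfig(**cfg))
        assert a.expr.values.equals(b.expr.values)
        assert a.geno.values.equals(b.geno.values)
        assert a.truth_map.assignment_signature() == b.truth_map.assignment_signature()

    def test_different_seeds_differ(self):
        a = simulate.simulate_cohort(SimulationConfig(seed=14, n_samples=24))
        b = simulate.simulate_cohort(SimulationConfig(seed=15, n_samples=24))
        assert not a.expr.values.equals(b.expr.values)
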