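import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from adipomod import (
    ModuleSpec,
    SyntheticDesign,
    TraitTable,
    associate_modules,
    build_modules,
    conditional_reassessment,
    flag_trait_correlated_genes,
    generate_cohort,
    module_profiles,
    partial_spearman,
    quantile_normalize,
    spearman_correlation,
)

from conftest import make_matrix


class TestSpearman:
    def test_perfect_monotone_agreement(self):
        x = np.array([1, 4, 9, 16, 25], dtype=float)
        y = np.array([0.1, 0.2, 0.5, 0.9, 3.0])
        rho, _ = spearman_correlation(x, y)
        assert rho == pytest.approx(1.0)
        rho, _ = spearman_correlation(x, y[::-1])
        assert rho == pytest.approx(-1.0)

    def test_hand_ranked_tie_example(self):
        # y ranks (1, 2, 3.5, 5, 3.5); Pearson on ranks = 8/sqrt(95)
        rho, _ = spearman_correlation([1, 2, 3, 4, 5], [5, 6, 7, 8, 7])
        assert rho == pytest.approx(0.8208, abs=5e-5)

    def test_missing_pairs_dropped(self):
        x = np.array([1, 2, 3, 4, 5, 6, np.nan])
        y = np.array([2, 4, 6, 8, 10, 12, 100.0])
        rho, _ = spearman_correlation(x, y)
        assert rho == pytest.approx(1.0)

    def test_too_few_pairs_and_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            spearman_correlation([1, 2, 3], [1, 2, 3])
        with pytest.raises(ValueError):
            spearman_correlation([1, 1, 1, 1, 1], [1, 2, 3, 4, 5])

    @settings(deadline=None, max_examples=25, derandomize=True)
    @given(st.integers(0, 2**31 - 1))
    def test_invariant_under_monotone_transforms(self, seed):
        rng = np.random.default_rng(seed)
        x = rng.standard_normal(30)
        y = rng.standard_normal(30)
        rho0, p0 = spearman_correlation(x, y)
        rho1, p1 = spearman_correlation(np.exp(x), y**3)
        assert rho1 == pytest.approx(rho0, abs=1e-12)
        assert p1 == pytest.approx(p0, abs=1e-12)


class TestPartialSpearman:
    def test_empty_confounders_reduce_to_marginal(self, rng):
        x = rng.standard_normal(50)
        y = rng.standard_normal(50)
        assert partial_spearman(x, y, []) == spearman_correlation(x, y)

    def test_confounder_equal_to_y_degenerates_to_zero(self, rng):
        x = rng.standard_normal(50)
        y = rng.standard_normal(50)
        rho, p = partial_spearman(x, y, [y])
        assert abs(rho) < 1e-10
        assert p == 1.0

    def test_shared_driver_removed(self):
        # x and y both driven by z: marginal rho ~ 0.5, partial ~ 0
        rng = np.random.default_rng(123)
        n = 500
        z = rng.standard_normal(n)
        x = z + rng.standard_normal(n)
        y = z + rng.standard_normal(n)
        rho_m, _ = spearman_correlation(x, y)
        assert rho_m == pytest.approx(0.5, abs=0.1)
        rho_p, _ = partial_spearman(x, y, [z])
        assert abs(rho_p) < 0.1

    def test_independent_confounder_changes_little(self):
        rng = np.random.default_rng(7)
        n = 500
        x = rng.standard_normal(n)
        y = 0.6 * x + rng.standard_normal(n)
        w = rng.standard_normal(n)
        rho_m, _ = spearman_correlation(x, y)
        rho_p, _ = partial_spearman(x, y, [w])
        assert abs(rho_p - rho_m) < 0.05

    def test_collinear_confounders_rejected(self, rng):
        x = rng.standard_normal(30)
        y = rng.standard_normal(30)
        z = rng.standard_normal(30)
        with pytest.raises(ValueError, match="collinear"):
            partial_spearman(x, y, [z, 2 * z])


class TestAssociateModules:
    def _profiles(self, arr, samples):
        return pd.DataFrame(arr, index=[f"M{i}" for i in range(arr.shape[0])],
                            columns=samples)

    def test_planted_link_flagged_under_study_family(self):
        d = SyntheticDesign(trait_missing_rate=0.0)
        c = generate_cohort(d, seed=2)
        sat = quantile_normalize(c.sat)
        ms = build_modules(sat)
        prof = module_profiles(ms, sat)
        assoc = associate_modules(prof, c.traits, alpha=0.05,
                                  bonferroni_tests=67 * 14)
        assert assoc.threshold == pytest.approx(5.33e-5, rel=1e-3)
        truth = c.truth.set_index("probe_id")["module_id"]
        pm1 = set(truth[truth == "PM1"].index)
        hit = assoc.table[(assoc.table["trait"] == "HDL_cholesterol")
                          & assoc.table["significant"]]
        assert len(hit) == 1
        mod = [m for m in ms.multi()
               if set(m.member_probe_ids) == pm1][0]
        assert hit.iloc[0]["module_id"] == mod.module_id

    def test_family_null_controls_false_positives(self):
        # global null: family-wise error across replicates <= alpha-ish
        fams_with_fp = 0
        reps = 40
        for rep in range(reps):
            rng = np.random.default_rng(1000 + rep)
            samples = [f"S{j}" for j in range(50)]
            prof = self._profiles(rng.standard_normal((5, 50)), samples)
            traits = TraitTable(values=pd.DataFrame(
                rng.standard_normal((50, 5)),
                index=samples, columns=[f"T{k}" for k in range(5)]))
            a = associate_modules(prof, traits, alpha=0.05)
            fams_with_fp += a.table["significant"].any()
        assert fams_with_fp / reps <= 0.1

    def test_verdicts_invariant_to_ordering(self, rng, small_traits):
        samples = small_traits.sample_ids
        prof = self._profiles(rng.standard_normal((4, len(samples))), samples)
        a = associate_modules(prof, small_traits)
        b = associate_modules(prof.iloc[::-1], small_traits)
        key = lambda t: t.sort_values(["module_id", "trait"]).reset_index(drop=True)
        pd.testing.assert_frame_equal(key(a.table), key(b.table))

    def test_no_shared_samples_rejected(self, rng, small_traits):
        prof = self._profiles(rng.standard_normal((2, 10)),
                              [f"X{j}" for j in range(10)])
        with pytest.raises(ValueError, match="share no samples"):
            associate_modules(prof, small_traits)

    def test_zero_variance_trait_rejected(self, rng):
        samples = [f"S{j}" for j in range(20)]
        prof = self._profiles(rng.standard_normal((2, 20)), samples)
        traits = TraitTable(values=pd.DataFrame(
            {"flat": np.ones(20), "ok": rng.standard_normal(20)}, index=samples))
        with pytest.raises(ValueError, match="zero variance"):
            associate_modules(prof, traits)


class TestConditional:
    def _driven_cohort(self):
        # module driven by trait A; trait B correlated with A but not the module
        rng = np.random.default_rng(42)
        n = 300
        samples = [f"S{j}" for j in range(n)]
        a = rng.standard_normal(n)
        b = 0.8 * a + 0.6 * rng.standard_normal(n)
        profile = 0.9 * a + 0.5 * rng.standard_normal(n)
        prof = pd.DataFrame([profile], index=["M0"], columns=samples)
        traits = TraitTable(values=pd.DataFrame({"A": a, "B": b}, index=samples))
        return prof, traits

    def test_confounded_vs_robust_verdicts(self):
        prof, traits = self._driven_cohort()
        assoc = associate_modules(prof, traits, alpha=0.05)
        assert set(assoc.significant_pairs()["trait"]) == {"A", "B"}
        cond = conditional_reassessment(assoc, traits, {"given_A": ["A"], "given_B": ["B"]})
        t = cond.table
        fwd = t[t["direction"] == "forward"].set_index(["trait", "confounder_set"])
        assert fwd.loc[("B", "given_A"), "verdict"] == "confounded"
        assert fwd.loc[("A", "given_B"), "verdict"] == "robust"

    def test_reverse_direction_reported(self):
        prof, traits = self._driven_cohort()
        assoc = associate_modules(prof, traits, alpha=0.05)
        cond = conditional_reassessment(assoc, traits, {"given_B": ["B"]})
        rev = cond.table[cond.table["direction"] == "reverse"]
        assert not rev.empty
        # adjusting B for the driver A leaves no association
        row = rev[(rev["trait"] == "B") & (rev["confounders"] == "A")]
        assert (row["verdict"] == "confounded").all()

    def test_adjusting_pair_solely_for_itself_rejected(self):
        rng = np.random.default_rng(9)
        n = 200
        samples = [f"S{j}" for j in range(n)]
        a = rng.standard_normal(n)
        prof = pd.DataFrame([0.9 * a + 0.3 * rng.standard_normal(n)],
                            index=["M0"], columns=samples)
        traits = TraitTable(values=pd.DataFrame(
            {"A": a, "B": rng.standard_normal(n)}, index=samples))
        assoc = associate_modules(prof, traits, alpha=0.05)
        assert list(assoc.significant_pairs()["trait"]) == ["A"]
        with pytest.raises(ValueError, match="adjusted"):
            conditional_reassessment(assoc, traits, {"A_only": ["A"]})


class TestGeneFlags:
    def _module_and_matrix(self, rng, n=70):
        X = rng.standard_normal((6, n))
        trait = X[0] + 0.001 * rng.standard_normal(n)  # probe 0 ~ trait
        m = make_matrix(X, normalized=True)
        from adipomod.module_builder import Module

        mod = Module("M0", [f"P{i}" for i in range(6)], profile=X.mean(0))
        return mod, m, trait

    def test_trait_equal_probe_flagged(self, rng):
        mod, m, trait = self._module_and_matrix(rng)
        flags = flag_trait_correlated_genes(mod, m, trait)
        assert flags["P0"]

    def test_independent_probe_unflagged(self, rng):
        mod, m, trait = self._module_and_matrix(rng)
        flags = flag_trait_correlated_genes(mod, m, rng.standard_normal(70))
        assert not flags.all()

    def test_pcut_one_flags_everything(self, rng):
        mod, m, trait = self._module_and_matrix(rng)
        flags = flag_trait_correlated_genes(mod, m, trait, p_cut=1.0)
        assert flags.all()

    def test_gene_collapse_any_probe_rule(self, rng):
        from adipomod import ProbeAnnotation

        mod, m, trait = self._module_and_matrix(rng)
        ann = ProbeAnnotation(mapping={"P0": "G1", "P1": "G1", "P2": "G2"})
        flags = flag_trait_correlated_genes(mod, m, trait, ann=ann)
        assert flags["G1"]  # P0 flagged -> G1 flagged
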