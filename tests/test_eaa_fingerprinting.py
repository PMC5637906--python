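"""EAA delta-13C fingerprinting: centering, PCA, groups, Bayesian mixing."""

import numpy as np
import pytest

from paleodiet.data_model import IsotopeValue, ValidationError
from paleodiet.eaa_fingerprinting import (
    EAA_SET,
    EAAPattern,
    MCMCConfig,
    SourceGroup,
    aggregate_marine,
    build_source_groups,
    center_pattern,
    fit_mixture,
    pca_scores,
)


def raw_pattern(sid, leu, lys, phe, val, sd=0.0):
    return EAAPattern(
        sid,
        {
            "Leu": IsotopeValue(leu, sd),
            "Lys": IsotopeValue(lys, sd),
            "Phe": IsotopeValue(phe, sd),
            "Val": IsotopeValue(val, sd),
        },
    )


def centered_pattern(sid, vec, sd=0.4):
    values = {aa: IsotopeValue(float(v), sd) for aa, v in zip(EAA_SET, vec)}
    return EAAPattern(sid, values, centered=True, center_set=EAA_SET)


def source(name, vec, sd=0.3):
    return SourceGroup(
        name, ("a", "b"),
        dict(zip(EAA_SET, vec)), {aa: sd for aa in EAA_SET}, EAA_SET,
    )


SOURCE_A = source("A", [3.0, 1.0, -2.0, -2.0])
SOURCE_B = source("B", [-3.0, -1.0, 2.0, 2.0])


class TestCentering:
    def test_arithmetic_example(self):
        out = center_pattern(raw_pattern("s", -20.0, -22.0, -24.0, -26.0))
        assert [out.values[aa].mean for aa in EAA_SET] == [3.0, 1.0, -1.0, -3.0]
        assert out.centered

    def test_uniform_pattern_centers_to_zero(self):
        out = center_pattern(raw_pattern("s", -22.0, -22.0, -22.0, -22.0))
        assert all(v.mean == 0.0 for v in out.values.values())

    def test_idempotent(self):
        once = center_pattern(raw_pattern("s", -20.0, -22.0, -24.0, -26.0))
        twice = center_pattern(once)
        assert all(
            twice.values[aa].mean == pytest.approx(once.values[aa].mean)
            for aa in EAA_SET
        )

    def test_missing_eaa_error_names_it(self):
        p = EAAPattern("s", {"Leu": IsotopeValue(-20.0), "Lys": IsotopeValue(-22.0)})
        with pytest.raises(ValidationError, match="Phe"):
            center_pattern(p)

    def test_centered_sum_invariant_enforced(self):
        with pytest.raises(ValidationError, match="sum to zero"):
            EAAPattern(
                "s", {"Leu": IsotopeValue(1.0), "Lys": IsotopeValue(1.0)},
                centered=True, center_set=("Leu", "Lys"),
            )


class TestPCA:
    def _recentered(self, n=5, noise=0.3, seed=0):
        rng = np.random.default_rng(seed)
        out = []
        for label, base in (("a", [3.0, 1.0, -2.0, -2.0]), ("b", [-3.0, -1.0, 2.0, 2.0])):
            for i in range(n):
                vec = np.asarray(base) + rng.normal(0, noise, 4)
                vec = vec - vec.mean()
                out.append(centered_pattern(f"{label}{i}", vec))
        return out

    def test_two_separated_clusters_split_on_pc1(self):
        with pytest.warns(UserWarning, match="rank-deficient"):
            res = pca_scores(self._recentered())
        pc1 = res.scores["PC1"]
        a = pc1[[i for i in pc1.index if i.startswith("a")]]
        b = pc1[[i for i in pc1.index if i.startswith("b")]]
        assert a.max() < b.min() or b.max() < a.min()

    def test_duplicated_dataset_gives_identical_scores(self):
        import warnings

        patterns = self._recentered()
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            r1 = pca_scores(patterns)
            r2 = pca_scores(patterns)
        assert (r1.scores == r2.scores).all().all()

    def test_explained_variance_sums_to_total_variance(self):
        import warnings

        patterns = self._recentered()
        x = np.array([[p.values[aa].mean for aa in EAA_SET] for p in patterns])
        total = x.var(axis=0, ddof=1).sum()
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = pca_scores(patterns)
        assert res.explained_variance.sum() == pytest.approx(total)

    def test_fewer_than_three_patterns_rejected(self):
        with pytest.raises(ValidationError):
            pca_scores(self._recentered(n=1))


class TestSourceGroups:
    def test_identical_members_have_zero_sd(self):
        patterns = [centered_pattern(f"s{i}", [1.0, 1.0, -1.0, -1.0]) for i in range(3)]
        groups = build_source_groups(patterns, {f"s{i}": "G" for i in range(3)})
        assert all(sd == 0.0 for sd in groups[0].sds.values())

    def test_member_order_invariance(self):
        rng = np.random.default_rng(3)
        patterns = []
        for i in range(6):
            vec = rng.normal(0, 1, 4)
            patterns.append(centered_pattern(f"s{i}", vec - vec.mean()))
        assignment = {f"s{i}": ("X" if i < 3 else "Y") for i in range(6)}
        g1 = build_source_groups(patterns, assignment)
        g2 = build_source_groups(list(reversed(patterns)), assignment)
        assert g1 == g2

    def test_unknown_id_in_assignment_rejected(self):
        patterns = [centered_pattern("s0", [1.0, 1.0, -1.0, -1.0])]
        with pytest.raises(ValidationError, match="unknown"):
            build_source_groups(patterns, {"s0": "G", "ghost": "G"})

    def test_four_cluster_fixture_recovers_generating_means(self):
        from paleodiet.synthetic_data import FoodWebSpec, simulate_eaa

        spec = FoodWebSpec(seed=11, n_per_group=30)
        training, _, truth = simulate_eaa(spec)
        assignment = {
            r.sample_id: r.group_true
            for r in truth[truth["role"] == "training"].itertuples()
        }
        groups = build_source_groups(training, assignment)
        for g in groups:
            gen = spec.eaa_group_means[g.name]
            gen_centered = {
                aa: gen[aa] - np.mean(list(gen.values())) for aa in EAA_SET
            }
            for aa in EAA_SET:
                tol = 2 * spec.eaa_sd / np.sqrt(30) + 0.05
                assert g.means[aa] == pytest.approx(gen_centered[aa], abs=3 * tol)


class TestFitMixture:
    def test_consumer_on_source_mean_identified(self):
        consumer = centered_pattern("c", [3.0, 1.0, -2.0, -2.0])
        post = fit_mixture(consumer, [SOURCE_A, SOURCE_B], mcmc=MCMCConfig(seed=1))
        assert post.summary.loc["A", "mean"] > 0.9

    def test_identical_sources_sum_recovered_marginals_symmetric(self):
        twin = source("A2", [3.0, 1.0, -2.0, -2.0])
        consumer = centered_pattern("c", [3.0, 1.0, -2.0, -2.0])
        post = fit_mixture(consumer, [SOURCE_A, twin, SOURCE_B], mcmc=MCMCConfig(seed=2))
        total = post.summary.loc["A", "mean"] + post.summary.loc["A2", "mean"]
        assert total > 0.85
        assert abs(post.summary.loc["A", "mean"] - post.summary.loc["A2", "mean"]) < 0.15

    def test_flat_likelihood_recovers_uniform_prior(self):
        consumer = centered_pattern("c", [0.5, 0.5, -0.5, -0.5])
        post = fit_mixture(
            consumer, [SOURCE_A, SOURCE_B],
            mcmc=MCMCConfig(seed=3, model_error_sd=1e4),
        )
        for name in ("A", "B"):
            assert post.summary.loc[name, "mean"] == pytest.approx(0.5, abs=0.05)

    def test_every_draw_is_a_probability_vector(self):
        consumer = centered_pattern("c", [1.0, 0.0, -0.5, -0.5])
        post = fit_mixture(consumer, [SOURCE_A, SOURCE_B], mcmc=MCMCConfig(seed=4))
        assert np.all(post.draws >= 0)
        assert np.allclose(post.draws.sum(axis=1), 1.0, atol=1e-9)
        assert ((post.summary["mean"] >= 0) & (post.summary["mean"] <= 1)).all()

    def test_fixed_seed_reproducible_bit_for_bit(self):
        consumer = centered_pattern("c", [1.0, 0.0, -0.5, -0.5])
        p1 = fit_mixture(consumer, [SOURCE_A, SOURCE_B], mcmc=MCMCConfig(seed=5))
        p2 = fit_mixture(consumer, [SOURCE_A, SOURCE_B], mcmc=MCMCConfig(seed=5))
        assert (p1.summary == p2.summary).all().all()
        assert np.array_equal(p1.draws, p2.draws)

    def test_centering_set_mismatch_is_hard_error(self):
        values = {aa: IsotopeValue(0.0, 0.4) for aa in ("Leu", "Phe", "Val")}
        consumer = EAAPattern("c", values, centered=True, center_set=("Leu", "Phe", "Val"))
        with pytest.raises(ValidationError, match="centered over"):
            fit_mixture(consumer, [SOURCE_A, SOURCE_B])

    def test_single_source_rejected(self):
        consumer = centered_pattern("c", [1.0, 0.0, -0.5, -0.5])
        with pytest.raises(ValidationError):
            fit_mixture(consumer, [SOURCE_A])


class TestAggregateMarine:
    def _post(self):
        consumer = centered_pattern("c", [1.0, 0.0, -0.5, -0.5])
        return fit_mixture(consumer, [SOURCE_A, SOURCE_B], mcmc=MCMCConfig(seed=6))

    def test_all_sources_marine_gives_unity_every_draw(self):
        post = self._post()
        out = aggregate_marine(post, ["A", "B"])
        assert out["mean"] == pytest.approx(1.0, abs=1e-12)
        assert out["sd"] == pytest.approx(0.0, abs=1e-12)

    def test_aggregate_mean_is_sum_of_member_means(self):
        post = self._post()
        out = aggregate_marine(post, ["A"])
        assert out["mean"] == pytest.approx(float(post.summary.loc["A", "mean"]))

    def test_empty_label_set_rejected(self):
        with pytest.raises(ValidationError):
            aggregate_marine(self._post(), [])

    def test_unknown_label_rejected(self):
        with pytest.raises(ValidationError):
            aggregate_marine(self._post(), ["Z"])
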