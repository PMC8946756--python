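"""Spatial ICA: source recovery, templates, similarity, vetting, selection."""

import numpy as np
import pytest

from lowernet.ica import (
    ComponentSet,
    build_group_templates,
    low_frequency_fraction,
    pick_network_component,
    run_subject_ica,
    template_similarity,
    vet_component,
)


def mixture_volume(shape, t, sources, time_courses, noise_sd, rng):
    """4D volume = sum_k map_k x tc_k + noise."""
    data = rng.standard_normal((*shape, t)) * noise_sd
    for smap, tc in zip(sources, time_courses):
        data += smap[..., None] * tc
    return data


def blob(shape, center, radius):
    x, y, z = np.ogrid[: shape[0], : shape[1], : shape[2]]
    d2 = (x - center[0]) ** 2 + (y - center[1]) ** 2 + (z - center[2]) ** 2
    return (d2 <= radius**2).astype(float)


class TestRunSubjectIca:
    shape = (12, 12, 10)

    def planted_mixture(self, rng, t=80):
        s1 = blob(self.shape, (3, 3, 5), 2)
        s2 = blob(self.shape, (8, 8, 5), 2)
        s3 = blob(self.shape, (3, 8, 5), 2)
        tcs = rng.standard_normal((3, t)) * 3.0
        return [s1, s2, s3], mixture_volume(self.shape, t, [s1, s2, s3], tcs, 0.1, rng)

    def test_recovers_planted_orthogonal_sources(self):
        rng = np.random.default_rng(0)
        sources, data = self.planted_mixture(rng)
        mask = np.ones(self.shape, dtype=bool)
        cs = run_subject_ica(data, mask, n_components=5, rng_seed=1)
        for src in sources:
            sims = [
                abs(np.corrcoef(cs.spatial_maps[k][mask], src[mask])[0, 1])
                for k in range(5)
            ]
            assert max(sims) > 0.95

    def test_deterministic_given_seed(self):
        rng = np.random.default_rng(2)
        _, data = self.planted_mixture(rng)
        mask = np.ones(self.shape, dtype=bool)
        a = run_subject_ica(data, mask, 5, rng_seed=3)
        b = run_subject_ica(data, mask, 5, rng_seed=3)
        assert np.array_equal(a.spatial_maps, b.spatial_maps)
        assert np.array_equal(a.time_courses, b.time_courses)

    def test_maps_are_z_scored_with_positive_skewness(self):
        rng = np.random.default_rng(4)
        _, data = self.planted_mixture(rng)
        mask = np.ones(self.shape, dtype=bool)
        cs = run_subject_ica(data, mask, 5, rng_seed=5)
        from scipy import stats

        for k in range(5):
            vals = cs.spatial_maps[k][mask]
            assert abs(vals.mean()) < 1e-8
            assert vals.std() == pytest.approx(1.0, abs=1e-8)
            assert stats.skew(vals) >= 0

    def test_too_few_volumes_rejected(self):
        data = np.zeros((4, 4, 4, 30))
        with pytest.raises(ValueError, match="more volumes"):
            run_subject_ica(data, np.ones((4, 4, 4), dtype=bool), 30, 0)


class TestBuildGroupTemplates:
    def test_strong_network_controls_yield_covering_templates(self, model, node_templates):
        from lowernet.synthcohort import CohortSpec, generate_cohort
        from lowernet.preproc import preprocess_run

        spec = CohortSpec(
            n_vs=0, n_mcs=0, n_sd=0, n_controls=3,
            n_artifact_sources=0, spike_prob=0.0, rng_seed=21,
        )
        _, runs, _ = generate_cohort(spec, model)
        pre = [preprocess_run(r)[0].data for r in runs]
        templates = build_group_templates(
            pre, runs[0].brain_mask, node_templates, n_components=30, rng_seed=5
        )
        for net, node_mask in node_templates.items():
            cover = (templates[net] & node_mask).sum() / node_mask.sum()
            assert cover > 0.5, f"{net} covered {cover:.2f}"

    def test_fewer_than_two_controls_rejected(self, node_templates):
        with pytest.raises(ValueError, match="at least 2"):
            build_group_templates([np.zeros((4, 4, 4, 40))], np.ones((4, 4, 4), bool), node_templates)

    def test_unreachable_threshold_errors_naming_network(self, model, node_templates):
        from lowernet.synthcohort import CohortSpec, generate_cohort
        from lowernet.preproc import preprocess_run

        spec = CohortSpec(
            n_vs=0, n_mcs=0, n_sd=0, n_controls=2,
            n_artifact_sources=0, spike_prob=0.0, rng_seed=22,
        )
        _, runs, _ = generate_cohort(spec, model)
        pre = [preprocess_run(r)[0].data for r in runs]
        with pytest.raises(ValueError, match="empty"):
            build_group_templates(
                pre, runs[0].brain_mask, node_templates, n_components=30,
                z_thresh=np.inf, rng_seed=5,
            )


class TestTemplateSimilarity:
    def test_component_equal_to_template_gives_one(self):
        t = np.zeros((4, 4, 4), dtype=bool)
        t[1:3, 1:3, 1:3] = True
        mask = np.ones((4, 4, 4), dtype=bool)
        assert template_similarity(t.astype(float), t, mask) == pytest.approx(1.0)

    def test_constant_map_gives_zero_with_warning(self, caplog):
        mask = np.ones((3, 3, 3), dtype=bool)
        t = np.zeros((3, 3, 3), dtype=bool)
        t[0, 0, 0] = True
        assert template_similarity(np.ones((3, 3, 3)), t, mask) == 0.0

    def test_matches_hand_pearson_on_eight_voxels(self):
        comp = np.array([1.0, 2.0, 0.0, -1.0, 3.0, 0.5, -0.5, 1.5]).reshape(2, 2, 2)
        tmpl = np.array([1, 1, 0, 0, 1, 0, 0, 1], dtype=bool).reshape(2, 2, 2)
        mask = np.ones((2, 2, 2), dtype=bool)
        expected = np.corrcoef(comp.ravel(), tmpl.ravel().astype(float))[0, 1]
        assert template_similarity(comp, tmpl, mask) == pytest.approx(expected, abs=1e-12)

    def test_invariant_to_positive_rescaling(self):
        rng = np.random.default_rng(0)
        comp = rng.standard_normal((5, 5, 5))
        t = comp > 1.0
        mask = np.ones((5, 5, 5), dtype=bool)
        s1 = template_similarity(comp, t, mask)
        s2 = template_similarity(5.0 * comp, t, mask)
        assert s1 == pytest.approx(s2, abs=1e-12)


class TestVetComponent:
    shape = (10, 10, 8)
    tr = 2.8

    def network_like_component(self, rng, t=100):
        template = blob(self.shape, (5, 5, 4), 2.5) > 0
        comp = np.where(template, 4.0, 0.0) + 0.1 * rng.standard_normal(self.shape)
        time = np.arange(t) * self.tr
        tc = np.sin(2 * np.pi * 0.03 * time)
        return comp, tc, template

    def test_template_signal_with_slow_time_course_accepted(self):
        rng = np.random.default_rng(0)
        comp, tc, template = self.network_like_component(rng)
        mask = np.ones(self.shape, dtype=bool)
        vet = vet_component(comp, tc, template, mask, self.tr)
        assert vet.decision == "accept"
        assert vet.specificity_ratio >= 1.0
        assert vet.low_freq_fraction >= 0.5
        assert vet.smoothness >= 0.3

    def test_white_noise_time_course_rejected_via_smoothness(self):
        rng = np.random.default_rng(1)
        comp, _, template = self.network_like_component(rng)
        mask = np.ones(self.shape, dtype=bool)
        tc = rng.standard_normal(200)
        vet = vet_component(comp, tc, template, mask, self.tr)
        # white noise: low-frequency fraction near the band fraction, no smoothness
        band_fraction = 0.1 / (1 / (2 * self.tr))
        assert abs(vet.low_freq_fraction - band_fraction) < 0.15
        assert vet.smoothness < 0.3
        assert vet.decision == "reject"

    def test_map_outside_template_rejected_with_zero_ratio(self):
        rng = np.random.default_rng(2)
        template = blob(self.shape, (2, 2, 2), 1.5) > 0
        comp = np.where(blob(self.shape, (7, 7, 5), 2) > 0, 4.0, 0.0)
        tc = np.sin(2 * np.pi * 0.03 * np.arange(100) * self.tr)
        vet = vet_component(comp, tc, template, np.ones(self.shape, bool), self.tr)
        assert vet.specificity_ratio == 0.0
        assert vet.decision == "reject"

    def test_vetting_is_a_pure_function(self):
        rng = np.random.default_rng(3)
        comp, tc, template = self.network_like_component(rng)
        mask = np.ones(self.shape, dtype=bool)
        v1 = vet_component(comp, tc, template, mask, self.tr)
        v2 = vet_component(comp, tc, template, mask, self.tr)
        assert v1 == v2


class TestPickNetworkComponent:
    shape = (10, 10, 8)

    def component_set(self, maps, tcs):
        k = len(maps)
        return ComponentSet(
            spatial_maps=np.array(maps),
            time_courses=np.array(tcs),
            brain_mask=np.ones(self.shape, dtype=bool),
            n_components=k,
        )

    def slow_tc(self, t=100):
        return np.sin(2 * np.pi * 0.03 * np.arange(t) * 2.8)

    def test_planted_component_found_among_noise(self):
        rng = np.random.default_rng(0)
        template = blob(self.shape, (5, 5, 4), 2.5) > 0
        good = np.where(template, 4.0, 0.0)
        noise_maps = [rng.standard_normal(self.shape) for _ in range(4)]
        maps = noise_maps[:2] + [good] + noise_maps[2:]
        tcs = [rng.standard_normal(100) for _ in range(2)] + [self.slow_tc()] + [
            rng.standard_normal(100) for _ in range(2)
        ]
        pick = pick_network_component(self.component_set(maps, tcs), template, 2.8)
        assert pick is not None
        assert pick[0] == 2

    def test_override_forces_rejection_and_acceptance(self):
        rng = np.random.default_rng(5)
        template = blob(self.shape, (5, 5, 4), 2.5) > 0
        good = np.where(template, 4.0, 0.0)
        noise = rng.standard_normal(self.shape)
        maps = [good, noise]
        tcs = [self.slow_tc(), rng.standard_normal(100)]
        cs = self.component_set(maps, tcs)
        # force-reject the true component: nothing else passes
        assert pick_network_component(cs, template, 2.8, overrides={0: "reject"}) is None
        # force-accept the noise component: ranked second, returned after 0 is rejected
        pick = pick_network_component(
            cs, template, 2.8, overrides={0: "reject", 1: "accept"}
        )
        assert pick[0] == 1

    def test_all_noise_returns_none(self):
        rng = np.random.default_rng(1)
        template = blob(self.shape, (5, 5, 4), 2.5) > 0
        maps = [rng.standard_normal(self.shape) for _ in range(5)]
        tcs = [rng.standard_normal(100) for _ in range(5)]
        assert pick_network_component(self.component_set(maps, tcs), template, 2.8) is None

    def test_two_passing_components_resolved_by_similarity_then_index(self):
        template = blob(self.shape, (5, 5, 4), 2.5) > 0
        strong = np.where(template, 4.0, 0.0)
        weaker = np.where(template, 4.0, 0.0)
        weaker[0, 0, 0] = 4.0  # slightly less similar to the template
        maps = [weaker, strong]
        tcs = [self.slow_tc(), self.slow_tc()]
        pick = pick_network_component(self.component_set(maps, tcs), template, 2.8)
        assert pick[0] == 1
        # exact tie -> lower component index
        pick_tie = pick_network_component(
            self.component_set([strong, strong.copy()], tcs), template, 2.8
        )
        assert pick_tie[0] == 0


class TestLowFrequencyFraction:
    def test_pure_slow_oscillation_is_all_low_frequency(self):
        tc = np.sin(2 * np.pi * 0.03 * np.arange(200) * 2.8)
        assert low_frequency_fraction(tc, 2.8) > 0.99

    def test_fast_oscillation_has_no_low_frequency_power(self):
        tc = np.sin(2 * np.pi * 0.15 * np.arange(200) * 2.8)
        assert low_frequency_fraction(tc, 2.8) < 0.05
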