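import numpy as np
import pytest

from grnmaps.ensemble import EnsembleConfig, build_ensemble
from grnmaps.maps import (
    Element,
    FrozenContext,
    build_map,
    build_maps_for_genome,
    choose_element,
    choose_linked_elements,
    default_grid,
    draw_collapsed_value,
    legal_elements,
    sample_gpd,
)

from .conftest import make_genome


class TestGrid:
    def test_default_grid_is_11_points(self):
        grid = default_grid()
        assert len(grid) == 11
        assert grid[0] == 0.0 and grid[-1] == 1.0
        assert np.allclose(np.diff(grid), 0.1)

    def test_ten_point_variant(self):
        assert len(default_grid(10)) == 10


class TestLegalElements:
    def test_gp_only_active_entries(self):
        mask = np.zeros((3, 3))
        mask[1, 2] = 1
        g = make_genome(3, mask=mask)
        els = legal_elements(g, "GP")
        assert els == [Element("B", 1, 2)]

    def test_ep_includes_diffusion_for_lattice(self):
        g = make_genome(4, model_kind="lattice", d=[0.5, 0.5, 0.0, 0.0])
        els = legal_elements(g, "EP")
        kinds = {(e.kind, e.i) for e in els}
        assert ("E", 0) in kinds and ("D", 0) in kinds and ("D", 1) in kinds
        assert ("D", 2) not in kinds

    def test_pp_every_gene(self):
        g = make_genome(5)
        assert len(legal_elements(g, "PP")) == 5


class TestChooseElement:
    def test_singleton_chosen_with_probability_one(self, rng):
        mask = np.zeros((3, 3))
        mask[0, 1] = 1
        g = make_genome(3, mask=mask)
        for _ in range(10):
            assert choose_element(g, "GP", rng) == Element("B", 0, 1)

    def test_uniform_over_legal_set(self, rng):
        mask = np.zeros((2, 2))
        mask[:, :] = 1  # 4 legal GP elements
        g = make_genome(2, mask=mask)
        counts = {}
        n = 4000
        for _ in range(n):
            el = choose_element(g, "GP", rng)
            counts[el] = counts.get(el, 0) + 1
        for c in counts.values():
            assert abs(c - n / 4) < 4 * np.sqrt(n * 0.25 * 0.75)

    def test_empty_legal_set_reported(self, rng):
        g = make_genome(3)  # empty topology
        with pytest.raises(ValueError):
            choose_element(g, "GP", rng)

    def test_linked_elements_share_focal_gene(self, rng):
        g = make_genome(4, mask=np.ones((4, 4)), strengths=np.ones((4, 4)))
        els = choose_linked_elements(g, rng)
        assert els["GP"].i == els["EP"].i == els["PP"].i
        assert els["GP"].kind == "B" and els["EP"].kind == "E" and els["PP"].kind == "G0"


class TestBuildMap:
    def test_insensitive_genome_constant_map(self, fast_params):
        # gene 2 disconnected from both trait genes: perturbing its initial
        # value leaves the phenotype unchanged
        g = make_genome(3, mask=np.diag([1, 1, 0]), strengths=np.diag([2.0, 2.0, 0.0]))
        pmap = build_map(g, "PP", Element("G0", 2), params=fast_params)
        pts = pmap.viable_points()
        assert len(pts) == 11
        assert np.allclose(pts, pts[0], atol=1e-9)

    def test_determinism_noise_off(self, fast_params, small_ensemble, rng):
        genome, env = small_ensemble[1]
        el = choose_element(genome, "EP", rng)
        m1 = build_map(genome, "EP", el, frozen=FrozenContext(env=env), params=fast_params)
        m2 = build_map(genome, "EP", el, frozen=FrozenContext(env=env), params=fast_params)
        assert np.array_equal(m1.phenotypes, m2.phenotypes, equal_nan=True)

    def test_inactive_b_rejected_for_gp(self, fast_params):
        g = make_genome(3)
        with pytest.raises(ValueError):
            build_map(g, "GP", Element("B", 0, 0), params=fast_params)

    def test_overwrite_semantics(self, long_params):
        # perturbation overwrites: grid value 0 must zero the weight, giving
        # the no-input steady state regardless of the original B value
        g = make_genome(2, mask=[[1, 0], [0, 0]], strengths=[[2.0, 0.0], [0.0, 0.0]], g0=[0.5, 0.0])
        pmap = build_map(
            g, "GP", Element("B", 0, 0), grid=np.array([0.0, 0.0]), params=long_params, strict=True
        )
        assert np.allclose(pmap.phenotypes[:, 0], 0.0, atol=1e-4)

    def test_genome_not_mutated(self, fast_params, small_ensemble, rng):
        genome, env = small_ensemble[2]
        before = genome.interaction_strengths.copy()
        g0_before = genome.initial_state.copy()
        el = choose_element(genome, "GP", rng)
        build_map(genome, "GP", el, frozen=FrozenContext(env=env), params=fast_params)
        assert np.array_equal(genome.interaction_strengths, before)
        assert np.array_equal(genome.initial_state, g0_before)

    def test_monotone_single_gene_response(self, fast_params):
        # one self-regulating gene read out through positive coefficients:
        # increasing B increases the steady state monotonically
        g = make_genome(
            2,
            mask=[[1, 0], [0, 0]],
            strengths=[[0.0, 0.0], [0.0, 0.0]],
            g0=[0.5, 0.0],
            model_kind="multilinear",
            z=[[0.9, 0.0], [0.5, 0.0]],
        )
        pmap = build_map(g, "GP", Element("B", 0, 0), params=fast_params)
        t1 = pmap.phenotypes[pmap.viable_flags, 0]
        assert np.all(np.diff(t1) >= -1e-9)


class TestSampleGPD:
    def test_empty_sample(self, fast_params, rng):
        g = make_genome(3, mask=np.ones((3, 3)), strengths=np.ones((3, 3)))
        cloud = sample_gpd(g, 0, fast_params, rng)
        assert cloud.shape == (0, 2)

    def test_disconnected_genome_single_point(self, fast_params, rng):
        g = make_genome(3)  # M = 0, E base 0: nothing moves except G0 decay
        cloud = sample_gpd(g, 20, fast_params, rng, perturb_probability=0.0)
        assert len(cloud) == 20
        assert np.allclose(cloud, cloud[0], atol=1e-9)

    def test_map_contained_in_gpd_box(self, fast_params, small_ensemble, rng):
        # first fixture genome with a non-empty topology
        genome, env, maps = None, None, None
        for genome, env in small_ensemble:
            maps = build_maps_for_genome(genome, env, fast_params, rng)
            if maps is not None:
                break
        assert maps is not None
        frozen = FrozenContext(env=env)
        cloud = sample_gpd(genome, 400, fast_params, rng, frozen=frozen)
        lo = cloud.min(axis=0) - 1e-6
        hi = cloud.max(axis=0) + 1e-6
        for pmap in maps.values():
            pts = pmap.viable_points()
            assert np.all(pts >= lo - 0.5) and np.all(pts <= hi + 0.5)


class TestFrozenContext:
    def test_collapsed_value_never_zero(self, rng):
        xs = [draw_collapsed_value(rng) for _ in range(1000)]
        assert all(0 < x <= 1 for x in xs)

    def test_different_collapse_changes_phenotypes(self, fast_params, small_ensemble, rng):
        genome, env = small_ensemble[4]
        try:
            el_gp = choose_element(genome, "GP", rng)
        except ValueError:
            pytest.skip("empty topology fixture")
        el_pp = Element("G0", 0)
        m1 = build_map(
            genome, "PP", el_pp, frozen=FrozenContext(env=env, overrides={el_gp: 0.1}), params=fast_params
        )
        m2 = build_map(
            genome, "PP", el_pp, frozen=FrozenContext(env=env, overrides={el_gp: 0.9}), params=fast_params
        )
        # freezing a different collapsed value must not touch the genome
        assert not np.array_equal(m1.phenotypes, m2.phenotypes, equal_nan=True) or np.isnan(
            m1.phenotypes
        ).all()
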