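"""Generator contracts: hard core, determinism, render geometry, viability counts."""

import numpy as np
import pytest
from scipy.spatial.distance import pdist
from scipy import ndimage, stats

import nanopillar as npl
from nanopillar.synth import (
    InfeasiblePackingError,
    PatternSpec,
    RenderSpec,
    ViabilitySpec,
    generate_height_map,
    generate_pattern,
    generate_viability,
    render_micrograph,
)


class TestGeneratePattern:
    @pytest.mark.parametrize("seed", [0, 1, 2])
    @pytest.mark.parametrize("spacing", [None, 306.0])
    def test_hard_core_brute_force(self, seed, spacing):
        spec = PatternSpec(
            density=11, exclusion_radius=150, spacing=spacing, jitter_sd=10,
            field_width=4000, field_height=4000, seed=seed,
        )
        tips = generate_pattern(spec)
        assert pdist(tips.xy).min() >= 150.0

    def test_expected_count_and_bounds(self):
        spec = PatternSpec(density=11, exclusion_radius=150, spacing=None,
                           field_width=5000, field_height=5000, seed=3)
        tips = generate_pattern(spec)
        assert tips.n == 275  # round(11 * 25)
        assert tips.xy[:, 0].min() >= 0 and tips.xy[:, 0].max() <= 5000
        assert tips.xy[:, 1].min() >= 0 and tips.xy[:, 1].max() <= 5000
        assert pdist(tips.xy).min() >= 150.0

    def test_determinism(self):
        spec = PatternSpec(density=9, seed=42, field_width=3000, field_height=3000)
        a = generate_pattern(spec)
        b = generate_pattern(spec)
        np.testing.assert_array_equal(a.xy, b.xy)

    def test_infeasible_packing_names_limit(self):
        spec = PatternSpec(density=40, exclusion_radius=150, spacing=None,
                           field_width=3000, field_height=3000)
        with pytest.raises(InfeasiblePackingError, match="tips/um\\^2"):
            generate_pattern(spec)

    def test_csr_nearest_neighbour_law(self):
        # With no exclusion and no ordering the pattern is homogeneous Poisson:
        # interior NN distances follow P(D > r) = exp(-rho * pi * r^2).
        spec = PatternSpec(density=50, exclusion_radius=0, spacing=None, jitter_sd=0,
                           field_width=6000, field_height=6000, seed=7)
        tips = generate_pattern(spec)
        from scipy.spatial import cKDTree

        tree = cKDTree(tips.xy)
        margin = 300.0
        interior = np.all(
            (tips.xy >= margin) & (tips.xy <= 6000 - margin), axis=1
        )
        d = tree.query(tips.xy[interior], k=2)[0][:, 1]
        rho = 50e-6  # per nm^2
        cdf = lambda r: 1.0 - np.exp(-rho * np.pi * r**2)
        assert stats.kstest(d, cdf).pvalue > 0.01

    def test_bundling_merges_close_pairs(self):
        spec = PatternSpec(density=10, exclusion_radius=150, spacing=None,
                           jitter_sd=0, bundle_prob=1.0,
                           field_width=4000, field_height=4000, seed=5)
        merged = generate_pattern(spec)
        unmerged = generate_pattern(
            PatternSpec(density=10, exclusion_radius=150, spacing=None, jitter_sd=0,
                        bundle_prob=0.0, field_width=4000, field_height=4000, seed=5)
        )
        assert merged.n < unmerged.n
        assert pdist(merged.xy).min() >= 150.0

    def test_invalid_specs_rejected(self):
        with pytest.raises(ValueError):
            PatternSpec(density=-1)
        with pytest.raises(ValueError):
            PatternSpec(bundle_prob=1.5)
        with pytest.raises(ValueError):
            PatternSpec(field_width=0)


class TestRenderMicrograph:
    def test_single_tip_argmax_at_centre(self):
        tips = npl.TipSet(np.array([[500.0, 500.0]]), (0, 0, 1000, 1000))
        img = render_micrograph(tips, RenderSpec(noise_sd=0.0))
        i, j = np.unravel_index(np.argmax(img.data), img.data.shape)
        # tip at 500 nm maps to pixel coordinate 49.5
        assert abs(i - 49.5) <= 0.5 and abs(j - 49.5) <= 0.5

    def test_zero_tips_background(self):
        tips = npl.TipSet(np.empty((0, 2)), (0, 0, 1000, 1000))
        quiet = render_micrograph(tips, RenderSpec(noise_sd=0.0))
        assert np.all(quiet.data == 40.0)
        noisy = render_micrograph(tips, RenderSpec(noise_sd=5.0, seed=1))
        assert abs(noisy.data.mean() - 40.0) <= 3 * 5.0 / np.sqrt(noisy.data.size)

    def test_n_tips_n_local_maxima(self):
        spec = PatternSpec(density=8, spacing=306, jitter_sd=0,
                           field_width=4000, field_height=4000, seed=9)
        tips = generate_pattern(spec)
        img = render_micrograph(tips, RenderSpec(noise_sd=0.0))
        is_max = (img.data == ndimage.maximum_filter(img.data, size=5)) & (
            img.data > 40.0 + 1.0
        )
        n_max = ndimage.label(is_max)[1]  # plateau-safe count
        assert n_max == tips.n

    def test_pixel_size_guard(self):
        tips = npl.TipSet(np.array([[500.0, 500.0]]), (0, 0, 1000, 1000))
        with pytest.raises(ValueError, match="3 px"):
            render_micrograph(tips, RenderSpec(pixel_size_nm=50.0))


class TestHeightMap:
    def test_constant_summits_when_sd_zero(self):
        spec = PatternSpec(density=8, spacing=306, jitter_sd=0,
                           field_width=3000, field_height=3000, seed=11)
        tips = generate_pattern(spec)
        hm = generate_height_map(tips, height_mean=800.0, height_sd=0.0)
        assert hm.heights.max() == pytest.approx(800.0, rel=0.01)
        # every pillar summit reaches the common height
        for x, y in tips.xy:
            i = int(round(y / 10)) ; j = int(round(x / 10))
            lo_i, hi_i = max(0, i - 2), min(hm.heights.shape[0], i + 3)
            lo_j, hi_j = max(0, j - 2), min(hm.heights.shape[1], j + 3)
            assert hm.heights[lo_i:hi_i, lo_j:hi_j].max() == pytest.approx(800.0, rel=0.01)

    def test_flat_map_without_tips(self):
        tips = npl.TipSet(np.empty((0, 2)), (0, 0, 2000, 2000))
        hm = generate_height_map(tips, height_mean=800.0, height_sd=50.0)
        assert np.all(hm.heights == 0.0)
        ra, rq = npl.roughness(hm)
        assert ra == 0.0 and rq == 0.0

    def test_summit_heights_recover_generator_mean(self):
        # Height statistics drawn as for the tallest observed surface class:
        # mean 836.8 nm, spread 91.2 nm.
        spec = PatternSpec(density=10, spacing=306, jitter_sd=0,
                           field_width=8000, field_height=8000, seed=13)
        tips = generate_pattern(spec)
        hm = generate_height_map(tips, height_mean=836.8, height_sd=91.2, seed=13)
        summits = []
        for x, y in tips.xy:
            i, j = int(round(y / 10)), int(round(x / 10))
            lo_i, hi_i = max(0, i - 2), min(hm.heights.shape[0], i + 3)
            lo_j, hi_j = max(0, j - 2), min(hm.heights.shape[1], j + 3)
            summits.append(hm.heights[lo_i:hi_i, lo_j:hi_j].max())
        se = 91.2 / np.sqrt(len(summits))
        assert abs(np.mean(summits) - 836.8) <= 2 * se + 0.01 * 836.8


class TestViability:
    def test_no_kill_counts_indistinguishable(self):
        table = generate_viability(
            ViabilitySpec(kill_fraction=0.0, replicates=12, seed=3)
        )
        res = npl.paired_t_test(
            table["control_cfu"].to_numpy(), table["surface_cfu"].to_numpy()
        )
        assert res.p > 0.01

    def test_full_kill_zero_surface(self):
        table = generate_viability(ViabilitySpec(kill_fraction=1.0, replicates=6, seed=4))
        assert (table["surface_cfu"] == 0).all()

    def test_hand_arithmetic_efficiency(self):
        # 7.02e6 cells killed on 1 cm^2 over 180 min -> 3.9e4 cells/min/cm^2
        spec = ViabilitySpec(
            inoculum_cfu=7.02e6, kill_fraction=1.0, area_cm2=1.0,
            incubation_min=180.0, replicates=4, count_noise_cv=0.0, seed=0,
        )
        table = generate_viability(spec)
        result = npl.efficiency(
            npl.ViabilityTable(table, spec.area_cm2, spec.incubation_min)
        )
        assert result.mean == pytest.approx(3.9e4)
        assert spec.true_efficiency == pytest.approx(3.9e4)

    def test_determinism(self):
        spec = ViabilitySpec(seed=9)
        a, b = generate_viability(spec), generate_viability(spec)
        assert a.equals(b)
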