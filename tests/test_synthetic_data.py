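"""Synthetic scene generator: morphometry recovery, closure, determinism."""

import json

import numpy as np
import pytest
import shapely

from sporeseg.io_annotation import polygons_to_mask, read_annotations, read_image, read_mask
from sporeseg.particle_analysis import T0_FILTER, filter_particles, label_particles
from sporeseg.synthetic_data import (
    Scene,
    SceneSpec,
    make_dataset,
    render_scene,
    sample_cell_shape,
    sample_spore_shape,
    t0_spec,
    t120_spec,
)


def _poly_circularity(verts):
    poly = shapely.Polygon(verts)
    return 4 * np.pi * poly.area / poly.length**2


class TestShapeSampling:
    def test_circularity_target_one_gives_a_circle(self):
        spec = SceneSpec(spore_circularity=(0.999999, 0.999998, 0.9999999))
        verts = sample_spore_shape(spec, np.random.default_rng(0))
        radii = np.hypot(verts[:, 0] - verts[:, 0].mean(),
                         verts[:, 1] - verts[:, 1].mean())
        assert radii.std() / radii.mean() < 1e-3  # axis ratio 1

    def test_spore_area_median_recovered(self, rng):
        spec = SceneSpec()
        areas = [
            shapely.Polygon(sample_spore_shape(spec, rng)).area / spec.px_per_um**2
            for _ in range(2000)
        ]
        assert np.median(areas) == pytest.approx(1.11, rel=0.05)

    def test_cell_circularity_median_recovered(self, rng):
        spec = SceneSpec()
        circs = [_poly_circularity(sample_cell_shape(spec, rng)) for _ in range(2000)]
        assert abs(np.median(circs) - 0.58) < 0.05

    def test_cells_stochastically_larger_than_spores(self, rng):
        spec = SceneSpec()
        spore_areas = [shapely.Polygon(sample_spore_shape(spec, rng)).area
                       for _ in range(500)]
        cell_areas = [shapely.Polygon(sample_cell_shape(spec, rng)).area
                      for _ in range(500)]
        assert np.median(cell_areas) / np.median(spore_areas) > 2

    def test_seeded_sampling_reproducible(self):
        spec = SceneSpec()
        a = sample_spore_shape(spec, np.random.default_rng(42))
        b = sample_spore_shape(spec, np.random.default_rng(42))
        np.testing.assert_array_equal(a, b)

    def test_truncnorm_family_also_hits_median(self, rng):
        spec = SceneSpec(spore_area_family="truncnorm")
        areas = [
            shapely.Polygon(sample_spore_shape(spec, rng)).area / spec.px_per_um**2
            for _ in range(2000)
        ]
        assert np.median(areas) == pytest.approx(1.11, rel=0.06)


class TestRenderScene:
    def test_empty_spec_gives_all_background_mask(self):
        scene = render_scene(SceneSpec(image_size=(64, 64), n_spores=0,
                                       n_cells=0, debris_rate=0, seed=0))
        assert not scene.mask.pixels.any()
        assert scene.annotations == [] and scene.truth_particles == []

    def test_mask_equals_union_of_rasterized_annotations(self):
        scene = render_scene(SceneSpec(seed=11))
        assert scene.mask == polygons_to_mask(scene.annotations, scene.mask.shape)

    def test_component_count_accounts_for_merges(self):
        scene = render_scene(SceneSpec(n_spores=50, seed=5))
        assert scene.n_placed == 50
        assert len(scene.truth_particles) == 50 - scene.n_merged

    def test_same_seed_identical_pixels_different_seed_not(self):
        a = render_scene(SceneSpec(seed=3))
        b = render_scene(SceneSpec(seed=3))
        c = render_scene(SceneSpec(seed=4))
        np.testing.assert_array_equal(a.image.pixels, b.image.pixels)
        assert (a.image.pixels != c.image.pixels).any()

    def test_debris_rendered_but_excluded_from_mask(self):
        spec = SceneSpec(image_size=(128, 128), n_spores=0, n_cells=0,
                         debris_rate=8, noise_sd=0, illumination_gradient=0, seed=2)
        scene = render_scene(spec)
        assert not scene.mask.pixels.any()
        # debris darkens pixels relative to the flat background
        assert (scene.image.pixels < spec.background_level - 10).any()

    def test_contrast_polarity_flips_object_contrast(self):
        base = dict(image_size=(96, 96), n_spores=4, debris_rate=0,
                    noise_sd=0, illumination_gradient=0, seed=6)
        dark = render_scene(SceneSpec(**base))
        bright = render_scene(SceneSpec(**base, contrast_polarity=-1))
        bg = dark.spec.background_level
        assert dark.image.pixels[dark.mask.pixels].mean() < bg
        assert bright.image.pixels[bright.mask.pixels].mean() > bg

    def test_overcrowded_scene_raises(self):
        with pytest.raises(RuntimeError, match="could not place"):
            render_scene(SceneSpec(image_size=(48, 48), n_spores=60, seed=0))

    def test_t0_filter_recovers_most_true_spores(self):
        """Analyze-Particles-style filtering on generated masks keeps at
        least 95% of the true spores at default noise."""
        kept = total = 0
        for seed in range(3):
            scene = render_scene(t0_spec(seed=seed))
            particles = label_particles(scene.mask, px_per_um=scene.spec.px_per_um)
            kept += len(filter_particles(particles, T0_FILTER))
            total += scene.n_placed
        assert kept / total >= 0.95


class TestMakeDataset:
    def test_file_triples_and_manifest(self, tmp_path):
        spec0 = t0_spec(image_size=(96, 96), n_spores=6, seed=1)
        spec120 = t120_spec(image_size=(96, 96), n_spores=2, n_cells=3, seed=100)
        manifest = make_dataset(spec0, spec120, n_scenes=2, out=tmp_path)
        for tp in ("t0", "t120"):
            for i in range(2):
                for suffix in ("image.png", "mask.png", "annotations.json"):
                    assert (tmp_path / f"{tp}_{i:03d}_{suffix}").exists()
        assert json.loads((tmp_path / "manifest.json").read_text()) == manifest

    def test_regeneration_from_manifest_seeds_is_identical(self, tmp_path):
        spec0 = t0_spec(image_size=(96, 96), n_spores=6, seed=7)
        spec120 = t120_spec(image_size=(96, 96), n_spores=2, n_cells=3, seed=900)
        manifest = make_dataset(spec0, spec120, n_scenes=2, out=tmp_path)
        entry = manifest["timepoints"]["t0"]["scenes"][1]
        respec = SceneSpec(**{**manifest["timepoints"]["t0"]["spec"],
                              "image_size": (96, 96), "seed": entry["seed"]})
        scene = render_scene(respec)
        np.testing.assert_array_equal(
            scene.image.pixels, read_image(tmp_path / "t0_001_image.png").pixels
        )
        assert scene.mask == read_mask(tmp_path / "t0_001_mask.png")
        back = read_annotations(tmp_path / "t0_001_annotations.json")
        assert len(back) == len(scene.annotations)


class TestGerminationClosure:
    """The pipeline's germination rate must agree exactly with the same
    classification rule applied to the generator's truth table; and when
    the cell population is morphologically separated from the spore
    window, the rate recovers the true cell fraction."""

    def test_rate_matches_truth_table_classification(self):
        scene = render_scene(t120_spec(image_size=(384, 384), n_spores=10,
                                       n_cells=30, seed=21))
        particles = label_particles(scene.mask, px_per_um=scene.spec.px_per_um)
        from sporeseg.particle_analysis import classify_spore_like, germination_rate

        spore_like, _ = classify_spore_like(particles, T0_FILTER)
        got = germination_rate(len(particles), len(spore_like))
        # independent recomputation particle by particle
        expected_spore_like = sum(
            1 for p in particles
            if 0.2 <= p.circularity <= 0.95 and 50 <= p.area_px <= 750
        )
        assert got.spore_like == expected_spore_like
        assert got.germinated == len(particles) - expected_spore_like

    def test_separated_populations_recover_cell_fraction(self):
        # cells forced well above the 750 px spore ceiling
        big_cells = (8.0, 5.0, 14.0)  # um^2, all > 2.75
        n_sp, n_ce = 24, 36
        spore_like = germinated = 0
        for seed in range(3):
            scene = render_scene(
                SceneSpec(image_size=(768, 768), n_spores=n_sp, n_cells=n_ce,
                          cell_area_um2=big_cells, min_separation_px=2,
                          seed=40 + seed)
            )
            assert scene.n_merged == 0  # separation forbids contact merges
            particles = label_particles(scene.mask, px_per_um=16.5)
            from sporeseg.particle_analysis import classify_spore_like

            s, g = classify_spore_like(particles, T0_FILTER)
            spore_like += len(s)
            germinated += len(g)
        total = spore_like + germinated
        rate = germinated / total
        true_fraction = n_ce / (n_sp + n_ce)
        # binomial sampling error margin at this n
        margin = 3 * np.sqrt(true_fraction * (1 - true_fraction) / total)
        assert abs(rate - true_fraction) <= margin + 0.02
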