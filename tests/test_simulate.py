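import json

import numpy as np
import pytest

from leafspec.grids import CubeGeometry, nearest_band
from leafspec.pipeline import process_scan, segment_plant, compute_ndvi, normalize_by_reference
from leafspec.simulate import (
    BACKGROUND_REFLECTANCE,
    NULL_TRAITS,
    SPECIES,
    SceneSpec,
    SimulationConfig,
    TRAITS,
    chem_to_spectrum,
    default_spectral_model,
    generate_bundle,
    make_dataset,
    make_species_baseline,
    render_scene,
    sample_chemistry,
)


class TestChemistry:
    def test_water_content_identity_holds_exactly(self):
        chem = sample_chemistry(seed=0)
        recomputed = (chem.w_fresh - chem.w_dry) / chem.w_fresh * 100.0
        assert np.array_equal(recomputed.to_numpy(), chem.wc.to_numpy())
        assert (chem.w_dry <= chem.w_fresh).all()
        assert (chem[TRAITS] >= 0).all().all()

    def test_formula_example(self):
        # 10 g fresh, 2 g dry -> 80% water
        assert (10.0 - 2.0) / 10.0 * 100.0 == 80.0

    @pytest.mark.parametrize("seed", [0, 1, 99])
    def test_species_water_content_ranges(self, seed):
        chem = sample_chemistry(seed=seed)
        maize = chem[chem.species == "maize"].wc
        soy = chem[chem.species == "soybean"].wc
        assert maize.between(79.6, 91.0).all()
        assert soy.between(68.2, 81.9).all()

    def test_pooled_nitrogen_range_approached(self):
        """~1000 draws: N stays in [0.96, 5.68] and comes within 0.3 of
        both endpoints."""
        design = {k: v * 9 for k, v in
                  sample_chemistry(seed=0).groupby(
                      ["species", "experiment", "treatment"]).size().items()}
        chem = sample_chemistry(design, seed=4)
        assert len(chem) >= 1000
        assert chem.n.between(0.96, 5.68).all()
        assert chem.n.min() <= 0.96 + 0.3
        assert chem.n.max() >= 5.68 - 0.3

    def test_nutrient_means_ordered_for_responsive_traits(self):
        chem = sample_chemistry(seed=2)
        nut = chem[chem.experiment == "nutrient"]
        means = nut.groupby("treatment")["n"].mean()
        assert means["low"] < means["medium"] < means["high"]
        for trait in ("p", "k", "s"):
            m = nut.groupby("treatment")[trait].mean()
            assert m["low"] < m["medium"] < m["high"]

    def test_null_traits_have_no_treatment_effect_built_in(self):
        # large design so sampling noise cannot mimic a treatment effect
        design = {(sp, "nutrient", tr): 200 for sp in SPECIES
                  for tr in ("low", "medium", "high")}
        chem = sample_chemistry(design, seed=3)
        for trait in NULL_TRAITS:
            m = chem.groupby("treatment")[trait].mean()
            assert m.max() - m.min() < 0.2 * chem[trait].std()

    def test_invalid_design_rejected(self):
        with pytest.raises(ValueError):
            sample_chemistry({("maize", "water", "control"): 0}, seed=0)


class TestSpectralModel:
    def test_baselines_segmentable_and_bounded(self, grid243):
        for species in SPECIES:
            base = make_species_baseline(species, grid243)
            assert np.all((base >= 0.01) & (base <= 0.99))
            i705 = base[nearest_band(grid243, 705.0)]
            i750 = base[nearest_band(grid243, 750.0)]
            assert (i750 - i705) / (i750 + i705) > 0.2

    def test_water_trough_depths_ordered(self, grid243):
        """1450 nm trough deeper than 970 nm, as for liquid water."""
        for species in SPECIES:
            base = make_species_baseline(species, grid243)
            wl = grid243.band_centers_nm

            def depth(center):
                idx = nearest_band(grid243, center)
                shoulder = base[(wl > center - 160) & (wl < center - 90)].max()
                return shoulder - base[idx]

            assert depth(1450.0) > depth(970.0) > 0

    def test_reference_chemistry_returns_baseline_exactly(self, grid243):
        model = default_spectral_model(grid243, noise_sd=0.0)
        row = {"species": "maize", **model.references}
        spec = chem_to_spectrum(row, model, rng=0)
        assert np.allclose(spec, model.baselines["maize"])

    def test_raising_wc_deepens_1450_trough(self, grid243):
        model = default_spectral_model(grid243, noise_sd=0.0)
        lo = {"species": "soybean", **model.references, "wc": 70.0}
        hi = {"species": "soybean", **model.references, "wc": 90.0}
        idx = nearest_band(grid243, 1450.0)
        assert chem_to_spectrum(hi, model, 0)[idx] < chem_to_spectrum(lo, model, 0)[idx]

    def test_null_traits_leave_spectrum_unchanged(self, grid243):
        model = default_spectral_model(grid243, noise_sd=0.0)
        a = {"species": "maize", **model.references}
        b = dict(a, na=a["na"] * 10 + 1, b=a["b"] * 3 + 5)
        assert np.array_equal(chem_to_spectrum(a, model, 0),
                              chem_to_spectrum(b, model, 0))

    def test_linearity_in_traits_by_finite_difference(self, grid243):
        """Pre-noise, pre-clip the map is linear: finite differences
        recover each trait's loading vector."""
        model = default_spectral_model(grid243, noise_sd=0.0)
        base_row = {"species": "maize", **model.references}
        for trait in ("wc", "n", "cu"):
            step = 1.0
            bumped = dict(base_row, **{trait: model.references[trait] + step})
            diff = chem_to_spectrum(bumped, model, 0) - chem_to_spectrum(base_row, model, 0)
            assert np.allclose(diff, model.loadings[trait] * step, atol=1e-12)


class TestSceneRendering:
    @staticmethod
    def _flat_scene(geometry, noise_sd=0.0, gain=None):
        sil = np.zeros((geometry.n_lines, geometry.n_samples), bool)
        sil[4:12, 4:12] = True
        illum = np.ones_like(sil, float) if gain is None else gain
        return SceneSpec(sil, illum, noise_sd=noise_sd, seed=0)

    def test_zero_noise_flat_gain_inverts_to_input_spectrum(self, small_grid):
        geometry = CubeGeometry(16, 16, 5.0)
        model = default_spectral_model(small_grid, noise_sd=0.0)
        spectrum = model.baselines["maize"]
        scene = self._flat_scene(geometry)
        plant, ref = render_scene(spectrum, scene, small_grid, geometry)
        out = process_scan(plant, ref)
        # digitisation bound: rounding both cubes perturbs the ratio by at
        # most ~1 DN relative to the per-band reference signal
        from leafspec.simulate import lamp_spectrum

        signal = lamp_spectrum(small_grid) * scene.full_scale
        assert np.all(np.abs(out.reflectance - spectrum) <= 1.5 / (signal - 1.0))

    def test_gain_field_cancels_in_normalization(self, small_grid):
        geometry = CubeGeometry(16, 16, 5.0)
        model = default_spectral_model(small_grid, noise_sd=0.0)
        spectrum = model.baselines["soybean"]
        yy, xx = np.mgrid[0:16, 0:16]
        gain = 0.5 + 0.5 * xx / 15.0  # varies 2x across the chamber
        flat = self._flat_scene(geometry)
        varied = self._flat_scene(geometry, gain=gain)
        out_flat = process_scan(*render_scene(spectrum, flat, small_grid, geometry))
        out_var = process_scan(*render_scene(spectrum, varied, small_grid, geometry))
        assert np.max(np.abs(out_flat.reflectance - out_var.reflectance)) < 2e-3

    def test_background_only_scene_has_empty_mask(self, small_grid):
        geometry = CubeGeometry(8, 8, 5.0)
        sil = np.zeros((8, 8), bool)
        scene = SceneSpec(sil, np.ones((8, 8)), noise_sd=0.0, seed=0)
        spectrum = np.full(small_grid.n_bands, BACKGROUND_REFLECTANCE)
        plant, ref = render_scene(spectrum, scene, small_grid, geometry)
        mask = segment_plant(compute_ndvi(normalize_by_reference(plant, ref)))
        assert mask.n_pixels == 0

    def test_overflow_guard(self, small_grid):
        geometry = CubeGeometry(4, 4, 5.0)
        sil = np.ones((4, 4), bool)
        scene = SceneSpec(sil, np.full((4, 4), 10.0), full_scale=30000.0, seed=0)
        with pytest.raises(ValueError, match="16 bits"):
            render_scene(np.full(small_grid.n_bands, 0.5), scene, small_grid, geometry)


class TestDataset:
    def test_default_bundle_counts(self, default_bundle):
        chem, scenes = default_bundle
        assert len(chem) == 120 and len(scenes) == 120
        assert (chem.groupby("species").size() == 60).all()

    def test_bundle_reproducible_from_seed(self):
        config = SimulationConfig.mini()
        chem1, scenes1 = generate_bundle(config, seed=9)
        chem2, scenes2 = generate_bundle(config, seed=9)
        assert chem1.equals(chem2)
        for a, b in zip(scenes1, scenes2):
            assert np.array_equal(a.plant_cube.values, b.plant_cube.values)
            assert np.array_equal(a.reference_cube.values, b.reference_cube.values)

    def test_make_dataset_writes_complete_mini_bundle(self, tmp_path):
        config = SimulationConfig.mini()
        out = make_dataset(config, seed=1, out_dir=tmp_path / "bundle")
        n = sum(config.design.values())
        assert len(list(out.glob("*_plant.bil"))) == n
        assert len(list(out.glob("*_ref.bil"))) == n
        manifest = json.loads((out / "manifest.json").read_text())
        assert manifest["n_plants"] == n
        assert manifest["loadings_version"] == 1
        assert "synthetic" in manifest["background"] or "invented" in manifest["background"]
        with pytest.raises(FileExistsError):
            make_dataset(config, seed=1, out_dir=tmp_path / "bundle")
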