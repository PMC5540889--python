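"""Synthetic greenhouse imaging study: chemistry tables and paired cubes.

The simulator emulates the structure of the study the pipeline is built
for: 120 plants (60 maize + 60 soybean), half in a water-limitation
experiment (control vs limited watering, driving a wide water-content
range) and half in a nutrient experiment (low / medium / high fertilizer
driving macro- and micronutrient ranges). Each plant gets

* a chemistry row: fresh/dry weight, water content, and 12 nutrient
  concentrations drawn from treatment-shifted truncated normals whose
  pooled ranges match the field-realistic spans of the study design
  (maize WC 79.6-91.0%, soybean WC 68.2-81.9%, pooled N 0.96-5.68%);
* a ground-truth reflectance spectrum: a smooth vegetation baseline per
  species (low visible reflectance, a sharp red edge near 700-750 nm, an
  NIR plateau, and water-absorption troughs at 970/1240/1450 nm) plus a
  linear-in-traits perturbation from a frozen, versioned loading
  calibration (``loadings_v1.yaml``) plus band-wise spectral noise;
* a rendered scan pair: a plant cube (silhouette pixels carry the plant
  spectrum, background a flat low-NDVI reflector at 0.05) and a blank
  reference cube, both multiplied by the same non-uniform illumination
  field and halogen-like lamp spectrum, digitised to 16-bit with
  detector noise.

Chemistry is whole-plant constant per pixel, and the chemistry-to-
spectrum map is linear by construction, so a linear calibration can in
principle recover every trait that has a nonzero loading. Na and B are
given near-zero treatment effects and zero spectral loadings: they are
the built-in negative controls.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import yaml
from scipy import stats

from .envi import ROLE_PLANT, ROLE_REFERENCE, RawCube, write_bil
from .grids import CubeGeometry, WavelengthGrid, instrument_grid

#: Trait order used throughout tables and reports.
TRAITS = ["wc", "n", "p", "k", "mg", "ca", "s", "na", "fe", "mn", "b", "cu", "zn"]
TRAIT_UNITS = {
    "wc": "%", "n": "%", "p": "%", "k": "%", "mg": "%", "ca": "%",
    "s": "%", "na": "%", "fe": "ppm", "mn": "ppm", "b": "ppm",
    "cu": "ppm", "zn": "ppm",
}
#: Traits with no spectral loading (unpredictable by construction).
NULL_TRAITS = ["na", "b"]

SPECIES = ["maize", "soybean"]

_LOADINGS_FILE = Path(__file__).parent / "loadings_v1.yaml"

# --------------------------------------------------------------------------
# Chemistry sampling

#: Water-content sampling parameters per (species, experiment, treatment):
#: (mean, sd, low, high). Hard truncation keeps every draw inside the
#: species' observed range (maize 79.6-91.0, soybean 68.2-81.9).
_WC_PARAMS = {
    ("maize", "water", "control"): (88.5, 1.2, 85.0, 91.0),
    ("maize", "water", "limited"): (82.5, 1.5, 79.6, 86.5),
    ("maize", "nutrient", None): (87.0, 1.3, 83.0, 91.0),
    ("soybean", "water", "control"): (79.2, 1.2, 75.5, 81.9),
    ("soybean", "water", "limited"): (72.0, 1.8, 68.2, 76.5),
    ("soybean", "nutrient", None): (78.0, 1.3, 74.0, 81.9),
}

#: Nitrogen (%): treatment-driven in the nutrient experiment, pooled range
#: bounded to 0.96-5.68.
_N_PARAMS = {
    "low": (1.5, 0.35, 0.96, 2.6),
    "medium": (3.2, 0.5, 2.0, 4.6),
    "high": (4.9, 0.4, 3.5, 5.68),
    None: (3.5, 0.5, 2.0, 5.2),  # water-experiment plants, normally fertilised
}

#: Remaining traits: base level per species, relative SD, and nutrient
#: treatment multipliers (low/medium/high). Na and B get flat multipliers —
#: near-zero treatment response, mirroring their behaviour in the study.
_TRAIT_BASE = {
    # trait: ({species: base}, rel_sd, {treatment: multiplier})
    "p":  ({"maize": 0.30, "soybean": 0.35}, 0.12, {"low": 0.7, "medium": 1.0, "high": 1.3}),
    "k":  ({"maize": 1.8, "soybean": 2.2}, 0.12, {"low": 0.7, "medium": 1.0, "high": 1.3}),
    "mg": ({"maize": 0.35, "soybean": 0.45}, 0.12, {"low": 0.8, "medium": 1.0, "high": 1.2}),
    "ca": ({"maize": 0.60, "soybean": 1.30}, 0.12, {"low": 0.85, "medium": 1.0, "high": 1.15}),
    "s":  ({"maize": 0.20, "soybean": 0.25}, 0.12, {"low": 0.75, "medium": 1.0, "high": 1.25}),
    "na": ({"maize": 0.006, "soybean": 0.007}, 0.25, {"low": 1.0, "medium": 1.0, "high": 1.0}),
    "fe": ({"maize": 90.0, "soybean": 110.0}, 0.15, {"low": 0.8, "medium": 1.0, "high": 1.2}),
    "mn": ({"maize": 55.0, "soybean": 65.0}, 0.15, {"low": 0.8, "medium": 1.0, "high": 1.2}),
    "b":  ({"maize": 40.0, "soybean": 40.0}, 0.25, {"low": 1.0, "medium": 1.0, "high": 1.0}),
    "cu": ({"maize": 8.0, "soybean": 10.0}, 0.15, {"low": 0.75, "medium": 1.0, "high": 1.25}),
    "zn": ({"maize": 35.0, "soybean": 40.0}, 0.15, {"low": 0.8, "medium": 1.0, "high": 1.2}),
}

#: Default design: 2 species x (water: control/limited x 15, nutrient:
#: low/medium/high x 10) = 120 plants, 60 per species.
DEFAULT_DESIGN = {
    **{(sp, "water", tr): 15 for sp in SPECIES for tr in ("control", "limited")},
    **{(sp, "nutrient", tr): 10 for sp in SPECIES for tr in ("low", "medium", "high")},
}


def _truncnorm(rng, mean, sd, low, high, size):
    a, b = (low - mean) / sd, (high - mean) / sd
    return stats.truncnorm.rvs(a, b, loc=mean, scale=sd, size=size, random_state=rng)


def sample_chemistry(design: dict | None = None, seed: int = 0):
    """Draw a per-plant chemistry table for the given design.

    ``design`` maps (species, experiment, treatment) to a plant count;
    the default is the 120-plant study layout. Water content is drawn
    first and fresh/dry weights constructed to satisfy
    WC = (W_fresh - W_dry) / W_fresh x 100 exactly.
    """
    import pandas as pd

    if design is None:
        design = DEFAULT_DESIGN
    if any(count < 1 for count in design.values()):
        raise ValueError("every design cell needs a count >= 1")
    rng = np.random.default_rng(seed)
    rows = []
    idx = 0
    for (species, experiment, treatment), count in sorted(design.items()):
        wc_key = (species, experiment, treatment if experiment == "water" else None)
        wc_mean, wc_sd, wc_lo, wc_hi = _WC_PARAMS[wc_key]
        wc = _truncnorm(rng, wc_mean, wc_sd, wc_lo, wc_hi, count)
        n_key = treatment if experiment == "nutrient" else None
        n_mean, n_sd, n_lo, n_hi = _N_PARAMS[n_key]
        n_vals = _truncnorm(rng, n_mean, n_sd, n_lo, n_hi, count)
        # shoot biomass: maize larger; water-limited plants smaller
        base_fw = 140.0 if species == "maize" else 90.0
        if experiment == "water" and treatment == "limited":
            base_fw *= 0.7
        w_fresh = np.maximum(_truncnorm(rng, base_fw, 0.15 * base_fw,
                                        0.5 * base_fw, 1.6 * base_fw, count), 1.0)
        w_dry = w_fresh * (1.0 - wc / 100.0)
        for j in range(count):
            idx += 1
            row = {
                "id": f"{species[:2]}-{experiment[:3]}-{treatment[:3]}-{j + 1:02d}",
                "species": species,
                "experiment": experiment,
                "treatment": treatment,
                "w_fresh": float(w_fresh[j]),
                "w_dry": float(w_dry[j]),
                # recompute so the WC identity holds to the last bit
                "wc": float((w_fresh[j] - w_dry[j]) / w_fresh[j] * 100.0),
                "n": float(n_vals[j]),
            }
            for trait, (base, rel_sd, mult) in _TRAIT_BASE.items():
                mean = base[species] * (mult[treatment] if experiment == "nutrient" else 1.0)
                sd = rel_sd * mean
                row[trait] = float(_truncnorm(rng, mean, sd, max(mean - 3 * sd, 0.0),
                                              mean + 3 * sd, 1)[0])
            rows.append(row)
    frame = pd.DataFrame(rows)
    return frame[["id", "species", "experiment", "treatment",
                  "w_fresh", "w_dry"] + TRAITS]


# --------------------------------------------------------------------------
# Spectral model

@dataclass
class SpectralModel:
    """Linear chemistry-to-reflectance map on a wavelength grid."""

    grid: WavelengthGrid
    baselines: dict          # species -> (n_bands,) reflectance
    loadings: dict           # trait -> (n_bands,) response per trait unit
    references: dict         # trait -> centering constant
    noise_sd: float = 0.002  # band-wise reflectance noise
    version: int = 1

    def nonzero_traits(self) -> list:
        return [t for t in TRAITS if np.any(self.loadings[t] != 0)]


def _gauss(wl, center, width):
    return np.exp(-((wl - center) ** 2) / (2.0 * width**2))


def make_species_baseline(species: str, grid: WavelengthGrid) -> np.ndarray:
    """Vegetation-like baseline reflectance for one species.

    Low visible reflectance, a logistic red edge near 700-750 nm, an NIR
    plateau sloping into the SWIR, and water troughs at 970, 1240 and
    1450 nm (deepest at 1450). The two species differ in plateau height,
    red-edge position and visible level, enough to separate in PC space.
    """
    if species not in SPECIES:
        raise ValueError(f"unknown species {species!r}")
    wl = grid.band_centers_nm
    if species == "maize":
        vis, nir, edge_nm, slope = 0.08, 0.50, 714.0, 1.1e-4
    else:
        vis, nir, edge_nm, slope = 0.11, 0.42, 719.0, 0.7e-4
    r = vis + (nir - vis) / (1.0 + np.exp(-(wl - edge_nm) / 11.0))
    r -= slope * np.clip(wl - 1000.0, 0.0, None)  # gentle SWIR decline
    # water absorption troughs; 1450 nm the deepest
    for center, width, depth in ((970.0, 30.0, 0.05), (1240.0, 40.0, 0.09),
                                 (1450.0, 60.0, 0.22)):
        r -= depth * _gauss(wl, center, width)
    return np.clip(r, 0.01, 0.99)


def load_loadings_config(path=None) -> dict:
    """Read the frozen loading calibration (trait band responses)."""
    with open(path or _LOADINGS_FILE) as fh:
        return yaml.safe_load(fh)


def default_spectral_model(grid: WavelengthGrid | None = None,
                           noise_sd: float = 0.002) -> SpectralModel:
    """The study's spectral model on the instrument grid (loadings v1)."""
    grid = grid or instrument_grid()
    config = load_loadings_config()
    wl = grid.band_centers_nm
    loadings, references = {}, {}
    for trait in TRAITS:
        entry = config["traits"][trait]
        references[trait] = float(entry["reference"])
        vec = np.zeros_like(wl)
        for g in entry["gaussians"]:
            vec += g["amplitude"] * _gauss(wl, g["center"], g["width"])
        loadings[trait] = vec
    baselines = {sp: make_species_baseline(sp, grid) for sp in SPECIES}
    return SpectralModel(grid, baselines, loadings, references,
                         noise_sd=noise_sd, version=int(config["version"]))


def chem_to_spectrum(chem_row, model: SpectralModel,
                     rng: np.random.Generator | int | None = None) -> np.ndarray:
    """Ground-truth reflectance for one plant: baseline + linear trait terms
    + band-wise Gaussian noise, clipped to [0.01, 0.99].
    """
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    r = model.baselines[chem_row["species"]].copy()
    for trait in TRAITS:
        r = r + model.loadings[trait] * (float(chem_row[trait]) - model.references[trait])
    if model.noise_sd > 0:
        r = r + rng.normal(0.0, model.noise_sd, size=r.size)
    return np.clip(r, 0.01, 0.99)


# --------------------------------------------------------------------------
# Scene rendering

#: Flat background reflectance (pot carrier / belt): low NDVI, segmentable
#: away from vegetation. Invented — no background spectra exist for the
#: real chamber.
BACKGROUND_REFLECTANCE = 0.05
DEFAULT_FULL_SCALE = 30000.0


@dataclass
class SceneSpec:
    """One rendered scene: silhouette, illumination, detector noise."""

    silhouette: np.ndarray       # (lines, samples) bool
    illumination: np.ndarray     # (lines, samples) positive gains
    noise_sd: float = 15.0       # DN detector noise
    full_scale: float = DEFAULT_FULL_SCALE
    seed: int | None = None

    def __post_init__(self):
        if self.silhouette.shape != self.illumination.shape:
            raise ValueError("silhouette and illumination shapes differ")
        if np.any(self.illumination <= 0):
            raise ValueError("illumination gains must be strictly positive")


def lamp_spectrum(grid: WavelengthGrid, temperature_k: float = 2600.0) -> np.ndarray:
    """Halogen-like relative lamp spectrum (Planck curve, peak-normalised)."""
    wl_m = grid.band_centers_nm * 1e-9
    h, c, kb = 6.62607e-34, 2.99792e8, 1.380649e-23
    radiance = 1.0 / (wl_m**5 * (np.exp(h * c / (wl_m * kb * temperature_k)) - 1.0))
    return radiance / radiance.max()


def make_silhouette(geometry: CubeGeometry, rng=None,
                    fill_fraction: float = 0.25) -> np.ndarray:
    """A blob-like plant silhouette covering roughly ``fill_fraction``."""
    rng = np.random.default_rng(rng)
    L, S = geometry.n_lines, geometry.n_samples
    yy, xx = np.mgrid[0:L, 0:S]
    cy, cx = L / 2 + rng.uniform(-L / 10, L / 10), S / 2 + rng.uniform(-S / 10, S / 10)
    radius = np.sqrt(fill_fraction * L * S / np.pi)
    mask = (yy - cy) ** 2 + (xx - cx) ** 2 <= radius**2
    # a few elliptical leaves around the core
    for _ in range(4):
        ang = rng.uniform(0, 2 * np.pi)
        ly, lx = cy + 0.8 * radius * np.sin(ang), cx + 0.8 * radius * np.cos(ang)
        mask |= ((yy - ly) / (0.5 * radius)) ** 2 + ((xx - lx) / (0.3 * radius)) ** 2 <= 1.0
    return mask


def make_illumination(geometry: CubeGeometry, rng=None,
                      contrast: float = 1.7) -> np.ndarray:
    """Smooth non-uniform gain field, brightest near a random hot spot."""
    rng = np.random.default_rng(rng)
    L, S = geometry.n_lines, geometry.n_samples
    yy, xx = np.mgrid[0:L, 0:S]
    cy, cx = rng.uniform(0.3, 0.7) * L, rng.uniform(0.3, 0.7) * S
    sigma = 0.6 * max(L, S)
    bump = np.exp(-(((yy - cy) ** 2 + (xx - cx) ** 2) / (2 * sigma**2)))
    lo = 1.0 / contrast
    return lo + (1.0 - lo) * bump


def render_scene(spectrum: np.ndarray, scene: SceneSpec, grid: WavelengthGrid,
                 geometry: CubeGeometry) -> tuple[RawCube, RawCube]:
    """Digitise a plant scene and its blank reference scan.

    Reference DN = round(gain x lamp x full_scale); plant DN adds the
    reflectance factor (the plant spectrum inside the silhouette, the
    flat background outside) and detector noise. Both cubes share the
    illumination field, so dividing them recovers reflectance.
    """
    lamp = lamp_spectrum(grid)
    gain = scene.illumination[:, :, None]
    signal = gain * lamp[None, None, :] * scene.full_scale
    if signal.max() > 0xFFFF:
        raise ValueError("illumination x full_scale overflows 16 bits")
    refl = np.where(scene.silhouette[:, :, None], spectrum[None, None, :],
                    BACKGROUND_REFLECTANCE)
    rng = np.random.default_rng(scene.seed)
    plant_dn = signal * refl
    if scene.noise_sd > 0:
        plant_dn = plant_dn + rng.normal(0.0, scene.noise_sd, size=plant_dn.shape)
    plant_dn = np.clip(np.rint(plant_dn), 0, 0xFFFF).astype(np.uint16)
    ref_dn = np.clip(np.rint(signal), 0, 0xFFFF).astype(np.uint16)
    plant = RawCube(plant_dn, grid, geometry, role=ROLE_PLANT)
    reference = RawCube(ref_dn, grid, geometry, role=ROLE_REFERENCE)
    return plant, reference


# --------------------------------------------------------------------------
# Dataset assembly

@dataclass
class SimulationConfig:
    """Everything that defines one simulated imaging campaign."""

    design: dict = field(default_factory=lambda: dict(DEFAULT_DESIGN))
    n_lines: int = 40
    n_samples: int = 40
    pixel_size_mm: float = 5.0
    spectral_noise_sd: float = 0.002
    detector_noise_sd: float = 15.0
    full_scale: float = DEFAULT_FULL_SCALE
    n_bands: int = 243
    start_nm: float = 550.0
    end_nm: float = 1700.0

    @classmethod
    def mini(cls) -> "SimulationConfig":
        """CI-scale bundle: 8 plants, 16x16 pixel cubes, 24 bands.

        Two plants per stratum so the bundle remains splittable."""
        design = {(sp, "water", "control"): 2 for sp in SPECIES}
        design.update({(sp, "nutrient", "high"): 2 for sp in SPECIES})
        return cls(design=design, n_lines=16, n_samples=16, n_bands=24)

    def grid(self) -> WavelengthGrid:
        from .grids import build_wavelength_grid
        return build_wavelength_grid(self.start_nm, self.end_nm, self.n_bands)

    def geometry(self) -> CubeGeometry:
        return CubeGeometry(self.n_lines, self.n_samples, self.pixel_size_mm)


@dataclass
class PlantScene:
    """One simulated plant: chemistry, true spectrum, rendered cube pair."""

    plant_id: str
    chem: dict
    true_spectrum: np.ndarray
    plant_cube: RawCube
    reference_cube: RawCube


def generate_bundle(config: SimulationConfig | None = None, seed: int = 0):
    """Generate the full in-memory bundle: (chem table, list of scenes).

    Fully reproducible: every per-plant random stream is spawned from
    ``seed`` via a SeedSequence, so the same seed gives an identical
    bundle.
    """
    config = config or SimulationConfig()
    chem = sample_chemistry(config.design, seed=seed)
    grid = config.grid()
    geometry = config.geometry()
    model = default_spectral_model(grid, noise_sd=config.spectral_noise_sd)
    scenes = []
    children = np.random.SeedSequence(seed).spawn(len(chem))
    for (_, row), seq in zip(chem.iterrows(), children):
        rng = np.random.default_rng(seq)
        spectrum = chem_to_spectrum(row, model, rng)
        scene = SceneSpec(
            silhouette=make_silhouette(geometry, rng),
            illumination=make_illumination(geometry, rng),
            noise_sd=config.detector_noise_sd,
            full_scale=config.full_scale,
            seed=int(rng.integers(0, 2**31 - 1)),
        )
        plant, reference = render_scene(spectrum, scene, grid, geometry)
        scenes.append(PlantScene(row["id"], row.to_dict(), spectrum, plant, reference))
    return chem, scenes


def make_dataset(config: SimulationConfig | None = None, seed: int = 0,
                 out_dir="simulated", force: bool = False):
    """Write a full fixture bundle to disk.

    Produces ``<id>_plant.bil(.hdr)`` / ``<id>_ref.bil(.hdr)`` per plant,
    ``chemistry.csv``, and ``manifest.json`` recording the seed, loadings
    version, per-plant true spectra and the synthetic-background note.
    """
    config = config or SimulationConfig()
    out = Path(out_dir)
    if out.exists() and any(out.iterdir()) and not force:
        raise FileExistsError(f"{out} exists and is not empty; pass force=True")
    out.mkdir(parents=True, exist_ok=True)
    chem, scenes = generate_bundle(config, seed=seed)
    chem.to_csv(out / "chemistry.csv", index=False)
    manifest = {
        "seed": int(seed),
        "loadings_version": 1,
        "background": "synthetic flat reflector at "
                      f"{BACKGROUND_REFLECTANCE} (invented; no real "
                      "chamber-background spectra exist)",
        "n_plants": len(scenes),
        "plants": {},
    }
    for sc in scenes:
        stem = sc.plant_id
        write_bil(sc.plant_cube, out / f"{stem}_plant.bil")
        write_bil(sc.reference_cube, out / f"{stem}_ref.bil")
        manifest["plants"][stem] = {
            "plant_cube": f"{stem}_plant.bil",
            "reference_cube": f"{stem}_ref.bil",
            "true_spectrum": [round(float(v), 6) for v in sc.true_spectrum],
        }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return out
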