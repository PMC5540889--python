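"""Per-trait calibration/validation reporting — the study's summary table.

For every chemical trait, a PLS1 calibration is fitted on the
calibration half with LOOCV factor selection; the report then carries,
side by side, the cross-validation statistics (computed on the held-out
LOOCV predictions) and the independent validation statistics (the model
applied once to the untouched validation half): R2, RMSE, RPD, MAPE and
the selected model size.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import metrics
from .pls import DEFAULT_MAX_FACTORS, PLSCalibration
from .screening import SplitSpec
from .simulate import TRAITS

REPORT_COLUMNS = [
    "trait", "n_cal", "r2_cv", "rmse_cv", "rpd_cv", "mape_cv", "model_size",
    "n_val", "r2_val", "rmse_val", "rpd_val", "mape_val", "quality_val",
]


@dataclass
class TraitReport:
    """Fitted models, the summary table, and scatter data for one run."""

    table: pd.DataFrame
    models: dict
    scatter: pd.DataFrame
    skipped: list = field(default_factory=list)

    def summary(self) -> str:
        with pd.option_context("display.width", 140, "display.precision", 3):
            header = "PLSR calibration/validation report"
            return f"{header}\n{'=' * len(header)}\n{self.table.to_string(index=False)}"

    def plot_scatter(self, trait: str, ax=None):
        """Measured-vs-predicted scatter for one trait, both phases."""
        import matplotlib.pyplot as plt

        data = self.scatter[self.scatter.trait == trait]
        if ax is None:
            _, ax = plt.subplots()
        for phase, marker in (("cross-validation", "o"), ("validation", "s")):
            sub = data[data.phase == phase]
            ax.scatter(sub.measured, sub.predicted, s=18, alpha=0.75,
                       marker=marker, label=phase)
        lo = min(data.measured.min(), data.predicted.min())
        hi = max(data.measured.max(), data.predicted.max())
        ax.plot([lo, hi], [lo, hi], "k--", lw=1)
        ax.set_xlabel(f"measured {trait}")
        ax.set_ylabel(f"predicted {trait}")
        ax.legend()
        return ax


def _spectral_columns(spectra: pd.DataFrame) -> list:
    cols = []
    for c in spectra.columns:
        try:
            float(c)
        except (TypeError, ValueError):
            continue
        cols.append(c)
    return cols


def build_report(spectra: pd.DataFrame, chem: pd.DataFrame, split: SplitSpec,
                 traits=None, max_factors: int = DEFAULT_MAX_FACTORS,
                 r2_mode: str = "pearson") -> TraitReport:
    """Fit and evaluate one PLS1 model per trait.

    ``spectra`` holds one row per plant (an ``id`` column plus one
    reflectance column per band, named by wavelength); ``chem`` the
    measured traits. Traits absent from ``chem`` are skipped with a
    warning entry rather than failing the whole report.
    """
    traits = list(traits) if traits is not None else TRAITS
    band_cols = _spectral_columns(spectra)
    if not band_cols:
        raise ValueError("spectra table has no wavelength-named columns")
    spectra = spectra.set_index("id")
    chem = chem.set_index("id")
    X_cal = spectra.loc[split.calibration_ids, band_cols].to_numpy(float)
    X_val = spectra.loc[split.validation_ids, band_cols].to_numpy(float)

    rows, models, scatter_rows, skipped = [], {}, [], []
    for trait in traits:
        if trait not in chem.columns or chem[trait].isna().any():
            import warnings
            warnings.warn(f"trait {trait!r} missing/incomplete; skipped", stacklevel=2)
            skipped.append(trait)
            continue
        y_cal = chem.loc[split.calibration_ids, trait].to_numpy(float)
        y_val = chem.loc[split.validation_ids, trait].to_numpy(float)
        results = PLSCalibration(y_cal, X_cal, trait=trait,
                                 max_factors=max_factors).fit()
        yhat_cv = results.cv_predictions
        yhat_val = results.predict(X_val)
        cv = metrics.evaluate(y_cal, yhat_cv, trait=trait, phase="cross-validation",
                              model_size=results.n_factors, r2_mode=r2_mode)
        val = metrics.evaluate(y_val, yhat_val, trait=trait, phase="validation",
                               model_size=results.n_factors, r2_mode=r2_mode)
        rows.append({
            "trait": trait, "n_cal": cv.n, "r2_cv": cv.r2, "rmse_cv": cv.rmse,
            "rpd_cv": cv.rpd, "mape_cv": cv.mape, "model_size": results.n_factors,
            "n_val": val.n, "r2_val": val.r2, "rmse_val": val.rmse,
            "rpd_val": val.rpd, "mape_val": val.mape, "quality_val": val.quality,
        })
        models[trait] = results
        for ids, measured, predicted, phase in (
            (split.calibration_ids, y_cal, yhat_cv, "cross-validation"),
            (split.validation_ids, y_val, yhat_val, "validation"),
        ):
            species = chem.loc[list(ids), "species"] if "species" in chem.columns else None
            for k, pid in enumerate(ids):
                scatter_rows.append({
                    "id": pid, "trait": trait, "phase": phase,
                    "measured": float(measured[k]), "predicted": float(predicted[k]),
                    "species": None if species is None else species.iloc[k],
                })
    table = pd.DataFrame(rows, columns=REPORT_COLUMNS)
    return TraitReport(table, models, pd.DataFrame(scatter_rows), skipped)


def build_per_species_reports(spectra: pd.DataFrame, chem: pd.DataFrame,
                              split: SplitSpec, traits=None, **kwargs) -> dict:
    """Within-species submodels: the same workflow restricted to one
    species' plants at a time (calibration and validation halves both
    subset). Runs through the identical code path as the pooled model.
    """
    out = {}
    for species in sorted(chem["species"].unique()):
        keep = set(chem.loc[chem.species == species, "id"])
        sub_split = SplitSpec(
            [i for i in split.calibration_ids if i in keep],
            [i for i in split.validation_ids if i in keep],
            split.strata, split.seed,
        )
        sub_chem = chem[chem.id.isin(keep)]
        sub_spectra = spectra[spectra.id.isin(keep)]
        out[species] = build_report(sub_spectra, sub_chem, sub_split,
                                    traits=traits, **kwargs)
    return out


def spectra_to_frame(ids, spectra, grid, n_pixels=None) -> pd.DataFrame:
    """Assemble per-plant spectra into the wavelength-labelled CSV layout."""
    data = {"id": list(ids)}
    arr = np.asarray(spectra, dtype=float)
    for j, wl in enumerate(grid.band_centers_nm):
        data[f"{wl:.4f}"] = arr[:, j]
    frame = pd.DataFrame(data)
    if n_pixels is not None:
        frame["n_pixels"] = n_pixels
    return frame
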