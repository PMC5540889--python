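"""Partial least squares regression (PLS1, NIPALS) for spectral calibration.

The modelling objects follow the Model / Results pattern:
:class:`PLSCalibration` is built from a calibration design (spectra
``X``, trait values ``y``) and ``fit()`` returns a
:class:`PLSCalibrationResults` carrying the regression vector, the
latent-factor decomposition, the cross-validation curve, and a
``summary()`` table. Prediction and evaluation hang off the results
object.

Model form
----------
For a single response, NIPALS PLS1 is non-iterative per component. On
mean-centered ``X`` (n x p) and ``y`` (n,), for each factor a:

    w_a = X'y / ||X'y||          (weight: covariance direction)
    t_a = X w_a                  (score)
    p_a = X't_a / (t_a't_a)      (x-loading)
    q_a = y't_a / (t_a't_a)      (y-loading)
    X <- X - t_a p_a' ; y <- y - q_a t_a     (deflation)

The regression vector on centered data is B = W (P'W)^{-1} q, and
predictions are y_mean + (X - x_mean) B. Data are mean-centered only —
no autoscaling, the convention for reflectance spectra whose bands share
a scale. The factor count is chosen by leave-one-out cross-validation:
the smallest count attaining the minimum RMSE of the held-out
predictions, capped by default at 12 factors.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import metrics

DEFAULT_MAX_FACTORS = 12


class DegenerateResponseError(ValueError):
    """The calibration response has zero variance."""


class IncompatibleModelError(ValueError):
    """New spectra do not match the model's band count."""


def _nipals_pls1(Xc: np.ndarray, yc: np.ndarray, n_factors: int):
    """Core NIPALS loop on centered data.

    Returns (weights W, x-loadings P, y-loadings q, scores T), with
    factors in columns.
    """
    n, p = Xc.shape
    W = np.empty((p, n_factors))
    P = np.empty((p, n_factors))
    q = np.empty(n_factors)
    T = np.empty((n, n_factors))
    X = Xc.copy()
    y = yc.copy()
    for a in range(n_factors):
        w = X.T @ y
        norm = np.linalg.norm(w)
        if norm == 0:
            # residual X carries no covariance with y: truncate
            W, P, q, T = W[:, :a], P[:, :a], q[:a], T[:, :a]
            break
        w /= norm
        t = X @ w
        tt = t @ t
        if tt == 0:
            W, P, q, T = W[:, :a], P[:, :a], q[:a], T[:, :a]
            break
        pa = X.T @ t / tt
        qa = y @ t / tt
        X -= np.outer(t, pa)
        y -= qa * t
        W[:, a], P[:, a], q[a], T[:, a] = w, pa, qa, t
    return W, P, q, T


@dataclass
class PLSCalibrationResults:
    """Fitted PLS1 calibration for one trait.

    ``coefficients`` is the per-band regression vector on centered data;
    ``predict`` applies ``y_mean + (X - x_mean) @ coefficients``.
    """

    trait: str
    x_mean: np.ndarray
    y_mean: float
    weights: np.ndarray
    x_loadings: np.ndarray
    y_loadings: np.ndarray
    scores: np.ndarray
    coefficients: np.ndarray
    n_factors: int
    rmse_cv_curve: np.ndarray | None = None
    cv_predictions: np.ndarray | None = None
    model: "PLSCalibration | None" = field(default=None, repr=False)

    def predict(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        squeeze = X.ndim == 1
        X = np.atleast_2d(X)
        if X.shape[1] != self.x_mean.size:
            raise IncompatibleModelError(
                f"spectra have {X.shape[1]} bands, model expects {self.x_mean.size}"
            )
        yhat = self.y_mean + (X - self.x_mean) @ self.coefficients
        return yhat[0] if squeeze else yhat

    @property
    def fittedvalues(self) -> np.ndarray:
        return self.predict(self.model.X) if self.model is not None else None

    @property
    def rmse_cv(self) -> float | None:
        """RMSE of the held-out LOOCV predictions at the selected size."""
        if self.cv_predictions is None or self.model is None:
            return None
        return metrics.rmse(self.model.y, self.cv_predictions)

    def summary(self) -> str:
        lines = [
            f"PLS1 calibration: {self.trait}",
            "=" * 40,
            f"bands:                {self.x_mean.size}",
            f"calibration plants:   {self.scores.shape[0]}",
            f"latent factors:       {self.n_factors}",
            f"y mean:               {self.y_mean:.5g}",
        ]
        if self.rmse_cv_curve is not None:
            lines.append(f"RMSE_CV (selected):   {self.rmse_cv:.5g}")
            curve = ", ".join(f"{v:.4g}" for v in self.rmse_cv_curve)
            lines.append(f"RMSE_CV curve:        [{curve}]")
        if self.model is not None:
            stats = metrics.evaluate(
                self.model.y, self.fittedvalues, trait=self.trait, phase="training"
            )
            lines.append(f"training R2:          {stats.r2:.4f}")
            lines.append(f"training RMSE:        {stats.rmse:.5g}")
        return "\n".join(lines)

    def plot_predictions(self, y, X=None, ax=None):
        """Measured-vs-predicted scatter with the 1:1 line."""
        import matplotlib.pyplot as plt

        yhat = self.predict(X) if X is not None else self.cv_predictions
        if ax is None:
            _, ax = plt.subplots()
        ax.scatter(y, yhat, s=18, alpha=0.8)
        lo, hi = min(np.min(y), np.min(yhat)), max(np.max(y), np.max(yhat))
        ax.plot([lo, hi], [lo, hi], "k--", lw=1)
        ax.set_xlabel(f"measured {self.trait}")
        ax.set_ylabel(f"predicted {self.trait}")
        return ax


class PLSCalibration:
    """PLS1 calibration model for one chemical trait.

    Parameters
    ----------
    y : array (n,)
        Lab-measured trait values for the calibration plants.
    X : array (n, p)
        Reflectance spectra (rows = plants, columns = bands).
    trait : str
        Trait name carried into results and reports.
    max_factors : int
        Cap on latent factors considered during cross-validation
        (default 12; additionally bounded by n - 2 and p).
    """

    def __init__(self, y, X, trait: str = "trait",
                 max_factors: int = DEFAULT_MAX_FACTORS):
        self.X = np.asarray(X, dtype=float)
        self.y = np.asarray(y, dtype=float)
        if self.X.ndim != 2:
            raise ValueError("X must be 2-D (plants x bands)")
        if self.y.shape != (self.X.shape[0],):
            raise ValueError("y length must match the number of rows of X")
        if np.ptp(self.y) == 0:
            raise DegenerateResponseError(f"response {trait!r} has zero variance")
        self.trait = trait
        self.max_factors = int(max_factors)

    @classmethod
    def from_dataframe(cls, data, trait: str, band_columns=None, **kwargs):
        """Build from a DataFrame holding trait and spectral columns.

        ``band_columns`` defaults to every column whose name parses as a
        number (the wavelength-labelled reflectance columns).
        """
        if band_columns is None:
            band_columns = [c for c in data.columns if _is_number(c)]
        X = data[band_columns].to_numpy(dtype=float)
        y = data[trait].to_numpy(dtype=float)
        return cls(y, X, trait=trait, **kwargs)

    @property
    def nobs(self) -> int:
        return self.X.shape[0]

    def _max_usable_factors(self, n_rows: int) -> int:
        return max(1, min(self.max_factors, n_rows - 1, self.X.shape[1]))

    def fit(self, n_factors: int | None = None) -> PLSCalibrationResults:
        """Fit the calibration.

        With ``n_factors=None`` the factor count is selected by
        leave-one-out cross-validation (smallest count attaining the
        minimum RMSE_CV); the results then carry the full RMSE_CV curve
        and the held-out predictions at the selected size.
        """
        if n_factors is None:
            curve, cv_preds = self.loocv_curve()
            # smallest factor count attaining the minimum; counts whose
            # RMSE_CV sits within numerical noise of the minimum (1e-9 of
            # the response scale) are treated as tied, so noise-free data
            # resolve to the true rank rather than to spurious extra factors
            tol = 1e-9 * max(float(np.std(self.y)), np.finfo(float).tiny)
            selected = int(np.argmax(curve <= curve.min() + tol)) + 1
            results = self._fit_exact(selected)
            results.rmse_cv_curve = curve
            results.cv_predictions = cv_preds[:, selected - 1]
            return results
        return self._fit_exact(int(n_factors))

    def _fit_exact(self, n_factors: int) -> PLSCalibrationResults:
        if n_factors < 1:
            raise ValueError("n_factors must be >= 1")
        if n_factors > min(self.nobs - 1, self.X.shape[1]):
            raise ValueError(
                f"n_factors={n_factors} exceeds min(n-1, p)="
                f"{min(self.nobs - 1, self.X.shape[1])}"
            )
        x_mean = self.X.mean(axis=0)
        y_mean = float(self.y.mean())
        W, P, q, T = _nipals_pls1(self.X - x_mean, self.y - y_mean, n_factors)
        coef = W @ np.linalg.solve(P.T @ W, q)
        return PLSCalibrationResults(
            trait=self.trait,
            x_mean=x_mean,
            y_mean=y_mean,
            weights=W,
            x_loadings=P,
            y_loadings=q,
            scores=T,
            coefficients=coef,
            n_factors=W.shape[1],
            model=self,
        )

    def loocv_curve(self, max_factors: int | None = None):
        """Leave-one-out RMSE_CV per factor count.

        Returns ``(curve, cv_predictions)`` where ``curve[a-1]`` is the
        RMSE of held-out predictions using ``a`` factors and
        ``cv_predictions[i, a-1]`` is plant i's prediction from the model
        fitted without it. Deterministic: no randomness in the fold loop.
        """
        n = self.nobs
        if n < 3:
            raise ValueError("LOOCV needs at least 3 calibration plants")
        cap = max_factors if max_factors is not None else self.max_factors
        # each fold fits on n-1 rows, so at most n-2 factors are usable
        A = max(1, min(cap, n - 2, self.X.shape[1]))
        preds = np.empty((n, A))
        for i in range(n):
            keep = np.ones(n, dtype=bool)
            keep[i] = False
            Xi, yi = self.X[keep], self.y[keep]
            x_mean = Xi.mean(axis=0)
            y_mean = yi.mean()
            W, P, q, T = _nipals_pls1(Xi - x_mean, yi - y_mean, A)
            xc = self.X[i] - x_mean
            # accumulate predictions factor by factor
            a_fit = W.shape[1]
            t_held = np.empty(a_fit)
            x_res = xc.copy()
            for a in range(a_fit):
                t_held[a] = x_res @ W[:, a]
                x_res = x_res - t_held[a] * P[:, a]
            partial = y_mean + np.cumsum(t_held * q[:a_fit])
            if a_fit < A:  # rank-deficient fold: pad with the last model
                partial = np.concatenate(
                    [partial, np.full(A - a_fit, partial[-1] if a_fit else y_mean)]
                )
            preds[i] = partial
        curve = np.sqrt(np.mean((preds - self.y[:, None]) ** 2, axis=0))
        return curve, preds


def _is_number(name) -> bool:
    try:
        float(name)
    except (TypeError, ValueError):
        return False
    return True


# ---------------------------------------------------------------------------
# Functional wrappers mirroring the procedural chemometrics workflow.

def fit_plsr(X, y, n_factors: int, trait: str = "trait") -> PLSCalibrationResults:
    """Fit a PLS1 model with a fixed factor count."""
    return PLSCalibration(y, X, trait=trait).fit(n_factors=n_factors)


def predict(model: PLSCalibrationResults, X) -> np.ndarray:
    """Apply a fitted calibration to new spectra."""
    return model.predict(X)


def loocv_select(X, y, max_factors: int = DEFAULT_MAX_FACTORS,
                 trait: str = "trait") -> PLSCalibrationResults:
    """Fit with LOOCV factor selection; results carry curve + CV predictions."""
    return PLSCalibration(y, X, trait=trait, max_factors=max_factors).fit()
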