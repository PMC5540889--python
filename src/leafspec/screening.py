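"""Pre-modelling steps: PCA outlier screening, stratified splitting,
and the calibration/validation balance check.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

BALANCE_ALPHA = 0.05


class UnsplittableStratumError(ValueError):
    """A stratum with a single plant cannot appear in both halves."""


@dataclass
class PCAResult:
    """Mean-centered PCA of the spectra matrix.

    ``outlier`` flags plants whose score on any retained component lies
    more than 3 SD from that component's mean. Flags are advisory: the
    default policy retains flagged plants.
    """

    scores: np.ndarray
    loadings: np.ndarray
    explained_variance: np.ndarray
    outlier: np.ndarray
    mean: np.ndarray

    @property
    def n_components(self) -> int:
        return self.loadings.shape[1]


def pca_screen(X, n_components: int = 3, sd_threshold: float = 3.0) -> PCAResult:
    """PCA on mean-centered spectra with score-based outlier flagging.

    A degenerate (rank-deficient) matrix triggers a warning and the
    retained components are truncated to the effective rank.
    """
    X = np.asarray(X, dtype=float)
    n, p = X.shape
    if n < n_components + 1:
        raise ValueError("need at least n_components + 1 plants")
    mean = X.mean(axis=0)
    Xc = X - mean
    U, s, Vt = np.linalg.svd(Xc, full_matrices=False)
    tol = s[0] * max(n, p) * np.finfo(float).eps if s.size else 0.0
    rank = int(np.sum(s > tol))
    if rank < n_components:
        warnings.warn(
            f"spectra matrix has rank {rank} < {n_components}; "
            "components truncated",
            stacklevel=2,
        )
    k = min(n_components, max(rank, 1))
    scores = U[:, :k] * s[:k]
    loadings = Vt[:k].T
    explained = s[:k] ** 2 / max(n - 1, 1)

    score_sd = scores.std(axis=0, ddof=1) if n > 1 else np.ones(k)
    score_sd = np.where(score_sd == 0, 1.0, score_sd)
    z = np.abs(scores - scores.mean(axis=0)) / score_sd
    outlier = np.any(z > sd_threshold, axis=1)
    return PCAResult(scores, loadings, explained, outlier, mean)


@dataclass
class SplitSpec:
    """A stratified calibration/validation partition of the plant ids."""

    calibration_ids: list = field(default_factory=list)
    validation_ids: list = field(default_factory=list)
    strata: dict = field(default_factory=dict)
    seed: int | None = None

    def __post_init__(self):
        overlap = set(self.calibration_ids) & set(self.validation_ids)
        if overlap:
            raise ValueError(f"ids in both halves: {sorted(overlap)[:5]}")


def stratified_split(ids, strata, fraction: float = 0.5, seed: int = 0) -> SplitSpec:
    """Split plants into calibration/validation halves within strata.

    Each stratum (e.g. a species x treatment cell) is shuffled with the
    seeded generator and divided so the two halves' counts differ by at
    most one. Deterministic given ``seed``.
    """
    ids = list(ids)
    strata = list(strata)
    if len(ids) != len(strata):
        raise ValueError("ids and strata must have equal length")
    if not 0 < fraction < 1:
        raise ValueError("fraction must be in (0, 1)")
    rng = np.random.default_rng(seed)
    groups: dict = {}
    for pid, s in zip(ids, strata):
        groups.setdefault(s, []).append(pid)
    cal, val = [], []
    # largest-remainder rounding across strata so odd strata alternate
    # their extra plant and the overall split stays as even as possible
    remainder = 0.0
    for label in sorted(groups, key=str):
        members = groups[label]
        if len(members) < 2:
            raise UnsplittableStratumError(
                f"stratum {label!r} has {len(members)} plant(s); need >= 2"
            )
        order = rng.permutation(len(members))
        exact = fraction * len(members)
        n_cal = int(np.floor(exact))
        remainder += exact - n_cal
        if remainder >= 0.5:
            n_cal += 1
            remainder -= 1.0
        n_cal = min(max(n_cal, 1), len(members) - 1)
        for rank, idx in enumerate(order):
            (cal if rank < n_cal else val).append(members[idx])
    return SplitSpec(sorted(cal, key=str), sorted(val, key=str),
                     {s: len(m) for s, m in groups.items()}, seed)


def check_split_balance(chem: pd.DataFrame, split: SplitSpec,
                        traits=None, alpha: float = BALANCE_ALPHA) -> pd.DataFrame:
    """Welch two-sample test per trait between the two halves.

    Returns a frame with one row per trait (t statistic, p-value,
    ``flagged`` where p < alpha, half means). Traits with zero variance
    in both halves are skipped with a note. Advisory only — no
    multiplicity correction.
    """
    if "id" not in chem.columns:
        raise ValueError("chem table needs an 'id' column")
    chem = chem.set_index("id")
    missing = (set(split.calibration_ids) | set(split.validation_ids)) - set(chem.index)
    if missing:
        raise ValueError(f"split ids missing from chem table: {sorted(missing)[:5]}")
    if traits is None:
        traits = [c for c in chem.columns
                  if pd.api.types.is_numeric_dtype(chem[c])]
    cal = chem.loc[split.calibration_ids]
    val = chem.loc[split.validation_ids]
    rows = []
    for trait in traits:
        a, b = cal[trait].to_numpy(float), val[trait].to_numpy(float)
        if np.std(a) == 0 and np.std(b) == 0:
            rows.append({"trait": trait, "t": np.nan, "p": np.nan,
                         "flagged": False, "note": "zero variance; test skipped",
                         "mean_cal": a.mean(), "mean_val": b.mean()})
            continue
        t, p = stats.ttest_ind(a, b, equal_var=False)
        rows.append({"trait": trait, "t": float(t), "p": float(p),
                     "flagged": bool(p < alpha), "note": "",
                     "mean_cal": a.mean(), "mean_val": b.mean()})
    return pd.DataFrame(rows)
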