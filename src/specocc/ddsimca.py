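"""Data-driven SIMCA one-class classifier.

The target class is modeled by PCA on the column-centered calibration
matrix.  Each sample is reduced to two distances: the score distance
``h_i = sum_a t_ia^2 / lambda_a`` (a Mahalanobis-type leverage within the
k-dimensional model subspace) and the orthogonal distance
``v_i = ||x_i - x_hat_i||^2`` (squared residual norm outside it).  Both are
treated as scaled chi-square variables with data-estimated degrees of
freedom N_h and N_v, so the total distance

    c = N_h * h / h0 + N_v * v / v0        ~  chi2(N_h + N_v)

gives a chi-square acceptance region at significance ``alpha`` and, with a
multiplicity-adjusted level, an outlier boundary at ``gamma``.  Training
samples between the two boundaries are "extreme"; beyond the outer one they
are outliers.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.optimize import brentq

from .dataset import SpectrumSet


class DDSIMCAError(ValueError):
    pass


class DegenerateDataError(DDSIMCAError):
    """Zero variance of a distance; DoF cannot be estimated by moments."""


CATEGORIES = ("regular", "extreme", "outlier")


@dataclass
class DDSIMCAModel:
    """Fitted PCA basis plus chi-square acceptance parameters."""

    mean_spectrum: np.ndarray
    loadings: np.ndarray          # p x k, orthonormal columns
    eigenvalues: np.ndarray       # per-PC training score variance (ddof=1)
    k: int
    h0: float
    v0: float
    N_h: float
    N_v: float
    alpha: float
    gamma: float
    c_crit: float
    c_out: float
    n_train: int
    wavenumbers: np.ndarray = field(default=None)  # type: ignore[assignment]
    dof_method: str = "moments"
    k_requested: int = 0
    degenerate_v: bool = False
    train_h: np.ndarray = field(default=None)  # type: ignore[assignment]
    train_v: np.ndarray = field(default=None)  # type: ignore[assignment]

    @property
    def total_dof(self) -> float:
        return self.N_h + (self.N_v if not self.degenerate_v else 0.0)

    # -- serialization --------------------------------------------------
    def to_json(self, path: str | Path) -> Path:
        path = Path(path)
        doc = {}
        for key, val in asdict(self).items():
            doc[key] = val.tolist() if isinstance(val, np.ndarray) else val
        path.parent.mkdir(parents=True, exist_ok=True)
        path.write_text(json.dumps(doc))
        return path

    @classmethod
    def from_json(cls, path: str | Path) -> "DDSIMCAModel":
        doc = json.loads(Path(path).read_text())
        for key in ("mean_spectrum", "loadings", "eigenvalues", "wavenumbers",
                    "train_h", "train_v"):
            if doc.get(key) is not None:
                doc[key] = np.asarray(doc[key], float)
        return cls(**doc)


@dataclass
class ExtremePlotData:
    """Observed vs expected counts beyond a grid of significance levels."""

    alpha_grid: np.ndarray
    expected: np.ndarray
    observed: np.ndarray
    tolerance_low: np.ndarray
    tolerance_high: np.ndarray
    n_train: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "alpha": self.alpha_grid,
                "expected": self.expected,
                "observed": self.observed,
                "tolerance_low": self.tolerance_low,
                "tolerance_high": self.tolerance_high,
            }
        )


@dataclass
class PCSelection:
    """Cross-validated sensitivity curve over candidate PC counts."""

    chosen_k: int
    candidates: list[int]
    acceptance: list[float]      # CV target-class acceptance rate per candidate
    n_eval: int


def _moments_dof(x: np.ndarray, what: str) -> tuple[float, float]:
    """Method-of-moments fit of a scaled chi-square: N = 2*mean^2/var."""
    center = float(np.mean(x))
    var = float(np.var(x, ddof=1))
    if var <= 0:
        raise DegenerateDataError(
            f"zero variance of {what}; moments DoF estimation failed "
            "(try dof_method='robust')"
        )
    return center, 2.0 * center**2 / var


def _robust_dof(x: np.ndarray, what: str) -> tuple[float, float]:
    """Quantile-matching fit of a scaled chi-square (outlier tolerant).

    Solves q75/q50 of chi2(N) = q75/q50 of the data for N, then rescales so
    the medians agree.
    """
    q50, q75 = np.quantile(x, [0.5, 0.75])
    if not q75 > q50 > 0:
        raise DegenerateDataError(f"degenerate quantiles of {what}")
    ratio = q75 / q50

    def f(n: float) -> float:
        return stats.chi2.ppf(0.75, n) / stats.chi2.ppf(0.5, n) - ratio

    lo, hi = 0.05, 2000.0
    if f(lo) < 0:       # heavier spread than chi2(0.05): clip
        n_est = lo
    elif f(hi) > 0:     # tighter than chi2(2000): clip
        n_est = hi
    else:
        n_est = brentq(f, lo, hi, xtol=1e-8)
    center = q50 * n_est / stats.chi2.ppf(0.5, n_est)
    return float(center), float(n_est)


_DOF_ESTIMATORS = {"moments": _moments_dof, "robust": _robust_dof}


def _distances(
    X: np.ndarray,
    mean: np.ndarray,
    loadings: np.ndarray,
    eigenvalues: np.ndarray,
) -> tuple[np.ndarray, np.ndarray]:
    Xc = X - mean
    scores = Xc @ loadings
    h = (scores**2 / eigenvalues).sum(axis=1)
    resid = Xc - scores @ loadings.T
    v = (resid**2).sum(axis=1)
    return h, v


def fit_ddsimca(
    train: SpectrumSet,
    k: int,
    alpha: float = 0.01,
    gamma: float = 0.01,
    dof_method: str = "moments",
    round_dof: bool = False,
) -> DDSIMCAModel:
    """Fit the one-class PCA model on target-class calibration spectra.

    Parameters
    ----------
    k : int
        Number of principal components.  If the centered calibration matrix
        has numerical rank below ``k``, the model is fitted with the
        effective rank (recorded as ``k`` with the request in
        ``k_requested``).
    alpha, gamma : float
        Type-I error of the acceptance boundary and the significance of the
        outlier boundary (the latter is multiplicity-adjusted per dataset:
        ``gamma_adj = 1 - (1 - gamma)^(1/n)``).
    dof_method : {"moments", "robust"}
        Degrees-of-freedom estimator for the scaled chi-square distance
        distributions.
    round_dof : bool
        Round the estimated DoF to integers clipped to [1, 250] (a common
        toolbox convention); default keeps positive reals.
    """
    n, p = train.intensities.shape
    if not 1 <= k < n:
        raise DDSIMCAError(f"k={k} must satisfy 1 <= k < n_train={n}")
    if dof_method not in _DOF_ESTIMATORS:
        raise DDSIMCAError(f"unknown dof_method {dof_method!r}")
    X = train.intensities
    mean = X.mean(axis=0)
    Xc = X - mean
    U, S, Vt = np.linalg.svd(Xc, full_matrices=False)
    tol = S[0] * max(n, p) * np.finfo(float).eps if S.size else 0.0
    rank = int(np.sum(S > tol))
    if rank == 0:
        raise DDSIMCAError("training matrix has zero variance")
    k_eff = min(k, rank, n - 1, p)
    loadings = Vt[:k_eff].T
    eigenvalues = S[:k_eff] ** 2 / (n - 1)
    h, v = _distances(X, mean, loadings, eigenvalues)

    estimator = _DOF_ESTIMATORS[dof_method]
    h0, N_h = estimator(h, "the score distance h")
    v_scale = float(np.mean(Xc**2))
    degenerate_v = float(np.mean(v)) <= max(v_scale, 1.0) * 1e-24
    if degenerate_v:
        # data lie exactly in the model subspace: the orthogonal distance
        # carries no information and is dropped from the total distance
        v0, N_v = 1.0, 0.0
    else:
        v0, N_v = estimator(v, "the orthogonal distance v")
    if round_dof:
        N_h = float(np.clip(round(N_h), 1, 250))
        if not degenerate_v:
            N_v = float(np.clip(round(N_v), 1, 250))

    dof = N_h + (0.0 if degenerate_v else N_v)
    c_crit = float(stats.chi2.ppf(1 - alpha, dof))
    gamma_adj = 1.0 - (1.0 - gamma) ** (1.0 / n)
    c_out = float(stats.chi2.ppf(1 - gamma_adj, dof))
    return DDSIMCAModel(
        mean_spectrum=mean,
        loadings=loadings,
        eigenvalues=eigenvalues,
        k=k_eff,
        h0=h0,
        v0=v0,
        N_h=N_h,
        N_v=N_v,
        alpha=alpha,
        gamma=gamma,
        c_crit=c_crit,
        c_out=c_out,
        n_train=n,
        wavenumbers=train.wavenumbers.copy(),
        dof_method=dof_method,
        k_requested=k,
        degenerate_v=degenerate_v,
        train_h=h,
        train_v=v,
    )


def total_distance(model: DDSIMCAModel, h: np.ndarray, v: np.ndarray) -> np.ndarray:
    """Combined chi-square distance ``N_h h/h0 + N_v v/v0`` (v dropped when
    the fit was subspace-degenerate)."""
    c = model.N_h * np.asarray(h) / model.h0
    if not model.degenerate_v:
        c = c + model.N_v * np.asarray(v) / model.v0
    return c


def classify_ddsimca(model: DDSIMCAModel, data: SpectrumSet) -> pd.DataFrame:
    """Distance records for new samples.

    Returns one row per sample with columns ``sample_id, h, v, c, category,
    accepted``; ``accepted`` means regular (``c <= c_crit``, ties accepted).
    """
    if model.wavenumbers is not None and not np.array_equal(
        data.wavenumbers, model.wavenumbers
    ):
        raise DDSIMCAError(
            "wavenumber axis differs from the training axis; no silent interpolation"
        )
    h, v = _distances(data.intensities, model.mean_spectrum, model.loadings, model.eigenvalues)
    c = total_distance(model, h, v)
    category = np.where(
        c <= model.c_crit, "regular", np.where(c <= model.c_out, "extreme", "outlier")
    )
    return pd.DataFrame(
        {
            "sample_id": data.sample_ids,
            "h": h,
            "v": v,
            "c": c,
            "category": category,
            "accepted": c <= model.c_crit,
        }
    )


def select_pcs_by_target_sensitivity(
    train: SpectrumSet,
    k_candidates: Sequence[int] = range(1, 11),
    alpha: float = 0.01,
    gamma: float = 0.01,
    dof_method: str = "moments",
    folds: int = 5,
    seed: int = 0,
) -> PCSelection:
    """Choose the PC count by cross-validated target-class sensitivity.

    The calibration set is split into ``folds`` random folds; for each
    candidate k the model is refitted without each fold and the held-out
    acceptance rate pooled.  The chosen k is the smallest candidate whose
    acceptance is within one binomial standard error of the maximum (a
    parsimony rule: more PCs are only taken when they buy real sensitivity).
    """
    n = train.n_samples
    if folds < 2:
        raise DDSIMCAError("need at least 2 folds")
    if n < folds:
        raise DDSIMCAError(f"n_train={n} smaller than folds={folds}")
    candidates = sorted(set(int(k) for k in k_candidates))
    rng = np.random.default_rng(seed)
    order = rng.permutation(n)
    fold_ids = np.array_split(order, folds)
    acceptance: list[float] = []
    for k in candidates:
        accepted = 0
        total = 0
        ok = True
        for held in fold_ids:
            keep = np.setdiff1d(order, held)
            try:
                model = fit_ddsimca(
                    train.take(keep), k, alpha=alpha, gamma=gamma, dof_method=dof_method
                )
                rec = classify_ddsimca(model, train.take(held))
            except DDSIMCAError:
                ok = False
                break
            accepted += int(rec["accepted"].sum())
            total += len(rec)
        acceptance.append(accepted / total if ok and total else np.nan)
    acc = np.asarray(acceptance)
    if np.all(np.isnan(acc)):
        raise DDSIMCAError("all PC candidates degenerate; selection failed")
    best = np.nanmax(acc)
    se = np.sqrt(best * (1 - best) / n)
    for k, a in zip(candidates, acc):
        if not np.isnan(a) and a >= best - se:
            chosen = k
            break
    return PCSelection(chosen_k=chosen, candidates=candidates,
                       acceptance=list(acc), n_eval=n)


def extreme_plot(
    model: DDSIMCAModel,
    train: SpectrumSet,
    alpha_grid: Optional[np.ndarray] = None,
) -> ExtremePlotData:
    """Observed vs theoretically expected extreme counts on the training set.

    For each significance level alpha on a log-spaced grid, the expected
    number of training samples beyond the chi-square threshold is
    ``n * alpha``; the observed count and a 95% binomial envelope are
    reported.  A well-specified model tracks the identity line.
    """
    rec = classify_ddsimca(model, train)
    c = rec["c"].to_numpy()
    n = len(c)
    if alpha_grid is None:
        alpha_grid = np.logspace(np.log10(0.5 / n), 0, 30)
    alpha_grid = np.asarray(alpha_grid, float)
    dof = model.total_dof
    thresholds = stats.chi2.ppf(1 - alpha_grid, dof)
    observed = np.array([(c > t).sum() for t in thresholds])
    lo = stats.binom.ppf(0.025, n, alpha_grid)
    hi = stats.binom.ppf(0.975, n, alpha_grid)
    return ExtremePlotData(
        alpha_grid=alpha_grid,
        expected=n * alpha_grid,
        observed=observed,
        tolerance_low=lo,
        tolerance_high=hi,
        n_train=n,
    )
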