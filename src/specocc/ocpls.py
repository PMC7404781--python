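"""One-class partial least squares (OCPLS).

A PLS1 model regresses a constant unit response y = 1 on the target-class
spectra.  Because mixtures with mass fractions summing to one reproduce the
unit response exactly, deviations of the predicted response flag samples
whose composition leaves the target class.  Note the spectra are *not*
column-centered for this regression: with centered columns the first PLS
weight X'y would vanish identically for a constant response.  Centering
enters instead through the two decision statistics, which are referenced to
the training center:

* Hotelling's T^2 of the mean-centered latent scores (within-model
  distance), bounded by the usual F-quantile limit
  ``A (n^2 - 1) / (n (n - A)) * F_{1-alpha}(A, n - A)``;
* the absolute centered residual ACR = |y_hat - mean(y_hat_train)| of the
  predicted response, bounded by a two-sided normal-theory limit
  ``z_{1-alpha/2} * sd(residuals)``.

A sample is accepted only when both statistics are within their limits; the
two limits split the diagnostic plane into four quadrants (regular, good
leverage, response outlier, bad leverage).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
import numpy as np
import pandas as pd
from scipy import stats

from .dataset import SpectrumSet


class OCPLSError(ValueError):
    pass


QUADRANTS = ("regular", "good_leverage", "response_outlier", "bad_leverage")


@dataclass
class OCPLSModel:
    """Fitted PLS basis plus T^2 / ACR acceptance limits."""

    mean_spectrum: np.ndarray     # training center (reference only; X not centered)
    weights: np.ndarray           # p x A
    loadings: np.ndarray          # p x A
    q: np.ndarray                 # per-LV response loadings
    rotation: np.ndarray          # p x A, scores = X @ rotation
    regression_coefficients: np.ndarray
    A: int
    score_means: np.ndarray
    score_variances: np.ndarray   # ddof=1 training score variances
    t2_limit: float
    residual_center: float
    residual_sd: float
    acr_limit: float
    alpha: float
    n_train: int
    wavenumbers: np.ndarray = field(default=None)  # type: ignore[assignment]

    def to_json(self, path: str | Path) -> Path:
        path = Path(path)
        doc = {}
        for key, val in asdict(self).items():
            doc[key] = val.tolist() if isinstance(val, np.ndarray) else val
        path.parent.mkdir(parents=True, exist_ok=True)
        path.write_text(json.dumps(doc))
        return path

    @classmethod
    def from_json(cls, path: str | Path) -> "OCPLSModel":
        doc = json.loads(Path(path).read_text())
        for key in ("mean_spectrum", "weights", "loadings", "q", "rotation",
                    "regression_coefficients", "score_means", "score_variances",
                    "wavenumbers"):
            if doc.get(key) is not None:
                doc[key] = np.asarray(doc[key], float)
        return cls(**doc)


@dataclass
class MCCVCurve:
    """Monte-Carlo cross-validation residual curve over LV counts."""

    lv_grid: list[int]
    residual_sd: list[float]
    chosen_A: int
    splits: int
    holdout_fraction: float
    seed: int
    tolerance: float = 0.05

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"lv": self.lv_grid, "residual_sd": self.residual_sd})


def _pls1(X: np.ndarray, y: np.ndarray, A: int):
    """PLS1 factor extraction (deterministic single-response NIPALS).

    Returns (W, P, Q, T, a_eff); extraction stops early when X is deflated
    to numerical zero (rank exhausted).
    """
    n, p = X.shape
    Xd = X.copy()
    W = np.zeros((p, A))
    P = np.zeros((p, A))
    Q = np.zeros(A)
    T = np.zeros((n, A))
    norm0 = np.linalg.norm(X.T @ y)
    a_eff = 0
    for a in range(A):
        w = Xd.T @ y
        nw = np.linalg.norm(w)
        if not np.isfinite(nw) or nw <= max(norm0, 1.0) * 1e-12:
            break
        w /= nw
        t = Xd @ w
        tt = float(t @ t)
        if tt <= 0:
            break
        P[:, a] = Xd.T @ t / tt
        Q[a] = float(y @ t) / tt
        W[:, a] = w
        T[:, a] = t
        Xd -= np.outer(t, P[:, a])
        a_eff = a + 1
    if a_eff == 0:
        raise OCPLSError("no PLS component could be extracted (X'y is zero)")
    return W[:, :a_eff], P[:, :a_eff], Q[:a_eff], T[:, :a_eff], a_eff


def fit_ocpls(train: SpectrumSet, A: int, alpha: float = 0.01) -> OCPLSModel:
    """Fit the one-class PLS model on target-class calibration spectra.

    ``A`` latent variables are extracted (fewer if the data rank is
    exhausted first, recorded in the model).  ``alpha`` sets both the T^2
    F-limit and the two-sided ACR limit.
    """
    n, p = train.intensities.shape
    if not 1 <= A < n:
        raise OCPLSError(f"A={A} must satisfy 1 <= A < n_train={n}")
    X = train.intensities
    y = np.ones(n)
    W, P, Q, T, a_eff = _pls1(X, y, A)
    rotation = W @ np.linalg.inv(P.T @ W)
    coef = rotation @ Q
    score_means = T.mean(axis=0)
    score_vars = T.var(axis=0, ddof=1)
    if np.any(score_vars <= 0):
        raise OCPLSError("zero-variance latent score; reduce A")
    if n <= a_eff:
        raise OCPLSError("too few samples for the T^2 limit")
    t2_limit = (
        a_eff * (n**2 - 1) / (n * (n - a_eff)) * stats.f.ppf(1 - alpha, a_eff, n - a_eff)
    )
    yhat = T @ Q
    resid = yhat - 1.0
    residual_center = float(resid.mean())
    residual_sd = float(resid.std(ddof=1))
    acr_limit = float(stats.norm.ppf(1 - alpha / 2) * residual_sd)
    return OCPLSModel(
        mean_spectrum=X.mean(axis=0),
        weights=W,
        loadings=P,
        q=Q,
        rotation=rotation,
        regression_coefficients=coef,
        A=a_eff,
        score_means=score_means,
        score_variances=score_vars,
        t2_limit=float(t2_limit),
        residual_center=residual_center,
        residual_sd=residual_sd,
        acr_limit=acr_limit,
        alpha=alpha,
        n_train=n,
        wavenumbers=train.wavenumbers.copy(),
    )


def _statistics(model: OCPLSModel, X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    T = X @ model.rotation
    z = (T - model.score_means) / np.sqrt(model.score_variances)
    t2 = (z**2).sum(axis=1)
    yhat = T @ model.q
    acr = np.abs((yhat - 1.0) - model.residual_center)
    return t2, acr


def classify_ocpls(model: OCPLSModel, data: SpectrumSet) -> pd.DataFrame:
    """Per-sample T^2 / ACR records and four-quadrant diagnosis.

    Columns: ``sample_id, t2, acr, quadrant, accepted``; accepted means both
    statistics within their limits (ties accepted).
    """
    if model.wavenumbers is not None and not np.array_equal(
        data.wavenumbers, model.wavenumbers
    ):
        raise OCPLSError(
            "wavenumber axis differs from the training axis; no silent interpolation"
        )
    t2, acr = _statistics(model, data.intensities)
    big_t2 = t2 > model.t2_limit
    big_acr = acr > model.acr_limit
    quadrant = np.where(
        big_t2,
        np.where(big_acr, "bad_leverage", "good_leverage"),
        np.where(big_acr, "response_outlier", "regular"),
    )
    return pd.DataFrame(
        {
            "sample_id": data.sample_ids,
            "t2": t2,
            "acr": acr,
            "quadrant": quadrant,
            "accepted": ~(big_t2 | big_acr),
        }
    )


def refit_without_outliers(
    train: SpectrumSet, A: int, alpha: float = 0.01
) -> tuple[OCPLSModel, np.ndarray]:
    """Fit, drop training samples outside the limits, and refit once.

    Returns the refitted model and the boolean mask of retained samples.
    Mirrors the common practice of excluding calibration outliers before
    building the final model.
    """
    first = fit_ocpls(train, A, alpha=alpha)
    rec = classify_ocpls(first, train)
    keep = rec["accepted"].to_numpy()
    if keep.all() or keep.sum() <= A:
        return first, np.ones(train.n_samples, dtype=bool)
    model = fit_ocpls(train.take(np.where(keep)[0]), A, alpha=alpha)
    return model, keep


def mccv_select_lvs(
    train: SpectrumSet,
    max_lvs: int = 10,
    splits: int = 100,
    holdout_fraction: float = 0.2,
    seed: int = 0,
    tolerance: float = 0.05,
) -> MCCVCurve:
    """Monte-Carlo cross-validation over the number of latent variables.

    For each random split the model is fitted on the kept part and the
    held-out unit responses predicted; the standard deviation of the pooled
    prediction residuals is reported per LV count.  The chosen count is the
    smallest whose residual SD is within ``tolerance`` (relative) of the
    minimum — a parsimony rule over the usual flat-bottomed MCCV curve.
    """
    n = train.n_samples
    if splits < 10:
        raise OCPLSError("use at least 10 Monte-Carlo splits")
    if not 0 < holdout_fraction < 1:
        raise OCPLSError("holdout_fraction must be in (0, 1)")
    n_hold = max(1, int(round(n * holdout_fraction)))
    n_keep = n - n_hold
    if n_keep < 2 or max_lvs >= n_keep:
        raise OCPLSError(
            f"max_lvs={max_lvs} too large for kept-part size {n_keep}"
        )
    rng = np.random.default_rng(seed)
    residuals: list[list[float]] = [[] for _ in range(max_lvs)]
    X = train.intensities
    for _ in range(splits):
        perm = rng.permutation(n)
        hold, keep = perm[:n_hold], perm[n_hold:]
        W, P, Q, T, a_eff = _pls1(X[keep], np.ones(n_keep), max_lvs)
        for a in range(1, max_lvs + 1):
            a_use = min(a, a_eff)
            rot = W[:, :a_use] @ np.linalg.inv(P[:, :a_use].T @ W[:, :a_use])
            coef = rot @ Q[:a_use]
            yhat = X[hold] @ coef
            residuals[a - 1].extend(yhat - 1.0)
    sds = [float(np.std(np.asarray(r), ddof=1)) if len(r) > 1 else float("nan")
           for r in residuals]
    finite = [s for s in sds if np.isfinite(s)]
    if not finite:
        raise OCPLSError("MCCV produced no usable residuals")
    best = min(finite)
    chosen = next(
        a for a, s in enumerate(sds, start=1)
        if np.isfinite(s) and s <= best * (1.0 + tolerance) + 1e-10
    )
    return MCCVCurve(
        lv_grid=list(range(1, max_lvs + 1)),
        residual_sd=sds,
        chosen_A=chosen,
        splits=splits,
        holdout_fraction=holdout_fraction,
        seed=seed,
        tolerance=tolerance,
    )
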