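"""Shapley attribution for the fitted linear decision function.

For a linear model f(x) = w.x + b with an independent-feature background
reference, the Shapley value has the closed form phi_i = w_i (x_i - mean_i of
the background).  A model-agnostic Monte-Carlo permutation estimator with
background-replacement imputation is provided alongside; for linear models it
is an unbiased estimator of the same quantity and serves as the sampling
route, with the closed form as its oracle.  Attribution is computed on the
decision score, not a probability; the background is the training set.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .errors import InvalidInputError

DEFAULT_N_PERMUTATIONS = 2000


def shap_linear_exact(w: np.ndarray, b: float, X: np.ndarray, background: np.ndarray) -> np.ndarray:
    """Exact Shapley values of w.x+b: phi_i = w_i * (x_i - background mean_i)."""
    w = np.asarray(w, dtype=float)
    X_arr = np.asarray(X, dtype=float)
    was_1d = X_arr.ndim == 1
    X2 = np.atleast_2d(X_arr)
    background = np.atleast_2d(np.asarray(background, dtype=float))
    if background.size == 0:
        raise InvalidInputError("background must be nonempty")
    if X2.shape[1] != w.shape[0] or background.shape[1] != w.shape[0]:
        raise InvalidInputError("dimension mismatch between w, X and background")
    phi = w[None, :] * (X2 - background.mean(axis=0)[None, :])
    return phi[0] if was_1d else phi


def shap_sampling(
    f,
    x: np.ndarray,
    background: np.ndarray,
    n_perm: int = DEFAULT_N_PERMUTATIONS,
    seed: int = 0,
) -> np.ndarray:
    """Monte-Carlo permutation Shapley estimate for a single sample.

    For each permutation a background row is drawn; features are switched from
    the background value to x's value in permutation order, and each feature
    is credited with the resulting change in f.  Unbiased for the Shapley
    value of f under the empirical background distribution; deterministic
    given the seed.
    """
    x = np.asarray(x, dtype=float).ravel()
    background = np.atleast_2d(np.asarray(background, dtype=float))
    if background.size == 0:
        raise InvalidInputError("background must be nonempty")
    if n_perm < 1:
        raise InvalidInputError("n_perm must be >= 1")
    d = x.shape[0]
    rng = np.random.default_rng(seed)
    perms = np.argsort(rng.random((n_perm, d)), axis=1)
    bg_rows = background[rng.integers(0, background.shape[0], size=n_perm)]

    # build the n_perm x (d+1) evaluation points in one batch:
    # point k (k>=1) has the first k permuted features replaced by x
    points = np.repeat(bg_rows[:, None, :], d + 1, axis=1)  # (n_perm, d+1, d)
    for k in range(1, d + 1):
        rows = np.arange(n_perm)
        feats = perms[:, :k]
        points[rows[:, None], k, feats] = x[feats]
    vals = np.asarray(f(points.reshape(-1, d))).reshape(n_perm, d + 1)
    deltas = np.diff(vals, axis=1)  # (n_perm, d), delta k belongs to perms[:, k]
    phi = np.zeros(d)
    np.add.at(phi, perms.ravel(), deltas.ravel())
    return phi / n_perm


def shap_matrix(
    w: np.ndarray, b: float, X: pd.DataFrame, background: np.ndarray
) -> pd.DataFrame:
    """Exact attribution for every row of X (columns = features)."""
    phi = shap_linear_exact(np.asarray(w), b, X.to_numpy(), background)
    return pd.DataFrame(np.atleast_2d(phi), index=X.index, columns=X.columns)


def rank_features(shap_values: pd.DataFrame, X: pd.DataFrame | None = None):
    """Features ordered by mean |phi|, plus plot-ready long-format exports.

    Returns (ranking frame, long-format frame for summary/dependence plots).
    """
    if shap_values.shape[0] == 0:
        raise InvalidInputError("empty Shapley matrix")
    ranking = (
        shap_values.abs()
        .mean(axis=0)
        .sort_values(ascending=False)
        .rename("mean_abs_shap")
        .reset_index()
        .rename(columns={"index": "feature"})
    )
    long = shap_values.reset_index(names="patient_id").melt(
        id_vars="patient_id", var_name="feature", value_name="shap_value"
    )
    if X is not None:
        xv = X.reset_index(names="patient_id").melt(
            id_vars="patient_id", var_name="feature", value_name="feature_value"
        )
        long = long.merge(xv, on=["patient_id", "feature"])
    return ranking, long


def force_decomposition(shap_values: pd.DataFrame, base_value: float) -> pd.DataFrame:
    """Per-patient additive decomposition: base value + sum(phi) = f(x)."""
    out = shap_values.copy()
    out.insert(0, "base_value", base_value)
    out["prediction"] = base_value + shap_values.sum(axis=1)
    return out
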