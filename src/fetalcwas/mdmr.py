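"""Multivariate distance matrix regression (MDMR) with permutation inference.

Given a subject x subject dissimilarity matrix D (here Manhattan distances
between connectivity profiles) and a design matrix X, MDMR asks how much of
the between-subject dissimilarity the predictors explain. The squared
distances are double-centered (Gower) into G = -1/2 C (D∘D) C with
C = I - 11'/n; with hat matrix H = X(X'X)^-1 X' and m non-intercept
columns, the omnibus statistic is

    pseudo-F = [tr(HGH)/m] / [tr((I-H)G(I-H))/(n-m-1)],
    pseudo-R2 = tr(HGH)/tr(G).

When D is the Euclidean distance on a univariate response this reduces
exactly to the classical regression F and R2 — the module's primary oracle.
Significance comes from permutations: raw row relabeling for the omnibus
test, and the Freedman-Lane scheme (permuting reduced-model residuals, so
nuisance covariates are conditioned on) for per-factor tests. The
permutation p-value uses the (b+1)/(B+1) estimator, so p >= 1/(B+1).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist

from fetalcwas.exceptions import DesignError, InputError

DEFAULT_PERMUTATIONS = 100_000

OMNIBUS = "omnibus"


@dataclass(frozen=True)
class MDMRResult:
    """Pseudo-F / pseudo-R2 / permutation p for one tested factor."""

    unit: str
    factor: str
    pseudo_f: float
    pseudo_r2: float
    p_perm: float
    n_permutations: int


def manhattan_distances(profiles: np.ndarray) -> np.ndarray:
    """Subject x subject Manhattan (L1) distance matrix.

    ``profiles`` is (n_subjects, n_features); entry [a, b] is
    sum_f |profile_a[f] - profile_b[f]|.
    """
    profiles = np.asarray(profiles, dtype=float)
    if profiles.ndim != 2:
        raise InputError("profiles must be a 2-D (subject x feature) matrix")
    if profiles.shape[0] < 2:
        raise InputError("need at least 2 subjects")
    if not np.all(np.isfinite(profiles)):
        raise InputError("profiles contain missing or non-finite values")
    return cdist(profiles, profiles, metric="cityblock")


def gower_center(d: np.ndarray) -> np.ndarray:
    """Double-centered inner-product matrix G = -1/2 C (D∘D) C."""
    d = np.asarray(d, dtype=float)
    n = d.shape[0]
    if d.shape != (n, n):
        raise InputError("distance matrix must be square")
    a = -0.5 * d * d
    row_means = a.mean(axis=1, keepdims=True)
    col_means = a.mean(axis=0, keepdims=True)
    return a - row_means - col_means + a.mean()


def _hat(x: np.ndarray) -> np.ndarray:
    q, r = np.linalg.qr(x)
    if np.linalg.matrix_rank(r) < x.shape[1]:
        raise DesignError("design matrix is rank deficient")
    return q @ q.T


def _validate_design(x: pd.DataFrame) -> None:
    if "intercept" not in x.columns:
        raise DesignError("design matrix must contain an 'intercept' column")
    mat = x.to_numpy(dtype=float)
    if np.linalg.matrix_rank(mat) < mat.shape[1]:
        raise DesignError("design matrix is rank deficient")


def design_matrix(
    covariates: pd.DataFrame, columns: list[str]
) -> pd.DataFrame:
    """Design with an intercept plus the named covariate columns."""
    missing = [c for c in columns if c not in covariates.columns]
    if missing:
        raise DesignError(f"covariates missing columns: {missing}")
    x = pd.DataFrame({"intercept": np.ones(len(covariates))})
    for c in columns:
        x[c] = covariates[c].to_numpy(dtype=float)
    _validate_design(x)
    return x


def _pseudo_f(tr_hg: float, tr_g: float, m: int, n: int) -> tuple[float, float]:
    resid = tr_g - tr_hg
    df2 = n - m - 1
    if df2 <= 0:
        raise DesignError(f"no residual degrees of freedom (n={n}, m={m})")
    f = (tr_hg / m) / (resid / df2) if resid > 0 else np.inf
    r2 = tr_hg / tr_g if tr_g > 0 else 0.0
    return f, r2


def mdmr_fit(
    d: np.ndarray,
    x: pd.DataFrame,
    factors: list[str] | None = None,
    permutations: int = DEFAULT_PERMUTATIONS,
    seed: int = 0,
    unit: str = "whole_connectome",
) -> list[MDMRResult]:
    """Omnibus and per-factor MDMR tests on one distance matrix.

    Parameters
    ----------
    d : (n, n) distance matrix, rows aligned with ``x``.
    x : design DataFrame containing an ``intercept`` column; every
        non-intercept column enters the model.
    factors : non-intercept columns to test conditionally (Freedman-Lane);
        defaults to all of them.
    permutations : number of row permutations (>= 1).
    seed : RNG seed for the permutation stream.

    Returns the omnibus result first, then one result per factor.
    """
    if permutations < 1:
        raise InputError("permutations must be >= 1")
    d = np.asarray(d, dtype=float)
    n = d.shape[0]
    if x.shape[0] != n:
        raise InputError("design rows are not aligned with the distance matrix")
    _validate_design(x)
    predictors = [c for c in x.columns if c != "intercept"]
    if factors is None:
        factors = predictors
    unknown = [f for f in factors if f not in predictors]
    if unknown:
        raise DesignError(f"factors not in design: {unknown}")
    m = len(predictors)
    g = gower_center(d)
    tr_g = float(np.trace(g))
    xm = x.to_numpy(dtype=float)
    h = _hat(xm)
    tr_hg = float(np.sum(h * g))  # tr(HGH) = tr(HG) since H idempotent
    f_obs, r2_obs = _pseudo_f(tr_hg, tr_g, m, n)

    rng = np.random.default_rng(seed)
    results = []

    # omnibus: raw relabeling of subjects
    exceed = 0
    for _ in range(permutations):
        perm = rng.permutation(n)
        gp = g[np.ix_(perm, perm)]
        f_p, _ = _pseudo_f(float(np.sum(h * gp)), tr_g, m, n)
        if f_p >= f_obs:
            exceed += 1
    p_omni = (1 + exceed) / (permutations + 1)
    results.append(
        MDMRResult(unit, OMNIBUS, f_obs, r2_obs, p_omni, permutations)
    )

    for factor in factors:
        x_red = x.drop(columns=[factor]).to_numpy(dtype=float)
        h_red = _hat(x_red)
        tr_hredg = float(np.sum(h_red * g))
        num_obs = tr_hg - tr_hredg
        den_obs = tr_g - tr_hg
        df2 = n - m - 1
        f_factor = (num_obs / 1.0) / (den_obs / df2) if den_obs > 0 else np.inf
        r2_factor = num_obs / tr_g if tr_g > 0 else 0.0
        resid_proj = np.eye(n) - h_red
        exceed = 0
        for _ in range(permutations):
            perm = rng.permutation(n)
            # Freedman-Lane: permuted outcome = P*residuals + fitted,
            # expressed directly on the Gower matrix
            t = resid_proj[perm] + h_red
            gp = t @ g @ t.T
            tr_gp = float(np.trace(gp))
            tr_hgp = float(np.sum(h * gp))
            num_p = tr_hgp - float(np.sum(h_red * gp))
            den_p = tr_gp - tr_hgp
            f_p = (num_p / 1.0) / (den_p / df2) if den_p > 0 else np.inf
            if f_p >= f_factor:
                exceed += 1
        p_factor = (1 + exceed) / (permutations + 1)
        results.append(
            MDMRResult(unit, factor, f_factor, r2_factor, p_factor, permutations)
        )
    return results


def results_to_frame(results: list[MDMRResult]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "unit": [r.unit for r in results],
            "factor": [r.factor for r in results],
            "pseudo_F": [r.pseudo_f for r in results],
            "pseudo_R2": [r.pseudo_r2 for r in results],
            "p_perm": [r.p_perm for r in results],
            "n_perm": [r.n_permutations for r in results],
        }
    )


def screen_covariates(
    d: np.ndarray,
    covariates: pd.DataFrame,
    candidates: list[str],
    keep_threshold: float = 0.10,
    permutations: int = 999,
    seed: int = 0,
) -> list[str]:
    """Marginal covariate screening for model building.

    Each candidate is tested alone (intercept + candidate) against the
    distance matrix; candidates with marginal omnibus permutation p below
    ``keep_threshold`` are retained. This mirrors the practice of keeping
    only covariates that help explain profile variability.
    """
    kept = []
    for i, c in enumerate(candidates):
        x = design_matrix(covariates, [c])
        res = mdmr_fit(d, x, factors=[], permutations=permutations, seed=seed + i)
        if res[0].p_perm < keep_threshold:
            kept.append(c)
    return kept


def cwas_scan(
    edge_matrix: np.ndarray,
    x: pd.DataFrame,
    mode: str = "whole_connectome",
    factors: list[str] | None = None,
    permutations: int = DEFAULT_PERMUTATIONS,
    seed: int = 0,
    roi_labels: list[str] | None = None,
) -> pd.DataFrame:
    """Connectome-wide MDMR over subjects.

    ``edge_matrix`` is (n_subjects, n_edges) of Fisher-z values in canonical
    upper-triangle order. Mode ``whole_connectome`` runs a single fit on the
    full edge-vector distances; mode ``per_roi`` rebuilds each ROI's
    (n_rois - 1)-feature connectivity profile and fits one MDMR per ROI.
    """
    edge_matrix = np.asarray(edge_matrix, dtype=float)
    n_sub, n_edges = edge_matrix.shape
    if n_sub < 2:
        raise InputError("need at least 2 subjects")
    if mode == "whole_connectome":
        d = manhattan_distances(edge_matrix)
        res = mdmr_fit(d, x, factors, permutations, seed, unit="whole_connectome")
        return results_to_frame(res)
    if mode != "per_roi":
        raise InputError(f"unknown mode {mode!r}")
    n_rois = int(round((1 + np.sqrt(1 + 8 * n_edges)) / 2))
    if n_rois * (n_rois - 1) // 2 != n_edges:
        raise InputError(f"edge count {n_edges} is not C(n,2) for any n")
    if roi_labels is None:
        roi_labels = [f"ROI{k + 1:03d}" for k in range(n_rois)]
    iu, ju = np.triu_indices(n_rois, k=1)
    all_results = []
    for k in range(n_rois):
        cols = np.flatnonzero((iu == k) | (ju == k))
        d = manhattan_distances(edge_matrix[:, cols])
        res = mdmr_fit(d, x, factors, permutations, seed + k, unit=roi_labels[k])
        all_results.extend(res)
    return results_to_frame(all_results)
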