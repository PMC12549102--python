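"""Network-pair enrichment of edge-behavior correlations.

Each of the C(n_rois, 2) edges is screened by the Pearson correlation of
its Fisher-z connectivity with a behavior score across subjects (two-tailed
t-test, p < alpha marks a "strong" association; no multiple-testing
correction at the edge level). Edges are then grouped into network pairs —
the K(K+1)/2 unordered module pairs including within-module pairs — and a
1-df chi-square test asks, per pair, whether it holds more strong
associations than expected if those associations were spread uniformly over
all edges. Enrichment is one-sided: only over-representation counts.

Because the chi-square's asymptotic reference is unreliable for sparse
counts, significance comes from a permutation null in which the behavior
score is shuffled and the *entire* screening-plus-counting pipeline is
re-run per permutation.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from fetalcwas.communities import ModulePartition
from fetalcwas.exceptions import DegenerateInputError, InputError

DEFAULT_ALPHA = 0.05
DEFAULT_PERMUTATIONS = 1000


def _edge_correlations(edge_matrix: np.ndarray, behavior: np.ndarray) -> np.ndarray:
    """Pearson r of each edge column with the behavior vector (vectorized)."""
    y = behavior - behavior.mean()
    x = edge_matrix - edge_matrix.mean(axis=0, keepdims=True)
    denom = np.sqrt((x * x).sum(axis=0) * (y * y).sum())
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (x.T @ y) / denom
    return np.clip(np.nan_to_num(r), -1.0, 1.0)


def correlation_pvalues(r: np.ndarray, n: int) -> np.ndarray:
    """Two-tailed p from the t distribution with n-2 df."""
    r = np.asarray(r, dtype=float)
    with np.errstate(divide="ignore"):
        t = r * np.sqrt(n - 2) / np.sqrt(1.0 - r * r)
    return 2.0 * stats.t.sf(np.abs(t), df=n - 2)


def edge_behavior_correlations(
    edge_matrix: np.ndarray,
    behavior: np.ndarray,
    edge_index: list[tuple[str, str]],
    alpha: float = DEFAULT_ALPHA,
) -> pd.DataFrame:
    """Per-edge correlation screen against one behavior score.

    Returns a DataFrame with columns roi_i, roi_j, r, p, significant,
    direction (sign of r).
    """
    edge_matrix = np.asarray(edge_matrix, dtype=float)
    behavior = np.asarray(behavior, dtype=float)
    n = edge_matrix.shape[0]
    if behavior.shape != (n,):
        raise InputError("behavior length does not match subject count")
    if n < 4:
        raise InputError("need at least 4 subjects for the edge screen")
    if np.ptp(behavior) == 0:
        raise DegenerateInputError("behavior score is constant across subjects")
    if edge_matrix.shape[1] != len(edge_index):
        raise InputError("edge matrix width does not match the edge index")
    r = _edge_correlations(edge_matrix, behavior)
    p = correlation_pvalues(r, n)
    return pd.DataFrame(
        {
            "roi_i": [e[0] for e in edge_index],
            "roi_j": [e[1] for e in edge_index],
            "r": r,
            "p": p,
            "significant": p < alpha,
            "direction": np.sign(r).astype(int),
        }
    )


def edge_pair_ids(
    edge_index: list[tuple[str, str]],
    partition: ModulePartition,
    roi_labels: list[str],
) -> tuple[np.ndarray, pd.DataFrame]:
    """Map each edge to its unordered network pair.

    Returns (pair_id per edge, pair table with module_a <= module_b and
    n_edges per pair). All K(K+1)/2 pairs appear in the table, including
    pairs that happen to contain no edges.
    """
    label_to_module = dict(zip(roi_labels, partition.assignment))
    missing = {l for e in edge_index for l in e} - set(roi_labels)
    if missing:
        raise InputError(f"edges reference ROIs absent from the partition: {sorted(missing)}")
    k = partition.n_modules
    pairs = [(a, b) for a in range(1, k + 1) for b in range(a, k + 1)]
    pair_lookup = {p: i for i, p in enumerate(pairs)}
    ids = np.empty(len(edge_index), dtype=int)
    for idx, (ri, rj) in enumerate(edge_index):
        ma, mb = label_to_module[ri], label_to_module[rj]
        ids[idx] = pair_lookup[(min(ma, mb), max(ma, mb))]
    table = pd.DataFrame(
        {
            "module_a": [p[0] for p in pairs],
            "module_b": [p[1] for p in pairs],
            "n_edges": np.bincount(ids, minlength=len(pairs)),
        }
    )
    return ids, table


def _chi2_per_pair(
    sig_counts: np.ndarray, n_edges: np.ndarray, total_sig: int, total_edges: int
) -> np.ndarray:
    """Vectorized 1-df Pearson chi-square (no continuity correction).

    2x2 table per pair: in-pair/out-pair x significant/not. Pairs with no
    edges (or degenerate margins) get chi2 = 0.
    """
    a = sig_counts.astype(float)
    row1 = n_edges.astype(float)  # a + c
    s = float(total_sig)
    e = float(total_edges)
    with np.errstate(invalid="ignore", divide="ignore"):
        d = (e - row1) - (s - a)
        num = e * (a * d - (s - a) * (row1 - a)) ** 2
        den = s * (e - s) * row1 * (e - row1)
        chi2 = np.where(den > 0, num / den, 0.0)
    return chi2


def pair_chi2(
    stats_table: pd.DataFrame,
    partition: ModulePartition,
    roi_labels: list[str],
) -> pd.DataFrame:
    """Observed enrichment table across all network pairs.

    Columns: module_a, module_b, n_edges, observed_significant,
    expected_significant, chi2, enriched (observed > expected).
    """
    edge_index = list(zip(stats_table["roi_i"], stats_table["roi_j"]))
    ids, table = edge_pair_ids(edge_index, partition, roi_labels)
    sig = stats_table["significant"].to_numpy(dtype=bool)
    total_edges = len(edge_index)
    total_sig = int(sig.sum())
    observed = np.bincount(ids[sig], minlength=len(table))
    n_edges = table["n_edges"].to_numpy()
    expected = total_sig * n_edges / total_edges
    chi2 = _chi2_per_pair(observed, n_edges, total_sig, total_edges)
    table = table.copy()
    table["observed_significant"] = observed
    table["expected_significant"] = expected
    table["chi2"] = chi2
    table["enriched"] = observed > expected
    return table


def enrichment_permutation(
    edge_matrix: np.ndarray,
    behavior: np.ndarray,
    partition: ModulePartition,
    edge_index: list[tuple[str, str]],
    roi_labels: list[str],
    permutations: int = DEFAULT_PERMUTATIONS,
    alpha: float = DEFAULT_ALPHA,
    seed: int = 0,
) -> pd.DataFrame:
    """Enrichment table with permutation p-values.

    Per permutation the behavior score is shuffled and the full edge screen
    and per-pair chi-square are recomputed. The test is one-sided: the
    working statistic is chi2 when a pair is over-represented and 0
    otherwise, and p_perm = (1 + #{permuted stat >= observed stat}) /
    (permutations + 1). Pairs with observed <= expected are never called
    enriched (their p_perm is reported as 1).
    """
    if permutations < 1:
        raise InputError("permutations must be >= 1")
    edge_matrix = np.asarray(edge_matrix, dtype=float)
    behavior = np.asarray(behavior, dtype=float)
    n = edge_matrix.shape[0]
    stats_table = edge_behavior_correlations(edge_matrix, behavior, edge_index, alpha)
    observed_table = pair_chi2(stats_table, partition, roi_labels)
    ids, _ = edge_pair_ids(edge_index, partition, roi_labels)
    n_pairs = len(observed_table)
    n_edges = observed_table["n_edges"].to_numpy()
    total_edges = len(edge_index)
    obs_stat = np.where(
        observed_table["enriched"].to_numpy(), observed_table["chi2"].to_numpy(), 0.0
    )
    rng = np.random.default_rng(seed)
    exceed = np.zeros(n_pairs)
    for _ in range(permutations):
        perm_scores = rng.permutation(behavior)
        r = _edge_correlations(edge_matrix, perm_scores)
        p = correlation_pvalues(r, n)
        sig = p < alpha
        total_sig = int(sig.sum())
        counts = np.bincount(ids[sig], minlength=n_pairs)
        expected = total_sig * n_edges / total_edges
        chi2 = _chi2_per_pair(counts, n_edges, total_sig, total_edges)
        perm_stat = np.where(counts > expected, chi2, 0.0)
        exceed += perm_stat >= obs_stat
    p_perm = (1 + exceed) / (permutations + 1)
    p_perm[obs_stat == 0] = 1.0
    out = observed_table.copy()
    out["p_perm"] = p_perm
    out["n_perm"] = permutations
    return out
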