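"""Subject-level functional connectomes.

A connectome is the ROI x ROI matrix of pairwise Pearson correlations of the
retained BOLD volumes, Fisher-z transformed (atanh) to stabilise variance.
All downstream stages work either on the symmetric z matrix or on its
canonical upper-triangle vectorization: for 100 ROIs that is the familiar
4950-element edge vector.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from fetalcwas.exceptions import DegenerateInputError, InputError

#: |r| is clipped to this before atanh so z stays finite for perfect
#: correlations; the shift is ~8 z units, far beyond any real edge.
R_CLIP = 1.0 - 1e-7

_SYMMETRY_TOL = 1e-10


@dataclass
class Connectome:
    """Symmetric Fisher-z connectivity matrix for one scan."""

    scan_id: str
    z_matrix: np.ndarray
    roi_labels: list[str]

    def __post_init__(self) -> None:
        self.z_matrix = np.asarray(self.z_matrix, dtype=float)
        n = len(self.roi_labels)
        if self.z_matrix.shape != (n, n):
            raise InputError(
                f"z_matrix shape {self.z_matrix.shape} does not match "
                f"{n} ROI labels"
            )
        if not np.allclose(self.z_matrix, self.z_matrix.T, atol=_SYMMETRY_TOL):
            raise InputError("z_matrix is not symmetric")

    @property
    def n_rois(self) -> int:
        return len(self.roi_labels)


@dataclass
class EdgeVector:
    """Upper-triangle (i<j, row-major) vectorization of a connectome."""

    scan_id: str
    values: np.ndarray
    edge_index: list[tuple[str, str]] = field(repr=False)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if len(self.values) != len(self.edge_index):
            raise InputError("edge vector length does not match edge index")


def canonical_edge_index(roi_labels: Sequence[str]) -> list[tuple[str, str]]:
    """Row-major upper-triangle (i<j) pair ordering shared by all modules."""
    n = len(roi_labels)
    iu, ju = np.triu_indices(n, k=1)
    return [(roi_labels[i], roi_labels[j]) for i, j in zip(iu, ju)]


def pearson_connectome(
    timeseries: np.ndarray, mask: np.ndarray | None = None
) -> np.ndarray:
    """Pearson correlation matrix over the retained volumes.

    Parameters
    ----------
    timeseries : (n_rois, n_volumes) array of BOLD signals.
    mask : optional per-volume boolean keep mask; only retained volumes
        enter the correlation.

    Returns
    -------
    (n_rois, n_rois) symmetric correlation matrix with unit diagonal.
    """
    ts = np.asarray(timeseries, dtype=float)
    if ts.ndim != 2:
        raise InputError("timeseries must be a 2-D (ROI x volume) matrix")
    if mask is not None:
        mask = np.asarray(mask, dtype=bool)
        if mask.shape != (ts.shape[1],):
            raise InputError(
                f"mask length {mask.shape} does not match {ts.shape[1]} volumes"
            )
        ts = ts[:, mask]
    if ts.shape[1] < 3:
        raise InputError(
            f"need at least 3 retained volumes, got {ts.shape[1]}"
        )
    sd = ts.std(axis=1)
    constant = np.flatnonzero(sd == 0)
    if constant.size:
        raise DegenerateInputError(
            f"constant time series for ROI indices {constant.tolist()}"
        )
    r = np.corrcoef(ts)
    np.fill_diagonal(r, 1.0)
    return (r + r.T) / 2.0


def fisher_z(r):
    """Variance-stabilising Fisher transform z = atanh(r).

    |r| is clipped to ``R_CLIP`` first so that perfect correlations map to a
    large finite z rather than infinity. Raises for |r| > 1.
    """
    r = np.asarray(r, dtype=float)
    if np.any(np.abs(r) > 1):
        raise InputError("correlations must satisfy |r| <= 1")
    z = np.arctanh(np.clip(r, -R_CLIP, R_CLIP))
    return z if z.ndim else float(z)


def build_connectome(
    timeseries: np.ndarray,
    roi_labels: Sequence[str],
    mask: np.ndarray | None = None,
    scan_id: str = "scan",
) -> Connectome:
    """Pearson -> Fisher-z connectome with zeroed diagonal."""
    r = pearson_connectome(timeseries, mask)
    z = fisher_z(r)
    np.fill_diagonal(z, 0.0)  # self-edges are excluded downstream
    return Connectome(scan_id=scan_id, z_matrix=z, roi_labels=list(roi_labels))


def vectorize_edges(c: Connectome) -> EdgeVector:
    """Upper-triangle edge vector in the canonical (i<j) ordering."""
    iu, ju = np.triu_indices(c.n_rois, k=1)
    return EdgeVector(
        scan_id=c.scan_id,
        values=c.z_matrix[iu, ju],
        edge_index=canonical_edge_index(c.roi_labels),
    )


def devectorize_edges(
    v: EdgeVector | np.ndarray, roi_labels: Sequence[str]
) -> np.ndarray:
    """Inverse of :func:`vectorize_edges` (diagonal set to 0)."""
    values = v.values if isinstance(v, EdgeVector) else np.asarray(v, float)
    n = len(roi_labels)
    if len(values) != n * (n - 1) // 2:
        raise InputError(
            f"edge vector length {len(values)} is not C({n},2)"
        )
    z = np.zeros((n, n))
    iu, ju = np.triu_indices(n, k=1)
    z[iu, ju] = values
    z[ju, iu] = values
    return z


def roi_profile(c: Connectome, roi: str) -> np.ndarray:
    """Connectivity profile: z values linking `roi` to every other ROI.

    Returned in canonical label order with the self-entry dropped, so the
    profile has length n_rois - 1.
    """
    try:
        k = c.roi_labels.index(roi)
    except ValueError:
        raise InputError(f"unknown ROI label: {roi!r}") from None
    row = c.z_matrix[k]
    return np.delete(row, k)


def connectome_to_frame(c: Connectome) -> pd.DataFrame:
    """Square labelled DataFrame for CSV output."""
    return pd.DataFrame(c.z_matrix, index=c.roi_labels, columns=c.roi_labels)


def edges_to_frame(v: EdgeVector, r_values: np.ndarray | None = None) -> pd.DataFrame:
    """Long-format edge table (roi_i, roi_j, z [, r])."""
    df = pd.DataFrame(v.edge_index, columns=["roi_i", "roi_j"])
    if r_values is not None:
        df["r"] = np.asarray(r_values, dtype=float)
    df["z"] = v.values
    return df
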