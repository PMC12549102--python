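"""Shared helpers for the test suite."""

import numpy as np

from fetalcwas import connectome


def build_edge_matrix(cohort, labels):
    """Stack a cohort's Fisher-z edge vectors (no censoring applied)."""
    vectors = [
        connectome.vectorize_edges(
            connectome.build_connectome(s.timeseries, labels, scan_id=s.scan_id)
        )
        for s in cohort.scans
    ]
    return np.stack([v.values for v in vectors]), vectors[0].edge_index
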