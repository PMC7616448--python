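"""Normalization and neuronal-marker cell filtering."""

from __future__ import annotations

import logging

import numpy as np
import scipy.sparse as sp

from .data import CountMatrix, GeneSet

logger = logging.getLogger(__name__)

#: Markers used to retain neuronal nuclei (pan-neuronal transcripts).
NEURONAL_MARKERS = GeneSet(name="neuronal_markers", symbols=("Meg3", "Rbfox3", "Snap25"))


def log_normalize(matrix: CountMatrix, scale: float = 1e4) -> CountMatrix:
    """Library-size normalize and log-transform: ``ln(1 + count / total * scale)``.

    ``total`` is the cell's raw count sum; cells with zero total keep an
    all-zero normalized column. Returns a new :class:`CountMatrix` carrying
    the normalized layer; raw counts are unchanged.
    """
    if scale <= 0:
        raise ValueError("scale must be positive")
    counts = matrix.counts.tocsc().astype(np.float64)
    totals = np.asarray(counts.sum(axis=0)).ravel()
    factors = np.zeros_like(totals)
    nonzero = totals > 0
    factors[nonzero] = scale / totals[nonzero]
    normalized = counts @ sp.diags(factors)
    np.log1p(normalized.data, out=normalized.data)
    return CountMatrix(
        gene_symbols=list(matrix.gene_symbols),
        cell_ids=list(matrix.cell_ids),
        counts=matrix.counts,
        normalized=normalized.tocsr(),
        norm_scale=scale,
    )


def filter_neuronal(
    matrix: CountMatrix,
    markers: GeneSet = NEURONAL_MARKERS,
    min_markers_detected: int = 1,
) -> CountMatrix:
    """Retain cells detecting (raw count > 0) at least ``min_markers_detected`` markers.

    Marker symbols absent from the matrix are ignored with a warning; if none
    of the markers is present the filter is unconfigurable and raises.
    The gene axis is unchanged; the operation is idempotent.
    """
    present = markers.present_in(matrix)
    missing = [s for s in markers if s not in present]
    if missing:
        logger.warning("markers absent from matrix, ignored: %s", ", ".join(missing))
    if not present:
        raise ValueError(f"none of the marker genes {list(markers)} is present in the matrix")
    if min_markers_detected < 0:
        raise ValueError("min_markers_detected must be >= 0")
    rows = matrix.gene_indices(present)
    detected = np.asarray((matrix.counts[rows] > 0).sum(axis=0)).ravel()
    keep = detected >= min_markers_detected
    return matrix.subset_cells(keep)
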