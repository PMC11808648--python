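"""Fixed-radius pair search shared by the contact, RDF and energy modules.

A k-d tree prunes the candidate set; candidates are then re-filtered with a
strict ``d < cutoff`` comparison so ties at exactly the cutoff never count
(the contact definition is a strict inequality).  When an orthorhombic box
is supplied, distances follow the minimum-image convention.
"""

from __future__ import annotations

from typing import Optional, Tuple

import numpy as np
from scipy.spatial import cKDTree

from .model import ConfigurationError


def _wrap(coords: np.ndarray, box: np.ndarray) -> np.ndarray:
    return np.mod(coords, box)


def minimum_image_distances(
    a: np.ndarray, b: np.ndarray, box: Optional[np.ndarray]
) -> np.ndarray:
    """Row-wise distances between paired coordinates."""
    d = a - b
    if box is not None:
        d -= box * np.round(d / box)
    return np.linalg.norm(d, axis=-1)


def pairs_within(
    coords_a: np.ndarray,
    coords_b: np.ndarray,
    cutoff: float,
    box: Optional[np.ndarray] = None,
    strict: bool = True,
) -> Tuple[np.ndarray, np.ndarray, np.ndarray]:
    """All (i, j, d) with ``d(a_i, b_j) < cutoff`` (``<=`` if not strict).

    Indices are positions within ``coords_a`` / ``coords_b``.
    """
    if cutoff <= 0:
        raise ConfigurationError("cutoff must be positive")
    coords_a = np.asarray(coords_a, dtype=np.float64)
    coords_b = np.asarray(coords_b, dtype=np.float64)
    if coords_a.size == 0 or coords_b.size == 0:
        empty = np.empty(0, dtype=np.int64)
        return empty, empty, np.empty(0, dtype=np.float64)
    if box is not None:
        box = np.asarray(box, dtype=np.float64)
        if np.any(cutoff >= box / 2):
            raise ConfigurationError(
                "cutoff must be smaller than half the shortest box length "
                "for minimum-image pair search"
            )
        tree_a = cKDTree(_wrap(coords_a, box), boxsize=box)
        tree_b = cKDTree(_wrap(coords_b, box), boxsize=box)
    else:
        tree_a = cKDTree(coords_a)
        tree_b = cKDTree(coords_b)
    sdm = tree_a.sparse_distance_matrix(tree_b, cutoff, output_type="coo_matrix")
    i, j, d = sdm.row.astype(np.int64), sdm.col.astype(np.int64), sdm.data
    keep = d < cutoff if strict else d <= cutoff
    return i[keep], j[keep], d[keep]
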