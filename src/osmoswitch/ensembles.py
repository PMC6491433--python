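"""Descriptors applied to conformational ensembles.

These are the quantities used to characterize heterogeneity in simulation
snapshots: convex-hull volume as a proxy for overall molecular size,
per-residue contact probability, and pairwise Calpha-Calpha distance
distributions (e.g. for the Tyr40-Trp67 FRET pair analog).
"""

from __future__ import annotations

import numpy as np
from scipy.spatial import ConvexHull, QhullError
from scipy.spatial.distance import cdist

from .datatypes import Ensemble

__all__ = ["ensemble_volume", "contact_probability", "distance_distribution"]


def ensemble_volume(conformation) -> float:
    """Convex-hull volume (A^3) of one conformation's coordinates."""
    xyz = np.asarray(conformation, dtype=float)
    if xyz.ndim != 2 or xyz.shape[1] != 3 or xyz.shape[0] < 4:
        raise ValueError("need at least 4 points in 3-D")
    try:
        return float(ConvexHull(xyz).volume)
    except QhullError as err:
        raise ValueError(f"degenerate geometry (coplanar points?): {err}") from err


def contact_probability(ens: Ensemble, residue_index: int,
                        cutoff_A: float = 8.0) -> float:
    """Mean fraction of other residues within ``cutoff_A`` of the query.

    The contact definition (Calpha-Calpha distance below the cutoff,
    averaged first over partner residues, then over ensemble members) is
    part of the returned quantity's meaning and is fixed here.
    """
    if cutoff_A <= 0:
        raise ValueError("cutoff must be positive")
    qi = ens.index_of(residue_index)
    fracs = []
    for m in ens.members:
        d = np.linalg.norm(m - m[qi], axis=1)
        d = np.delete(d, qi)
        fracs.append(np.mean(d < cutoff_A))
    return float(np.mean(fracs))


def distance_distribution(ens: Ensemble, residue_a: int,
                          residue_b: int) -> np.ndarray:
    """Per-member Calpha-Calpha distance (A) between two residues."""
    ia, ib = ens.index_of(residue_a), ens.index_of(residue_b)
    return np.array([float(np.linalg.norm(m[ia] - m[ib])) for m in ens.members])
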