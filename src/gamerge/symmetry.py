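"""Laue-group symmetry and reduction of Miller indices to an asymmetric unit.

Merging statistics compare symmetry-equivalent observations, so every Miller
index is first mapped to a canonical representative of its orbit under the
Laue group (the point group of the diffraction pattern, which always contains
inversion).  The canonical representative is the lexicographically greatest
(h, k, l) over the full orbit; this rule is deterministic and independent of
input order.

When Friedel's law is not assumed (anomalous data), each observation keeps a
Friedel sign recording whether the symmetry operation that produced the
canonical index involved inversion (-1) or not (+1), so that I+ and I- can be
merged separately downstream.

Rotation matrices are taken from gemmi's space-group tables; the Laue group is
the closure of the point-group rotations under inversion.
"""

from __future__ import annotations

from functools import lru_cache

import gemmi
import numpy as np

__all__ = ["laue_operations", "laue_group_symbol", "reduce_indices", "UnsupportedSymmetryError"]

# Laue classes covered by the built-in reduction; arbitrary space-group
# numbers within these classes are accepted via gemmi's tables.
SUPPORTED_LAUE_CLASSES = ("-1", "2/m", "mmm", "-3", "-3m", "4/m", "4/mmm", "6/m", "6/mmm", "m-3", "m-3m")


class UnsupportedSymmetryError(ValueError):
    pass


def _spacegroup(space_group_number: int) -> gemmi.SpaceGroup:
    sg = gemmi.find_spacegroup_by_number(space_group_number)
    if sg is None:
        raise UnsupportedSymmetryError(
            f"unknown space-group number {space_group_number}; "
            f"supported Laue classes: {', '.join(SUPPORTED_LAUE_CLASSES)}"
        )
    return sg


def laue_group_symbol(space_group_number: int) -> str:
    """Hermann–Mauguin symbol of the Laue class of a space group."""
    return _spacegroup(space_group_number).laue_str()


@lru_cache(maxsize=None)
def laue_operations(space_group_number: int) -> np.ndarray:
    """Integer rotation matrices of the Laue group, shape (n_ops, 3, 3).

    The set is closed under multiplication and contains -I.  Raises
    :class:`UnsupportedSymmetryError` for symbols outside the supported
    Laue classes.
    """
    sg = _spacegroup(space_group_number)
    if sg.laue_str() not in SUPPORTED_LAUE_CLASSES:
        raise UnsupportedSymmetryError(
            f"space group {space_group_number} ({sg.hm}) has unsupported Laue class "
            f"{sg.laue_str()}; supported: {', '.join(SUPPORTED_LAUE_CLASSES)}"
        )
    den = gemmi.Op.DEN
    rots = {tuple(tuple(int(x) // den for x in row) for row in op.rot) for op in sg.operations()}
    # closure under inversion gives the Laue group
    rots |= {tuple(tuple(-x for x in row) for row in r) for r in rots}
    ops = np.array(sorted(rots), dtype=np.int64)
    return ops


def reduce_indices(
    hkl: np.ndarray, space_group_number: int, friedel_law: bool = True
) -> tuple[np.ndarray, np.ndarray]:
    """Map each index to the canonical asymmetric-unit representative.

    Parameters
    ----------
    hkl : (n, 3) integer array of Miller indices.
    space_group_number : space group of the data.
    friedel_law : when True, Friedel signs are not tracked (all 0); when
        False the sign records whether the reducing operation included
        inversion (+1 no, -1 yes).

    Returns
    -------
    (reduced, friedel_sign) : (n, 3) int array and (n,) int array.

    The representative is the lexicographically greatest equivalent over the
    full Laue orbit (inversion included).  For centric reflections, where the
    representative is reachable both with and without inversion, the sign is
    reported as +1.
    """
    hkl = np.asarray(hkl, dtype=np.int64)
    if hkl.ndim != 2 or hkl.shape[1] != 3:
        raise ValueError("hkl must have shape (n, 3)")
    laue = laue_operations(space_group_number)
    # point-group rotations (no inversion): the half of the Laue group
    # reachable without -I; identified by pairing each op with its negative.
    sg = _spacegroup(space_group_number)
    den = gemmi.Op.DEN
    proper = {tuple(tuple(int(x) // den for x in row) for row in op.rot) for op in sg.operations()}
    signs_per_op = np.array(
        [1 if tuple(tuple(int(x) for x in row) for row in op) in proper else -1 for op in laue],
        dtype=np.int64,
    )

    # orbit[o, n, 3] = hkl @ op_o  (row-vector convention: h' = h R, the
    # transformation of Miller indices under a real-space rotation R)
    orbit = np.einsum("oji,nj->oni", laue, hkl)
    # lexicographic argmax via a scalar key; indices are bounded so base fits
    m = int(np.abs(hkl).max(initial=0)) + 1
    base = 2 * m + 1
    key = (orbit[..., 0] * base + orbit[..., 1]) * base + orbit[..., 2]
    # prefer sign +1 on ties (centric reflections): stable argmax over ops
    # ordered with proper ops first
    order = np.argsort(-signs_per_op, kind="stable")
    key = key[order]
    orbit = orbit[order]
    signs_per_op = signs_per_op[order]
    best = np.argmax(key, axis=0)
    n = hkl.shape[0]
    reduced = orbit[best, np.arange(n), :]
    if friedel_law:
        friedel_sign = np.zeros(n, dtype=np.int64)
    else:
        friedel_sign = signs_per_op[best]
        # centric reflections: the canonical index is reachable without
        # inversion as well; argmax with proper ops first already yields +1
    return reduced, friedel_sign
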