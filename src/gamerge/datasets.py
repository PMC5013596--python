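"""Sub-data-set container and XDS_ASCII-dialect I/O.

A *sub-data set* is a small oscillation wedge integrated from one crystal (or
one position on a crystal): a partial list of unmerged intensity observations
plus the cell and symmetry metadata needed to merge it with others.

Observations are stored column-wise in numpy arrays for speed; the
:class:`ReflectionObservation` record view is provided for convenience and
testing.

The file dialect is the XDS_ASCII.HKL subset this tool needs: ``!``-prefixed
header lines carrying ``SPACE_GROUP_NUMBER``, ``UNIT_CELL_CONSTANTS`` and
``FRIEDEL'S_LAW``, whitespace-separated records with at least
``H K L IOBS SIGMA(IOBS)`` columns, and an ``!END_OF_DATA`` terminator.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, NamedTuple, Sequence

import numpy as np

from .cell import UnitCell
from .symmetry import reduce_indices

logger = logging.getLogger(__name__)

__all__ = [
    "ReflectionObservation",
    "SubDataset",
    "XdsFormatError",
    "EmptyDatasetError",
    "read_xds_ascii",
    "write_xds_ascii",
    "reduce_to_asu",
    "validate_pool",
]


class XdsFormatError(ValueError):
    """Missing or garbled header/record in an XDS_ASCII-dialect file."""


class EmptyDatasetError(ValueError):
    """No surviving observation records after filtering."""


class ReflectionObservation(NamedTuple):
    """One measured intensity (record view onto SubDataset arrays)."""

    h: int
    k: int
    l: int
    hr: int
    kr: int
    lr: int
    intensity: float
    sigma: float
    friedel_sign: int
    subset_id: str


@dataclass
class SubDataset:
    """One sub-data set: metadata plus column-wise observation arrays.

    ``hkl`` is the original index as integrated, ``hkl_red`` the asymmetric-
    unit representative (filled by :func:`reduce_to_asu`; ``None`` before).
    """

    id: str
    cell: UnitCell
    space_group_number: int
    friedel_law: bool
    hkl: np.ndarray  # (n, 3) int
    intensity: np.ndarray  # (n,) float
    sigma: np.ndarray  # (n,) float
    hkl_red: np.ndarray | None = None  # (n, 3) int after reduction
    friedel_sign: np.ndarray | None = None  # (n,) int in {-1, 0, +1}
    source_path: str = ""
    n_dropped: int = 0

    def __post_init__(self) -> None:
        self.hkl = np.asarray(self.hkl, dtype=np.int64)
        self.intensity = np.asarray(self.intensity, dtype=np.float64)
        self.sigma = np.asarray(self.sigma, dtype=np.float64)
        if len(self.hkl) == 0:
            raise EmptyDatasetError(f"sub-data set {self.id!r} has no observations")
        if np.any(self.sigma <= 0):
            raise ValueError("all stored sigmas must be positive (filter at read time)")

    def __len__(self) -> int:
        return len(self.intensity)

    @property
    def reduced(self) -> bool:
        return self.hkl_red is not None

    @property
    def observations(self) -> Iterator[ReflectionObservation]:
        red = self.hkl_red if self.reduced else np.zeros_like(self.hkl)
        fs = self.friedel_sign if self.friedel_sign is not None else np.zeros(len(self), dtype=int)
        for i in range(len(self)):
            yield ReflectionObservation(
                *map(int, self.hkl[i]),
                *map(int, red[i]),
                float(self.intensity[i]),
                float(self.sigma[i]),
                int(fs[i]),
                self.id,
            )

    def d_spacings(self) -> np.ndarray:
        """Resolution of every observation (Å), from the reduced index if present."""
        idx = self.hkl_red if self.reduced else self.hkl
        return self.cell.d_spacing(idx)


_REQUIRED_HEADER = {
    "space_group": "!SPACE_GROUP_NUMBER=",
    "cell": "!UNIT_CELL_CONSTANTS=",
    "friedel": "!FRIEDEL'S_LAW=",
}


def read_xds_ascii(path: str | Path, subset_id: str | None = None) -> SubDataset:
    """Read one sub-data set from an XDS_ASCII-dialect file.

    Records with sigma <= 0 are dropped (and counted in ``n_dropped``);
    indices are *not* reduced — call :func:`reduce_to_asu` afterwards.
    """
    path = Path(path)
    space_group = None
    cell = None
    friedel = None
    hkl: list[tuple[int, int, int]] = []
    intensity: list[float] = []
    sigma: list[float] = []
    n_dropped = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line:
                continue
            if line.startswith("!"):
                if line.startswith(_REQUIRED_HEADER["space_group"]):
                    try:
                        space_group = int(line.split("=", 1)[1].split()[0])
                    except (ValueError, IndexError) as exc:
                        raise XdsFormatError(f"{path}:{lineno}: garbled SPACE_GROUP_NUMBER") from exc
                elif line.startswith(_REQUIRED_HEADER["cell"]):
                    try:
                        vals = [float(x) for x in line.split("=", 1)[1].split()]
                        cell = UnitCell(*vals)
                    except (ValueError, TypeError) as exc:
                        raise XdsFormatError(f"{path}:{lineno}: garbled UNIT_CELL_CONSTANTS") from exc
                elif line.startswith(_REQUIRED_HEADER["friedel"]):
                    token = line.split("=", 1)[1].strip().upper()
                    if token not in ("TRUE", "FALSE"):
                        raise XdsFormatError(f"{path}:{lineno}: FRIEDEL'S_LAW must be TRUE or FALSE")
                    friedel = token == "TRUE"
                elif line.startswith("!END_OF_DATA"):
                    break
                continue
            parts = line.split()
            if len(parts) < 5:
                raise XdsFormatError(
                    f"{path}:{lineno}: record needs at least H K L IOBS SIGMA(IOBS), got {len(parts)} columns"
                )
            try:
                h, k, l = int(parts[0]), int(parts[1]), int(parts[2])
                iobs, sig = float(parts[3]), float(parts[4])
            except ValueError as exc:
                raise XdsFormatError(f"{path}:{lineno}: unparsable record {line!r}") from exc
            if sig <= 0:
                n_dropped += 1
                continue
            hkl.append((h, k, l))
            intensity.append(iobs)
            sigma.append(sig)
    for name, prefix in _REQUIRED_HEADER.items():
        value = {"space_group": space_group, "cell": cell, "friedel": friedel}[name]
        if value is None:
            raise XdsFormatError(f"{path}: missing required header field {prefix}")
    if n_dropped:
        logger.warning("%s: dropped %d record(s) with sigma <= 0", path, n_dropped)
    if not hkl:
        raise EmptyDatasetError(f"{path}: no records with sigma > 0")
    return SubDataset(
        id=subset_id if subset_id is not None else path.stem,
        cell=cell,
        space_group_number=space_group,
        friedel_law=friedel,
        hkl=np.array(hkl, dtype=np.int64),
        intensity=np.array(intensity),
        sigma=np.array(sigma),
        source_path=str(path),
        n_dropped=n_dropped,
    )


def write_xds_ascii(ds: SubDataset, path: str | Path) -> None:
    """Write a sub-data set in the same dialect :func:`read_xds_ascii` reads.

    Floats are written with shortest round-trip repr so a write/read cycle
    preserves every field bit-exactly.
    """
    path = Path(path)
    lines = [
        "!FORMAT=XDS_ASCII    MERGE=FALSE    FRIEDEL'S_LAW=" + ("TRUE" if ds.friedel_law else "FALSE"),
        f"!SPACE_GROUP_NUMBER= {ds.space_group_number}",
        "!UNIT_CELL_CONSTANTS= {} {} {} {} {} {}".format(
            ds.cell.a, ds.cell.b, ds.cell.c, ds.cell.alpha, ds.cell.beta, ds.cell.gamma
        ),
        "!FRIEDEL'S_LAW= " + ("TRUE" if ds.friedel_law else "FALSE"),
        "!ITEM_H=1",
        "!ITEM_K=2",
        "!ITEM_L=3",
        "!ITEM_IOBS=4",
        "!ITEM_SIGMA(IOBS)=5",
        "!END_OF_HEADER",
    ]
    for (h, k, l), iobs, sig in zip(ds.hkl, ds.intensity, ds.sigma):
        # shortest round-trip repr keeps write->read bit-exact
        lines.append(f"{int(h)} {int(k)} {int(l)} {float(iobs)!r} {float(sig)!r}")
    lines.append("!END_OF_DATA")
    path.write_text("\n".join(lines) + "\n")


def reduce_to_asu(ds: SubDataset) -> SubDataset:
    """Fill in asymmetric-unit indices and Friedel signs (in place; returns ds).

    Idempotent: reducing an already-reduced set recomputes the same arrays.
    """
    reduced, signs = reduce_indices(ds.hkl, ds.space_group_number, ds.friedel_law)
    ds.hkl_red = reduced
    ds.friedel_sign = signs
    return ds


def validate_pool(pool: Sequence[SubDataset]) -> None:
    """Check that a pool is mergeable: one space group, near-identical cells.

    Cells may differ from the pool median by < 2% per edge and < 2° per angle
    (consistent indexing of near-isomorphous crystals is assumed upstream);
    larger deviations raise.
    """
    if not pool:
        raise ValueError("empty pool")
    sgs = {ds.space_group_number for ds in pool}
    if len(sgs) > 1:
        raise ValueError(f"pool mixes space groups {sorted(sgs)}")
    med = UnitCell(
        *(
            float(np.median([getattr(ds.cell, f) for ds in pool]))
            for f in ("a", "b", "c", "alpha", "beta", "gamma")
        )
    )
    for ds in pool:
        if ds.cell != med and not ds.cell.close_to(med):
            raise ValueError(
                f"sub-data set {ds.id!r} cell {ds.cell} deviates > 2%/2° from pool median {med}"
            )
        if ds.cell != med:
            warnings.warn(f"sub-data set {ds.id!r} cell differs slightly from pool median", stacklevel=2)
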