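"""Occurrence cleaning and replicate train/test splitting.

Cleaning keeps at most one record per valid grid cell (the standard
"trim duplicate occurrences" rule used to reduce sampling bias at the
working resolution), and replicate splits are independent seeded random
75/25 partitions of the thinned records.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .geo_io import GridGeometry, OccurrenceSet, cell_indices

log = logging.getLogger(__name__)

__all__ = ["SplitSpec", "thin_to_grid", "split_replicates"]


@dataclass
class SplitSpec:
    """Replicated random train/test partition settings."""

    test_fraction: float = 0.25
    n_replicates: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.test_fraction < 1.0:
            raise ValueError("test_fraction must be in (0, 1)")
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be >= 1")


def thin_to_grid(occ: OccurrenceSet, geometry: GridGeometry) -> OccurrenceSet:
    """Keep the first-encountered record in each valid grid cell.

    Records falling outside the grid or on nodata cells are dropped
    (with a logged count).  Idempotent: thinning a thinned set is a
    no-op.  Output size equals the number of distinct occupied valid
    cells.
    """
    rows, cols, inside = cell_indices(geometry, occ.lon, occ.lat)
    valid = geometry.valid_mask
    usable = inside.copy()
    usable[inside] = valid[rows[inside], cols[inside]]
    n_dropped = int((~usable).sum())
    if n_dropped:
        log.info(
            "thin_to_grid: dropped %d of %d records outside the grid or on "
            "nodata cells",
            n_dropped,
            len(occ),
        )
    seen: set[tuple[int, int]] = set()
    keep: list[int] = []
    for i in np.nonzero(usable)[0]:
        cell = (int(rows[i]), int(cols[i]))
        if cell not in seen:
            seen.add(cell)
            keep.append(int(i))
    return occ.select(keep)


def split_replicates(
    occ: OccurrenceSet, spec: SplitSpec
) -> list[tuple[OccurrenceSet, OccurrenceSet]]:
    """Independent seeded random (train, test) partitions.

    The test size is ``test_fraction * n`` rounded half-up; train and
    test are disjoint and their union is the input.
    """
    n = len(occ)
    if n < 2:
        raise ValueError(f"need at least 2 records to split, got {n}")
    n_test = int(np.floor(spec.test_fraction * n + 0.5))
    n_test = min(max(n_test, 1), n - 1)
    out = []
    for r in range(spec.n_replicates):
        rng = np.random.default_rng(np.random.SeedSequence(spec.seed, spawn_key=(r,)))
        perm = rng.permutation(n)
        test_idx = np.sort(perm[:n_test])
        train_idx = np.sort(perm[n_test:])
        out.append((occ.select(train_idx), occ.select(test_idx)))
    return out
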