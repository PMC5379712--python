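"""Explicit counting rules for already-scored microscopy records.

Three scoring schemes are implemented exactly as stated experimentally:

* chromatin-fiber co-localization: a fiber is positive when at least 50%
  (inclusive by default; a strict mode uses >50%) of its tagged CENP-A foci
  co-localize with CENP-C;
* centromeric replication timing: the percentage of EdU+/CENP-B+ double
  foci over all CENP-B foci, pooled over the cells of an S-phase stage
  (aggregate counts, not a mean of per-cell ratios);
* mitotic defects: four exclusive categories from two booleans —
  normal, lagging, multipolar, lagging+multipolar.

No image processing happens here: inputs are tabular records produced by an
external co-localization/scoring step.
"""

from __future__ import annotations

import os
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .model import ModelError

__all__ = [
    "FiberRecord",
    "CellCycleCount",
    "MitoticCell",
    "FiberScore",
    "score_fibers",
    "replication_fraction",
    "classify_mitoses",
    "MITOTIC_CATEGORIES",
    "read_fiber_records",
    "read_cellcycle_counts",
    "read_mitotic_cells",
    "synthetic_fiber_records",
]

PHASES = ("earlyS", "midS", "lateS")
MITOTIC_CATEGORIES = ("normal", "lagging", "multipolar", "lagging+multipolar")


@dataclass(frozen=True)
class FiberRecord:
    fiber_id: str
    n_spots: int
    n_coloc: int

    def __post_init__(self) -> None:
        if self.n_spots < 1:
            raise ModelError(f"fiber {self.fiber_id}: n_spots must be >= 1")
        if not 0 <= self.n_coloc <= self.n_spots:
            raise ModelError(f"fiber {self.fiber_id}: need 0 <= n_coloc <= n_spots")

    @property
    def fraction(self) -> float:
        return self.n_coloc / self.n_spots


@dataclass(frozen=True)
class CellCycleCount:
    cell_id: str
    phase: str
    n_cenpb: int
    n_double: int

    def __post_init__(self) -> None:
        if self.phase not in PHASES:
            raise ModelError(f"phase must be one of {PHASES}, got {self.phase!r}")
        if self.n_cenpb < 0 or not 0 <= self.n_double <= self.n_cenpb:
            raise ModelError(f"cell {self.cell_id}: need 0 <= n_double <= n_cenpb")


@dataclass(frozen=True)
class MitoticCell:
    cell_id: str
    lagging: bool
    multipolar: bool


@dataclass
class FiberScore:
    n_positive: int
    n_total: int
    fraction: float  # full precision
    percent: int  # rounded for reporting


def score_fibers(
    records: list[FiberRecord], threshold: float = 0.5, strict: bool = False
) -> FiberScore:
    """Count co-localization-positive fibers.

    A fiber is positive when its co-localized fraction is >= threshold
    (or > threshold with ``strict=True``).  The reported percentage is
    rounded to the nearest integer; the full-precision fraction is kept.
    """

    if not records:
        raise ModelError("no fiber records")
    if strict:
        positive = sum(1 for r in records if r.fraction > threshold)
    else:
        positive = sum(1 for r in records if r.fraction >= threshold)
    fraction = positive / len(records)
    return FiberScore(positive, len(records), fraction, int(round(100 * fraction)))


def replication_fraction(counts: list[CellCycleCount], phase: str) -> float:
    """Pooled percentage of EdU+/CENP-B+ foci over all CENP-B foci in a phase."""

    if phase not in PHASES:
        raise ModelError(f"phase must be one of {PHASES}, got {phase!r}")
    sub = [c for c in counts if c.phase == phase]
    if not sub:
        raise ModelError(f"no records for phase {phase!r}")
    total = sum(c.n_cenpb for c in sub)
    if total == 0:
        raise ModelError(f"zero CENP-B foci in phase {phase!r}")
    return 100.0 * sum(c.n_double for c in sub) / total


def classify_mitoses(cells: list[MitoticCell]) -> dict[str, dict[str, float]]:
    """Partition mitotic cells into the four defect categories.

    Returns ``{category: {"count": int, "percent": float}}`` with all four
    categories always present (empty ones report 0); percentages sum to 100.
    """

    if not cells:
        raise ModelError("no mitotic cells")
    counts = dict.fromkeys(MITOTIC_CATEGORIES, 0)
    for c in cells:
        if c.lagging and c.multipolar:
            cat = "lagging+multipolar"
        elif c.lagging:
            cat = "lagging"
        elif c.multipolar:
            cat = "multipolar"
        else:
            cat = "normal"
        counts[cat] += 1
    n = len(cells)
    return {
        cat: {"count": counts[cat], "percent": 100.0 * counts[cat] / n}
        for cat in MITOTIC_CATEGORIES
    }


# --------------------------------------------------------------------------
# TSV record schemas

def read_fiber_records(path: str | os.PathLike) -> list[FiberRecord]:
    """TSV with header: fiber_id, n_spots, n_coloc."""

    df = pd.read_csv(path, sep="\t")
    return [
        FiberRecord(str(r.fiber_id), int(r.n_spots), int(r.n_coloc))
        for r in df.itertuples()
    ]


def read_cellcycle_counts(path: str | os.PathLike) -> list[CellCycleCount]:
    """TSV with header: cell_id, phase, n_cenpb, n_double."""

    df = pd.read_csv(path, sep="\t")
    return [
        CellCycleCount(str(r.cell_id), str(r.phase), int(r.n_cenpb), int(r.n_double))
        for r in df.itertuples()
    ]


def read_mitotic_cells(path: str | os.PathLike) -> list[MitoticCell]:
    """TSV with header: cell_id, lagging, multipolar (0/1)."""

    df = pd.read_csv(path, sep="\t")
    return [
        MitoticCell(str(r.cell_id), bool(int(r.lagging)), bool(int(r.multipolar)))
        for r in df.itertuples()
    ]


def synthetic_fiber_records(
    n_fibers: int, n_positive: int, seed: int = 0, threshold: float = 0.5
) -> tuple[list[FiberRecord], int]:
    """Fixture generator: fiber records with a known positive count.

    Positives get a co-localized fraction >= threshold, negatives strictly
    below it; returns the records and the planted positive count.
    """

    if not 0 <= n_positive <= n_fibers:
        raise ModelError("need 0 <= n_positive <= n_fibers")
    rng = np.random.default_rng(seed)
    records = []
    for i in range(n_fibers):
        n_spots = int(rng.integers(4, 21))
        if i < n_positive:
            lo = int(np.ceil(threshold * n_spots))
            n_coloc = int(rng.integers(lo, n_spots + 1))
        else:
            hi = int(np.ceil(threshold * n_spots)) - 1
            n_coloc = int(rng.integers(0, max(hi, 0) + 1))
        records.append(FiberRecord(f"fiber{i:03d}", n_spots, n_coloc))
    return records, n_positive
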