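"""Threshold-based rarefaction.

Instead of repeatedly resampling reads without replacement, a sequencing
depth d is *simulated* by discarding every OTU whose relative abundance
does not reach 100/d percent — at depth 500 that is 0.2%, at 50,000 it is
0.002%.  The procedure is deterministic, which removes the stochastic
noise of classical rarefaction, and at depth 10,000 it coincides exactly
with the pipeline's 0.01% abundance filter.

The depth-equivalence factor compares strategies on a shared depth grid:
how much deeper must the reference (typically the unsorted-sample
surrogate ``g``) be sequenced to match the richness a size-sorted,
small-enriched strategy reaches at a lower depth.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd


class RarefactionError(ValueError):
    pass


@dataclass
class RecoveryCurve:
    """Richness as a function of a swept parameter (depth or mixing ratio)."""

    label: str
    x: np.ndarray
    richness: np.ndarray
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.x = np.asarray(self.x, dtype=float)
        self.richness = np.asarray(self.richness, dtype=int)
        if self.x.shape != self.richness.shape:
            raise RarefactionError("x and richness must align")
        if np.any(np.diff(self.x) <= 0):
            raise RarefactionError("x must be strictly increasing")
        if np.any(self.richness < 0):
            raise RarefactionError("richness must be non-negative")

    def at(self, x_value: float) -> int:
        idx = np.nonzero(self.x == x_value)[0]
        if idx.size == 0:
            raise RarefactionError(f"x = {x_value} not on the grid of {self.label!r}")
        return int(self.richness[idx[0]])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"strategy": self.label, "x": self.x,
                             "richness": self.richness})


def threshold_for_depth(depth: float) -> float:
    """Filtering threshold (in percent) simulating a sequencing depth.

    100/depth: 0.2% for 500 reads, 0.002% for 50,000 reads.
    """
    if depth < 1:
        raise RarefactionError(f"depth must be >= 1, got {depth}")
    return 100.0 / depth


def rarefy_by_threshold(column: pd.Series, depth: float) -> set[str]:
    """OTUs whose relative abundance reaches the depth's threshold.

    ``column`` may hold counts or relative abundances; an all-zero column
    yields the empty set.  OTUs exactly at the threshold are retained
    (exclusion requires the minimum abundance *not* to be reached).
    """
    col = pd.Series(column, dtype=float)
    total = col.sum()
    if total <= 0:
        return set()
    # percent scale keeps the boundary exact (1 read in 10,000 = 0.01%)
    rel_pct = col * 100.0 / total
    keep = (col > 0) & (rel_pct >= threshold_for_depth(depth))
    return set(col.index[keep])


def default_depth_grid(low: int = 500, high: int = 50_000,
                       n: int = 19) -> np.ndarray:
    """Log-spaced integer depth grid, 500..50,000 by default."""
    grid = np.unique(np.round(np.geomspace(low, high, n)).astype(int))
    return grid


def recovery_curves(columns_by_strategy: Mapping[str, pd.Series],
                    depths: Sequence[float] | None = None,
                    mode: str = "unspecified") -> list[RecoveryCurve]:
    """Richness-versus-depth curve per strategy via threshold rarefaction.

    ``mode`` is recorded in provenance: the caller prepares inputs either
    with replicates simply summed ("pooled" — no consistency or 0.01%
    filtering) or after the full quality filter ("filtered").
    """
    depths = np.sort(np.asarray(default_depth_grid() if depths is None else depths,
                                dtype=float))
    curves = []
    for label, col in columns_by_strategy.items():
        richness = np.array([len(rarefy_by_threshold(col, d)) for d in depths])
        curves.append(RecoveryCurve(label, depths, richness,
                                    provenance={"mode": mode}))
    return curves


@dataclass(frozen=True)
class EquivalenceResult:
    """Outcome of a depth-equivalence lookup for one strategy."""

    strategy: str
    factor: float | None  # None when the target richness is never reached
    matched_depth: float | None
    target_richness: int
    max_richness: int

    @property
    def reached(self) -> bool:
        return self.factor is not None


def depth_equivalence_factor(curves: Sequence[RecoveryCurve],
                             reference_strategy: str,
                             reference_depth: float,
                             ) -> dict[str, EquivalenceResult]:
    """Depth multiple saved by each strategy relative to the reference.

    For each non-reference curve, find the smallest grid depth d whose
    richness reaches the reference's richness at ``reference_depth``; the
    factor is reference_depth / d (grid lookup, no interpolation).  The
    reference maps to factor 1.
    """
    by_label = {c.label: c for c in curves}
    if reference_strategy not in by_label:
        raise RarefactionError(f"reference {reference_strategy!r} not among curves")
    ref = by_label[reference_strategy]
    target = ref.at(reference_depth)
    out: dict[str, EquivalenceResult] = {}
    for label, curve in by_label.items():
        if label == reference_strategy:
            out[label] = EquivalenceResult(label, 1.0, reference_depth,
                                           target, int(curve.richness.max()))
            continue
        hit = np.nonzero(curve.richness >= target)[0]
        if hit.size:
            d = float(curve.x[hit[0]])
            out[label] = EquivalenceResult(label, reference_depth / d, d,
                                           target, int(curve.richness.max()))
        else:
            out[label] = EquivalenceResult(label, None, None, target,
                                           int(curve.richness.max()))
    return out
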