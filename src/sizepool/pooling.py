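"""In silico pooling of size fractions.

Given per-fraction OTU read-count columns, these routines reconstruct
pooled samples without re-sequencing: dry-weight-proportional pooling
(simulating an unsorted sample), named volume-proportion strategies, the
S+M versus L+XL ratio sweep in 5% steps at 10,000 reads with a 0.01%
threshold, and the equal quarter-depth pool of the four fractions filtered
at 0.04% each.

All pooling is done on relative read abundances; a 0.01% threshold at
10,000 reads corresponds to exactly one expected read, so thresholds act
on fractional expected counts rather than rounded integers.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from .rarefaction import RecoveryCurve
from .table import FRACTIONS


class PoolingError(ValueError):
    """Raised for invalid schemes, weights, or missing fractions."""


@dataclass(frozen=True)
class PoolingScheme:
    """Named volume proportions over size fractions, summing to one."""

    name: str
    proportions: Mapping[str, float]

    def __post_init__(self) -> None:
        object.__setattr__(self, "proportions", dict(self.proportions))
        unknown = set(self.proportions) - set(FRACTIONS)
        if unknown:
            raise PoolingError(f"unknown fractions in scheme {self.name!r}: "
                               f"{sorted(unknown)}")
        shares = np.array(list(self.proportions.values()), dtype=float)
        if (shares < 0).any() or (shares > 1).any():
            raise PoolingError(f"scheme {self.name!r}: shares must lie in [0, 1]")
        if abs(shares.sum() - 1.0) > 1e-9:
            raise PoolingError(
                f"scheme {self.name!r}: shares sum to {shares.sum():.12f}, not 1"
            )


#: Fixed named strategies.  g and invg depend on measured dry weights and
#: are built by :func:`named_scheme`.  Exact study proportions for the
#: small-enriching strategies are design choices (see docs/methods.md) and
#: user-overridable.
FIXED_SCHEMES: dict[str, dict[str, float]] = {
    "equ": {f: 0.25 for f in FRACTIONS},
    "4x": {"S": 64 / 85, "M": 16 / 85, "L": 4 / 85, "XL": 1 / 85},
    "log": {"S": 1000 / 1111, "M": 100 / 1111, "L": 10 / 1111, "XL": 1 / 1111},
    "fibo": {"S": 8 / 18, "M": 5 / 18, "L": 3 / 18, "XL": 2 / 18},
}


def named_scheme(name: str, weights: Mapping[str, float] | None = None) -> PoolingScheme:
    """Build one of the six study strategies.

    ``g`` pools proportionally to fraction dry weight (unsorted-sample
    surrogate), ``invg`` proportionally to reciprocal dry weight
    (zero-weight fractions get zero share); both require ``weights``.
    """
    if name in FIXED_SCHEMES:
        return PoolingScheme(name, FIXED_SCHEMES[name])
    if name in ("g", "invg"):
        if weights is None:
            raise PoolingError(f"scheme {name!r} requires fraction dry weights")
        w = {f: float(weights.get(f, 0.0)) for f in FRACTIONS}
        if any(v < 0 for v in w.values()):
            raise PoolingError("dry weights must be non-negative")
        if name == "invg":
            w = {f: (1.0 / v if v > 0 else 0.0) for f, v in w.items()}
        total = sum(w.values())
        if total == 0:
            raise PoolingError("all fraction weights are zero")
        return PoolingScheme(name, {f: v / total for f, v in w.items()})
    raise PoolingError(f"unknown scheme {name!r}")


@dataclass
class PooledProfile:
    """Relative OTU abundances of an in-silico pooled sample.

    ``abundance`` sums to one whenever any OTU is present; ``provenance``
    records constituent samples, scheme and depth for reporting.
    """

    abundance: pd.Series
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        ab = pd.Series(self.abundance, dtype=float)
        if (ab < 0).any():
            raise PoolingError("relative abundances must be non-negative")
        total = ab.sum()
        if total > 0 and abs(total - 1.0) > 1e-9:
            raise PoolingError(f"relative abundances sum to {total!r}, not 1")
        self.abundance = ab

    def expected_counts(self, depth: int) -> pd.Series:
        """Expected (fractional) read counts at the given sequencing depth."""
        return self.abundance * depth

    def richness(self, threshold_pct: float = 0.0) -> int:
        """Number of OTUs at or above ``threshold_pct`` relative abundance."""
        ab = self.abundance
        return int(((ab > 0) & (ab * 100.0 >= threshold_pct)).sum())


def _relative(columns: Mapping[str, pd.Series]) -> dict[str, pd.Series]:
    rel = {}
    for frac, col in columns.items():
        col = pd.Series(col, dtype=float)
        total = col.sum()
        rel[frac] = col / total if total > 0 else col
    return rel


def _union_index(columns: Mapping[str, pd.Series]) -> pd.Index:
    idx = pd.Index([])
    for col in columns.values():
        idx = idx.union(pd.Series(col).index, sort=False)
    return idx


def pool_by_scheme(fraction_columns: Mapping[str, pd.Series],
                   scheme: PoolingScheme) -> PooledProfile:
    """Mix per-fraction read columns with a scheme's volume proportions.

    Columns are converted to relative abundances on the union of their OTU
    ids (absent OTUs count as zero); the profile is the scheme-weighted sum,
    renormalized so it sums to one whenever any OTU is present.
    """
    missing = [f for f, share in scheme.proportions.items()
               if share > 0 and f not in fraction_columns]
    if missing:
        raise PoolingError(f"scheme {scheme.name!r} needs fractions missing from "
                           f"inputs: {missing}")
    rel = _relative(fraction_columns)
    idx = _union_index(fraction_columns)
    mix = pd.Series(0.0, index=idx)
    for frac, share in scheme.proportions.items():
        if share > 0:
            mix = mix.add(share * rel[frac].reindex(idx, fill_value=0.0),
                          fill_value=0.0)
    total = mix.sum()
    if total > 0:
        mix = mix / total
    return PooledProfile(mix, provenance={"scheme": scheme.name,
                                          "proportions": dict(scheme.proportions),
                                          "fractions": sorted(fraction_columns)})


def pool_by_weight(fraction_columns: Mapping[str, pd.Series],
                   weights: Mapping[str, float],
                   name: str = "by_weight") -> PooledProfile:
    """Pool proportionally to fraction dry weights (unsorted-sample surrogate)."""
    w = {f: float(weights[f]) for f in fraction_columns}
    if any(v < 0 for v in w.values()):
        raise PoolingError("dry weights must be non-negative")
    total = sum(w.values())
    if total == 0:
        raise PoolingError("all fraction weights are zero")
    scheme = PoolingScheme(name, {f: v / total for f, v in w.items()})
    profile = pool_by_scheme(fraction_columns, scheme)
    profile.provenance["weights"] = w
    return profile


def build_combined_fraction(columns: Mapping[str, pd.Series],
                            weights: Mapping[str, float],
                            name: str | None = None) -> PooledProfile:
    """Weight-proportional pool of exactly two (quality-filtered) fractions.

    Used to reconstruct the S+M and L+XL halves of the two-fraction sweep.
    """
    if len(columns) != 2:
        raise PoolingError(f"expected exactly two fractions, got {sorted(columns)}")
    label = name or "+".join(sorted(columns, key=list(FRACTIONS).index))
    return pool_by_weight(columns, weights, name=label)


def two_fraction_sweep(small: PooledProfile, large: PooledProfile,
                       step_pct: int = 5, depth: int = 10_000,
                       threshold_pct: float = 0.01) -> RecoveryCurve:
    """Sweep the S+M : L+XL mixing ratio and record surviving OTU richness.

    The ratio r runs from 0 to 100 in ``step_pct`` steps and is the percent
    of the small (S+M) profile in the mix: ``mix = (r/100)*small +
    (1-r/100)*large``.  At each r, OTUs whose mixed relative abundance is
    strictly below ``threshold_pct`` are discarded and the survivor count
    recorded.  ``depth`` is carried in the provenance: at the default
    10,000 reads the 0.01% cut equals one expected read.
    """
    if step_pct <= 0 or 100 % step_pct != 0:
        raise PoolingError("step_pct must divide 100")
    idx = small.abundance.index.union(large.abundance.index, sort=False)
    s = small.abundance.reindex(idx, fill_value=0.0)
    l = large.abundance.reindex(idx, fill_value=0.0)
    ratios = np.arange(0, 101, step_pct)
    richness = np.empty(ratios.size, dtype=int)
    for i, r in enumerate(ratios):
        mix = (r / 100.0) * s + (1 - r / 100.0) * l
        richness[i] = int(((mix > 0) & (mix * 100.0 >= threshold_pct)).sum())
    return RecoveryCurve(
        label="S+M_vs_L+XL",
        x=ratios.astype(float),
        richness=richness,
        provenance={"x": "percent_small_fraction", "depth": depth,
                    "threshold_pct": threshold_pct, "step_pct": step_pct},
    )


def equal_quarter_pool(fraction_columns: Mapping[str, pd.Series],
                       per_fraction_threshold_pct: float = 0.04) -> int:
    """Richness of the four fractions pooled at quarter depth each.

    Each fraction is filtered at ``per_fraction_threshold_pct`` of its own
    total (0.04% emulates one read at a quarter of 10,000); the result is
    the size of the union of surviving OTU sets.
    """
    missing = [f for f in FRACTIONS if f not in fraction_columns]
    if missing:
        raise PoolingError(f"missing fractions: {missing}")
    survivors: set[str] = set()
    for frac in FRACTIONS:
        col = pd.Series(fraction_columns[frac], dtype=float)
        total = col.sum()
        if total == 0:
            continue
        rel_pct = col * 100.0 / total
        survivors |= set(col.index[(col > 0) & (rel_pct >= per_fraction_threshold_pct)])
    return len(survivors)
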