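"""OTU-table quality filtering.

Cleanup follows the order used for the sequenced study data:

1. subtract, per OTU, the maximum read count observed in any negative
   control from every sample, flooring at zero;
2. discard read counts below 0.01% relative abundance per sample (counts
   exactly at the threshold survive; column totals are taken once, before
   any zeroing);
3. zero counts not present in both extraction replicates, then sum the two
   replicates into one column.

OTUs left without reads anywhere are dropped at the end so that per-step
removal logs stay interpretable.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .table import OTUTable, OTUTableError, SampleMeta


class FilterError(ValueError):
    """Raised when a filtering precondition is violated."""


@dataclass(frozen=True)
class ReplicatePairing:
    """Pairs of sample ids that are extraction replicates of one library."""

    pairs: tuple[tuple[str, str], ...]

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for a, b in self.pairs:
            for sid in (a, b):
                if sid in seen:
                    raise FilterError(f"sample {sid!r} appears in more than one pair")
                seen.add(sid)

    @classmethod
    def from_table(cls, table: OTUTable) -> "ReplicatePairing":
        """Pair replicates sharing (source, category, fraction, strategy)."""
        groups: dict[tuple, list[SampleMeta]] = {}
        for s in table.samples:
            if s.category == "negative_control":
                continue
            key = (s.source, s.category, s.fraction, s.strategy)
            groups.setdefault(key, []).append(s)
        pairs = []
        for key, members in groups.items():
            if len(members) == 2:
                members = sorted(members, key=lambda m: (m.replicate is None,
                                                         m.replicate))
                pairs.append((members[0].sample_id, members[1].sample_id))
            elif len(members) > 2:
                raise FilterError(
                    f"{len(members)} replicates for library {key}; expected <= 2"
                )
        return cls(tuple(pairs))

    def validate_against(self, table: OTUTable) -> None:
        ids = set(table.sample_ids)
        for a, b in self.pairs:
            if a not in ids or b not in ids:
                raise FilterError(f"pair ({a!r}, {b!r}) not present in table")
            ma, mb = table.meta(a), table.meta(b)
            if (ma.source, ma.category, ma.fraction, ma.strategy) != \
                    (mb.source, mb.category, mb.fraction, mb.strategy):
                raise FilterError(f"pair ({a!r}, {b!r}) does not share library metadata")


def subtract_negative_controls(table: OTUTable) -> OTUTable:
    """Subtract each OTU's maximum negative-control count from all samples.

    Negative-control columns are dropped from the result.  Raises
    :class:`FilterError` if the table contains no negative controls, so a
    deliberate skip stays explicit at the call site.
    """
    neg_ids = [s.sample_id for s in table.samples
               if s.category == "negative_control"]
    if not neg_ids:
        raise FilterError("no negative controls in table; skip this step explicitly")
    keep = [s for s in table.samples if s.sample_id not in set(neg_ids)]
    m = table.counts[neg_ids].max(axis=1)
    cleaned = table.counts[[s.sample_id for s in keep]].sub(m, axis=0).clip(lower=0)
    return table.with_counts(cleaned, keep)


def relative_abundance_filter(table: OTUTable,
                              threshold_pct: float = 0.01) -> OTUTable:
    """Zero counts whose per-sample relative abundance is below the threshold.

    Column totals are computed once, before zeroing; counts exactly at the
    threshold are kept ("below ... discarded" is a strict inequality).
    All-zero columns pass through unchanged.
    """
    if threshold_pct < 0:
        raise FilterError("threshold_pct must be >= 0")
    counts = table.counts.copy()
    totals = counts.sum(axis=0)
    # compare on the percent scale: 1 read in 10,000 is exactly 0.01 in
    # floating point, so the boundary rule holds without epsilon games
    rel_pct = (counts * 100.0).div(totals.replace(0, 1), axis=1)
    counts[rel_pct.lt(threshold_pct)] = 0
    return table.with_counts(counts)


def merge_replicates(table: OTUTable, pairing: ReplicatePairing,
                     require_both: bool = True) -> OTUTable:
    """Combine replicate pairs into single summed columns.

    With ``require_both`` (the consistency filter), an OTU's counts are
    zeroed in both replicates unless both are positive.  Unpaired
    non-negative-control samples pass through unmerged with a warning;
    negative-control columns pass through untouched.
    """
    pairing.validate_against(table)
    partner = {}
    for a, b in pairing.pairs:
        partner[a] = b
        partner[b] = a
    out_cols: dict[str, pd.Series] = {}
    out_meta: list[SampleMeta] = []
    done: set[str] = set()
    for s in table.samples:
        sid = s.sample_id
        if sid in done:
            continue
        if sid in partner:
            other = partner[sid]
            a, b = table.counts[sid], table.counts[other]
            if require_both:
                present = (a > 0) & (b > 0)
                a, b = a.where(present, 0), b.where(present, 0)
            merged_meta = s.merged()
            out_cols[merged_meta.sample_id] = a + b
            out_meta.append(merged_meta)
            done.update((sid, other))
        else:
            if s.category != "negative_control":
                warnings.warn(f"sample {sid!r} has no replicate partner; "
                              "passed through unmerged", stacklevel=2)
            out_cols[sid] = table.counts[sid]
            out_meta.append(s)
            done.add(sid)
    counts = pd.DataFrame(out_cols, index=table.counts.index)
    return table.with_counts(counts, out_meta)


def replicate_consistency_filter(table: OTUTable,
                                 pairing: ReplicatePairing) -> OTUTable:
    """Zero counts not present in both extraction replicates, then merge pairs."""
    return merge_replicates(table, pairing, require_both=True)


def _richness(table: OTUTable) -> int:
    return int((table.counts.sum(axis=1) > 0).sum())


def quality_filter(table: OTUTable,
                   pairing: ReplicatePairing | None = None,
                   threshold_pct: float = 0.01,
                   skip_negatives: bool = False,
                   ) -> tuple[OTUTable, pd.DataFrame]:
    """Full cleanup: negatives -> abundance threshold -> replicate merge.

    Returns the filtered table (all-zero OTU rows dropped) and a per-step
    log of reads and OTUs removed.
    """
    log_rows = []

    def log(step: str, before: OTUTable, after: OTUTable) -> None:
        log_rows.append({
            "step": step,
            "reads_removed": int(before.counts.to_numpy().sum()
                                 - after.counts.to_numpy().sum()),
            "otus_removed": _richness(before) - _richness(after),
        })

    current = table
    if not skip_negatives:
        neg_ids = [s.sample_id for s in current.samples
                   if s.category == "negative_control"]
        before = current.drop_samples(neg_ids) if neg_ids else current
        current = subtract_negative_controls(current)
        log("subtract_negative_controls", before, current)
    else:
        neg_ids = [s.sample_id for s in current.samples
                   if s.category == "negative_control"]
        if neg_ids:
            current = current.drop_samples(neg_ids)

    before = current
    current = relative_abundance_filter(current, threshold_pct)
    log(f"relative_abundance_filter_{threshold_pct}pct", before, current)

    if pairing is None:
        pairing = ReplicatePairing.from_table(current)
    before = current
    current = replicate_consistency_filter(current, pairing)
    log("replicate_consistency_filter", before, current)

    current = current.drop_zero_otus()
    return current, pd.DataFrame(log_rows)
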