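"""Shared fixtures builders and independent brute-force oracles.

The oracles here deliberately avoid the package's own code paths: exact
rational arithmetic with fractions.Fraction, plain dict/set enumeration.
"""

from __future__ import annotations

from fractions import Fraction
from typing import Mapping

import pandas as pd

import sizepool as sp


def make_table(columns: Mapping[str, Mapping[str, int]],
               order: list[str] | None = None) -> sp.OTUTable:
    """Build an OTUTable from {sample_id: {otu_id: count}} with parseable ids."""
    df = pd.DataFrame(columns).fillna(0).astype(int)
    if order is not None:
        df = df.loc[order]
    return sp.OTUTable(df)


def hand_filter_fixture() -> tuple[sp.OTUTable, pd.DataFrame]:
    """Six-OTU table whose three-step cleanup was executed by hand.

    Designed so each step removes a disjoint set: negative subtraction
    floors O2's second replicate, the 0.01% threshold zeroes O6's
    second-replicate single read (and keeps O2/O3 sitting exactly at the
    cut), replicate consistency then removes O2 and O6 entirely.
    """
    table = make_table({
        "L1_S_r1": {"O1": 100, "O2": 9, "O3": 2, "O4": 19885, "O5": 10, "O6": 8},
        "L1_S_r2": {"O1": 120, "O2": 6, "O3": 40, "O4": 19807, "O5": 40, "O6": 1},
        "neg_1": {"O1": 3, "O2": 7, "O3": 0, "O4": 0, "O5": 0, "O6": 0},
        "neg_2": {"O1": 7, "O2": 0, "O3": 0, "O4": 0, "O5": 0, "O6": 0},
    }, order=["O1", "O2", "O3", "O4", "O5", "O6"])
    expected = pd.DataFrame(
        {"L1_S": {"O1": 206, "O3": 42, "O4": 39692, "O5": 50}}
    ).loc[["O1", "O3", "O4", "O5"]].astype(int)
    expected.index.name = "OTU_ID"
    return table, expected


def threshold_survivors_oracle(counts: Mapping[str, int],
                               threshold: Fraction) -> set[str]:
    """OTUs at or above an exact relative-abundance threshold."""
    total = sum(counts.values())
    if total == 0:
        return set()
    return {otu for otu, c in counts.items()
            if c > 0 and Fraction(c, total) >= threshold}


def sweep_oracle(small: Mapping[str, int], large: Mapping[str, int],
                 step_pct: int, threshold: Fraction) -> list[int]:
    """Brute-force mixture/threshold enumeration over all ratios.

    ``small``/``large`` are integer count profiles; ratio r is the percent
    of the small profile in the mix, r = 0, step, ..., 100.
    """
    s_tot, l_tot = sum(small.values()), sum(large.values())
    ids = sorted(set(small) | set(large))
    rel_s = {i: Fraction(small.get(i, 0), s_tot) for i in ids}
    rel_l = {i: Fraction(large.get(i, 0), l_tot) for i in ids}
    richness = []
    for r in range(0, 101, step_pct):
        w = Fraction(r, 100)
        n = 0
        for i in ids:
            mix = w * rel_s[i] + (1 - w) * rel_l[i]
            if mix > 0 and mix >= threshold:
                n += 1
        richness.append(n)
    return richness


def presence_sharing_oracle(fraction_presence: Mapping[str, set[str]]) -> dict[int, int]:
    """Per-k counts of OTUs present in exactly k fractions."""
    all_otus = set().union(*fraction_presence.values())
    hist = {k: 0 for k in range(1, 5)}
    for otu in all_otus:
        k = sum(otu in members for members in fraction_presence.values())
        if k:
            hist[k] += 1
    return hist
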