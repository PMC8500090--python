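"""Size-class assignment, sharing, dissimilarity, clustering."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import sizepool as sp
from sizepool.analysis import UNASSIGNED, AnalysisError, DissimilarityMatrix

from helpers import make_table, presence_sharing_oracle


def fraction_table(columns):
    """Table of merged fraction libraries (sample ids like L1_S)."""
    return make_table(columns)


def test_assignment_follows_highest_combined_abundance():
    """An OTU abundant in two classes gets the more abundant one (M over L)."""
    table = fraction_table({
        "L1_S": {"OTU1": 0, "OTU2": 10_000},
        "L1_M": {"OTU1": 5570, "OTU2": 4430},
        "L1_L": {"OTU1": 4320, "OTU2": 5680},
        "L1_XL": {"OTU1": 0, "OTU2": 10_000},
    })
    assignment = sp.assign_size_classes(table)
    ev = assignment.evidence("OTU1")
    assert ev["L"] == pytest.approx(0.432)
    assert ev["M"] == pytest.approx(0.557)
    assert assignment.classes["OTU1"] == "M"


def test_assignment_single_fraction_and_unassigned():
    full = make_table({
        "L1_S": {"OTU1": 100, "OTU2": 0},
        "L1_M": {"OTU1": 0, "OTU2": 0},
        "L1_L": {"OTU1": 0, "OTU2": 0},
        "L1_XL": {"OTU1": 0, "OTU2": 0},
        "L1_g": {"OTU1": 10, "OTU2": 90},  # OTU2 only in a pooled lysate
    })
    assignment = sp.assign_size_classes(full.select(category="fraction"))
    assert assignment.classes["OTU1"] == "S"
    assert assignment.classes["OTU2"] == UNASSIGNED


def test_assignment_tie_goes_to_smaller_class_and_is_flagged():
    table = fraction_table({
        "L1_S": {"OTU1": 50, "OTU2": 50},
        "L1_M": {"OTU1": 50, "OTU2": 50},
    })
    assignment = sp.assign_size_classes(table)
    assert assignment.classes["OTU1"] == "S"
    assert bool(assignment.frame.loc["OTU1", "tie"])


def test_assignment_rejects_duplicate_libraries():
    table = make_table({"L1_S_r1": {"O": 1}, "L1_S_r2": {"O": 1}})
    with pytest.raises(AnalysisError, match="merge replicates"):
        sp.assign_size_classes(table)


def test_assignment_evidence_sums_across_sources(filtered_table, experiment):
    """Reported class always attains the maximum of the evidence vector."""
    assignment = sp.assign_size_classes(filtered_table.select(category="fraction"))
    ev = assignment.frame[list(sp.FRACTIONS)]
    assigned = assignment.classes != UNASSIGNED
    attained = ev.to_numpy().max(axis=1)
    chosen = np.array([ev.at[otu, c] if c != UNASSIGNED else np.nan
                       for otu, c in assignment.classes.items()])
    assert np.allclose(chosen[assigned.to_numpy()],
                       attained[assigned.to_numpy()])
    # unassigned means zero support everywhere
    assert (ev.to_numpy()[~assigned.to_numpy()].sum(axis=1) == 0).all()


def test_spectrum_symmetry_and_degenerate_cases():
    table = fraction_table({
        "L1_S": {"a": 1, "b": 0, "c": 0, "d": 0},
        "L1_M": {"a": 0, "b": 1, "c": 0, "d": 0},
        "L1_L": {"a": 0, "b": 0, "c": 1, "d": 0},
        "L1_XL": {"a": 0, "b": 0, "c": 0, "d": 1},
    })
    spectrum = sp.size_class_spectrum(sp.assign_size_classes(table))
    assert spectrum[list(sp.FRACTIONS)].tolist() == [25.0] * 4
    assert spectrum[UNASSIGNED] == 0.0
    assert spectrum.sum() == pytest.approx(100.0, abs=0.01)

    empty_support = fraction_table({"L1_S": {"a": 0, "b": 0}})
    all_un = sp.size_class_spectrum(sp.assign_size_classes(empty_support))
    assert all_un[UNASSIGNED] == 100.0


def test_spectrum_sums_to_100_on_simulation(filtered_table):
    spectrum = sp.size_class_spectrum(
        sp.assign_size_classes(filtered_table.select(category="fraction")))
    assert spectrum.sum() == pytest.approx(100.0, abs=0.01)


def test_fraction_sharing_degenerate_and_oracle():
    disjoint = fraction_table({
        "L1_S": {"a": 1, "b": 1, "x": 0},
        "L1_M": {"x": 2, "a": 0, "b": 0},
    })
    hist = sp.fraction_sharing(disjoint)
    assert hist[1] == 3 and hist[2] == 0

    everywhere = fraction_table({f"L1_{f}": {"a": 1} for f in sp.FRACTIONS})
    assert sp.fraction_sharing(everywhere)[4] == 1

    rng = np.random.default_rng(0)
    counts = pd.DataFrame(
        rng.integers(0, 2, size=(6, 4)) * rng.integers(1, 9, size=(6, 4)),
        index=[f"O{i}" for i in range(6)],
        columns=[f"L1_{f}" for f in sp.FRACTIONS])
    table = sp.OTUTable(counts)
    hist = sp.fraction_sharing(table)
    presence = {f: set(counts.index[counts[f"L1_{f}"] > 0])
                for f in sp.FRACTIONS}
    oracle = presence_sharing_oracle(presence)
    assert {k: int(v) for k, v in hist.items()} == oracle
    assert hist.sum() == len(set().union(*presence.values()))


def test_dissimilarity_identity_disjoint_and_hand_value():
    identical = pd.DataFrame({"a": [3, 1], "b": [3, 1]}, index=["x", "y"])
    for metric in ("jaccard", "bray_curtis"):
        dm = sp.dissimilarity(identical, metric=metric)
        assert dm.matrix[0, 1] == pytest.approx(0.0)

    disjoint = pd.DataFrame({"a": [5, 0], "b": [0, 7]}, index=["x", "y"])
    assert sp.dissimilarity(disjoint, "jaccard").matrix[0, 1] == pytest.approx(1.0)
    assert sp.dissimilarity(disjoint, "bray_curtis").matrix[0, 1] == pytest.approx(1.0)

    p = pd.DataFrame({"a": [0.5, 0.5, 0.0], "b": [0.5, 0.0, 0.5]})
    assert sp.dissimilarity(p, "bray_curtis").matrix[0, 1] == pytest.approx(0.5)


def test_dissimilarity_rejects_empty_sample():
    bad = pd.DataFrame({"a": [1, 2], "b": [0, 0]})
    with pytest.raises(AnalysisError, match="'b'"):
        sp.dissimilarity(bad, "jaccard")
    with pytest.raises(AnalysisError, match="two samples"):
        sp.dissimilarity(pd.DataFrame({"a": [1]}), "jaccard")


@settings(max_examples=40, derandomize=True, deadline=None)
@given(data=st.lists(st.lists(st.integers(0, 100), min_size=3, max_size=3),
                     min_size=2, max_size=6),
       metric=st.sampled_from(["jaccard", "bray_curtis"]))
def test_dissimilarity_metric_properties(data, metric):
    """Symmetry, zero diagonal and [0, 1] range on random profiles."""
    df = pd.DataFrame(np.asarray(data).T,
                      columns=[f"s{i}" for i in range(len(data))])
    if (df.sum(axis=0) == 0).any():
        return
    dm = sp.dissimilarity(df, metric)
    m = dm.matrix
    assert np.allclose(m, m.T)
    assert np.allclose(np.diag(m), 0.0)
    assert ((m >= 0) & (m <= 1)).all()


def test_cluster_dendrogram_two_and_three_samples():
    two = DissimilarityMatrix(["a", "b"], np.array([[0, .3], [.3, 0]]), "jaccard")
    linkage, newick = sp.cluster_dendrogram(two)
    assert linkage.shape == (1, 4)
    assert linkage[0, 2] == pytest.approx(0.3)

    three = DissimilarityMatrix(
        ["A", "B", "C"],
        np.array([[0.0, 0.1, 0.9], [0.1, 0.0, 0.9], [0.9, 0.9, 0.0]]),
        "bray_curtis")
    linkage, newick = sp.cluster_dendrogram(three)
    assert linkage[0, 2] == pytest.approx(0.1)   # A and B merge first
    assert linkage[1, 2] == pytest.approx(0.9)   # C joins at 0.9
    assert "A" in newick and newick.endswith(";")


def test_small_enriched_lysates_cluster_with_small_fraction(filtered_table):
    """log/4x pools resemble the individually sequenced S fraction more
    than the unsorted-sample surrogate g does (read abundances)."""
    cols = {}
    for s in filtered_table.samples:
        if s.source != "L1":
            continue
        if s.category == "fraction" and s.fraction == "S":
            cols["S"] = s.sample_id
        if s.category == "pooled_lysate" and s.strategy in ("g", "log", "4x"):
            cols[s.strategy] = s.sample_id
    sub = filtered_table.counts[[cols[k] for k in ("S", "g", "log", "4x")]]
    sub = sub.loc[sub.sum(axis=1) > 0]
    dm = sp.dissimilarity(sub, "bray_curtis")
    d = pd.DataFrame(dm.matrix, index=["S", "g", "log", "4x"],
                     columns=["S", "g", "log", "4x"])
    assert d.loc["S", "log"] < d.loc["S", "g"]
    assert d.loc["S", "4x"] < d.loc["S", "g"]
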