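"""Community summaries: OTU size-class assignment, sharing, dissimilarity.

An OTU's size class is estimated from the individually sequenced size
fractions: its relative read abundance is summed over the source samples
for each fraction, and the fraction with the highest combined abundance is
assigned.  OTUs seen only in pooled lysates (never in a fraction library)
remain unassigned.  Ties resolve toward the smaller class and are flagged.

Sample-by-sample dissimilarity uses Jaccard distance on presence/absence
and Bray-Curtis on relative abundances, with average-linkage hierarchical
clustering serialized as Newick.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist, squareform
from skbio.tree import TreeNode

from .table import FRACTIONS, OTUTable

UNASSIGNED = "unassigned"


class AnalysisError(ValueError):
    pass


@dataclass
class SizeClassAssignment:
    """Per-OTU size-class call with its supporting evidence.

    ``frame`` columns: one evidence column per fraction (summed relative
    abundances), ``size_class`` in {S, M, L, XL, unassigned}, and ``tie``
    flagging OTUs whose maximum evidence is shared by several classes.
    """

    frame: pd.DataFrame

    @property
    def classes(self) -> pd.Series:
        return self.frame["size_class"]

    def evidence(self, otu_id: str) -> pd.Series:
        return self.frame.loc[otu_id, list(FRACTIONS)]


def _fraction_libraries(table: OTUTable) -> dict[tuple[str, str], str]:
    """Map (source, fraction) -> sample id; duplicates are an error."""
    libs: dict[tuple[str, str], str] = {}
    for s in table.samples:
        if s.category != "fraction":
            continue
        key = (s.source, s.fraction)
        if key in libs:
            raise AnalysisError(f"duplicate library for source/fraction {key}; "
                                "merge replicates first")
        libs[key] = s.sample_id
    return libs


def assign_size_classes(table: OTUTable) -> SizeClassAssignment:
    """Assign a size class to every OTU from per-fraction read abundances.

    ``table`` must hold quality-filtered fraction libraries (one column
    per source sample and fraction; replicates already merged).  Evidence
    per class is the sum of the OTU's relative abundances over source
    samples; the argmax wins, ties going to the smaller class.
    """
    libs = _fraction_libraries(table)
    if not libs:
        raise AnalysisError("table holds no fraction libraries")
    rel = table.relative_abundance()
    evidence = pd.DataFrame(0.0, index=table.counts.index, columns=list(FRACTIONS))
    for (source, fraction), sid in libs.items():
        evidence[fraction] += rel[sid]
    values = evidence.to_numpy()
    has_support = values.sum(axis=1) > 0
    # first argmax in FRACTIONS order => ties resolve toward the smaller class
    winner = np.asarray(list(FRACTIONS))[values.argmax(axis=1)]
    classes = pd.Series(np.where(has_support, winner, UNASSIGNED),
                        index=evidence.index, name="size_class")
    n_max = (values == values.max(axis=1, keepdims=True)).sum(axis=1)
    tie = pd.Series(has_support & (n_max > 1), index=evidence.index, name="tie")
    frame = evidence.copy()
    frame["size_class"] = classes
    frame["tie"] = tie
    return SizeClassAssignment(frame)


def size_class_spectrum(assignment: SizeClassAssignment) -> pd.Series:
    """Percentage of OTUs per size class, including unassigned; sums to 100."""
    if assignment.frame.empty:
        raise AnalysisError("empty assignment")
    order = list(FRACTIONS) + [UNASSIGNED]
    counts = assignment.classes.value_counts().reindex(order, fill_value=0)
    return 100.0 * counts / counts.sum()


def fraction_sharing(table: OTUTable) -> pd.Series:
    """Histogram of OTUs by the number of size fractions they occur in.

    Presence means any nonzero filtered count in any source sample's
    library of that fraction.  Index runs 1..4; OTUs absent from all
    fractions are not counted.
    """
    libs = _fraction_libraries(table)
    if not libs:
        raise AnalysisError("table holds no fraction libraries")
    present = pd.DataFrame(False, index=table.counts.index, columns=list(FRACTIONS))
    for (source, fraction), sid in libs.items():
        present[fraction] |= table.counts[sid] > 0
    k = present.sum(axis=1)
    hist = k[k > 0].value_counts().reindex(range(1, len(FRACTIONS) + 1),
                                           fill_value=0).sort_index()
    hist.index.name = "n_fractions"
    return hist


@dataclass
class DissimilarityMatrix:
    """Symmetric pairwise dissimilarities in [0, 1] with a zero diagonal."""

    labels: list[str]
    matrix: np.ndarray
    metric: str

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=float)
        if m.shape != (len(self.labels), len(self.labels)):
            raise AnalysisError("matrix shape does not match labels")
        if not np.allclose(m, m.T) or not np.allclose(np.diag(m), 0):
            raise AnalysisError("matrix must be symmetric with zero diagonal")
        if (m < -1e-12).any() or (m > 1 + 1e-12).any():
            raise AnalysisError("dissimilarities must lie in [0, 1]")
        self.matrix = np.clip(m, 0.0, 1.0)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.matrix, index=self.labels, columns=self.labels)


def dissimilarity(profiles: pd.DataFrame | OTUTable,
                  metric: str = "bray_curtis") -> DissimilarityMatrix:
    """Pairwise sample dissimilarity.

    ``jaccard`` works on presence/absence sets, ``bray_curtis`` on
    per-sample relative abundances.  Samples with zero total are rejected
    by name.
    """
    df = profiles.counts if isinstance(profiles, OTUTable) else pd.DataFrame(profiles)
    if df.shape[1] < 2:
        raise AnalysisError("need at least two samples")
    totals = df.sum(axis=0)
    empty = list(totals.index[totals == 0])
    if empty:
        raise AnalysisError(f"samples with zero total reads: {empty}")
    if metric == "jaccard":
        data = (df > 0).T.to_numpy()
        dist = pdist(data, metric="jaccard")
    elif metric == "bray_curtis":
        rel = (df / totals).T.to_numpy()
        dist = pdist(rel, metric="braycurtis")
    else:
        raise AnalysisError(f"unknown metric {metric!r}")
    return DissimilarityMatrix(list(df.columns), squareform(dist), metric)


def cluster_dendrogram(matrix: DissimilarityMatrix,
                       method: str = "average") -> tuple[np.ndarray, str]:
    """Agglomerative clustering of a dissimilarity matrix.

    Returns the scipy linkage matrix and the tree in Newick form (leaf
    names are sample labels).  Average linkage (UPGMA) by default.
    """
    if len(matrix.labels) < 2:
        raise AnalysisError("need at least two samples to cluster")
    condensed = squareform(matrix.matrix, checks=False)
    linkage = hierarchy.linkage(condensed, method=method)
    tree = TreeNode.from_linkage_matrix(linkage, matrix.labels)
    return linkage, str(tree).strip()
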