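"""Formula-keyed spectral similarity and complete-linkage clustering.

Spectra are compared after annotation, in one of two modes: vectors
keyed by product-ion formula, or by neutral-loss composition.  Entries
are square roots of relative intensities; the NO3− reagent ion and the
precursor peak are excluded (the reagent ion reflects adduct binding
strength, and the precursor would saturate self-similarity).  Pairwise
cosine similarity feeds complete-linkage agglomerative clustering on the
cosine distance 1 − s.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import linkage, to_tree
from scipy.spatial.distance import squareform

from .annotate import AnnotatedPeak

__all__ = ["SpectrumVector", "build_vector", "cosine", "pairwise",
           "SimilarityMatrix", "Dendrogram", "cluster"]

MODES = ("product_ions", "neutral_losses")


@dataclass(frozen=True)
class SpectrumVector:
    mode: str
    entries: Mapping[str, float]

    def __post_init__(self) -> None:
        if self.mode not in MODES:
            raise ValueError(f"unknown mode {self.mode!r}")
        if any(v < 0 for v in self.entries.values()):
            raise ValueError("vector entries must be non-negative")

    def norm(self) -> float:
        return math.sqrt(sum(v * v for v in self.entries.values()))


def build_vector(annotated: Sequence[AnnotatedPeak], mode: str,
                 include_precursor: bool = False) -> SpectrumVector:
    """sqrt(relative intensity), keyed by product formula or by loss
    composition.  Relative intensities of peaks sharing a key are summed
    before the square root.  Unassigned and reagent-ion peaks never
    enter; the precursor is excluded unless explicitly requested.
    """
    if mode not in MODES:
        raise ValueError(f"unknown mode {mode!r}")
    acc: dict[str, float] = {}
    for a in annotated:
        if a.role == "reagent_ion" or a.role == "unassigned":
            continue
        if a.role == "precursor" and not include_precursor:
            continue
        if mode == "product_ions":
            key = None if a.formula is None else str(a.formula)
        else:
            key = None if a.neutral_loss is None else str(a.neutral_loss)
        if key is None:
            continue
        acc[key] = acc.get(key, 0.0) + (a.peak.rel_intensity or 0.0)
    return SpectrumVector(mode, {k: math.sqrt(v) for k, v in acc.items()})


def cosine(a: SpectrumVector, b: SpectrumVector) -> float:
    """Cosine similarity over the union key set; 0 for an empty vector."""
    if a.mode != b.mode:
        raise ValueError(f"mode mismatch: {a.mode!r} vs {b.mode!r}")
    na, nb = a.norm(), b.norm()
    if na == 0 or nb == 0:
        return 0.0
    dot = sum(v * b.entries.get(k, 0.0) for k, v in a.entries.items())
    return min(1.0, dot / (na * nb))


@dataclass
class SimilarityMatrix:
    labels: list[str]
    values: np.ndarray
    mode: str

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.labels, columns=self.labels)

    def masked(self, threshold: float = 0.2) -> pd.DataFrame:
        """Display mask: entries below the threshold blanked (NaN).  The
        mask is presentation only and never feeds clustering."""
        frame = self.to_frame().copy()
        return frame.where(frame.values >= threshold)


def pairwise(vectors: Mapping[str, SpectrumVector],
             mode: str | None = None) -> SimilarityMatrix:
    """Symmetric unit-diagonal cosine matrix over labeled vectors."""
    labels = sorted(vectors)
    if len(labels) < 2:
        raise ValueError("pairwise similarity needs at least two spectra")
    modes = {vectors[l].mode for l in labels}
    if len(modes) != 1:
        raise ValueError(f"mixed vector modes {sorted(modes)}")
    mode = mode or modes.pop()
    n = len(labels)
    values = np.eye(n)
    for i in range(n):
        for j in range(i + 1, n):
            s = cosine(vectors[labels[i]], vectors[labels[j]])
            values[i, j] = values[j, i] = s
    return SimilarityMatrix(labels, values, mode)


@dataclass
class Dendrogram:
    """Complete-linkage merge tree over spectrum labels.

    ``merges`` is a scipy linkage matrix (rows: left id, right id, merge
    height in cosine distance, cluster size).
    """

    labels: list[str]
    merges: np.ndarray

    def heights(self) -> list[float]:
        return [float(h) for h in self.merges[:, 2]]

    def to_newick(self) -> str:
        tree = to_tree(self.merges)

        def esc(label: str) -> str:
            return "".join("_" if ch in "(),:;[] \t'\"" else ch for ch in label)

        def walk(node) -> str:
            if node.is_leaf():
                return esc(self.labels[node.id])
            left, right = node.get_left(), node.get_right()
            parts = []
            for child in (left, right):
                bl = node.dist - child.dist
                parts.append(f"{walk(child)}:{bl:.6f}")
            return "(" + ",".join(parts) + ")"

        return walk(tree) + ";"

    def cut(self, height: float) -> list[set[str]]:
        """Flat clusters obtained by cutting strictly above *height*."""
        from scipy.cluster.hierarchy import fcluster
        assignment = fcluster(self.merges, t=height, criterion="distance")
        groups: dict[int, set[str]] = {}
        for label, g in zip(self.labels, assignment):
            groups.setdefault(int(g), set()).add(label)
        return list(groups.values())


def cluster(matrix: SimilarityMatrix) -> Dendrogram:
    """Complete-linkage agglomerative clustering of cosine distance.

    Labels are processed in lexicographic order so tie-breaking is
    deterministic and permutation-invariant.
    """
    if len(matrix.labels) < 2:
        raise ValueError("clustering needs at least two spectra")
    order = np.argsort(np.asarray(matrix.labels, dtype=object))
    labels = [matrix.labels[i] for i in order]
    values = matrix.values[np.ix_(order, order)]
    dist = 1.0 - np.clip(values, 0.0, 1.0)
    np.fill_diagonal(dist, 0.0)
    dist = (dist + dist.T) / 2.0
    condensed = squareform(dist, checks=False)
    merges = linkage(condensed, method="complete")
    return Dendrogram(labels=labels, merges=merges)
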