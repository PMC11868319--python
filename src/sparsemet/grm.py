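"""Genomic relationship machinery for dominant 0/1 marker data.

Builds the VanRaden genomic relationship matrix G from presence/absence
marker calls on doubled-haploid lines, filters markers on allele frequency,
conditions the (typically ill-conditioned) G for inversion, and derives the
principal-component score matrix and marker distance matrix consumed by the
training/testing-set relationship measures.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy.linalg import cho_factor, cho_solve
from scipy.spatial.distance import pdist, squareform

__all__ = [
    "MarkerMatrix",
    "FilterReport",
    "GenomicRelationship",
    "PcaScores",
    "filter_markers",
    "vanraden_g",
    "condition_and_invert",
    "distance_matrix",
    "pca_scores",
]


@dataclass
class MarkerMatrix:
    """Lines x markers matrix of dominant 0/1 calls.

    Allele frequency per marker is the column mean of the calls (the lines
    are fully homozygous, so presence of the marker is the allele count).
    """

    line_ids: list
    marker_ids: list
    calls: np.ndarray

    def __post_init__(self):
        self.calls = np.asarray(self.calls, dtype=float)
        if self.calls.ndim != 2:
            raise ValueError("calls must be a 2-D lines x markers array")
        n, m = self.calls.shape
        if len(self.line_ids) != n or len(self.marker_ids) != m:
            raise ValueError("line/marker id lengths do not match calls shape")
        if len(set(self.line_ids)) != n:
            raise ValueError("line_ids must be unique")
        if np.isnan(self.calls).any():
            raise ValueError("marker matrix contains missing cells")
        bad = ~np.isin(self.calls, (0.0, 1.0))
        if bad.any():
            raise ValueError("marker calls must be coded 0/1")

    @property
    def n_lines(self) -> int:
        return self.calls.shape[0]

    @property
    def n_markers(self) -> int:
        return self.calls.shape[1]

    @property
    def allele_freq(self) -> np.ndarray:
        return self.calls.mean(axis=0)

    def to_csv(self, path) -> None:
        df = pd.DataFrame(self.calls.astype(int), index=self.line_ids,
                          columns=self.marker_ids)
        df.to_csv(path, index_label="line")

    @classmethod
    def from_csv(cls, path) -> "MarkerMatrix":
        df = pd.read_csv(path, index_col=0)
        return cls(list(df.index.astype(str)), list(df.columns), df.to_numpy(float))


@dataclass
class FilterReport:
    """Bookkeeping from an allele-frequency filter pass."""

    n_input: int
    n_kept: int
    n_removed_below: int
    n_removed_above: int

    @property
    def n_removed(self) -> int:
        return self.n_removed_below + self.n_removed_above

    @property
    def removed_fraction(self) -> float:
        return self.n_removed / self.n_input

    @property
    def removed_below_fraction(self) -> float:
        return self.n_removed_below / self.n_input


def filter_markers(m: MarkerMatrix, min_freq: float = 0.05,
                   max_freq: float = 0.95) -> tuple[MarkerMatrix, FilterReport]:
    """Keep markers with allele frequency in [min_freq, max_freq] (inclusive).

    Raises if the filter would remove every marker.
    """
    if not (0.0 <= min_freq < max_freq <= 1.0):
        raise ValueError("need 0 <= min_freq < max_freq <= 1")
    p = m.allele_freq
    below = p < min_freq
    above = p > max_freq
    keep = ~(below | above)
    if not keep.any():
        raise ValueError("allele-frequency filter removed all markers")
    report = FilterReport(m.n_markers, int(keep.sum()),
                          int(below.sum()), int(above.sum()))
    out = MarkerMatrix(list(m.line_ids),
                       [mid for mid, k in zip(m.marker_ids, keep) if k],
                       m.calls[:, keep])
    return out, report


@dataclass
class GenomicRelationship:
    """VanRaden G plus (after conditioning) its blended form and inverse."""

    line_ids: list
    G: np.ndarray
    denominator: float = 0.0
    blend_weight: float | None = None
    G_cond: np.ndarray | None = None
    G_inv: np.ndarray | None = None
    eigen_floor: float | None = None
    logdet_cond: float | None = None

    @property
    def n_lines(self) -> int:
        return self.G.shape[0]

    def to_csv(self, path, which: str = "G") -> None:
        mat = {"G": self.G, "G_cond": self.G_cond, "G_inv": self.G_inv}[which]
        if mat is None:
            raise ValueError(f"{which} not computed yet")
        pd.DataFrame(mat, index=self.line_ids, columns=self.line_ids).to_csv(
            path, index_label="line")


def vanraden_g(m: MarkerMatrix) -> GenomicRelationship:
    """G = ZZ' / (2 * sum p_j (1 - p_j)) with Z the p-centered 0/1 calls.

    The 2 p q scaling is the conventional biallelic normalisation; under the
    0/1 doubled-haploid coding it rescales G by a global constant, which
    cancels in every correlation downstream.
    """
    p = m.allele_freq
    denom = 2.0 * float(np.sum(p * (1.0 - p)))
    if denom <= 0.0:
        raise ValueError("all markers are monomorphic; VanRaden denominator is 0")
    Z = m.calls - p
    G = (Z @ Z.T) / denom
    G = 0.5 * (G + G.T)
    return GenomicRelationship(list(m.line_ids), G, denominator=denom)


def condition_and_invert(g: GenomicRelationship,
                         blend_weight: float = 0.02) -> GenomicRelationship:
    """Blend G toward the identity and invert the blended matrix.

    conditioned = (1 - w) G + w I.  Duplicate lines (full sibs with
    identical marker profiles) make the raw G singular; a small identity
    blend restores positive definiteness without materially changing the
    relationship structure.
    """
    if not (0.0 <= blend_weight < 1.0):
        raise ValueError("blend_weight must be in [0, 1)")
    n = g.n_lines
    cond = (1.0 - blend_weight) * g.G + blend_weight * np.eye(n)
    try:
        c, low = cho_factor(cond, lower=True)
    except np.linalg.LinAlgError as exc:  # pragma: no cover - defensive
        raise np.linalg.LinAlgError(
            f"Cholesky failed at blend_weight={blend_weight}; "
            "try a larger blend weight") from exc
    G_inv = cho_solve((c, low), np.eye(n))
    G_inv = 0.5 * (G_inv + G_inv.T)
    logdet = 2.0 * float(np.sum(np.log(np.diag(c))))
    floor = float(np.linalg.eigvalsh(cond)[0])
    return replace(g, blend_weight=blend_weight, G_cond=cond, G_inv=G_inv,
                   eigen_floor=floor, logdet_cond=logdet)


def distance_matrix(m: MarkerMatrix) -> np.ndarray:
    """Euclidean distance between line rows of the 0/1 marker matrix."""
    return squareform(pdist(m.calls, metric="euclidean"))


@dataclass
class PcaScores:
    """Principal-component scores of G: P = V sqrt(Lambda), PP' ~ G."""

    line_ids: list
    P: np.ndarray
    explained_variance: np.ndarray

    @property
    def k(self) -> int:
        return self.P.shape[1]

    def to_csv(self, path) -> None:
        cols = [f"PC{i + 1}" for i in range(self.k)]
        pd.DataFrame(self.P, index=self.line_ids, columns=cols).to_csv(
            path, index_label="line")


def pca_scores(g: GenomicRelationship, k: int | None = None) -> PcaScores:
    """Eigendecompose G; scores are eigenvectors scaled by sqrt eigenvalues.

    Components ordered by decreasing eigenvalue; eigenvalues below zero
    (numerical noise, or rank deficiency before conditioning) are clipped
    with a warning.
    """
    n = g.n_lines
    if k is None:
        k = n
    if k > n:
        raise ValueError(f"k={k} exceeds number of lines {n}")
    w, v = np.linalg.eigh(g.G)
    order = np.argsort(w)[::-1]
    w, v = w[order], v[:, order]
    if w[-1] < -1e-8 * max(1.0, abs(w[0])):
        warnings.warn(
            f"G has negative eigenvalues (min {w[-1]:.3e}); clipping at 0",
            stacklevel=2)
    w = np.clip(w, 0.0, None)
    P = v[:, :k] * np.sqrt(w[:k])
    return PcaScores(list(g.line_ids), P, w[:k])
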