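"""Marker dosage matrices aligned to a pedigree, and the derived designs.

Dosages count copies of the allele labelled "1" (0/1/2).  The module computes
allele frequencies, the per-marker effect variance implied by an additive
genetic variance, the genomic relationship G = WW', and the
Mendelian-sampling marker designs

    S = W_d - D W_b        (within-family deviation from the parental mean)
    C = 2 W_d - D W_b      (S plus the direct marker term W_d)

used by the Mendelian-segregation model.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .pedigree_algebra import Pedigree

__all__ = [
    "MarkerMatrix",
    "VarianceComponents",
    "allele_frequencies",
    "marker_variance_from_additive",
    "genomic_relationship",
    "ms_design",
]


@dataclass(frozen=True)
class VarianceComponents:
    """Known variance components (never estimated here).

    sigma_u2 : additive/infinitesimal variance (base individuals in the MS
               model, whole pedigree otherwise)
    sigma_m2 : variance of each marked (marker-attached) effect
    sigma_e2 : residual variance
    """

    sigma_u2: float | None = None
    sigma_m2: float | None = None
    sigma_e2: float | None = None

    def require(self, *names: str) -> None:
        for name in names:
            value = getattr(self, name)
            if value is None or value <= 0:
                raise ValueError(f"{name} must be a positive known variance, got {value}")


@dataclass(frozen=True)
class MarkerMatrix:
    """Dosage matrix row-aligned to a pedigree's internal order.

    W[i, j] is the 0/1/2 dosage of individual ``ped.ids[i]`` at marker j.
    """

    W: np.ndarray
    marker_ids: tuple
    ped: Pedigree

    def __post_init__(self):
        W = np.asarray(self.W, dtype=float)
        if W.ndim != 2:
            raise ValueError("W must be 2-dimensional")
        if W.shape[0] != self.ped.n:
            raise ValueError(
                f"W has {W.shape[0]} rows but pedigree has {self.ped.n} individuals"
            )
        if W.shape[1] != len(self.marker_ids):
            raise ValueError("marker_ids length does not match W columns")
        if not np.isin(W, (0.0, 1.0, 2.0)).all():
            bad = W[~np.isin(W, (0.0, 1.0, 2.0))][:5]
            raise ValueError(f"dosages must be 0/1/2 with no missing values; saw {bad}")
        object.__setattr__(self, "W", W)

    @property
    def n_markers(self) -> int:
        return self.W.shape[1]

    @property
    def W_b(self) -> np.ndarray:
        """Rows for base individuals."""
        return self.W[: self.ped.n_base]

    @property
    def W_d(self) -> np.ndarray:
        """Rows for descendants."""
        return self.W[self.ped.n_base:]

    def rows(self, ids) -> np.ndarray:
        return self.W[[self.ped.index_of(i) for i in ids]]

    def drop_monomorphic(self) -> "MarkerMatrix":
        keep = self.W.std(axis=0) > 0
        return MarkerMatrix(
            W=self.W[:, keep],
            marker_ids=tuple(m for m, k in zip(self.marker_ids, keep) if k),
            ped=self.ped,
        )


def allele_frequencies(markers: MarkerMatrix, subset=None) -> np.ndarray:
    """Frequency of allele "1" per marker: half the mean dosage over ``subset``.

    ``subset`` is an iterable of individual ids (default: all individuals).
    """
    if subset is None:
        W = markers.W
    else:
        idx = [markers.ped.index_of(i) for i in subset]
        if not idx:
            raise ValueError("empty subset for allele frequencies")
        W = markers.W[idx]
    return W.mean(axis=0) / 2.0


def marker_variance_from_additive(sigma_u2: float, p: np.ndarray) -> float:
    """Per-marker effect variance sigma_m2 = sigma_u2 / (2 sum_j p_j (1 - p_j)).

    Spreads a known additive variance over the markers under Hardy-Weinberg
    and linkage-equilibrium heterozygosity; monomorphic markers contribute
    nothing to the denominator.
    """
    p = np.asarray(p, dtype=float)
    denom = 2.0 * np.sum(p * (1.0 - p))
    if denom <= 0:
        raise ValueError("zero marked variance denominator: all markers monomorphic")
    return float(sigma_u2) / denom


def genomic_relationship(markers: MarkerMatrix, center: bool = False,
                         scale: bool = False) -> np.ndarray:
    """Genomic relationship G = WW' on raw dosages.

    The default is the plain cross-product, the form under which SNP-BLUP
    with Var(m) = I sigma_m2 and GBLUP with Var(u) = G sigma_m2 coincide.
    ``center`` subtracts 2p per column and ``scale`` divides by
    2 sum p(1-p) (the VanRaden form); both default off.
    """
    W = markers.W
    if center or scale:
        p = allele_frequencies(markers)
        if center:
            W = W - 2.0 * p
        if scale:
            denom = 2.0 * np.sum(p * (1.0 - p))
            if denom <= 0:
                raise ValueError("cannot scale: all markers monomorphic")
            return (W @ W.T) / denom
    return W @ W.T


def ms_design(markers: MarkerMatrix, D: np.ndarray):
    """Mendelian-sampling marker designs for the descendants.

    Returns ``(S, C)`` with S = W_d - D W_b (molecular Mendelian sampling:
    each descendant's dosages minus its pedigree-expected dosages from the
    base) and C = 2 W_d - D W_b = S + W_d, the coefficient matrix of the
    marker term in the MS phenotype model.
    """
    W_b, W_d = markers.W_b, markers.W_d
    D = np.asarray(D, dtype=float)
    if D.shape != (W_d.shape[0], W_b.shape[0]):
        raise ValueError(
            f"D has shape {D.shape}, expected ({W_d.shape[0]}, {W_b.shape[0]})"
        )
    DWb = D @ W_b
    S = W_d - DWb
    C = 2.0 * W_d - DWb
    return S, C
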