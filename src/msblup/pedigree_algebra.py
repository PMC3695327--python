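"""Pedigree parsing and relationship-matrix algebra.

A pedigree is viewed as a directed acyclic graph whose adjacency matrix P
has a row per individual with 1's at the two parents (a single entry of 2
under self-mating).  The Laplacian-like matrix M = I - P/2 encodes "individual
minus mean of parents"; its block structure under a base-first ordering yields
the transmission matrix D = -M_dd^{-1} M_db, which attributes each descendant
genome to the base (founder) individuals.  The classical additive relationship
matrix A and its sparse inverse are built from the same factorization.

Conventions
-----------
* Individuals are internally reordered base-first, then topologically among
  descendants (parents before offspring).  ``Pedigree.ids`` is in this
  internal order; ``Pedigree.input_order`` maps back to the caller's order.
* Unknown parents are represented by index -1.  An individual is *base* iff
  both parents are unknown; individuals with exactly one known parent are
  rejected (the model assumes descendants have two known parents).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp

__all__ = [
    "Pedigree",
    "PedigreeMatrices",
    "PedigreeError",
    "parse_pedigree",
    "build_P",
    "build_M_blocks",
    "build_D",
    "build_A",
    "build_A_inverse",
    "inbreeding_coefficients",
    "reconstruct_u",
]

#: tokens accepted as "parent unknown" in input records / files
MISSING_TOKENS = {"", "0", "na", "NA", ".", None, 0}


class PedigreeError(ValueError):
    """Raised for structurally invalid pedigrees (cycles, orphans, duplicates)."""


@dataclass(frozen=True)
class Pedigree:
    """Validated pedigree in base-first topological order.

    Attributes
    ----------
    ids : list of str
        Individual identifiers, base individuals first, then descendants in
        an order where every parent precedes its offspring.
    sire, dam : ndarray of int
        Parent indices into ``ids`` (-1 for unknown; both -1 iff base).
    is_base : ndarray of bool
        True for founders (both parents unknown).
    input_order : ndarray of int
        ``input_order[k]`` is the internal index of the k-th input record.
    """

    ids: tuple
    sire: np.ndarray
    dam: np.ndarray
    is_base: np.ndarray
    input_order: np.ndarray
    _index: dict = field(repr=False, default=None)

    def __post_init__(self):
        object.__setattr__(self, "_index", {j: i for i, j in enumerate(self.ids)})

    @property
    def n(self) -> int:
        return len(self.ids)

    @property
    def n_base(self) -> int:
        return int(self.is_base.sum())

    @property
    def n_desc(self) -> int:
        return self.n - self.n_base

    def index_of(self, individual_id) -> int:
        try:
            return self._index[individual_id]
        except KeyError:
            raise KeyError(f"individual not in pedigree: {individual_id!r}") from None

    @property
    def base_ids(self) -> tuple:
        return self.ids[: self.n_base]

    @property
    def desc_ids(self) -> tuple:
        return self.ids[self.n_base:]


@dataclass
class PedigreeMatrices:
    """All derived pedigree matrices in the pedigree's internal order."""

    P: sp.csr_matrix
    M: sp.csr_matrix
    M_bb: sp.csr_matrix
    M_bd: sp.csr_matrix
    M_db: sp.csr_matrix
    M_dd: sp.csr_matrix
    D: np.ndarray
    A: np.ndarray
    A_inv: sp.csr_matrix


def _is_missing(token) -> bool:
    if token in MISSING_TOKENS:
        return True
    if isinstance(token, str) and token.strip().lower() in {"", "0", "na", "."}:
        return True
    if isinstance(token, float) and np.isnan(token):
        return True
    return False


def parse_pedigree(records) -> Pedigree:
    """Validate and topologically sort (id, sire, dam) records.

    Parameters
    ----------
    records : iterable of (id, sire, dam)
        Parent fields may be ``None``, ``""``, ``"0"``, ``"NA"`` or ``"."``
        for "unknown".  Input order is arbitrary; parents may appear after
        their offspring.

    Returns
    -------
    Pedigree
        Internally ordered base-first; ``input_order`` maps record positions
        to internal indices.

    Raises
    ------
    PedigreeError
        On duplicate ids, a single known parent, an unresolved parent
        reference, or a cycle; the message names the offending individual.
    """
    records = [(str(r[0]), r[1], r[2]) for r in records]
    ids_in = [r[0] for r in records]
    seen = set()
    for i in ids_in:
        if i in seen:
            raise PedigreeError(f"duplicate id: {i}")
        seen.add(i)

    parents = {}
    for iid, s, d in records:
        s_missing, d_missing = _is_missing(s), _is_missing(d)
        if s_missing != d_missing:
            raise PedigreeError(f"single known parent: {iid}")
        if s_missing:
            parents[iid] = None
        else:
            s, d = str(s), str(d)
            for p in (s, d):
                if p not in seen:
                    raise PedigreeError(
                        f"unresolved parent reference: {p} (offspring {iid})"
                    )
            parents[iid] = (s, d)

    # Kahn topological sort with base individuals as sources, base-first order.
    base = [i for i in ids_in if parents[i] is None]
    base_set = set(base)
    desc = [i for i in ids_in if parents[i] is not None]
    children = {i: [] for i in ids_in}
    remaining = {}
    for i in desc:
        deps = set(parents[i]) - base_set
        remaining[i] = len(deps)
        for p in deps:
            children[p].append(i)
    order = list(base)
    queue = [i for i in desc if remaining[i] == 0]
    pos = 0
    while pos < len(queue):
        i = queue[pos]
        pos += 1
        order.append(i)
        for c in children[i]:
            remaining[c] -= 1
            if remaining[c] == 0:
                queue.append(c)
    if len(order) != len(ids_in):
        cyclic = sorted(set(ids_in) - set(order))
        raise PedigreeError(f"cycle involving: {', '.join(cyclic)}")

    index = {iid: k for k, iid in enumerate(order)}
    n = len(order)
    sire = np.full(n, -1, dtype=np.int64)
    dam = np.full(n, -1, dtype=np.int64)
    for iid in desc:
        s, d = parents[iid]
        sire[index[iid]] = index[s]
        dam[index[iid]] = index[d]
    is_base = sire < 0
    input_order = np.array([index[i] for i in ids_in], dtype=np.int64)
    return Pedigree(
        ids=tuple(order), sire=sire, dam=dam, is_base=is_base, input_order=input_order
    )


def build_P(ped: Pedigree) -> sp.csr_matrix:
    """Parent-adjacency matrix: row i holds 1 at each parent of i.

    Base rows are all zero; a self-mated descendant gets a single entry of 2
    so that P/2 still averages the (identical) parental contributions.
    """
    rows, cols, vals = [], [], []
    for i in range(ped.n):
        if ped.is_base[i]:
            continue
        s, d = ped.sire[i], ped.dam[i]
        if s == d:
            rows.append(i); cols.append(s); vals.append(2.0)
        else:
            rows.extend([i, i]); cols.extend([s, d]); vals.extend([1.0, 1.0])
    return sp.csr_matrix((vals, (rows, cols)), shape=(ped.n, ped.n))


def build_M_blocks(ped: Pedigree) -> dict:
    """M = I - P/2 and its base/descendant blocks.

    Under the internal base-first topological order M is unit lower
    triangular with M_bb = I and M_bd = 0.
    """
    P = build_P(ped)
    M = (sp.identity(ped.n, format="csr") - 0.5 * P).tocsr()
    nb = ped.n_base
    return {
        "P": P,
        "M": M,
        "M_bb": M[:nb, :nb],
        "M_bd": M[:nb, nb:],
        "M_db": M[nb:, :nb],
        "M_dd": M[nb:, nb:],
    }


def build_D(ped: Pedigree) -> np.ndarray:
    """Transmission matrix D = -M_dd^{-1} M_db (N_d x N_b, dense).

    Row r gives the expected fraction of descendant r's genome contributed by
    each base individual; rows sum to 1 and entries lie in [0, 1].  Solved by
    forward substitution (M_dd is unit lower triangular).
    """
    blocks = build_M_blocks(ped)
    nb, nd = ped.n_base, ped.n_desc
    if nd == 0:
        return np.zeros((0, nb))
    rhs = -blocks["M_db"].toarray()
    M_dd = blocks["M_dd"].toarray()
    from scipy.linalg import solve_triangular

    return solve_triangular(M_dd, rhs, lower=True, unit_diagonal=True) + 0.0


def build_A(ped: Pedigree) -> np.ndarray:
    """Additive relationship matrix by the recursive tabular method.

    a_jj = 1 + a(sire_j, dam_j)/2 and a_ij = (a(i, sire_j) + a(i, dam_j))/2
    for i < j in topological order.
    """
    n = ped.n
    A = np.zeros((n, n))
    for j in range(n):
        s, d = ped.sire[j], ped.dam[j]
        if s < 0:
            A[j, j] = 1.0
        else:
            A[j, j] = 1.0 + 0.5 * A[s, d]
            row = 0.5 * (A[:j, s] + A[:j, d])
            A[:j, j] = row
            A[j, :j] = row
    return A


def inbreeding_coefficients(ped: Pedigree) -> np.ndarray:
    """F_i = a_ii - 1 via the tabular method."""
    return np.diag(build_A(ped)) - 1.0


def _theta_diagonal(ped: Pedigree, F: np.ndarray | None = None) -> np.ndarray:
    """Diagonal of the within-family (Mendelian-sampling) variance matrix.

    Theta_ii = 1 for base individuals and 1/2 - (F_sire + F_dam)/4 for
    descendants, so that A = M^{-1} Theta M^{-T}.
    """
    if F is None:
        F = inbreeding_coefficients(ped)
    theta = np.ones(ped.n)
    desc = ~ped.is_base
    theta[desc] = 0.5 - 0.25 * (F[ped.sire[desc]] + F[ped.dam[desc]])
    return theta


def build_A_inverse(ped: Pedigree, method: str = "auto") -> sp.csr_matrix:
    """Sparse inverse of A.

    ``method="henderson"`` uses the factorization A^{-1} = M' Theta^{-1} M
    (Henderson's rules with inbreeding); ``"dense"`` inverts the tabular A
    directly.  ``"auto"`` picks dense below 500 individuals for exactness of
    the cross-check and the sparse factorization above.
    """
    if method == "auto":
        method = "dense" if ped.n <= 500 else "henderson"
    if method == "dense":
        return sp.csr_matrix(np.linalg.inv(build_A(ped)))
    if method == "henderson":
        M = build_M_blocks(ped)["M"]
        theta_inv = sp.diags(1.0 / _theta_diagonal(ped))
        return (M.T @ theta_inv @ M).tocsr()
    raise ValueError(f"unknown method: {method}")


def build_all(ped: Pedigree) -> PedigreeMatrices:
    """Convenience bundle of every derived matrix."""
    blocks = build_M_blocks(ped)
    return PedigreeMatrices(
        P=blocks["P"], M=blocks["M"], M_bb=blocks["M_bb"], M_bd=blocks["M_bd"],
        M_db=blocks["M_db"], M_dd=blocks["M_dd"], D=build_D(ped),
        A=build_A(ped), A_inv=build_A_inverse(ped),
    )


def reconstruct_u(u_b: np.ndarray, phi: np.ndarray, ped: Pedigree) -> np.ndarray:
    """Genetic values from base values and Mendelian-sampling deviations.

    Applies the recursion u_i = (u_sire + u_dam)/2 + phi_i for descendants
    (u_i = u_b,i for base individuals), i.e. the action of M^{-1} on the
    stacked vector [u_b; phi].
    """
    u_b = np.asarray(u_b, dtype=float)
    phi = np.asarray(phi, dtype=float)
    if u_b.shape != (ped.n_base,):
        raise ValueError(f"u_b has length {u_b.size}, expected {ped.n_base}")
    if phi.shape != (ped.n_desc,):
        raise ValueError(f"phi has length {phi.size}, expected {ped.n_desc}")
    u = np.empty(ped.n)
    u[: ped.n_base] = u_b
    for i in range(ped.n_base, ped.n):
        u[i] = 0.5 * (u[ped.sire[i]] + u[ped.dam[i]]) + phi[i - ped.n_base]
    return u


def write_matrix_triplets(matrix, row_ids, col_ids, path) -> None:
    """Write a matrix as labelled (row_id, col_id, value) triplets, zeros skipped."""
    mat = sp.coo_matrix(matrix)
    df = pd.DataFrame(
        {
            "row": [row_ids[i] for i in mat.row],
            "col": [col_ids[j] for j in mat.col],
            "value": mat.data,
        }
    )
    df.to_csv(path, sep="\t", index=False)
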