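"""Henderson mixed-model equations for four genetic-prediction models.

All models are single-trait BLUP at *known* variance components, with a
single fixed effect (the mean):

* ``II`` - individual infinitesimal model: y = mu + Zu + e, Var(u) = A sigma_u2
* ``M``  - marker (SNP-BLUP) model:        y = mu + ZWm + e, Var(m) = I sigma_m2
* ``MI`` - marker plus individual model:   y = mu + Zu + ZWm + e
* ``MS`` - Mendelian segregation model:    y = mu + Z_d D u_b
                                               + Z_d (2W_d - D W_b) m + e

In MS the infinitesimal effects are carried only by the base individuals
(u_b, Var = I sigma_u2) and every descendant's deviation from its pedigree
expectation is traced by the markers through the Mendelian-sampling design
S = W_d - D W_b.

The mixed-model equations are assembled and solved directly when their
dimension is modest.  When the number of random effects greatly exceeds the
number of records (dense SNP panels), the solver switches to the equivalent
observation-space form — solving an n x n phenotypic-covariance system and
back-mapping the BLUPs — which yields the same solutions exactly.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
from scipy.linalg import cho_factor, cho_solve

from .marker_data import MarkerMatrix, VarianceComponents, ms_design
from .pedigree_algebra import Pedigree, build_A, build_A_inverse, build_D

__all__ = [
    "ModelFit",
    "assemble_mme",
    "fit_model_II",
    "fit_model_M",
    "fit_model_MI",
    "fit_model_MS",
    "gls_oracle",
]

logger = logging.getLogger(__name__)

#: MME dimension above which the observation-space solver is used instead of
#: a direct factorization of the mixed-model equations.
MME_DIRECT_LIMIT = 1500


@dataclass
class ModelFit:
    """Solution of one model fit.

    ``u_hat`` holds the model-implied total genetic value for every pedigree
    individual (in the pedigree's internal order), including unphenotyped
    ones.  ``components`` keeps the separate pieces (e.g. residual polygenic
    vs marker part in MI) where the model has more than one.
    """

    kind: str
    ids: tuple
    mu_hat: float
    u_hat: np.ndarray
    u_b_hat: np.ndarray | None = None
    m_hat: np.ndarray | None = None
    components: dict = field(default_factory=dict)
    diagnostics: dict = field(default_factory=dict)

    def predictions(self, ids) -> np.ndarray:
        index = {j: i for i, j in enumerate(self.ids)}
        return self.u_hat[[index[i] for i in ids]]


def _as_incidence(Z, ped: Pedigree):
    """Accept an incidence matrix or a sequence of phenotyped ids/indices."""
    if sp.issparse(Z):
        return Z.tocsr()
    Z = np.asarray(Z)
    if Z.ndim == 2:
        return sp.csr_matrix(Z)
    if Z.dtype.kind in "iu":
        idx = Z.astype(int)
    else:
        idx = np.array([ped.index_of(i) for i in Z])
    n = len(idx)
    return sp.csr_matrix((np.ones(n), (np.arange(n), idx)), shape=(n, ped.n))


def assemble_mme(X, random_blocks, y, sigma_e2):
    """Assemble Henderson's mixed-model equations.

    Parameters
    ----------
    X : (n, p) fixed-effect design.
    random_blocks : list of (T, K_inv, sigma2)
        Design matrix, prior precision (None for identity) and variance of
        each random vector.  The prior enters as K_inv * sigma_e2 / sigma2.
    y : (n,) phenotypes.
    sigma_e2 : residual variance.

    Returns
    -------
    (lhs, rhs, offsets) : dense coefficient matrix, right-hand side, and the
    start offset of each effect block (fixed first).
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    y = np.asarray(y, dtype=float)
    designs = [X] + [np.asarray(T.toarray() if sp.issparse(T) else T, dtype=float)
                     for T, _, _ in random_blocks]
    sizes = [d.shape[1] for d in designs]
    offsets = np.concatenate([[0], np.cumsum(sizes)])
    dim = offsets[-1]
    lhs = np.zeros((dim, dim))
    rhs = np.zeros(dim)
    for a, Ta in enumerate(designs):
        ra = slice(offsets[a], offsets[a + 1])
        rhs[ra] = Ta.T @ y
        for b, Tb in enumerate(designs):
            if b < a:
                continue
            block = Ta.T @ Tb
            lhs[ra, offsets[b]:offsets[b + 1]] = block
            if b != a:
                lhs[offsets[b]:offsets[b + 1], ra] = block.T
    for k, (_, K_inv, sigma2) in enumerate(random_blocks):
        if sigma2 <= 0:
            raise ValueError("random-effect variance must be positive")
        lam = sigma_e2 / sigma2
        r = slice(offsets[k + 1], offsets[k + 2])
        if K_inv is None:
            lhs[r, r] += lam * np.eye(sizes[k + 1])
        else:
            K_inv = K_inv.toarray() if sp.issparse(K_inv) else np.asarray(K_inv)
            lhs[r, r] += lam * K_inv
    return lhs, rhs, offsets


def _solve_blup(y, blocks, sigma_e2):
    """Solve for (mu_hat, [BLUP per block]) with a mean-only fixed effect.

    ``blocks`` is a list of (T, K, K_inv, sigma2); K/K_inv may be None for
    identity.  Uses the direct MME when small, otherwise the equivalent
    observation-space solve (V = sum T K T' sigma2 + I sigma_e2).
    """
    y = np.asarray(y, dtype=float)
    n = y.size
    X = np.ones((n, 1))
    dim = 1 + sum(T.shape[1] for T, _, _, _ in blocks)
    if dim <= MME_DIRECT_LIMIT:
        lhs, rhs, offsets = assemble_mme(
            X, [(T, K_inv, s2) for T, _, K_inv, s2 in blocks], y, sigma_e2
        )
        sol = np.linalg.solve(lhs, rhs)
        mu_hat = float(sol[0])
        effects = [sol[offsets[k + 1]:offsets[k + 2]] for k in range(len(blocks))]
        resid = lhs @ sol - rhs
        diag = {"solver": "mme_direct", "dimension": dim,
                "residual_norm": float(np.linalg.norm(resid))}
        return mu_hat, effects, diag
    # observation-space route: exact BLUP via the phenotypic covariance
    V = sigma_e2 * np.eye(n)
    for T, K, _, s2 in blocks:
        T = np.asarray(T.toarray() if sp.issparse(T) else T, dtype=float)
        if K is None:
            V += s2 * (T @ T.T)
        else:
            K = K.toarray() if sp.issparse(K) else np.asarray(K)
            V += s2 * (T @ K @ T.T)
    c, low = cho_factor(V)
    Vinv_y = cho_solve((c, low), y)
    Vinv_1 = cho_solve((c, low), np.ones(n))
    mu_hat = float(np.ones(n) @ Vinv_y / (np.ones(n) @ Vinv_1))
    r = cho_solve((c, low), y - mu_hat)
    effects = []
    for T, K, _, s2 in blocks:
        T = np.asarray(T.toarray() if sp.issparse(T) else T, dtype=float)
        e = s2 * (T.T @ r)
        if K is not None:
            K = K.toarray() if sp.issparse(K) else np.asarray(K)
            e = s2 * (K @ (T.T @ r))
        effects.append(e)
    diag = {"solver": "observation_space", "dimension": dim, "n_obs": n}
    return mu_hat, effects, diag


def fit_model_II(y, Z, ped: Pedigree, variance: VarianceComponents) -> ModelFit:
    """Pedigree BLUP (individual infinitesimal model), Var(u) = A sigma_u2.

    Every pedigree individual receives a prediction: unphenotyped ones are
    pulled in through the relationship structure A.
    """
    variance.require("sigma_u2", "sigma_e2")
    Z = _as_incidence(Z, ped)
    A_inv = build_A_inverse(ped)
    A = build_A(ped)
    mu, (u,), diag = _solve_blup(
        y, [(Z, A, A_inv, variance.sigma_u2)], variance.sigma_e2
    )
    return ModelFit(kind="II", ids=ped.ids, mu_hat=mu, u_hat=u,
                    diagnostics=diag)


def fit_model_M(y, Z, markers: MarkerMatrix, variance: VarianceComponents) -> ModelFit:
    """SNP-BLUP (marker model), Var(m) = I sigma_m2; u_hat = W m_hat.

    Equivalent to GBLUP with G = WW' sigma_m2: the same u_hat for every
    genotyped individual.
    """
    variance.require("sigma_m2", "sigma_e2")
    ped = markers.ped
    Z = _as_incidence(Z, ped)
    T = Z @ markers.W
    mu, (m,), diag = _solve_blup(y, [(T, None, None, variance.sigma_m2)],
                                 variance.sigma_e2)
    u_hat = markers.W @ m
    return ModelFit(kind="M", ids=ped.ids, mu_hat=mu, u_hat=u_hat, m_hat=m,
                    diagnostics=diag)


def fit_model_MI(y, Z, markers: MarkerMatrix, ped: Pedigree,
                 variance: VarianceComponents) -> ModelFit:
    """Marker plus individual model: residual polygenic u alongside Wm.

    The reported genetic value is the total u_hat + (W m_hat); both pieces
    are kept in ``components``.
    """
    variance.require("sigma_u2", "sigma_m2", "sigma_e2")
    Z = _as_incidence(Z, ped)
    A_inv = build_A_inverse(ped)
    A = build_A(ped)
    T_m = Z @ markers.W
    mu, (u, m), diag = _solve_blup(
        y,
        [(Z, A, A_inv, variance.sigma_u2), (T_m, None, None, variance.sigma_m2)],
        variance.sigma_e2,
    )
    marker_part = markers.W @ m
    return ModelFit(
        kind="MI", ids=ped.ids, mu_hat=mu, u_hat=u + marker_part, m_hat=m,
        components={"polygenic": u, "marker": marker_part}, diagnostics=diag,
    )


def fit_model_MS(y, Z, markers: MarkerMatrix, ped: Pedigree,
                 variance: VarianceComponents, design_choice: str = "eq7") -> ModelFit:
    """Mendelian-segregation model.

    Base individuals carry independent infinitesimal effects u_b reached
    through the transmission matrix D; descendants' deviations are traced by
    the marker design 2W_d - DW_b.  Only descendant phenotypes enter the
    likelihood; phenotypes on base individuals are dropped with a warning.

    ``design_choice`` selects the descendant genetic-value composition:
    ``"eq7"`` (default) u_d = D u_b + (2W_d - DW_b) m, consistent with the
    phenotype model; ``"eq6"`` u_d = D u_b + (W_d - DW_b) m, the pure
    transmission decomposition without the direct marker term.
    """
    if design_choice not in ("eq7", "eq6"):
        raise ValueError(f"design_choice must be 'eq7' or 'eq6', got {design_choice!r}")
    variance.require("sigma_u2", "sigma_m2", "sigma_e2")
    Z = _as_incidence(Z, ped)
    y = np.asarray(y, dtype=float)
    nb = ped.n_base
    # restrict records to descendants
    obs_idx = np.asarray(Z.argmax(axis=1)).ravel()
    on_base = obs_idx < nb
    if on_base.any():
        logger.warning(
            "MS model ignores %d phenotype record(s) on base individuals",
            int(on_base.sum()),
        )
        Z = Z[~on_base]
        y = y[~on_base]
    if y.size == 0:
        raise ValueError("MS model requires phenotypes on descendants")
    Z_d = Z[:, nb:]
    D = build_D(ped)
    S, C = ms_design(markers, D)
    T_b = Z_d @ D
    T_m = Z_d @ C
    mu, (u_b, m), diag = _solve_blup(
        y,
        [(T_b, None, None, variance.sigma_u2), (T_m, None, None, variance.sigma_m2)],
        variance.sigma_e2,
    )
    u_hat = np.empty(ped.n)
    u_hat[:nb] = u_b
    marker_design = C if design_choice == "eq7" else S
    u_hat[nb:] = D @ u_b + marker_design @ m
    diag["design_choice"] = design_choice
    return ModelFit(
        kind="MS", ids=ped.ids, mu_hat=mu, u_hat=u_hat, u_b_hat=u_b, m_hat=m,
        components={"transmitted": np.concatenate([u_b, D @ u_b]),
                    "marker": np.concatenate([np.zeros(nb), marker_design @ m])},
        diagnostics=diag,
    )


def gls_oracle(y, X, cov_blocks, sigma_e2):
    """Closed-form GLS/BLUP reference (test oracle; dense, small n only).

    ``cov_blocks`` is a list of (T_k, K_k, sigma2_k); the data covariance is
    V = sum_k T_k K_k T_k' sigma2_k + I sigma_e2 (K None means identity).
    Returns (beta_hat, [BLUP_k]) with beta_hat = (X'V^-1 X)^-1 X'V^-1 y and
    BLUP_k = Cov(v_k, y) V^-1 (y - X beta_hat) = sigma2_k K_k T_k' V^-1 (...).
    """
    y = np.asarray(y, dtype=float)
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[0] != y.size:
        X = X.T
    n = y.size
    V = sigma_e2 * np.eye(n)
    cross = []
    for T, K, sigma2 in cov_blocks:
        T = np.asarray(T.toarray() if sp.issparse(T) else T, dtype=float)
        K = np.eye(T.shape[1]) if K is None else (
            K.toarray() if sp.issparse(K) else np.asarray(K, dtype=float))
        V += sigma2 * (T @ K @ T.T)
        cross.append(sigma2 * (K @ T.T))  # Cov(v_k, y) transposed applied later
    V_inv = np.linalg.inv(V)
    beta = np.linalg.solve(X.T @ V_inv @ X, X.T @ V_inv @ y)
    resid = y - X @ beta
    blups = [c @ V_inv @ resid for c in cross]
    return beta, blups
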