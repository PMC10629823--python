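"""Sparse canonical correlation between community and driver matrices.

Finds K pairs of sparse weight vectors (u_k over families, v_k over
abiotic drivers) maximizing u' X'Z v subject to unit L2 norms and L1
budgets, via penalized rank-one decomposition of the cross-product
matrix M = X'Z with deflation: alternate soft-thresholded updates

    u <- normalize(S(M v, delta_u)),   v <- normalize(S(M' u, delta_v)),

where each delta is found by bisection so the L1 norm meets its budget
c * sqrt(p). With c = 1 the penalty is inactive and the procedure
reduces to the leading singular triplet of M. Driver importance is the
d_k-weighted sum of absolute loadings across components, ranked within
the climate and biocide classes separately.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

__all__ = [
    "SccaConfig",
    "SccaResult",
    "scca_fit",
    "rank_drivers",
    "variance_explained",
]


@dataclass(frozen=True)
class SccaConfig:
    """Tuning knobs for the sparse CCA fit.

    ``c_u``/``c_v`` in [0, 1] scale the L1 budgets ``c * sqrt(p)``; 1
    deactivates the penalty (dense SVD), values near 0 force a single
    nonzero weight. Initialization is the deterministic leading
    singular vector, so ``seed`` only matters if random restarts are
    ever requested.
    """

    n_components: int = 5
    c_u: float = 0.5
    c_v: float = 0.7
    max_iter: int = 200
    tol: float = 1e-9
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.n_components < 1:
            raise ValueError("n_components must be >= 1")
        for name in ("c_u", "c_v"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")


@dataclass
class SccaResult:
    """Fitted components: columns of U/V are unit-L2 weight vectors."""

    family_names: list[str]
    driver_names: list[str]
    U: np.ndarray  # families x K
    V: np.ndarray  # drivers x K
    d: np.ndarray  # singular values of the (deflated) cross-product
    rho: np.ndarray  # canonical correlations corr(Xu_k, Zv_k)
    converged: list[bool]
    objective_history: list[np.ndarray] = field(default_factory=list)

    @property
    def n_components(self) -> int:
        return self.U.shape[1]

    def driver_loadings(self, k: int) -> dict[str, float]:
        return dict(zip(self.driver_names, self.V[:, k]))

    def family_loadings(self, k: int) -> dict[str, float]:
        return dict(zip(self.family_names, self.U[:, k]))


def _soft(a: np.ndarray, delta: float) -> np.ndarray:
    return np.sign(a) * np.maximum(np.abs(a) - delta, 0.0)


def _sparse_unit(a: np.ndarray, budget: float) -> np.ndarray:
    """Unit-L2 soft-thresholded vector with L1 norm <= budget.

    The threshold is located by bisection; budget < 1 is infeasible for
    a unit vector and is clamped to 1 (single nonzero entry).
    """
    budget = max(budget, 1.0)
    norm = np.linalg.norm(a)
    if norm == 0:
        out = np.zeros_like(a)
        out[0] = 1.0
        return out
    u = a / norm
    if np.abs(u).sum() <= budget + 1e-12:
        return u
    lo, hi = 0.0, float(np.abs(a).max())
    for _ in range(100):
        mid = (lo + hi) / 2.0
        s = _soft(a, mid)
        ns = np.linalg.norm(s)
        if ns == 0 or np.abs(s / ns).sum() > budget:
            lo = mid
        else:
            hi = mid
    s = _soft(a, hi)
    return s / np.linalg.norm(s)


def scca_fit(
    X: np.ndarray,
    Z: np.ndarray,
    config: SccaConfig = SccaConfig(),
    family_names: Sequence[str] | None = None,
    driver_names: Sequence[str] | None = None,
) -> SccaResult:
    """Fit K sparse components of the cross-product of two z-scored blocks.

    ``X`` is layers x families, ``Z`` layers x drivers, both with
    column mean 0 (z-scoring is the caller's convention). Components
    are extracted greedily with rank-one deflation; each component's
    alternation is a monotone ascent on u'Mv. Non-convergence within
    ``max_iter`` flags the component but is not fatal.
    """
    X = np.asarray(X, dtype=float)
    Z = np.asarray(Z, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    if Z.ndim == 1:
        Z = Z[:, None]
    if X.shape[0] != Z.shape[0]:
        raise ValueError("X and Z must share the layer axis")
    if X.shape[0] < 3:
        raise ValueError("need at least 3 layers")
    if not (np.all(np.isfinite(X)) and np.all(np.isfinite(Z))):
        raise ValueError("inputs must be finite (no absent values)")
    p_x, p_z = X.shape[1], Z.shape[1]
    K = min(config.n_components, p_x, p_z)
    budget_u = config.c_u * np.sqrt(p_x)
    budget_v = config.c_v * np.sqrt(p_z)

    M = X.T @ Z
    U = np.zeros((p_x, K))
    V = np.zeros((p_z, K))
    d = np.zeros(K)
    rho = np.zeros(K)
    converged: list[bool] = []
    history: list[np.ndarray] = []
    for k in range(K):
        # deterministic init from the dense leading singular vector
        uu, _ss, vvt = np.linalg.svd(M, full_matrices=False)
        u, v = uu[:, 0], vvt[0, :]
        # the trace starts at the first constrained iterate: the dense
        # init is unconstrained, so only subsequent steps obey ascent
        obj_trace: list[float] = []
        ok = False
        for _ in range(config.max_iter):
            u = _sparse_unit(M @ v, budget_u)
            v = _sparse_unit(M.T @ u, budget_v)
            obj = float(u @ M @ v)
            obj_trace.append(obj)
            if len(obj_trace) >= 2 and abs(obj_trace[-1] - obj_trace[-2]) <= config.tol * max(
                1.0, abs(obj)
            ):
                ok = True
                break
        dk = float(u @ M @ v)
        if dk < 0:  # orient the component so its singular value is positive
            u, dk = -u, -dk
        # sign convention: largest-magnitude driver loading positive
        j = int(np.argmax(np.abs(v)))
        if v[j] < 0:
            u, v = -u, -v
        U[:, k], V[:, k], d[k] = u, v, dk
        xu, zv = X @ u, Z @ v
        if xu.std() > 0 and zv.std() > 0:
            rho[k] = float(np.corrcoef(xu, zv)[0, 1])
        converged.append(ok)
        history.append(np.asarray(obj_trace))
        M = M - dk * np.outer(u, v)
    return SccaResult(
        family_names=list(family_names) if family_names is not None else [f"x{i}" for i in range(p_x)],
        driver_names=list(driver_names) if driver_names is not None else [f"z{i}" for i in range(p_z)],
        U=U,
        V=V,
        d=d,
        rho=rho,
        converged=converged,
        objective_history=history,
    )


def rank_drivers(
    result: SccaResult, classes: Mapping[str, str] | None = None
) -> dict[str, list[tuple[str, float]]]:
    """Rank drivers by their contribution to the overall covariance.

    importance(driver) = sum_k d_k * |v_k[driver]|, sorted descending
    with lexicographic tie-break. When a ``classes`` map (driver ->
    "climate" | "biocide") is given, rankings are produced per class;
    otherwise a single "all" ranking is returned.
    """
    imp = (np.abs(result.V) * result.d[None, :]).sum(axis=1)
    scores = dict(zip(result.driver_names, imp))
    if classes is None:
        groups = {"all": list(result.driver_names)}
    else:
        groups = {}
        for name in result.driver_names:
            groups.setdefault(classes[name], []).append(name)
    out = {}
    for clazz, names in groups.items():
        out[clazz] = sorted(
            ((n, float(scores[n])) for n in names), key=lambda t: (-t[1], t[0])
        )
    return out


def variance_explained(result: SccaResult, X: np.ndarray, Z: np.ndarray) -> dict[str, float]:
    """Redundancy indices for both blocks.

    ``biotic``: the fraction of X's total (centered) variance captured
    by least-squares regression of X's columns on the K abiotic
    canonical variates Z v_k; ``abiotic`` symmetrically for Z on the
    biotic variates X u_k.
    """
    X = np.asarray(X, dtype=float)
    Z = np.asarray(Z, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    if Z.ndim == 1:
        Z = Z[:, None]
    return {
        "biotic": _redundancy(X, Z @ result.V),
        "abiotic": _redundancy(Z, X @ result.U),
    }


def _redundancy(Y: np.ndarray, T: np.ndarray) -> float:
    """Fraction of column-centered Y variance explained by projecting on T."""
    Yc = Y - Y.mean(axis=0)
    Tc = T - T.mean(axis=0)
    total = float((Yc**2).sum())
    if total == 0:
        return 0.0
    coef, *_ = np.linalg.lstsq(Tc, Yc, rcond=None)
    fitted = Tc @ coef
    frac = float((fitted**2).sum()) / total
    return min(max(frac, 0.0), 1.0)
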