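"""Restricted maximum likelihood for linear mixed models with arbitrary
covariance structures.

The model is

    y = X beta + sum_k u_k + e,   u_k ~ N(0, sigma2_k S_k),  e ~ N(0, sigma2_e I)

for user-supplied symmetric PSD structures S_k (kinship matrix, position-wise
IBD matrix, block design products Z Z', ...).  The residual variance is
profiled out analytically, leaving an optimisation over the variance ratios
lambda_k = sigma2_k / sigma2_e >= 0, carried out on the log scale by a
batched Nelder-Mead search (variances estimated at 0 land on the lower clamp
and are snapped to the boundary).

Two implementation points matter for genome scans:

* the combined support of the structures is decomposed into connected
  components (families / half-sib clusters), so every likelihood evaluation
  factorises into small per-block Cholesky problems, and
* all linear algebra is batched over both blocks and an arbitrary number of
  phenotype vectors with their own parameters, which is what makes
  Churchill-Doerge permutation thresholds affordable: one optimiser step
  advances every permutation simultaneously, and permutations whose simplex
  has converged drop out of subsequent evaluations.

The per-block inner loop (assemble K = I + sum lambda_k S_k, factor it,
whiten [X | y], accumulate the quadratic forms) is compiled with numba when
available; a vectorised NumPy path computes identical quantities otherwise.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components

__all__ = ["VarianceComponents", "fit_vc_model", "BlockedREML"]

_LOG_LO = -18.0  # exp(-18) ~ 1.5e-8: effective zero for a variance ratio
_LOG_HI = 9.0
_ZERO_SNAP = 1e-6

try:  # pragma: no cover - exercised implicitly everywhere
    import numba

    @numba.njit(cache=True, fastmath=True)
    def _accumulate_group(S, lam, Yblk, Xblk, logdet, M):  # pragma: no cover
        """Fused per-block REML quadratic forms.

        S: (k, nb, m, m) structures; lam: (B, k) ratios; Yblk: (nb, m, B);
        Xblk: (nb, m, p).  Adds 2*log|chol K| into logdet (B,) and
        R' K^-1 R into M (B, p+1, p+1) for R = [X | y_b].
        """
        k, nb, m, _ = S.shape
        B = lam.shape[0]
        p = Xblk.shape[2]
        q = p + 1
        K = np.empty((m, m))
        R = np.empty((m, q))
        for b in range(B):
            for blk in range(nb):
                for i in range(m):
                    for j in range(i + 1):
                        acc = 0.0
                        for t in range(k):
                            acc += lam[b, t] * S[t, blk, i, j]
                        K[i, j] = acc
                    K[i, i] += 1.0
                # in-place lower Cholesky
                ld = 0.0
                for i in range(m):
                    for j in range(i + 1):
                        s = K[i, j]
                        for t in range(j):
                            s -= K[i, t] * K[j, t]
                        if i == j:
                            if s < 1e-12:
                                s = 1e-12
                            K[i, i] = np.sqrt(s)
                            ld += np.log(K[i, i])
                        else:
                            K[i, j] = s / K[j, j]
                logdet[b] += 2.0 * ld
                for i in range(m):
                    for t in range(p):
                        R[i, t] = Xblk[blk, i, t]
                    R[i, p] = Yblk[blk, i, b]
                # forward substitution: R <- L^-1 R
                for i in range(m):
                    for t in range(q):
                        s = R[i, t]
                        for j in range(i):
                            s -= K[i, j] * R[j, t]
                        R[i, t] = s / K[i, i]
                for t1 in range(q):
                    for t2 in range(t1 + 1):
                        s = 0.0
                        for i in range(m):
                            s += R[i, t1] * R[i, t2]
                        M[b, t1, t2] += s
                        if t1 != t2:
                            M[b, t2, t1] += s

    _HAVE_NUMBA = True
except ImportError:  # pragma: no cover
    _HAVE_NUMBA = False


def _accumulate_group_numpy(S, lam, Yblk, Xblk, logdet, M):
    """NumPy twin of the numba kernel (batched Cholesky + LU solves)."""
    k, nb, m, _ = S.shape
    B = lam.shape[0]
    p = Xblk.shape[2]
    K = np.einsum("bk,knij->bnij", lam, S, optimize=True)
    K += np.eye(m)
    L = np.linalg.cholesky(K)
    logdet += 2.0 * np.log(np.diagonal(L, axis1=-2, axis2=-1)).sum(axis=(1, 2))
    yb = np.moveaxis(Yblk, -1, 0)[..., None]  # (B, nb, m, 1)
    R = np.concatenate([np.broadcast_to(Xblk, (B, nb, m, p)), yb], axis=-1)
    KiR = np.linalg.solve(K, R)
    M += np.einsum("bnmi,bnmj->bij", R, KiR, optimize=True)


@dataclass
class VarianceComponents:
    """REML fit summary: fixed effects and variance components."""

    beta: np.ndarray
    sigma2: dict[str, float]  # one entry per random structure
    sigma2_e: float
    log_restricted_likelihood: float
    converged: bool
    n: int
    n_fixed: int

    @property
    def sigma2_a(self) -> float:
        return self.sigma2.get("additive", next(iter(self.sigma2.values())))

    @property
    def sigma2_q(self) -> float:
        return self.sigma2.get("qtl", 0.0)


class BlockedREML:
    """Profiled-REML evaluator over the connected components of the model.

    Parameters
    ----------
    X : (n, p) full-column-rank fixed-effect design.
    structures : list of (n, n) symmetric covariance structures.  Their
        combined off-diagonal support defines the block decomposition; the
        blocks are fixed at construction, but the *values* of a structure can
        be swapped per genomic position via :meth:`set_structure` (the scan
        re-uses one evaluator because the IBD support never grows beyond the
        family structure).
    """

    def __init__(
        self,
        X: np.ndarray,
        structures: list[np.ndarray],
        support: np.ndarray | None = None,
    ):
        X = np.asarray(X, dtype=float)
        n, p = X.shape
        if np.linalg.matrix_rank(X) < p:
            raise ValueError("fixed-effect design X is rank deficient")
        self.n, self.p = n, p
        self.k = len(structures)

        adj = np.zeros((n, n), dtype=bool)
        for s in structures:
            adj |= np.abs(np.asarray(s)) > 1e-12
        if support is not None:
            adj |= np.abs(np.asarray(support)) > 1e-12
        _, labels = connected_components(csr_matrix(adj), directed=False)

        comp_members: dict[int, list[int]] = {}
        for i, lab in enumerate(labels):
            comp_members.setdefault(lab, []).append(i)
        by_size: dict[int, list[list[int]]] = {}
        for members in comp_members.values():
            by_size.setdefault(len(members), []).append(members)

        self.groups: list[dict] = []
        for m_size in sorted(by_size):
            idx = np.asarray(by_size[m_size])  # (nb, m)
            S = np.ascontiguousarray(
                np.stack(
                    [
                        np.asarray(s, dtype=float)[idx[:, :, None], idx[:, None, :]]
                        for s in structures
                    ]
                )
            )  # (k, nb, m, m)
            Xg = np.ascontiguousarray(X[idx])  # (nb, m, p)
            self.groups.append({"idx": idx, "S": S, "X": Xg})

    def set_structure(self, k: int, matrix: np.ndarray) -> None:
        """Replace structure ``k``'s values (support must stay within blocks)."""
        M = np.asarray(matrix, dtype=float)
        for g in self.groups:
            idx = g["idx"]
            g["S"][k] = M[idx[:, :, None], idx[:, None, :]]

    def _blocks_of(self, Y: np.ndarray) -> list[np.ndarray]:
        """Split a phenotype batch Y (n, B) into per-group (nb, m, B) arrays."""
        return [np.ascontiguousarray(Y[g["idx"]]) for g in self.groups]

    def loglik(
        self,
        log_lam: np.ndarray,
        Y_blocks: list[np.ndarray],
        rows: np.ndarray | None = None,
        want_beta: bool = False,
    ):
        """Profiled restricted log-likelihood for each batch element.

        ``log_lam``: (B, k) log variance ratios; ``Y_blocks``: output of
        :meth:`_blocks_of` for an (n, B) phenotype batch; ``rows`` optionally
        restricts evaluation to a subset of batch elements (``log_lam`` must
        then already be the subset).
        """
        lam = np.ascontiguousarray(np.exp(np.clip(log_lam, _LOG_LO, _LOG_HI)))
        B = lam.shape[0]
        n, p = self.n, self.p
        M_acc = np.zeros((B, p + 1, p + 1))
        logdetK = np.zeros(B)
        for g, Yb_full in zip(self.groups, Y_blocks):
            Yb = Yb_full if rows is None else np.ascontiguousarray(Yb_full[:, :, rows])
            if _HAVE_NUMBA:
                _accumulate_group(g["S"], lam, Yb, g["X"], logdetK, M_acc)
            else:
                _accumulate_group_numpy(g["S"], lam, Yb, g["X"], logdetK, M_acc)

        XtKiX = M_acc[:, :p, :p]
        XtKiy = M_acc[:, :p, p]
        ytKiy = M_acc[:, p, p]
        beta = np.linalg.solve(XtKiX, XtKiy[..., None])[..., 0]
        rq = np.maximum(ytKiy - np.einsum("bi,bi->b", XtKiy, beta), 1e-300)
        sigma2 = rq / (n - p)
        _, logdetXKX = np.linalg.slogdet(XtKiX)
        ll = -0.5 * (
            logdetK + logdetXKX + (n - p) * (1.0 + np.log(2.0 * np.pi * sigma2))
        )
        if want_beta:
            return ll, sigma2, beta
        return ll

    def fit(
        self,
        Y: np.ndarray,
        extra_starts: list[np.ndarray] | None = None,
        default_starts: bool = True,
        init_simplex: np.ndarray | None = None,
        iters: int = 70,
        polish_iters: int = 30,
        tol: float = 1e-7,
    ) -> dict:
        """Maximise the restricted likelihood for each column of Y (n, B).

        Runs a batched Nelder-Mead from a generic interior start and a
        near-boundary start (plus any ``extra_starts``, each (k,) or (B, k));
        keeps the best per batch element, then polishes with a small simplex.
        ``default_starts=False`` drops the generic starts, and
        ``init_simplex`` (B, k+1, k) replaces the start logic entirely with a
        single search from a caller-built simplex (used by the scan, whose
        warm-start simplex already spans the null solution and a
        moderate-QTL vertex).

        Returns dict with ``loglik`` (B,), ``lam`` (B, k), ``sigma2_e`` (B,),
        ``beta`` (B, p), ``converged`` (B,).
        """
        Y = np.asarray(Y, dtype=float)
        if Y.ndim == 1:
            Y = Y[:, None]
        B = Y.shape[1]
        k = self.k
        Yb = self._blocks_of(Y)

        def f(x, rows=None):
            return self.loglik(x, Yb, rows=rows)

        if init_simplex is not None:
            simplexes = [np.asarray(init_simplex, dtype=float)]
        else:
            starts: list[np.ndarray] = []
            if default_starts:
                starts += [np.full((B, k), -1.0), np.full((B, k), _LOG_LO)]
            for s in extra_starts or []:
                s = np.asarray(s, dtype=float)
                starts.append(np.broadcast_to(s, (B, k)).copy())
            if not starts:
                raise ValueError("no optimiser starts supplied")
            simplexes = [_simplex_around(x0, step=2.0) for x0 in starts]

        best_x = None
        best_f = np.full(B, -np.inf)
        spread = np.zeros(B)
        for s0 in simplexes:
            x, fx, spread = _nelder_mead_batch(f, s0, iters=iters, tol=tol)
            if best_x is None:
                best_x, best_f = x, fx
            else:
                better = fx > best_f
                best_x = np.where(better[:, None], x, best_x)
                best_f = np.maximum(fx, best_f)
        if polish_iters:
            x, fx, spread = _nelder_mead_batch(
                f, _simplex_around(best_x, step=0.25), iters=polish_iters, tol=tol
            )
            better = fx > best_f
            best_x = np.where(better[:, None], x, best_x)
            best_f = np.maximum(fx, best_f)

        best_x = np.clip(best_x, _LOG_LO, _LOG_HI)
        ll, sigma2_e, beta = self.loglik(best_x, Yb, want_beta=True)
        lam = np.exp(best_x)
        lam[lam < _ZERO_SNAP] = 0.0
        return {
            "loglik": ll,
            "lam": lam,
            "sigma2_e": sigma2_e,
            "beta": beta,
            "converged": spread < 1e-4,
        }


def _simplex_around(x0: np.ndarray, step: float) -> np.ndarray:
    """Axis-aligned initial simplex (B, k+1, k) around start points (B, k)."""
    B, k = x0.shape
    simplex = np.repeat(x0[:, None, :], k + 1, axis=1)
    for j in range(k):
        simplex[:, j + 1, j] += step
    return simplex


def _nelder_mead_batch(f, simplex0: np.ndarray, iters: int, tol: float = 1e-7):
    """Batched Nelder-Mead maximisation of ``f`` from simplexes (B, k+1, k).

    Every batch element runs its own simplex; evaluations are shared batched
    calls restricted to the still-active elements.  The best vertex is never
    discarded.  Returns (x_best, f_best, final simplex spread).
    """
    simplex = np.array(simplex0, dtype=float)
    B, nv, k = simplex.shape
    fvals = np.stack([f(simplex[:, v]) for v in range(nv)], axis=1)  # (B, nv)
    active = np.arange(B)

    for _ in range(iters):
        sub = simplex[active]
        fsub = fvals[active]
        order = np.argsort(-fsub, axis=1)  # best first
        sub = np.take_along_axis(sub, order[:, :, None], axis=1)
        fsub = np.take_along_axis(fsub, order, axis=1)

        spread = fsub[:, 0] - fsub[:, -1]
        done = spread < tol
        if done.any():
            simplex[active] = sub
            fvals[active] = fsub
            active = active[~done]
            if active.size == 0:
                break
            sub = sub[~done]
            fsub = fsub[~done]

        centroid = sub[:, :-1].mean(axis=1)
        worst = sub[:, -1]
        xr = centroid + (centroid - worst)
        fr = f(xr, rows=active)
        best_f = fsub[:, 0]
        second_worst_f = fsub[:, -2]
        worst_f = fsub[:, -1]

        new_x = xr.copy()
        new_f = fr.copy()
        expand = fr > best_f
        if expand.any():
            loc = np.flatnonzero(expand)
            xe = centroid[loc] + 2.0 * (centroid[loc] - worst[loc])
            fe = f(xe, rows=active[loc])
            take = fe > fr[loc]
            new_x[loc[take]] = xe[take]
            new_f[loc[take]] = fe[take]

        accept = new_f > second_worst_f
        contract = ~accept
        if contract.any():
            loc = np.flatnonzero(contract)
            xc = centroid[loc] + 0.5 * (worst[loc] - centroid[loc])
            fc = f(xc, rows=active[loc])
            ok = fc > worst_f[loc]
            new_x[loc[ok]] = xc[ok]
            new_f[loc[ok]] = fc[ok]
            accept[loc[ok]] = True
            shrink = loc[~ok]
            if shrink.size:
                sub[shrink, 1:] = sub[shrink, 0:1] + 0.5 * (
                    sub[shrink, 1:] - sub[shrink, 0:1]
                )
                for v in range(1, nv):
                    fv = f(sub[shrink, v], rows=active[shrink])
                    fsub[shrink, v] = fv

        sub[accept, -1] = new_x[accept]
        fsub[accept, -1] = new_f[accept]
        simplex[active] = sub
        fvals[active] = fsub

    order = np.argsort(-fvals, axis=1)
    simplex = np.take_along_axis(simplex, order[:, :, None], axis=1)
    fvals = np.take_along_axis(fvals, order, axis=1)
    return simplex[:, 0], fvals[:, 0], fvals[:, 0] - fvals[:, -1]


def _check_structure(name: str, S: np.ndarray, n: int) -> np.ndarray:
    S = np.asarray(S, dtype=float)
    if S.shape != (n, n):
        raise ValueError(f"structure {name!r} must be {n} x {n}")
    if not np.allclose(S, S.T, atol=1e-8):
        raise ValueError(f"structure {name!r} is not symmetric")
    if S.any():
        w = np.linalg.eigvalsh(S)
        if w.min() < -1e-6 * max(1.0, w.max()):
            raise ValueError(f"structure {name!r} is not positive semi-definite")
    return S


def fit_vc_model(
    y: np.ndarray,
    X: np.ndarray,
    random_structures: dict[str, np.ndarray] | list[np.ndarray],
    validate: bool = True,
) -> VarianceComponents:
    """REML fit of a Gaussian mixed model with the given covariance structures.

    Parameters
    ----------
    y : (n,) response.
    X : (n, p) fixed-effect design (must have full column rank).
    random_structures
        Mapping name -> (n, n) symmetric PSD matrix (or a list; names then
        default to ``vc0``, ``vc1``, ...).  A residual component is always
        included and need not be listed.
    validate
        Check symmetry/PSD of each structure (skipped inside genome scans
        where the structures are produced by the package itself).

    Returns
    -------
    VarianceComponents with estimates constrained to be non-negative.
    """
    if not isinstance(random_structures, dict):
        random_structures = {f"vc{i}": s for i, s in enumerate(random_structures)}
    y = np.asarray(y, dtype=float)
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    n = y.shape[0]
    names = list(random_structures)
    mats = [
        _check_structure(nm, random_structures[nm], n)
        if validate
        else np.asarray(random_structures[nm], dtype=float)
        for nm in names
    ]
    engine = BlockedREML(X, mats)
    res = engine.fit(y)
    lam = res["lam"][0]
    s2e = float(res["sigma2_e"][0])
    return VarianceComponents(
        beta=res["beta"][0],
        sigma2={nm: float(l * s2e) for nm, l in zip(names, lam)},
        sigma2_e=s2e,
        log_restricted_likelihood=float(res["loglik"][0]),
        converged=bool(res["converged"][0]),
        n=n,
        n_fixed=X.shape[1],
    )
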