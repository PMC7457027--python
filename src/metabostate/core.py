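"""Core dynamics: shifted-Hill kinetics, the regulatory ODE right-hand
side, quasi-steady-state metabolic rates, and multistable steady-state
finding with linear stability classification.

The regulatory system is

    dx/dt = g_x * F_g(state) - k_x * F_k(state) * x,   x in {A, H, Rmt, Rnox}

where ``F_g`` and ``F_k`` are products of shifted-Hill multipliers over
the incoming production / degradation edges of ``x`` (an empty product is
1).  mtROS production is modulated by the oxidative flux OX = G1 + F, so
the metabolic layer feeds back on the regulatory layer even though the
pathway rates themselves are algebraic in (A, H).

Steady states are found by a damped multi-start Newton search run as one
vectorized batch over all starts; roots are deduplicated at a relative
tolerance and classified stable/unstable by the sign of the largest real
part of the numerically differentiated Jacobian's eigenvalues.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import NamedTuple, Sequence

import numpy as np
from scipy.integrate import solve_ivp

from .params import (
    DEGRADATION,
    PRODUCTION,
    RATE_NAMES,
    REGULATORS,
    ModelParameters,
    ParameterError,
    SolverSettings,
)

logger = logging.getLogger(__name__)


class RegulatoryState(NamedTuple):
    """Levels of the four regulators (A, H in nM; Rmt, Rnox in mM)."""

    A: float
    H: float
    Rmt: float
    Rnox: float


class MetabolicRates(NamedTuple):
    """Quasi-steady-state pathway rates (mM/min) and their ATP outputs
    (mM ATP/min)."""

    G1: float
    G2: float
    F: float
    G1_atp: float
    G2_atp: float
    F_atp: float


@dataclass(frozen=True)
class SteadyStateRecord:
    """One converged root of the regulatory system."""

    state: RegulatoryState
    rates: MetabolicRates
    stable: bool
    max_eig_real: float     # 1/hour
    residual: float         # scaled (dimensionless) max-norm residual
    param_set_id: int = 0


def shifted_hill(x, x0: float, n: int, lam: float):
    """Shifted Hill multiplier ``lam + (1 - lam) / (1 + (x/x0)**n)``.

    Equals 1 at ``x = 0`` and tends to ``lam`` as ``x`` grows, so
    ``lam > 1`` is activation and ``lam < 1`` inhibition; always bounded
    between ``min(1, lam)`` and ``max(1, lam)``.
    """
    if not (x0 > 0):
        raise ParameterError("Hill threshold x0 must be > 0")
    if not (lam > 0):
        raise ParameterError("fold-change lam must be > 0")
    if n < 1:
        raise ParameterError("Hill coefficient n must be >= 1")
    x = np.asarray(x, dtype=float)
    if np.any(x < 0):
        raise ValueError("regulator level x must be non-negative")
    out = lam + (1.0 - lam) / (1.0 + (x / x0) ** n)
    return out if out.ndim else float(out)


def _hill_product(values: dict, edges) -> np.ndarray | float:
    mult = 1.0
    for e in edges:
        mult = mult * shifted_hill(values[e.source], e.x0, e.n, e.lam)
    return mult


def metabolic_rates(A, H, params: ModelParameters) -> MetabolicRates:
    """Pathway rates at given pAMPK / HIF-1 levels.

    The metabolic layer is assumed equilibrated at each (A, H): each rate
    is its basal value times the product of shifted-Hill factors of its
    incoming edges (G1 and F activated by A, G1 repressed by H; G2
    activated by H, repressed by A under the shipped topology).
    """
    A = np.asarray(A, dtype=float)
    H = np.asarray(H, dtype=float)
    if np.any(A < 0) or np.any(H < 0):
        raise ValueError("A and H must be non-negative")
    values = {"A": A, "H": H}
    out = {}
    for r in RATE_NAMES:
        out[r] = params.rate_basal[r] * _hill_product(values, params.edges_onto(r))
    return MetabolicRates(
        G1=out["G1"], G2=out["G2"], F=out["F"],
        G1_atp=params.atp_yield["G1"] * out["G1"],
        G2_atp=params.atp_yield["G2"] * out["G2"],
        F_atp=params.atp_yield["F"] * out["F"],
    )


def _regulator_values(X: np.ndarray, params: ModelParameters) -> dict:
    values = {v: X[..., i] for i, v in enumerate(REGULATORS)}
    if any(e.source == "OX" for e in params.edges):
        rates = metabolic_rates(values["A"], values["H"], params)
        values["OX"] = rates.G1 + rates.F
    return values


def rhs(state, params: ModelParameters) -> np.ndarray:
    """Time derivatives of (A, H, Rmt, Rnox), per hour.

    ``state`` may be a single state (length-4) or a batch with shape
    ``(..., 4)``; the result has the same shape.
    """
    X = np.asarray(state, dtype=float)
    if X.shape[-1] != 4:
        raise ValueError("state must have 4 components (A, H, Rmt, Rnox)")
    if np.any(X < 0):
        raise ValueError("negative regulator level")
    values = _regulator_values(X, params)
    out = np.empty_like(X)
    for i, v in enumerate(REGULATORS):
        fg = _hill_product(values, params.edges_onto(v, PRODUCTION))
        fk = _hill_product(values, params.edges_onto(v, DEGRADATION))
        out[..., i] = params.g[v] * fg - params.k[v] * fk * X[..., i]
    return out


# ---------------------------------------------------------------------------
# steady-state search


class _Compiled:
    """Edge lists flattened to index/coefficient arrays so the Newton
    batch evaluates the right-hand side with a handful of vectorized
    operations instead of per-edge Python loops.  Semantics match
    :func:`rhs` / :func:`metabolic_rates` exactly."""

    _VAR_INDEX = {v: i for i, v in enumerate(REGULATORS)} | {"OX": 4}

    def __init__(self, params: ModelParameters):
        self.params = params
        self.gvec = np.array([params.g[v] for v in REGULATORS])
        self.kvec = np.array([params.k[v] for v in REGULATORS])
        self.scale = self.gvec / self.kvec
        self.basal = np.array([params.rate_basal[r] for r in RATE_NAMES])
        rate_edges = [e for e in params.edges if e.target in RATE_NAMES]
        reg_edges = [e for e in params.edges if e.target in REGULATORS]
        self.needs_ox = any(e.source == "OX" for e in reg_edges)

        def pack(edges):
            return (
                np.array([self._VAR_INDEX[e.source] for e in edges], dtype=int),
                np.array([e.x0 for e in edges]),
                np.array([float(e.n) for e in edges]),
                np.array([e.lam for e in edges]),
            )

        self.r_src, self.r_x0, self.r_n, self.r_lam = pack(rate_edges)
        self.r_tgt = [
            np.flatnonzero([e.target == r for e in rate_edges]) for r in RATE_NAMES
        ]
        self.g_src, self.g_x0, self.g_n, self.g_lam = pack(reg_edges)
        self.g_prod = [
            np.flatnonzero([e.target == v and e.arm == PRODUCTION for e in reg_edges])
            for v in REGULATORS
        ]
        self.g_deg = [
            np.flatnonzero([e.target == v and e.arm == DEGRADATION for e in reg_edges])
            for v in REGULATORS
        ]

    @staticmethod
    def _mult(V, src, x0, n, lam):
        # (S, E) shifted-Hill multipliers for the packed edges
        return lam + (1.0 - lam) / (1.0 + (V[:, src] / x0) ** n)

    def rates_g1_f(self, X: np.ndarray) -> np.ndarray:
        M = self._mult(X, self.r_src, self.r_x0, self.r_n, self.r_lam)
        g1 = self.basal[0] * M[:, self.r_tgt[0]].prod(axis=1)
        f = self.basal[2] * M[:, self.r_tgt[2]].prod(axis=1)
        return g1 + f

    def rhs(self, X: np.ndarray) -> np.ndarray:
        if self.needs_ox:
            V = np.concatenate([X, self.rates_g1_f(X)[:, None]], axis=1)
        else:
            V = X
        M = self._mult(V, self.g_src, self.g_x0, self.g_n, self.g_lam)
        out = np.empty_like(X)
        for i in range(4):
            fg = M[:, self.g_prod[i]].prod(axis=1) if len(self.g_prod[i]) else 1.0
            fk = M[:, self.g_deg[i]].prod(axis=1) if len(self.g_deg[i]) else 1.0
            out[:, i] = self.gvec[i] * fg - self.kvec[i] * fk * X[:, i]
        return out

    def scaled_residual(self, U: np.ndarray) -> np.ndarray:
        return self.rhs(np.clip(U, 0.0, None) * self.scale) / self.gvec


def _scales(params: ModelParameters) -> np.ndarray:
    # basal steady state g/k per variable: the natural magnitude of each axis
    return np.array([params.g[v] / params.k[v] for v in REGULATORS])


def _scaled_residual(U: np.ndarray, params: ModelParameters,
                     scale: np.ndarray, kvec: np.ndarray) -> np.ndarray:
    """Dimensionless residual: rhs evaluated at x = U*scale, divided by
    the turnover flux k_x * (g_x / k_x) = g_x of each variable."""
    return rhs(np.clip(U, 0.0, None) * scale, params) / (kvec * scale)


def numerical_jacobian(x: np.ndarray, params: ModelParameters,
                       rel_step: float = 1e-6) -> np.ndarray:
    """Central-difference Jacobian of ``rhs`` at ``x`` (units 1/hour)."""
    x = np.asarray(x, dtype=float)
    scale = _scales(params)
    J = np.empty((4, 4))
    for j in range(4):
        h = rel_step * max(abs(x[j]), scale[j])
        xp, xm = x.copy(), x.copy()
        xp[j] += h
        xm[j] = max(xm[j] - h, 0.0)
        J[:, j] = (rhs(xp, params) - rhs(xm, params)) / (xp[j] - xm[j])
    return J


def _newton_batch(U0: np.ndarray, params: ModelParameters, tol: float,
                  max_iter: int, compiled: "_Compiled | None" = None) -> np.ndarray:
    """Damped Newton from a batch of scaled starts; returns converged
    scaled roots (m, 4)."""
    cm = compiled or _Compiled(params)
    back_alphas = np.array([0.5, 0.25, 0.1, 0.03])
    U = U0.copy()
    R = cm.scaled_residual(U)
    rn = np.abs(R).max(axis=1)
    alive = np.ones(len(U), dtype=bool)
    roots: list[np.ndarray] = []
    for _ in range(max_iter):
        done = alive & (rn < tol)
        if done.any():
            roots.extend(U[done])
            alive &= ~done
        idx = np.flatnonzero(alive)
        if idx.size == 0:
            break
        Ua, Ra, rna = U[idx], R[idx], rn[idx]
        m = len(idx)
        # forward-difference Jacobian: all 4 perturbations in one call
        h = 1e-7 * np.maximum(Ua, 1e-3)                     # (m, 4)
        Up = np.repeat(Ua[None], 4, axis=0)                 # (4, m, 4)
        for j in range(4):
            Up[j, :, j] += h[:, j]
        Rp = cm.scaled_residual(Up.reshape(4 * m, 4)).reshape(4, m, 4)
        J = np.moveaxis((Rp - Ra[None]) / h.T[:, :, None], 0, 2)  # (m, 4, 4)
        J += 1e-12 * np.eye(4)          # ridge guards fold-point singularity
        try:
            delta = np.linalg.solve(J, -Ra[..., None])[..., 0]
        except np.linalg.LinAlgError:
            delta = np.stack(
                [np.linalg.lstsq(Ji, -Ri, rcond=None)[0] for Ji, Ri in zip(J, Ra)]
            )
        # full Newton step first; backtrack only rows it did not improve
        Unew = np.clip(Ua + delta, 1e-9, 1e7)
        Rnew = cm.scaled_residual(Unew)
        new_rn = np.abs(Rnew).max(axis=1)
        need = np.flatnonzero(~(new_rn < rna))
        if need.size:
            nb = len(back_alphas)
            cand = np.clip(
                Ua[need][None] + back_alphas[:, None, None] * delta[need][None],
                1e-9, 1e7,
            )                                               # (nb, |need|, 4)
            Rc = cm.scaled_residual(cand.reshape(nb * need.size, 4))
            Rc = Rc.reshape(nb, need.size, 4)
            cand_rn = np.abs(Rc).max(axis=2)
            improved = cand_rn < rna[need][None]
            first = np.argmax(improved, axis=0)
            best = np.where(improved.any(axis=0), first, np.argmin(cand_rn, axis=0))
            sel = np.arange(need.size)
            Unew[need] = cand[best, sel]
            Rnew[need] = Rc[best, sel]
            new_rn[need] = cand_rn[best, sel]
        U[idx], R[idx], rn[idx] = Unew, Rnew, new_rn
        # abandon diverging starts
        alive[idx[new_rn > 1e12]] = False
    final = alive & (rn < tol)
    if final.any():
        roots.extend(U[final])
    return np.array(roots) if roots else np.empty((0, 4))


def _dedup(roots: np.ndarray, rtol: float) -> np.ndarray:
    """Greedy deduplication at relative max-norm tolerance (scaled coords)."""
    accepted: list[np.ndarray] = []
    order = np.lexsort(roots.T[::-1])
    for u in roots[order]:
        if not any(
            np.max(np.abs(u - v) / np.maximum(np.abs(v), 1e-12)) < rtol
            for v in accepted
        ):
            accepted.append(u)
    return np.array(accepted) if accepted else np.empty((0, 4))


def _integration_fallback(params: ModelParameters, scale: np.ndarray,
                          rng: np.random.Generator, n: int = 6) -> np.ndarray:
    """Forward-integrate to attractors when Newton finds nothing."""
    ends = []
    for _ in range(n):
        x0 = scale * 10 ** rng.uniform(-2, 1, size=4)
        sol = solve_ivp(lambda t, x: rhs(np.clip(x, 0, None), params),
                        (0.0, 2000.0), x0, method="LSODA",
                        rtol=1e-8, atol=1e-10 * scale)
        if sol.success:
            ends.append(np.clip(sol.y[:, -1], 1e-9, None) / scale)
    return np.array(ends) if ends else np.empty((0, 4))


def find_steady_states(
    params: ModelParameters,
    n_starts: int | None = None,
    tol: float | None = None,
    dedup_rtol: float | None = None,
    rng: np.random.Generator | None = None,
    settings: SolverSettings | None = None,
    param_set_id: int = 0,
) -> list[SteadyStateRecord]:
    """Multi-start steady-state search with stability classification.

    Starts are sampled log-uniformly over a box spanning ``box_lo`` to
    ``box_hi`` times the basal level g/k of each variable.  Converged
    roots (scaled residual below ``tol``) are deduplicated at relative
    tolerance ``dedup_rtol``; each surviving root is classified by the
    largest real part of the Jacobian eigenvalues, and the quasi-steady
    metabolic rates are attached.  Returns an empty list (with a log
    message) if no start converges even after an integration fallback.
    """
    settings = settings or SolverSettings()
    n_starts = settings.n_starts if n_starts is None else n_starts
    tol = settings.tol if tol is None else tol
    dedup_rtol = settings.dedup_rtol if dedup_rtol is None else dedup_rtol
    if n_starts < 1:
        raise ValueError("n_starts must be >= 1")
    rng = rng or np.random.default_rng()

    compiled = _Compiled(params)
    scale = compiled.scale
    lo, hi = np.log10(settings.box_lo), np.log10(settings.box_hi)
    U0 = 10 ** rng.uniform(lo, hi, size=(n_starts, 4))
    roots = _newton_batch(U0, params, tol, settings.max_iter, compiled)
    if len(roots) == 0:
        ends = _integration_fallback(params, scale, rng)
        if len(ends):
            roots = _newton_batch(ends, params, tol, settings.max_iter, compiled)
    if len(roots) == 0:
        logger.warning("no steady state converged for param_set_id=%d", param_set_id)
        return []
    roots = _dedup(roots, dedup_rtol)

    kvec = np.array([params.k[v] for v in REGULATORS])
    records = []
    for u in roots:
        x = u * scale
        res = float(np.abs(_scaled_residual(u, params, scale, kvec)).max())
        J = numerical_jacobian(x, params)
        max_eig = float(np.max(np.linalg.eigvals(J).real))
        rates = metabolic_rates(x[0], x[1], params)
        records.append(SteadyStateRecord(
            state=RegulatoryState(*(float(v) for v in x)),
            rates=MetabolicRates(*(float(v) for v in rates)),
            stable=max_eig < settings.stability_eig_threshold,
            max_eig_real=max_eig,
            residual=res,
            param_set_id=param_set_id,
        ))
    records.sort(key=lambda r: (r.state.A, r.state.H))
    return records


def integrate(params: ModelParameters, x0: Sequence[float], t_span=(0.0, 500.0),
              rtol: float = 1e-8):
    """Forward integration of the regulatory system (convenience wrapper,
    used for stability cross-checks)."""
    scale = _scales(params)
    return solve_ivp(lambda t, x: rhs(np.clip(x, 0, None), params),
                     t_span, np.asarray(x0, dtype=float), method="LSODA",
                     rtol=rtol, atol=1e-10 * scale, dense_output=True)
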