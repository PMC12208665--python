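"""Occupancy estimation against the observed map.

The relaxed problem is a convex QP over conformer weights w:

    min ||rho_calc(w) - rho_obs||^2   s.t.  w >= 0,  sum(w) <= 1,

restricted to the footprint mask.  It is solved exactly through active-set
nonnegative least squares: the sum constraint, when active, is enforced by a
penalty row sharpened until the original KKT system is satisfied.

Model selection adds the cardinality constraint: at most ``cardinality``
nonzero weights, each at least ``t_min`` (mixed-integer constraints
z_i * t_min <= w_i <= z_i, z_i binary).  With screened candidate pools the
subset space is small, so the MIQP is solved by exhaustive enumeration over
all supports of size <= cardinality, each reduced to a tiny box-and-simplex
QP solved exactly by active-set enumeration.  This is globally optimal by
construction and needs no MIQP solver dependency.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np

from .density import DensityGrid, FootprintMask, density_at_points, scale_calc_to_obs

__all__ = [
    "DesignMatrix",
    "OccupancySolution",
    "build_design_matrix",
    "solve_qp",
    "solve_miqp",
    "qp_screen",
    "project_capped_simplex",
]

# weights below this are zeroed in QP solutions
WEIGHT_ZERO_TOL = 1e-4
# KKT residual target for the relaxed QP
KKT_TOL = 1e-8
# default batch size for screening large candidate pools
QP_BATCH_SIZE = 300


@dataclass(eq=False)
class DesignMatrix:
    """Per-candidate calculated density on the mask plus the observed vector."""

    A: np.ndarray                    # (n_candidates, n_voxels)
    b: np.ndarray                    # (n_voxels,)
    _gram: np.ndarray | None = None
    _atb: np.ndarray | None = None

    def __post_init__(self):
        self.A = np.atleast_2d(np.asarray(self.A, dtype=float))
        self.b = np.asarray(self.b, dtype=float).ravel()
        if self.A.shape[1] != self.b.shape[0]:
            raise ValueError("design matrix / observed vector shape mismatch")
        if not np.all(np.isfinite(self.b)):
            raise ValueError("observed vector must be finite")

    @property
    def n_candidates(self) -> int:
        return self.A.shape[0]

    @property
    def gram(self) -> np.ndarray:
        if self._gram is None:
            self._gram = self.A @ self.A.T
        return self._gram

    @property
    def atb(self) -> np.ndarray:
        if self._atb is None:
            self._atb = self.A @ self.b
        return self._atb

    @property
    def btb(self) -> float:
        return float(self.b @ self.b)

    def rss(self, w: np.ndarray) -> float:
        w = np.asarray(w, float)
        return float(w @ self.gram @ w - 2.0 * w @ self.atb + self.btb)


@dataclass(eq=False)
class OccupancySolution:
    weights: np.ndarray
    objective: float                  # residual sum of squares
    status: str = "optimal"

    @property
    def selected(self) -> np.ndarray:
        return np.flatnonzero(self.weights > 0)


def build_design_matrix(candidates, obs: DensityGrid, mask: FootprintMask,
                        resolution: float | None = None,
                        atomic_numbers=None, scale: bool = True) -> DesignMatrix:
    """Candidate densities evaluated at the masked voxel centers.

    When ``scale`` is set, the observed vector is rescaled so that the
    least-squares fit of the summed candidate density to the observation has
    unit scale: observed maps are on arbitrary units and residuals must
    compare like with like.
    """
    res = obs.resolution if resolution is None else resolution
    pts = obs.voxel_coords(mask.indices)
    rows = [density_at_points(pts, c, res, atomic_numbers=atomic_numbers)
            for c in candidates]
    A = np.vstack(rows)
    b = mask.extract(obs).astype(float)
    if scale:
        mean_calc = A.mean(axis=0)
        denom = float(mean_calc @ mean_calc)
        if denom > 0:
            s = float(mean_calc @ b) / denom
            if s > 0:
                b = b / s
    return DesignMatrix(A, b)


def project_capped_simplex(x: np.ndarray) -> np.ndarray:
    """Euclidean projection onto {w >= 0, sum(w) <= 1}."""
    y = np.maximum(x, 0.0)
    if y.sum() <= 1.0:
        return y
    # project onto the probability simplex
    u = np.sort(x)[::-1]
    css = np.cumsum(u) - 1.0
    rho = np.nonzero(u - css / (np.arange(len(x)) + 1) > 0)[0][-1]
    theta = css[rho] / (rho + 1.0)
    return np.maximum(x - theta, 0.0)


def _kkt_residual(G, c, w) -> float:
    """Max KKT violation for min w'Gw - 2c'w s.t. w >= 0, sum w <= 1."""
    g = 2.0 * (G @ w - c)
    support = w > 1e-12
    sum_active = w.sum() > 1.0 - 1e-10
    lam = max(0.0, float(-g[support].mean())) if (sum_active and support.any()) else 0.0
    stat = np.abs(g[support] + lam).max() if support.any() else 0.0
    dual = max(0.0, float(-(g[~support] + lam).min())) if (~support).any() else 0.0
    prim = max(0.0, w.sum() - 1.0, float(-w.min()) if len(w) else 0.0)
    return max(stat, dual, prim)


def solve_qp(design: DesignMatrix, tol: float = KKT_TOL) -> OccupancySolution:
    """Global minimizer of the relaxed occupancy QP, via active-set NNLS.

    Without the sum constraint the problem is nonnegative least squares,
    which Lawson-Hanson solves exactly.  When that solution exceeds unit
    total weight the simplex face is active; the equality sum(w) = 1 is then
    enforced through a heavily weighted penalty row, sharpened until the
    exact KKT conditions of the original problem hold to ``tol``.
    Non-convergence raises (no silent fallback).
    """
    from scipy.optimize import nnls

    G, c = design.gram, design.atb
    n = design.n_candidates
    if n == 0:
        raise ValueError("empty design matrix")
    if not np.any(c):
        w = np.zeros(n)
        return OccupancySolution(w, design.rss(w), "optimal")
    if not np.any(np.diag(G) > 0):
        raise RuntimeError("degenerate design (zero candidate densities)")
    At = design.A.T
    w, _ = nnls(At, design.b)
    if w.sum() > 1.0 + 1e-12:
        scale = np.sqrt(np.max(np.diag(G)))
        rho = 1e3 * scale
        for _ in range(6):
            aug = np.vstack([At, np.full((1, n), rho)])
            bb = np.concatenate([design.b, [rho]])
            w, _ = nnls(aug, bb)
            if w.sum() > 1.0:          # round the penalty residual away
                w = w / w.sum()
            if _kkt_residual(G, c, w) < tol:
                break
            rho *= 30.0
    if _kkt_residual(G, c, w) >= tol:
        raise RuntimeError(
            f"QP did not reach KKT tolerance {tol:g} "
            f"(residual {_kkt_residual(G, c, w):g})")
    w[w < WEIGHT_ZERO_TOL] = 0.0
    return OccupancySolution(w, design.rss(w), "optimal")


# ---------------------------------------------------------------------------
# exact small QP over a fixed support (box [t_min, 1], sum <= 1)

def _solve_support_qp(Gs: np.ndarray, cs: np.ndarray, t_min: float):
    """Exact minimizer of w'Gw - 2c'w with t_min <= w_i <= 1, sum w <= 1.

    Active-set enumeration: each variable free / at t_min / at 1, the sum
    constraint active or not.  Returns (weights, objective-without-b'b) or
    None when the support is infeasible.
    """
    k = len(cs)
    if k * t_min > 1.0 + 1e-12:
        return None
    best_w, best_obj = None, np.inf

    def try_state(states, sum_active):
        nonlocal best_w, best_obj
        free = [i for i, s in enumerate(states) if s == 0]
        w = np.empty(k)
        for i, s in enumerate(states):
            if s == 1:
                w[i] = t_min
            elif s == 2:
                w[i] = 1.0
        fixed_sum = sum(w[i] for i, s in enumerate(states) if s != 0)
        nf = len(free)
        lam = 0.0
        if nf:
            Gff = Gs[np.ix_(free, free)]
            rhs = cs[free].copy()
            for i, s in enumerate(states):
                if s != 0:
                    rhs -= Gs[np.ix_(free, [i])].ravel() * w[i]
            try:
                if sum_active:
                    kkt = np.zeros((nf + 1, nf + 1))
                    kkt[:nf, :nf] = 2.0 * Gff
                    kkt[:nf, nf] = 1.0
                    kkt[nf, :nf] = 1.0
                    full_rhs = np.concatenate([2.0 * rhs, [1.0 - fixed_sum]])
                    sol = np.linalg.solve(kkt, full_rhs)
                    w[free], lam = sol[:nf], sol[nf]
                else:
                    w[free] = np.linalg.solve(2.0 * Gff, 2.0 * rhs)
            except np.linalg.LinAlgError:
                return
        elif sum_active:
            if abs(fixed_sum - 1.0) > 1e-10:
                return
        # primal feasibility
        if np.any(w < t_min - 1e-9) or np.any(w > 1.0 + 1e-9):
            return
        if w.sum() > 1.0 + 1e-9:
            return
        # dual feasibility
        if sum_active and lam < -1e-9:
            return
        g = 2.0 * (Gs @ w - cs)
        for i, s in enumerate(states):
            if s == 1 and g[i] + lam < -1e-7:       # at lower bound
                return
            if s == 2 and g[i] + lam > 1e-7:        # at upper bound
                return
        obj = float(w @ Gs @ w - 2.0 * w @ cs)
        if obj < best_obj - 1e-14:
            best_obj, best_w = obj, np.clip(w, t_min, 1.0)

    # fast path: all free, sum inactive
    try_state((0,) * k, False)
    if best_w is not None and best_w.sum() <= 1.0 - 1e-9:
        return best_w, best_obj
    from itertools import product
    for states in product((0, 1, 2), repeat=k):
        for sum_active in (False, True):
            if states == (0,) * k and not sum_active:
                continue
            try_state(states, sum_active)
    if best_w is None:
        return None
    return best_w, best_obj


def solve_miqp(design: DesignMatrix, cardinality: int,
               t_min: float = 0.20) -> OccupancySolution:
    """Cardinality-constrained selection by exhaustive subset enumeration.

    Among all supports of size <= cardinality, returns the one whose exact
    constrained QP has the lowest residual; ties break to the
    lexicographically smallest index set (smaller supports enumerate first).
    The empty model (all weights zero) is always feasible.
    """
    n = design.n_candidates
    if not 1 <= cardinality <= n:
        raise ValueError("cardinality must be within [1, n_candidates]")
    if not 0.0 < t_min < 1.0:
        raise ValueError("t_min must lie in (0, 1)")
    G, c = design.gram, design.atb
    best_w = np.zeros(n)
    best_obj = 0.0                       # w'Gw - 2c'w for w = 0
    for size in range(1, cardinality + 1):
        for subset in combinations(range(n), size):
            idx = list(subset)
            res = _solve_support_qp(G[np.ix_(idx, idx)], c[idx], t_min)
            if res is None:
                continue
            ws, obj = res
            if obj < best_obj - 1e-12:
                best_obj = obj
                best_w = np.zeros(n)
                best_w[idx] = ws
    return OccupancySolution(best_w, best_obj + design.btb)


def qp_screen(candidates, obs: DensityGrid, mask: FootprintMask,
              batch_size: int = QP_BATCH_SIZE, resolution: float | None = None,
              atomic_numbers=None):
    """Batched QP screen of a large candidate pool.

    Candidates are scored in batches; those with nonzero weight are pooled
    and re-solved in one global QP.  Returns (survivors, weights, solution).
    """
    candidates = list(candidates)
    if not candidates:
        raise ValueError("no candidates to screen")
    surviving: list[int] = []
    for start in range(0, len(candidates), batch_size):
        batch = candidates[start:start + batch_size]
        design = build_design_matrix(batch, obs, mask, resolution=resolution,
                                     atomic_numbers=atomic_numbers)
        sol = solve_qp(design)
        surviving.extend(start + i for i in sol.selected)
    pool = [candidates[i] for i in surviving]
    if not pool:
        # degenerate map (e.g. zero observation): keep the first candidate
        pool = [candidates[0]]
        surviving = [0]
    design = build_design_matrix(pool, obs, mask, resolution=resolution,
                                 atomic_numbers=atomic_numbers)
    sol = solve_qp(design)
    keep = sol.selected
    if keep.size == 0:
        keep = np.array([0])
    survivors = [pool[i] for i in keep]
    return survivors, sol.weights[keep], sol
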