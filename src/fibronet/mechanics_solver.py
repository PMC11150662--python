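"""Elastic equilibrium, strain extraction, rupture pruning, stiffness assay.

The network's mechanical state is the minimum of the total potential

    U(x) = sum_springs 1/2 K (L - L0)^2  -  sum_nodes f_ext . x

with K = E*A/L0 per spring and the external forces frozen at the boundary
reaction values of the prestressed network. Springs are Hookean in tension
and compression (no buckling model). Two engines are provided: a
deterministic quasi-Newton relaxation (default) and a random-displacement
annealing schedule kept as a fidelity check; they agree in final energy on
fixtures.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import connected_components

from .network_geometry import SpringNetwork, internal_forces

__all__ = [
    "EquilibriumResult",
    "spring_constant",
    "equilibrate",
    "spring_strains",
    "prune_ruptured",
    "stiffness_assay",
    "total_spring_energy",
]


@dataclass
class EquilibriumResult:
    coords: np.ndarray
    residual: float          # max net-force magnitude over free nodes
    iterations: int
    converged: bool
    energy: float


def spring_constant(E: float, A: float, L0: float):
    """Hookean spring constant K = E*A/L0 (vectorized over arrays)."""
    E, A, L0 = np.asarray(E, dtype=float), np.asarray(A, dtype=float), np.asarray(L0, dtype=float)
    if np.any(E <= 0) or np.any(A <= 0) or np.any(L0 <= 0):
        raise ValueError("E, A and L0 must all be positive")
    out = E * A / L0
    return float(out) if out.ndim == 0 else out


def total_spring_energy(net: SpringNetwork, coords: np.ndarray | None = None) -> float:
    x = net.nodes if coords is None else coords
    live = net.spring_alive
    L = net.lengths(x)[live]
    K = net.E * net.A[live] / net.L0[live]
    return float(0.5 * np.sum(K * (L - net.L0[live]) ** 2))


def _balanced_forces(net: SpringNetwork, coords: np.ndarray) -> np.ndarray:
    """External forces with rigid-body components removed per connected component.

    Rupture can strand a component whose frozen boundary forces no longer sum
    to zero force/torque; statics is then solved in the component's comoving
    frame by projecting out the net force (uniformly) and net torque (via the
    rigid-rotation generator field).
    """
    f = net.boundary_forces.copy()
    f[~net.node_alive] = 0.0
    n = len(net.nodes)
    live = net.springs[net.spring_alive]
    adj = coo_matrix((np.ones(len(live)), (live[:, 0], live[:, 1])), shape=(n, n))
    ncomp, labels = connected_components(adj, directed=False)
    for comp in range(ncomp):
        mask = (labels == comp) & net.node_alive
        m = int(mask.sum())
        if m == 0:
            continue
        fc = f[mask]
        net_force = fc.sum(axis=0)
        if np.any(net_force != 0.0):
            fc = fc - net_force / m
        r = coords[mask] - coords[mask].mean(axis=0)
        tau = float(np.sum(r[:, 0] * fc[:, 1] - r[:, 1] * fc[:, 0]))
        if tau != 0.0:
            r2 = float(np.sum(r ** 2))
            if r2 > 0:
                gen = np.column_stack([-r[:, 1], r[:, 0]])
                fc = fc - (tau / r2) * gen
        f[mask] = fc
    return f


def equilibrate(net: SpringNetwork, mode: str = "relax", tol: float | None = None,
                seed: int | None = None, pin_boundary: bool = False,
                with_external: bool = True, max_iter: int = 2000,
                update: bool = True) -> EquilibriumResult:
    """Minimize total elastic energy minus boundary-force work.

    mode="relax" (default): damped Newton with the analytic tangent
    stiffness matrix (see ``_newton_relax``).
    mode="anneal": random node displacements of progressively decreasing
    amplitude, accepted when they lower the energy — a simulated-annealing
    style scheme retained as a cross-check, not the workhorse.

    ``pin_boundary`` holds boundary nodes at their current positions (used
    during the stiffness assay and network generation); external forces then
    do no work and are omitted. Dead nodes never move. The solution is
    written back to ``net.nodes`` unless ``update=False``.
    """
    if tol is None:
        tol = 1e-6 * net.E * (net.A[net.spring_alive].mean() if net.n_live_springs else 1.0)
    x0 = net.nodes.copy()
    free = net.node_alive.copy()
    if pin_boundary:
        free &= ~net.is_boundary
    if not free.any() or net.n_live_springs == 0:
        return EquilibriumResult(x0, 0.0, 0, True, total_spring_energy(net, x0))

    use_ext = with_external and not pin_boundary
    f_ext = _balanced_forces(net, x0) if use_ext else np.zeros_like(x0)

    live = net.spring_alive
    si, sj = net.springs[live, 0], net.springs[live, 1]
    K = net.E * net.A[live] / net.L0[live]
    L0 = net.L0[live]
    n = len(net.nodes)
    free_idx = np.flatnonzero(free)

    def forces_full(x: np.ndarray) -> np.ndarray:
        d = x[sj] - x[si]
        L = np.hypot(d[:, 0], d[:, 1])
        L = np.maximum(L, 1e-300)
        t = K * (1.0 - L0 / L)
        fx = np.bincount(si, weights=t * d[:, 0], minlength=n) \
            - np.bincount(sj, weights=t * d[:, 0], minlength=n)
        fy = np.bincount(si, weights=t * d[:, 1], minlength=n) \
            - np.bincount(sj, weights=t * d[:, 1], minlength=n)
        return np.column_stack([fx, fy]) + f_ext

    def energy(x: np.ndarray) -> float:
        d = x[sj] - x[si]
        L = np.hypot(d[:, 0], d[:, 1])
        u = 0.5 * np.sum(K * (L - L0) ** 2)
        if use_ext:
            u -= float(np.sum(f_ext * x))
        return float(u)

    if mode == "relax":
        coords, iterations = _newton_relax(
            x0, free_idx, si, sj, K, L0, energy, forces_full, tol, max_iter)
    elif mode == "anneal":
        rng = np.random.default_rng(seed)
        coords = x0.copy()
        mean_L0 = float(L0.mean())
        amp = 0.1 * mean_L0
        e_cur = energy(coords)
        iterations = 0
        while amp > 1e-9 * mean_L0 and iterations < max_iter:
            improved = False
            order = rng.permutation(free_idx)
            for node in order:
                step = amp * _unit(rng)
                trial = coords.copy()
                trial[node] += step
                e_new = energy(trial)
                if e_new < e_cur:
                    coords = trial
                    e_cur = e_new
                    improved = True
            amp *= 0.85 if not improved else 0.97
            iterations += 1
    else:
        raise ValueError(f"unknown mode: {mode!r}")

    f = forces_full(coords)
    residual = float(np.hypot(f[free_idx, 0], f[free_idx, 1]).max())
    converged = residual <= tol
    if update:
        net.nodes = coords
    return EquilibriumResult(coords, residual, iterations, converged, energy(coords))


def _newton_relax(x0, free_idx, si, sj, K, L0, energy, forces_full,
                  tol, max_iter):
    """Damped Newton minimization with the analytic tangent stiffness matrix.

    The elastic energy is nearly quadratic around the warm-start coordinates
    (remodeling perturbs areas a little per iteration), so assembling the
    exact 2x2 per-spring Hessian blocks and solving the sparse normal system
    converges in a handful of steps where first-order methods need hundreds.
    A Levenberg-style diagonal shift keeps the step a descent direction when
    compressed springs make the Hessian indefinite; rigid-body null modes
    are harmless because the balanced load has no component along them.
    """
    from scipy.sparse import coo_matrix as _coo
    from scipy.sparse.linalg import splu

    n = len(x0)
    nf = len(free_idx)
    rank = -np.ones(n, dtype=np.intp)
    rank[free_idx] = np.arange(nf)
    ri, rj = rank[si], rank[sj]
    eye = np.eye(2)

    def assemble(x):
        d = x[sj] - x[si]
        L = np.maximum(np.hypot(d[:, 0], d[:, 1]), 1e-300)
        u = d / L[:, None]
        uu = u[:, :, None] * u[:, None, :]
        B = K[:, None, None] * ((1.0 - L0 / L)[:, None, None] * (eye - uu) + uu)
        rows, cols, data = [], [], []
        off = np.array([0, 1])
        for ra, rb, sign in ((ri, ri, 1.0), (rj, rj, 1.0),
                             (ri, rj, -1.0), (rj, ri, -1.0)):
            ok = (ra >= 0) & (rb >= 0)
            if not ok.any():
                continue
            rows.append((2 * ra[ok, None, None] + off[None, :, None]
                         + 0 * off[None, None, :]).ravel())
            cols.append((2 * rb[ok, None, None] + off[None, None, :]
                         + 0 * off[None, :, None]).ravel())
            data.append((sign * B[ok]).ravel())
        H = _coo((np.concatenate(data),
                  (np.concatenate(rows), np.concatenate(cols))),
                 shape=(2 * nf, 2 * nf)).tocsc()
        return H

    x = x0.copy()
    f = forces_full(x)
    resid = float(np.hypot(f[free_idx, 0], f[free_idx, 1]).max())
    e_cur = energy(x)
    lam = 0.0
    scale = float(K.mean())
    it = 0
    while resid > tol and it < max_iter:
        H = assemble(x)
        g = -f[free_idx].ravel()
        step_ok = False
        for _ in range(12):
            try:
                shift = lam * scale
                M = H if shift == 0.0 else H + shift * _speye(2 * nf)
                dx = splu(M.tocsc()).solve(-g)
            except RuntimeError:
                lam = max(lam * 10.0, 1e-8)
                continue
            t = 1.0
            while t > 1e-6:
                trial = x.copy()
                trial[free_idx] += t * dx.reshape(-1, 2)
                e_new = energy(trial)
                if e_new <= e_cur + 1e-12 * max(abs(e_cur), 1.0):
                    step_ok = True
                    break
                t *= 0.5
            if step_ok:
                x = trial
                e_cur = e_new
                lam = max(lam / 4.0, 1e-9)
                break
            lam = max(lam * 10.0, 1e-8)
        if not step_ok:
            break
        f = forces_full(x)
        resid = float(np.hypot(f[free_idx, 0], f[free_idx, 1]).max())
        it += 1
    return x, it


def _speye(k):
    from scipy.sparse import identity
    return identity(k, format="csc")


def _unit(rng) -> np.ndarray:
    theta = rng.uniform(0.0, 2.0 * np.pi)
    return np.array([np.cos(theta), np.sin(theta)])


def spring_strains(net: SpringNetwork, coords: np.ndarray | None = None) -> np.ndarray:
    """Per-spring engineering strain at the given (default current) coordinates."""
    return net.strains(coords)


def prune_ruptured(net: SpringNetwork):
    """Remove digested springs and the debris they leave behind.

    A spring with A <= 0 has ruptured. A surviving spring both of whose
    endpoints have no other live spring is isolated and removed too; nodes
    left without any spring die. Returns (net, removed spring ids, removed
    node ids); idempotent. Agents stranded on removed nodes are the caller's
    (abm) concern.
    """
    removed_springs: list[int] = []
    ruptured = net.spring_alive & (net.A <= 0.0)
    if ruptured.any():
        removed_springs.extend(np.flatnonzero(ruptured).tolist())
        net.spring_alive[ruptured] = False
    deg = net.degrees()
    live_ids = np.flatnonzero(net.spring_alive)
    for s in live_ids:
        i, j = net.springs[s]
        if deg[i] == 1 and deg[j] == 1:
            net.spring_alive[s] = False
            removed_springs.append(int(s))
    newly_dead = net.node_alive & (net.degrees() == 0)
    removed_nodes = np.flatnonzero(newly_dead).tolist()
    net.node_alive[newly_dead] = False
    return net, removed_springs, removed_nodes


def stiffness_assay(net: SpringNetwork, n_steps: int = 5, step_strain: float = 0.02,
                    tol: float | None = None) -> tuple[float, float]:
    """Strain-energy stiffness of the network (unnormalized).

    The boundary is stretched isotropically about the live-node centroid in
    ``n_steps`` accumulating increments of ``step_strain``; after each
    stretch the interior is re-equilibrated with the boundary pinned and the
    spring energies are summed. A second-order polynomial is fit to energy
    vs cumulative strain (including the zero point) and its quadratic
    coefficient is the stiffness. Run-level curves divide by the iteration-0
    value. Operates on a copy; the run state is untouched.

    Returns (quadratic coefficient, rms residual of the fit).
    """
    work = net.copy()
    alive = work.node_alive
    centroid = work.nodes[alive].mean(axis=0)
    b = work.is_boundary & alive
    base_boundary = work.nodes[b].copy()
    strains = [0.0]
    energies = [total_spring_energy(work)]
    for k in range(1, n_steps + 1):
        s = k * step_strain
        work.nodes[b] = centroid + (1.0 + s) * (base_boundary - centroid)
        equilibrate(work, pin_boundary=True, tol=tol)
        strains.append(s)
        energies.append(total_spring_energy(work))
    coeffs = np.polyfit(strains, energies, 2)
    fit = np.polyval(coeffs, strains)
    rms = float(np.sqrt(np.mean((fit - energies) ** 2)))
    return float(coeffs[0]), rms
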