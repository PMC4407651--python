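"""Stokes cell problems on voxel water domains and the upscaled conductivity.

Homogenization of slow pore-scale flow yields Darcy's law
``u = -K (grad p0 - rho g e_z)`` with a permeability tensor parameterized
by three corrector problems, one per driving direction k:

    -lap(nu_k) + grad(pi_k) = e_k   in the water domain Omega_w,
    div(nu_k) = 0                   in Omega_w,
    nu_k = 0                        on soil and air interfaces Gamma,

with, on the outer cube faces, either true periodicity (for a reflected,
periodic geometry) or the equivalent mirror-symmetry conditions on the
un-reflected sample: on the faces normal to k, zero pressure correction,
zero normal gradient of the through-flow component and zero tangential
velocity; on the remaining faces, zero normal velocity and zero normal
gradient of pressure and in-plane velocity.  The driving force sign is
chosen so corrector velocities and K are non-negative.

Discretization is a staggered (MAC) finite-difference scheme native to
the voxel grid: pressures at cell centres, velocity components on cell
faces, solid walls honoured halfway between voxel centres.  The problem
is solved in voxel units; all physical scaling enters through the voxel
edge length and viscosity when the tensor is assembled:

    K_jk = (dx^2 / mu) <e_j . nu_k>,

the average taken over the whole cell (solid included as zeros), which
reproduces the plane-Poiseuille limit K = phi a^2 / (12 mu) exactly as
the resolution grows.  Hydraulic conductivity is K_h = rho g K_kk in
cm/s.  The symmetric-boundary discretization is the exact algebraic
folding of the periodic discretization of the reflected geometry, which
is the correctness oracle used in the tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage, sparse
from scipy.sparse import linalg as spla

from .phase_io import STRUCT_6, PhaseVolume
from .rev_sampling import REVSample

#: Water density (kg m^-3), dynamic viscosity (kg m^-1 s^-1) and
#: gravitational acceleration (m s^-2) used throughout.
RHO = 1.0e3
MU = 1.0e-3
GRAVITY = 9.8

_DIRECTIONS = {"z": 0, "y": 1, "x": 2, 0: 0, 1: 1, 2: 2}


def _axsl(axis: int, sl, ndim: int = 3) -> tuple:
    idx = [slice(None)] * ndim
    idx[axis] = sl
    return tuple(idx)


def _shift(arr: np.ndarray, axis: int, s: int, fill) -> np.ndarray:
    """Value at position p of the result is arr[p + s*e_axis]; out-of-grid
    positions receive ``fill``."""
    out = np.full_like(arr, fill)
    n = arr.shape[axis]
    if s == 1:
        out[_axsl(axis, slice(0, n - 1))] = arr[_axsl(axis, slice(1, n))]
    else:
        out[_axsl(axis, slice(1, n))] = arr[_axsl(axis, slice(0, n - 1))]
    return out


# ---------------------------------------------------------------------
# Flow domain
# ---------------------------------------------------------------------

@dataclass
class FlowDomain:
    """The water mask of an REV prepared for the cell problem.

    Air is a rigid no-slip obstacle (the non-wetting phase is stationary),
    so the flow domain is the water phase only.  Water components not
    face-connected across the domain in a given axis are retained — they
    self-consistently carry zero net flow — but flagged.
    """

    mask: np.ndarray
    voxel_size_um: float
    percolates: dict[int, bool]
    n_components: int
    n_isolated: int

    @property
    def empty(self) -> bool:
        return not bool(self.mask.any())


def flow_domain(sample: REVSample | PhaseVolume) -> FlowDomain:
    """Extract the water domain Omega_w and its connectivity flags."""
    volume = sample.volume if isinstance(sample, REVSample) else sample
    mask = volume.water_mask
    lab, n = ndimage.label(mask, structure=STRUCT_6)
    percolates = {}
    spanning: set[int] = set()
    for axis in range(3):
        lo = np.unique(lab[_axsl(axis, 0)])
        hi = np.unique(lab[_axsl(axis, -1)])
        common = np.intersect1d(lo, hi)
        common = common[common > 0]
        percolates[axis] = common.size > 0
        spanning.update(int(c) for c in common)
    n_isolated = n - len(spanning)
    return FlowDomain(mask, volume.voxel_size_um, percolates, n, n_isolated)


# ---------------------------------------------------------------------
# Cell problem
# ---------------------------------------------------------------------

@dataclass
class CellProblemSolution:
    """Discrete corrector solution for one driving direction.

    ``mean_velocity[j]`` is the volume average of e_j . nu_k over the
    whole cell in voxel units (so K_jk = mean_velocity[j] * dx^2 / mu).
    Face-velocity arrays live on the staggered grids (zeros on inactive
    faces); pressure corrections at fluid cell centres.
    """

    direction: int
    shape: tuple[int, int, int]
    mode: str
    mean_velocity: np.ndarray
    residual: float
    iterations: int
    n_unknowns: int
    max_divergence: float
    u_faces: list[np.ndarray] | None = None
    pressure: np.ndarray | None = None
    residual_history: list[float] = field(default_factory=list)


class StokesConvergenceError(RuntimeError):
    """Raised when the Krylov solver fails to reach tolerance."""

    def __init__(self, message: str, history: list[float]):
        super().__init__(message)
        self.residual_history = history


def solve_cell_problem(
    mask: np.ndarray,
    direction: int | str,
    tolerance: float = 1e-8,
    mode: str = "symmetric",
    method: str = "auto",
    maxiter: int | None = None,
    keep_fields: bool = True,
) -> CellProblemSolution:
    """Solve one corrector problem on a binary water mask.

    Parameters
    ----------
    mask
        3D boolean array, True on water voxels.
    direction
        Driving direction k: 0/1/2 or 'z'/'y'/'x' (axis 0 is z).
    tolerance
        Relative residual target (> 0).
    mode
        'symmetric' (mirror-symmetry outer boundaries, the default for
        un-reflected samples) or 'periodic' (for reflected geometries).
    method
        'direct' (sparse LU), 'minres' (Jacobi-preconditioned MINRES on
        the symmetric saddle system), or 'auto' (direct below ~1.5e5
        unknowns).
    """
    k = _DIRECTIONS[direction]
    if not tolerance > 0:
        raise ValueError("tolerance must be positive")
    if mode not in {"symmetric", "periodic"}:
        raise ValueError("mode must be 'symmetric' or 'periodic'")
    mask = np.ascontiguousarray(mask, dtype=bool)
    if mask.ndim != 3:
        raise ValueError("mask must be 3D")
    shape = mask.shape
    if not mask.any():
        return CellProblemSolution(
            k, shape, mode, np.zeros(3), 0.0, 0, 0, 0.0,
            u_faces=[np.zeros(_face_shape(shape, m, mode)) for m in range(3)]
            if keep_fields
            else None,
            pressure=np.zeros(shape) if keep_fields else None,
        )
    if mask.all():
        raise ValueError(
            "all-fluid cell with no solid or air: the net driving force is "
            "unbalanced and no steady Stokes solution exists"
        )

    sysm = _assemble(mask, k, mode)
    M, rhs, n_u, G = sysm["M"], sysm["rhs"], sysm["n_u"], sysm["G"]

    n = M.shape[0]
    if method == "auto":
        # sparse LU fill-in makes the direct path slower than MINRES well
        # before memory becomes a concern
        method = "direct" if n <= 15_000 else "minres"

    history: list[float] = []
    if method == "direct":
        lu = spla.splu(M.tocsc())
        x = lu.solve(rhs)
        iters = 1
    elif method == "minres":
        dv = M.diagonal().copy()
        dv[n_u:] = 1.0
        dv[dv <= 0] = 1.0
        inv = 1.0 / dv
        precond = spla.LinearOperator((n, n), matvec=lambda v: inv * v)
        Mc = M.tocsr()
        nb = np.linalg.norm(rhs)
        it_count = [0]

        def _cb(xk):
            it_count[0] += 1
            if it_count[0] % 25 == 0:  # sampled true-residual history
                history.append(float(np.linalg.norm(Mc @ xk - rhs) / nb))

        if maxiter is None:
            maxiter = 30_000
        # minres monitors the preconditioned residual; drive it two orders
        # below the requested tolerance so the true residual lands near it
        x, info = spla.minres(
            Mc, rhs, rtol=1e-2 * tolerance, maxiter=maxiter, M=precond, callback=_cb
        )
        iters = it_count[0]
        rel = float(np.linalg.norm(Mc @ x - rhs) / nb)
        if info != 0 and rel > 50 * tolerance:
            raise StokesConvergenceError(
                f"MINRES failed to converge: info={info}, relative residual "
                f"{rel:.3e} after {iters} iterations",
                history,
            )
    else:
        raise ValueError(f"unknown method {method!r}")

    rel_res = float(np.linalg.norm(M @ x - rhs) / np.linalg.norm(rhs))
    u = x[:n_u]
    p = x[n_u:]
    div = G.T @ u
    max_div = float(np.abs(div).max()) if div.size else 0.0

    mean_v = np.array(
        [
            float((sysm["w_all"][sysm["fidx"][m][sysm["act"][m]]] * u[
                sysm["fidx"][m][sysm["act"][m]]
            ]).sum())
            / mask.size
            for m in range(3)
        ]
    )

    u_faces = None
    pressure = None
    if keep_fields:
        u_faces = []
        for m in range(3):
            arr = np.zeros(sysm["act"][m].shape)
            arr[sysm["act"][m]] = u[sysm["fidx"][m][sysm["act"][m]]]
            u_faces.append(arr)
        pressure = np.zeros(shape)
        pressure[mask] = p

    return CellProblemSolution(
        k,
        shape,
        mode,
        mean_v,
        rel_res,
        iters,
        n,
        max_div,
        u_faces=u_faces,
        pressure=pressure,
        residual_history=history,
    )


def _face_shape(shape, m, mode):
    if mode == "periodic":
        return shape
    fs = list(shape)
    fs[m] += 1
    return tuple(fs)


def _assemble(mask: np.ndarray, k: int, mode: str) -> dict:
    """Build the symmetric saddle-point system [[A, G], [G^T, 0]] x = [b, 0].

    Rows of symmetry-plane through-flow faces are folded from the
    periodic discretization of the reflected geometry (row weight 1/2),
    so 'symmetric' on a sample and 'periodic' on its reflection are the
    same algebraic problem.
    """
    shape = mask.shape
    solid = ~mask
    n_p = int(mask.sum())
    pidx = np.full(shape, -1, dtype=np.int64)
    pidx[mask] = np.arange(n_p)

    act: list[np.ndarray] = []
    fidx: list[np.ndarray] = []
    offset = 0
    for m in range(3):
        if mode == "periodic":
            a = mask & np.roll(mask, 1, axis=m)
        else:
            n = shape[m]
            fs = list(shape)
            fs[m] += 1
            a = np.zeros(fs, dtype=bool)
            a[_axsl(m, slice(1, n))] = (
                mask[_axsl(m, slice(0, n - 1))] & mask[_axsl(m, slice(1, n))]
            )
            if m == k:
                a[_axsl(m, slice(0, 1))] = mask[_axsl(m, slice(0, 1))]
                a[_axsl(m, slice(n, n + 1))] = mask[_axsl(m, slice(n - 1, n))]
        idx = np.full(a.shape, -1, dtype=np.int64)
        idx[a] = offset + np.arange(int(a.sum()))
        offset += int(a.sum())
        act.append(a)
        fidx.append(idx)
    n_u = offset

    # flanking-cell lookups per face grid (clamped for symmetric, wrapped
    # for periodic; the clamp at the symmetry plane is the mirror cell)
    pL, pR, nsolid = [], [], []
    for m in range(3):
        n = shape[m]
        if mode == "periodic":
            l_ = np.roll(pidx, 1, axis=m)
            r_ = pidx
            sl_ = np.roll(solid, 1, axis=m)
            sr_ = solid
        else:
            l_ = np.concatenate(
                [pidx[_axsl(m, slice(0, 1))], pidx], axis=m
            )
            r_ = np.concatenate(
                [pidx, pidx[_axsl(m, slice(n - 1, n))]], axis=m
            )
            sl_ = np.concatenate(
                [solid[_axsl(m, slice(0, 1))], solid], axis=m
            )
            sr_ = np.concatenate(
                [solid, solid[_axsl(m, slice(n - 1, n))]], axis=m
            )
        pL.append(l_)
        pR.append(r_)
        nsolid.append(sl_.astype(np.int8) + sr_.astype(np.int8))

    rows_A: list[np.ndarray] = []
    cols_A: list[np.ndarray] = []
    vals_A: list[np.ndarray] = []
    rows_G: list[np.ndarray] = []
    cols_G: list[np.ndarray] = []
    vals_G: list[np.ndarray] = []
    b = np.zeros(n_u)
    w_all = np.ones(n_u)

    for m in range(3):
        a = act[m]
        ridx = fidx[m][a]
        if ridx.size == 0:
            continue
        diag = np.zeros(ridx.size)

        if mode == "symmetric" and m == k:
            pos_m = np.arange(a.shape[m])
            pos = np.broadcast_to(
                pos_m.reshape([-1 if ax == m else 1 for ax in range(3)]), a.shape
            )[a]
            plane_lo = pos == 0
            plane_hi = pos == shape[m]
            w_all[ridx[plane_lo | plane_hi]] = 0.5
        else:
            plane_lo = np.zeros(ridx.size, dtype=bool)
            plane_hi = np.zeros(ridx.size, dtype=bool)
        nonplane = ~(plane_lo | plane_hi)

        # ---- tangential slots ---------------------------------------
        for d in range(3):
            if d == m:
                continue
            for s in (-1, 1):
                if mode == "periodic":
                    nbv = np.roll(fidx[m], -s, axis=d)[a]
                    out = np.zeros(ridx.size, dtype=bool)
                else:
                    nbv = _shift(fidx[m], d, s, fill=-2)[a]
                    out = nbv == -2
                active_nb = nbv >= 0
                rows_A.append(ridx[active_nb])
                cols_A.append(nbv[active_nb])
                vals_A.append(np.full(int(active_nb.sum()), -1.0))
                diag[active_nb] += 1.0
                inact = nbv == -1
                if inact.any():
                    if mode == "periodic":
                        nsv = np.roll(nsolid[m], -s, axis=d)[a][inact]
                    else:
                        nsv = _shift(nsolid[m], d, s, fill=0)[a][inact]
                    diag[inact] += np.where(nsv == 2, 2.0, 1.0)
                if out.any() and mode == "symmetric" and d == k:
                    diag[out] += 2.0  # tangential no-slip ghost on Gamma_xk

        # ---- longitudinal slots -------------------------------------
        if mode == "periodic":
            for s in (-1, 1):
                nbv = np.roll(fidx[m], -s, axis=m)[a]
                active_nb = nbv >= 0
                rows_A.append(ridx[active_nb])
                cols_A.append(nbv[active_nb])
                vals_A.append(np.full(int(active_nb.sum()), -1.0))
                diag += 1.0  # inactive neighbour is an exact zero face
        else:
            for s in (-1, 1):
                nbv = _shift(fidx[m], m, s, fill=-2)[a]
                sel = nonplane
                active_nb = sel & (nbv >= 0)
                rows_A.append(ridx[active_nb])
                cols_A.append(nbv[active_nb])
                vals_A.append(np.full(int(active_nb.sum()), -1.0))
                diag[sel] += 1.0
            # folded symmetry-plane faces: ghost mirrors the first
            # interior face, both longitudinal slots merge onto it
            for plane, s in ((plane_lo, 1), (plane_hi, -1)):
                if not plane.any():
                    continue
                diag[plane] += 2.0
                nbv = _shift(fidx[m], m, s, fill=-2)[a][plane]
                ok = nbv >= 0
                rows_A.append(ridx[plane][ok])
                cols_A.append(nbv[ok])
                vals_A.append(np.full(int(ok.sum()), -2.0))

        rows_A.append(ridx)
        cols_A.append(ridx)
        vals_A.append(diag)

        # ---- pressure gradient --------------------------------------
        pLv = pL[m][a]
        pRv = pR[m][a]
        for sel, col, val in (
            (nonplane, pRv, 1.0),
            (nonplane, pLv, -1.0),
            (plane_lo, pRv, 2.0),
            (plane_hi, pLv, -2.0),
        ):
            use = sel & (col >= 0)
            rows_G.append(ridx[use])
            cols_G.append(col[use])
            vals_G.append(np.full(int(use.sum()), val))

        if m == k:
            b[ridx] = 1.0

    rA = np.concatenate(rows_A)
    cA = np.concatenate(cols_A)
    vA = np.concatenate(vals_A) * w_all[rA]
    rG = np.concatenate(rows_G)
    cG = np.concatenate(cols_G)
    vG = np.concatenate(vals_G) * w_all[rG]
    b *= w_all

    G = sparse.coo_matrix((vG, (rG, cG)), shape=(n_u, n_p)).tocsr()
    A = sparse.coo_matrix((vA, (rA, cA)), shape=(n_u, n_u)).tocsr()

    pins = _pressure_pins(mask, k, mode)
    pin_rows = np.asarray([n_u + pidx[tuple(c)] for c in pins], dtype=np.int64)

    M = sparse.bmat([[A, G], [G.T, None]], format="coo")
    if pin_rows.size:
        M = M + sparse.coo_matrix(
            (np.ones(pin_rows.size), (pin_rows, pin_rows)), shape=M.shape
        )
    rhs = np.concatenate([b, np.zeros(n_p)])
    return {
        "M": M.tocsr(),
        "G": G,
        "rhs": rhs,
        "n_u": n_u,
        "act": act,
        "fidx": fidx,
        "w_all": w_all,
    }


def _pressure_pins(mask: np.ndarray, k: int, mode: str) -> list[tuple[int, ...]]:
    """One pressure gauge pin per fluid component without a Dirichlet face.

    In symmetric mode the pressure correction vanishes on the through-flow
    boundaries, which fixes the gauge of every component reaching them; in
    periodic mode (and for enclosed components) the gauge is free and one
    cell per component is pinned to zero.
    """
    lab, n = ndimage.label(mask, structure=STRUCT_6)
    if n == 0:
        return []
    if mode == "periodic":
        lab = _merge_periodic_labels(lab)
        comps = np.unique(lab[lab > 0])
        pinned = set(int(c) for c in comps)
    else:
        touching = np.unique(
            np.concatenate(
                [lab[_axsl(k, 0)].ravel(), lab[_axsl(k, -1)].ravel()]
            )
        )
        touching = set(int(t) for t in touching if t > 0)
        comps = np.unique(lab[lab > 0])
        pinned = set(int(c) for c in comps) - touching
    pins = []
    for c in pinned:
        coords = np.argwhere(lab == c)
        pins.append(tuple(coords[0]))
    return pins


def _merge_periodic_labels(lab: np.ndarray) -> np.ndarray:
    """Union component labels across periodic boundaries."""
    parent = {}

    def find(x):
        while parent.get(x, x) != x:
            parent[x] = parent.get(parent[x], parent[x])
            x = parent[x]
        return x

    def union(x, y):
        rx, ry = find(x), find(y)
        if rx != ry:
            parent[max(rx, ry)] = min(rx, ry)

    for axis in range(3):
        lo = lab[_axsl(axis, 0)].ravel()
        hi = lab[_axsl(axis, -1)].ravel()
        both = (lo > 0) & (hi > 0)
        for a, bb in zip(lo[both], hi[both]):
            union(int(a), int(bb))
    out = lab.copy()
    for val in np.unique(lab[lab > 0]):
        root = find(int(val))
        if root != val:
            out[lab == val] = root
    return out


# ---------------------------------------------------------------------
# Conductivity assembly
# ---------------------------------------------------------------------

@dataclass
class ConductivityResult:
    """Permeability tensor and hydraulic conductivity of one REV.

    ``K`` maps a driving force density (Pa/m) to mean velocity (m/s), so
    its entries carry units m^3 s kg^-1.  ``K_h_cm_s[k] = rho g K_kk`` in
    cm/s is the gravity-driven hydraulic conductivity.
    """

    K: np.ndarray
    K_h_cm_s: np.ndarray
    L_y_mm: float
    voxel_size_um: float
    level: int = 0
    percolates: dict[int, bool] | None = None
    sample_id: str = ""
    potential_kpa: float | None = None


def assemble_conductivity(
    solutions: list[CellProblemSolution] | dict[int, CellProblemSolution],
    voxel_size_um: float,
    mu: float = MU,
    rho: float = RHO,
    g: float = GRAVITY,
    level: int = 0,
    percolates: dict[int, bool] | None = None,
    sample_id: str = "",
    potential_kpa: float | None = None,
) -> ConductivityResult:
    """Assemble K (and K_h) from per-direction corrector solutions.

    K_jk = (dx^2/mu) <e_j . nu_k>, averaged over the periodic unit cell;
    with the negative-unit-force sign convention the diagonal is
    non-negative by the discrete energy identity.

    For 'symmetric' solves the cell is the reflected geometry, on which
    the off-diagonal averages vanish identically: the j-component of the
    k-corrector is odd under the mirror in axis j, so its full-cell
    integral cancels between mirror images.  The assembled tensor is
    therefore diagonal for symmetric solves (the half-domain averages
    remain available as diagnostics on each solution).  A full tensor
    with non-trivial off-diagonals — exactly symmetric because all three
    correctors share one operator — is obtained from 'periodic' solves
    on a geometry taken as its own unit cell.
    """
    if isinstance(solutions, dict):
        sols = list(solutions.values())
    else:
        sols = list(solutions)
    if not sols:
        raise ValueError("no solutions given")
    shapes = {s.shape for s in sols}
    if len(shapes) != 1:
        raise ValueError(f"inconsistent domain shapes among solutions: {shapes}")
    dirs = [s.direction for s in sols]
    if len(set(dirs)) != len(dirs):
        raise ValueError("duplicate directions among solutions")

    dx_m = voxel_size_um * 1e-6
    K = np.zeros((3, 3))
    solved = np.zeros(3, dtype=bool)
    for s in sols:
        col = s.mean_velocity * dx_m**2 / mu
        if s.mode == "symmetric":
            # full-cell (reflected) off-diagonal averages are exactly zero
            masked = np.zeros(3)
            masked[s.direction] = col[s.direction]
            col = masked
        K[:, s.direction] = col
        solved[s.direction] = True
    # sign convention: diagonals are non-negative up to round-off
    for d in range(3):
        if solved[d] and K[d, d] < 0:
            K[d, d] = 0.0

    shape = sols[0].shape
    L_y_mm = max(shape) * voxel_size_um * 1e-3
    K_h = np.full(3, np.nan)
    K_h[solved] = rho * g * np.diag(K)[solved] * 100.0  # m/s -> cm/s
    return ConductivityResult(
        K,
        K_h,
        L_y_mm,
        voxel_size_um,
        level=level,
        percolates=percolates,
        sample_id=sample_id,
        potential_kpa=potential_kpa,
    )


def solve_conductivity(
    sample: REVSample | PhaseVolume | np.ndarray,
    voxel_size_um: float | None = None,
    directions=(0, 1, 2),
    tolerance: float = 1e-8,
    mode: str = "symmetric",
    method: str = "auto",
    **kwargs,
) -> ConductivityResult:
    """Convenience wrapper: flow domain -> cell problems -> conductivity."""
    if isinstance(sample, np.ndarray):
        if voxel_size_um is None:
            raise ValueError("voxel_size_um required for a bare mask")
        mask = sample.astype(bool)
        dom = None
        pot = None
        sid = ""
        level = 0
    else:
        dom = flow_domain(sample)
        mask = dom.mask
        voxel_size_um = dom.voxel_size_um
        vol = sample.volume if isinstance(sample, REVSample) else sample
        pot = vol.potential_kpa
        sid = sample.parent_id if isinstance(sample, REVSample) else ""
        level = sample.level if isinstance(sample, REVSample) else 0
    sols = []
    for d in directions:
        sols.append(
            solve_cell_problem(
                mask, d, tolerance=tolerance, mode=mode, method=method,
                keep_fields=False, **kwargs,
            )
        )
    return assemble_conductivity(
        sols,
        voxel_size_um,
        level=level,
        percolates=dom.percolates if dom else None,
        sample_id=sid,
        potential_kpa=pot,
    )


def darcy_velocity(
    result: ConductivityResult,
    pressure_gradient: np.ndarray,
    rho: float = RHO,
    g: float = GRAVITY,
) -> np.ndarray:
    """Average Darcy velocity u = -K (grad p0 - rho g e_z), m/s.

    Axis 0 of the voxel grids is taken as the vertical z; a hydrostatic
    gradient grad p0 = rho g e_z balances gravity and yields zero flow.
    """
    grad = np.asarray(pressure_gradient, dtype=float)
    if grad.shape != (3,):
        raise ValueError("pressure_gradient must be a 3-vector (Pa/m)")
    K = np.asarray(result.K, dtype=float)
    if not np.isfinite(K).all():
        raise ValueError("conductivity tensor must be finite")
    e_z = np.array([1.0, 0.0, 0.0])
    return -K @ (grad - rho * g * e_z)
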