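"""Water release characteristics, REV convergence statistics, and the
van Genuchten retention/conductivity model.

The retention curve is

    theta(h) = (theta_s - theta_r) / (1 + (alpha h)^n)^m + theta_r,

with m = 1 - 1/n, and the relative hydraulic conductivity (Mualem form)

    k_r(h) = {1 - (alpha h)^(n-1) [1 + (alpha h)^n]^(-m)}^2
             / [1 + (alpha h)^n]^(m/2),

so K(h) = Ksat * k_r(h).  The residual water content theta_r is taken as
negligible (zero) throughout.  Heads are in cm of water; the
kPa-to-head conversion uses the same rho = 1000 kg/m^3 and g = 9.8 m/s^2
as the flow module, giving 10.2041 cm per kPa.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

from .stokes_cell import GRAVITY, RHO, ConductivityResult

#: Head equivalent of 1 kPa of matric suction, cm of water column.
KPA_TO_CM_HEAD = 1.0e3 / (RHO * GRAVITY) * 100.0


def head_cm_from_kpa(potential_kpa: float | np.ndarray) -> float | np.ndarray:
    """Hydraulic head (cm, >= 0) equivalent to a matric potential (kPa, <= 0)."""
    return np.abs(potential_kpa) * KPA_TO_CM_HEAD


@dataclass
class WRCPoint:
    """One point of a water release characteristic."""

    potential_kpa: float
    theta: float
    k_cm_s: float | None = None

    @property
    def head_cm(self) -> float:
        return float(head_cm_from_kpa(self.potential_kpa))


@dataclass
class VanGenuchtenParams:
    """van Genuchten parameters with theta_r fixed at zero.

    ``alpha`` is in cm^-1, ``n`` dimensionless (> 1), ``m = 1 - 1/n``
    exactly.  ``ksat_cm_s`` is the saturated conductivity, reported
    alongside the fitted shape parameters but measured (computed) at
    h = 0 rather than fitted.
    """

    theta_s: float
    alpha_per_cm: float
    n: float
    theta_r: float = 0.0
    ksat_cm_s: float | None = None

    def __post_init__(self) -> None:
        if not (0.0 <= self.theta_r < self.theta_s <= 1.0):
            raise ValueError("need 0 <= theta_r < theta_s <= 1")
        if not self.alpha_per_cm > 0:
            raise ValueError("alpha must be positive")
        if not self.n > 1:
            raise ValueError("n must exceed 1")

    @property
    def m(self) -> float:
        return 1.0 - 1.0 / self.n


def vg_theta(h_cm, params: VanGenuchtenParams):
    """Volumetric water content theta(h); h in cm of head (>= 0)."""
    h = np.asarray(h_cm, dtype=float)
    if np.any(h < 0):
        raise ValueError("head must be non-negative")
    ah_n = (params.alpha_per_cm * h) ** params.n
    theta = (params.theta_s - params.theta_r) * (1.0 + ah_n) ** (
        -params.m
    ) + params.theta_r
    return theta if theta.shape else float(theta)


def vg_relative_k(h_cm, params: VanGenuchtenParams):
    """Relative hydraulic conductivity k_r(h) in [0, 1]; h in cm (>= 0).

    Values that land outside [0, 1] by less than 1e-12 through round-off
    are clipped; anything farther out raises.
    """
    h = np.asarray(h_cm, dtype=float)
    if np.any(h < 0):
        raise ValueError("head must be non-negative")
    ah = params.alpha_per_cm * h
    ah_n = ah**params.n
    numer = (1.0 - ah ** (params.n - 1.0) * (1.0 + ah_n) ** (-params.m)) ** 2
    kr = numer / (1.0 + ah_n) ** (params.m / 2.0)
    out_low = kr < -1e-12
    out_high = kr > 1.0 + 1e-12
    if np.any(out_low) or np.any(out_high):
        raise FloatingPointError("relative conductivity left [0,1] beyond round-off")
    kr = np.clip(kr, 0.0, 1.0)
    return kr if kr.shape else float(kr)


# ---------------------------------------------------------------------
# Fitting
# ---------------------------------------------------------------------

@dataclass
class VGFitResult:
    """Best-fit parameters with residual diagnostics."""

    params: VanGenuchtenParams
    cost: float
    theta_residuals: np.ndarray
    logk_residuals: np.ndarray
    n_starts: int
    success: bool


def fit_vg(
    wrc: list[WRCPoint],
    k: list[WRCPoint] | None = None,
    alpha_grid: np.ndarray | None = None,
    n_grid: np.ndarray | None = None,
) -> VGFitResult:
    """Fit (theta_s, alpha, n) by multistart nonlinear least squares.

    Retention and (optionally) conductivity data are fitted jointly with
    equal aggregate weight per dataset: theta residuals are normalised by
    the saturated water content scale, conductivity residuals taken on a
    log scale (K spans decades), and each dataset divided by the square
    root of its point count.  theta_r is fixed at zero; Ksat is the
    computed conductivity at h = 0, not a fitted parameter.
    """
    heads = np.array([p.head_cm for p in wrc])
    thetas = np.array([p.theta for p in wrc])
    if np.unique(np.round(heads, 9)).size < 4:
        raise ValueError("need at least 4 distinct heads to fit 3 parameters")
    if np.ptp(thetas) < 1e-12:
        raise ValueError("degenerate (flat) retention data")

    ksat = None
    kh = kv = None
    if k:
        kh_all = np.array([p.head_cm for p in k])
        kv_all = np.array([p.k_cm_s for p in k], dtype=float)
        at_sat = kh_all == 0
        if at_sat.any():
            ksat = float(kv_all[at_sat][0])
        else:
            ksat = float(np.nanmax(kv_all))
        use = (kh_all > 0) & (kv_all > 0) & np.isfinite(kv_all)
        kh, kv = kh_all[use], kv_all[use]
        if kh.size == 0 or ksat <= 0:
            kh = kv = None

    theta_scale = max(float(thetas.max()), 1e-6)
    n_theta = heads.size
    n_k = kh.size if kh is not None else 0

    def residuals(x):
        theta_s, log_alpha, log_nm1 = x
        p = VanGenuchtenParams(
            theta_s=min(max(theta_s, 1e-6), 1.0),
            alpha_per_cm=float(np.exp(log_alpha)),
            n=1.0 + float(np.exp(log_nm1)),
        )
        r_theta = (vg_theta(heads, p) - thetas) / theta_scale / np.sqrt(n_theta)
        if n_k:
            kr = np.maximum(np.asarray(vg_relative_k(kh, p)), 1e-300)
            r_k = (np.log10(kr) - np.log10(kv / ksat)) / np.sqrt(n_k)
            return np.concatenate([r_theta, r_k])
        return r_theta

    if alpha_grid is None:
        alpha_grid = np.geomspace(0.005, 0.5, 5)
    if n_grid is None:
        n_grid = np.linspace(1.15, 3.5, 5)
    bounds = (
        [1e-3, np.log(1e-4), np.log(1e-3)],
        [1.0, np.log(10.0), np.log(30.0)],
    )
    best = None
    for a0 in alpha_grid:
        for n0 in n_grid:
            x0 = [min(theta_scale, 1.0), np.log(a0), np.log(n0 - 1.0)]
            try:
                res = least_squares(
                    residuals,
                    x0,
                    bounds=bounds,
                    xtol=1e-15,
                    ftol=1e-15,
                    gtol=1e-15,
                    max_nfev=2000,
                )
            except Exception:  # noqa: BLE001 - a bad start is not fatal
                continue
            if best is None or res.cost < best.cost:
                best = res
    if best is None:
        raise RuntimeError("fit failed from every start of the (alpha, n) grid")

    theta_s, log_alpha, log_nm1 = best.x
    params = VanGenuchtenParams(
        theta_s=float(theta_s),
        alpha_per_cm=float(np.exp(log_alpha)),
        n=1.0 + float(np.exp(log_nm1)),
        ksat_cm_s=ksat,
    )
    r = residuals(best.x)
    return VGFitResult(
        params=params,
        cost=float(best.cost),
        theta_residuals=r[:n_theta],
        logk_residuals=r[n_theta:],
        n_starts=len(alpha_grid) * len(n_grid),
        success=bool(best.success),
    )


# ---------------------------------------------------------------------
# REV convergence statistics
# ---------------------------------------------------------------------

@dataclass
class ConvergenceSeries:
    """Mean and SD of hydraulic conductivity per dyadic REV level.

    One row per level j: REV volume V_0/2^j, subsample count, mean and
    standard deviation of K_h over the subsamples, and a convergence flag
    set where the mean changed by less than ``rel_tol`` relative to the
    next coarser (larger-volume) level.
    """

    table: pd.DataFrame
    axis: int
    rel_tol: float

    @property
    def converged_level(self) -> int | None:
        ok = self.table[self.table["converged"]]
        return int(ok["j"].iloc[0]) if len(ok) else None


def convergence_stats(
    results: list[ConductivityResult],
    axis: int = 0,
    rel_tol: float = 0.1,
) -> ConvergenceSeries:
    """Aggregate per-REV conductivities into a convergence series by level.

    Levels with fewer than two results raise (a standard deviation needs
    replication); empty levels are skipped with a warning.
    """
    by_level: dict[int, list[ConductivityResult]] = {}
    for r in results:
        by_level.setdefault(r.level, []).append(r)
    rows = []
    for j in sorted(by_level):
        group = by_level[j]
        if len(group) < 2:
            raise ValueError(
                f"level j={j} has {len(group)} result(s); need >= 2 per level"
            )
        vals = np.array([g.K_h_cm_s[axis] for g in group], dtype=float)
        vols = np.array([g.L_y_mm**3 for g in group])
        rows.append(
            {
                "j": j,
                "volume_mm3": float(vols.mean()),
                "n": len(group),
                "mean_K_h_cm_s": float(vals.mean()),
                "sd_K_h_cm_s": float(vals.std(ddof=1)),
            }
        )
    if not rows:
        warnings.warn("no levels with results", stacklevel=2)
        return ConvergenceSeries(pd.DataFrame(), axis, rel_tol)
    df = pd.DataFrame(rows).sort_values("j").reset_index(drop=True)
    converged = [False]
    for i in range(1, len(df)):
        prev = df["mean_K_h_cm_s"].iloc[i - 1]
        cur = df["mean_K_h_cm_s"].iloc[i]
        scale = abs(cur) if cur != 0 else 1.0
        converged.append(abs(cur - prev) < rel_tol * scale)
    df["converged"] = converged
    return ConvergenceSeries(df, axis, rel_tol)
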