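"""1D steady-state reaction-diffusion model of ammonium around a consortium.

Ammonium diffusing from porewater (concentration C0 at the aggregate surface)
is assimilated by cells with first-order kinetics, D * laplacian(C) = k * C.
The depletion length lambda = sqrt(D / k) sets the e-folding scale of the
resulting gradient. Closed forms:

  planar semi-infinite:  C(x) = C0 * exp(-x / lambda)
  sphere of radius R:    C(r) = C0 * (R / r) * sinh(r / lambda) / sinh(R / lambda)

Where C drops below the diazotrophy-induction threshold C*, nitrogen fixation
is expected to switch on; ``threshold_depth`` locates that crossing and
``diazotrophy_fraction`` gives the volume fraction of the domain below C*.
A finite-difference solver provides an independent numerical route, verified
against the closed forms.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
from scipy.linalg import solve_banded

from .errors import ConvergenceError, DegenerateDataError, ParameterError

logger = logging.getLogger(__name__)

#: Free-solution ammonium diffusivity near 25 C, um^2/s (stated assumption).
DEFAULT_D_UM2_S = 1980.0
#: Lowest literature threshold for diazotrophy shut-off, uM.
DEFAULT_CSTAR_UM = 25.0

_PLANAR_EXTENT_LAMBDAS = 12.0  # truncation depth of the semi-infinite domain


@dataclass(frozen=True)
class RdParams:
    """Model parameters: diffusivity D (um^2/s), uptake rate k (1/s), boundary
    concentration C0 (uM), induction threshold Cstar (uM), geometry and, for
    spheres, radius R (um)."""

    k: float
    C0: float
    D: float = DEFAULT_D_UM2_S
    Cstar: float = DEFAULT_CSTAR_UM
    geometry: str = "spherical"
    R: float | None = None

    def __post_init__(self):
        if self.D <= 0:
            raise ParameterError("D must be > 0")
        if self.k < 0:
            raise ParameterError("k must be >= 0")
        if self.C0 <= 0:
            raise ParameterError("C0 must be > 0")
        if self.Cstar < 0:
            raise ParameterError("Cstar must be >= 0")
        if self.geometry not in ("planar_semi_infinite", "spherical"):
            raise ParameterError(f"unknown geometry {self.geometry!r}")
        if self.geometry == "spherical" and (self.R is None or self.R <= 0):
            raise ParameterError("spherical geometry requires R > 0")


@dataclass(frozen=True)
class RdProfile:
    """Concentration versus position. Planar: position = depth below the
    surface, ascending from 0. Spherical: position = radius, ascending from 0
    to R (the surface)."""

    position_um: np.ndarray
    conc_uM: np.ndarray
    geometry: str
    C0: float

    def __post_init__(self):
        if np.any(self.conc_uM < 0):
            raise ParameterError("concentrations must be nonnegative")

    @property
    def surface_conc(self) -> float:
        i = 0 if self.geometry == "planar_semi_infinite" else -1
        return float(self.conc_uM[i])

    def depth_profile(self) -> tuple[np.ndarray, np.ndarray]:
        """(depth below surface ascending, concentration) for either geometry."""
        if self.geometry == "planar_semi_infinite":
            return self.position_um, self.conc_uM
        R = self.position_um[-1]
        return (R - self.position_um)[::-1], self.conc_uM[::-1]


def depletion_length(D: float, k: float) -> float:
    """lambda = sqrt(D / k) in um; infinite (no-gradient regime) when k = 0."""
    if D <= 0:
        raise ParameterError("D must be > 0")
    if k < 0:
        raise ParameterError("k must be >= 0")
    if k == 0:
        logger.info("depletion_length: k = 0, no-gradient regime (lambda = inf)")
        return math.inf
    return math.sqrt(D / k)


def analytic_concentration(params: RdParams, positions: np.ndarray) -> np.ndarray:
    """Closed-form C at arbitrary positions (depth for planar, radius for sphere)."""
    positions = np.asarray(positions, dtype=float)
    if params.k == 0:
        return np.full_like(positions, params.C0)
    lam = depletion_length(params.D, params.k)
    if params.geometry == "planar_semi_infinite":
        return params.C0 * np.exp(-positions / lam)
    R = params.R
    with np.errstate(invalid="ignore", divide="ignore"):
        c = params.C0 * (R / positions) * np.sinh(positions / lam) / np.sinh(R / lam)
    center = params.C0 * (R / lam) / np.sinh(R / lam)
    return np.where(positions == 0.0, center, c)


def analytic_profile(params: RdParams, n_grid: int = 2001) -> RdProfile:
    """Closed-form profile on a uniform grid (12 depletion lengths for planar)."""
    if params.geometry == "planar_semi_infinite":
        lam = depletion_length(params.D, params.k)
        extent = _PLANAR_EXTENT_LAMBDAS * (lam if math.isfinite(lam) else 1.0)
        pos = np.linspace(0.0, extent, n_grid)
    else:
        pos = np.linspace(0.0, params.R, n_grid)
    return RdProfile(
        position_um=pos,
        conc_uM=analytic_concentration(params, pos),
        geometry=params.geometry,
        C0=params.C0,
    )


def numeric_profile(
    params: RdParams, n_grid: int = 64, tol: float = 1e-7, max_doublings: int = 14
) -> RdProfile:
    """Second-order finite-difference solution with grid-doubling to tolerance.

    Planar: domain [0, 12 lambda], Dirichlet C0 at the surface, exact radiation
    condition C' = -C/lambda at the truncation boundary. Spherical: substitution
    u = r C reduces the radial operator to u'' = u / lambda^2 with u(0) = 0 and
    u(R) = R C0. The grid is doubled until the maximum relative change between
    successive solutions (compared at coincident points) falls below ``tol``.
    Tolerances much below 1e-7 are unreachable in double precision: the
    second-difference roundoff error grows as eps / h^2 on fine grids.
    """
    if n_grid < 10:
        raise ParameterError("n_grid must be >= 10")
    if params.k == 0:
        if params.geometry == "planar_semi_infinite":
            pos = np.linspace(0.0, _PLANAR_EXTENT_LAMBDAS, n_grid)
        else:
            pos = np.linspace(0.0, params.R, n_grid)
        return RdProfile(
            position_um=pos,
            conc_uM=np.full(n_grid, params.C0),
            geometry=params.geometry,
            C0=params.C0,
        )
    prev = None
    n = n_grid
    for _ in range(max_doublings + 1):
        pos, conc = _solve_once(params, n)
        if prev is not None:
            coarse = conc[::2]
            change = np.max(np.abs(coarse - prev) / np.maximum(np.abs(prev), 1e-300))
            if change < tol:
                return RdProfile(
                    position_um=pos, conc_uM=conc, geometry=params.geometry, C0=params.C0
                )
        prev = conc
        n = 2 * (n - 1) + 1  # doubled grid shares every coarse point
    raise ConvergenceError(
        f"numeric_profile: not converged to tol={tol} within {max_doublings} grid doublings "
        f"(final n={n})"
    )


def _solve_once(params: RdParams, n: int) -> tuple[np.ndarray, np.ndarray]:
    lam = depletion_length(params.D, params.k)
    if params.geometry == "planar_semi_infinite":
        L = _PLANAR_EXTENT_LAMBDAS * lam
        x = np.linspace(0.0, L, n)
        h = x[1] - x[0]
        # unknowns C_1..C_{n-1}; C_0 = C0 Dirichlet
        m = n - 1
        ab = np.zeros((3, m))
        rhs = np.zeros(m)
        diag = -2.0 - (h / lam) ** 2
        ab[0, 1:] = 1.0  # superdiagonal
        ab[1, :] = diag
        ab[2, :-1] = 1.0  # subdiagonal
        rhs[0] = -params.C0
        # radiation boundary at x=L via ghost node: C_{n} = C_{n-2} - 2 h C_{n-1}/lam
        ab[1, -1] = diag - 2.0 * h / lam
        ab[2, -2] = 2.0
        c_inner = solve_banded((1, 1), ab, rhs)
        conc = np.concatenate([[params.C0], c_inner])
        return x, np.maximum(conc, 0.0)
    # spherical: u = r C, u'' = u / lam^2, u(0) = 0, u(R) = R C0
    R = params.R
    r = np.linspace(0.0, R, n)
    h = r[1] - r[0]
    m = n - 2
    ab = np.zeros((3, m))
    rhs = np.zeros(m)
    diag = -2.0 - (h / lam) ** 2
    ab[0, 1:] = 1.0
    ab[1, :] = diag
    ab[2, :-1] = 1.0
    rhs[-1] = -R * params.C0
    u_inner = solve_banded((1, 1), ab, rhs)
    u = np.concatenate([[0.0], u_inner, [R * params.C0]])
    with np.errstate(invalid="ignore"):
        conc = u / r
    # C(0) = u'(0), one-sided second-order difference
    conc[0] = (4.0 * u[1] - u[2]) / (2.0 * h)
    return r, np.maximum(conc, 0.0)


def threshold_depth(profile: RdProfile, Cstar: float) -> float | None:
    """First depth below the surface where C < Cstar (linear interpolation).

    Returns 0.0 when Cstar >= the surface concentration, None when the profile
    never crosses. The profile must be monotone non-increasing with depth.
    """
    depth, conc = profile.depth_profile()
    if np.any(np.diff(conc) > 1e-9 * max(profile.C0, 1.0)):
        raise DegenerateDataError("profile is not monotone non-increasing with depth")
    if Cstar >= conc[0]:
        return 0.0
    below = conc < Cstar
    if not below.any():
        return None
    i = int(np.argmax(below))
    c0, c1 = conc[i - 1], conc[i]
    d0, d1 = depth[i - 1], depth[i]
    if c0 == c1:
        return float(d1)
    return float(d0 + (c0 - Cstar) / (c0 - c1) * (d1 - d0))


def diazotrophy_fraction(profile: RdProfile, Cstar: float) -> float:
    """Fraction of the domain volume with C < Cstar.

    Length-weighted over the profile's domain for the planar geometry;
    r^2 (volume)-weighted for the sphere, i.e. (r*/R)^3 for a crossing at
    radius r*.
    """
    depth, conc = profile.depth_profile()
    if Cstar > profile.surface_conc and Cstar > conc.max():
        return 1.0
    xstar = threshold_depth(profile, Cstar)
    if xstar is None:
        return 0.0
    extent = float(depth[-1])
    if profile.geometry == "planar_semi_infinite":
        return max(0.0, (extent - xstar) / extent)
    R = extent  # spherical: maximum depth equals the radius
    rstar = max(0.0, R - xstar)
    return (rstar / R) ** 3


def profile_to_csv(profile: RdProfile, path) -> None:
    import pandas as pd

    pd.DataFrame(
        {"position_um": profile.position_um, "conc_uM": profile.conc_uM}
    ).to_csv(path, index=False)
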