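"""Independent oracle implementations used only by the test suite.

Each oracle solves the same physical problem as the package along a
different numerical route: iterative plate stacking and transfer-matrix
powers for the leaf model, a slab-discretised four-stream integration for
the canopy model, and quadrature for the Gaussian divergence.
"""

from __future__ import annotations

import numpy as np
from scipy.linalg import expm

from lianaspec.canopy import ViewGeometry, _geom_factors


def stack_plates_iteratively(r1, t1, n_extra: int):
    """Reflectance/transmittance of n_extra identical layers, one at a time.

    Classical adding of a symmetric layer (r1, t1) onto a growing pile:
    R' = r1 + t1^2 R / (1 - r1 R); T' = t1 T / (1 - r1 R).
    """
    R = np.zeros_like(r1)
    T = np.ones_like(t1)
    for _ in range(n_extra):
        denom = 1.0 - r1 * R
        R, T = r1 + t1**2 * R / denom, t1 * T / denom
    return R, T


def stack_plates_matrix_power(r1, t1, n_extra: float):
    """Pile of plates via a real (possibly fractional) transfer-matrix power.

    The two-flux transfer matrix of a symmetric layer is
    M = (1/T) [[T^2 - R^2, R], [-R, 1]]; stacking multiplies matrices, and a
    real-valued layer count corresponds to the matrix fractional power,
    evaluated per wavelength by eigen-decomposition.
    """
    r1 = np.atleast_1d(np.asarray(r1, float))
    t1 = np.atleast_1d(np.asarray(t1, float))
    R_out = np.empty_like(r1)
    T_out = np.empty_like(t1)
    for i, (R, T) in enumerate(zip(r1, t1)):
        M = np.array([[(T**2 - R**2) / T, R / T], [-R / T, 1.0 / T]])
        vals, vecs = np.linalg.eig(M)
        Mp = (vecs @ np.diag(np.asarray(vals, complex) ** n_extra) @ np.linalg.inv(vecs)).real
        T_out[i] = 1.0 / Mp[1, 1]
        R_out[i] = Mp[0, 1] / Mp[1, 1]
    return R_out, T_out


def slab_four_stream(layers, soil_reflectance: float, geom: ViewGeometry, n_slab: int = 200):
    """Brute-force slab discretisation of the layered four-stream problem.

    ``layers`` is a list of (rho, tau, lidf, lai) scalars describing the
    canopy from top to bottom at ONE wavelength.  The coupled linear ODE for
    (direct beam, downward diffuse, upward diffuse, observer radiance) is
    propagated through ``n_slab`` thin sub-slabs per layer via per-slab
    matrix exponentials; the two-point boundary problem (unit input at the
    top, Lambertian soil at the bottom) is then solved linearly.  No hotspot
    correlation (compare against the analytic model at hotspot = 0).

    Returns (rso, rdo, rsd, rdd).
    """
    mats = []
    for rho, tau, lidf, lai in layers:
        g = _geom_factors(lidf, geom)
        ks, ko, bf, sob, sof = g["ks"], g["ko"], g["bf"], g["sob"], g["sof"]
        sdb, sdf = 0.5 * (ks + bf), 0.5 * (ks - bf)
        dob, dof = 0.5 * (ko + bf), 0.5 * (ko - bf)
        ddb, ddf = 0.5 * (1 + bf), 0.5 * (1 - bf)
        sigb = ddb * rho + ddf * tau
        sigf = ddf * rho + ddb * tau
        att = 1.0 - sigf
        sb = sdb * rho + sdf * tau
        sf = sdf * rho + sdb * tau
        vb = dob * rho + dof * tau
        vf = dof * rho + dob * tau
        w = sob * rho + sof * tau
        A = np.array(
            [
                [-ks, 0.0, 0.0, 0.0],
                [sf, -att, sigb, 0.0],
                [-sb, -sigb, att, 0.0],
                [-w, -vb, -vf, ko],
            ]
        )
        P = np.linalg.matrix_power(expm(A * (lai / n_slab)), n_slab)
        mats.append(P)
    M = np.eye(4)
    for P in mats:
        M = P @ M  # propagate state [Es, D, U, Eo] from top to bottom

    rs = soil_reflectance

    def solve(Es0, D0):
        a = M[:, :2] @ np.array([Es0, D0])
        B = M[:, 2:]
        C = np.array([B[2] - rs * (B[0] + B[1]), B[3] - rs * (B[0] + B[1])])
        d = -np.array([a[2] - rs * (a[0] + a[1]), a[3] - rs * (a[0] + a[1])])
        return np.linalg.solve(C, d)  # (U(0), Eo(0))

    Us, Eos = solve(1.0, 0.0)
    Ud, Eod = solve(0.0, 1.0)
    return Eos, Eod, Us, Ud
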