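"""Real spherical harmonics with analytic Cartesian gradients.

Convention: orthonormal on the unit sphere, Condon-Shortley phase omitted,
m > 0 are the cosine components and m < 0 the sine components:

    Y_lm ~ N_lm P_l^m(cos th) cos(m ph)   (m >= 0)
    Y_l,-m ~ N_lm P_l^m(cos th) sin(m ph) (m > 0)

All downstream rotational invariants are convention-independent; the fixed
convention only makes the coupling solver unambiguous.

Everything is evaluated through the *regular solid harmonics*
S_lm(v) = r^l Y_lm(v/r), which are polynomials in the Cartesian components,
using the standard homogeneous recursions

    A_m + i B_m = (x + i y)^m
    Q_m^m   = (2m-1)!!
    Q_m+1^m = (2m+1) z Q_m^m
    Q_l^m   = [ (2l-1) z Q_l-1^m - (l-1+m) r^2 Q_l-2^m ] / (l - m)

so gradients follow exactly by differentiating the recursion.  Y is
homogeneous of degree 0 in the input vector, hence its gradient with respect
to the *unnormalized* vector is purely tangential.
"""

from __future__ import annotations

import math

import numpy as np

__all__ = ["lm_index", "n_lm", "real_spherical_harmonics"]


def lm_index(l: int, m: int) -> int:
    """Flat index of (l, m) in the [l=0..l_max, m=-l..l] layout."""
    return l * l + l + m


def n_lm(l_max: int) -> int:
    return (l_max + 1) ** 2


def _normalization(l: int, m: int) -> float:
    if m == 0:
        return math.sqrt((2 * l + 1) / (4.0 * math.pi))
    return math.sqrt(
        (2 * l + 1) / (2.0 * math.pi) * math.factorial(l - m) / math.factorial(l + m)
    )


def real_spherical_harmonics(vectors, l_max: int):
    """Values and gradients of all Y_lm, l <= l_max, at one or more vectors.

    Parameters
    ----------
    vectors : (3,) or (N, 3) array; need not be normalized, but must be
        nonzero (a zero vector raises ValueError).
    l_max : highest angular degree.

    Returns
    -------
    Y : (..., (l_max+1)^2) values
    dY : (..., (l_max+1)^2, 3) gradients with respect to the unnormalized
        input vector.
    """
    v = np.asarray(vectors, dtype=float)
    single = v.ndim == 1
    v = np.atleast_2d(v)
    N = v.shape[0]
    x, y, z = v[:, 0], v[:, 1], v[:, 2]
    r2 = x * x + y * y + z * z
    if np.any(r2 <= 0.0):
        raise ValueError("zero vector passed to real_spherical_harmonics")
    r = np.sqrt(r2)

    nlm = n_lm(l_max)
    Y = np.empty((N, nlm))
    dY = np.empty((N, nlm, 3))

    # azimuthal polynomials A_m, B_m and their gradients (in x, y)
    A = [np.ones(N)]
    B = [np.zeros(N)]
    for m in range(1, l_max + 1):
        A.append(x * A[m - 1] - y * B[m - 1])
        B.append(x * B[m - 1] + y * A[m - 1])

    # Q_l^m(z, u) with u = r^2, plus partials dQ/dz and dQ/du
    Q: dict[tuple[int, int], np.ndarray] = {}
    Qz: dict[tuple[int, int], np.ndarray] = {}
    Qu: dict[tuple[int, int], np.ndarray] = {}
    for m in range(0, l_max + 1):
        dfact = float(math.prod(range(1, 2 * m, 2))) if m > 0 else 1.0
        Q[(m, m)] = np.full(N, dfact)
        Qz[(m, m)] = np.zeros(N)
        Qu[(m, m)] = np.zeros(N)
        if m + 1 <= l_max:
            Q[(m + 1, m)] = (2 * m + 1) * z * Q[(m, m)]
            Qz[(m + 1, m)] = (2 * m + 1) * Q[(m, m)]
            Qu[(m + 1, m)] = np.zeros(N)
        for l in range(m + 2, l_max + 1):
            c1, c2 = (2 * l - 1), (l - 1 + m)
            denom = l - m
            Q[(l, m)] = (c1 * z * Q[(l - 1, m)] - c2 * r2 * Q[(l - 2, m)]) / denom
            Qz[(l, m)] = (
                c1 * (Q[(l - 1, m)] + z * Qz[(l - 1, m)]) - c2 * r2 * Qz[(l - 2, m)]
            ) / denom
            Qu[(l, m)] = (
                c1 * z * Qu[(l - 1, m)]
                - c2 * (Q[(l - 2, m)] + r2 * Qu[(l - 2, m)])
            ) / denom

    for l in range(0, l_max + 1):
        rl = r ** l
        for m in range(-l, l + 1):
            am = abs(m)
            nrm = _normalization(l, am)
            ang = A[am] if m >= 0 else B[am]
            q = Q[(l, am)]
            S = nrm * q * ang
            # dS/d(x,y,z); u = r^2 contributes 2*v through Qu
            if m >= 0:
                dax, day = am * A[am - 1] if am > 0 else np.zeros(N), (
                    -am * B[am - 1] if am > 0 else np.zeros(N)
                )
            else:
                dax, day = am * B[am - 1], am * A[am - 1]
            dSx = nrm * (Qu[(l, am)] * 2.0 * x * ang + q * dax)
            dSy = nrm * (Qu[(l, am)] * 2.0 * y * ang + q * day)
            dSz = nrm * ((Qz[(l, am)] + Qu[(l, am)] * 2.0 * z) * ang)
            idx = lm_index(l, m)
            Y[:, idx] = S / rl
            # grad(S r^-l) = (grad S) r^-l - l S r^-(l+2) v
            fac = l * S / (rl * r2)
            dY[:, idx, 0] = dSx / rl - fac * x
            dY[:, idx, 1] = dSy / rl - fac * y
            dY[:, idx, 2] = dSz / rl - fac * z

    if single:
        return Y[0], dY[0]
    return Y, dY
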