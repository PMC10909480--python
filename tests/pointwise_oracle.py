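"""Single-point plane-stress oracle for homogeneous macro tests.

Solves the same macro test as the FE homogenization but at one material
point, using scipy root finders on the transverse macro conditions --
an independent route to the apparent modulus of a homogeneous cell.
"""
import numpy as np
from scipy.optimize import brentq, fsolve

from histomech.constitutive import condensed_response_batch, _params_arrays


def pointwise_apparent(material, angle_deg, kind, eps):
    C10, D1, k1, k2, kap = _params_arrays(material)

    def cauchy(F):
        lam3, P2, _, _ = condensed_response_batch(
            F, angle_deg, C10, D1, k1, k2, kap)
        return P2 @ F.T / (np.linalg.det(F) * lam3)

    if kind in ("uniaxial-1", "uniaxial-2"):
        ax = 0 if kind == "uniaxial-1" else 1

        def p_transverse(eT):
            F = np.eye(2)
            F[ax, ax] += eps
            F[1 - ax, 1 - ax] += eT
            _, P2, _, _ = condensed_response_batch(
                F, angle_deg, C10, D1, k1, k2, kap)
            return float(P2[1 - ax, 1 - ax])

        eT = brentq(p_transverse, -0.3, 0.3, xtol=1e-14)
        F = np.eye(2)
        F[ax, ax] += eps
        F[1 - ax, 1 - ax] += eT
        return abs(cauchy(F)[ax, ax]) / abs(eps)

    def p_normals(x):
        F = np.array([[1 + x[0], eps / 2], [eps / 2, 1 + x[1]]])
        _, P2, _, _ = condensed_response_batch(
            F, angle_deg, C10, D1, k1, k2, kap)
        return [float(P2[0, 0]), float(P2[1, 1])]

    import warnings
    with warnings.catch_warnings():
        # minpack reports stalled progress once it hits float64 floor
        warnings.simplefilter("ignore", RuntimeWarning)
        x = fsolve(p_normals, [0.0, 0.0], xtol=1e-13)
    assert np.abs(p_normals(x)).max() < 1e-8  # root really found
    F = np.array([[1 + x[0], eps / 2], [eps / 2, 1 + x[1]]])
    return abs(cauchy(F)[0, 1]) / abs(eps)
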