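"""Independent reference integrator for the Bloch-McConnell equations.

Written separately from the package's matrix-exponential propagator and
kept deliberately naive: the coupled ODE right-hand side is assembled
term by term from the physical definitions and integrated with an
explicit adaptive Runge-Kutta (DOP853) at tight tolerance.  Used as the
oracle the production propagator is checked against.
"""

import numpy as np
from scipy.integrate import solve_ivp

GAMMA = 42.577478518e6  # Hz/T for 1H


def z_reference(pools, b1_uT, t_sat, field_T, offset_ppm, rtol=1e-11):
    """Z = Mz_water(t_sat)/M0 by explicit ODE integration.

    ``pools``: list of (shift_ppm, T1, T2, fraction, k_to_water); exactly
    one entry must have fraction 1 and shift 0 (water).
    """
    w1 = 2 * np.pi * GAMMA * b1_uT * 1e-6
    ppm2rad = 2 * np.pi * GAMMA * field_T * 1e-6
    iw = [i for i, p in enumerate(pools) if p[3] == 1.0 and p[0] == 0.0]
    assert len(iw) == 1
    iw = iw[0]
    n = len(pools)

    def rhs(_, m):
        dm = np.zeros_like(m)
        mw = m[3 * iw : 3 * iw + 3]
        for i, (shift, T1, T2, f, k) in enumerate(pools):
            x, y, z = m[3 * i : 3 * i + 3]
            dw = (shift - offset_ppm) * ppm2rad
            dx = -x / T2 + dw * y
            dy = -dw * x - y / T2 + w1 * z
            dz = -w1 * y - (z - f) / T1
            if i != iw:
                # solute <-> water exchange, detailed balance
                dx += -k * x + f * k * mw[0]
                dy += -k * y + f * k * mw[1]
                dz += -k * z + f * k * mw[2]
                dm[3 * iw] += k * x - f * k * mw[0]
                dm[3 * iw + 1] += k * y - f * k * mw[1]
                dm[3 * iw + 2] += k * z - f * k * mw[2]
            dm[3 * i] += dx
            dm[3 * i + 1] += dy
            dm[3 * i + 2] += dz
        return dm

    m0 = np.zeros(3 * n)
    for i, p in enumerate(pools):
        m0[3 * i + 2] = p[3]
    sol = solve_ivp(rhs, (0.0, t_sat), m0, method="DOP853",
                    rtol=rtol, atol=1e-13, dense_output=False)
    assert sol.success
    return sol.y[3 * iw + 2, -1]
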