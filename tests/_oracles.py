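"""Independent numerical oracles used by the test suite.

These deliberately avoid the package's exponential-convolution solution
path: the compartment ODEs are integrated directly with a stiff
variable-order solver over the same piecewise-linear plasma input.
"""

import numpy as np
from scipy.integrate import solve_ivp

from petkin.tac import frame_average


def ode_tissue_curve(spec, params, plasma, whole_blood, schedule, grid_dt=1.0):
    """Frame-averaged model TAC from direct stiff ODE integration."""
    end = schedule.total_duration
    grid = np.arange(0.0, end + grid_dt / 2, grid_dt)
    cp = np.interp(grid, plasma.time, plasma.value)
    K1, k2, k3, k4 = (params.K1 / 60.0, params.k2 / 60.0,
                      params.k3 / 60.0, params.k4 / 60.0)
    if spec.name == "1T1k":
        k2 = k3 = k4 = 0.0
    elif spec.name == "1T2k":
        k3 = k4 = 0.0
    elif spec.name == "2T3k":
        k4 = 0.0

    def rhs(t, y):
        cpt = np.interp(t, grid, cp)
        return [K1 * cpt - (k2 + k3) * y[0] + k4 * y[1], k3 * y[0] - k4 * y[1]]

    sol = solve_ivp(rhs, (0.0, end), [0.0, 0.0], t_eval=grid, method="LSODA",
                    rtol=1e-10, atol=1e-8, max_step=grid_dt)
    ct = sol.y[0] + sol.y[1]
    if spec.fit_vb:
        cwb = np.interp(grid, whole_blood.time, whole_blood.value)
        ct = (1.0 - params.vB) * ct + params.vB * cwb
    return frame_average(grid, ct, schedule)
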