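"""Independent reference implementations used as test oracles.

These deliberately avoid the package's integration path: a fixed-step RK4
integrator with an explicit history ring buffer for the delayed conversion,
and the closed-form Bateman cascade solution for sequential first-order
chains.
"""

from __future__ import annotations

import numpy as np

from losartan_pkpd import DoseRegimen, ModelParameters, dose_to_amount


def rk4_dde_reference(
    params: ModelParameters,
    dose: DoseRegimen,
    t_end: float,
    h: float = 5e-4,
    delay_mode: str = "metabolite",
    valve_fn=None,
) -> tuple[np.ndarray, np.ndarray]:
    """Fixed-step RK4 with a linear-interpolation history buffer.

    Returns (times, states[n, 6]) with compartment amounts in the same order
    as the package's state vector (without the AUC extras). Requires the
    delay T to be zero or much larger than the step h.
    """
    p = params
    n = int(round(t_end / h))
    times = np.linspace(0.0, n * h, n + 1)
    y = np.zeros(6)
    y[0] = dose_to_amount(dose)
    if valve_fn is None:
        valve_fn = lambda t: p.a * (1.0 + np.sin(2.0 * np.pi * t / p.b)) / 2.0  # noqa: E731

    hist_t = times
    hist_cc = np.zeros(n + 1)  # A_cc at completed grid points
    filled = 0  # index of last filled entry

    def lagged(t: float) -> float:
        tau = t - p.T
        if tau <= 0:
            return 0.0
        # linear interpolation on the filled part of the buffer
        i = min(int(tau / h), filled - 1)
        i = max(i, 0)
        t_i = hist_t[i]
        frac = (tau - t_i) / h
        upper = hist_cc[min(i + 1, filled)]
        return hist_cc[i] * (1 - frac) + frac * upper

    delayed = p.T > 1e-6 and p.k_m > 0

    def rhs(t: float, y: np.ndarray) -> np.ndarray:
        a_st, a_int, a_ent, a_cc, a_per, a_m = y
        v_sg = valve_fn(t)
        if delayed:
            gain = p.k_m * lagged(t)
            loss = gain if delay_mode == "symmetric" else p.k_m * a_cc
        else:
            gain = loss = p.k_m * a_cc
        return np.array(
            [
                -v_sg * a_st,
                v_sg * a_st - (p.k_int_ent + p.k_int_ex) * a_int + p.k_ent_int * a_ent,
                p.k_int_ent * a_int - (p.k_ent_int + p.k_ent_cc) * a_ent,
                p.k_ent_cc * a_ent
                - loss
                - (p.CL_p / p.Vp_1) * a_cc
                - (p.Q / p.Vp_1) * a_cc
                + (p.Q / p.Vp_2) * a_per,
                (p.Q / p.Vp_1) * a_cc - (p.Q / p.Vp_2) * a_per,
                gain - (p.CL_m / p.Vm) * a_m,
            ]
        )

    out = np.zeros((n + 1, 6))
    out[0] = y
    hist_cc[0] = y[3]
    for i in range(n):
        t = times[i]
        filled = i
        k1 = rhs(t, y)
        k2 = rhs(t + h / 2, y + h / 2 * k1)
        k3 = rhs(t + h / 2, y + h / 2 * k2)
        k4 = rhs(t + h, y + h * k3)
        y = y + h / 6 * (k1 + 2 * k2 + 2 * k3 + k4)
        out[i + 1] = y
        hist_cc[i + 1] = y[3]
    return times, out


def bateman_chain_amount(
    t: np.ndarray, initial: float, rates: tuple[float, ...]
) -> np.ndarray:
    """Amount in the last stage of a sequential first-order chain.

    ``rates`` are the exit rates of each stage (the last entry being the
    elimination rate of the terminal stage); all rates must be distinct.
    The classic Bateman cascade solution:

        A_n(t) = A_0 * (prod_{i<n} k_i) * sum_i exp(-k_i t) / prod_{j!=i} (k_j - k_i)
    """
    rates = np.asarray(rates, dtype=float)
    n = len(rates)
    if len(np.unique(rates)) != n:
        raise ValueError("Bateman closed form requires distinct rates")
    t = np.asarray(t, dtype=float)
    coeff = initial * np.prod(rates[:-1])
    total = np.zeros_like(t)
    for i in range(n):
        denom = np.prod([rates[j] - rates[i] for j in range(n) if j != i])
        total = total + np.exp(-rates[i] * t) / denom
    return coeff * total
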