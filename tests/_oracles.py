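"""Independent numerical oracles used only by the tests.

These deliberately avoid the closed-form production code paths: the
concentration oracle integrates the two-compartment ODE system directly,
and the likelihood oracle integrates the marginal likelihood over the
random effects by dense tensor-product Gauss-Hermite quadrature.
"""

from __future__ import annotations

import numpy as np
from numpy.polynomial.hermite_e import hermegauss
from scipy.integrate import solve_ivp

from dalbapk.estimation import _h_batch
from dalbapk.pk import PKParameters, Regimen
from dalbapk.population import PopulationModel, scaled_param_array


def ode_concentration(
    params: PKParameters, regimen: Regimen, times, rtol: float = 1e-11
) -> np.ndarray:
    """Central concentration by piecewise ODE integration (no closed form)."""
    times = np.asarray(times, dtype=float)
    k10 = params.cl / params.v1
    k12 = params.q / params.v1
    k21 = params.q / params.v2

    def rhs(t, y, rate):
        a1, a2 = y
        return [rate - (k10 + k12) * a1 + k21 * a2, k12 * a1 - k21 * a2]

    boundaries = sorted(
        {0.0, *(e.time for e in regimen.events), *(e.end for e in regimen.events),
         float(times[-1]) if times.size else 0.0}
    )
    out = np.zeros(times.size)
    y = np.zeros(2)
    for lo, hi in zip(boundaries, boundaries[1:]):
        if hi <= lo:
            continue
        rate = 0.0
        for e in regimen.events:
            if e.time <= lo < e.end:
                rate = e.rate
        mask = (times > lo) & (times <= hi)
        eval_t = times[mask]
        if eval_t.size and eval_t[-1] == hi:
            t_eval = eval_t
        else:
            t_eval = np.concatenate([eval_t, [hi]])
        sol = solve_ivp(
            rhs, (lo, hi), y, args=(rate,), t_eval=t_eval,
            rtol=rtol, atol=1e-12, method="LSODA",
        )
        if eval_t.size:
            out[mask] = sol.y[0][: eval_t.size]
        y = sol.y[:, -1]
    out[times <= 0.0] = 0.0
    return out / params.v1


def quadrature_ofv(dataset, model: PopulationModel, n_nodes: int = 25) -> float:
    """-2 log marginal likelihood by dense Gauss-Hermite quadrature over eta."""
    x, w = hermegauss(n_nodes)
    w = w / np.sqrt(2.0 * np.pi)
    omegas = model.omegas
    X = np.array(np.meshgrid(x, x, x, x, indexing="ij")).reshape(4, -1).T
    W = np.prod(
        np.array(np.meshgrid(w, w, w, w, indexing="ij")).reshape(4, -1).T, axis=1
    )
    total = 0.0
    for subj in dataset.subjects:
        base = scaled_param_array(model, subj.weight, subj.covariates or None)
        etas = X * omegas[None, :]
        h = _h_batch(subj, base, etas, omegas, model.resid_b, 1e-6)
        prior = np.sum(etas**2 / (omegas**2)[None, :], axis=1)
        m2ll_data = h - prior - (4.0 * np.log(2 * np.pi) + 2.0 * np.sum(np.log(omegas)))
        log_integrand = -0.5 * m2ll_data + np.log(W)
        mx = log_integrand.max()
        total += -2.0 * (mx + np.log(np.exp(log_integrand - mx).sum()))
    return total
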