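"""Independent, naive transcriptions of the update equations.

Written directly from the printed difference equations in plain Python,
deliberately sharing no code with the package: these are the reference
the step implementations are checked against (to 1e-12 relative) on
random states.
"""

import math


def _logistic(x):
    if x >= 0:
        return 1.0 / (1.0 + math.exp(-x))
    return math.exp(x) / (1.0 + math.exp(x))


def _hill(q, lower, mid, exponent):
    if q <= lower:
        return 0.0
    return (q - lower) ** exponent / (
        (q - lower) ** exponent + (mid - lower) ** exponent
    )


def _controls(n, d, q, alpha, N_c, sigma_N, p, q3_includes_p2=True):
    fD = max(1.0 / (1.0 + alpha[i] * d[i]) for i in range(len(d)))
    fN = _logistic((n - N_c) / sigma_N)
    q1 = p["m_r"] * (n + sum(d))
    q2 = q1 + p["m_d"] * p["p1"] * n
    q3 = q2 + (p["p2"] if q3_includes_p2 else 1.0) * fD * p["m_d"] * n
    q4 = q3 + fD * fN * p["m_d"] * p["p3"] * n
    a1 = _hill(q, q1, (q1 + q2) / 2.0, p["hill_exponent"])
    a2 = _hill(q, q2, (q2 + q3) / 2.0, p["hill_exponent"])
    a3 = _hill(q, q3, (q3 + q4) / 2.0, p["hill_exponent"])
    fQ = 1.0 - math.exp(-p["beta_Q"] * q)
    q_mu = 1.5 * q4
    if q > 10.0 * q_mu or p["mu_Q_max"] == 0.0:
        muQ = 0.0
    else:
        muQ = p["mu_Q_max"] * (q - q_mu) ** 2 / (
            (q - q_mu) ** 2 + (q1 - q_mu) ** 2
        )
    return fD, fN, a1, a2, a3, fQ, muQ


def full_step_oracle(n, d, q, D_bar, rho_bar, sigma_D, sigma_rho, alpha,
                     N_c, sigma_N, p):
    """One step of the full model: neoblast, differentiated-cell, and
    resource-pool updates transcribed term by term.

    ``p`` is a plain dict of parameter values. Returns (n', d', q').
    """
    I = len(d)
    fD, fN, a1, a2, a3, fQ, muQ = _controls(n, d, q, alpha, N_c, sigma_N, p)

    # mortality rates: resource term + level and proportion logistics
    total = sum(d)
    M = []
    for i in range(I):
        rho_i = d[i] / total
        M.append(
            muQ
            + p["mu_i"][i] * (
                _logistic((d[i] - D_bar[i]) / sigma_D[i])
                + _logistic((rho_i - rho_bar[i]) / sigma_rho[i])
            )
        )

    # total progeny production
    P = n * fD * (p["p2"] * a2 + 2.0 * p["p3"] * fN * a3)

    # neoblasts
    n_next = n * (1.0 + p["p1"] * a1 - p["p3"] * fD * fN * a3)

    # differentiated cells: survival + relative-need share of progeny
    need_sum = sum(D_bar[k] / d[k] for k in range(I))
    d_next = [
        d[i] * math.exp(-M[i]) + fQ * P * (D_bar[i] / d[i]) / need_sum
        for i in range(I)
    ]

    # resource pool
    q_next = (
        q
        + p["Y_e"] * d[0] ** p["delta"]
        + p["gamma_p"] * (1.0 - fQ) * P
        + p["gamma"] * sum(d[i] * (1.0 - math.exp(-M[i])) for i in range(I))
        - p["m_r"] * (n + sum(d))
        - p["m_d"] * n * (
            p["p1"] * a1 + fD * (p["p2"] * a2 + fN * p["p3"] * a3)
        )
    )
    if q_next < 0.0:
        q_next = 0.0
    return n_next, d_next, q_next


def simple_step_oracle(n, d, q, alpha, N_c, sigma_N, p):
    """One step of the single-class model; returns (n', d', q')."""
    fD, fN, a1, a2, a3, fQ, muQ = _controls(n, [d], q, [alpha], N_c, sigma_N, p)
    mu_tot = p["mu"] + muQ
    n_next = n * (1.0 + p["p1"] * a1 - p["p3"] * fD * fN * a3)
    d_next = d * math.exp(-mu_tot) + n * fD * (
        p["p2"] * a2 + 2.0 * p["p3"] * fN * a3
    )
    q_next = (
        q
        + p["Y_e"] * d ** p["delta"]
        + p["gamma"] * d * (1.0 - math.exp(-mu_tot))
        - p["m_r"] * (n + d)
        - p["m_d"] * n * (
            p["p1"] * a1 + fD * (p["p2"] * a2 + fN * p["p3"] * a3)
        )
    )
    if q_next < 0.0:
        q_next = 0.0
    return n_next, d_next, q_next
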