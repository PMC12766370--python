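"""Independent literal transcriptions of the published ROR and BCPNN
formulas, kept deliberately separate from the package implementation so the
two routes can be compared table-by-table in tests."""

from math import exp, log, log2, sqrt


def ror_with_ci(a, b, c, d):
    """ROR = a*d/b/c; 95% CI = e^(ln ROR +- 1.96*(1/a+1/b+1/c+1/d)^0.5).
    Returns None when a zero cell makes the estimate undefined."""
    if a == 0 or b == 0 or c == 0 or d == 0:
        return None
    ror = a * d / b / c
    half_width = 1.96 * (1 / a + 1 / b + 1 / c + 1 / d) ** 0.5
    return ror, exp(log(ror) - half_width), exp(log(ror) + half_width)


def bcpnn_ic(a, b, c, d, alpha=2.0, beta=2.0, alpha_i=1.0, beta_j=1.0, gamma_ij=1.0):
    """E(IC), V(IC) and IC_025 = E(IC) - 2*sqrt(V(IC)), step by step."""
    N = a + b + c + d
    gamma = gamma_ij * (N + alpha) * (N + beta) / ((a + b + alpha_i) * (a + c + beta_j))
    e_ic = log2(
        (a + gamma_ij) * (N + alpha) * (N + beta)
        / ((N + gamma) * (a + b + alpha_i) * (a + c + beta_j))
    )
    v_ic = (1 / log(2) ** 2) * (
        (N - a + gamma - gamma_ij) / ((a + gamma_ij) * (1 + N + gamma))
        + (N - a - b + alpha - alpha_i) / ((a + b + alpha_i) * (1 + N + alpha))
        + (N - a - c + beta - beta_j) / ((a + c + beta_j) * (1 + N + beta))
    )
    ic025 = e_ic - 2 * sqrt(v_ic)
    return e_ic, v_ic, ic025
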