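"""Independent numerical oracles used by the test suite.

These deliberately avoid the package's closed-form code paths: the
competing-risk cumulative incidence is recomputed by integrating the ODE
system  S' = -(lam+mu) S,  CI' = lam S  on a fine grid with classical RK4
sub-steps aligned to the hazard bands.
"""

from __future__ import annotations

import math

import numpy as np


def numeric_cuminc(lam, mu, widths, dt: float = 1e-3) -> float:
    """Fine-grid RK4 integration of the cause-specific cumulative incidence."""
    S, ci = 1.0, 0.0
    for lam_i, mu_i, w in zip(lam, mu, widths):
        total = lam_i + mu_i
        n_steps = max(1, math.ceil(w / dt))
        h = w / n_steps

        def deriv(s):
            return -total * s, lam_i * s

        for _ in range(n_steps):
            k1s, k1c = deriv(S)
            k2s, k2c = deriv(S + 0.5 * h * k1s)
            k3s, k3c = deriv(S + 0.5 * h * k2s)
            k4s, k4c = deriv(S + h * k3s)
            ci += (h / 6.0) * (k1c + 2 * k2c + 2 * k3c + k4c)
            S += (h / 6.0) * (k1s + 2 * k2s + 2 * k3s + k4s)
    return ci


def random_rate_config(rng: np.random.Generator, n_bands_max: int = 6):
    """Random piecewise-constant hazard segments (lam, mu, widths)."""
    n = int(rng.integers(1, n_bands_max + 1))
    lam = rng.uniform(0.0, 0.03, n)
    mu = rng.uniform(0.0, 0.05, n)
    widths = rng.uniform(0.5, 6.0, n)
    return lam, mu, widths
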