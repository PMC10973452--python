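"""Closed-form solution of the transcription--splicing--degradation model.

The model describes the expected abundance of unspliced (u) and spliced (s)
mRNA of one gene:

    du/dt = alpha - beta * u
    ds/dt = beta * u - gamma * s

with transcription rate alpha (molecules per unit latent time), splicing rate
beta and degradation rate gamma (both per unit latent time).  A gene is in
*induction* while alpha > 0 and switches to *repression* (alpha = 0) at latent
time ``t_switch``.  At steady state u/s -> gamma/beta, which is the slope of
the phase-portrait line velocity estimation relies on; the instantaneous
velocity is ds/dt = beta*u - gamma*s.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["KineticParams", "simulate_kinetics", "true_velocity"]


@dataclass(frozen=True)
class KineticParams:
    """Per-gene kinetic rates and the induction-to-repression switch time.

    alpha : transcription rate, >= 0
    beta : splicing rate, > 0
    gamma : degradation rate, > 0
    t_switch : latent time of the alpha -> 0 switch, finite and >= 0
    """

    alpha: float
    beta: float
    gamma: float
    t_switch: float = np.inf

    def __post_init__(self) -> None:
        if self.alpha < 0:
            raise ValueError(f"alpha must be >= 0, got {self.alpha}")
        if self.beta <= 0 or self.gamma <= 0:
            raise ValueError(
                f"beta and gamma must be > 0, got beta={self.beta}, gamma={self.gamma}"
            )
        if self.t_switch < 0:
            raise ValueError(f"t_switch must be >= 0, got {self.t_switch}")


def _solution(alpha, beta, gamma, t, u0, s0):
    """Expected (u, s) at time(s) t for constant alpha from (u0, s0)."""
    t = np.asarray(t, dtype=float)
    ebt = np.exp(-beta * t)
    egt = np.exp(-gamma * t)
    u = u0 * ebt + (alpha / beta) * (1.0 - ebt)
    if np.isclose(beta, gamma, rtol=1e-12, atol=1e-300):
        # gamma -> beta limit: (e^{-gt} - e^{-bt})/(g - b) -> -t e^{-bt}
        cross = (alpha - beta * u0) * (-t * ebt)
    else:
        cross = ((alpha - beta * u0) / (gamma - beta)) * (egt - ebt)
    s = s0 * egt + (alpha / gamma) * (1.0 - egt) + cross
    return u, s


def simulate_kinetics(params: KineticParams, t, u0: float = 0.0, s0: float = 0.0):
    """Expected unspliced/spliced abundance at latent time(s) ``t``.

    During induction (t < t_switch) the constant-alpha solution from
    (u0, s0) applies; past the switch, transcription is off (alpha = 0) and
    the trajectory restarts from the abundances reached at t_switch.

    Parameters
    ----------
    params
        Kinetic rates; ``beta == gamma`` is handled by the limiting
        expression with the ``t * exp(-beta t)`` secular term.
    t
        Scalar or array of latent times, all >= 0.
    u0, s0
        Abundances at t = 0 (default: empty gene).

    Returns
    -------
    (u, s) with the same shape as ``t``.
    """
    t_in = np.asarray(t, dtype=float)
    scalar = t_in.ndim == 0
    t = np.atleast_1d(t_in)
    if np.any(t < 0):
        raise ValueError("latent time t must be >= 0")
    a, b, g, ts = params.alpha, params.beta, params.gamma, params.t_switch

    t_ind = np.minimum(t, ts)
    u, s = _solution(a, b, g, t_ind, u0, s0)
    past = t > ts
    if np.any(past):
        u_sw, s_sw = _solution(a, b, g, ts, u0, s0)
        u_rep, s_rep = _solution(0.0, b, g, t[past] - ts, u_sw, s_sw)
        u = u.copy()
        s = s.copy()
        u[past] = u_rep
        s[past] = s_rep
    if scalar:
        return float(u[0]), float(s[0])
    return u, s


def true_velocity(params: KineticParams, t, u0: float = 0.0, s0: float = 0.0):
    """ds/dt = beta*u - gamma*s along the closed-form trajectory."""
    u, s = simulate_kinetics(params, t, u0=u0, s0=s0)
    return params.beta * u - params.gamma * s
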