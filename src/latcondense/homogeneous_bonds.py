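"""Bond kinetics in the spatially homogeneous regime before phase separation.

While the LAT density stays uniform at L0, the bond density per LAT molecule
phi obeys the flux-free limit of the bond reaction-diffusion equation,

    dphi/ds = (v/2 - phi)^2 - K_D * phi,        s = k1_hat * L0 * t,

a Riccati equation with dissociation constant K_D = km1_hat/(k1_hat*L0) and
valency v (phi is bounded by v/2: every bond engages two binding sites).
Its closed-form solution, the steady state phi_inf = -lambda1, the largest
dissociation constant K_D_max = (v/2 - phi_th)^2 / phi_th for which the
phase-separation threshold phi_th is ever reached, and the threshold-crossing
time tau_th are implemented here.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "BindingParams",
    "RiccatiRates",
    "dissociation_constant",
    "riccati_rates",
    "phi_of_t",
    "phi_steady_state",
    "max_KD",
    "threshold_time",
]


@dataclass(frozen=True)
class BindingParams:
    """Non-dimensional rate constants and valency of LAT crosslinking.

    Defaults are the reference parameter set: k1_hat = 1/3e4, km1_hat = 1/3e5
    (so K_D = 1/30 at L0 = 3), valency v = 3, threshold phi_th = 1.
    """

    k1_hat: float = (1.0 / 3.0) * 1e-4
    km1_hat: float = (1.0 / 3.0) * 1e-5
    L0: float = 3.0
    v: float = 3.0
    phi_th: float = 1.0

    def __post_init__(self) -> None:
        if self.k1_hat <= 0:
            raise ValueError("k1_hat must be positive")
        if self.km1_hat < 0:
            raise ValueError("km1_hat must be non-negative")
        if self.L0 <= 0 or self.v <= 0:
            raise ValueError("L0 and v must be positive")
        if not (0.0 < self.phi_th < self.v / 2.0):
            raise ValueError(
                f"phi_th must lie in (0, v/2)={(0, self.v / 2)}, got {self.phi_th}"
            )


@dataclass(frozen=True)
class RiccatiRates:
    """Roots lambda1 >= lambda2 of the Riccati steady-state quadratic.

    Vieta identities: lambda1*lambda2 = v^2/4, lambda1+lambda2 = -(v + K_D).
    The stable steady state of phi is -lambda1.
    """

    lambda1: float
    lambda2: float

    def __post_init__(self) -> None:
        if self.lambda1 < self.lambda2:
            raise ValueError("lambda1 must be the larger root")


def dissociation_constant(p: BindingParams) -> float:
    """K_D = km1_hat / (k1_hat * L0)."""
    return p.km1_hat / (p.k1_hat * p.L0)


def riccati_rates(K_D: float, v: float) -> RiccatiRates:
    """Rate constants lambda_{1,2} = -(v+K_D)/2 +/- sqrt(2vK_D + K_D^2)/2."""
    if K_D <= 0:
        raise ValueError(
            "riccati_rates requires K_D > 0; use the K_D = 0 irreversible "
            "branch of phi_of_t instead"
        )
    if v <= 0:
        raise ValueError("v must be positive")
    half_sum = 0.5 * (v + K_D)
    half_disc = 0.5 * np.sqrt(K_D * (2.0 * v + K_D))
    return RiccatiRates(lambda1=-half_sum + half_disc, lambda2=-half_sum - half_disc)


def phi_of_t(t_star, rates: RiccatiRates | None = None, *, v: float | None = None):
    """Bond density per LAT at scaled time s = k1_hat*L0*t.

    phi(s) = l1*l2*(e^{l1 s} - e^{l2 s}) / (l1 e^{l2 s} - l2 e^{l1 s});
    phi(0) = 0, monotone increasing, phi(inf) = -lambda1.  Evaluated in a
    form normalized by e^{l1 s} so large times underflow gracefully to the
    steady state instead of overflowing.

    The irreversible limit K_D = 0 (pass ``v`` instead of ``rates``) is the
    Bernoulli solution phi = (v/2) * (v s/2) / (1 + v s/2).
    """
    s = np.asarray(t_star, dtype=float)
    if np.any(s < 0):
        raise ValueError("t_star must be non-negative")
    if rates is None:
        if v is None:
            raise ValueError("provide rates (K_D > 0) or v (K_D = 0 limit)")
        x = 0.5 * v * s
        return (0.5 * v) * x / (1.0 + x)
    l1, l2 = rates.lambda1, rates.lambda2
    if l1 == l2:
        # degenerate K_D -> 0+ discriminant: same Bernoulli form about -l1
        x = -l1 * s
        return -l1 * x / (1.0 + x)
    # divide through by e^{l1 s}; exponent (l2-l1)*s <= 0 never overflows
    decay = np.exp((l2 - l1) * s)
    return l1 * l2 * (1.0 - decay) / (l1 * decay - l2)


def phi_steady_state(K_D: float, v: float) -> float:
    """Steady-state bond density phi_inf = -lambda1 (v/2 in the K_D=0 limit)."""
    if K_D == 0:
        return v / 2.0
    return -riccati_rates(K_D, v).lambda1


def max_KD(v: float, phi_th: float) -> float:
    """Largest K_D for which phi(inf) reaches phi_th.

    From the steady state (v/2 - phi)^2 = K_D*phi evaluated at phi = phi_th:
    K_D_max = (v/2 - phi_th)^2 / phi_th.
    """
    if not (0.0 < phi_th < v / 2.0):
        raise ValueError(f"phi_th must lie in (0, v/2), got {phi_th}")
    return (v / 2.0 - phi_th) ** 2 / phi_th


def threshold_time(p: BindingParams) -> float:
    """Time tau_th at which phi first reaches phi_th; +inf if it never does.

    For 0 < K_D <= K_D_max,

        tau_th = ln[(phi_th*l1 + l1*l2) / (phi_th*l2 + l1*l2)]
                 / (k1_hat * L0 * (l1 - l2)),

    which diverges as K_D -> K_D_max from below.  K_D = 0 uses the Bernoulli
    inverse.  tau_th is in the same (non-dimensional) time unit as k1_hat.
    """
    K_D = dissociation_constant(p)
    scale = p.k1_hat * p.L0
    if K_D == 0:
        x = p.phi_th / (p.v / 2.0 - p.phi_th)  # vs/2 at crossing
        return float(2.0 * x / (p.v * scale))
    if K_D > max_KD(p.v, p.phi_th):
        return float("inf")
    r = riccati_rates(K_D, p.v)
    l1, l2 = r.lambda1, r.lambda2
    num = p.phi_th * l1 + l1 * l2
    den = p.phi_th * l2 + l1 * l2
    if num <= 0 or den <= 0:
        # phi_th is at or beyond the steady state: unreachable in finite time
        return float("inf")
    return float(np.log(num / den) / (scale * (l1 - l2)))
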