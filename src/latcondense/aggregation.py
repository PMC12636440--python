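"""Smoluchowski aggregation kinetics for membrane-bound LAT clusters.

Irreversible coagulation of clusters on a supported lipid bilayer,

    dc_i/dt = 1/2 * sum_{j<i} k_{i-j,j} c_{i-j} c_j  -  c_i * sum_j k_ij c_j,

with a composite kernel k_ij = k_ij^Br * k_ij^rxn that interpolates between
reaction-limited (RLCA) and diffusion-limited (DLCA) cluster aggregation.
The Brownian part follows from Evans–Sackmann membrane hydrodynamics applied
to fractal aggregates with hydrodynamic radius R_H(i) = R0 * i**gamma_H; the
reactive part is P*N_ij / (P*N_ij + 1 - P) with N_ij = N11*(i*j)**sigma
collisions per encounter.

All rates are expressed in the non-dimensional time
t* = C_Br * kBT * c1_0 * t / (4 pi eta_m), in which the Brownian kernel is
simply 1/f(eps_i) + 1/f(eps_j) with f(eps) = eps^2/4 + eps*K1(eps)/K0(eps).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.integrate import solve_ivp
from scipy.special import k0e, k1e

__all__ = [
    "KernelParams",
    "ClusterDistribution",
    "AggregationTrajectory",
    "collision_number",
    "reactive_kernel",
    "hydrodynamic_radius",
    "cluster_diffusivity",
    "brownian_kernel",
    "assemble_kernel",
    "aggregation_rhs",
    "simulate_aggregation",
    "mean_cluster_size",
    "dimer_peak_time",
    "crossover_size",
    "dlca_exponent",
]


@dataclass(frozen=True)
class KernelParams:
    """Physical and kernel parameters of the aggregation model.

    Defaults are the reference parameter set: binding probability P = 1e-2,
    N11 = 1 collision per monomer encounter, sigma = 1, membrane viscosity
    eta_m = 0.1 pN us/nm, membrane-substrate friction b_s = 1e-2 pN us/nm^3,
    mobility-mass exponent gamma_H = 2/3, monomer radius R0 = 2 nm.
    """

    P: float = 1e-2
    N11: float = 1.0
    sigma: float = 1.0
    eta_m: float = 0.1
    b_s: float = 1e-2
    gamma_H: float = 2.0 / 3.0
    R0: float = 2.0
    c1_0: float = 1.0
    Nmax: int = 400
    mass_loss_frac: float = 0.05

    def __post_init__(self) -> None:
        if not (0.0 < self.P <= 1.0):
            raise ValueError(f"P must lie in (0, 1], got {self.P}")
        for name in ("N11", "sigma", "eta_m", "b_s", "gamma_H", "R0", "c1_0"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive, got {getattr(self, name)}")
        if self.Nmax < 2:
            raise ValueError(f"Nmax must be >= 2, got {self.Nmax}")
        if not (0.0 < self.mass_loss_frac < 1.0):
            raise ValueError(
                f"mass_loss_frac must lie in (0, 1), got {self.mass_loss_frac}"
            )

    def with_(self, **kwargs) -> "KernelParams":
        """Return a copy with the given fields replaced."""
        return replace(self, **kwargs)


@dataclass
class ClusterDistribution:
    """Concentrations c_i of clusters of size i = 1..Nmax at one instant."""

    c: np.ndarray
    t_star: float = 0.0

    def __post_init__(self) -> None:
        self.c = np.asarray(self.c, dtype=float)
        if self.c.ndim != 1 or self.c.size < 2:
            raise ValueError("c must be a 1-D array indexed by sizes 1..Nmax (>=2)")
        if np.any(self.c < 0):
            raise ValueError("cluster concentrations must be non-negative")

    @property
    def sizes(self) -> np.ndarray:
        return np.arange(1, self.c.size + 1)

    @property
    def mass(self) -> float:
        """First moment sum_i i*c_i (conserved until truncation losses)."""
        return float(np.dot(self.sizes, self.c))


@dataclass
class AggregationTrajectory:
    """Time-ordered record of an aggregation run."""

    times: np.ndarray
    states: list = field(default_factory=list)
    mean_sizes: np.ndarray = None
    mass_retained: np.ndarray = None
    terminated_by_mass_loss: bool = False
    params: KernelParams = None


def collision_number(i, j, N11: float, sigma: float):
    """Number of collisions N_ij = N11*(i*j)**sigma per encounter."""
    i = np.asarray(i)
    j = np.asarray(j)
    if np.any(i < 1) or np.any(j < 1):
        raise ValueError("cluster sizes must be >= 1")
    return N11 * (i * j) ** sigma


def reactive_kernel(i, j, P: float, N11: float, sigma: float):
    """Binding probability per encounter, P*N_ij / (P*N_ij + 1 - P).

    Tends to P*N_ij in the RLCA limit (P*N_ij << 1) and saturates at 1 in
    the DLCA limit; identically 1 when P = 1.
    """
    if not (0.0 < P <= 1.0):
        raise ValueError(f"P must lie in (0, 1], got {P}")
    N = collision_number(i, j, N11, sigma)
    return P * N / (P * N + (1.0 - P))


def hydrodynamic_radius(i, R0: float, gamma_H: float):
    """Hydrodynamic radius R_H(i) = R0 * i**gamma_H of a fractal i-mer."""
    i = np.asarray(i)
    if np.any(i < 1):
        raise ValueError("cluster sizes must be >= 1")
    return R0 * i ** float(gamma_H)


def _drag_shape(eps):
    """f(eps) = eps^2/4 + eps*K1(eps)/K0(eps); drag is 4*pi*eta_m*f(eps).

    The scaled Bessel functions k1e/k0e keep the ratio finite for any eps,
    so no asymptotic branch is needed.
    """
    eps = np.asarray(eps, dtype=float)
    return eps * eps / 4.0 + eps * k1e(eps) / k0e(eps)


def _epsilon(i, params: KernelParams):
    return hydrodynamic_radius(i, params.R0, params.gamma_H) * np.sqrt(
        params.b_s / params.eta_m
    )


def cluster_diffusivity(i, params: KernelParams, kBT: float = 1.0):
    """Evans–Sackmann diffusivity of an i-mer, D_i = kBT / lambda_T(i).

    lambda_T = 4 pi eta_m [eps^2/4 + eps K1(eps)/K0(eps)] with the reduced
    radius eps_i = R_H(i) sqrt(b_s/eta_m).  Logarithmic (membrane-viscosity
    dominated) for eps -> 0, and ~ eps^-2 (substrate-friction dominated)
    for eps -> infinity, hence D_i ~ i^(-2 gamma_H) for large clusters.
    """
    eps = _epsilon(i, params)
    return kBT / (4.0 * np.pi * params.eta_m * _drag_shape(eps))


def brownian_kernel(i, j, params: KernelParams):
    """Encounter-rate kernel in t* units: 1/f(eps_i) + 1/f(eps_j).

    The proportionality constant C_Br and kBT/(4 pi eta_m) are absorbed
    into the non-dimensional time, leaving a purely geometric rate.
    """
    return 1.0 / _drag_shape(_epsilon(i, params)) + 1.0 / _drag_shape(
        _epsilon(j, params)
    )


def _check_kernel_size(Nmax: int) -> None:
    """Memory guard for the dense Nmax x Nmax kernel matrix."""
    if Nmax > 10_000:
        warnings.warn(
            f"Nmax={Nmax} implies a dense {Nmax}x{Nmax} kernel matrix; "
            "expect high memory use",
            RuntimeWarning,
        )


def assemble_kernel(params: KernelParams) -> np.ndarray:
    """Dense symmetric composite kernel K[i-1, j-1] = k_Br(i,j)*k_rxn(i,j)."""
    _check_kernel_size(params.Nmax)
    sizes = np.arange(1, params.Nmax + 1)
    inv_f = 1.0 / _drag_shape(_epsilon(sizes, params))
    k_br = inv_f[:, None] + inv_f[None, :]
    k_rxn = reactive_kernel(
        sizes[:, None], sizes[None, :], params.P, params.N11, params.sigma
    )
    return k_br * k_rxn


class _RHS:
    """Vectorized Smoluchowski right-hand side for a fixed kernel matrix.

    The gain term (a weighted convolution over pairs i-j, j) is evaluated by
    summing the anti-diagonals of the pair-rate matrix K_ab * c_a * c_b with
    a precomputed bincount index; O(Nmax^2) per call with no Python loop.
    """

    def __init__(self, K: np.ndarray):
        self.K = K
        n = K.shape[0]
        a = np.arange(1, n + 1)
        # pair (a, b) produces size a+b; index 0..2n-2 maps to sizes 2..2n
        self._pair_size_idx = (a[:, None] + a[None, :] - 2).ravel()

    def __call__(self, t, c):
        K = self.K
        n = K.shape[0]
        # evaluate on the non-negative part: round-off-level negative
        # excursions from the integrator then relax back to zero instead of
        # feeding back through the quadratic loss term
        c = np.maximum(c, 0.0)
        Kc = K @ c
        loss = c * Kc
        pair = (K * np.outer(c, c)).ravel()
        gain_all = np.bincount(self._pair_size_idx, weights=pair, minlength=2 * n - 1)
        dc = -loss
        dc[1:] += 0.5 * gain_all[: n - 1]
        return dc


def aggregation_rhs(c: ClusterDistribution | np.ndarray, K: np.ndarray) -> np.ndarray:
    """dc/dt* of the truncated Smoluchowski system for distribution c.

    The loss sum runs over all j <= Nmax; pairs with i + j > Nmax leave the
    tracked system, so the first moment of the returned rate equals minus the
    mass flux past the truncation boundary.
    """
    arr = c.c if isinstance(c, ClusterDistribution) else np.asarray(c, dtype=float)
    if np.any(arr < 0):
        raise ValueError("concentrations must be non-negative")
    if K.shape[0] != arr.size:
        raise ValueError(f"kernel size {K.shape[0]} != distribution size {arr.size}")
    return _RHS(K)(0.0, arr)


def mean_cluster_size(c: ClusterDistribution | np.ndarray) -> float:
    """Number-weighted mean cluster size s = sum_i i*c_i / sum_j c_j."""
    arr = c.c if isinstance(c, ClusterDistribution) else np.asarray(c, dtype=float)
    total = arr.sum()
    if total <= 0:
        raise ValueError("mean cluster size undefined for an all-zero distribution")
    return float(np.dot(np.arange(1, arr.size + 1), arr) / total)


def simulate_aggregation(
    params: KernelParams,
    t_star_max: float,
    reltol: float = 1e-8,
    abstol: float = 1e-12,
) -> AggregationTrajectory:
    """Integrate the truncated system from a monomer-only initial condition.

    Adaptive explicit Runge-Kutta 4(5); terminates at t_star_max or when the
    retained mass drops below 1 - mass_loss_frac of the initial mass (mass
    leaks only through coagulation events past Nmax).  Concentrations more
    negative than -abstol abort; smaller excursions are clipped to zero.
    """
    K = assemble_kernel(params)
    rhs = _RHS(K)
    c0 = np.zeros(params.Nmax)
    c0[0] = params.c1_0
    m0 = params.c1_0
    sizes = np.arange(1, params.Nmax + 1)

    def mass_event(t, c):
        return np.dot(sizes, c) / m0 - (1.0 - params.mass_loss_frac)

    mass_event.terminal = True
    mass_event.direction = -1

    sol = solve_ivp(
        rhs,
        (0.0, t_star_max),
        c0,
        method="RK45",
        rtol=reltol,
        atol=abstol,
        events=mass_event,
        dense_output=False,
    )
    if not sol.success and sol.status != 1:
        raise RuntimeError(
            f"aggregation integration failed at t*={sol.t[-1] if sol.t.size else 0}: "
            f"{sol.message}"
        )

    times = sol.t
    cs = sol.y.T
    if sol.status == 1 and sol.t_events[0].size:
        times = np.append(times, sol.t_events[0][-1])
        cs = np.vstack([cs, sol.y_events[0][-1]])

    states, means, mass = [], [], []
    for t, c in zip(times, cs):
        if np.any(c < -abstol):
            raise RuntimeError(
                f"integrator produced concentration < -abstol at t*={t}"
            )
        c = np.clip(c, 0.0, None)
        states.append(ClusterDistribution(c=c, t_star=float(t)))
        means.append(mean_cluster_size(c))
        mass.append(float(np.dot(sizes, c) / m0))

    return AggregationTrajectory(
        times=np.asarray(times),
        states=states,
        mean_sizes=np.asarray(means),
        mass_retained=np.asarray(mass),
        terminated_by_mass_loss=bool(sol.status == 1),
        params=params,
    )


def dimer_peak_time(params: KernelParams) -> float:
    """Characteristic lag time: when the dimer concentration peaks.

    In the reduced monomer-dimer system
        dc1/dt = -k11 c1^2,    dc2/dt = 1/2 k11 c1^2 - k12 c1 c2,
    the dimer concentration is maximal at

        t_char2 = (mu^(1/(mu-1)) - 1) / (c1_0 * k11),   mu = k12/k11,

    with the analytic limit (e - 1)/(c1_0*k11) as mu -> 1.  mu is evaluated
    from the full composite kernel.  For P << 1, mu is independent of P and
    k11 ~ P, hence t_char2 ~ 1/P.
    """
    k11 = brownian_kernel(1, 1, params) * reactive_kernel(
        1, 1, params.P, params.N11, params.sigma
    )
    k12 = brownian_kernel(1, 2, params) * reactive_kernel(
        1, 2, params.P, params.N11, params.sigma
    )
    mu = k12 / k11
    if abs(mu - 1.0) < 1e-10:
        tau = np.e - 1.0
    else:
        tau = mu ** (1.0 / (mu - 1.0)) - 1.0
    return float(tau / (params.c1_0 * k11))


def crossover_size(P: float, N11: float, sigma: float) -> float:
    """RLCA-to-DLCA crossover size i_cross = (1/(P*N11))**(1/(2*sigma)).

    Defined by the encounter becoming reaction-unlimited,
    k_rxn(i_cross, i_cross) ~ 1 (exactly 1/(2-P) at the closed form).
    """
    if not (0.0 < P < 1.0):
        raise ValueError(f"P must lie in (0, 1) for a crossover, got {P}")
    i_cross = (1.0 / (P * N11)) ** (1.0 / (2.0 * sigma))
    if P * N11 >= 1.0:
        warnings.warn(
            "P*N11 >= 1: no reaction-limited regime (i_cross <= 1)", RuntimeWarning
        )
    return float(i_cross)


def dlca_exponent(gamma_H: float) -> float:
    """Late-time DLCA growth exponent z in s ~ t**z, z = 1/(1 + 2*gamma_H)."""
    if gamma_H < 0:
        raise ValueError("gamma_H must be non-negative")
    return 1.0 / (1.0 + 2.0 * gamma_H)
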