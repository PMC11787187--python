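"""Single-region in vivo model: constant monomers, clearance, fixed points.

In a brain region, monomer production and removal are assumed homeostatic,
so m is held at m_0; secondary nucleation saturates with the aggregate mass
M (sigma(M) = K_M/(K_M + M^2)); and every size class i is removed at a
first-order clearance rate lambda_i.  The model then has a healthy trivial
state (no aggregates) and, for weak enough clearance, a diseased state with
a nonzero equilibrium size distribution.  The two exchange stability in a
transcritical bifurcation at a critical clearance rate.

Steady states follow a geometric-type recurrence
p_i* = delta_i p_{i-1}*, delta_i = 2 k_plus m_0 / (lambda_i + 2 k_plus m_0),
so the distribution is exactly geometric for size-independent clearance.
Writing Delta_i for the cumulative product and Delta = sum_k k Delta_k, the
dimer balance inverts in closed form (the saturation factor enters only
through that one equation) to

    M* = sqrt(K_M (k_2 m_0^2 Delta - lambda_2 - 2 k_plus m_0)
              / (lambda_2 + 2 k_plus m_0)),     p_2* = M*/Delta,

which for constant clearance reduces to the moment-system fixed point M_2.
The diseased state exists iff Delta converges and the radicand is positive;
the vanishing radicand defines the exact bifurcation point, available as
``FixedPoint.lam_crit`` from :func:`fixed_point_constant`.
:func:`critical_clearance` evaluates the conventional closed-form threshold
expressions per clearance family (see docs/methods.md for how the constant
-clearance closed form relates to the exact existence boundary).

Clearance families: constant lambda; linear-in-size i*lambda_0;
inverse-size lambda_0/i; windowed (a drug elevates clearance by lambda_drug
on sizes n_0..n_1 over a background lambda_a); arbitrary tabulated rates.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.integrate import solve_ivp

from .parameters import KN_HOMOGENEOUS, KineticParameters
from .trajectory import (
    IntegrationError,
    TrajectoryResult,
    check_tail_mass,
    clip_small_negatives,
)

__all__ = [
    "ClearanceSpec",
    "FixedPoint",
    "clearance_rate",
    "simulate_invivo",
    "simulate_invivo_moments",
    "fixed_point_constant",
    "critical_clearance",
    "bifurcation_threshold",
    "empirical_critical_clearance",
    "equilibrium_distribution",
    "peak_and_timescales",
    "interval_mass_reduction",
    "compare_interval_targets",
]

VARIANTS = ("constant", "linear_in_size", "inverse_size", "windowed", "tabulated")


@dataclass(frozen=True)
class ClearanceSpec:
    """Per-size clearance rule lambda_i.

    Use the constructors :meth:`constant`, :meth:`linear_in_size`,
    :meth:`inverse_size`, :meth:`windowed`, :meth:`tabulated`, or
    :meth:`parse` (CLI syntax, e.g. ``"windowed:10,1e5,5,15"``).
    """

    variant: str
    lam: float = 0.0  # constant variant
    lam0: float = 0.0  # size-dependent variants
    lam_a: float = 0.0  # windowed background
    lam_drug: float = 0.0  # windowed increment
    n0: int = 2
    n1: int = 2
    table: tuple[float, ...] = field(default_factory=tuple)  # rates for sizes 2, 3, ...

    def __post_init__(self) -> None:
        if self.variant not in VARIANTS:
            raise ValueError(f"unknown clearance variant {self.variant!r}")
        for name in ("lam", "lam0", "lam_a", "lam_drug"):
            if getattr(self, name) < 0:
                raise ValueError(f"clearance rate {name} must be >= 0")
        if self.variant == "windowed" and self.n0 > self.n1:
            raise ValueError(f"windowed spec needs n0 <= n1, got {self.n0} > {self.n1}")
        if self.variant == "tabulated" and not self.table:
            raise ValueError("tabulated spec needs a non-empty rate table")
        if any(v < 0 for v in self.table):
            raise ValueError("tabulated clearance rates must be >= 0")

    @classmethod
    def constant(cls, lam: float) -> "ClearanceSpec":
        return cls(variant="constant", lam=float(lam))

    @classmethod
    def linear_in_size(cls, lam0: float) -> "ClearanceSpec":
        return cls(variant="linear_in_size", lam0=float(lam0))

    @classmethod
    def inverse_size(cls, lam0: float) -> "ClearanceSpec":
        return cls(variant="inverse_size", lam0=float(lam0))

    @classmethod
    def windowed(
        cls, lam_a: float, lam_drug: float, n0: int, n1: int
    ) -> "ClearanceSpec":
        return cls(
            variant="windowed",
            lam_a=float(lam_a),
            lam_drug=float(lam_drug),
            n0=int(n0),
            n1=int(n1),
        )

    @classmethod
    def tabulated(cls, table) -> "ClearanceSpec":
        """Explicit rates for sizes 2, 3, ...; the last entry extends to all
        larger sizes."""
        return cls(variant="tabulated", table=tuple(float(v) for v in table))

    @classmethod
    def parse(cls, text: str) -> "ClearanceSpec":
        """Parse CLI syntax like ``constant:10`` or ``windowed:10,1e5,5,15``."""
        try:
            variant, _, argstr = text.partition(":")
            args = [float(v) for v in argstr.split(",")] if argstr else []
            if variant == "constant":
                return cls.constant(*args)
            if variant in ("linear", "linear_in_size"):
                return cls.linear_in_size(*args)
            if variant in ("inverse", "inverse_size"):
                return cls.inverse_size(*args)
            if variant == "windowed":
                lam_a, lam_drug, n0, n1 = args
                return cls.windowed(lam_a, lam_drug, int(n0), int(n1))
        except (TypeError, ValueError) as exc:
            raise ValueError(f"bad clearance spec {text!r}: {exc}") from exc
        raise ValueError(f"bad clearance spec {text!r}")

    def rates(self, sizes: np.ndarray) -> np.ndarray:
        """Vector of lambda_i for an integer size array (all sizes >= 2)."""
        sizes = np.asarray(sizes)
        if np.any(sizes < 2):
            raise ValueError("clearance is defined for aggregate sizes i >= 2")
        if self.variant == "constant":
            return np.full(sizes.shape, self.lam, dtype=float)
        if self.variant == "linear_in_size":
            return self.lam0 * sizes.astype(float)
        if self.variant == "inverse_size":
            return self.lam0 / sizes.astype(float)
        if self.variant == "windowed":
            out = np.full(sizes.shape, self.lam_a, dtype=float)
            out[(sizes >= self.n0) & (sizes <= self.n1)] += self.lam_drug
            return out
        idx = np.minimum(sizes - 2, len(self.table) - 1)
        return np.asarray(self.table, dtype=float)[idx]

    def describe(self) -> str:
        if self.variant == "constant":
            return f"constant:{self.lam:g}"
        if self.variant in ("linear_in_size", "inverse_size"):
            return f"{self.variant}:{self.lam0:g}"
        if self.variant == "windowed":
            return (
                f"windowed:{self.lam_a:g},{self.lam_drug:g},{self.n0},{self.n1}"
            )
        return f"tabulated[{len(self.table)}]"


def clearance_rate(spec: ClearanceSpec, i: int) -> float:
    """Clearance rate lambda_i for a single aggregate size i >= 2."""
    if i < 2:
        raise ValueError(f"aggregate size must be >= 2, got {i}")
    return float(spec.rates(np.array([i]))[0])


@dataclass
class FixedPoint:
    """Equilibrium of the single-region model.

    ``lam_crit`` is the exact clearance threshold at which the nontrivial
    state disappears (NaN where no closed form applies, e.g. tabulated
    clearance); ``exists`` is False above threshold, in which case the
    trivial healthy state (all zeros) is the global attractor and the
    starred fields are zero.
    """

    P_star: float
    M_star: float
    p_star: np.ndarray | None
    exists: bool
    lam_crit: float = math.nan
    condition_failed: str | None = None

    @property
    def sizes(self) -> np.ndarray:
        return np.arange(2, len(self.p_star) + 2)


def _kn_source(params: KineticParameters, m0: float, include_kn: bool) -> float:
    """Homogeneous primary nucleation source k_n m0^2 (in vivo convention)."""
    if not include_kn:
        return 0.0
    if params.kn_convention != KN_HOMOGENEOUS:
        raise ValueError(
            "in vivo nucleation uses the homogeneous convention k_n m^2; "
            "tag the parameters with .with_convention('homogeneous') "
            "(before any rescaling) or pass include_kn=False"
        )
    return params.k_n * m0 * m0


def _sigma_M(M, K_M):
    return K_M / (K_M + M * M)


def default_dimer_seed(params: KineticParameters) -> dict[int, float]:
    """Reference seeding convention: p_2(0) = m_0 * 1e-4, nothing larger."""
    return {2: params.m_0 * 1e-4}


def simulate_invivo(
    params: KineticParameters,
    spec: ClearanceSpec,
    seed: dict[int, float] | np.ndarray | None = None,
    t_end: float = 1.0,
    N: int = 300,
    include_kn: bool = False,
    n_out: int = 400,
    rtol: float = 1e-8,
    check_tail: bool = True,
) -> TrajectoryResult:
    """Integrate the size-resolved single-region model (m held at m_0).

    Default seeding is the dimer convention p_2(0) = m_0 * 1e-4 when
    ``seed`` is None and primary nucleation is off; pass ``seed={}`` for a
    truly empty start.
    """
    if N < 3:
        raise ValueError(f"truncation size N must be >= 3, got {N}")
    m0 = params.m_0
    if seed is None and not include_kn:
        seed = default_dimer_seed(params)
    from .invitro import _seed_table

    p0 = _seed_table(seed if seed is not None else {}, N, m0)
    sizes = np.arange(2, N + 1)
    lam = spec.rates(sizes)
    kn_src = _kn_source(params, m0, include_kn)
    k_plus, k_2, K_M = params.k_plus, params.k_2, params.K_M
    elong = 2.0 * k_plus * m0
    fsz = sizes.astype(float)

    def rhs(t, p):
        M = p @ fsz
        sec = k_2 * _sigma_M(M, K_M) * m0 * m0 * M
        dp = np.empty_like(p)
        dp[0] = kn_src - elong * p[0] + sec
        dp[1:] = elong * (p[:-1] - p[1:])
        dp[-1] = elong * p[-2]
        dp -= lam * p
        return dp

    sol = solve_ivp(
        rhs,
        (0.0, t_end),
        p0,
        method="LSODA",
        t_eval=np.linspace(0.0, t_end, n_out),
        rtol=rtol,
        atol=1e-12 * m0,
    )
    if not sol.success:
        raise IntegrationError(f"in vivo integration failed: {sol.message}")
    p = clip_small_negatives(sol.y.T, floor_scale=1e-12 * m0)
    if check_tail:
        check_tail_mass(sol.t, p, sizes)
    meta = dict(
        model="invivo_local",
        params=vars(params),
        clearance=spec.describe(),
        N=N,
        rtol=rtol,
        include_kn=include_kn,
    )
    if spec.variant == "constant" and spec.lam > 0:
        fp = fixed_point_constant(params, spec.lam)
        meta["M2"] = fp.M_star
        meta["lam_crit"] = fp.lam_crit
    return TrajectoryResult(t=sol.t, m=np.full_like(sol.t, m0), p=p, metadata=meta)


def simulate_invivo_moments(
    params: KineticParameters,
    lam,
    seed_moments: tuple[float, float] | None = None,
    t_end: float = 1.0,
    include_kn: bool = False,
    n_out: int = 400,
    rtol: float = 1e-8,
    t0: float = 0.0,
    dense: bool = False,
) -> TrajectoryResult:
    """Integrate the (P, M) moment system for size-independent clearance.

    ``lam`` is a constant rate or a callable lambda(t) (used for dosing
    profiles).  The closure is exact for size-independent clearance; any
    per-size :class:`ClearanceSpec` other than constant is rejected.
    ``seed_moments`` is (P(0), M(0)); default is the dimer convention
    P(0) = m_0*1e-4, M(0) = 2e-4*m_0.
    """
    if isinstance(lam, ClearanceSpec):
        if lam.variant != "constant":
            raise ValueError(
                "moment closure requires size-independent clearance; got "
                f"variant {lam.variant!r}"
            )
        lam = lam.lam
    lam_t = lam if callable(lam) else (lambda t, _v=float(lam): _v)
    m0 = params.m_0
    if seed_moments is None:
        p2 = m0 * 1e-4
        seed_moments = (p2, 2.0 * p2)
    kn_src = _kn_source(params, m0, include_kn)
    k_plus, k_2, K_M = params.k_plus, params.k_2, params.K_M

    def rhs(t, y):
        P, M = y
        sec = k_2 * _sigma_M(M, K_M) * m0 * m0 * M
        lv = lam_t(t)
        dP = -lv * P + kn_src + sec
        dM = -lv * M + 2.0 * kn_src + 2.0 * k_plus * m0 * P + 2.0 * sec
        return [dP, dM]

    sol = solve_ivp(
        rhs,
        (t0, t0 + t_end),
        list(seed_moments),
        method="LSODA",
        t_eval=np.linspace(t0, t0 + t_end, n_out),
        rtol=rtol,
        atol=1e-12 * m0,
        dense_output=dense,
    )
    if not sol.success:
        raise IntegrationError(f"moment integration failed: {sol.message}")
    traj = TrajectoryResult(
        t=sol.t,
        m=np.full_like(sol.t, m0),
        P_series=sol.y[0],
        M_series=sol.y[1],
        metadata=dict(
            model="invivo_moments",
            params=vars(params),
            include_kn=include_kn,
            rtol=rtol,
        ),
    )
    if not callable(lam) and lam > 0:
        fp = fixed_point_constant(params, lam)
        traj.metadata["M2"] = fp.M_star
        traj.metadata["lam_crit"] = fp.lam_crit
    if dense:
        traj.metadata["dense_sol"] = sol.sol
    return traj


def bifurcation_threshold(params: KineticParameters) -> float:
    """Exact constant-clearance bifurcation point of the moment system.

    Vanishing of the nontrivial fixed point's radicand,
    lambda^2 - 2 k_2 m_0^2 lambda - 2 k_plus k_2 m_0^3 = 0, which is also
    where the trivial state loses stability:
    lambda* = k_2 m_0^2 + sqrt(k_2 m_0^3 (k_2 m_0 + 2 k_plus)).
    """
    c2 = params.k_2 * params.m_0**2
    a0 = 2.0 * params.k_plus * params.m_0
    return c2 + math.sqrt(c2 * c2 + a0 * c2)


def fixed_point_constant(params: KineticParameters, lam: float) -> FixedPoint:
    """Nontrivial fixed point (P_2, M_2) under constant clearance.

    M_2 = sqrt(K_M(-lam^2 + 2 lam k_2 m_0^2 + 2 k_plus k_2 m_0^3))/lam;
    exists only below the bifurcation threshold (vanishing radicand).
    The geometric size distribution p_i* is tabulated out to where its tail
    is negligible, so M_star = sum_i i p_i* holds on the table.
    """
    if lam <= 0:
        raise ValueError(f"clearance rate must be positive, got {lam}")
    m0, k_plus, k_2, K_M = params.m_0, params.k_plus, params.k_2, params.K_M
    lam_crit = bifurcation_threshold(params)
    radicand = K_M * (-lam * lam + 2.0 * lam * k_2 * m0**2 + 2.0 * k_plus * k_2 * m0**3)
    sizes = np.arange(2, 303)
    if radicand <= 0:
        return FixedPoint(
            P_star=0.0,
            M_star=0.0,
            p_star=np.zeros(sizes.size),
            exists=False,
            lam_crit=lam_crit,
            condition_failed="C3",
        )
    M2 = math.sqrt(radicand) / lam
    P2 = math.sqrt(radicand) / (2.0 * (k_plus * m0 + lam))
    delta = 2.0 * k_plus * m0 / (lam + 2.0 * k_plus * m0)
    # geometric distribution; full sums: sum k delta^{k-2} = (2-delta)/(1-delta)^2
    Delta = (2.0 - delta) / (1.0 - delta) ** 2
    p2 = M2 / Delta
    # table long enough that the geometric tail is fully resolved
    n_tab = int(min(max(300, math.ceil(-30.0 / math.log(delta))), 5e6))
    sizes = np.arange(2, n_tab + 2)
    p_star = p2 * delta ** (sizes - 2.0)
    return FixedPoint(
        P_star=P2, M_star=M2, p_star=p_star, exists=True, lam_crit=lam_crit
    )


def critical_clearance(params: KineticParameters, spec_variant: str) -> float:
    """Closed-form critical clearance threshold per clearance family.

    constant:       k_2 m_0^2 + sqrt(2 k_2 m_0^3 (k_2 m_0 + k_plus))
    linear_in_size: (k_plus k_2 m_0^3 - 1) / (k_plus m_0 - k_2 m_0^2)
    inverse_size:   2a (a + 4 k_2 m_0^2) / (a + k_2 m_0^2),  a = 2 k_plus m_0
                    (approximately 2a since a >> k_2 m_0^2)
    Above threshold the aggregate-free state is the only attractor.  For the
    constant family this conventional closed form sits ~1% above the exact
    bifurcation point (:func:`bifurcation_threshold`); see docs/methods.md.
    """
    m0, k_plus, k_2 = params.m_0, params.k_plus, params.k_2
    if spec_variant == "constant":
        return k_2 * m0**2 + math.sqrt(2.0 * k_2 * m0**3 * (k_2 * m0 + k_plus))
    if spec_variant == "linear_in_size":
        return (k_plus * k_2 * m0**3 - 1.0) / (k_plus * m0 - k_2 * m0**2)
    if spec_variant == "inverse_size":
        a = 2.0 * k_plus * m0
        return 2.0 * a * (a + 4.0 * k_2 * m0**2) / (a + k_2 * m0**2)
    raise ValueError(
        f"no closed-form critical clearance for variant {spec_variant!r}"
    )


def empirical_critical_clearance(
    params: KineticParameters,
    lo: float,
    hi: float,
    n_iter: int = 40,
    rel_tol: float = 1e-4,
    t_end: float = 2.0,
    threshold: float | None = None,
) -> float:
    """Locate the constant-clearance bifurcation by bisection on ODE outcomes.

    A seeded moment run at clearance lam is classified as subcritical if the
    late-time mass stays above ``threshold`` (default 1e-6 * m_0).  The
    initial bracket [lo, hi] must straddle the transition.
    """
    m0 = params.m_0
    if threshold is None:
        threshold = 1e-6 * m0

    def invaded(lam: float) -> bool:
        traj = simulate_invivo_moments(params, lam, t_end=t_end, n_out=5, rtol=1e-8)
        return traj.M[-1] > threshold

    if not invaded(lo) or invaded(hi):
        raise ValueError(f"bracket [{lo}, {hi}] does not straddle the bifurcation")
    for _ in range(n_iter):
        mid = 0.5 * (lo + hi)
        if invaded(mid):
            lo = mid
        else:
            hi = mid
        if hi - lo < rel_tol * hi:
            break
    return 0.5 * (lo + hi)


def equilibrium_distribution(
    params: KineticParameters,
    spec: ClearanceSpec,
    N: int | None = None,
    max_N: int = 2**21,
) -> FixedPoint:
    """Equilibrium size distribution p_i* for an arbitrary clearance rule.

    With N=None (default) the truncation grows until the tail satisfies
    N * Delta_N < 1e-8 * Delta, so the sums are converged; an explicit N is
    honoured verbatim (useful for comparing against an ODE run truncated at
    the same N).  ``exists=False`` reports which existence condition failed:
    "C1/C2" (divergent size sums, unbounded aggregate growth) or "C3"
    (clearance above threshold, trivial state globally attracting).
    """
    auto = N is None
    n_trunc = 4096 if auto else int(N)
    while True:
        sizes = np.arange(2, n_trunc + 1)
        delta = 2.0 * params.k_plus * params.m_0 / (
            spec.rates(sizes) + 2.0 * params.k_plus * params.m_0
        )
        # Delta_i = prod_{j=3..i} delta_j (Delta_2 = 1)
        log_Delta = np.concatenate(([0.0], np.cumsum(np.log(delta[1:]))))
        Delta_i = np.exp(log_Delta)
        Delta = float(sizes @ Delta_i)
        tail_ok = n_trunc * Delta_i[-1] < 1e-8 * Delta
        if not auto or tail_ok or n_trunc >= max_N:
            break
        n_trunc *= 2
    if auto and not tail_ok:
        warnings.warn(
            f"size sums not converged at N={n_trunc} (heavy clearance tail); "
            "equilibrium existence reported as C1/C2 failure",
            RuntimeWarning,
            stacklevel=2,
        )
        return FixedPoint(
            P_star=0.0,
            M_star=0.0,
            p_star=None,
            exists=False,
            condition_failed="C1/C2",
        )
    m0, k_plus, k_2, K_M = params.m_0, params.k_plus, params.k_2, params.K_M
    a0 = 2.0 * k_plus * m0
    lam2 = clearance_rate(spec, 2)
    arg = k_2 * m0 * m0 * Delta - lam2 - a0
    if arg <= 0:
        return FixedPoint(
            P_star=0.0,
            M_star=0.0,
            p_star=np.zeros(sizes.size),
            exists=False,
            condition_failed="C3",
        )
    M_star = math.sqrt(K_M * arg / (lam2 + a0))
    p2 = M_star / Delta
    p_star = p2 * Delta_i
    return FixedPoint(
        P_star=float(p_star.sum()), M_star=M_star, p_star=p_star, exists=True
    )


def peak_and_timescales(
    traj: TrajectoryResult, epsilon: float, m_eq: float | None = None
) -> tuple[float, float, float]:
    """Peak toxic mass and the growth/relaxation timescales of a seeded run.

    Returns (M_max, tau_1, tau_2): the maximum of M(t), its time, and the
    first later time with |M - M_eq| < epsilon.  ``m_eq`` defaults to the
    fixed-point mass recorded in the trajectory metadata.  All three are
    NaN when the peak is not interior (monotone trajectory), tau_2 alone is
    NaN when the band is never entered.
    """
    if m_eq is None:
        m_eq = traj.metadata.get("M2")
        if m_eq is None:
            raise ValueError("m_eq not given and no fixed point in metadata")
    M = np.asarray(traj.M)
    k = int(np.argmax(M))
    if k == 0 or k == M.size - 1:
        return (math.nan, math.nan, math.nan)
    M_max, tau1 = float(M[k]), float(traj.t[k])
    inside = np.abs(M[k:] - m_eq) < epsilon
    if not inside.any():
        return (M_max, tau1, math.nan)
    return (M_max, tau1, float(traj.t[k + int(np.argmax(inside))]))


def interval_mass_reduction(
    params: KineticParameters,
    lam_a: float,
    lam_drug: float,
    n0: int,
    n1: int,
    N: int | None = None,
) -> float:
    """Equilibrium toxic mass when clearance is elevated on sizes n0..n1.

    Windowed clearance lambda_i = lam_a + lam_drug for n0 <= i <= n1, else
    lam_a.  Returns M*; 0 when no diseased equilibrium exists.
    """
    if not 2 <= n0 <= n1:
        raise ValueError(f"need 2 <= n0 <= n1, got ({n0}, {n1})")
    spec = ClearanceSpec.windowed(lam_a, lam_drug, n0, n1)
    return equilibrium_distribution(params, spec, N=N).M_star


def compare_interval_targets(
    params: KineticParameters,
    lam: float,
    intervals: list[tuple[int, int]],
    N: int | None = None,
) -> list[float]:
    """Equilibrium mass held in each size interval under constant clearance.

    The mass sum_{k in [n0, n1]} k Delta_k p_2* is what a clearance drug
    targeting that window removes instantaneously from the untreated
    equilibrium.  The per-size mass k p_k* peaks near size 2 k_plus m_0 /
    lam; among equal-width windows beyond that size, the lower window holds
    more mass.  (The self-consistent equilibrium under a sustained window,
    :func:`interval_mass_reduction`, favors small-size targeting at every
    size, because suppressing small aggregates also chokes the elongation
    flux into all larger sizes.)  Intervals (inclusive) must be
    non-overlapping and of equal width.
    """
    widths = {hi - lo for lo, hi in intervals}
    if len(widths) > 1:
        raise ValueError(f"intervals must have equal width, got widths {widths}")
    spans = sorted(intervals)
    for (lo1, hi1), (lo2, _hi2) in zip(spans, spans[1:]):
        if lo2 <= hi1:
            raise ValueError(f"overlapping intervals ({lo1},{hi1}) and ({lo2},{_hi2})")
    fp = equilibrium_distribution(params, ClearanceSpec.constant(lam), N=N)
    if not fp.exists:
        raise ValueError(f"no diseased equilibrium at clearance {lam}")
    sizes = fp.sizes
    out = []
    for lo, hi in intervals:
        mask = (sizes >= lo) & (sizes <= hi)
        out.append(float(sizes[mask] @ fp.p_star[mask]))
    return out
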