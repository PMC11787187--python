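"""Aging and damage: toxic mass degrades clearance toward a basal floor.

Accumulated aggregate mass damages vascular, enzymatic and glymphatic waste
removal, so the clearance rates themselves become dynamic:

    d lambda_i / dt = beta_i * M * (mu_i - lambda_i),

decaying monotonically from an initial capacity lambda_init,i toward the
basal clearance capacity mu_i <= lambda_init,i (maximal damage).  Since
M >= 0, lambda_i(t) stays in [mu_i, lambda_init,i] for all time.  Once
clearance has relaxed to mu the dynamics coincide with the static-clearance
model at rate mu, so the long-term fate is set by where mu sits relative to
the critical clearance ("basal capacity" regimes).  Primary nucleation
(homogeneous, k_n m^2) is kept on by default here: an initially healthy
region (lambda_init above critical) holds only a tiny nucleation-fed
aggregate population, yet that population slowly erodes clearance and can
eventually tip the region into invasion.
"""

from __future__ import annotations

import numpy as np
from scipy.integrate import solve_ivp
from dataclasses import dataclass

from .invivo_local import (
    ClearanceSpec,
    _kn_source,
    _sigma_M,
    critical_clearance,
    simulate_invivo,
)
from .parameters import KineticParameters
from .trajectory import (
    IntegrationError,
    TrajectoryResult,
    check_tail_mass,
    clip_small_negatives,
)

__all__ = ["DamageSpec", "simulate_damage", "simulate_damage_moments", "classify_regime"]


@dataclass(frozen=True)
class DamageSpec:
    """Damage-driven clearance decay parameters.

    beta : damage rate coefficient, units 1/(concentration * time); scalar
        (applied to every size) or per-size array.
    mu : basal clearance capacity (floor), time^-1; scalar or per-size.
    lam_init : initial clearance, time^-1; scalar or per-size.
    """

    beta: float | np.ndarray
    mu: float | np.ndarray
    lam_init: float | np.ndarray

    def __post_init__(self) -> None:
        if np.any(np.asarray(self.beta) < 0):
            raise ValueError("damage rate beta must be >= 0")
        if np.any(np.asarray(self.mu) < 0) or np.any(np.asarray(self.lam_init) < 0):
            raise ValueError("clearance rates must be >= 0")
        if np.any(np.asarray(self.mu) > np.asarray(self.lam_init)):
            raise ValueError(
                "basal capacity mu must not exceed the initial clearance "
                "(the model describes decay only)"
            )

    def is_scalar(self) -> bool:
        return all(
            np.isscalar(v) or np.asarray(v).ndim == 0
            for v in (self.beta, self.mu, self.lam_init)
        )

    def arrays(self, n_sizes: int):
        to = lambda v: np.broadcast_to(np.asarray(v, dtype=float), (n_sizes,)).copy()
        return to(self.beta), to(self.mu), to(self.lam_init)


def simulate_damage(
    params: KineticParameters,
    dspec: DamageSpec,
    seed: dict[int, float] | np.ndarray | None = None,
    t_end: float = 1.0,
    N: int = 300,
    include_kn: bool = True,
    n_out: int = 400,
    rtol: float = 1e-8,
    check_tail: bool = True,
    log_time: bool = False,
) -> TrajectoryResult:
    """Size-resolved single-region run with dynamically decaying clearance.

    State is (p_2..p_N, lambda_2..lambda_N).  The returned trajectory
    carries the clearance series in ``clearance`` (shape (T, N-1)).
    ``log_time`` uses a geometric output grid, useful because damage-driven
    invasion can be many orders of magnitude slower than the aggregation
    kinetics.
    """
    if N < 3:
        raise ValueError(f"truncation size N must be >= 3, got {N}")
    m0 = params.m_0
    from .invitro import _seed_table

    if seed is None and not include_kn:
        seed = {2: m0 * 1e-4}
    p0 = _seed_table(seed if seed is not None else {}, N, m0)
    sizes = np.arange(2, N + 1)
    fsz = sizes.astype(float)
    beta, mu, lam0 = dspec.arrays(N - 1)
    kn_src = _kn_source(params, m0, include_kn)
    k_plus, k_2, K_M = params.k_plus, params.k_2, params.K_M
    elong = 2.0 * k_plus * m0
    n_p = N - 1

    def rhs(t, y):
        p, lam = y[:n_p], y[n_p:]
        M = p @ fsz
        sec = k_2 * _sigma_M(M, K_M) * m0 * m0 * M
        dp = np.empty_like(p)
        dp[0] = kn_src - elong * p[0] + sec
        dp[1:] = elong * (p[:-1] - p[1:])
        dp[-1] = elong * p[-2]
        dp -= lam * p
        dlam = beta * M * (mu - lam)
        return np.concatenate((dp, dlam))

    if log_time:
        t_eval = np.geomspace(max(t_end * 1e-6, 1e-12), t_end, n_out)
    else:
        t_eval = np.linspace(0.0, t_end, n_out)
    atol_p = min(1e-12 * m0, 1e-6 * kn_src) if kn_src > 0 else 1e-12 * m0
    atol = np.concatenate(
        (np.full(n_p, atol_p), np.full(n_p, 1e-8 * max(float(np.max(lam0)), 1.0)))
    )
    sol = solve_ivp(
        rhs,
        (0.0, t_end),
        np.concatenate((p0, lam0)),
        method="LSODA",
        t_eval=t_eval,
        rtol=rtol,
        atol=atol,
    )
    if not sol.success:
        raise IntegrationError(f"damage integration failed: {sol.message}")
    p = clip_small_negatives(sol.y[:n_p].T, floor_scale=1e-12 * m0)
    lam = sol.y[n_p:].T
    if check_tail:
        check_tail_mass(sol.t, p, sizes)
    return TrajectoryResult(
        t=sol.t,
        m=np.full_like(sol.t, m0),
        p=p,
        clearance=lam,
        metadata=dict(
            model="damage",
            params=vars(params),
            damage=dict(
                beta=np.asarray(dspec.beta).tolist(),
                mu=np.asarray(dspec.mu).tolist(),
                lam_init=np.asarray(dspec.lam_init).tolist(),
            ),
            N=N,
            rtol=rtol,
            include_kn=include_kn,
        ),
    )


def simulate_damage_moments(
    params: KineticParameters,
    dspec: DamageSpec,
    seed_moments: tuple[float, float] = (0.0, 0.0),
    t_end: float = 1.0,
    include_kn: bool = True,
    n_out: int = 400,
    rtol: float = 1e-8,
    log_time: bool = False,
) -> TrajectoryResult:
    """Moment-level damage run (P, M, lambda); size-independent spec only.

    With scalar damage parameters every lambda_i shares one trajectory, the
    moment closure is exact, and decade-spanning invasion timescales can be
    integrated cheaply.
    """
    if not dspec.is_scalar():
        raise ValueError("moment closure requires size-independent damage spec")
    m0 = params.m_0
    beta, mu, lam0 = float(np.asarray(dspec.beta)), float(np.asarray(dspec.mu)), float(
        np.asarray(dspec.lam_init)
    )
    kn_src = _kn_source(params, m0, include_kn)
    k_plus, k_2, K_M = params.k_plus, params.k_2, params.K_M

    def rhs(t, y):
        P, M, lam = y
        sec = k_2 * _sigma_M(M, K_M) * m0 * m0 * M
        dP = -lam * P + kn_src + sec
        dM = -lam * M + 2.0 * kn_src + 2.0 * k_plus * m0 * P + 2.0 * sec
        dlam = beta * M * (mu - lam)
        return [dP, dM, dlam]

    if log_time:
        t_eval = np.geomspace(max(t_end * 1e-9, 1e-12), t_end, n_out)
    else:
        t_eval = np.linspace(0.0, t_end, n_out)
    # the nucleation-fed quiescent mass can sit ~20 decades below lambda,
    # so the moments need their own absolute tolerance floor
    atol_pm = min(1e-12 * m0, 1e-6 * kn_src) if kn_src > 0 else 1e-12 * m0
    sol = solve_ivp(
        rhs,
        (0.0, t_end),
        [seed_moments[0], seed_moments[1], lam0],
        method="LSODA",
        t_eval=t_eval,
        rtol=rtol,
        atol=[atol_pm, atol_pm, 1e-8 * max(lam0, 1.0)],
    )
    if not sol.success:
        raise IntegrationError(f"damage moment integration failed: {sol.message}")
    return TrajectoryResult(
        t=sol.t,
        m=np.full_like(sol.t, m0),
        P_series=sol.y[0],
        M_series=sol.y[1],
        clearance=sol.y[2],
        metadata=dict(
            model="damage_moments",
            params=vars(params),
            damage=dict(beta=beta, mu=mu, lam_init=lam0),
            rtol=rtol,
            include_kn=include_kn,
        ),
    )


#: Regime labels relative to the critical basal clearance capacity mu_crit.
STABLE_BASAL = "stable_basal_capacity"  # mu > mu_crit: damage cannot tip the region
DELAYED_INVASION = "delayed_invasion"  # lam_init > mu_crit > mu: slow erosion, then invasion
IMMEDIATE_INVASION = "immediate_invasion"  # lam_init < mu_crit: subcritical from the start


def classify_regime(dspec: DamageSpec, params: KineticParameters) -> str:
    """Classify the long-term fate by (lambda_init, mu) vs the critical rate.

    Only defined for size-independent specs; mu_crit is the constant-family
    critical clearance of the underlying kinetics.
    """
    if not dspec.is_scalar():
        raise ValueError("regime classification requires a size-independent spec")
    mu = float(np.asarray(dspec.mu))
    lam0 = float(np.asarray(dspec.lam_init))
    mu_crit = critical_clearance(params, "constant")
    if mu > mu_crit:
        return STABLE_BASAL
    if lam0 > mu_crit:
        return DELAYED_INVASION
    return IMMEDIATE_INVASION
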