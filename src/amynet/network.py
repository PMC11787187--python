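"""Brain-scale transport: local aggregation kinetics coupled by the graph
Laplacian of a weighted connectome.

Aggregates travel between brain regions along axonal bundles.  On a weighted
graph with adjacency A, the unnormalized Laplacian (off-diagonal -A_ij,
diagonal row sums) generates diffusion that conserves mass per size class
and produces no flux between regions at equal concentration.  Each node runs
the single-region in vivo kinetics (constant local monomer pool, clearance,
secondary nucleation saturating in the local mass M_j), and every size class
i diffuses with its own coefficient rho_i — either size-independent or
decaying as rho_0 / i^3 with molecular weight, in which case only the small
nuclei move appreciably and invasion is driven by dimer spread.

``simulate_network`` integrates the full size-resolved system (V nodes x
(N-1) sizes plus V monomer pools); ``simulate_network_moments`` integrates
the exactly closed per-node (P_j, M_j) system, valid for size-independent
diffusion and constant clearance.  ``invasion_metrics`` extracts per-region
arrival times and ranks from normalized toxic-mass curves.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import sparse
from scipy.integrate import solve_ivp

from .invivo_local import ClearanceSpec, _kn_source, _sigma_M, fixed_point_constant
from .parameters import KineticParameters
from .trajectory import IntegrationError, check_tail_mass, clip_small_negatives

__all__ = [
    "Connectome",
    "NetworkTrajectory",
    "build_laplacian",
    "diffusion_profile",
    "simulate_network",
    "simulate_network_moments",
    "invasion_metrics",
]


@dataclass
class Connectome:
    """Weighted undirected brain graph: node labels and adjacency."""

    labels: list[str]
    adjacency: np.ndarray

    def __post_init__(self) -> None:
        self.adjacency = np.asarray(self.adjacency, dtype=float)
        V = len(self.labels)
        if self.adjacency.shape != (V, V):
            raise ValueError(
                f"adjacency shape {self.adjacency.shape} does not match "
                f"{V} node labels"
            )

    @property
    def V(self) -> int:
        return len(self.labels)

    @property
    def laplacian(self) -> np.ndarray:
        """Mass-conserving graph Laplacian: L = diag(row sums of A) - A."""
        A = self.adjacency
        return np.diag(A.sum(axis=1)) - A

    def index(self, label: str) -> int:
        try:
            return self.labels.index(label)
        except ValueError:
            raise KeyError(
                f"node label {label!r} not in connectome ({self.V} nodes)"
            ) from None

    def degrees(self) -> np.ndarray:
        return (self.adjacency > 0).sum(axis=1)

    def path_lengths_from(self, label: str) -> np.ndarray:
        """Unweighted shortest-path (hop) distance from a node to all nodes."""
        import networkx as nx

        G = nx.from_numpy_array(self.adjacency)
        dist = nx.single_source_shortest_path_length(G, self.index(label))
        out = np.full(self.V, np.inf)
        for j, d in dist.items():
            out[j] = d
        return out


def build_laplacian(adjacency, labels: list[str] | None = None) -> Connectome:
    """Validate an adjacency matrix and wrap it as a :class:`Connectome`.

    Requires a square, symmetric (to 1e-12), non-negative matrix with zero
    diagonal; offending indices are reported on failure.
    """
    A = np.asarray(adjacency, dtype=float)
    if A.ndim != 2 or A.shape[0] != A.shape[1]:
        raise ValueError(f"adjacency must be square, got shape {A.shape}")
    asym = np.abs(A - A.T)
    if asym.max(initial=0.0) > 1e-12:
        i, j = np.unravel_index(np.argmax(asym), A.shape)
        raise ValueError(
            f"adjacency not symmetric at ({i},{j}): {A[i, j]!r} vs {A[j, i]!r}"
        )
    if (A < 0).any():
        i, j = np.unravel_index(np.argmin(A), A.shape)
        raise ValueError(f"negative edge weight {A[i, j]!r} at ({i},{j})")
    if np.diag(A).any():
        (k,) = np.nonzero(np.diag(A))[:1]
        raise ValueError(f"nonzero diagonal (self edge) at node {int(k[0])}")
    if labels is None:
        labels = [f"node_{i}" for i in range(A.shape[0])]
    return Connectome(labels=list(labels), adjacency=A)


def diffusion_profile(rho0: float, mode: str = "constant", N: int = 300) -> np.ndarray:
    """Per-size diffusion coefficients rho_i for sizes 1..N.

    ``constant``: rho_i = rho0; ``inverse_cube``: rho_i = rho0 / i^3
    (soluble-peptide scaling with the reciprocal cube of molecular weight).
    """
    if rho0 < 0:
        raise ValueError("diffusion coefficient must be >= 0")
    sizes = np.arange(1, N + 1, dtype=float)
    if mode == "constant":
        return np.full(N, float(rho0))
    if mode == "inverse_cube":
        return rho0 / sizes**3
    raise ValueError(f"unknown diffusion mode {mode!r}")


@dataclass
class NetworkTrajectory:
    """Per-node trajectories of a network simulation."""

    t: np.ndarray
    labels: list[str]
    m: np.ndarray  # (T, V) monomer concentrations
    p: np.ndarray | None = None  # (T, V, S) sizes 2..N
    P_series: np.ndarray | None = None  # (T, V)
    M_series: np.ndarray | None = None  # (T, V)
    metadata: dict = field(default_factory=dict)

    @property
    def sizes(self) -> np.ndarray:
        return np.arange(2, self.p.shape[2] + 2)

    @property
    def M(self) -> np.ndarray:
        if self.M_series is not None:
            return self.M_series
        return self.p @ self.sizes.astype(float)

    @property
    def P(self) -> np.ndarray:
        if self.P_series is not None:
            return self.P_series
        return self.p.sum(axis=2)

    def node(self, label: str) -> int:
        return self.labels.index(label)

    def to_frame(self) -> pd.DataFrame:
        """Tidy per-node moment series: time, node, m, P, M."""
        M, P = self.M, self.P
        frames = [
            pd.DataFrame(
                {
                    "time": self.t,
                    "node": lab,
                    "m": self.m[:, j],
                    "P": P[:, j],
                    "M": M[:, j],
                }
            )
            for j, lab in enumerate(self.labels)
        ]
        return pd.concat(frames, ignore_index=True)


def _clearance_matrix(clearance, labels, sizes) -> np.ndarray:
    """(V, S) clearance rates from a uniform spec or per-node mapping."""
    V, S = len(labels), sizes.size
    if isinstance(clearance, ClearanceSpec):
        return np.broadcast_to(clearance.rates(sizes), (V, S)).copy()
    out = np.empty((V, S))
    missing = [lab for lab in labels if lab not in clearance]
    if missing:
        raise KeyError(f"no clearance spec for nodes {missing}")
    for j, lab in enumerate(labels):
        out[j] = clearance[lab].rates(sizes)
    return out


def _seed_state(connectome, params, seed, S) -> np.ndarray:
    p0 = np.zeros((connectome.V, S))
    node = seed["node"]
    rows = slice(None) if node == "*" else connectome.index(node)
    amount = float(seed.get("amount", params.m_0))
    kind = seed.get("kind", "dimer")
    if kind == "dimer":
        p0[rows, 0] = amount
    elif kind == "mass":
        p0[rows, 0] = amount / 2.0  # mass seed deposited as dimers, M(0) = amount
    else:
        raise ValueError(f"unknown seed kind {kind!r} (use 'dimer' or 'mass')")
    return p0


def _jac_sparsity(V, S, A) -> sparse.lil_matrix:
    """Sparsity pattern for the size-resolved network Jacobian.

    Layout: [m_0..m_{V-1}, p(node 0, sizes 2..N), p(node 1, ...), ...].
    """
    n = V + V * S
    J = sparse.lil_matrix((n, n), dtype=np.int8)
    nb = A > 0
    J[:V, :V] = nb | np.eye(V, dtype=bool)
    for v in range(V):
        base = V + v * S
        rows = slice(base, base + S)
        # local coupling: p2 row sees every size (through M); p_i sees i-1, i
        J[base, rows] = 1
        J[base, v] = 1  # monomer dependence
        for s in range(1, S):
            J[base + s, base + s] = 1
            J[base + s, base + s - 1] = 1
            J[base + s, v] = 1
        # transport: same size at neighbouring nodes
        for u in np.nonzero(nb[v])[0]:
            ub = V + u * S
            for s in range(S):
                J[base + s, ub + s] = 1
    return J


def simulate_network(
    connectome: Connectome,
    params: KineticParameters,
    clearance,
    rho,
    seed: dict,
    t_end: float,
    N: int = 100,
    include_kn: bool = False,
    n_out: int = 200,
    rtol: float = 1e-6,
    check_tail: bool = True,
) -> NetworkTrajectory:
    """Integrate the size-resolved network model.

    Parameters
    ----------
    clearance : ClearanceSpec or {label: ClearanceSpec}
        Uniform or per-node clearance.
    rho : array (sizes 1..N) or tuple (rho0, mode)
        Per-size diffusion coefficients; see :func:`diffusion_profile`.
    seed : dict
        ``{"node": label, "kind": "dimer"|"mass", "amount": conc}``.  A
        dimer seed sets p_2 = amount at the node; a mass seed deposits
        M(0) = amount as dimers; node ``"*"`` seeds every node uniformly.
        All monomer pools start uniform at m_0.
    """
    V, S = connectome.V, N - 1
    sizes = np.arange(2, N + 1)
    fsz = sizes.astype(float)
    if isinstance(rho, tuple):
        rho = diffusion_profile(rho[0], rho[1], N)
    rho = np.asarray(rho, dtype=float)
    if rho.shape != (N,):
        raise ValueError(f"diffusion profile must cover sizes 1..{N}")
    lam = _clearance_matrix(clearance, connectome.labels, sizes)
    L = connectome.laplacian
    m0 = params.m_0
    p0 = _seed_state(connectome, params, seed, S)
    kn_on = include_kn
    kn_coeff = _kn_source(params, 1.0, include_kn) if kn_on else 0.0  # k_n only
    k_plus, k_2, K_M = params.k_plus, params.k_2, params.K_M
    rho_agg = rho[1:]

    def rhs(t, y):
        m = y[:V]
        p = y[V:].reshape(V, S)
        M = p @ fsz
        sec = k_2 * _sigma_M(M, K_M) * m * m * M
        elong = 2.0 * k_plus * m
        dp = np.empty_like(p)
        dp[:, 0] = kn_coeff * m * m - elong * p[:, 0] + sec
        dp[:, 1:] = elong[:, None] * (p[:, :-1] - p[:, 1:])
        dp[:, -1] = elong * p[:, -2]
        dp -= lam * p
        dp -= (L @ p) * rho_agg[None, :]
        dm = -rho[0] * (L @ m)
        return np.concatenate((dm, dp.ravel()))

    y0 = np.concatenate((np.full(V, m0), p0.ravel()))
    sol = solve_ivp(
        rhs,
        (0.0, t_end),
        y0,
        method="BDF",
        t_eval=np.linspace(0.0, t_end, n_out),
        rtol=rtol,
        atol=1e-12 * m0,
        jac_sparsity=_jac_sparsity(V, S, connectome.adjacency),
    )
    if not sol.success:
        raise IntegrationError(f"network integration failed: {sol.message}")
    y = clip_small_negatives(sol.y.T, floor_scale=1e-10 * m0)
    m = y[:, :V]
    p = y[:, V:].reshape(-1, V, S)
    if check_tail:
        for j in range(V):
            check_tail_mass(sol.t, p[:, j, :], sizes)
    return NetworkTrajectory(
        t=sol.t,
        labels=list(connectome.labels),
        m=m,
        p=p,
        metadata=dict(
            model="network",
            params=vars(params),
            N=N,
            rtol=rtol,
            seed=dict(seed),
            rho0=float(rho[0]),
        ),
    )


def simulate_network_moments(
    connectome: Connectome,
    params: KineticParameters,
    lam: float,
    rho0: float,
    seed: dict,
    t_end: float,
    include_kn: bool = False,
    n_out: int = 300,
    rtol: float = 1e-8,
) -> NetworkTrajectory:
    """Integrate the per-node (P_j, M_j) moment system.

    Exact closure requires size-independent diffusion rho0 and constant
    clearance lam.  Monomers stay uniform at m_0 (no gradient, no flux).
    """
    V = connectome.V
    L = connectome.laplacian
    m0 = params.m_0
    kn_src = _kn_source(params, m0, include_kn)
    k_plus, k_2, K_M = params.k_plus, params.k_2, params.K_M
    P0 = np.zeros(V)
    M0 = np.zeros(V)
    j = connectome.index(seed["node"])
    amount = float(seed.get("amount", m0))
    if seed.get("kind", "mass") == "mass":
        M0[j] = amount
        P0[j] = amount / 2.0
    else:
        P0[j] = amount
        M0[j] = 2.0 * amount

    def rhs(t, y):
        P, M = y[:V], y[V:]
        sec = k_2 * _sigma_M(M, K_M) * m0 * m0 * M
        dP = -lam * P + kn_src + sec - rho0 * (L @ P)
        dM = -lam * M + 2.0 * kn_src + 2.0 * k_plus * m0 * P + 2.0 * sec - rho0 * (
            L @ M
        )
        return np.concatenate((dP, dM))

    sol = solve_ivp(
        rhs,
        (0.0, t_end),
        np.concatenate((P0, M0)),
        method="LSODA",
        t_eval=np.linspace(0.0, t_end, n_out),
        rtol=rtol,
        atol=1e-12 * m0,
    )
    if not sol.success:
        raise IntegrationError(f"network moment integration failed: {sol.message}")
    fp = fixed_point_constant(params, lam)
    return NetworkTrajectory(
        t=sol.t,
        labels=list(connectome.labels),
        m=np.full((sol.t.size, V), m0),
        P_series=sol.y[:V].T,
        M_series=sol.y[V:].T,
        metadata=dict(
            model="network_moments",
            params=vars(params),
            lam=lam,
            rho0=rho0,
            M2=fp.M_star,
            seed=dict(seed),
        ),
    )


def invasion_metrics(
    traj: NetworkTrajectory,
    theta: float = 0.5,
    m_sat: float | np.ndarray | None = None,
) -> pd.DataFrame:
    """Per-node invasion time and rank from normalized toxic-mass curves.

    Invasion time is the first (interpolated) t with M_j(t)/M_sat,j >= theta;
    M_sat defaults to the single-region saturation mass recorded in the
    trajectory metadata.  Nodes never crossing get NaN time and are ranked
    last; ties broken by node order.
    """
    if m_sat is None:
        m_sat = traj.metadata.get("M2")
        if m_sat is None:
            raise ValueError("m_sat not given and no saturation mass in metadata")
    m_sat = np.broadcast_to(np.asarray(m_sat, dtype=float), (len(traj.labels),))
    M = traj.M
    times = np.full(len(traj.labels), math.nan)
    for j in range(len(traj.labels)):
        ratio = M[:, j] / m_sat[j]
        above = ratio >= theta
        if above.any():
            k = int(np.argmax(above))
            if k == 0:
                times[j] = traj.t[0]
            else:
                f = (theta - ratio[k - 1]) / (ratio[k] - ratio[k - 1])
                times[j] = traj.t[k - 1] + f * (traj.t[k] - traj.t[k - 1])
    order = np.lexsort((np.arange(len(times)), np.where(np.isnan(times), np.inf, times)))
    rank = np.empty(len(times), dtype=int)
    rank[order] = np.arange(1, len(times) + 1)
    return pd.DataFrame(
        {"node": traj.labels, "invasion_time": times, "rank": rank}
    )
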