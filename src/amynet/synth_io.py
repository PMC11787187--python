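"""Synthetic connectomes, graph file I/O, and reproducible study fixtures.

Real structural connectomes come from diffusion-MRI tractography and are
out of scope here; what the transport model needs from them is their
topology class: sparse, small-world, positive heavy-tailed edge weights,
with identifiable seed regions and low-degree peripheral nodes.
:func:`generate_connectome` draws such a graph deterministically from a
Watts-Strogatz backbone with log-normal weights, attaches a weakly
connected peripheral node (``frontal_pole``), and labels a handful of nodes
after the anatomical regions used as canonical seeding sites
(posterior cingulate, entorhinal cortex), so the usual seeding scenarios
map directly onto the synthetic graph.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np

from .invivo_local import ClearanceSpec
from .network import Connectome, build_laplacian
from .parameters import (
    KineticParameters,
    ab42_hepes_parameters,
    rescale_parameters,
)

__all__ = [
    "SyntheticGraphSpec",
    "generate_connectome",
    "read_edgelist",
    "write_edgelist",
    "read_graphml",
    "write_graphml",
    "Fixture",
    "make_fixture",
    "FIXTURE_NAMES",
]

#: Anatomical-style labels assigned to the first nodes of a synthetic graph
#: (the peripheral low-degree node is always "frontal_pole").
_REGION_NAMES = [
    "posterior_cingulate",
    "entorhinal",
    "precuneus",
    "hippocampus",
    "isthmus_cingulate",
    "inferior_parietal",
    "middle_temporal",
    "superior_frontal",
    "lateral_occipital",
    "fusiform",
]


@dataclass(frozen=True)
class SyntheticGraphSpec:
    """Parameters of the synthetic small-world weighted connectome.

    V counts the core small-world nodes; one extra peripheral node
    ("frontal_pole", single weak edge) is appended, so the graph has V + 1
    nodes in total.  Weights are log-normal(weight_mu, weight_sigma).
    """

    V: int = 40
    mean_degree: int = 6
    rewiring: float = 0.1
    weight_mu: float = 0.0
    weight_sigma: float = 0.75
    seed_node: str = "posterior_cingulate"
    peripheral_weight_factor: float = 1e-2  # edge weight of the peripheral node,
    # relative to the median core weight
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.V < 4:
            raise ValueError("need at least 4 nodes")
        if not 0.0 <= self.rewiring <= 1.0:
            raise ValueError("rewiring probability must be in [0, 1]")
        if self.mean_degree < 2 or self.mean_degree >= self.V:
            raise ValueError("mean degree must be in [2, V)")


def _labels(n: int) -> list[str]:
    base = _REGION_NAMES[: min(n, len(_REGION_NAMES))]
    base += [f"region_{i:02d}" for i in range(len(base), n)]
    return base


def generate_connectome(
    spec: SyntheticGraphSpec, max_attempts: int = 50
) -> Connectome:
    """Draw a connected, weighted small-world graph deterministically.

    A Watts-Strogatz ring (k = mean_degree, rewiring probability as given)
    is redrawn until connected (bounded attempts) and its edges get i.i.d.
    log-normal weights.  A peripheral "frontal_pole" node is then attached
    by a single weak edge (``peripheral_weight_factor`` times the median
    core weight) to the core node at maximal hop distance from the
    designated seed node — mirroring the anatomy, where the frontal pole is
    both sparsely connected and remote from the posterior seeding sites.
    """
    rng = np.random.default_rng(spec.rng_seed)
    G = None
    for _ in range(max_attempts):
        cand = nx.watts_strogatz_graph(
            spec.V, spec.mean_degree, spec.rewiring, seed=int(rng.integers(2**31))
        )
        if nx.is_connected(cand):
            G = cand
            break
    if G is None:
        raise RuntimeError(
            f"no connected draw in {max_attempts} attempts; "
            "increase mean_degree or lower rewiring"
        )
    labels = _labels(spec.V) + ["frontal_pole"]
    A = np.zeros((spec.V + 1, spec.V + 1))
    for u, v in G.edges:
        w = float(rng.lognormal(spec.weight_mu, spec.weight_sigma))
        A[u, v] = A[v, u] = w
    core = A[: spec.V, : spec.V]
    seed_idx = labels.index(spec.seed_node) if spec.seed_node in labels else 0
    dist = nx.single_source_shortest_path_length(G, seed_idx)
    anchor = max(dist, key=lambda n: (dist[n], -core[n].sum()))
    weak = float(np.median(core[core > 0]) * spec.peripheral_weight_factor)
    A[spec.V, anchor] = A[anchor, spec.V] = weak
    return build_laplacian(A, labels)


def write_edgelist(connectome: Connectome, path: str | Path) -> None:
    """CSV edge list with header source_label,target_label,weight
    (undirected, each pair once)."""
    path = Path(path)
    A = connectome.adjacency
    with path.open("w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["source_label", "target_label", "weight"])
        for i in range(connectome.V):
            for j in range(i + 1, connectome.V):
                if A[i, j] > 0:
                    w.writerow(
                        [connectome.labels[i], connectome.labels[j], repr(float(A[i, j]))]
                    )


def read_edgelist(path: str | Path) -> Connectome:
    """Read a CSV edge list (see :func:`write_edgelist`); lossless round trip.

    Duplicate edges, self edges and malformed rows are rejected with their
    line numbers.
    """
    path = Path(path)
    labels: list[str] = []
    index: dict[str, int] = {}
    edges: list[tuple[int, int, float]] = []
    seen: set[tuple[int, int]] = set()
    with path.open(newline="") as fh:
        reader = csv.reader(fh)
        header = next(reader, None)
        if header is None or [h.strip() for h in header[:3]] != [
            "source_label",
            "target_label",
            "weight",
        ]:
            raise ValueError(
                f"{path}:1: expected header 'source_label,target_label,weight', "
                f"got {header!r}"
            )
        for ln, row in enumerate(reader, start=2):
            if not row or (len(row) == 1 and not row[0].strip()):
                continue
            if len(row) != 3:
                raise ValueError(f"{path}:{ln}: expected 3 columns, got {len(row)}")
            src, dst, wtxt = (c.strip() for c in row)
            try:
                w = float(wtxt)
            except ValueError:
                raise ValueError(f"{path}:{ln}: bad weight {wtxt!r}") from None
            if w <= 0:
                raise ValueError(f"{path}:{ln}: weight must be positive, got {w}")
            if src == dst:
                raise ValueError(f"{path}:{ln}: self edge on {src!r}")
            for lab in (src, dst):
                if lab not in index:
                    index[lab] = len(labels)
                    labels.append(lab)
            key = tuple(sorted((index[src], index[dst])))
            if key in seen:
                raise ValueError(f"{path}:{ln}: duplicate edge {src!r}-{dst!r}")
            seen.add(key)
            edges.append((index[src], index[dst], w))
    A = np.zeros((len(labels), len(labels)))
    for i, j, w in edges:
        A[i, j] = A[j, i] = w
    return build_laplacian(A, labels)


def write_graphml(connectome: Connectome, path: str | Path) -> None:
    G = nx.Graph()
    G.add_nodes_from(connectome.labels)
    A = connectome.adjacency
    for i in range(connectome.V):
        for j in range(i + 1, connectome.V):
            if A[i, j] > 0:
                G.add_edge(
                    connectome.labels[i], connectome.labels[j], weight=float(A[i, j])
                )
    nx.write_graphml(G, str(path))


def read_graphml(path: str | Path) -> Connectome:
    G = nx.read_graphml(str(path))
    labels = list(G.nodes)
    A = np.zeros((len(labels), len(labels)))
    idx = {lab: k for k, lab in enumerate(labels)}
    for u, v, data in G.edges(data=True):
        A[idx[u], idx[v]] = A[idx[v], idx[u]] = float(data.get("weight", 1.0))
    return build_laplacian(A, labels)


@dataclass
class Fixture:
    """A named, fully specified study scenario (parameters + configuration)."""

    name: str
    description: str
    params: KineticParameters
    config: dict = field(default_factory=dict)
    connectome: Connectome | None = None


FIXTURE_NAMES = (
    "fig5_local",
    "fig8_damage",
    "fig9_network",
    "fig13_window",
    "fig16_dosing",
)


def make_fixture(name: str, rng_seed: int = 0) -> Fixture:
    """Build one of the bundled study scenarios on the reference kinetics.

    All fixtures use the Aβ42 HEPES parameter set in micromolar-hour units
    (concentration scale 1e6); scenarios needing a connectome use the
    synthetic small-world graph.
    """
    params = ab42_hepes_parameters(scaled=True)
    if name == "fig5_local":
        return Fixture(
            name=name,
            description=(
                "Seeded single-region dynamics at subcritical constant "
                "clearance: growth to a toxic peak, relaxation to M_2"
            ),
            params=params,
            config=dict(
                clearance=ClearanceSpec.constant(10.0),
                seed_dimer_frac=1e-4,
                include_kn=False,
                t_end=2.0,
            ),
        )
    if name == "fig8_damage":
        return Fixture(
            name=name,
            description=(
                "Damage-coupled clearance decay (moment level): initially "
                "supercritical clearance eroded toward a subcritical basal "
                "capacity by nucleation-fed toxic mass"
            ),
            params=rescale_parameters(
                ab42_hepes_parameters(scaled=False).with_convention("homogeneous"),
                1e6,
            ),
            config=dict(
                beta=1e11,
                mu=10.0,
                lam_init=2e4,
                include_kn=True,
                t_end=1e10,
            ),
        )
    if name == "fig9_network":
        spec = SyntheticGraphSpec(V=30, rng_seed=rng_seed)
        return Fixture(
            name=name,
            description=(
                "Brain-network invasion (moment level): uniform subcritical "
                "clearance 10, diffusion 0.01, mass seed m_0 in the "
                "posterior cingulate"
            ),
            params=params,
            config=dict(
                lam=10.0,
                rho0=0.01,
                seed=dict(node="posterior_cingulate", kind="mass"),
                t_end=0.1,
            ),
            connectome=generate_connectome(spec),
        )
    if name == "fig13_window":
        return Fixture(
            name=name,
            description=(
                "Size-window drug targeting: equilibrium toxic mass for "
                "clearance elevated by 1e5 on windows of width 10 over a "
                "background of 10"
            ),
            params=params,
            config=dict(
                lam_a=10.0,
                lam_drug=1e5,
                window_starts=[5, 15, 25, 35, 45],
                window_width=10,
            ),
        )
    if name == "fig16_dosing":
        return Fixture(
            name=name,
            description=(
                "Dosing-regime optimization under integrated clearance "
                "budgets C_max"
            ),
            params=params,
            config=dict(
                lam_a=10.0,
                A=1.0,
                t_max=28.0,
                C_max_values=[100.0, 200.0, 400.0, 800.0, 1600.0],
                n_B=10,
            ),
        )
    raise ValueError(f"unknown fixture {name!r}; available: {FIXTURE_NAMES}")
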