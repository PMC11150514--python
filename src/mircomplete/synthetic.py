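"""Synthetic fixtures with the statistical structure the method assumes.

A planted dataset draws nonnegative latent factors for miRNAs and
diseases; their product (scaled to [0, 1]) is the ground-truth association
propensity, the top fraction of its entries become the known binary
associations, and RBF kernels over the latent factors play the role of the
externally supplied similarity matrices.  A layered toy ontology DAG with
a shared root supports hand-checkable semantic-similarity values.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
from scipy.spatial.distance import pdist, squareform

from .io import AssociationMatrix, DiseaseDAG, LabeledMatrix, Role

__all__ = [
    "SyntheticSpec",
    "PlantedDataset",
    "WorkedExample",
    "generate_planted_dataset",
    "generate_toy_dag",
    "hold_out_ones",
    "worked_example_fixture",
]


@dataclass(frozen=True)
class SyntheticSpec:
    """Parameters of a planted low-rank association benchmark.

    Defaults give a 60 x 40 system of latent rank 3 where 30% of the pairs
    are recorded associations — dense enough that a hold-out fold still
    leaves informative interaction profiles, and small enough to re-solve
    many times in a CV loop.
    """

    nm: int = 60
    nd: int = 40
    latent_rank: int = 3
    density: float = 0.3
    noise_sd: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if self.latent_rank > min(self.nm, self.nd):
            raise ValueError("latent_rank must not exceed min(nm, nd)")
        if not 0.0 < self.density < 1.0:
            raise ValueError("density must lie in (0, 1)")
        if self.density * self.nm * self.nd < 1:
            raise ValueError("density too low: no association would be planted")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")


@dataclass
class PlantedDataset:
    """Planted benchmark: associations, similarities and the latent truth."""

    assoc: AssociationMatrix
    MM: LabeledMatrix
    DD: LabeledMatrix
    truth: np.ndarray  # nm x nd propensities in [0, 1]
    spec: SyntheticSpec


def _rbf_similarity(
    factors: np.ndarray, ids: list[str], role: Role, noise_sd: float, rng: np.random.Generator
) -> LabeledMatrix:
    d2 = squareform(pdist(factors, metric="sqeuclidean"))
    off = d2[d2 > 0]
    gamma = 1.0 / float(off.mean()) if off.size else 1.0
    values = np.exp(-gamma * d2)
    if noise_sd > 0:
        noise = rng.normal(0.0, noise_sd, size=values.shape)
        values = values + (noise + noise.T) / 2.0
    values = np.clip((values + values.T) / 2.0, 0.0, 1.0)
    np.fill_diagonal(values, 1.0)
    return LabeledMatrix(ids, ids, values, role).validate()


def generate_planted_dataset(spec: SyntheticSpec) -> PlantedDataset:
    """Draw a planted low-rank dataset, fully reproducible from the seed.

    The truth matrix is the product of nonnegative latent factors scaled by
    its maximum (so with ``noise_sd = 0`` its rank equals ``latent_rank``
    exactly); exactly ``floor(density * nm * nd)`` of the largest truth
    entries become known associations, with index-order tie-breaking.
    """
    rng = np.random.default_rng(spec.seed)
    mirna_ids = [f"m{i + 1:03d}" for i in range(spec.nm)]
    disease_ids = [f"d{j + 1:03d}" for j in range(spec.nd)]
    G = rng.uniform(0.0, 1.0, size=(spec.nm, spec.latent_rank))
    F = rng.uniform(0.0, 1.0, size=(spec.nd, spec.latent_rank))
    truth = G @ F.T
    truth /= truth.max()
    n_ones = int(spec.density * spec.nm * spec.nd)
    flat_order = np.argsort(-truth, axis=None, kind="stable")
    values = np.zeros(truth.size)
    values[flat_order[:n_ones]] = 1.0
    assoc = AssociationMatrix(mirna_ids, disease_ids, values.reshape(truth.shape))
    MM = _rbf_similarity(G, mirna_ids, Role.MM, spec.noise_sd, rng)
    DD = _rbf_similarity(F, disease_ids, Role.DD, spec.noise_sd, rng)
    return PlantedDataset(assoc=assoc, MM=MM, DD=DD, truth=truth, spec=spec)


def hold_out_ones(
    assoc: AssociationMatrix, fraction: float, rng: np.random.Generator
) -> tuple[AssociationMatrix, np.ndarray]:
    """Mask a fraction of the known 1-entries; return (train, held_out_idx)."""
    if not 0.0 <= fraction < 1.0:
        raise ValueError("fraction must lie in [0, 1)")
    ones = np.argwhere(assoc.values == 1.0)
    n_mask = int(round(fraction * len(ones)))
    pick = rng.choice(len(ones), size=n_mask, replace=False)
    held = ones[pick]
    train = assoc.copy()
    if n_mask:
        train.values[held[:, 0], held[:, 1]] = 0.0
    return train, held


# ---------------------------------------------------------------------------
# toy ontology DAGs


def generate_toy_dag(
    levels: int, branching: int, n_diseases: int, seed: int = 0, phi: float = 0.5
) -> DiseaseDAG:
    """Layered ontology tree with a shared root; diseases sit at the leaves.

    ``levels = 1`` degenerates to isolated single-term diseases.  Each
    disease is rooted at a distinct leaf term (chosen by seed when there
    are more leaves than diseases).
    """
    if levels < 1:
        raise ValueError("levels must be >= 1")
    rng = np.random.default_rng(seed)
    graph = nx.DiGraph()
    if levels == 1:
        roots = {f"d{i + 1}": f"d{i + 1}" for i in range(n_diseases)}
        graph.add_nodes_from(roots.values())
        return DiseaseDAG(graph, roots, phi)
    layers: list[list[str]] = [["root"]]
    graph.add_node("root")
    for lvl in range(1, levels):
        layer = []
        for parent in layers[lvl - 1]:
            for b in range(branching):
                node = f"t{lvl}_{len(layer)}"
                layer.append(node)
                graph.add_edge(node, parent)  # child -> parent
        layers.append(layer)
    leaves = layers[-1]
    if n_diseases > len(leaves):
        raise ValueError(f"{n_diseases} diseases but only {len(leaves)} leaf terms")
    chosen = rng.choice(len(leaves), size=n_diseases, replace=False)
    roots = {f"d{i + 1}": leaves[c] for i, c in enumerate(sorted(chosen))}
    return DiseaseDAG(graph, roots, phi)


# ---------------------------------------------------------------------------
# hand-worked example bundle


@dataclass
class WorkedExample:
    """Tiny fixed system with hand-derived expected values attached."""

    assoc: AssociationMatrix
    chain_dag: DiseaseDAG      # d -> p -> g
    diamond_dag: DiseaseDAG    # d -> {p1, p2} -> g
    shared_root_dag: DiseaseDAG  # d1 -> g <- d2
    prox_q: np.ndarray
    prox_w: np.ndarray
    prox_tau: float
    expected: dict = field(default_factory=dict)


def worked_example_fixture() -> WorkedExample:
    """The fixed 3 miRNA x 2 disease system used across module examples."""
    assoc = AssociationMatrix(
        ["m1", "m2", "m3"],
        ["d1", "d2"],
        np.array([[1.0, 0.0], [0.0, 1.0], [0.0, 0.0]]),
    )
    chain = nx.DiGraph([("d", "p"), ("p", "g")])
    chain_dag = DiseaseDAG(chain, {"d": "d"}, phi=0.5)
    diamond = nx.DiGraph([("d", "p1"), ("d", "p2"), ("p1", "g"), ("p2", "g")])
    diamond_dag = DiseaseDAG(diamond, {"d": "d"}, phi=0.5)
    shared = nx.DiGraph([("d1", "g"), ("d2", "g")])
    shared_root_dag = DiseaseDAG(shared, {"d1": "d1", "d2": "d2"}, phi=0.5)
    return WorkedExample(
        assoc=assoc,
        chain_dag=chain_dag,
        diamond_dag=diamond_dag,
        shared_root_dag=shared_root_dag,
        prox_q=np.diag([3.0, 1.0]),
        prox_w=np.array([0.0, 1.0]),
        prox_tau=0.5,
        expected={
            "n_associations": 2,
            "w1_chain": {"d": 1.0, "p": 0.5, "g": 0.25},
            "w1_diamond_g": 0.25,
            "ds1_shared_root": 1.0 / 3.0,
            "prox_result_diag": (3.0, 0.5),
        },
    )
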