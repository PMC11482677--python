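"""Bipartite plant-pollinator networks and their structural metrics.

The central object is :class:`BipartiteNetwork`, a labelled plant x animal
incidence matrix in the web-of-life CSV layout (rows = plants, columns =
pollinators).  Metrics provided here are the ones commonly used to relate
network architecture to dynamical behaviour: connectance, nestedness
(NODF and a weighted variant), bipartite modularity and shortest-path
betweenness centrality, plus the target-selection rules used by the
perturbation experiments.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd

__all__ = [
    "BipartiteNetwork",
    "read_web_of_life",
    "connectance",
    "nodf",
    "weighted_nodf",
    "modularity",
    "betweenness_centrality",
    "select_targets",
    "metrics_table",
]


class InvalidNetworkError(ValueError):
    """Raised when an incidence matrix violates the network invariants."""


@dataclass(eq=False)
class BipartiteNetwork:
    """A plant x pollinator incidence matrix with species labels.

    Parameters
    ----------
    plant_labels, animal_labels
        Row and column identifiers.
    incidence
        Non-negative S_P x S_A matrix; entries may be visit counts or 0/1.
    provenance
        Free-text source tag (file name, generator spec, ...).

    Species are indexed with plants first (0 .. S_P-1) and animals after
    (S_P .. S_P+S_A-1) everywhere in this package.
    """

    plant_labels: list
    animal_labels: list
    incidence: np.ndarray
    provenance: str = ""

    def __post_init__(self) -> None:
        self.incidence = np.asarray(self.incidence, dtype=float)
        if self.incidence.ndim != 2:
            raise InvalidNetworkError("incidence must be a 2-D matrix")
        sp, sa = self.incidence.shape
        if sp < 1 or sa < 1:
            raise InvalidNetworkError("network needs at least one species per guild")
        if len(self.plant_labels) != sp or len(self.animal_labels) != sa:
            raise InvalidNetworkError("label lengths do not match matrix shape")
        if np.any(self.incidence < 0) or not np.all(np.isfinite(self.incidence)):
            raise InvalidNetworkError("incidence entries must be finite and >= 0")
        b = self.binary
        if np.any(b.sum(axis=1) == 0) or np.any(b.sum(axis=0) == 0):
            raise InvalidNetworkError("every species must have degree >= 1")

    # -- basic descriptors -------------------------------------------------
    @property
    def n_plants(self) -> int:
        return self.incidence.shape[0]

    @property
    def n_animals(self) -> int:
        return self.incidence.shape[1]

    @property
    def n_species(self) -> int:
        return self.n_plants + self.n_animals

    @property
    def binary(self) -> np.ndarray:
        """0/1 view of the incidence matrix (any positive count -> 1)."""
        return (self.incidence > 0).astype(float)

    @property
    def n_links(self) -> int:
        return int(self.binary.sum())

    @property
    def degrees(self) -> np.ndarray:
        """Per-species degree, plants first then animals."""
        b = self.binary
        return np.concatenate([b.sum(axis=1), b.sum(axis=0)]).astype(int)

    @property
    def species_labels(self) -> list:
        return list(self.plant_labels) + list(self.animal_labels)

    def binarized(self) -> "BipartiteNetwork":
        return BipartiteNetwork(
            list(self.plant_labels),
            list(self.animal_labels),
            self.binary,
            provenance=self.provenance,
        )

    def to_graph(self) -> nx.Graph:
        """Undirected bipartite graph; node ids are species indices."""
        g = nx.Graph()
        sp = self.n_plants
        g.add_nodes_from(range(sp), bipartite=0)
        g.add_nodes_from(range(sp, self.n_species), bipartite=1)
        rows, cols = np.nonzero(self.binary)
        g.add_edges_from(zip(rows.tolist(), (cols + sp).tolist()))
        return g

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.incidence, index=self.plant_labels, columns=self.animal_labels
        )

    def write_csv(self, path) -> None:
        self.to_frame().to_csv(path)


def read_web_of_life(path, binarize: bool = False) -> BipartiteNetwork:
    """Read a web-of-life style CSV incidence matrix.

    Expects comma-separated values with the first row and first column
    holding species labels and a numeric body.  Rows are one guild
    (plants), columns the other (pollinators).  Species with no
    interactions are dropped with a warning; counts are mapped to 0/1
    when ``binarize`` is set.
    """
    df = pd.read_csv(path, index_col=0)
    body = df.apply(pd.to_numeric, errors="coerce")
    if body.isna().any().any():
        r, c = np.argwhere(body.isna().values)[0]
        raise ValueError(
            f"non-numeric cell at row '{df.index[r]}', column '{df.columns[c]}' in {path}"
        )
    mat = body.values.astype(float)
    row_deg = (mat > 0).sum(axis=1)
    col_deg = (mat > 0).sum(axis=0)
    if np.any(row_deg == 0) or np.any(col_deg == 0):
        dropped = [str(df.index[i]) for i in np.flatnonzero(row_deg == 0)]
        dropped += [str(df.columns[j]) for j in np.flatnonzero(col_deg == 0)]
        warnings.warn(
            f"dropping {len(dropped)} zero-degree species from {path}: {dropped}",
            stacklevel=2,
        )
        mat = mat[row_deg > 0][:, col_deg > 0]
        plants = [df.index[i] for i in np.flatnonzero(row_deg > 0)]
        animals = [df.columns[j] for j in np.flatnonzero(col_deg > 0)]
    else:
        plants, animals = list(df.index), list(df.columns)
    if mat.size == 0:
        raise InvalidNetworkError(f"empty network after pruning: {path}")
    if binarize:
        mat = (mat > 0).astype(float)
    return BipartiteNetwork(plants, animals, mat, provenance=str(path))


def connectance(net: BipartiteNetwork, denominator: str = "bipartite_product") -> float:
    """Realized fraction of possible links.

    ``bipartite_product`` (default) divides the link count L by S_P * S_A,
    the number of possible plant-animal links; ``all_species_squared``
    divides by (S_P + S_A)^2.
    """
    L = net.n_links
    if denominator == "bipartite_product":
        return L / (net.n_plants * net.n_animals)
    if denominator == "all_species_squared":
        return L / net.n_species**2
    raise ValueError(f"unknown connectance denominator: {denominator!r}")


def _nodf_axis_score(b: np.ndarray) -> tuple[float, int]:
    """Sum of paired-overlap scores over row pairs of ``b``, and pair count.

    A pair (i, j) contributes |row_i & row_j| / fill_j when fill_i >
    fill_j (the decreasing-fill condition) and 0 when the fills are equal.
    """
    fills = b.sum(axis=1)
    shared = b @ b.T
    fi = fills[:, None]
    fj = fills[None, :]
    denom = np.where(fj > 0, fj, 1.0)
    scores = np.where(fi > fj, shared / denom, 0.0)
    n = b.shape[0]
    return float(scores.sum()), n * (n - 1) // 2


def nodf(net: BipartiteNetwork) -> float:
    """Nestedness by overlap and decreasing fill, on a 0-1 scale.

    Averages paired overlap over all row pairs and all column pairs; a
    pair with equal marginal fills contributes 0.  Perfectly nested
    matrices score 1, matrices with all-equal marginals score 0.
    """
    b = net.binary
    if min(b.shape) < 2:
        warnings.warn("NODF undefined for 1xN matrix; returning 0", stacklevel=2)
        return 0.0
    s_rows, n_rows = _nodf_axis_score(b)
    s_cols, n_cols = _nodf_axis_score(b.T)
    return (s_rows + s_cols) / (n_rows + n_cols)


def _wnodf_axis_score(w: np.ndarray) -> tuple[float, int]:
    fills = (w > 0).sum(axis=1)
    # less[i, j] = number of columns where 0 < w[j] < w[i]
    less = ((w[None, :, :] > 0) & (w[None, :, :] < w[:, None, :])).sum(axis=2)
    fi = fills[:, None]
    fj = fills[None, :]
    denom = np.where(fj > 0, fj, 1)
    scores = np.where(fi > fj, less / denom, 0.0)
    n = w.shape[0]
    return float(scores.sum()), n * (n - 1) // 2


def weighted_nodf(net: BipartiteNetwork) -> float:
    """Weighted nestedness (WNODF-style), 0-1 scale.

    For a pair satisfying the decreasing-fill condition, counts the cells
    where the lower-fill vector has a positive weight strictly smaller
    than the corresponding cell of the higher-fill vector.  On an
    all-binary matrix every strict comparison fails, so the binary NODF is
    returned instead with a warning.
    """
    w = net.incidence
    if np.array_equal(w, net.binary):
        warnings.warn(
            "matrix is binary; weighted_nodf falls back to nodf", stacklevel=2
        )
        return nodf(net)
    if min(w.shape) < 2:
        warnings.warn("WNODF undefined for 1xN matrix; returning 0", stacklevel=2)
        return 0.0
    s_rows, n_rows = _wnodf_axis_score(w)
    s_cols, n_cols = _wnodf_axis_score(w.T)
    return (s_rows + s_cols) / (n_rows + n_cols)


def modularity(net: BipartiteNetwork, seed: int = 0) -> float:
    """Newman modularity of the best Louvain partition of the bipartite graph.

    Deterministic for a fixed ``seed``.
    """
    g = net.to_graph()
    communities = nx.community.louvain_communities(g, seed=seed)
    return nx.community.modularity(g, communities)


def betweenness_centrality(net: BipartiteNetwork) -> np.ndarray:
    """Normalized shortest-path betweenness per species (plants first)."""
    g = net.to_graph()
    bc = nx.betweenness_centrality(g, normalized=True)
    return np.array([bc[i] for i in range(net.n_species)])


def select_targets(
    net: BipartiteNetwork,
    strategy: str = "highest_degree",
    k: int = 3,
    seed: int | None = None,
) -> list[int]:
    """Choose species indices to perturb.

    ``highest_degree`` returns the single most-connected species (plant or
    pollinator; ties broken by lowest index, plants sorting before
    animals); ``lowest_degree`` its mirror, the species with the fewest
    interactions (the "specialist" control in perturbation experiments).
    ``top_centrality`` returns the ``k`` species with the highest
    betweenness.  ``random`` draws ``k`` species reproducibly from
    ``seed``.
    """
    if strategy == "highest_degree":
        return [int(np.argmax(net.degrees))]
    if strategy == "lowest_degree":
        return [int(np.argmin(net.degrees))]
    if k <= 0:
        raise ValueError("k must be positive")
    if k > net.n_species:
        raise ValueError("k exceeds the number of species")
    if strategy == "top_centrality":
        bc = betweenness_centrality(net)
        order = np.lexsort((np.arange(net.n_species), -bc))
        return [int(i) for i in order[:k]]
    if strategy == "random":
        rng = np.random.default_rng(seed)
        return [int(i) for i in rng.choice(net.n_species, size=k, replace=False)]
    raise ValueError(f"unknown target-selection strategy: {strategy!r}")


def metrics_table(
    nets,
    ids=None,
    connectance_mode: str = "bipartite_product",
    seed: int = 0,
) -> pd.DataFrame:
    """Tidy per-network metric table (one row per network)."""
    rows = []
    for pos, net in enumerate(nets):
        bc = betweenness_centrality(net)
        weighted = not np.array_equal(net.incidence, net.binary)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            wn = weighted_nodf(net) if weighted else np.nan
        rows.append(
            {
                "network_id": ids[pos] if ids is not None else net.provenance or pos,
                "S_P": net.n_plants,
                "S_A": net.n_animals,
                "L": net.n_links,
                "connectance": connectance(net, connectance_mode),
                "NODF": nodf(net),
                "wNODF": wn,
                "modularity": modularity(net, seed=seed),
                "mean_betweenness": float(bc.mean()),
                "median_betweenness": float(np.median(bc)),
            }
        )
    return pd.DataFrame(rows)
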