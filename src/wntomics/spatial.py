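"""Delaunay neighborhood graphs, cell-cell interaction profiles, and
interaction-pattern clustering of images.

Each image's cells become nodes of an undirected Delaunay graph; the
interaction score of an ordered phenotype pair (A, B) is the mean number
of type-B Delaunay neighbors per type-A cell — edge count between A and B
divided by the number of A cells, homotypic edges contributing once per
endpoint.  Per-image score vectors over the four phenotypes of interest
are z-scored and clustered with k-means (k = 4 by default); clusters are
renamed in ascending total-interaction order so cluster 0 is always the
"weak interaction" pattern.  Cluster membership is compared between
genotypes with a Fisher exact test on a designated cluster grouping.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial import Delaunay, QhullError
from sklearn.cluster import KMeans

from .io import CellTable
from .phenotyping import PHENOTYPES
from .stats import fisher_exact_2x2

__all__ = [
    "NeighborGraph",
    "ClusterConfig",
    "build_graph",
    "interaction_profile",
    "pair_scores",
    "pair_columns",
    "cluster_images",
    "cluster_enrichment",
]

log = logging.getLogger(__name__)


@dataclass
class ImageGraph:
    cell_ids: np.ndarray
    phenotypes: np.ndarray
    edges: np.ndarray        # (m, 2) int indices, i < j


@dataclass
class NeighborGraph:
    """Per-image Delaunay adjacency with phenotype labels on nodes."""

    images: dict[str, ImageGraph] = field(default_factory=dict)

    def edge_count(self, image_id: str) -> int:
        return len(self.images[image_id].edges)


@dataclass(frozen=True)
class ClusterConfig:
    k: int = 4
    n_init: int = 10
    seed: int = 0
    standardize: bool = True

    def __post_init__(self) -> None:
        if self.k < 1:
            raise ValueError("k must be >= 1")


def build_graph(table: CellTable, max_edge_um: float | None = None) -> NeighborGraph:
    """Delaunay triangulation per image; optional edge-length cutoff.

    Images with fewer than 3 cells, or with all cells collinear, yield an
    empty graph with a log line.  Duplicate coordinates are jittered by
    1e-6 µm with a warning so the triangulation is defined.
    """
    if "phenotype" not in table.cells.columns:
        raise ValueError("phenotype column required; run phenotype_cells first")
    graphs: dict[str, ImageGraph] = {}
    for image_id, sub in table.per_image():
        xy = sub[["x_um", "y_um"]].to_numpy(float)
        ids = sub["cell_id"].to_numpy()
        phen = sub["phenotype"].to_numpy()
        if len(sub) < 3:
            log.info("build_graph: image %s has <3 cells, empty graph", image_id)
            graphs[image_id] = ImageGraph(ids, phen, np.empty((0, 2), int))
            continue
        if pd.DataFrame(xy).duplicated().any():
            log.warning("build_graph: duplicate coordinates in image %s, "
                        "jittering by 1e-6 µm", image_id)
            rng = np.random.default_rng(0)
            xy = xy + rng.uniform(-1e-6, 1e-6, size=xy.shape)
        try:
            tri = Delaunay(xy)
        except QhullError:
            log.info("build_graph: image %s is degenerate (collinear), "
                     "empty graph", image_id)
            graphs[image_id] = ImageGraph(ids, phen, np.empty((0, 2), int))
            continue
        simp = tri.simplices
        pairs = np.vstack([simp[:, [0, 1]], simp[:, [1, 2]], simp[:, [0, 2]]])
        pairs = np.sort(pairs, axis=1)
        edges = np.unique(pairs, axis=0)
        if max_edge_um is not None:
            lengths = np.linalg.norm(xy[edges[:, 0]] - xy[edges[:, 1]], axis=1)
            edges = edges[lengths <= max_edge_um]
        graphs[image_id] = ImageGraph(ids, phen, edges)
    return NeighborGraph(images=graphs)


def pair_columns(phenotypes=None) -> list[str]:
    """Ordered-pair feature names ``"A->B"`` over the phenotypes of interest."""
    phenotypes = phenotypes or PHENOTYPES
    return [f"{a}->{b}" for a in phenotypes for b in phenotypes]


def interaction_profile(graph: NeighborGraph, phenotypes=None) -> pd.DataFrame:
    """Per-image interaction scores for all ordered phenotype pairs.

    score(A->B) = (# A-B edges) / (# A cells); a homotypic A-A edge counts
    once per endpoint, i.e. contributes 2 to the numerator.  Pairs with no
    A cell in the image are missing (NaN), not zero.  The reciprocity
    identity score(A->B) * n_A = score(B->A) * n_B holds exactly.
    """
    phenotypes = phenotypes or PHENOTYPES
    rows = {}
    for image_id, g in graph.images.items():
        scores = pair_scores(g.phenotypes, g.edges, phenotypes)
        rows[image_id] = {f"{a}->{b}": scores[i, j]
                          for i, a in enumerate(phenotypes)
                          for j, b in enumerate(phenotypes)}
    return pd.DataFrame.from_dict(rows, orient="index")[pair_columns(phenotypes)]


def pair_scores(labels: np.ndarray, edges: np.ndarray, phenotypes) -> np.ndarray:
    """Ordered-pair score matrix for one image (vectorized edge tally).

    ``scores[i, j]`` = edge count between phenotypes i and j divided by the
    number of phenotype-i cells (NaN when there is none); homotypic edges
    contribute once per endpoint.
    """
    k = len(phenotypes)
    code = {p: i for i, p in enumerate(phenotypes)}
    lab = np.array([code.get(p, -1) for p in labels])
    n_of = np.bincount(lab[lab >= 0], minlength=k).astype(float)
    counts = np.zeros((k, k))
    if len(edges):
        cu, cv = lab[edges[:, 0]], lab[edges[:, 1]]
        keep = (cu >= 0) & (cv >= 0)
        cu, cv = cu[keep], cv[keep]
        np.add.at(counts, (cu, cv), 1.0)
        np.add.at(counts, (cv, cu), 1.0)  # homotypic: once per endpoint => +2
    with np.errstate(invalid="ignore", divide="ignore"):
        scores = counts / n_of[:, None]
    scores[n_of == 0, :] = np.nan
    return scores


def cluster_images(profiles: pd.DataFrame, cfg: ClusterConfig = ClusterConfig()):
    """k-means over per-image interaction vectors, weak-first labeling.

    Missing scores are imputed as 0 (logged); features are z-scored across
    images unless ``standardize`` is off.  Clusters are renumbered by
    ascending mean total raw interaction, so label 0 is the weakest
    ("weak interaction") pattern and label k-1 the strongest.

    Returns ``(labels, centroids)``: a Series image -> cluster label and
    a DataFrame of centroids in the (possibly standardized) feature space,
    indexed by the renumbered labels.
    """
    if len(profiles) < cfg.k:
        raise ValueError(f"need >= k={cfg.k} images, got {len(profiles)}")
    X = profiles.to_numpy(float)
    n_missing = int(np.isnan(X).sum())
    if n_missing:
        log.info("cluster_images: imputed %d missing score(s) as 0", n_missing)
        X = np.nan_to_num(X, nan=0.0)
    raw_total = X.sum(axis=1)
    if cfg.standardize:
        mu, sd = X.mean(axis=0), X.std(axis=0)
        sd[sd == 0] = 1.0
        X = (X - mu) / sd
    km = KMeans(n_clusters=cfg.k, n_init=cfg.n_init, random_state=cfg.seed)
    raw_labels = km.fit_predict(X)
    magnitude = np.array([raw_total[raw_labels == c].mean() for c in range(cfg.k)])
    order = np.argsort(magnitude, kind="stable")     # weakest first
    remap = np.empty(cfg.k, int)
    remap[order] = np.arange(cfg.k)
    labels = pd.Series(remap[raw_labels], index=profiles.index, name="cluster")
    centroids = pd.DataFrame(km.cluster_centers_[order],
                             index=np.arange(cfg.k), columns=profiles.columns)
    return labels, centroids


def cluster_enrichment(labels: pd.Series, genotype: pd.Series,
                       clusters_of_interest) -> dict:
    """Genotype composition of interaction clusters, with a Fisher test.

    Builds the full cluster x genotype contingency table, collapses it to
    2x2 on membership in ``clusters_of_interest`` (e.g. the immune-enriched
    clusters) vs the rest, and tests WT vs MUT with the two-sided Fisher
    exact test.  Every image must carry a genotype.
    """
    missing = [i for i in labels.index if i not in genotype.index]
    if missing:
        raise ValueError(f"genotype missing for image {missing[0]!r}")
    genotype = genotype.loc[labels.index]
    table = pd.crosstab(labels, genotype)
    in_group = labels.isin(list(clusters_of_interest))
    a = int((in_group & (genotype == "WT")).sum())
    b = int((~in_group & (genotype == "WT")).sum())
    c = int((in_group & (genotype == "MUT")).sum())
    d = int((~in_group & (genotype == "MUT")).sum())
    p = fisher_exact_2x2((a, b, c, d))
    return {
        "contingency": table,
        "collapsed": {"WT": (a, b), "MUT": (c, d)},
        "fisher_p": p,
        "frac_in_group": {
            "WT": a / (a + b) if a + b else np.nan,
            "MUT": c / (c + d) if c + d else np.nan,
        },
    }
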