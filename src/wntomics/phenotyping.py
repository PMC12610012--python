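"""Multiplex-immunofluorescence phenotyping: intensity summarization, batch
normalization, decision-tree gating, tumor masks, compartments, densities.

Cells arrive as segmented records with per-cell pixel intensity samples for
the four-marker panel (CK, CD8, FOXP3, CD68).  Each cell's marker expression
is the 97.5% quantile of its pixel samples; per-image (batch) intensity
shifts are removed with a parametric empirical-Bayes location/scale
adjustment (the ComBat model with batch as the only covariate); phenotypes
are assigned by a first-match decision tree (CK+ -> tumor, else CD8+ ->
CD8 T cell, else CD68+ -> macrophage, else FOXP3+ -> Treg, else other).
Tumor masks are concave hulls over DBSCAN-clustered tumor cells (isolated
tumor cells are discarded as noise); cells inside a mask are intra-tumoral,
outside stromal; densities are cells per mm^2 by phenotype and compartment,
with total tissue area approximated by a concave hull over all cells.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import shapely
from shapely.geometry import MultiPoint, Point
from shapely.prepared import prep
from sklearn.cluster import DBSCAN

from .io import MARKERS, CellTable

__all__ = [
    "PhenotypeConfig",
    "MaskConfig",
    "TumorMask",
    "summarize_cell_intensity",
    "summarize_table",
    "combat_normalize",
    "phenotype_cells",
    "build_tumor_mask",
    "masks_to_geojson",
    "assign_compartments",
    "compute_densities",
]

log = logging.getLogger(__name__)

UM2_PER_MM2 = 1e6

#: phenotypes of interest, panel order; "other" is the fall-through label
PHENOTYPES = ["tumor", "CD8_T", "macrophage", "Treg"]

DEFAULT_PRIORITY = [("CK", "tumor"), ("CD8", "CD8_T"),
                    ("CD68", "macrophage"), ("FOXP3", "Treg")]


@dataclass
class PhenotypeConfig:
    """Gating thresholds and the ordered first-match decision tree."""

    thresholds: dict[str, float]
    priority: list[tuple[str, str]] = field(default_factory=lambda: list(DEFAULT_PRIORITY))
    quantile_q: float = 0.975

    def __post_init__(self) -> None:
        if not 0 < self.quantile_q < 1:
            raise ValueError("quantile_q must be in (0,1)")
        phen = [p for _, p in self.priority]
        if len(set(phen)) != len(phen):
            raise ValueError("priority must name each phenotype once")
        for marker, _ in self.priority:
            if marker not in self.thresholds or not np.isfinite(self.thresholds[marker]):
                raise ValueError(f"missing/non-finite threshold for {marker!r}")


@dataclass
class MaskConfig:
    """Tumor-mask construction parameters.

    ``dbscan_eps_um``/``dbscan_min_pts`` control the isolation filter
    (roughly 2-3 cell diameters and a handful of neighbors); ``concavity``
    controls the hull tightness — larger values approach the convex hull.
    """

    dbscan_eps_um: float = 30.0
    dbscan_min_pts: int = 5
    concavity: float = 2.0
    convex: bool = False  # fall back to convex hulls (recorded in metadata)

    def __post_init__(self) -> None:
        if self.dbscan_eps_um <= 0:
            raise ValueError("dbscan_eps_um must be > 0")
        if self.dbscan_min_pts < 1:
            raise ValueError("dbscan_min_pts must be >= 1")
        if self.concavity <= 0:
            raise ValueError("concavity must be > 0")

    @property
    def hull_ratio(self) -> float:
        """Concave-hull ratio in [0,1]; 1 = convex, 0 = tightest."""
        return 1.0 if self.convex else self.concavity / (self.concavity + 1.0)


@dataclass
class TumorMask:
    """Per-image mask polygons (µm coordinates) and their areas in mm²."""

    geometries: dict[str, shapely.Geometry]
    area_mm2: dict[str, float]
    convex: bool = False


def summarize_cell_intensity(pixel_samples, q: float = 0.975) -> float:
    """q-quantile of a cell's pixel samples, linear interpolation (type 7)."""
    samples = np.asarray(pixel_samples, float)
    if samples.size == 0:
        raise ValueError("no pixel samples")
    if not 0 < q < 1:
        raise ValueError("q must be in (0,1)")
    return float(np.quantile(samples, q))


def summarize_table(table: CellTable, q: float = 0.975) -> CellTable:
    """Fill the marker intensity columns from the pixel payload.

    Each marker column becomes the per-cell ``q``-quantile of that cell's
    pixel samples.  Tables without a pixel payload are returned unchanged
    (their intensity columns are taken as already summarized).
    """
    if table.pixels is None:
        return table
    cells = table.cells.copy()
    for marker in MARKERS:
        if marker in table.pixels:
            cells[marker] = np.quantile(table.pixels[marker], q, axis=1)
    return CellTable(cells=cells, pixels=table.pixels)


# ---------------------------------------------------------------------------
# ComBat batch normalization
# ---------------------------------------------------------------------------

def combat_normalize(intensities: pd.DataFrame, batch,
                     max_iter: int = 200, tol: float = 1e-6) -> pd.DataFrame:
    """Parametric empirical-Bayes batch adjustment of cell x marker intensities.

    Implements the ComBat location/scale model with batch as the only
    covariate: per marker, data are standardized against the
    batch-size-weighted grand mean and the pooled residual variance;
    per-batch location (gamma) and scale (delta^2) estimates are shrunk
    toward across-marker priors (normal for location, inverse-gamma for
    scale, both moment-matched) by the standard iterative conditional
    solution; the adjusted data are rescaled back.

    Parameters
    ----------
    intensities : pandas.DataFrame
        One row per cell, one column per marker.
    batch : sequence
        Per-cell batch (image) labels, length = n cells.
    max_iter, tol
        Convergence controls of the EB fixed-point iteration.

    Returns
    -------
    pandas.DataFrame
        Same shape/index/columns, batch-adjusted.

    Raises
    ------
    ValueError
        If any batch has fewer than 3 cells (named in the message).
    """
    X = intensities.to_numpy(float).T           # markers x cells
    batch = np.asarray(batch)
    if batch.shape[0] != X.shape[1]:
        raise ValueError("batch labels must align with rows of intensities")
    levels, codes = np.unique(batch, return_inverse=True)
    n_batches = levels.size
    sizes = np.bincount(codes)
    small = sizes < 3
    if small.any():
        raise ValueError(f"batch {levels[small][0]!r} has {sizes[small][0]} "
                         "cells; need >= 3 per batch")
    if n_batches == 1:
        log.info("combat_normalize: single batch, returning input unchanged")
        return intensities.copy()

    G, n = X.shape
    # per-marker batch means and the weighted grand mean
    batch_means = np.stack([X[:, codes == i].mean(axis=1)
                            for i in range(n_batches)], axis=1)   # G x I
    grand = batch_means @ (sizes / n)                             # G
    resid = X - batch_means[:, codes]
    var_pooled = (resid ** 2).mean(axis=1)                        # G
    sd = np.sqrt(np.maximum(var_pooled, 1e-24))

    Z = (X - grand[:, None]) / sd[:, None]

    gamma_hat = np.stack([Z[:, codes == i].mean(axis=1)
                          for i in range(n_batches)], axis=1)     # G x I
    delta_hat = np.stack([Z[:, codes == i].var(axis=1, ddof=1)
                          for i in range(n_batches)], axis=1)     # G x I

    # moment-matched hyperpriors across markers, per batch
    gamma_bar = gamma_hat.mean(axis=0)                            # I
    tau2 = gamma_hat.var(axis=0, ddof=1)                          # I
    d_mean = delta_hat.mean(axis=0)
    d_var = delta_hat.var(axis=0, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        lam = np.where(d_var > 0, (2 * d_var + d_mean ** 2) / d_var, np.inf)
        theta = np.where(d_var > 0, (d_mean * d_var + d_mean ** 3) / d_var,
                         d_mean)

    gamma_star = gamma_hat.copy()
    delta_star = np.maximum(delta_hat.copy(), 1e-12)
    for i in range(n_batches):
        Zi = Z[:, codes == i]
        ni = sizes[i]
        g, d2 = gamma_hat[:, i].copy(), delta_star[:, i].copy()
        if not np.isfinite(lam[i]) or tau2[i] == 0:
            # degenerate prior (identical estimates across markers): no shrinkage
            gamma_star[:, i] = gamma_hat[:, i]
            delta_star[:, i] = np.maximum(delta_hat[:, i], 1e-12)
            continue
        for _ in range(max_iter):
            g_new = (ni * tau2[i] * gamma_hat[:, i] + d2 * gamma_bar[i]) \
                / (ni * tau2[i] + d2)
            ss = ((Zi - g_new[:, None]) ** 2).sum(axis=1)
            d2_new = (theta[i] + 0.5 * ss) / (ni / 2.0 + lam[i] - 1.0)
            d2_new = np.maximum(d2_new, 1e-12)
            if (np.abs(g_new - g).max() < tol
                    and np.abs(d2_new - d2).max() < tol):
                g, d2 = g_new, d2_new
                break
            g, d2 = g_new, d2_new
        gamma_star[:, i], delta_star[:, i] = g, d2

    Z_adj = (Z - gamma_star[:, codes]) / np.sqrt(delta_star[:, codes])
    X_adj = Z_adj * sd[:, None] + grand[:, None]
    return pd.DataFrame(X_adj.T, index=intensities.index,
                        columns=intensities.columns)


# ---------------------------------------------------------------------------
# phenotyping
# ---------------------------------------------------------------------------

def phenotype_cells(table: CellTable, cfg: PhenotypeConfig) -> CellTable:
    """Assign exactly one phenotype per cell by the first-match rule."""
    cells = table.cells.copy()
    for marker, _ in cfg.priority:
        if marker not in cells.columns:
            raise ValueError(f"missing marker column {marker!r}")
    phenotype = pd.Series("other", index=cells.index, dtype=object)
    unassigned = pd.Series(True, index=cells.index)
    for marker, label in cfg.priority:
        positive = unassigned & (cells[marker] >= cfg.thresholds[marker])
        phenotype[positive] = label
        unassigned &= ~positive
    cells["phenotype"] = phenotype
    return CellTable(cells=cells, pixels=table.pixels)


# ---------------------------------------------------------------------------
# tumor masks, compartments, densities
# ---------------------------------------------------------------------------

def _hull(points: np.ndarray, ratio: float):
    """Concave hull of a point cloud; degenerate clouds yield empty polygons."""
    if len(points) < 3:
        return shapely.Polygon()
    geom = shapely.concave_hull(MultiPoint(points.tolist()), ratio=ratio,
                                allow_holes=False)
    if geom.geom_type not in ("Polygon", "MultiPolygon") or geom.area == 0:
        geom = MultiPoint(points.tolist()).convex_hull
        if geom.geom_type not in ("Polygon", "MultiPolygon"):
            return shapely.Polygon()  # collinear
    return geom


def build_tumor_mask(table: CellTable, cfg: MaskConfig = MaskConfig()) -> TumorMask:
    """DBSCAN-filtered concave-hull tumor masks, one geometry per image.

    Tumor cells are clustered with DBSCAN (Euclidean, ``dbscan_eps_um``,
    ``dbscan_min_pts``); noise cells — spatially isolated tumor cells —
    are discarded; each cluster contributes one concave-hull polygon and
    the mask is their union.  Images without any tumor cluster get an
    empty mask (area 0) with a log line.
    """
    if "phenotype" not in table.cells.columns:
        raise ValueError("phenotype column required; run phenotype_cells first")
    geoms: dict[str, shapely.Geometry] = {}
    areas: dict[str, float] = {}
    for image_id, sub in table.per_image():
        tumor = sub[sub["phenotype"] == "tumor"]
        if len(tumor) < cfg.dbscan_min_pts:
            log.info("build_tumor_mask: image %s has no tumor cluster", image_id)
            geoms[image_id] = shapely.Polygon()
            areas[image_id] = 0.0
            continue
        xy = tumor[["x_um", "y_um"]].to_numpy(float)
        labels = DBSCAN(eps=cfg.dbscan_eps_um, min_samples=cfg.dbscan_min_pts).fit_predict(xy)
        polys = []
        for lab in np.unique(labels):
            if lab == -1:
                continue
            polys.append(_hull(xy[labels == lab], cfg.hull_ratio))
        if not polys:
            log.info("build_tumor_mask: image %s has no tumor cluster", image_id)
            geoms[image_id] = shapely.Polygon()
            areas[image_id] = 0.0
            continue
        mask = shapely.union_all(polys)
        geoms[image_id] = mask
        areas[image_id] = mask.area / UM2_PER_MM2
    return TumorMask(geometries=geoms, area_mm2=areas, convex=cfg.convex)


def masks_to_geojson(mask: TumorMask, path) -> None:
    """Export mask polygons as a GeoJSON FeatureCollection (µm coordinates)."""
    import json

    from shapely.geometry import mapping

    features = []
    for image_id, geom in mask.geometries.items():
        features.append({
            "type": "Feature",
            "properties": {"image_id": image_id,
                           "area_mm2": mask.area_mm2[image_id],
                           "convex": mask.convex},
            "geometry": None if geom.is_empty else mapping(geom),
        })
    with open(path, "w", encoding="utf-8") as fh:
        json.dump({"type": "FeatureCollection", "features": features}, fh)
        fh.write("\n")


def assign_compartments(table: CellTable, mask: TumorMask) -> CellTable:
    """Label each cell tumor/stroma by boundary-inclusive point-in-mask."""
    cells = table.cells.copy()
    compartment = pd.Series("stroma", index=cells.index, dtype=object)
    for image_id, sub in table.per_image():
        geom = mask.geometries.get(image_id)
        if geom is None or geom.is_empty:
            continue
        prepared = prep(geom)
        inside = [prepared.covers(Point(x, y))
                  for x, y in sub[["x_um", "y_um"]].to_numpy(float)]
        compartment.loc[sub.index[inside]] = "tumor"
    cells["compartment"] = compartment
    return CellTable(cells=cells, pixels=table.pixels)


def compute_densities(table: CellTable, mask: TumorMask,
                      cfg: MaskConfig = MaskConfig()) -> pd.DataFrame:
    """Cells per mm² by (image, phenotype, compartment).

    Total tissue area is the concave hull over ALL cells of the image
    (same concavity as the mask); the tumor area is the mask clipped to
    the tissue hull; stromal area is their difference, floored at zero
    with a log line if negative.  Images with fewer than 3 cells have no
    defined area and are skipped with a log line.
    """
    if "compartment" not in table.cells.columns:
        raise ValueError("compartment column required; run assign_compartments first")
    rows = []
    for image_id, sub in table.per_image():
        if len(sub) < 3:
            log.info("compute_densities: image %s has <3 cells, skipped", image_id)
            continue
        tissue = _hull(sub[["x_um", "y_um"]].to_numpy(float), cfg.hull_ratio)
        total_area = tissue.area / UM2_PER_MM2
        if total_area == 0:
            log.info("compute_densities: image %s has degenerate geometry, skipped",
                     image_id)
            continue
        geom = mask.geometries.get(image_id, shapely.Polygon())
        tumor_area = geom.intersection(tissue).area / UM2_PER_MM2
        stroma_area = total_area - tumor_area
        if stroma_area < 0:
            log.info("compute_densities: image %s stromal area < 0, floored", image_id)
            stroma_area = 0.0
        areas = {"tumor": tumor_area, "stroma": stroma_area, "total": total_area}
        for phen in PHENOTYPES + ["other"]:
            of_phen = sub[sub["phenotype"] == phen]
            counts = {
                "tumor": int((of_phen["compartment"] == "tumor").sum()),
                "stroma": int((of_phen["compartment"] == "stroma").sum()),
            }
            counts["total"] = counts["tumor"] + counts["stroma"]
            for comp, area in areas.items():
                dens = counts[comp] / area if area > 0 else np.nan
                rows.append({"image_id": image_id, "phenotype": phen,
                             "compartment": comp, "count": counts[comp],
                             "area_mm2": area, "density_per_mm2": dens})
    return pd.DataFrame(rows)
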