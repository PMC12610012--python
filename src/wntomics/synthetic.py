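"""Synthetic data with planted ground truth for every pipeline stage.

The generator emulates the structure of a two-cohort CTNNB1-mutant
endometrial-carcinoma proteomic study without any external download:

* a discovery cohort of 18 tumors (12 WT / 6 MUT) with ~1,600 quantified
  proteins on the log2 scale;
* a validation cohort of 60 tumors (37 WT / 23 MUT) with a larger proteome
  and a matched transcriptome (~9,000 features, containing >= 90% of the
  discovery features), the planted differential features shifted
  concordantly in all three matrices;
* gene-set collections in which "enriched" sets draw >= 60% of their
  members from planted differential features of one direction;
* multi-image segmented-cell tables on 1.2 mm TMA-core discs with latent
  phenotypes, per-genotype planted densities (MUT images get lower CD8
  density), marker pixel-intensity samples recoverable by thresholding,
  additive per-image batch shifts, and four spatial interaction regimes
  (weak / tumor_immune / immune_immune / tumor_clustered).

Every output is deterministic given the configuration seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.stats import norm

from .io import MARKERS, CellTable, ExpressionMatrix, GeneSetCollection

__all__ = [
    "SimulationConfig",
    "SyntheticTruth",
    "gen_cohort_pair",
    "gen_gene_sets",
    "gen_cell_tables",
    "default_thresholds",
    "DISC_DIAMETER_UM",
    "DISC_AREA_MM2",
    "REGIMES",
]

#: TMA core geometry: a 1.2 mm diameter disc
DISC_DIAMETER_UM = 1200.0
DISC_RADIUS_UM = DISC_DIAMETER_UM / 2.0
DISC_AREA_MM2 = np.pi * (DISC_RADIUS_UM / 1000.0) ** 2   # ~1.131 mm^2

#: spatial interaction regimes an image can be generated under
REGIMES = ["weak", "tumor_immune", "immune_immune", "tumor_clustered"]

#: marker whose positivity defines each latent phenotype
PHENOTYPE_MARKER = {"tumor": "CK", "CD8_T": "CD8",
                    "macrophage": "CD68", "Treg": "FOXP3"}

# latent intensity model: marker-positive and -negative cell means, the
# cell-to-cell spread, and the lognormal pixel spread within a cell
MU_POS, MU_NEG = 3.0, 0.5
CELL_SD = 0.3
PIXEL_SIGMA = 0.25


@dataclass(frozen=True)
class SimulationConfig:
    """All knobs of the synthetic study, with study-structure defaults.

    Cohort sizes mirror the emulated study design (12/6 discovery,
    37/23 validation); effect size and noise are chosen so planted
    differential proteins are strong but not trivial at n = 18
    (|log2FC| = 1.5 against residual sd 0.5); cell tables default to 40
    TMA-core images of roughly 2,000 cells each with a WT-vs-MUT CD8
    density contrast on the scale reported for endometrial TILs
    (450 vs 280 cells/mm^2).
    """

    n_discovery_wt: int = 12
    n_discovery_mut: int = 6
    n_validation_wt: int = 37
    n_validation_mut: int = 23
    n_proteins: int = 1600
    n_validation_features: int = 9000
    validation_overlap: float = 0.95   # fraction of discovery ids present in validation
    frac_true_de: float = 0.10
    effect_size_log2: float = 1.5
    noise_sd: float = 0.5
    discordance_frac: float = 0.0      # planted features flipped in validation
    dropout_frac: float = 0.0          # MCAR missingness in validation proteome
    n_gene_sets: int = 100
    set_size_range: tuple[int, int] = (10, 60)
    frac_enriched_sets: float = 0.10
    n_images: int = 40
    cells_per_image_range: tuple[int, int] = (1000, 3500)
    batch_shift_sd: float = 0.5
    interaction_regime: str = "genotype_linked"
    n_pixels_per_cell: int = 40
    phenotype_densities: dict = field(default_factory=lambda: {
        "tumor": 700.0, "CD8_T_WT": 450.0, "CD8_T_MUT": 280.0,
        "macrophage": 150.0, "Treg": 70.0, "other": 400.0,
    })
    seed: int = 0

    def __post_init__(self) -> None:
        counts = dict(n_discovery_wt=self.n_discovery_wt,
                      n_discovery_mut=self.n_discovery_mut,
                      n_validation_wt=self.n_validation_wt,
                      n_validation_mut=self.n_validation_mut,
                      n_proteins=self.n_proteins,
                      n_validation_features=self.n_validation_features,
                      n_gene_sets=self.n_gene_sets, n_images=self.n_images)
        for name, v in counts.items():
            if v < 1:
                raise ValueError(f"{name} must be >= 1, got {v}")
        for name in ("frac_true_de", "frac_enriched_sets"):
            v = getattr(self, name)
            if not 0 <= v < 1:
                raise ValueError(f"{name} must be in [0,1), got {v}")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be > 0")
        if self.batch_shift_sd < 0:
            raise ValueError("batch_shift_sd must be >= 0")
        if self.set_size_range[0] < 3 or self.set_size_range[0] > self.set_size_range[1]:
            raise ValueError("set_size_range must be (min>=3, max>=min)")
        if self.n_validation_features < self.n_proteins:
            raise ValueError("n_validation_features must be >= n_proteins")
        if self.interaction_regime not in REGIMES + ["cycle", "genotype_linked"]:
            raise ValueError(f"unknown interaction_regime {self.interaction_regime!r}")
        if self.n_pixels_per_cell < 1:
            raise ValueError("n_pixels_per_cell must be >= 1")

    def with_(self, **kw) -> "SimulationConfig":
        return replace(self, **kw)


@dataclass
class SyntheticTruth:
    """Planted ground truth the tests and acceptance checks recover."""

    de_proteins: dict[str, int] = field(default_factory=dict)     # id -> +1/-1
    enriched_sets: dict[str, int] = field(default_factory=dict)   # name -> +1/-1
    image_regime: dict[str, str] = field(default_factory=dict)
    image_genotype: dict[str, str] = field(default_factory=dict)
    planted_densities: dict[tuple[str, str], float] = field(default_factory=dict)


# ---------------------------------------------------------------------------
# expression cohorts
# ---------------------------------------------------------------------------

def _sample_ids(prefix: str, n_wt: int, n_mut: int):
    ids = ([f"{prefix}_WT_{i+1:02d}" for i in range(n_wt)]
           + [f"{prefix}_MUT_{i+1:02d}" for i in range(n_mut)])
    groups = pd.Series(["WT"] * n_wt + ["MUT"] * n_mut, index=ids)
    return ids, groups


def _make_matrix(rng, feature_ids, groups, baseline, effects, noise_sd):
    """baseline + group shift (MUT only) + Gaussian noise, log2 scale."""
    n_f, n_s = len(feature_ids), len(groups)
    vals = baseline[:, None] + rng.normal(0.0, noise_sd, size=(n_f, n_s))
    mut_cols = (groups.values == "MUT")
    vals[:, mut_cols] += effects[:, None]
    return ExpressionMatrix(
        values=pd.DataFrame(vals, index=feature_ids, columns=groups.index),
        groups=groups.copy(),
    )


def gen_cohort_pair(config: SimulationConfig):
    """Discovery proteome, validation proteome, validation transcriptome.

    Planted differential features shift the MUT group mean by
    ``±effect_size_log2`` concordantly in all three matrices (a
    ``discordance_frac`` of them can be flipped in the validation
    datasets); every other feature is group-null.  Returns the three
    :class:`ExpressionMatrix` objects and the :class:`SyntheticTruth`.
    """
    rng = np.random.default_rng(config.seed)
    disc_ids = [f"P{i+1:05d}" for i in range(config.n_proteins)]

    n_overlap = int(round(config.validation_overlap * config.n_proteins))
    overlap = sorted(rng.choice(config.n_proteins, size=n_overlap, replace=False))
    overlap_ids = [disc_ids[i] for i in overlap]
    n_extra = config.n_validation_features - n_overlap
    extra_ids = [f"V{i+1:05d}" for i in range(n_extra)]
    val_ids = overlap_ids + extra_ids

    n_de = int(round(config.frac_true_de * config.n_proteins))
    de_idx = rng.choice(config.n_proteins, size=n_de, replace=False)
    directions = rng.choice([-1, 1], size=n_de)
    truth = SyntheticTruth(
        de_proteins={disc_ids[i]: int(d) for i, d in zip(de_idx, directions)})

    disc_effect = np.zeros(config.n_proteins)
    for i, d in zip(de_idx, directions):
        disc_effect[i] = d * config.effect_size_log2

    flip = {}
    if config.discordance_frac > 0 and n_de > 0:
        n_flip = int(round(config.discordance_frac * n_de))
        for i in rng.choice(n_de, size=n_flip, replace=False):
            flip[disc_ids[de_idx[i]]] = True

    val_effect = np.zeros(len(val_ids))
    for j, fid in enumerate(val_ids):
        d = truth.de_proteins.get(fid)
        if d is not None:
            val_effect[j] = (-d if flip.get(fid) else d) * config.effect_size_log2

    _, disc_groups = _sample_ids("D", config.n_discovery_wt, config.n_discovery_mut)
    _, val_groups = _sample_ids("V", config.n_validation_wt, config.n_validation_mut)

    disc_base = rng.normal(0.0, 2.0, size=config.n_proteins)
    val_base_prot = rng.normal(0.0, 2.0, size=len(val_ids))
    val_base_rna = rng.normal(0.0, 2.0, size=len(val_ids))

    discovery = _make_matrix(rng, disc_ids, disc_groups, disc_base,
                             disc_effect, config.noise_sd)
    val_prot = _make_matrix(rng, val_ids, val_groups, val_base_prot,
                            val_effect, config.noise_sd)
    val_rna = _make_matrix(rng, val_ids, val_groups, val_base_rna,
                           val_effect, config.noise_sd)

    if config.dropout_frac > 0:
        drop = rng.random(val_prot.values.shape) < config.dropout_frac
        val_prot.values.values[drop] = np.nan
    return discovery, val_prot, val_rna, truth


# ---------------------------------------------------------------------------
# gene sets
# ---------------------------------------------------------------------------

def gen_gene_sets(config: SimulationConfig, truth: SyntheticTruth) -> GeneSetCollection:
    """Gene sets over the discovery universe; enriched sets load one direction.

    Each enriched set draws >= 60% of its members from planted
    differential features of a single direction (the rest from non-DE
    features); null sets sample uniformly from the whole feature universe,
    so they overlap the planted features only by chance.  Set names and
    the truth object record which sets are enriched and their direction.
    When no differential features were planted, every set is null.
    """
    rng = np.random.default_rng(config.seed + 1)
    universe = [f"P{i+1:05d}" for i in range(config.n_proteins)]
    de_up = sorted(f for f, d in truth.de_proteins.items() if d > 0)
    de_down = sorted(f for f, d in truth.de_proteins.items() if d < 0)
    non_de = sorted(set(universe) - set(truth.de_proteins))

    lo, hi = config.set_size_range
    if hi > len(universe):
        raise ValueError("set size range exceeds feature universe")
    n_enriched = int(round(config.frac_enriched_sets * config.n_gene_sets))
    if n_enriched > 0 and not truth.de_proteins:
        import logging
        logging.getLogger(__name__).warning(
            "gen_gene_sets: no planted DE features; emitting null sets only")
        n_enriched = 0
    sets: dict[str, tuple[str, list[str]]] = {}
    for s in range(config.n_gene_sets):
        size = int(rng.integers(lo, hi + 1))
        if s < n_enriched:
            direction = 1 if s % 2 == 0 else -1
            pool = de_up if direction > 0 else de_down
            n_seed = int(np.ceil(0.6 * size))
            if n_seed > len(pool):
                # shrink the set so the >=60% seeded-fraction guarantee holds
                size = max(3, int(len(pool) / 0.6))
                n_seed = int(np.ceil(0.6 * size))
            if n_seed == 0 or n_seed > len(pool):
                raise ValueError("no planted DE features of the required "
                                 "direction to seed enriched sets")
            members = list(rng.choice(pool, size=n_seed, replace=False))
            n_fill = min(size - n_seed, len(non_de))
            members += list(rng.choice(non_de, size=n_fill, replace=False))
            tag = "up" if direction > 0 else "down"
            name = f"SET{s+1:04d}_{tag}"
            truth.enriched_sets[name] = direction
            desc = f"planted_enriched_{tag}"
        else:
            name = f"SET{s+1:04d}_null"
            members = list(rng.choice(universe, size=size, replace=False))
            desc = "null"
        sets[name] = (desc, members)
    return GeneSetCollection(sets)


# ---------------------------------------------------------------------------
# cell tables
# ---------------------------------------------------------------------------

def default_thresholds(q: float = 0.975) -> dict[str, float]:
    """Gating thresholds at the planted midpoint of the intensity model.

    A marker-positive cell's summarized intensity concentrates near
    ``MU_POS * exp(z_q * PIXEL_SIGMA)`` (the q-quantile of the lognormal
    pixel spread around the cell mean), a negative cell's near the same
    multiple of ``MU_NEG``; the threshold is the midpoint.
    """
    zq = norm.ppf(q)
    factor = float(np.exp(zq * PIXEL_SIGMA))
    mid = 0.5 * (MU_POS + MU_NEG) * factor
    return {m: mid for m in MARKERS}


def _uniform_in_disc(rng, n):
    r = DISC_RADIUS_UM * np.sqrt(rng.random(n))
    theta = rng.random(n) * 2 * np.pi
    return np.column_stack([DISC_RADIUS_UM + r * np.cos(theta),
                            DISC_RADIUS_UM + r * np.sin(theta)])


def _clustered_in_disc(rng, n, n_centers, spread_um, centers=None):
    """Gaussian aggregates around centers sampled away from the rim."""
    if n == 0:
        return np.empty((0, 2)), centers
    if centers is None:
        margin = min(3 * spread_um, 0.8 * DISC_RADIUS_UM)
        r = (DISC_RADIUS_UM - margin) * np.sqrt(rng.random(n_centers))
        theta = rng.random(n_centers) * 2 * np.pi
        centers = np.column_stack([DISC_RADIUS_UM + r * np.cos(theta),
                                   DISC_RADIUS_UM + r * np.sin(theta)])
    assign = rng.integers(0, len(centers), size=n)
    pts = centers[assign] + rng.normal(0, spread_um, size=(n, 2))
    return _clamp_to_disc(rng, pts), centers


def _near_points(rng, n, anchors, spread_um):
    if n == 0 or len(anchors) == 0:
        return _uniform_in_disc(rng, n)
    idx = rng.integers(0, len(anchors), size=n)
    pts = anchors[idx] + rng.normal(0, spread_um, size=(n, 2))
    return _clamp_to_disc(rng, pts)


def _clamp_to_disc(rng, pts):
    """Resample points that fell outside the core; clamp stragglers radially."""
    center = np.array([DISC_RADIUS_UM, DISC_RADIUS_UM])
    for _ in range(20):
        d = np.linalg.norm(pts - center, axis=1)
        out = d > DISC_RADIUS_UM
        if not out.any():
            return pts
        pts[out] = center + (pts[out] - center) * (
            (DISC_RADIUS_UM * rng.random(out.sum()) ** 0.5 / d[out])[:, None])
    return pts


def _place_cells(rng, counts: dict[str, int], regime: str):
    """Positions per phenotype under one interaction regime."""
    immune = ["CD8_T", "macrophage", "Treg"]
    pos: dict[str, np.ndarray] = {}
    if regime == "weak":
        for p, n in counts.items():
            pos[p] = _uniform_in_disc(rng, n)
    elif regime == "tumor_clustered":
        pos["tumor"], _ = _clustered_in_disc(rng, counts["tumor"], 5, 70.0)
        for p in immune + ["other"]:
            pos[p] = _uniform_in_disc(rng, counts[p])
    elif regime == "tumor_immune":
        pos["tumor"], _ = _clustered_in_disc(rng, counts["tumor"], 5, 70.0)
        for p in immune:
            pos[p] = _near_points(rng, counts[p], pos["tumor"], 25.0)
        pos["other"] = _uniform_in_disc(rng, counts["other"])
    elif regime == "immune_immune":
        centers = None
        for p in immune:
            pos[p], centers = _clustered_in_disc(rng, counts[p], 3, 50.0,
                                                 centers=centers)
        pos["tumor"] = _uniform_in_disc(rng, counts["tumor"])
        pos["other"] = _uniform_in_disc(rng, counts["other"])
    else:
        raise ValueError(f"unknown regime {regime!r}")
    return pos


def _assign_regimes(rng, config, genotypes):
    mode = config.interaction_regime
    if mode in REGIMES:
        return [mode] * config.n_images
    if mode == "cycle":
        return [REGIMES[i % len(REGIMES)] for i in range(config.n_images)]
    # genotype_linked: MUT cores are predominantly weakly interactive
    probs = {
        "MUT": [0.90, 0.10, 0.00, 0.00],
        "WT": [0.25, 0.30, 0.30, 0.15],
    }
    return [REGIMES[rng.choice(len(REGIMES), p=probs[g])] for g in genotypes]


def gen_cell_tables(config: SimulationConfig):
    """Segmented-cell tables for ``n_images`` TMA cores, with planted truth.

    Per image: the genotype alternates WT/MUT; phenotype counts are Poisson
    draws from the planted per-mm² densities on the 1.2 mm disc (MUT images
    use the lower CD8 density); positions follow the image's interaction
    regime; each cell gets ``n_pixels_per_cell`` lognormal pixel samples
    per marker around its latent mean (marker-positive for its phenotype's
    marker, background otherwise) plus an additive per-image, per-marker
    batch shift ~ Normal(0, batch_shift_sd).  The latent phenotype is
    stored in the ``true_phenotype`` column.
    """
    rng = np.random.default_rng(config.seed + 2)
    truth = SyntheticTruth()
    genotypes = ["WT" if i % 2 == 0 else "MUT" for i in range(config.n_images)]
    regimes = _assign_regimes(rng, config, genotypes)

    frames = []
    pixel_chunks: dict[str, list[np.ndarray]] = {m: [] for m in MARKERS}
    dens_cfg = config.phenotype_densities
    for i in range(config.n_images):
        image_id = f"img{i+1:03d}"
        genotype, regime = genotypes[i], regimes[i]
        truth.image_genotype[image_id] = genotype
        truth.image_regime[image_id] = regime

        densities = {
            "tumor": dens_cfg["tumor"],
            "CD8_T": dens_cfg[f"CD8_T_{genotype}"],
            "macrophage": dens_cfg["macrophage"],
            "Treg": dens_cfg["Treg"],
            "other": dens_cfg["other"],
        }
        for p, d in densities.items():
            truth.planted_densities[(image_id, p)] = d
        counts = {p: int(rng.poisson(d * DISC_AREA_MM2))
                  for p, d in densities.items()}
        positions = _place_cells(rng, counts, regime)

        phen_col, xs, ys = [], [], []
        for p in ["tumor", "CD8_T", "macrophage", "Treg", "other"]:
            phen_col += [p] * counts[p]
            xs.append(positions[p][:, 0])
            ys.append(positions[p][:, 1])
        n_cells = len(phen_col)
        xy = np.column_stack([np.concatenate(xs), np.concatenate(ys)])

        shift = {m: rng.normal(0.0, config.batch_shift_sd) if config.batch_shift_sd > 0
                 else 0.0 for m in MARKERS}
        for m in MARKERS:
            positive = np.array([PHENOTYPE_MARKER.get(p) == m for p in phen_col])
            cell_mean = np.where(positive, MU_POS, MU_NEG) \
                + rng.normal(0.0, CELL_SD, size=n_cells)
            cell_mean = np.maximum(cell_mean, 0.05)
            pix = cell_mean[:, None] * np.exp(
                rng.normal(0.0, PIXEL_SIGMA,
                           size=(n_cells, config.n_pixels_per_cell)))
            pixel_chunks[m].append(pix + shift[m])

        frames.append(pd.DataFrame({
            "cell_id": [f"c{j+1:05d}" for j in range(n_cells)],
            "image_id": image_id,
            "x_um": xy[:, 0], "y_um": xy[:, 1],
            "CK": np.nan, "CD8": np.nan, "FOXP3": np.nan, "CD68": np.nan,
            "true_phenotype": phen_col,
        }))

    cells = pd.concat(frames, ignore_index=True)
    pixels = {m: np.vstack(chunks) for m, chunks in pixel_chunks.items()}
    return CellTable(cells=cells, pixels=pixels), truth
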