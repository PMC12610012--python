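"""Quantile summarization, ComBat (incl. an sva cross-check), gating,
tumor masks, compartments and densities."""

import subprocess
import sys

import numpy as np
import pandas as pd
import pytest

from wntomics.io import MARKERS, CellTable
from wntomics.phenotyping import (MaskConfig, PhenotypeConfig,
                                  assign_compartments, build_tumor_mask,
                                  combat_normalize, compute_densities,
                                  phenotype_cells, summarize_cell_intensity,
                                  summarize_table)
from wntomics.synthetic import SimulationConfig, default_thresholds, gen_cell_tables


class TestQuantile:
    def test_constant_vector(self):
        assert summarize_cell_intensity([5, 5, 5]) == 5.0

    def test_linear_interpolation_order_statistic(self):
        # (n-1)*q = 99*0.975 = 96.525 -> between 97 and 98: 97.525
        assert summarize_cell_intensity(np.arange(1, 101), 0.975) == \
            pytest.approx(97.525)

    def test_median_convention(self):
        assert summarize_cell_intensity([1, 2, 3, 4], 0.5) == 2.5

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            summarize_cell_intensity([])

    def test_pixel_quantile_exceeds_mean(self, small_cells):
        """Lognormal pixel spread: the 97.5% quantile sits above the mean."""
        table, _ = small_cells
        pix = table.pixels["CK"][:200]
        q = np.quantile(pix, 0.975, axis=1)
        assert np.all(q > pix.mean(axis=1))


def frame(values):
    return pd.DataFrame(values, columns=MARKERS)


class TestCombat:
    def test_single_batch_identity(self, rng):
        df = frame(rng.normal(size=(20, 4)))
        out = combat_normalize(df, ["b1"] * 20)
        assert np.allclose(out.to_numpy(), df.to_numpy(), atol=1e-9)

    def test_small_batch_rejected_by_name(self, rng):
        df = frame(rng.normal(size=(5, 4)))
        with pytest.raises(ValueError, match="tiny"):
            combat_normalize(df, ["big", "big", "big", "tiny", "tiny"])

    def test_noiseless_shift_equalized(self):
        """Two batches differing by +2 on one marker, no within-batch noise."""
        base = np.tile([1.0, 2.0, 3.0, 4.0], (10, 1))
        shifted = base.copy()
        shifted[:, 0] += 2.0
        df = frame(np.vstack([base, shifted]))
        batch = ["b1"] * 10 + ["b2"] * 10
        out = combat_normalize(df, batch)
        means = out.groupby(np.array(batch)).mean()
        assert np.allclose(means.loc["b1"], means.loc["b2"], atol=1e-6)
        # grand means preserved
        assert np.allclose(out.mean(), df.mean(), atol=1e-6)

    def test_matches_sva_combat(self, rng, tmp_path):
        """Cross-check against the Bioconductor reference implementation."""
        n_per = [30, 40, 25]
        batch = np.repeat(["b1", "b2", "b3"], n_per)
        X = rng.normal(2, 1, size=(len(batch), 4))
        X[batch == "b2"] += [0.6, -0.4, 0.0, 0.2]
        X[batch == "b3"] *= [1.2, 1.0, 0.8, 1.1]
        df = frame(X)
        df.to_csv(tmp_path / "in.csv", index=False)
        pd.Series(batch).to_csv(tmp_path / "batch.csv", index=False, header=False)
        script = (
            'suppressMessages(library(sva));'
            f'x <- t(as.matrix(read.csv("{tmp_path}/in.csv")));'
            f'b <- scan("{tmp_path}/batch.csv", what="character", quiet=TRUE);'
            'res <- ComBat(dat=x, batch=b, par.prior=TRUE);'
            f'write.csv(t(res), "{tmp_path}/out.csv", row.names=FALSE)'
        )
        subprocess.run(["Rscript", "-e", script], check=True,
                       capture_output=True)
        ref = pd.read_csv(tmp_path / "out.csv").to_numpy()
        out = combat_normalize(df, batch).to_numpy()
        assert np.abs(out - ref).max() < 1e-5

    def test_reduces_batch_variance_without_hurting_gating(self):
        """Planted per-image shifts shrink; phenotype recovery is preserved."""
        cfg = SimulationConfig(n_images=8, batch_shift_sd=0.5,
                               interaction_regime="weak", seed=3,
                               phenotype_densities={
                                   "tumor": 300.0, "CD8_T_WT": 150.0,
                                   "CD8_T_MUT": 100.0, "macrophage": 80.0,
                                   "Treg": 40.0, "other": 150.0})
        table, _ = gen_cell_tables(cfg)
        summ = summarize_table(table)

        def between_image_var(cells):
            return (cells.groupby("image_id")[MARKERS].mean().var(axis=0)
                    .mean())

        before = between_image_var(summ.cells)
        norm = combat_normalize(summ.cells[MARKERS], summ.cells["image_id"])
        cells_after = summ.cells.copy()
        cells_after[MARKERS] = norm
        after = between_image_var(cells_after)
        assert after <= 0.5 * before

        pcfg = PhenotypeConfig(thresholds=default_thresholds())
        acc_before = (phenotype_cells(summ, pcfg).cells["phenotype"]
                      == summ.cells["true_phenotype"]).mean()
        acc_after = (phenotype_cells(CellTable(cells=cells_after), pcfg)
                     .cells["phenotype"] == summ.cells["true_phenotype"]).mean()
        assert acc_after >= acc_before - 0.01


class TestPhenotyping:
    CFG = PhenotypeConfig(thresholds={m: 1.0 for m in MARKERS})

    def make_table(self, rows):
        n = len(rows)
        cells = pd.DataFrame(rows, columns=MARKERS)
        cells.insert(0, "y_um", np.arange(n, dtype=float))
        cells.insert(0, "x_um", np.arange(n, dtype=float))
        cells.insert(0, "image_id", "i1")
        cells.insert(0, "cell_id", [f"c{i}" for i in range(n)])
        return CellTable(cells=cells)

    def test_priority_ck_wins(self):
        table = self.make_table([[2.0, 2.0, 0.0, 0.0]])  # CK+ and CD8+
        out = phenotype_cells(table, self.CFG)
        assert out.cells["phenotype"].iloc[0] == "tumor"

    def test_all_below_is_other(self):
        out = phenotype_cells(self.make_table([[0.1, 0.2, 0.3, 0.4]]), self.CFG)
        assert out.cells["phenotype"].iloc[0] == "other"

    def test_partition_single_label(self):
        out = phenotype_cells(self.make_table([[2, 0, 2, 0], [0, 2, 0, 2],
                                               [0, 0, 0, 2], [0, 0, 2, 0]]),
                              self.CFG)
        assert list(out.cells["phenotype"]) == ["tumor", "CD8_T",
                                                "macrophage", "Treg"]

    def test_missing_marker_rejected(self):
        from wntomics.io import FormatError
        cells = self.make_table([[1, 1, 1, 1]]).cells.drop(columns=["CD68"])
        with pytest.raises(FormatError, match="CD68"):
            CellTable(cells=cells)

    def test_shift_free_recovery(self, small_cells):
        """Thresholds at planted midpoints recover the latent phenotype."""
        table, _ = small_cells
        summ = summarize_table(table)
        out = phenotype_cells(summ, PhenotypeConfig(thresholds=default_thresholds()))
        acc = (out.cells["phenotype"] == out.cells["true_phenotype"]).mean()
        assert acc >= 0.95


def grid_table(nx=10, ny=10, spacing=20.0, phenotype="tumor", extra=None):
    xs, ys = np.meshgrid(np.arange(nx) * spacing, np.arange(ny) * spacing)
    pts = np.column_stack([xs.ravel(), ys.ravel()])
    if extra is not None:
        pts = np.vstack([pts, extra])
    n = len(pts)
    cells = pd.DataFrame({
        "cell_id": [f"c{i}" for i in range(n)], "image_id": "i1",
        "x_um": pts[:, 0], "y_um": pts[:, 1],
        "CK": 0.0, "CD8": 0.0, "FOXP3": 0.0, "CD68": 0.0,
        "phenotype": phenotype,
    })
    return CellTable(cells=cells)


class TestMasksAndDensities:
    def test_no_tumor_cells_empty_mask(self):
        table = grid_table(phenotype="CD8_T")
        mask = build_tumor_mask(table)
        assert mask.area_mm2["i1"] == 0.0
        comp = assign_compartments(table, mask)
        assert (comp.cells["compartment"] == "stroma").all()

    def test_grid_single_cluster_area(self):
        """10x10 grid at 20 µm spacing: one cluster, ~180x180 µm hull."""
        table = grid_table()
        mask = build_tumor_mask(table, MaskConfig(dbscan_eps_um=30,
                                                  dbscan_min_pts=5))
        expected = (180.0 * 180.0) / 1e6
        assert mask.area_mm2["i1"] == pytest.approx(expected, rel=0.15)

    def test_isolated_cell_is_noise(self):
        far = np.array([[500.0 + 180.0, 500.0 + 180.0]])
        with_outlier = grid_table(extra=far)
        base = build_tumor_mask(grid_table())
        mask = build_tumor_mask(with_outlier)
        assert mask.area_mm2["i1"] == pytest.approx(base.area_mm2["i1"])

    def test_geojson_export(self, tmp_path):
        import json
        from wntomics.phenotyping import masks_to_geojson
        mask = build_tumor_mask(grid_table())
        masks_to_geojson(mask, tmp_path / "m.geojson")
        geo = json.loads((tmp_path / "m.geojson").read_text())
        assert geo["type"] == "FeatureCollection"
        feat = geo["features"][0]
        assert feat["properties"]["image_id"] == "i1"
        assert feat["geometry"]["type"] in ("Polygon", "MultiPolygon")

    def test_boundary_cell_is_tumor(self):
        table = grid_table()
        mask = build_tumor_mask(table)
        comp = assign_compartments(table, mask)
        # a grid corner lies exactly on the hull boundary
        corner = comp.cells[(comp.cells["x_um"] == 0) & (comp.cells["y_um"] == 0)]
        assert corner["compartment"].iloc[0] == "tumor"

    def test_density_on_unit_square(self):
        """100 cells whose hull is exactly 1 mm² give density 100/mm²."""
        table = grid_table(nx=10, ny=10, spacing=1000.0 / 9, phenotype="CD8_T")
        mask = build_tumor_mask(table)         # no tumor cells: empty
        comp = assign_compartments(table, mask)
        dens = compute_densities(comp, mask)
        total = dens[(dens["phenotype"] == "CD8_T")
                     & (dens["compartment"] == "total")]
        assert total["area_mm2"].iloc[0] == pytest.approx(1.0, rel=1e-6)
        assert total["density_per_mm2"].iloc[0] == pytest.approx(100.0, rel=1e-6)

    def test_density_conservation(self, small_cells):
        table, _ = small_cells
        summ = summarize_table(table)
        out = phenotype_cells(summ, PhenotypeConfig(thresholds=default_thresholds()))
        mask = build_tumor_mask(out)
        out = assign_compartments(out, mask)
        dens = compute_densities(out, mask)
        for image_id, sub in dens.groupby("image_id"):
            total = sub[sub["compartment"] == "total"]
            n_cells = (out.cells["image_id"] == image_id).sum()
            assert total["count"].sum() == n_cells
            area = total["area_mm2"].iloc[0]
            assert total["density_per_mm2"].sum() == pytest.approx(n_cells / area)
            # mask area never exceeds tissue area
            tumor_rows = sub[sub["compartment"] == "tumor"]
            assert tumor_rows["area_mm2"].iloc[0] <= area + 1e-9

    def test_tumor_core_compartment_recovery(self):
        """Clustered latent tumor cells end up inside the tumor mask."""
        cfg = SimulationConfig(n_images=4, batch_shift_sd=0.0,
                               interaction_regime="tumor_immune", seed=5,
                               phenotype_densities={
                                   "tumor": 800.0, "CD8_T_WT": 150.0,
                                   "CD8_T_MUT": 100.0, "macrophage": 60.0,
                                   "Treg": 30.0, "other": 150.0})
        table, _ = gen_cell_tables(cfg)
        summ = summarize_table(table)
        out = phenotype_cells(summ, PhenotypeConfig(thresholds=default_thresholds()))
        mask = build_tumor_mask(out)
        out = assign_compartments(out, mask)
        tumor_cells = out.cells[out.cells["true_phenotype"] == "tumor"]
        frac = (tumor_cells["compartment"] == "tumor").mean()
        assert frac >= 0.90
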