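import numpy as np
import pandas as pd
import pytest

from adiposcreen import imaging
from adiposcreen import synthetic_plate as sp


def blank_field(level=100, shape=(128, 128)):
    return np.full(shape, level, dtype=np.uint16)


class TestSegmentNuclei:
    def test_blank_field_empty_table(self):
        nuclei = imaging.segment_nuclei(blank_field())
        assert len(nuclei) == 0

    def test_empty_image_is_error(self):
        with pytest.raises(ValueError):
            imaging.segment_nuclei(np.empty((0, 0)))

    def test_fifteen_disjoint_nuclei_recovered_exactly(self, field_factory):
        truth, im = field_factory(seed=21, n_cells=15, frac=0.0,
                                  config=sp.ImagingConfig(field_shape=(512, 512)))
        nuclei = imaging.segment_nuclei(im.nuclei_channel)
        assert len(nuclei) == 15
        got = nuclei[["centroid_row", "centroid_col"]].to_numpy()
        for cell in truth.cells:
            dists = np.hypot(got[:, 0] - cell.nucleus_centroid[0],
                             got[:, 1] - cell.nucleus_centroid[1])
            assert dists.min() < 1.0

    def test_touching_nuclei_declumped(self):
        # centers 1.5 radii apart -> merged blob must split into two
        cfg = sp.ImagingConfig(field_shape=(128, 128))
        truth = sp.FieldTruth("A1", 0, [
            sp.CellTruth(1, (64.0, 60.0), 6.0, False),
            sp.CellTruth(2, (64.0, 69.0), 6.0, False),
        ])
        im = sp.render_field(truth, cfg)
        assert len(imaging.segment_nuclei(im.nuclei_channel)) == 2

    def test_size_filter_excludes_out_of_range(self, field_factory):
        _, im = field_factory(seed=22, n_cells=5, frac=0.0)
        params = imaging.SegmentationParams(min_area=5000)
        assert len(imaging.segment_nuclei(im.nuclei_channel, params)) == 0


class TestDelineateCells:
    def test_one_nucleus_one_region_containing_it(self):
        nuclei = pd.DataFrame(
            [{"nucleus_id": 1, "centroid_row": 50.0, "centroid_col": 50.0, "area": 100}]
        )
        labels = imaging.delineate_cells(nuclei, blank_field())
        assert labels[50, 50] == 1
        assert set(np.unique(labels)) == {0, 1}

    def test_regions_pairwise_disjoint_one_per_nucleus(self, field_factory):
        _, im = field_factory(seed=23, n_cells=8, frac=0.0)
        nuclei = imaging.segment_nuclei(im.nuclei_channel)
        labels = imaging.delineate_cells(nuclei, im.lipid_channel)
        present = set(np.unique(labels)) - {0}
        assert present == set(nuclei["nucleus_id"])
        # each nucleus centroid sits in its own region
        for _, row in nuclei.iterrows():
            r, c = int(round(row.centroid_row)), int(round(row.centroid_col))
            assert labels[r, c] == row.nucleus_id

    def test_expansion_radius_bounds_regions(self):
        nuclei = pd.DataFrame(
            [{"nucleus_id": 1, "centroid_row": 64.0, "centroid_col": 64.0, "area": 100}]
        )
        labels = imaging.delineate_cells(nuclei, blank_field(), max_expansion_radius=10.0)
        assert labels[64, 64] == 1
        assert labels[64, 80] == 0


class TestDetectDroplets:
    def test_blank_channel_no_droplets(self):
        assert len(imaging.detect_droplets(blank_field())) == 0

    def test_forty_disjoint_droplets_counted_with_area_tolerance(self, effect_model, placement):
        cfg = sp.ImagingConfig(field_shape=(512, 512))
        rng = np.random.default_rng(31)
        truth = sp.simulate_field_truth(rng, "A1", 0, 1.0, 14, effect_model, cfg, placement)
        assert truth.n_droplets >= 40
        im = sp.render_field(truth, cfg)
        droplets = imaging.detect_droplets(im.lipid_channel)
        assert len(droplets) == truth.n_droplets
        true_area = sum(np.pi * d.radius**2 for d in truth.all_droplets())
        assert droplets["area"].sum() == pytest.approx(true_area, rel=0.10)

    def test_min_area_filter(self, field_factory):
        _, im = field_factory(seed=33, n_cells=6, frac=1.0)
        few = imaging.detect_droplets(
            im.lipid_channel, imaging.DropletParams(min_droplet_area=10_000)
        )
        assert len(few) == 0


class TestAssignDroplets:
    @staticmethod
    def _droplet_row(droplet_id, row, col):
        return {
            "droplet_id": droplet_id, "centroid_row": float(row),
            "centroid_col": float(col), "area": 9,
            "integrated_intensity": 90.0, "cell_id": pd.NA,
        }

    def _table(self, rows, label_map=None, kept=None):
        frame = pd.DataFrame(rows, columns=imaging.DROPLET_COLUMNS).astype({"cell_id": "Int64"})
        if label_map is not None:
            frame.attrs["label_map"] = label_map
            frame.attrs["kept_labels"] = kept or {}
        return frame

    def test_droplet_inside_cell_assigned_to_it(self):
        cells = np.zeros((64, 64), dtype=np.int32)
        cells[10:30, 10:30] = 1
        lab = np.zeros_like(cells)
        lab[18:22, 18:22] = 1
        droplets = self._table([self._droplet_row(1, 20, 20)], lab, {1: 1})
        out = imaging.assign_droplets(droplets, cells)
        assert out.loc[0, "cell_id"] == 1

    def test_max_overlap_wins(self):
        cells = np.zeros((64, 64), dtype=np.int32)
        cells[:, :20] = 1  # A
        cells[:, 20:] = 2  # B
        lab = np.zeros_like(cells)
        lab[10:20, 14:24] = 1  # 60% in A, 40% in B
        droplets = self._table([self._droplet_row(1, 15, 18)], lab, {1: 1})
        out = imaging.assign_droplets(droplets, cells)
        assert out.loc[0, "cell_id"] == 1

    def test_equidistant_tie_breaks_to_lower_id(self):
        cells = np.zeros((64, 64), dtype=np.int32)
        cells[30:34, 10:14] = 2
        cells[30:34, 50:54] = 1
        # droplet centroid exactly midway between the two blocks
        droplets = self._table([self._droplet_row(1, 31.5, 31.5)])
        out = imaging.assign_droplets(droplets, cells, max_assign_distance=30.0)
        assert out.loc[0, "cell_id"] == 1

    def test_far_droplet_unassigned_but_counted(self):
        cells = np.zeros((64, 64), dtype=np.int32)
        cells[0:4, 0:4] = 1
        droplets = self._table([self._droplet_row(1, 60, 60)])
        out = imaging.assign_droplets(droplets, cells, max_assign_distance=5.0)
        assert out.loc[0, "cell_id"] is pd.NA
        tables = imaging.ObjectTables(("A1", 0), pd.DataFrame(columns=imaging.NUCLEI_COLUMNS), cells, out)
        e = imaging.compute_image_endpoints(tables)
        assert e.droplet_count == 1 and e.total_area == 9


class TestImageEndpoints:
    def test_empty_tables_all_zero(self):
        tables = imaging.ObjectTables(
            ("A1", 0),
            pd.DataFrame(columns=imaging.NUCLEI_COLUMNS),
            np.zeros((8, 8), dtype=np.int32),
            pd.DataFrame(columns=imaging.DROPLET_COLUMNS),
        )
        e = imaging.compute_image_endpoints(tables)
        assert (e.nuclei_count, e.droplet_count, e.total_area, e.total_intensity) == (0, 0, 0.0, 0.0)

    def test_total_area_is_sum(self):
        droplets = pd.DataFrame(
            [
                {"droplet_id": i, "centroid_row": 0.0, "centroid_col": 0.0,
                 "area": a, "integrated_intensity": 10.0 * a, "cell_id": pd.NA}
                for i, a in enumerate([100, 200, 300], 1)
            ]
        )
        tables = imaging.ObjectTables(
            ("A1", 0), pd.DataFrame(columns=imaging.NUCLEI_COLUMNS),
            np.zeros((8, 8), dtype=np.int32), droplets,
        )
        e = imaging.compute_image_endpoints(tables)
        assert e.total_area == 600
        assert e.total_intensity == 6000.0

    def test_endpoints_survive_csv_roundtrip(self, tmp_path, field_factory):
        truth, im = field_factory(seed=41, n_cells=8, frac=0.8)
        tables = imaging.segment_field(im.nuclei_channel, im.lipid_channel, truth.field_id)
        before = imaging.compute_image_endpoints(tables)
        path = tmp_path / "droplets.csv"
        tables.droplets.to_csv(path, index=False)
        reread = pd.read_csv(path).astype({"cell_id": "Int64"})
        tables2 = imaging.ObjectTables(truth.field_id, tables.nuclei, tables.cells, reread)
        after = imaging.compute_image_endpoints(tables2)
        assert before == after

    def test_adding_droplet_monotone(self, effect_model, placement):
        cfg = sp.ImagingConfig(field_shape=(256, 256))
        truth = sp.simulate_field_truth(
            np.random.default_rng(51), "A1", 0, 1.0, 4, effect_model, cfg, placement
        )
        im = sp.render_field(truth, cfg)
        base = imaging.compute_image_endpoints(
            imaging.segment_field(im.nuclei_channel, im.lipid_channel, truth.field_id)
        )
        # plant one extra droplet in empty space
        extra = sp.Droplet((200.0, 40.0), 6.0, 2000.0)
        cell0 = truth.cells[0]
        truth.cells[0] = sp.CellTruth(
            cell0.cell_id, cell0.nucleus_centroid, cell0.nucleus_radius, True,
            cell0.droplets + (extra,),
        )
        im2 = sp.render_field(truth, cfg)
        more = imaging.compute_image_endpoints(
            imaging.segment_field(im2.nuclei_channel, im2.lipid_channel, truth.field_id)
        )
        assert more.droplet_count >= base.droplet_count
        assert more.total_area >= base.total_area
        assert more.total_intensity >= base.total_intensity


class TestSegmentField:
    def test_mismatched_shapes_rejected(self):
        with pytest.raises(ValueError):
            imaging.segment_field(blank_field(), blank_field(shape=(64, 64)), ("A1", 0))

    def test_conservation_totals_equal_table_sums(self, field_factory):
        truth, im = field_factory(seed=61, n_cells=10, frac=0.7)
        tables = imaging.segment_field(im.nuclei_channel, im.lipid_channel, truth.field_id)
        e = imaging.compute_image_endpoints(tables)
        assert e.total_area == tables.droplets["area"].sum()
        assert e.total_intensity == tables.droplets["integrated_intensity"].sum()
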