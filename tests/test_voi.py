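import numpy as np
import pytest

from planarquant.grid import Mask3D, ROI2D, VoxelGrid
from planarquant.phantom import Organ, PhantomSpec, build_phantom
from planarquant.voi import (
    DegenerateGeometryError,
    EmptyMaskError,
    backproject_roi_to_column,
    body_mask,
    build_background_rois,
    measure_geometry,
    project_mask_to_roi,
    roi_centroid,
    segment_kidney,
    true_background_voi,
)

ISO = (1.0, 1.0, 1.0)


def grid(data, spacing=ISO):
    return VoxelGrid(np.asarray(data, float), spacing)


def slab_masks(nx=20, ny=30, nz=10, body_y=(5, 25), kid=None):
    body = np.zeros((nx, ny, nz), bool)
    body[:, body_y[0] : body_y[1], :] = True
    masks = {"body": Mask3D(body, ISO, "body")}
    if kid is not None:
        k = np.zeros((nx, ny, nz), bool)
        k[kid] = True
        masks["kidney"] = Mask3D(k, ISO, "kidney")
    return masks


class TestBodyMask:
    def test_clean_separation(self):
        data = np.zeros((16, 16, 8))
        data[4:12, 4:12, 2:6] = 10.0
        m = body_mask(grid(data), threshold=5.0)
        assert np.array_equal(m.voxels, data >= 5)

    def test_all_below_threshold_rejected(self):
        with pytest.raises(EmptyMaskError):
            body_mask(grid(np.full((8, 8, 8), 2.0)), threshold=5.0)

    def test_largest_component_kept(self):
        # three 6-connected blobs of known sizes: 27, 8, 1 voxels
        data = np.zeros((20, 20, 8))
        data[1:4, 1:4, 1:4] = 10.0  # 27
        data[10:12, 10:12, 1:3] = 10.0  # 8
        data[17, 17, 6] = 10.0  # 1
        m = body_mask(grid(data), threshold=5.0)
        assert m.voxel_count == 27
        assert m.voxels[2, 2, 2] and not m.voxels[10, 10, 1]

    def test_holes_filled_along_ap_columns(self):
        data = np.zeros((10, 12, 6))
        data[2:8, 2:10, 1:5] = 10.0
        data[4, 5, 3] = 0.0  # interior hole in an AP column
        m = body_mask(grid(data), threshold=5.0)
        assert m.voxels[4, 5, 3]


class TestSegmentKidney:
    def make_phantom(self):
        spec = PhantomSpec(
            grid_shape=(48, 48, 24),
            voxel_spacing=(2.21, 2.21, 4.42),
            body=Organ("body_shape", "ellipsoid", (53, 53, 53), (48, 48, 50), 1.0, 0.0),
            kidneys=(Organ("kidney", "ellipsoid", (53, 53, 53), (20, 20, 20), 10.0, 40.0),),
        )
        return build_phantom(spec)

    def test_recovers_phantom_kidney(self):
        ph = self.make_phantom()
        seg = segment_kidney(ph.activity, (24, 24, 12), frac=0.5)
        truth = ph.organ_masks["kidney"].voxels
        dice = 2 * (seg.voxels & truth).sum() / (seg.voxels.sum() + truth.sum())
        assert dice >= 0.95

    def test_frac_one_keeps_only_max(self):
        data = np.ones((16, 16, 16))
        data[8, 8, 8] = 100.0
        seg = segment_kidney(
            grid(data, (10, 10, 10)), (8, 8, 8), frac=1.0, min_volume_ml=0.0
        )
        assert seg.voxel_count == 1

    def test_background_seed_rejected(self):
        ph = self.make_phantom()
        with pytest.raises(EmptyMaskError):
            segment_kidney(ph.activity, (2, 2, 2), frac=0.5)


class TestProjectBackproject:
    def test_single_voxel_single_pixel(self):
        v = np.zeros((8, 8, 8), bool)
        v[3, 4, 5] = True
        roi = project_mask_to_roi(Mask3D(v, ISO))
        assert roi.pixel_count == 1 and roi.pixels[3, 5]

    def test_full_column_projects_to_one_pixel(self):
        v = np.zeros((8, 12, 8), bool)
        v[3, 1:11, 5] = True
        roi = project_mask_to_roi(Mask3D(v, ISO))
        assert roi.pixel_count == 1

    def test_sphere_projects_to_disc(self):
        n = 41
        c = np.arange(n) - 20.0
        x, y, z = np.meshgrid(c, c, c, indexing="ij")
        sphere = x**2 + y**2 + z**2 <= 10.0**2
        roi = project_mask_to_roi(Mask3D(sphere, ISO))
        ix, iz = np.nonzero(roi.pixels)
        r = np.sqrt((ix - 20.0) ** 2 + (iz - 20.0) ** 2)
        assert r.max() <= 11.0  # disc of matching radius +-1 pixel
        # every pixel within radius-1 is covered
        xx, zz = np.meshgrid(c, c, indexing="ij")
        inner = np.sqrt(xx**2 + zz**2) <= 9.0
        assert roi.pixels[inner].all()

    def test_backproject_slab_column_counts(self):
        masks = slab_masks()
        pix = np.zeros((20, 10), bool)
        pix[5:9, 3:6] = True
        roi = ROI2D(pix, (1.0, 1.0))
        col = backproject_roi_to_column(roi, masks["body"])
        assert col.voxel_count == roi.pixel_count * 20  # slab thickness 20 voxels

    def test_pixel_outside_body_contributes_nothing(self):
        masks = slab_masks(nx=20)
        body = masks["body"]
        body.voxels[15:, :, :] = False
        pix = np.zeros((20, 10), bool)
        pix[16, 4] = True  # outside body silhouette
        pix[5, 4] = True
        col = backproject_roi_to_column(ROI2D(pix, (1.0, 1.0)), body)
        assert col.voxel_count == 20

    def test_roi_fully_outside_body_rejected(self):
        masks = slab_masks(nx=20)
        body = masks["body"]
        body.voxels[15:, :, :] = False
        pix = np.zeros((20, 10), bool)
        pix[17, 4] = True
        with pytest.raises(EmptyMaskError):
            backproject_roi_to_column(ROI2D(pix, (1.0, 1.0)), body)

    def test_ellipsoid_body_column_equals_chord(self):
        n = 31
        c = np.arange(n) - 15.0
        x, y, z = np.meshgrid(c, c, c, indexing="ij", sparse=True)
        ell = (x / 12.0) ** 2 + (y / 14.0) ** 2 + (z / 10.0) ** 2 <= 1.0
        body = Mask3D(ell, ISO, "body")
        pix = np.zeros((n, n), bool)
        pix[12:19, 12:19] = True
        col = backproject_roi_to_column(ROI2D(pix, (1.0, 1.0)), body)
        # per-pixel chord oracle: count body voxels along each AP column
        for ix in range(12, 19):
            for iz in range(12, 19):
                assert col.voxels[ix, :, iz].sum() == ell[ix, :, iz].sum()

    def test_project_backproject_project_idempotent(self, rng):
        masks = slab_masks()
        pix = rng.random((20, 10)) > 0.6
        pix[0, :] = True  # ensure some pixels survive body clipping
        roi = ROI2D(pix, (1.0, 1.0))
        col = backproject_roi_to_column(roi, masks["body"])
        roi2 = project_mask_to_roi(col)
        col2 = backproject_roi_to_column(roi2, masks["body"])
        assert np.array_equal(roi2.pixels, project_mask_to_roi(col2).pixels)


class TestTrueBackground:
    def test_set_arithmetic_in_slab(self):
        masks = slab_masks(kid=(slice(8, 12), slice(10, 18), slice(3, 7)))
        roi = project_mask_to_roi(masks["kidney"])
        col = backproject_roi_to_column(roi, masks["body"])
        tb = true_background_voi(col, masks["kidney"])
        assert tb.voxel_count == col.voxel_count - masks["kidney"].voxel_count
        assert not (tb.voxels & masks["kidney"].voxels).any()

    def test_kidney_equal_column_is_degenerate(self):
        v = np.zeros((8, 8, 8), bool)
        v[2:5, 2:5, 2:5] = True
        m = Mask3D(v, ISO)
        with pytest.raises(DegenerateGeometryError):
            true_background_voi(m, m)

    def test_kidney_not_subset_rejected(self):
        a = np.zeros((8, 8, 8), bool)
        b = np.zeros((8, 8, 8), bool)
        a[2:5, 2:5, 2:5] = True
        b[4:7, 4:7, 4:7] = True
        with pytest.raises(ValueError):
            true_background_voi(Mask3D(a, ISO), Mask3D(b, ISO))


class TestBackgroundRois:
    @pytest.fixture
    def disc_roi(self):
        n = 64
        c = np.arange(n) - 32.0
        xx, zz = np.meshgrid(c, c, indexing="ij")
        return ROI2D(np.sqrt(xx**2 + zz**2) <= 10.0, (1.0, 1.0), "kidney")

    def test_partition_exact(self, disc_roi):
        rois = build_background_rois(disc_roi)
        band = rois["B11"].pixels
        union = np.zeros_like(band)
        total = 0
        for k in range(1, 11):
            sector = rois[f"B{k}"].pixels
            assert not (union & sector).any()  # pairwise disjoint
            union |= sector
            total += sector.sum()
        assert np.array_equal(union, band)
        assert total == band.sum()

    def test_gap_from_kidney(self, disc_roi):
        from scipy import ndimage

        rois = build_background_rois(disc_roi, gap=2, width=4)
        dist = ndimage.distance_transform_edt(~disc_roi.pixels)
        band = rois["B11"].pixels
        assert dist[band].min() > 2
        assert dist[band].max() <= 6
        assert not (band & disc_roi.pixels).any()

    def test_angle_assignment_convention(self, disc_roi):
        rois = build_background_rois(disc_roi)
        cx, cz = roi_centroid(disc_roi)
        # cranial pixel (dz > 0, dx = 0) lies at 0 degrees -> B1
        assert rois["B1"].pixels[int(round(cx)), int(round(cz)) + 13]
        # patient-left pixel (dx > 0, dz = 0) lies at 90 degrees -> B3
        assert rois["B3"].pixels[int(round(cx)) + 13, int(round(cz))]
        # caudal pixel at 180 degrees -> B6
        assert rois["B6"].pixels[int(round(cx)), int(round(cz)) - 13]

    def test_half_open_bins(self):
        # a pixel at exactly 36 degrees belongs to B2, not B1
        theta = np.radians(36.0)
        dx, dz = np.sin(theta), np.cos(theta)
        assert int(np.floor(np.degrees(np.arctan2(dx, dz)) % 360 / 36)) == 1

    def test_kidney_touching_edge_rejected(self):
        pix = np.zeros((16, 16), bool)
        pix[0:6, 6:10] = True
        with pytest.raises((EmptyMaskError, DegenerateGeometryError)):
            build_background_rois(ROI2D(pix, (1.0, 1.0)))

    def test_empty_roi_rejected(self):
        with pytest.raises(EmptyMaskError):
            build_background_rois(ROI2D(np.zeros((8, 8), bool), (1.0, 1.0)))


class TestMeasureGeometry:
    def test_box_kidney_in_slab(self):
        # 4 cm kidney in a 20 cm slab with 5 cm of dorsal tissue (1 mm voxels)
        masks = slab_masks(
            nx=20, ny=250, nz=10, body_y=(10, 210), kid=(slice(6, 14), slice(120, 160), slice(3, 7))
        )
        g = measure_geometry(masks["kidney"], masks["body"], (1.0, 1.0, 1.0))
        assert g.t_k == pytest.approx(4.0)
        assert g.t_p == pytest.approx(20.0)
        assert g.d_k == pytest.approx(5.0)

    def test_kidney_touching_back_surface(self):
        masks = slab_masks(
            nx=20, ny=60, nz=10, body_y=(5, 55), kid=(slice(6, 14), slice(45, 55), slice(3, 7))
        )
        g = measure_geometry(masks["kidney"], masks["body"], (1.0, 1.0, 1.0))
        assert g.d_k == 0.0

    def test_ellipsoid_volume_within_5pct(self):
        spec = PhantomSpec(
            grid_shape=(64, 64, 40),
            voxel_spacing=(2.21, 2.21, 4.42),
            body=Organ("body_shape", "ellipsoid", (70, 70, 85), (60, 60, 80), 0.0, 0.0),
            kidneys=(Organ("kidney", "ellipsoid", (70, 70, 85), (33, 33, 33), 10.0, 40.0),),
        )
        ph = build_phantom(spec)
        g = measure_geometry(
            ph.organ_masks["kidney"], ph.organ_masks["body"], (2.21, 2.21, 4.42)
        )
        analytic = 4.0 / 3.0 * np.pi * 3.3**3
        assert abs(g.v_k - analytic) / analytic < 0.05

    def test_empty_mask_rejected(self):
        masks = slab_masks()
        empty = Mask3D(np.zeros((20, 30, 10), bool), ISO)
        with pytest.raises(EmptyMaskError):
            measure_geometry(empty, masks["body"], (1.0, 1.0, 1.0))
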