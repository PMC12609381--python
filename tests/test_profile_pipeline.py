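"""Digitization chain tests: masks, boundaries, calibration, standardization."""

import numpy as np
import pytest

from ovogeom.epe_model import EPEParams, sample_curve
from ovogeom.profile_pipeline import (RawBoundary, calibrate_scale,
                                      extract_boundary, read_binary_image,
                                      read_profile_csv, standardize_points,
                                      standardize_profile, write_profile_csv)
from ovogeom.synthetic_data import render_image, save_silhouette


def disk_mask(radius=100, pad=20):
    n = 2 * (radius + pad) + 1
    yy, xx = np.mgrid[:n, :n]
    c = radius + pad
    return (yy - c) ** 2 + (xx - c) ** 2 <= radius ** 2


class TestReadBinaryImage:
    def test_round_trip_of_rendered_silhouette(self, tmp_path, egg_params):
        mask = render_image(egg_params)
        path = tmp_path / "egg.png"
        save_silhouette(mask, path)
        recovered = read_binary_image(path)
        np.testing.assert_array_equal(recovered, mask)

    def test_all_white_image_is_empty_foreground(self, tmp_path):
        from PIL import Image
        path = tmp_path / "white.png"
        Image.fromarray(np.full((50, 50), 255, np.uint8)).save(path)
        with pytest.raises(ValueError, match="empty foreground"):
            read_binary_image(path)

    def test_both_phases_touching_border_is_ambiguous(self, tmp_path):
        from PIL import Image
        arr = np.zeros((60, 60), np.uint8)
        arr[:, 30:] = 255  # black left half, white right half
        path = tmp_path / "ambig.png"
        Image.fromarray(arr).save(path)
        with pytest.raises(ValueError, match="border"):
            read_binary_image(path)


class TestExtractBoundary:
    def test_disk_boundary_matches_circle(self):
        boundary = extract_boundary(disk_mask(radius=100))
        centre = np.array([120.0, 120.0])
        r = np.linalg.norm(boundary.pixel_points - centre, axis=1)
        assert len(boundary.pixel_points) > 500
        assert np.all(np.abs(r - 100.0) < 1.0)

    def test_largest_of_two_components_is_traced(self):
        mask = disk_mask(radius=60)
        mask[5:10, 5:10] = True  # small spurious blob
        boundary = extract_boundary(mask)
        centre = boundary.pixel_points.mean(axis=0)
        assert np.linalg.norm(centre - [80, 80]) < 2.0

    def test_tiny_component_rejected(self):
        mask = np.zeros((30, 30), bool)
        mask[15, 15] = True
        with pytest.raises(ValueError):
            extract_boundary(mask)

    def test_empty_mask_rejected(self):
        with pytest.raises(ValueError):
            extract_boundary(np.zeros((20, 20), bool))


class TestCalibration:
    def test_scale_from_known_chord(self):
        boundary = extract_boundary(disk_mask(radius=250))
        cal = calibrate_scale(boundary, measured_length=5.0)
        assert cal.scale == pytest.approx(5.0 / 500.0, rel=5e-3)

    def test_rendered_length_recovered(self, egg_params, tmp_path):
        mask = render_image(egg_params)
        cal = calibrate_scale(extract_boundary(mask), 2 * egg_params.b)
        prof = standardize_profile(cal, 1000)
        length = prof.x.max() - prof.x.min()
        assert length == pytest.approx(2 * egg_params.b, rel=5e-3)

    def test_nonpositive_length_rejected(self):
        boundary = extract_boundary(disk_mask(radius=60))
        with pytest.raises(ValueError):
            calibrate_scale(boundary, 0.0)

    def test_uncalibrated_boundary_rejected(self):
        boundary = extract_boundary(disk_mask(radius=60))
        with pytest.raises(ValueError, match="calibrated"):
            standardize_profile(boundary)


class TestStandardization:
    def test_rotated_ellipse_realigned(self):
        """A 30 deg-rotated ellipse comes back with its long axis on x."""
        t = np.linspace(0, 2 * np.pi, 720, endpoint=False)
        pts = np.column_stack([2.0 * np.cos(t), 1.2 * np.sin(t)])
        ang = np.deg2rad(30)
        rot = np.array([[np.cos(ang), -np.sin(ang)],
                        [np.sin(ang), np.cos(ang)]])
        prof = standardize_points(pts @ rot.T + [3.0, -1.5], 1000)
        # chord endpoints on the x-axis, symmetric about origin
        assert prof.points[0] == pytest.approx([-2.0, 0.0], abs=2e-3)
        tip_angle = np.rad2deg(np.arctan2(abs(prof.points[0][1]), 2.0))
        assert tip_angle < 0.1
        assert abs(prof.x.max() + prof.x.min()) < 1e-9

    def test_default_n_is_1000(self, egg_params):
        mask = render_image(egg_params)
        cal = calibrate_scale(extract_boundary(mask), 2 * egg_params.b)
        assert standardize_profile(cal).n_points == 1000

    def test_equidistance(self, egg_params):
        mask = render_image(egg_params)
        cal = calibrate_scale(extract_boundary(mask), 2 * egg_params.b)
        prof = standardize_profile(cal)
        closed = np.vstack([prof.points, prof.points[:1]])
        seg = np.linalg.norm(np.diff(closed, axis=0), axis=1)
        assert seg.max() / seg.min() < 1.1

    def test_idempotent_on_standardized_profiles(self, egg_params):
        prof = sample_curve(egg_params, 1000)
        again = standardize_profile(prof, 1000)
        np.testing.assert_allclose(again.points, prof.points, atol=1e-9)


class TestRawBoundary:
    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError):
            RawBoundary(np.zeros((10, 2)), (50, 50))


class TestCsvRoundTrip:
    def test_write_read(self, tmp_path, egg_params):
        prof = sample_curve(egg_params, 200)
        path = tmp_path / "prof.csv"
        write_profile_csv(prof, path)
        back = read_profile_csv(path)
        np.testing.assert_allclose(back.points, prof.points, atol=1e-5)
        assert path.read_text().splitlines()[0] == "x_cm,y_cm"

    def test_wrong_header_rejected(self, tmp_path):
        path = tmp_path / "bad.csv"
        path.write_text("u,v\n0,0\n1,1\n")
        with pytest.raises(ValueError, match="x_cm"):
            read_profile_csv(path)
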