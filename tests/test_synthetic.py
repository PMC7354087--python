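"""Generators: determinism, analytic phantoms, recoverable ground truth."""

import json
from pathlib import Path

import numpy as np
import pytest

from emphyquant.foci import detect_foci
from emphyquant.imaging import (HUCalibrator, LABEL_WATER, mean_hu,
                                segment_lung, t2_ratio)
from emphyquant.io import (load_manifest, read_ct_volume,
                           read_histology_section, read_mr_slice,
                           read_point_set)
from emphyquant.stereology import compute_lm, measure_chords
from emphyquant.synthetic import (DegenerateGeometryError, GroupSpec,
                                  PlacementError, StudyDesign,
                                  exhaustive_mean_chord,
                                  generate_alveolar_section,
                                  generate_ct_volume, generate_mr_slice,
                                  generate_study, inject_leukocyte_foci)


class TestAlveolarSections:
    def test_parallel_septa_analytic_chords(self):
        sec, truth = generate_alveolar_section(
            "parallel_septa", period_um=50, septum_um=10,
            size_px=256, pixel_size_um=1.0, seed=0)
        assert truth.true_mean_chord_um == 40.0
        cs = measure_chords(sec, orientation="horizontal", line_spacing_um=20)
        assert np.all(cs.lengths_um == 40.0)

    def test_determinism(self):
        a, _ = generate_alveolar_section(size_px=256, seed=7)
        b, _ = generate_alveolar_section(size_px=256, seed=7)
        assert np.array_equal(a.tissue_mask, b.tissue_mask)

    def test_sub_resolution_period_rejected(self):
        with pytest.raises(DegenerateGeometryError):
            generate_alveolar_section(period_um=3, septum_um=1,
                                      pixel_size_um=2.0, seed=0)

    def test_emphysema_strictly_enlarges_airspaces(self):
        """Wall removal increases the true mean chord, monotonically in f."""
        chords = []
        for f in (0.0, 0.25, 0.5):
            _, truth = generate_alveolar_section(
                "voronoi_foam", emphysema_fraction=f, size_px=512,
                pixel_size_um=2.0, seed=11)
            chords.append(truth.true_mean_chord_um)
        assert chords[0] < chords[1] < chords[2]

    def test_emphysema_measured_by_stereology(self):
        """Lm(f=0.5) > Lm(f=0) when measured with the 15-field estimator."""
        lms = {}
        for f in (0.0, 0.5):
            sec, _ = generate_alveolar_section(
                "voronoi_foam", emphysema_fraction=f, size_px=1024,
                pixel_size_um=2.0, seed=5)
            lms[f] = compute_lm([sec], n_fields=15, field_size_px=150,
                                seed=0).lm_um
        assert lms[0.5] > lms[0.0]

    def test_truth_matches_independent_oracle(self, foam_section):
        section, truth = foam_section
        assert truth.true_mean_chord_um == pytest.approx(
            exhaustive_mean_chord(section.tissue_mask,
                                  section.pixel_size_um))


class TestLeukocyteInjection:
    def test_empty_case(self):
        pset, truth = inject_leukocyte_foci((2000, 2000), 0,
                                            background_density_per_mm2=0.0,
                                            seed=0)
        assert pset.points.shape == (0, 2) and truth.true_n_foci == 0

    def test_determinism(self):
        a, _ = inject_leukocyte_foci((4000, 4000), 4, seed=3)
        b, _ = inject_leukocyte_foci((4000, 4000), 4, seed=3)
        assert np.array_equal(a.points, b.points)

    def test_detector_recovers_injected_count(self):
        pset, truth = inject_leukocyte_foci((6000, 4000), 3,
                                            cells_per_focus=25, seed=1)
        assert detect_foci(pset).n_foci == truth.true_n_foci == 3

    def test_cells_per_focus_must_pass_cluster_rule(self):
        with pytest.raises(ValueError):
            inject_leukocyte_foci((4000, 4000), 1, cells_per_focus=20, seed=0)

    def test_overcrowded_section_fails_placement(self):
        with pytest.raises(PlacementError):
            inject_leukocyte_foci((600, 600), 30, seed=0)


class TestCtVolumes:
    def test_noiseless_round_trip_is_exact(self):
        vol, voi, truth = generate_ct_volume(-400.0, 0.0, seed=2)
        cal = HUCalibrator().fit(vol.voxels, vol.labels)
        hu = cal.transform(vol.voxels)
        res = mean_hu(hu, voi, segment_lung(hu))
        assert res.mean_hu == pytest.approx(-400.0, abs=1e-9)

    def test_water_region_calibrates_to_zero(self):
        vol, _, _ = generate_ct_volume(-400.0, 0.0, seed=2)
        hu = HUCalibrator().fit(vol.voxels, vol.labels).transform(vol.voxels)
        assert hu[vol.labels == LABEL_WATER].mean() == pytest.approx(0.0,
                                                                     abs=1e-9)

    def test_calibration_is_nontrivial(self):
        """Raw units differ from HU: the hidden affine map must be undone."""
        vol, voi, truth = generate_ct_volume(-400.0, 0.0, seed=6)
        assert abs(vol.voxels[voi].mean() - (-400.0)) > 10.0

    @pytest.mark.parametrize("seed", range(30))
    def test_noisy_voi_mean_within_standard_error_bound(self, seed):
        """Mean HU stays within 3 * sd / sqrt(n) of truth, seed by seed."""
        vol, voi, _ = generate_ct_volume(-400.0, 20.0, seed=seed)
        hu = HUCalibrator().fit(vol.voxels, vol.labels).transform(vol.voxels)
        res = mean_hu(hu, voi, None)
        bound = 3 * 20.0 / np.sqrt(res.n_voxels_used)
        # calibration references are themselves noisy; allow their (small)
        # standard error on top of the VOI's own
        assert abs(res.mean_hu - (-400.0)) < bound + 2.0

    def test_shape_validation(self):
        with pytest.raises(ValueError):
            generate_ct_volume(shape=(8, 8, 8), seed=0)


class TestMrSlices:
    def test_noiseless_ratio_by_construction(self):
        mr, truth = generate_mr_slice(300.0, 250.0, noise_sd=0.0, seed=0)
        assert t2_ratio(mr).ratio_lung == pytest.approx(1.2)
        assert truth.true_t2_ratio == pytest.approx(1.2)

    def test_identity_ratio(self):
        mr, _ = generate_mr_slice(250.0, 250.0, noise_sd=0.0, seed=0)
        assert t2_ratio(mr).ratio_lung == pytest.approx(1.0)

    def test_cs_like_elevation(self):
        """Lung 318 over muscle 250 is a 27.2% elevation vs parity."""
        mr, _ = generate_mr_slice(318.0, 250.0, noise_sd=0.0, seed=0)
        assert t2_ratio(mr).ratio_lung == pytest.approx(1.272)

    def test_zero_muscle_rejected(self):
        with pytest.raises(ValueError):
            generate_mr_slice(300.0, 0.0, seed=0)


@pytest.fixture(scope="module")
def tiny_study(tmp_path_factory):
    design = StudyDesign(
        groups=[GroupSpec("control", 2), GroupSpec("CS", 2, lm_scale=1.2,
                                                   foci_per_20mm2=10.98)],
        timepoints=(0, 12), sections_per_subject=3,
        histology_size_px=384, histology_pixel_size_um=2.0,
        foci_section_um=(4000.0, 3000.0), ct_shape=(24, 24, 24))
    out = tmp_path_factory.mktemp("study")
    manifest = generate_study(design, seed=9, out_dir=out)
    return design, out, manifest


class TestGenerateStudy:
    def test_manifest_counts(self, tiny_study):
        design, out, manifest = tiny_study
        assert manifest.subject_id.nunique() == 4
        hist = manifest[manifest.modality == "histology"]
        assert hist.groupby("subject_id").size().eq(3).all()
        ct = manifest[manifest.modality == "ct"]
        assert ct.groupby("subject_id").size().eq(2).all()  # two timepoints

    def test_byte_identical_regeneration(self, tiny_study, tmp_path):
        design, out, _ = tiny_study
        out2 = tmp_path / "again"
        generate_study(design, seed=9, out_dir=out2)
        files1 = sorted(p.relative_to(out) for p in out.rglob("*")
                        if p.is_file())
        files2 = sorted(p.relative_to(out2) for p in out2.rglob("*")
                        if p.is_file())
        assert files1 == files2
        for rel in files1:
            assert (out / rel).read_bytes() == (out2 / rel).read_bytes(), rel

    def test_artifacts_round_trip_through_readers(self, tiny_study):
        """Every generated file is readable by the downstream modules."""
        _, out, _ = tiny_study
        manifest = load_manifest(out / "manifest.csv")
        root = manifest.attrs["root"]
        for row in manifest.itertuples():
            if row.modality == "histology":
                sec = read_histology_section(row, root)
                truth = json.loads(row.truth_json)
                assert sec.tissue_mask.any() and not sec.tissue_mask.all()
                assert truth["true_mean_chord_um"] > 0
            elif row.modality == "points":
                pset = read_point_set(row, root)
                assert pset.section_area_mm2 == pytest.approx(12.0)
            elif row.modality == "ct":
                vol = read_ct_volume(row, root)
                assert vol.voxels.shape == vol.labels.shape
            elif row.modality == "mri":
                mr = read_mr_slice(row, root)
                assert t2_ratio(mr).ratio_lung > 0
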