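import numpy as np
import pytest

from meglabel.formats import (
    Dipole,
    DipoleGroup,
    FormatError,
    LookupTable,
    flirt_to_world,
    load_displacement_field,
    load_volume,
    read_coreg,
    read_dip,
    read_lookup_table,
    read_transform,
    save_displacement_field,
    save_volume,
    write_coreg,
    write_dip,
    write_lookup_table,
    write_transform,
)
from meglabel.geometry import DeformationField, Frame, FrameTransform, Volume

from conftest import random_affine


def _dipole(i, **kw):
    base = dict(
        id=f"IED_{i:03d}",
        begin_ms=10.0 * i,
        end_ms=10.0 * i + 5.0,
        position=(1.25 * i, -2.5, 3.75),
        moment=(10.0, -20.0, 5.0),
        q_nam=200.0,
        gof_pct=88.5,
        chi2_reduced=1.2,
        conf_volume_mm3=350.0,
    )
    base.update(kw)
    return Dipole(**base)


class TestDipFiles:
    def test_write_read_round_trip(self, tmp_path):
        group = DipoleGroup(
            task="IED",
            dipoles=[
                _dipole(1),
                _dipole(2, chi2_reduced=None, conf_volume_mm3=None),
                _dipole(3, gof_pct=80.0),
            ],
        )
        path = write_dip(group, tmp_path / "IED.dip")
        back = read_dip(path)
        assert back.task == "IED"
        assert len(back) == 3
        for a, b in zip(group, back):
            assert a.id == b.id
            np.testing.assert_allclose(a.position, b.position, atol=1e-6)
            np.testing.assert_allclose(a.moment, b.moment, atol=1e-6)
            assert abs(a.gof_pct - b.gof_pct) < 1e-6
            assert (a.chi2_reduced is None) == (b.chi2_reduced is None)
            assert (a.conf_volume_mm3 is None) == (b.conf_volume_mm3 is None)

    def test_comment_only_file_is_no_dipoles_error(self, tmp_path):
        p = tmp_path / "SEF.dip"
        p.write_text("# nothing here\n# still nothing\n\n")
        with pytest.raises(FormatError, match="no dipoles"):
            read_dip(p)

    def test_bad_coordinate_names_line_number(self, tmp_path):
        p = tmp_path / "LEF.dip"
        p.write_text("# header\n0 5 1.0 oops 3.0 0 0 1 200 90\n")
        with pytest.raises(FormatError, match=r"LEF\.dip:2"):
            read_dip(p)

    def test_refuses_empty_group(self, tmp_path):
        with pytest.raises(ValueError, match="dipole-less"):
            write_dip(DipoleGroup(task="IED", dipoles=[]), tmp_path / "x.dip")

    def test_single_dipole_single_data_row(self, tmp_path):
        path = write_dip(DipoleGroup(task="SEF", dipoles=[_dipole(1, id="SEF_001")]),
                         tmp_path / "SEF.dip")
        rows = [l for l in path.read_text().splitlines()
                if l.strip() and not l.startswith("#")]
        assert len(rows) == 1

    def test_double_write_is_byte_stable(self, tmp_path):
        rng = np.random.default_rng(3)
        dipoles = [
            _dipole(
                i,
                position=rng.uniform(-80, 80, 3),
                moment=rng.normal(size=3) * 100,
                q_nam=float(rng.uniform(100, 500)),
                gof_pct=float(rng.uniform(50, 100)),
            )
            for i in range(100)
        ]
        group = DipoleGroup(task="IED", dipoles=dipoles)
        a = write_dip(group, tmp_path / "a.dip").read_bytes()
        b = write_dip(group, tmp_path / "b.dip").read_bytes()
        assert a == b

    def test_dipole_field_validation(self):
        with pytest.raises(ValueError, match="gof"):
            _dipole(1, gof_pct=101.0)
        with pytest.raises(ValueError, match="begin_ms"):
            _dipole(1, begin_ms=10.0, end_ms=5.0)
        with pytest.raises(ValueError, match="confidence volume"):
            _dipole(1, conf_volume_mm3=-5.0)


class TestLookupTables:
    def test_printed_aal_entry(self, tmp_path):
        p = tmp_path / "lut.txt"
        p.write_text('85 "Temporal_Mid_L"\n')
        table = read_lookup_table(p, atlas_name="AAL_MNI_V4")
        assert table.entries[85] == "Temporal_Mid_L"

    def test_blank_lines_and_comments_skipped(self, tmp_path):
        p = tmp_path / "lut.txt"
        p.write_text('# header\n\n1 "A"\n\n# mid comment\n2 "B"\n')
        table = read_lookup_table(p, atlas_name="toy")
        assert len(table.entries) == 2

    @pytest.mark.parametrize(
        "text,match",
        [
            ('7 "A"\n7 "B"\n', "duplicate"),
            ('0 "zero"\n', "reserved"),
            ('-3 "neg"\n', "negative"),
            ("5\n", "expected"),
        ],
    )
    def test_malformed_tables_rejected(self, tmp_path, text, match):
        p = tmp_path / "lut.txt"
        p.write_text(text)
        with pytest.raises(FormatError, match=match):
            read_lookup_table(p, atlas_name="toy")

    def test_write_read_round_trip_exact(self, tmp_path):
        table = LookupTable("toy", {1: "region_1", 85: "Temporal_Mid_L"})
        back = read_lookup_table(write_lookup_table(table, tmp_path / "t.txt"), "toy")
        assert back.entries == table.entries


class TestCanonicalTransforms:
    def test_round_trip(self, tmp_path):
        rng = np.random.default_rng(9)
        t = FrameTransform(random_affine(rng), Frame.WORLD, Frame.TEMPLATE)
        back = read_transform(write_transform(t, tmp_path / "norm.txt"))
        assert back.source == Frame.WORLD and back.target == Frame.TEMPLATE
        np.testing.assert_allclose(back.matrix, t.matrix, atol=1e-9)

    def test_coreg_identity_mm(self, tmp_path):
        t = FrameTransform(np.eye(4), Frame.HEAD, Frame.WORLD)
        back = read_coreg(write_coreg(t, tmp_path / "coreg.txt", head_unit="mm"))
        assert back.is_identity()

    def test_coreg_meter_unit_scales_positions(self, tmp_path):
        t = FrameTransform(np.eye(4), Frame.HEAD, Frame.WORLD)
        back = read_coreg(write_coreg(t, tmp_path / "coreg.txt", head_unit="m"))
        np.testing.assert_allclose(back.apply((0.1, 0.0, 0.0)), (100.0, 0.0, 0.0))

    def test_missing_unit_declaration_rejected(self, tmp_path):
        p = tmp_path / "coreg.txt"
        p.write_text(
            "# meglabel coreg v1\nsource_frame: HEAD\ntarget_frame: WORLD\n"
            "matrix:\n1 0 0 0\n0 1 0 0\n0 0 1 0\n0 0 0 1\n"
        )
        with pytest.raises(FormatError, match="head_unit"):
            read_coreg(p)

    def test_wrong_matrix_shape_rejected(self, tmp_path):
        p = tmp_path / "norm.txt"
        p.write_text(
            "# meglabel transform v1\nsource_frame: WORLD\ntarget_frame: TEMPLATE\n"
            "units: mm\nmatrix:\n1 0 0 0\n0 1 0 0\n0 0 1 0\n"
        )
        with pytest.raises(FormatError, match="4x4"):
            read_transform(p)


def _iso_volume(shape, voxel, flip_x=False, world_frame=Frame.WORLD):
    affine = np.diag([voxel, voxel, voxel, 1.0])
    if flip_x:
        affine[0, 0] = -voxel
    affine[:3, 3] = -(np.asarray(shape) - 1) / 2.0 * voxel
    return Volume(
        np.zeros(shape), FrameTransform(affine, Frame.VOXEL, world_frame)
    )


class TestFlirtMatrices:
    def test_identity_on_identical_negative_determinant_grids(self):
        vol = _iso_volume((32, 32, 32), 1.0, flip_x=True)
        fix = _iso_volume((32, 32, 32), 1.0, flip_x=True, world_frame=Frame.TEMPLATE)
        t = flirt_to_world(np.eye(4), vol, fix)
        assert t.is_identity(atol=1e-9)

    def test_translation_matches_hand_computed_convention(self):
        # independent oracle: walk each probe point through the documented
        # scaled-voxel convention step by step
        moving = _iso_volume((20, 22, 24), 2.0)  # positive det -> x flip
        fixed = _iso_volume((20, 22, 24), 2.0, world_frame=Frame.TEMPLATE)
        flirt = np.eye(4)
        flirt[0, 3] = 4.0  # 4 mm x-translation in scaled-voxel space
        t = flirt_to_world(flirt, moving, fixed)

        rng = np.random.default_rng(2)
        probes = rng.uniform(-15, 15, size=(8, 3))
        for p in probes:
            vox = np.linalg.inv(moving.affine) @ np.append(p, 1.0)
            sv = np.array(
                [
                    (moving.shape[0] - 1 - vox[0]) * 2.0,  # flipped x
                    vox[1] * 2.0,
                    vox[2] * 2.0,
                    1.0,
                ]
            )
            sv_fix = flirt @ sv
            vox_fix = np.array(
                [
                    fixed.shape[0] - 1 - sv_fix[0] / 2.0,
                    sv_fix[1] / 2.0,
                    sv_fix[2] / 2.0,
                    1.0,
                ]
            )
            expected = (fixed.affine @ vox_fix)[:3]
            np.testing.assert_allclose(t.apply(p), expected, atol=1e-9)

    def test_conversion_inverts_cleanly_on_probe_points(self):
        rng = np.random.default_rng(4)
        moving = _iso_volume((16, 16, 16), 2.0)
        fixed = _iso_volume((24, 24, 24), 1.5, world_frame=Frame.TEMPLATE)
        flirt = random_affine(rng, max_t=5, max_angle_deg=5)
        fwd = flirt_to_world(flirt, moving, fixed)
        # converting the inverse FLIRT matrix with roles swapped must undo it
        class _Swap:
            affine = fixed.affine
            shape = fixed.shape
        class _Swap2:
            affine = moving.affine
            shape = moving.shape
        back = flirt_to_world(np.linalg.inv(flirt), _Swap, _Swap2)
        probes = rng.uniform(-10, 10, size=(8, 3))
        np.testing.assert_allclose(
            back.apply(fwd.apply(probes)), probes, atol=1e-9
        )

    def test_flirt_dialect_requires_geometry(self, tmp_path):
        p = tmp_path / "x.mat"
        p.write_text("1 0 0 0\n0 1 0 0\n0 0 1 0\n0 0 0 1\n")
        with pytest.raises(FormatError, match="geometr"):
            read_transform(p, dialect="flirt_mat")


class TestNiftiRoundTrips:
    def test_volume_affine_preserved_exactly(self, tmp_path):
        rng = np.random.default_rng(6)
        affine = random_affine(rng, max_t=50)
        vol = Volume(
            rng.integers(0, 5, size=(6, 7, 8)),
            FrameTransform(affine, Frame.VOXEL, Frame.WORLD),
            role="label",
        )
        back = load_volume(save_volume(vol, tmp_path / "x.nii"), role="label")
        np.testing.assert_allclose(back.affine, vol.affine, atol=1e-5)
        np.testing.assert_array_equal(back.values, vol.values)

    def test_displacement_field_round_trip(self, tmp_path):
        rng = np.random.default_rng(7)
        df = DeformationField(
            rng.normal(size=(5, 6, 7, 3)).astype(np.float32),
            FrameTransform(np.eye(4), Frame.VOXEL, Frame.WORLD),
        )
        back = load_displacement_field(save_displacement_field(df, tmp_path / "w.nii"))
        np.testing.assert_allclose(back.displacements, df.displacements, atol=1e-6)
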