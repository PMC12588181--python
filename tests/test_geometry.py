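import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from jawlever import (
    DegenerateGeometryError,
    GeometrySpec,
    InvalidInputError,
    JawGeometry,
    MuscleTarget,
    derive_action_line,
    distance_to_bite_point,
    generate_geometry,
    read_landmarks_csv,
    read_landmarks_json,
    rotate_mandible,
    write_landmarks_csv,
)


def simple_geometry(origin, insertion=(5.0, 0.0, 0.0)):
    return JawGeometry(
        condyle=(0.0, 0.0, 0.0),
        origins={"m": origin},
        insertions={"m": insertion},
        bite_points={"incisor": (20.0, 0.0, 0.0)},
    )


class TestDeriveActionLine:
    def test_pure_mediolateral_pull_is_degenerate(self):
        geom = simple_geometry(origin=(5.0, 0.0, 4.0))
        with pytest.raises(DegenerateGeometryError, match="'m'"):
            derive_action_line(geom, "m")

    def test_sagittal_pull_perpendicular_to_lever(self):
        geom = simple_geometry(origin=(5.0, 7.0, 0.0))  # straight dorsal pull
        line = derive_action_line(geom, "m")
        assert line.phi == pytest.approx(90.0, abs=1e-12)
        assert line.theta == pytest.approx(90.0, abs=1e-12)
        assert line.lever == pytest.approx(5.0)
        assert line.moment_sign == -1  # dorsal pull anterior of condyle closes

    def test_ventral_pull_is_opening(self):
        geom = simple_geometry(origin=(5.0, -7.0, 0.0))
        assert derive_action_line(geom, "m").moment_sign == +1

    def test_action_through_condyle_has_zero_moment(self):
        # pull from insertion straight towards the condyle: theta = 180
        geom = simple_geometry(origin=(-3.0, 0.0, 0.0))
        line = derive_action_line(geom, "m")
        assert line.theta == pytest.approx(180.0)
        assert line.moment_sign == 0

    def test_unknown_muscle_is_lookup_error(self):
        with pytest.raises(KeyError):
            derive_action_line(simple_geometry((5, 1, 0)), "nope")

    def test_round_trip_through_generator(self):
        spec = GeometrySpec(
            muscles={"MS": MuscleTarget(phi=59.70, theta=63.89, lever=5.2)},
            d_cbp={"m4": 10.0},
        )
        line = derive_action_line(generate_geometry(spec), "MS")
        assert line.phi == pytest.approx(59.70, abs=1e-6)
        assert line.theta == pytest.approx(63.89, abs=1e-6)
        assert line.lever == pytest.approx(5.2, abs=1e-9)


class TestRotation:
    def test_zero_delta_is_identity(self, ref_geometry):
        rotated = rotate_mandible(ref_geometry, 0.0)
        for m in ref_geometry.muscles:
            np.testing.assert_array_equal(
                rotated.insertions[m], ref_geometry.insertions[m]
            )

    def test_quarter_turn_opening_convention(self):
        geom = simple_geometry(origin=(5.0, 7.0, 0.0), insertion=(1.0, 0.0, 0.0))
        rotated = rotate_mandible(geom, 90.0)
        np.testing.assert_allclose(
            rotated.insertions["m"], [0.0, -1.0, 0.0], atol=1e-12
        )

    def test_two_half_steps_equal_one_step(self, ref_geometry):
        twice = rotate_mandible(rotate_mandible(ref_geometry, 0.5), 0.5)
        once = rotate_mandible(ref_geometry, 1.0)
        for m in ref_geometry.muscles:
            np.testing.assert_allclose(
                twice.insertions[m], once.insertions[m], atol=1e-12
            )
        assert twice.gape == pytest.approx(once.gape)

    def test_origins_and_condyle_fixed(self, ref_geometry):
        rotated = rotate_mandible(ref_geometry, 12.5)
        np.testing.assert_array_equal(rotated.condyle, ref_geometry.condyle)
        for m in ref_geometry.muscles:
            np.testing.assert_array_equal(
                rotated.origins[m], ref_geometry.origins[m]
            )

    @given(delta=st.floats(-90, 90))
    @settings(max_examples=40, deadline=None)
    def test_rotation_is_isometry_about_condyle(self, delta):
        import jawlever.reference as reference

        geom = reference.reference_geometry()
        rotated = rotate_mandible(geom, delta)
        for m in geom.muscles:
            before = np.linalg.norm(geom.insertions[m] - geom.condyle)
            after = np.linalg.norm(rotated.insertions[m] - rotated.condyle)
            assert after == pytest.approx(before, abs=1e-9)
        for bp in geom.bite_points:
            assert distance_to_bite_point(rotated, bp) == pytest.approx(
                distance_to_bite_point(geom, bp), abs=1e-9
            )


class TestDistances:
    def test_out_lever_along_axis(self):
        geom = simple_geometry(origin=(5, 1, 0))
        assert distance_to_bite_point(geom, "incisor") == pytest.approx(20.0)

    def test_unknown_bite_point(self):
        with pytest.raises(KeyError, match="unknown bite point"):
            distance_to_bite_point(simple_geometry((5, 1, 0)), "m4")

    def test_bite_point_on_condyle_rejected_at_construction(self):
        with pytest.raises(InvalidInputError, match="coincides"):
            JawGeometry(
                condyle=(0, 0, 0),
                origins={"m": (1.0, 1.0, 0.0)},
                insertions={"m": (2.0, 0.0, 0.0)},
                bite_points={"bp": (0.0, 0.0, 0.0)},
            )


class TestValidation:
    def test_origin_insertion_mismatch(self):
        with pytest.raises(InvalidInputError, match="same muscles"):
            JawGeometry((0, 0, 0), {"a": (1, 0, 0)}, {"b": (1, 1, 0)}, {})

    def test_coincident_origin_insertion(self):
        with pytest.raises(InvalidInputError, match="coincide"):
            JawGeometry((0, 0, 0), {"a": (1, 0, 0)}, {"a": (1, 0, 0)}, {})

    def test_nonfinite_coordinates(self):
        with pytest.raises(InvalidInputError, match="finite"):
            JawGeometry((0, 0, float("nan")), {}, {}, {})


def test_landmark_csv_and_json_round_trip(tmp_path, ref_geometry):
    path = tmp_path / "landmarks.csv"
    write_landmarks_csv(ref_geometry, path)
    back = read_landmarks_csv(path)
    for m in ref_geometry.muscles:
        np.testing.assert_allclose(back.origins[m], ref_geometry.origins[m])
        np.testing.assert_allclose(back.insertions[m], ref_geometry.insertions[m])

    import json

    jpath = tmp_path / "landmarks.json"
    jpath.write_text(json.dumps({
        "condyle": list(ref_geometry.condyle),
        "origins": {m: list(p) for m, p in ref_geometry.origins.items()},
        "insertions": {m: list(p) for m, p in ref_geometry.insertions.items()},
        "bite_points": {b: list(p) for b, p in ref_geometry.bite_points.items()},
    }))
    back2 = read_landmarks_json(jpath)
    np.testing.assert_allclose(back2.condyle, ref_geometry.condyle)


def test_landmark_csv_schema_errors(tmp_path):
    from jawlever import SchemaError

    p = tmp_path / "bad.csv"
    p.write_text("landmark,role,x_mm,y_mm\nc,condyle,0,0\n")
    with pytest.raises(SchemaError, match="z_mm"):
        read_landmarks_csv(p)
    p.write_text(
        "landmark,role,x_mm,y_mm,z_mm\nc,condyle,0,0,0\nx,weird,1,1,1\n"
    )
    with pytest.raises(SchemaError, match="weird"):
        read_landmarks_csv(p)
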