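import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from jawlever import (
    InvalidInputError,
    ModelError,
    PlanarModel,
    PlanarMuscle,
    SchemaError,
    mechanics_from_geometry,
    project_to_sagittal,
    read_planar_csv,
    resultant_at_bite_point,
    total_bite_force,
)
from jawlever.reference import study_record

from .conftest import random_landmark_geometry
from .oracles import oracle_bite_force


class TestSagittalProjection:
    @pytest.mark.parametrize(
        "f3d, phi, expected",
        [
            (7.458, 59.70, 6.439),  # mostly sagittal masseter superficialis
            (4.356, 8.14, 0.617),   # strongly mediolateral deep temporal
        ],
    )
    def test_published_projections(self, f3d, phi, expected):
        assert project_to_sagittal(f3d, phi) == pytest.approx(expected, abs=2e-3)

    def test_fully_sagittal_muscle_keeps_everything(self):
        assert project_to_sagittal(3.25, 90.0) == pytest.approx(3.25)

    @given(f3d=st.floats(0, 50), phi=st.floats(0, 180))
    @settings(max_examples=100, deadline=None)
    def test_matches_radical_form_and_bounds(self, f3d, phi):
        f2d = project_to_sagittal(f3d, phi)
        # radical form: F2D^2 = F3D^2 - (F3D cos phi)^2, asserted as the
        # Pythagorean identity (stable even where the subtraction cancels)
        mediolateral = f3d * math.cos(math.radians(phi))
        assert f2d**2 + mediolateral**2 == pytest.approx(
            f3d**2, rel=1e-12, abs=1e-300
        )
        assert 0.0 <= f2d <= f3d + 1e-12

    def test_angle_domain_enforced(self):
        with pytest.raises(InvalidInputError):
            project_to_sagittal(1.0, -5.0)
        with pytest.raises(InvalidInputError):
            project_to_sagittal(1.0, 180.5)


class TestResultant:
    def test_action_through_joint_contributes_nothing(self):
        assert resultant_at_bite_point(5.0, 0.0, 7.0, 12.0) == 0.0

    def test_closed_form(self):
        assert resultant_at_bite_point(4.0, 30.0, 5.0, 10.0) == pytest.approx(1.0)

    def test_scale_invariance_of_lever_ratio(self):
        a = resultant_at_bite_point(4.0, 30.0, 5.0, 10.0)
        b = resultant_at_bite_point(4.0, 30.0, 10.0, 20.0)
        assert a == pytest.approx(b, rel=1e-12)

    def test_division_guard(self):
        with pytest.raises(InvalidInputError):
            resultant_at_bite_point(4.0, 30.0, 5.0, 0.0)


class TestTotalBiteForce:
    def test_published_closed_mouth_totals(self, planar_m2851):
        """Bilateral sums over the 11 closers match the published study."""
        for bp in ("incisor", "m4"):
            res = planar_m2851.bite_force(bp)
            assert res.total_force == pytest.approx(
                study_record(bp, "M2851")["fcalc_closed"], abs=0.02
            )
            assert res.excluded == ("PtLat",)

    def test_single_closer_doubles(self):
        model = PlanarModel(
            muscles=(PlanarMuscle("m", 2.0, 90.0, 30.0, 5.0),),
            d_cbp={"bp": 10.0},
        )
        # R = 5 * sin30 * 2 / 10 = 0.5 -> doubled
        assert model.bite_force("bp").total_force == pytest.approx(1.0)

    def test_total_is_twice_sum_of_contributions(self, planar_m2851):
        res = planar_m2851.bite_force("m4")
        assert res.total_force == pytest.approx(
            2.0 * sum(res.per_muscle.values()), abs=1e-9
        )

    def test_all_openers_is_model_error(self):
        model = PlanarModel(
            muscles=(PlanarMuscle("m", 2.0, 90.0, 30.0, 5.0),),
            d_cbp={"bp": 10.0},
            openers=frozenset({"m"}),
        )
        with pytest.raises(ModelError):
            model.bite_force("bp")

    def test_anterior_bite_point_is_weaker(self, planar_m2851):
        """Longer out-lever (incisor) must transmit less force than the molar."""
        f_i = planar_m2851.bite_force("incisor").total_force
        f_m = planar_m2851.bite_force("m4").total_force
        assert f_i < f_m

    @given(scale=st.floats(0.1, 10.0))
    @settings(max_examples=30, deadline=None)
    def test_linearity_in_muscle_stress(self, scale):
        """Scaling the stress (hence every F3Dmax) scales Fcalc exactly."""
        import jawlever.reference as reference

        model = reference.planar_model_m2851()
        base = model.bite_force("m4").total_force
        scaled = PlanarModel(
            muscles=tuple(
                PlanarMuscle(m.muscle, m.f3dmax * scale, m.phi, m.theta, m.lever)
                for m in model.muscles
            ),
            d_cbp=dict(model.d_cbp),
            openers=model.openers,
        )
        assert scaled.bite_force("m4").total_force == pytest.approx(
            scale * base, rel=1e-12
        )


class TestGeometryAgreement:
    def test_matches_cross_product_oracle_on_random_geometries(self):
        """Moment-balance path equals explicit 3D cross products to 1e-9."""
        rng = np.random.default_rng(20240917)
        for _ in range(100):
            geom = random_landmark_geometry(rng)
            forces = {m: float(rng.uniform(0.5, 10.0)) for m in geom.muscles}
            mech = mechanics_from_geometry(geom, forces)
            ours = total_bite_force(mech, "bp").total_force
            assert ours == pytest.approx(
                oracle_bite_force(geom, forces, "bp"), abs=1e-9
            )

    def test_architecture_and_force_inputs_agree(self, ref_geometry, arch_m2851,
                                                 constants, ref_forces):
        from jawlever import compute_f3dmax

        closers = [a for a in arch_m2851 if a.name != "Di"]
        mech_arch = mechanics_from_geometry(ref_geometry, closers, constants)
        by_arch = {m.muscle: m.f3dmax for m in mech_arch}
        for a in closers:
            assert by_arch[a.name] == pytest.approx(
                compute_f3dmax(a, constants), rel=1e-12
            )


def test_planar_csv_reader(tmp_path, planar_m2851):
    path = tmp_path / "planar.csv"
    import pandas as pd

    pd.DataFrame(
        [
            {"muscle": m.muscle, "f3dmax_N": m.f3dmax, "phi_deg": m.phi,
             "theta_deg": m.theta, "lever_mm": m.lever}
            for m in planar_m2851.muscles
        ]
    ).to_csv(path, index=False)
    model = read_planar_csv(path, planar_m2851.d_cbp, planar_m2851.openers)
    assert model.bite_force("m4").total_force == pytest.approx(
        planar_m2851.bite_force("m4").total_force, rel=1e-12
    )
    bad = tmp_path / "bad.csv"
    bad.write_text("muscle,f3dmax_N\nMS,7\n")
    with pytest.raises(SchemaError, match="phi_deg"):
        read_planar_csv(bad, {"m4": 10.0})
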