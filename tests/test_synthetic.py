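import numpy as np
import pytest

from jawlever import (
    GeometrySpec,
    InvalidInputError,
    MuscleTarget,
    compute_pcsa,
    architecture_from_frame,
    derive_action_line,
    distance_to_bite_point,
    generate_architecture,
    generate_geometry,
    mechanics_from_geometry,
    spec_from_planar,
    total_bite_force,
)
from jawlever.reference import OUT_LEVER_RATIO


class TestGenerateGeometry:
    def test_round_trip_of_published_angle_targets(self, planar_m2851):
        """Every (phi, theta, lever) target is recovered to < 1e-6 degrees."""
        geom = generate_geometry(spec_from_planar(planar_m2851))
        for pm in planar_m2851.muscles:
            line = derive_action_line(geom, pm.muscle)
            assert line.phi == pytest.approx(pm.phi, abs=1e-6)
            assert line.theta == pytest.approx(pm.theta, abs=1e-6)
            assert line.lever == pytest.approx(pm.lever, rel=1e-9)
            expected_sign = 1 if pm.muscle in planar_m2851.openers else -1
            assert line.moment_sign == expected_sign
        for bp, d in planar_m2851.d_cbp.items():
            assert distance_to_bite_point(geom, bp) == pytest.approx(d, rel=1e-9)

    def test_same_seed_same_coordinates(self):
        spec = GeometrySpec(
            muscles={"a": MuscleTarget(60.0, 70.0, 5.0)},
            d_cbp={"bp": 10.0},
            noise_sd=0.05,
            seed=7,
        )
        g1, g2 = generate_geometry(spec), generate_geometry(spec)
        np.testing.assert_array_equal(g1.origins["a"], g2.origins["a"])
        np.testing.assert_array_equal(g1.insertions["a"], g2.insertions["a"])

    def test_noise_perturbs_but_different_seeds_differ(self):
        base = dict(
            muscles={"a": MuscleTarget(60.0, 70.0, 5.0)}, d_cbp={"bp": 10.0},
            noise_sd=0.05,
        )
        g1 = generate_geometry(GeometrySpec(**base, seed=1))
        g2 = generate_geometry(GeometrySpec(**base, seed=2))
        assert not np.allclose(g1.origins["a"], g2.origins["a"])

    def test_out_lever_ratio_sets_bite_force_ratio(self, planar_m2851):
        """Fcalc scales as 1/out-lever: the incisor/molar force ratio is the
        inverse of the out-lever ratio."""
        geom = generate_geometry(spec_from_planar(planar_m2851))
        forces = {m.muscle: m.f3dmax for m in planar_m2851.muscles}
        mech = mechanics_from_geometry(geom, forces)
        f_i = total_bite_force(mech, "incisor").total_force
        f_m = total_bite_force(mech, "m4").total_force
        assert f_i / f_m == pytest.approx(1.0 / OUT_LEVER_RATIO, rel=1e-9)

    def test_full_pipeline_round_trip_matches_planar_computation(self,
                                                                 planar_m2851):
        """spec -> geometry -> equilibrium equals the direct planar path."""
        geom = generate_geometry(spec_from_planar(planar_m2851))
        forces = {m.muscle: m.f3dmax for m in planar_m2851.muscles}
        mech = mechanics_from_geometry(geom, forces)
        direct = planar_m2851.bite_force("m4")
        lifted = total_bite_force(mech, "m4")
        assert lifted.total_force == pytest.approx(direct.total_force, abs=1e-9)
        for m, r in direct.per_muscle.items():
            assert lifted.per_muscle[m] == pytest.approx(r, abs=1e-9)

    @pytest.mark.parametrize(
        "kwargs",
        [
            dict(muscles={}, d_cbp={"bp": 10.0}),
            dict(muscles={"a": MuscleTarget(60, 70, 5)}, d_cbp={}),
            dict(muscles={"a": MuscleTarget(60, 70, 5)}, d_cbp={"bp": -1.0}),
        ],
    )
    def test_invalid_specs_rejected(self, kwargs):
        with pytest.raises(InvalidInputError):
            GeometrySpec(**kwargs)

    def test_zero_lever_target_is_infeasible(self):
        with pytest.raises(InvalidInputError, match="lever"):
            MuscleTarget(60.0, 70.0, 0.0)


class TestGenerateArchitecture:
    def test_deterministic_given_seed(self):
        t1 = generate_architecture(seed=3)
        t2 = generate_architecture(seed=3)
        assert t1.equals(t2)

    def test_doubling_masses_doubles_forces(self, constants):
        from jawlever import compute_f3dmax

        df = generate_architecture(seed=5)
        doubled = df.assign(mass_g=2 * df.mass_g)
        for a, b in zip(
            architecture_from_frame(df), architecture_from_frame(doubled)
        ):
            assert compute_f3dmax(b, constants) == pytest.approx(
                2 * compute_f3dmax(a, constants), rel=1e-12
            )

    def test_thirteen_muscles_get_the_didelphid_labels(self):
        df = generate_architecture(n_muscles=13, seed=0)
        assert "MS" in set(df.muscle) and "Di" in set(df.muscle)
        assert df.loc[df.muscle == "Di", "role"].item() == "opener"
        assert set(generate_architecture(n_muscles=5, seed=0).muscle) == {
            "m01", "m02", "m03", "m04", "m05"
        }

    def test_pcsa_distribution_lands_in_the_dissection_range(self, constants):
        """Most draws fall inside the observed 0.011-0.149 cm2 band."""
        df = generate_architecture(n_muscles=1000, seed=11)
        pcsas = np.array([
            compute_pcsa(a, constants) for a in architecture_from_frame(df)
        ])
        frac = np.mean((pcsas >= 0.011) & (pcsas <= 0.149))
        assert frac >= 0.85
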