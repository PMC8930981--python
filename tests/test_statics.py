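"""Static equilibrium solver: moments, bite forces, sweeps, percent-of-max."""

import dataclasses

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

import jawstatics as js
from jawstatics.statics import StaticsError


class TestMomentAboutAxis:
    def test_cross_product_arithmetic(self):
        m = js.moment_about_axis(
            np.array([0.0, 0.0, 10.0]), js.Point3(10, 0, 0),
            js.Point3(0, 0, 0), np.array([0.0, 1.0, 0.0]),
        )
        assert m == pytest.approx(-100.0)

    def test_force_on_axis_zero(self):
        m = js.moment_about_axis(
            np.array([0.0, 0.0, 10.0]), js.Point3(0, 7, 0),
            js.Point3(0, 0, 0), np.array([0.0, 1.0, 0.0]),
        )
        assert m == pytest.approx(0.0)

    def test_force_parallel_to_position_zero(self):
        m = js.moment_about_axis(
            np.array([5.0, 0.0, 5.0]), js.Point3(1, 0, 1),
            js.Point3(0, 0, 0), np.array([0.0, 1.0, 0.0]),
        )
        assert m == pytest.approx(0.0)

    def test_non_unit_axis_rejected(self):
        with pytest.raises(StaticsError, match="unit"):
            js.moment_about_axis(
                np.zeros(3), js.Point3(0, 0, 0), js.Point3(0, 0, 0),
                np.array([0.0, 0.5, 0.0]),
            )


class TestSolveBiteForce:
    def test_planar_lever_law(self, planar_toy):
        # 30 N total at 10 mm in-lever; jaw tip 40 mm out -> 7.5 N
        sol = js.solve_bite_force(planar_toy, "jaw_tip", 0.0)
        assert sol.bite_force == pytest.approx(7.5, rel=1e-12)

    def test_out_lever_halved_force_doubled(self, planar_toy):
        # 18 mm point vs a hypothetical 36 mm one: closed form scales as 1/r
        model = dataclasses.replace(
            planar_toy,
            bite_points=(
                js.BitePoint("jaw_tip", js.Point3(20, 0, 0)),
                js.BitePoint("posterior_most", js.Point3(40, 0, 0)),
            ),
        )
        near = js.solve_bite_force(model, "jaw_tip", 0.0)
        far = js.solve_bite_force(model, "posterior_most", 0.0)
        assert near.bite_force == pytest.approx(2 * far.bite_force, rel=1e-12)
        assert near.bite_force == pytest.approx(15.0, rel=1e-12)

    @pytest.mark.parametrize("seed", range(100))
    def test_matches_brute_force_oracle(self, seed, equilibrium_oracle):
        model = js.make_random_jaw(seed=seed)
        theta = float(np.random.default_rng(seed).uniform(-25, 25))
        gape = [10.0, 30.0, 60.0][seed % 3]
        sol = js.solve_bite_force(model, "posterior_caniniform", gape, theta)
        fb, joint = equilibrium_oracle(model, "posterior_caniniform", gape, theta)
        if fb >= 0:
            assert sol.bite_force == pytest.approx(fb, rel=1e-9)
            np.testing.assert_allclose(sol.joint_force, joint, rtol=1e-9, atol=1e-9)
        else:
            assert sol.clamped and sol.bite_force == 0.0

    @pytest.mark.parametrize("gape", [0.0, 10.0, 30.0, 60.0])
    @pytest.mark.parametrize("theta", [-20.0, 0.0, 20.0])
    def test_force_and_moment_balance(self, planar_family, gape, theta):
        model, _ = planar_family
        sol = js.solve_bite_force(model, "anterior_caniniform", gape, theta)
        pose = js.open_jaw(model, gape)
        center, axis = js.joint_axis(pose)
        u = js.reaction_direction(axis, theta)
        total_f = sum(
            (js.muscle_force(m).vector() for m in pose.muscles), start=np.zeros(3)
        ) + sol.bite_force * u + sol.joint_force
        np.testing.assert_allclose(total_f, 0.0, atol=1e-9)
        bp = pose.bite_point("anterior_caniniform")
        total_m = sum(
            js.moment_about_axis(js.muscle_force(m).vector(), m.insertion, center, axis)
            for m in pose.muscles
        ) + js.moment_about_axis(sol.bite_force * u, bp.position, center, axis)
        assert abs(total_m) < 1e-9

    def test_linear_in_stress_and_acsa(self, planar_toy):
        base = js.solve_bite_force(planar_toy, "jaw_tip", 10.0, 5.0)
        double_stress = js.solve_bite_force(planar_toy, "jaw_tip", 10.0, 5.0, stress=60.0)
        assert double_stress.bite_force == pytest.approx(2 * base.bite_force, rel=1e-12)
        doubled = dataclasses.replace(
            planar_toy,
            muscles=tuple(
                dataclasses.replace(m, acsa=2 * m.acsa) for m in planar_toy.muscles
            ),
        )
        assert js.solve_bite_force(doubled, "jaw_tip", 10.0, 5.0).bite_force == (
            pytest.approx(2 * base.bite_force, rel=1e-12)
        )

    def test_geometric_scale_invariance(self):
        model = js.make_random_jaw(seed=5)
        s = 3.7

        def scale_pt(p):
            return js.Point3(s * p.x, s * p.y, s * p.z)

        scaled = dataclasses.replace(
            model,
            joint_left=scale_pt(model.joint_left),
            joint_right=scale_pt(model.joint_right),
            muscles=tuple(
                dataclasses.replace(
                    m, origin=scale_pt(m.origin), insertion=scale_pt(m.insertion)
                )
                for m in model.muscles
            ),
            bite_points=tuple(
                js.BitePoint(bp.label, scale_pt(bp.position)) for bp in model.bite_points
            ),
        )
        a = js.solve_bite_force(model, "jaw_tip", 30.0, 10.0)
        b = js.solve_bite_force(scaled, "jaw_tip", 30.0, 10.0)
        assert b.bite_force == pytest.approx(a.bite_force, rel=1e-9)

    def test_opening_orientation_clamped_to_zero(self, planar_toy):
        flipped = dataclasses.replace(
            planar_toy,
            muscles=tuple(
                dataclasses.replace(
                    m, origin=js.Point3(m.origin.x, m.origin.y, -m.origin.z)
                )
                for m in planar_toy.muscles
            ),
        )
        sol = js.solve_bite_force(flipped, "jaw_tip", 0.0)
        assert sol.clamped and sol.bite_force == 0.0

    def test_reaction_through_joint_unsolvable(self, planar_toy):
        # at 60 deg gape a -30 deg reaction passes through the hinge axis
        with pytest.raises(StaticsError, match="moment arm"):
            js.solve_bite_force(planar_toy, "jaw_tip", 60.0, -30.0)

    def test_unilateral_model_warns(self):
        m = js.JawModel(
            joint_left=js.Point3(0, 4, 0),
            joint_right=js.Point3(0, -4, 0),
            muscles=(
                js.MuscleBundle(
                    "m1", "external_adductor", "left",
                    origin=js.Point3(8, 3, 15), insertion=js.Point3(10, 3, 0), acsa=1.0,
                ),
            ),
            bite_points=(js.BitePoint("jaw_tip", js.Point3(30, 0, 0)),),
        )
        with pytest.warns(UserWarning, match="one side"):
            js.solve_bite_force(m, "jaw_tip", 0.0)

    def test_bad_orientation_range_rejected(self):
        with pytest.raises(StaticsError):
            js.ReactionOrientation(90.0)


class TestRunSimulation:
    def test_default_cardinality_single_point(self, planar_toy):
        model = dataclasses.replace(planar_toy, bite_points=planar_toy.bite_points[:1])
        df = js.run_simulation(model)
        assert len(df) == 3 * 1 * 13  # 3 gapes x 1 point x 13 orientations

    def test_acsa_doubling_scales_all_forces(self, planar_toy):
        df = js.run_simulation(planar_toy)
        doubled = dataclasses.replace(
            planar_toy,
            muscles=tuple(
                dataclasses.replace(m, acsa=2 * m.acsa) for m in planar_toy.muscles
            ),
        )
        df2 = js.run_simulation(doubled)
        ok = df["bite_force_N"].notna()
        np.testing.assert_allclose(
            df2.loc[ok, "bite_force_N"], 2 * df.loc[ok, "bite_force_N"], rtol=1e-12
        )

    def test_vertical_bite_force_non_increasing_in_gape(self, planar_family):
        # dorsal posterior origins: at the vertical orientation the closed
        # form says force declines with gape at every bite point
        model, expected = planar_family
        for label in ("jaw_tip", "posterior_most"):
            forces = [expected[(label, g)] for g in (10.0, 30.0, 60.0)]
            assert forces == sorted(forces, reverse=True)
            solved = [
                js.solve_bite_force(model, label, g).bite_force
                for g in (10.0, 30.0, 60.0)
            ]
            np.testing.assert_allclose(solved, forces, rtol=1e-9)

    def test_errors_recorded_as_row_status(self, planar_toy):
        df = js.run_simulation(planar_toy)
        failed = df[df["status"].str.startswith("error")]
        assert len(failed) > 0  # gape 60 / -30 deg passes through the hinge
        assert df["bite_force_N"].notna().sum() == len(df) - len(failed)

    def test_per_condition_max_flagged(self, planar_toy):
        df = js.run_simulation(planar_toy)
        for (_, _), grp in df.groupby(["gape_deg", "bite_point"]):
            flagged = grp[grp["is_max"]]
            assert len(flagged) == 1
            assert flagged["bite_force_N"].iloc[0] == grp["bite_force_N"].max()

    def test_out_lever_law_across_collinear_points(self, planar_toy):
        df = js.run_simulation(
            planar_toy, js.SimulationConfig(gapes_deg=(0.0,), orientation_max_deg=0.0,
                                            orientation_min_deg=0.0)
        )
        levers = {"jaw_tip": 40.0, "anterior_caniniform": 32.0,
                  "posterior_caniniform": 24.0, "posterior_most": 18.0}
        products = [
            row.bite_force_N * levers[row.bite_point] for row in df.itertuples()
        ]
        np.testing.assert_allclose(products, products[0], rtol=1e-12)


class TestPercentOfMax:
    def _table(self, forces):
        return pd.DataFrame(
            {
                "bite_point": [bp for bp, _, _ in forces],
                "gape_deg": [g for _, g, _ in forces],
                "orientation_deg": 0.0,
                "bite_force_N": [f for _, _, f in forces],
                "joint_force_N": 0.0,
                "joint_angle_deg": 0.0,
                "status": "ok",
                "is_max": False,
            }
        )

    def test_printed_force_ratio_56(self):
        df = self._table([("posterior_most", 10.0, 256.0), ("jaw_tip", 10.0, 143.0)])
        out = js.percent_of_max(df)
        assert out.loc[out.bite_point == "jaw_tip", "pct_of_max"].item() == 56
        assert out.loc[out.bite_point == "posterior_most", "pct_of_max"].item() == 100

    def test_printed_force_ratio_89(self):
        df = self._table([("posterior_most", 10.0, 256.0), ("posterior_most", 30.0, 229.0)])
        out = js.percent_of_max(df)
        assert out.loc[out.gape_deg == 30.0, "pct_of_max"].item() == 89

    def test_single_row_is_100(self):
        out = js.percent_of_max(self._table([("jaw_tip", 10.0, 42.0)]))
        assert out["pct_of_max"].item() == 100

    def test_empty_rejected(self):
        with pytest.raises(StaticsError):
            js.percent_of_max(self._table([]))

    @given(st.lists(st.floats(1.0, 500.0), min_size=1, max_size=12))
    def test_percent_bounds_and_max_row(self, forces):
        df = self._table([("jaw_tip", 10.0, f) for f in forces])
        out = js.percent_of_max(df)
        assert out["pct_of_max"].max() == 100
        assert (out["pct_of_max"] >= 0).all() and (out["pct_of_max"] <= 100).all()
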