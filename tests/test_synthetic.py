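"""Neutral-landscape generator and change-operator semantics."""

import numpy as np
import pytest

from forestfrag import (OPERATOR_EFFECTS, OperatorStep, ScenarioSpec,
                        apply_operator, generate_initial_map,
                        generate_scenario, label_patches)
from forestfrag.metrics import compute_cell_metrics


def spec(rows=80, cols=80, p=0.5, ac=0.6, seed=1, operators=()):
    return ScenarioSpec(rows=rows, cols=cols, pixel_size=30.0,
                        forest_proportion=p, autocorrelation=ac,
                        operators=list(operators), seed=seed)


class TestInitialMap:
    def test_determinism_same_seed(self):
        m1 = generate_initial_map(spec(seed=3))
        m2 = generate_initial_map(spec(seed=3))
        np.testing.assert_array_equal(m1.values, m2.values)

    def test_distinct_seeds_differ(self):
        m1 = generate_initial_map(spec(seed=3))
        m2 = generate_initial_map(spec(seed=4))
        assert not np.array_equal(m1.values, m2.values)

    @pytest.mark.parametrize("p", [0.3, 0.5, 0.7])
    def test_realized_proportion(self, p):
        m = generate_initial_map(spec(p=p, seed=5))
        realized = m.forest_pixels / m.values.size
        assert realized == pytest.approx(p, abs=0.01)

    def test_autocorrelation_controls_clumpiness(self):
        """High autocorrelation gives fewer patches and larger MPA at equal p."""
        n_patches = {0.1: [], 0.9: []}
        mpa = {0.1: [], 0.9: []}
        for seed in range(8):
            for ac in (0.1, 0.9):
                m = generate_initial_map(spec(ac=ac, seed=100 + seed))
                lab = label_patches(m.values, pixel_size=30.0)
                n_patches[ac].append(lab.n_patches)
                mpa[ac].append(lab.patch_areas.mean())
        assert np.mean(n_patches[0.9]) < np.mean(n_patches[0.1])
        assert np.mean(mpa[0.9]) > np.mean(mpa[0.1])


class TestOperators:
    def base_map(self, seed=7, p=0.5, ac=0.7):
        return generate_initial_map(spec(p=p, ac=ac, seed=seed))

    def test_zero_intensity_identity(self):
        m = self.base_map()
        for op in OPERATOR_EFFECTS:
            out = apply_operator(m, op, 0.0, seed=1)
            np.testing.assert_array_equal(out.values, m.values)

    def test_attrition_removes_smallest_patches(self):
        m = self.base_map(seed=11, ac=0.3)
        lab = label_patches(m.values)
        n0 = lab.n_patches
        assert n0 >= 5
        # remove the 2 smallest of n0 patches
        out = apply_operator(m, "attrition", 2 / n0, seed=2)
        lab2 = label_patches(out.values)
        assert lab2.n_patches == n0 - 2
        assert lab2.patch_areas.min() >= np.sort(lab.patch_areas)[2] - 1e-12

    def test_edge_erosion_shrinks_without_new_seeds(self):
        m = self.base_map(seed=12)
        out = apply_operator(m, "edge_erosion", 0.5, seed=3)
        assert out.forest_pixels < m.forest_pixels
        # no forest appears where there was none
        assert not (out.forest_mask & ~m.forest_mask).any()

    def test_dissection_increases_patch_count(self):
        m = self.base_map(seed=13, ac=0.9)
        out = apply_operator(m, "dissection", 0.8, seed=4)
        assert label_patches(out.values).n_patches > label_patches(m.values).n_patches
        assert out.forest_pixels < m.forest_pixels

    def test_infill_grows_only_adjacent(self):
        m = self.base_map(seed=14)
        out = apply_operator(m, "infill", 0.7, seed=5)
        gained = out.forest_mask & ~m.forest_mask
        assert gained.any()
        # every gained pixel touches the original forest (4-neighbourhood)
        from forestfrag.synthetic import _neighbour_count
        assert (_neighbour_count(m.forest_mask)[gained] > 0).all()

    def test_seeding_adds_patches(self):
        m = self.base_map(seed=15, p=0.3, ac=0.8)
        out = apply_operator(m, "seeding", 0.5, seed=6)
        assert label_patches(out.values).n_patches > label_patches(m.values).n_patches

    def test_region_mask_respected(self):
        m = self.base_map(seed=16)
        region = (0, 40, 0, 80)
        out = apply_operator(m, "edge_erosion", 0.9, seed=7, region=region)
        np.testing.assert_array_equal(out.values[40:], m.values[40:])
        assert (out.values[:40] != m.values[:40]).any()

    def test_unknown_operator_rejected(self):
        with pytest.raises(ValueError, match="unknown operator"):
            apply_operator(self.base_map(), "clearcut", 0.5, seed=1)

    def test_intensity_out_of_range_rejected(self):
        with pytest.raises(ValueError, match="intensity"):
            OperatorStep("infill", 1.5)

    @pytest.mark.parametrize("operator", sorted(OPERATOR_EFFECTS))
    def test_fc_direction_matches_truth_table(self, operator):
        """Realized forest-cover change agrees with the operator's planted sign."""
        want = OPERATOR_EFFECTS[operator].get("dFC")
        hits = 0
        n_rep = 10
        for seed in range(n_rep):
            m = self.base_map(seed=200 + seed, ac=0.5)
            out = apply_operator(m, operator, 0.4, seed=[7, seed])
            dfc = out.forest_pixels - m.forest_pixels
            if want is None or np.sign(dfc) == want:
                hits += 1
        assert hits == n_rep

    def test_metric_signs_for_dissection_and_infill(self):
        """The two signature operators move all three metrics as planted,
        under the classifier's up/down convention (up = strictly positive)."""

        def updown(delta):
            return 1 if delta > 0 else -1

        for operator in ("dissection", "infill"):
            want = OPERATOR_EFFECTS[operator]
            agree = 0
            n_rep = 10
            for seed in range(n_rep):
                m = self.base_map(seed=300 + seed, ac=0.8)
                out = apply_operator(m, operator, 0.6, seed=[8, seed])
                A = m.values.size * 30.0 ** 2
                r1 = compute_cell_metrics(m.values, 30.0, A)
                r2 = compute_cell_metrics(out.values, 30.0, A)
                ok = (updown(r2["ED"] - r1["ED"]) == want["dED"]
                      and updown(r2["PD"] - r1["PD"]) == want["dPD"]
                      and updown(r2["MPA"] - r1["MPA"]) == want["dMPA"])
                agree += ok
            assert agree >= 0.9 * n_rep


class TestScenario:
    def test_empty_schedule_identity(self):
        m1, m2, truth = generate_scenario(spec(seed=20))
        np.testing.assert_array_equal(m1.values, m2.values)
        assert truth.empty
        assert (m1.epoch, m2.epoch) == (2000, 2020)

    def test_truth_table_records_planted_signs(self):
        sp = spec(seed=21, operators=[OperatorStep("dissection", 0.5),
                                      OperatorStep("infill", 0.3)])
        _, _, truth = generate_scenario(sp)
        row = truth.set_index("operator").loc["dissection"]
        assert (row["dED"], row["dPD"], row["dMPA"]) == (1, 1, -1)
        assert truth.set_index("operator").loc["infill", "dFFI"] == -1

    def test_schedule_streams_independent(self):
        """Editing an earlier entry's intensity does not change which pixels a
        later operator draws (named per-index streams)."""
        base = [OperatorStep("edge_erosion", 0.1, (0, 40, 0, 80)),
                OperatorStep("seeding", 0.3, (40, 80, 0, 80))]
        alt = [OperatorStep("edge_erosion", 0.2, (0, 40, 0, 80)),
               OperatorStep("seeding", 0.3, (40, 80, 0, 80))]
        _, m2a, _ = generate_scenario(spec(seed=22, operators=base))
        _, m2b, _ = generate_scenario(spec(seed=22, operators=alt))
        # lower half (seeding region) identical despite upper-half change
        np.testing.assert_array_equal(m2a.values[40:], m2b.values[40:])

    def test_yaml_roundtrip(self, tmp_path):
        path = tmp_path / "spec.yaml"
        path.write_text(
            "rows: 40\ncols: 40\npixel_size: 30\nforest_proportion: 0.4\n"
            "autocorrelation: 0.5\nseed: 9\noperators:\n"
            "  - operator: dissection\n    intensity: 0.4\n"
            "    region: [0, 20, 0, 40]\n")
        sp = ScenarioSpec.from_yaml(path)
        assert sp.operators[0].operator == "dissection"
        assert sp.operators[0].region == (0, 20, 0, 40)
        m1, m2, _ = generate_scenario(sp)
        assert m1.shape == (40, 40)

    def test_bad_operator_name_in_yaml(self, tmp_path):
        path = tmp_path / "spec.yaml"
        path.write_text("rows: 10\ncols: 10\noperators:\n"
                        "  - operator: bulldoze\n    intensity: 0.5\n")
        with pytest.raises(ValueError, match="bulldoze"):
            ScenarioSpec.from_yaml(path)
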