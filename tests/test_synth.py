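"""Synthetic study generator: trees, groups, traits, outlines, rasters."""

import numpy as np
import pytest

from caudalmorph.efa import efa_decompose, efa_normalize
from caudalmorph.outlines import extract_outline
from caudalmorph.synth import (ShapeParams, assign_convergent_groups,
                               is_monophyletic, make_study_like_dataset,
                               rasterize_outline, simulate_group_traits,
                               simulate_yule_tree, synth_pygostyle_outline,
                               write_bundle)


class TestYuleTree:
    def test_tip_count_and_labels(self):
        t = simulate_yule_tree(8, seed=1)
        assert t.n_tips == 8
        assert len(set(t.tips)) == 8

    def test_deterministic(self):
        assert simulate_yule_tree(12, seed=4).to_newick() == \
            simulate_yule_tree(12, seed=4).to_newick()

    def test_unit_depth(self):
        t = simulate_yule_tree(20, seed=5)
        assert np.allclose(t.node_depths()[:20], 1.0, atol=1e-9)

    def test_minimum_size_enforced(self):
        with pytest.raises(ValueError):
            simulate_yule_tree(2, seed=1)


class TestGroups:
    def test_single_origin_is_monophyletic(self):
        t = simulate_yule_tree(32, seed=6)
        g = assign_convergent_groups(t, 3, {"a": 1, "b": 1, "rest": 1}, 7)
        members = set(g.mapping[g.mapping == "a"].index)
        if len(members) > 1:
            assert is_monophyletic(t, members)

    def test_multiple_origins_not_monophyletic(self):
        t = simulate_yule_tree(48, seed=8)
        g = assign_convergent_groups(t, 3, {"diver": 4, "a": 1, "rest": 1}, 9)
        divers = set(g.mapping[g.mapping == "diver"].index)
        assert not is_monophyletic(t, divers)

    def test_every_tip_labelled_once(self):
        t = simulate_yule_tree(24, seed=10)
        g = assign_convergent_groups(t, 4, {"a": 2, "b": 1, "c": 1, "d": 1}, 11)
        assert sorted(g.mapping.index) == sorted(t.tips)
        assert g.mapping.notna().all()


class TestGroupTraits:
    def test_deterministic(self):
        t = simulate_yule_tree(16, seed=12)
        g = assign_convergent_groups(t, 2, {"a": 1, "b": 1}, 13)
        A = simulate_group_traits(t, g, 2.0, 0.5, 3, 14)
        B = simulate_group_traits(t, g, 2.0, 0.5, 3, 14)
        assert np.array_equal(A.to_numpy(), B.to_numpy())

    def test_group_mean_separation(self):
        t = simulate_yule_tree(40, seed=15)
        g = assign_convergent_groups(t, 3, {"a": 1, "b": 1, "c": 1}, 16)
        X = simulate_group_traits(t, g, 8.0, 0.0, 3, 17)
        means = X.groupby(g.mapping).mean()
        for i in range(len(means)):
            for j in range(i + 1, len(means)):
                d = np.linalg.norm(means.iloc[i] - means.iloc[j])
                assert d == pytest.approx(8.0, rel=0.35)

    def test_zero_effect_zero_shift(self):
        t = simulate_yule_tree(16, seed=18)
        g = assign_convergent_groups(t, 2, {"a": 1, "b": 1}, 19)
        from caudalmorph.phylo import simulate_bm
        from caudalmorph.synth import _subseed

        X = simulate_group_traits(t, g, 0.0, 1.0, 2, 20)
        resid = simulate_bm(t, np.eye(2), 1.0, _subseed(20, 1))
        assert np.allclose(X.to_numpy(), resid.to_numpy())


class TestOutlineFamily:
    def test_wellformed_closed_polygon(self):
        o = synth_pygostyle_outline(ShapeParams())
        assert len(o.points) >= 128
        assert o.signed_area() > 0

    def test_elongation_monotone_in_aspect_ratio(self):
        aspects = []
        for e in (1.2, 1.8, 2.4, 3.0, 3.6):
            o = synth_pygostyle_outline(ShapeParams(elongation=e))
            pts = o.points
            aspects.append(np.ptp(pts[:, 0]) / np.ptp(pts[:, 1]))
        assert np.all(np.diff(aspects) > 0)

    def test_constriction_halves_mid_width(self):
        def mid_width(c):
            o = synth_pygostyle_outline(ShapeParams(elongation=2.0, constriction=c))
            pts = o.points
            x = pts[:, 0]
            mid = np.abs(x - (x.min() + x.max()) / 2) < 0.03 * np.ptp(x)
            return np.ptp(pts[mid, 1])

        ratio = mid_width(0.5) / mid_width(0.0)
        assert ratio == pytest.approx(0.5, abs=0.05)

    def test_invalid_params_rejected(self):
        with pytest.raises(ValueError):
            ShapeParams(elongation=-1.0)
        with pytest.raises(ValueError):
            ShapeParams(taper=1.5)
        with pytest.raises(ValueError):
            ShapeParams(constriction=1.0)


class TestRasterize:
    def test_area_conserved(self):
        o = synth_pygostyle_outline(ShapeParams(elongation=2.0))
        img = rasterize_outline(o, 150.0)
        ratio = img.sum() / (150.0**2 * o.signed_area())
        assert 0.98 <= ratio <= 1.02

    def test_round_trip_descriptors(self):
        o = synth_pygostyle_outline(ShapeParams(elongation=2.0, taper=0.4,
                                                deflection=0.2))
        img = rasterize_outline(o, 150.0)
        back = extract_outline(img)
        d_src = efa_normalize(efa_decompose(o, 8))
        d_back = efa_normalize(efa_decompose(back, 8))
        assert np.abs(d_src.coeffs - d_back.coeffs).max() < 2e-2

    def test_circle_round_trip(self, circle_outline):
        img = rasterize_outline(circle_outline, 150.0)  # 300 px diameter
        back = extract_outline(img)
        d_src = efa_normalize(efa_decompose(circle_outline, 6))
        d_back = efa_normalize(efa_decompose(back, 6))
        assert np.abs(d_src.coeffs - d_back.coeffs).max() < 1e-2

    def test_resolution_too_low_rejected(self, circle_outline):
        with pytest.raises(ValueError, match="resolution"):
            rasterize_outline(circle_outline, 2.0)


class TestBundle:
    def test_contract(self, study_bundle):
        b = study_bundle
        assert b.tree.n_tips == 51
        assert len(set(b.groups.mapping)) == 5
        counts = b.specimen_species.value_counts()
        assert counts.min() >= 2 and counts.max() <= 4
        assert set(b.measurements["position"]) == {"first", "middle", "last"}

    def test_deterministic(self, study_bundle):
        again = make_study_like_dataset(51, seed=1)
        sid = sorted(study_bundle.outlines)[0]
        assert np.array_equal(study_bundle.outlines[sid].points,
                              again.outlines[sid].points)
        assert study_bundle.tree.to_newick() == again.tree.to_newick()

    def test_divers_convergent_in_default_bundle(self, study_bundle):
        m = study_bundle.groups.mapping
        divers = set(m[m == "Wing-Propelled Pursuit Dive"].index)
        assert not is_monophyletic(study_bundle.tree, divers)

    def test_write_round_trip(self, tmp_path, study_bundle):
        write_bundle(study_bundle, tmp_path)
        assert (tmp_path / "tree.nwk").exists()
        assert (tmp_path / "groups.csv").exists()
        assert len(list((tmp_path / "outlines").glob("*.csv"))) == \
            len(study_bundle.outlines)
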