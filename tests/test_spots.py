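"""Spot detection, summary map, profiles and frequencies."""

import numpy as np
import pytest

import combisom as cs
from combisom import Modality


def _p(grid, kind="Gex", subject="grp"):
    return cs.Portrait(np.asarray(grid, dtype=float), kind, subject)


def _plateau(shape, blocks, value=1.0):
    g = np.zeros(shape)
    for (r0, r1, c0, c1) in blocks:
        g[r0:r1, c0:c1] = value
    return g


class TestDetect:
    def test_single_plateau(self):
        grid = _plateau((8, 8), [(2, 5, 2, 5)])
        spots = cs.detect_spots(_p(grid), 0.9, "over")
        assert len(spots) == 1
        assert spots[0].n_units == 9

    def test_two_separated_plateaus(self):
        grid = _plateau((10, 10), [(0, 2, 0, 2), (6, 9, 6, 9)])
        spots = cs.detect_spots(_p(grid), 0.9, "over")
        assert len(spots) == 2

    def test_under_sign_mirrors(self):
        grid = -_plateau((8, 8), [(1, 4, 1, 4)])
        assert len(cs.detect_spots(_p(grid), 0.9, "under")) == 1
        assert cs.detect_spots(_p(grid), 0.9, "over") == []

    def test_min_size_filters_speckle(self):
        grid = np.zeros((8, 8))
        grid[0, 0] = 1.0  # single-cell speckle
        assert cs.detect_spots(_p(grid), 0.9, "over", min_size=3) == []

    def test_threshold_fraction_bounds(self):
        with pytest.raises(ValueError, match="threshold_fraction"):
            cs.detect_spots(_p(np.ones((4, 4))), 1.5, "over")

    def test_nonpositive_max_warns_empty(self, caplog):
        with caplog.at_level("WARNING"):
            out = cs.detect_spots(_p(-np.ones((4, 4))), 0.9, "over")
        assert out == []
        assert "not positive" in caplog.text

    def test_matches_flood_fill_oracle(self, rng):
        """Components identical to an exhaustive BFS flood fill."""
        from scipy import ndimage

        raw = rng.normal(size=(16, 16))
        smooth = ndimage.gaussian_filter(raw, sigma=2.0)
        spots = cs.detect_spots(_p(smooth), 0.8, "over", min_size=1)
        mask = smooth >= 0.8 * smooth.max()
        # BFS with 8-neighbourhood
        seen = np.zeros_like(mask, dtype=bool)
        comps = []
        for i in range(16):
            for j in range(16):
                if mask[i, j] and not seen[i, j]:
                    comp, stack = set(), [(i, j)]
                    seen[i, j] = True
                    while stack:
                        r, c = stack.pop()
                        comp.add(r * 16 + c)
                        for dr in (-1, 0, 1):
                            for dc in (-1, 0, 1):
                                rr, cc = r + dr, c + dc
                                if 0 <= rr < 16 and 0 <= cc < 16 and mask[rr, cc] and not seen[rr, cc]:
                                    seen[rr, cc] = True
                                    stack.append((rr, cc))
                    comps.append(frozenset(comp))
        assert {s.member_units for s in spots} == set(comps)

    def test_threshold_monotonicity(self, rng):
        """Raising the threshold never increases the selected cell count."""
        from scipy import ndimage

        smooth = ndimage.gaussian_filter(rng.normal(size=(14, 14)), sigma=1.5)
        counts = []
        for frac in (0.5, 0.6, 0.7, 0.8, 0.9):
            spots = cs.detect_spots(_p(smooth), frac, "over")
            counts.append(sum(s.n_units for s in spots))
        assert counts == sorted(counts, reverse=True)


def _toy_model(grid_side, assignment):
    n = grid_side**2
    return cs.SOMModel(
        grid_side=grid_side,
        unit_vectors=np.zeros((n, 6)),
        weights=cs.weight_preset("balanced"),
        gene_ids=tuple(assignment),
        assignment=dict(assignment),
        training_config=cs.TrainingConfig(),
        sample_ids=("s0", "s1"),
    )


class TestSummaryMap:
    def test_single_plateau_labelled_a(self):
        model = _toy_model(8, {"g0": 0})
        grid = _plateau((8, 8), [(2, 5, 2, 5)])
        label_grid, spots = cs.spot_summary_map([_p(grid)], model)
        assert [s.label for s in spots] == ["A"]
        assert (label_grid > 0).sum() == 9

    def test_clockwise_labelling(self):
        model = _toy_model(10, {"g0": 0})
        grid = _plateau((10, 10), [(0, 2, 0, 2)]) + _plateau((10, 10), [(7, 10, 7, 10)])
        _, spots = cs.spot_summary_map([_p(grid)], model)
        by_label = {s.label: s for s in spots}
        # top-left quadrant comes first in the clockwise order
        assert min(by_label["A"].member_units) < min(by_label["B"].member_units)

    def test_gene_membership_matches_assignment(self):
        assignment = {"g0": 18, "g1": 19, "g2": 0, "g3": 18}
        model = _toy_model(8, assignment)
        grid = np.zeros((8, 8))
        grid[2, 2:5] = 1.0  # units 18,19,20
        _, spots = cs.spot_summary_map([_p(grid)], model)
        (spot,) = spots
        # a gene is a member iff its BMU is a member unit
        for g, u in assignment.items():
            assert (g in spot.member_genes) == (u in spot.member_units)

    def test_planted_module_recovery(self, cohort, model, summary_spots):
        """Every planted module of the default cohort maps to exactly one
        detected spot with gene-membership Jaccard >= 0.8."""
        _, truth = cohort
        _, spots = summary_spots
        best_of = {}
        for name in [m.name for m in truth.config.modules]:
            planted = set(truth.module_genes(name))
            js = [
                len(planted & set(s.member_genes)) / len(planted | set(s.member_genes))
                for s in spots
            ]
            best = int(np.argmax(js))
            assert js[best] >= 0.8, f"{name}: best Jaccard {js[best]:.2f}"
            best_of[name] = best
        assert len(set(best_of.values())) == 5  # one distinct spot per module


class TestSpotDerived:
    def test_profiles_singleton_unit(self, rng):
        dec = {m: rng.normal(size=(9, 4)) for m in cs.MODALITIES}
        spot = cs.SpotModule(sign="over", member_units=frozenset({5}))
        prof = cs.spot_profiles(spot, dec)
        np.testing.assert_array_equal(prof[Modality.GEX], dec[Modality.GEX][5])

    def test_profiles_mean_loop_oracle(self, rng):
        dec = {m: rng.normal(size=(9, 4)) for m in cs.MODALITIES}
        units = frozenset({1, 3, 7})
        prof = cs.spot_profiles(cs.SpotModule(sign="over", member_units=units), dec)
        manual = sum(dec[Modality.DME][u] for u in sorted(units)) / 3
        np.testing.assert_allclose(prof[Modality.DME], manual, atol=1e-12)

    def test_profiles_nan_for_zero_weight_modality(self, rng):
        dec = {
            Modality.GEX: rng.normal(size=(9, 4)),
            Modality.DME: rng.normal(size=(9, 4)),
            Modality.CNV: np.full((9, 4), np.nan),
        }
        prof = cs.spot_profiles(cs.SpotModule(sign="over", member_units=frozenset({0})), dec)
        assert np.isnan(prof[Modality.CNV]).all()

    def test_correlation_identical_modalities(self, rng):
        vals = rng.normal(size=(6, 8))
        spot = cs.SpotModule(
            sign="over", member_units=frozenset({0}),
            member_genes=tuple(f"g{i}" for i in range(6)),
        )
        _, r = cs.spot_correlation(spot, vals, vals, [f"g{i}" for i in range(6)])
        assert r == pytest.approx(1.0)

    def test_correlation_too_few_genes(self, rng):
        vals = rng.normal(size=(2, 4))
        spot = cs.SpotModule(
            sign="over", member_units=frozenset({0}), member_genes=("g0", "g1")
        )
        with pytest.raises(ValueError, match="fewer than 3"):
            cs.spot_correlation(spot, vals, vals, ["g0", "g1"])

    def test_anticoupled_module_strongly_negative(self):
        """A heterogeneous repressive module with low noise yields r <= -0.9
        between per-gene mean methylation and expression."""
        cfg = cs.default_config()
        cfg.module_loading_spread = 0.4
        cfg.noise_sd = {m: 0.05 for m in cs.MODALITIES}
        cfg.low_purity_fraction = 0.0
        cfg.gradient_amplitude = 0.0  # isolate the repressive coupling
        ds, truth = cs.generate(cfg, seed=5)
        genes = truth.module_genes("rtk-like-hyperMe")
        spot = cs.SpotModule(
            sign="over", member_units=frozenset({0}), member_genes=genes
        )
        cent = cs.centralize_dataset(ds)
        wt = [a.sample_id for a in ds.annotations if a.group_label == "IDH-wt-like"]
        cols = [list(ds.sample_ids).index(s) for s in wt]
        _, r = cs.spot_correlation(
            spot, cent.dme.values, cent.gex.values, ds.gene_ids, cols
        )
        assert r <= -0.9

    def test_frequencies_identical_portraits(self):
        grid = _plateau((6, 6), [(0, 2, 0, 2)])
        portraits = {f"s{j}": _p(grid, subject=f"s{j}") for j in range(4)}
        table = cs.spot_frequencies(portraits, {"G": [f"s{j}" for j in range(4)]})
        assert table.fractions["G"] == {1: 1.0}

    def test_frequencies_sum_to_one_and_match_loop(self, rng):
        from scipy import ndimage

        portraits = {}
        for j in range(6):
            g = ndimage.gaussian_filter(rng.normal(size=(10, 10)), 1.5)
            portraits[f"s{j}"] = _p(g, subject=f"s{j}")
        groups = {"G1": ["s0", "s1", "s2"], "G2": ["s3", "s4", "s5"]}
        table = cs.spot_frequencies(portraits, groups, 0.7)
        for g, members in groups.items():
            assert sum(table.fractions[g].values()) == pytest.approx(1.0)
            for s in members:
                n = len(cs.detect_spots(portraits[s], 0.7, "over")) + len(
                    cs.detect_spots(portraits[s], 0.7, "under")
                )
                assert n in table.fractions[g]
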