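"""Centralization, harmonization, weighted combination and decomposition."""

import numpy as np
import pytest

import combisom as cs
from combisom import Modality

from conftest import make_dataset, make_matrix


class TestCentralize:
    def test_row_mean_removed(self):
        m = make_matrix(Modality.GEX, [[2.0, 4.0, 6.0], [5.0, 5.0, 5.0]])
        c = cs.centralize(m)
        np.testing.assert_allclose(c.values[0], [-2.0, 0.0, 2.0])
        np.testing.assert_allclose(c.values[1], [0.0, 0.0, 0.0])
        assert c.centralized

    def test_random_matrix_vs_loop_oracle(self, rng):
        vals = rng.normal(size=(10, 6)) * 3 + 1
        c = cs.centralize(make_matrix(Modality.DME, vals))
        # independent per-row loop
        for i in range(10):
            expected = [vals[i, j] - sum(vals[i]) / 6 for j in range(6)]
            np.testing.assert_allclose(c.values[i], expected, atol=1e-12)
            assert abs(c.values[i].mean()) < 1e-12

    def test_single_sample_rejected(self):
        with pytest.raises(ValueError, match="two samples"):
            cs.centralize(make_matrix(Modality.GEX, [[1.0]]))

    def test_double_centralization_rejected(self):
        m = cs.centralize(make_matrix(Modality.GEX, [[1.0, 2.0]]))
        with pytest.raises(ValueError, match="already"):
            cs.centralize(m)


class TestHarmonize:
    def test_global_sd_division(self, rng):
        ds = cs.centralize_dataset(make_dataset(rng))
        sd_before = float(ds.gex.values.std())  # brute-force reference
        h = cs.harmonize(ds)
        np.testing.assert_allclose(h.gex.values, ds.gex.values / sd_before, rtol=1e-12)
        assert float(h.gex.values.std()) == pytest.approx(1.0, abs=1e-9)

    def test_scales_equalized_across_modalities(self, rng):
        ds = cs.centralize_dataset(make_dataset(rng))
        h = cs.harmonize(ds)
        for m in h.matrices():
            assert float(m.values.std()) == pytest.approx(1.0, abs=1e-9)

    def test_all_zero_modality_left_with_warning(self, rng, caplog):
        gex = make_matrix(Modality.GEX, np.zeros((4, 3)), centralized=True)
        base = make_dataset(rng, n_genes=4, n_samples=3)
        ds = cs.MultiOmicsDataset(
            gex, cs.centralize(base.dme), cs.centralize(base.cnv)
        )
        with caplog.at_level("WARNING"):
            h = cs.harmonize(ds)
        assert "SD is 0" in caplog.text
        assert (h.gex.values == 0).all()

    def test_uncentralized_rejected(self, rng):
        with pytest.raises(ValueError, match="centralized"):
            cs.harmonize(make_dataset(rng))

    def test_scale_equivariance(self, rng):
        """Multiplying a raw modality by any positive constant leaves its
        harmonized matrix unchanged."""
        ds = make_dataset(rng)
        scaled = cs.MultiOmicsDataset(
            make_matrix(Modality.GEX, ds.gex.values * 7.3,
                        genes=list(ds.gene_ids), samples=list(ds.sample_ids)),
            ds.dme, ds.cnv,
        )
        h1 = cs.harmonize(cs.centralize_dataset(ds))
        h2 = cs.harmonize(cs.centralize_dataset(scaled))
        np.testing.assert_allclose(h1.gex.values, h2.gex.values, atol=1e-12)


def _harmonized(rng, n_genes=12, n_samples=6):
    return cs.harmonize(cs.centralize_dataset(make_dataset(rng, n_genes, n_samples)))


class TestCombine:
    def test_block_scaling_example(self):
        gex = make_matrix(Modality.GEX, [[1.0, 0.0]], centralized=False)
        # build a dataset-like combine by hand: use the documented block rule
        ds = _manual_harmonized([[1.0, 0.0]], [[0.0, 1.0]], [[1.0, 1.0]])
        prof = cs.combine(ds, cs.WeightConfig(1 / 3, 1 / 3, 1 / 3))
        np.testing.assert_allclose(
            prof.vectors[0], np.array([1, 0, 0, 1, 1, 1]) / 3, atol=1e-12
        )

    def test_single_ome_limit(self):
        ds = _manual_harmonized([[1.0, -1.0]], [[0.5, -0.5]], [[2.0, -2.0]])
        prof = cs.combine(ds, cs.WeightConfig(1.0, 0.0, 0.0))
        np.testing.assert_allclose(prof.vectors[0], [1.0, -1.0, 0, 0, 0, 0])

    def test_weight_sum_enforced(self, rng):
        with pytest.raises(ValueError, match="sum to 1"):
            cs.combine(_harmonized(rng), cs.WeightConfig(0.5, 0.4, 0.2))

    def test_combined_distance_identity(self, rng):
        """Euclidean distance between combined vectors equals
        sqrt(sum_b w_b^2 d_b^2) over per-modality distances."""
        h = _harmonized(rng)
        w = cs.WeightConfig(0.5, 0.3, 0.2)
        prof = cs.combine(h, w)
        d_combined = np.linalg.norm(prof.vectors[0] - prof.vectors[1])
        per_mod = [
            np.linalg.norm(m.values[0] - m.values[1]) for m in h.matrices()
        ]
        expected = np.sqrt(sum((wb * db) ** 2 for wb, db in zip(w.as_array(), per_mod)))
        assert d_combined == pytest.approx(expected, rel=1e-12)

    def test_weight_continuity_to_pure_gex(self, rng):
        """Combined pairwise distances converge monotonically to pure-Gex
        distances as w_e -> 1."""
        h = _harmonized(rng)
        gex_d = _pairwise(h.gex.values)
        errs = []
        for w_e in (1 / 3, 0.6, 0.9, 1.0):
            w = cs.WeightConfig(w_e, (1 - w_e) / 2, (1 - w_e) / 2)
            d = _pairwise(cs.combine(h, w).vectors) / w_e
            errs.append(np.abs(d - gex_d).max())
        assert errs == sorted(errs, reverse=True)
        assert errs[-1] < 1e-12


def _pairwise(x):
    from scipy.spatial.distance import pdist

    return pdist(x)


def _manual_harmonized(e, m, c):
    """Bypass the harmonization scaling to test combine's layout on exact
    values (flags set by construction)."""
    mats = []
    for mod, vals in zip((Modality.GEX, Modality.DME, Modality.CNV), (e, m, c)):
        arr = np.asarray(vals, dtype=float)
        om = make_matrix(mod, arr)
        om.centralized = True  # exact test values, zero-mean by construction
        om.harmonized = True
        mats.append(om)
    return cs.MultiOmicsDataset(*mats)


class TestDecompose:
    def test_round_trip_recovers_blocks(self, rng):
        """Units set equal to combined gene vectors decompose back to the
        harmonized inputs within 1e-12."""
        h = _harmonized(rng, n_genes=4, n_samples=3)
        w = cs.WeightConfig(0.2, 0.5, 0.3)
        prof = cs.combine(h, w)
        model = cs.SOMModel(
            grid_side=2,
            unit_vectors=prof.vectors,
            weights=w,
            gene_ids=prof.gene_ids,
            assignment={g: i for i, g in enumerate(prof.gene_ids)},
            training_config=cs.TrainingConfig(),
            sample_ids=prof.sample_ids,
        )
        dec = cs.decompose(model)
        for mat in h.matrices():
            np.testing.assert_allclose(dec[mat.modality], mat.values, atol=1e-12)

    def test_zero_weight_gives_nan(self, rng, caplog):
        h = _harmonized(rng, n_genes=4, n_samples=3)
        w = cs.WeightConfig(0.5, 0.5, 0.0)
        prof = cs.combine(h, w)
        model = cs.SOMModel(
            grid_side=2, unit_vectors=prof.vectors, weights=w,
            gene_ids=prof.gene_ids,
            assignment={g: i for i, g in enumerate(prof.gene_ids)},
            training_config=cs.TrainingConfig(), sample_ids=prof.sample_ids,
        )
        with caplog.at_level("WARNING"):
            dec = cs.decompose(model)
        assert np.isnan(dec[Modality.CNV]).all()
        assert np.isfinite(dec[Modality.GEX]).all()

    def test_corrupted_width_rejected(self, rng):
        h = _harmonized(rng, n_genes=4, n_samples=3)
        prof = cs.combine(h, cs.weight_preset("balanced"))
        model = cs.SOMModel(
            grid_side=2, unit_vectors=prof.vectors[:, :-1],
            weights=prof.weights, gene_ids=prof.gene_ids,
            assignment={g: i for i, g in enumerate(prof.gene_ids)},
            training_config=cs.TrainingConfig(), sample_ids=prof.sample_ids,
        )
        with pytest.raises(ValueError, match="width"):
            cs.decompose(model)
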