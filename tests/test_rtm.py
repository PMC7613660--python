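"""Training-database generation: LHS design, surrogate physics, labels."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from s2trait import (
    TABLE1_RANGES,
    RTMParams,
    augment_nonvegetated,
    build_training_db,
    derive_labels,
    forward_reflectance,
    sample_lhs,
    simulate_fvc,
)
from s2trait._surrogate import ALPHA, BAND_CENTERS_NM, RHO_INF, RHO_SOIL
from s2trait.rtm import _default_free


def _mid_params(**overrides) -> RTMParams:
    return RTMParams(**{**_default_free(), **overrides})


class TestSampleLHS:
    def test_all_samples_in_range(self):
        samples = sample_lhs(1000, seed=0)
        assert len(samples) == 1000
        for p in samples:
            p.validate()

    def test_single_sample_degenerate(self):
        (p,) = sample_lhs(1)
        p.validate()

    @pytest.mark.parametrize("n,seed", [(50, 7), (10, 0), (37, 5)])
    def test_one_sample_per_stratum_every_marginal(self, n, seed):
        samples = sample_lhs(n, seed=seed)
        for name, (lo, hi) in TABLE1_RANGES.items():
            vals = np.array([getattr(p, name) for p in samples])
            counts, _ = np.histogram(vals, bins=n, range=(lo, hi))
            assert np.all(counts == 1), f"stratification broken for {name}"

    def test_fixed_parameters_constant(self):
        for p in sample_lhs(20, seed=1):
            assert p.Hot == 0.01 and p.OZA == 0.0 and p.DDR == 80.0
            assert p.rAA == 0.0 and p.Cbrown == 0.0

    def test_reproducible_under_seed(self):
        a = sample_lhs(25, seed=9)
        b = sample_lhs(25, seed=9)
        assert a == b

    def test_rejects_bad_inputs(self):
        with pytest.raises(ValueError, match="positive"):
            sample_lhs(0)
        with pytest.raises(ValueError, match="LAI"):
            sample_lhs(5, ranges={"LAI": (7.0, 0.1)})


class TestSurrogate:
    def test_reflectance_in_unit_interval(self):
        for p in sample_lhs(50, seed=2):
            r = forward_reflectance(p).reflectance
            assert r.shape == (10,)
            assert np.all((r >= 0) & (r <= 1))

    def test_sparse_canopy_decomposes_into_soil_plus_leaf_term(self):
        p = _mid_params(LAI=0.1, soil=0.5)
        r = forward_reflectance(p).reflectance
        k = np.cos(np.radians(p.ALIA))
        p0 = np.exp(-k * p.LAI)
        soil_term = p0 * p.soil * RHO_SOIL
        leaf_term = r - soil_term
        # At LAI = 0.1 the gap fraction dominates; in the chlorophyll
        # absorption bands the leaf contribution is marginal.
        assert np.all(leaf_term >= 0)
        for b in (0, 2, 3):  # 493, 665, 704 nm
            assert leaf_term[b] < 0.20 * r[b]

    def test_closure_limit_dense_canopy(self):
        p = _mid_params(LAI=15.0, ALIA=30.0, soil=0.0)
        r = forward_reflectance(p).reflectance
        k = np.cos(np.radians(p.ALIA))
        dm = (p.Cm + p.CBC) * 1e4
        from s2trait._surrogate import BETA, GAMMA
        rho_leaf = RHO_INF * np.exp(
            -(ALPHA * p.Cab + BETA * p.EWT + GAMMA * dm))
        assert np.allclose(r, rho_leaf, atol=1e-3)

    def test_chlorophyll_darkens_visible_not_swir(self):
        lo = forward_reflectance(_mid_params(Cab=20.0)).reflectance
        hi = forward_reflectance(_mid_params(Cab=60.0)).reflectance
        for b, nm in [(0, 493), (2, 665), (3, 704)]:
            assert hi[b] < lo[b], f"Cab should darken {nm} nm"
        for b in (8, 9):  # 1610, 2190 nm
            assert abs(hi[b] - lo[b]) < 1e-6

    def test_water_darkens_swir(self):
        lo = forward_reflectance(_mid_params(EWT=0.005)).reflectance
        hi = forward_reflectance(_mid_params(EWT=0.04)).reflectance
        for b in (8, 9):
            assert hi[b] < lo[b]

    def test_unknown_backend_and_bad_params_rejected(self):
        with pytest.raises(ValueError, match="backend"):
            forward_reflectance(_mid_params(), backend="6s")
        with pytest.raises(ValueError, match="LAI"):
            forward_reflectance(_mid_params(LAI=-1.0))


class TestFVC:
    def test_empty_canopy(self):
        assert simulate_fvc(0.0, 45.0) == 0.0

    def test_dense_canopy_value(self):
        # 1 - exp(-7 cos 30 deg)
        assert simulate_fvc(7.0, 30.0) == pytest.approx(0.997671, abs=1e-5)

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(
        lai1=st.floats(0, 7), lai2=st.floats(0, 7),
        alia=st.floats(30, 70),
    )
    def test_monotone_in_lai(self, lai1, lai2, alia):
        lo, hi = sorted([lai1, lai2])
        assert simulate_fvc(lo, alia) <= simulate_fvc(hi, alia)

    def test_negative_lai_rejected(self):
        with pytest.raises(ValueError):
            simulate_fvc(-0.5, 45.0)


class TestLabels:
    def test_ccc_direct(self):
        _, ccc, _ = derive_labels(_mid_params(Cab=40.0, LAI=3.0), fvc=0.5)
        assert ccc == pytest.approx(1.2)

    def test_vwc_direct(self):
        _, _, vwc = derive_labels(_mid_params(EWT=0.02, LAI=3.0), fvc=0.8)
        assert vwc == pytest.approx(480.0)

    def test_zero_canopy(self):
        lai, ccc, vwc = derive_labels(_mid_params(LAI=0.0), fvc=0.0)
        assert lai == ccc == vwc == 0.0

    def test_bad_fvc_rejected(self):
        with pytest.raises(ValueError):
            derive_labels(_mid_params(), fvc=1.5)


class TestTrainingDB:
    def test_label_invariants_hold(self, small_db):
        ts = small_db
        assert len(ts) == 80
        assert set(ts.provenance) == {"vegetated"}
        # CCC bounded by range propagation from the design bounds.
        assert np.all(ts.ccc >= 5 * 0.1 / 100 - 1e-12)
        assert np.all(ts.ccc <= 75 * 7 / 100 + 1e-12)

    def test_label_conservation_recovers_cab(self):
        ts = build_training_db(n=40, seed=11)
        samples = sample_lhs(40, seed=11)
        cab = np.array([p.Cab for p in samples])
        assert np.allclose(ts.ccc / ts.lai * 100, cab, atol=1e-10)

    def test_bit_identical_under_seed(self):
        a = build_training_db(n=30, seed=5)
        b = build_training_db(n=30, seed=5)
        assert np.array_equal(a.spectra, b.spectra)
        assert np.array_equal(a.vwc, b.vwc)

    def test_csv_round_trip(self, small_db, tmp_path):
        from s2trait import TrainingSet
        p = tmp_path / "train.csv"
        small_db.to_csv(p)
        back = TrainingSet.from_csv(p)
        assert np.allclose(back.spectra, small_db.spectra)
        assert np.allclose(back.vwc, small_db.vwc)
        assert back.meta["seed"] == small_db.meta["seed"]


class TestAugmentation:
    def test_counts_appended(self, small_db):
        out = augment_nonvegetated(small_db, n_bare=4, n_senescent=6, seed=0)
        assert len(out) == 90
        assert np.sum(out.provenance == "bare") == 4
        assert np.sum(out.provenance == "senescent") == 6

    def test_zero_counts_identity(self, small_db):
        assert augment_nonvegetated(small_db, 0, 0) is small_db

    def test_bare_records_have_zero_labels(self, small_db):
        out = augment_nonvegetated(small_db, n_bare=5, n_senescent=0, seed=1)
        bare = out.provenance == "bare"
        assert np.all(out.lai[bare] == 0)
        assert np.all(out.ccc[bare] == 0)
        assert np.all(out.vwc[bare] == 0)

    def test_senescent_labels_consistent(self, small_db):
        out = augment_nonvegetated(small_db, n_bare=0, n_senescent=8, seed=2)
        sen = out.provenance == "senescent"
        assert np.all(out.ccc[sen] <= 5 * 5 / 100 + 1e-12)
        assert np.all(out.lai[sen] >= 1.0)
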