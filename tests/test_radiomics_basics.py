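import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from ctharmony import radiomics as rx


class TestSchema:
    def test_total_and_group_counts(self):
        s = rx.build_schema()
        assert len(s) == 455
        assert len(s.groups) == 30

    def test_class_roster_sizes(self):
        sizes = {k: len(v) for k, v in rx.MATRIX_CLASSES.items()}
        assert sizes == {"firstorder": 18, "glcm": 22, "glrlm": 16,
                         "glszm": 16, "gldm": 14, "ngtdm": 5}

    def test_original_firstorder_group_membership(self):
        s = rx.build_schema()
        assert len(s.group_members("original_firstorder")) == 18
        assert "original_firstorder_Mean" in s.feature_ids
        assert "wavelet-LL_glrlm_ShortRunEmphasis" in s.feature_ids

    def test_feature_ids_unique(self):
        ids = rx.build_schema().feature_ids
        assert len(ids) == len(set(ids))


class TestDiscretize:
    @pytest.mark.parametrize(
        "values, width, expected",
        [
            ([0, 24.9, 25, 51], 25, [1, 1, 2, 3]),
            ([-50, 0, 50], 25, [1, 3, 5]),
            ([7.0, 7.0, 7.0], 10, [1, 1, 1]),
        ],
    )
    def test_hand_examples(self, values, width, expected):
        assert rx.discretize(np.array(values, float), width).tolist() == expected

    def test_rejects_nonpositive_width(self):
        with pytest.raises(rx.ParameterError):
            rx.discretize(np.array([1.0, 2.0]), 0)

    @settings(max_examples=50, deadline=None)
    @given(
        st.lists(st.floats(-2000, 3000, allow_nan=False), min_size=1, max_size=50),
        st.floats(0.5, 200),
    )
    def test_labels_start_at_one_and_scale(self, values, width):
        lab = rx.discretize(np.array(values), width)
        assert lab.min() == 1
        # span bounded by the value range over the bin width
        assert lab.max() - 1 <= (max(values) - min(values)) / width + 1


class TestWaveletSubbands:
    def test_constant_image_has_zero_detail(self):
        sb = rx.wavelet_subbands(np.full((33, 40), 7.0))
        for k in ("LH", "HL", "HH"):
            assert np.allclose(sb[k], 0.0, atol=1e-10)
        assert np.allclose(sb["LL"], 14.0)  # unnormalised single-level SWT

    def test_shapes_match_input_even_for_odd_dims(self, rng):
        img = rng.normal(size=(31, 45))
        sb = rx.wavelet_subbands(img)
        assert set(sb) == {"LL", "LH", "HL", "HH"}
        assert all(v.shape == img.shape for v in sb.values())

    def test_step_edge_energy_lands_in_matching_subband(self):
        # intensity change across columns (a vertical edge) -> LH
        edge = np.zeros((32, 32))
        edge[:, 16:] = 100.0
        sb = rx.wavelet_subbands(edge)
        energies = {k: float((v**2).sum()) for k, v in sb.items() if k != "LL"}
        assert max(energies, key=energies.get) == "LH"
        # and across rows -> HL
        sb = rx.wavelet_subbands(edge.T)
        energies = {k: float((v**2).sum()) for k, v in sb.items() if k != "LL"}
        assert max(energies, key=energies.get) == "HL"


class TestFirstOrder:
    def test_constant_roi(self):
        vals = np.full(25, 42.0)
        binned = rx.discretize(vals, 25.0)
        f = rx.firstorder_features(vals, binned, 1.0)
        assert f["Variance"] == 0.0
        assert f["Mean"] == 42.0
        assert f["Entropy"] == 0.0
        assert f["Uniformity"] == 1.0
        assert f["Skewness"] == 0.0

    def test_agrees_with_direct_numpy(self, rng):
        vals = rng.normal(60, 15, size=200)
        binned = rx.discretize(vals, 5.0)
        f = rx.firstorder_features(vals, binned, 1.0)
        assert f["Mean"] == pytest.approx(vals.mean())
        assert f["Variance"] == pytest.approx(vals.var())
        assert f["RootMeanSquared"] == pytest.approx(np.sqrt((vals**2).mean()))
        assert f["Median"] == pytest.approx(np.median(vals))
        assert f["Range"] == pytest.approx(np.ptp(vals))
        from scipy import stats as sps
        assert f["Skewness"] == pytest.approx(sps.skew(vals))
        assert f["Kurtosis"] == pytest.approx(sps.kurtosis(vals, fisher=False))
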