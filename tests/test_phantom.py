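import numpy as np
import pytest

from ctharmony import phantom as ph


def test_phantom_deterministic_and_label_invariants():
    a = ph.make_phantom(seed=1)
    b = ph.make_phantom(seed=1)
    assert np.array_equal(a.base_hu, b.base_hu)
    assert np.array_equal(a.organ_labels, b.organ_labels)
    assert np.array_equal(a.enhancement_hu, b.enhancement_hu)
    # every organ role present
    present = set(np.unique(a.organ_labels))
    for lab in (ph.LIVER, ph.SPLEEN, ph.KIDNEY, ph.MUSCLE, ph.VESSEL, ph.AIR, ph.FAT):
        assert lab in present
    air = a.organ_labels == ph.AIR
    assert np.all(a.base_hu[air] <= -900)
    assert np.all(a.enhancement_hu[air] == 0)
    assert np.all(a.enhancement_hu >= 0)


def test_vessel_enhancement_exceeds_liver():
    p = ph.make_phantom(seed=1)
    v = p.enhancement_hu[p.organ_labels == ph.VESSEL].mean()
    l = p.enhancement_hu[p.organ_labels == ph.LIVER].mean()
    assert v > l


def test_phantom_too_small_names_organ():
    with pytest.raises(ph.PhantomSizingError, match="liver"):
        ph.make_phantom(ph.GeometryConfig(shape=(32, 32)), seed=0)


def test_identity_protocol_reproduces_clean_map():
    p = ph.make_phantom(seed=2)
    f = ph.make_noise_field(p.base_hu.shape, np.random.default_rng(0))
    img = ph.render_protocol(p, ph.ProtocolParams("id", 1.0, 0.0, 0.0, 0.0), f)
    assert np.array_equal(img, p.base_hu + p.enhancement_hu)


def test_render_rejects_mismatched_noise_field():
    p = ph.make_phantom(seed=2)
    with pytest.raises(ValueError, match="shape"):
        ph.render_protocol(p, ph.DEFAULT_PROTOCOLS["IR"],
                           np.zeros((16, 16)))


def test_noise_magnitude_ordering_fbp_above_ir():
    p = ph.make_phantom(seed=3)
    f = ph.make_noise_field(p.base_hu.shape, np.random.default_rng(1))
    muscle = p.organ_labels == ph.MUSCLE

    def residual_sd(params):
        noisy = ph.render_protocol(p, params, f)
        clean = ph.render_protocol(
            p,
            ph.ProtocolParams(params.label, params.contrast_gain,
                              params.psf_sigma_mm, 0.0, params.noise_corr_sigma_mm),
            f,
        )
        return (noisy - clean)[muscle].std()

    assert residual_sd(ph.DEFAULT_PROTOCOLS["FBP"]) > residual_sd(
        ph.DEFAULT_PROTOCOLS["IR"]
    )


def test_monoenergetic_contrast_ordering_in_vessel(small_cohort):
    for stack, rois in small_cohort:
        vessel = next(r for r in rois if r.organ_role == "vessel")
        m = vessel.mask(stack.shape, rois.pixel_spacing_mm)
        assert stack.images["M40"][m].mean() > stack.images["M70"][m].mean()


def test_cohort_structure_and_roster(small_cohort):
    assert len(small_cohort) == 3
    rosters = []
    centers = []
    for stack, rois in small_cohort:
        assert set(stack.images) == {"FBP", "IR", "M40", "M70"}
        assert len({im.shape for im in stack.images.values()}) == 1
        assert stack.target_label == "IR"
        rosters.append([r.organ_role for r in rois])
        centers.append([r.center for r in rois])
    # identical organ roster: 2 liver, 2 spleen, 2 kidney, 2 muscle, 1 vessel, 1 air
    assert rosters[0] == ["liver"] * 2 + ["spleen"] * 2 + ["kidney"] * 2 + \
        ["muscle"] * 2 + ["vessel", "air"]
    assert all(r == rosters[0] for r in rosters)
    # but jittered geometry: centres differ between subjects
    assert centers[0] != centers[1]


def test_cohort_rejects_empty_protocol_set():
    with pytest.raises(ValueError, match="empty"):
        ph.make_cohort(2, protocol_set={}, seed=0)


def test_roi_areas_follow_small_vessel_convention(small_cohort):
    _, rois = small_cohort[0]
    for r in rois:
        expected = 120.0 if r.organ_role == "vessel" else 240.0
        assert np.pi * r.radius_mm**2 == pytest.approx(expected)
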