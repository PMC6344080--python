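"""Synthetic-data generators: chains, scenes, particles, rendering."""

import numpy as np
import pytest

from afmbind import binding as B
from afmbind import synthetic as S


# --------------------------------------------------------------------------
# Worm-like chains
# --------------------------------------------------------------------------

def test_chain_contour_is_exact_and_segments_equal():
    ch = S.generate_wlc_chain(587, seed=3)
    assert ch.contour_nm == pytest.approx(587 * 0.34, rel=1e-9)
    seg = np.linalg.norm(np.diff(ch.vertices, axis=0), axis=1)
    assert np.ptp(seg) < 1e-9


def test_rigid_limit_is_a_straight_rod():
    ch = S.generate_wlc_chain(587, persistence_nm=1e12, seed=1)
    e2e = np.linalg.norm(ch.vertices[-1] - ch.vertices[0])
    assert e2e == pytest.approx(ch.contour_nm, rel=1e-6)


def test_ensemble_end_to_end_matches_planar_wlc_closed_form():
    """Mean-squared end-to-end distance of the 2-D chain: the tangent
    correlation decays as exp(-s/2P), so <R^2> = 2[lam*L - lam^2(1-e^(-L/lam))]
    with lam = 2P."""
    P, n_bp = 50.0, 587
    L = n_bp * 0.34
    lam = 2.0 * P
    analytic = 2.0 * (lam * L - lam**2 * (1.0 - np.exp(-L / lam)))
    rng = np.random.default_rng(0)
    r2 = np.array(
        [
            np.sum((c.vertices[-1] - c.vertices[0]) ** 2)
            for c in (S.generate_wlc_chain(n_bp, P, rng=rng) for _ in range(10_000))
        ]
    )
    sem = r2.std() / np.sqrt(r2.size)
    assert abs(r2.mean() - analytic) < 4.0 * sem


def test_chain_generation_is_deterministic():
    a = S.generate_wlc_chain(400, seed=11)
    b = S.generate_wlc_chain(400, seed=11)
    np.testing.assert_array_equal(a.vertices, b.vertices)


def test_circle_perimeter_is_exact():
    c = S.generate_circle(587)
    assert c.closed
    assert c.contour_nm == pytest.approx(587 * 0.34, rel=1e-12)


# --------------------------------------------------------------------------
# Scenes
# --------------------------------------------------------------------------

def test_scene_multimer_fractions_by_construction():
    chains, gt = S.build_bridged_scene(200, multimer_fractions={2: 0.1}, seed=0)
    assert len(chains) == 200
    dimers = [m for m in gt.molecules if m["type"] == "dna_multimer"]
    assert len(dimers) == 20
    for m in dimers:
        assert m["k"] == 2
        assert m["true_contour_nm"] == pytest.approx(2 * 587 * 0.34)


def test_all_circles_scene():
    chains, gt = S.build_bridged_scene(20, circle_fraction=1.0, seed=0)
    assert all(m["type"] == "circle" for m in gt.molecules)
    assert all(c.closed for c in chains)


def test_ground_truth_is_complete_no_orphan_objects():
    """Every bright pixel belongs to a recorded molecule (within the ridge
    footprint plus the tip-dilation margin); outside those footprints only
    noise remains (5-sigma excursions are vanishingly unlikely)."""
    chains, gt = S.build_bridged_scene(6, seed=9)
    noise = 0.05
    tip = 5.0
    topo = S.render_scene(chains, gt, tip_radius_nm=tip, noise_rms_nm=noise, seed=9)[0]
    scale = topo.scale
    margin_px = int(np.ceil((3 * 2.0 + tip + 2 * scale) / scale))
    footprint = np.zeros_like(topo.heights, dtype=bool)
    for c in chains:
        for x, y in c.vertices:
            r, co = int(round(y / scale)), int(round(x / scale))
            footprint[
                max(0, r - margin_px) : r + margin_px + 1,
                max(0, co - margin_px) : co + margin_px + 1,
            ] = True
    orphan = (topo.heights > 5 * noise) & ~footprint
    assert orphan.sum() == 0


# --------------------------------------------------------------------------
# Particle templates
# --------------------------------------------------------------------------

@pytest.mark.parametrize("cid,n_spots", [("I", 1), ("II", 1), ("III", 2), ("IV", 3), ("V", 4)])
def test_particle_class_lobe_counts(cid, n_spots):
    tpl = S.place_particle(cid)
    assert len(tpl.lobes) == n_spots


def test_unknown_particle_class_is_an_error():
    with pytest.raises(ValueError):
        S.place_particle("VI")


def test_single_lobe_template_volume_matches_gaussian_integral():
    tpl = S.place_particle("I", spot_height_nm=2.0, spot_sigma_nm=4.0)
    assert tpl.volume_nm3 == pytest.approx(2 * np.pi * 2.0 * 4.0**2, rel=0.01)


def test_two_lobe_template_volume_is_additive_without_rod():
    tpl = S.place_particle("III", rod_height_nm=0.0, spot_height_nm=2.0, spot_sigma_nm=4.0)
    assert tpl.volume_nm3 == pytest.approx(2 * 2 * np.pi * 2.0 * 16.0, rel=0.01)


def test_dumbbell_maxima_are_at_the_requested_separation():
    tpl = S.place_particle("III", spot_sep_nm=30.0)
    topo = S.render_topograph([S.ParticlePlacement(tpl, (100.0, 100.0), 0.0)], scale_nm_per_px=1.0, size_px=200)
    row = topo.heights[100]
    peaks = np.where((row > np.roll(row, 1)) & (row > np.roll(row, -1)) & (row > 1.0))[0]
    assert len(peaks) == 2
    assert abs(peaks[1] - peaks[0]) == pytest.approx(30.0, abs=1.5)


# --------------------------------------------------------------------------
# Rendering
# --------------------------------------------------------------------------

def _straight_rod(y=128.0):
    # pixel-row-aligned at 1 nm/px so the ridge crest is sampled exactly
    return S.WlcChain(np.array([[40.0, y], [216.0, y]]), 0.34, 518, 0)


def test_clean_rod_peaks_at_the_configured_ridge_height():
    topo = S.render_topograph([_straight_rod()], scale_nm_per_px=1.0, size_px=256)
    assert topo.heights.max() == pytest.approx(0.5, abs=1e-6)


def test_tip_dilation_broadens_and_never_raises_the_ridge():
    # a tall, narrow ridge: the tip cannot follow its flanks, so the
    # apparent footprint widens while the apex height cannot increase
    kw = dict(scale_nm_per_px=1.0, size_px=256, dna_height_nm=2.0, dna_sigma_nm=1.0)
    sharp = S.render_topograph([_straight_rod()], **kw)
    broad = S.render_topograph([_straight_rod()], tip_radius_nm=5.0, **kw)
    assert broad.heights.max() <= sharp.heights.max() + 1e-12
    w_sharp = (sharp.heights > 0.25).sum()
    w_broad = (broad.heights > 0.25).sum()
    assert w_broad > w_sharp


def test_zero_tip_radius_is_a_noop():
    a = S.render_topograph([_straight_rod()], scale_nm_per_px=1.0, size_px=256, tip_radius_nm=0.0)
    b = S.render_topograph([_straight_rod()], scale_nm_per_px=1.0, size_px=256)
    np.testing.assert_array_equal(a.heights, b.heights)


def test_rendered_particle_volume_matches_template():
    tpl = S.place_particle("III")
    topo = S.render_topograph([S.ParticlePlacement(tpl, (128.0, 128.0), 0.7)], scale_nm_per_px=1.0, size_px=256)
    rendered = float(topo.heights.sum())  # 1 nm^2 pixels
    assert rendered == pytest.approx(tpl.volume_nm3, rel=0.05)


def test_out_of_field_objects_warn():
    rod = S.WlcChain(np.array([[900.0, 500.0], [1400.0, 500.0]]), 0.34, 1470, 0)
    with pytest.warns(UserWarning, match="clipped"):
        S.render_topograph([rod])


def test_render_is_deterministic_per_seed():
    chains, gt = S.build_bridged_scene(4, seed=2)
    a = S.render_scene(chains, gt, noise_rms_nm=0.05, line_offset_rms_nm=0.1, seed=2)[0]
    b = S.render_scene(chains, gt, noise_rms_nm=0.05, line_offset_rms_nm=0.1, seed=2)[0]
    np.testing.assert_array_equal(a.heights, b.heights)


def test_topograph_tiff_sidecar_roundtrip(tmp_path):
    topo = S.render_topograph([_straight_rod()], noise_rms_nm=0.02, seed=4)
    path = tmp_path / "field.tif"
    topo.write(path)
    back = S.Topograph.read(path)
    assert back.scale == pytest.approx(topo.scale)
    np.testing.assert_allclose(back.heights, topo.heights, atol=1e-6)


# --------------------------------------------------------------------------
# Titration generator
# --------------------------------------------------------------------------

def test_noiseless_titration_lies_on_the_model_curve():
    p = B.HyperbolicParams(100.0, 16.0, 2.0)
    grid = np.linspace(0.0, 200.0, 9)
    t = S.generate_titration("hyperbolic", p, grid, 0.0, 1, 0)[0]
    np.testing.assert_allclose(t.signal, B.hyperbolic_model(grid, p))


def test_titration_generator_is_deterministic():
    p = B.Ic50Params(75.0, 55.0, 100.0)
    grid = np.geomspace(1.0, 1000.0, 10)
    a = S.generate_titration("ic50", p, grid, 2.0, 2, 42)
    b = S.generate_titration("ic50", p, grid, 2.0, 2, 42)
    for ta, tb in zip(a, b):
        np.testing.assert_array_equal(ta.signal, tb.signal)


def test_tight_binding_roundtrip_recovers_stoichiometry():
    sets = [
        S.generate_titration(
            "tight_binding",
            B.TightBindingParams(50.0, 1.5, 0.5, 2.0),
            np.linspace(0.0, 3 * pc, 14),
            0.0,
            1,
            0,
            probe_conc=pc,
        )[0]
        for pc in (50.0, 100.0, 200.0)
    ]
    r = B.fit_stoichiometry_global(sets, fixed_kd=1.5)
    assert r.params.n == pytest.approx(0.5, rel=1e-6)
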