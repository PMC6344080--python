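"""Binding models, fitters and the mechanistic competition oracle."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from afmbind import binding as B
from afmbind import synthetic as S


# --------------------------------------------------------------------------
# Closed-form models
# --------------------------------------------------------------------------

@pytest.mark.parametrize(
    "i_vv,i_vh,expected",
    [(1.0, 1.0, 0.0), (1.0, 0.0, 1.0), (2.0, 1.0, 0.25)],
)
def test_anisotropy_from_intensities(i_vv, i_vh, expected):
    assert B.compute_anisotropy(B.IntensityPair(i_vv, i_vh)) == pytest.approx(expected)


def test_anisotropy_degenerate_denominator_is_an_error():
    with pytest.raises(ValueError):
        B.compute_anisotropy(B.IntensityPair(0.0, 0.0))


def test_normalize_signal_endpoints_and_midpoint():
    assert B.normalize_signal(0.1, 0.1, 0.3) == pytest.approx(0.0)
    assert B.normalize_signal(0.3, 0.1, 0.3) == pytest.approx(100.0)
    assert B.normalize_signal(0.2, 0.1, 0.3) == pytest.approx(50.0)
    with pytest.raises(ValueError):
        B.normalize_signal(0.2, 0.3, 0.3)


@settings(derandomize=True, max_examples=50)
@given(
    a=st.floats(-0.4, 0.9),
    a_min=st.floats(-0.3, 0.0),
    a_max=st.floats(0.1, 1.0),
)
def test_normalization_roundtrips(a, a_min, a_max):
    pct = B.normalize_signal(a, a_min, a_max)
    assert B.denormalize_signal(pct, a_min, a_max) == pytest.approx(a, abs=1e-12)


def test_hyperbola_offset_halfsaturation_and_competition_start():
    p = B.HyperbolicParams(b_max=100.0, k_d=16.0, c=0.0)
    assert B.hyperbolic_model(0.0, p) == pytest.approx(0.0)
    assert B.hyperbolic_model(16.0, p) == pytest.approx(50.0)
    # probe occupancy at the competition-assay starting point, 50 nM protein
    assert B.hyperbolic_model(50.0, p) == pytest.approx(75.76, abs=0.01)


def test_ic50_decay_limits():
    p = B.Ic50Params(c=75.0, ic50=55.0, b_ini=100.0)
    assert B.ic50_model(0.0, p) == pytest.approx(100.0)
    assert B.ic50_model(55.0, p) == pytest.approx(100.0 - 37.5)
    assert B.ic50_model(1e12, p) == pytest.approx(25.0, abs=1e-6)


def test_tight_binding_stoichiometric_limits():
    # vanishing K_d: the titration is a straight line to saturation
    p = B.TightBindingParams(b_max=80.0, k_d=1e-10, n=0.5, b_ini=5.0)
    dna = 100.0
    s = p.n * dna
    assert B.tight_binding_model(2 * s, dna, p) == pytest.approx(85.0, rel=1e-5)
    assert B.tight_binding_model(s / 2, dna, p) == pytest.approx(45.0, rel=1e-5)


def test_tight_binding_reduces_to_hyperbola_without_depletion():
    p = B.TightBindingParams(b_max=100.0, k_d=16.0, n=0.5, b_ini=0.0)
    dna = (16.0 / 1000.0) / p.n  # effective sites = K_d / 1000
    grid = np.linspace(0.0, 1000 * 16.0, 400)
    hyp = B.hyperbolic_model(grid, B.HyperbolicParams(100.0, 16.0, 0.0))
    tb = B.tight_binding_model(grid, dna, p)
    assert np.max(np.abs(tb - hyp)) < 1e-3 * 100.0


@pytest.mark.parametrize(
    "conc,k_d,expected",
    [(48.0, 16.0, 0.75), (50.0, 16.0, 0.758), (16.0, 16.0, 0.5)],
)
def test_fraction_bound(conc, k_d, expected):
    assert B.fraction_bound(conc, k_d) == pytest.approx(expected, abs=5e-4)


# --------------------------------------------------------------------------
# Fitters: exact recovery on noiseless data
# --------------------------------------------------------------------------

@settings(derandomize=True, max_examples=25, deadline=None)
@given(
    b_max=st.floats(10.0, 200.0),
    k_d=st.floats(1.0, 100.0),
    c=st.floats(-10.0, 10.0),
)
def test_fit_hyperbolic_exact_on_noiseless_data(b_max, k_d, c):
    grid = np.concatenate([[0.0], np.geomspace(k_d / 20, 20 * k_d, 11)])
    t = S.generate_titration("hyperbolic", B.HyperbolicParams(b_max, k_d, c), grid, 0.0, 1, 0)[0]
    r = B.fit_hyperbolic(t)
    assert r.converged
    assert r.params.k_d == pytest.approx(k_d, rel=1e-6)
    assert r.params.b_max == pytest.approx(b_max, rel=1e-6)


@settings(derandomize=True, max_examples=25, deadline=None)
@given(
    c=st.floats(20.0, 100.0),
    ic50=st.floats(5.0, 500.0),
    b_ini=st.floats(50.0, 150.0),
)
def test_fit_ic50_exact_on_noiseless_data(c, ic50, b_ini):
    grid = np.concatenate([[0.0], np.geomspace(ic50 / 20, 40 * ic50, 11)])
    t = S.generate_titration("ic50", B.Ic50Params(c, ic50, b_ini), grid, 0.0, 1, 0)[0]
    r = B.fit_ic50(t)
    assert r.converged
    assert r.params.ic50 == pytest.approx(ic50, rel=1e-6)
    assert r.params.c == pytest.approx(c, rel=1e-6)


def test_fit_hyperbolic_montecarlo_median_unbiased():
    """Noisy replicates (3% of amplitude) recover the true K_d in the median."""
    grid = np.linspace(0.0, 250.0, 12)
    rng_seed = 100
    kds = []
    for rep in range(1000):
        t = S.generate_titration(
            "hyperbolic", B.HyperbolicParams(100.0, 16.0, 0.0), grid, 3.0, 1, rng_seed + rep
        )[0]
        r = B.fit_hyperbolic(t, n_starts=1)
        if r.converged:
            kds.append(r.params.k_d)
    med = float(np.median(kds))
    assert abs(med - 16.0) / 16.0 < 0.10


def test_unidentifiable_designs_raise():
    t = B.Titration(conc=np.zeros(8), signal=np.zeros(8), probe_conc=5.0, mode="direct")
    with pytest.raises(ValueError):
        B.fit_hyperbolic(t)


def test_flat_competition_curve_is_flagged():
    grid = np.concatenate([[0.0], np.geomspace(1.0, 1000.0, 9)])
    t = S.generate_titration("ic50", B.Ic50Params(0.0, 50.0, 100.0), grid, 0.0, 1, 0)[0]
    r = B.fit_ic50(t)
    assert not r.converged
    assert "unidentifiable" in r.message


def test_fits_invariant_under_affine_signal_transform():
    grid = np.concatenate([[0.0], np.geomspace(1.0, 400.0, 11)])
    t = S.generate_titration("hyperbolic", B.HyperbolicParams(80.0, 16.0, 5.0), grid, 0.0, 1, 0)[0]
    k1 = B.fit_hyperbolic(t).params.k_d
    t.signal = 3.5 * t.signal - 40.0
    k2 = B.fit_hyperbolic(t).params.k_d
    assert k2 == pytest.approx(k1, rel=1e-9)


# --------------------------------------------------------------------------
# Global stoichiometry fit
# --------------------------------------------------------------------------

def _tight_binding_sets(n, noise, seed):
    sets = []
    for j, pc in enumerate((50.0, 100.0, 200.0)):
        sets.append(
            S.generate_titration(
                "tight_binding",
                B.TightBindingParams(b_max=50.0, k_d=1.5, n=n, b_ini=2.0),
                np.linspace(0.0, 3.0 * pc, 14),
                noise,
                1,
                seed + 31 * j,
                probe_conc=pc,
            )[0]
        )
    return sets


def test_global_stoichiometry_exact_on_noiseless_data():
    r = B.fit_stoichiometry_global(_tight_binding_sets(0.5, 0.0, 0), fixed_kd=1.5)
    assert r.converged
    assert r.params.n == pytest.approx(0.5, rel=1e-6)
    assert r.extra["dna_per_tetramer"] == pytest.approx(2.0, rel=1e-6)


def test_single_low_probe_dataset_flags_wide_stderr():
    t = S.generate_titration(
        "tight_binding",
        B.TightBindingParams(b_max=50.0, k_d=1.5, n=0.5, b_ini=2.0),
        np.linspace(0.0, 15.0, 10),
        0.5,
        1,
        7,
        probe_conc=5.0,  # only ~3x K_d: regime violation
    )
    r = B.fit_stoichiometry_global(t, fixed_kd=1.5)
    assert "poorly constrained" in r.message


def test_identical_probe_concentrations_warn():
    sets = [
        S.generate_titration(
            "tight_binding",
            B.TightBindingParams(50.0, 1.5, 0.5, 2.0),
            np.linspace(0.0, 300.0, 12),
            0.0,
            1,
            i,
            probe_conc=100.0,
        )[0]
        for i in range(2)
    ]
    with pytest.warns(RuntimeWarning, match="weakly identified"):
        B.fit_stoichiometry_global(sets, fixed_kd=1.5)


# --------------------------------------------------------------------------
# Mechanistic competition equilibrium
# --------------------------------------------------------------------------

def _quadratic_single_ligand(r_tot, d_tot, k):
    """Independent closed form: free receptor for one ligand, one receptor."""
    b = k + d_tot - r_tot
    return (-b + np.sqrt(b * b + 4 * k * r_tot)) / 2.0


def test_solver_matches_single_ligand_quadratic():
    sys = B.CompetitionSystem(r_tot=50.0, dp_tot=5.0, dc_tot=0.0, k_p=16.0, k_c=100.0)
    free_r, fp, _ = B.solve_competition_equilibrium(sys)
    assert free_r == pytest.approx(_quadratic_single_ligand(50.0, 5.0, 16.0), rel=1e-10)
    assert fp == pytest.approx(free_r / (16.0 + free_r), rel=1e-12)


def test_solver_symmetric_ligands_bind_equally():
    sys = B.CompetitionSystem(r_tot=30.0, dp_tot=8.0, dc_tot=8.0, k_p=12.0, k_c=12.0)
    _, fp, fc = B.solve_competition_equilibrium(sys)
    assert fp == pytest.approx(fc, rel=1e-12)


@settings(derandomize=True, max_examples=100, deadline=None)
@given(
    r_tot=st.floats(0.1, 1000.0),
    dp=st.floats(0.0, 500.0),
    dc=st.floats(0.0, 5000.0),
    k_p=st.floats(0.1, 500.0),
    k_c=st.floats(0.1, 5000.0),
)
def test_solver_conserves_mass(r_tot, dp, dc, k_p, k_c):
    sys = B.CompetitionSystem(r_tot, dp, dc, k_p, k_c)
    free_r, fp, fc = B.solve_competition_equilibrium(sys)
    total = free_r + fp * dp + fc * dc
    assert total == pytest.approx(r_tot, rel=1e-9)
    assert 0.0 <= fp <= 1.0 and 0.0 <= fc <= 1.0


def test_probe_occupancy_monotone_in_competitor_and_affinity():
    base = dict(r_tot=50.0, dp_tot=5.0, k_p=16.0)
    occ_dc = [
        B.solve_competition_equilibrium(B.CompetitionSystem(dc_tot=dc, k_c=100.0, **base))[1]
        for dc in (0.0, 10.0, 100.0, 1000.0)
    ]
    assert all(a > b for a, b in zip(occ_dc, occ_dc[1:]))
    occ_kc = [
        B.solve_competition_equilibrium(B.CompetitionSystem(dc_tot=200.0, k_c=kc, **base))[1]
        for kc in (1000.0, 100.0, 10.0, 1.0)
    ]
    assert all(a > b for a, b in zip(occ_kc, occ_kc[1:]))


def _fitted_ic50(k_c):
    grid = np.concatenate([[0.0], np.geomspace(1.0, 400.0 * k_c, 14)])
    t = S.generate_titration(
        "mechanistic", dict(r_tot=50.0, k_p=16.0, k_c=k_c, amp=100.0), grid, 0.0, 1, 0, probe_conc=5.0
    )[0]
    return B.fit_ic50(t).params.ic50


def test_ic50_from_mechanistic_curves_tracks_competitor_kd():
    """IC50 rises monotonically with K_comp and becomes proportional for
    weak competitors, while staying above the floor set by probe affinity."""
    kcs = [16.0, 160.0, 800.0, 1600.0, 8000.0]
    ic50s = [_fitted_ic50(k) for k in kcs]
    assert all(a < b for a, b in zip(ic50s, ic50s[1:]))
    assert all(v > 16.0 for v in ic50s)  # floor: probe K_d
    # weak-competitor regime (k_c/k_p >= 50): proportionality within 20%/decade
    ratios = [v / k for v, k in zip(ic50s[2:], kcs[2:])]
    assert max(ratios) / min(ratios) < 1.2


# --------------------------------------------------------------------------
# Normalisation modes and I/O
# --------------------------------------------------------------------------

def test_normalize_titration_fitted_mode_uses_plateaus():
    grid = np.concatenate([[0.0], np.geomspace(1.0, 300.0, 11)])
    t = S.generate_titration("hyperbolic", B.HyperbolicParams(0.2, 16.0, 0.1), grid, 0.0, 1, 0)[0]
    norm = B.normalize_titration(t, mode="fitted")
    # fitted plateaus are exact on noiseless data: 0 at c, 100 at c + b_max
    assert norm.signal[0] == pytest.approx(0.0, abs=1e-6)
    assert norm.signal[-1] == pytest.approx(
        100.0 * B.hyperbolic_model(grid[-1], B.HyperbolicParams(1.0, 16.0, 0.0)), rel=1e-6
    )


def test_titration_csv_roundtrip(tmp_path):
    grid = np.linspace(0.0, 100.0, 8)
    tits = S.generate_titration("hyperbolic", B.HyperbolicParams(90.0, 20.0, 1.0), grid, 1.0, 3, 5)
    path = tmp_path / "titration.csv"
    B.write_titration_csv(path, tits)
    back = B.read_titration_csv(path, probe_conc=5.0, mode="direct")
    assert len(back) == 3
    np.testing.assert_allclose(back[1].signal, tits[1].signal)


def test_malformed_csv_reports_location(tmp_path):
    path = tmp_path / "bad.csv"
    path.write_text("conc_nM,signal,replicate\n0,1.0,0\n5,,0\n")
    with pytest.raises(ValueError, match="row 3"):
        B.read_titration_csv(path, probe_conc=5.0, mode="direct")
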