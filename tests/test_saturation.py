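import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy import integrate, stats

from oncoscreen.errors import (
    DegenerateSignalError,
    InsufficientDataError,
    InsufficientReplicatesError,
)
from oncoscreen.saturation import (
    PPIScore,
    SaturationPoint,
    acceptor_donor_ratio,
    bret_ratio,
    call_hits,
    fit_saturation,
    hyperbolic_auc,
    net_bret,
    saturation_auc,
    saturation_model,
    score_from_aucs,
    score_ppi,
    scores_to_frame,
    trfret_foc,
    trfret_ratio,
)


# ---------------------------------------------------------------------------
# elementary ratios
# ---------------------------------------------------------------------------

def test_bret_ratio_values_and_guard():
    assert bret_ratio(500, 1000) == 0.5
    assert bret_ratio(0, 1000) == 0.0
    with pytest.raises(DegenerateSignalError):
        bret_ratio(100, 0)


def test_net_bret_difference_may_be_negative():
    assert net_bret(0.5, 0.5) == 0.0
    assert net_bret(0.35, 0.10) == pytest.approx(0.25)
    # below-background pairs go negative here and are excluded at the fit stage
    y = net_bret(0.08, 0.10)
    assert y == pytest.approx(-0.02)
    assert SaturationPoint(x=1.0, y=y).excluded
    with pytest.raises(ValueError):
        net_bret(np.inf, 0.1)


def test_acceptor_donor_ratio():
    assert acceptor_donor_ratio(2000, 1000) == 2.0
    assert acceptor_donor_ratio(0, 1000) == 0.0
    with pytest.raises(DegenerateSignalError):
        acceptor_donor_ratio(100, 0)


def test_trfret_ratio_and_fold_change():
    assert trfret_ratio(50, 100000) == pytest.approx(5.0)
    assert trfret_ratio(0, 100000) == 0.0
    with pytest.raises(DegenerateSignalError):
        trfret_ratio(50, 0)
    assert trfret_foc(10, 5) == 2.0
    assert trfret_foc(7, 7) == 1.0
    with pytest.raises(DegenerateSignalError):
        trfret_foc(10, 0)


# ---------------------------------------------------------------------------
# saturation fitting
# ---------------------------------------------------------------------------

def test_noiseless_fit_recovers_generating_parameters(x_grid):
    y = saturation_model(x_grid, 0.2, 1.0)
    fit = fit_saturation((x_grid, y))
    assert fit.converged
    assert fit.bret_max == pytest.approx(0.2, abs=1e-6)
    assert fit.bret50 == pytest.approx(1.0, abs=1e-6)
    assert fit.n_points_used == 6


def test_all_zero_response_pins_plateau_and_flags_unidentifiable(x_grid):
    fit = fit_saturation((x_grid, np.zeros_like(x_grid)))
    assert fit.bret_max == 0.0
    assert not fit.converged


def test_negative_points_are_excluded_from_fit(x_grid):
    y = saturation_model(x_grid, 0.2, 1.0)
    y[0], y[3] = -0.01, -0.02
    fit = fit_saturation((x_grid, y))
    assert fit.n_points_used == 4
    assert fit.converged
    # remaining noiseless points still pin the model
    assert fit.bret_max == pytest.approx(0.2, abs=1e-5)


def test_too_few_usable_points_raises(x_grid):
    y = saturation_model(x_grid, 0.2, 1.0)
    y[:4] = -1.0
    with pytest.raises(InsufficientDataError):
        fit_saturation((x_grid, y))


def test_fitted_curve_is_nondecreasing(x_grid):
    rng = np.random.default_rng(11)
    y = saturation_model(x_grid, 0.2, 1.0) + rng.normal(0, 0.01, x_grid.size)
    fit = fit_saturation((x_grid, y))
    grid = np.linspace(0, 10, 200)
    pred = saturation_model(grid, fit.bret_max, fit.bret50)
    assert (np.diff(pred) >= -1e-12).all()


def test_b50_recovery_under_assay_noise(x_grid):
    """Median relative error of the half-saturation parameter stays below
    10% for 4-replicate, 6-point curves at 5%-of-plateau Gaussian noise."""
    rng = np.random.default_rng(7)
    bmax, b50 = 0.2, 1.0
    errors = []
    for _ in range(200):
        estimates = []
        for _ in range(4):  # replicate curves, fit independently as in scoring
            y = saturation_model(x_grid, bmax, b50) + rng.normal(0, 0.05 * bmax, x_grid.size)
            fit = fit_saturation((x_grid, y))
            if fit.converged:
                estimates.append(fit.bret50)
        errors.append(abs(np.mean(estimates) - b50) / b50)
    assert np.median(errors) < 0.10


# ---------------------------------------------------------------------------
# AUC
# ---------------------------------------------------------------------------

def test_closed_form_auc_matches_quadrature():
    assert hyperbolic_auc(1.0, 1.0, 1.0) == pytest.approx(1 - np.log(2), abs=1e-12)
    rng = np.random.default_rng(5)
    for _ in range(50):
        bmax = rng.uniform(0.01, 2.0)
        b50 = rng.uniform(0.05, 10.0)
        x_max = rng.uniform(0.1, 20.0)
        num, _ = integrate.quad(lambda x: saturation_model(x, bmax, b50), 0, x_max)
        assert hyperbolic_auc(bmax, b50, x_max) == pytest.approx(num, abs=1e-8)


def test_auc_degenerate_and_limiting_cases():
    assert hyperbolic_auc(0.0, 1.0, 5.0) == 0.0
    # B50 -> 0+ saturates instantly: rectangle Bmax * x_max
    assert hyperbolic_auc(0.3, 1e-14, 5.0) == pytest.approx(1.5, rel=1e-6)
    with pytest.raises(ValueError):
        hyperbolic_auc(1.0, 1.0, 0.0)


def test_auc_monotone_in_bounds_and_plateau():
    aucs_x = [hyperbolic_auc(0.2, 1.0, xm) for xm in (0.5, 1, 2, 4, 8)]
    assert all(np.diff(aucs_x) > 0)
    aucs_b = [hyperbolic_auc(b, 1.0, 4.0) for b in (0.05, 0.1, 0.2, 0.4)]
    assert all(np.diff(aucs_b) > 0)


def test_saturation_auc_requires_converged_fit(x_grid):
    fit = fit_saturation((x_grid, saturation_model(x_grid, 0.2, 1.0)))
    assert saturation_auc(fit, 8.0) == pytest.approx(hyperbolic_auc(0.2, 1.0, 8.0), abs=1e-6)
    fit.converged = False
    fit.bret_max = 0.1
    with pytest.raises(InsufficientDataError):
        saturation_auc(fit, 8.0)


# ---------------------------------------------------------------------------
# scoring
# ---------------------------------------------------------------------------

def test_foc_uses_larger_control_mean():
    s = score_from_aucs([4.0, 4.1, 3.9, 4.0], [1.0, 1.0, 1.0, 1.0], [0.8, 0.8, 0.8, 0.8])
    assert s.foc == pytest.approx(np.mean([4.0, 4.1, 3.9, 4.0]) / 1.0)
    assert s.is_hit  # p from a 4-vs-8 t-test on this separation is far below 1e-3


def test_identical_ppi_and_control_replicates_are_null():
    reps = [1.0, 2.0, 1.5, 1.8]
    s = score_from_aucs(reps, reps, reps)
    assert s.foc == pytest.approx(1.0)
    assert s.p_foc == pytest.approx(1.0)
    assert not s.is_hit


def test_p_foc_matches_hand_computed_pooled_t():
    rng = np.random.default_rng(3)
    ppi = 4.0 + rng.normal(0, 0.01, 4)
    ctrl = 1.0 + rng.normal(0, 0.01, 8)
    s = score_from_aucs(ppi, ctrl[:4], ctrl[4:])
    n1, n2 = len(ppi), len(ctrl)
    sp2 = ((n1 - 1) * ppi.var(ddof=1) + (n2 - 1) * ctrl.var(ddof=1)) / (n1 + n2 - 2)
    t = (ppi.mean() - ctrl.mean()) / np.sqrt(sp2 * (1 / n1 + 1 / n2))
    p = 2 * stats.t.sf(abs(t), n1 + n2 - 2)
    assert s.p_foc == pytest.approx(p, abs=1e-10)
    assert s.p_foc <= 0.001


def test_nonpositive_control_scale_flags_non_callable():
    s = score_from_aucs([1.0, 1.1, 0.9, 1.0], [-0.1, -0.2, -0.1, -0.1], [-0.3, -0.2, -0.1, -0.2])
    assert not s.callable
    assert np.isnan(s.foc)
    assert not s.is_hit


def test_insufficient_control_replicates_raise():
    with pytest.raises(InsufficientReplicatesError):
        score_from_aucs([1.0, 1.0, 1.0], [0.5], [0.5, 0.6])


@given(scale=st.floats(min_value=1e-3, max_value=1e3))
def test_foc_invariant_under_common_auc_rescaling(scale):
    base = dict(
        auc_ppi=[4.0, 4.2, 3.8, 4.1], auc_ctrl1=[1.0, 1.1, 0.9, 1.0], auc_ctrl2=[0.8, 0.9, 0.7, 0.8]
    )
    s1 = score_from_aucs(**base)
    s2 = score_from_aucs(**{k: [scale * a for a in v] for k, v in base.items()})
    assert s2.foc == pytest.approx(s1.foc, rel=1e-9)


def test_score_ppi_from_curves_uses_common_x_max(x_grid):
    rng = np.random.default_rng(9)

    def curves(bmax, grid):
        return [
            (grid, saturation_model(grid, bmax, 1.0) + rng.normal(0, 0.002, grid.size))
            for _ in range(4)
        ]

    # PPI series measured over a shorter expression range than the controls
    short = x_grid[:-1]
    s = score_ppi(curves(0.2, short), curves(0.02, x_grid), curves(0.02, x_grid))
    assert s.x_max == pytest.approx(short.max())
    assert s.is_hit


def test_hit_calling_boundaries_and_ordering():
    def fake(acceptor, foc, p):
        hit = foc >= 4.0 and p <= 0.001
        return PPIScore("bait", acceptor, [1] * 4, [1] * 4, [1] * 4, 8.0, foc, p, hit)

    scores = [
        fake("A", 4.0, 1e-4),   # inclusive boundary: hit
        fake("B", 3.9, 1e-4),   # below FOC cutoff
        fake("C", 10.0, 0.01),  # significant fold change but p too large
        fake("D", 4.0, 1e-5),   # tie on foc with A, smaller p ranks first
        fake("E", 7.0, 1e-3),   # inclusive p boundary: hit
    ]
    hits = call_hits(scores)
    assert list(hits["acceptor"]) == ["E", "D", "A"]
    with pytest.raises(ValueError):
        call_hits([])
    frame = scores_to_frame(scores)
    assert len(frame) == 5 and frame["is_hit"].sum() == 3
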