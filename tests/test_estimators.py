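"""Univariable MR estimators against closed-form and brute-force oracles."""

import numpy as np
import pytest
from scipy import stats

import mrpath.estimators as est
from mrpath.errors import InsufficientInstrumentsError
from mrpath.sensitivity import cochran_q, egger_intercept_test

from conftest import make_harmonized, random_harmonized


# ---------------------------------------------------------------- Wald ratios


def test_wald_ratio_arithmetic_and_sign():
    h = make_harmonized([0.2, -0.2], [0.02, 0.02], [0.1, 0.1])
    wr = est.wald_ratios(h)
    assert wr["ratio"].tolist() == pytest.approx([0.5, -0.5])
    assert wr["se"].tolist() == pytest.approx([0.1, 0.1])


def test_wald_ratios_match_elementwise_recomputation():
    rng = np.random.default_rng(7)
    h = random_harmonized(rng, n=20)
    wr = est.wald_ratios(h)
    k = h.kept
    np.testing.assert_allclose(wr["ratio"], k["beta_out"] / k["beta_exp"], rtol=1e-14)
    np.testing.assert_allclose(
        wr["se"], k["se_out"] / np.abs(k["beta_exp"]), rtol=1e-14
    )


def test_zero_exposure_beta_excluded():
    h = make_harmonized([0.2, 0.0, 0.1], [0.02] * 3, [0.1, 0.1, 0.05])
    assert len(est.wald_ratios(h)) == 2


def test_second_order_se_exceeds_first_order():
    h = make_harmonized([0.2], [0.02], [0.1], sx=[0.05])
    assert est.wald_ratios(h, second_order=True)["se"][0] > est.wald_ratios(h)["se"][0]


# ------------------------------------------------------------------------ IVW


def test_ivw_exact_fit_fixed_equals_random():
    bx = np.array([0.1, 0.2, 0.3])
    h = make_harmonized(bx, [0.01, 0.02, 0.03], 0.5 * bx)
    fixed, random = est.ivw(h, "fixed"), est.ivw(h, "random")
    assert fixed.beta == pytest.approx(0.5, abs=1e-12)
    assert fixed.se == pytest.approx(random.se)
    assert cochran_q(h).Q == pytest.approx(0, abs=1e-20)


def test_ivw_two_snp_closed_form():
    # equal outcome ses and equal |bx| -> ratio-variance-weighted mean of 0.4, 0.6
    h = make_harmonized([0.1, 0.1], [0.01, 0.01], [0.04, 0.06])
    beta = est.ivw(h, "fixed").beta
    w = 0.1**2 / 0.01**2
    expected = (w * 0.4 + w * 0.6) / (2 * w)
    assert beta == pytest.approx(expected, rel=1e-12)
    assert beta == pytest.approx(0.5, rel=1e-12)


def test_ivw_closed_form_sum_oracle():
    rng = np.random.default_rng(11)
    h = random_harmonized(rng, n=15)
    k = h.kept
    bx, by, sy = (k[c].to_numpy() for c in ("beta_exp", "beta_out", "se_out"))
    expected = np.sum(bx * by / sy**2) / np.sum(bx**2 / sy**2)
    assert est.ivw(h, "fixed").beta == pytest.approx(expected, rel=1e-12)


def test_ivw_random_inflates_only_under_overdispersion():
    rng = np.random.default_rng(3)
    h_noisy = random_harmonized(rng, n=30)
    h_noisy.data["beta_out"] += rng.normal(0, 0.2, 30)  # gross heterogeneity
    assert est.ivw(h_noisy, "random").se > est.ivw(h_noisy, "fixed").se
    h_clean = make_harmonized([0.1, 0.2, 0.3], [0.01] * 3, [0.05, 0.1, 0.15])
    assert est.ivw(h_clean, "random").se == pytest.approx(est.ivw(h_clean, "fixed").se)


def test_ivw_needs_two_snps():
    with pytest.raises(InsufficientInstrumentsError, match="[Ww]ald"):
        est.ivw(make_harmonized([0.1], [0.01], [0.05]))


def test_ivw_two_identical_snps_equals_wald_ratio():
    h = make_harmonized([0.2, 0.2], [0.02, 0.02], [0.1, 0.1])
    wr = est.wald_ratios(h)
    assert est.ivw(h, "fixed").beta == pytest.approx(wr["ratio"][0], rel=1e-12)


# ---------------------------------------------------------------------- Egger


def test_egger_recovers_exact_line():
    bx = np.linspace(0.05, 0.3, 10)
    by = 0.02 + 0.3 * bx
    h = make_harmonized(bx, np.full(10, 0.01), by)
    e = est.mr_egger(h)
    assert e.beta == pytest.approx(0.3, abs=1e-10)
    assert e.egger_intercept.value == pytest.approx(0.02, abs=1e-10)
    assert cochran_q(h, about="egger").Q == pytest.approx(0, abs=1e-16)


def test_egger_orientation_invariance():
    rng = np.random.default_rng(5)
    h = random_harmonized(rng, n=12)
    e1 = est.mr_egger(h)
    flipped = h.data.copy()
    flip = rng.random(12) < 0.5
    flipped.loc[flip, ["beta_exp", "beta_out"]] *= -1
    h2 = make_harmonized(
        flipped["beta_exp"], flipped["se_out"], flipped["beta_out"]
    )
    e2 = est.mr_egger(h2)
    assert e1.beta == pytest.approx(e2.beta, rel=1e-12)
    assert e1.egger_intercept.value == pytest.approx(e2.egger_intercept.value, rel=1e-12)


def test_egger_normal_equations_oracle():
    rng = np.random.default_rng(13)
    h = random_harmonized(rng, n=10)
    k = h.kept
    bx, by, sy = (k[c].to_numpy() for c in ("beta_exp", "beta_out", "se_out"))
    s = np.sign(bx)
    bx, by = bx * s, by * s
    W = np.diag(1 / sy**2)
    X = np.column_stack([np.ones_like(bx), bx])
    coef = np.linalg.solve(X.T @ W @ X, X.T @ W @ by)
    e = est.mr_egger(h)
    assert e.egger_intercept.value == pytest.approx(coef[0], rel=1e-10)
    assert e.beta == pytest.approx(coef[1], rel=1e-10)


def test_egger_needs_three_snps():
    with pytest.raises(InsufficientInstrumentsError):
        est.mr_egger(make_harmonized([0.1, 0.2], [0.01] * 2, [0.05, 0.1]))


# ------------------------------------------------------------- weighted median


def test_weighted_median_equal_weights_is_plain_median():
    h = make_harmonized([0.1, 0.1, 0.1], [0.01] * 3, [0.01, 0.05, 0.09])
    wm = est.weighted_median(h, n_boot=200, seed=0)
    assert wm.beta == pytest.approx(0.5, abs=1e-12)


def test_weighted_median_dominant_weight_converges_to_its_ratio():
    # one SNP carries ~98% of the weight; the interpolated weighted median
    # approaches its ratio
    h = make_harmonized(
        [0.1, 0.1, 0.1], [0.001, 0.05, 0.05], [0.05, 0.01, 0.09]
    )
    wm = est.weighted_median(h, n_boot=200, seed=0)
    assert wm.beta == pytest.approx(0.5, abs=0.02)


def _weighted_median_oracle(ratios, weights):
    """Independent loop over the cumulative normalized weights."""
    order = np.argsort(ratios)
    r = np.asarray(ratios)[order]
    w = np.asarray(weights)[order]
    cum = []
    run = 0.0
    for wi in w:
        cum.append((run + wi / 2) / w.sum())
        run += wi
    cum = np.asarray(cum)
    if 0.5 <= cum[0]:
        return r[0]
    if 0.5 >= cum[-1]:
        return r[-1]
    i = int(np.searchsorted(cum, 0.5, side="right")) - 1
    frac = (0.5 - cum[i]) / (cum[i + 1] - cum[i])
    return r[i] + frac * (r[i + 1] - r[i])


@pytest.mark.parametrize("seed", range(5))
def test_weighted_median_matches_interpolation_oracle(seed):
    rng = np.random.default_rng(seed)
    h = random_harmonized(rng, n=11)
    wr = est.wald_ratios(h)
    expected = _weighted_median_oracle(wr["ratio"], 1 / wr["se"] ** 2)
    wm = est.weighted_median(h, n_boot=50, seed=1)
    assert wm.beta == pytest.approx(expected, rel=1e-12)


def test_weighted_median_bootstrap_seeded():
    h = make_harmonized([0.1, 0.2, 0.15, 0.12], [0.01] * 4, [0.05, 0.11, 0.07, 0.06])
    a = est.weighted_median(h, n_boot=100, seed=9)
    b = est.weighted_median(h, n_boot=100, seed=9)
    assert a.se == b.se


# ----------------------------------------------------------------------- mode


def test_mode_majority_cluster():
    h = make_harmonized([0.1] * 4, [0.01] * 4, [0.05, 0.05, 0.05, 0.2])
    m = est.mode_estimate(h, weighted=False, n_boot=50, seed=0)
    assert m.beta == pytest.approx(0.5, abs=0.05)


def test_mode_degenerate_equal_ratios():
    h = make_harmonized([0.1, 0.2, 0.4], [0.01] * 3, [0.05, 0.1, 0.2])
    m = est.mode_estimate(h, weighted=True, n_boot=50, seed=0)
    assert m.beta == pytest.approx(0.5, abs=1e-12)


def _kde_argmax_oracle(ratios, weights, bandwidth, grid_size=4097):
    """Double-loop density evaluation on the same deterministic grid."""
    lo, hi = min(ratios) - 3 * bandwidth, max(ratios) + 3 * bandwidth
    grid = np.linspace(lo, hi, grid_size)
    best_x, best_d = grid[0], -1.0
    for x in grid:
        d = sum(
            w * np.exp(-0.5 * ((x - r) / bandwidth) ** 2)
            for r, w in zip(ratios, weights)
        )
        if d > best_d:
            best_x, best_d = x, d
    return best_x


@pytest.mark.parametrize("weighted", [False, True])
def test_mode_matches_grid_oracle(weighted):
    rng = np.random.default_rng(21)
    ratios = np.concatenate([rng.normal(0.5, 0.02, 6), rng.normal(1.5, 0.02, 3)])
    ses = rng.uniform(0.01, 0.05, 9)
    h = make_harmonized(np.full(9, 0.1), ses * 0.1, ratios * 0.1)
    m = est.mode_estimate(h, weighted=weighted, n_boot=20, seed=0)
    wr = est.wald_ratios(h)
    w = 1 / wr["se"].to_numpy() ** 2 if weighted else np.ones(9)
    w = w / w.sum()
    sd = np.std(wr["ratio"], ddof=1)
    mad = stats.median_abs_deviation(wr["ratio"], scale="normal")
    bw = max(1e-8, 0.9 * min(sd, mad) * 9 ** (-0.2))
    expected = _kde_argmax_oracle(wr["ratio"].to_numpy(), w, bw)
    assert m.beta == pytest.approx(expected, rel=1e-10)


# ------------------------------------------------------- selection & OR scale


def _dummy(method, pval=0.5):
    return est._estimate(method, 5, 0.1, 0.05, pval)


class _Het:
    def __init__(self, pval):
        self.pval = pval


@pytest.mark.parametrize(
    "pleio_p,q_p,expected",
    [
        (0.60, 0.01, est.IVW_RANDOM),
        (0.60, 0.50, est.IVW_FIXED),
        (0.01, 0.50, est.EGGER),
        (0.01, 0.01, est.EGGER),
        (0.049, 0.5, est.EGGER),  # strict < 0.05
    ],
)
def test_select_primary_rule(pleio_p, q_p, expected):
    estimates = {m: _dummy(m) for m in (est.IVW_FIXED, est.IVW_RANDOM, est.EGGER)}
    from mrpath.sensitivity import PleiotropyTest

    pleio = PleiotropyTest(0.01, 0.005, pleio_p, pleio_p < 0.05)
    got = est.select_primary(estimates, _Het(q_p), pleio)
    assert got.method == expected


def test_to_odds_scale_null_and_closed_form():
    assert est.to_odds_scale(0.0, 0.1)["or_"] == 1.0
    o = est.to_odds_scale(0.1, 0.05)
    assert o["or_"] == pytest.approx(np.exp(0.1))
    assert o["ci_low"] == pytest.approx(np.exp(0.1 - 1.96 * 0.05))
    assert o["ci_high"] == pytest.approx(np.exp(0.1 + 1.96 * 0.05))
    assert o["ci_low"] < o["or_"] < o["ci_high"]


# ------------------------------------------------------------------ properties


@pytest.mark.parametrize("c", [0.5, 2.0, -3.0])
def test_rescaling_equivariance(c):
    """beta_exp -> c*beta_exp scales every estimator's beta by 1/c."""
    rng = np.random.default_rng(17)
    h = random_harmonized(rng, n=10)
    hs = make_harmonized(
        c * h.kept["beta_exp"], h.kept["se_out"], h.kept["beta_out"],
        sx=abs(c) * h.kept["se_exp"],
    )
    for f in (
        lambda x: est.ivw(x, "fixed"),
        est.mr_egger,
        lambda x: est.weighted_median(x, 100, 2),
    ):
        assert f(hs).beta == pytest.approx(f(h).beta / c, rel=1e-9)


def test_estimators_agree_without_pleiotropy():
    """Clean homogeneous data: IVW, Egger slope and weighted median agree
    within 2 joint SEs."""
    rng = np.random.default_rng(29)
    n = 50
    bx = rng.uniform(0.05, 0.3, n)
    sy = np.full(n, 0.005)
    by = 0.2 * bx + rng.normal(0, sy)
    h = make_harmonized(bx, sy, by)
    ivw_e = est.ivw(h, "fixed")
    egger_e = est.mr_egger(h)
    wm_e = est.weighted_median(h, 200, 4)
    for a, b in [(ivw_e, egger_e), (ivw_e, wm_e), (egger_e, wm_e)]:
        joint = np.hypot(a.se, b.se)
        assert abs(a.beta - b.beta) < 2 * joint
    assert not egger_intercept_test(egger_e).pleiotropic


def test_ivw_parameter_recovery_coverage():
    """Simulated 50 instruments, true effect 0.1: the estimate lies inside
    its own 95% CI in >= 93 of 100 seeded replicates."""
    hits = 0
    for seed in range(100):
        rng = np.random.default_rng(1000 + seed)
        n = 50
        bx = rng.uniform(0.02, 0.1, n)
        sy = np.full(n, 1 / np.sqrt(0.32 * 50_000))
        by = 0.1 * bx + rng.normal(0, sy)
        e = est.ivw(make_harmonized(bx, sy, by), "fixed")
        hits += e.ci_low <= 0.1 <= e.ci_high
    assert hits >= 93
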