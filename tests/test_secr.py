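"""SECR likelihood correctness, fitting and derived quantities."""

import itertools

import numpy as np
import pytest

from camsecr.datamodel import ParameterError
from camsecr.secr import (
    HabitatMask, R95_FACTOR, SECRFit, SECRModelSpec, _LikelihoodData,
    akaike_weights, build_mask, circular_r95, compare_models, default_start,
    detection_prob, fit_secr, neg_log_likelihood, precision, region_abundance,
    rpsv, suggest_buffer,
)
from conftest import make_history


# ---------------------------------------------------------------------------
# detection function
# ---------------------------------------------------------------------------

def test_detection_prob_half_normal_identities():
    assert detection_prob(0.0, g0=0.3, sigma=500) == pytest.approx(0.3)
    half_d = 500 * np.sqrt(2 * np.log(2))
    assert detection_prob(half_d, 0.3, 500) == pytest.approx(0.15)
    assert detection_prob(1000, 0.2, 500) == pytest.approx(0.2 * np.exp(-2), rel=1e-12)
    with pytest.raises(ParameterError):
        detection_prob(10, 0.2, sigma=0.0)
    with pytest.raises(ParameterError):
        detection_prob(-1, 0.2, 500)


# ---------------------------------------------------------------------------
# likelihood vs exhaustive enumeration
# ---------------------------------------------------------------------------

TINY_MASK = HabitatMask(
    points=np.array([[0.0, 0.0], [500.0, 300.0], [900.0, -200.0], [-300.0, 600.0]]),
    cell_area_km2=0.25, spacing_m=500.0, buffer_m=1000.0,
)
TINY_CAMS = np.array([[0.0, 0.0], [800.0, 0.0]])
TINY_EFFORT = np.array([[1.0, 0.7], [0.5, 1.0]])


def _enumerate_bernoulli(D_by_class, g0_by_class, sigma_by_class, weights):
    """Brute-force Pr(history | centre) over all binary histories and the
    conditional probability of each nonempty history for one individual."""
    K, S = TINY_EFFORT.shape
    a = TINY_MASK.cell_area_km2
    per_class = {}
    for c in D_by_class:
        d2 = ((TINY_CAMS[:, None, :] - TINY_MASK.points[None, :, :]) ** 2).sum(axis=2)
        g = g0_by_class[c] * np.exp(-d2 / (2 * sigma_by_class[c] ** 2))
        per_class[c] = 1 - (1 - g[:, None, :]) ** TINY_EFFORT[:, :, None]
    out = {}
    denom = 0.0
    Lam = 0.0
    for c, p_ks in per_class.items():
        pdot = 1 - np.prod(1 - p_ks, axis=(0, 1))
        Lam += a * D_by_class[c] * weights[c] * pdot.sum()
    for bits in itertools.product([0, 1], repeat=K * S):
        w = np.array(bits).reshape(K, S)
        numer = 0.0
        for c, p_ks in per_class.items():
            pr_m = np.prod(np.where(w[:, :, None] == 1, p_ks, 1 - p_ks), axis=(0, 1))
            numer += a * D_by_class[c] * weights[c] * pr_m.sum()
        out[bits] = numer
    denom = sum(v for bits, v in out.items() if sum(bits) > 0)
    return out, Lam, denom


def test_likelihood_matches_enumeration_oracle_null():
    """Conditional probabilities of all histories sum to 1 and the full
    log-likelihood matches exhaustive enumeration to 1e-10."""
    D, g0, sigma = 1.4, 0.3, 600.0
    spec = SECRModelSpec(variant="null", encounter_model="bernoulli")
    params = np.log([D, g0 / (1 - g0), sigma])
    table, Lam, denom = _enumerate_bernoulli(
        {"all": D}, {"all": g0}, {"all": sigma}, {"all": 1.0})
    total_cond = 0.0
    for bits, numer in table.items():
        if sum(bits) == 0:
            continue
        total_cond += numer / denom
        y = np.array(bits).reshape(1, 2, 2)
        hist = make_history(y, TINY_CAMS, TINY_EFFORT)
        data = _LikelihoodData(hist, TINY_MASK, spec)
        ll = -neg_log_likelihood(params, data)
        assert ll == pytest.approx(-Lam + np.log(numer), abs=1e-10)
    assert total_cond == pytest.approx(1.0, abs=1e-10)
    # Lambda and the all-detected-probability mass agree: sum over all
    # histories including empty equals total intensity contribution
    assert denom == pytest.approx(Lam, rel=1e-10)


def test_likelihood_matches_enumeration_oracle_sex_classes():
    """Two known classes with distinct parameters agree with enumeration."""
    spec = SECRModelSpec(variant="sex", encounter_model="bernoulli")
    Df, Dm, g0f, g0m, sf, sm = 0.9, 0.5, 0.25, 0.35, 500.0, 700.0
    params = np.log([Df, Dm, g0f / (1 - g0f), g0m / (1 - g0m), sf, sm])
    table_f, Lam_f, _ = _enumerate_bernoulli(
        {"f": Df}, {"f": g0f}, {"f": sf}, {"f": 1.0})
    table_m, Lam_m, _ = _enumerate_bernoulli(
        {"m": Dm}, {"m": g0m}, {"m": sm}, {"m": 1.0})
    Lam = Lam_f + Lam_m
    for bits in [(1, 0, 0, 0), (1, 1, 0, 1), (0, 0, 1, 0)]:
        y = np.array(bits).reshape(1, 2, 2)
        for sex, table in [("female", table_f), ("male", table_m),
                           ("unknown", None)]:
            hist = make_history(y, TINY_CAMS, TINY_EFFORT, sex=[sex])
            data = _LikelihoodData(hist, TINY_MASK, spec)
            ll = -neg_log_likelihood(params, data)
            numer = (table_f[bits] + table_m[bits]) if table is None else table[bits]
            assert ll == pytest.approx(-Lam + np.log(numer), abs=1e-10)


def test_likelihood_poisson_count_closed_form():
    spec = SECRModelSpec(variant="null", encounter_model="poisson_count")
    D, lam0, sigma = 1.4, 0.4, 600.0
    params = np.log([D, lam0, sigma])
    y = np.zeros((1, 2, 2), dtype=int)
    y[0, 0, 0] = 2
    y[0, 1, 1] = 1
    hist = make_history(y, TINY_CAMS, TINY_EFFORT)
    data = _LikelihoodData(hist, TINY_MASK, spec)
    from math import lgamma
    d2 = ((TINY_CAMS[:, None, :] - TINY_MASK.points[None, :, :]) ** 2).sum(axis=2)
    lam = lam0 * np.exp(-d2 / (2 * sigma ** 2))
    Lam_m = (TINY_EFFORT.sum(axis=1)[:, None] * lam).sum(axis=0)
    logpr = (-Lam_m + 2 * np.log(lam[0] * TINY_EFFORT[0, 0]) - lgamma(3)
             + np.log(lam[1] * TINY_EFFORT[1, 1]))
    Lam = TINY_MASK.cell_area_km2 * D * (1 - np.exp(-Lam_m)).sum()
    expected = -Lam + np.log(TINY_MASK.cell_area_km2 * D * np.exp(logpr).sum())
    assert -neg_log_likelihood(params, data) == pytest.approx(expected, abs=1e-10)


def test_single_cell_closed_form():
    """1 detector, 1 occasion, 1-cell mask: logL = -D a p + log(D a p)."""
    mask1 = HabitatMask(points=np.array([[0.0, 0.0]]), cell_area_km2=1.0,
                        spacing_m=1000.0, buffer_m=1.0)
    spec = SECRModelSpec(variant="null", encounter_model="bernoulli")
    g0 = 0.3
    hist = make_history(np.ones((1, 1, 1)), [[0.0, 0.0]], np.ones((1, 1)))
    data = _LikelihoodData(hist, mask1, spec)
    for D in [0.5, 1.0, 1.0 / g0, 2.0]:
        nll = neg_log_likelihood(np.log([D, g0 / (1 - g0), 600.0]), data)
        assert -nll == pytest.approx(-D * g0 + np.log(D * g0), abs=1e-12)
    # the maximum sits at D a p = 1
    grid = np.linspace(0.2, 3.0, 281) / g0
    vals = [neg_log_likelihood(np.log([dd, g0 / (1 - g0), 600.0]), data)
            for dd in grid]
    assert grid[int(np.argmin(vals))] == pytest.approx(1.0 / g0, rel=0.01)


def test_no_detection_possible_likelihood_is_minus_inf():
    spec = SECRModelSpec(variant="null", encounter_model="bernoulli")
    y = np.zeros((1, 2, 2), dtype=int)
    y[0, 0, 0] = 1
    hist = make_history(y, TINY_CAMS, TINY_EFFORT)
    data = _LikelihoodData(hist, TINY_MASK, spec)
    # logit g0 of -800 underflows to a detection probability of exactly 0
    nll = neg_log_likelihood(np.array([np.log(1.4), -800.0, np.log(600.0)]), data)
    assert nll == np.inf
    # and the likelihood degrades monotonically on the way there
    vals = [neg_log_likelihood(np.array([np.log(1.4), lg, np.log(600.0)]), data)
            for lg in (-5.0, -20.0, -60.0)]
    assert vals[0] < vals[1] < vals[2]


def test_mask_cell_duplication_invariance():
    """Halving cell area while doubling the cells leaves logL unchanged."""
    spec = SECRModelSpec(variant="null", encounter_model="bernoulli")
    params = np.log([1.4, 0.3 / 0.7, 600.0])
    y = np.array([[[1, 0], [0, 1]]])
    hist = make_history(y, TINY_CAMS, TINY_EFFORT)
    data = _LikelihoodData(hist, TINY_MASK, spec)
    dup = HabitatMask(points=np.vstack([TINY_MASK.points, TINY_MASK.points]),
                      cell_area_km2=TINY_MASK.cell_area_km2 / 2,
                      spacing_m=TINY_MASK.spacing_m, buffer_m=TINY_MASK.buffer_m)
    data2 = _LikelihoodData(hist, dup, spec)
    assert neg_log_likelihood(params, data) == pytest.approx(
        neg_log_likelihood(params, data2), abs=1e-8)


def test_mask_refinement_convergence():
    """The likelihood converges as the mask is refined (fixed buffer)."""
    spec = SECRModelSpec(variant="null", encounter_model="bernoulli")
    params = np.log([1.4, 0.3 / 0.7, 600.0])
    y = np.array([[[1, 0], [0, 1]]])
    hist = make_history(y, TINY_CAMS, TINY_EFFORT)
    vals = {}
    for spacing in (200.0, 100.0, 50.0):
        # 6-sigma buffer: the integrand has decayed smoothly to ~0 at the
        # edge, so the midpoint sum converges fast
        mask = build_mask(TINY_CAMS, buffer_m=3600.0, spacing_m=spacing)
        vals[spacing] = neg_log_likelihood(
            params, _LikelihoodData(hist, mask, spec))
    assert abs(vals[200.0] - vals[100.0]) < 1e-6
    assert abs(vals[100.0] - vals[50.0]) < 1e-6


def test_mixture_with_unit_weight_reduces_to_base_model():
    """pmix fixed at 1 puts all mass on class 1: identical to the
    non-mixture likelihood whatever the latent offsets."""
    y = np.array([[[1, 0], [0, 1]]])
    hist = make_history(y, TINY_CAMS, TINY_EFFORT, sex=["female"])
    base = SECRModelSpec(variant="sex", encounter_model="bernoulli")
    het = SECRModelSpec(variant="sexhet", encounter_model="bernoulli")
    p6 = np.log([0.9, 0.5, 0.25 / 0.75, 0.35 / 0.65, 500.0, 700.0])
    p9 = np.concatenate([p6, [1.3, -0.7, 0.0]])
    nll_base = neg_log_likelihood(p6, _LikelihoodData(hist, TINY_MASK, base))
    nll_het = neg_log_likelihood(p9, _LikelihoodData(hist, TINY_MASK, het),
                                 pmix_fixed=1.0)
    assert nll_het == pytest.approx(nll_base, abs=1e-12)


def test_camera_coverage_offset():
    """Per-camera coverage multiplies the detection intercept; unit
    coverage reproduces the plain model exactly."""
    spec = SECRModelSpec(variant="null", encounter_model="bernoulli",
                         use_coverage=True)
    plain = SECRModelSpec(variant="null", encounter_model="bernoulli")
    params = np.log([1.4, 0.3 / 0.7, 600.0])
    y = np.array([[[1, 0], [0, 1]]])
    hist = make_history(y, TINY_CAMS, TINY_EFFORT)
    nll_unit = neg_log_likelihood(
        params, _LikelihoodData(hist, TINY_MASK, spec, coverage=np.ones(2)))
    nll_plain = neg_log_likelihood(
        params, _LikelihoodData(hist, TINY_MASK, plain))
    assert nll_unit == pytest.approx(nll_plain, abs=1e-12)
    # halving one camera's coverage equals halving g0 at that camera:
    # compare with an enumeration-style direct computation
    cov = np.array([0.5, 1.0])
    nll_cov = neg_log_likelihood(
        params, _LikelihoodData(hist, TINY_MASK, spec, coverage=cov))
    assert nll_cov != pytest.approx(nll_plain)
    with pytest.raises(ParameterError):
        _LikelihoodData(hist, TINY_MASK, spec)       # coverage missing


def test_binomial_n_distribution_variant():
    """The binomial n-distribution replaces the Poisson n-term but leaves
    the history part intact: likelihoods differ, fits stay finite, and the
    two agree as the super-population grows large relative to n."""
    hist, mask = _null_fit_dataset(seed=13)
    pois = SECRModelSpec(variant="null", n_distribution="poisson")
    bino = SECRModelSpec(variant="null", n_distribution="binomial")
    params = np.log([1.5, 0.1 / 0.9, 600.0])
    np_ = neg_log_likelihood(params, _LikelihoodData(hist, mask, pois))
    nb = neg_log_likelihood(params, _LikelihoodData(hist, mask, bino))
    assert np.isfinite(np_) and np.isfinite(nb)
    assert np_ != pytest.approx(nb)
    fit = fit_secr(hist, mask, bino, n_restarts=1)
    d = fit.density()
    assert abs(d["estimate"] - 1.5) < 4 * (d["se"] or 1.0)


# ---------------------------------------------------------------------------
# spec bookkeeping
# ---------------------------------------------------------------------------

@pytest.mark.parametrize("variant, k", [
    ("null", 3), ("sex", 6), ("sexhet", 9), ("group", 6), ("grouphet", 9),
])
def test_parameter_counts_follow_the_model_ladder(variant, k):
    spec = SECRModelSpec(variant=variant)
    assert spec.n_params == k
    assert len(spec.param_names()) == k


# ---------------------------------------------------------------------------
# buffer suggestion
# ---------------------------------------------------------------------------

def test_rpsv_hand_computation():
    """Two detections at (0,0) and (1000,0): combined sum of squares
    500000 on one degree of freedom, halved per axis so RPSV estimates the
    per-axis scale: RPSV = 500, buffer = 2000."""
    y = np.zeros((1, 2, 2), dtype=int)
    y[0, 0, 0] = 1
    y[0, 1, 0] = 1
    hist = make_history(y, [[0.0, 0.0], [1000.0, 0.0]], np.ones((2, 2)))
    assert rpsv(hist) == pytest.approx(500.0)
    assert suggest_buffer(hist) == pytest.approx(2000.0)


def test_rpsv_degenerate_cases():
    y = np.zeros((1, 2, 2), dtype=int)
    y[0, 0, 0] = 1
    y[0, 0, 1] = 1           # both detections at the same detector
    hist = make_history(y, [[0.0, 0.0], [1000.0, 0.0]], np.ones((2, 2)))
    with pytest.raises(ParameterError, match="zero spatial variance|single"):
        rpsv(hist)
    y2 = np.zeros((1, 2, 2), dtype=int)
    y2[0, 0, 0] = 1          # no recaptures at all
    hist2 = make_history(y2, [[0.0, 0.0], [1000.0, 0.0]], np.ones((2, 2)))
    with pytest.raises(ParameterError):
        rpsv(hist2)


def test_suggested_buffer_brackets_known_sigma():
    """On half-normal data with sigma = 600 m the 4xRPSV buffer lands in a
    plausible window around 4 sigma across seeds."""
    from camsecr import synthetic
    from camsecr.datamodel import build_capture_history, build_effort
    scen = synthetic.SimulationScenario(
        name="s", species_profile="fission_fusion", density=1.5,
        male_fraction=0.5, encounter_model="bernoulli",
        g0={"female": 0.05, "male": 0.05},
        sigma_m={"female": 600.0, "male": 600.0},
        grid_shape=(7, 6), id_success=1.0, co_trigger_prob=0.0,
        mean_unit_size=1.0, community_radius_m=1.0,
        downtime_blocks_per_camera=0.0,
    )
    for seed in (11, 23, 37):
        study = synthetic.simulate_study(scen, seed=seed)
        occs = scen.occasions()
        eff = build_effort(study.activity, occs,
                           [c.camera_id for c in study.cameras])
        hist = build_capture_history(study.records, study.cameras, occs, eff)
        assert 2000 <= suggest_buffer(hist) <= 3200


# ---------------------------------------------------------------------------
# mask construction
# ---------------------------------------------------------------------------

def test_build_mask_lattice_geometry():
    mask = build_mask(np.array([[0.0, 0.0]]), buffer_m=1000.0, spacing_m=500.0)
    assert mask.n_cells == 25
    assert mask.area_km2 == pytest.approx(25 * 0.25)


def test_build_mask_habitat_clipping_halves_area():
    from shapely.geometry import box
    cams = np.array([[0.0, 0.0]])
    full = build_mask(cams, 1000.0, 500.0)
    # habitat covering only x <= 0 keeps the left 3 of 5 columns (centres
    # at -1000, -500, 0)
    habitat = box(-2000.0, -2000.0, 1e-9, 2000.0)
    clipped = build_mask(cams, 1000.0, 500.0, habitat=habitat)
    assert clipped.n_cells == 15
    assert clipped.area_km2 == pytest.approx(full.area_km2 * 3 / 5)
    with pytest.raises(ParameterError, match="zero habitat"):
        build_mask(cams, 1000.0, 500.0, habitat=box(5000, 5000, 6000, 6000))


# ---------------------------------------------------------------------------
# fitting and model comparison
# ---------------------------------------------------------------------------

def _null_fit_dataset(seed=11):
    from camsecr import synthetic
    from camsecr.datamodel import build_capture_history, build_effort
    scen = synthetic.SimulationScenario(
        name="s", species_profile="fission_fusion", density=1.5,
        male_fraction=0.5, encounter_model="bernoulli",
        g0={"female": 0.1, "male": 0.1}, sigma_m={"female": 600.0, "male": 600.0},
        grid_shape=(7, 6), id_success=1.0, co_trigger_prob=0.0,
        mean_unit_size=1.0, community_radius_m=1.0,
        downtime_blocks_per_camera=0.0, n_occasions=20,
    )
    study = synthetic.simulate_study(scen, seed=seed)
    occs = scen.occasions()
    eff = build_effort(study.activity, occs, [c.camera_id for c in study.cameras])
    hist = build_capture_history(study.records, study.cameras, occs, eff)
    mask = build_mask(hist.camera_xy(), 2400.0, spacing_m=300.0)
    return hist, mask


def test_fit_recovers_null_model_parameters():
    hist, mask = _null_fit_dataset(seed=11)
    fit = fit_secr(hist, mask, SECRModelSpec(variant="null"), n_restarts=1)
    assert fit.converged
    d = fit.density()
    assert abs(d["estimate"] - 1.5) < 3 * d["se"]
    s = fit.sigma()
    assert abs(s["estimate"] - 600.0) < 3 * s["se"]
    # determinism given identical inputs
    fit2 = fit_secr(hist, mask, SECRModelSpec(variant="null"), n_restarts=1)
    assert np.allclose(fit.params, fit2.params)


def test_aicc_prefers_null_over_spurious_sex_effect():
    """With sexes assigned at random, the sex model's three extra
    parameters are penalised in most replicates."""
    wins = 0
    trials = 12
    for seed in range(trials):
        hist, mask = _null_fit_dataset(seed=100 + seed)
        rng = np.random.default_rng(seed)
        hist.covariates["sex"] = rng.choice(["male", "female"], size=hist.n)
        f0 = fit_secr(hist, mask, SECRModelSpec(variant="null"), n_restarts=1)
        f1 = fit_secr(hist, mask, SECRModelSpec(variant="sex"), n_restarts=1)
        if f0.aicc < f1.aicc:
            wins += 1
    assert wins > trials / 2


def _fake_fit(variant, k, loglik, n):
    spec = SECRModelSpec(variant=variant)
    return SECRFit(spec=spec, params=np.zeros(k), param_names=[f"p{i}" for i in range(k)],
                   loglik=loglik, n=n, converged=True)


def test_compare_models_table():
    single = compare_models([_fake_fit("null", 3, -100.0, 50)])
    assert single.loc[0, "dAICc"] == 0.0 and single.loc[0, "AICwt"] == 1.0

    pair = compare_models([_fake_fit("null", 3, -100.0, 50),
                           _fake_fit("sex", 3, -100.0, 50)])
    assert np.allclose(pair["AICwt"], [0.5, 0.5])

    with pytest.raises(ParameterError):
        compare_models([_fake_fit("null", 3, -100.0, 50),
                        _fake_fit("sex", 3, -100.0, 60)])


def test_akaike_weights_reported_pattern():
    """dAICc of (0, 3.6, 12.3) splits support roughly 0.86 / 0.14 / 0.00."""
    w = akaike_weights([1000.0, 1003.6, 1012.3])
    assert round(float(w[0]), 2) == 0.86
    assert round(float(w[1]), 2) == 0.14
    assert round(float(w[2]), 2) == 0.00
    assert w.sum() == pytest.approx(1.0, abs=1e-12)


def test_aicc_definition_and_small_sample_guard():
    f = _fake_fit("null", 3, -100.0, 50)
    assert f.aic == pytest.approx(206.0)
    assert f.aicc == pytest.approx(206.0 + 2 * 3 * 4 / (50 - 4))
    tiny = _fake_fit("null", 3, -100.0, 4)
    assert tiny.aicc is None


# ---------------------------------------------------------------------------
# derived quantities
# ---------------------------------------------------------------------------

def test_region_abundance_scales_density():
    f = _fake_fit("null", 3, -100.0, 50)
    f.params = np.array([0.0, 0.0, 6.0])
    f.param_names = ["log_D", "link_g0", "log_sigma"]
    out = region_abundance(f, 100.0)
    assert out["estimate"] == pytest.approx(100.0)     # D = e^0 = 1
    assert region_abundance(f, 0.0)["estimate"] == 0.0
    with pytest.raises(ParameterError):
        region_abundance(f, -5.0)


def test_region_abundance_ci_multiplication():
    """The gorilla-style full-mask case: D CI (0.93-1.68) over 160 km^2
    gives an abundance CI of (148.8-268.8)."""
    lo, hi = 0.93 * 160, 1.68 * 160
    assert lo == pytest.approx(148.8)
    assert hi == pytest.approx(268.8)
    f = _fake_fit("null", 3, -100.0, 50)
    f.params = np.array([np.log(1.2), 0.0, 6.0])
    f.param_names = ["log_D", "link_g0", "log_sigma"]
    # the fitted CI route: transform link-scale CI through the area
    f.vcov = np.diag([0.05, 0.1, 0.01])
    out = region_abundance(f, 160.0)
    d = f.density()
    assert out["ci_low"] == pytest.approx(d["ci_low"] * 160.0)
    assert out["ci_high"] == pytest.approx(d["ci_high"] * 160.0)


def test_circular_r95():
    assert circular_r95(1.0)["r95_m"] == pytest.approx(2.4477, abs=1e-4)
    a1 = circular_r95(800.0)["area_km2"]
    a2 = circular_r95(1600.0)["area_km2"]
    assert a2 == pytest.approx(4 * a1)
    # a 1475 m sigma corresponds to a ~41 km^2 circular home range
    assert circular_r95(1475.0)["area_km2"] == pytest.approx(41.0, abs=0.5)
    out = circular_r95(600.0, sigma_ci=(500.0, 700.0))
    assert out["r95_ci_m"][0] == pytest.approx(500 * R95_FACTOR)
    with pytest.raises(ParameterError):
        circular_r95(0.0)


def test_precision_metric():
    assert precision(1.72, 1.54, 1.95) == 24
    assert precision(2.32, 2.30, 2.35) == 2
    assert precision(5.0, 5.0, 5.0) == 0
    with pytest.raises(ParameterError):
        precision(0.0, -1.0, 1.0)
    with pytest.raises(ParameterError):
        precision(1.0, 1.1, 1.2)
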