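import math

import numpy as np
import pytest

from hbboundary.embryo import (
    HillBoundaryModel,
    SyntheticEmbryo,
    align_embryos,
    embryos_to_frame,
    empirical_delta_x,
    fit_hill,
    generate_embryos,
    strip_cv,
)
from hbboundary.models import hill_numeric
from hbboundary.resolution import bernoulli_delta_x
from hbboundary.scan import steep_chain_model
from hbboundary.units import EL_BOUNDARY, LAMBDA_EL


@pytest.fixture(scope="module")
def moderate_model():
    """Moderately steep chain with fast enough switching to average."""
    return steep_chain_model(6, intermediate_weight=0.35, time_scale=50.0)


@pytest.fixture(scope="module")
def frozen_model():
    """Frozen-switching chain: Bernoulli readouts with H = 6."""
    return steep_chain_model(6, time_scale=1e-9)


@pytest.fixture(scope="module")
def frozen_embryos(frozen_model):
    # offset-free and noise-free: the raw coordinates are already
    # boundary-aligned, isolating the binned statistics from alignment
    # jitter
    return generate_embryos(
        frozen_model, "nc13", n_embryos=8, nuclei_per_row=200,
        noise_cv=0.0, offset_sd=0.0, seed=7,
    )


# -- generation -------------------------------------------------------------


def test_default_embryo_counts(moderate_model):
    assert len(generate_embryos(moderate_model, "nc12", nuclei_per_row=8, n_rows=1, seed=0)) == 8
    assert len(generate_embryos(moderate_model, "nc13", nuclei_per_row=8, n_rows=1, seed=0)) == 4


def test_no_embryos_requested(moderate_model):
    assert generate_embryos(moderate_model, "nc13", n_embryos=0, seed=0) == []


def test_unknown_cycle_rejected(moderate_model):
    with pytest.raises(ValueError):
        generate_embryos(moderate_model, "nc99", seed=0)


def test_embryo_invariants(moderate_model):
    (e,) = generate_embryos(moderate_model, "nc13", n_embryos=1, seed=3)
    assert np.all(e.x_el >= -50) and np.all(e.x_el <= 50)
    assert np.all(e.readout >= 0)
    with pytest.raises(ValueError):
        SyntheticEmbryo(0, "nc13", [60.0], [1.0], 0.0, 0.0, 0)
    with pytest.raises(ValueError):
        SyntheticEmbryo(0, "nc13", [0.0], [-1.0], 0.0, 0.0, 0)


def test_noise_free_bin_means_follow_activation_curve(frozen_model):
    """Without measurement noise or offsets, per-position mean readouts
    equal the model's activation probability up to SSA sampling error."""
    from hbboundary.models import activation_probability

    embs = generate_embryos(
        frozen_model, "nc13", n_embryos=8, nuclei_per_row=21, n_rows=12,
        noise_cv=0.0, offset_sd=0.0, fluorescence_scale=1.0, seed=11,
    )
    x = np.concatenate([e.x_el for e in embs])
    y = np.concatenate([e.readout for e in embs])
    for x_el in np.unique(x)[3:-3]:
        sel = x == x_el
        p = activation_probability(frozen_model, (EL_BOUNDARY - x_el) / LAMBDA_EL)
        n = sel.sum()
        se = math.sqrt(max(p * (1 - p), 1e-6) / n)
        assert abs(y[sel].mean() - p) < 4 * se + 1e-6


# -- alignment --------------------------------------------------------------


def test_alignment_recovers_injected_offset(moderate_model):
    embs = generate_embryos(
        moderate_model, "nc13", n_embryos=1, noise_cv=0.05, offset_sd=0.0, seed=5
    )
    from dataclasses import replace

    # inject a known +3% EL boundary offset by shifting the coordinates
    moved = [replace(embs[0], x_el=np.clip(embs[0].x_el + 3.0, -50, 50))]
    aligned = align_embryos(moved)
    shift = aligned[0].x_el_aligned[0] - moved[0].x_el[0]
    assert shift == pytest.approx(-3.0, abs=1.5)


def test_alignment_zero_offset_and_idempotence(moderate_model):
    embs = generate_embryos(
        moderate_model, "nc13", n_embryos=2, noise_cv=0.05, offset_sd=0.0, seed=6
    )
    aligned = align_embryos(embs)
    shifts = [a.x_el_aligned[0] - e.x_el[0] for a, e in zip(aligned, embs)]
    assert np.all(np.abs(shifts) < 1.5)
    again = align_embryos(aligned)
    for a, b in zip(aligned, again):
        assert np.allclose(a.x_el_aligned, b.x_el_aligned, atol=1e-9)


def test_alignment_fails_on_flat_profile():
    flat = SyntheticEmbryo(0, "nc13", np.linspace(-40, 40, 30), np.full(30, 5.0), 0.0, 0.0, 0)
    with pytest.raises(ValueError):
        align_embryos([flat])


# -- Hill boundary fit ------------------------------------------------------


def test_fit_recovers_exact_hill_data():
    """Noise-free data drawn from an exact Hill curve: self-recovery."""
    rng = np.random.default_rng(0)
    x = np.linspace(-35, 25, 60)
    tf = np.exp((EL_BOUNDARY - x) / LAMBDA_EL)
    h_true = 3.0
    y = tf**h_true / (1.0 + tf**h_true)
    embryos_x = np.tile(x, 3)
    embryos_y = np.tile(y, 3)
    ids = np.repeat([0, 1, 2], len(x))
    res = HillBoundaryModel(embryos_x, embryos_y, ids).fit()
    assert res.hill == pytest.approx(3.0, abs=0.01)
    assert res.tf0 == pytest.approx(1.0, abs=0.01)
    assert not res.diverged
    lo, hi = res.conf_int()[1]
    assert lo <= res.hill <= hi
    assert "Hill boundary fit" in res.summary()


def test_fit_flags_step_data():
    x = np.linspace(-35, 25, 60)
    y = (x < EL_BOUNDARY).astype(float)
    res = HillBoundaryModel(np.tile(x, 2), np.tile(y, 2), np.repeat([0, 1], 60)).fit()
    assert res.diverged


def test_fit_needs_enough_bins():
    with pytest.raises(ValueError):
        HillBoundaryModel(np.array([0.0, 1.0]), np.array([1.0, 0.5]), np.array([0, 0])).fit()


def test_fit_recovers_generator_hill(moderate_model):
    h_true = hill_numeric(moderate_model)
    embs = align_embryos(generate_embryos(moderate_model, "nc12", seed=42))
    res = fit_hill(embs)
    lo, hi = res.conf_int()[1]
    assert lo <= h_true <= hi
    assert res.hill == pytest.approx(h_true, rel=0.25)


def test_bootstrap_ci_contains_estimate(moderate_model):
    embs = align_embryos(generate_embryos(moderate_model, "nc13", seed=9))
    res = fit_hill(embs, ci_method="bootstrap", n_boot=60, seed=1)
    lo, hi = res.conf_int()[1]
    assert lo <= res.hill <= hi


# -- empirical resolution and strip CV -------------------------------------


def test_empirical_delta_x_matches_bernoulli_oracle(frozen_embryos):
    res = empirical_delta_x(frozen_embryos)
    closed = bernoulli_delta_x(6.0).delta_x_el
    assert abs(res.delta_x_el - closed) <= res.grid_step_el + 1e-9


def test_perfectly_separated_data_resolves_at_first_bin():
    x = np.linspace(-40, 30, 100)
    y = np.where(x < EL_BOUNDARY, 10.0, 0.0) + np.linspace(0, 0.1, 100)
    e = SyntheticEmbryo(0, "nc13", x, np.clip(y, 0, None), 0.0, 0.0, 0)
    res = empirical_delta_x([e], bin_width=5.0)
    assert res.delta_x_el == 5.0


def test_identical_readouts_unresolvable():
    x = np.linspace(-40, 30, 100)
    e = SyntheticEmbryo(0, "nc13", x, np.full(100, 3.0), 0.0, 0.0, 0)
    res = empirical_delta_x([e], bin_width=5.0)
    assert not res.resolvable


def test_strip_cv_values(frozen_embryos):
    # Bernoulli(0.5) readouts at the boundary strip: CV ~ 1
    assert strip_cv(frozen_embryos) == pytest.approx(1.0, abs=0.15)
    # constant readouts: CV = 0
    e = SyntheticEmbryo(0, "nc13", np.linspace(-10, 0, 20), np.full(20, 2.0), 0.0, 0.0, 0)
    assert strip_cv([e], centre_el=-5.0) == 0.0


def test_posterior_strip_noisier_than_boundary(frozen_embryos):
    """Nuclei posterior of the boundary express rarely, inflating the
    relative readout error of their strip."""
    cv_boundary = strip_cv(frozen_embryos, centre_el=EL_BOUNDARY)
    cv_posterior = strip_cv(frozen_embryos, centre_el=EL_BOUNDARY + 7.5)
    assert cv_posterior >= cv_boundary


# -- export -----------------------------------------------------------------


def test_frame_schema(moderate_model):
    embs = align_embryos(
        generate_embryos(moderate_model, "nc13", n_embryos=2, nuclei_per_row=10, n_rows=1, seed=1)
    )
    df = embryos_to_frame(embs)
    assert list(df.columns) == [
        "embryo_id", "nc", "nucleus_id", "x_el_raw", "x_el_aligned", "readout",
    ]
    assert len(df) == 20
    assert df["x_el_aligned"].notna().all()
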