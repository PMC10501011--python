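import dataclasses

import numpy as np
import pytest

from chmfit.chm import (
    CHMFeaturizer,
    CHMModel,
    Dataset,
    NonlinearParams,
    SearchSpace,
    chm_energy,
    density_diagonal,
    density_matrix,
    density_offdiagonal,
    energy_decomposition,
    evaluate_report,
    fit_chm,
    fit_linear,
    fit_pip_baseline,
    optimize_nonlinear,
    total_electron_count,
)
from chmfit.constants import HARTREE_TO_CM
from chmfit.integrals import core_matrices
from chmfit.molsys import (
    Configuration,
    InputError,
    apply_permutation,
    build_perm_group,
    distances_batch,
)
from chmfit.pipbasis import enumerate_invariant_basis, evaluate_basis_batch
from util import random_config


def zero_model(typing, n_atoms, M, nlparams):
    f = CHMFeaturizer(typing, n_atoms, M)
    return CHMModel(
        featurizer=f, coeffs=np.zeros(f.n_columns), nlparams=nlparams,
    )


def random_model(typing, n_atoms, M, nlparams, rng, scale=0.05):
    f = CHMFeaturizer(typing, n_atoms, M)
    return CHMModel(
        featurizer=f,
        coeffs=rng.normal(scale=scale, size=f.n_columns),
        nlparams=nlparams,
    )


# ---------------------------------------------------------------------------
# densities


def test_zero_coeff_populations_heh(heh_typing):
    nl = NonlinearParams(d0=2.0, t0=2.0, alpha={"He": 1.2, "H": 0.8})
    model = zero_model(heh_typing, 2, 1, nl)
    c = Configuration(elements=("He", "H"),
                      coords=np.array([[0, 0, 0], [0, 0, 0.79]]))
    assert density_diagonal(c, model, 0) == pytest.approx(2.0)
    assert density_diagonal(c, model, 1) == pytest.approx(0.0)
    assert density_offdiagonal(c, model, (0, 1)) == pytest.approx(0.0)


def test_zero_coeff_populations_h3(h3_typing, h3_nlparams):
    model = zero_model(h3_typing, 3, 2, h3_nlparams)
    rng = np.random.default_rng(0)
    c = random_config(["H"] * 3, rng)
    for a in range(3):
        assert density_diagonal(c, model, a) == pytest.approx(2.0 / 3.0)


def test_density_diagonal_covariance(h3_typing, h3_nlparams):
    rng = np.random.default_rng(1)
    model = random_model(h3_typing, 3, 2, h3_nlparams, rng)
    c = random_config(["H"] * 3, rng)
    swap = (1, 0, 2)
    moved = apply_permutation(c, swap, typing=h3_typing)
    assert density_diagonal(moved, model, 1) == pytest.approx(
        density_diagonal(c, model, 0), rel=1e-12
    )
    assert density_diagonal(moved, model, 0) == pytest.approx(
        density_diagonal(c, model, 1), rel=1e-12
    )


def test_density_offdiagonal_covariance(ch5_typing):
    nl = NonlinearParams(d0=2.0, t0=1.5, alpha={"C": 1.0, "H": 1.0})
    rng = np.random.default_rng(2)
    model = random_model(ch5_typing, 6, 1, nl, rng)
    c = random_config(["C"] + ["H"] * 5, rng)
    perm = (0, 2, 1, 3, 4, 5)  # H1 <-> H2
    moved = apply_permutation(c, perm, typing=ch5_typing)
    # P_1c -> P_2c for every other atom c
    for other in (3, 4, 5):
        assert density_offdiagonal(moved, model, (2, other)) == pytest.approx(
            density_offdiagonal(c, model, (1, other)), rel=1e-10, abs=1e-14
        )
    assert density_offdiagonal(moved, model, (1, 2)) == pytest.approx(
        density_offdiagonal(c, model, (1, 2)), rel=1e-10, abs=1e-14
    )


def test_density_offdiagonal_symmetric_and_decaying(h3_typing, h3_nlparams):
    rng = np.random.default_rng(3)
    model = random_model(h3_typing, 3, 2, h3_nlparams, rng)
    c = random_config(["H"] * 3, rng)
    assert density_offdiagonal(c, model, (0, 1)) == pytest.approx(
        density_offdiagonal(c, model, (1, 0)), rel=1e-14
    )
    far = Configuration(
        elements=("H",) * 3,
        coords=np.array([[0, 0, 0], [0, 0, 40.0], [0, 40.0, 0]]),
    )
    assert abs(density_offdiagonal(far, model, (0, 1))) < 1e-12


def test_density_diag_for_pair_rejected(h3_typing, h3_nlparams):
    model = zero_model(h3_typing, 3, 2, h3_nlparams)
    rng = np.random.default_rng(4)
    c = random_config(["H"] * 3, rng)
    with pytest.raises(InputError):
        density_offdiagonal(c, model, (1, 1))


# ---------------------------------------------------------------------------
# energies


def test_zero_coeff_energy_is_core(h3_typing, h3_nlparams):
    model = zero_model(h3_typing, 3, 2, h3_nlparams)
    rng = np.random.default_rng(5)
    c = random_config(["H"] * 3, rng)
    typing_a = dataclasses.replace(h3_typing, exponents=h3_nlparams.alpha)
    cm = core_matrices(c, typing_a)
    expected = cm.Enuc + (2.0 / 3.0) * np.trace(cm.Hcore)
    assert chm_energy(c, model) == pytest.approx(expected, rel=1e-12)
    assert model.predict([c])[0] == pytest.approx(expected, rel=1e-12)


def test_chm_energy_matches_predict(h3_typing, h3_nlparams):
    rng = np.random.default_rng(6)
    model = random_model(h3_typing, 3, 2, h3_nlparams, rng)
    for _ in range(5):
        c = random_config(["H"] * 3, rng)
        assert chm_energy(c, model) == pytest.approx(
            model.predict([c])[0], abs=1e-12
        )


def test_energy_permutation_invariance(h3_typing, h3_chm2_model):
    group = build_perm_group(h3_typing, 3)
    rng = np.random.default_rng(7)
    for _ in range(20):
        c = random_config(["H"] * 3, rng)
        e0 = h3_chm2_model.predict([c])[0]
        for perm in group.elements:
            moved = apply_permutation(c, perm, typing=h3_typing)
            assert h3_chm2_model.predict([moved])[0] == pytest.approx(
                e0, abs=1e-10
            )


def test_total_electron_count_zero_coeffs(ch5_typing, h3_typing, h3_nlparams):
    nl = NonlinearParams(d0=2.0, t0=1.5, alpha={"C": 1.0, "H": 1.0})
    model = zero_model(ch5_typing, 6, 1, nl)
    rng = np.random.default_rng(8)
    c = random_config(["C"] + ["H"] * 5, rng)
    assert total_electron_count(c, model) == pytest.approx(10.0, rel=1e-12)
    m3 = zero_model(h3_typing, 3, 2, h3_nlparams)
    c3 = random_config(["H"] * 3, rng)
    assert total_electron_count(c3, m3) == pytest.approx(2.0, rel=1e-12)


def test_electron_count_matrix_contraction_oracle(h3_typing, h3_nlparams):
    rng = np.random.default_rng(9)
    model = random_model(h3_typing, 3, 2, h3_nlparams, rng)
    c = random_config(["H"] * 3, rng)
    typing_a = dataclasses.replace(h3_typing, exponents=h3_nlparams.alpha)
    cm = core_matrices(c, typing_a)
    P = density_matrix(c, model)
    assert total_electron_count(c, model) == pytest.approx(
        float(np.sum(P * cm.S)), abs=1e-12
    )


def test_energy_decomposition(h3_typing, h3_chm2_model):
    rng = np.random.default_rng(10)
    c = random_config(["H"] * 3, rng)
    hf_like, corr = energy_decomposition(c, h3_chm2_model)
    total = chm_energy(c, h3_chm2_model) * HARTREE_TO_CM
    assert hf_like + corr == pytest.approx(total, abs=1e-9)
    # zero correction coefficients -> zero correction component
    zero_corr = CHMModel(
        featurizer=h3_chm2_model.featurizer,
        coeffs=h3_chm2_model.coeffs.copy(),
        nlparams=h3_chm2_model.nlparams,
        energy_offset=h3_chm2_model.energy_offset,
    )
    blocks = dict(
        (n, (lo, hi)) for n, _, lo, hi in
        h3_chm2_model.featurizer.column_blocks()
    )
    lo, hi = blocks["corr"]
    zero_corr.coeffs[lo:hi] = 0.0
    _, corr0 = energy_decomposition(c, zero_corr)
    assert corr0 == pytest.approx(0.0, abs=1e-12)


# ---------------------------------------------------------------------------
# design matrix


def test_design_columns_ch5(ch5_typing):
    f = CHMFeaturizer(ch5_typing, 6, 4)
    assert f.L == 101
    assert f.n_columns == 501  # 4 classes x 100 + 101


def test_design_columns_heh(heh_typing):
    f = CHMFeaturizer(heh_typing, 2, 1)
    assert f.L == 2
    assert f.n_columns == 3 * (f.L - 1) + f.L  # 5


def test_design_row_targets(h3_typing, h3_dataset, h3_nlparams):
    f = CHMFeaturizer(h3_typing, 3, 2)
    X, base, Xq = f.design(
        h3_dataset.configs[:10], h3_nlparams, with_charge_rows=True
    )
    assert X.shape == (10, f.n_columns)
    assert Xq.shape == X.shape
    # correction block has a constant-one column
    lo, hi = [(lo, hi) for n, _, lo, hi in f.column_blocks() if n == "corr"][0]
    np.testing.assert_allclose(X[:, lo], 1.0, atol=1e-14)
    np.testing.assert_allclose(Xq[:, lo:hi], 0.0)


def test_empty_dataset_rejected(h3_typing, h3_nlparams):
    f = CHMFeaturizer(h3_typing, 3, 2)
    with pytest.raises(InputError):
        f.design([], h3_nlparams)


# ---------------------------------------------------------------------------
# linear solver


def test_fit_linear_synthetic_recovery():
    rng = np.random.default_rng(11)
    X = rng.normal(size=(60, 8))
    c_true = rng.normal(size=8)
    y = X @ c_true
    c, diag = fit_linear(X, y)
    np.testing.assert_allclose(X @ c, y, atol=1e-9)
    assert diag["rank"] == 8


def test_fit_linear_duplicated_rows():
    rng = np.random.default_rng(12)
    X = rng.normal(size=(30, 5))
    y = rng.normal(size=30)
    c1, _ = fit_linear(X, y)
    c2, _ = fit_linear(np.vstack([X, X]), np.concatenate([y, y]))
    np.testing.assert_allclose(c1, c2, atol=1e-10)


def test_fit_linear_zero_weight_removes_contamination():
    rng = np.random.default_rng(13)
    X = rng.normal(size=(40, 4))
    y = X @ rng.normal(size=4)
    Xc = np.vstack([X, rng.normal(size=(1, 4))])
    yc = np.concatenate([y, [57.0]])
    w = np.concatenate([np.ones(40), [0.0]])
    c_clean, _ = fit_linear(X, y)
    c_weighted, _ = fit_linear(Xc, yc, w)
    np.testing.assert_allclose(c_clean, c_weighted, atol=1e-9)


def test_fit_linear_rank_deficient_min_norm():
    X = np.ones((10, 3))
    y = np.full(10, 6.0)
    c, diag = fit_linear(X, y)
    assert diag["rank"] == 1
    np.testing.assert_allclose(c, 2.0, atol=1e-10)  # minimum-norm split


def test_fit_linear_all_zero_weights():
    with pytest.raises(InputError):
        fit_linear(np.ones((3, 1)), np.ones(3), np.zeros(3))


# ---------------------------------------------------------------------------
# model fits


def test_pip_exact_fit_on_polynomial_data(h3_typing, h3_dataset):
    """Data generated from a degree-M invariant polynomial fits exactly."""
    basis = enumerate_invariant_basis(h3_typing, 3, 2)
    d0 = 1.4
    rng = np.random.default_rng(14)
    c_true = rng.normal(size=basis.L)
    D = distances_batch(h3_dataset.coords_array())
    y = evaluate_basis_batch(basis, D, d0) @ c_true
    ds = Dataset(configs=h3_dataset.configs, energies=y)
    rep = fit_pip_baseline(ds, h3_typing, 2, d0)
    assert rep.rmse_train < 1e-6  # cm^-1


def test_pip_rmse_nonincreasing_in_m(h3_typing, h3_dataset):
    rmses = [
        fit_pip_baseline(h3_dataset, h3_typing, M, 1.4).rmse_train
        for M in (1, 2, 3, 4)
    ]
    assert all(b <= a + 1e-9 for a, b in zip(rmses, rmses[1:]))


def test_chm_rmse_nonincreasing_in_m(h3_typing, h3_dataset, h3_nlparams):
    rmses = [
        fit_chm(h3_dataset, h3_typing, M, h3_nlparams,
                charge_weight=0.0).rmse_train
        for M in (1, 2, 3)
    ]
    assert all(b <= a + 1e-9 for a, b in zip(rmses, rmses[1:]))


def test_chm_beats_pip_at_zero_charge_weight(h3_typing, h3_dataset,
                                             h3_nlparams):
    for M in (1, 2, 3):
        chm = fit_chm(h3_dataset, h3_typing, M, h3_nlparams,
                      charge_weight=0.0).rmse_train
        pip = fit_pip_baseline(h3_dataset, h3_typing, M,
                               h3_nlparams.d0).rmse_train
        assert chm <= pip + 1e-9


def test_synthetic_chm_recovery(h3_typing, h3_dataset, h3_nlparams):
    """Energies generated by a known CHM model are reproduced exactly."""
    rng = np.random.default_rng(15)
    truth = random_model(h3_typing, 3, 2, h3_nlparams, rng, scale=0.02)
    energies = truth.predict(h3_dataset.configs)
    ds = Dataset(configs=h3_dataset.configs, energies=energies)
    rep = fit_chm(ds, h3_typing, 2, h3_nlparams, charge_weight=0.0)
    pred = rep.model.predict(ds.configs)
    scale = max(1.0, float(np.max(np.abs(energies))))
    assert np.max(np.abs(pred - energies)) / scale < 1e-8


def test_fit_report_consistency(h3_chm2_report, h3_dataset):
    rep = h3_chm2_report
    recomputed = float(np.sqrt(np.mean(rep.residuals_train**2)))
    assert rep.rmse_train == pytest.approx(recomputed, abs=1e-10)
    assert rep.max_error("train")[0] >= rep.rmse_train
    ev = evaluate_report(rep.model, h3_dataset)
    assert ev.rmse_train == pytest.approx(rep.rmse_train, abs=1e-9)


def test_evaluate_on_training_set_matches(h3_typing, h3_dataset, h3_nlparams):
    rep = fit_chm(h3_dataset, h3_typing, 2, h3_nlparams, test=h3_dataset)
    assert rep.rmse_test == pytest.approx(rep.rmse_train, abs=1e-10)


# ---------------------------------------------------------------------------
# nonlinear search


def small_space():
    return SearchSpace(d0=(0.5, 2.0, 3), t0=(0.5, 2.0, 3),
                       alpha=(0.4, 1.2, 3))


def test_optimize_deterministic(h3_typing, h3_dataset):
    sub = Dataset(configs=h3_dataset.configs[:120],
                  energies=h3_dataset.energies[:120])
    kw = dict(search_space=small_space(), seed=3, n_sweeps=1,
              refine_maxfev=10)
    best1, rep1 = optimize_nonlinear(sub, None, h3_typing, 1, **kw)
    best2, rep2 = optimize_nonlinear(sub, None, h3_typing, 1, **kw)
    assert best1 == best2
    assert rep1.rmse_train == rep2.rmse_train


def test_optimize_returns_argmin_over_evaluated_points(
    h3_typing, h3_dataset, monkeypatch
):
    """The returned objective is <= every objective evaluated in the search."""
    import chmfit.chm as chm_mod

    sub = Dataset(configs=h3_dataset.configs[:120],
                  energies=h3_dataset.energies[:120])
    seen = []
    original = chm_mod.fit_chm

    def spy(*args, **kwargs):
        rep = original(*args, **kwargs)
        if rep.rmse_test is not None:
            seen.append(rep.rmse_test)
        return rep

    monkeypatch.setattr(chm_mod, "fit_chm", spy)
    _, rep = optimize_nonlinear(sub, None, h3_typing, 1,
                                search_space=small_space(), n_sweeps=1,
                                refine_maxfev=10)
    assert seen
    assert rep.rmse_test <= min(seen) + 1e-9


def test_optimize_recovers_known_ranges(h3_typing, h3_dataset):
    """Data from a known (d0*, t0*) model is matched within the grid."""
    rng = np.random.default_rng(16)
    truth_nl = NonlinearParams(d0=1.0, t0=1.0, alpha={"H": 0.8})
    truth = random_model(h3_typing, 3, 1, truth_nl, rng, scale=0.02)
    sub_configs = h3_dataset.configs[:150]
    ds = Dataset(configs=sub_configs, energies=truth.predict(sub_configs))
    space = SearchSpace(d0=(0.5, 2.0, 3), t0=(0.5, 2.0, 3),
                        alpha=(0.8, 0.8001, 2))
    best, rep = optimize_nonlinear(ds, None, h3_typing, 1,
                                   search_space=space, charge_weight=0.0,
                                   n_sweeps=2, refine_maxfev=0)
    # 3-point log grid on [0.5, 2]: truth 1.0 is the middle point
    assert best.d0 == pytest.approx(1.0, rel=1e-6)
    assert best.t0 == pytest.approx(1.0, rel=1e-6)
    assert rep.rmse_train < 1e-6


def test_unbounded_space_rejected(h3_typing, h3_dataset):
    with pytest.raises(InputError):
        optimize_nonlinear(
            h3_dataset, None, h3_typing, 1,
            search_space=SearchSpace(d0=(1.0, np.inf, 3)),
            n_sweeps=1, refine_maxfev=0,
        )
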