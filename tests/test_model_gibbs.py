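import numpy as np
import pandas as pd
import pytest

import tdgibbs as t
from tdgibbs import _kernels
from tdgibbs.gibbs import (
    CovarianceSet,
    GibbsConfig,
    GibbsSampler,
    SampleStore,
    run_chain,
    sample_inverse_wishart,
)
from tdgibbs.model import build_model_frame
from tdgibbs.pedigree import PedigreeEntry, a_inverse
from tdgibbs.phenotypes import assign_classes


def _toy_records(n_cows=8, recs=5, herds=2, seed=0):
    rng = np.random.default_rng(seed)
    rows = []
    for c in range(n_cows):
        herd = f"H{c % herds}"
        for k in range(recs):
            rows.append(
                dict(
                    cow=f"C{c:02d}", herd=herd, test_year=2011, test_month=1 + k % 3,
                    calving_year=2010, calving_month=1 + c % 12, age_at_calving=24,
                    dim=int(rng.integers(5, 306)),
                    scs=float(3 + rng.normal()), milk=float(30 + 3 * rng.normal()),
                    fat_kg=float(1 + 0.2 * rng.normal()),
                    protein_kg=float(1 + 0.15 * rng.normal()),
                    milk_dummy=0.0,
                )
            )
    return pd.DataFrame(rows)


def _toy_frame(n_cows=8, recs=5, seed=0):
    rec = _toy_records(n_cows, recs, seed=seed)
    ped = [PedigreeEntry("S0"), PedigreeEntry("S1")] + [
        PedigreeEntry(f"C{c:02d}", f"S{c % 2}", None) for c in range(n_cows)
    ]
    rel = a_inverse(ped)
    return build_model_frame(rec, assign_classes(rec), rel)


# ----------------------------------------------------------------- model frame


def test_frame_counts(small_sim, small_frame):
    edited, _ = t.apply_edits(small_sim.records)
    assert small_frame.n_records == len(edited)
    assert small_frame.z_as.shape[1] == 6 and small_frame.z_hy.shape[1] == 5
    assert small_frame.n_animals == len(small_sim.pedigree)
    assert small_frame.n_cows == edited["cow"].nunique()
    assert small_frame.n_fixed_columns == (
        small_frame.n_hym + 6 * small_frame.n_as + 5 * small_frame.n_hy
    )


def test_two_herds_one_month_two_hym_levels():
    rec = _toy_records(n_cows=4, recs=5, herds=2)
    rec["test_month"] = 1
    frame = build_model_frame(rec, assign_classes(rec), a_inverse(
        [PedigreeEntry(f"C{c:02d}") for c in range(4)]
    ))
    assert frame.n_hym == 2


def test_missing_cow_in_pedigree_is_error():
    rec = _toy_records(n_cows=3)
    rel = a_inverse([PedigreeEntry("C00")])
    with pytest.raises(ValueError, match="C01"):
        build_model_frame(rec, assign_classes(rec), rel)


def test_missing_trait_rejected():
    rec = _toy_records(n_cows=3)
    rec.loc[0, "milk"] = np.nan
    rel = a_inverse([PedigreeEntry(f"C{c:02d}") for c in range(3)])
    with pytest.raises(ValueError, match="finite"):
        build_model_frame(rec, assign_classes(rec), rel)


# -------------------------------------------------------------- configuration


def test_chain_bookkeeping_is_exact():
    cfg = GibbsConfig(chain_length=200_000, burn_in=10_000, thin=10)
    assert cfg.n_retained == 19_000


def test_invalid_configs_rejected():
    with pytest.raises(ValueError):
        GibbsConfig(chain_length=100, burn_in=100)
    with pytest.raises(ValueError):
        GibbsConfig(thin=0)


def test_inverse_wishart_df_guard():
    with pytest.raises(ValueError):
        sample_inverse_wishart(np.eye(4), 3, np.random.default_rng(0))


def test_inverse_wishart_concentrates_on_scatter():
    """With many 'animals' the posterior draw concentrates on S/n."""
    rng = np.random.default_rng(0)
    truth = t.SimulationTruth().G0
    n = 100_000
    u = rng.standard_normal((n, 4)) @ np.linalg.cholesky(truth).T
    S = u.T @ u
    draws = np.array([sample_inverse_wishart(S, n, rng) for _ in range(20)])
    rel = np.linalg.norm(draws.mean(axis=0) - S / n) / np.linalg.norm(S / n)
    assert rel < 0.02


# ------------------------------------------------------------------- sampling


def test_determinism_same_seed(small_frame):
    cfg = GibbsConfig(chain_length=120, burn_in=40, thin=2, seed=9)
    a = run_chain(small_frame, cfg)
    b = run_chain(small_frame, cfg)
    np.testing.assert_array_equal(a.samples, b.samples)
    np.testing.assert_array_equal(a.cycles, b.cycles)


def test_stored_samples_positive_definite(small_store):
    for k in range(len(small_store)):
        for M in small_store.matrices(k):
            assert np.linalg.eigvalsh(M).min() > 0


def test_permutation_invariance_of_labels(small_sim):
    """Relabelling herd and cow identifiers (record order unchanged) leaves
    the stored covariance chain bit-identical."""
    edited, _ = t.apply_edits(small_sim.records)
    rel = t.a_inverse(small_sim.pedigree)
    cfg = GibbsConfig(chain_length=80, burn_in=20, thin=2, seed=3)

    frame1 = build_model_frame(edited, assign_classes(edited), rel)
    a = run_chain(frame1, cfg)

    rename = lambda x: x.replace("C", "K") if x else x
    relabeled = edited.copy()
    relabeled["herd"] = relabeled["herd"].map(lambda h: f"ZZ-{h}")
    ped2 = [
        PedigreeEntry(rename(e.animal), rename(e.sire), rename(e.dam))
        for e in small_sim.pedigree
    ]
    relabeled["cow"] = relabeled["cow"].map(rename)
    rel2 = t.a_inverse(ped2)
    frame2 = build_model_frame(relabeled, assign_classes(relabeled), rel2)
    b = run_chain(frame2, cfg)
    np.testing.assert_array_equal(a.samples, b.samples)


def test_trait_decoupling_with_diagonal_covariances():
    """With diagonal G0/P0/R0 held fixed, traits are conditionally
    independent: perturbing one trait's data leaves the other traits'
    sampled effects untouched."""
    frame = _toy_frame()
    covs = CovarianceSet(np.eye(4), np.eye(4), np.eye(4))
    cfg = GibbsConfig(chain_length=10, burn_in=1, thin=1, seed=5)

    s1 = GibbsSampler(frame, cfg, start=covs)
    for _ in range(5):
        s1.sample_location_effects()

    frame2 = _toy_frame()
    frame2.y = frame2.y.copy()
    frame2.y[:, 1] += 7.0  # shift milk only
    s2 = GibbsSampler(frame2, cfg, start=covs)
    for _ in range(5):
        s2.sample_location_effects()

    np.testing.assert_array_equal(s1.u_an[:, [0, 2, 3]], s2.u_an[:, [0, 2, 3]])
    np.testing.assert_array_equal(s1.u_pe[:, [0, 2, 3]], s2.u_pe[:, [0, 2, 3]])
    assert not np.allclose(s1.u_fix[:, 1], s2.u_fix[:, 1])


def test_zero_record_level_draws_from_prior():
    """An i.i.d. random-effect level without records is drawn from N(0, P0)."""
    P0 = t.SimulationTruth().P0
    R_inv = np.linalg.inv(t.SimulationTruth().R0)
    P_inv = np.linalg.inv(P0)
    u = np.zeros((1, 4))
    e = np.zeros((0, 4))
    indptr = np.array([0, 0], dtype=np.int64)
    rows = np.zeros(0, dtype=np.int64)
    z = np.random.default_rng(0).standard_normal((1, 4))
    ok = _kernels.sweep_iid(e, u, indptr, rows, R_inv, P_inv, z.copy())
    assert ok
    L = np.linalg.cholesky(P_inv)
    expected = np.linalg.solve(L.T, z[0])  # mean 0 + L^-T z, covariance P0
    np.testing.assert_allclose(u[0], expected, atol=1e-12)


def test_location_sampler_matches_gls_oracle():
    """Conjugate oracle: with covariances held fixed, the long-run mean of
    the location draws reproduces the generalized-least-squares fit."""
    rec = _toy_records(n_cows=8, recs=6, herds=4, seed=1)
    rec["dim"] = 155  # constant covariates: the contemporary group is the
    # only fixed effect that varies, and its indicator columns are disjoint
    ped = [PedigreeEntry(f"C{c:02d}") for c in range(8)]
    frame = build_model_frame(rec, assign_classes(rec), a_inverse(ped))
    truth = t.SimulationTruth()
    covs = CovarianceSet(np.eye(4) * 1e-10, np.eye(4) * 1e-10, truth.R0)
    cfg = GibbsConfig(chain_length=10, burn_in=1, thin=1, seed=2)
    s = GibbsSampler(frame, cfg, start=covs)
    draws = []
    for _ in range(4000):
        s.sample_location_effects()
        draws.append(frame.fixed_design() @ s.u_fix)  # fitted values
    draws = np.asarray(draws)[500:]
    fit_mcmc = draws.mean(axis=0)
    X = frame.fixed_design().toarray()
    fit_gls = X @ (np.linalg.pinv(X) @ frame.y)  # same-X GLS = OLS fit
    mcse = draws.std(axis=0) / np.sqrt(len(draws) / 10)
    assert np.all(np.abs(fit_mcmc - fit_gls) < 3 * mcse + 1e-3)


def test_chain_store_round_trip(tmp_path, small_store):
    p = tmp_path / "samples.csv"
    small_store.save(p)
    again = SampleStore.load(p)
    np.testing.assert_allclose(again.samples, small_store.samples)
    assert again.names == small_store.names


def test_checkpoint_resume_bit_identical(tmp_path, small_frame):
    cfg_full = GibbsConfig(chain_length=200, burn_in=60, thin=4, seed=13,
                           checkpoint_every=100)
    full = run_chain(small_frame, cfg_full, checkpoint_dir=tmp_path / "a")

    cfg_half = GibbsConfig(chain_length=100, burn_in=60, thin=4, seed=13,
                           checkpoint_every=100)
    run_chain(small_frame, cfg_half, checkpoint_dir=tmp_path / "b")
    resumed = run_chain(small_frame, cfg_full, checkpoint_dir=tmp_path / "b",
                        resume=True)
    np.testing.assert_array_equal(full.samples, resumed.samples)
    np.testing.assert_array_equal(full.cycles, resumed.cycles)
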