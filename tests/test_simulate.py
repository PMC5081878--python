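import numpy as np
import pytest

import tdgibbs as t
from tdgibbs.pedigree import PedigreeEntry, relationship_matrix
from tdgibbs.phenotypes import apply_edits
from tdgibbs.simulate import (
    SimulationDesign,
    SimulationTruth,
    simulate_breeding_values,
    simulate_pedigree,
    simulate_records,
)


def test_truth_defaults_are_consistent():
    truth = SimulationTruth()
    h2 = truth.heritabilities()
    assert np.all((h2 > 0) & (h2 < 1))
    assert h2[1] == pytest.approx(0.204, abs=5e-4)  # milk
    rg = truth.genetic_correlations()
    assert rg[1, 3] == pytest.approx(0.90)  # milk-protein
    for M in (truth.G0, truth.P0, truth.R0):
        assert np.linalg.eigvalsh(M).min() > 0


def test_truth_rejects_non_pd():
    bad = np.eye(4)
    bad[0, 1] = bad[1, 0] = 2.0
    with pytest.raises(ValueError, match="positive definite"):
        SimulationTruth(G0=bad)


def test_pedigree_counts_and_parents():
    d = SimulationDesign(n_sires=10, n_dams=100, n_cows=200, generations=1)
    ped = simulate_pedigree(d, np.random.default_rng(0))
    assert len(ped) == 310
    cows = [e for e in ped if e.animal.startswith("C")]
    assert len(cows) == 200
    assert all(e.sire and e.dam for e in cows)


def test_two_generation_dams_are_recorded_cows():
    d = SimulationDesign(n_sires=10, n_dams=40, n_cows=100, generations=2,
                         mating="random")
    ped = simulate_pedigree(d, np.random.default_rng(1))
    cows = {e.animal for e in ped if e.animal.startswith("C")}
    second = [e for e in ped if e.animal.startswith("C")][50:]
    assert all(e.dam in cows for e in second)


def test_paternal_half_sibs_quarter_related():
    d = SimulationDesign(n_sires=2, n_dams=50, n_cows=40, generations=1)
    ped = simulate_pedigree(d, np.random.default_rng(2))
    A = relationship_matrix(ped)
    ids = [e.animal for e in ped]
    by = {e.animal: e for e in ped}
    cows = [a for a in ids if a.startswith("C")]
    found = 0
    for i, a in enumerate(cows):
        for b in cows[i + 1:]:
            ea, eb = by[a], by[b]
            if ea.sire == eb.sire and ea.dam != eb.dam:
                assert A[ids.index(a), ids.index(b)] == pytest.approx(0.25)
                found += 1
    assert found > 10


def test_zero_cows_rejected():
    with pytest.raises(ValueError):
        SimulationDesign(n_cows=0)


def test_schedule_outside_lactation_rejected():
    with pytest.raises(ValueError, match="305"):
        SimulationDesign(records_per_cow=12, test_interval=30)


# ------------------------------------------------------------ breeding values


def test_founder_bv_covariance_matches_G0():
    truth = SimulationTruth()
    ped = [PedigreeEntry(f"F{i}") for i in range(100_000)]
    bv = simulate_breeding_values(ped, truth.G0, np.random.default_rng(0))
    emp = np.cov(bv.to_numpy().T)
    rel_err = np.linalg.norm(emp - truth.G0) / np.linalg.norm(truth.G0)
    assert rel_err < 0.02


def test_offspring_mean_is_parent_average():
    truth = SimulationTruth()
    n_off = 20_000
    ped = [PedigreeEntry("S"), PedigreeEntry("D")] + [
        PedigreeEntry(f"C{i}", "S", "D") for i in range(n_off)
    ]
    rng = np.random.default_rng(1)
    bv = simulate_breeding_values(ped, truth.G0, rng)
    pa = 0.5 * (bv.loc["S"].to_numpy() + bv.loc["D"].to_numpy())
    off = bv.iloc[2:].to_numpy()
    se = np.sqrt(0.5 * np.diag(truth.G0) / n_off)
    assert np.all(np.abs(off.mean(axis=0) - pa) < 3 * se)
    # Mendelian-sampling variance is half the additive variance
    emp = np.cov(off.T)
    np.testing.assert_allclose(emp, 0.5 * truth.G0, rtol=0.12, atol=2e-3)


def test_zero_G0_gives_zero_bvs():
    ped = [PedigreeEntry("A"), PedigreeEntry("B"), PedigreeEntry("C", "A", "B")]
    bv = simulate_breeding_values(ped, np.zeros((4, 4)), np.random.default_rng(0))
    assert (bv.to_numpy() == 0).all()


def test_exact_moments_bv_scatter():
    truth = SimulationTruth()
    d = SimulationDesign(n_cows=300, n_sires=30, n_dams=100)
    ped = simulate_pedigree(d, np.random.default_rng(3))
    rel = t.a_inverse(ped)
    bv = simulate_breeding_values(ped, truth.G0, np.random.default_rng(3), exact_moments=True)
    u = bv.loc[rel.ids].to_numpy()
    S = u.T @ (rel.a_inv @ u) / rel.n
    np.testing.assert_allclose(S, truth.G0, rtol=1e-8, atol=1e-10)


# ------------------------------------------------------------------- records


def _plain_truth(**kw):
    base = dict(
        hym_sd=np.zeros(4),
        as_coef_sd=np.zeros(4),
        hy_coef_sd=np.zeros(4),
    )
    base.update(kw)
    return SimulationTruth(**base)


def test_residual_only_variance_decomposition():
    """With zero G0-proxy, PE, HYM and curve variation, per-trait record
    variance reduces to the residual diagonal."""
    truth = _plain_truth(P0=np.eye(4) * 1e-12)
    d = SimulationDesign(n_cows=1000, n_sires=20, n_dams=100, generations=1,
                         exact_moments=False)
    rng = np.random.default_rng(4)
    ped = simulate_pedigree(d, rng)
    bv = simulate_breeding_values(ped, np.zeros((4, 4)), rng)
    rec, _ = simulate_records(ped, bv, truth, d, rng)
    y = np.column_stack([
        np.log2(rec["scc"] / 100) + 3,
        rec["milk"],
        rec["milk"] * rec["fat_pct"] / 100,
        rec["milk"] * rec["protein_pct"] / 100,
    ])
    emp = y.var(axis=0, ddof=1)
    np.testing.assert_allclose(emp, np.diag(truth.R0), rtol=0.06)


def test_repeatability_covariance_across_records():
    """Across two records of one cow (no genetics, no fixed variation) the
    covariance equals P0."""
    truth = _plain_truth()
    d = SimulationDesign(n_cows=10_000, n_sires=20, n_dams=100, generations=1,
                         records_per_cow=2, exact_moments=False)
    rng = np.random.default_rng(5)
    ped = simulate_pedigree(d, rng)
    bv = simulate_breeding_values(ped, np.zeros((4, 4)), rng)
    rec, _ = simulate_records(ped, bv, truth, d, rng)
    y1 = rec.iloc[0::2]["milk"].to_numpy()
    y2 = rec.iloc[1::2]["milk"].to_numpy()
    cov = np.cov(y1, y2)[0, 1]
    assert cov == pytest.approx(truth.P0[1, 1], rel=0.08)


def test_records_survive_edits_losslessly(small_sim):
    kept, rep = apply_edits(small_sim.records)
    assert rep.n_kept == len(small_sim.records)
    assert rep.removed_min_records == 0


def test_edit_stress_leaves_tails():
    d = SimulationDesign(n_cows=400, n_sires=20, n_dams=100, edit_stress=True,
                         exact_moments=False)
    data = t.simulate_dataset(d, seed=6)
    # unclipped SCC occasionally exceeds 500 at the default truth
    assert (data.records["scc"] > 500).any() or (data.records["scc"] < 1).any()


def test_truth_payload_round_trip(tmp_path, small_sim):
    small_sim.write(tmp_path)
    assert (tmp_path / "records.csv").exists()
    assert (tmp_path / "pedigree.txt").exists()
    import json

    payload = json.loads((tmp_path / "truth.json").read_text())
    assert payload["heritability"]["milk"] == pytest.approx(0.204, abs=5e-4)
    ped = t.read_pedigree(tmp_path / "pedigree.txt")
    assert {e.animal for e in ped} == {e.animal for e in small_sim.pedigree}


def test_dataset_deterministic():
    d = SimulationDesign(n_cows=50, n_sires=5, n_dams=20)
    a = t.simulate_dataset(d, seed=9)
    b = t.simulate_dataset(d, seed=9)
    assert a.records.equals(b.records)
    assert a.pedigree == b.pedigree
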