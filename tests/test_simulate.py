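"""Generative structure of the synthetic test-day data."""

import numpy as np
import pandas as pd
import pytest

from lactrr.basis import legendre_matrix
from lactrr.pedigree import relationship_matrix
from lactrr.prep import residual_class
from lactrr.simulate import (
    SimulationConfig,
    simulate_dataset,
    simulate_genetic_values,
    simulate_pedigree,
    simulate_true_effects,
    simulate_two_generation_pedigree,
)


def _small_config(**kw):
    base = dict(n_sires=4, daughters_per_sire=6, n_dams=10, n_herds=2,
                order=1, k_g=np.diag([0.4, 0.04]), k_p=np.diag([0.3, 0.03]))
    base.update(kw)
    return SimulationConfig(**base)


class TestDeterminism:
    def test_same_seed_identical_records(self):
        cfg = _small_config()
        d1 = simulate_dataset(cfg, seed=7)
        d2 = simulate_dataset(cfg, seed=7)
        assert d1.records.equals(d2.records)
        assert d1.records.to_csv() == d2.records.to_csv()

    def test_different_seed_differs(self):
        cfg = _small_config()
        assert not simulate_dataset(cfg, seed=7).records.equals(
            simulate_dataset(cfg, seed=8).records)


class TestGeneticValues:
    def test_zero_covariance_gives_zero_vectors(self):
        ped, goats = simulate_pedigree(3, 5, 4, seed=1)
        rng = np.random.default_rng(0)
        a = simulate_genetic_values(ped, np.zeros((3, 3)), rng)
        assert np.all(a == 0)

    def test_founder_covariance_recovers_k_g(self):
        # 20,000 unrelated founders: empirical covariance within 5% Frobenius
        from lactrr.pedigree import Pedigree
        ped = Pedigree.from_records([(i, 0, 0) for i in range(1, 20001)])
        K = np.array([[0.4, 0.05], [0.05, 0.08]])
        rng = np.random.default_rng(123)
        a = simulate_genetic_values(ped, K, rng)
        emp = np.cov(a.T)
        assert np.linalg.norm(emp - K) / np.linalg.norm(K) < 0.05

    def test_mendelian_deviation_independent_of_midparent(self):
        ped, goats = simulate_pedigree(50, 50, 40, seed=2)  # 2000 offspring
        rng = np.random.default_rng(5)
        K = np.diag([0.4, 0.04])
        a = simulate_genetic_values(ped, K, rng)
        idx = ped.index_of(goats)
        mid = 0.5 * (a[ped.sire_idx[idx]] + a[ped.dam_idx[idx]])
        dev = a[idx] - mid
        corr = np.corrcoef(mid[:, 0], dev[:, 0])[0, 1]
        assert abs(corr) < 0.06
        # deviation variance close to half the founder variance
        assert np.var(dev[:, 0]) == pytest.approx(0.5 * 0.4, rel=0.12)

    def test_parent_offspring_covariance_half_k(self):
        ped, goats = simulate_pedigree(40, 40, 50, seed=3)
        rng = np.random.default_rng(6)
        K = np.diag([0.4, 0.04])
        a = simulate_genetic_values(ped, K, rng)
        idx = ped.index_of(goats)
        cov = np.cov(a[ped.sire_idx[idx], 0], a[idx, 0])[0, 1]
        assert cov == pytest.approx(0.2, rel=0.15)


class TestRecords:
    def test_noise_free_records_reconstruct_from_truth(self):
        cfg = _small_config(k_p=np.zeros((2, 2)), residual=np.zeros(9))
        data = simulate_dataset(cfg, seed=13)
        rec = data.records
        idx = data.pedigree.index_of(rec["goat"])
        Phi = legendre_matrix(1, rec["dim"].to_numpy())
        genetic = np.einsum("ij,ij->i", Phi, data.effects.genetic[idx])
        expect = _fixed_surface(data) + genetic
        assert np.allclose(rec["y"].to_numpy(), expect, atol=1e-10)

    def test_lactation_lengths_within_printed_range(self):
        data = simulate_dataset(_small_config(), seed=17)
        ll = data.records["lactation_length"]
        assert ll.between(180, 350).all()
        assert data.records["dim"].between(7, 270).all()
        assert (data.records["dim"] <= ll).all()

    def test_test_intervals_within_schedule(self):
        data = simulate_dataset(_small_config(), seed=19)
        for _, grp in data.records.groupby("goat"):
            gaps = np.diff(np.sort(grp["dim"].to_numpy()))
            assert np.all((gaps >= 28) & (gaps <= 35))

    def test_residual_class_variances_recovered(self):
        # 50,000+ records, signal subtracted: per-class variance within 10%
        cfg = SimulationConfig(n_sires=100, daughters_per_sire=70, n_dams=500,
                               n_herds=40, order=0, k_g=[[0.0]], k_p=[[0.0]],
                               htd_sd=0.0, year_age_sd=0.0, year_period_sd=0.0,
                               class_curve_sd=0.0)
        data = simulate_dataset(cfg, seed=23)
        rec = data.records
        assert len(rec) > 50000
        fixed = _fixed_surface(data)
        noise = rec["y"].to_numpy() - fixed
        cls = residual_class(rec["dim"].to_numpy())
        for c in range(1, 10):
            v = np.var(noise[cls == c])
            assert v == pytest.approx(cfg.residual[c - 1], rel=0.10)

    def test_halfsib_intraclass_correlation_near_quarter_h2(self):
        # leg0 truth, no PE, constant residual, no fixed-effect noise: the
        # intraclass correlation of one record per paternal half-sib
        # daughter is h2/4 for the daily heritability
        sg, se = 0.8, 0.6            # daily genetic var sg/2 = 0.4, h2 = 0.4
        cfg = SimulationConfig(n_sires=60, daughters_per_sire=40, n_dams=2000,
                               n_herds=30, order=0, k_g=[[sg]], k_p=[[0.0]],
                               residual=np.full(9, se), htd_sd=0.0,
                               year_age_sd=0.0, year_period_sd=0.0,
                               class_curve_sd=0.0)
        data = simulate_dataset(cfg, seed=29)
        rec = data.records.assign(
            dev=data.records["y"].to_numpy() - _fixed_surface(data))
        one = rec.groupby("goat").first().reset_index()   # single TD per goat
        groups = [g["dev"].to_numpy() for _, g in one.groupby("sire")]
        k = min(len(g) for g in groups)
        Y = np.stack([g[:k] for g in groups])             # balanced ANOVA
        msb = k * Y.mean(1).var(ddof=1)
        msw = Y.var(1, ddof=1).mean()
        icc = (msb - msw) / (msb + (k - 1) * msw)
        h2_daily = (sg / 2) / (sg / 2 + se)
        assert icc == pytest.approx(h2_daily / 4, abs=0.04)


class TestTwoGenerationPedigree:
    def test_dams_are_phenotyped_with_known_parents(self):
        ped, goats, gen = simulate_two_generation_pedigree(8, 80, 20, seed=4)
        assert goats.size == 80 + 8 * 20
        assert set(gen) == {0, 1}
        idx = ped.index_of(goats)
        assert np.all(ped.sire_idx[idx] >= 0)
        assert np.all(ped.dam_idx[idx] >= 0)

    def test_grandsire_families_pass_progeny_filter(self):
        ped, goats, gen = simulate_two_generation_pedigree(8, 80, 20, seed=4)
        dams = goats[gen == 0]
        idx = ped.index_of(dams)
        sires_of_dams = ped.animals[ped.sire_idx[idx]]
        counts = pd.Series(sires_of_dams).value_counts()
        assert counts.min() >= 20

    def test_dam_generation_kids_in_first_year(self):
        cfg = SimulationConfig(n_sires=5, daughters_per_sire=20, n_dams=50,
                               n_herds=3, order=1,
                               k_g=np.diag([0.4, 0.04]),
                               k_p=np.diag([0.3, 0.03]),
                               phenotyped_dams=True)
        data = simulate_dataset(cfg, seed=6)
        rec = data.records
        # dams appear in the pedigree as parents of other recorded goats
        recorded = set(rec["goat"])
        dams_recorded = recorded & set(rec["dam"])
        assert len(dams_recorded) > 0


def _fixed_surface(data):
    """Recompute the deterministic fixed part of each record from truth."""
    from lactrr.basis import gestation_covariates, lactation_stage_covariates
    rec = data.records
    eff = data.effects
    day_offset = ((np.asarray(rec["test_date"], dtype="datetime64[D]")
                   - np.datetime64("2000-09-01")) // np.timedelta64(1, "D"))
    y = np.asarray([data.htd_effects[(int(h), int(t))]
                    for h, t in zip(rec["herd"], day_offset)])
    y = y + np.asarray([eff.year_age[(int(j), int(k))]
                        for j, k in zip(rec["year"], rec["age_class"])])
    y = y + np.asarray([eff.year_period[(int(j), int(l))]
                        for j, l in zip(rec["year"], rec["period_class"])])
    N = lactation_stage_covariates(rec["dim"].to_numpy())
    y = y + N @ eff.base_curve_coefs
    y = y + np.einsum("ij,ij->i", N,
                      eff.age_curve_coefs[rec["age_class"].to_numpy() - 1])
    y = y + np.einsum("ij,ij->i", N,
                      eff.period_curve_coefs[rec["period_class"].to_numpy() - 1])
    y = y + gestation_covariates(
        rec["gestation_days"].to_numpy(dtype=float)) @ eff.gestation_coefs
    return y
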