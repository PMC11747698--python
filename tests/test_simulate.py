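"""Generator: design structure, genetic sampling, phenotype statistics."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import norm

from taintgen.simulate import (ConfigurationError, MatrixError,
                               SimulationConfig, apply_missingness, simulate,
                               simulate_breeding_values, simulate_pedigree,
                               simulate_phenotypes, substream)


def small_cfg(**kw):
    base = dict(n_sires=5, n_progeny=40, dams_per_sire=8, n_grandsires=2,
                n_assessors=2, months_per_station=2, missing_assessors=(),
                seed=3)
    base.update(kw)
    return SimulationConfig(**base)


def test_default_design_matches_study_dimensions():
    cfg = SimulationConfig()
    ped = simulate_pedigree(cfg)
    layout = cfg.id_layout()
    assert layout["progeny"].size == 1016
    assert 1800 <= len(ped) <= 2100          # close to the study's 1,934
    # progeny have one sire and one dam; dams are unknown-parent founders
    prog = set(layout["progeny"].tolist())
    si, di = ped.parent_indices()
    for i, a in enumerate(ped.animal.tolist()):
        if a in prog:
            assert si[i] >= 0 and di[i] >= 0


def test_pedigree_is_acyclic_and_deterministic():
    cfg = small_cfg()
    p1 = simulate_pedigree(cfg)
    p2 = simulate_pedigree(cfg)
    pd.testing.assert_frame_equal(p1.to_frame(), p2.to_frame())
    # topological validity is enforced at construction; smallest family:
    tiny = simulate_pedigree(small_cfg(n_sires=1, n_progeny=2,
                                       dams_per_sire=1, n_grandsires=0))
    si, _ = tiny.parent_indices()
    assert (si >= 0).sum() == 2              # two sibs share the one sire


def test_invalid_configuration_rejected():
    with pytest.raises(ConfigurationError):
        small_cfg(n_sires=0)
    with pytest.raises(MatrixError):
        # indefinite G (correlation > 1 equivalent)
        bad = np.eye(3)
        bad[0, 1] = bad[1, 0] = 2.0
        small_cfg(G_true=bad, R_true=np.eye(3), n_assessors=1)


def test_breeding_values_zero_for_null_genetics():
    cfg = small_cfg()
    ped = simulate_pedigree(cfg)
    u = simulate_breeding_values(ped, np.zeros((4, 4)), substream(1, "bv"))
    assert np.all(u == 0.0)


def test_sire_offspring_covariance_is_half():
    """2,000 independent sire-offspring pairs, single trait, sigma_u^2 = 1."""
    n = 2000
    animal = np.arange(1, 3 * n + 1)
    sire = np.r_[np.zeros(2 * n), animal[:n]]
    dam = np.r_[np.zeros(2 * n), animal[n:2 * n]]
    from taintgen.pedigree import Pedigree
    ped = Pedigree.from_records(animal, sire, dam)
    u = simulate_breeding_values(ped, np.eye(1), substream(9, "bv"))[:, 0]
    pos_s = ped.positions(animal[:n])
    pos_o = ped.positions(animal[2 * n:])
    cov = np.cov(u[pos_s], u[pos_o])[0, 1]
    assert cov == pytest.approx(0.5, abs=0.06)
    # founder variance follows the law of large numbers
    assert u[pos_s].var() == pytest.approx(1.0, abs=0.1)


def test_phenotype_moments_and_null_limit():
    cfg = SimulationConfig(missing_assessors=())
    ds = simulate(cfg)
    ph = ds.phenotypes
    se_w = cfg.weight_sd / np.sqrt(len(ph))
    assert abs(ph.weight_kg.mean() - 94.9) < 3 * se_w
    assert abs(ph.weight_kg.std() - 4.81) < 3 * 4.81 / np.sqrt(2 * len(ph))
    assert (ph.ska_ppm > 0).all() and (ph.anon_ppm > 0).all()

    null = small_cfg(G_true=np.zeros((4, 4)), R_true=np.zeros((4, 4)),
                     class_effect_sd=0.0, beta_weight=0.0, beta_age=0.0,
                     trait_means=np.zeros(4))
    ped = simulate_pedigree(null)
    u = simulate_breeding_values(ped, null.G_true, substream(3, "bv"))
    ph0, _ = simulate_phenotypes(ped, u, null)
    np.testing.assert_allclose(np.log10(ph0.ska_ppm), 0.0, atol=1e-12)
    np.testing.assert_allclose(np.log10(ph0.anon_ppm), 0.0, atol=1e-12)


def test_half_sib_intraclass_correlation():
    """Paternal half-sib ANOVA: t = h2/4 for an h2=0.5 trait."""
    m3 = np.eye(3)
    cfg = SimulationConfig(
        n_sires=100, n_progeny=4000, dams_per_sire=40, n_grandsires=0,
        sire_dams_recorded=False, n_assessors=1, n_stations=1,
        months_per_station=1, missing_assessors=(), class_effect_sd=0.0,
        beta_weight=0.0, beta_age=0.0,
        G_true=0.5 * m3, R_true=0.5 * m3, seed=17)
    ds = simulate(cfg)
    sires = dict(zip(ds.pedigree.animal.tolist(), ds.pedigree.sire.tolist()))
    ph = ds.phenotypes
    y = np.log10(ph.ska_ppm.to_numpy())
    fam = ph.animal_id.map(sires)
    k = 40
    means = pd.Series(y).groupby(fam.values).mean()
    msb = k * ((means - y.mean()) ** 2).sum() / (len(means) - 1)
    msw = ((y - fam.map(means).to_numpy()) ** 2).sum() / (len(y) - len(means))
    t = ((msb - msw) / k) / (((msb - msw) / k) + msw)
    assert t == pytest.approx(0.125, abs=0.05)


def test_score_frequencies_match_threshold_masses():
    """With fixed effects removed, class frequencies follow the cutpoints."""
    cfg = SimulationConfig(
        n_sires=20, n_progeny=4000, dams_per_sire=200, n_grandsires=0,
        n_assessors=2, months_per_station=1, n_stations=1,
        missing_assessors=(), class_effect_sd=0.0,
        beta_weight=0.0, beta_age=0.0, seed=23)
    ds = simulate(cfg)
    for a in (1, 2):
        scores = ds.phenotypes[f"sens_{a}"].to_numpy()
        freq = np.bincount(scores.astype(int), minlength=6) / scores.size
        masses = np.diff(np.r_[0.0, norm.cdf(cfg.score_thresholds[a - 1]),
                               1.0])
        np.testing.assert_allclose(freq, masses, atol=0.03)


def test_missingness_exact_counts_identity_and_determinism():
    cfg = SimulationConfig(missing_assessors=(4, 5))
    ds = simulate(cfg)
    counts = {a: int(ds.phenotypes[f"sens_{a}"].notna().sum())
              for a in range(1, 11)}
    assert counts[4] == counts[5] == 856
    assert all(counts[a] == 1016 for a in (1, 2, 3, 6, 7, 8, 9, 10))

    none = SimulationConfig(missing_assessors=())
    ph = simulate(none).phenotypes
    pd.testing.assert_frame_equal(apply_missingness(ph, none), ph)

    again = simulate(cfg).phenotypes
    pd.testing.assert_frame_equal(ds.phenotypes, again)

    with pytest.raises(ConfigurationError):
        apply_missingness(ph.head(100), cfg)


def test_full_dataset_determinism_and_invariants():
    cfg = small_cfg(missing_assessors=(1,), missing_observed_count=30)
    d1 = simulate(cfg)
    d2 = simulate(cfg)
    pd.testing.assert_frame_equal(d1.phenotypes, d2.phenotypes)
    pd.testing.assert_frame_equal(d1.true_breeding_values,
                                  d2.true_breeding_values)
    scores = d1.phenotypes[["sens_1", "sens_2"]].to_numpy()
    obs = scores[~np.isnan(scores)]
    assert np.isin(obs, np.arange(6)).all()
    # every phenotyped animal is in the pedigree
    d1.pedigree.positions(d1.phenotypes.animal_id)
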