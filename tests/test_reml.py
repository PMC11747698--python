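"""REML engine: likelihood correctness, EM behaviour, AI sampling theory."""

import numpy as np
import pandas as pd
import pytest

from taintgen import (ModelSpec, Pedigree, SimulationConfig,
                      VarianceComponents, ai_information, derived_parameters,
                      em_reml, reml_loglik, simulate)
from taintgen.io import analysis_table
from taintgen.reml import DesignError, _Workspace

TRAITS4 = ["SKAt", "ANONt", "SENSt_1", "SENSt_2"]


# ---------------------------------------------------------------------------
# shared balanced half-sib fixture (single trait)
# ---------------------------------------------------------------------------

@pytest.fixture(scope="module")
def half_sib_fit():
    """Balanced design: 40 unrelated sires x 20 progeny, h2_true = 0.5."""
    cfg = SimulationConfig(
        n_sires=40, n_progeny=800, dams_per_sire=20, n_grandsires=0,
        sire_dams_recorded=False, n_assessors=1, months_per_station=1,
        n_stations=1, missing_assessors=(), class_effect_sd=0.0,
        beta_weight=0.0, beta_age=0.0, G_true=np.diag([0.5] * 3),
        R_true=np.diag([0.5] * 3), seed=11)
    ds = simulate(cfg)
    table, _ = analysis_table(ds.phenotypes)
    model = ModelSpec(traits=["SKAt"], class_columns=(),
                      covariate_columns=())
    vc = em_reml(table, ds.pedigree, model, tol=1e-10, max_rounds=500,
                 accelerate=True)
    return ds, table, model, vc


def _anova_components(ds, table, k=20):
    sires = dict(zip(ds.pedigree.animal.tolist(), ds.pedigree.sire.tolist()))
    y = table["SKAt"].to_numpy()
    fam = table.animal_id.map(sires)
    means = pd.Series(y).groupby(fam.values).mean()
    s = len(means)
    msb = k * ((means - y.mean()) ** 2).sum() / (s - 1)
    msw = ((y - fam.map(means).to_numpy()) ** 2).sum() / (s * (k - 1))
    sig_s = (msb - msw) / k
    return 4 * sig_s, msw - 3 * sig_s, msb, msw, s


def test_balanced_half_sib_matches_anova(half_sib_fit):
    """Animal-model REML equals Henderson ANOVA on balanced data."""
    ds, table, model, vc = half_sib_fit
    su, se, *_ = _anova_components(ds, table)
    assert vc.G[0, 0] == pytest.approx(su, rel=1e-6)
    assert vc.R[0, 0] == pytest.approx(se, rel=1e-6)


def test_ai_se_matches_balanced_sampling_theory(half_sib_fit):
    """AI SEs equal the exact ANOVA sampling variances on balanced data."""
    ds, table, model, vc = half_sib_fit
    su, se, msb, msw, s = _anova_components(ds, table)
    k = 20
    var_msb = 2 * msb ** 2 / (s - 1)
    var_msw = 2 * msw ** 2 / (s * (k - 1))
    se_su = np.sqrt(16 / k ** 2 * (var_msb + var_msw))
    se_se = np.sqrt((1 + 3 / k) ** 2 * var_msw + 9 / k ** 2 * var_msb)
    ai = ai_information(vc, table, ds.pedigree, model)
    assert ai.se_G[0, 0] == pytest.approx(se_su, rel=0.02)
    assert ai.se_R[0, 0] == pytest.approx(se_se, rel=0.02)
    assert np.all(ai.se_G >= 0) and np.allclose(ai.se_G, ai.se_G.T)


def test_doubling_data_shrinks_se_by_sqrt2(half_sib_fit):
    ds, table, model, vc = half_sib_fit
    shift = 10 ** 6
    t2 = table.copy()
    t2["animal_id"] = t2["animal_id"] + shift
    pf = ds.pedigree.to_frame()
    pf2 = pf.copy()
    pf2["animal"] += shift
    pf2["sire"] = np.where(pf2["sire"] > 0, pf2["sire"] + shift, 0)
    pf2["dam"] = np.where(pf2["dam"] > 0, pf2["dam"] + shift, 0)
    ped2 = Pedigree.from_frame(pd.concat([pf, pf2], ignore_index=True))
    big = pd.concat([table, t2], ignore_index=True)
    ai1 = ai_information(vc, table, ds.pedigree, model)
    ai2 = ai_information(vc, big, ped2, model)
    assert ai2.se_G[0, 0] / ai1.se_G[0, 0] == pytest.approx(
        1 / np.sqrt(2), rel=1e-6)


# ---------------------------------------------------------------------------
# likelihood properties
# ---------------------------------------------------------------------------

def test_loglik_is_maximal_at_estimates(small_dataset):
    ds, table, model = small_dataset
    vc = em_reml(table, ds.pedigree, model, tol=1e-6, max_rounds=120,
                 accelerate=True)
    ll_hat = reml_loglik(vc, table, ds.pedigree, model)
    inflated = VarianceComponents(model.traits, vc.G, 10.0 * vc.R)
    assert reml_loglik(inflated, table, ds.pedigree, model) < ll_hat


def test_loglik_invariant_to_fixed_effect_coding(small_dataset):
    """REML projects out the fixed effects: level coding cannot matter."""
    ds, table, model = small_dataset
    vc = VarianceComponents(model.traits, np.array(ds.config.G_true),
                            np.array(ds.config.R_true))
    ll1 = reml_loglik(vc, table, ds.pedigree, model)
    relabel = table.copy()
    relabel["station"] = relabel["station"].map({1: "C", 2: "A", 3: "B"})
    ll2 = reml_loglik(vc, relabel, ds.pedigree, model)
    assert ll2 == pytest.approx(ll1, abs=1e-7)


def test_all_missing_record_leaves_estimates_unchanged(small_dataset):
    ds, table, model = small_dataset
    vc1 = em_reml(table, ds.pedigree, model, tol=1e-7, max_rounds=40)
    extra_id = int(ds.pedigree.animal.max()) + 1
    ped = Pedigree.from_frame(pd.concat(
        [ds.pedigree.to_frame(),
         pd.DataFrame({"animal": [extra_id], "sire": [0], "dam": [0]})],
        ignore_index=True))
    row = {c: (extra_id if c == "animal_id" else
               (1 if c in ("station", "month") else
                (90.0 if c == "weight_kg" else
                 (170.0 if c == "age_d" else np.nan))))
           for c in table.columns}
    bigger = pd.concat([table, pd.DataFrame([row])], ignore_index=True)
    vc2 = em_reml(bigger, ped, model, tol=1e-7, max_rounds=40)
    np.testing.assert_allclose(vc2.G, vc1.G, atol=1e-10)
    np.testing.assert_allclose(vc2.R, vc1.R, atol=1e-10)


def test_null_heritability_limit():
    """Data simulated without genetics: G estimates collapse toward zero."""
    m3 = np.eye(3)
    cfg = SimulationConfig(
        n_sires=30, n_progeny=600, dams_per_sire=20, n_grandsires=0,
        sire_dams_recorded=False, n_assessors=1, months_per_station=1,
        missing_assessors=(), class_effect_sd=0.0, beta_weight=0.0,
        beta_age=0.0, G_true=0.0 * m3, R_true=0.5 * m3, seed=29)
    ds = simulate(cfg)
    table, _ = analysis_table(ds.phenotypes)
    model = ModelSpec(traits=["SKAt"], class_columns=("station",),
                      covariate_columns=())
    vc = em_reml(table, ds.pedigree, model, tol=1e-6, max_rounds=250)
    h2 = vc.G[0, 0] / (vc.G[0, 0] + vc.R[0, 0])
    assert h2 < 0.08
    assert vc.R[0, 0] == pytest.approx(0.5, rel=0.15)


def test_em_trace_is_monotone(small_dataset):
    ds, table, model = small_dataset
    vc = em_reml(table, ds.pedigree, model, tol=1e-9, max_rounds=60)
    diffs = np.diff(vc.loglik_trace)
    assert np.all(diffs >= -1e-8)


# ---------------------------------------------------------------------------
# derived parameters
# ---------------------------------------------------------------------------

def test_derived_parameters_against_independent_formulas(
        random_pd_matrices):
    G = random_pd_matrices(4)
    R = random_pd_matrices(4)
    vc = VarianceComponents([f"t{i}" for i in range(4)], G, R)
    gp = derived_parameters(vc)
    for i in range(4):
        assert gp.h2[i] == pytest.approx(G[i, i] / (G[i, i] + R[i, i]))
        for j in range(4):
            assert gp.r_G[i, j] == pytest.approx(
                G[i, j] / np.sqrt(G[i, i] * G[j, j]))
            assert gp.r_R[i, j] == pytest.approx(
                R[i, j] / np.sqrt(R[i, i] * R[j, j]))
            assert gp.r_P[i, j] == pytest.approx(
                (G[i, j] + R[i, j]) / np.sqrt(
                    (G[i, i] + R[i, i]) * (G[j, j] + R[j, j])))


def test_published_heritability_arithmetic():
    """h2 from printed variance pairs reproduces the printed values."""
    vc = VarianceComponents(["a", "b"],
                            np.diag([0.37, 0.28]), np.diag([0.88, 1.50]))
    gp = derived_parameters(vc)
    assert round(float(gp.h2[0]), 2) == 0.30
    assert round(float(gp.h2[1]), 2) == 0.16


def test_design_errors():
    df = pd.DataFrame({
        "animal_id": [1, 2], "station": [1, 1], "month": [1, 1],
        "weight_kg": [90.0, 91.0], "age_d": [170.0, np.nan],
        "SKAt": [0.1, 0.2]})
    ped = Pedigree.from_records([1, 2], [0, 0], [0, 0])
    with pytest.raises(DesignError):
        em_reml(df, ped, ModelSpec(traits=["SKAt"]))
    dup = pd.concat([df, df.head(1)], ignore_index=True)
    dup["age_d"] = 170.0
    with pytest.raises(DesignError):
        em_reml(dup, ped, ModelSpec(traits=["SKAt"]))


def test_mme_loglik_matches_dense_construction(small_dataset):
    """MME-based likelihood differences equal a dense V computation."""
    ds, table, model = small_dataset
    G1 = np.array(ds.config.G_true)
    R1 = np.array(ds.config.R_true)
    G2, R2 = 1.5 * G1, 0.7 * R1 + 0.05 * np.eye(4)

    ws = _Workspace(table, ds.pedigree, model)
    A = ws.ped.relationship_matrix()
    apos = np.empty(ws.n, dtype=int)
    for pat in ws.patterns:
        apos[pat.idx] = pat.anim
    AG = A[np.ix_(apos, apos)]
    m = ws.m
    idx = [(j, t) for j in range(ws.n) for t in range(m)]
    N = len(idx)
    X = np.zeros((N, ws.p))
    y = np.zeros(N)
    for a, (j, s) in enumerate(idx):
        X[a, s * ws.pf:(s + 1) * ws.pf] = ws.F[j]
        y[a] = ws.Y[j, s]

    def dense_ll(G, R):
        V = (np.einsum("jk,st->jskt", AG, G).reshape(N, N)
             + np.kron(np.eye(ws.n), R))
        Vi = np.linalg.inv(V)
        XVX = X.T @ Vi @ X
        beta = np.linalg.solve(XVX, X.T @ Vi @ y)
        res = y - X @ beta
        return -0.5 * (np.linalg.slogdet(V)[1]
                       + np.linalg.slogdet(XVX)[1] + res @ Vi @ res)

    d_mme = (reml_loglik(VarianceComponents(model.traits, G1, R1),
                         table, ds.pedigree, model)
             - reml_loglik(VarianceComponents(model.traits, G2, R2),
                           table, ds.pedigree, model))
    d_dense = dense_ll(G1, R1) - dense_ll(G2, R2)
    assert d_mme == pytest.approx(d_dense, abs=1e-6)
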