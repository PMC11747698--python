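"""Synthetic boar-taint data with the covariance structure the model assumes.

The generator emulates a progeny-test design: Pietrain sires (with a
short paternal pedigree of their own) mated to unrelated crossbred dams,
progeny reared across testing stations and slaughtered around 95 kg /
176 d.  True breeding values follow u ~ N(0, A x G) via sequential
Mendelian sampling; phenotypes add a station-by-month class effect,
regressions on slaughter weight and age, and residuals e ~ N(0, R).
Compound traits are simulated on the log10 scale and stored back on the
observed ppm scale (exactly invertible, no detection-limit censoring);
sensory traits are genuinely ordinal: a continuous liability is
discretized at per-assessor cutpoints, so the Snell stage downstream has
real work to do.

All randomness flows from ``config.seed`` through named substreams, so a
fixed config is bit-reproducible stage by stage.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import params
from .pedigree import Pedigree


class ConfigurationError(ValueError):
    """Inconsistent or non-positive simulation settings."""


class MatrixError(ValueError):
    """A covariance matrix is not symmetric positive semidefinite."""


def substream(seed: int, name: str) -> np.random.Generator:
    """Deterministic named child stream of a top-level seed."""
    return np.random.default_rng(
        np.random.SeedSequence([int(seed), zlib.crc32(name.encode())]))


def _check_covariance(mat: np.ndarray, name: str, m: int) -> np.ndarray:
    arr = np.asarray(mat, dtype=float)
    if arr.shape != (m, m):
        raise MatrixError(f"{name} must be {m}x{m}, got {arr.shape}")
    if not np.allclose(arr, arr.T, atol=1e-10):
        raise MatrixError(f"{name} is not symmetric")
    if np.linalg.eigvalsh(arr).min() < -1e-8 * max(np.trace(arr), 1.0):
        raise MatrixError(f"{name} is not positive semidefinite")
    return 0.5 * (arr + arr.T)


@dataclass
class SimulationConfig:
    """Population design, true parameters and bookkeeping for one run.

    Defaults reproduce the study conditions: 50 sires with ~1,016 progeny
    over 3 stations, 10 assessors with heterogeneous score distributions,
    and two assessors observed on only 856 animals.
    """

    n_sires: int = 50
    n_progeny: int = 1016
    dams_per_sire: int = 16
    n_grandsires: int = 25
    sire_dams_recorded: bool = True
    n_stations: int = 3
    months_per_station: int = 12
    n_assessors: int = 10
    G_true: np.ndarray | None = None
    R_true: np.ndarray | None = None
    trait_labels: list[str] = field(default_factory=list)
    trait_means: np.ndarray | None = None
    score_thresholds: np.ndarray | None = None
    weight_mean: float = 94.9
    weight_sd: float = 4.81
    age_mean: float = 175.9
    age_sd: float = 11.31
    class_effect_sd: np.ndarray | None = None
    beta_weight: np.ndarray | None = None
    beta_age: np.ndarray | None = None
    missing_assessors: tuple[int, ...] = (4, 5)
    missing_observed_count: int = 856
    seed: int = 1

    def __post_init__(self):
        for name in ("n_sires", "n_progeny", "dams_per_sire", "n_stations",
                     "months_per_station", "n_assessors"):
            if getattr(self, name) < 1:
                raise ConfigurationError(f"{name} must be >= 1")
        if self.n_grandsires < 0:
            raise ConfigurationError("n_grandsires must be >= 0")
        k = self.n_assessors
        m = 2 + k
        if self.G_true is None or self.R_true is None:
            G, R = params.study_covariances(min(k, 10))
            if k > 10:
                raise ConfigurationError(
                    "default parameters cover at most 10 assessors")
            if self.G_true is None:
                self.G_true = G
            if self.R_true is None:
                self.R_true = R
        self.G_true = _check_covariance(self.G_true, "G_true", m)
        self.R_true = _check_covariance(self.R_true, "R_true", m)
        if not self.trait_labels:
            self.trait_labels = params.trait_labels(k)
        if len(self.trait_labels) != m:
            raise ConfigurationError("trait_labels must have 2 + k entries")
        if self.trait_means is None:
            self.trait_means = np.r_[
                params.SKAT_MEAN, params.ANONT_MEAN, np.zeros(k)]
        self.trait_means = np.asarray(self.trait_means, dtype=float)
        if self.score_thresholds is None:
            if k > 10:
                raise ConfigurationError("no default thresholds beyond 10")
            self.score_thresholds = params.default_thresholds(k)
        self.score_thresholds = np.asarray(self.score_thresholds, float)
        if self.score_thresholds.shape != (k, 5):
            raise ConfigurationError("score_thresholds must be k x 5")
        if np.any(np.diff(self.score_thresholds, axis=1) < -1e-12):
            raise ConfigurationError(
                "score thresholds must be non-decreasing per assessor")
        if self.class_effect_sd is None:
            self.class_effect_sd = 0.1 * np.sqrt(
                np.diag(self.G_true) + np.diag(self.R_true))
        self.class_effect_sd = np.broadcast_to(
            np.asarray(self.class_effect_sd, float), (m,)).copy()
        if self.beta_weight is None:
            self.beta_weight = np.r_[0.002, 0.002, np.full(k, 0.01)]
        if self.beta_age is None:
            self.beta_age = np.r_[0.001, 0.001, np.full(k, 0.005)]
        self.beta_weight = np.broadcast_to(
            np.asarray(self.beta_weight, float), (m,)).copy()
        self.beta_age = np.broadcast_to(
            np.asarray(self.beta_age, float), (m,)).copy()
        bad = [a for a in self.missing_assessors if not 1 <= a <= k]
        if bad:
            raise ConfigurationError(f"missing_assessors out of range: {bad}")

    # -- id layout ---------------------------------------------------------

    def id_layout(self) -> dict[str, np.ndarray]:
        """Deterministic id blocks: grandsires, granddams, sires, dams, progeny."""
        nxt = 1
        gs = np.arange(nxt, nxt + self.n_grandsires); nxt += self.n_grandsires
        n_gd = self.n_sires if (self.sire_dams_recorded and self.n_grandsires)\
            else 0
        gd = np.arange(nxt, nxt + n_gd); nxt += n_gd
        sires = np.arange(nxt, nxt + self.n_sires); nxt += self.n_sires
        dams = np.arange(nxt, nxt + self.n_sires * self.dams_per_sire)
        nxt += dams.size
        progeny = np.arange(nxt, nxt + self.n_progeny)
        return {"grandsires": gs, "granddams": gd, "sires": sires,
                "dams": dams, "progeny": progeny}


@dataclass
class SimulatedDataset:
    """Generated pedigree, phenotypes, and the simulation truth."""

    config: SimulationConfig
    pedigree: Pedigree
    phenotypes: pd.DataFrame
    true_breeding_values: pd.DataFrame   # indexed by animal id, trait columns
    true_liabilities: pd.DataFrame       # continuous sensory traits, progeny


# ---------------------------------------------------------------------------
# Operations
# ---------------------------------------------------------------------------

def simulate_pedigree(config: SimulationConfig) -> Pedigree:
    """Pedigree with sire ancestry, unrelated founder dams, and progeny.

    Sires may carry up to two further paternal generations (grandsires
    shared round-robin, plus an own founder dam each); commercial dams
    are unrelated founders nested within sire.  Progeny are allocated to
    sires as evenly as possible and to dams round-robin within sire.
    """
    ids = config.id_layout()
    animal, sire, dam = [], [], []
    for g in ids["grandsires"]:
        animal.append(g); sire.append(0); dam.append(0)
    for d in ids["granddams"]:
        animal.append(d); sire.append(0); dam.append(0)
    for i, s in enumerate(ids["sires"]):
        gs = ids["grandsires"][i % len(ids["grandsires"])] \
            if len(ids["grandsires"]) else 0
        gd = ids["granddams"][i] if len(ids["granddams"]) else 0
        animal.append(s); sire.append(gs); dam.append(gd)
    for d in ids["dams"]:
        animal.append(d); sire.append(0); dam.append(0)
    counts = np.full(config.n_sires, config.n_progeny // config.n_sires)
    counts[:config.n_progeny % config.n_sires] += 1
    pidx = 0
    for i, s in enumerate(ids["sires"]):
        sire_dams = ids["dams"][i * config.dams_per_sire:
                                (i + 1) * config.dams_per_sire]
        for j in range(counts[i]):
            animal.append(ids["progeny"][pidx])
            sire.append(s)
            dam.append(sire_dams[j % len(sire_dams)])
            pidx += 1
    return Pedigree.from_records(animal, sire, dam)


def simulate_breeding_values(pedigree: Pedigree, G_true,
                             rng: np.random.Generator) -> np.ndarray:
    """True breeding values by sequential Mendelian sampling.

    Founders draw N(0, G); offspring are the mean of their known parents
    plus a segregation deviate with variance d_i * G, where d_i accounts
    for unknown parents and parental inbreeding.  Across replicates the
    stacked values have covariance A x G.
    """
    G = _check_covariance(np.asarray(G_true, float), "G_true",
                          np.asarray(G_true).shape[0])
    m = G.shape[0]
    vals, vecs = np.linalg.eigh(G)
    L = vecs * np.sqrt(np.clip(vals, 0.0, None))
    n = len(pedigree)
    si, di = pedigree.parent_indices()
    d = pedigree.mendelian_variances()
    z = rng.standard_normal((n, m)) @ L.T
    u = np.zeros((n, m))
    for i in range(n):
        parent_mean = np.zeros(m)
        if si[i] >= 0:
            parent_mean += 0.5 * u[si[i]]
        if di[i] >= 0:
            parent_mean += 0.5 * u[di[i]]
        u[i] = parent_mean + np.sqrt(d[i]) * z[i]
    return u


def _implied_liability_sd(config: SimulationConfig) -> np.ndarray:
    """Model-implied marginal SD per trait (class + covariate + u + e)."""
    return np.sqrt(config.class_effect_sd ** 2
                   + (config.beta_weight * config.weight_sd) ** 2
                   + (config.beta_age * config.age_sd) ** 2
                   + np.diag(config.G_true) + np.diag(config.R_true))


def simulate_phenotypes(pedigree: Pedigree, breeding_values: np.ndarray,
                        config: SimulationConfig
                        ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Phenotype table for the progeny plus their continuous liabilities.

    Returns ``(phenotypes, liabilities)``.  Continuous trait values are
    class effect + weight/age regressions + u + e around the trait mean;
    compounds are stored on the ppm scale (10**log10-value) and sensory
    liabilities are discretized at the standardized per-assessor
    cutpoints into ordinal 0-5 scores.
    """
    m = 2 + config.n_assessors
    if breeding_values.shape != (len(pedigree), m):
        raise MatrixError("breeding values do not match pedigree / traits")
    ids = config.id_layout()
    progeny = ids["progeny"]
    n = progeny.size
    rows = pedigree.positions(progeny)

    rng_cls = substream(config.seed, "class_effects")
    n_classes = config.n_stations * config.months_per_station
    class_effects = (rng_cls.standard_normal((n_classes, m))
                     * config.class_effect_sd)

    rng = substream(config.seed, "phenotypes")
    station = rng.integers(1, config.n_stations + 1, size=n)
    month = rng.integers(1, config.months_per_station + 1, size=n)
    cls_index = (station - 1) * config.months_per_station + (month - 1)
    weight = config.weight_mean + config.weight_sd * rng.standard_normal(n)
    age = config.age_mean + config.age_sd * rng.standard_normal(n)

    vals, vecs = np.linalg.eigh(config.R_true)
    Lr = vecs * np.sqrt(np.clip(vals, 0.0, None))
    resid = rng.standard_normal((n, m)) @ Lr.T

    y = (config.trait_means[None, :]
         + class_effects[cls_index]
         + np.outer(weight - config.weight_mean, config.beta_weight)
         + np.outer(age - config.age_mean, config.beta_age)
         + breeding_values[rows] + resid)

    sd = _implied_liability_sd(config)
    sd = np.where(sd > 0, sd, 1.0)   # degenerate (all-zero) traits
    liab = y[:, 2:]
    liab_std = (liab - config.trait_means[None, 2:]) / sd[None, 2:]
    scores = np.empty((n, config.n_assessors), dtype=np.int64)
    for a in range(config.n_assessors):
        scores[:, a] = np.searchsorted(
            config.score_thresholds[a], liab_std[:, a], side="left")

    data = {"animal_id": progeny, "station": station, "month": month,
            "weight_kg": weight, "age_d": age,
            "ska_ppm": 10.0 ** y[:, 0], "anon_ppm": 10.0 ** y[:, 1]}
    for a in range(config.n_assessors):
        data[f"sens_{a + 1}"] = scores[:, a].astype(float)
    phenos = pd.DataFrame(data)
    liab_df = pd.DataFrame(
        {"animal_id": progeny,
         **{f"liab_{a + 1}": liab[:, a]
            for a in range(config.n_assessors)}})
    return phenos, liab_df


def apply_missingness(table: pd.DataFrame, config: SimulationConfig
                      ) -> pd.DataFrame:
    """Blank out seeded random records for the reduced-panel assessors.

    Each configured assessor keeps exactly ``missing_observed_count``
    observed scores; everything else in the table is untouched.
    """
    out = table.copy()
    n = len(out)
    if not config.missing_assessors:
        return out
    if config.missing_observed_count > n:
        raise ConfigurationError(
            f"observed count {config.missing_observed_count} exceeds "
            f"table size {n}")
    for a in config.missing_assessors:
        col = f"sens_{a}"
        if col not in out.columns:
            raise ConfigurationError(f"column {col} not in table")
        rng = substream(config.seed, f"missingness_{a}")
        drop = rng.choice(n, size=n - config.missing_observed_count,
                          replace=False)
        out.iloc[drop, out.columns.get_loc(col)] = np.nan
    return out


def simulate(config: SimulationConfig) -> SimulatedDataset:
    """Run the full generator: pedigree, breeding values, phenotypes."""
    ped = simulate_pedigree(config)
    bv = simulate_breeding_values(
        ped, config.G_true, substream(config.seed, "breeding_values"))
    phenos, liab = simulate_phenotypes(ped, bv, config)
    phenos = apply_missingness(phenos, config)
    bv_df = pd.DataFrame(bv, columns=config.trait_labels)
    bv_df.insert(0, "animal_id", ped.animal)
    return SimulatedDataset(config, ped, phenos, bv_df, liab)
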