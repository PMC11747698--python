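"""TSV input/output and table assembly.

Phenotypes travel as TSV with one row per animal (empty cell = missing);
pedigrees as 3-column TSV with 0 coding an unknown parent; covariance
matrices as labelled TSV.  ``analysis_table`` turns an observed-scale
phenotype table into the modelling table: log10 compounds plus
Snell-transformed sensory scores.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .pedigree import Pedigree
from .reml import VarianceComponents
from .snell import snell_transform_frame

FLOAT_FORMAT = "%.10g"


def assessor_columns(df: pd.DataFrame) -> list[str]:
    """Ordinal score columns sens_1..sens_k in panel order."""
    cols = [c for c in df.columns if c.startswith("sens_")]
    return sorted(cols, key=lambda c: int(c.split("_")[1]))


def write_phenotypes(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False, float_format=FLOAT_FORMAT)


def read_phenotypes(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_pedigree(ped: Pedigree, path) -> None:
    ped.to_frame().to_csv(path, sep="\t", index=False)


def read_pedigree(path) -> Pedigree:
    return Pedigree.from_frame(pd.read_csv(path, sep="\t"))


def write_labelled_matrix(mat: np.ndarray, labels, path) -> None:
    pd.DataFrame(mat, index=labels, columns=labels).to_csv(
        path, sep="\t", float_format=FLOAT_FORMAT)


def read_labelled_matrix(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=0)


def write_components(vc: VarianceComponents, out_dir) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    write_labelled_matrix(vc.G, vc.trait_labels, out / "G.tsv")
    write_labelled_matrix(vc.R, vc.trait_labels, out / "R.tsv")
    if vc.se_G is not None:
        write_labelled_matrix(vc.se_G, vc.trait_labels, out / "se_G.tsv")
    if vc.se_R is not None:
        write_labelled_matrix(vc.se_R, vc.trait_labels, out / "se_R.tsv")


def read_components(path) -> VarianceComponents:
    """Read G/R (and SEs when present) from a directory or a G file path."""
    p = Path(path)
    base = p if p.is_dir() else p.parent
    G = read_labelled_matrix(base / "G.tsv")
    R = read_labelled_matrix(base / "R.tsv")
    labels = list(G.index)
    if list(R.index) != labels:
        raise ValueError("G and R trait labels disagree")
    se_G = se_R = None
    if (base / "se_G.tsv").exists():
        se_G = read_labelled_matrix(base / "se_G.tsv").to_numpy()
    if (base / "se_R.tsv").exists():
        se_R = read_labelled_matrix(base / "se_R.tsv").to_numpy()
    return VarianceComponents(labels, G.to_numpy(), R.to_numpy(),
                              se_G=se_G, se_R=se_R)


def analysis_table(phenos: pd.DataFrame) -> tuple[pd.DataFrame, dict]:
    """Modelling table: log10 compounds + Snell scores, plus the scales.

    Compound concentrations must be strictly positive on the ppm scale
    (the log10 transform admits no zeros; censoring is not modelled).
    """
    for col in ("ska_ppm", "anon_ppm"):
        vals = phenos[col].to_numpy(float)
        if np.any(vals[~np.isnan(vals)] <= 0):
            raise ValueError(f"{col} must be strictly positive for log10")
    out = phenos[["animal_id", "station", "month",
                  "weight_kg", "age_d"]].copy()
    out["SKAt"] = np.log10(phenos["ska_ppm"].to_numpy(float))
    out["ANONt"] = np.log10(phenos["anon_ppm"].to_numpy(float))
    senst, scales = snell_transform_frame(phenos, assessor_columns(phenos))
    out = pd.concat([out, senst], axis=1)
    return out, scales


def parameter_report(vc: VarianceComponents, params) -> pd.DataFrame:
    """Per-trait parameter table: h2, variances, correlations with causals.

    Mirrors the customary multivariate-model report: one row per trait
    with heritability (+SE when available), genetic and residual
    variances, and phenotypic/genetic/residual correlations with SKAt
    and ANONt.
    """
    labels = vc.trait_labels
    rows = []
    for i, lab in enumerate(labels):
        row = {"trait": lab, "h2": params.h2[i],
               "var_g": vc.G[i, i], "var_r": vc.R[i, i]}
        if params.se_h2 is not None:
            row["se_h2"] = params.se_h2[i]
        if vc.se_G is not None:
            row["se_var_g"] = vc.se_G[i, i]
            row["se_var_r"] = vc.se_R[i, i]
        for c, cname in ((0, "SKAt"), (1, "ANONt")):
            if i == c:
                continue
            row[f"rP_{cname}"] = params.r_P[i, c]
            row[f"rG_{cname}"] = params.r_G[i, c]
            row[f"rR_{cname}"] = params.r_R[i, c]
        rows.append(row)
    return pd.DataFrame(rows)


def recursive_report(rec, trait_labels) -> pd.DataFrame:
    """Recursive-model table: h2, variances, Delta sigma_u^2, correlations."""
    rows = []
    for i, lab in enumerate(trait_labels):
        row = {"trait": lab, "h2": rec.parameters.h2[i],
               "var_g": rec.G_RM[i, i], "delta_gvar_pct": rec.delta_gvar[i],
               "var_r": rec.R_RM[i, i]}
        for c, cname in ((0, "SKAt"), (1, "ANONt")):
            if i == c:
                continue
            row[f"rP_{cname}"] = rec.parameters.r_P[i, c]
            row[f"rG_{cname}"] = rec.parameters.r_G[i, c]
        rows.append(row)
    return pd.DataFrame(rows)


def combination_report(results) -> pd.DataFrame:
    """Flat ranking table for a list of GroupResult."""
    return pd.DataFrame([
        {"members": " ".join(map(str, r.group.members)), "h2": r.h2,
         "rG_SKAt": r.rG_SKAt, "rG_ANONt": r.rG_ANONt,
         "rP_SKAt": r.rP_SKAt, "rP_ANONt": r.rP_ANONt}
        for r in results])


def snell_report(phenos: pd.DataFrame) -> pd.DataFrame:
    """Per-assessor frequency/scale report (one row per assessor).

    Columns: class frequencies f0..f5, Snell class values v0..v5, the
    raw-score mean/SD and the transformed-score mean/SD.
    """
    from .snell import class_frequencies, snell_scale

    rows = []
    for col in assessor_columns(phenos):
        dist = class_frequencies(phenos[col].to_numpy(), assessor_id=col)
        scale = snell_scale(dist)
        raw = phenos[col].to_numpy(float)
        raw = raw[~np.isnan(raw)]
        row = {"assessor": col, "n": dist.n}
        row.update({f"f{c}": dist.frequencies[c] for c in range(6)})
        row.update({f"v{c}": scale.class_values[c] for c in range(6)})
        row.update({"raw_mean": raw.mean(), "raw_sd": raw.std(),
                    "snell_mean": scale.mean, "snell_sd": scale.sd})
        rows.append(row)
    return pd.DataFrame(rows)
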