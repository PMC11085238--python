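"""Phenotype summarization: BLUEs, ANOVA variance components, heritability.

Phenotype records are long-format trial data Y_ijk (line × environment ×
replicate-within-environment) for one or more traits.  The line model is

    Y_ijk = μ + E_i + R_j(E_i) + G_k + ε_ijk

with genotype treated as fixed when estimating per-line BLUEs.  Broad-sense
heritability on a line-mean basis is

    h² = σ²G / (σ²G + σ²GE/e + σ²ε/(r·e))

with method-of-moments components from the two-way ANOVA mean squares:
σ²ε = MS_error, σ²GE = (MS_GE − MS_error)/r, σ²G = (MS_G − MS_GE)/(r·e).
Substituting these into the h² formula collapses it to
(MS_G − MS_GE)/MS_G, independent of e and r; both routes are computed and
cross-checked.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger("soygp")

REQUIRED_COLUMNS = ("line", "env", "rep", "trait", "value")


def validate_phenotypes(p: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in REQUIRED_COLUMNS if c not in p.columns]
    if missing:
        raise ValueError(f"phenotype table missing columns {missing}")
    if not np.isfinite(p["value"].to_numpy(float)).all():
        raise ValueError("phenotype values must be finite")
    return p


@dataclass
class VarianceComponents:
    """ANOVA mean squares, method-of-moments components and h² for one trait."""

    ms_G: float
    ms_GE: float
    ms_E: float
    ms_R: float
    ms_error: float
    df_G: int
    df_GE: int
    df_E: int
    df_R: int
    df_error: int
    sigma2_G: float
    sigma2_GE: float
    sigma2_e: float
    e: int
    r: int
    h2: float


def _sum_coded(labels: np.ndarray, levels: np.ndarray) -> np.ndarray:
    """Sum-to-zero contrast columns (len(levels) − 1 of them)."""
    k = len(levels)
    cols = np.zeros((len(labels), max(k - 1, 0)))
    index = {lv: i for i, lv in enumerate(levels)}
    for row, lab in enumerate(labels):
        i = index[lab]
        if i < k - 1:
            cols[row, i] = 1.0
        else:
            cols[row, :] = -1.0
    return cols


def compute_blues(p: pd.DataFrame, trait: str | None = None) -> pd.DataFrame:
    """Least-squares adjusted line means across environments.

    Genotype enters as a fixed effect (one dummy per line, no intercept);
    environment and replicate-within-environment enter as sum-to-zero
    contrasts, so each line's coefficient is its mean adjusted to the
    average environment.  For balanced data this equals the raw line mean.
    Returns a DataFrame indexed by line with one column per trait.
    """
    validate_phenotypes(p)
    traits = [trait] if trait else sorted(p["trait"].unique())
    out = {}
    for t in traits:
        d = p[p["trait"] == t]
        if d.empty:
            raise ValueError(f"no records for trait {t!r}")
        counts = d.groupby("line").size()
        if (counts == 0).any():
            raise ValueError("line with zero records")
        lines = np.sort(d["line"].unique())
        envs = np.sort(d["env"].unique())
        reps = np.sort(d["rep"].unique())
        cell = d.groupby(["line", "env", "rep"]).size()
        if len(cell) == len(lines) * len(envs) * len(reps) and (cell == 1).all():
            # balanced design: sum-to-zero environment/replicate contrasts
            # are orthogonal to the line dummies, so the adjusted mean is
            # exactly the raw line mean
            out[t] = d.groupby("line")["value"].mean().loc[lines]
            continue
        line_idx = {l: i for i, l in enumerate(lines)}
        Xg = np.zeros((len(d), len(lines)))
        Xg[np.arange(len(d)), [line_idx[l] for l in d["line"]]] = 1.0
        blocks = [Xg, _sum_coded(d["env"].to_numpy(), envs)]
        for env in envs:
            sel = (d["env"] == env).to_numpy()
            reps = np.sort(d.loc[sel, "rep"].unique())
            if len(reps) > 1:
                cols = np.zeros((len(d), len(reps) - 1))
                cols[sel] = _sum_coded(d.loc[sel, "rep"].to_numpy(), reps)
                blocks.append(cols)
        X = np.hstack(blocks)
        y = d["value"].to_numpy(float)
        coef, *_ = np.linalg.lstsq(X, y, rcond=None)
        out[t] = pd.Series(coef[: len(lines)], index=lines)
    blues = pd.DataFrame(out)
    blues.index.name = "line"
    return blues


def anova_components(p: pd.DataFrame, trait: str) -> VarianceComponents:
    """Two-way ANOVA (G, E, R(E), G×E, error) with method-of-moments components.

    Requires ≥ 2 environments and ≥ 2 replicates.  Balanced designs use the
    closed-form sums of squares; near-balanced data fall back to sequential
    (Type-I) sums of squares with a warning.  Negative component estimates
    are truncated at zero with a warning.
    """
    validate_phenotypes(p)
    d = p[p["trait"] == trait]
    if d.empty:
        raise ValueError(f"no records for trait {trait!r}")
    lines = np.sort(d["line"].unique())
    envs = np.sort(d["env"].unique())
    reps = np.sort(d["rep"].unique())
    g_, e_, r_ = len(lines), len(envs), len(reps)
    if e_ < 2 or r_ < 2:
        raise ValueError("ANOVA needs >= 2 environments and >= 2 replicates")
    cell = d.groupby(["line", "env", "rep"]).size()
    balanced = len(cell) == g_ * e_ * r_ and (cell == 1).all()
    if balanced:
        ss = _balanced_ss(d, lines, envs, reps)
    else:
        warnings.warn(
            "unbalanced design: using sequential (Type-I) sums of squares",
            stacklevel=2,
        )
        ss = _type1_ss(d, lines, envs, reps)
    df_E, df_R = e_ - 1, e_ * (r_ - 1)
    df_G, df_GE = g_ - 1, (g_ - 1) * (e_ - 1)
    df_err = max(int(len(d) - 1 - df_E - df_R - df_G - df_GE), 1)
    ms_E, ms_R = ss["E"] / df_E, ss["R"] / df_R if df_R else 0.0
    ms_G, ms_GE = ss["G"] / df_G, ss["GE"] / df_GE
    ms_err = ss["error"] / df_err
    s2e = ms_err
    s2ge = (ms_GE - ms_err) / r_
    s2g = (ms_G - ms_GE) / (r_ * e_)
    if s2ge < 0 or s2g < 0:
        warnings.warn("negative variance component truncated at 0", stacklevel=2)
    s2ge, s2g = max(s2ge, 0.0), max(s2g, 0.0)
    h2 = heritability_from_components(s2g, s2ge, s2e, e_, r_)
    return VarianceComponents(
        ms_G=ms_G, ms_GE=ms_GE, ms_E=ms_E, ms_R=ms_R, ms_error=ms_err,
        df_G=df_G, df_GE=df_GE, df_E=df_E, df_R=df_R, df_error=df_err,
        sigma2_G=s2g, sigma2_GE=s2ge, sigma2_e=s2e, e=e_, r=r_, h2=h2,
    )


def _balanced_ss(d, lines, envs, reps):
    g_, e_, r_ = len(lines), len(envs), len(reps)
    y = d.pivot_table(index="line", columns=["env", "rep"], values="value")
    y = y.loc[lines].to_numpy()  # (g, e*r), env-major columns
    Y = y.reshape(g_, e_, r_)
    gm = Y.mean()
    mG = Y.mean(axis=(1, 2))
    mE = Y.mean(axis=(0, 2))
    mER = Y.mean(axis=0)
    mGE = Y.mean(axis=2)
    ss_G = e_ * r_ * np.sum((mG - gm) ** 2)
    ss_E = g_ * r_ * np.sum((mE - gm) ** 2)
    ss_R = g_ * np.sum((mER - mE[:, None]) ** 2)
    ss_GE = r_ * np.sum((mGE - mG[:, None] - mE[None, :] + gm) ** 2)
    ss_tot = np.sum((Y - gm) ** 2)
    return {
        "G": ss_G, "E": ss_E, "R": ss_R, "GE": ss_GE,
        "error": ss_tot - ss_G - ss_E - ss_R - ss_GE,
    }


def _type1_ss(d, lines, envs, reps):
    """Sequential sums of squares in the order E, R(E), G, G×E."""
    y = d["value"].to_numpy(float)
    n = len(y)

    def dummies(labels, levels):
        idx = {lv: i for i, lv in enumerate(levels)}
        M = np.zeros((n, len(levels)))
        M[np.arange(n), [idx[l] for l in labels]] = 1.0
        return M

    E = dummies(d["env"].to_numpy(), envs)
    er_labels = list(zip(d["env"], d["rep"]))
    er_levels = sorted(set(er_labels))
    R = dummies(er_labels, er_levels)
    G = dummies(d["line"].to_numpy(), lines)
    ge_labels = list(zip(d["line"], d["env"]))
    ge_levels = sorted(set(ge_labels))
    GE = dummies(ge_labels, ge_levels)
    X = np.ones((n, 1))
    rss = [float(np.sum((y - X @ np.linalg.lstsq(X, y, rcond=None)[0]) ** 2))]
    for block in (E, R, G, GE):
        X = np.hstack([X, block])
        res = y - X @ np.linalg.lstsq(X, y, rcond=None)[0]
        rss.append(float(np.sum(res**2)))
    return {
        "E": rss[0] - rss[1], "R": rss[1] - rss[2],
        "G": rss[2] - rss[3], "GE": rss[3] - rss[4], "error": rss[4],
    }


def heritability_from_components(
    sigma2_G: float, sigma2_GE: float, sigma2_e: float, e: int, r: int
) -> float:
    """h² = σ²G / (σ²G + σ²GE/e + σ²ε/(r·e)) on the line-mean basis."""
    if e < 1 or r < 1:
        raise ValueError("e and r must be >= 1")
    denom = sigma2_G + sigma2_GE / e + sigma2_e / (r * e)
    if denom <= 0:
        raise ValueError("zero phenotypic variance: h2 undefined")
    return float(np.clip(sigma2_G / denom, 0.0, 1.0))


def heritability_from_mean_squares(ms_G: float, ms_GE: float) -> float:
    """The algebraically reduced mean-square route: (MS_G − MS_GE)/MS_G."""
    if ms_G <= 0:
        raise ValueError("MS_G must be positive")
    return float(np.clip((ms_G - ms_GE) / ms_G, 0.0, 1.0))


def broad_sense_h2(vc: VarianceComponents) -> float:
    """Heritability from a fitted VarianceComponents (component route)."""
    return heritability_from_components(
        vc.sigma2_G, vc.sigma2_GE, vc.sigma2_e, vc.e, vc.r
    )


def descriptive_stats(values) -> dict:
    """Min, max, mean, SD (n−1), CV, moment skewness and excess kurtosis."""
    x = np.asarray(values, dtype=float)
    if x.size < 2:
        raise ValueError("need at least 2 values")
    sd = float(np.std(x, ddof=1))
    mean = float(np.mean(x))
    return {
        "n": int(x.size),
        "min": float(np.min(x)),
        "max": float(np.max(x)),
        "mean": mean,
        "sd": sd,
        "cv": sd / mean if mean != 0 else np.nan,
        "skewness": float(stats.skew(x, bias=True)) if sd > 0 else 0.0,
        "kurtosis": float(stats.kurtosis(x, bias=True)) if sd > 0 else 0.0,
    }


def trait_correlation(x, y) -> float:
    """Pearson product-moment correlation between two trait vectors."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.size < 3:
        raise ValueError("need equal-length vectors with n >= 3")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("zero variance")
    return float(stats.pearsonr(x, y)[0])
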