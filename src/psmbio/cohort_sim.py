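"""Synthetic cirrhosis-cohort datasheet generator.

Draws per-patient continuous variables (demographics, labs, imaging
biomarkers) from a Gaussian copula whose *observed-scale* Pearson
correlations match a configurable target matrix, maps marginals to normal
or log-normal distributions, recomputes MELD from the simulated labs, and
derives the binary clinical markers (ascites on imaging, paracentesis
history, varices, variceal bleed, SBP, TIPS ...) by thresholding a shared
latent severity score so that severity-linked group differences emerge
jointly rather than independently.

The default parameters reproduce the marginal means/SDs, prevalences and
biomarker-laboratory correlation structure of a 224-patient contrast-MRI
cirrhosis cohort; the simulator exists so the downstream statistics
pipeline can be exercised end-to-end without clinical data.
"""

from __future__ import annotations

import json
import math
from pathlib import Path
from typing import Literal, Optional

import numpy as np
import pandas as pd
from pydantic import BaseModel, Field, model_validator

from psmbio.biomarkers import compute_meld

__all__ = ["Marginal", "CohortSimParams", "default_params", "simulate_cohort", "write_cohort"]

#: copula variable order (binaries and MELD are derived, not drawn)
CONTINUOUS_VARS = (
    "age", "bmi", "albumin", "creatinine", "tbili", "inr",
    "sff", "smi", "cefr_art", "cefr_pv", "cefr_del",
)

BINARY_VARS = ("sex_f", "api", "ph", "vpi", "vbh", "sbp", "tips", "diabetes", "thyroid")


class Marginal(BaseModel):
    """Mean/SD of one continuous variable plus its distribution family."""

    mean: float
    sd: float = Field(gt=0.0)
    dist: Literal["normal", "lognormal"] = "normal"

    def lognormal_params(self) -> tuple[float, float]:
        """(mu, sigma) of ln X matching this mean and SD."""
        s2 = math.log(1.0 + (self.sd / self.mean) ** 2)
        return math.log(self.mean) - s2 / 2.0, math.sqrt(s2)


class CohortSimParams(BaseModel):
    """Everything the simulator needs; defaults come from the reference cohort."""

    n: int = Field(default=224, gt=1)
    marginals: dict[str, Marginal]
    #: target Pearson correlations on the observed scale, (var_a, var_b, r);
    #: unlisted pairs default to 0 before the PSD repair
    correlations: list[tuple[str, str, float]]
    prevalences: dict[str, float]
    #: latent-severity loading in [0, 1) per binary; 0 = independent draw
    loadings: dict[str, float]
    #: grade composition among positives, mildest first
    api_grade_probs: dict[str, float]
    varices_grade_probs: dict[str, float]
    etiology_probs: dict[str, float]
    height_mean_by_sex: dict[str, float] = {"M": 1.76, "F": 1.62}
    height_sd: float = 0.07
    #: max |adjustment| tolerated during PSD repair of the latent matrix
    psd_tolerance: float = 0.1
    seed: int = 0

    @model_validator(mode="after")
    def _check(self) -> "CohortSimParams":
        for var in CONTINUOUS_VARS:
            if var not in self.marginals:
                raise ValueError(f"missing marginal for {var!r}")
        for a, b, r in self.correlations:
            for v in (a, b):
                if v not in CONTINUOUS_VARS:
                    raise ValueError(f"correlation names unknown variable {v!r}")
            if not -1.0 < r < 1.0:
                raise ValueError(f"correlation {a}-{b} out of (-1, 1): {r}")
        for key in BINARY_VARS:
            p = self.prevalences.get(key)
            if p is None or not 0.0 < p < 1.0:
                raise ValueError(f"prevalence for {key!r} must be in (0, 1)")
            lam = self.loadings.get(key, 0.0)
            if not 0.0 <= lam < 1.0:
                raise ValueError(f"loading for {key!r} must be in [0, 1)")
        for probs in (self.api_grade_probs, self.varices_grade_probs, self.etiology_probs):
            if abs(sum(probs.values()) - 1.0) > 1e-6:
                raise ValueError("grade/etiology probabilities must sum to 1")
        return self


def default_params(n: int = 224, seed: int = 0) -> CohortSimParams:
    """Reference-cohort defaults: marginals, prevalences and the signed
    biomarker-laboratory correlation targets.

    Labs with strong right skew (creatinine, total bilirubin, INR — printed
    SD above half the mean) and the fat fraction are log-normal; the rest
    are normal.
    """
    marginals = {
        "age": Marginal(mean=60.0, sd=10.0),
        "bmi": Marginal(mean=31.0, sd=7.3),
        "albumin": Marginal(mean=3.55, sd=0.65),
        "creatinine": Marginal(mean=0.93, sd=0.38, dist="lognormal"),
        "tbili": Marginal(mean=1.64, sd=2.11, dist="lognormal"),
        "inr": Marginal(mean=1.25, sd=0.35, dist="lognormal"),
        "sff": Marginal(mean=0.13, sd=0.08, dist="lognormal"),
        "smi": Marginal(mean=5.25, sd=1.95),
        "cefr_art": Marginal(mean=0.10, sd=0.12),
        "cefr_pv": Marginal(mean=0.22, sd=0.14),
        "cefr_del": Marginal(mean=0.25, sd=0.16),
    }
    correlations = [
        # laboratory / anthropometric vs imaging biomarkers
        ("albumin", "sff", -0.03), ("albumin", "smi", 0.10),
        ("albumin", "cefr_art", 0.06), ("albumin", "cefr_pv", 0.15),
        ("albumin", "cefr_del", 0.13),
        ("creatinine", "sff", -0.05), ("creatinine", "smi", 0.08),
        ("creatinine", "cefr_art", -0.06), ("creatinine", "cefr_pv", -0.04),
        ("creatinine", "cefr_del", -0.04),
        ("tbili", "sff", -0.12), ("tbili", "smi", -0.15),
        ("tbili", "cefr_art", -0.12), ("tbili", "cefr_pv", -0.22),
        ("tbili", "cefr_del", -0.20),
        ("inr", "sff", -0.02), ("inr", "smi", -0.01),
        ("inr", "cefr_art", -0.07), ("inr", "cefr_pv", -0.15),
        ("inr", "cefr_del", -0.10),
        ("bmi", "sff", 0.34), ("bmi", "smi", 0.36),
        ("bmi", "cefr_art", 0.04), ("bmi", "cefr_pv", 0.02),
        ("bmi", "cefr_del", 0.05),
        # biomarker-biomarker pairs with reported associations
        ("sff", "cefr_pv", 0.13), ("sff", "cefr_del", 0.15),
    ]
    prevalences = {
        "sex_f": 89 / 224,
        "api": 83 / 224,       # any ascites including trace
        "ph": 47 / 224,
        "vpi": 164 / 224,      # any varices including small
        "vbh": 38 / 224,
        "sbp": 18 / 224,
        "tips": 15 / 224,
        "diabetes": 103 / 224,
        "thyroid": 19 / 224,
    }
    loadings = {
        "sex_f": 0.0,
        "api": 0.6,
        "ph": 0.6,
        "vpi": 0.5,
        "vbh": 0.4,
        "sbp": 0.4,
        "tips": 0.3,
        "diabetes": 0.0,
        "thyroid": 0.0,
    }
    api_grade_probs = {"trace": 32 / 83, "small": 23 / 83, "moderate": 19 / 83, "large": 9 / 83}
    varices_grade_probs = {"small": 128 / 164, "moderate": 18 / 164, "large": 18 / 164}
    etiology_probs = {
        "viral": 69 / 224, "nash": 66 / 224, "etoh": 61 / 224, "other": 11 / 224,
        "etoh+viral": 11 / 224, "etoh+nash": 3 / 224, "nash+viral": 2 / 224,
        "viral+other": 1 / 224,
    }
    return CohortSimParams(
        n=n,
        marginals=marginals,
        correlations=correlations,
        prevalences=prevalences,
        loadings=loadings,
        api_grade_probs=api_grade_probs,
        varices_grade_probs=varices_grade_probs,
        etiology_probs=etiology_probs,
        seed=seed,
    )


# ---------------------------------------------------------------------------
# copula machinery
# ---------------------------------------------------------------------------

def _latent_rho(r: float, ma: Marginal, mb: Marginal) -> float:
    """Latent normal correlation producing observed Pearson r after the
    marginal transforms (exact moment matching for normal/log-normal pairs).
    """
    kinds = (ma.dist, mb.dist)
    if kinds == ("normal", "normal"):
        return r
    if "normal" in kinds:
        logm = ma if ma.dist == "lognormal" else mb
        _, s = logm.lognormal_params()
        return r * math.sqrt(math.expm1(s * s)) / s
    _, s1 = ma.lognormal_params()
    _, s2 = mb.lognormal_params()
    arg = 1.0 + r * math.sqrt(math.expm1(s1 * s1) * math.expm1(s2 * s2))
    if arg <= 0:
        raise ValueError(f"target correlation {r} infeasible for these log-normals")
    return math.log(arg) / (s1 * s2)


def _build_latent_corr(params: CohortSimParams) -> tuple[np.ndarray, float]:
    k = len(CONTINUOUS_VARS)
    idx = {v: i for i, v in enumerate(CONTINUOUS_VARS)}
    corr = np.eye(k)
    for a, b, r in params.correlations:
        rho = _latent_rho(r, params.marginals[a], params.marginals[b])
        if not -1.0 < rho < 1.0:
            raise ValueError(f"latent correlation for {a}-{b} out of range: {rho:.3f}")
        corr[idx[a], idx[b]] = corr[idx[b], idx[a]] = rho
    repaired, max_adj = _nearest_psd(corr)
    if max_adj > params.psd_tolerance:
        raise ValueError(
            f"PSD repair moved a correlation by {max_adj:.3f} "
            f"(> tolerance {params.psd_tolerance}); targets are inconsistent"
        )
    return repaired, max_adj


def _nearest_psd(corr: np.ndarray, eps: float = 1e-8) -> tuple[np.ndarray, float]:
    """Eigenvalue clipping followed by re-normalisation to unit diagonal."""
    vals, vecs = np.linalg.eigh(corr)
    if vals.min() >= eps:
        return corr, 0.0
    clipped = (vecs * np.maximum(vals, eps)) @ vecs.T
    d = np.sqrt(np.diag(clipped))
    repaired = clipped / np.outer(d, d)
    np.fill_diagonal(repaired, 1.0)
    return repaired, float(np.abs(repaired - corr).max())


def _quantile_threshold_binary(
    latent_score: np.ndarray, prevalence: float, rng: np.random.Generator, loading: float
) -> tuple[np.ndarray, np.ndarray]:
    """Threshold loading*severity + noise at the sample quantile matching
    the prevalence; returns (boolean vector, underlying score).
    """
    n = latent_score.size
    noise = rng.standard_normal(n)
    score = loading * latent_score + math.sqrt(1.0 - loading**2) * noise
    k = int(round(n * prevalence))
    k = min(max(k, 1), n - 1)
    cutoff = np.partition(score, n - k)[n - k]
    return score >= cutoff, score


def _assign_grades(
    positive: np.ndarray,
    score: np.ndarray,
    grade_probs: dict[str, float],
) -> np.ndarray:
    """Ordinal grades among positives, milder grades at lower severity."""
    grades = np.full(positive.size, "no", dtype=object)
    pos_idx = np.flatnonzero(positive)
    order = pos_idx[np.argsort(score[pos_idx], kind="stable")]
    counts = _largest_remainder(len(pos_idx), list(grade_probs.values()))
    start = 0
    for grade, count in zip(grade_probs.keys(), counts):
        grades[order[start:start + count]] = grade
        start += count
    return grades


def _largest_remainder(total: int, probs: list[float]) -> list[int]:
    raw = [p * total for p in probs]
    counts = [int(math.floor(x)) for x in raw]
    short = total - sum(counts)
    remainders = sorted(range(len(raw)), key=lambda i: raw[i] - counts[i], reverse=True)
    for i in remainders[:short]:
        counts[i] += 1
    return counts


def simulate_cohort(params: Optional[CohortSimParams] = None) -> pd.DataFrame:
    """Draw one synthetic patient datasheet.

    The MELD column is recomputed from the simulated labs (never drawn), so
    it is internally consistent with creatinine/bilirubin/INR by
    construction. The latent severity score behind the clinical binaries is
    the MELD-coefficient-weighted sum of the latent laboratory z-scores, so
    severity-marked subgroups inherit the configured biomarker-laboratory
    correlations.
    """
    if params is None:
        params = default_params()
    rng = np.random.default_rng(params.seed)
    n = params.n
    k = len(CONTINUOUS_VARS)

    latent_corr, _ = _build_latent_corr(params)
    chol = np.linalg.cholesky(latent_corr)
    z = rng.standard_normal((n, k)) @ chol.T

    data: dict[str, np.ndarray] = {}
    for j, var in enumerate(CONTINUOUS_VARS):
        m = params.marginals[var]
        if m.dist == "normal":
            data[var] = m.mean + m.sd * z[:, j]
        else:
            mu, s = m.lognormal_params()
            data[var] = np.exp(mu + s * z[:, j])

    idx = {v: i for i, v in enumerate(CONTINUOUS_VARS)}
    severity = (
        0.957 * z[:, idx["creatinine"]]
        + 0.378 * z[:, idx["tbili"]]
        + 1.120 * z[:, idx["inr"]]
    )
    severity = (severity - severity.mean()) / severity.std()

    flags: dict[str, np.ndarray] = {}
    scores: dict[str, np.ndarray] = {}
    for key in BINARY_VARS:
        flags[key], scores[key] = _quantile_threshold_binary(
            severity, params.prevalences[key], rng, params.loadings.get(key, 0.0)
        )

    meld = np.array(
        [
            compute_meld(cr, tb, i_)
            for cr, tb, i_ in zip(data["creatinine"], data["tbili"], data["inr"])
        ],
        dtype=np.int64,
    )

    sex = np.where(flags["sex_f"], "F", "M")
    height = np.array(
        [rng.normal(params.height_mean_by_sex[s], params.height_sd) for s in sex]
    )
    height = np.clip(height, 1.30, 2.10)

    api_grade = _assign_grades(flags["api"], scores["api"], params.api_grade_probs)
    varices_grade = _assign_grades(flags["vpi"], scores["vpi"], params.varices_grade_probs)
    etiology = rng.choice(
        list(params.etiology_probs.keys()),
        size=n,
        p=list(params.etiology_probs.values()),
    )

    df = pd.DataFrame(
        {
            "id": [f"P{i + 1:04d}" for i in range(n)],
            "sex": sex,
            "age": data["age"],
            "height": height,
            "bmi": data["bmi"],
            "albumin": data["albumin"],
            "creatinine": data["creatinine"],
            "tbili": data["tbili"],
            "inr": data["inr"],
            "meld": meld,
            "etiology": etiology,
            "api_grade": api_grade,
            "varices_grade": varices_grade,
            "ph": flags["ph"].astype(int),
            "sbp": flags["sbp"].astype(int),
            "vbh": flags["vbh"].astype(int),
            "tips": flags["tips"].astype(int),
            "diabetes": flags["diabetes"].astype(int),
            "thyroid": flags["thyroid"].astype(int),
            "sff": data["sff"],
            "smi": data["smi"],
            "cefr_art": data["cefr_art"],
            "cefr_pv": data["cefr_pv"],
            "cefr_del": data["cefr_del"],
        }
    )
    return df


def write_cohort(
    df: pd.DataFrame, out_csv: str | Path, params: Optional[CohortSimParams] = None
) -> Path:
    """Write the datasheet CSV plus a JSON sidecar of the true parameters."""
    out_csv = Path(out_csv)
    out_csv.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(out_csv, index=False)
    if params is not None:
        sidecar = out_csv.with_suffix(".params.json")
        sidecar.write_text(params.model_dump_json(indent=2))
    return out_csv
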