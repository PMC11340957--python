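"""Cohort loading, table generation and the reproduction harness.

``load_cohort`` reads an S1-style per-patient CSV into the canonical schema
(with header aliasing, unit guards and derived columns); ``run_analysis``
recomputes the three result tables -- population descriptives, biomarker
group comparisons against clinical severity markers, and
biomarker-laboratory Pearson correlations -- plus ROC curves for the
high-MELD group; ``reproduce`` compares a recomputed analysis against the
bundled published reference values cell by cell.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from importlib import resources
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
from scipy.stats import false_discovery_control

from psmbio import stats as pstats
from psmbio.biomarkers import compute_meld

__all__ = [
    "BIOMARKERS",
    "GROUPINGS",
    "LAB_VARS",
    "load_cohort",
    "LoadedCohort",
    "run_analysis",
    "AnalysisReport",
    "reproduce",
    "load_reference_tables",
]

BIOMARKERS = ("sff", "smi", "cefr_art", "cefr_pv", "cefr_del")
#: Table-2 style dichotomies: column -> (label_a, label_b)
GROUPINGS = {
    "sex": ("M", "F"),
    "api": ("yes", "no"),
    "ph": ("yes", "no"),
    "vpi": ("yes", "no"),
    "vbh": ("yes", "no"),
    "high_meld": (">17", "<=17"),
}
LAB_VARS = ("albumin", "creatinine", "tbili", "inr", "meld", "bmi")

MELD_THRESHOLD_DEFAULT = 17

REQUIRED_COLUMNS = (
    "id", "sex", "height", "bmi", "albumin", "creatinine", "tbili", "inr",
    "ph", "vbh", "sff", "smi", "cefr_art", "cefr_pv", "cefr_del",
)
OPTIONAL_COLUMNS = (
    "age", "meld", "etiology", "api_grade", "varices_grade", "api", "vpi",
    "sbp", "tips", "diabetes", "thyroid",
)

#: built-in header aliases (normalised: lower-case, non-alphanumerics -> _)
DEFAULT_ALIASES = {
    "patient_id": "id", "patient": "id", "mrn": "id", "subject": "id",
    "gender": "sex", "sex_assigned_at_birth": "sex",
    "age_years": "age", "age_yrs": "age",
    "height_m": "height", "height_cm": "height", "height_meters": "height",
    "bmi_kg_m2": "bmi", "body_mass_index": "bmi",
    "albumin_g_dl": "albumin", "alb": "albumin",
    "creatinine_mg_dl": "creatinine", "cr": "creatinine",
    "total_bilirubin": "tbili", "bilirubin": "tbili", "tbil": "tbili",
    "total_bilirubin_mg_dl": "tbili", "tbili_mg_dl": "tbili",
    "international_normalized_ratio": "inr",
    "meld_score": "meld",
    "ascites": "api_grade", "ascites_grade": "api_grade",
    "ascites_volume": "api_grade",
    "varices": "varices_grade", "variceal_size": "varices_grade",
    "paracentesis": "ph", "paracentesis_history": "ph",
    "variceal_bleed": "vbh", "variceal_bleed_history": "vbh",
    "spontaneous_bacterial_peritonitis": "sbp", "sbp_history": "sbp",
    "thyroid_dysfunction": "thyroid", "diabetes_mellitus": "diabetes",
    "cirrhosis_etiology": "etiology",
    "psm_sff": "sff", "psm_smi": "smi",
    "psm_cefr_art": "cefr_art", "psm_cefr_pv": "cefr_pv",
    "psm_cefr_del": "cefr_del",
    "cefr_arterial": "cefr_art", "cefr_portal_venous": "cefr_pv",
    "cefr_delayed": "cefr_del",
}

_TRUTHY = {"1", "true", "yes", "y", "t"}
_FALSY = {"0", "false", "no", "n", "f", ""}
_NO_GRADES = {"no", "none", "absent", "0"}


@dataclass
class LoadedCohort:
    """Validated cohort table plus the load-time audit trail."""

    df: pd.DataFrame
    audit: list[str] = field(default_factory=list)
    n_rows: int = 0
    meld_discrepancies: int = 0


def _normalise_header(name: str) -> str:
    out = "".join(c if c.isalnum() else "_" for c in name.strip().lower())
    while "__" in out:
        out = out.replace("__", "_")
    return out.strip("_")


def _parse_bool(series: pd.Series, column: str, audit: list[str]) -> pd.Series:
    def one(v) -> float:
        if pd.isna(v):
            return np.nan
        s = str(v).strip().lower()
        if s in _TRUTHY:
            return 1.0
        if s in _FALSY:
            return 0.0
        try:
            return float(bool(float(s)))
        except ValueError:
            audit.append(f"{column}: unparseable boolean {v!r} -> missing")
            return np.nan

    return series.map(one)


def load_cohort(
    path: str | Path,
    alias_map: Optional[dict[str, str]] = None,
    meld_threshold: int = MELD_THRESHOLD_DEFAULT,
) -> LoadedCohort:
    """Read and validate a per-patient cohort CSV.

    Header names are normalised and resolved through the built-in alias
    table plus any user ``alias_map`` (raw header -> canonical name). Unit
    guard: a height column with median > 3 is assumed to be centimetres and
    converted with a warning. Derived columns: ``api`` / ``vpi`` from the
    ascites / varices grades (any grade including trace/small counts as
    present), ``high_meld`` from the threshold, and ``meld_from_labs``
    recomputed from creatinine/bilirubin/INR with a discrepancy count
    against any stored MELD column.
    """
    audit: list[str] = []
    raw = pd.read_csv(path)
    audit.append(f"read {len(raw)} rows x {raw.shape[1]} columns from {path}")

    user_aliases = {
        _normalise_header(k): v for k, v in (alias_map or {}).items()
    }
    rename: dict[str, str] = {}
    for col in raw.columns:
        norm = _normalise_header(col)
        target = user_aliases.get(norm) or DEFAULT_ALIASES.get(norm, norm)
        rename[col] = target
    df = raw.rename(columns=rename)

    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        candidates = sorted(set(df.columns) - set(REQUIRED_COLUMNS))
        raise ValueError(
            f"required columns missing after alias resolution: {missing}; "
            f"unmatched columns available for aliasing: {candidates}"
        )

    # unit guard: height in cm
    height = pd.to_numeric(df["height"], errors="coerce")
    if height.dropna().median() > 3.0:
        audit.append("height column median > 3: interpreted as cm, converted to m")
        height = height / 100.0
    df["height"] = height
    bad_height = (~height.between(0.5, 2.5)) & height.notna()
    if bad_height.any():
        audit.append(f"height outside (0.5, 2.5) m for {int(bad_height.sum())} row(s); retained")

    for col in ("age", "bmi", "albumin", "creatinine", "tbili", "inr",
                "sff", "smi", "cefr_art", "cefr_pv", "cefr_del", "meld"):
        if col in df.columns:
            df[col] = pd.to_numeric(df[col], errors="coerce")
    for col in ("albumin", "creatinine", "tbili", "inr"):
        nonpos = (df[col] <= 0) & df[col].notna()
        if nonpos.any():
            audit.append(f"{col}: {int(nonpos.sum())} non-positive value(s) set to missing")
            df.loc[nonpos, col] = np.nan

    for col in ("ph", "vbh", "sbp", "tips", "diabetes", "thyroid", "api", "vpi"):
        if col in df.columns:
            df[col] = _parse_bool(df[col], col, audit)

    df["sex"] = df["sex"].astype(str).str.strip().str.upper().str[0]
    bad_sex = ~df["sex"].isin(["M", "F"])
    if bad_sex.any():
        audit.append(f"sex: {int(bad_sex.sum())} unparseable value(s) set to missing")
        df.loc[bad_sex, "sex"] = np.nan

    # derived binaries from ordinal grades: any grade (incl. trace/small)
    # counts as present on imaging
    if "api_grade" in df.columns:
        grade = df["api_grade"].astype(str).str.strip().str.lower()
        df["api"] = (~grade.isin(_NO_GRADES) & df["api_grade"].notna()).astype(float)
    if "varices_grade" in df.columns:
        grade = df["varices_grade"].astype(str).str.strip().str.lower()
        df["vpi"] = (~grade.isin(_NO_GRADES) & df["varices_grade"].notna()).astype(float)
    for col in ("api", "vpi"):
        if col not in df.columns:
            raise ValueError(
                f"cannot derive {col!r}: provide either the grade column or the binary"
            )

    recomputed = []
    for cr, tb, inr_ in zip(df["creatinine"], df["tbili"], df["inr"]):
        if pd.isna(cr) or pd.isna(tb) or pd.isna(inr_):
            recomputed.append(np.nan)
        else:
            recomputed.append(compute_meld(float(cr), float(tb), float(inr_)))
    df["meld_from_labs"] = recomputed
    discrepancies = 0
    if "meld" in df.columns and df["meld"].notna().any():
        both = df["meld"].notna() & df["meld_from_labs"].notna()
        discrepancies = int((df.loc[both, "meld"] != df.loc[both, "meld_from_labs"]).sum())
        if discrepancies:
            audit.append(
                f"stored MELD differs from MELD recomputed from labs in "
                f"{discrepancies} row(s); stored values kept for analysis"
            )
    else:
        df["meld"] = df["meld_from_labs"]
        audit.append("no stored MELD column: using MELD recomputed from labs")

    df["high_meld"] = (df["meld"] > meld_threshold).astype(float)
    df.loc[df["meld"].isna(), "high_meld"] = np.nan

    return LoadedCohort(
        df=df, audit=audit, n_rows=len(df), meld_discrepancies=discrepancies
    )


# ---------------------------------------------------------------------------
# analysis
# ---------------------------------------------------------------------------

@dataclass
class AnalysisReport:
    """Descriptives, comparison grid, correlation grid, ROC and metadata."""

    table1: dict
    table2: list[dict]
    table3: list[dict]
    roc: dict
    metadata: dict

    def to_json(self) -> str:
        """Deterministic JSON: sorted keys, native float repr, no timestamps."""
        payload = asdict(self)
        return json.dumps(payload, sort_keys=True, indent=2, allow_nan=True)

    def table2_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.table2)

    def table3_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.table3)

    def write(self, out_dir: str | Path, stem: str = "analysis") -> dict[str, Path]:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        paths = {
            "json": out / f"{stem}.json",
            "table2": out / f"{stem}_table2.csv",
            "table3": out / f"{stem}_table3.csv",
        }
        paths["json"].write_text(self.to_json())
        self.table2_frame().to_csv(paths["table2"], index=False)
        self.table3_frame().to_csv(paths["table3"], index=False)
        return paths


def _group_masks(df: pd.DataFrame, grouping: str) -> tuple[pd.Series, pd.Series]:
    if grouping == "sex":
        return df["sex"] == "M", df["sex"] == "F"
    if grouping == "high_meld":
        return df["high_meld"] == 1, df["high_meld"] == 0
    return df[grouping] == 1, df[grouping] == 0


def _descriptives(df: pd.DataFrame) -> dict:
    cont = {}
    for var in ("age", "bmi", "meld", "albumin", "creatinine", "tbili", "inr",
                "sff", "smi", "cefr_art", "cefr_pv", "cefr_del"):
        if var in df.columns:
            s = pd.to_numeric(df[var], errors="coerce").dropna()
            if len(s):
                cont[var] = {
                    "mean": float(s.mean()), "sd": float(s.std(ddof=1)),
                    "min": float(s.min()), "max": float(s.max()), "n": int(len(s)),
                }
    counts: dict[str, int] = {"n": int(len(df))}
    counts["sex_m"] = int((df["sex"] == "M").sum())
    counts["sex_f"] = int((df["sex"] == "F").sum())
    for col in ("api", "ph", "vpi", "vbh", "sbp", "tips", "diabetes", "thyroid"):
        if col in df.columns:
            counts[col] = int((df[col] == 1).sum())
    categorical: dict[str, dict] = {}
    for col in ("api_grade", "varices_grade", "etiology"):
        if col in df.columns:
            categorical[col] = {
                str(k): int(v) for k, v in df[col].value_counts().items()
            }
    return {"continuous": cont, "counts": counts, "categorical": categorical}


def run_analysis(
    df: pd.DataFrame,
    meld_threshold: int = MELD_THRESHOLD_DEFAULT,
    config: Optional[dict] = None,
) -> AnalysisReport:
    """Recompute the full cohort analysis from a validated table.

    Every comparison cell records the test actually used (Welch t vs
    Mann-Whitney, chosen by per-group Shapiro-Wilk at 0.05) along with the
    p-value of the alternative test as a sensitivity check. No multiplicity
    correction is applied to the primary p-values; a Benjamini-Hochberg
    column (``p_bh``) is attached as clearly supplementary output.
    """
    df = df.copy()
    if "high_meld" not in df.columns:
        df["high_meld"] = (df["meld"] > meld_threshold).astype(float)
    for binary, grade_col in (("api", "api_grade"), ("vpi", "varices_grade")):
        if binary not in df.columns:
            if grade_col not in df.columns:
                raise ValueError(f"need column {binary!r} or {grade_col!r}")
            grade = df[grade_col].astype(str).str.strip().str.lower()
            df[binary] = (~grade.isin(_NO_GRADES) & df[grade_col].notna()).astype(float)

    table2: list[dict] = []
    for grouping, labels in GROUPINGS.items():
        mask_a, mask_b = _group_masks(df, grouping)
        for biomarker in BIOMARKERS:
            a = pd.to_numeric(df.loc[mask_a, biomarker], errors="coerce")
            b = pd.to_numeric(df.loc[mask_b, biomarker], errors="coerce")
            cell: dict = {"grouping": grouping, "biomarker": biomarker,
                          "group_a": labels[0], "group_b": labels[1]}
            try:
                res = pstats.compare_groups(
                    a, b, variable=biomarker, group_labels=labels
                )
                cell.update(
                    mean_a=res.mean_a, sd_a=res.sd_a, n_a=res.n_a,
                    mean_b=res.mean_b, sd_b=res.sd_b, n_b=res.n_b,
                    test_used=res.test_used, p=res.p, p_other=res.p_other,
                    decision_flips=res.decision_flips,
                    normality_p_a=res.normality_p[0],
                    normality_p_b=res.normality_p[1],
                )
            except ValueError as exc:
                cell.update(error=str(exc), p=None)
            table2.append(cell)

    table3: list[dict] = []
    pairs = [(lab, bm) for lab in LAB_VARS for bm in BIOMARKERS]
    pairs += [
        (BIOMARKERS[i], BIOMARKERS[j])
        for i in range(len(BIOMARKERS))
        for j in range(i + 1, len(BIOMARKERS))
    ]
    for var_a, var_b in pairs:
        x = pd.to_numeric(df[var_a], errors="coerce")
        y = pd.to_numeric(df[var_b], errors="coerce")
        cell = {"var_a": var_a, "var_b": var_b}
        try:
            res = pstats.pearson_ci(x, y, pair=(var_a, var_b))
            cell.update(r=res.r, ci_low=res.ci_low, ci_high=res.ci_high,
                        p=res.p, n=res.n)
        except ValueError as exc:
            cell.update(error=str(exc), p=None)
        table3.append(cell)

    # supplementary BH column over all primary p-values
    all_cells = [c for c in table2 + table3 if c.get("p") is not None]
    if all_cells:
        adjusted = false_discovery_control([c["p"] for c in all_cells], method="bh")
        for c, p_bh in zip(all_cells, adjusted):
            c["p_bh"] = float(p_bh)

    roc: dict = {"positive": f"meld>{meld_threshold}", "orientation": "low", "curves": {}}
    labels_ok = df["high_meld"].notna()
    y = df.loc[labels_ok, "high_meld"] == 1
    if y.nunique() == 2:
        for biomarker in ("cefr_art", "cefr_pv", "cefr_del"):
            scores = pd.to_numeric(df.loc[labels_ok, biomarker], errors="coerce")
            keep = scores.notna()
            res = pstats.roc_auc(scores[keep], y[keep], positive_direction="low")
            roc["curves"][biomarker] = {
                "auc": res["auc"],
                "fpr": res["fpr"].tolist(),
                "tpr": res["tpr"].tolist(),
                "n_pos": res["n_pos"],
                "n_neg": res["n_neg"],
            }
    else:
        roc["error"] = "high-MELD group empty or universal: ROC not computable"

    config = dict(config or {})
    config.setdefault("meld_threshold", meld_threshold)
    config_hash = hashlib.sha256(
        json.dumps(config, sort_keys=True).encode()
    ).hexdigest()[:16]
    from psmbio import __version__

    metadata = {
        "n": int(len(df)),
        "config": config,
        "config_hash": config_hash,
        "package_version": __version__,
    }
    return AnalysisReport(
        table1=_descriptives(df), table2=table2, table3=table3,
        roc=roc, metadata=metadata,
    )


# ---------------------------------------------------------------------------
# reproduction against the bundled reference values
# ---------------------------------------------------------------------------

def load_reference_tables() -> dict:
    """The bundled published reference values (descriptives, comparison and
    correlation tables) for the 224-patient cohort."""
    with resources.files("psmbio.data").joinpath("reference_tables.json").open() as fh:
        return json.load(fh)


def _parse_printed_p(p: str) -> tuple[float, bool]:
    """Printed p-value -> (numeric bound, is_upper_bound)."""
    p = p.strip()
    if p.startswith("<"):
        return float(p[1:]), True
    return float(p), False


def _printed_tolerance(text_value: float) -> float:
    """Half a unit in the last printed decimal place."""
    s = f"{text_value}"
    decimals = len(s.split(".")[1]) if "." in s else 0
    return 0.5 * 10.0 ** (-decimals)


def reproduce(df: pd.DataFrame, meld_threshold: int = MELD_THRESHOLD_DEFAULT) -> pd.DataFrame:
    """Recompute the analysis and diff it against the reference tables.

    Returns one row per checkable cell with the recomputed value, the
    reference value, the absolute difference and whether it agrees within
    the reference's printed rounding. Discrepancies are reported, never
    suppressed; with a synthetic cohort substantial differences in the
    comparison cells are expected (they are emergent, not parameters).
    """
    report = run_analysis(df, meld_threshold=meld_threshold)
    ref = load_reference_tables()
    rows: list[dict] = []

    for var, target in ref["table1"]["continuous"].items():
        computed = report.table1["continuous"].get(var)
        if computed is None:
            continue
        for stat in ("mean", "sd"):
            tol = _printed_tolerance(target[stat])
            diff = abs(computed[stat] - target[stat])
            rows.append({
                "table": "table1", "cell": f"{var}.{stat}",
                "computed": computed[stat], "reference": target[stat],
                "abs_diff": diff, "within_rounding": diff <= tol,
            })
    for key, target_count in ref["table1"]["counts"].items():
        computed_count = report.table1["counts"].get(key)
        if computed_count is None:
            continue
        rows.append({
            "table": "table1", "cell": f"count.{key}",
            "computed": computed_count, "reference": target_count,
            "abs_diff": abs(computed_count - target_count),
            "within_rounding": computed_count == target_count,
        })

    t2 = {(c["grouping"], c["biomarker"]): c for c in report.table2}
    for grouping, block in ref["table2"].items():
        for biomarker in BIOMARKERS:
            target = block[biomarker]
            cell = t2.get((grouping, biomarker))
            if cell is None or cell.get("p") is None:
                continue
            for stat in ("mean_a", "mean_b"):
                tol = _printed_tolerance(target[stat])
                diff = abs(cell[stat] - target[stat])
                rows.append({
                    "table": "table2", "cell": f"{grouping}.{biomarker}.{stat}",
                    "computed": cell[stat], "reference": target[stat],
                    "abs_diff": diff, "within_rounding": diff <= tol,
                })
            bound, is_upper = _parse_printed_p(target["p"])
            p_ok = cell["p"] < bound if is_upper else (
                abs(cell["p"] - bound) <= _printed_tolerance(bound)
            )
            rows.append({
                "table": "table2", "cell": f"{grouping}.{biomarker}.p",
                "computed": cell["p"], "reference": target["p"],
                "abs_diff": np.nan if is_upper else abs(cell["p"] - bound),
                "within_rounding": bool(p_ok),
            })

    t3 = {(c["var_a"], c["var_b"]): c for c in report.table3}
    ref_pairs = [
        (lab, bm, target)
        for lab, block in ref["table3"].items()
        for bm, target in block.items()
    ] + [
        tuple(key.split("~")) + (target,)
        for key, target in ref["biomarker_pairs"].items()
    ]
    for var_a, var_b, target in ref_pairs:
        cell = t3.get((var_a, var_b)) or t3.get((var_b, var_a))
        if cell is None or cell.get("p") is None:
            continue
        tol = _printed_tolerance(target["r"])
        diff = abs(cell["r"] - target["r"])
        rows.append({
            "table": "table3", "cell": f"{var_a}~{var_b}.r",
            "computed": cell["r"], "reference": target["r"],
            "abs_diff": diff, "within_rounding": diff <= tol,
        })
    return pd.DataFrame(rows)
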