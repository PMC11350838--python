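"""Subgroup (stratified) ensemble analyses.

Runs the spline ensemble within strata -- histology subtype, smoking
status, sex, age group, pack-year tertiles among current smokers, study
site -- with a COMMON reference exposure (the pooled-cohort lowest-risk
exposure, default 58 Bq/m^3) so stratum odds ratios are comparable.
Histology strata take the subtype's cases against ALL controls.  The
stratifying covariate is dropped from the adjustment set, as is any
covariate that is constant within a stratum; sites lacking cases or
controls within a stratum are excluded from it (logged on the result).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .ensemble import EnsembleResult, SplineConfig, run_ensemble
from .logistic import ADJUSTMENT_FIELDS, DesignSpec

__all__ = ["STRATUM_KINDS", "Stratum", "make_strata", "stratified_ensemble"]

log = logging.getLogger(__name__)

STRATUM_KINDS = (
    "histology",
    "smoking_status",
    "sex",
    "age_group",
    "pack_year_tertile",
    "study_site",
)

AGE_GROUP_LABELS = ("<=60", "60-68", "69-74", "75+")


@dataclass
class Stratum:
    label: str
    frame: pd.DataFrame
    drop_fields: tuple[str, ...] = ()
    info: dict | None = None


def _age_group(age: float) -> str:
    if age <= 60:
        return "<=60"
    if age <= 68:
        return "60-68"
    if age <= 74:
        return "69-74"
    return "75+"


def make_strata(cohort: pd.DataFrame, kind: str) -> list[Stratum]:
    """Partition (or, for histology, overlap) a cohort into analysis strata."""
    if kind not in STRATUM_KINDS:
        raise ValueError(f"unknown stratification kind {kind!r}")
    out: list[Stratum] = []
    cases = cohort[cohort["is_case"] == 1]
    controls = cohort[cohort["is_case"] == 0]

    if kind == "histology":
        for sub in ("AdenoLC", "SqCLC", "SCLC", "LCLC", "unknown"):
            sub_cases = cases[cases["histology"] == sub]
            if len(sub_cases) == 0:
                continue
            frame = pd.concat([sub_cases, controls], ignore_index=True)
            out.append(Stratum(sub, frame))
    elif kind == "smoking_status":
        for level in ("never", "former", "current"):
            frame = cohort[cohort["smoking_status"] == level]
            if len(frame):
                out.append(Stratum(level, frame.reset_index(drop=True), ("smoking_status",)))
    elif kind == "sex":
        for level in ("male", "female"):
            frame = cohort[cohort["sex"] == level]
            if len(frame):
                out.append(Stratum(level, frame.reset_index(drop=True), ("sex",)))
    elif kind == "age_group":
        groups = cohort["age"].apply(_age_group)
        for label in AGE_GROUP_LABELS:
            frame = cohort[groups == label]
            if len(frame):
                out.append(Stratum(label, frame.reset_index(drop=True)))
    elif kind == "pack_year_tertile":
        current = cohort[cohort["smoking_status"] == "current"]
        if len(current) == 0:
            raise ValueError("no current smokers: cannot form pack-year tertiles")
        cuts = np.quantile(current["pack_years"].to_numpy(float), [1 / 3, 2 / 3])
        py = current["pack_years"].to_numpy(float)
        tert = np.digitize(py, cuts)  # 0,1,2
        for i, label in enumerate(("T1", "T2", "T3")):
            frame = current[tert == i]
            if len(frame):
                out.append(
                    Stratum(
                        label,
                        frame.reset_index(drop=True),
                        ("smoking_status",),
                        info={"cut_points": [float(c) for c in cuts]},
                    )
                )
    else:  # study_site
        for site in sorted(cohort["site"].astype(str).unique()):
            frame = cohort[cohort["site"].astype(str) == site]
            out.append(Stratum(site, frame.reset_index(drop=True)))
    if not out:
        raise ValueError(f"stratification by {kind} produced no strata")
    return out


def _stratum_design(frame: pd.DataFrame, base: DesignSpec, drop: tuple[str, ...]) -> DesignSpec:
    """Adjustment set for a stratum: drop the stratifier and constants."""
    adjust = []
    for f in base.adjust:
        if f in drop:
            continue
        if frame[f].nunique() <= 1:
            log.info("dropping constant covariate %r within stratum", f)
            continue
        adjust.append(f)
    return DesignSpec(adjust=tuple(adjust))


def _usable_sites(frame: pd.DataFrame) -> tuple[pd.DataFrame, list[str]]:
    """Keep only sites with both cases and controls present."""
    dropped = []
    keep_mask = np.ones(len(frame), bool)
    for site, grp in frame.groupby(frame["site"].astype(str)):
        y = grp["is_case"].to_numpy(int)
        if y.min() == y.max():
            dropped.append(site)
            keep_mask &= (frame["site"].astype(str) != site).to_numpy()
    return frame[keep_mask].reset_index(drop=True), dropped


def stratified_ensemble(
    cohort: pd.DataFrame,
    kind: str,
    configs: list[SplineConfig] | None = None,
    design: DesignSpec = DesignSpec(),
    report_exposures=(25.0, 158.0),
    reference_exposure: float = 58.0,
    min_per_arm: int = 50,
) -> tuple[pd.DataFrame, dict[str, EnsembleResult]]:
    """One ensemble per stratum, all referenced to a common exposure.

    Returns a summary table (stratum, counts, OR and CI per reported
    exposure, per-stratum LRE) plus the per-stratum
    :class:`~radonrisk.ensemble.EnsembleResult` objects.  Strata with
    fewer than ``min_per_arm`` subjects in either arm are skipped and
    listed in the summary with null estimates.
    """
    results: dict[str, EnsembleResult] = {}
    rows = []
    for stratum in make_strata(cohort, kind):
        frame, dropped_sites = _usable_sites(stratum.frame)
        y = frame["is_case"].to_numpy(int) if len(frame) else np.array([0])
        n_cases, n_controls = int(y.sum()), int((1 - y).sum())
        row = {
            "stratum": stratum.label,
            "n_cases": n_cases,
            "n_controls": n_controls,
            "dropped_sites": ",".join(dropped_sites),
            "skipped": False,
        }
        if n_cases < min_per_arm or n_controls < min_per_arm:
            log.warning("stratum %s too small (%d/%d); skipped", stratum.label, n_cases, n_controls)
            row.update({"skipped": True, "lre": np.nan})
            rows.append(row)
            continue
        sdesign = _stratum_design(frame, design, stratum.drop_fields)
        res = run_ensemble(
            frame,
            configs=configs,
            design=sdesign,
            report_exposures=report_exposures,
            reference_exposure=reference_exposure,
        )
        results[stratum.label] = res
        row["lre"] = res.lre if res.lre is not None else np.nan
        for _, r in res.or_table.iterrows():
            e = f"{r['exposure']:g}"
            row[f"or_{e}"] = r["or"]
            row[f"or_{e}_lo"] = r["lo"]
            row[f"or_{e}_hi"] = r["hi"]
        rows.append(row)
    return pd.DataFrame(rows), results
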