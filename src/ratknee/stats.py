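"""Knee-level statistics and summary-table construction.

Normality is assessed with the Shapiro-Wilk test, group comparisons with
one-way ANOVA, and post-hoc pairwise comparisons with Tukey's HSD, matching
the study's analysis plan.  Because the factor structure of the original
analysis is not fully specified, comparisons are run as separate one-way
ANOVAs per outcome and compartment: across varus levels within a model type,
and across model types within a varus level.

Records are knee-level: one row per (knee, model type, varus level,
compartment) with peak pressure (MPa) and contact area (mm^2).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multicomp import pairwise_tukeyhsd

from .reference import ALL_MODEL_TYPES, FEA_MODEL_TYPES


class DegenerateDataError(ValueError):
    """Raised when a statistic is undefined for the given data."""


RECORD_COLUMNS = ["knee_id", "model_type", "varus_level", "compartment",
                  "peak_pressure", "contact_area"]


def validate_records(records: pd.DataFrame) -> pd.DataFrame:
    missing = set(RECORD_COLUMNS) - set(records.columns)
    if missing:
        raise ValueError(f"records missing columns {sorted(missing)}")
    for col in ("peak_pressure", "contact_area"):
        vals = records[col].to_numpy(dtype=float)
        bad = np.isfinite(vals) & (vals < 0)
        if bad.any():
            raise ValueError(f"{col} must be >= 0")
    dup = records.duplicated(subset=["knee_id", "model_type", "varus_level", "compartment"])
    if dup.any():
        raise ValueError("duplicate (knee, model_type, level, compartment) records")
    return records


# ----------------------------------------------------------------------
# tests
# ----------------------------------------------------------------------

def test_normality(values) -> tuple[float, float]:
    """Shapiro-Wilk (W, p).  Constant samples have undefined W and raise."""
    x = np.asarray(values, dtype=float)
    if len(x) < 3:
        raise DegenerateDataError("Shapiro-Wilk requires n >= 3")
    if len(x) > 5000:
        raise DegenerateDataError("Shapiro-Wilk p-values unreliable for n > 5000")
    if np.ptp(x) == 0:
        raise DegenerateDataError("Shapiro-Wilk W undefined for a constant sample")
    w, p = sps.shapiro(x)
    return float(w), float(p)


@dataclass
class AnovaResult:
    F: float
    df_between: int
    df_within: int
    p: float


def anova_oneway(groups) -> AnovaResult:
    """Classical one-way ANOVA over >= 2 groups, each with n >= 2."""
    gs = [np.asarray(g, dtype=float) for g in groups]
    if len(gs) < 2 or any(len(g) < 2 for g in gs):
        raise DegenerateDataError("ANOVA needs >= 2 groups with n >= 2 each")
    allv = np.concatenate(gs)
    if np.ptp(allv) == 0:
        raise DegenerateDataError("F undefined: zero between- and within-group variance")
    F, p = sps.f_oneway(*gs)
    return AnovaResult(F=float(F), df_between=len(gs) - 1,
                       df_within=len(allv) - len(gs), p=float(p))


def tukey_hsd(groups, labels=None, alpha: float = 0.05) -> pd.DataFrame:
    """Studentized-range adjusted pairwise comparisons.

    Returns one row per pair: (group_a, group_b, difference, p_adjusted).
    With two groups the adjusted p equals the pooled two-sample t-test p.
    """
    gs = [np.asarray(g, dtype=float) for g in groups]
    if len(gs) < 2 or any(len(g) < 2 for g in gs):
        raise DegenerateDataError("Tukey HSD needs >= 2 groups with n >= 2 each")
    if np.ptp(np.concatenate(gs)) == 0:
        raise DegenerateDataError("Tukey HSD undefined for all-constant data")
    if labels is None:
        labels = [f"g{i}" for i in range(len(gs))]
    endog = np.concatenate(gs)
    grp = np.concatenate([[str(lab)] * len(g) for lab, g in zip(labels, gs)])
    res = pairwise_tukeyhsd(endog, grp, alpha=alpha)
    frame = pd.DataFrame(res.summary().data[1:], columns=res.summary().data[0])
    return pd.DataFrame({
        "group_a": frame["group1"],
        "group_b": frame["group2"],
        "difference": frame["meandiff"].astype(float),
        "p_adjusted": np.asarray(res.pvalues, dtype=float),
    })


# ----------------------------------------------------------------------
# summary tables
# ----------------------------------------------------------------------

@dataclass
class SummaryTables:
    """Group-mean tables (2-decimal presentation) plus derived deltas and flags."""

    peak_pressure: pd.DataFrame     # index (model_type, varus_level), columns compartments
    contact_area: pd.DataFrame
    deltas: pd.DataFrame            # long: outcome, model_type, compartment, level, delta
    aggregates: dict[str, float]
    flags: list[str] = field(default_factory=list)


def _mean_table(records: pd.DataFrame, value: str) -> pd.DataFrame:
    sub = records.dropna(subset=[value])
    if sub.empty:
        return pd.DataFrame()
    table = sub.pivot_table(index=["model_type", "varus_level"], columns="compartment",
                            values=value, aggfunc="mean")
    return table.round(2)


def make_summary_tables(records: pd.DataFrame,
                        pressure_aggregate_models=FEA_MODEL_TYPES,
                        area_aggregate_models=ALL_MODEL_TYPES) -> SummaryTables:
    """Group means per (model type, level, compartment) and deltas vs neutral.

    Deltas are computed on the rounded means, matching the printed
    presentation.  The headline aggregates are the maxima of the medial
    increases and lateral decreases over the stated model-type subsets: the
    published maximum pressure changes are consistent with the FEA model
    types only, while the area aggregates span all three model types; both
    conventions are explicit parameters, and inconsistencies are flagged
    rather than resolved.
    """
    records = validate_records(records)
    missing = []
    levels = sorted(records["varus_level"].unique())
    for mt in records["model_type"].unique():
        for lv in levels:
            for side in ("medial", "lateral"):
                sel = (records["model_type"] == mt) & (records["varus_level"] == lv) \
                    & (records["compartment"] == side)
                if not sel.any():
                    missing.append((mt, lv, side))
    if missing:
        raise ValueError(f"incomplete factorial records; missing cells: {missing}")
    if 0 not in levels:
        raise ValueError("records must include the neutral (0 %) level")

    pressure = _mean_table(records, "peak_pressure")
    area = _mean_table(records, "contact_area")

    delta_rows = []
    for outcome, table in (("peak_pressure", pressure), ("contact_area", area)):
        if table.empty:
            continue
        for mt in table.index.get_level_values(0).unique():
            block = table.loc[mt]
            if 0 not in block.index:
                continue
            base = block.loc[0]
            for lv in block.index:
                if lv == 0:
                    continue
                for side in block.columns:
                    delta_rows.append({
                        "outcome": outcome, "model_type": mt, "compartment": side,
                        "varus_level": int(lv),
                        "delta": float(block.loc[lv, side] - base[side]),
                    })
    deltas = pd.DataFrame(delta_rows)

    def _max_delta(outcome: str, side: str, models, sign: float) -> float:
        if deltas.empty:
            return float("nan")
        sel = deltas[(deltas["outcome"] == outcome) & (deltas["compartment"] == side)
                     & (deltas["model_type"].isin(models))]
        if sel.empty:
            return float("nan")
        return float((sign * sel["delta"]).max())

    aggregates = {
        "max_medial_pressure_increase": _max_delta("peak_pressure", "medial",
                                                   pressure_aggregate_models, +1.0),
        "max_lateral_pressure_decrease": _max_delta("peak_pressure", "lateral",
                                                    pressure_aggregate_models, -1.0),
        "max_medial_area_increase": _max_delta("contact_area", "medial",
                                               area_aggregate_models, +1.0),
        "max_lateral_area_decrease": _max_delta("contact_area", "lateral",
                                                area_aggregate_models, -1.0),
    }

    flags = []
    all_medial_press = _max_delta("peak_pressure", "medial", list(records["model_type"].unique()), +1.0)
    if np.isfinite(all_medial_press) and np.isfinite(aggregates["max_medial_pressure_increase"]) \
            and all_medial_press > aggregates["max_medial_pressure_increase"] + 1e-9:
        flags.append(
            "medial pressure increase outside the FEA model types "
            f"({all_medial_press:.2f} MPa) exceeds the FEA-only aggregate "
            f"({aggregates['max_medial_pressure_increase']:.2f} MPa)"
        )
    return SummaryTables(peak_pressure=pressure, contact_area=area, deltas=deltas,
                         aggregates=aggregates, flags=flags)


def max_area_increase(increases: pd.DataFrame, models=ALL_MODEL_TYPES) -> float:
    """Maximum medial contact-area increase over model types, from printed increments."""
    sel = increases[increases["model_type"].isin(models)]
    return float(sel["delta_mm2"].max())


def compare_model_types(records: pd.DataFrame, outcome: str = "peak_pressure",
                        model_types=FEA_MODEL_TYPES) -> pd.DataFrame:
    """One-way ANOVA of an outcome between model types, per (level, compartment).

    Cells where every value is identical across both groups (e.g. a fully
    unloaded compartment) have an undefined F and are reported with p = NaN.
    """
    validate_records(records)
    rows = []
    for lv in sorted(records["varus_level"].unique()):
        for side in ("medial", "lateral"):
            groups = []
            for mt in model_types:
                sel = records[(records["model_type"] == mt) & (records["varus_level"] == lv)
                              & (records["compartment"] == side)]
                groups.append(sel.sort_values("knee_id")[outcome].to_numpy(dtype=float))
            try:
                res = anova_oneway(groups)
                rows.append({"varus_level": lv, "compartment": side, "F": res.F,
                             "df_between": res.df_between, "df_within": res.df_within,
                             "p": res.p})
            except DegenerateDataError:
                rows.append({"varus_level": lv, "compartment": side, "F": np.nan,
                             "df_between": len(groups) - 1,
                             "df_within": sum(len(g) for g in groups) - len(groups),
                             "p": np.nan})
    return pd.DataFrame(rows)


def compare_levels(records: pd.DataFrame, outcome: str = "peak_pressure") -> pd.DataFrame:
    """One-way ANOVA of an outcome across varus levels, per (model type, compartment)."""
    validate_records(records)
    rows = []
    for mt in records["model_type"].unique():
        for side in ("medial", "lateral"):
            groups = []
            for lv in sorted(records["varus_level"].unique()):
                sel = records[(records["model_type"] == mt) & (records["varus_level"] == lv)
                              & (records["compartment"] == side)]
                groups.append(sel.sort_values("knee_id")[outcome].to_numpy(dtype=float))
            try:
                res = anova_oneway(groups)
                rows.append({"model_type": mt, "compartment": side, "F": res.F, "p": res.p})
            except DegenerateDataError:
                rows.append({"model_type": mt, "compartment": side, "F": np.nan, "p": np.nan})
    return pd.DataFrame(rows)
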