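"""Expression and circular-to-linear quantification.

Per target and sample: reads per million uniquely assigned reads (RPM) for
chimeric and linear junction reads, and the circular-to-linear ratio
CLR = circ / (circ + lin). An undefined CLR (both counts zero) is reported as
missing, never imputed. Low-expression targets (fewer junction reads than a
threshold) are flagged and excluded from condition-comparison candidate lists
but retained in all tables.
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd
from scipy import stats as _stats


class QuantError(ValueError):
    pass


def rpm(raw: float, total_unique: float) -> float:
    """Reads per million uniquely assigned reads."""
    if total_unique <= 0:
        raise QuantError("total_unique must be > 0 for RPM")
    if raw < 0 or raw > total_unique:
        raise QuantError("require 0 <= raw <= total_unique")
    return raw / total_unique * 1e6

def clr(n_chimeric: float, n_linear: float) -> float | None:
    """Circular-to-linear ratio circ/(circ+lin); None when both counts are zero."""
    if n_chimeric < 0 or n_linear < 0:
        raise QuantError("counts must be >= 0")
    denom = n_chimeric + n_linear
    if denom == 0:
        return None
    return n_chimeric / denom


def flag_low_expression(n_chimeric: int, n_linear: int,
                        min_junction_reads: int = 10) -> bool:
    """True iff the target has fewer junction-spanning reads than the threshold."""
    return (n_chimeric + n_linear) < min_junction_reads


def quantify(
    counts: pd.DataFrame,
    total_unique: int | None = None,
    include_non_junction: bool = False,
    min_junction_reads: int = 10,
) -> pd.DataFrame:
    """Per-target quantification from a classifier counts table.

    The RPM denominator defaults to the sample's uniquely assigned read total
    (chimeric + linear + non_junction over all targets is an over-count when
    evidence is shared within primer groups, so the caller should pass the
    classifier's label totals when available; the denominator used is recorded
    in the output). include_non_junction adds non-junction reads to the linear
    evidence for the CLR denominator (an alternative 'all aligned reads'
    definition of linear support).
    """
    required = {"target_id", "sample_id", "n_chimeric", "n_linear", "n_non_junction"}
    missing = required - set(counts.columns)
    if missing:
        raise QuantError(f"counts table missing columns: {sorted(missing)}")
    rows = []
    for sample_id, sub in counts.groupby("sample_id", sort=True):
        denom = total_unique
        if denom is None:
            denom = int(
                sub["n_chimeric"].sum() + sub["n_linear"].sum()
                + sub["n_non_junction"].sum()
            )
        for _, rec in sub.iterrows():
            n_lin = int(rec.n_linear) + (
                int(rec.n_non_junction) if include_non_junction else 0
            )
            n_chi = int(rec.n_chimeric)
            ratio = clr(n_chi, n_lin)
            rows.append(
                {
                    "target_id": rec.target_id,
                    "sample_id": sample_id,
                    "n_chimeric": n_chi,
                    "n_linear": n_lin,
                    "n_non_junction": int(rec.n_non_junction),
                    "rpm_chimeric": rpm(n_chi, denom) if denom > 0 else math.nan,
                    "rpm_linear": rpm(n_lin, denom) if denom > 0 else math.nan,
                    "clr": math.nan if ratio is None else ratio,
                    "clr_defined": ratio is not None,
                    "low_expression": flag_low_expression(
                        n_chi, n_lin, min_junction_reads
                    ),
                    "rpm_denominator": denom,
                }
            )
    return pd.DataFrame(rows)


def pearson_correlation(x, y, exclude: list | None = None, labels=None):
    """Pearson product-moment correlation (r, two-sided p).

    With labels given (e.g. target ids), entries whose label is in exclude are
    dropped first — used to re-test replicate agreement after removing a
    dominant outlier target."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise QuantError("x and y must have equal length")
    if exclude:
        if labels is None:
            raise QuantError("exclude requires labels")
        keep = ~np.isin(np.asarray(labels), list(exclude))
        x, y = x[keep], y[keep]
    mask = np.isfinite(x) & np.isfinite(y)
    x, y = x[mask], y[mask]
    if x.size < 3:
        raise QuantError("need at least 3 finite paired values")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise QuantError("zero variance: correlation undefined")
    r, p = _stats.pearsonr(x, y)
    return float(r), float(p)


def compare_conditions(
    quant: pd.DataFrame,
    condition_of: dict,
    reference_condition: str | None = None,
) -> pd.DataFrame:
    """Per-target CLR comparison across conditions.

    condition_of maps sample_id -> condition label. Output: mean CLR per
    condition, delta versus the reference condition (default: first condition
    in sorted order), mean chimeric/linear RPM per condition (to inspect
    reciprocal isoform changes), and an excluded flag set when the target is
    low-expression in any sample."""
    df = quant.copy()
    unknown = set(df["sample_id"]) - set(condition_of)
    if unknown:
        raise QuantError(f"samples without condition label: {sorted(unknown)}")
    df["condition"] = df["sample_id"].map(condition_of)
    conditions = sorted(df["condition"].unique())
    ref = reference_condition or conditions[0]
    if ref not in conditions:
        raise QuantError(f"reference condition {ref!r} not present")
    rows = []
    for tid, sub in df.groupby("target_id", sort=True):
        row: dict = {"target_id": tid}
        for cond_name in conditions:
            cc = sub[sub["condition"] == cond_name]
            row[f"clr_{cond_name}"] = float(cc["clr"].mean())
            row[f"rpm_chimeric_{cond_name}"] = float(cc["rpm_chimeric"].mean())
            row[f"rpm_linear_{cond_name}"] = float(cc["rpm_linear"].mean())
        for cond_name in conditions:
            if cond_name != ref:
                row[f"clr_delta_{cond_name}_vs_{ref}"] = (
                    row[f"clr_{cond_name}"] - row[f"clr_{ref}"]
                )
        row["excluded_low_expression"] = bool(sub["low_expression"].any())
        rows.append(row)
    return pd.DataFrame(rows)


def delta_delta_ct(
    ct_target_treated: float,
    ct_ref_treated: float,
    ct_target_ctrl: float,
    ct_ref_ctrl: float,
) -> float:
    """Relative qPCR fold change 2^(-ddCt) versus the control condition."""
    for v in (ct_target_treated, ct_ref_treated, ct_target_ctrl, ct_ref_ctrl):
        if not math.isfinite(v):
            raise QuantError("Ct values must be finite")
    ddct = (ct_target_treated - ct_ref_treated) - (ct_target_ctrl - ct_ref_ctrl)
    return 2.0 ** (-ddct)


def qpcr_fold_changes(ct_table: pd.DataFrame, reference_condition: str) -> pd.DataFrame:
    """Fold changes from a Ct table with columns sample, condition, target,
    ct_target, ct_reference; normalized to the reference gene and to the mean
    delta-Ct of the reference-condition samples per target."""
    required = {"sample", "condition", "target", "ct_target", "ct_reference"}
    missing = required - set(ct_table.columns)
    if missing:
        raise QuantError(f"Ct table missing columns: {sorted(missing)}")
    df = ct_table.copy()
    df["dct"] = df["ct_target"] - df["ct_reference"]
    rows = []
    for target, sub in df.groupby("target", sort=True):
        ctrl = sub[sub["condition"] == reference_condition]
        if ctrl.empty:
            raise QuantError(f"{target}: no sample in condition {reference_condition!r}")
        base = float(ctrl["dct"].mean())
        for _, rec in sub.iterrows():
            rows.append(
                {
                    "target": target,
                    "sample": rec["sample"],
                    "condition": rec["condition"],
                    "fold_change": 2.0 ** (-(rec["dct"] - base)),
                }
            )
    return pd.DataFrame(rows)
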