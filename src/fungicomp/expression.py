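"""qPCR ΔΔCt fold changes and differential protein-spot calling.

Relative qPCR quantification uses the comparative-Ct method against an
internal control gene (18S rRNA in the original assay design)::

    ΔCt  = Ct(target) − Ct(control gene)        per condition
    ΔΔCt = ΔCt(treatment) − ΔCt(control)
    fold = 2^(−ΔΔCt)

Replicate Ct values are averaged before ΔCt (the formula on Ct means);
per-replicate pairing is available via ``per_replicate=True``.

Two-dimensional-gel spot quantification compares mean spot intensities
between conditions: a spot is up-regulated when fold ≥ 1.5 and P < 0.05,
down-regulated when fold ≤ 1/1.5 and P < 0.05.  The P-value comes from a
two-sided Welch t-test on log-transformed intensities; no multiple-testing
correction is applied by default (a Benjamini–Hochberg option exists).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "FoldChangeResult",
    "SpotCall",
    "ddct_fold_change",
    "differential_spots",
    "read_measurement_table",
]

TREATMENT = "treatment"
CONTROL = "control"


@dataclass(frozen=True)
class FoldChangeResult:
    gene_id: str
    delta_delta_ct: float
    fold_change: float


@dataclass(frozen=True)
class SpotCall:
    spot_id: str
    fold_change: float
    p_value: float
    label: str  # up / down / unchanged


def read_measurement_table(path: str, value_column: str) -> pd.DataFrame:
    """Read a headered TSV/CSV with columns id, condition, replicate, value."""
    sep = "," if str(path).endswith(".csv") else "\t"
    df = pd.read_csv(path, sep=sep)
    required = {"id", "condition", "replicate", value_column}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    return df


def _mean_ct(ct: pd.DataFrame, gene: str, condition: str) -> float:
    cell = ct[(ct["id"] == gene) & (ct["condition"] == condition)]["ct"]
    if cell.empty:
        raise ValueError(f"no Ct measurements for gene {gene!r}, condition {condition!r}")
    return float(cell.mean())


def ddct_fold_change(
    ct: pd.DataFrame,
    target_gene: str,
    control_gene: str,
    treatment_label: str = TREATMENT,
    control_label: str = CONTROL,
    per_replicate: bool = False,
) -> FoldChangeResult:
    """Fold change of ``target_gene`` by the 2^(−ΔΔCt) method.

    ``ct`` needs columns ``id``, ``condition``, ``replicate``, ``ct`` with
    both genes measured in both conditions.  With ``per_replicate=True``,
    ΔCt is formed within each replicate (paired by replicate index) and
    ΔΔCt is the difference of replicate-mean ΔCts — identical to the default
    when replicates are balanced.
    """
    if (ct["ct"] <= 0).any():
        raise ValueError("Ct values must be positive cycle numbers")
    if per_replicate:
        dcts = {}
        for condition in (treatment_label, control_label):
            sub = ct[ct["condition"] == condition]
            tgt = sub[sub["id"] == target_gene].set_index("replicate")["ct"]
            ref = sub[sub["id"] == control_gene].set_index("replicate")["ct"]
            common = tgt.index.intersection(ref.index)
            if common.empty:
                raise ValueError(
                    f"no paired replicates for gene {target_gene!r}, "
                    f"condition {condition!r}"
                )
            dcts[condition] = float((tgt[common] - ref[common]).mean())
        ddct = dcts[treatment_label] - dcts[control_label]
    else:
        dct_treat = _mean_ct(ct, target_gene, treatment_label) - _mean_ct(
            ct, control_gene, treatment_label
        )
        dct_ctrl = _mean_ct(ct, target_gene, control_label) - _mean_ct(
            ct, control_gene, control_label
        )
        ddct = dct_treat - dct_ctrl
    return FoldChangeResult(
        gene_id=target_gene, delta_delta_ct=ddct, fold_change=2.0 ** (-ddct)
    )


def differential_spots(
    spots: pd.DataFrame,
    fold_threshold: float = 1.5,
    alpha: float = 0.05,
    treatment_label: str = TREATMENT,
    control_label: str = CONTROL,
    fdr_correct: bool = False,
) -> pd.DataFrame:
    """Call up/down/unchanged spots between two conditions.

    ``spots`` needs columns ``id``, ``condition``, ``replicate``,
    ``intensity`` (non-negative) with ≥ 2 replicates per condition per spot.
    Fold = mean(treatment)/mean(control); the P-value is a two-sided Welch
    t-test on log intensities.  ``fdr_correct=True`` replaces raw P-values
    with Benjamini–Hochberg adjusted ones before thresholding.
    """
    if (spots["intensity"] < 0).any():
        raise ValueError("negative spot intensity")
    rows = []
    for spot_id, group in spots.groupby("id", sort=True):
        t = group[group["condition"] == treatment_label]["intensity"].to_numpy(float)
        c = group[group["condition"] == control_label]["intensity"].to_numpy(float)
        if len(t) < 2 or len(c) < 2:
            raise ValueError(f"spot {spot_id!r}: need >=2 replicates per condition")
        if c.mean() == 0:
            raise ValueError(f"spot {spot_id!r}: zero control mean intensity")
        fold = t.mean() / c.mean()
        with np.errstate(divide="ignore"):
            log_t, log_c = np.log(np.maximum(t, 1e-300)), np.log(np.maximum(c, 1e-300))
        if np.allclose(log_t, log_t[0]) and np.allclose(log_c, log_c[0]):
            p = 0.0 if not math.isclose(log_t[0], log_c[0]) else 1.0
        else:
            p = float(stats.ttest_ind(log_t, log_c, equal_var=False).pvalue)
        rows.append({"id": spot_id, "fold_change": fold, "p_value": p})
    result = pd.DataFrame(rows)
    if fdr_correct and len(result):
        result["p_value"] = stats.false_discovery_control(result["p_value"], method="bh")
    labels = []
    for _, row in result.iterrows():
        if row["p_value"] < alpha and row["fold_change"] >= fold_threshold:
            labels.append("up")
        elif row["p_value"] < alpha and row["fold_change"] <= 1.0 / fold_threshold:
            labels.append("down")
        else:
            labels.append("unchanged")
    result["label"] = labels
    return result
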