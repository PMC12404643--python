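"""Cardiac-function and expression measurement formulas.

These are the downstream read-outs applied to numbers extracted from
imaging and qPCR: heart rate from the duration of five cardiac cycles,
ventricular fractional area change (FAC) from end-diastolic and
end-systolic cross-sectional areas, and relative transcript abundance
by the 2^(-ddCt) method normalized to a reference gene and to the mean
of control samples.  Image segmentation itself is out of scope; the
module starts from measured areas and Ct values.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)


def heart_rate_bpm(cycle_time_5beats: float) -> float:
    """Beats per minute from the time (s) spanning five cardiac cycles."""
    if cycle_time_5beats <= 0:
        raise ValueError("cycle time must be positive")
    return (5.0 / cycle_time_5beats) * 60.0


def fractional_area_change(area_d: float, area_s: float) -> float:
    """Ventricular FAC in percent: ((diastole - systole) / diastole) * 100.

    A systolic area exceeding the diastolic area yields a negative FAC;
    this is flagged (it usually indicates swapped frames) but returned.
    """
    if area_d <= 0:
        raise ValueError("diastolic area must be positive")
    fac = (area_d - area_s) / area_d * 100.0
    if fac < 0:
        logger.warning("systolic area exceeds diastolic area (FAC=%.2f%%)", fac)
    return fac


def average_replicates(measurements: pd.DataFrame) -> pd.DataFrame:
    """Per-animal means over replicate cardiac-cycle measurements.

    Expects columns animal_id, area_diastole, area_systole and
    optionally cycle_time_5beats.  FAC is computed per replicate and
    then averaged; the FAC of the averaged areas is emitted alongside
    (``fac_of_mean_areas``) since the two differ when contraction varies
    across cycles.
    """
    df = measurements.copy()
    if df.empty:
        raise ValueError("no measurements")
    df["fac"] = [fractional_area_change(d, s)
                 for d, s in zip(df["area_diastole"], df["area_systole"])]
    if "cycle_time_5beats" in df.columns:
        df["heart_rate_bpm"] = [heart_rate_bpm(t) for t in df["cycle_time_5beats"]]
    agg = {"area_diastole": "mean", "area_systole": "mean", "fac": "mean"}
    if "heart_rate_bpm" in df.columns:
        agg["heart_rate_bpm"] = "mean"
    out = df.groupby("animal_id", sort=True).agg(agg).reset_index()
    out["fac_of_mean_areas"] = [
        fractional_area_change(d, s)
        for d, s in zip(out["area_diastole"], out["area_systole"])
    ]
    return out


def ddct_fold_change(table: pd.DataFrame, reference_gene: str,
                     control_group: str = "control") -> pd.DataFrame:
    """Per-sample dCt, ddCt and 2^(-ddCt) fold change.

    ``table`` has columns sample_id, group, gene, ct with exactly one
    reference-gene row per sample.  For each target gene:
    dCt = Ct_target - Ct_reference; ddCt = dCt - mean(dCt over control
    samples of that gene); fold = 2^(-ddCt).  The raw ddCt column is
    always emitted so alternative transforms stay available downstream.
    """
    required = {"sample_id", "group", "gene", "ct"}
    if not required.issubset(table.columns):
        raise ValueError(f"Ct table needs columns {sorted(required)}")
    if not np.isfinite(table["ct"]).all():
        raise ValueError("non-finite Ct value")
    ref = table[table["gene"] == reference_gene]
    ref_ct: dict[str, float] = {}
    for sample, grp in ref.groupby("sample_id"):
        if len(grp) != 1:
            raise ValueError(f"sample {sample!r} has {len(grp)} reference-gene "
                             f"Ct rows; expected exactly 1")
        ref_ct[sample] = float(grp["ct"].iloc[0])
    targets = table[table["gene"] != reference_gene]
    missing = sorted(set(targets["sample_id"]) - set(ref_ct))
    if missing:
        raise ValueError(f"missing reference-gene Ct for sample(s): "
                         f"{', '.join(missing)}")

    rows = []
    for gene, grp in targets.groupby("gene"):
        dct = grp["ct"].to_numpy(dtype=float) - np.array(
            [ref_ct[s] for s in grp["sample_id"]])
        is_control = (grp["group"] == control_group).to_numpy()
        if not is_control.any():
            raise ValueError(f"no {control_group!r} samples for gene {gene!r}")
        control_mean = float(dct[is_control].mean())
        ddct = dct - control_mean
        for (sample, group), d, dd in zip(
                zip(grp["sample_id"], grp["group"]), dct, ddct):
            rows.append({"sample_id": sample, "group": group, "gene": gene,
                         "dct": float(d), "ddct": float(dd),
                         "fold_change": float(2.0 ** (-dd))})
    return pd.DataFrame(rows)
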