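"""Compliance statistics and inter-model agreement.

Exceedance against the PC-TWA is strict (a value exactly at the limit is
compliant, and a left-censored value never exceeds).  Agreement between two
models' integer risk-level assignments uses unweighted Cohen's kappa with
the large-sample normal significance test under the null of chance
agreement (the "Approx. Sig." conventionally reported by SPSS).
"""
from __future__ import annotations

import math
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from scipy.stats import norm
from pydantic import BaseModel, ConfigDict, Field

__all__ = [
    "KappaResult",
    "exceedance_fraction",
    "stel_compliance",
    "level_distribution",
    "cohen_kappa",
    "interpret_kappa",
]


class KappaResult(BaseModel):
    model_config = ConfigDict(extra="forbid", ser_json_inf_nan="constants")

    kappa: float = Field(ge=-1, le=1)
    p_observed: float = Field(ge=0, le=1)
    p_expected: float = Field(ge=0, le=1)
    z: float
    p_value: float = Field(ge=0, le=1)
    interpretation: Literal["lack", "average", "good"]


def exceedance_fraction(
    values: Sequence[tuple[float, bool]], limit: float
) -> tuple[int, float]:
    """Count and fraction of measurements strictly above the limit.

    ``values`` are (concentration, censored) pairs; censored measurements
    never exceed.
    """
    if not values:
        raise ValueError("exceedance_fraction requires a non-empty sequence")
    count = sum(1 for v, cens in values if not cens and v > limit)
    return count, count / len(values)


def stel_compliance(c_stel: float, pc_twa: float) -> bool:
    """Short-term compliance: C-STEL must stay below twice the PC-TWA."""
    return c_stel < 2.0 * pc_twa


def level_distribution(results: pd.DataFrame, include_total: bool = True) -> pd.DataFrame:
    """Percent of SEGs per (group, model, risk level).

    ``results`` needs columns ``group``, ``model``, ``risk_level``.  Returns
    a long table with ``count``, ``n`` (group size) and ``percent``
    (100*count/n); with ``include_total`` an all-groups block labelled
    ``total`` is appended.  Percentages sum to 100 per (group, model).
    """
    if results.empty:
        raise ValueError("level_distribution requires a non-empty results table")
    frames = [results[["group", "model", "risk_level"]]]
    if include_total:
        total = results[["model", "risk_level"]].copy()
        total.insert(0, "group", "total")
        frames.append(total)
    stacked = pd.concat(frames, ignore_index=True)
    counts = (
        stacked.groupby(["group", "model", "risk_level"], sort=True)
        .size()
        .rename("count")
        .reset_index()
    )
    sizes = stacked.groupby(["group", "model"]).size().rename("n").reset_index()
    out = counts.merge(sizes, on=["group", "model"])
    out["percent"] = 100.0 * out["count"] / out["n"]
    return out


def interpret_kappa(kappa: float) -> str:
    """Consistency bands: <0.40 lack; [0.40, 0.75) average; >=0.75 good."""
    if kappa < 0.40:
        return "lack"
    if kappa < 0.75:
        return "average"
    return "good"


def cohen_kappa(labels_a: Sequence, labels_b: Sequence) -> KappaResult:
    """Unweighted Cohen's kappa between two raters with a null-hypothesis z test.

    kappa = (p_o - p_e) / (1 - p_e), with p_o the observed and p_e the
    chance agreement from the confusion-matrix margins.  The two-sided
    p-value uses the large-sample variance of kappa under independence,

        var0 = [p_e + p_e^2 - sum_i p_i. p_.i (p_i. + p_.i)] / [n (1-p_e)^2].

    Two identical constant vectors give p_e = 1; kappa is then defined as 1
    with p_value 1 (no evidence against chance is obtainable from a single
    category).
    """
    a = list(labels_a)
    b = list(labels_b)
    if len(a) != len(b):
        raise ValueError(f"label vectors differ in length: {len(a)} vs {len(b)}")
    n = len(a)
    if n < 2:
        raise ValueError("need at least two paired labels")
    cats = sorted(set(a) | set(b))
    idx = {c: i for i, c in enumerate(cats)}
    k = len(cats)
    cm = np.zeros((k, k))
    for x, y in zip(a, b):
        cm[idx[x], idx[y]] += 1
    cm /= n
    p_row = cm.sum(axis=1)
    p_col = cm.sum(axis=0)
    p_o = float(np.trace(cm))
    p_e = float(p_row @ p_col)
    if p_e >= 1.0 - 1e-15:
        return KappaResult(
            kappa=1.0, p_observed=p_o, p_expected=1.0, z=math.nan, p_value=1.0,
            interpretation="good",
        )
    kappa = (p_o - p_e) / (1.0 - p_e)
    var0 = (p_e + p_e**2 - float(np.sum(p_row * p_col * (p_row + p_col)))) / (
        n * (1.0 - p_e) ** 2
    )
    if var0 <= 0:
        z, p_value = math.nan, 1.0
    else:
        z = kappa / math.sqrt(var0)
        p_value = 2.0 * float(norm.sf(abs(z)))
    return KappaResult(
        kappa=float(np.clip(kappa, -1.0, 1.0)),
        p_observed=p_o,
        p_expected=p_e,
        z=z,
        p_value=min(p_value, 1.0),
        interpretation=interpret_kappa(kappa),
    )
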