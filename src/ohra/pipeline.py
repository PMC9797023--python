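"""End-to-end orchestration: run the whole model battery on a SEG table.

Produces one tidy results row per (SEG, model), the aggregate summaries
(group compliance statistics, per-model risk-level distributions, EPA
acceptability ratios), pairwise model-agreement kappas, and the seeded
replication pipeline (simulate -> assess -> compare).
"""
from __future__ import annotations

import json
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from . import __version__
from .coshh import assess_coshh
from .epa import assess_epa
from .profiles import (
    ChemicalProfile,
    RubricConfig,
    SEGRecord,
    benzene_profile,
    default_rubric,
    summarize_group,
    write_seg_table,
)
from .semiquant import SEMIQUANT_METHODS, run_model
from .simulate import default_sim_configs, generate_seg_dataset
from .stats import cohen_kappa, level_distribution

__all__ = [
    "ALL_MODELS",
    "MODEL_ALIASES",
    "resolve_models",
    "assess",
    "summarize",
    "kappa_matrix",
    "replicate",
    "RESULT_COLUMNS",
]

ALL_MODELS: tuple[str, ...] = ("coshh", "epa") + SEMIQUANT_METHODS
MODEL_ALIASES = {"sg-ei": "singapore_ei", "cn-ei": "chinese_ei", "all": None}

RESULT_COLUMNS = [
    "seg_id", "group", "model", "hr", "er", "risk_score", "risk_level",
    "label", "hq", "ir", "hq_acceptable", "ir_acceptable",
]


def resolve_models(names: Sequence[str]) -> list[str]:
    """Expand aliases; 'all' selects the full battery."""
    out: list[str] = []
    for name in names:
        if name == "all":
            return list(ALL_MODELS)
        resolved = MODEL_ALIASES.get(name, name)
        if resolved not in ALL_MODELS:
            raise ValueError(
                f"unknown model {name!r}; expected one of "
                f"{sorted(set(ALL_MODELS) | (set(MODEL_ALIASES) - {'all'}))} or 'all'"
            )
        out.append(resolved)
    return out


def assess(
    records: Sequence[SEGRecord],
    profile: ChemicalProfile,
    rubric: RubricConfig,
    models: Sequence[str] = ("all",),
    ec_mode: Optional[str] = None,
) -> pd.DataFrame:
    """Run the requested models on every SEG; one tidy row per (SEG, model)."""
    rows = []
    for model in resolve_models(models):
        for rec in records:
            row: dict = {c: np.nan for c in RESULT_COLUMNS}
            row.update(seg_id=rec.seg_id, group=rec.group, model=model)
            if model == "coshh":
                a = assess_coshh(rec, profile, rubric)
                row.update(
                    hr=a.hazard_band, er=a.exposure_band,
                    risk_level=a.risk_level, label=a.label,
                )
            elif model == "epa":
                e = assess_epa(rec, profile, rubric, ec_mode=ec_mode)
                row.update(
                    hq=e.hq, ir=e.ir,
                    hq_acceptable=e.hq_acceptable, ir_acceptable=e.ir_acceptable,
                    label="acceptable risk" if e.hq_acceptable else "unacceptable risk",
                )
            else:
                r = run_model(rec, profile, rubric, model)
                row.update(
                    hr=r.hr.hr, er=r.er.er, risk_score=r.risk_score,
                    risk_level=r.risk_level, label=r.label,
                )
            rows.append(row)
    return pd.DataFrame(rows, columns=RESULT_COLUMNS)


def summarize(
    records: Sequence[SEGRecord],
    results: pd.DataFrame,
    profile: ChemicalProfile,
) -> dict:
    """Aggregate statistics: compliance per group, level distributions, EPA ratios."""
    by_group: dict[str, dict] = {}
    for group in sorted({r.group for r in records}):
        members = [r for r in records if r.group == group]
        s = summarize_group(members, profile.pc_twa)
        by_group[group] = {
            "n": s.n,
            "mean_c_twa": s.mean,
            "n_censored": s.n_censored,
            "exceed_count": s.exceed_count,
            "exceed_percent": 100.0 * s.exceed_fraction,
        }

    summary: dict = {"groups": by_group}
    semi = results[results["model"].isin(SEMIQUANT_METHODS)]
    if not semi.empty:
        dist = level_distribution(semi)
        summary["level_distribution"] = dist.to_dict(orient="records")
    epa = results[results["model"] == "epa"]
    if not epa.empty:
        summary["epa"] = {
            group: {
                "hq_unacceptable_percent": 100.0 * float((~g["hq_acceptable"].astype(bool)).mean()),
                "ir_unacceptable_percent": 100.0 * float((~g["ir_acceptable"].astype(bool)).mean()),
            }
            for group, g in epa.groupby("group")
        }
    coshh = results[results["model"] == "coshh"]
    if not coshh.empty:
        summary["coshh_levels"] = sorted(coshh["risk_level"].astype(int).unique().tolist())
    return summary


def kappa_matrix(
    results: pd.DataFrame, models: Sequence[str] = SEMIQUANT_METHODS
) -> pd.DataFrame:
    """Pairwise Cohen's kappa between models' risk-level assignments."""
    levels = {
        m: results[results["model"] == m].set_index("seg_id")["risk_level"]
        for m in models
    }
    rows = []
    for i, a in enumerate(models):
        for b in models[i + 1:]:
            joined = pd.concat([levels[a], levels[b]], axis=1, join="inner")
            k = cohen_kappa(joined.iloc[:, 0].tolist(), joined.iloc[:, 1].tolist())
            rows.append({
                "model_a": a, "model_b": b, "kappa": k.kappa,
                "p_value": k.p_value, "interpretation": k.interpretation,
            })
    return pd.DataFrame(rows)


def _manifest(seed: int, models: Sequence[str], inputs: dict) -> dict:
    return {
        "tool": "ohra", "version": __version__, "seed": seed,
        "models": list(models), "inputs": inputs,
    }


def replicate(
    seed: int,
    out_dir: Optional[str | Path] = None,
    rubric: Optional[RubricConfig] = None,
    profile: Optional[ChemicalProfile] = None,
) -> dict:
    """Simulate the default survey, run every model, and compare models.

    Returns a report dict with the simulated dataset's aggregates, the
    pairwise kappas, and explicit deterministic checks (the banding outcomes
    a benzene survey determines regardless of the random draws).  When
    ``out_dir`` is given, writes segs.csv, results.csv, kappa.csv and
    report.json there; same seed, same bytes.
    """
    rubric = rubric or default_rubric()
    profile = profile or benzene_profile()
    configs = default_sim_configs(seed=seed)
    records = generate_seg_dataset(configs, seed=seed)
    results = assess(records, profile, rubric, models=("all",))
    summary = summarize(records, results, profile)
    kappas = kappa_matrix(results)

    coshh_levels = results.loc[results["model"] == "coshh", "risk_level"].astype(int)
    censored_ratio = results.merge(
        pd.DataFrame({
            "seg_id": [r.seg_id for r in records],
            "censored": [r.c_twa_censored for r in records],
        }),
        on="seg_id",
    )
    fully = censored_ratio[(censored_ratio["model"] == "ratio") & censored_ratio["censored"]]
    checks = {
        "coshh_all_level_4": bool((coshh_levels == 4).all()),
        "censored_ratio_all_level_2": bool((fully["risk_level"].astype(int) == 2).all()),
    }
    best = kappas.loc[kappas["kappa"].idxmax()] if not kappas.empty else None
    report = {
        "manifest": _manifest(seed, ALL_MODELS, {"dataset": "simulated-default"}),
        "n_segs": len(records),
        "summary": summary,
        "kappa": kappas.to_dict(orient="records"),
        "highest_agreement_pair": (
            None if best is None else
            {"models": [best["model_a"], best["model_b"]], "kappa": float(best["kappa"])}
        ),
        "deterministic_checks": checks,
    }
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        header = json.dumps(_manifest(seed, ALL_MODELS, {"dataset": "simulated-default"}))
        write_seg_table(records, out / "segs.csv", rubric, header_comment=header)
        with open(out / "results.csv", "w", newline="") as fh:
            fh.write(f"# {header}\n")
            results.to_csv(fh, index=False)
        kappas.to_csv(out / "kappa.csv", index=False)
        with open(out / "report.json", "w") as fh:
            json.dump(report, fh, indent=2, default=float)
    return report
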