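"""End-to-end study orchestration.

Scores both instruments for the week each participant used them, runs the
DLW computation for both weeks, and produces the full validation battery per
instrument: zero-order (and, when ages are supplied, age-adjusted partial)
Pearson correlations for AEE/TEE/PAL, Bland-Altman agreement for AEE and TEE,
a paired t-test of method means, compliance accounting, and the 3-SD
high-outlier sensitivity reanalysis.
"""

from __future__ import annotations

import dataclasses
import datetime as _dt
import json
from pathlib import Path
from typing import Dict, List, Optional

import numpy as np

from . import io as _io
from .calorimetry import bmr_from_series
from .constants import DEFAULTS, StudyConstants
from .dlw import dlw_week
from .par24 import score_week
from .recall7 import score_recall_week
from .simulate import NoiseConfig, StudyData, simulate_study
from .stats import (bland_altman, compliance, flag_outliers, paired_t,
                    partial_pearson, pearson)

DAYS_PER_WEEK = 7


def _round(x, nd):
    return None if x is None else round(float(x), nd)


def _week_of(date: _dt.date, start: _dt.date) -> int:
    """0-based study week of a calendar day."""
    return (date - start).days // DAYS_PER_WEEK


def _corr_block(x, y, ages=None) -> dict:
    res = pearson(x, y)
    block = {"r": _round(res.r, 3), "p": _round(res.p, 4), "n": res.n}
    if ages is not None:
        pres = partial_pearson(x, y, np.asarray(ages)[:, None])
        block["partial_r_age"] = _round(pres.r, 3)
        block["partial_p_age"] = _round(pres.p, 4)
    return block


def _ba_block(a, b, constants) -> dict:
    res = bland_altman(a, b, constants)
    return {
        "mean_diff_mj": _round(res.mean_diff, 2),
        "sd_diff_mj": _round(res.sd_diff, 2),
        "loa_low_mj": _round(res.loa_low, 2),
        "loa_high_mj": _round(res.loa_high, 2),
        "trend_slope": _round(res.trend_slope, 3),
        "trend_intercept": _round(res.trend_intercept, 3),
        "trend_r": _round(res.trend_r, 3),
        "trend_p": _round(res.trend_p, 4),
        "n": res.n,
    }


def analyze_study(diary_days, recall_days, isotope_samples, doses,
                  gas_series=None, bmr_kcal: Optional[Dict[str, float]] = None,
                  ages: Optional[Dict[str, float]] = None,
                  constants: StudyConstants = DEFAULTS) -> dict:
    """Run the full validation battery on in-memory study data.

    ``diary_days``/``recall_days`` map participant -> list of days; the week
    each instrument was used is inferred from the dates (study start = the
    earliest date on file). BMR comes from ``gas_series`` via the Weir
    acceptance rule unless ``bmr_kcal`` is given directly.
    """
    if gas_series is None and bmr_kcal is None:
        raise ValueError("need gas_series or bmr_kcal to establish BMR")

    all_dates = [d.date for days in diary_days.values() for d in days]
    all_dates += [d.date for days in recall_days.values() for d in days]
    if not all_dates:
        raise ValueError("no instrument days supplied")
    start = min(all_dates)

    bmr: Dict[str, dict] = {}
    pids = sorted(set(diary_days) | set(recall_days) | set(isotope_samples))
    for pid in pids:
        if bmr_kcal is not None and pid in bmr_kcal:
            bmr[pid] = {"kcal": bmr_kcal[pid], "accepted": True}
        elif gas_series is not None and pid in gas_series:
            res = bmr_from_series(gas_series[pid], constants=constants)
            bmr[pid] = {"kcal": res.bmr_kcal_day, "accepted": res.accepted}
        else:
            raise ValueError(f"no BMR source for participant {pid}")

    # per-participant weekly outcomes paired with same-week DLW
    pairs = {inst: {"web_tee": [], "web_aee": [], "web_pal": [],
                    "dlw_tee": [], "dlw_aee": [], "dlw_pal": [],
                    "pid": [], "age": []}
             for inst in ("par24", "recall7")}
    dlw_notes = {}
    for pid in pids:
        if pid not in doses or pid not in isotope_samples:
            continue
        bmr_kc = bmr[pid]["kcal"]
        bmr_mj = bmr_kc * constants.kcal_to_mj
        for inst, days in (("par24", diary_days.get(pid, [])),
                           ("recall7", recall_days.get(pid, []))):
            if not days:
                continue
            weeks = sorted({_week_of(d.date, start) for d in days})
            week = weeks[0]
            use = [d for d in days if _week_of(d.date, start) == week]
            if inst == "par24":
                from .compendium import default_compendium
                outcome = score_week(use, bmr_kc, default_compendium(),
                                     constants)
            else:
                outcome = score_recall_week(use, bmr_kc, constants)
            ref = dlw_week(isotope_samples[pid], doses[pid], bmr_mj,
                           week + 1, constants)
            dlw_notes[pid] = {"nd_no_ratio": ref.nd_no_ratio,
                              "qc_ok": ref.qc_ok}
            from .par24 import aee_from_tee
            bucket = pairs[inst]
            bucket["web_tee"].append(outcome.tee_mj)
            bucket["web_aee"].append(outcome.aee_mj)
            bucket["web_pal"].append(outcome.pal)
            bucket["dlw_tee"].append(ref.tee_mj_day)
            bucket["dlw_aee"].append(aee_from_tee(ref.tee_mj_day, bmr_mj,
                                                  constants))
            bucket["dlw_pal"].append(ref.pal)
            bucket["pid"].append(pid)
            bucket["age"].append(None if ages is None else ages.get(pid))

    report = {
        "constants": dataclasses.asdict(constants),
        "n_participants": len(pids),
        "significance_threshold": constants.alpha,
        "instruments": {},
        "dlw_qc": {
            "nd_no_mean": _round(np.mean([v["nd_no_ratio"]
                                          for v in dlw_notes.values()]), 3)
            if dlw_notes else None,
            "n_flagged": sum(1 for v in dlw_notes.values()
                             if not v["qc_ok"]),
        },
    }

    for inst, bucket in pairs.items():
        n = len(bucket["pid"])
        block: dict = {"n_pairs": n}
        comp_done = sum(
            len([d for d in (diary_days if inst == "par24"
                             else recall_days).get(pid, [])])
            for pid in pids)
        comp_total = len(pids) * DAYS_PER_WEEK
        done, total, pct = compliance(min(comp_done, comp_total), comp_total)
        block["compliance"] = {"completed_days": done, "total_days": total,
                               "pct": pct}
        if n >= 3:
            ages_vec = (None if any(a is None for a in bucket["age"])
                        else bucket["age"])
            for metric in ("aee", "tee", "pal"):
                block[f"{metric}_correlation"] = _corr_block(
                    bucket[f"web_{metric}"], bucket[f"dlw_{metric}"], ages_vec)
            for metric in ("aee", "tee"):
                block[f"{metric}_bland_altman"] = _ba_block(
                    bucket[f"web_{metric}"], bucket[f"dlw_{metric}"],
                    constants)
            t, pv = paired_t(bucket["web_tee"], bucket["dlw_tee"])
            block["tee_paired_t"] = {"t": _round(t, 3), "p": _round(pv, 4)}
            block["mean_web_tee_mj"] = _round(np.mean(bucket["web_tee"]), 2)
            block["mean_dlw_tee_mj"] = _round(np.mean(bucket["dlw_tee"]), 2)
            block["mean_web_aee_mj"] = _round(np.mean(bucket["web_aee"]), 2)
            block["mean_dlw_aee_mj"] = _round(np.mean(bucket["dlw_aee"]), 2)

            out_idx = flag_outliers(bucket["web_tee"], k_sd=3.0)
            if out_idx:
                keep = [i for i in range(n) if i not in out_idx]
                sens = {"excluded": [bucket["pid"][i] for i in out_idx]}
                if len(keep) >= 3:
                    for metric in ("aee", "tee"):
                        res = pearson([bucket[f"web_{metric}"][i] for i in keep],
                                      [bucket[f"dlw_{metric}"][i] for i in keep])
                        sens[f"{metric}_r"] = _round(res.r, 3)
                        sens[f"{metric}_p"] = _round(res.p, 4)
                block["outlier_sensitivity"] = sens
            else:
                block["outlier_sensitivity"] = {"excluded": []}
        report["instruments"][inst] = block
    return report


def run_study(config: "_io.RunConfig") -> dict:
    """Load (or simulate) the inputs named in ``config``, analyze, and write
    report.json plus a short human-readable report.txt to the output dir."""
    constants = config.constants
    ages = None
    if config.simulate_n:
        data = simulate_study(config.simulate_n, config.seed,
                              constants=constants)
        diary, recall = data.diary_days, data.recall_days
        iso, doses, gas = data.isotope_samples, data.doses, data.gas_series
        ages = {p.id: p.age for p in data.participants}
        bmr_direct = None
    else:
        for name in ("diary", "recall", "isotopes", "doses"):
            if getattr(config, name) is None:
                raise ValueError(f"config is missing the '{name}' input path")
        diary, rejected = _io.read_diary_csv(config.diary)
        recall = _io.read_recall_csv(config.recall)
        iso = _io.read_isotope_csv(config.isotopes)
        doses = _io.read_dose_csv(config.doses)
        gas = _io.read_gas_csv(config.gas) if config.gas else None
        bmr_direct = _io.read_bmr_csv(config.bmr) if config.bmr else None

    report = analyze_study(diary, recall, iso, doses, gas_series=gas,
                           bmr_kcal=bmr_direct, ages=ages,
                           constants=constants)
    report["seed"] = config.seed
    report["overridden_constants"] = config.overridden

    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    (outdir / "report.json").write_text(
        json.dumps(report, indent=2, sort_keys=True) + "\n", encoding="utf-8")
    (outdir / "report.txt").write_text(_format_report(report),
                                       encoding="utf-8")
    return report


def _format_report(report: dict) -> str:
    lines = [
        "Physical-activity instrument validation against DLW",
        f"participants: {report['n_participants']}",
        "",
    ]
    for inst, block in report["instruments"].items():
        lines.append(f"[{inst}]")
        comp = block.get("compliance", {})
        if comp:
            lines.append(
                f"  compliance: {comp['completed_days']}/{comp['total_days']}"
                f" days ({comp['pct']}%)")
        for metric in ("aee", "tee", "pal"):
            c = block.get(f"{metric}_correlation")
            if c:
                lines.append(f"  {metric.upper()} r = {c['r']} (p = {c['p']},"
                             f" n = {c['n']})")
        ba = block.get("aee_bland_altman")
        if ba:
            lines.append(
                f"  AEE Bland-Altman: mean diff {ba['mean_diff_mj']} MJ, "
                f"LoA [{ba['loa_low_mj']}, {ba['loa_high_mj']}] MJ")
        lines.append("")
    qc = report.get("dlw_qc", {})
    if qc.get("nd_no_mean") is not None:
        lines.append(f"DLW QC: mean Nd/No = {qc['nd_no_mean']}, "
                     f"{qc['n_flagged']} flagged")
    return "\n".join(lines) + "\n"
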