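"""End-to-end study driver: simulate -> endotype -> reliability -> report.

Runs the full synthetic reliability study and renders the standard
tables: per-trait night-to-night agreement (median (IQR) per night,
paired difference, ICC), stratified reliability by sleep stage and body
position, SEM/MDD per assessment mode, night-to-night delta
correlations, and Bland-Altman pairs.  Every output file carries the
configuration hash and seed; a rerun with identical configuration is
bit-identical.
"""

from __future__ import annotations

import dataclasses
import json
import shutil
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .cohort import NightRecording, TraitConfig, simulate_cohort
from .endotypes import STRATA, estimate_recording, fit_night
from .io import config_hash, config_to_dict, write_cohort, write_table
from .reliability import (MeasurementMatrix, bland_altman, bootstrap_two_night_sem,
                          delta_correlation, mdd_from_sem, reliability_summary)

__all__ = ["StudyConfig", "run_study", "estimate_cohort", "trait_matrix",
           "reliability_table", "stratified_icc_table", "two_night_sem_table",
           "delta_correlation_table", "render_markdown"]

# traits on their reporting scale (upper-airway traits transformed)
TRAIT_COLUMNS = {
    "LG1": "lg1",
    "ArTh": "arth",
    "VRA": "vra",
    "LGn": "lgn",
    "Delay": "delay_s",
    "Vpassive": "vpassive_t",
    "Vactive": "vactive_t",
    "Vcomp": "vcomp_t",
    "Vmin": "vmin",
}
PSG_COLUMNS = {
    "AHI": "ahi",
    "ODI": "odi",
    "TST": "tst_min",
    "SleepEfficiency": "sleep_efficiency",
    "REMpct": "rem_pct",
    "SupinePct": "supine_pct",
}
ALL_COLUMNS = {**PSG_COLUMNS, **TRAIT_COLUMNS}


@dataclass
class StudyConfig:
    """Configuration of one full study run."""

    traits: TraitConfig = field(default_factory=TraitConfig)
    step_s: float = 210.0
    strata: tuple[str, ...] = tuple(STRATA)
    primary_stratum: str = "nrem-all"
    nights: tuple[int, int] = (0, 1)
    alpha: float = 0.003
    boot_iters: int = 500       # two-night-average bootstrap
    sem_boot: int = 1000        # SEM CI bootstrap
    include_drive: bool = True

    def __post_init__(self) -> None:
        if not self.strata:
            raise ValueError("at least one stratum required")
        for s in self.strata:
            if s not in STRATA:
                raise ValueError(f"unknown stratum {s!r}")
        if max(self.nights) >= self.traits.n_nights:
            raise ValueError("configured night pair exceeds n_nights")


def estimate_cohort(recordings: list[NightRecording], strata=None,
                    step_s: float = 210.0, progress: bool = False) -> pd.DataFrame:
    """Estimate traits for every recording under every stratum.

    Returns the long trait table: one row per (subject, night, stratum)
    with window counts, the nine traits (raw and transformed) and the
    night's scored summary metrics.
    """
    strata = {k: STRATA[k] for k in (strata or STRATA)} if not isinstance(strata, dict) else strata
    rows = []
    for rec in recordings:
        fitted = fit_night(rec, step_s=step_s)
        ests = estimate_recording(rec, strata=strata, fitted=fitted)
        for label, es in ests.items():
            row = {
                "subject": rec.subject_id,
                "night": rec.night_index,
                "stratum": label,
                "n_windows": es.n_windows,
                "lg1": es.lg1, "lgn": es.lgn, "delay_s": es.delay_s,
                "arth": es.arth, "vra": es.vra,
                "vpassive_raw": es.vpassive, "vactive_raw": es.vactive,
                "vcomp_raw": es.vcomp, "vmin": es.vmin,
                "vpassive_t": es.vpassive_t, "vactive_t": es.vactive_t,
                "vcomp_t": es.vcomp_t,
                "vactive_extrapolated": es.vactive_extrapolated,
            }
            row.update({
                "ahi": rec.summary.ahi, "odi": rec.summary.odi,
                "tst_min": rec.summary.tst_min,
                "sleep_efficiency": rec.summary.sleep_efficiency,
                "rem_pct": rec.summary.rem_pct, "supine_pct": rec.summary.supine_pct,
            })
            rows.append(row)
    return pd.DataFrame(rows)


def trait_matrix(traits: pd.DataFrame, column: str, stratum: str,
                 nights=(0, 1), name: str = "") -> MeasurementMatrix | None:
    """Wide n x k matrix of one trait; subjects with any missing night dropped."""
    sub = traits[traits["stratum"] == stratum]
    wide = sub.pivot_table(index="subject", columns="night", values=column,
                           aggfunc="first")
    cols = [n for n in nights if n in wide.columns]
    if len(cols) < len(nights):
        return None
    wide = wide[list(nights)].dropna()
    if len(wide) < 3:
        return None
    return MeasurementMatrix(wide.to_numpy(), trait=name or column)


def reliability_table(traits: pd.DataFrame, stratum: str, nights=(0, 1),
                      alpha: float = 0.003, seed: int = 0,
                      sem_boot: int = 1000) -> pd.DataFrame:
    """Per-trait agreement battery over one pair of nights.

    One row per PSG metric and endotypic trait: per-night median (IQR),
    paired difference mean +/- SD with p, ICC (95% CI) with
    interpretation, agreement SEM (95% CI) and MDD.
    """
    rows = []
    for name, col in ALL_COLUMNS.items():
        m = trait_matrix(traits, col, stratum, nights, name=name)
        if m is None:
            rows.append({"trait": name, "n": 0})
            continue
        res = reliability_summary(m, alpha=alpha, n_boot=sem_boot, seed=seed)
        q = {}
        for occ, j in enumerate(nights):
            v = m.values[:, occ]
            q[f"median_{occ + 1}"] = float(np.median(v))
            q[f"q1_{occ + 1}"] = float(np.quantile(v, 0.25))
            q[f"q3_{occ + 1}"] = float(np.quantile(v, 0.75))
        rows.append({
            "trait": name, "n": res.n, **q,
            "mean_diff": res.mean_diff, "sd_diff": res.sd_diff,
            "t": res.t_stat, "p": res.p_value, "significant": res.significant,
            "shapiro_p": res.shapiro_p,
            "icc": res.icc, "icc_lo": res.icc_ci[0], "icc_hi": res.icc_ci[1],
            "sem": res.sem, "sem_lo": res.sem_ci[0], "sem_hi": res.sem_ci[1],
            "mdd": res.mdd, "interpretation": res.interpretation,
        })
    return pd.DataFrame(rows)


def stratified_icc_table(traits: pd.DataFrame, strata, nights=(0, 1),
                         alpha: float = 0.003, seed: int = 0) -> pd.DataFrame:
    """ICC per stratum per trait with retained recordings and window counts."""
    rows = []
    for stratum in strata:
        sub = traits[(traits["stratum"] == stratum) & (traits["n_windows"] > 0)]
        n_rec = int(len(sub))
        mean_windows = float(sub["n_windows"].mean()) if n_rec else float("nan")
        row = {"stratum": stratum, "n_recordings": n_rec, "mean_windows": mean_windows}
        m0 = trait_matrix(traits, "lg1", stratum, nights)
        row["n_subjects"] = m0.n if m0 is not None else 0
        for name, col in TRAIT_COLUMNS.items():
            m = trait_matrix(traits, col, stratum, nights, name=name)
            if m is None:
                row[f"icc_{name}"] = float("nan")
                continue
            res = reliability_summary(m, alpha=alpha, n_boot=10, seed=seed)
            row[f"icc_{name}"] = res.icc
        rows.append(row)
    return pd.DataFrame(rows)


def two_night_sem_table(traits: pd.DataFrame, stratum: str, iters: int = 500,
                        seed: int = 0) -> pd.DataFrame:
    """Single-night vs two-night-average SEM/MDD from four repeated nights."""
    rows = []
    for name, col in ALL_COLUMNS.items():
        m = trait_matrix(traits, col, stratum, nights=(0, 1, 2, 3), name=name)
        if m is None:
            rows.append({"trait": name, "n": 0})
            continue
        single = reliability_summary(
            MeasurementMatrix(m.values[:, :2], trait=name), n_boot=10, seed=seed)
        sem2, (lo, hi), mdd2 = bootstrap_two_night_sem(m, iters=iters, seed=seed)
        rows.append({
            "trait": name, "n": m.n,
            "sem_single": single.sem, "mdd_single": single.mdd,
            "sem_two_night": sem2, "sem_two_night_lo": lo, "sem_two_night_hi": hi,
            "mdd_two_night": mdd2,
            "mdd_reduction_pct": 100.0 * (1.0 - mdd2 / single.mdd)
            if single.mdd > 0 else float("nan"),
        })
    return pd.DataFrame(rows)


def delta_correlation_table(traits: pd.DataFrame, stratum: str, nights=(0, 1),
                            threshold: float = 0.4) -> pd.DataFrame:
    """|r| screen between night-to-night changes in traits and PSG metrics."""
    # deltas aligned on common subjects across all metrics
    sub = traits[traits["stratum"] == stratum]
    wide = {name: sub.pivot_table(index="subject", columns="night", values=col, aggfunc="first")
            for name, col in ALL_COLUMNS.items()}
    joint = pd.DataFrame({
        name: w[nights[1]] - w[nights[0]]
        for name, w in wide.items()
        if nights[0] in w.columns and nights[1] in w.columns
    }).dropna()
    rows = []
    for trait in TRAIT_COLUMNS:
        if trait not in joint.columns:
            continue
        for psg in PSG_COLUMNS:
            if psg not in joint.columns:
                continue
            r, flagged = delta_correlation(joint[trait], joint[psg], threshold)
            rows.append({"trait": trait, "psg_metric": psg, "n": len(joint),
                         "r": r, "relevant": flagged})
    return pd.DataFrame(rows)


def bland_altman_table(traits: pd.DataFrame, stratum: str, nights=(0, 1)) -> pd.DataFrame:
    """Per-subject (mean, difference) pairs for every trait, for plotting."""
    rows = []
    for name, col in ALL_COLUMNS.items():
        m = trait_matrix(traits, col, stratum, nights, name=name)
        if m is None:
            continue
        bias, loa, pairs = bland_altman(m)
        for mean, diff in pairs:
            rows.append({"trait": name, "mean": mean, "diff": diff,
                         "bias": bias, "loa_lo": loa[0], "loa_hi": loa[1]})
    return pd.DataFrame(rows)


def render_markdown(df: pd.DataFrame, floatfmt: str = "%.2f") -> str:
    """Minimal GitHub-style markdown table rendering."""
    def fmt(x):
        if isinstance(x, float):
            return "" if not np.isfinite(x) else floatfmt % x
        return str(x)
    cols = list(df.columns)
    lines = ["| " + " | ".join(cols) + " |",
             "| " + " | ".join("---" for _ in cols) + " |"]
    for _, row in df.iterrows():
        lines.append("| " + " | ".join(fmt(row[c]) for c in cols) + " |")
    return "\n".join(lines) + "\n"


def run_study(config: StudyConfig, outdir, seed: int | None = None,
              keep_partial: bool = False) -> dict:
    """Execute the full pipeline and write all artifacts under outdir.

    Returns a dict of the main result tables.  On failure the partial
    output directory is removed and the error names the failed stage.
    """
    outdir = Path(outdir)
    tc = config.traits
    if seed is not None:
        tc = dataclasses.replace(tc, rng_seed=seed)
    meta = f"endotrait config_hash={config_hash(tc)} seed={tc.rng_seed}"
    stage = "setup"
    try:
        stage = "simulate"
        truths, recordings = simulate_cohort(tc)
        write_cohort(outdir / "cohort", tc, truths, recordings,
                     include_drive=config.include_drive)

        stage = "endotype"
        traits = estimate_cohort(recordings, strata=config.strata, step_s=config.step_s)
        write_table(traits, outdir / "traits.tsv", meta)

        stage = "reliability"
        rel = reliability_table(traits, config.primary_stratum, config.nights,
                                alpha=config.alpha, seed=tc.rng_seed,
                                sem_boot=config.sem_boot)
        write_table(rel, outdir / "reliability.tsv", meta)
        strat = stratified_icc_table(traits, config.strata, config.nights,
                                     alpha=config.alpha, seed=tc.rng_seed)
        write_table(strat, outdir / "stratified_icc.tsv", meta)
        ba = bland_altman_table(traits, config.primary_stratum, config.nights)
        write_table(ba, outdir / "bland_altman.tsv", meta)
        dc = delta_correlation_table(traits, config.primary_stratum, config.nights)
        write_table(dc, outdir / "delta_correlations.tsv", meta)
        results = {"traits": traits, "reliability": rel, "stratified": strat,
                   "bland_altman": ba, "delta_correlations": dc}
        if tc.n_nights >= 4:
            twon = two_night_sem_table(traits, config.primary_stratum,
                                       iters=config.boot_iters, seed=tc.rng_seed)
            write_table(twon, outdir / "two_night_sem.tsv", meta)
            results["two_night"] = twon

        stage = "report"
        report = ["# Synthetic endotype reliability study", "",
                  f"`{meta}`", "",
                  f"n = {tc.n_subjects} subjects x {tc.n_nights} nights; "
                  f"primary stratum: {config.primary_stratum}", "",
                  "## Night-to-night agreement", "",
                  render_markdown(rel[[c for c in (
                      "trait", "n", "median_1", "median_2", "mean_diff", "sd_diff",
                      "p", "icc", "icc_lo", "icc_hi", "sem", "mdd", "interpretation")
                      if c in rel.columns]]),
                  "## Stratified ICC", "",
                  render_markdown(strat)]
        if "two_night" in results:
            report += ["## Two-night averaging", "",
                       render_markdown(results["two_night"])]
        (outdir / "report.md").write_text("\n".join(report), encoding="utf-8")
        with open(outdir / "metadata.json", "w", encoding="utf-8") as fh:
            json.dump({"config_hash": config_hash(tc), "seed": tc.rng_seed,
                       "config": config_to_dict(tc),
                       "strata": list(config.strata),
                       "alpha": config.alpha, "step_s": config.step_s},
                      fh, indent=2)
        return results
    except Exception as exc:
        if outdir.exists() and not keep_partial:
            shutil.rmtree(outdir)
        raise RuntimeError(f"study stage '{stage}' failed: {exc}") from exc
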