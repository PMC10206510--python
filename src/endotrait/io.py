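"""TSV serialisation of cohorts, trait tables and reliability results.

All tables are UTF-8, tab-separated, '.' decimal, one header row.  Each
file written by the pipeline starts with a single comment line carrying
the configuration hash and seed so any artifact can be traced to the
run that produced it; readers skip comment lines.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from pathlib import Path

import pandas as pd

from .cohort import NightRecording, SubjectTruth, TraitConfig, TraitMoments
from .scoring import SleepSummary

__all__ = [
    "config_hash", "config_to_dict", "config_from_dict",
    "write_cohort", "read_cohort", "write_table", "read_table",
]

FLOAT_FMT = "%.6g"


def config_to_dict(config: TraitConfig) -> dict:
    d = dataclasses.asdict(config)
    d["traits"] = {k: dataclasses.asdict(v) if dataclasses.is_dataclass(v) else dict(v)
                   for k, v in config.traits.items()}
    return d


def config_from_dict(d: dict) -> TraitConfig:
    d = dict(d)
    d["traits"] = {k: TraitMoments(**v) for k, v in d["traits"].items()}
    return TraitConfig(**d)


def config_hash(config: TraitConfig) -> str:
    """Short stable digest of the full configuration."""
    blob = json.dumps(config_to_dict(config), sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()[:12]


def write_table(df: pd.DataFrame, path, header_meta: str | None = None) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w", encoding="utf-8") as fh:
        if header_meta:
            fh.write(f"# {header_meta}\n")
        df.to_csv(fh, sep="\t", index=False, float_format=FLOAT_FMT)


def read_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#")


def _truth_frame(truths: list[SubjectTruth], extra: dict | None = None) -> pd.DataFrame:
    rows = []
    for tr in truths:
        for j in range(len(tr.lg1)):
            row = {"subject": tr.subject_id, "night": j}
            row.update(tr.night(j))
            rows.append(row)
    df = pd.DataFrame(rows)
    if extra:
        for k, v in extra.items():
            df[k] = v
    return df


def write_cohort(outdir, config: TraitConfig, truths: list[SubjectTruth],
                 recordings: list[NightRecording], include_drive: bool = True) -> None:
    """Write a simulated cohort as the standard five TSV tables + config echo.

    breaths/epochs/events/arousals tables are concatenated over
    subject-nights with subject and night key columns; truth.tsv carries
    the ground-truth per-night traits (plus the realized
    lowest-decile Vmin) and summaries.tsv the scored sleep metrics.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    meta = f"endotrait config_hash={config_hash(config)} seed={config.rng_seed}"

    def tag(rec: NightRecording, df: pd.DataFrame) -> pd.DataFrame:
        out = df.copy()
        out.insert(0, "night", rec.night_index)
        out.insert(0, "subject", rec.subject_id)
        return out

    breaths = pd.concat([tag(r, r.breaths) for r in recordings], ignore_index=True)
    breaths = breaths.rename(columns={"ventilation": "ventilation_pct", "drive": "drive_pct"})
    if not include_drive:
        breaths = breaths.drop(columns=["drive_pct"])
    write_table(breaths, outdir / "breaths.tsv", meta)
    write_table(pd.concat([tag(r, r.epochs) for r in recordings], ignore_index=True),
                outdir / "epochs.tsv", meta)
    write_table(pd.concat([tag(r, r.events) for r in recordings], ignore_index=True),
                outdir / "events.tsv", meta)
    write_table(pd.concat([tag(r, r.arousals) for r in recordings], ignore_index=True),
                outdir / "arousals.tsv", meta)

    vmin_real = {(r.subject_id, r.night_index): r.vmin_realized for r in recordings}
    truth = _truth_frame(truths)
    truth["vmin_realized"] = [vmin_real.get((s, n), float("nan"))
                              for s, n in zip(truth["subject"], truth["night"])]
    write_table(truth, outdir / "truth.tsv", meta)

    summaries = pd.DataFrame([{
        "subject": r.subject_id, "night": r.night_index,
        **dataclasses.asdict(r.summary),
    } for r in recordings])
    write_table(summaries, outdir / "summaries.tsv", meta)

    with open(outdir / "config.json", "w", encoding="utf-8") as fh:
        json.dump({"config": config_to_dict(config),
                   "config_hash": config_hash(config)}, fh, indent=2)


def read_cohort(indir) -> tuple[TraitConfig, pd.DataFrame, list[NightRecording]]:
    """Load a cohort directory back into recordings.

    Returns (config, truth table, recordings).  The latent drive column
    is retained if present (simulated cohorts); estimation never reads
    it.
    """
    indir = Path(indir)
    with open(indir / "config.json", encoding="utf-8") as fh:
        config = config_from_dict(json.load(fh)["config"])
    truth = read_table(indir / "truth.tsv")
    breaths = read_table(indir / "breaths.tsv").rename(
        columns={"ventilation_pct": "ventilation", "drive_pct": "drive"})
    epochs = read_table(indir / "epochs.tsv")
    events = read_table(indir / "events.tsv")
    arousals = read_table(indir / "arousals.tsv")
    summaries = read_table(indir / "summaries.tsv")

    recordings = []
    for (subj, night), b in breaths.groupby(["subject", "night"], sort=True):
        def sub(df):
            m = (df["subject"] == subj) & (df["night"] == night)
            return df[m].drop(columns=["subject", "night"]).reset_index(drop=True)
        srow = summaries[(summaries["subject"] == subj) & (summaries["night"] == night)]
        summary = SleepSummary(**srow.drop(columns=["subject", "night"]).iloc[0].to_dict()) \
            if len(srow) else SleepSummary.invalid()
        tr = truth[(truth["subject"] == subj) & (truth["night"] == night)]
        recordings.append(NightRecording(
            subject_id=str(subj), night_index=int(night),
            breaths=b.drop(columns=["subject", "night"]).reset_index(drop=True),
            epochs=sub(epochs), events=sub(events), arousals=sub(arousals),
            summary=summary,
            vmin_realized=float(tr["vmin_realized"].iloc[0]) if len(tr) else float("nan"),
        ))
    return config, truth, recordings
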