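"""End-to-end orchestration: classify -> score -> crude battery -> adjusted models.

The analysis set is restricted to wave-2 completers.  All numbers are kept at
full precision internally; rounding happens only when report files are
written (odds ratios and CI bounds at 2 decimals, p-values at 3, with
``<0.001`` below 0.0005).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import __version__
from .effects import (
    EXPOSURE_DEFINITIONS,
    OVERALL,
    EffectEstimate,
    EstimationError,
    run_crude_battery,
)
from .lexicon import (
    ALL_CATEGORIES,
    Lexicon,
    UtteranceRecord,
    build_frequency_table,
    default_lexicon,
    flag_records,
    load_lexicon,
    tabulate_flag_counts,
)
from .logistic import AGE_LEVELS, JOB_LEVELS, SEX_LEVELS, ModelSpec, adjusted_or
from .scoring import CESD_CUTOFF, PSQI_CUTOFF, dichotomize_exposure

OUTCOME_LABELS = {"cesd_case": "CES-D", "psqi_poor": "PSQI"}


class PipelineError(RuntimeError):
    """Stage failure with enough context to locate the offending input."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


@dataclass
class RunConfig:
    cohort_path: str | Path
    lexicon_path: str | Path | None = None
    lemma_map_path: str | Path | None = None
    output_dir: str | Path = "reports"
    cesd_cutoff: int = CESD_CUTOFF
    psqi_cutoff: int = PSQI_CUTOFF
    z: float = 1.959964
    zero_cell_correction: bool = False
    baseline_as_caseness: bool = False
    min_frequency: int = 2
    seed: int | None = None

    def validate(self) -> None:
        if self.cesd_cutoff <= 0 or self.psqi_cutoff <= 0:
            raise PipelineError("config", "cutoffs must be positive integers")
        if not Path(self.cohort_path).exists():
            raise PipelineError("config", f"cohort file not found: {self.cohort_path}")

    def digest(self) -> str:
        """Hash of the analysis-relevant configuration (output location excluded)."""
        doc = {k: str(v) for k, v in dataclasses.asdict(self).items()
               if k != "output_dir"}
        return hashlib.sha256(json.dumps(doc, sort_keys=True).encode()).hexdigest()


def load_cohort(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, dtype={"participant_id": str}, keep_default_na=False,
                       na_values=[""])


def resolve_lexicon(config: RunConfig) -> Lexicon:
    if config.lexicon_path is None:
        return default_lexicon()
    try:
        return load_lexicon(config.lexicon_path, config.lemma_map_path)
    except Exception as exc:
        raise PipelineError("lexicon", str(exc)) from exc


def build_analysis_frame(
    cohort: pd.DataFrame, lexicon: Lexicon, config: RunConfig
) -> pd.DataFrame:
    """Wave-2 completers with exposure, per-category flags and caseness columns."""
    if "followed_up" in cohort.columns:
        frame = cohort[cohort["followed_up"] == 1].copy()
    else:
        frame = cohort.copy()
    if frame.empty:
        raise PipelineError("score", "no wave-2 completers in the cohort")
    frame = frame.reset_index(drop=True)
    dupes = frame["participant_id"][frame["participant_id"].duplicated()]
    if not dupes.empty:
        raise PipelineError("score", f"duplicate participant_id {dupes.iloc[0]!r}")

    try:
        frame["exposed"] = [
            dichotomize_exposure(int(v)) for v in frame["exposure_likert"]
        ]
    except (TypeError, ValueError) as exc:
        raise PipelineError("score", f"bad exposure_likert value: {exc}") from exc

    records = [
        UtteranceRecord(pid, "" if pd.isna(text) else str(text))
        for pid, text in zip(frame["participant_id"], frame["utterance_text"])
    ]
    exposed_records = [r for r, e in zip(records, frame["exposed"]) if e]
    flags = flag_records(exposed_records, lexicon)
    for cat in ALL_CATEGORIES:
        frame[cat] = [
            pid in flags and flags[pid].flags[cat] for pid in frame["participant_id"]
        ]
    frame[OVERALL] = frame["exposed"]

    for col, cutoff, out in (
        ("cesd_total_w2", config.cesd_cutoff, "cesd_case"),
        ("psqi_global_w2", config.psqi_cutoff, "psqi_poor"),
    ):
        if frame[col].isna().any():
            bad = frame.loc[frame[col].isna(), "participant_id"].iloc[0]
            raise PipelineError("score", f"missing {col} for participant {bad}")
        frame[out] = frame[col].astype(float) >= cutoff
    return frame


def crude_estimates(frame: pd.DataFrame, config: RunConfig) -> list[EffectEstimate]:
    pids = list(frame["participant_id"])
    exposed = dict(zip(pids, frame["exposed"]))
    from .lexicon import UtteranceFlags  # local to avoid a cycle at import time

    flags = {
        pid: UtteranceFlags(pid, {cat: bool(row[cat]) for cat in ALL_CATEGORIES}, {})
        for pid, (_, row) in zip(pids, frame.iterrows())
        if row["exposed"]
    }
    outcomes = {
        out: dict(zip(pids, frame[out])) for out in ("cesd_case", "psqi_poor")
    }
    try:
        return run_crude_battery(
            exposed, flags, outcomes, z=config.z,
            zero_cell_correction=config.zero_cell_correction,
        )
    except EstimationError as exc:
        raise PipelineError("crude", str(exc)) from exc


def adjusted_estimates(
    frame: pd.DataFrame, config: RunConfig
) -> list[EffectEstimate]:
    estimates = []
    for definition in EXPOSURE_DEFINITIONS:
        for outcome in ("cesd_case", "psqi_poor"):
            spec = ModelSpec(
                outcome=outcome,
                exposure_term=definition,
                baseline_as_caseness=config.baseline_as_caseness,
            )
            try:
                estimate, _ = adjusted_or(frame, spec, z=config.z)
            except Exception as exc:
                raise PipelineError(
                    "adjust", f"{definition} vs {outcome}: {exc}"
                ) from exc
            estimates.append(estimate)
    return estimates


# ---------------------------------------------------------------------------
# Report formatting


def format_or(value: float) -> str:
    return f"{value:.2f}"


def format_p(p: float) -> str:
    return "<0.001" if p < 0.0005 else f"{p:.3f}"


def demographic_table(frame: pd.DataFrame) -> pd.DataFrame:
    """Counts and percentages by overall exposure (wave-1 covariates)."""
    groups = {
        "all": frame,
        "not_exposed": frame[~frame["exposed"]],
        "exposed": frame[frame["exposed"]],
    }
    rows = []
    specs = [
        ("sex", SEX_LEVELS),
        ("age_class", AGE_LEVELS),
        ("job_class", JOB_LEVELS),
    ]
    for col, levels in specs:
        for level in levels:
            row = {"characteristic": col, "level": level}
            for name, g in groups.items():
                count = int((g[col].astype(str) == level).sum())
                row[f"{name}_n"] = count
                row[f"{name}_pct"] = round(100 * count / len(g), 1) if len(g) else 0.0
            rows.append(row)
    for col, label in (("marital", "married"), ("night_shift", "applicable")):
        row = {"characteristic": col, "level": label}
        for name, g in groups.items():
            count = int(g[col].astype(bool).sum())
            row[f"{name}_n"] = count
            row[f"{name}_pct"] = round(100 * count / len(g), 1) if len(g) else 0.0
        rows.append(row)
    for col in ("cesd_total_w1", "psqi_global_w1"):
        row = {"characteristic": col, "level": "mean (sd)"}
        for name, g in groups.items():
            row[f"{name}_n"] = round(float(g[col].mean()), 1) if len(g) else float("nan")
            row[f"{name}_pct"] = round(float(g[col].std(ddof=1)), 1) if len(g) > 1 else float("nan")
        rows.append(row)
    return pd.DataFrame(rows)


def run_full_analysis(config: RunConfig) -> dict[str, Path]:
    """Execute every stage and write the report bundle; returns written paths."""
    config.validate()
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    lexicon = resolve_lexicon(config)
    try:
        cohort = load_cohort(config.cohort_path)
    except Exception as exc:
        raise PipelineError("load", str(exc)) from exc
    frame = build_analysis_frame(cohort, lexicon, config)

    paths: dict[str, Path] = {}

    # Table 1 analogue
    demo = demographic_table(frame)
    paths["demographics"] = outdir / "table1_demographics.tsv"
    demo.to_csv(paths["demographics"], sep="\t", index=False, lineterminator="\n")

    # Table 2 analogue: flag counts among the exposed, split by caseness
    from .lexicon import UtteranceFlags

    exposed_frame = frame[frame["exposed"]]
    flag_objects = [
        UtteranceFlags(row["participant_id"],
                       {cat: bool(row[cat]) for cat in ALL_CATEGORIES}, {})
        for _, row in exposed_frame.iterrows()
    ]
    counts = tabulate_flag_counts(flag_objects)
    count_rows = []
    for definition in EXPOSURE_DEFINITIONS:
        mask = exposed_frame["exposed"] if definition == OVERALL else exposed_frame[definition]
        sub = exposed_frame[mask]
        count_rows.append({
            "exposure": definition,
            "cesd_case": int(sub["cesd_case"].sum()),
            "cesd_noncase": int((~sub["cesd_case"]).sum()),
            "psqi_case": int(sub["psqi_poor"].sum()),
            "psqi_noncase": int((~sub["psqi_poor"]).sum()),
            "total": len(sub),
        })
    paths["flag_counts"] = outdir / "table2_flag_counts.tsv"
    pd.DataFrame(count_rows).to_csv(paths["flag_counts"], sep="\t", index=False,
                                    lineterminator="\n")

    # crude + adjusted effect tables
    crude = crude_estimates(frame, config)
    adjusted = adjusted_estimates(frame, config)
    crude_rows = [e.to_dict() for e in crude]
    paths["crude_effects"] = outdir / "crude_effects.csv"
    pd.DataFrame(crude_rows).to_csv(paths["crude_effects"], index=False,
                                    lineterminator="\n")

    adj_by_key = {(e.exposure_label, e.outcome_label): e for e in adjusted}
    table3_rows = []
    for e in crude:
        adj = adj_by_key[(e.exposure_label, e.outcome_label)]
        table3_rows.append({
            "exposure": e.exposure_label,
            "outcome": OUTCOME_LABELS[e.outcome_label],
            "crude_or": format_or(e.odds_ratio),
            "crude_ci": f"({format_or(e.ci_low)}, {format_or(e.ci_high)})",
            "crude_p": format_p(e.p_value),
            "adj_or": format_or(adj.odds_ratio),
            "adj_ci": f"({format_or(adj.ci_low)}, {format_or(adj.ci_high)})",
            "adj_p": format_p(adj.p_value),
        })
    paths["effects"] = outdir / "table3_effects.csv"
    pd.DataFrame(table3_rows).to_csv(paths["effects"], index=False, lineterminator="\n")

    # Figure 1 analogue: per-category lemma frequency tables
    utterances = [
        UtteranceRecord(row["participant_id"], str(row["utterance_text"]))
        for _, row in exposed_frame.iterrows()
        if not pd.isna(row["utterance_text"]) and str(row["utterance_text"])
    ]
    for cat in ALL_CATEGORIES:
        table = build_frequency_table(
            utterances, cat, lexicon, min_frequency=config.min_frequency
        )
        path = outdir / f"frequency_{cat}.tsv"
        table.to_tsv(path)
        paths[f"frequency_{cat}"] = path

    run_log = {
        "version": __version__,
        "config_sha256": config.digest(),
        "seed": config.seed,
        "n_analyzed": int(len(frame)),
        "n_exposed": int(counts.overall),
        "flag_counts": counts.by_category,
        "outputs": {k: str(v) for k, v in paths.items()},
    }
    paths["run_log"] = outdir / "run_log.json"
    with open(paths["run_log"], "w", encoding="utf-8") as fh:
        json.dump(run_log, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return paths
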