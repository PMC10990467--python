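"""Two-wave synthetic cohort generator.

Produces participant records with the statistical shape of the study design:
covariates drawn from configurable margins, baseline instrument scores from
truncated normals, Bernoulli exposure (optionally confounded with the baseline
depression score), independent multi-label aggression-type flags with
lexicon-consistent utterance text, Bernoulli attrition, and wave-2 caseness
from a logistic outcome model.  Hidden ``truth`` bookkeeping lets tests
compare every pipeline stage against the generating process.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml
from scipy.special import expit, logit
from scipy.stats import truncnorm

from .lexicon import ALL_CATEGORIES, EXPLICIT_CATEGORIES, OTHER
from .logistic import AGE_LEVELS, JOB_LEVELS, SEX_LEVELS
from .scoring import CESD_CUTOFF, PSQI_CUTOFF

CESD_MAX = 60
PSQI_MAX = 21

#: Default utterance phrase pools.  Each explicit-category phrase contains at
#: least one default-lexicon pattern for its category and no pattern of any
#: other category; neutral phrases contain no pattern at all, so classifying
#: generated text round-trips exactly to the planted flags.
DEFAULT_PHRASE_POOLS: dict[str, list[str]] = {
    "job_performance": [
        "You are useless!",
        "What an idiot.",
        "Such a poor memory.",
        "Just quit already.",
        "You should resign.",
    ],
    "personality_looks": [
        "Nice bald head.",
        "You little shit.",
        "So ugly.",
    ],
    "life_threat": [
        "Please die.",
        "I will kill you.",
    ],
    "neutral": [
        "You are so slow today.",
        "Why are you even here?",
        "Go home now!",
        "Nobody wants you around.",
    ],
}

DEFAULT_PERPETRATORS = ("supervisor", "colleague", "customer", "subordinate")


class ConfigError(ValueError):
    """Raised for infeasible or inconsistent generator configurations."""


def _margins(counts: Sequence[int]) -> tuple[float, ...]:
    total = sum(counts)
    return tuple(c / total for c in counts)


@dataclass
class OutcomeModel:
    """Logistic model for one wave-2 outcome.

    ``baseline_coef`` multiplies the baseline score centered at its configured
    mean; ``covariate_coefficients`` is keyed by design-column names such as
    ``sex[female]`` or ``night_shift``.
    """

    intercept: float
    type_log_ors: dict[str, float]
    baseline_coef: float
    covariate_coefficients: dict[str, float] = field(default_factory=dict)


@dataclass
class GeneratorConfig:
    n_baseline: int = 800
    follow_up_rate: float = 0.63
    seed: int = 0

    # covariate margins (defaults follow the analyzed cohort's frequencies)
    sex_margin: tuple[float, ...] = _margins((296, 204))
    age_margin: tuple[float, ...] = _margins((20, 82, 143, 174, 81))
    job_margin: tuple[float, ...] = _margins((145, 97, 20, 174, 64))
    married_p: float = 298 / 500
    night_shift_p: float = 38 / 500

    # baseline instrument scores
    cesd_mean: float = 12.5
    cesd_sd: float = 7.9
    psqi_mean: float = 5.1
    psqi_sd: float = 2.6

    # exposure process
    exposure_prevalence: float = 108 / 500
    #: log-odds of exposure per SD of baseline CES-D (confounding hook, off by default)
    exposure_baseline_coef: float = 0.0
    type_probabilities: dict[str, float] = field(
        default_factory=lambda: {
            "job_performance": 37 / 108,
            "personality_looks": 21 / 108,
            "life_threat": 9 / 108,
        }
    )

    # wave-2 outcome models; intercepts calibrated once by simulation so the
    # default configuration yields marginal prevalences near 25% and 37%
    cesd_model: OutcomeModel = field(
        default_factory=lambda: OutcomeModel(
            intercept=-1.36,
            type_log_ors={
                "job_performance": 0.69,
                "personality_looks": 0.41,
                "life_threat": 1.39,
                "other": 0.18,
            },
            baseline_coef=0.08,
        )
    )
    psqi_model: OutcomeModel = field(
        default_factory=lambda: OutcomeModel(
            intercept=-0.72,
            type_log_ors={
                "job_performance": 1.10,
                "personality_looks": 0.30,
                "life_threat": 0.80,
                "other": 0.41,
            },
            baseline_coef=0.15,
        )
    )

    phrase_pools: dict[str, list[str]] = field(
        default_factory=lambda: {k: list(v) for k, v in DEFAULT_PHRASE_POOLS.items()}
    )
    perpetrators: tuple[str, ...] = DEFAULT_PERPETRATORS

    def validate(self) -> None:
        if self.n_baseline < 0:
            raise ConfigError("n_baseline must be non-negative")
        if not (0 < self.follow_up_rate <= 1):
            raise ConfigError("follow_up_rate must be in (0, 1]")
        for name, margin, levels in (
            ("sex_margin", self.sex_margin, SEX_LEVELS),
            ("age_margin", self.age_margin, AGE_LEVELS),
            ("job_margin", self.job_margin, JOB_LEVELS),
        ):
            if len(margin) != len(levels):
                raise ConfigError(f"{name} must have {len(levels)} entries")
            if any(p < 0 for p in margin) or abs(sum(margin) - 1.0) > 1e-9:
                raise ConfigError(f"{name} must be non-negative and sum to 1")
        for name, p in (
            ("married_p", self.married_p),
            ("night_shift_p", self.night_shift_p),
            ("exposure_prevalence", self.exposure_prevalence),
        ):
            if not (0 <= p <= 1):
                raise ConfigError(f"{name} must be in [0, 1]")
        for cat in EXPLICIT_CATEGORIES:
            p = self.type_probabilities.get(cat, 0.0)
            if not (0 <= p <= 1):
                raise ConfigError(f"type probability for {cat!r} must be in [0, 1]")
        if self.exposure_prevalence > 0:
            for cat in EXPLICIT_CATEGORIES:
                if self.type_probabilities.get(cat, 0.0) > 0 and not self.phrase_pools.get(cat):
                    raise ConfigError(f"phrase pool for {cat!r} is empty but its type "
                                      "probability is positive")
            p_none = np.prod(
                [1 - self.type_probabilities.get(c, 0.0) for c in EXPLICIT_CATEGORIES]
            )
            if p_none > 0 and not self.phrase_pools.get("neutral"):
                raise ConfigError(
                    "neutral phrase pool is empty but residual utterances are possible; "
                    "raise the type probabilities or provide neutral phrases"
                )

    # -- YAML round trip -----------------------------------------------------

    def to_yaml(self, path: str | Path) -> None:
        doc = dataclasses.asdict(self)
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(doc, fh, allow_unicode=True, sort_keys=False)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "GeneratorConfig":
        with open(path, encoding="utf-8") as fh:
            doc = yaml.safe_load(fh) or {}
        for key in ("cesd_model", "psqi_model"):
            if key in doc and isinstance(doc[key], dict):
                doc[key] = OutcomeModel(**doc[key])
        for key in ("sex_margin", "age_margin", "job_margin", "perpetrators"):
            if key in doc and isinstance(doc[key], list):
                doc[key] = tuple(doc[key])
        return cls(**doc)


@dataclass
class Wave2:
    exposure_likert: int
    utterance_text: str
    perpetrator: str | None
    cesd_total: int
    psqi_global: int


@dataclass
class ParticipantRecord:
    participant_id: str
    sex: str
    age_class: str
    job_class: str
    night_shift: bool
    marital: bool
    cesd_total_w1: int
    psqi_global_w1: int
    wave2: Wave2 | None
    #: generator bookkeeping; never consumed by analysis code
    truth: dict = field(default_factory=dict, repr=False)


def _truncated_scores(
    rng: np.random.Generator,
    n: int,
    mean: float,
    sd: float,
    low: float,
    high: float,
) -> np.ndarray:
    if n == 0:
        return np.zeros(0, dtype=int)
    a, b = (low - mean) / sd, (high - mean) / sd
    draws = truncnorm.rvs(a, b, loc=mean, scale=sd, size=n, random_state=rng)
    return np.clip(np.rint(draws), low, high).astype(int)


def _conditional_totals(
    rng: np.random.Generator,
    case: np.ndarray,
    cutoff: int,
    maximum: int,
    mean: float,
    sd: float,
) -> np.ndarray:
    """Totals consistent with modelled caseness: >= cutoff for cases, < otherwise."""
    totals = np.zeros(case.size, dtype=int)
    n_case = int(case.sum())
    totals[case] = _truncated_scores(
        rng, n_case, max(mean, cutoff + 0.5 * sd), sd, cutoff, maximum
    )
    totals[~case] = _truncated_scores(
        rng, case.size - n_case, min(mean, cutoff - sd), sd, 0, cutoff - 1
    )
    return totals


def _covariate_offsets(
    model: OutcomeModel,
    sex: np.ndarray,
    age: np.ndarray,
    job: np.ndarray,
    night: np.ndarray,
    married: np.ndarray,
) -> np.ndarray:
    offset = np.zeros(sex.size)
    for name, coef in model.covariate_coefficients.items():
        if name.startswith("sex["):
            offset += coef * (sex == name[4:-1])
        elif name.startswith("age_class["):
            offset += coef * (age == name[10:-1])
        elif name.startswith("job_class["):
            offset += coef * (job == name[10:-1])
        elif name == "night_shift":
            offset += coef * night
        elif name == "marital":
            offset += coef * married
        else:
            raise ConfigError(f"unknown covariate coefficient {name!r}")
    return offset


def generate_cohort(
    config: GeneratorConfig, seed: int | None = None
) -> list[ParticipantRecord]:
    """Generate a fully reproducible two-wave cohort.

    ``seed`` overrides ``config.seed``; a single :class:`numpy.random.Generator`
    drives every draw, so equal seeds give identical cohorts.
    """
    config.validate()
    rng = np.random.default_rng(config.seed if seed is None else seed)
    n = config.n_baseline

    sex = rng.choice(SEX_LEVELS, size=n, p=config.sex_margin)
    age = rng.choice(AGE_LEVELS, size=n, p=config.age_margin)
    job = rng.choice(JOB_LEVELS, size=n, p=config.job_margin)
    night = rng.random(n) < config.night_shift_p
    married = rng.random(n) < config.married_p

    cesd_w1 = _truncated_scores(rng, n, config.cesd_mean, config.cesd_sd, 0, CESD_MAX)
    psqi_w1 = _truncated_scores(rng, n, config.psqi_mean, config.psqi_sd, 0, PSQI_MAX)

    if config.exposure_prevalence == 0:
        exposed = np.zeros(n, dtype=bool)
    elif config.exposure_baseline_coef != 0.0:
        z = (cesd_w1 - config.cesd_mean) / config.cesd_sd
        p_exp = expit(logit(config.exposure_prevalence) + config.exposure_baseline_coef * z)
        exposed = rng.random(n) < p_exp
    else:
        exposed = rng.random(n) < config.exposure_prevalence

    type_flags = {}
    for cat in EXPLICIT_CATEGORIES:
        p = config.type_probabilities.get(cat, 0.0)
        type_flags[cat] = exposed & (rng.random(n) < p)
    any_explicit = np.logical_or.reduce([type_flags[c] for c in EXPLICIT_CATEGORIES])
    type_flags[OTHER] = exposed & ~any_explicit

    likert = np.where(exposed, rng.integers(2, 6, size=n), 1)
    followed = rng.random(n) < config.follow_up_rate

    lps, cases, totals = {}, {}, {}
    for label, model, w1, cutoff, maximum, mean, sd in (
        ("cesd", config.cesd_model, cesd_w1, CESD_CUTOFF, CESD_MAX,
         config.cesd_mean, config.cesd_sd),
        ("psqi", config.psqi_model, psqi_w1, PSQI_CUTOFF, PSQI_MAX,
         config.psqi_mean, config.psqi_sd),
    ):
        lp = np.full(n, model.intercept)
        for cat in ALL_CATEGORIES:
            lp += model.type_log_ors.get(cat, 0.0) * type_flags[cat]
        lp += model.baseline_coef * (w1 - mean)
        lp += _covariate_offsets(model, sex, age, job, night, married)
        lps[label] = lp
        cases[label] = rng.random(n) < expit(lp)
        totals[label] = _conditional_totals(rng, cases[label], cutoff, maximum, mean, sd)

    records: list[ParticipantRecord] = []
    width = max(4, len(str(max(n, 1))))
    for i in range(n):
        truth = {
            "exposed": bool(exposed[i]),
            "flags": {cat: bool(type_flags[cat][i]) for cat in ALL_CATEGORIES},
            "lp_cesd": float(lps["cesd"][i]),
            "lp_psqi": float(lps["psqi"][i]),
            "cesd_case_w2": bool(cases["cesd"][i]),
            "psqi_case_w2": bool(cases["psqi"][i]),
        }
        wave2 = None
        if followed[i]:
            if exposed[i]:
                phrases = []
                for cat in EXPLICIT_CATEGORIES:
                    if type_flags[cat][i]:
                        phrases.append(str(rng.choice(config.phrase_pools[cat])))
                if not phrases:
                    phrases.append(str(rng.choice(config.phrase_pools["neutral"])))
                text = " ".join(phrases)
                perpetrator = str(rng.choice(config.perpetrators)) if config.perpetrators else None
            else:
                text, perpetrator = "", None
            wave2 = Wave2(
                exposure_likert=int(likert[i]),
                utterance_text=text,
                perpetrator=perpetrator,
                cesd_total=int(totals["cesd"][i]),
                psqi_global=int(totals["psqi"][i]),
            )
        records.append(
            ParticipantRecord(
                participant_id=f"P{i + 1:0{width}d}",
                sex=str(sex[i]),
                age_class=str(age[i]),
                job_class=str(job[i]),
                night_shift=bool(night[i]),
                marital=bool(married[i]),
                cesd_total_w1=int(cesd_w1[i]),
                psqi_global_w1=int(psqi_w1[i]),
                wave2=wave2,
                truth=truth,
            )
        )
    return records


def cohort_to_frame(records: Iterable[ParticipantRecord]) -> pd.DataFrame:
    """Flatten records to the pipeline's cohort CSV schema (truth excluded)."""
    rows = []
    for r in records:
        row = {
            "participant_id": r.participant_id,
            "sex": r.sex,
            "age_class": r.age_class,
            "job_class": r.job_class,
            "night_shift": int(r.night_shift),
            "marital": int(r.marital),
            "cesd_total_w1": r.cesd_total_w1,
            "psqi_global_w1": r.psqi_global_w1,
            "followed_up": int(r.wave2 is not None),
            "exposure_likert": r.wave2.exposure_likert if r.wave2 else "",
            "utterance_text": r.wave2.utterance_text if r.wave2 else "",
            "perpetrator": (r.wave2.perpetrator or "") if r.wave2 else "",
            "cesd_total_w2": r.wave2.cesd_total if r.wave2 else "",
            "psqi_global_w2": r.wave2.psqi_global if r.wave2 else "",
        }
        rows.append(row)
    return pd.DataFrame(rows)


def truth_to_frame(records: Iterable[ParticipantRecord]) -> pd.DataFrame:
    rows = []
    for r in records:
        if not r.truth:
            raise ValueError(f"record {r.participant_id} lacks truth bookkeeping")
        row = {"participant_id": r.participant_id, "exposed": int(r.truth["exposed"])}
        for cat in ALL_CATEGORIES:
            row[f"flag_{cat}"] = int(r.truth["flags"][cat])
        row["lp_cesd"] = r.truth["lp_cesd"]
        row["lp_psqi"] = r.truth["lp_psqi"]
        row["cesd_case_w2"] = int(r.truth["cesd_case_w2"])
        row["psqi_case_w2"] = int(r.truth["psqi_case_w2"])
        rows.append(row)
    return pd.DataFrame(rows)


def truth_report(records: Sequence[ParticipantRecord]) -> dict:
    """Generator bookkeeping aggregates for oracle comparisons in tests.

    Counts cover wave-2 completers only, matching the analysis set.
    """
    for r in records:
        if not r.truth:
            raise ValueError(f"record {r.participant_id} lacks truth bookkeeping")
    completers = [r for r in records if r.wave2 is not None]
    exposed = [r for r in completers if r.truth["exposed"]]
    flag_counts = {
        cat: sum(r.truth["flags"][cat] for r in exposed) for cat in ALL_CATEGORIES
    }
    cells = {}
    for outcome in ("cesd", "psqi"):
        case_key = f"{outcome}_case_w2"
        for definition in ("overall",) + ALL_CATEGORIES:
            a = b = c = d = 0
            for r in completers:
                exp = (
                    r.truth["exposed"] if definition == "overall"
                    else r.truth["flags"][definition]
                )
                case = r.truth[case_key]
                if exp and case:
                    a += 1
                elif exp:
                    b += 1
                elif case:
                    c += 1
                else:
                    d += 1
            cells[(definition, outcome)] = (a, b, c, d)
    return {
        "n_baseline": len(records),
        "n_completers": len(completers),
        "n_exposed": len(exposed),
        "flag_counts": flag_counts,
        "cells": cells,
    }
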