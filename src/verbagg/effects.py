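"""Crude effect estimation: 2x2 tables, odds ratios, Woolf intervals, Wald p.

The crude odds ratio is the cross-product ad/bc.  Its confidence interval is
the Woolf interval exp(ln OR +/- z * sqrt(1/a + 1/b + 1/c + 1/d)), and the
p-value is the two-sided Wald test of ln OR against the standard normal.
A Haldane-Anscombe 0.5 correction for zero cells is available but off by
default.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

from scipy.stats import norm

from .lexicon import ALL_CATEGORIES, EXPLICIT_CATEGORIES, OTHER, UtteranceFlags

#: Default normal quantile for 95% two-sided intervals.
Z_95 = 1.959964

OVERALL = "overall"
#: Exposure definitions reported by the crude battery, in output order.
EXPOSURE_DEFINITIONS: tuple[str, ...] = (OVERALL,) + ALL_CATEGORIES


class EstimationError(ValueError):
    """Raised when an estimate cannot be computed from the given cells."""


@dataclass(frozen=True)
class ContingencyTable:
    """2x2 exposure-by-outcome cell counts.

    a: exposed cases, b: exposed non-cases, c: unexposed cases,
    d: unexposed non-cases.
    """

    a: int
    b: int
    c: int
    d: int
    exposure_label: str = ""
    outcome_label: str = ""

    def __post_init__(self) -> None:
        for name in "abcd":
            if getattr(self, name) < 0:
                raise ValueError(f"cell {name} is negative")

    @property
    def n(self) -> int:
        return self.a + self.b + self.c + self.d

    @property
    def exposed(self) -> int:
        return self.a + self.b

    @property
    def cases(self) -> int:
        return self.a + self.c

    @classmethod
    def from_margins(
        cls,
        exposed_cases: int,
        exposed_noncases: int,
        total_cases: int,
        total_n: int,
        exposure_label: str = "",
        outcome_label: str = "",
    ) -> "ContingencyTable":
        """Build the table from the exposed cells plus the study margins."""
        c = total_cases - exposed_cases
        d = total_n - total_cases - exposed_noncases
        if c < 0 or d < 0:
            raise ValueError("margins inconsistent with exposed cells")
        return cls(exposed_cases, exposed_noncases, c, d, exposure_label, outcome_label)

    def transposed(self) -> "ContingencyTable":
        """Swap the exposed and unexposed rows."""
        return replace(self, a=self.c, b=self.d, c=self.a, d=self.b)


def build_2x2(
    exposed: Sequence[bool],
    case: Sequence[bool],
    exposure_label: str = "",
    outcome_label: str = "",
) -> ContingencyTable:
    """Cross-tabulate two aligned per-participant boolean vectors."""
    if len(exposed) != len(case):
        raise EstimationError(
            f"length mismatch: {len(exposed)} exposure values vs {len(case)} outcomes"
        )
    a = b = c = d = 0
    for e, k in zip(exposed, case):
        if e and k:
            a += 1
        elif e:
            b += 1
        elif k:
            c += 1
        else:
            d += 1
    return ContingencyTable(a, b, c, d, exposure_label, outcome_label)


@dataclass(frozen=True)
class EffectEstimate:
    odds_ratio: float
    ci_low: float
    ci_high: float
    log_or_se: float
    p_value: float
    method: str  # "crude_woolf" | "adjusted_wald"
    correction_applied: bool = False
    exposure_label: str = ""
    outcome_label: str = ""
    table: ContingencyTable | None = field(default=None, repr=False)

    def to_dict(self) -> dict:
        row = {
            "exposure": self.exposure_label,
            "outcome": self.outcome_label,
            "or": self.odds_ratio,
            "ci_low": self.ci_low,
            "ci_high": self.ci_high,
            "log_or_se": self.log_or_se,
            "p": self.p_value,
            "method": self.method,
            "correction_applied": self.correction_applied,
        }
        if self.table is not None:
            row.update(
                n=self.table.n, a=self.table.a, b=self.table.b,
                c=self.table.c, d=self.table.d,
            )
        return row


def wald_estimate(
    log_or: float,
    log_or_se: float,
    z: float = Z_95,
    method: str = "adjusted_wald",
    **labels,
) -> EffectEstimate:
    """Turn a log-OR and its SE into an OR with CI and two-sided p-value."""
    p = 2.0 * norm.sf(abs(log_or) / log_or_se)
    return EffectEstimate(
        odds_ratio=math.exp(log_or),
        ci_low=math.exp(log_or - z * log_or_se),
        ci_high=math.exp(log_or + z * log_or_se),
        log_or_se=log_or_se,
        p_value=float(p),
        method=method,
        **labels,
    )


def crude_or(
    table: ContingencyTable,
    z: float = Z_95,
    zero_cell_correction: bool = False,
) -> EffectEstimate:
    """Crude odds ratio with Woolf confidence interval and Wald p-value."""
    cells = {"a": table.a, "b": table.b, "c": table.c, "d": table.d}
    corrected = False
    values = cells
    if any(v == 0 for v in cells.values()):
        if not zero_cell_correction:
            zero = next(k for k, v in cells.items() if v == 0)
            raise EstimationError(
                f"cell {zero!r} is zero in table "
                f"({table.exposure_label or '?'} x {table.outcome_label or '?'}); "
                "enable zero_cell_correction to apply the 0.5 adjustment"
            )
        values = {k: v + 0.5 for k, v in cells.items()}
        corrected = True
    a, b, c, d = values["a"], values["b"], values["c"], values["d"]
    log_or = math.log(a * d / (b * c))
    se = math.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    est = wald_estimate(
        log_or, se, z=z, method="crude_woolf",
        exposure_label=table.exposure_label, outcome_label=table.outcome_label,
    )
    return replace(est, correction_applied=corrected, table=table)


def run_crude_battery(
    exposed: Mapping[str, bool],
    flags: Mapping[str, UtteranceFlags],
    outcomes: Mapping[str, Mapping[str, bool]],
    z: float = Z_95,
    zero_cell_correction: bool = False,
) -> list[EffectEstimate]:
    """One crude estimate per (exposure definition x outcome).

    ``exposed`` maps participant id -> overall exposure; ``flags`` holds the
    classification for exposed participants; ``outcomes`` maps outcome label ->
    participant id -> caseness.  For a category exposure the reference group is
    every other participant (including the unexposed), which is what the study
    tabulation implies.
    """
    if not exposed:
        raise EstimationError("empty cohort")
    pids = sorted(exposed)
    estimates = []
    for definition in EXPOSURE_DEFINITIONS:
        if definition == OVERALL:
            vector = [bool(exposed[pid]) for pid in pids]
        else:
            vector = [
                pid in flags and flags[pid].flags[definition] for pid in pids
            ]
        for outcome_label, case_map in outcomes.items():
            case_vector = [bool(case_map[pid]) for pid in pids]
            table = build_2x2(vector, case_vector, definition, outcome_label)
            estimates.append(crude_or(table, z=z, zero_cell_correction=zero_cell_correction))
    return estimates
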