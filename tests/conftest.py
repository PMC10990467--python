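from __future__ import annotations

from pathlib import Path

import pytest

from verbagg.lexicon import default_lexicon

FIXTURES = Path(__file__).parent / "fixtures"

# Published exposed-cell counts per (exposure definition, outcome), with the
# analysis-set margins: 500 participants, 125 depression cases, 186 poor-sleep
# cases.  Keys: definition -> (exposed_cases, exposed_noncases).
N_TOTAL = 500
CESD_CASES = 125
PSQI_CASES = 186

CESD_CELLS = {
    "overall": (44, 64),
    "job_performance": (20, 17),
    "personality_looks": (10, 11),
    "life_threat": (7, 2),
    "other": (24, 48),
}
PSQI_CELLS = {
    "overall": (64, 44),
    "job_performance": (27, 10),
    "personality_looks": (12, 9),
    "life_threat": (6, 3),
    "other": (42, 30),
}

# Printed crude odds ratios (2-decimal) for the same grid.
PRINTED_CRUDE_OR = {
    ("overall", "cesd"): 2.64,
    ("job_performance", "cesd"): 4.01,
    ("personality_looks", "cesd"): 2.88,
    ("life_threat", "cesd"): 11.06,
    ("other", "cesd"): 1.62,
    ("overall", "psqi"): 3.22,
    ("job_performance", "psqi"): 5.16,
    ("personality_looks", "psqi"): 2.34,
    ("life_threat", "psqi"): 3.46,
    ("other", "psqi"): 2.76,
}

# Printed 95% CI bounds; the overall/cesd interval is excluded (typographical
# duplication of the overall/psqi interval in the source table).
PRINTED_CRUDE_CI = {
    ("overall", "psqi"): (2.07, 5.00),
    ("job_performance", "cesd"): (2.03, 7.93),
    ("job_performance", "psqi"): (2.44, 10.93),
    ("personality_looks", "cesd"): (1.19, 6.95),
    ("personality_looks", "psqi"): (0.97, 5.66),
    ("life_threat", "cesd"): (2.27, 53.98),
    ("life_threat", "psqi"): (0.85, 13.99),
    ("other", "cesd"): (0.94, 2.77),
    ("other", "psqi"): (1.66, 4.60),
}

# Printed p-values at their printed precision.
PRINTED_P = {
    ("personality_looks", "cesd"): ("%.3f", 0.019),
    ("personality_looks", "psqi"): ("%.3f", 0.060),
    ("life_threat", "cesd"): ("%.3f", 0.003),
    ("other", "cesd"): ("%.2f", 0.08),
    ("life_threat", "psqi"): ("%.3f", 0.082),
}


def paper_cells(definition: str, outcome: str) -> tuple[int, int, int, int]:
    """Full 2x2 cells from the exposed cells and the study margins."""
    cells = CESD_CELLS if outcome == "cesd" else PSQI_CELLS
    total_cases = CESD_CASES if outcome == "cesd" else PSQI_CASES
    a, b = cells[definition]
    return a, b, total_cases - a, N_TOTAL - total_cases - b


@pytest.fixture(scope="session")
def lexicon():
    return default_lexicon()


@pytest.fixture(scope="session")
def example_sentences_path() -> Path:
    return FIXTURES / "example_sentences.csv"
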