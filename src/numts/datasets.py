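"""Published per-species summary inputs for the 11 Drosophila genomes.

These printed tables are inputs to the statistical summaries (correlation
of genome size with numt content, genus averages, rearrangement totals);
they are not outputs of this package. Genome sizes are assembly sizes in
Mb with repeat fractions in parentheses in the source; average numt length
excludes internal duplications and interrupting sequence.
"""

from __future__ import annotations

import pandas as pd

from .tree import RECENT_BRANCH_LABELS, drosophila_tree  # noqa: F401 (re-export)

SPECIES_ORDER = [
    "D_melanogaster",
    "D_simulans",
    "D_sechellia",
    "D_yakuba",
    "D_erecta",
    "D_ananassae",
    "D_persimilis",
    "D_willistoni",
    "D_mojavensis",
    "D_virilis",
    "D_grimshawi",
]


def species_numt_table() -> pd.DataFrame:
    """Genome size (Mb), repeat fraction (%), numt counts, average numt
    length (bp) and total numt content (bp) per species."""
    data = {
        "genome_size_mb": [118, 111, 115, 127, 134, 176, 138, 187, 172, 161, 138],
        "repeat_pct": [5.35, 2.73, 3.67, 12.04, 6.97, 24.93, 8.47, 15.57, 13.96, 8.92, 2.84],
        "n_numts": [4, 5, 25, 9, 20, 26, 54, 67, 24, 59, 9],
        "avg_length_bp": [210, 700, 1502, 1497, 1255, 1537, 1335, 900, 3029, 2506, 2075],
        "total_numt_bp": [838, 3501, 37553, 13471, 25103, 39952, 72107, 60284, 72689, 147862, 18673],
    }
    return pd.DataFrame(data, index=SPECIES_ORDER)


def rearrangement_event_table() -> pd.DataFrame:
    """Gross rearrangement events per species: "events (affected numts)"
    split into separate columns; '-' cells are zeros."""
    rows = {
        #                 interruptions  deletions  inversions  duplications
        "D_melanogaster": (0, 0, 0, 0, 0, 0, 0, 0),
        "D_simulans": (0, 0, 0, 0, 0, 0, 0, 0),
        "D_sechellia": (2, 2, 1, 1, 1, 1, 0, 0),
        "D_yakuba": (4, 2, 5, 3, 0, 0, 1, 1),
        "D_erecta": (0, 0, 4, 2, 0, 0, 0, 0),
        "D_ananassae": (5, 5, 0, 0, 0, 0, 0, 0),
        "D_persimilis": (0, 0, 5, 4, 2, 2, 1, 1),
        "D_willistoni": (21, 8, 12, 7, 1, 1, 4, 4),
        "D_mojavensis": (12, 6, 4, 3, 0, 0, 3, 3),
        "D_virilis": (15, 8, 16, 11, 2, 2, 9, 5),
        "D_grimshawi": (0, 0, 1, 1, 0, 0, 0, 0),
    }
    cols = [
        "interruptions", "interruptions_numts",
        "deletions", "deletions_numts",
        "inversions", "inversions_numts",
        "duplications", "duplications_numts",
    ]
    return pd.DataFrame.from_dict(rows, orient="index", columns=cols).loc[SPECIES_ORDER]


def branch_insertion_rate_table() -> pd.Series:
    """Published per-terminal-branch insertion rates (insertions/My)."""
    rates = {
        "D_melanogaster": 0.12,
        "D_simulans": 0.23,
        "D_sechellia": 1.92,
        "D_yakuba": 0.45,
        "D_erecta": 0.75,
        "D_ananassae": 0.47,
        "D_persimilis": 0.66,
        "D_willistoni": 0.80,
        "D_mojavensis": 0.66,
        "D_virilis": 1.71,
        "D_grimshawi": 0.14,
    }
    return pd.Series(rates, name="insertion_rate")


# Printed headline counts used by the summary statistics.
TOTAL_NUMTS = 302
REARRANGED_NUMTS = 79
PARALOGOUS_NUMTS = 93
PARALOG_SETS = 26
TERMINAL_INSERTION_MASS = 238.7
INTERNAL_INSERTION_MASS = 27.3
INTRONIC_NUMTS = 24
REPEAT_ADJACENT_NUMTS = 92
REPEAT_TESTED_NUMTS = 233
FLANK_EXCLUDED_NUMTS = 69
GENOME_REPEAT_FRACTION = 0.15
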