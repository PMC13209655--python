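"""COG functional-category profiling and percentage-point comparison.

Proteins may carry several single-letter COG categories ("EG"); each letter
is counted independently ("expanded").  Unassigned entries ("-", empty) and
category S are merged into one "unknown function" bucket.  Counts are
normalized to the total number of expanded assignments per genome and
expressed as percentages, and a focal genome is compared against each
comparator and the comparator mean as percentage-point differences.
"""

from __future__ import annotations

import warnings
from collections import Counter
from dataclasses import dataclass

import pandas as pd

# R (general function prediction only) stays distinct by default; only S and
# unassigned entries fold into the unknown bucket.
COG_LETTERS = "JAKLBDYVTMNZWUOCGEFHIPQR"
UNKNOWN = "unknown"


@dataclass
class COGProfile:
    genome_id: str
    counts: dict               # letter (or "unknown") -> expanded count
    total_expanded: int

    @property
    def percents(self) -> dict:
        return {k: 100.0 * v / self.total_expanded for k, v in self.counts.items()}


def expand(assignments, merge_r: bool = False) -> Counter:
    """Expanded letter counts of multi-letter COG assignment strings.

    "EG" adds one to E and one to G.  "S", "-", empty and missing values
    accrue to the unknown bucket (so does R when ``merge_r``); an
    unrecognized letter triggers a warning and also lands in unknown.
    """
    counts: Counter = Counter()
    for assignment in assignments:
        text = "" if assignment is None or assignment != assignment else str(assignment)
        text = text.strip()
        if text in ("", "-"):
            counts[UNKNOWN] += 1
            continue
        for letter in text:
            if letter == "S" or (merge_r and letter == "R"):
                counts[UNKNOWN] += 1
            elif letter in COG_LETTERS:
                counts[letter] += 1
            else:
                warnings.warn(f"unrecognized COG letter {letter!r}; "
                              "counted as unknown", stacklevel=2)
                counts[UNKNOWN] += 1
    return counts


def profile(genome_id: str, assignments, merge_r: bool = False) -> COGProfile:
    counts = expand(assignments, merge_r=merge_r)
    total = sum(counts.values())
    if total == 0:
        raise ValueError(f"{genome_id}: no COG assignments to profile")
    return COGProfile(genome_id=genome_id, counts=dict(counts),
                      total_expanded=total)


def diff_profiles(focal: COGProfile, comparators: list) -> pd.DataFrame:
    """Per-letter focal vs comparator percentages and pp differences.

    ``pp_difference`` is the focal percentage minus the comparator mean
    percentage, kept at full precision; report-time rounding shows both the
    full-precision difference and the difference of 2-decimal rounded
    percentages (they can disagree in the last digit).
    """
    if not comparators:
        raise ValueError("need at least one comparator profile")
    letters = [*COG_LETTERS, UNKNOWN]
    fp = focal.percents
    rows = []
    for letter in letters:
        f = fp.get(letter, 0.0)
        comps = {c.genome_id: c.percents.get(letter, 0.0) for c in comparators}
        mean = sum(comps.values()) / len(comps)
        rows.append({
            "category": letter,
            "focal_pct": f,
            **{f"{gid}_pct": v for gid, v in comps.items()},
            "comparator_mean_pct": mean,
            "pp_difference": f - mean,
            "pp_difference_rounded": round(round(f, 2) - round(mean, 2), 2),
        })
    return pd.DataFrame(rows)


def read_assignments(path: str, query_col: str = "query",
                     category_col: str = "COG_category") -> list:
    """COG category strings from an eggNOG-mapper style TSV."""
    df = pd.read_csv(path, sep="\t", comment="#")
    if category_col not in df.columns:
        raise ValueError(f"column {category_col!r} not found in {path}")
    return df[category_col].tolist()
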