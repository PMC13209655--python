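"""Mobile-genetic-element profiling and Poisson rate-ratio comparison.

Annotation product strings are screened case-insensitively against keyword
lists for five MGE classes (transposase, integrase, phage-related,
recombinase, repeat protein).  Each feature is assigned to at most one
class by a precedence order, so category counts never double-count.

Per-genome counts are compared between a focal genome and a comparator
group with a Poisson log-linear model using log effective genome size as
the exposure offset.  For that two-group model the maximum-likelihood rate
ratio has the closed form

    RR = (y_f / s_f) / (sum y_c / sum s_c),
    SE(log RR) = sqrt(1/y_f + 1/sum y_c),

with Wald 95% intervals exp(log RR +/- 1.96 SE) and a two-sided normal
p-value; zero counts get a 0.5 continuity correction and a flag.  The
repeat class is reported descriptively only, never inferentially, because
repeat-domain annotations are functionally heterogeneous.
"""

from __future__ import annotations

import re
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

MGE_CATEGORIES = ("transposase", "integrase", "phage", "recombinase", "repeat")
INFERENTIAL_CATEGORIES = ("transposase", "integrase", "phage", "recombinase")

DEFAULT_KEYWORDS = {
    "transposase": ["transposase", "insertion sequence", "IS family"],
    "integrase": ["integrase"],
    "phage": ["phage", "prophage", "capsid", "terminase", "portal",
              "tail protein"],
    "recombinase": ["recombinase", "resolvase", "site-specific recombination"],
    "repeat": ["repeat"],
}
# most specific mobile function first
DEFAULT_PRECEDENCE = ("transposase", "integrase", "phage", "recombinase",
                      "repeat")


@dataclass
class RateRatioResult:
    category: str
    rate_ratio: float
    ci_low: float
    ci_high: float
    p_value: float
    se_log: float
    dispersion: float | None = None
    flagged: bool = False


def categorize(records: pd.DataFrame, keyword_map: dict | None = None,
               precedence: tuple | None = None) -> pd.DataFrame:
    """Label each record with its first matching MGE category, or None.

    ``records`` needs a ``product`` column; matching is case-insensitive
    substring search, and the first category in ``precedence`` whose
    keywords match wins (primary-assignment rule: one category per record).
    """
    keyword_map = DEFAULT_KEYWORDS if keyword_map is None else keyword_map
    precedence = tuple(keyword_map) if precedence is None else precedence
    patterns = {
        cat: re.compile("|".join(re.escape(k.lower()) for k in keyword_map[cat]))
        for cat in precedence
    }

    def label(product) -> str | None:
        text = ("" if product is None or product != product else str(product)).lower()
        for cat in precedence:
            if patterns[cat].search(text):
                return cat
        return None

    out = records.copy()
    out["category"] = [label(p) for p in out["product"]]
    return out


def count_table(records: pd.DataFrame, sizes: dict,
                categories: tuple = MGE_CATEGORIES) -> pd.DataFrame:
    """Per-genome category counts with zero-filled categories and sizes.

    ``records`` must already carry a ``category`` column (see
    :func:`categorize`).  A ``replicon`` column, if present, is carried
    through as ``replicon_class`` so plasmid-scale rows can be kept out of
    chromosome-scale comparisons.
    """
    genomes = list(dict.fromkeys(records["genome_id"]))
    missing = [g for g in genomes if g not in sizes]
    if missing:
        raise KeyError(f"no effective genome size for: {', '.join(missing)}")
    rows = []
    for genome, grp in records.groupby("genome_id", sort=False):
        counts = grp["category"].value_counts()
        row = {"genome_id": genome}
        for cat in categories:
            row[cat] = int(counts.get(cat, 0))
        row["size_bp"] = sizes[genome]
        if "replicon" in grp.columns:
            kinds = set(grp["replicon"])
            row["replicon_class"] = kinds.pop() if len(kinds) == 1 else "mixed"
        rows.append(row)
    if not rows:  # empty record list -> all-zero table for known genomes
        rows = [{"genome_id": g, **{c: 0 for c in categories},
                 "size_bp": sizes[g]} for g in sizes]
    return pd.DataFrame(rows)


def poisson_rate_ratio(y_f: int, size_f: float, y_c, sizes_c,
                       category: str = "") -> RateRatioResult:
    """Two-group Poisson rate ratio with a log genome-size offset.

    The closed form is the exact MLE of the log-linear model with a focal
    indicator.  Degenerate zero counts are continuity-corrected by 0.5 and
    flagged rather than raised.
    """
    y_c = np.asarray(y_c, dtype=float)
    sizes_c = np.asarray(sizes_c, dtype=float)
    if size_f <= 0 or np.any(sizes_c <= 0):
        raise ValueError("genome sizes must be positive")
    if y_f < 0 or np.any(y_c < 0):
        raise ValueError("counts must be non-negative")
    yf, yc = float(y_f), float(y_c.sum())
    sc = float(sizes_c.sum())
    flagged = yf == 0 or yc == 0
    if flagged:
        yf += 0.5
        yc += 0.5
    rr = (yf / size_f) / (yc / sc)
    se = float(np.sqrt(1 / yf + 1 / yc))
    log_rr = float(np.log(rr))
    z = log_rr / se
    return RateRatioResult(
        category=category,
        rate_ratio=rr,
        ci_low=float(np.exp(log_rr - 1.959963984540054 * se)),
        ci_high=float(np.exp(log_rr + 1.959963984540054 * se)),
        p_value=float(2 * stats.norm.sf(abs(z))),
        se_log=se,
        dispersion=overdispersion(y_c, sizes_c),
        flagged=flagged,
    )


def overdispersion(y_c, sizes_c) -> float | None:
    """Pearson chi-square / df of comparator counts under a common rate.

    Returns None when fewer than two comparators are available.
    """
    y_c = np.asarray(y_c, dtype=float)
    sizes_c = np.asarray(sizes_c, dtype=float)
    n = len(y_c)
    if n < 2:
        return None
    lam = y_c.sum() / sizes_c.sum()
    mu = lam * sizes_c
    if np.any(mu == 0):
        return None
    return float(((y_c - mu) ** 2 / mu).sum() / (n - 1))


def rate_ratio_table(counts: pd.DataFrame, focal: str,
                     categories: tuple = INFERENTIAL_CATEGORIES) -> pd.DataFrame:
    """Focal-vs-comparators rate ratios per inferential MGE category.

    Plasmid-class rows (``replicon_class == 'plasmid'``) are never pooled
    into these chromosome/genome-scale comparisons; the repeat class is
    excluded from inference by default.
    """
    df = counts
    if "replicon_class" in df.columns:
        df = df[df["replicon_class"] != "plasmid"]
    focal_rows = df[df["genome_id"] == focal]
    if len(focal_rows) != 1:
        raise ValueError(f"expected exactly one chromosome-scale row for {focal!r}")
    comp = df[df["genome_id"] != focal]
    if comp.empty:
        raise ValueError("no comparator genomes")
    frow = focal_rows.iloc[0]
    out = []
    for cat in categories:
        res = poisson_rate_ratio(
            int(frow[cat]), float(frow["size_bp"]),
            comp[cat].to_numpy(), comp["size_bp"].to_numpy(), category=cat,
        )
        out.append(vars(res))
    return pd.DataFrame(out)
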