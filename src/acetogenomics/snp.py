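"""Codon-level SNP consequences from per-gene ortholog alignments.

Orthologous CDS panels aligned against a designated reference strain are
scanned column-by-column for single-nucleotide differences.  Each variant
codon (the reference codon with all of that strain's substitutions applied
jointly) is classified as synonymous, nonsynonymous, nonsense (sense to
stop) or stop-loss (stop to sense) under the bacterial genetic code
(translation table 11).  Per (gene, strain) metrics follow:

* SNPs/nt  = SNP count / number of assessable (ungapped, unambiguous) sites
* Ti/Tv    = transitions / transversions (undefined when no transversions)
* nonsynonymous fraction = nonsynonymous / (synonymous + nonsynonymous +
  nonsense + stop-loss), counted over variable codons

and are summarized per resilience mechanism and isolation-source lineage.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from Bio.Data import CodonTable

_TABLE11 = CodonTable.unambiguous_dna_by_id[11]
BASES = frozenset("ACGT")
CONSEQUENCE_CLASSES = ("synonymous", "nonsynonymous", "nonsense", "stop_loss")

# Mechanism-representative gene panel for the acetic-acid resilience layers.
DEFAULT_MECHANISM_MAP = {
    "acsA": "acetate_metabolism", "ackA": "acetate_metabolism",
    "pta": "acetate_metabolism", "aarC": "acetate_metabolism",
    "mqo": "acetate_metabolism", "acnA": "acetate_metabolism",
    "oprM_1": "efflux_transport",
    "groEL": "chaperone_stress", "dnaK": "chaperone_stress",
    "srpA": "ros_detox",
}

# Isolation-source lineages of the eight strains; the focal vinegar isolate
# is the reference and belongs to no group.
DEFAULT_LINEAGE_MAP = {
    "LMG1625": "Beer", "LMG1608": "Beer", "R-82820": "Beer",
    "R-82821": "Beer", "R-82823": "Beer", "R-83281": "Beer",
    "LMG1545": "Vinegar",
}


class FrameshiftError(ValueError):
    """Reference row carries an internal gap run not divisible by three."""


@dataclass
class OrthologPanel:
    """Per-gene multiple alignment of CDSs with a designated reference row."""

    gene_id: str
    alignment: dict            # strain -> aligned sequence (gapped, upper)
    reference: str             # strain id of the reference row
    mechanism: str = "other"

    def __post_init__(self) -> None:
        self.alignment = {k: v.upper() for k, v in self.alignment.items()}
        lengths = {len(v) for v in self.alignment.values()}
        if len(lengths) != 1:
            raise ValueError(f"{self.gene_id}: aligned rows differ in length")
        if self.reference not in self.alignment:
            raise ValueError(f"{self.gene_id}: reference {self.reference!r} missing")

    @property
    def strains(self) -> list:
        return [s for s in self.alignment if s != self.reference]

    @property
    def width(self) -> int:
        return len(self.alignment[self.reference])


@dataclass
class SNPRecord:
    gene_id: str
    strain: str
    ref_pos: int               # 1-based ungapped reference CDS coordinate
    ref_base: str
    alt_base: str
    codon_index: int           # 1-based
    consequence: str
    transition: bool


@dataclass
class VariationMetrics:
    gene_id: str
    strain: str
    snps_per_nt: float
    titv: float | None
    nonsyn_fraction: float | None
    counts: dict = field(default_factory=dict)
    n_snps: int = 0
    compared_sites: int = 0


def translate_codon(codon: str) -> str:
    """Amino acid (one letter) or '*' for a stop, bacterial table 11."""
    if codon in _TABLE11.stop_codons:
        return "*"
    return _TABLE11.forward_table[codon]


def classify_consequence(ref_codon: str, alt_codon: str) -> str:
    """Codon-substitution class under translation table 11.

    stop->stop counts as synonymous; any ambiguity code raises ValueError
    (callers flag such codons rather than classifying them).
    """
    ref_codon, alt_codon = ref_codon.upper(), alt_codon.upper()
    for codon in (ref_codon, alt_codon):
        if len(codon) != 3 or any(b not in BASES for b in codon):
            raise ValueError(f"unclassifiable codon {codon!r}")
    ref_aa, alt_aa = translate_codon(ref_codon), translate_codon(alt_codon)
    if ref_aa == alt_aa:
        return "synonymous"
    if alt_aa == "*":
        return "nonsense"
    if ref_aa == "*":
        return "stop_loss"
    return "nonsynonymous"


def is_transition(ref_base: str, alt_base: str) -> bool:
    return {ref_base, alt_base} in ({"A", "G"}, {"C", "T"})


# ---------------------------------------------------------------------------
# frame trimming and SNP calling
# ---------------------------------------------------------------------------

def trim_to_frame(panel: OrthologPanel) -> OrthologPanel:
    """Trim 3' columns so the ungapped reference length is a codon multiple.

    Internal reference gap runs whose length is not divisible by three shift
    the frame mid-gene; such genes are flagged via :class:`FrameshiftError`
    and should be excluded from codon-level analysis.
    """
    ref = panel.alignment[panel.reference]
    run = 0
    for ch in ref.strip("-"):
        if ch == "-":
            run += 1
        elif run:
            if run % 3:
                raise FrameshiftError(
                    f"{panel.gene_id}: internal reference gap of {run} nt"
                )
            run = 0
    ungapped = sum(1 for ch in ref if ch != "-")
    excess = ungapped % 3
    if excess == 0:
        return panel
    # walk back from the 3' end until `excess` reference bases are dropped
    cut = len(ref)
    dropped = 0
    while dropped < excess:
        cut -= 1
        if ref[cut] != "-":
            dropped += 1
    return OrthologPanel(
        gene_id=panel.gene_id,
        alignment={s: row[:cut] for s, row in panel.alignment.items()},
        reference=panel.reference,
        mechanism=panel.mechanism,
    )


def call_snps(panel: OrthologPanel):
    """Call per-strain SNPs against the reference row of a trimmed panel.

    Returns ``(records, compared_sites)`` where ``compared_sites`` maps each
    non-reference strain to its count of assessable columns (both rows in
    {A,C,G,T}).  Columns with a gap or ambiguity code in either row are
    skipped.  Consequences are classified per variable codon with all of the
    strain's substitutions in that codon applied jointly.
    """
    ref = panel.alignment[panel.reference]
    # ungapped reference coordinate per column (1-based; 0 where ref gapped)
    ref_pos = np.zeros(len(ref), dtype=int)
    pos = 0
    for i, ch in enumerate(ref):
        if ch != "-":
            pos += 1
            ref_pos[i] = pos
    ref_cds = ref.replace("-", "")
    records: list = []
    compared: dict = {}
    for strain in panel.strains:
        row = panel.alignment[strain]
        diffs: dict = {}      # ref position -> alt base
        n_compared = 0
        for i, (rb, ab) in enumerate(zip(ref, row)):
            if rb in BASES and ab in BASES:
                n_compared += 1
                if rb != ab:
                    diffs[int(ref_pos[i])] = ab
        compared[strain] = n_compared
        by_codon: dict = {}
        for p in diffs:
            by_codon.setdefault((p - 1) // 3, []).append(p)
        for codon_i, positions in sorted(by_codon.items()):
            ref_codon = ref_cds[codon_i * 3 : codon_i * 3 + 3]
            alt_codon = list(ref_codon)
            for p in positions:
                alt_codon[(p - 1) % 3] = diffs[p]
            consequence = classify_consequence(ref_codon, "".join(alt_codon))
            for p in sorted(positions):
                rb = ref_cds[p - 1]
                records.append(
                    SNPRecord(
                        gene_id=panel.gene_id, strain=strain, ref_pos=p,
                        ref_base=rb, alt_base=diffs[p],
                        codon_index=codon_i + 1, consequence=consequence,
                        transition=is_transition(rb, diffs[p]),
                    )
                )
    return records, compared


def metrics(records: list, gene_id: str, strain: str,
            compared_sites: int) -> VariationMetrics:
    """Per-(gene, strain) SNPs/nt, Ti/Tv and nonsynonymous fraction.

    Each SNP contributes to SNPs/nt and Ti/Tv; each variable codon is
    counted once in the nonsynonymous-fraction denominator.
    """
    if compared_sites <= 0:
        raise ValueError("compared_sites must be positive")
    recs = [r for r in records if r.gene_id == gene_id and r.strain == strain]
    n_ti = sum(r.transition for r in recs)
    n_tv = len(recs) - n_ti
    codons = {}
    for r in recs:
        codons[r.codon_index] = r.consequence
    counts = {c: 0 for c in CONSEQUENCE_CLASSES}
    for consequence in codons.values():
        counts[consequence] += 1
    n_var = len(codons)
    return VariationMetrics(
        gene_id=gene_id,
        strain=strain,
        snps_per_nt=len(recs) / compared_sites,
        titv=(n_ti / n_tv) if n_tv else None,
        nonsyn_fraction=(counts["nonsynonymous"] / n_var) if n_var else None,
        counts=counts,
        n_snps=len(recs),
        compared_sites=compared_sites,
    )


def panel_metrics(panel: OrthologPanel) -> list:
    """Convenience: trim, call and score one panel for every strain."""
    trimmed = trim_to_frame(panel)
    records, compared = call_snps(trimmed)
    return [
        metrics(records, panel.gene_id, strain, compared[strain])
        for strain in trimmed.strains
    ]


# ---------------------------------------------------------------------------
# coordinate liftover
# ---------------------------------------------------------------------------

def liftover(ref_row: str, target_row: str, positions: list) -> list:
    """Map 1-based ungapped reference positions to target coordinates.

    Both rows must come from the same alignment.  A position whose column is
    gapped in the target maps to ``None``.
    """
    if len(ref_row) != len(target_row):
        raise ValueError("rows must share alignment width")
    ref_to_col = {}
    pos = 0
    for i, ch in enumerate(ref_row):
        if ch != "-":
            pos += 1
            ref_to_col[pos] = i
    target_pos = np.cumsum([ch != "-" for ch in target_row])
    out = []
    for p in positions:
        if p not in ref_to_col:
            raise ValueError(f"position {p} outside the ungapped reference")
        col = ref_to_col[p]
        out.append(int(target_pos[col]) if target_row[col] != "-" else None)
    return out


# ---------------------------------------------------------------------------
# mechanism x lineage summaries
# ---------------------------------------------------------------------------

def group_summary(all_metrics: list, mechanism_map: dict | None = None,
                  lineage_map: dict | None = None) -> pd.DataFrame:
    """Distribution summaries of each metric per (mechanism, lineage) cell.

    Metrics are pooled over (gene, strain) pairs; undefined Ti/Tv or
    nonsynonymous-fraction values are excluded from that metric's summary,
    with the number used reported alongside.
    """
    mechanism_map = DEFAULT_MECHANISM_MAP if mechanism_map is None else mechanism_map
    lineage_map = DEFAULT_LINEAGE_MAP if lineage_map is None else lineage_map
    rows = []
    for m in all_metrics:
        lineage = lineage_map.get(m.strain)
        if lineage is None:
            continue
        rows.append({
            "mechanism": mechanism_map.get(m.gene_id, "other"),
            "lineage": lineage,
            "gene_id": m.gene_id,
            "strain": m.strain,
            "snps_per_nt": m.snps_per_nt,
            "titv": np.nan if m.titv is None else m.titv,
            "nonsyn_fraction": (np.nan if m.nonsyn_fraction is None
                                else m.nonsyn_fraction),
        })
    long = pd.DataFrame(rows)
    if long.empty:
        return pd.DataFrame()
    out = []
    for (mech, lin), grp in long.groupby(["mechanism", "lineage"]):
        entry = {"mechanism": mech, "lineage": lin, "n_pairs": len(grp)}
        for metric in ("snps_per_nt", "titv", "nonsyn_fraction"):
            vals = grp[metric].dropna()
            entry[f"{metric}_n"] = len(vals)
            entry[f"{metric}_median"] = vals.median() if len(vals) else np.nan
            entry[f"{metric}_q1"] = vals.quantile(0.25) if len(vals) else np.nan
            entry[f"{metric}_q3"] = vals.quantile(0.75) if len(vals) else np.nan
            entry[f"{metric}_mean"] = vals.mean() if len(vals) else np.nan
        out.append(entry)
    return pd.DataFrame(out)


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def read_panel_fasta(path: str, gene_id: str, reference: str,
                     mechanism: str = "other") -> OrthologPanel:
    from Bio import SeqIO

    alignment = {rec.id: str(rec.seq) for rec in SeqIO.parse(path, "fasta")}
    return OrthologPanel(gene_id=gene_id, alignment=alignment,
                         reference=reference, mechanism=mechanism)


def snp_table(records: list) -> pd.DataFrame:
    """SNP records as a VCF-like table (gene, pos, ref, alt, strain, ...)."""
    return pd.DataFrame(
        [{"gene": r.gene_id, "pos": r.ref_pos, "ref": r.ref_base,
          "alt": r.alt_base, "strain": r.strain, "codon": r.codon_index,
          "consequence": r.consequence,
          "transition": r.transition} for r in records]
    )
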