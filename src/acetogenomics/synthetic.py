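"""Synthetic inputs with planted ground truth for every pipeline stage.

The generators emulate the evidence structure the analysis stages look for,
at the study's conditions, without requiring any sequence download:

* circular replicons with two replichores of opposite GC-skew bias, a
  DnaA-box cluster planted around the origin, one dif consensus instance at
  the terminus, an AT-rich island and marker genes (GFF3 companion);
* annotation tables whose mobile-genetic-element keyword counts are Poisson
  draws at specified per-Mb rates;
* per-gene ortholog CDS panels with planted SNPs at target Ti/Tv and
  nonsynonymous proportions;
* block-structured gene presence-absence matrices.

Every generator is deterministic given its seed, and its truth record is
exactly recoverable by the corresponding analysis stage at noise 0.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .replicon import DNAA_BOX, Replicon
from .snp import (
    OrthologPanel,
    SNPRecord,
    classify_consequence,
    is_transition,
    translate_codon,
)

_TI_PARTNER = {"A": "G", "G": "A", "C": "T", "T": "C"}
_TV_PARTNERS = {"A": "CT", "G": "CT", "C": "AG", "T": "AG"}


class FeatureCollisionError(ValueError):
    """Two planted sequence features would overwrite the same bases."""


def _default_markers(length: int, ori: int, dif: int) -> dict:
    """Replication-initiation genes near ori and xer recombinases near dif."""
    def w(start: int, span: int) -> tuple:
        s = (start - 1) % length + 1
        return (s, (s + span - 2) % length + 1, "+")

    return {
        "dnaA": w(ori + 1000, 1350),
        "dnaN": w(ori + 2500, 1100),
        "recF": w(ori + 3700, 1100),
        "gyrB": w(ori + 4900, 2400),
        "xerC": w(dif + 500, 900),
        "xerD": w(dif + 1500, 900),
    }


@dataclass
class ReplicontTruth:
    """Planted layout of a simulated circular replicon (1-based, inclusive)."""

    length: int = 100_000
    ori_pos: int = 25_000
    dif_pos: int = 75_000
    skew_amplitude: float = 0.3
    n_dnaa_boxes: int = 7
    box_mismatches: list = field(default_factory=list)
    at_rich_span: tuple | None = None
    marker_genes: dict | None = None
    gc_fraction: float = 0.578
    seed: int = 0

    def __post_init__(self) -> None:
        if self.length < 20_000:
            raise ValueError("length must be >= 20 kb")
        if not (1 <= self.ori_pos <= self.length and 1 <= self.dif_pos <= self.length):
            raise ValueError("ori/dif positions must lie on the replicon")
        if self.ori_pos == self.dif_pos:
            raise ValueError("ori and dif must differ")
        if self.n_dnaa_boxes < 0:
            raise ValueError("n_dnaa_boxes must be >= 0")
        if not self.box_mismatches:
            self.box_mismatches = [0] * self.n_dnaa_boxes
        if len(self.box_mismatches) != self.n_dnaa_boxes:
            raise ValueError("box_mismatches length must equal n_dnaa_boxes")
        if self.at_rich_span is None:
            s = (self.ori_pos + 600 - 1) % self.length + 1
            self.at_rich_span = (s, (s + 299 - 1) % self.length + 1)
        if self.marker_genes is None:
            self.marker_genes = _default_markers(self.length, self.ori_pos,
                                                 self.dif_pos)
    # marker genes are annotation intervals only; they never overwrite bases


def _circular_intervals_overlap(a: tuple, b: tuple, length: int) -> bool:
    def expand(iv):
        s, e = iv
        return [(s, e)] if s <= e else [(s, length), (1, e)]

    for s1, e1 in expand(a):
        for s2, e2 in expand(b):
            if s1 <= e2 and s2 <= e1:
                return True
    return False


def simulate_replicon(truth: ReplicontTruth):
    """Simulate a circular replicon realizing a planted truth layout.

    Background bases are i.i.d. with the stated GC fraction; the G/C split
    is biased by ``skew_amplitude`` with opposite sign on the two replichore
    arcs (ori -> dif negative-skew, dif -> ori positive-skew, so the
    cumulative GC skew peaks at ori and troughs at dif).  Planted motifs
    overwrite background bases; overlapping planted features raise
    :class:`FeatureCollisionError`.

    Returns ``(Replicon, truth)``.
    """
    rng = np.random.default_rng(truth.seed)
    L = truth.length
    g, a = truth.gc_fraction, truth.skew_amplitude
    if not (0 <= a < 1):
        raise ValueError("skew_amplitude must be in [0, 1)")
    pos0 = np.arange(L)
    arc_len = (truth.dif_pos - truth.ori_pos) % L
    on_ori_to_dif = ((pos0 + 1 - truth.ori_pos) % L) < arc_len
    # sign -1 on ori->dif arc, +1 on dif->ori arc
    sign = np.where(on_ori_to_dif, -1.0, 1.0)
    p_g = g / 2 * (1 + sign * a)
    p_c = g / 2 * (1 - sign * a)
    p_a = np.full(L, (1 - g) / 2)
    probs = np.stack([p_a, p_c, p_g, p_a], axis=1)  # A, C, G, T
    u = rng.random(L)
    cum = np.cumsum(probs, axis=1)
    idx = (u[:, None] > cum).sum(axis=1)
    seq = np.array(list("ACGT"), dtype="U1")[idx]

    planted: list = []

    def plant(start1: int, bases: str, label: str) -> None:
        end1 = (start1 + len(bases) - 2) % L + 1
        iv = (start1, end1)
        for other_label, other_iv in planted:
            if _circular_intervals_overlap(iv, other_iv, L):
                raise FeatureCollisionError(
                    f"planted {label} at {iv} collides with {other_label} at {other_iv}"
                )
        planted.append((label, iv))
        for k, b in enumerate(bases):
            seq[(start1 - 1 + k) % L] = b

    # AT-rich island: strongly AT-biased i.i.d. stretch
    s, e = truth.at_rich_span
    span_len = (e - s) % L + 1
    at_bases = "".join(
        rng.choice(list("ATGC"), size=span_len, p=[0.425, 0.425, 0.075, 0.075])
    )
    plant(s, at_bases, "at_rich_span")

    # dif consensus instance, fixed arms with random spacer
    spacer = "".join(rng.choice(list("ACGT"), size=6))
    plant(truth.dif_pos, "GTT" + spacer + "AAC", "dif_site")

    # DnaA boxes scattered within +/- 500 bp of ori
    box_len = len(DNAA_BOX)
    offsets: list = []
    for i, n_mm in enumerate(truth.box_mismatches):
        for _ in range(1000):
            off = int(rng.integers(-500, 501 - box_len))
            if all(abs(off - o) >= box_len for o in offsets):
                offsets.append(off)
                break
        else:
            raise FeatureCollisionError("cannot place DnaA boxes without overlap")
        box = list(DNAA_BOX)
        mm_pos = rng.choice(box_len, size=n_mm, replace=False)
        for p in mm_pos:
            box[p] = rng.choice([b for b in "ACGT" if b != box[p]])
        plant((truth.ori_pos - 1 + off) % L + 1, "".join(box), f"dnaa_box_{i}")

    replicon = Replicon(id=f"sim_replicon_seed{truth.seed}", sequence="".join(seq),
                        circular=True)
    return replicon, truth


# ---------------------------------------------------------------------------
# MGE annotation tables
# ---------------------------------------------------------------------------

# Phrase banks are unambiguous w.r.t. the default keyword map: each phrase
# matches its own category's keywords and no other's.
MGE_PHRASES = {
    "transposase": [
        "IS5 family transposase", "IS30 family transposase",
        "IS110 family transposase", "IS3 family transposase",
        "Tn3 family transposase", "IS481 family transposase",
    ],
    "integrase": [
        "site-specific integrase", "tyrosine-type integrase",
        "integrase core domain protein",
    ],
    "phage": [
        "phage major capsid protein", "phage terminase large subunit",
        "phage portal protein", "prophage tail fiber protein",
        "phage holin", "phage tail protein",
    ],
    "recombinase": [
        "tyrosine recombinase", "serine recombinase",
        "DNA recombinase", "resolvase domain protein",
    ],
    "repeat": [
        "LPXTG-motif repeat protein", "tetratricopeptide repeat protein",
        "ankyrin repeat protein",
    ],
}

FILLER_PHRASES = [
    "hypothetical protein", "DNA polymerase III subunit beta",
    "ABC transporter ATP-binding protein", "30S ribosomal protein S4",
    "PQQ-dependent alcohol dehydrogenase", "elongation factor Tu",
    "acetate kinase", "molecular chaperone DnaK", "citrate synthase",
    "outer membrane efflux channel", "NADH-quinone oxidoreductase subunit",
]


def simulate_mge_table(genome_size: int, rates_per_mb: dict, seed: int = 0,
                       genome_id: str = "simgenome",
                       replicon_class: str = "chromosome",
                       filler_per_mb: float = 100.0):
    """Annotation table with Poisson MGE counts at given per-Mb rates.

    Returns ``(table, truth_counts)``; the table has columns genome_id,
    feature_id, product, replicon and includes non-MGE filler rows.
    """
    if any(r < 0 for r in rates_per_mb.values()):
        raise ValueError("rates must be non-negative")
    rng = np.random.default_rng(seed)
    mb = genome_size / 1e6
    rows = []
    truth = {}
    for category in MGE_PHRASES:
        rate = rates_per_mb.get(category, 0.0)
        n = int(rng.poisson(rate * mb))
        truth[category] = n
        for _ in range(n):
            rows.append(str(rng.choice(MGE_PHRASES[category])))
    n_filler = int(rng.poisson(filler_per_mb * mb))
    for _ in range(n_filler):
        rows.append(str(rng.choice(FILLER_PHRASES)))
    order = rng.permutation(len(rows))
    table = pd.DataFrame({
        "genome_id": genome_id,
        "feature_id": [f"{genome_id}_{i + 1:05d}" for i in range(len(rows))],
        "product": [rows[i] for i in order],
        "replicon": replicon_class,
    })
    return table, truth


# ---------------------------------------------------------------------------
# ortholog panels with planted SNPs
# ---------------------------------------------------------------------------

@dataclass
class MutationTruth:
    """Targets for planted variation in simulated ortholog panels."""

    per_gene_snp_count: int = 10
    titv_target: float = 2.0
    nonsyn_target: float = 0.25
    seed: int = 0


def _random_cds(rng, n_codons: int) -> str:
    """ATG + random internal sense codons + TAA."""
    codons = ["ATG"]
    while len(codons) < n_codons - 1:
        codon = "".join(rng.choice(list("ACGT"), size=3))
        if translate_codon(codon) != "*":
            codons.append(codon)
    codons.append("TAA")
    return "".join(codons)


def _plant_snp(rng, ref_cds: str, available: list, want_ti: bool,
               want_nonsyn: bool):
    """Pick (codon, offset, alt base) realizing the drawn Ti/Tv and class.

    Scans codons in random order; within a codon, base offsets and
    transversion partners in random order.  Only synonymous/nonsynonymous
    outcomes are planted (no nonsense or stop-loss).
    """
    want = "nonsynonymous" if want_nonsyn else "synonymous"
    for ci in rng.permutation(available):
        ci = int(ci)
        ref_codon = ref_cds[ci * 3 : ci * 3 + 3]
        for off in rng.permutation(3):
            off = int(off)
            ref_base = ref_codon[off]
            alts = ([_TI_PARTNER[ref_base]] if want_ti
                    else [ _TV_PARTNERS[ref_base][i]
                           for i in rng.permutation(2)])
            for alt in alts:
                alt_codon = ref_codon[:off] + alt + ref_codon[off + 1 :]
                if classify_consequence(ref_codon, alt_codon) == want:
                    return ci, off, alt
    return None


def simulate_ortholog_panel(n_genes: int, n_strains: int, gene_length: int,
                            mutation: MutationTruth,
                            reference: str = "KSO5",
                            strain_names: list | None = None,
                            mechanisms: list | None = None):
    """Ungapped per-gene alignments with planted SNPs and their truth list.

    Strain 0 is the reference; every other strain differs from it only at
    planted positions (at most one per codon per strain).  Per planted SNP
    the transition indicator is Bernoulli(titv/(1+titv)) and the
    synonymous/nonsynonymous class Bernoulli(nonsyn_target), realized
    exactly by construction.  Returns ``(panels, truth_records)`` with truth
    as :class:`~acetogenomics.snp.SNPRecord` in reference CDS coordinates.
    """
    if gene_length < 10:
        raise ValueError("gene_length must be >= 10 codons")
    rng = np.random.default_rng(mutation.seed)
    if strain_names is None:
        strain_names = [f"S{i}" for i in range(1, n_strains)]
    if len(strain_names) != n_strains - 1:
        raise ValueError("need n_strains - 1 alternate strain names")
    available_codons = list(range(1, gene_length - 1))  # keep start/stop intact
    if mutation.per_gene_snp_count > len(available_codons):
        raise ValueError(
            f"requested {mutation.per_gene_snp_count} SNPs but only "
            f"{len(available_codons)} mutable codon positions"
        )
    p_ti = mutation.titv_target / (1 + mutation.titv_target)
    panels, truth = [], []
    for gi in range(n_genes):
        gene_id = f"gene_{gi + 1:03d}"
        mechanism = mechanisms[gi] if mechanisms else "other"
        ref_cds = _random_cds(rng, gene_length)
        alignment = {reference: ref_cds}
        for strain in strain_names:
            seq = list(ref_cds)
            free = list(available_codons)
            for _ in range(mutation.per_gene_snp_count):
                want_ti = bool(rng.random() < p_ti)
                want_nonsyn = bool(rng.random() < mutation.nonsyn_target)
                pick = _plant_snp(rng, ref_cds, free, want_ti, want_nonsyn)
                if pick is None:
                    raise RuntimeError("could not realize requested SNP draw")
                ci, off, alt = pick
                free.remove(ci)
                pos = ci * 3 + off + 1
                ref_base = ref_cds[pos - 1]
                seq[pos - 1] = alt
                ref_codon = ref_cds[ci * 3 : ci * 3 + 3]
                alt_codon = ref_codon[:off] + alt + ref_codon[off + 1 :]
                truth.append(SNPRecord(
                    gene_id=gene_id, strain=strain, ref_pos=pos,
                    ref_base=ref_base, alt_base=alt, codon_index=ci + 1,
                    consequence=classify_consequence(ref_codon, alt_codon),
                    transition=is_transition(ref_base, alt),
                ))
            alignment[strain] = "".join(seq)
        panels.append(OrthologPanel(gene_id=gene_id, alignment=alignment,
                                    reference=reference, mechanism=mechanism))
    truth.sort(key=lambda r: (r.gene_id, r.strain, r.ref_pos))
    return panels, truth


# ---------------------------------------------------------------------------
# presence-absence matrices
# ---------------------------------------------------------------------------

def simulate_presence_absence(n_genomes: int, block_spec: list, seed: int = 0,
                              noise: float = 0.0,
                              genome_names: list | None = None) -> pd.DataFrame:
    """Binary gene-cluster x genome matrix from block specifications.

    ``block_spec`` is a list of ``(gene_count, genome_subset)`` pairs where
    the subset lists genome names (or indices) carrying that block.  Noise
    flips each cell independently at the stated rate; rows left all-absent
    are dropped (a cluster absent everywhere is unobservable).
    """
    rng = np.random.default_rng(seed)
    if genome_names is None:
        genome_names = [f"g{i + 1}" for i in range(n_genomes)]
    if len(genome_names) != n_genomes:
        raise ValueError("genome_names length must equal n_genomes")
    name_set = set(genome_names)
    rows, index = [], []
    for bi, (gene_count, subset) in enumerate(block_spec):
        subset = [genome_names[s] if isinstance(s, int) else s for s in subset]
        if not set(subset) <= name_set:
            raise ValueError(f"block {bi}: subset not within the genome set")
        base = [1 if g in subset else 0 for g in genome_names]
        for gi in range(gene_count):
            rows.append(list(base))
            index.append(f"block{bi + 1}_gene{gi + 1}")
    mat = pd.DataFrame(rows, index=index, columns=genome_names, dtype=int)
    if noise > 0:
        flips = rng.random(mat.shape) < noise
        mat = (mat.values ^ flips).astype(int)
        mat = pd.DataFrame(mat, index=index, columns=genome_names)
    return mat[mat.sum(axis=1) > 0]
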