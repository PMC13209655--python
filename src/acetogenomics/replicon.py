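"""Replicon architecture: assembly statistics, GC skew, and oriC/dif calling.

Replication in bacteria with a single circular chromosome proceeds
bidirectionally from one origin (oriC) to a terminus region carrying the
*dif* site, where XerC/XerD resolve chromosome dimers.  The two replichores
acquire opposite strand-composition biases, so the windowed GC skew
(G - C)/(G + C) changes sign at both loci and the cumulative skew series has
its extrema there.  oriC is additionally marked by a cluster of DnaA-box
9-mers (TTATCCACA and close variants in Alphaproteobacteria) and an AT-rich
unwinding element adjacent to replication-initiation genes (dnaA, dnaN,
recF, gyrB); dif matches the consensus 5'-GTTN{6}AAC-3' near xerC/xerD.

This module computes the evidence layers and combines them into calls.
Because the sign convention of the skew decides which cumulative extremum is
"the maximum", the ori extremum is defined operationally as whichever
extremum is corroborated by the DnaA-box cluster, and dif as the opposite
extremum.  All coordinates are 1-based inclusive, matching GenBank.
"""

from __future__ import annotations

import os
import tempfile
from dataclasses import dataclass, field

import numpy as np
from Bio import SeqIO
from Bio.Data import IUPACData
from Bio.Seq import Seq

# IUPAC degenerate-nucleotide alphabet; N in the *subject* sequence never
# counts as a match at a fixed motif position.
IUPAC_SETS = {k: set(v) for k, v in IUPACData.ambiguous_dna_values.items()}

DNAA_BOX = "TTATCCACA"
DIF_CONSENSUS = "GTTNNNNNNAAC"
REPLICATION_INITIATION_GENES = ("dnaA", "dnaN", "recF", "gyrB")
XER_GENES = ("xerC", "xerD")


class AllAmbiguousError(ValueError):
    """Raised when a composition statistic is undefined (no A/C/G/T bases)."""


@dataclass
class Replicon:
    """A named nucleotide sequence with topology flag."""

    id: str
    sequence: str
    circular: bool = True

    def __post_init__(self) -> None:
        self.sequence = self.sequence.upper()
        if len(self.sequence) == 0:
            raise ValueError(f"replicon {self.id!r} has empty sequence")

    @property
    def length(self) -> int:
        return len(self.sequence)


@dataclass
class SkewProfile:
    window: int
    step: int
    centers: np.ndarray        # 1-based window centers
    skew: np.ndarray           # (G-C)/(G+C) per window
    cumulative: np.ndarray     # running sum of skew
    zero_gc: np.ndarray        # flags for windows with G+C == 0
    argmax: int                # 1-based bp of cumulative maximum
    argmin: int                # 1-based bp of cumulative minimum


@dataclass
class MotifHit:
    start: int                 # 1-based leftmost coordinate on the + strand
    strand: str                # '+' or '-'
    mismatches: int
    matched_seq: str           # motif-oriented (reverse-complemented for '-')


@dataclass
class Cluster:
    hits: list
    cluster_hits: int
    span: tuple                # (start, end) 1-based of first/last hit
    midpoint: int              # 1-based


@dataclass
class OriCCall:
    position: int | None
    cluster_hits: int
    cluster_span: tuple | None
    skew_extremum_pos: int | None
    at_rich: bool
    nearby_genes: list
    confident: bool
    reasons: list = field(default_factory=list)


@dataclass
class DifCall:
    position: int | None
    matched_seq: str | None
    distance_to_skew_min: int | None
    near_xer: bool
    reasons: list = field(default_factory=list)


# ---------------------------------------------------------------------------
# composition and assembly statistics
# ---------------------------------------------------------------------------

def gc_content(replicon: Replicon) -> float:
    """GC fraction (#G + #C) / (#A + #C + #G + #T); N excluded entirely."""
    s = replicon.sequence
    gc = s.count("G") + s.count("C")
    acgt = gc + s.count("A") + s.count("T")
    if acgt == 0:
        raise AllAmbiguousError(
            f"replicon {replicon.id!r}: GC content undefined (no unambiguous bases)"
        )
    return gc / acgt


def assembly_stats(replicons: list) -> dict:
    """Total span, contig count, N50/L50, and pooled GC of an assembly.

    N50 is the smallest length among the largest contigs whose cumulative
    sum first reaches half the total; L50 is how many contigs that takes.
    """
    if not replicons:
        raise ValueError("assembly_stats requires at least one replicon")
    lengths = sorted((r.length for r in replicons), reverse=True)
    total = sum(lengths)
    half = total / 2
    acc = 0
    for i, length in enumerate(lengths, start=1):
        acc += length
        if acc >= half:
            n50, l50 = length, i
            break
    gc = sum(r.sequence.count("G") + r.sequence.count("C") for r in replicons)
    acgt = gc + sum(r.sequence.count("A") + r.sequence.count("T") for r in replicons)
    return {
        "total_bp": total,
        "n_contigs": len(lengths),
        "n50": n50,
        "l50": l50,
        "gc": gc / acgt if acgt else float("nan"),
    }


# ---------------------------------------------------------------------------
# GC skew
# ---------------------------------------------------------------------------

def skew_profile(replicon: Replicon, window: int = 1000, step: int = 100) -> SkewProfile:
    """Windowed GC skew with circular wrap-around and its cumulative series.

    Windows start every ``step`` bp; on a circular replicon they cover the
    whole circle (wrapping past the end), on a linear one only full windows
    are emitted.  Windows devoid of G and C get skew 0 and a flag.
    """
    if not (1 <= step <= window):
        raise ValueError("require window >= step >= 1")
    L = replicon.length
    if window >= L:
        raise ValueError(f"window {window} must be smaller than replicon length {L}")
    seq = np.frombuffer(replicon.sequence.encode(), dtype=np.uint8)
    is_g = (seq == ord("G")).astype(np.int64)
    is_c = (seq == ord("C")).astype(np.int64)
    if replicon.circular:
        starts = np.arange(0, L, step)
        is_g = np.concatenate([is_g, is_g[:window]])
        is_c = np.concatenate([is_c, is_c[:window]])
    else:
        starts = np.arange(0, L - window + 1, step)
    cg = np.concatenate([[0], np.cumsum(is_g)])
    cc = np.concatenate([[0], np.cumsum(is_c)])
    g = cg[starts + window] - cg[starts]
    c = cc[starts + window] - cc[starts]
    denom = g + c
    zero = denom == 0
    skew = np.where(zero, 0.0, (g - c) / np.where(zero, 1, denom))
    cumulative = np.cumsum(skew)
    centers = (starts + window // 2) % L + 1
    return SkewProfile(
        window=window,
        step=step,
        centers=centers,
        skew=skew,
        cumulative=cumulative,
        zero_gc=zero,
        argmax=int(centers[int(np.argmax(cumulative))]),
        argmin=int(centers[int(np.argmin(cumulative))]),
    )


def circular_distance(a: int, b: int, length: int) -> int:
    """Shortest arc distance between two 1-based positions on a circle."""
    d = abs(a - b) % length
    return min(d, length - d)


# ---------------------------------------------------------------------------
# motif scanning
# ---------------------------------------------------------------------------

def _motif_match_matrix(seq_codes: np.ndarray, motif: str, L: int, circular: bool):
    """Mismatch count at every start for one motif orientation (vectorized)."""
    m = len(motif)
    n_starts = L if circular else L - m + 1
    if n_starts <= 0:
        return np.zeros(0, dtype=np.int64)
    ext = np.concatenate([seq_codes, seq_codes[: m - 1]]) if circular else seq_codes
    mism = np.zeros(n_starts, dtype=np.int64)
    for j, letter in enumerate(motif):
        allowed = IUPAC_SETS[letter]
        col = ext[j : j + n_starts]
        ok = np.zeros(n_starts, dtype=bool)
        if letter == "N":
            # N in the motif matches any base, including subject N
            ok[:] = True
        else:
            for base in allowed:
                ok |= col == ord(base)
        mism += ~ok
    return mism


def scan_motif(replicon: Replicon, motif: str, max_mismatch: int = 0) -> list:
    """All positions (both strands, circular wrap) matching an IUPAC motif.

    A hit's ``start`` is the leftmost + strand coordinate of the matched
    window regardless of strand; ``matched_seq`` is reported in motif
    orientation.  Mismatches are counted at non-N motif positions only, and
    an N in the subject never satisfies a fixed motif position.
    """
    motif = motif.upper()
    if len(motif) > 50:
        raise ValueError("motif longer than 50 bp")
    for letter in motif:
        if letter not in IUPAC_SETS:
            raise ValueError(f"invalid IUPAC letter {letter!r} in motif")
    seq_codes = np.frombuffer(replicon.sequence.encode(), dtype=np.uint8)
    L, m = replicon.length, len(motif)
    hits = []
    rc = str(Seq(motif).reverse_complement())
    for strand, mot in (("+", motif), ("-", rc)):
        mism = _motif_match_matrix(seq_codes, mot, L, replicon.circular)
        for start0 in np.nonzero(mism <= max_mismatch)[0]:
            start0 = int(start0)
            if start0 + m <= L:
                window = replicon.sequence[start0 : start0 + m]
            else:
                window = replicon.sequence[start0:] + replicon.sequence[: start0 + m - L]
            matched = window if strand == "+" else str(Seq(window).reverse_complement())
            hits.append(
                MotifHit(
                    start=start0 + 1,
                    strand=strand,
                    mismatches=int(mism[start0]),
                    matched_seq=matched,
                )
            )
    hits.sort(key=lambda h: (h.start, h.strand))
    return hits


def find_dnaa_cluster(hits: list, length: int, min_hits: int = 7, span: int = 1000,
                      circular: bool = True):
    """Densest window of DnaA-box hits; ties resolved to the leftmost start.

    Returns a :class:`Cluster` when the best window holds >= ``min_hits``
    hits, else ``None``.  Windows are anchored at hit starts and may wrap.
    """
    if not hits:
        return None
    starts = [h.start for h in hits]
    n = len(starts)
    ext = starts + ([s + length for s in starts] if circular else [])
    best_count, best_anchor_idx = 0, 0
    for i in range(n):
        lo = starts[i]
        count = sum(1 for s in ext if lo <= s < lo + span)
        if count > best_count:
            best_count, best_anchor_idx = count, i
    if best_count < min_hits:
        return None
    lo = starts[best_anchor_idx]
    members = [h for h, s in zip(hits + hits, ext) if lo <= s < lo + span]
    first = members[0].start
    last_hit = members[-1]
    last_end = last_hit.start + len(last_hit.matched_seq) - 1
    mid = first + (((last_end - first) % length) // 2)
    return Cluster(
        hits=members,
        cluster_hits=best_count,
        span=(first, ((last_end - 1) % length) + 1),
        midpoint=((mid - 1) % length) + 1,
    )


def at_rich_regions(replicon: Replicon, window: int = 100, margin: float = 0.10) -> list:
    """Maximal runs of windows whose AT fraction exceeds the genome AT + margin.

    Consecutive (non-overlapping) windows of ``window`` bp are scored; runs
    of qualifying windows are merged into (start, end, at_fraction) tuples,
    1-based inclusive.
    """
    L = replicon.length
    if window >= L:
        raise ValueError("window must be smaller than the replicon")
    genome_at = 1.0 - gc_content(replicon)
    threshold = genome_at + margin
    seq = np.frombuffer(replicon.sequence.encode(), dtype=np.uint8)
    is_at = ((seq == ord("A")) | (seq == ord("T"))).astype(np.int64)
    is_acgt = is_at + ((seq == ord("G")) | (seq == ord("C"))).astype(np.int64)
    n_win = L // window
    regions = []
    run_start = None
    for i in range(n_win):
        lo, hi = i * window, (i + 1) * window
        denom = is_acgt[lo:hi].sum()
        frac = is_at[lo:hi].sum() / denom if denom else 0.0
        if frac >= threshold:
            if run_start is None:
                run_start = lo
        elif run_start is not None:
            regions.append(_region(run_start, lo, is_at, is_acgt))
            run_start = None
    if run_start is not None:
        regions.append(_region(run_start, n_win * window, is_at, is_acgt))
    return regions


def _region(lo: int, hi: int, is_at, is_acgt) -> tuple:
    denom = is_acgt[lo:hi].sum()
    return (lo + 1, hi, float(is_at[lo:hi].sum() / denom) if denom else 0.0)


# ---------------------------------------------------------------------------
# origin and terminus calls
# ---------------------------------------------------------------------------

def call_oric(replicon: Replicon, annotations: list | None = None, *,
              window: int = 1000, step: int = 100, max_mismatch: int = 1,
              min_hits: int = 7, cluster_span: int = 1000,
              skew_tolerance: int = 50_000) -> OriCCall:
    """Call oriC from DnaA-box clustering corroborated by the skew extremum.

    The call position is the midpoint of the densest DnaA-box window.  The
    call is confident when the cluster holds >= ``min_hits`` boxes and lies
    within ``skew_tolerance`` of a cumulative-skew extremum (whichever
    extremum the cluster corroborates).  Gene proximity (dnaA/dnaN/recF/gyrB
    within 5 kb) and AT-richness within 2 kb are reported as extra evidence;
    absent annotations mean that evidence is unavailable, not failed.
    """
    reasons = []
    hits = scan_motif(replicon, DNAA_BOX, max_mismatch=max_mismatch)
    if not hits:
        return OriCCall(None, 0, None, None, False, [], False,
                        ["no DnaA-box motif hits"])
    cluster = find_dnaa_cluster(hits, replicon.length, min_hits=1,
                                span=cluster_span, circular=replicon.circular)
    position = cluster.midpoint
    prof = skew_profile(replicon, window=window, step=step)
    d_max = circular_distance(position, prof.argmax, replicon.length)
    d_min = circular_distance(position, prof.argmin, replicon.length)
    extremum = prof.argmax if d_max <= d_min else prof.argmin
    d_ext = min(d_max, d_min)
    confident = cluster.cluster_hits >= min_hits and d_ext <= skew_tolerance
    if cluster.cluster_hits < min_hits:
        reasons.append(
            f"only {cluster.cluster_hits} DnaA boxes in best {cluster_span} bp window"
            f" (need {min_hits})"
        )
    if d_ext > skew_tolerance:
        reasons.append("skew extremum not corroborated")
    at_rich = any(
        circular_distance(position, s, replicon.length) <= 2000
        or circular_distance(position, e, replicon.length) <= 2000
        or _within(position, s, e)
        for s, e, _ in at_rich_regions(replicon)
    )
    nearby = []
    if annotations:
        for gene in annotations:
            if gene["name"] in REPLICATION_INITIATION_GENES and (
                circular_distance(position, gene["start"], replicon.length) <= 5000
                or circular_distance(position, gene["end"], replicon.length) <= 5000
            ):
                nearby.append(gene["name"])
    return OriCCall(
        position=position,
        cluster_hits=cluster.cluster_hits,
        cluster_span=cluster.span,
        skew_extremum_pos=extremum,
        at_rich=at_rich,
        nearby_genes=sorted(set(nearby)),
        confident=confident,
        reasons=reasons,
    )


def _within(pos: int, start: int, end: int) -> bool:
    return start <= pos <= end


def call_dif(replicon: Replicon, annotations: list | None = None,
             skew: SkewProfile | None = None,
             oric: OriCCall | None = None) -> DifCall:
    """Pick the dif consensus match closest to the terminus skew extremum.

    All exact GTTN{6}AAC matches are candidates (the consensus is its own
    reverse complement, so a + strand scan covers both strands); the one
    minimizing circular distance to the cumulative-skew extremum opposite
    the oriC-corroborated one wins, smaller coordinate on ties.
    """
    if skew is None:
        skew = skew_profile(replicon)
    if oric is None:
        oric = call_oric(replicon, annotations)
    # terminus extremum = the one opposite the ori-corroborated extremum
    if oric.skew_extremum_pos is not None and oric.skew_extremum_pos == skew.argmax:
        ter = skew.argmin
    else:
        ter = skew.argmax
    matches = [h for h in scan_motif(replicon, DIF_CONSENSUS, 0) if h.strand == "+"]
    if not matches:
        return DifCall(None, None, None, False, ["no dif consensus match"])
    best = min(
        matches,
        key=lambda h: (circular_distance(h.start, ter, replicon.length), h.start),
    )
    near_xer = False
    if annotations:
        near_xer = any(
            g["name"] in XER_GENES
            and circular_distance(best.start, g["start"], replicon.length) <= 10_000
            for g in annotations
        )
    return DifCall(
        position=best.start,
        matched_seq=best.matched_seq,
        distance_to_skew_min=circular_distance(best.start, ter, replicon.length),
        near_xer=near_xer,
    )


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def read_fasta(path: str, circular: bool = True) -> list:
    """Read a (multi-)FASTA into Replicon records."""
    return [
        Replicon(id=rec.id, sequence=str(rec.seq), circular=circular)
        for rec in SeqIO.parse(path, "fasta")
    ]


def write_fasta(replicons: list, path: str) -> None:
    with open(path, "w") as fh:
        for r in replicons:
            fh.write(f">{r.id}\n")
            for i in range(0, r.length, 70):
                fh.write(r.sequence[i : i + 70] + "\n")


def read_gff_genes(path: str) -> list:
    """Gene name/coordinate records from a GFF3 file.

    Returns dicts with keys name, start, end, strand (1-based inclusive).
    The Name attribute is preferred, falling back to gene then ID.
    """
    import gffutils

    db = gffutils.create_db(path, dbfn=":memory:", force=True,
                            merge_strategy="create_unique", keep_order=True)
    genes = []
    for feat in db.all_features():
        if feat.featuretype not in ("gene", "CDS"):
            continue
        name = (feat.attributes.get("Name") or feat.attributes.get("gene")
                or feat.attributes.get("ID") or [feat.id])[0]
        genes.append({"name": name, "start": feat.start, "end": feat.end,
                      "strand": feat.strand})
    return genes


def write_gff_genes(genes: dict, seqid: str, length: int, path: str) -> None:
    """Write marker genes ({name: (start, end, strand)}) as minimal GFF3."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        fh.write(f"##sequence-region {seqid} 1 {length}\n")
        for name, (start, end, strand) in sorted(genes.items(), key=lambda kv: kv[1][0]):
            fh.write(
                f"{seqid}\tacetogenomics\tgene\t{start}\t{end}\t.\t{strand}\t.\t"
                f"ID={name};Name={name}\n"
            )
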