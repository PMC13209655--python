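"""SNP calling, codon-consequence classification, metrics and liftover."""

import itertools

import numpy as np
import pytest
from hypothesis import assume, given, settings
from hypothesis import strategies as st

from acetogenomics.snp import (
    FrameshiftError,
    OrthologPanel,
    SNPRecord,
    call_snps,
    classify_consequence,
    group_summary,
    liftover,
    metrics,
    panel_metrics,
    trim_to_frame,
)
from acetogenomics.synthetic import MutationTruth, simulate_ortholog_panel
from conftest import GENETIC_CODE, oracle_consequence


def make_panel(ref, alts, gene_id="g1", reference="KSO5"):
    alignment = {reference: ref}
    for i, a in enumerate(alts):
        alignment[f"S{i + 1}"] = a
    return OrthologPanel(gene_id=gene_id, alignment=alignment,
                         reference=reference)


class TestClassifyConsequence:
    @pytest.mark.parametrize("ref,alt,expected", [
        ("AAA", "AAG", "synonymous"),      # Lys -> Lys
        ("GAA", "TAA", "nonsense"),        # Glu -> stop
        ("TAA", "CAA", "stop_loss"),       # stop -> Gln
        ("TAA", "TGA", "synonymous"),      # stop -> stop
        ("GCT", "GTT", "nonsynonymous"),   # Ala -> Val
    ])
    def test_examples(self, ref, alt, expected):
        assert classify_consequence(ref, alt) == expected

    def test_ambiguity_code_rejected(self):
        with pytest.raises(ValueError):
            classify_consequence("ANA", "AAA")

    def test_full_single_base_mutation_space_vs_oracle(self):
        # all 64 x 9 single-base codon mutants against the frozen code table
        n = 0
        for codon in map("".join, itertools.product("ACGT", repeat=3)):
            for pos in range(3):
                for base in "ACGT":
                    if base == codon[pos]:
                        continue
                    alt = codon[:pos] + base + codon[pos + 1 :]
                    assert classify_consequence(codon, alt) == \
                        oracle_consequence(codon, alt)
                    n += 1
        assert n == 64 * 9


class TestTrimToFrame:
    def test_trims_to_codon_multiple(self):
        ref = "ATG" + "A" * 299  # 302 nt -> 300
        panel = make_panel(ref, [ref])
        trimmed = trim_to_frame(panel)
        assert trimmed.width == 300

    def test_in_frame_unchanged(self):
        ref = "ATGAAATAA"
        panel = make_panel(ref, [ref])
        assert trim_to_frame(panel).alignment == panel.alignment

    def test_gapped_reference_trimmed_on_reference_bases(self):
        ref = "ATGAAA---CCCG"    # 10 reference nt -> drop one
        alt = "ATGAAATTTCCCG"
        trimmed = trim_to_frame(make_panel(ref, [alt]))
        assert trimmed.alignment["KSO5"].replace("-", "") == "ATGAAACCC"

    def test_internal_frameshift_gap_flagged(self):
        ref = "ATGA--AATAA"
        with pytest.raises(FrameshiftError):
            trim_to_frame(make_panel(ref, ["ATGAcgAATAA".upper()]))

    def test_generator_panels_all_in_frame(self):
        panels, _ = simulate_ortholog_panel(
            5, 4, 40, MutationTruth(per_gene_snp_count=5, seed=3))
        for p in panels:
            assert trim_to_frame(p).alignment == p.alignment


class TestCallSNPs:
    def test_identical_rows_no_snps(self):
        records, compared = call_snps(make_panel("ATGAAATAA", ["ATGAAATAA"]))
        assert records == [] and compared["S1"] == 9

    def test_planted_truth_recovered_exactly(self):
        mt = MutationTruth(per_gene_snp_count=12, titv_target=2.0,
                           nonsyn_target=0.3, seed=21)
        panels, truth = simulate_ortholog_panel(4, 6, 100, mt)
        records = []
        for p in panels:
            recs, _ = call_snps(trim_to_frame(p))
            records.extend(recs)
        records.sort(key=lambda r: (r.gene_id, r.strain, r.ref_pos))
        assert records == truth

    def test_count_equals_hamming_mismatch_oracle(self, rng):
        # per-strain SNP count must equal the ungapped-column mismatch count
        mt = MutationTruth(per_gene_snp_count=15, seed=22)
        panels, _ = simulate_ortholog_panel(3, 5, 80, mt)
        for p in panels:
            recs, _ = call_snps(p)
            ref = p.alignment[p.reference]
            for strain in p.strains:
                ham = sum(a != b for a, b in zip(ref, p.alignment[strain]))
                assert sum(r.strain == strain for r in recs) == ham

    def test_gap_and_ambiguity_columns_skipped(self):
        panel = make_panel("ATGAAACCCTAA", ["ATGA-ACCNTAA"])
        records, compared = call_snps(panel)
        assert records == [] and compared["S1"] == 10

    def test_joint_codon_substitution(self):
        # two substitutions in one codon classified from the joint alt codon:
        # AAA (Lys) -> with A2G and A3C jointly AGC (Ser), nonsynonymous
        records, _ = call_snps(make_panel("ATGAAATAA", ["ATGAGCTAA"]))
        assert len(records) == 2
        assert all(r.consequence == "nonsynonymous" for r in records)
        assert {r.ref_pos for r in records} == {5, 6}


class TestMetrics:
    def test_snps_per_nt(self):
        recs = [SNPRecord("g", "s", p, "A", "G", (p - 1) // 3 + 1,
                          "synonymous", True) for p in (3, 6, 9, 12, 15)]
        m = metrics(recs, "g", "s", 500)
        assert m.snps_per_nt == pytest.approx(0.01)

    def test_titv_ratio(self):
        muts = [("A", "G"), ("C", "T"), ("A", "C")]
        recs = [SNPRecord("g", "s", i + 1, r, a, i + 1, "synonymous",
                          {r, a} in ({"A", "G"}, {"C", "T"}))
                for i, (r, a) in enumerate(muts)]
        assert metrics(recs, "g", "s", 100).titv == pytest.approx(2.0)

    def test_titv_undefined_without_transversions(self):
        recs = [SNPRecord("g", "s", 1, "A", "G", 1, "synonymous", True)]
        assert metrics(recs, "g", "s", 100).titv is None

    def test_nonsyn_fraction(self):
        classes = ["synonymous"] * 3 + ["nonsynonymous"]
        recs = [SNPRecord("g", "s", 3 * i + 1, "A", "G", i + 1, c, True)
                for i, c in enumerate(classes)]
        m = metrics(recs, "g", "s", 100)
        assert m.nonsyn_fraction == pytest.approx(0.25)

    def test_consequence_counts_sum_to_variable_codons(self):
        mt = MutationTruth(per_gene_snp_count=20, seed=5)
        panels, _ = simulate_ortholog_panel(2, 4, 60, mt)
        for m in panel_metrics(panels[0]):
            assert sum(m.counts.values()) == 20  # one SNP per codon planted

    def test_no_variable_codons_undefined(self):
        m = metrics([], "g", "s", 100)
        assert m.nonsyn_fraction is None and m.snps_per_nt == 0.0


class TestLiftover:
    def test_identity_on_ungapped_rows(self):
        assert liftover("ACGTACGT", "ACGTACGT", [1, 5, 8]) == [1, 5, 8]

    def test_target_insertion_shifts_coordinates(self):
        ref = "---ACGTACGT"
        tgt = "TTTACGTACGT"
        assert liftover(ref, tgt, [1, 4]) == [4, 7]

    def test_target_gap_maps_to_none(self):
        assert liftover("ACGT", "AC-T", [1, 3, 4]) == [1, None, 3]

    def test_position_outside_reference_raises(self):
        with pytest.raises(ValueError):
            liftover("ACGT", "ACGT", [5])

    def test_round_trip_identity(self, rng):
        # ref -> target -> ref is the identity wherever both are defined
        for _ in range(20):
            cols = rng.integers(0, 3, size=60)  # 0 both, 1 ref gap, 2 tgt gap
            ref = "".join("-" if c == 1 else "A" for c in cols)
            tgt = "".join("-" if c == 2 else "C" for c in cols)
            n_ref = ref.count("A")
            if n_ref == 0:
                continue
            fwd = liftover(ref, tgt, list(range(1, n_ref + 1)))
            for p, q in zip(range(1, n_ref + 1), fwd):
                if q is not None:
                    assert liftover(tgt, ref, [q]) == [p]


@settings(max_examples=60, deadline=None, derandomize=True)
@given(st.lists(st.sampled_from([0, 1, 2]), min_size=1, max_size=80))
def test_liftover_round_trip_property(cols):
    """ref -> target -> ref is the identity wherever both are ungapped."""
    ref = "".join("-" if c == 1 else "A" for c in cols)
    tgt = "".join("-" if c == 2 else "C" for c in cols)
    n_ref = ref.count("A")
    assume(n_ref > 0)
    fwd = liftover(ref, tgt, list(range(1, n_ref + 1)))
    for p, q in zip(range(1, n_ref + 1), fwd):
        if q is not None:
            assert liftover(tgt, ref, [q]) == [p]


class TestGroupSummary:
    def test_single_value_median(self):
        mt = MutationTruth(per_gene_snp_count=6, seed=1)
        panels, _ = simulate_ortholog_panel(1, 2, 50, mt,
                                            strain_names=["LMG1545"])
        summary = group_summary(panel_metrics(panels[0]),
                                mechanism_map={"gene_001": "ros_detox"})
        row = summary.iloc[0]
        assert row["lineage"] == "Vinegar"
        assert row["snps_per_nt_median"] == pytest.approx(6 / 150)

    def test_planted_rate_ordering_between_lineages(self):
        # lineage A planted at 4x the SNP rate of lineage B
        hi = MutationTruth(per_gene_snp_count=20, seed=31)
        lo = MutationTruth(per_gene_snp_count=5, seed=32)
        ok = 0
        for rep in range(20):
            hi.seed, lo.seed = 100 + rep, 200 + rep
            ph, _ = simulate_ortholog_panel(3, 4, 80, hi,
                                            strain_names=["b1", "b2", "b3"])
            pl, _ = simulate_ortholog_panel(3, 4, 80, lo,
                                            strain_names=["v1", "v2", "v3"])
            ms = [m for p in ph + pl for m in panel_metrics(p)]
            lineage = {f"b{i}": "Beer" for i in range(1, 4)}
            lineage.update({f"v{i}": "Vinegar" for i in range(1, 4)})
            s = group_summary(ms, mechanism_map={}, lineage_map=lineage)
            s = s.set_index("lineage")
            ok += (s.loc["Beer", "snps_per_nt_median"]
                   > s.loc["Vinegar", "snps_per_nt_median"])
        assert ok >= 19

    def test_undefined_values_excluded_with_counts(self):
        recs = [SNPRecord("g", "LMG1545", 1, "A", "G", 1, "synonymous", True)]
        m = metrics(recs, "g", "LMG1545", 100)  # Ti/Tv undefined (no Tv)
        s = group_summary([m], mechanism_map={"g": "other"}).iloc[0]
        assert s["titv_n"] == 0 and np.isnan(s["titv_median"])
        assert s["snps_per_nt_n"] == 1
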