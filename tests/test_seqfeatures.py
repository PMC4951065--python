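"""CAI, folding energy, composition features, pI, feature table assembly."""

import numpy as np
import pandas as pd
import pytest

from dielomix._fold import MIN_LOOP, _PAIR_ENERGY, mfe_energy
from dielomix.datatypes import GeneSequenceRecord
from dielomix.seqfeatures import (
    AA_ALPHABET,
    assemble_feature_table,
    compute_cai,
    compute_composition_features,
    compute_mfe,
    gc3,
    isoelectric_point,
)


def enumerate_mfe(seq: str) -> float:
    """Exhaustive minimum energy over all non-crossing structures (oracle).

    Independent of the DP: recursively decides, for the last base, whether it
    stays unpaired or pairs with any admissible partner.
    """
    s = seq.upper().replace("T", "U")

    def best(i: int, j: int) -> float:
        if j - i < MIN_LOOP + 1:
            return 0.0
        # base j unpaired
        out = best(i, j - 1)
        for k in range(i, j - MIN_LOOP):
            e = _PAIR_ENERGY.get((s[k], s[j]))
            if e is not None:
                out = min(out, best(i, k - 1) + best(k + 1, j - 1) + e)
        return out

    return best(0, len(s) - 1)


class TestCai:
    def test_all_optimal_codons_give_one(self):
        ref = {"GCC": 10, "GCA": 2, "GCG": 1, "GCT": 1}  # Ala family
        assert compute_cai("GCCGCCGCC", ref) == pytest.approx(1.0)

    def test_constant_half_weight(self):
        ref = {"GCC": 10, "GCA": 5, "GCG": 1, "GCT": 1}
        assert compute_cai("GCAGCAGCA", ref) == pytest.approx(0.5)

    def test_met_only_gene_is_missing(self):
        assert np.isnan(compute_cai("ATG", {"ATG": 5}))

    def test_synonymous_permutation_invariance(self):
        rng = np.random.default_rng(0)
        ref = {"GCC": 8, "GCA": 4, "AAA": 3, "AAG": 9, "GAT": 5, "GAC": 2}
        codons = ["GCC", "GCA", "AAA", "AAG", "GAT", "GAC"] * 3
        base = compute_cai("".join(codons), ref)
        for _ in range(5):
            rng.shuffle(codons)
            assert compute_cai("".join(codons), ref) == pytest.approx(base)

    def test_bad_cds_rejected(self):
        with pytest.raises(ValueError):
            compute_cai("GC", {})


class TestMfe:
    def test_unpairable_sequence_is_zero(self):
        assert mfe_energy("AAAAAAAAAA") == 0.0

    def test_three_gc_stack(self):
        assert mfe_energy("GGGAAAACCC") == -9.0

    def test_never_positive_and_matches_oracle(self):
        rng = np.random.default_rng(1)
        for _ in range(40):
            n = rng.integers(1, 11)
            seq = "".join(rng.choice(list("ACGU"), size=n))
            got = mfe_energy(seq)
            assert got <= 0
            assert got == pytest.approx(enumerate_mfe(seq))

    def test_tu_equivalence_and_validation(self):
        assert mfe_energy("GGGAAAACCC") == mfe_energy("GGGAAAACCC".replace("C", "C"))
        assert compute_mfe("GGGTTTTCCC") == compute_mfe("GGGUUUUCCC")
        with pytest.raises(ValueError, match="non-ACGTU"):
            compute_mfe("GGXCC")

    def test_cds_first50_region(self):
        seq = "A" * 50 + "GGGAAAACCC"
        assert compute_mfe(seq, region="cds_first50") == 0.0

    def test_pluggable_engine(self):
        assert compute_mfe("GGGAAAACCC", engine=lambda s: -42.0) == -42.0


class TestComposition:
    def test_gc3(self):
        assert gc3("ATGGCG") == 1.0
        assert gc3("ATAGCA") == 0.0

    def test_tt_dinucleotide_fraction(self):
        rec = GeneSequenceRecord("g", "ATGAAATAA", utr5="ACGT", utr3="TTTT")
        feats = compute_composition_features(rec)
        assert feats["utr3_tt"] == pytest.approx(1.0)

    def test_proportions_sum_to_one(self):
        rec = GeneSequenceRecord(
            "g", "ATGGCGAAATTTCGATCATAA", utr5="ACGTAC", utr3="TTAAGG"
        )
        feats = compute_composition_features(rec)
        for region in ("cds", "utr5", "utr3", "mrna"):
            assert sum(feats[f"{region}_{b}"] for b in "acgt") == pytest.approx(1.0)
            dinucs = [v for k, v in feats.items()
                      if k.startswith(f"{region}_") and len(k.split("_")[-1]) == 2]
            assert sum(dinucs) == pytest.approx(1.0)
        aa_total = sum(feats[f"aa_{a.lower()}"] for a in AA_ALPHABET)
        assert aa_total == pytest.approx(1.0)

    def test_absent_utr_features_are_missing_not_zero(self):
        rec = GeneSequenceRecord("g", "ATGAAATAA", utr5="", utr3="")
        feats = compute_composition_features(rec)
        assert np.isnan(feats["utr5_gc_content"]) and np.isnan(feats["len_utr3"])

    def test_glycine_dipeptide_pi(self):
        # symmetric titratable groups: pI = (9.60 + 2.34) / 2
        assert isoelectric_point("GG") == pytest.approx(5.97, abs=1e-3)

    def test_relative_cds_length(self):
        rec = GeneSequenceRecord("g", "ATGTAA", utr5="AA", utr3="TT")
        feats = compute_composition_features(rec)
        assert feats["relative_cds_len"] == pytest.approx(0.6)


class TestAssembly:
    def test_complete_records_have_no_incomplete_flags(self):
        records = [
            GeneSequenceRecord(f"g{i}", "ATGGCGAAATGA", utr5="ACGTACGT", utr3="TTGGAACC")
            for i in range(3)
        ]
        table = assemble_feature_table(records)
        assert table.incomplete.sum() == 0
        assert "cai" in table.values.columns and "mfe_utr5" in table.values.columns

    def test_missing_utr_flags_incomplete(self):
        records = [
            GeneSequenceRecord("g0", "ATGGCGAAATGA", utr5="ACGTACGT", utr3="TTGGAACC"),
            GeneSequenceRecord("g1", "ATGGCGAAATGA", utr5="ACGTACGT", utr3=""),
        ]
        with pytest.warns(UserWarning, match="incomplete"):
            table = assemble_feature_table(records)
        assert not table.incomplete["g0"] and table.incomplete["g1"]
        assert list(table.complete_genes) == ["g0"]

    def test_duplicate_ids_rejected(self):
        records = [
            GeneSequenceRecord("g0", "ATGTAA"),
            GeneSequenceRecord("g0", "ATGTAA"),
        ]
        with pytest.raises(ValueError, match="duplicate"):
            assemble_feature_table(records)

    def test_reference_codon_table_override_changes_cai(self):
        records = [
            GeneSequenceRecord("g0", "ATGGCAGCATGA", utr5="ACGTA", utr3="TACGT"),
            GeneSequenceRecord("g1", "ATGGCCGCCTGA", utr5="ACGTA", utr3="TACGT"),
        ]
        t1 = assemble_feature_table(records, reference_codon_counts={"GCC": 10, "GCA": 1})
        t2 = assemble_feature_table(records, reference_codon_counts={"GCC": 1, "GCA": 10})
        assert t1.values.loc["g1", "cai"] > t1.values.loc["g0", "cai"]
        assert t2.values.loc["g0", "cai"] > t2.values.loc["g1", "cai"]

    def test_annotations_merged_as_flags(self):
        records = [
            GeneSequenceRecord("g0", "ATGGCGAAATGA", utr5="ACGTT", utr3="GGCCA"),
        ]
        annot = pd.DataFrame({"chloroplast": [1]}, index=["g0"])
        table = assemble_feature_table(records, annotations=annot)
        assert table.values.loc["g0", "annot_chloroplast"] == 1.0
        assert table.metadata.loc["annot_chloroplast", "category"] == "annotation flag"


def test_halflife_proxy_behind_flag():
    records = [
        GeneSequenceRecord("g0", "ATGGTGGCGTGA", utr5="ACGTA", utr3="TACGT"),
        GeneSequenceRecord("g1", "ATGCAAGCGTGA", utr5="ACGTA", utr3="TACGT"),
    ]
    default = assemble_feature_table(records)
    assert "halflife_nend" not in default.values.columns
    with_proxy = assemble_feature_table(records, include_halflife_proxy=True)
    # Val after Met is maximally stabilizing; Gln destabilizing
    assert with_proxy.values.loc["g0", "halflife_nend"] > \
        with_proxy.values.loc["g1", "halflife_nend"]
    assert with_proxy.metadata.loc["halflife_nend", "category"] == "physicochemical"
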