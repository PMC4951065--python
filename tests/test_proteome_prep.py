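"""Peptide filtering, quantile normalization, rollup and differential tests."""

import numpy as np
import pandas as pd
import pytest

from dielomix.datatypes import ExpressionMatrix, PeptideTable
from dielomix.proteome_prep import (
    EmptyFilterError,
    filter_peptides,
    normalize_and_rollup,
    presence_absence,
    progressive_differential,
    quantile_normalize,
    rollup_proteins,
)


def _mapping(entries):
    return pd.DataFrame(
        {
            "protein_ids": [tuple(p) for p in entries.values()],
            "unique": [len(p) == 1 for p in entries.values()],
        },
        index=pd.Index(entries.keys(), name="peptide_id"),
    )


class TestFiltering:
    def test_coverage_threshold_keeps_half_observed_peptide(self, toy_peptide_table):
        # B_p1 is seen in 3/12 datasets (below half), B_p2 in 12/12
        kept = filter_peptides(toy_peptide_table, variance_quantile=0)
        assert "B_p1" not in kept.abundance.index
        # A peptide observed in exactly 6 of 12 datasets meets the 50% rule
        assert "E_p1" in kept.abundance.index and "E_p2" in kept.abundance.index

    def test_single_peptide_proteins_dropped(self, toy_peptide_table):
        kept = filter_peptides(toy_peptide_table, variance_quantile=0)
        proteins = {p[0] for p in kept.mapping["protein_ids"]}
        assert "C" not in proteins  # only one peptide
        assert "B" not in proteins  # one peptide left after coverage filter
        assert "D" not in proteins  # second peptide is shared, not unique
        assert {"A", "E"} <= proteins

    def test_zero_variance_quantile_is_noop(self, toy_peptide_table):
        a = filter_peptides(toy_peptide_table, variance_quantile=0)
        b = filter_peptides(toy_peptide_table, variance_quantile=0.0)
        pd.testing.assert_frame_equal(a.abundance, b.abundance)

    def test_variance_filter_removes_erratic_peptide(self):
        rng = np.random.default_rng(0)
        n = 40
        ds = pd.DataFrame(
            {"timepoint": ["T1"] * 12, "biorep": [1] * 12, "techrep": range(12)},
            index=[f"d{i}" for i in range(12)],
        )
        rows = {f"P{i}_p{j}": 5 + rng.normal(0, 0.05, 12) for i in range(n // 2) for j in (1, 2)}
        rows["P0_p1"] = 5 + rng.normal(0, 3.0, 12)  # erratic
        ab = pd.DataFrame(rows).T
        ab.columns = ds.index
        mapping = _mapping({k: (k.split("_")[0],) for k in rows})
        pep = PeptideTable(ab, mapping, ds)
        kept = filter_peptides(pep, variance_quantile=0.95)
        assert "P0_p1" not in kept.abundance.index

    def test_everything_filtered_raises(self, toy_peptide_table):
        with pytest.raises(EmptyFilterError):
            filter_peptides(toy_peptide_table, min_dataset_fraction=1.1)


class TestQuantileNormalization:
    def test_order_statistic_means(self):
        df = pd.DataFrame({"a": [1.0, 2.0, 3.0], "b": [4.0, 5.0, 6.0]})
        out = quantile_normalize(df)
        expected = pd.DataFrame({"a": [2.5, 3.5, 4.5], "b": [2.5, 3.5, 4.5]})
        pd.testing.assert_frame_equal(out, expected)

    def test_columns_share_sorted_values(self):
        rng = np.random.default_rng(1)
        df = pd.DataFrame(rng.normal(size=(50, 4)), columns=list("abcd"))
        out = quantile_normalize(df)
        ref = np.sort(out["a"].to_numpy())
        for col in "bcd":
            np.testing.assert_allclose(np.sort(out[col].to_numpy()), ref)


class TestRollup:
    def test_identical_peptides_give_peptide_row(self):
        mat = pd.DataFrame(
            {"s1": [1.0, 1.0], "s2": [2.0, 2.0]}, index=["p1", "p2"]
        )
        mapping = _mapping({"p1": ("X",), "p2": ("X",)})
        data, counts = rollup_proteins(mat, mapping)
        np.testing.assert_allclose(data.loc["X"], [1.0, 2.0])
        assert counts["X"] == 2

    def test_constant_offset_invariance(self):
        # p1 has the most observations, so it anchors the rollup; a constant
        # ionization offset on p2 must cancel exactly.
        rng = np.random.default_rng(2)
        base = rng.normal(5, 1, 6)
        p2 = base + 0.3
        p2[0] = np.nan  # one missing value -> p1 is the reference
        mat = pd.DataFrame(
            {"p1": base, "p2": p2}, index=[f"s{i}" for i in range(6)]
        ).T
        mapping = _mapping({"p1": ("X",), "p2": ("X",)})
        data, _ = rollup_proteins(mat, mapping)
        np.testing.assert_allclose(data.loc["X"], base)
        # and any constant gives the same answer
        mat2 = mat.copy()
        mat2.loc["p2"] = mat.loc["p2"] + 1.7
        data2, _ = rollup_proteins(mat2, mapping)
        np.testing.assert_allclose(data2.loc["X"], base)

    def test_rollup_via_pipeline_has_two_peptide_minimum(self, toy_peptide_table):
        filtered = filter_peptides(toy_peptide_table, variance_quantile=0)
        protein = normalize_and_rollup(filtered, level="timepoint")
        assert (protein.n_peptides >= 2).all()
        assert list(protein.data.columns) == ["T1", "T2"]


class TestPresence:
    def test_hand_computed_presence_calls(self, toy_peptide_table):
        presence = presence_absence(toy_peptide_table)
        # A: 2 unique fully observed peptides -> present at both.
        # B: B_p1 covers 3 of 6 T1 datasets (exactly the 50% rule) and B_p2 is
        #    fully observed -> present at T1 only.
        # E: 2 peptides covering all of T1 only -> present at T1, absent T2.
        # D: one unique peptide only -> absent; C single peptide -> absent.
        assert presence["T1"] == {"A", "B", "E"}
        assert presence["T2"] == {"A"}
        assert presence["all"] == {"A"}

    def test_presence_monotone_in_dataset_fraction(self, toy_peptide_table):
        strict = presence_absence(toy_peptide_table, min_dataset_fraction=0.9)
        lax = presence_absence(toy_peptide_table, min_dataset_fraction=0.3)
        for tp in ("T1", "T2", "all"):
            assert strict[tp] <= lax[tp]

    def test_no_missingness_means_all_present(self, noiseless_bundle):
        # every protein has >=1 peptide; only those with >=2 unique count
        presence = presence_absence(noiseless_bundle.peptides)
        mapping = noiseless_bundle.peptides.mapping
        per_protein = mapping[mapping["unique"]].groupby(
            mapping["protein_ids"].map(lambda p: p[0])
        ).size()
        expected = set(per_protein.index[per_protein >= 2])
        for tp in noiseless_bundle.protein.timepoints:
            assert presence[tp] == expected


class TestProgressiveDifferential:
    def _matrix(self, values):
        cols, meta = [], []
        for tp in ("T1", "T2", "T3", "T4"):
            for rep in (1, 2, 3):
                cols.append(f"{tp}_b{rep}")
                meta.append((f"{tp}_b{rep}", tp, rep))
        data = pd.DataFrame(values, index=["prot1"], columns=cols)
        samples = pd.DataFrame(
            meta, columns=["sample_id", "timepoint", "biorep"]
        ).set_index("sample_id")
        return ExpressionMatrix(data, samples)

    def test_identical_groups_not_significant(self):
        expr = self._matrix([[5.0] * 12])
        out = progressive_differential(expr)
        assert out.empty

    def test_planted_tenfold_shift_detected(self):
        rng = np.random.default_rng(3)
        vals = np.concatenate([
            rng.normal(5, 0.05, 3),   # T1
            rng.normal(6, 0.05, 3),   # T2 = 10x up
            rng.normal(6, 0.05, 3),
            rng.normal(6, 0.05, 3),
        ])
        out = progressive_differential(self._matrix([vals]))
        row = out[out["comparison"] == "T1->T2"]
        assert len(row) == 1 and row["direction"].iloc[0] == "up"
        assert row["p"].iloc[0] < 0.05

    def test_alpha_one_reports_everything(self):
        rng = np.random.default_rng(4)
        out = progressive_differential(
            self._matrix([rng.normal(5, 0.1, 12)]), alpha=1.0
        )
        assert set(out["comparison"]) == {"T3->T4", "T4->T1", "T1->T2", "T2->T3"}

    def test_single_replicate_errors(self):
        data = pd.DataFrame([[1.0, 2.0]], index=["p"], columns=["a", "b"])
        samples = pd.DataFrame(
            {"timepoint": ["T1", "T2"], "biorep": [1, 1]}, index=["a", "b"]
        )
        with pytest.raises(ValueError, match="replicates"):
            progressive_differential(ExpressionMatrix(data, samples))
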