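"""Core in-memory containers shared by all analysis stages.

All expression values are log10 abundances. Samples are described by a
sample sheet (one row per measurement column) so that replicate structure
travels with the matrix.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from Bio.Seq import Seq

TIMEPOINT_LABELS = ("T1", "T2", "T3", "T4")  # mid-day, dusk, pre-dawn, lights-on


def timepoint_order(timepoints) -> list[str]:
    """Canonical ordering of time-point labels (T1, T2, ... by numeric suffix)."""
    return sorted(set(timepoints), key=lambda t: (len(str(t)), str(t)))


@dataclass
class ExpressionMatrix:
    """Gene x sample abundance matrix for one data type (mRNA or protein).

    Parameters
    ----------
    data : DataFrame
        Genes in rows, sample ids in columns, log10 abundance values.
    samples : DataFrame
        Indexed by sample id; must carry a ``timepoint`` column and may
        carry ``biorep`` / ``techrep`` / ``datatype`` columns.
    """

    data: pd.DataFrame
    samples: pd.DataFrame

    def __post_init__(self) -> None:
        missing = [c for c in self.data.columns if c not in self.samples.index]
        if missing:
            raise ValueError(f"samples sheet lacks entries for columns: {missing[:5]}")
        if "timepoint" not in self.samples.columns:
            raise ValueError("sample sheet must contain a 'timepoint' column")

    @property
    def genes(self) -> pd.Index:
        return self.data.index

    @property
    def timepoints(self) -> list[str]:
        return timepoint_order(self.samples.loc[self.data.columns, "timepoint"])

    def timepoint_means(self) -> pd.DataFrame:
        """Average replicate columns within each time point (NaN-aware)."""
        tp = self.samples.loc[self.data.columns, "timepoint"]
        out = self.data.T.groupby(tp.values).mean().T
        return out[self.timepoints]

    def subset_genes(self, genes) -> "ExpressionMatrix":
        return ExpressionMatrix(self.data.loc[list(genes)], self.samples)


@dataclass
class PeptideTable:
    """Peptide x instrument-dataset log10 abundances with protein mapping.

    ``mapping`` is indexed by peptide id with columns ``protein_ids`` (tuple
    of protein ids) and ``unique`` (True iff exactly one protein id).
    ``datasets`` is indexed by dataset id with columns ``timepoint``,
    ``biorep``, ``techrep``.
    """

    abundance: pd.DataFrame
    mapping: pd.DataFrame
    datasets: pd.DataFrame

    def __post_init__(self) -> None:
        if not self.abundance.index.equals(self.mapping.index):
            self.mapping = self.mapping.loc[self.abundance.index]
        uniq = self.mapping["protein_ids"].map(len) == 1
        if not (self.mapping["unique"] == uniq).all():
            raise ValueError("unique flag inconsistent with protein_ids cardinality")
        vals = self.abundance.to_numpy(dtype=float)
        if np.isinf(vals).any():
            raise ValueError("abundances must be finite where present")

    @property
    def n_datasets(self) -> int:
        return self.abundance.shape[1]

    def subset(self, peptide_ids) -> "PeptideTable":
        idx = list(peptide_ids)
        return PeptideTable(
            self.abundance.loc[idx], self.mapping.loc[idx], self.datasets
        )


@dataclass
class GeneSequenceRecord:
    """CDS / UTR / protein sequences for one gene, with completeness flags."""

    gene_id: str
    cds: str
    utr5: str = ""
    utr3: str = ""
    protein: str = ""
    utr5_complete: bool = True
    utr3_complete: bool = True

    def __post_init__(self) -> None:
        if len(self.cds) % 3 != 0:
            raise ValueError(f"{self.gene_id}: CDS length not a multiple of 3")
        if not self.protein:
            self.protein = str(Seq(self.cds).translate()).rstrip("*")

    def validate(self) -> None:
        """Check the CDS translates to the stored protein with a single terminal stop."""
        aa = str(Seq(self.cds).translate())
        if "*" in aa[:-1]:
            raise ValueError(f"{self.gene_id}: internal stop codon")
        if aa.rstrip("*") != self.protein:
            raise ValueError(f"{self.gene_id}: protein does not match CDS translation")

    @property
    def transcript(self) -> str:
        return self.utr5 + self.cds + self.utr3


@dataclass
class GroundTruth:
    """Planted parameters of a simulated study (per-gene arrays keyed by gene id)."""

    genes: list[str]
    delay_class: dict[str, str]          # "delay0".."delay3", "anti", "independent"
    hptr: dict[str, bool]
    hptr_sign: dict[str, int]            # +1 over-estimated, -1 under-estimated, 0 none
    codon_bias: dict[str, float]
    feature_effects: dict[str, float] = field(default_factory=dict)
    baseline: dict[str, float] = field(default_factory=dict)
    hptr_program: dict[str, str] = field(default_factory=dict)
    protein_true: pd.DataFrame | None = None  # gene x sample, before peptide sampling
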