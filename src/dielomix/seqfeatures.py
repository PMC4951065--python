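"""Sequence-derived features used as proxies for post-transcriptional regulation.

Computes, per gene, a table of real-valued features from the CDS, UTRs and
protein sequence: nucleotide and dinucleotide composition, GC3, lengths,
minimum folding energy (MFE) of the UTRs and of the first 50 CDS
nucleotides, codon adaptation index (CAI), amino-acid and amino-acid-class
proportions, and a hypothetical isoelectric point. Optional binary
annotations (predicted chloroplast localization, Introner-element status)
are merged in as extra columns.
"""

from __future__ import annotations

import itertools
import warnings
from collections import Counter
from dataclasses import dataclass
from typing import Callable, Iterable, Mapping

import numpy as np
import pandas as pd
from Bio.Data.CodonTable import standard_dna_table

from dielomix._fold import mfe_energy
from dielomix.datatypes import ExpressionMatrix, GeneSequenceRecord

# ---------------------------------------------------------------------------
# codon machinery

STOP_CODONS = set(standard_dna_table.stop_codons)
CODON_TO_AA = dict(standard_dna_table.forward_table)  # sense codons only
SENSE_CODONS = sorted(CODON_TO_AA)

_SYNONYMS: dict[str, list[str]] = {}
for _codon, _aa in CODON_TO_AA.items():
    _SYNONYMS.setdefault(_aa, []).append(_codon)
for _aa in _SYNONYMS:
    _SYNONYMS[_aa].sort()

#: amino acids excluded from CAI (single-codon families carry no information)
CAI_EXCLUDED_AA = {"M", "W"}

AA_ALPHABET = sorted(_SYNONYMS)

#: amino-acid class groupings (documented convention; configurable)
AA_CLASSES: dict[str, str] = {
    "acidic": "DE",
    "basic": "KRH",
    "polar": "STNQCY",
    "nonpolar": "AVLIPFMWG",
    "aromatic": "FWY",
    "aliphatic": "AVLI",
}

#: pKa values for the isoelectric-point bisection (classic textbook table)
DEFAULT_PKA = {
    "n_term": 9.60,
    "c_term": 2.34,
    "D": 3.65,
    "E": 4.25,
    "C": 8.33,
    "Y": 10.07,
    "H": 6.00,
    "K": 10.53,
    "R": 12.48,
}

_DINUCS = ["".join(p) for p in itertools.product("ACGT", repeat=2)]

#: N-end-rule half-life estimates in hours (mammalian reticulocyte values),
#: keyed by the residue after the initiator Met; a crude stability proxy
#: that is off by default because it did not add predictive value.
NEND_HALFLIFE_HOURS = {
    "A": 4.4, "R": 1.0, "N": 1.4, "D": 1.1, "C": 1.2, "E": 1.0, "Q": 0.8,
    "G": 30.0, "H": 3.5, "I": 20.0, "L": 5.5, "K": 1.3, "M": 30.0, "F": 1.1,
    "P": 20.0, "S": 1.9, "T": 7.2, "W": 2.8, "Y": 2.8, "V": 100.0,
}


def halflife_proxy(protein: str) -> float:
    """N-end-rule half-life proxy (hours) from the residue after Met."""
    if len(protein) < 2:
        return float("nan")
    return NEND_HALFLIFE_HOURS.get(protein[1], float("nan"))


def split_codons(cds: str) -> list[str]:
    cds = cds.upper().replace("U", "T")
    if len(cds) % 3 != 0:
        raise ValueError("CDS length not divisible by 3")
    return [cds[i : i + 3] for i in range(0, len(cds), 3)]


def compute_cai(cds: str, reference_codon_counts: Mapping[str, float]) -> float:
    """Codon adaptation index of a CDS against a reference codon-usage set.

    Relative adaptiveness w(c) = count(c) / max count among synonymous codons
    in the reference (zero counts get a 0.5 pseudocount); CAI is the geometric
    mean of w over the gene's codons, excluding Met, Trp and stop codons.
    Returns NaN when no informative codons remain.
    """
    counts = {c: float(reference_codon_counts.get(c, 0.0)) for c in SENSE_CODONS}
    for c in counts:
        if counts[c] <= 0.0:
            counts[c] = 0.5
    w: dict[str, float] = {}
    for aa, codons in _SYNONYMS.items():
        mx = max(counts[c] for c in codons)
        for c in codons:
            w[c] = counts[c] / mx
    logs = []
    for codon in split_codons(cds):
        if codon in STOP_CODONS:
            continue
        aa = CODON_TO_AA.get(codon)
        if aa is None:
            raise ValueError(f"invalid codon {codon!r}")
        if aa in CAI_EXCLUDED_AA:
            continue
        logs.append(np.log(w[codon]))
    if not logs:
        return float("nan")
    return float(np.exp(np.mean(logs)))


def codon_counts(sequences: Iterable[str]) -> Counter:
    """Aggregate sense-codon counts over a collection of CDS strings."""
    counts: Counter = Counter()
    for cds in sequences:
        for codon in split_codons(cds):
            if codon in CODON_TO_AA:
                counts[codon] += 1
    return counts


# ---------------------------------------------------------------------------
# folding

Folder = Callable[[str], float]


def compute_mfe(seq: str, region: str | None = None, engine: Folder | None = None) -> float:
    """Minimum folding energy of a region.

    ``region`` selects the sequence slice: ``"cds_first50"`` folds the first
    min(50, len) nucleotides; ``"utr5"``/``"utr3"``/None fold the whole input.
    ``engine`` replaces the built-in dynamic-programming folder with an
    external thermodynamic one (any callable ``str -> float``).
    """
    if len(seq) == 0:
        raise ValueError("empty sequence")
    if region == "cds_first50":
        seq = seq[: min(50, len(seq))]
    folder = engine or mfe_energy
    return float(folder(seq))


# ---------------------------------------------------------------------------
# composition

def isoelectric_point(
    protein: str, pka: Mapping[str, float] = DEFAULT_PKA, tol: float = 1e-4
) -> float:
    """Hypothetical pI by bisection on the Henderson-Hasselbalch net charge."""
    if not protein:
        return float("nan")
    counts = Counter(protein)

    def net_charge(ph: float) -> float:
        pos = 1.0 / (1.0 + 10 ** (ph - pka["n_term"]))
        for aa in "HKR":
            if aa in pka and counts.get(aa, 0):
                pos += counts[aa] / (1.0 + 10 ** (ph - pka[aa]))
        neg = 1.0 / (1.0 + 10 ** (pka["c_term"] - ph))
        for aa in "DECY":
            if aa in pka and counts.get(aa, 0):
                neg += counts[aa] / (1.0 + 10 ** (pka[aa] - ph))
        return pos - neg

    lo, hi = 0.0, 14.0
    while hi - lo > tol:
        mid = 0.5 * (lo + hi)
        if net_charge(mid) > 0:
            lo = mid
        else:
            hi = mid
    return round(0.5 * (lo + hi), 4)


def _mono_props(seq: str) -> dict[str, float]:
    n = len(seq)
    out = {b: seq.count(b) / n for b in "ACGT"}
    # "gc_content" avoids colliding with the GC *dinucleotide* proportion
    out["gc_content"] = out["G"] + out["C"]
    return out


def _dinuc_props(seq: str) -> dict[str, float]:
    n = len(seq) - 1
    if n < 1:
        return {d: float("nan") for d in _DINUCS}
    counts = Counter(seq[i : i + 2] for i in range(n))
    return {d: counts.get(d, 0) / n for d in _DINUCS}


def gc3(cds: str) -> float:
    thirds = cds.upper()[2::3]
    return sum(c in "GC" for c in thirds) / len(thirds)


def compute_composition_features(
    record: GeneSequenceRecord,
    aa_classes: Mapping[str, str] = AA_CLASSES,
    pka: Mapping[str, float] = DEFAULT_PKA,
) -> dict[str, float]:
    """Composition/length/physicochemical features for one gene.

    Features of an absent UTR come back as NaN (missing, never zero).
    """
    feats: dict[str, float] = {}
    cds = record.cds.upper()
    regions = {"cds": cds, "mrna": record.transcript.upper()}
    for name, seq in (("utr5", record.utr5), ("utr3", record.utr3)):
        regions[name] = seq.upper() if seq else ""

    for region, seq in regions.items():
        if seq:
            for base, val in _mono_props(seq).items():
                feats[f"{region}_{base.lower()}"] = val
            for dn, val in _dinuc_props(seq).items():
                feats[f"{region}_{dn.lower()}"] = val
            feats[f"len_{region}"] = float(len(seq))
        else:
            for base in ("a", "c", "g", "t", "gc_content"):
                feats[f"{region}_{base}"] = float("nan")
            for dn in _DINUCS:
                feats[f"{region}_{dn.lower()}"] = float("nan")
            feats[f"len_{region}"] = float("nan")

    feats["cds_gc3"] = gc3(cds)
    feats["relative_cds_len"] = len(cds) / len(record.transcript)

    prot = record.protein
    n_aa = len(prot)
    for aa in AA_ALPHABET:
        feats[f"aa_{aa.lower()}"] = prot.count(aa) / n_aa if n_aa else float("nan")
    for cls, members in aa_classes.items():
        feats[f"aaclass_{cls}"] = (
            sum(prot.count(a) for a in members) / n_aa if n_aa else float("nan")
        )
    feats["pi"] = isoelectric_point(prot, pka=pka)
    return feats


# ---------------------------------------------------------------------------
# feature table assembly

@dataclass
class FeatureTable:
    """Gene x feature table with per-feature metadata and completeness flags."""

    values: pd.DataFrame                   # gene x feature
    metadata: pd.DataFrame                 # feature -> region, category
    incomplete: pd.Series                  # gene -> bool (missing required features)

    @property
    def complete_genes(self) -> pd.Index:
        return self.values.index[~self.incomplete]


_CATEGORY_BY_PREFIX = [
    ("mfe_", "structure"),
    ("aa_", "amino-acid proportion"),
    ("aaclass_", "amino-acid class proportion"),
    ("len_", "length"),
    ("relative_cds_len", "length"),
    ("cai", "codon usage"),
    ("cds_gc3", "codon usage"),
    ("pi", "physicochemical"),
    ("halflife", "physicochemical"),
]


def _feature_category(name: str) -> str:
    for prefix, cat in _CATEGORY_BY_PREFIX:
        if name.startswith(prefix):
            return cat
    return "nucleotide/dinucleotide composition"


def _feature_region(name: str) -> str:
    for region in ("utr5", "utr3", "mrna", "cds"):
        if region in name:
            return region
    return (
        "protein"
        if name.startswith(("aa_", "aaclass_", "pi", "halflife"))
        else "gene"
    )


def assemble_feature_table(
    records: Iterable[GeneSequenceRecord],
    annotations: pd.DataFrame | None = None,
    mrna: ExpressionMatrix | None = None,
    reference_codon_counts: Mapping[str, float] | None = None,
    mfe_engine: Folder | None = None,
    reference_top_fraction: float = 0.1,
    include_halflife_proxy: bool = False,
) -> FeatureTable:
    """Compute the full feature table for a collection of gene records.

    The CAI reference set defaults to the aggregate codon counts of the top
    ``reference_top_fraction`` of genes by mean mRNA abundance (Sharp-Li style
    highly-expressed reference); pass ``reference_codon_counts`` to override.
    Genes with any missing required feature (e.g. an absent UTR) are flagged
    incomplete and excluded later from model training.
    """
    records = list(records)
    ids = [r.gene_id for r in records]
    if len(set(ids)) != len(ids):
        dupes = [g for g, c in Counter(ids).items() if c > 1]
        raise ValueError(f"duplicate gene ids: {dupes[:5]}")

    if reference_codon_counts is None:
        if mrna is None:
            reference_codon_counts = codon_counts(r.cds for r in records)
        else:
            means = mrna.data.mean(axis=1)
            means = means[means.index.intersection(ids)]
            n_top = max(1, int(np.ceil(reference_top_fraction * len(means))))
            top = set(means.sort_values(ascending=False).index[:n_top])
            reference_codon_counts = codon_counts(
                r.cds for r in records if r.gene_id in top
            )

    rows = {}
    for rec in records:
        feats = compute_composition_features(rec)
        feats["cai"] = compute_cai(rec.cds, reference_codon_counts)
        feats["mfe_utr5"] = (
            compute_mfe(rec.utr5, engine=mfe_engine) if rec.utr5 else float("nan")
        )
        feats["mfe_utr3"] = (
            compute_mfe(rec.utr3, engine=mfe_engine) if rec.utr3 else float("nan")
        )
        feats["mfe_cds50"] = compute_mfe(rec.cds, region="cds_first50", engine=mfe_engine)
        if include_halflife_proxy:
            feats["halflife_nend"] = halflife_proxy(rec.protein)
        rows[rec.gene_id] = feats

    values = pd.DataFrame.from_dict(rows, orient="index")
    if annotations is not None:
        extra = annotations.reindex(values.index)
        for col in extra.columns:
            values[f"annot_{col}"] = extra[col].astype(float)

    meta = pd.DataFrame(
        {
            "region": [_feature_region(f) for f in values.columns],
            "category": [
                "annotation flag" if f.startswith("annot_") else _feature_category(f)
                for f in values.columns
            ],
        },
        index=values.columns,
    )
    required = [c for c in values.columns if not c.startswith("annot_")]
    incomplete = values[required].isna().any(axis=1)
    n_inc = int(incomplete.sum())
    if n_inc:
        warnings.warn(f"{n_inc} genes flagged incomplete (missing required features)")
    return FeatureTable(values=values, metadata=meta, incomplete=incomplete)
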