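"""Peptide-level proteomics preparation.

Filters peptides (uniqueness, dataset coverage, residual variance), quantile
normalizes, averages technical then biological replicates, rolls peptides up
to protein abundances (reference-peptide scaling + median, RRollup-style),
and produces presence/absence and progressive adjacent-time-point
differential summaries.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from dielomix.datatypes import ExpressionMatrix, PeptideTable, timepoint_order


class EmptyFilterError(ValueError):
    """No peptides survive filtering."""


def _protein_of(mapping: pd.DataFrame) -> pd.Series:
    """Primary protein id per peptide (first mapped protein)."""
    return mapping["protein_ids"].map(lambda p: p[0])


def filter_peptides(
    pep: PeptideTable,
    min_dataset_fraction: float = 0.5,
    variance_quantile: float = 0.95,
) -> PeptideTable:
    """Uniqueness, coverage, variance and single-peptide-protein filters.

    Keeps unique peptides observed in at least
    ceil(min_dataset_fraction * n_datasets) instrument datasets, drops
    peptides whose residual variance around a fitted mean-variance trend
    exceeds the ``variance_quantile`` quantile (0 disables the variance
    filter), then removes proteins left with a single peptide.
    """
    if pep.abundance.empty:
        raise EmptyFilterError("empty peptide table")
    keep = pep.mapping["unique"].to_numpy()

    n_obs = pep.abundance.notna().sum(axis=1).to_numpy()
    min_obs = math.ceil(min_dataset_fraction * pep.n_datasets)
    keep &= n_obs >= min_obs

    if variance_quantile > 0:
        means = pep.abundance.mean(axis=1).to_numpy()
        variances = pep.abundance.var(axis=1, ddof=1).to_numpy()
        ok = keep & np.isfinite(means) & np.isfinite(variances)
        if ok.sum() >= 3:
            slope, intercept = np.polyfit(means[ok], variances[ok], 1)
            resid = variances - (slope * means + intercept)
            thresh = np.quantile(resid[ok], variance_quantile)
            keep &= ~(np.isfinite(resid) & (resid > thresh))

    kept_ids = pep.abundance.index[keep]
    if len(kept_ids) == 0:
        raise EmptyFilterError("no peptides survive filtering")
    sub = pep.subset(kept_ids)

    # proteins represented by a single peptide are removed
    per_protein = _protein_of(sub.mapping).value_counts()
    multi = set(per_protein.index[per_protein >= 2])
    final = sub.mapping.index[_protein_of(sub.mapping).isin(multi)]
    if len(final) == 0:
        raise EmptyFilterError("no peptides survive filtering")
    return sub.subset(final)


def quantile_normalize(df: pd.DataFrame) -> pd.DataFrame:
    """Classic quantile normalization of columns (NaN-aware).

    Each column's sorted values are replaced by the across-column means of
    order statistics; with missing values, columns are mapped through a
    common quantile grid by interpolation.
    """
    out = df.copy()
    n_obs = df.notna().sum()
    if n_obs.nunique() == 1 and not df.isna().any().any():
        ref = np.sort(df.to_numpy(), axis=0).mean(axis=1)
        ranks = df.rank(method="average")
        for col in df.columns:
            r = ranks[col].to_numpy() - 1.0
            # average ranks interpolate between order statistics on ties
            out[col] = np.interp(r, np.arange(len(ref)), ref)
        return out
    grid = np.linspace(0, 1, 101)
    col_q = {
        col: np.nanquantile(df[col].to_numpy(float), grid) for col in df.columns
    }
    ref_q = np.mean(np.column_stack(list(col_q.values())), axis=1)
    for col in df.columns:
        vals = df[col].to_numpy(float)
        mask = np.isfinite(vals)
        if mask.sum() == 0:
            continue
        ranks = stats.rankdata(vals[mask])
        q = (ranks - 1) / max(mask.sum() - 1, 1)
        out.loc[mask, col] = np.interp(q, grid, ref_q)
    return out


@dataclass
class ProteinMatrix(ExpressionMatrix):
    """Protein x sample matrix with provenance (peptides contributing)."""

    n_peptides: pd.Series = None  # type: ignore[assignment]


def _average_replicates(
    pep: PeptideTable, level: str
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Average technical (and, for level='timepoint', biological) replicates."""
    ds = pep.datasets.loc[pep.abundance.columns]
    if level == "timepoint":
        groups = ds["timepoint"].astype(str)
        meta = pd.DataFrame(
            {"timepoint": sorted(groups.unique(), key=list(timepoint_order(groups)).index)}
        )
        meta.index = meta["timepoint"]
    elif level == "biorep":
        groups = ds["timepoint"].astype(str) + "_b" + ds["biorep"].astype(str)
        meta = (
            ds.assign(group=groups)
            .drop_duplicates("group")
            .set_index("group")[["timepoint", "biorep"]]
        )
    else:
        raise ValueError("level must be 'timepoint' or 'biorep'")
    if level == "timepoint":
        # average technical replicates within biorep first, then bioreps
        inner = ds["timepoint"].astype(str) + "_b" + ds["biorep"].astype(str)
        tech_avg = pep.abundance.T.groupby(inner.values).mean().T
        tp_of = {
            g: g.rsplit("_b", 1)[0] for g in tech_avg.columns
        }
        avg = tech_avg.T.groupby(pd.Series(tp_of)).mean().T
        avg = avg[meta.index]
    else:
        avg = pep.abundance.T.groupby(groups.values).mean().T
        avg = avg[meta.index]
    return avg, meta


def rollup_proteins(
    peptide_matrix: pd.DataFrame, mapping: pd.DataFrame
) -> tuple[pd.DataFrame, pd.Series]:
    """RRollup-style peptide-to-protein summarization.

    Per protein: the reference peptide is the one with the most observations
    (ties -> highest median); every other peptide is shifted by the median of
    its paired differences to the reference; the protein value per sample is
    the median across shifted peptides. Peptides with no overlapping
    observations with the reference are excluded with a warning.
    """
    protein_of = _protein_of(mapping)
    rows, counts = {}, {}
    for protein, pep_ids in protein_of.groupby(protein_of).groups.items():
        block = peptide_matrix.loc[list(pep_ids)]
        n_obs = block.notna().sum(axis=1)
        med = block.median(axis=1)
        ref_id = sorted(
            block.index, key=lambda p: (-n_obs[p], -med[p], str(p))
        )[0]
        ref = block.loc[ref_id]
        shifted, used = [], 0
        for pid in block.index:
            row = block.loc[pid]
            overlap = row.notna() & ref.notna()
            if pid != ref_id and not overlap.any():
                warnings.warn(
                    f"peptide {pid} has no overlap with reference of {protein}; excluded"
                )
                continue
            shift = 0.0 if pid == ref_id else float((ref - row)[overlap].median())
            shifted.append(row + shift)
            used += 1
        rows[protein] = pd.concat(shifted, axis=1).median(axis=1)
        counts[protein] = used
    data = pd.DataFrame(rows).T
    data.index.name = "protein_id"
    return data.sort_index(), pd.Series(counts).sort_index()


def normalize_and_rollup(pep: PeptideTable, level: str = "timepoint") -> ProteinMatrix:
    """Quantile normalize, average replicates, roll up peptides to proteins.

    ``level='timepoint'`` averages technical then biological replicates
    (sample-level abundances); ``level='biorep'`` keeps biological replicates
    separate (needed for the progressive differential testing).
    """
    normed = PeptideTable(
        quantile_normalize(pep.abundance), pep.mapping, pep.datasets
    )
    avg, meta = _average_replicates(normed, level)
    data, counts = rollup_proteins(avg, pep.mapping)
    return ProteinMatrix(data, meta, n_peptides=counts)


def presence_absence(
    pep: PeptideTable,
    min_unique_peptides: int = 2,
    min_dataset_fraction: float = 0.5,
    per_timepoint: bool = True,
) -> dict[str, set[str]]:
    """Per-time-point protein presence sets.

    A protein is present at a time point iff at least ``min_unique_peptides``
    of its unique peptides are each observed in >= ceil(min_dataset_fraction
    x n datasets) of that time point's instrument datasets (or of all
    datasets when ``per_timepoint`` is False). The special key ``"all"``
    holds proteins present at every time point.
    """
    uniq = pep.mapping["unique"]
    protein_of = _protein_of(pep.mapping)
    ds = pep.datasets.loc[pep.abundance.columns]
    tps = timepoint_order(ds["timepoint"])
    presence: dict[str, set[str]] = {}
    for tp in tps:
        cols = ds.index[ds["timepoint"] == tp]
        n_ds = pep.n_datasets if not per_timepoint else len(cols)
        min_obs = math.ceil(min_dataset_fraction * n_ds)
        obs = pep.abundance[cols].notna().sum(axis=1)
        good = uniq & (obs >= min_obs)
        counts = protein_of[good].value_counts()
        presence[tp] = set(counts.index[counts >= min_unique_peptides])
    presence["all"] = set.intersection(*(presence[tp] for tp in tps)) if tps else set()
    return presence


def progressive_differential(
    protein_reps: ExpressionMatrix,
    alpha: float = 0.05,
    order: list[str] | None = None,
) -> pd.DataFrame:
    """Welch t-tests between adjacent time points, walked progressively.

    The default walk follows the diel cycle starting at the pre-dawn point:
    T3->T4, T4->T1, T1->T2, T2->T3. Returns one row per protein with
    p < ``alpha`` in a comparison: protein_id, comparison, direction
    (up/down from the first to the second time point), t, p.
    """
    tps = protein_reps.timepoints
    samples = protein_reps.samples.loc[protein_reps.data.columns]
    counts = samples.groupby("timepoint").size()
    if (counts < 2).any():
        raise ValueError("need >= 2 biological replicates per time point")
    if order is None:
        start = tps.index("T3") if "T3" in tps else 0
        cycle = tps[start:] + tps[:start]
        order = [f"{a}->{b}" for a, b in zip(cycle, cycle[1:] + cycle[:1])]
    rows = []
    for comparison in order:
        a, b = comparison.split("->")
        cols_a = samples.index[samples["timepoint"] == a]
        cols_b = samples.index[samples["timepoint"] == b]
        for protein in protein_reps.data.index:
            va = protein_reps.data.loc[protein, cols_a].dropna()
            vb = protein_reps.data.loc[protein, cols_b].dropna()
            if len(va) < 2 or len(vb) < 2:
                continue
            if va.var(ddof=1) == 0 and vb.var(ddof=1) == 0:
                t, p = 0.0, 1.0
            else:
                t, p = stats.ttest_ind(vb, va, equal_var=False)
            if p < alpha:
                rows.append(
                    {
                        "protein_id": protein,
                        "comparison": comparison,
                        "direction": "up" if vb.mean() > va.mean() else "down",
                        "t": float(t),
                        "p": float(p),
                    }
                )
    return pd.DataFrame(rows, columns=["protein_id", "comparison", "direction", "t", "p"])
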