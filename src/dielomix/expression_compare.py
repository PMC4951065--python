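"""Gene-level mRNA-protein comparison over the diel time course.

z-scores matched per-gene profiles, computes pooled/per-time-point/log-ratio
Spearman correlations, assigns delay-aware correlation classes (Pearson R
against circularly shifted profiles, |R| > 0.75 high threshold, |R| <= 0.1
low), and tests observed class frequencies against a permutation null that
shuffles which protein profile goes with which mRNA profile.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

HIGH_R = 0.75
LOW_R = 0.1

LABEL_LOW = "low"
LABEL_UNCLASSIFIED = "unclassified"


def class_label(delay: int, sign: int) -> str:
    if sign > 0:
        return "correlated" if delay == 0 else f"delayed-{delay}-correlated"
    return "anti-correlated" if delay == 0 else f"delayed-{delay}-anticorrelated"


@dataclass
class JointProfiles:
    """Matched z-scored mRNA/protein time-point profiles (gene x timepoint)."""

    mrna_z: pd.DataFrame
    protein_z: pd.DataFrame
    constant_genes: list[str] = field(default_factory=list)

    @property
    def genes(self) -> pd.Index:
        return self.mrna_z.index

    @property
    def n_timepoints(self) -> int:
        return self.mrna_z.shape[1]


def _zscore_rows(df: pd.DataFrame) -> tuple[pd.DataFrame, np.ndarray]:
    vals = df.to_numpy(float)
    mean = vals.mean(axis=1, keepdims=True)
    sd = vals.std(axis=1, ddof=1, keepdims=True)
    constant = (sd.ravel() == 0) | ~np.isfinite(sd.ravel())
    sd_safe = np.where(sd > 0, sd, 1.0)
    return pd.DataFrame((vals - mean) / sd_safe, index=df.index, columns=df.columns), constant


def zscore_profiles(mrna, protein) -> JointProfiles:
    """Standardize per-gene time-point profiles (mean 0, sample SD 1).

    Accepts :class:`~dielomix.datatypes.ExpressionMatrix` (replicates are
    averaged within time points first) or gene x timepoint DataFrames.
    Genes with a constant profile in either data type are flagged and
    excluded from class assignment.
    """
    m = mrna.timepoint_means() if hasattr(mrna, "timepoint_means") else mrna
    p = protein.timepoint_means() if hasattr(protein, "timepoint_means") else protein
    genes = m.index.intersection(p.index)
    if len(genes) == 0:
        raise ValueError("mRNA and protein matrices share no genes")
    m, p = m.loc[genes], p.loc[genes]
    if list(m.columns) != list(p.columns):
        p = p[m.columns]
    mz, m_const = _zscore_rows(m)
    pz, p_const = _zscore_rows(p)
    const = m_const | p_const
    constant_genes = list(genes[const])
    if constant_genes:
        warnings.warn(f"{len(constant_genes)} constant profiles flagged")
    return JointProfiles(mz[~const], pz[~const], constant_genes)


@dataclass
class PooledCorrelation:
    pooled_rs: float
    pooled_p: float
    per_timepoint_rs: dict[str, float]
    logratio_rs: float
    logratio_p: float
    reference_timepoint: str


def pooled_correlations(mrna, protein, reference_timepoint: str = "T3") -> PooledCorrelation:
    """Spearman correlations pooled over all (gene, time point) pairs.

    Also reports per-time-point coefficients and the correlation of log10
    ratios of each non-reference time point to the reference time point.
    """
    m = mrna.timepoint_means() if hasattr(mrna, "timepoint_means") else mrna
    p = protein.timepoint_means() if hasattr(protein, "timepoint_means") else protein
    genes = m.index.intersection(p.index)
    m, p = m.loc[genes], p.loc[genes, m.columns]
    if m.size < 3:
        raise ValueError("need at least 3 pooled (gene, timepoint) pairs")
    if reference_timepoint not in m.columns:
        raise ValueError(f"reference time point {reference_timepoint!r} not present")
    pooled_rs, pooled_p = stats.spearmanr(m.to_numpy().ravel(), p.to_numpy().ravel())
    per_tp = {
        tp: float(stats.spearmanr(m[tp], p[tp]).statistic) for tp in m.columns
    }
    others = [tp for tp in m.columns if tp != reference_timepoint]
    m_ratio = m[others].sub(m[reference_timepoint], axis=0)
    p_ratio = p[others].sub(p[reference_timepoint], axis=0)
    lr_rs, lr_p = stats.spearmanr(m_ratio.to_numpy().ravel(), p_ratio.to_numpy().ravel())
    return PooledCorrelation(
        float(pooled_rs), float(pooled_p), per_tp, float(lr_rs), float(lr_p),
        reference_timepoint,
    )


def _delay_correlations(mz: np.ndarray, pz: np.ndarray) -> np.ndarray:
    """R[g, k] = Pearson R between mRNA profile and protein shifted back by k."""
    n_tp = mz.shape[1]
    R = np.empty((mz.shape[0], n_tp))
    for k in range(n_tp):
        R[:, k] = (mz * np.roll(pz, -k, axis=1)).sum(axis=1) / (n_tp - 1)
    return np.clip(R, -1.0, 1.0)


def _classify(R: np.ndarray, high: float, low: float) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Exclusive class per gene: smallest delay k with |R_k| > high wins.

    Returns (delay, sign, is_low) arrays; sign 0 marks low/unclassified.
    """
    n, n_tp = R.shape
    delay = np.full(n, -1)
    sign = np.zeros(n, dtype=int)
    hit = np.abs(R) > high
    for k in range(n_tp - 1, -1, -1):
        delay = np.where(hit[:, k], k, delay)
        sign = np.where(hit[:, k], np.sign(R[:, k]).astype(int), sign)
    is_low = (delay < 0) & (np.abs(R[:, 0]) <= low)
    return delay, sign, is_low


def assign_correlation_classes(
    profiles: JointProfiles, high: float = HIGH_R, low: float = LOW_R
) -> pd.DataFrame:
    """Exclusive correlation class per gene, plus per-delay R values.

    Delays use circular shifts of the protein profile (the diel cycle is
    periodic, and delayed-by-(T-1) classes are impossible with truncated
    overlap on T points). Columns: best_delay, R (at the winning delay, or
    at delay 0 for low/unclassified), class, and R_delay{k} for every k.
    """
    if profiles.n_timepoints < 3:
        raise ValueError("need at least 3 time points")
    R = _delay_correlations(profiles.mrna_z.to_numpy(), profiles.protein_z.to_numpy())
    delay, sign, is_low = _classify(R, high, low)
    labels = []
    for d, s, lo in zip(delay, sign, is_low):
        if d >= 0:
            labels.append(class_label(int(d), int(s)))
        else:
            labels.append(LABEL_LOW if lo else LABEL_UNCLASSIFIED)
    out = pd.DataFrame(
        {
            "best_delay": np.where(delay >= 0, delay, 0),
            "R": np.where(delay >= 0, R[np.arange(len(delay)), np.maximum(delay, 0)], R[:, 0]),
            "class": labels,
        },
        index=profiles.genes,
    )
    for k in range(profiles.n_timepoints):
        out[f"R_delay{k}"] = R[:, k]
    return out


@dataclass
class PermutationNull:
    observed_counts: dict[str, int]
    null_mean: dict[str, float]
    p_values: dict[str, float]
    n_permutations: int
    null_counts: pd.DataFrame  # permutation x class


def _count_classes(R, high, low, n_tp) -> dict[str, int]:
    delay, sign, is_low = _classify(R, high, low)
    counts: dict[str, int] = {}
    for k in range(n_tp):
        for s, nm in ((1, class_label(k, 1)), (-1, class_label(k, -1))):
            counts[nm] = int(((delay == k) & (sign == s)).sum())
    counts[LABEL_LOW] = int(is_low.sum())
    counts[LABEL_UNCLASSIFIED] = int(((delay < 0) & ~is_low).sum())
    return counts


def permutation_class_test(
    profiles: JointProfiles,
    n_perm: int = 10000,
    seed: int | None = None,
    high: float = HIGH_R,
    low: float = LOW_R,
) -> PermutationNull:
    """Permutation null for class frequencies.

    Each permutation shuffles which gene's protein profile is paired with
    which mRNA profile, reassigns classes, and records per-class counts.
    Empirical p per class is two-sided on the count with the add-one
    estimator: a permutation is as or more extreme than the observation when
    its count is at least as far from the null mean, and
    p = (1 + #extreme) / (1 + n_perm).
    """
    if len(profiles.genes) < 2:
        raise ValueError("need at least 2 genes")
    if n_perm < 100:
        warnings.warn("fewer than 100 permutations: p-values will be coarse")
    rng = np.random.default_rng(seed)
    mz = profiles.mrna_z.to_numpy()
    pz = profiles.protein_z.to_numpy()
    n_tp = profiles.n_timepoints
    observed = _count_classes(_delay_correlations(mz, pz), high, low, n_tp)
    classes = list(observed)
    null = np.empty((n_perm, len(classes)), dtype=int)
    for b in range(n_perm):
        perm = rng.permutation(len(mz))
        counts = _count_classes(_delay_correlations(mz, pz[perm]), high, low, n_tp)
        null[b] = [counts[c] for c in classes]
    obs_vec = np.array([observed[c] for c in classes])
    center = null.mean(axis=0)
    extreme = (np.abs(null - center) >= np.abs(obs_vec - center)).sum(axis=0)
    p = (1.0 + extreme) / (1.0 + n_perm)
    return PermutationNull(
        observed_counts=observed,
        null_mean={c: float(null[:, i].mean()) for i, c in enumerate(classes)},
        p_values={c: float(p[i]) for i, c in enumerate(classes)},
        n_permutations=n_perm,
        null_counts=pd.DataFrame(null, columns=classes),
    )
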