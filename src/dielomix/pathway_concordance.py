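"""Pathway-level concordance of mRNA and protein co-expression.

Gene-gene Pearson correlations per data type are ranked and scored against
pathway *gene-pair* sets (every pathway expanded to all unordered pairs of
its analyzed genes) with a GSEA running-sum enrichment score; concordance of
a pathway between the two data types is the signed product of its two
enrichment scores:

    CS_p = sign(ES_p^mRNA) * sign(ES_p^prot) * |ES_p^mRNA| * |ES_p^prot|

which is numerically es_mrna * es_prot, bounded by [-1, 1].
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd


def pairwise_gene_correlations(expr) -> pd.Series:
    """Pearson correlation of across-time profiles for every unordered gene pair.

    Accepts an ExpressionMatrix (replicates averaged within time points) or a
    gene x timepoint DataFrame. Returns a Series indexed by (gene_a, gene_b)
    tuples (lexicographic order within the pair), sorted descending by R;
    ties broken by pair id for determinism. Constant profiles are excluded
    with a warning.
    """
    df = expr.timepoint_means() if hasattr(expr, "timepoint_means") else expr
    if df.shape[1] < 3:
        raise ValueError("need at least 3 time points per profile")
    sd = df.std(axis=1, ddof=1)
    constant = sd[sd == 0].index
    if len(constant):
        warnings.warn(f"{len(constant)} constant profiles excluded")
        df = df.drop(index=constant)
    genes = list(df.index)
    corr = np.corrcoef(df.to_numpy(float))
    iu = np.triu_indices(len(genes), k=1)
    pairs = [tuple(sorted((genes[i], genes[j]))) for i, j in zip(*iu)]
    s = pd.Series(corr[iu], index=pd.Index(pairs, tupleize_cols=False))
    order = sorted(range(len(s)), key=lambda i: (-s.iloc[i], pairs[i]))
    return s.iloc[order]


def expand_pathways_to_pairs(
    pathways: dict[str, list[str]], universe
) -> dict[str, set[tuple[str, str]]]:
    """All unordered gene pairs per pathway, restricted to the analyzed universe.

    Pathways with fewer than 2 analyzed genes are dropped with a warning.
    """
    universe = set(universe)
    out: dict[str, set[tuple[str, str]]] = {}
    for name, genes in pathways.items():
        members = sorted(set(genes) & universe)
        if len(members) < 2:
            warnings.warn(f"pathway {name!r} has <2 analyzed genes; dropped")
            continue
        out[name] = {
            tuple(sorted(p)) for p in itertools.combinations(members, 2)
        }
    return out


def gsea_enrichment_score(
    ranked: pd.Series,
    pairset: set[tuple[str, str]],
    weight_exponent: float = 1.0,
) -> float:
    """Weighted Kolmogorov-Smirnov running-sum enrichment score.

    Walking the ranked list from top to bottom, hits increment the running
    sum by |score|^p normalized by the sum over hits; misses decrement by
    1/(N - N_hits). ES is the signed maximum deviation from zero.
    """
    if not pairset:
        raise ValueError("empty pair set")
    index_pairs = set(ranked.index)
    missing = pairset - index_pairs
    if missing:
        raise ValueError(
            f"{len(missing)} pairs in the set are absent from the ranked list"
        )
    n = len(ranked)
    is_hit = np.fromiter((p in pairset for p in ranked.index), dtype=bool, count=n)
    n_hits = int(is_hit.sum())
    if n_hits == n:
        raise ValueError("pair set equals the whole ranked list (miss weight undefined)")
    weights = np.abs(ranked.to_numpy(float)) ** weight_exponent
    hit_total = weights[is_hit].sum()
    if hit_total == 0:
        steps = np.where(is_hit, 1.0 / n_hits, -1.0 / (n - n_hits))
    else:
        steps = np.where(is_hit, weights / hit_total, -1.0 / (n - n_hits))
    running = np.cumsum(steps)
    peak = np.argmax(np.abs(running))
    return float(np.clip(running[peak], -1.0, 1.0))


def concordance_score(es_mrna: float, es_prot: float) -> float:
    """Signed product of the two enrichment scores (sign(0) = 0 convention)."""
    for name, v in (("es_mrna", es_mrna), ("es_prot", es_prot)):
        if not -1.0 <= v <= 1.0:
            raise ValueError(f"{name}={v} outside [-1, 1]")
    return float(
        np.sign(es_mrna) * np.sign(es_prot) * abs(es_mrna) * abs(es_prot)
    )


@dataclass
class ConcordanceResult:
    table: pd.DataFrame  # pathway x (es_mrna, es_protein, cs, n_pairs)


def pathway_concordance(
    mrna,
    protein,
    pathways: dict[str, list[str]],
    weight_exponent: float = 1.0,
) -> ConcordanceResult:
    """Full pipeline: rank pair correlations per data type, score each pathway."""
    ranked_m = pairwise_gene_correlations(mrna)
    ranked_p = pairwise_gene_correlations(protein)
    universe_m = {g for pair in ranked_m.index for g in pair}
    universe_p = {g for pair in ranked_p.index for g in pair}
    universe = universe_m & universe_p
    pairsets = expand_pathways_to_pairs(pathways, universe)
    rows = {}
    for name, pairs in pairsets.items():
        es_m = gsea_enrichment_score(ranked_m, pairs, weight_exponent)
        es_p = gsea_enrichment_score(ranked_p, pairs, weight_exponent)
        rows[name] = {
            "es_mrna": es_m,
            "es_protein": es_p,
            "cs": concordance_score(es_m, es_p),
            "n_pairs": len(pairs),
        }
    table = pd.DataFrame.from_dict(rows, orient="index").sort_values(
        "cs", ascending=False
    )
    return ConcordanceResult(table=table)
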