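"""Synthetic diel study generator with known ground truth.

Emulates the study design the downstream analyses expect: 4 time points
(mid-day, dusk, pre-dawn, lights-on) x 3 biological replicates of mRNA, with
protein measured at the peptide level over 4 technical replicates per
biological sample. Each gene gets a diel-periodic mRNA profile (two-harmonic
sinusoid over the 4-point cycle), a planted mRNA-protein relationship class
(delayed by 0-3 points via circular shift, anti-correlated, or independent),
planted sequence-feature effects on protein abundance, and an optional
hypothetically post-transcriptionally regulated (HPTR) subset whose protein
program departs from the feature model.

A pure first-harmonic profile would make delay-2 indistinguishable from
anti-correlation on 4 samples (shifting a 4-point sinusoid by half a period
negates it); the second harmonic breaks that degeneracy so every planted
class is recoverable at zero noise.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from dielomix.datatypes import (
    ExpressionMatrix,
    GeneSequenceRecord,
    GroundTruth,
    PeptideTable,
)
from dielomix.seqfeatures import (
    CODON_TO_AA,
    _SYNONYMS,
    compute_cai,
    compute_mfe,
)

DELAY_CLASSES = ("delay0", "delay1", "delay2", "delay3", "anti", "independent")

#: designated optimal codon per amino acid (fixed, GC-leaning choice)
OPTIMAL_CODON = {
    aa: max(codons, key=lambda c: (c[2] in "GC", c))
    for aa, codons in _SYNONYMS.items()
}

_AA_FOR_SAMPLING = sorted(set(CODON_TO_AA.values()))


class ConfigurationError(ValueError):
    """Raised when a SimulationConfig violates its invariants."""


@dataclass
class SimulationConfig:
    """Parameters of the simulated diel study.

    Expression values are log10 abundances throughout; all noise SDs are in
    log10 units. ``delay_class_probs`` assigns each gene a planted
    mRNA-protein relationship; ``feature_effect_sizes`` maps feature names
    (as produced by :mod:`dielomix.seqfeatures`) to coefficients applied to
    the across-gene z-score of that feature.
    """

    n_genes: int = 500
    n_timepoints: int = 4
    n_bioreps: int = 3
    n_techreps: int = 4
    delay_class_probs: dict[str, float] = field(
        default_factory=lambda: {
            "delay0": 0.25,
            "delay1": 0.30,
            "delay2": 0.10,
            "delay3": 0.05,
            "anti": 0.15,
            "independent": 0.15,
        }
    )
    hptr_fraction: float = 0.10
    feature_effect_sizes: dict[str, float] = field(
        default_factory=lambda: {"cai": 0.5, "mfe_utr5": 0.3}
    )
    noise_sd_mrna: float = 0.10
    noise_sd_protein: float = 0.10
    noise_sd_peptide: float = 0.10
    missing_rate: float = 0.05
    seed: int = 0
    # sequence model
    mean_protein_length: int = 200
    utr_length_median: float = 80.0
    utr_length_sigma: float = 0.5
    utr_missing_rate: float = 0.05
    # expression model
    baseline_mean: float = 2.5
    baseline_sd: float = 0.5
    amplitude_range: tuple[float, float] = (0.4, 0.9)
    # centred near 1/sqrt(2), where the spurious cross-shift correlations of a
    # two-harmonic 4-point profile are all ~1/3 (far from the 0.75 threshold)
    harmonic2_ratio: tuple[float, float] = (0.6, 0.85)
    mrna_coupling: float = 0.8
    baseline_hinge_coef: float = 0.6
    baseline_hinge_knot: float = 2.5
    hptr_offset: float = 1.0
    hptr_independent_fraction: float = 0.5
    # peptide model
    peptides_per_protein: tuple[int, int] = (1, 6)
    peptide_offset_sd: float = 0.3
    shared_peptide_fraction: float = 0.05
    # synthetic pathway sets
    n_pathways_coherent: int = 8
    n_pathways_random: int = 8
    pathway_size_range: tuple[int, int] = (8, 25)

    def validate(self) -> None:
        for name in ("n_genes", "n_timepoints", "n_bioreps", "n_techreps"):
            if getattr(self, name) < 1:
                raise ConfigurationError(f"{name} must be >= 1")
        total = sum(self.delay_class_probs.values())
        if abs(total - 1.0) > 1e-9:
            raise ConfigurationError(
                f"delay_class_probs must sum to 1 (got {total})"
            )
        unknown = set(self.delay_class_probs) - set(DELAY_CLASSES)
        if unknown:
            raise ConfigurationError(f"unknown delay classes: {sorted(unknown)}")
        for name in (
            "hptr_fraction",
            "missing_rate",
            "utr_missing_rate",
            "shared_peptide_fraction",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigurationError(f"{name} must be in [0, 1] (got {v})")
        for name in ("noise_sd_mrna", "noise_sd_protein", "noise_sd_peptide"):
            if getattr(self, name) < 0:
                raise ConfigurationError(f"{name} must be >= 0")

    @classmethod
    def strong_hptr_regime(cls, n_genes: int = 2000, seed: int = 0, **overrides) -> "SimulationConfig":
        """The strong-effect post-transcriptional regime.

        10% of genes carry a stable (arrhythmic) protein program offset by
        2 log10 units (a hundred-fold change, i.e. translational silencing /
        strong stabilization) at measurement noise SD 0.15. This is the
        condition under which residual-quantile HPTR detection is expected
        to operate well; weaker offsets blur into the residual spread of the
        delayed classes.
        """
        params = dict(
            n_genes=n_genes,
            seed=seed,
            hptr_fraction=0.10,
            hptr_offset=2.0,
            hptr_independent_fraction=1.0,
            noise_sd_mrna=0.15,
            noise_sd_protein=0.15,
        )
        params.update(overrides)
        return cls(**params)

    def rng(self, stage: int) -> np.random.Generator:
        """Stage-independent generator: stream ``stage`` of the global seed."""
        return np.random.default_rng(np.random.SeedSequence((self.seed, stage)))

    @property
    def timepoints(self) -> list[str]:
        return [f"T{i + 1}" for i in range(self.n_timepoints)]


# ---------------------------------------------------------------------------
# sequences

def _sample_cds(rng: np.random.Generator, n_aa: int, bias: float) -> str:
    aas = rng.choice(_AA_FOR_SAMPLING, size=n_aa - 1)
    codons = ["ATG"]
    for aa in aas:
        if rng.random() < bias:
            codons.append(OPTIMAL_CODON[aa])
        else:
            codons.append(_SYNONYMS[aa][rng.integers(len(_SYNONYMS[aa]))])
    codons.append("TAA")
    return "".join(codons)


def _sample_utr(rng: np.random.Generator, median: float, sigma: float) -> str:
    length = max(10, int(rng.lognormal(math.log(median), sigma)))
    return "".join(rng.choice(list("ACGT"), size=length))


def generate_sequences(
    config: SimulationConfig,
) -> tuple[list[GeneSequenceRecord], GroundTruth]:
    """Generate per-gene CDS/UTR/protein sequences and the planted truth.

    The gene-specific codon-bias parameter is the probability that each codon
    is the designated optimal codon for its amino acid (bias 1 => CAI of 1
    against any reference in which those codons dominate). The bias is drawn
    correlated with the gene's expression baseline (Gaussian copula) so that
    CAI behaves like a translational-optimization proxy.
    """
    config.validate()
    rng = config.rng(1)
    n = config.n_genes
    genes = [f"g{i:05d}" for i in range(n)]

    # correlated latent normals: baseline expression and codon bias
    z = rng.multivariate_normal([0, 0], [[1.0, 0.5], [0.5, 1.0]], size=n)
    baseline = config.baseline_mean + config.baseline_sd * z[:, 0]
    from scipy.stats import norm

    bias = 0.2 + 0.75 * norm.cdf(z[:, 1])

    classes = rng.choice(
        list(config.delay_class_probs),
        size=n,
        p=list(config.delay_class_probs.values()),
    )
    n_hptr = int(round(config.hptr_fraction * n))
    hptr_idx = rng.choice(n, size=n_hptr, replace=False)
    hptr = np.zeros(n, dtype=bool)
    hptr[hptr_idx] = True
    hptr_sign = np.zeros(n, dtype=int)
    # alternate +1 / -1 over the HPTR genes (even split between tails)
    hptr_sign[hptr_idx] = np.where(np.arange(n_hptr) % 2 == 0, 1, -1)
    # a fraction follow an independent profile, the rest keep coupling with
    # inverted feature effects
    hptr_program = np.full(n, "", dtype=object)
    n_indep = int(round(config.hptr_independent_fraction * n_hptr))
    hptr_program[hptr_idx] = np.where(
        np.arange(n_hptr) < n_indep, "independent", "inverted"
    )

    records = []
    for i, gene in enumerate(genes):
        n_aa = max(
            50, int(rng.lognormal(math.log(config.mean_protein_length), 0.35))
        )
        cds = _sample_cds(rng, n_aa, bias[i])
        utr5 = (
            ""
            if rng.random() < config.utr_missing_rate
            else _sample_utr(rng, config.utr_length_median, config.utr_length_sigma)
        )
        utr3 = (
            ""
            if rng.random() < config.utr_missing_rate
            else _sample_utr(rng, config.utr_length_median, config.utr_length_sigma)
        )
        records.append(
            GeneSequenceRecord(
                gene_id=gene,
                cds=cds,
                utr5=utr5,
                utr3=utr3,
                utr5_complete=bool(utr5),
                utr3_complete=bool(utr3),
            )
        )

    truth = GroundTruth(
        genes=genes,
        delay_class={g: c for g, c in zip(genes, classes)},
        hptr={g: bool(h) for g, h in zip(genes, hptr)},
        hptr_sign={g: int(s) for g, s in zip(genes, hptr_sign)},
        codon_bias={g: float(b) for g, b in zip(genes, bias)},
        feature_effects=dict(config.feature_effect_sizes),
        baseline={g: float(b) for g, b in zip(genes, baseline)},
        hptr_program={g: str(p) for g, p in zip(genes, hptr_program)},
    )
    return records, truth


# ---------------------------------------------------------------------------
# expression

def _diel_profile(
    rng: np.random.Generator, n_tp: int, amp_range, ratio_range
) -> np.ndarray:
    """Two-harmonic periodic profile sampled at n_tp points over one cycle.

    The second harmonic breaks the delay-2/anti degeneracy of a pure
    sinusoid. At n_tp = 4 a phase-shifted second harmonic aliases to
    sin(phi) * (-1)^t, so its sampled component is built directly as the
    alternating vector (random sign) at the intended amplitude.
    """
    t = np.arange(n_tp)
    a1 = rng.uniform(*amp_range)
    a2 = a1 * rng.uniform(*ratio_range)
    phi1 = rng.uniform(0, 2 * np.pi)
    first = a1 * np.sin(2 * np.pi * t / n_tp + phi1)
    if n_tp == 4:
        sign = 1.0 if rng.random() < 0.5 else -1.0
        second = a2 * sign * (-1.0) ** t / np.sqrt(2.0)
    else:
        phi2 = rng.uniform(0, 2 * np.pi)
        second = a2 * np.sin(4 * np.pi * t / n_tp + phi2)
    return first + second


def _planted_feature_term(
    records: list[GeneSequenceRecord],
    truth: GroundTruth,
    config: SimulationConfig,
) -> np.ndarray:
    """Sum of planted feature effects, per gene, using realized sequences."""
    n = len(records)
    term = np.zeros(n)
    if not config.feature_effect_sizes:
        return term
    # realized feature values (NaN -> column mean, i.e. no effect)
    cols = {}
    need_cai = "cai" in config.feature_effect_sizes
    if need_cai:
        from dielomix.seqfeatures import codon_counts

        order = np.argsort([-truth.baseline[r.gene_id] for r in records])
        top = order[: max(1, n // 10)]
        ref = codon_counts(records[i].cds for i in top)
        cols["cai"] = np.array([compute_cai(r.cds, ref) for r in records])
    for feat in config.feature_effect_sizes:
        if feat == "cai":
            continue
        if feat == "mfe_utr5":
            cols[feat] = np.array(
                [compute_mfe(r.utr5) if r.utr5 else np.nan for r in records]
            )
        elif feat == "mfe_utr3":
            cols[feat] = np.array(
                [compute_mfe(r.utr3) if r.utr3 else np.nan for r in records]
            )
        else:
            raise ConfigurationError(
                f"unsupported planted feature effect: {feat!r} "
                "(supported: cai, mfe_utr5, mfe_utr3)"
            )
    for feat, beta in config.feature_effect_sizes.items():
        x = cols[feat].astype(float)
        mu = np.nanmean(x)
        sd = np.nanstd(x, ddof=1)
        zcol = np.where(np.isnan(x), 0.0, (x - mu) / (sd if sd > 0 else 1.0))
        term = term + beta * zcol
    return term


def generate_expression(
    truth: GroundTruth,
    config: SimulationConfig,
    records: list[GeneSequenceRecord] | None = None,
) -> tuple[ExpressionMatrix, ExpressionMatrix]:
    """Matched mRNA and (noiseless gene-level) protein expression.

    mRNA(g, t) = baseline_g + periodic profile + replicate noise. For a gene
    of delay class k the protein tracks the circularly shifted clean mRNA
    profile (coupling < 1), plus a hinge term in the gene's baseline, plus
    the planted feature effects; "anti" genes flip the coupling sign and
    "independent" genes get their own profile. HPTR genes depart from this
    program (independent profile, or inverted feature effects) and carry a
    persistent offset whose sign determines the residual tail they land in.
    """
    config.validate()
    if set(truth.genes) != set(truth.delay_class):
        raise ValueError("truth.delay_class inconsistent with truth.genes")
    rng = config.rng(2)
    genes = truth.genes
    n = len(genes)
    n_tp = config.n_timepoints
    tps = config.timepoints

    baseline = np.array([truth.baseline[g] for g in genes])
    profiles = np.vstack(
        [
            _diel_profile(rng, n_tp, config.amplitude_range, config.harmonic2_ratio)
            for _ in range(n)
        ]
    )
    mrna_clean = baseline[:, None] + profiles  # gene x timepoint

    feature_term = (
        _planted_feature_term(records, truth, config)
        if records is not None
        else np.zeros(n)
    )

    protein_clean = np.empty_like(mrna_clean)
    hinge = config.baseline_hinge_coef * np.maximum(
        0.0, baseline - config.baseline_hinge_knot
    )
    for i, g in enumerate(genes):
        cls = truth.delay_class[g]
        program = getattr(truth, "hptr_program", {}).get(g, "")
        feat_i = feature_term[i]
        if truth.hptr[g] and program == "inverted":
            feat_i = -feat_i
        if truth.hptr[g] and program == "independent":
            # stable protein program decoupled from the cycling mRNA (the
            # classic post-transcriptional signature: flat protein, diel mRNA)
            coupled = np.full(n_tp, config.mrna_coupling * baseline[i])
        elif cls == "independent":
            indep = baseline[i] + _diel_profile(
                rng, n_tp, config.amplitude_range, config.harmonic2_ratio
            )
            coupled = config.mrna_coupling * indep
        elif cls == "anti":
            coupled = config.mrna_coupling * (2 * baseline[i] - mrna_clean[i])
        else:
            k = int(cls[len("delay") :])
            coupled = config.mrna_coupling * np.roll(mrna_clean[i], k)
        protein_clean[i] = coupled + hinge[i] + feat_i
        if truth.hptr[g]:
            protein_clean[i] -= truth.hptr_sign[g] * config.hptr_offset

    # replicate-level matrices
    mrna_cols, mrna_rows, mrna_meta = [], [], []
    for t_idx, tp in enumerate(tps):
        for rep in range(1, config.n_bioreps + 1):
            sid = f"mrna_{tp}_b{rep}"
            mrna_cols.append(sid)
            mrna_meta.append((sid, tp, rep, "mrna"))
            mrna_rows.append(
                mrna_clean[:, t_idx]
                + rng.normal(0, config.noise_sd_mrna, size=n)
            )
    mrna_df = pd.DataFrame(
        np.column_stack(mrna_rows), index=genes, columns=mrna_cols
    )
    mrna_samples = pd.DataFrame(
        mrna_meta, columns=["sample_id", "timepoint", "biorep", "datatype"]
    ).set_index("sample_id")

    prot_cols, prot_rows, prot_meta = [], [], []
    for t_idx, tp in enumerate(tps):
        for rep in range(1, config.n_bioreps + 1):
            sid = f"prot_{tp}_b{rep}"
            prot_cols.append(sid)
            prot_meta.append((sid, tp, rep, "protein"))
            prot_rows.append(
                protein_clean[:, t_idx]
                + rng.normal(0, config.noise_sd_protein, size=n)
            )
    prot_df = pd.DataFrame(
        np.column_stack(prot_rows), index=genes, columns=prot_cols
    )
    prot_samples = pd.DataFrame(
        prot_meta, columns=["sample_id", "timepoint", "biorep", "datatype"]
    ).set_index("sample_id")

    truth.protein_true = prot_df.copy()
    return (
        ExpressionMatrix(mrna_df, mrna_samples),
        ExpressionMatrix(prot_df, prot_samples),
    )


# ---------------------------------------------------------------------------
# peptides

def generate_peptides(
    protein: ExpressionMatrix, config: SimulationConfig
) -> PeptideTable:
    """Sample a peptide-level table from gene-level protein abundances.

    Each protein yields 1-6 peptides; a peptide's log10 abundance in an
    instrument dataset is the protein's replicate value plus a fixed
    per-peptide offset (ionization-efficiency surrogate, constant across
    samples — exactly what RRollup removes) plus technical noise. Entries go
    missing independently with ``missing_rate``; a configurable fraction of
    peptides additionally map to a second protein (unique flag False).
    """
    config.validate()
    rng = config.rng(3)
    genes = list(protein.data.index)
    lo, hi = config.peptides_per_protein
    n_peps = rng.integers(lo, hi + 1, size=len(genes))

    dataset_ids, dataset_meta = [], []
    for tp in protein.timepoints:
        reps = protein.samples[protein.samples["timepoint"] == tp]
        for rep_sid, rep_row in reps.iterrows():
            for tech in range(1, config.n_techreps + 1):
                did = f"ds_{tp}_b{rep_row['biorep']}_t{tech}"
                dataset_ids.append(did)
                dataset_meta.append(
                    (did, tp, int(rep_row["biorep"]), tech, rep_sid)
                )
    datasets = pd.DataFrame(
        dataset_meta,
        columns=["dataset_id", "timepoint", "biorep", "techrep", "source_sample"],
    ).set_index("dataset_id")

    pep_ids, pep_proteins, rows = [], [], []
    for gi, gene in enumerate(genes):
        base = protein.data.loc[gene, datasets["source_sample"]].to_numpy(float)
        for p in range(n_peps[gi]):
            pid = f"{gene}_pep{p + 1}"
            offset = rng.normal(0, config.peptide_offset_sd)
            vals = (
                base
                + offset
                + rng.normal(0, config.noise_sd_peptide, size=len(dataset_ids))
            )
            if config.missing_rate > 0:
                miss = rng.random(len(vals)) < config.missing_rate
                vals = np.where(miss, np.nan, vals)
            pep_ids.append(pid)
            pep_proteins.append([gene])
            rows.append(vals)

    # mark a fraction of peptides as shared with a second, random protein
    n_total = len(pep_ids)
    n_shared = int(round(config.shared_peptide_fraction * n_total))
    if n_shared and len(genes) > 1:
        shared_idx = rng.choice(n_total, size=n_shared, replace=False)
        for si in shared_idx:
            own = pep_proteins[si][0]
            other = genes[rng.integers(len(genes))]
            while other == own:
                other = genes[rng.integers(len(genes))]
            pep_proteins[si] = [own, other]

    abundance = pd.DataFrame(np.vstack(rows), index=pep_ids, columns=dataset_ids)
    mapping = pd.DataFrame(
        {
            "protein_ids": [tuple(p) for p in pep_proteins],
            "unique": [len(p) == 1 for p in pep_proteins],
        },
        index=pd.Index(pep_ids, name="peptide_id"),
    )
    return PeptideTable(abundance, mapping, datasets[["timepoint", "biorep", "techrep"]])


# ---------------------------------------------------------------------------
# pathways and full-study bundle

def generate_pathways(
    truth: GroundTruth,
    config: SimulationConfig,
    mrna: ExpressionMatrix | None = None,
) -> dict[str, list[str]]:
    """Synthetic pathway gene sets: co-expressed (coherent) and random.

    A coherent pathway is a seed gene plus the genes whose mRNA time-point
    profiles correlate best with it, drawn from the delay-0 class so that
    the co-expression carries over to the protein program (these pathways
    should score positive concordance); random pathways are uniform draws.
    """
    rng = config.rng(4)
    genes = np.array(truth.genes)
    lo, hi = config.pathway_size_range
    pathways: dict[str, list[str]] = {}
    pool = np.array(
        [g for g in genes if truth.delay_class[g] == "delay0" and not truth.hptr[g]]
    )
    if mrna is not None and len(pool) >= lo + 1:
        tp = mrna.timepoint_means().loc[pool]
        z = tp.sub(tp.mean(axis=1), axis=0)
        z = z.div(np.sqrt((z**2).sum(axis=1)), axis=0)
        corr = z.to_numpy() @ z.to_numpy().T
        for i in range(config.n_pathways_coherent):
            seed_idx = int(rng.integers(len(pool)))
            size = int(rng.integers(lo, min(hi, len(pool)) + 1))
            best = np.argsort(-corr[seed_idx])[:size]
            pathways[f"pw_coherent_{i:02d}"] = sorted(pool[best])
    for i in range(config.n_pathways_random):
        size = int(rng.integers(lo, hi + 1))
        sel = rng.choice(genes, size=min(size, len(genes)), replace=False)
        pathways[f"pw_random_{i:02d}"] = sorted(sel)
    return pathways


@dataclass
class StudyBundle:
    """Everything one simulated study produces."""

    config: SimulationConfig
    records: list[GeneSequenceRecord]
    truth: GroundTruth
    mrna: ExpressionMatrix
    protein: ExpressionMatrix
    peptides: PeptideTable
    pathways: dict[str, list[str]]


def simulate_study(config: SimulationConfig) -> StudyBundle:
    """Run all generators with one config; deterministic for a given seed."""
    records, truth = generate_sequences(config)
    mrna, protein = generate_expression(truth, config, records=records)
    peptides = generate_peptides(protein, config)
    pathways = generate_pathways(truth, config, mrna=mrna)
    return StudyBundle(config, records, truth, mrna, protein, peptides, pathways)


def write_study(bundle: StudyBundle, outdir: str | Path) -> None:
    """Write FASTA / TSV / GMT / JSON artifacts of a simulated study."""
    from dielomix import io as dio

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    dio.write_fasta(
        outdir / "cds.fa", {r.gene_id: r.cds for r in bundle.records}
    )
    dio.write_fasta(
        outdir / "utr5.fa",
        {r.gene_id: r.utr5 for r in bundle.records if r.utr5},
    )
    dio.write_fasta(
        outdir / "utr3.fa",
        {r.gene_id: r.utr3 for r in bundle.records if r.utr3},
    )
    dio.write_fasta(
        outdir / "protein.fa", {r.gene_id: r.protein for r in bundle.records}
    )
    dio.write_expression_tsv(outdir / "mrna.tsv", bundle.mrna)
    dio.write_expression_tsv(outdir / "protein.tsv", bundle.protein)
    dio.write_peptides_tsv(
        outdir / "peptides.tsv", outdir / "peptide_samples.tsv", bundle.peptides
    )
    dio.write_gmt(outdir / "pathways.gmt", bundle.pathways)
    truth = bundle.truth
    payload = {
        "delay_class": truth.delay_class,
        "hptr": truth.hptr,
        "hptr_sign": truth.hptr_sign,
        "codon_bias": truth.codon_bias,
        "feature_effects": truth.feature_effects,
    }
    (outdir / "truth.json").write_text(json.dumps(payload, indent=1))
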