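"""Synthetic cohorts with the statistical structure the pipeline assumes.

A cohort consists of negative-binomial RNA-seq counts with a planted
two-subtype immune program, exponential survival with a subtype-linked
hazard, and a MAF whose per-sample nonsynonymous burden is subtype-linked.
A second "immunotherapy" cohort shares the same gene-level baselines, with
responders carrying the sub1 program.

Defaults emulate a small bulk RNA-seq training cohort: 60 samples, 500
genes of which 100 form the immune program, a two-fold-per-unit log2 shift
delta=2 in sub1, NB dispersion 0.2, log-normal library sizes (sigma=0.3),
exponential overall-survival hazard 0.03/month for the immune-enriched
subtype with hazard ratio 3 for sub2, 25% censoring, and mean TMB 6 vs 2
mutations/Mb over a 35 Mb exome footprint.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .io import ClinicalTable, ExpressionMatrix, MafTable, SubtypeAssignment

DEFAULT_DRIVERS = (
    "PIK3CA", "FBXW7", "EP300", "TP53", "KMT2C",
    "KMT2D", "NFE2L2", "PTEN", "STK11", "ERBB2",
)

_NONSYN_CLASSES = np.array([
    "Missense_Mutation", "Nonsense_Mutation", "Splice_Site",
    "Frame_Shift_Del", "Frame_Shift_Ins", "In_Frame_Del",
    "In_Frame_Ins", "Nonstop_Mutation", "Translation_Start_Site",
])
_NONSYN_PROBS = np.array([0.70, 0.10, 0.05, 0.05, 0.04, 0.03, 0.02, 0.005, 0.005])

# pyrimidine-reference substitution classes with a C>T transition bias
_SUBST_CLASSES = [("C", "T"), ("C", "G"), ("C", "A"), ("T", "C"), ("T", "A"), ("T", "G")]
_SUBST_PROBS = np.array([0.40, 0.15, 0.15, 0.15, 0.075, 0.075])
_COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A"}


@dataclass
class CohortConfig:
    """Parameters of the planted-subtype generator."""

    n_samples: int = 60
    n_genes: int = 500
    n_program_genes: int = 100
    log2_effect: float = 2.0          # delta: log2 shift of program genes in sub1
    n_program2_genes: int = 60        # second program, shifted down in sub1
    log2_effect2: float = 1.5
    program_factor_sd: float = 0.6    # per-program latent co-expression factor (log2)
    nb_dispersion: float = 0.2        # alpha in var = mu + alpha mu^2
    log2_mean_range: tuple[float, float] = (3.0, 10.0)
    # program genes sit lower so the planted programs stay a small library
    # fraction, as immune programs do in a whole transcriptome
    program_log2_mean_range: tuple[float, float] = (3.0, 7.0)
    library_size_sigma: float = 0.3
    subtype_prevalence: float = 0.5   # pi = P(sub1)
    baseline_hazard: float = 0.03     # events/month for sub1
    hazard_ratio: float = 3.0         # HR of sub2 vs sub1
    censoring_rate: float = 0.25      # target censored fraction
    tmb_sub1: float = 6.0             # mean nonsynonymous muts/Mb
    tmb_sub2: float = 2.0
    footprint_mb: float = 35.0
    driver_genes: tuple[str, ...] = DEFAULT_DRIVERS
    driver_fraction: float = 0.2
    n_background_mut_genes: int = 50
    silent_fraction: float = 0.3      # silent variants per nonsynonymous variant
    seed: int = 0
    sampling_stream: int = 0          # distinguishes cohorts sharing one gene universe

    def validate(self) -> None:
        if not 0 < self.subtype_prevalence < 1:
            raise ValueError("subtype_prevalence must be in (0,1)")
        if self.log2_effect < 0:
            raise ValueError("log2_effect must be >= 0")
        if self.n_program_genes + self.n_program2_genes > self.n_genes:
            raise ValueError("program genes exceed n_genes")
        for name in ("baseline_hazard", "hazard_ratio", "footprint_mb"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if not 0 <= self.censoring_rate < 1:
            raise ValueError("censoring_rate must be in [0,1)")


@dataclass
class SyntheticCohort:
    expression: ExpressionMatrix
    clinical: ClinicalTable
    maf: MafTable
    true_labels: SubtypeAssignment
    program_gene_ids: list[str] = field(default_factory=list)
    program2_gene_ids: list[str] = field(default_factory=list)


#: Marker symbols planted into the immune program so the formula-defined
#: scores (CYT, checkpoint/INFG/CD8 signatures) are subtype-linked.
PROGRAM_MARKERS = [
    "GZMA", "PRF1", "CD8A", "CD8B", "CD274", "CTLA4", "HAVCR2", "LAG3",
    "PDCD1", "PDCD1LG2", "CXCL10", "CXCL9", "HLA-DRA", "IDO1", "IFNG", "STAT1",
]

#: Antigen-presentation genes planted into the background (the study found
#: no consistent subtype link for the APM score).
BACKGROUND_MARKERS = [
    "HLA-A", "HLA-B", "HLA-C", "TAP1", "TAP2", "TAPBP", "ERAP1", "ERAP2",
    "CANX", "CALR", "B2M", "PDIA3", "PSMB5", "PSMB6", "PSMB7", "PSMB8",
    "PSMB9", "PSMB10",
]


def _gene_baselines(config: CohortConfig):
    """Per-gene baselines shared by the main and immunotherapy cohorts.

    Drawn from a dedicated stream keyed on the config seed so that paired
    cohorts share gene identities, baseline means, and the program genes.
    Known marker symbols are planted so downstream score formulas apply.
    """
    rng = np.random.default_rng([config.seed, 7919])
    lo, hi = config.log2_mean_range
    log2_means = rng.uniform(lo, hi, size=config.n_genes)
    plo, phi = config.program_log2_mean_range
    both = rng.choice(config.n_genes,
                      size=config.n_program_genes + config.n_program2_genes,
                      replace=False)
    program_idx = np.sort(both[: config.n_program_genes])
    program2_idx = np.sort(both[config.n_program_genes:])
    log2_means[both] = rng.uniform(plo, phi, size=both.size)
    gene_ids = np.array([f"GENE{i + 1:04d}" for i in range(config.n_genes)], dtype=object)
    gene_ids[program_idx] = [f"IMM{j + 1:03d}" for j in range(config.n_program_genes)]
    gene_ids[program2_idx] = [f"STR{j + 1:03d}" for j in range(config.n_program2_genes)]
    n_mark = min(len(PROGRAM_MARKERS), config.n_program_genes)
    gene_ids[program_idx[:n_mark]] = PROGRAM_MARKERS[:n_mark]
    background_idx = np.setdiff1d(np.arange(config.n_genes), both)
    n_bg = min(len(BACKGROUND_MARKERS), len(background_idx))
    gene_ids[background_idx[:n_bg]] = BACKGROUND_MARKERS[:n_bg]
    # per-gene loading signs of the within-program latent factors; mean-zero
    # over the program so the subtype contrast itself is untouched
    sign1 = rng.choice([-1.0, 1.0], size=config.n_program_genes)
    sign2 = rng.choice([-1.0, 1.0], size=config.n_program2_genes)
    return gene_ids, log2_means, program_idx, program2_idx, sign1, sign2


def _nb_counts(rng, mu: np.ndarray, alpha: float) -> np.ndarray:
    """NB(mean mu, var mu + alpha mu^2) counts; Poisson limit at alpha=0."""
    if alpha <= 0:
        return rng.poisson(mu)
    n = 1.0 / alpha
    p = n / (n + mu)
    return rng.negative_binomial(n, p)


def _sample_counts(rng, config, baselines, program_shift, program2_shift):
    """Count matrix (genes x samples) with planted program shifts.

    Each program additionally carries a shared latent log2 factor
    (sd ``program_factor_sd``) with gene-specific loading signs, so its
    genes co-vary within subtypes (as co-regulated programs do in real
    cohorts) without moving the program mean.
    """
    _, log2_means, program_idx, program2_idx, sign1, sign2 = baselines
    n = len(program_shift)
    shift = np.zeros((config.n_genes, n))
    shift[program_idx, :] = program_shift[None, :]
    shift[program2_idx, :] = program2_shift[None, :]
    if config.program_factor_sd > 0:
        u = rng.normal(0, config.program_factor_sd, n)
        v = rng.normal(0, config.program_factor_sd, n)
        shift[program_idx, :] += sign1[:, None] * u[None, :]
        shift[program2_idx, :] += sign2[:, None] * v[None, :]
    mu = np.power(2.0, log2_means[:, None] + shift)
    lib = rng.lognormal(0.0, config.library_size_sigma, size=n)
    mu = mu * lib[None, :]
    return _nb_counts(rng, mu, config.nb_dispersion)


def _simulate_maf(rng, config, sample_ids, is_sub1) -> MafTable:
    bg_genes = np.array([f"MUTBG{i + 1:02d}" for i in range(config.n_background_mut_genes)])
    drivers = np.array(config.driver_genes, dtype=object)
    n_driv = len(drivers)
    # half the drivers enriched in sub1, half in sub2 (weight 3:1)
    w_sub1 = np.where(np.arange(n_driv) < n_driv // 2, 3.0, 1.0)
    w_sub2 = np.where(np.arange(n_driv) < n_driv // 2, 1.0, 3.0)
    rows = []
    for s, sid in enumerate(sample_ids):
        tmb = config.tmb_sub1 if is_sub1[s] else config.tmb_sub2
        n_nonsyn = rng.poisson(tmb * config.footprint_mb)
        n_silent = rng.poisson(config.silent_fraction * tmb * config.footprint_mb)
        w = w_sub1 if is_sub1[s] else w_sub2
        for n_var, silent in ((n_nonsyn, False), (n_silent, True)):
            if n_var == 0:
                continue
            to_driver = rng.random(n_var) < config.driver_fraction
            genes = np.empty(n_var, dtype=object)
            genes[~to_driver] = rng.choice(bg_genes, size=int((~to_driver).sum()))
            if to_driver.any():
                genes[to_driver] = rng.choice(
                    drivers, size=int(to_driver.sum()), p=w / w.sum()
                )
            if silent:
                classes = np.full(n_var, "Silent", dtype=object)
            else:
                classes = rng.choice(_NONSYN_CLASSES, size=n_var, p=_NONSYN_PROBS)
            for gene, vclass in zip(genes, classes):
                chrom = str(rng.integers(1, 23))
                pos = int(rng.integers(1, 100_000_000))
                if vclass in ("Frame_Shift_Del", "In_Frame_Del"):
                    vtype, ref, alt = "DEL", "".join(rng.choice(list("ACGT"), 3)), "-"
                elif vclass in ("Frame_Shift_Ins", "In_Frame_Ins"):
                    vtype, ref, alt = "INS", "-", "".join(rng.choice(list("ACGT"), 2))
                else:
                    vtype = "SNP"
                    ref, alt = _SUBST_CLASSES[rng.choice(6, p=_SUBST_PROBS)]
                    if rng.random() < 0.5:  # random strand
                        ref, alt = _COMPLEMENT[ref], _COMPLEMENT[alt]
                rows.append((gene, chrom, pos, ref, alt, vclass, vtype, sid))
    df = pd.DataFrame(
        rows,
        columns=[
            "Hugo_Symbol", "Chromosome", "Start_Position", "Reference_Allele",
            "Tumor_Seq_Allele2", "Variant_Classification", "Variant_Type",
            "Tumor_Sample_Barcode",
        ],
    )
    return MafTable(df)


def simulate_cohort(config: CohortConfig) -> SyntheticCohort:
    """Generate a full cohort (expression, survival, MAF, true labels).

    Deterministic given ``config.seed``.
    """
    config.validate()
    baselines = _gene_baselines(config)
    gene_ids, _, program_idx, program2_idx = baselines[0], baselines[1], baselines[2], baselines[3]
    rng = np.random.default_rng([config.seed, 1, config.sampling_stream])

    prefix = "S" if config.sampling_stream == 0 else f"C{config.sampling_stream}S"
    sample_ids = [f"{prefix}{i + 1:03d}" for i in range(config.n_samples)]
    is_sub1 = rng.random(config.n_samples) < config.subtype_prevalence
    if is_sub1.all() or (~is_sub1).all():  # degenerate draw on tiny cohorts
        is_sub1[0] = not is_sub1[0]
    shift = np.where(is_sub1, config.log2_effect, 0.0)
    shift2 = np.where(is_sub1, -config.log2_effect2, 0.0)
    counts = _sample_counts(rng, config, baselines, shift, shift2)
    expr = ExpressionMatrix(
        pd.DataFrame(counts, index=gene_ids, columns=sample_ids), "raw_counts"
    )

    hazard = np.where(is_sub1, config.baseline_hazard,
                      config.baseline_hazard * config.hazard_ratio)
    event_time = rng.exponential(1.0 / hazard)
    c = config.censoring_rate
    if c > 0:
        cens_hazard = hazard * c / (1.0 - c)
        cens_time = rng.exponential(1.0 / cens_hazard)
    else:
        cens_time = np.full(config.n_samples, np.inf)
    os_time = np.minimum(event_time, cens_time)
    os_event = (event_time < cens_time).astype(int)
    # PFS: faster clock, same subtype effect
    pfs_event_time = rng.exponential(1.0 / (1.4 * hazard))
    pfs_cens = np.minimum(cens_time, os_time)
    pfs_time = np.minimum(pfs_event_time, pfs_cens)
    pfs_event = (pfs_event_time < pfs_cens).astype(int)
    clinical = ClinicalTable(
        pd.DataFrame(
            {
                "os_time": os_time,
                "os_event": os_event,
                "pfs_time": pfs_time,
                "pfs_event": pfs_event,
                "age": np.round(rng.normal(52, 9, config.n_samples), 1),
            },
            index=pd.Index(sample_ids, name="sample_id"),
        )
    )

    maf = _simulate_maf(rng, config, sample_ids, is_sub1)
    labels = pd.Series(
        np.where(is_sub1, "sub1", "sub2"), index=sample_ids, name="subtype"
    )
    truth = SubtypeAssignment(labels, cohort="synthetic", k=2)
    return SyntheticCohort(expr, clinical, maf, truth, list(gene_ids[program_idx]),
                           list(gene_ids[program2_idx]))


def simulate_immunotherapy_cohort(
    config: CohortConfig, response_effect: float, n_samples: int | None = None
) -> tuple[ExpressionMatrix, pd.Series]:
    """Cohort of treated patients: responders carry the sub1 program.

    Responders ("R") have the program genes shifted by ``response_effect``
    log2 units; non-responders ("NR") share the sub2 background. Gene-level
    baselines are shared with :func:`simulate_cohort` for the same config.
    """
    config.validate()
    if response_effect < 0:
        raise ValueError("response_effect must be >= 0")
    baselines = _gene_baselines(config)
    gene_ids = baselines[0]
    rng = np.random.default_rng([config.seed, 2])
    n = n_samples or config.n_samples
    sample_ids = [f"T{i + 1:03d}" for i in range(n)]
    responder = rng.random(n) < 0.5
    if responder.all() or (~responder).all():
        responder[0] = not responder[0]
    shift = np.where(responder, response_effect, 0.0)
    shift2 = np.where(responder, -config.log2_effect2, 0.0) \
        if response_effect > 0 else np.zeros(n)
    counts = _sample_counts(rng, config, baselines, shift, shift2)
    expr = ExpressionMatrix(
        pd.DataFrame(counts, index=gene_ids, columns=sample_ids), "raw_counts"
    )
    labels = pd.Series(np.where(responder, "R", "NR"), index=sample_ids, name="response")
    return expr, labels


def write_cohort(cohort: SyntheticCohort, outdir) -> None:
    """Write a cohort directory consumable by the CLI."""
    from pathlib import Path

    from . import io as _io

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    _io.write_expression(cohort.expression, outdir / "expression.tsv")
    _io.write_clinical(cohort.clinical, outdir / "clinical.tsv")
    _io.write_maf(cohort.maf, outdir / "mutations.maf")
    _io.write_assignment(cohort.true_labels, outdir / "truth.tsv")
    with open(outdir / "program_genes.txt", "w") as fh:
        fh.write("\n".join(cohort.program_gene_ids) + "\n")


def default_config(seed: int = 0, **overrides) -> CohortConfig:
    return replace(CohortConfig(seed=seed), **overrides)


def synthetic_gene_sets(config: CohortConfig):
    """Synthetic stand-ins for the curated gene-set inputs.

    Builds, from the generator's own gene universe: a 28-cell-type panel
    (each set sampling the immune program plus a little background noise),
    stromal/immune sets, an immune-related-gene screening list, and toy
    pathway sets for GSEA. These emulate the role of the curated
    collections (cell-type signatures, stromal/immune panels, pathway
    GMTs) without reproducing their actual content.

    Returns ``{"cell_types": GeneSetCollection, "stromal_immune":
    GeneSetCollection, "irg_list": [...], "pathways": GeneSetCollection}``.
    """
    from .io import GeneSetCollection
    from .scoring import ADAPTIVE_CELL_TYPES, INNATE_CELL_TYPES

    gene_ids, _, program_idx, program2_idx, _, _ = _gene_baselines(config)
    program = list(gene_ids[program_idx])
    exclude = set(program) | set(gene_ids[program2_idx])
    background = [g for g in gene_ids if g not in exclude]
    rng = np.random.default_rng([config.seed, 7920])
    cell_sets = {}
    for name in [*ADAPTIVE_CELL_TYPES, *INNATE_CELL_TYPES]:
        n_prog = 12 if name not in ("Mast cell", "Gamma delta T cell") else 2
        genes = list(rng.choice(program, size=min(n_prog, len(program)),
                                replace=False))
        genes += list(rng.choice(background, size=3, replace=False))
        cell_sets[name] = list(dict.fromkeys(genes))
    stromal_immune = GeneSetCollection({
        "immune": program,
        "stromal": list(rng.choice(background, size=min(50, len(background)),
                                   replace=False)),
    })
    irg = program + list(gene_ids[program2_idx]) + list(
        rng.choice(background, size=min(150, len(background)), replace=False))
    pathways = {"IMMUNE_PROGRAM": list(rng.choice(program, size=min(30, len(program)),
                                                  replace=False))}
    for i in range(5):
        pathways[f"RANDOM_SET_{i + 1}"] = list(
            rng.choice(background, size=20, replace=False))
    return {
        "cell_types": GeneSetCollection(cell_sets),
        "stromal_immune": stromal_immune,
        "irg_list": list(dict.fromkeys(irg)),
        "pathways": GeneSetCollection(pathways),
    }
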