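"""Synthetic two-compartment cohorts with known ground truth.

A bulk tumor sample is modelled as a transcript-level mixture of a tumor and
a microenvironment (TME) compartment: with per-sample purity p, the observed
log2 expression of gene g is

    y_g = log2( p * 2^{x_T(g)} + (1 - p) * 2^{x_E(g)} ) + Normal(0, noise_sd)

so mixing happens on the linear scale, where transcripts actually add.  Each
compartment's log2 expression starts from a shared per-gene baseline
mu_g ~ Normal(0, 1).  Genes expressed preferentially in one compartment carry
a compartment-restricted baseline elevation delta_g ~ Uniform(0.5, 1.5):
tumor targets and pos_background genes in the tumor compartment, env targets
and neg_background genes in the TME compartment, nonspecific targets in both.
This is what makes compartment-specific genes purity-correlated in the mixed
observation — the structure the profile builder and the reference-gene
adjustment rely on.  On top of the baseline, latent per-sample activities
a_T, a_E ~ Normal(0, activity_sd) shift each target by
effect_size * a * w_g in its compartment (nonspecific targets respond to
both).  Target affinity weights w_g ~ Uniform(0.5, 1) are emitted as a
binding table with p-values 10^(-10 w), the exact preimage of the affinity
mapping; decoy genes receive sub-threshold affinities.

Everything is a pure function of (config, seed).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ValidationError
from .io import CNVSegments, ExpressionMatrix, HG19_GENOME_SIZE

__all__ = [
    "SimulationConfig",
    "SimulationTruth",
    "CohortBundle",
    "ScreenBundle",
    "simulate_two_compartment",
    "simulate_screen_cohorts",
    "simulate_segments",
    "default_screen_config",
    "write_cohort",
]

GENE_CLASSES = (
    "tumor_target",
    "env_target",
    "nonspecific_target",
    "pos_background",
    "neg_background",
    "neutral",
)


@dataclass(frozen=True)
class SimulationConfig:
    """Two-compartment cohort generator settings (defaults = study conditions)."""

    n_samples: int = 200
    n_genes: int = 5000
    n_tumor_targets: int = 120
    n_env_targets: int = 170
    n_nonspecific_targets: int = 90
    n_pos_background: int = 400
    n_neg_background: int = 400
    effect_size: float = 1.0  # log2 shift per unit activity (times weight)
    noise_sd: float = 0.5  # residual log2-scale SD
    purity_range: tuple[float, float] = (0.3, 0.9)
    activity_sd: float = 1.0
    tumor_activity_sd: float | None = None  # override; None = activity_sd
    env_activity_sd: float | None = None
    baseline_shift_range: tuple[float, float] = (0.5, 1.5)
    n_decoy_bindings: int = 300  # non-target genes given sub-threshold affinities
    seed: int = 0

    def __post_init__(self) -> None:
        counts = (
            self.n_tumor_targets,
            self.n_env_targets,
            self.n_nonspecific_targets,
            self.n_pos_background,
            self.n_neg_background,
        )
        if any(c < 0 for c in counts) or sum(counts) > self.n_genes:
            raise ValidationError("gene-class counts must be >= 0 and sum to <= n_genes")
        if self.noise_sd <= 0:
            raise ValidationError("noise_sd must be > 0")
        lo, hi = self.purity_range
        if not (0 <= lo <= hi <= 1):
            raise ValidationError("purity_range must satisfy 0 <= lo <= hi <= 1")
        if self.n_samples < 2 or self.n_genes < 2:
            raise ValidationError("need at least 2 samples and 2 genes")

    @property
    def tumor_sd(self) -> float:
        return self.activity_sd if self.tumor_activity_sd is None else self.tumor_activity_sd

    @property
    def env_sd(self) -> float:
        return self.activity_sd if self.env_activity_sd is None else self.env_activity_sd


@dataclass
class SimulationTruth:
    """Ground truth: per-sample latent state and per-gene class/parameters."""

    samples: pd.DataFrame  # index sample: purity, a_T, a_E
    genes: pd.DataFrame  # index gene: class, weight, delta, mu


@dataclass
class CohortBundle:
    expression: ExpressionMatrix  # raw log2 observations (not yet median-centered)
    purity: pd.Series
    binding: pd.DataFrame  # gene, p_value
    truth: SimulationTruth


@dataclass
class ScreenBundle:
    tumor: ExpressionMatrix
    celllines: ExpressionMatrix
    purity: pd.Series
    tme_tfs: list
    tumor_tfs: list
    truth: SimulationTruth


def _draw_purity(rng: np.random.Generator, n: int, purity_range) -> np.ndarray:
    lo, hi = purity_range
    return np.full(n, float(lo)) if lo == hi else rng.uniform(lo, hi, size=n)


def _gene_classes(cfg: SimulationConfig) -> np.ndarray:
    classes = np.array(["neutral"] * cfg.n_genes, dtype=object)
    bounds = np.cumsum(
        [
            cfg.n_tumor_targets,
            cfg.n_env_targets,
            cfg.n_nonspecific_targets,
            cfg.n_pos_background,
            cfg.n_neg_background,
        ]
    )
    starts = np.concatenate([[0], bounds[:-1]])
    for cls, s, e in zip(GENE_CLASSES[:-1], starts, bounds):
        classes[s:e] = cls
    return classes


def simulate_two_compartment(cfg: SimulationConfig) -> CohortBundle:
    """Generate a mixed-compartment cohort with binding table and ground truth."""
    rng = np.random.default_rng(cfg.seed)
    genes = np.array([f"G{i:05d}" for i in range(cfg.n_genes)], dtype=object)
    samples = [f"S{i:04d}" for i in range(cfg.n_samples)]
    classes = _gene_classes(cfg)

    mu = rng.normal(0.0, 1.0, size=cfg.n_genes)
    lo, hi = cfg.baseline_shift_range
    delta = rng.uniform(lo, hi, size=cfg.n_genes)
    delta[classes == "neutral"] = 0.0

    is_target = np.isin(classes, ("tumor_target", "env_target", "nonspecific_target"))
    weight = np.zeros(cfg.n_genes)
    weight[is_target] = rng.uniform(0.5, 1.0, size=int(is_target.sum()))

    purity = _draw_purity(rng, cfg.n_samples, cfg.purity_range)
    a_t = rng.normal(0.0, 1.0, size=cfg.n_samples) * cfg.tumor_sd
    a_e = rng.normal(0.0, 1.0, size=cfg.n_samples) * cfg.env_sd

    in_tumor = np.isin(classes, ("tumor_target", "nonspecific_target", "pos_background"))
    in_env = np.isin(classes, ("env_target", "nonspecific_target", "neg_background"))
    t_responsive = np.isin(classes, ("tumor_target", "nonspecific_target"))
    e_responsive = np.isin(classes, ("env_target", "nonspecific_target"))

    base = mu[:, None]
    x_t = base + (delta * in_tumor)[:, None] + cfg.effect_size * np.outer(
        weight * t_responsive, a_t
    )
    x_e = base + (delta * in_env)[:, None] + cfg.effect_size * np.outer(
        weight * e_responsive, a_e
    )
    mixed = np.log2(purity[None, :] * np.exp2(x_t) + (1.0 - purity)[None, :] * np.exp2(x_e))
    observed = mixed + rng.normal(0.0, cfg.noise_sd, size=mixed.shape)

    expr = ExpressionMatrix(
        values=pd.DataFrame(observed, index=pd.Index(genes, name="gene"), columns=samples)
    )

    # binding table: exact preimage of the affinity map for targets, plus decoys
    target_idx = np.flatnonzero(is_target)
    non_target_idx = np.flatnonzero(~is_target)
    n_decoys = min(cfg.n_decoy_bindings, non_target_idx.size)
    decoy_idx = rng.choice(non_target_idx, size=n_decoys, replace=False)
    decoy_w = rng.uniform(0.01, 0.45, size=n_decoys)
    binding = pd.DataFrame(
        {
            "gene": np.concatenate([genes[target_idx], genes[decoy_idx]]),
            "p_value": np.concatenate(
                [10.0 ** (-10.0 * weight[target_idx]), 10.0 ** (-10.0 * decoy_w)]
            ),
        }
    ).sort_values("gene", kind="stable").reset_index(drop=True)

    truth = SimulationTruth(
        samples=pd.DataFrame(
            {"purity": purity, "a_T": a_t, "a_E": a_e},
            index=pd.Index(samples, name="sample"),
        ),
        genes=pd.DataFrame(
            {"class": classes, "weight": weight, "delta": delta, "mu": mu},
            index=pd.Index(genes, name="gene"),
        ),
    )
    return CohortBundle(
        expression=expr,
        purity=pd.Series(purity, index=pd.Index(samples, name="sample"), name="purity"),
        binding=binding,
        truth=truth,
    )


def default_screen_config() -> SimulationConfig:
    """Study conditions for the TF screen benchmark: 50 tumors, 500 genes.

    TME-restricted genes (immune/stromal markers) show multi-log2 tissue vs
    cell-line contrasts in practice, so the planted effect is 3 log2 units
    (8-fold) around a 0.5-log2 noise floor.
    """
    return SimulationConfig(
        n_samples=50,
        n_genes=500,
        n_tumor_targets=0,
        n_env_targets=0,
        n_nonspecific_targets=0,
        n_pos_background=0,
        n_neg_background=0,
        effect_size=3.0,
        noise_sd=0.5,
        purity_range=(0.3, 0.9),
        seed=0,
    )


def simulate_screen_cohorts(
    cfg: SimulationConfig,
    n_celllines: int = 30,
    n_tme_tfs: int = 20,
    n_tumor_tfs: int = 10,
) -> ScreenBundle:
    """Generate matched tumor and pure cell-line cohorts with planted TFs.

    Planted TME TFs are expressed only in the environment compartment
    (elevated by effect_size in x_E); planted tumor TFs are up-shifted in the
    tumor compartment.  Cell lines are drawn at purity 1 (pure tumor), tumors
    as mixtures over ``cfg.purity_range``.
    """
    if n_tme_tfs + n_tumor_tfs > cfg.n_genes:
        raise ValidationError("planted TF counts exceed n_genes")
    rng = np.random.default_rng(cfg.seed)
    genes = np.array([f"G{i:05d}" for i in range(cfg.n_genes)], dtype=object)
    tumor_samples = [f"S{i:04d}" for i in range(cfg.n_samples)]
    cell_samples = [f"CL{i:04d}" for i in range(n_celllines)]

    classes = np.array(["neutral"] * cfg.n_genes, dtype=object)
    classes[:n_tme_tfs] = "env_target"
    classes[n_tme_tfs : n_tme_tfs + n_tumor_tfs] = "tumor_target"

    mu = rng.normal(0.0, 1.0, size=cfg.n_genes)
    shift = cfg.effect_size * rng.uniform(0.75, 1.25, size=cfg.n_genes)
    shift[classes == "neutral"] = 0.0

    x_t = mu + shift * (classes == "tumor_target")
    x_e = mu + shift * (classes == "env_target")

    purity = _draw_purity(rng, cfg.n_samples, cfg.purity_range)
    mixed = np.log2(
        purity[None, :] * np.exp2(x_t)[:, None]
        + (1.0 - purity)[None, :] * np.exp2(x_e)[:, None]
    )
    tumor_obs = mixed + rng.normal(0.0, cfg.noise_sd, size=(cfg.n_genes, cfg.n_samples))
    cell_obs = x_t[:, None] + rng.normal(0.0, cfg.noise_sd, size=(cfg.n_genes, n_celllines))

    gene_index = pd.Index(genes, name="gene")
    truth = SimulationTruth(
        samples=pd.DataFrame(
            {"purity": purity},
            index=pd.Index(tumor_samples, name="sample"),
        ),
        genes=pd.DataFrame(
            {"class": classes, "weight": 0.0, "delta": shift, "mu": mu}, index=gene_index
        ),
    )
    return ScreenBundle(
        tumor=ExpressionMatrix(pd.DataFrame(tumor_obs, index=gene_index, columns=tumor_samples)),
        celllines=ExpressionMatrix(pd.DataFrame(cell_obs, index=gene_index, columns=cell_samples)),
        purity=pd.Series(purity, index=pd.Index(tumor_samples, name="sample"), name="purity"),
        tme_tfs=list(genes[classes == "env_target"]),
        tumor_tfs=list(genes[classes == "tumor_target"]),
        truth=truth,
    )


def simulate_segments(
    n_samples: int,
    target_burdens,
    genome_size: float = HG19_GENOME_SIZE,
    seed: int = 0,
    n_chromosomes: int = 22,
    clamp_floor: float = 0.25,
) -> CNVSegments:
    """Segments whose analytic CNV burden equals the requested value exactly.

    The genome is partitioned into ``n_chromosomes`` contiguous pieces whose
    sizes sum to ``genome_size`` exactly; each receives copy number
    2 * 2**b (gain) or 2 * 2**(-b) (loss, only while it stays above the clamp
    floor), both contributing |log2(C/2)| = b per bp, so the summed burden is
    the target to machine precision.  Negative targets are unachievable.
    """
    target_burdens = list(target_burdens)
    if len(target_burdens) != n_samples:
        raise ValidationError("need one target burden per sample")
    if any((not np.isfinite(b)) or b < 0 for b in target_burdens):
        raise ValidationError("target burdens must be finite and >= 0")
    genome_size = int(genome_size)
    rng = np.random.default_rng(seed)
    chrom_size = genome_size // n_chromosomes
    sizes = [chrom_size] * (n_chromosomes - 1) + [genome_size - chrom_size * (n_chromosomes - 1)]
    rows = []
    for i, b in enumerate(target_burdens):
        sample = f"S{i:04d}"
        deletions_ok = b <= np.log2(2.0 / clamp_floor)
        start = 1
        for c_idx, size in enumerate(sizes):
            if b == 0:
                copy = 2.0
            elif deletions_ok and rng.random() < 0.5:
                copy = 2.0 * 2.0 ** (-b)
            else:
                copy = 2.0 * 2.0**b
            rows.append((sample, f"chr{c_idx + 1}", start, start + size - 1, copy))
            start += size
    seg = pd.DataFrame(rows, columns=["sample", "chromosome", "start", "end", "copy_number"])
    return CNVSegments(segments=seg, genome_size=float(genome_size))


def write_cohort(bundle: CohortBundle, out_dir) -> dict:
    """Write expr.tsv, purity.tsv, binding.tsv and truth tables to a directory."""
    from pathlib import Path

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "expression": out / "expr.tsv",
        "purity": out / "purity.tsv",
        "binding": out / "binding.tsv",
        "truth_samples": out / "truth_samples.tsv",
        "truth_genes": out / "truth_genes.tsv",
    }
    bundle.expression.values.to_csv(paths["expression"], sep="\t", float_format="%.17g")
    bundle.purity.rename("purity").to_csv(paths["purity"], sep="\t", float_format="%.17g")
    bundle.binding.to_csv(paths["binding"], sep="\t", index=False, float_format="%.17g")
    bundle.truth.samples.to_csv(paths["truth_samples"], sep="\t", float_format="%.17g")
    bundle.truth.genes.to_csv(paths["truth_genes"], sep="\t", float_format="%.17g")
    return {k: str(v) for k, v in paths.items()}
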