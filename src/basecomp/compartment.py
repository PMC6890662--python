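"""Compartment-specific TF activity: target partitioning and purity-adjusted scoring.

Bulk tumor expression mixes malignant cells with the tumor microenvironment
(TME), so a TF active in both compartments produces a confounded single
activity estimate.  This module builds compartment-specific target profiles:
ChIP-derived binding p-values are mapped to affinity weights, high-affinity
targets are split into tumor-specific (positively purity-correlated),
environment-specific (negatively purity-correlated) and nonspecific sets, and
purity-correlated *non-target* genes are kept aside as reference genes.
Scoring the tumor targets against a background of positively purity-correlated
references (and env targets against negative references) cancels the purity
trend that would otherwise masquerade as activity: both foreground and
background move together with purity, so only activity-driven displacement of
the targets relative to the references registers in the score.

Per-sample output is a (G, T, E) triple: General activity from all targets on
the full gene universe, Tumor and Environmental activity from the restricted,
mutually disjoint universes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .base import WeightProfile, score_samples
from .errors import DegenerateInputError, ValidationError
from .io import ExpressionMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "PurityVector",
    "CompartmentProfile",
    "affinity_from_pvalue",
    "select_targets",
    "purity_correlation",
    "partition_targets",
    "select_reference_genes",
    "build_profile",
    "infer_compartment_activities",
    "read_profile",
    "write_profile",
    "read_purity",
]


def read_purity(path) -> pd.Series:
    """Read a per-sample tumor purity TSV (sample, purity) into a Series."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    s = pd.to_numeric(df.iloc[:, 0], errors="raise")
    s.index = s.index.astype(str)
    return PurityVector(s).values


@dataclass
class PurityVector:
    """Per-sample tumor purity in [0, 1]."""

    values: pd.Series

    def __post_init__(self) -> None:
        self.values = self.values.astype(float)
        v = self.values.to_numpy()
        if ((v < 0) | (v > 1)).any() or not np.isfinite(v).all():
            raise ValidationError("purity values must lie in [0, 1]")


@dataclass
class CompartmentProfile:
    """Tumor/environment/nonspecific target weights plus reference gene sets."""

    tf_name: str
    tumor_targets: pd.Series  # gene -> w
    env_targets: pd.Series
    nonspecific_targets: pd.Series
    pos_ref: frozenset = field(default_factory=frozenset)
    neg_ref: frozenset = field(default_factory=frozenset)
    affinity_cutoff: float = 0.5
    compartment_scc_cutoff: float = 0.1
    ref_scc_cutoff: float = 0.1
    ref_fdr: float | None = 0.05

    def __post_init__(self) -> None:
        self.tumor_targets = pd.Series(self.tumor_targets, dtype=float)
        self.env_targets = pd.Series(self.env_targets, dtype=float)
        self.nonspecific_targets = pd.Series(self.nonspecific_targets, dtype=float)
        self.pos_ref = frozenset(self.pos_ref)
        self.neg_ref = frozenset(self.neg_ref)
        sets = {
            "tumor": set(self.tumor_targets.index),
            "env": set(self.env_targets.index),
            "nonspecific": set(self.nonspecific_targets.index),
        }
        names = list(sets)
        for i, a in enumerate(names):
            for b in names[i + 1 :]:
                overlap = sets[a] & sets[b]
                if overlap:
                    raise ValidationError(
                        f"{a} and {b} targets overlap: {sorted(overlap)[:10]}"
                    )
        all_targets = sets["tumor"] | sets["env"] | sets["nonspecific"]
        for name, ref in (("pos_ref", self.pos_ref), ("neg_ref", self.neg_ref)):
            overlap = set(ref) & all_targets
            if overlap:
                raise ValidationError(f"{name} overlaps target sets: {sorted(overlap)[:10]}")
        for name, s in (
            ("tumor", self.tumor_targets),
            ("env", self.env_targets),
            ("nonspecific", self.nonspecific_targets),
        ):
            if len(s) and (s.to_numpy() < self.affinity_cutoff).any():
                raise ValidationError(f"{name} targets carry weights below the affinity cutoff")

    @property
    def all_targets(self) -> pd.Series:
        return pd.concat([self.tumor_targets, self.env_targets, self.nonspecific_targets])


def affinity_from_pvalue(p) -> np.ndarray | float:
    """Map a ChIP binding p-value to an affinity weight: w = min(1, -log10(p)/10).

    Anchored so that w = 0.5 corresponds to p = 1e-5 and saturates at 1 for
    p <= 1e-10; monotone non-increasing in p.
    """
    arr = np.asarray(p, dtype=float)
    if ((arr <= 0) | (arr > 1)).any() or not np.isfinite(arr).all():
        raise ValidationError("binding p-values must lie in (0, 1]")
    w = np.minimum(1.0, -np.log10(arr) / 10.0)
    return float(w) if np.isscalar(p) else w


def select_targets(bt: pd.DataFrame, affinity_cutoff: float = 0.5) -> pd.Series:
    """High-affinity targets (w >= cutoff) from a (gene, p_value) binding table."""
    w = affinity_from_pvalue(bt["p_value"].to_numpy())
    out = pd.Series(w, index=bt["gene"].astype(str))
    out = out[out >= affinity_cutoff]
    if out.empty:
        raise DegenerateInputError(
            f"no targets at affinity cutoff {affinity_cutoff}; cutoff too strict?"
        )
    return out.sort_index()


def purity_correlation(em: ExpressionMatrix, purity: pd.Series) -> pd.Series:
    """Per-gene Spearman correlation with tumor purity over shared samples.

    Constant gene rows get SCC = 0 (flagged in the log).  Requires >= 10
    shared samples.
    """
    purity = PurityVector(pd.Series(purity)).values
    shared = em.sample_ids.intersection(purity.index)
    if len(shared) < 10:
        raise ValidationError(f"only {len(shared)} shared samples; >= 10 required")
    X = em.values[shared].to_numpy()
    p = purity.loc[shared].to_numpy()
    # vectorized Spearman: Pearson on midranks
    rx = stats.rankdata(X, axis=1)
    rp = stats.rankdata(p)
    rx_c = rx - rx.mean(axis=1, keepdims=True)
    rp_c = rp - rp.mean()
    denom = np.sqrt((rx_c**2).sum(axis=1) * (rp_c**2).sum())
    degenerate = denom == 0
    if degenerate.any():
        logger.info("purity_correlation: %d constant rows set to SCC=0", int(degenerate.sum()))
    with np.errstate(invalid="ignore", divide="ignore"):
        scc = (rx_c @ rp_c) / denom
    scc[degenerate] = 0.0
    out = pd.Series(scc, index=em.gene_ids, name="scc")
    out.attrs["n_samples"] = int(len(shared))
    return out


def _spearman_pvalues(scc: np.ndarray, n: int) -> np.ndarray:
    """Two-sided p for Spearman coefficients via the t approximation (n-2 df)."""
    r = np.clip(scc, -1.0, 1.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = r * np.sqrt((n - 2) / (1.0 - r**2))
    p = 2.0 * stats.t.sf(np.abs(t), n - 2)
    p[np.abs(r) == 1.0] = 0.0
    return p


def purity_significance(
    scc: pd.Series, fdr: float = 0.05, n_samples: int | None = None
) -> pd.Series:
    """Boolean mask of genes whose purity correlation is BH-significant.

    One uniform screen applied to both target partitioning and reference-gene
    selection.  ``n_samples`` defaults to the cohort size recorded by
    :func:`purity_correlation`.
    """
    if n_samples is None:
        n_samples = scc.attrs.get("n_samples")
    if n_samples is None or n_samples <= 3:
        raise ValidationError("purity_significance needs the cohort size (n_samples)")
    q = stats.false_discovery_control(_spearman_pvalues(scc.to_numpy(), n_samples))
    return pd.Series(q < fdr, index=scc.index)


def partition_targets(
    targets: pd.Series,
    scc: pd.Series,
    compartment_scc_cutoff: float = 0.1,
    significant: pd.Series | None = None,
) -> tuple[pd.Series, pd.Series, pd.Series]:
    """Split targets into (tumor, env, nonspecific) by purity correlation.

    tumor: SCC > cutoff; env: SCC < -cutoff; everything else (including
    targets absent from the correlation table, logged) is nonspecific.
    Weights are carried along; the three outputs exactly partition the input.

    ``significant`` optionally restricts compartment calls to genes whose
    purity correlation passed a significance screen; it must be the same
    screen applied to reference-gene selection so that targets and references
    are drawn from purity-correlated genes under one uniform definition
    (mismatched strength distributions between the two let the purity
    confounder leak back into the compartment scores).
    """
    aligned = scc.reindex(targets.index)
    missing = aligned.index[aligned.isna()]
    if len(missing):
        logger.info("partition_targets: %d targets missing SCC -> nonspecific", len(missing))
    aligned = aligned.fillna(0.0)
    if significant is None:
        sig = pd.Series(True, index=targets.index)
    else:
        sig = significant.reindex(targets.index).fillna(False).astype(bool)
    tumor = targets[(aligned > compartment_scc_cutoff) & sig]
    env = targets[(aligned < -compartment_scc_cutoff) & sig]
    nonspecific = targets[~targets.index.isin(tumor.index) & ~targets.index.isin(env.index)]
    return tumor, env, nonspecific


def select_reference_genes(
    scc: pd.Series,
    targets: pd.Series,
    bt: pd.DataFrame | None = None,
    ref_scc_cutoff: float = 0.1,
    affinity_cutoff: float = 0.5,
    ref_fdr: float | None = 0.05,
    n_samples: int | None = None,
    significant: pd.Series | None = None,
) -> tuple[frozenset, frozenset]:
    """Purity-correlated non-target genes used as compartment backgrounds.

    pos_ref: SCC > cutoff; neg_ref: SCC < -cutoff; both exclude every target
    and every gene whose binding affinity reaches the target threshold.

    A raw SCC magnitude cutoff admits a non-trivial fraction of genuinely
    uncorrelated genes at genome scale (at n = 200 samples, ~8% of null genes
    exceed |SCC| = 0.1), and such chance references dilute the purity signal
    the background is supposed to carry, letting the confounder leak back into
    the compartment scores.  References are therefore additionally required to
    have a Benjamini-Hochberg-adjusted Spearman p below ``ref_fdr`` (default
    0.05) whenever the cohort size is known (``n_samples``, taken from
    ``scc.attrs`` when :func:`purity_correlation` produced the series).  Pass
    ``ref_fdr=None`` for the magnitude-only rule.
    """
    affinity = pd.Series(0.0, index=scc.index)
    if bt is not None:
        w = pd.Series(
            affinity_from_pvalue(bt["p_value"].to_numpy()), index=bt["gene"].astype(str)
        )
        affinity = w.reindex(scc.index, fill_value=0.0)
    if n_samples is None:
        n_samples = scc.attrs.get("n_samples")
    if significant is None:
        if ref_fdr is not None and n_samples is not None and n_samples > 3:
            significant = purity_significance(scc, fdr=ref_fdr, n_samples=n_samples)
        else:
            if ref_fdr is not None:
                logger.info(
                    "select_reference_genes: cohort size unknown, magnitude-only rule"
                )
            significant = pd.Series(True, index=scc.index)
    eligible = scc.index[
        ~scc.index.isin(targets.index) & (affinity < affinity_cutoff) & significant
    ]
    pos = frozenset(scc.loc[eligible][scc.loc[eligible] > ref_scc_cutoff].index)
    neg = frozenset(scc.loc[eligible][scc.loc[eligible] < -ref_scc_cutoff].index)
    if not pos or not neg:
        raise DegenerateInputError(
            "empty reference gene set (pos=%d, neg=%d); purity adjustment impossible"
            % (len(pos), len(neg))
        )
    return pos, neg


def build_profile(
    bt: pd.DataFrame,
    em: ExpressionMatrix,
    purity: pd.Series,
    tf_name: str = "TF",
    affinity_cutoff: float = 0.5,
    compartment_scc_cutoff: float = 0.1,
    ref_scc_cutoff: float = 0.1,
    ref_fdr: float | None = 0.05,
) -> CompartmentProfile:
    """Construct a compartment profile on a training cohort.

    Profiles are built once (binding table + expression + purity) and then
    applied frozen to other cohorts.
    """
    targets = select_targets(bt, affinity_cutoff)
    scc = purity_correlation(em, purity)
    # one significance screen shared by the partition and the reference pool,
    # so targets and references sample the purity-correlated genes identically
    significant = None
    if ref_fdr is not None:
        significant = purity_significance(scc, fdr=ref_fdr)
    tumor, env, nonspecific = partition_targets(
        targets, scc, compartment_scc_cutoff, significant=significant
    )
    for name, part in (("tumor", tumor), ("env", env)):
        if part.empty:
            raise DegenerateInputError(
                f"no {name}-specific targets at SCC cutoff {compartment_scc_cutoff}"
                + (
                    " with the significance screen; the cohort may be too small"
                    " for compartment calls (consider more samples or ref_fdr=None)"
                    if significant is not None
                    else ""
                )
            )
    pos_ref, neg_ref = select_reference_genes(
        scc, targets, bt, ref_scc_cutoff=ref_scc_cutoff, affinity_cutoff=affinity_cutoff,
        ref_fdr=ref_fdr, significant=significant,
    )
    logger.info(
        "profile %s: %d tumor / %d env / %d nonspecific targets; %d pos / %d neg refs",
        tf_name, len(tumor), len(env), len(nonspecific), len(pos_ref), len(neg_ref),
    )
    return CompartmentProfile(
        tf_name=tf_name,
        tumor_targets=tumor,
        env_targets=env,
        nonspecific_targets=nonspecific,
        pos_ref=pos_ref,
        neg_ref=neg_ref,
        affinity_cutoff=affinity_cutoff,
        compartment_scc_cutoff=compartment_scc_cutoff,
        ref_scc_cutoff=ref_scc_cutoff,
        ref_fdr=ref_fdr,
    )


def _check_coverage(name: str, members: pd.Index, present: pd.Index) -> pd.Index:
    kept = members.intersection(present)
    frac = len(kept) / len(members) if len(members) else 1.0
    logger.info("coverage of %s: %.1f%% (%d/%d)", name, 100 * frac, len(kept), len(members))
    if frac < 0.5:
        raise ValidationError(
            f"only {frac:.0%} of {name} present in the expression matrix (>= 50% required)"
        )
    return kept


def infer_compartment_activities(
    em: ExpressionMatrix,
    cp: CompartmentProfile,
    n_perm: int = 1000,
    seed: int = 0,
    mode: str = "zscore",
) -> pd.DataFrame:
    """Per-sample purity-adjusted (G, T, E) normalized activity scores.

    G uses all targets against the full gene universe; T restricts the
    universe to tumor targets plus positive reference genes (refs at w = 0);
    E to environment targets plus negative reference genes.  The T and E
    universes are disjoint by construction.  Returns a DataFrame indexed by
    sample with columns G, T, E.
    """
    genes = em.gene_ids
    tumor = _check_coverage("tumor targets", cp.tumor_targets.index, genes)
    env = _check_coverage("env targets", cp.env_targets.index, genes)
    pos_ref = _check_coverage("pos_ref", pd.Index(sorted(cp.pos_ref)), genes)
    neg_ref = _check_coverage("neg_ref", pd.Index(sorted(cp.neg_ref)), genes)

    branches = {
        "G": (WeightProfile(f"{cp.tf_name}:G", cp.all_targets), None),
        "T": (
            WeightProfile(f"{cp.tf_name}:T", cp.tumor_targets.loc[tumor]),
            tumor.union(pos_ref),
        ),
        "E": (
            WeightProfile(f"{cp.tf_name}:E", cp.env_targets.loc[env]),
            env.union(neg_ref),
        ),
    }
    out = {}
    for k, (label, (profile, universe)) in enumerate(branches.items()):
        branch_seed = int(
            np.random.SeedSequence(entropy=seed, spawn_key=(0xC0, k)).generate_state(1)[0]
            >> 1
        )
        scores = score_samples(
            em, profile, universe=universe, n_perm=n_perm, seed=branch_seed, mode=mode
        )
        out[label] = scores["normalized"]
    table = pd.DataFrame(out)
    table.index.name = "sample"
    table.attrs.update({"n_perm": n_perm, "mode": mode, "seed": seed, "tf": cp.tf_name})
    return table


_PROFILE_CLASSES = ("tumor", "env", "nonspecific", "pos_ref", "neg_ref")


def write_profile(cp: CompartmentProfile, path) -> None:
    """Serialize a profile as TSV (gene, weight, class) with a cutoff header."""
    rows = []
    for cls, series in (
        ("tumor", cp.tumor_targets),
        ("env", cp.env_targets),
        ("nonspecific", cp.nonspecific_targets),
    ):
        rows += [(g, w, cls) for g, w in series.sort_index().items()]
    rows += [(g, 0.0, "pos_ref") for g in sorted(cp.pos_ref)]
    rows += [(g, 0.0, "neg_ref") for g in sorted(cp.neg_ref)]
    df = pd.DataFrame(rows, columns=["gene", "weight", "class"])
    with open(path, "w") as fh:
        fh.write(f"# tf_name={cp.tf_name}\n")
        fh.write(f"# affinity_cutoff={cp.affinity_cutoff:.17g}\n")
        fh.write(f"# compartment_scc_cutoff={cp.compartment_scc_cutoff:.17g}\n")
        fh.write(f"# ref_scc_cutoff={cp.ref_scc_cutoff:.17g}\n")
        fh.write(f"# ref_fdr={'none' if cp.ref_fdr is None else format(cp.ref_fdr, '.17g')}\n")
        df.to_csv(fh, sep="\t", index=False, float_format="%.17g")


def read_profile(path) -> CompartmentProfile:
    meta = {}
    with open(path) as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            key, _, value = line[1:].strip().partition("=")
            meta[key.strip()] = value.strip()
    df = pd.read_csv(path, sep="\t", comment="#")
    if not set(df["class"]).issubset(_PROFILE_CLASSES):
        raise ValidationError(f"unknown profile classes: {set(df['class']) - set(_PROFILE_CLASSES)}")

    def series(cls: str) -> pd.Series:
        sub = df[df["class"] == cls]
        return pd.Series(sub["weight"].to_numpy(), index=sub["gene"].astype(str))

    return CompartmentProfile(
        tf_name=meta.get("tf_name", "TF"),
        tumor_targets=series("tumor"),
        env_targets=series("env"),
        nonspecific_targets=series("nonspecific"),
        pos_ref=frozenset(df[df["class"] == "pos_ref"]["gene"].astype(str)),
        neg_ref=frozenset(df[df["class"] == "neg_ref"]["gene"].astype(str)),
        affinity_cutoff=float(meta.get("affinity_cutoff", 0.5)),
        compartment_scc_cutoff=float(meta.get("compartment_scc_cutoff", 0.1)),
        ref_scc_cutoff=float(meta.get("ref_scc_cutoff", 0.1)),
        ref_fdr=None if meta.get("ref_fdr", "0.05") == "none" else float(meta.get("ref_fdr", 0.05)),
    )
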