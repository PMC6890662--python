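"""BASE: rank-based activity scoring from weighted target-gene profiles.

For one sample, genes are ranked by expression in descending order.  Two
cumulative distributions are accumulated down the ranking: a foreground

    f(i) = sum_{k<=i} |g_k w_k| / sum_{k<=n} |g_k w_k|

weighted by the profile weights w (binding affinities in [0, 1]), and a
complementary background

    b(i) = sum_{k<=i} |g_k (1 - w_k)| / sum_{k<=n} |g_k (1 - w_k)|.

The signed deviation of largest magnitude, d(i*) with d = f - b, is the
preliminary activity score: positive when high-weight genes concentrate at the
top of the ranking, negative when they sink to the bottom.  The preliminary
score is then normalized against a permutation null that shuffles the
gene-to-expression assignment within the scoring universe (weights fixed),
either as a z-score (default) or as a sign-stratified enrichment ratio.

Scores are only meaningful on per-gene median-centered relative expression;
:func:`score_samples` enforces the ``normalized`` flag.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import DegenerateInputError, ValidationError
from .io import ExpressionMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "WeightProfile",
    "RankedSample",
    "ActivityScore",
    "read_weight_profile",
    "write_weight_profile",
    "rank_genes",
    "running_sums",
    "preliminary_score",
    "normalize_score",
    "score_samples",
    "write_scores",
]


@dataclass
class WeightProfile:
    """Gene-level weights w in [0, 1] for one TF (or immune cell type)."""

    name: str
    weights: pd.Series  # gene -> w

    def __post_init__(self) -> None:
        if not isinstance(self.weights, pd.Series):
            self.weights = pd.Series(self.weights, dtype=float)
        self.weights = self.weights.astype(float)
        self.weights.index = self.weights.index.astype(str)
        if self.weights.index.has_duplicates:
            raise ValidationError(f"profile {self.name!r}: duplicate genes")
        w = self.weights.to_numpy()
        if w.size == 0:
            raise ValidationError(f"profile {self.name!r}: empty")
        if not np.isfinite(w).all() or (w < 0).any() or (w > 1).any():
            raise ValidationError(f"profile {self.name!r}: weights must lie in [0, 1]")
        if (w == 0).all():
            raise ValidationError(f"profile {self.name!r}: all weights zero, no foreground")
        if (w == 1).all():
            # valid only when scored against a wider universe that adds w=0 genes
            logger.warning("profile %r: all weights are 1; needs a wider universe", self.name)

    @property
    def n(self) -> int:
        return int(self.weights.size)


@dataclass
class RankedSample:
    """One sample's genes ordered by expression descending (ties: gene id asc)."""

    genes: np.ndarray  # ordered gene identifiers
    g: np.ndarray  # aligned expression values, descending
    w: np.ndarray  # aligned weights

    def __post_init__(self) -> None:
        if not (len(self.genes) == len(self.g) == len(self.w)):
            raise ValidationError("ranked sample arrays must share a length")


@dataclass
class ActivityScore:
    preliminary: float
    normalized: float
    n_perm: int
    mode: str


def read_weight_profile(path, name: str | None = None) -> WeightProfile:
    """Read a weight profile TSV: (gene, weight) or (gene, p_value, weight)."""
    df = pd.read_csv(path, sep="\t")
    cols = {c.lower(): c for c in df.columns}
    gene_col = cols.get("gene", df.columns[0])
    weight_col = cols.get("weight", df.columns[-1])
    weights = pd.Series(
        pd.to_numeric(df[weight_col], errors="raise").to_numpy(),
        index=df[gene_col].astype(str),
    )
    return WeightProfile(name=name or str(path), weights=weights)


def write_weight_profile(profile: WeightProfile, path) -> None:
    out = profile.weights.rename("weight").rename_axis("gene").reset_index()
    out.to_csv(path, sep="\t", index=False, float_format="%.17g")


def rank_genes(
    expression: pd.Series,
    profile: WeightProfile,
    universe: pd.Index | None = None,
) -> RankedSample:
    """Order a sample's genes by expression descending, ties by gene id ascending.

    Genes of the universe absent from the profile score as pure background
    (w = 0).  ``universe`` defaults to all genes in ``expression``.
    """
    if not isinstance(expression, pd.Series):
        expression = pd.Series(expression, dtype=float)
    expression.index = expression.index.astype(str)
    if universe is not None:
        expression = expression.loc[expression.index.intersection(universe)]
    if expression.empty:
        raise DegenerateInputError("empty intersection of expression genes and scoring universe")
    genes = expression.index.to_numpy(dtype=object)
    values = expression.to_numpy(dtype=float)
    order = np.lexsort((genes, -values))  # primary: value desc; secondary: gene asc
    genes = genes[order]
    values = values[order]
    w = profile.weights.reindex(genes, fill_value=0.0).to_numpy(dtype=float)
    return RankedSample(genes=genes, g=values, w=w)


def running_sums(rs: RankedSample) -> tuple[np.ndarray, np.ndarray]:
    """Foreground and background cumulative distributions f(i), b(i)."""
    absg = np.abs(rs.g)
    fw = absg * rs.w
    bw = absg * (1.0 - rs.w)
    denom_f = fw.sum()
    denom_b = bw.sum()
    if denom_f == 0:
        raise DegenerateInputError("foreground sum degenerated: sum |g_k w_k| = 0")
    if denom_b == 0:
        raise DegenerateInputError("background sum degenerated: sum |g_k (1 - w_k)| = 0")
    if np.ptp(rs.w) == 0:
        # constant w: the weight cancels algebraically and f == b exactly
        shared = np.cumsum(absg) / absg.sum()
        return shared, shared.copy()
    return np.cumsum(fw) / denom_f, np.cumsum(bw) / denom_b


def preliminary_score(f: np.ndarray, b: np.ndarray) -> float:
    """Signed maximal deviation d(i*) with d = f - b, ties at the smallest i."""
    d = np.asarray(f) - np.asarray(b)
    i = int(np.argmax(np.abs(d)))  # argmax returns the first maximal index
    return float(d[i])


def _signed_max_deviations(absg: np.ndarray, W: np.ndarray) -> np.ndarray:
    """Vectorized signed max deviation for many weight alignments.

    ``absg`` is |g| in rank order (length n); ``W`` is (m, n), one weight
    alignment per row.  Uses b-cumsum = cum|g| - f-cumsum to halve the work.
    """
    FW = absg[None, :] * W
    cf = np.cumsum(FW, axis=1)
    cum_abs = np.cumsum(absg)
    cb = cum_abs[None, :] - cf
    denom_f = cf[:, -1]
    denom_b = cb[:, -1]
    if (denom_f == 0).any():
        raise DegenerateInputError("foreground sum degenerated: sum |g_k w_k| = 0")
    if (denom_b == 0).any():
        raise DegenerateInputError("background sum degenerated: sum |g_k (1 - w_k)| = 0")
    if np.ptp(W) == 0:
        # constant weights cancel algebraically; every deviation is exactly 0
        return np.zeros(W.shape[0])
    D = cf / denom_f[:, None] - cb / denom_b[:, None]
    idx = np.argmax(np.abs(D), axis=1)
    return D[np.arange(D.shape[0]), idx]


def _null_scores(rs: RankedSample, n_perm: int, rng: np.random.Generator) -> np.ndarray:
    # Permuting the gene-to-expression assignment within the universe (weights
    # fixed to genes) and re-ranking is equivalent to permuting the alignment
    # of w against the sorted |g|; the latter vectorizes.
    W = np.tile(rs.w, (n_perm, 1))
    W = rng.permuted(W, axis=1)
    return _signed_max_deviations(np.abs(rs.g), W)


def normalize_score(
    rs: RankedSample,
    n_perm: int = 1000,
    seed: int | np.random.Generator = 0,
    mode: str = "zscore",
) -> ActivityScore:
    """Permutation-normalize the preliminary score of one ranked sample.

    ``zscore`` returns (obs - mean_null) / sd_null.  ``nes`` divides a positive
    observation by the mean of positive null scores and a negative one by the
    mean magnitude of negative null scores (GSEA-style normalized enrichment).
    Deterministic given ``seed``.
    """
    if n_perm < 100:
        raise ValidationError(f"n_perm must be >= 100, got {n_perm}")
    if mode not in ("zscore", "nes"):
        raise ValidationError(f"unknown normalization mode {mode!r}")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    obs = _signed_max_deviations(np.abs(rs.g), rs.w[None, :])[0]
    null = _null_scores(rs, n_perm, rng)
    if mode == "zscore":
        sd = null.std(ddof=1)
        if sd == 0:
            raise DegenerateInputError("permutation null has zero variance")
        normalized = (obs - null.mean()) / sd
    else:
        if obs == 0:
            normalized = 0.0
        elif obs > 0:
            pos = null[null > 0]
            if pos.size == 0:
                raise DegenerateInputError("no positive null scores for NES normalization")
            normalized = obs / pos.mean()
        else:
            neg = null[null < 0]
            if neg.size == 0:
                raise DegenerateInputError("no negative null scores for NES normalization")
            normalized = obs / np.abs(neg).mean()
    return ActivityScore(
        preliminary=float(obs), normalized=float(normalized), n_perm=n_perm, mode=mode
    )


def sample_seed(seed: int, index: int) -> np.random.Generator:
    """Deterministic per-sample generator derived from (seed, sample index)."""
    return np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=(index,)))


def score_samples(
    em: ExpressionMatrix,
    profile: WeightProfile,
    universe: pd.Index | None = None,
    n_perm: int = 1000,
    seed: int = 0,
    mode: str = "zscore",
) -> pd.DataFrame:
    """Score every sample of a median-centered expression matrix.

    Returns a DataFrame indexed by sample with ``preliminary`` and
    ``normalized`` columns (input order preserved).  Per-sample permutation
    streams are derived deterministically from ``(seed, sample index)`` so the
    result is independent of evaluation order.
    """
    if not em.normalized:
        raise ValidationError("expression must be per-gene median-centered before scoring")
    values = em.values
    if universe is not None:
        universe = pd.Index(universe).astype(str)
        keep = values.index.intersection(universe)
        if keep.empty:
            raise DegenerateInputError("scoring universe shares no genes with the matrix")
        values = values.loc[keep]
    rows = []
    for i, sample in enumerate(values.columns):
        col = values[sample]
        if np.ptp(col.to_numpy()) == 0:
            logger.warning("sample %r has constant expression; score is tie-break driven", sample)
        rs = rank_genes(col, profile)
        score = normalize_score(rs, n_perm=n_perm, seed=sample_seed(seed, i), mode=mode)
        rows.append((sample, score.preliminary, score.normalized))
    out = pd.DataFrame(rows, columns=["sample", "preliminary", "normalized"]).set_index("sample")
    out.attrs.update({"n_perm": n_perm, "mode": mode, "seed": seed, "profile": profile.name})
    return out


def write_scores(scores: pd.DataFrame, path) -> None:
    out = scores.copy()
    out["n_perm"] = scores.attrs.get("n_perm", "")
    out["mode"] = scores.attrs.get("mode", "")
    out["seed"] = scores.attrs.get("seed", "")
    out.to_csv(path, sep="\t", float_format="%.12g")
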