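"""Readers, writers and preprocessing for the tabular formats the pipeline touches.

Expression comes in as TSV (first column = gene symbol, header row = sample
IDs) or GCT v1.2; microarray data may arrive at the probe level with a
probe-to-gene map and is collapsed to gene level before scoring.  Copy-number
segments use the SEG convention (1-based inclusive coordinates), mutations a
minimal MAF, clinical annotations a plain TSV.  All readers transparently
accept gzip-compressed files.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd

from .errors import DegenerateInputError, ParseError, ValidationError

logger = logging.getLogger(__name__)

__all__ = [
    "ExpressionMatrix",
    "ProbeMatrix",
    "CNVSegments",
    "MutationTable",
    "ClinicalTable",
    "read_expression",
    "write_expression",
    "collapse_probesets",
    "median_normalize",
    "read_binding_table",
    "write_binding_table",
    "read_segments",
    "write_segments",
    "read_mutations",
    "write_mutations",
    "read_clinical",
]

#: Sum of UCSC hg19 chromosome lengths (chr1-22, X, Y), in bp.
HG19_GENOME_SIZE = 3_095_677_412

#: Sum of GRCh38 primary chromosome lengths (chr1-22, X, Y), in bp.
HG38_GENOME_SIZE = 3_088_269_832

GENOME_SIZES = {"hg19": HG19_GENOME_SIZE, "hg38": HG38_GENOME_SIZE}


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------


@dataclass
class ExpressionMatrix:
    """Gene x sample relative (log-scale) expression.

    ``values`` is a genes-by-samples DataFrame with unique gene symbols on the
    index.  ``normalized`` records whether per-gene median centering has been
    applied; the scoring engine requires it.
    """

    values: pd.DataFrame
    normalized: bool = False

    def __post_init__(self) -> None:
        if self.values.index.has_duplicates:
            dups = self.values.index[self.values.index.duplicated()].unique().tolist()
            raise ValidationError(f"duplicate gene identifiers: {dups[:10]}")
        if self.values.columns.has_duplicates:
            dups = self.values.columns[self.values.columns.duplicated()].unique().tolist()
            raise ValidationError(f"duplicate sample identifiers: {dups[:10]}")
        arr = self.values.to_numpy()
        if arr.size and not np.isfinite(arr).all():
            bad = np.argwhere(~np.isfinite(arr))[0]
            raise ValidationError(
                "non-finite expression value at gene "
                f"{self.values.index[bad[0]]!r}, sample {self.values.columns[bad[1]]!r}"
            )
        if self.normalized and self.values.shape[1] >= 2:
            med = np.nanmedian(arr, axis=1)
            if arr.size and np.abs(med).max() > 1e-9:
                raise ValidationError("normalized flag set but per-gene medians are not 0")

    @property
    def gene_ids(self) -> pd.Index:
        return self.values.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.values.columns

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape


@dataclass
class ProbeMatrix:
    """Probe-level intensities plus a many-to-one probe-to-gene map."""

    values: pd.DataFrame  # probes x samples
    probe_to_gene: Mapping[str, str]
    channel_mode: str  # "one_channel" | "two_channel"

    def __post_init__(self) -> None:
        if self.channel_mode not in ("one_channel", "two_channel"):
            raise ValidationError(f"unknown channel_mode {self.channel_mode!r}")
        if self.values.index.has_duplicates:
            raise ValidationError("duplicate probe identifiers")
        for probe, gene in self.probe_to_gene.items():
            if not gene:
                raise ValidationError(f"probe {probe!r} maps to an empty gene symbol")
        if not np.isfinite(self.values.to_numpy()).all():
            raise ValidationError("non-finite probe intensity")


@dataclass
class CNVSegments:
    """Per-sample copy-number segments with 1-based inclusive coordinates."""

    segments: pd.DataFrame  # sample, chromosome, start, end, copy_number
    genome_size: float = HG19_GENOME_SIZE

    REQUIRED = ("sample", "chromosome", "start", "end", "copy_number")

    def __post_init__(self) -> None:
        missing = [c for c in self.REQUIRED if c not in self.segments.columns]
        if missing:
            raise ValidationError(f"segment table missing columns: {missing}")
        if self.genome_size <= 0:
            raise ValidationError("genome_size must be positive")
        seg = self.segments
        bad = seg.index[seg["end"] < seg["start"]].tolist()
        if bad:
            raise ValidationError(f"segments with end < start at rows {bad[:10]}")
        bad = seg.index[seg["copy_number"] < 0].tolist()
        if bad:
            raise ValidationError(f"negative copy number at rows {bad[:10]}")

    @property
    def samples(self) -> list[str]:
        return list(pd.unique(self.segments["sample"]))

    def for_sample(self, sample: str) -> pd.DataFrame:
        sub = self.segments[self.segments["sample"] == sample]
        if sub.empty:
            raise ValidationError(f"sample {sample!r} has no segments")
        return sub

    def sizes(self) -> pd.Series:
        """Segment sizes s_i = end - start + 1."""
        return self.segments["end"] - self.segments["start"] + 1


#: MAF controlled vocabulary of variant classifications.
MAF_CLASSES = frozenset(
    {
        "Missense_Mutation",
        "Nonsense_Mutation",
        "Nonstop_Mutation",
        "Frame_Shift_Del",
        "Frame_Shift_Ins",
        "In_Frame_Del",
        "In_Frame_Ins",
        "Splice_Site",
        "Translation_Start_Site",
        "Silent",
        "Intron",
        "3'UTR",
        "5'UTR",
        "3'Flank",
        "5'Flank",
        "IGR",
        "RNA",
        "Targeted_Region",
        "De_novo_Start_InFrame",
        "De_novo_Start_OutOfFrame",
    }
)


@dataclass
class MutationTable:
    """Per-sample somatic mutation calls (minimal MAF columns)."""

    mutations: pd.DataFrame  # sample, gene, variant_classification

    REQUIRED = ("sample", "gene", "variant_classification")

    def __post_init__(self) -> None:
        missing = [c for c in self.REQUIRED if c not in self.mutations.columns]
        if missing:
            raise ValidationError(f"mutation table missing columns: {missing}")
        if (self.mutations["sample"].astype(str) == "").any():
            raise ValidationError("empty sample identifier in mutation table")
        unknown = set(self.mutations["variant_classification"]) - MAF_CLASSES
        if unknown:
            logger.warning("unknown variant classifications (kept): %s", sorted(unknown))


@dataclass
class ClinicalTable:
    """Follow-up time (days), 0/1 death indicator and optional covariates."""

    clinical: pd.DataFrame  # index: sample; columns: time, event, [stage, age, gender]

    def __post_init__(self) -> None:
        for col in ("time", "event"):
            if col not in self.clinical.columns:
                raise ValidationError(f"clinical table missing column {col!r}")
        if (self.clinical["time"] < 0).any():
            raise ValidationError("negative follow-up time")
        if not self.clinical["event"].isin([0, 1]).all():
            raise ValidationError("event indicator must be 0 or 1")


# ---------------------------------------------------------------------------
# expression
# ---------------------------------------------------------------------------


def _coerce_numeric(df: pd.DataFrame, what: str) -> pd.DataFrame:
    out = df.apply(pd.to_numeric, errors="coerce")
    if out.isna().any().any() and not df.isna().any().any():
        mask = out.isna() & ~df.isna()
        r, c = np.argwhere(mask.to_numpy())[0]
        raise ParseError(
            f"non-numeric {what} value {df.iat[r, c]!r} at row {df.index[r]!r}, "
            f"column {df.columns[c]!r}"
        )
    if out.isna().any().any():
        mask = out.isna()
        r, c = np.argwhere(mask.to_numpy())[0]
        raise ParseError(f"missing {what} value at row {df.index[r]!r}, column {df.columns[c]!r}")
    return out.astype(float)


def read_expression(path, format: str = "tsv", log_transform: bool = False) -> ExpressionMatrix:
    """Read a gene x sample expression matrix.

    ``format`` is ``"tsv"`` (header row of sample IDs, first column gene ID) or
    ``"gct"`` (v1.2, with its two-line preamble and Description column).  With
    ``log_transform`` raw values are replaced by log10(x + 1), the transform
    applied to RNA-seq quantifications before scoring.
    """
    if format == "tsv":
        df = pd.read_csv(path, sep="\t", index_col=0)
    elif format == "gct":
        with pd.io.common.get_handle(path, "r", compression="infer") as handle:
            lines = handle.handle.read().splitlines()
        if not lines or not lines[0].startswith("#1.2"):
            raise ParseError(f"{path}: not a GCT v1.2 file (missing '#1.2' header)")
        try:
            n_rows, n_cols = (int(x) for x in lines[1].split("\t")[:2])
        except Exception as exc:  # noqa: BLE001
            raise ParseError(f"{path}: malformed GCT dimension line {lines[1]!r}") from exc
        from io import StringIO

        df = pd.read_csv(StringIO("\n".join(lines[2:])), sep="\t", index_col=0)
        df = df.drop(columns=["Description"], errors="ignore")
        if df.shape != (n_rows, n_cols):
            raise ParseError(
                f"{path}: GCT header declares {n_rows}x{n_cols} but data is "
                f"{df.shape[0]}x{df.shape[1]}"
            )
    else:
        raise ValidationError(f"unknown expression format {format!r}")

    if df.index.has_duplicates:
        dups = df.index[df.index.duplicated()].unique().tolist()
        raise ParseError(f"duplicate gene rows: {dups}")
    df = _coerce_numeric(df, "expression")
    if log_transform:
        if (df.to_numpy() < 0).any():
            raise ValidationError("log transform requested on matrix with negative values")
        df = np.log10(df + 1.0)
    df.index = df.index.astype(str)
    df.index.name = "gene"
    return ExpressionMatrix(values=df, normalized=False)


def write_expression(em: ExpressionMatrix, path, format: str = "tsv") -> None:
    if format == "tsv":
        em.values.to_csv(path, sep="\t", float_format="%.17g")
    elif format == "gct":
        df = em.values.copy()
        df.insert(0, "Description", "na")
        with open(path, "w") as fh:
            fh.write("#1.2\n")
            fh.write(f"{df.shape[0]}\t{df.shape[1] - 1}\n")
            df.to_csv(fh, sep="\t", float_format="%.17g", index_label="Name")
    else:
        raise ValidationError(f"unknown expression format {format!r}")


def collapse_probesets(pm: ProbeMatrix) -> ExpressionMatrix:
    """Collapse a probe-level matrix to one row per gene.

    One-channel arrays keep, for each gene, the probeset with the highest mean
    hybridization intensity across all samples (computed on the raw scale,
    before any log transform); two-channel arrays average all of a gene's
    probesets per sample.  Unmapped probes are dropped with a logged count.
    """
    mapped = [p for p in pm.values.index if p in pm.probe_to_gene]
    n_dropped = pm.values.shape[0] - len(mapped)
    if n_dropped:
        logger.info("collapse_probesets: dropped %d unmapped probes", n_dropped)
    if not mapped:
        raise DegenerateInputError("no probes map to genes; nothing to collapse")

    values = pm.values.loc[mapped]
    genes = pd.Series([pm.probe_to_gene[p] for p in mapped], index=values.index, name="gene")

    if pm.channel_mode == "one_channel":
        # deterministic winner per gene: max mean intensity, ties by probe id
        winners = (
            pd.DataFrame(
                {
                    "gene": genes.to_numpy(),
                    "mean": values.mean(axis=1).to_numpy(),
                    "probe_id": values.index.to_numpy(),
                }
            )
            .sort_values(["mean", "probe_id"], ascending=[False, True], kind="stable")
            .drop_duplicates("gene")
        )
        out = values.loc[winners["probe_id"]]
        out.index = winners["gene"].to_numpy()
    else:
        out = values.groupby(genes).mean()
    out = out.sort_index()
    out.index.name = "gene"
    return ExpressionMatrix(values=out, normalized=False)


def median_normalize(em: ExpressionMatrix) -> ExpressionMatrix:
    """Subtract each gene's across-sample median (relative expression)."""
    if em.values.shape[1] < 2:
        raise DegenerateInputError("median normalization needs at least 2 samples")
    centered = em.values.sub(em.values.median(axis=1), axis=0)
    return ExpressionMatrix(values=centered, normalized=True)


# ---------------------------------------------------------------------------
# binding tables
# ---------------------------------------------------------------------------


def read_binding_table(path) -> pd.DataFrame:
    """Read a TF binding table of (gene, p_value) rows.

    p-values must lie in (0, 1]; duplicate genes keep the smallest p (logged).
    Returns a DataFrame with columns ``gene`` and ``p_value``.
    """
    df = pd.read_csv(path, sep="\t")
    if df.shape[1] < 2:
        raise ParseError(f"{path}: binding table needs at least 2 columns (gene, p_value)")
    cols = {c.lower(): c for c in df.columns}
    gene_col = cols.get("gene", df.columns[0])
    p_col = cols.get("p_value", cols.get("p", df.columns[1]))
    out = df[[gene_col, p_col]].rename(columns={gene_col: "gene", p_col: "p_value"})
    out["gene"] = out["gene"].astype(str)
    out["p_value"] = pd.to_numeric(out["p_value"], errors="raise")
    bad = out[(out["p_value"] <= 0) | (out["p_value"] > 1)]
    if not bad.empty:
        raise ValidationError(
            f"binding p-values outside (0, 1] for genes {bad['gene'].tolist()[:10]}"
        )
    n_dup = out["gene"].duplicated().sum()
    if n_dup:
        logger.info("read_binding_table: %d duplicate genes collapsed to min p", n_dup)
        out = out.groupby("gene", as_index=False)["p_value"].min()
    return out.sort_values("gene", kind="stable").reset_index(drop=True)


def write_binding_table(bt: pd.DataFrame, path) -> None:
    bt.to_csv(path, sep="\t", index=False, float_format="%.17g")


# ---------------------------------------------------------------------------
# SEG / MAF / clinical
# ---------------------------------------------------------------------------


def read_segments(
    path,
    values: str = "absolute",
    genome_size: float | str = "hg19",
) -> CNVSegments:
    """Read a SEG file into :class:`CNVSegments`.

    ``values`` declares whether the value column carries absolute copy number
    (``"absolute"``) or a log2 ratio (``"log2"``), the latter converted as
    C = 2 * 2**r.  Coordinates are 1-based inclusive.  ``genome_size`` is an
    assembly name (``hg19``/``hg38``) or a size in bp.
    """
    if values not in ("absolute", "log2"):
        raise ValidationError(f"values must be 'absolute' or 'log2', got {values!r}")
    if isinstance(genome_size, str):
        try:
            genome_size = GENOME_SIZES[genome_size]
        except KeyError:
            raise ValidationError(f"unknown assembly {genome_size!r}") from None
    df = pd.read_csv(path, sep="\t", comment="#")
    if df.shape[1] < 5:
        raise ParseError(f"{path}: SEG file needs >= 5 columns, got {df.shape[1]}")
    seg = pd.DataFrame(
        {
            "sample": df.iloc[:, 0].astype(str),
            "chromosome": df.iloc[:, 1].astype(str),
            "start": pd.to_numeric(df.iloc[:, 2], errors="raise").astype(int),
            "end": pd.to_numeric(df.iloc[:, 3], errors="raise").astype(int),
            "value": pd.to_numeric(df.iloc[:, -1], errors="raise").astype(float),
        }
    )
    errors = []
    bad = seg[seg["end"] < seg["start"]]
    errors += [f"row {i}: end < start" for i in bad.index[:10]]
    if values == "absolute":
        seg["copy_number"] = seg["value"]
        bad = seg[seg["copy_number"] < 0]
        errors += [f"row {i}: negative copy number" for i in bad.index[:10]]
    else:
        seg["copy_number"] = 2.0 * np.power(2.0, seg["value"])
    if errors:
        raise ValidationError(f"{path}: invalid segments:\n" + "\n".join(errors))
    return CNVSegments(
        segments=seg[["sample", "chromosome", "start", "end", "copy_number"]],
        genome_size=float(genome_size),
    )


def write_segments(segs: CNVSegments, path) -> None:
    df = segs.segments.rename(
        columns={
            "sample": "Sample",
            "chromosome": "Chromosome",
            "start": "Start",
            "end": "End",
            "copy_number": "Copy_Number",
        }
    )
    df.to_csv(path, sep="\t", index=False, float_format="%.17g")


def read_mutations(path) -> MutationTable:
    """Read a minimal MAF (Tumor_Sample_Barcode, Hugo_Symbol, Variant_Classification)."""
    df = pd.read_csv(path, sep="\t", comment="#")
    required = {
        "Tumor_Sample_Barcode": "sample",
        "Hugo_Symbol": "gene",
        "Variant_Classification": "variant_classification",
    }
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ParseError(f"{path}: MAF missing columns {missing}")
    out = df[list(required)].rename(columns=required)
    for col in out.columns:
        out[col] = out[col].astype(str)
    return MutationTable(mutations=out.reset_index(drop=True))


def write_mutations(mt: MutationTable, path) -> None:
    df = mt.mutations.rename(
        columns={
            "sample": "Tumor_Sample_Barcode",
            "gene": "Hugo_Symbol",
            "variant_classification": "Variant_Classification",
        }
    )
    df.to_csv(path, sep="\t", index=False)


def read_clinical(path) -> ClinicalTable:
    """Read a clinical TSV with sample IDs in the first column and time/event columns."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index = df.index.astype(str)
    cols = {c.lower(): c for c in df.columns}
    for needed in ("time", "event"):
        if needed not in cols:
            raise ParseError(f"{path}: clinical table missing column {needed!r}")
    df = df.rename(columns={cols["time"]: "time", cols["event"]: "event"})
    df["time"] = pd.to_numeric(df["time"], errors="raise")
    df["event"] = pd.to_numeric(df["event"], errors="raise").astype(int)
    return ClinicalTable(clinical=df)
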