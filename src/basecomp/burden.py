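"""Per-sample genomic burden statistics: CNV burden and total mutation burden.

CNV burden measures the genome-wide deviation of copy number from diploid:

    burden = sum_i | log2(C_i / 2) * s_i | / N

over a sample's segments (copy number C_i, size s_i = end - start + 1 bp),
scaled by the genome size N.  A diploid genome scores 0; a whole-genome
single-copy gain (C = 4) scores 1.  Total mutation burden (TMB) is the count
of non-silent mutations.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .errors import ValidationError
from .io import CNVSegments, GENOME_SIZES, MAF_CLASSES, MutationTable

logger = logging.getLogger(__name__)

__all__ = ["cnv_burden", "cnv_burden_all", "tmb", "tmb_all", "NONSILENT_CLASSES"]

#: Default non-silent variant classes counted by TMB.
NONSILENT_CLASSES = frozenset(
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
    }
)


def cnv_burden(segs: CNVSegments, sample: str, clamp_floor: float = 0.25) -> float:
    """CNV burden for one sample.

    Zero copy numbers (homozygous deletions) make log2 undefined and are
    clamped to ``clamp_floor`` (default 0.25, i.e. log2 ratio -3) with a log
    message.  Overlapping segments are summed as given, with a warning.
    """
    sub = segs.for_sample(sample)
    c = sub["copy_number"].to_numpy(dtype=float)
    s = (sub["end"] - sub["start"] + 1).to_numpy(dtype=float)
    n_clamped = int((c < clamp_floor).sum())
    if n_clamped:
        logger.info("cnv_burden(%s): clamped %d copy numbers below %g", sample, n_clamped,
                    clamp_floor)
    c = np.maximum(c, clamp_floor)
    _warn_overlaps(sub, sample)
    return float(np.abs(np.log2(c / 2.0) * s).sum() / segs.genome_size)


def _warn_overlaps(sub: pd.DataFrame, sample: str) -> None:
    for _, chrom_df in sub.groupby("chromosome"):
        srt = chrom_df.sort_values("start")
        if (srt["start"].to_numpy()[1:] <= srt["end"].to_numpy()[:-1]).any():
            logger.warning("cnv_burden(%s): overlapping segments summed as given", sample)
            return


def cnv_burden_all(segs: CNVSegments, clamp_floor: float = 0.25) -> pd.Series:
    """CNV burden for every sample in the segment table."""
    out = pd.Series(
        {s: cnv_burden(segs, s, clamp_floor=clamp_floor) for s in segs.samples},
        name="cnv_burden",
    )
    out.index.name = "sample"
    return out


def tmb(mt: MutationTable, sample: str, nonsilent_classes=NONSILENT_CLASSES) -> int:
    """Number of non-silent mutations for one sample."""
    sub = mt.mutations[mt.mutations["sample"] == sample]
    if sub.empty and sample not in set(mt.mutations["sample"]):
        raise ValidationError(f"sample {sample!r} absent from mutation table")
    unknown = set(sub["variant_classification"]) - MAF_CLASSES
    if unknown - set(nonsilent_classes):
        logger.warning("tmb(%s): classes outside the MAF vocabulary: %s", sample,
                       sorted(unknown - set(nonsilent_classes))[:5])
    return int(sub["variant_classification"].isin(nonsilent_classes).sum())


def tmb_all(mt: MutationTable, nonsilent_classes=NONSILENT_CLASSES) -> pd.Series:
    """TMB for every sample present in the mutation table."""
    counts = (
        mt.mutations[mt.mutations["variant_classification"].isin(nonsilent_classes)]
        .groupby("sample")
        .size()
    )
    all_samples = pd.Index(pd.unique(mt.mutations["sample"]))
    out = counts.reindex(all_samples, fill_value=0).astype(int).rename("tmb")
    out.index.name = "sample"
    return out


def genome_size(assembly: str = "hg19") -> int:
    """Total genome size in bp for a named assembly."""
    try:
        return GENOME_SIZES[assembly]
    except KeyError:
        raise ValidationError(f"unknown assembly {assembly!r}") from None
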