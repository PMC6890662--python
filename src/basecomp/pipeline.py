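"""End-to-end orchestration: profile -> scores -> stratification -> statistics.

One YAML config drives the whole run.  Every randomized stage derives its
stream from the top-level seed plus a stage tag, outputs are written with a
fixed float format, and a manifest records input hashes, the config and the
package version — re-running an identical config reproduces identical files.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .burden import cnv_burden_all, tmb_all
from .compartment import (
    build_profile,
    infer_compartment_activities,
    read_profile,
    read_purity,
    write_profile,
)
from .downstream import four_groups, km_logrank
from .errors import BasecompError, ValidationError
from .io import (
    median_normalize,
    read_binding_table,
    read_clinical,
    read_expression,
    read_mutations,
    read_segments,
)

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "run_pipeline", "PipelineError"]

FLOAT_FORMAT = "%.12g"


class PipelineError(BasecompError, RuntimeError):
    """A pipeline stage failed; the message names the stage."""


@dataclass
class PipelineConfig:
    expression: str
    out_dir: str
    purity: str | None = None
    binding: str | None = None
    profile: str | None = None  # pre-built profile TSV; alternative to binding+purity
    clinical: str | None = None
    seg: str | None = None
    maf: str | None = None
    expression_format: str = "tsv"
    log_transform: bool = False
    median_center: bool = True
    tf_name: str = "TF"
    affinity_cutoff: float = 0.5
    scc_cutoff: float = 0.1
    ref_scc_cutoff: float = 0.1
    ref_fdr: float | None = 0.05
    score_cutoff: float = 0.0
    n_perm: int = 1000
    seed: int = 17
    mode: str = "zscore"
    seg_values: str = "absolute"
    assembly: str = "hg19"

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValidationError(f"unknown config fields: {sorted(unknown)}")
        return cls(**raw)

    def validate(self) -> None:
        required = {"expression": self.expression}
        if self.profile is None:
            required["binding"] = self.binding
            required["purity"] = self.purity
            for name, value in (("binding", self.binding), ("purity", self.purity)):
                if value is None:
                    raise ValidationError(
                        f"T/E scoring requested without a profile: missing input {name!r}"
                    )
        else:
            required["profile"] = self.profile
        for name in ("clinical", "seg", "maf"):
            value = getattr(self, name)
            if value is not None:
                required[name] = value
        for name, value in required.items():
            if value is None or not Path(value).exists():
                raise ValidationError(f"missing input file for {name!r}: {value}")
        if not 0 <= self.scc_cutoff <= 1 or not 0 <= self.ref_scc_cutoff <= 1:
            raise ValidationError("SCC cutoffs must lie in [0, 1]")
        if not 0 <= self.affinity_cutoff <= 1:
            raise ValidationError("affinity cutoff must lie in [0, 1]")


def _stage_seed(seed: int, tag: str) -> int:
    digest = hashlib.sha256(f"{seed}:{tag}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)


def _sha256(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Run the full pipeline and return a dict of output paths.

    Stages: load/preprocess expression -> build or load the compartment
    profile -> per-sample (G, T, E) scoring -> four-group stratification ->
    log-rank survival comparison (if clinical data) -> CNV/TMB burden tables
    (if segments/MAF given).  A failing stage aborts the run with the stage
    named; outputs written before the failure are kept under a ``.quarantine``
    suffix.
    """
    cfg.validate()
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    outputs: dict[str, str] = {}
    stage = "setup"

    def emit(name: str, path: Path) -> None:
        outputs[name] = str(path)

    try:
        stage = "expression"
        em = read_expression(cfg.expression, format=cfg.expression_format,
                             log_transform=cfg.log_transform)
        em_scored = median_normalize(em) if cfg.median_center else em

        stage = "profile"
        if cfg.profile is not None:
            profile = read_profile(cfg.profile)
        else:
            purity = read_purity(cfg.purity)
            binding = read_binding_table(cfg.binding)
            profile = build_profile(
                binding,
                em_scored,
                purity,
                tf_name=cfg.tf_name,
                affinity_cutoff=cfg.affinity_cutoff,
                compartment_scc_cutoff=cfg.scc_cutoff,
                ref_scc_cutoff=cfg.ref_scc_cutoff,
                ref_fdr=cfg.ref_fdr,
            )
        profile_path = out / "profile.tsv"
        write_profile(profile, profile_path)
        emit("profile", profile_path)

        stage = "scoring"
        scores = infer_compartment_activities(
            em_scored,
            profile,
            n_perm=cfg.n_perm,
            seed=_stage_seed(cfg.seed, "scoring"),
            mode=cfg.mode,
        )
        scores_path = out / "scores.tsv"
        scores.to_csv(scores_path, sep="\t", float_format=FLOAT_FORMAT)
        emit("scores", scores_path)

        stage = "stratification"
        groups = four_groups(scores["T"], scores["E"], cutoff=cfg.score_cutoff)
        groups_path = out / "groups.tsv"
        groups.rename("group").to_csv(groups_path, sep="\t")
        emit("groups", groups_path)

        if cfg.clinical is not None:
            stage = "survival"
            clinical = read_clinical(cfg.clinical)
            res = km_logrank(groups, clinical)
            summary = res.group_sizes.rename("n").to_frame()
            summary["chi2"] = res.chi2
            summary["p_value"] = res.p_value
            summary["dof"] = res.dof
            surv_path = out / "survival.tsv"
            summary.to_csv(surv_path, sep="\t", float_format=FLOAT_FORMAT)
            emit("survival", surv_path)
            km = pd.concat(
                [df.assign(group=lab) for lab, df in res.curves.items()], ignore_index=True
            )
            km_path = out / "km_curves.tsv"
            km.to_csv(km_path, sep="\t", index=False, float_format=FLOAT_FORMAT)
            emit("km_curves", km_path)

        if cfg.seg is not None:
            stage = "cnv_burden"
            segs = read_segments(cfg.seg, values=cfg.seg_values, genome_size=cfg.assembly)
            cnv = cnv_burden_all(segs)
            cnv_path = out / "cnv_burden.tsv"
            cnv.to_csv(cnv_path, sep="\t", float_format=FLOAT_FORMAT)
            emit("cnv_burden", cnv_path)

        if cfg.maf is not None:
            stage = "tmb"
            mt = read_mutations(cfg.maf)
            tmb_path = out / "tmb.tsv"
            tmb_all(mt).to_csv(tmb_path, sep="\t")
            emit("tmb", tmb_path)

        stage = "manifest"
        inputs = {
            name: {"path": str(p), "sha256": _sha256(p)}
            for name, p in (
                ("expression", cfg.expression),
                ("purity", cfg.purity),
                ("binding", cfg.binding),
                ("profile", cfg.profile),
                ("clinical", cfg.clinical),
                ("seg", cfg.seg),
                ("maf", cfg.maf),
            )
            if p is not None
        }
        manifest = {
            "version": __version__,
            "config": dataclasses.asdict(cfg),
            "inputs": inputs,
            "outputs": {k: Path(v).name for k, v in outputs.items()},
            "stage_seeds": {"scoring": _stage_seed(cfg.seed, "scoring")},
        }
        manifest_path = out / "manifest.json"
        manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
        emit("manifest", manifest_path)
    except Exception as exc:
        for path in outputs.values():
            p = Path(path)
            if p.exists():
                p.rename(p.with_suffix(p.suffix + ".quarantine"))
        raise PipelineError(f"stage {stage!r} failed: {exc}") from exc
    return outputs
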