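"""End-to-end analysis pipeline over a csd allele survey.

Stages, in order: read and translate the sequence fragments, collapse them
into distinct alleles, compute all pairwise differences and the
functional-heterozygosity summaries, estimate minimal allelic richness per
group and overall, compare observed occurrence spectra and the two-group
overlap against resampled uniform-pool null models (including the
within-apiary deduplicated dataset), and classify worldwide novelty against
a reference set when one is supplied.

All tables are written as TSV, the run summary as deterministic JSON.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import nullmodels, novelty, pairdiff, richness, sequences

__all__ = ["PipelineConfig", "PipelineError", "run_pipeline"]

logger = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    """A stage failure, tagged with the stage name."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


@dataclass(frozen=True)
class PipelineConfig:
    """Paths and parameters for one pipeline run.

    The analysed fragments vary in length (the HVR length varies), so the
    region is specified by a frame offset plus the conserved flank lengths:
    each read is translated in full and its HVR span is
    ``[flank_left_len, length - flank_right_len)``.
    """

    input_fasta: str
    sample_sheet: str
    output_dir: str
    reference_fasta: str | None = None
    frame_offset: int = 0
    flank_left_len: int = 8
    flank_right_len: int = 8
    align: pairdiff.AlignParams = field(default_factory=pairdiff.AlignParams)
    min_hvr_threshold: int = 5
    alpha: float = 0.05
    convention: str = "lower_tail"
    steps: str = "draws"
    reps: int = 100
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "align" in raw:
            raw["align"] = pairdiff.AlignParams(**raw["align"])
        return cls(**raw)


def _translate_all(cfg: PipelineConfig, reads, sheet: pd.DataFrame):
    meta = sheet.set_index("id")
    alleles = []
    for rec in reads:
        usable = len(rec.seq) - cfg.frame_offset
        n_aa = usable // 3
        if n_aa <= cfg.flank_left_len + cfg.flank_right_len:
            raise PipelineError(
                "sequences", f"read {rec.id!r} too short for the configured flanks"
            )
        spec = sequences.RegionSpec(
            frame_offset=cfg.frame_offset,
            region_start=0,
            region_end=n_aa,
            hvr_start=cfg.flank_left_len,
            hvr_end=n_aa - cfg.flank_right_len,
        )
        row = meta.loc[rec.id] if rec.id in meta.index else None
        alleles.append(
            sequences.translate_region(
                rec,
                spec,
                apiary_id=None if row is None else row["apiary_id"],
                colony_id=None if row is None else row["colony_id"],
            )
        )
    return alleles


def _estimate_block(D: int, U: int, cfg: PipelineConfig) -> dict:
    try:
        est = richness.estimate_richness(
            D, U, alpha=cfg.alpha, convention=cfg.convention, steps=cfg.steps
        )
        return est.as_dict()
    except ValueError as err:
        return {"error": str(err), "draws": D, "distinct": U}


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Run every stage and write the report bundle; returns the summary."""
    out = Path(cfg.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    summary: dict = {"seed": cfg.seed, "config": _config_dict(cfg)}
    rng = np.random.default_rng(cfg.seed)

    # --- sequences ---------------------------------------------------------
    try:
        reads = sequences.read_fasta(cfg.input_fasta)
        sheet = sequences.read_sample_sheet(cfg.sample_sheet)
        alleles_all = _translate_all(cfg, reads, sheet)
        unique, counts, membership = sequences.collapse_identical(alleles_all)
    except (OSError, ValueError) as err:
        raise PipelineError("sequences", str(err)) from err
    obs = sheet.copy()
    obs["allele_id"] = obs["id"].map(membership)
    if obs["allele_id"].isna().any():
        missing = obs.loc[obs["allele_id"].isna(), "id"].tolist()[:5]
        raise PipelineError("sequences", f"sheet ids absent from FASTA: {missing}")
    pd.DataFrame(
        {
            "allele_id": [u.id for u in unique],
            "aa_seq": [u.aa_seq for u in unique],
            "n_observations": [counts[u.id] for u in unique],
        }
    ).to_csv(out / "alleles.tsv", sep="\t", index=False)
    summary["sequences"] = {
        "n_reads": len(reads),
        "n_observations": len(obs),
        "n_distinct_alleles": len(unique),
    }

    # --- pairdiff ----------------------------------------------------------
    try:
        pairs, pair_summary = pairdiff.all_pairs(
            unique, cfg.align, cfg.min_hvr_threshold
        )
    except (ValueError, RuntimeError) as err:
        raise PipelineError("pairdiff", str(err)) from err
    pairs.to_csv(out / "pairs.tsv", sep="\t", index=False)
    summary["pairdiff"] = pair_summary

    # --- richness ----------------------------------------------------------
    D_all, U_all = len(obs), len(unique)
    rich: dict = {"overall": _estimate_block(D_all, U_all, cfg)}
    groups = sorted(obs["group_id"].unique()) if "group_id" in obs.columns else []
    for g in groups:
        sub = obs[obs["group_id"] == g]
        rich[f"group_{g}"] = _estimate_block(len(sub), sub["allele_id"].nunique(), cfg)
    dedup = nullmodels.apiary_dedup(obs)
    rich["dedup"] = _estimate_block(len(dedup), dedup["allele_id"].nunique(), cfg)
    summary["richness"] = rich

    # --- nullmodels --------------------------------------------------------
    null_block: dict = {}
    n_hat_all = rich["overall"].get("n_hat")
    obs_spec = nullmodels.spectrum(obs["allele_id"])
    null_block["observed_spectrum"] = {int(k): v for k, v in sorted(obs_spec.counts.items())}
    if n_hat_all:
        null_spec = nullmodels.mean_spectrum(n_hat_all, D_all, cfg.reps, rng)
        null_block["null_spectrum"] = {
            int(k): v for k, v in sorted(null_spec.counts.items())
        }
        null_block["spectrum_chi2"] = _chi_or_error(obs_spec, null_spec)
    if len(groups) == 2:
        a = obs.loc[obs["group_id"] == groups[0], "allele_id"]
        b = obs.loc[obs["group_id"] == groups[1], "allele_id"]
        part = nullmodels.overlap_partition(a, b)
        null_block["observed_overlap"] = part.as_dict()
        if n_hat_all:
            exp_part = nullmodels.expected_overlap(
                n_hat_all, len(a), len(b), cfg.reps, rng
            )
            null_block["null_overlap"] = exp_part.as_dict()
            null_block["overlap_chi2"] = _chi_or_error(part, exp_part)
    dedup_spec = nullmodels.spectrum(dedup["allele_id"])
    null_block["dedup_spectrum"] = {int(k): v for k, v in sorted(dedup_spec.counts.items())}
    n_hat_dedup = rich["dedup"].get("n_hat")
    if n_hat_dedup:
        null_dedup = nullmodels.mean_spectrum(n_hat_dedup, len(dedup), cfg.reps, rng)
        null_block["dedup_spectrum_chi2"] = _chi_or_error(dedup_spec, null_dedup)
    dedup.to_csv(out / "dedup.tsv", sep="\t", index=False)
    summary["nullmodels"] = null_block

    # --- novelty -----------------------------------------------------------
    if cfg.reference_fasta:
        if not Path(cfg.reference_fasta).exists():
            raise PipelineError(
                "novelty", f"reference FASTA not found: {cfg.reference_fasta}"
            )
        ref_seqs = _read_protein_fasta(cfg.reference_fasta)
        n_apiaries = (
            obs.groupby("allele_id")["apiary_id"].nunique().to_dict()
        )
        nov_table = novelty.classify_novelty(unique, ref_seqs, n_apiaries)
        nov_table.to_csv(out / "novelty.tsv", sep="\t", index=False)
        counts2x2, props = novelty.rare_frequent_table(nov_table)
        summary["novelty"] = {
            "n_unique": int(nov_table["is_unique"].sum()),
            "n_known": int((~nov_table["is_unique"]).sum()),
            "table": {r: counts2x2.loc[r].to_dict() for r in counts2x2.index},
            "proportion_unique": props.to_dict(),
        }
    else:
        summary["novelty"] = {"skipped": "no reference FASTA supplied"}

    with open(out / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
        fh.write("\n")
    logger.info("pipeline complete: %s", out / "summary.json")
    return summary


def _chi_or_error(observed, expected) -> dict:
    try:
        return nullmodels.chi_square_compare(observed, expected).as_dict()
    except ValueError as err:
        return {"error": str(err)}


def _read_protein_fasta(path: str | Path) -> list[str]:
    from Bio import SeqIO

    seqs = [str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")]
    return seqs


def _config_dict(cfg: PipelineConfig) -> dict:
    d = dataclasses.asdict(cfg)
    return d
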