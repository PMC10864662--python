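"""Pipeline orchestration: the operations behind each CLI subcommand.

Each ``run_*`` function is a deterministic, importable step that reads/writes
the package's table formats and returns its in-memory results; the CLI is a
thin shell over these.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from . import cleavage_classifier as cc
from . import tmt_quant as tq
from .io_formats import (
    PeptideObservation,
    RunConfig,
    read_fasta,
    read_psm_table,
    write_table,
)

logger = logging.getLogger(__name__)


@dataclass
class ReportBundle:
    """Paths of emitted tables plus run metadata sufficient to reproduce the run."""

    paths: dict[str, str] = field(default_factory=dict)
    metadata: dict = field(default_factory=dict)

    def save_metadata(self, out_dir: Path) -> None:
        (out_dir / "run_metadata.json").write_text(json.dumps(self.metadata, indent=2))


def _config_hash(config: RunConfig) -> str:
    return hashlib.sha256(
        json.dumps(config.to_dict(), sort_keys=True).encode()
    ).hexdigest()[:16]


def run_classify(
    psm_path,
    fasta_path,
    config: RunConfig,
    out_dir,
) -> tuple[list[cc.SampleSummary], pd.DataFrame, ReportBundle]:
    """Classify a PSM table and emit per-sample summary + specificity tables."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    proteins = {r.accession: r for r in read_fasta(str(fasta_path))}
    observations, stats = read_psm_table(psm_path, config)
    from .io_formats import check_peptide_protein_consistency

    bad = check_peptide_protein_consistency(observations, proteins)
    classifications = cc.classify_observations(observations, config)
    summaries = cc.summarize_all_samples(classifications, config)
    profile = cc.specificity_profile(summaries)

    summary_path = out / "sample_summary.tsv"
    profile_path = out / "specificity_profile.tsv"
    write_table(cc.summaries_to_frame(summaries), summary_path)
    write_table(profile, profile_path)
    bundle = ReportBundle(
        paths={"sample_summary": str(summary_path), "specificity_profile": str(profile_path)},
        metadata={
            "config_hash": _config_hash(config),
            "seed": config.seed,
            "n_rows_read": stats.n_rows,
            "n_dropped_zero_intensity": stats.n_dropped_zero_intensity,
            "n_kept": stats.n_kept,
            "n_consistency_violations": len(bad),
            "n_samples": len(summaries),
        },
    )
    bundle.save_metadata(out)
    return summaries, profile, bundle


def run_quant(
    matrix: tq.ReporterMatrix,
    config: RunConfig,
    group1_channels: Sequence[str],
    group2_channels: Sequence[str],
    out_dir=None,
) -> tuple[tq.LogRatioTable, pd.DataFrame, pd.DataFrame]:
    """The full quantitation chain in fixed order.

    log2 ratios -> recursive Dixon per (peptide, channel) group of >2 PSMs ->
    median roll-up to peptide then protein -> mixture-mode alignment and
    trimmed-SD scaling -> moderated t (group1 vs group2) with BH adjustment.
    Returns (normalized protein table, differential results, diagnostics).
    """
    psm = tq.to_log_ratios(matrix)
    n_psm = len(psm.data)
    filtered, n_removed = tq.dixon_filter_table(psm, config.dixon_alpha)
    peptide = tq.rollup(filtered, tq.PEPTIDE_LEVEL)
    protein = tq.rollup(peptide, tq.PROTEIN_LEVEL)
    normalized, channel_diag = tq.align_and_scale(
        protein, config.trim_percentiles, seed=config.seed
    )

    wide = normalized.data.pivot_table(
        index="protein", columns="channel", values="log2_ratio", aggfunc="first"
    )
    diff = tq.moderated_t_test(wide, list(group1_channels), list(group2_channels))

    diagnostics = pd.DataFrame(
        [
            {
                "channel": d.channel,
                "offset": d.offset,
                "trimmed_sd": d.trimmed_sd,
                "scale_factor": d.scale_factor,
                "method": d.method,
            }
            for d in channel_diag
        ]
    )
    diagnostics.attrs["n_psm_ratios"] = n_psm
    diagnostics.attrs["n_dixon_removed"] = n_removed
    diagnostics.attrs["n_dropped_zero_reference"] = psm.n_dropped_zero_reference

    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        write_table(normalized.data, out / "protein_ratios.tsv")
        write_table(diff.reset_index(), out / "differential_abundance.tsv")
        counters = diagnostics.copy()
        write_table(counters, out / "normalization_diagnostics.tsv")
        (out / "quant_counts.json").write_text(
            json.dumps(
                {
                    "n_psm_ratios": n_psm,
                    "n_dixon_removed": n_removed,
                    "n_after_dixon": len(filtered.data),
                    "n_dropped_zero_reference": psm.n_dropped_zero_reference,
                    "config_hash": _config_hash(config),
                    "seed": config.seed,
                },
                indent=2,
            )
        )
    return normalized, diff, diagnostics


def run_correlate(
    protein_abundance: Mapping[str, float],
    summaries: Sequence[cc.SampleSummary],
    protease_class: Optional[str] = None,
    out_path=None,
) -> cc.CorrelationResult:
    """Correlate a target protease's abundance with per-sample nontryptic intensity."""
    result = cc.correlate_activity(protein_abundance, summaries, protease_class)
    if out_path is not None:
        write_table(
            pd.DataFrame(
                [
                    {
                        "r": result.r,
                        "n": result.n,
                        "p_value": result.p_value,
                        "defined": result.defined,
                        "protease_class": protease_class or "all",
                    }
                ]
            ),
            out_path,
        )
    return result


def run_cluster_input(
    protein_table: tq.LogRatioTable, out_path=None, missing_code: str = "NA"
) -> pd.DataFrame:
    """Wide proteins x channels matrix for heat-map / clustering tools.

    Missing values are encoded explicitly; all-missing rows are kept and
    counted in the log.
    """
    wide = protein_table.data.pivot_table(
        index="protein", columns="channel", values="log2_ratio", aggfunc="first",
        dropna=False,
    )
    n_all_missing = int(wide.isna().all(axis=1).sum())
    if n_all_missing:
        logger.info("%d all-missing protein rows in cluster matrix", n_all_missing)
    if out_path is not None:
        wide.to_csv(out_path, sep="\t", na_rep=missing_code, float_format="%.10g")
    return wide
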