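"""Pipeline orchestration and export of cross-cancer summary tables.

Runs the full per-cancer chain — differential expression, Metric ranking
with FPKM filtering, IHC scoring, heterodimer calling — from a YAML study
configuration, and exports the cross-cancer artifacts: a genes x cancers
log2 fold-change matrix (cells blanked where FDR >= threshold) and a
heterodimer call table with evidence classes.  Outputs are plain TSV/JSON
and deterministic for fixed inputs.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .catalog import load_catalog, load_pairing_rules
from .diffexpr import CountMatrix, run_de
from .dimercall import calls_table, expand_organ_map
from .ihc import score_table
from .prioritize import BORDERLINE_FRAC, FDR_THRESHOLD, FPKM_CUTOFF, rank_targets

__all__ = ["StudyConfig", "run_pipeline", "export_matrix", "linear_fold_change"]

log = logging.getLogger("dimertarget")


@dataclass
class CancerInputs:
    counts: str
    meta: str
    fpkm: str
    ihc: str | None = None


@dataclass
class StudyConfig:
    """Per-cancer input paths plus pipeline thresholds."""

    cancers: dict[str, CancerInputs]
    outdir: str = "results"
    fdr_threshold: float = FDR_THRESHOLD
    fpkm_cutoff: float = FPKM_CUTOFF
    borderline_frac: float = BORDERLINE_FRAC
    mode: str = "strict"
    pairing_rules: str | None = None
    organ_map: dict = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.fpkm_cutoff <= 0:
            raise ValueError("fpkm_cutoff must be positive")
        if self.fdr_threshold < 0:
            raise ValueError("fdr_threshold must be non-negative")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "StudyConfig":
        doc = yaml.safe_load(Path(path).read_text())
        cancers = {
            name: CancerInputs(**spec) for name, spec in doc.pop("cancers").items()
        }
        return cls(cancers=cancers, **doc)

    def validate_paths(self) -> None:
        for cancer, inp in self.cancers.items():
            for kind in ("counts", "meta", "fpkm", "ihc"):
                p = getattr(inp, kind)
                if p is not None and not Path(p).exists():
                    raise FileNotFoundError(
                        f"cancer {cancer}: missing {kind} file {p}"
                    )


def export_matrix(
    de_results: dict[str, pd.DataFrame], fdr_threshold: float = FDR_THRESHOLD
) -> pd.DataFrame:
    """Genes x cancers matrix of log2fc, missing where FDR >= threshold."""
    cols = {}
    for cancer in sorted(de_results):
        de = de_results[cancer]
        keep = de["fdr"] < fdr_threshold
        cols[cancer] = de["log2fc"].where(keep)
    return pd.DataFrame(cols).sort_index()


def linear_fold_change(log2fc: float) -> float:
    """Signed-reciprocal display convention: 2^x for x >= 0, else -2^(-x).

    A value of -2 reads "2-fold reduction"; display-only, never used in
    statistics.
    """
    if not np.isfinite(log2fc):
        return float("nan")
    return 2.0 ** log2fc if log2fc >= 0 else -(2.0 ** (-log2fc))


def run_pipeline(config: StudyConfig) -> dict:
    """Execute de -> rank -> ihc -> call per cancer and write all artifacts.

    Writes de/<cancer>.tsv, ranked/<cancer>.tsv, ihc_scores.tsv, calls.tsv,
    matrix_log2fc.tsv and summary.json under ``config.outdir``.  Returns the
    result bundle in memory.
    """
    config.validate_paths()
    catalog = load_catalog()
    rules = load_pairing_rules(config.pairing_rules, catalog)
    outdir = Path(config.outdir)
    (outdir / "de").mkdir(parents=True, exist_ok=True)
    (outdir / "ranked").mkdir(parents=True, exist_ok=True)

    de_results: dict[str, pd.DataFrame] = {}
    ranked_results: dict[str, pd.DataFrame] = {}
    ihc_frames = []
    call_frames = []
    summary: dict = {"cancers": {}, "mode": config.mode,
                     "fdr_threshold": config.fdr_threshold,
                     "fpkm_cutoff": config.fpkm_cutoff}

    for cancer in sorted(config.cancers):
        inp = config.cancers[cancer]
        t0 = time.perf_counter()
        cm = CountMatrix.from_tsv(inp.counts, inp.meta)
        de = run_de(cm)
        de_results[cancer] = de
        de.rename_axis("gene").to_csv(outdir / "de" / f"{cancer}.tsv", sep="\t")

        fpkm = pd.read_csv(inp.fpkm, sep="\t").set_index("gene")["fpkm"]
        ranked = rank_targets(
            de, fpkm, cutoff=config.fpkm_cutoff,
            borderline_frac=config.borderline_frac,
        )
        ranked_results[cancer] = ranked
        ranked.to_csv(outdir / "ranked" / f"{cancer}.tsv", sep="\t", index=False)

        if inp.ihc is not None:
            tallies = pd.read_csv(inp.ihc, sep="\t")
            scores = score_table(tallies)
            ihc_frames.append(scores)
            ihc_pass_all = scores.loc[scores["overexpressed"], ["gene", "cancer"]]
        else:
            ihc_pass_all = pd.DataFrame(columns=["gene", "cancer"])

        rna_pass = set(ranked.loc[ranked["eligible"], "gene"]) & set(catalog.genes)
        ihc_pass = set(
            ihc_pass_all.loc[ihc_pass_all["cancer"] == cancer, "gene"]
        ) & set(catalog.genes)
        calls = calls_table(cancer, rna_pass, ihc_pass, rules, catalog, mode=config.mode)
        call_frames.append(calls)
        summary["cancers"][cancer] = {
            "n_tested": int(de["tested"].sum()),
            "n_significant": int((de["fdr"] < config.fdr_threshold).sum()),
            "n_ranked": int(len(ranked)),
            "rna_pass": sorted(rna_pass),
            "ihc_pass": sorted(ihc_pass),
            "n_calls": int(len(calls)),
            "calls": sorted(calls["heterodimer"].tolist()),
        }
        log.info("%s: DE+rank+call in %.1fs", cancer, time.perf_counter() - t0)

    if ihc_frames:
        ihc_all = pd.concat(ihc_frames, ignore_index=True)
        if config.organ_map:
            ihc_all = expand_organ_map(ihc_all, config.organ_map)
        ihc_all.to_csv(outdir / "ihc_scores.tsv", sep="\t", index=False)

    calls_all = (
        pd.concat(call_frames, ignore_index=True)
        if call_frames
        else pd.DataFrame(columns=["cancer", "heterodimer", "alpha_gene",
                                   "beta_gene", "mode", "n_pass_subunits", "evidence"])
    )
    calls_all.to_csv(outdir / "calls.tsv", sep="\t", index=False)

    matrix = export_matrix(de_results, config.fdr_threshold)
    matrix.rename_axis("gene").to_csv(outdir / "matrix_log2fc.tsv", sep="\t")

    (outdir / "summary.json").write_text(json.dumps(summary, indent=1, sort_keys=True))
    return dict(
        de=de_results, ranked=ranked_results, calls=calls_all,
        matrix=matrix, summary=summary,
    )
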