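"""Rank overexpressed genes as drug targets and filter by absolute expression.

The ranking score for a significantly overexpressed gene is

    Metric = log2fc - FDR / 0.05,   clamped below at 0,

defined only for genes with FDR < 0.05 and log2fc > 0: a large fold change
raises the score, an FDR approaching the significance threshold subtracts
up to one unit.  Ranked genes are then filtered on absolute expression in
FPKM (fragments per kilobase of transcript per million mapped fragments);
the default cutoff of 10 FPKM marks a moderately expressed transcript.
Genes just under the cutoff (within 10% by default) are flagged borderline
rather than silently dropped.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

__all__ = ["compute_metric", "rank_targets", "fpkm_from_counts"]

FDR_THRESHOLD = 0.05
FPKM_CUTOFF = 10.0
BORDERLINE_FRAC = 0.10


def compute_metric(log2fc: float, fdr: float) -> float | None:
    """Ranking score max(0, log2fc - fdr/0.05), or None when ineligible.

    Returns None (gene excluded from ranking) when the FDR is missing or not
    below 0.05, or the gene is not overexpressed (log2fc <= 0).
    """
    if fdr is None or log2fc is None or not np.isfinite(fdr) or not np.isfinite(log2fc):
        return None
    if not 0.0 <= fdr <= 1.0:
        raise ValueError(f"fdr must be in [0, 1], got {fdr}")
    if fdr >= FDR_THRESHOLD or log2fc <= 0.0:
        return None
    return max(0.0, float(log2fc) - float(fdr) / FDR_THRESHOLD)


def rank_targets(
    de: pd.DataFrame,
    fpkm: pd.Series | dict,
    cutoff: float = FPKM_CUTOFF,
    borderline_frac: float = BORDERLINE_FRAC,
) -> pd.DataFrame:
    """Rank Metric-eligible genes and annotate FPKM pass/borderline flags.

    Parameters
    ----------
    de
        DE results indexed by gene with columns log2fc and fdr.
    fpkm
        Per-gene average FPKM.  Genes absent from the table are kept with
        fpkm missing and fpkm_pass False (warned).
    cutoff
        Absolute-expression threshold; a gene is actionable at fpkm >= cutoff.
    borderline_frac
        Width of the near-miss band: borderline when
        (1 - borderline_frac) * cutoff <= fpkm < cutoff.

    Returns a DataFrame sorted by metric descending (ties broken by gene
    symbol) with columns gene, metric, log2fc, fdr, fpkm, fpkm_pass,
    fpkm_borderline, eligible.
    """
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    fpkm = pd.Series(fpkm, dtype=float) if not isinstance(fpkm, pd.Series) else fpkm.astype(float)

    rows = []
    for gene, rec in de.iterrows():
        metric = compute_metric(rec["log2fc"], rec["fdr"])
        if metric is None:
            continue
        value = fpkm.get(gene, np.nan)
        if not np.isfinite(value):
            warnings.warn(f"gene {gene} missing from FPKM table; fpkm_pass=False")
            value = np.nan
        fpkm_pass = bool(np.isfinite(value) and value >= cutoff)
        borderline = bool(
            np.isfinite(value) and (1.0 - borderline_frac) * cutoff <= value < cutoff
        )
        rows.append(
            dict(
                gene=gene,
                metric=metric,
                log2fc=rec["log2fc"],
                fdr=rec["fdr"],
                fpkm=value,
                fpkm_pass=fpkm_pass,
                fpkm_borderline=borderline,
                eligible=fpkm_pass,
            )
        )
    out = pd.DataFrame(
        rows,
        columns=[
            "gene", "metric", "log2fc", "fdr", "fpkm",
            "fpkm_pass", "fpkm_borderline", "eligible",
        ],
    )
    return out.sort_values(
        ["metric", "gene"], ascending=[False, True], kind="mergesort"
    ).reset_index(drop=True)


def fpkm_from_counts(
    counts: pd.DataFrame,
    gene_lengths_bp: pd.Series,
    sample_mask=None,
) -> pd.Series:
    """Average FPKM per gene computed from raw counts and transcript lengths.

    FPKM[g, s] = count / (length_kb * mapped_millions); averaged over the
    samples selected by ``sample_mask`` (all samples when None).  Intended as
    a convenience when no external FPKM table is available; tumor-sample
    averages are conventional here.
    """
    mat = counts if sample_mask is None else counts.loc[:, sample_mask]
    lengths_kb = gene_lengths_bp.reindex(mat.index).astype(float) / 1e3
    if lengths_kb.isna().any() or (lengths_kb <= 0).any():
        raise ValueError("every gene needs a positive length")
    mapped_millions = mat.sum(axis=0) / 1e6
    fpkm = mat.div(mapped_millions, axis=1).div(lengths_kb, axis=0)
    return fpkm.mean(axis=1).rename("fpkm")
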