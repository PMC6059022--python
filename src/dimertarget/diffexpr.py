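"""Tumor-vs-normal differential expression on raw RNA-seq counts.

The model is the standard negative-binomial (NB) count regression used for
bulk RNA-seq: for gene g and sample s,

    K_gs ~ NB(mean = q_gs * f_gs,  variance = mu + alpha_g * mu^2)

where f_gs is a normalization factor combining a per-sample size factor
(median-of-ratios) with an optional externally supplied gene-by-sample
factor matrix (e.g. GC-content/length bias weights), rescaled so that the
gene-level component of every row has geometric mean 1 — this keeps
normalized counts on the scale of the raw counts.  A log-linear model with
a tumor/normal indicator is fit per gene with the log factors as offset;
the Wald statistic on the tumor coefficient gives the p-value, and the
coefficient divided by ln(2) is the log2 fold change (positive = higher in
tumor).  P-values are adjusted with the Benjamini-Hochberg step-up
procedure.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "CountMatrix",
    "size_factors",
    "build_normalization_matrix",
    "estimate_dispersion",
    "nb_wald_test",
    "bh_adjust",
    "run_de",
]

CONDITIONS = ("tumor", "normal")

#: floor for method-of-moments dispersion estimates (Poisson limit)
DISPERSION_FLOOR = 1e-8

#: cap on |beta| for the condition coefficient, natural-log scale
BETA_CAP = 20.0

GEOMEAN_TOL = 1e-8


class DEError(ValueError):
    pass


@dataclass
class CountMatrix:
    """Raw counts (genes x samples) with tumor/normal condition labels.

    ``counts`` is a pandas DataFrame indexed by unique HGNC gene symbols with
    sample IDs as columns; ``condition`` maps each sample to "tumor" or
    "normal".
    """

    counts: pd.DataFrame
    condition: pd.Series

    def __post_init__(self) -> None:
        if not self.counts.index.is_unique:
            dup = self.counts.index[self.counts.index.duplicated()].unique().tolist()
            raise DEError(f"duplicate gene ids: {dup}")
        if (self.counts.to_numpy() < 0).any():
            raise DEError("counts must be non-negative")
        self.condition = self.condition.reindex(self.counts.columns)
        if self.condition.isna().any():
            missing = self.condition.index[self.condition.isna()].tolist()
            raise DEError(f"samples missing a condition label: {missing}")
        bad = set(self.condition) - set(CONDITIONS)
        if bad:
            raise DEError(f"condition labels must be in {CONDITIONS}; got {sorted(bad)}")

    @property
    def gene_ids(self) -> pd.Index:
        return self.counts.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.counts.columns

    def is_tumor(self) -> np.ndarray:
        return (self.condition == "tumor").to_numpy()

    def require_replicates(self, n_min: int = 2) -> None:
        vc = self.condition.value_counts()
        for cond in CONDITIONS:
            if vc.get(cond, 0) < n_min:
                raise DEError(
                    f"need at least {n_min} samples per condition; "
                    f"{cond} has {vc.get(cond, 0)}"
                )

    @classmethod
    def from_tsv(cls, counts_path, meta_path) -> "CountMatrix":
        counts = pd.read_csv(counts_path, sep="\t", index_col=0)
        meta = pd.read_csv(meta_path, sep="\t")
        cond = meta.set_index("sample_id")["condition"]
        return cls(counts=counts, condition=cond)


def size_factors(counts: CountMatrix | pd.DataFrame) -> pd.Series:
    """Median-of-ratios per-sample size factors.

    The reference is the per-gene geometric mean across samples, computed over
    genes with nonzero counts in every sample; each sample's factor is the
    median ratio of its counts to that reference.
    """
    mat = counts.counts if isinstance(counts, CountMatrix) else counts
    x = mat.to_numpy(dtype=float)
    all_pos = (x > 0).all(axis=1)
    if not all_pos.any():
        raise DEError(
            "no gene has nonzero counts in all samples; size factors are "
            "undefined (consider a pseudo-reference fallback on filtered data)"
        )
    logx = np.log(x[all_pos])
    log_ref = logx.mean(axis=1, keepdims=True)  # geometric mean per gene
    factors = np.exp(np.median(logx - log_ref, axis=0))
    return pd.Series(factors, index=mat.columns, name="size_factor")


def build_normalization_matrix(
    counts: CountMatrix,
    gene_factors: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Gene x sample normalization factors with row-geomean-1 gene component.

    Each row of ``gene_factors`` (all ones when absent) is divided by its
    geometric mean, then multiplied by the per-sample size factors.  The
    gene-level component of every row therefore has geometric mean exactly 1,
    so normalized counts for a gene stay near the mean of its raw counts.
    """
    sf = size_factors(counts).to_numpy()
    n_genes, n_samples = counts.counts.shape
    if gene_factors is None:
        gf = np.ones((n_genes, n_samples))
    else:
        gf = gene_factors.reindex(index=counts.gene_ids, columns=counts.sample_ids).to_numpy(float)
        if np.isnan(gf).any() or (gf <= 0).any():
            raise DEError("gene factors must be positive and cover every gene/sample")
        gf = gf / np.exp(np.log(gf).mean(axis=1, keepdims=True))
    return pd.DataFrame(gf * sf[None, :], index=counts.gene_ids, columns=counts.sample_ids)


def estimate_dispersion(
    counts: CountMatrix, norm: pd.DataFrame
) -> pd.Series:
    """Per-gene NB dispersion via method of moments on normalized counts.

    Within each condition, alpha = (s^2 - m) / m^2 on the normalized counts;
    the two estimates are averaged and floored at the Poisson limit.  Genes
    with all-zero counts get NaN (untested downstream).
    """
    counts.require_replicates()
    y = counts.counts.to_numpy(float) / norm.to_numpy(float)
    tumor = counts.is_tumor()
    disp = np.full(y.shape[0], np.nan)
    per_cond = []
    for mask in (tumor, ~tumor):
        m = y[:, mask].mean(axis=1)
        v = y[:, mask].var(axis=1, ddof=1)
        with np.errstate(divide="ignore", invalid="ignore"):
            a = (v - m) / m**2
        per_cond.append(a)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN rows are fine
        a = np.nanmean(np.vstack(per_cond), axis=0)
    expressed = counts.counts.to_numpy().sum(axis=1) > 0
    disp[expressed] = np.maximum(a[expressed], DISPERSION_FLOOR)
    return pd.Series(disp, index=counts.gene_ids, name="dispersion")


def _fit_gene(
    y: np.ndarray, design: np.ndarray, offset: np.ndarray, alpha: float
) -> tuple[float, float]:
    """Fit NB GLM for one gene; return (beta_condition, se)."""
    fam = sm.families.NegativeBinomial(alpha=max(alpha, DISPERSION_FLOOR))
    model = sm.GLM(y, design, family=fam, offset=offset)
    res = model.fit(maxiter=100, tol=1e-8)
    return float(res.params[1]), float(res.bse[1])


def nb_wald_test(
    counts: CountMatrix,
    norm: pd.DataFrame,
    dispersion: pd.Series,
) -> pd.DataFrame:
    """Per-gene NB Wald test of tumor vs normal.

    Returns a DataFrame indexed by gene with columns log2fc, pvalue, fdr,
    mean_normalized_count, tested.  Genes with all-zero counts (or a failed
    fit after the convergence guard) are reported untested with missing
    statistics; the pipeline never aborts on a single gene.
    """
    counts.require_replicates()
    tumor = counts.is_tumor().astype(float)
    design = np.column_stack([np.ones_like(tumor), tumor])
    norm_np = norm.to_numpy(float)
    cmat = counts.counts.to_numpy(float)
    ln2 = np.log(2.0)

    rows = []
    for i, gene in enumerate(counts.gene_ids):
        y = cmat[i]
        alpha = dispersion.iloc[i]
        mean_norm = float((y / norm_np[i]).mean())
        if y.sum() == 0 or not np.isfinite(alpha):
            rows.append((gene, np.nan, np.nan, mean_norm, False))
            continue
        offset = np.log(norm_np[i])
        beta = se = np.nan
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                beta, se = _fit_gene(y, design, offset, alpha)
        except Exception:
            pass
        if not np.isfinite(beta) or not np.isfinite(se) or abs(beta) > BETA_CAP:
            # convergence guard: a 0.5 pseudocount shrinks infinite fold
            # changes (one condition all zero) to a finite, capped estimate
            try:
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    beta, se = _fit_gene(y + 0.5, design, offset, alpha)
                beta = float(np.clip(beta, -BETA_CAP, BETA_CAP))
            except Exception:
                warnings.warn(f"NB fit failed for gene {gene}; marked untested")
                rows.append((gene, np.nan, np.nan, mean_norm, False))
                continue
        z = beta / se if se > 0 else np.inf * np.sign(beta)
        pval = float(2.0 * stats.norm.sf(abs(z)))
        rows.append((gene, beta / ln2, pval, mean_norm, True))

    de = pd.DataFrame(
        rows, columns=["gene", "log2fc", "pvalue", "mean_normalized_count", "tested"]
    ).set_index("gene")
    de["fdr"] = bh_adjust(de["pvalue"])
    return de[["log2fc", "pvalue", "fdr", "mean_normalized_count", "tested"]]


def bh_adjust(pvalues) -> pd.Series | np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, NaN passed through."""
    p = np.asarray(pvalues, dtype=float)
    if np.nanmin(p, initial=0.0) < 0 or np.nanmax(p, initial=0.0) > 1:
        raise DEError("p-values must lie in [0, 1]")
    out = np.full(p.shape, np.nan)
    ok = np.isfinite(p)
    if ok.any():
        out[ok] = multipletests(p[ok], method="fdr_bh")[1]
    if isinstance(pvalues, pd.Series):
        return pd.Series(out, index=pvalues.index, name="fdr")
    return out


def run_de(
    counts: CountMatrix, gene_factors: pd.DataFrame | None = None
) -> pd.DataFrame:
    """Full DE stage: normalization, dispersion, Wald test, BH adjustment."""
    norm = build_normalization_matrix(counts, gene_factors)
    disp = estimate_dispersion(counts, norm)
    return nb_wald_test(counts, norm, disp)
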