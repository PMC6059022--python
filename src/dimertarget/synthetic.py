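"""Synthetic cohorts with the statistical structure the pipeline assumes.

Counts are drawn from a negative binomial parameterized by mean mu and
dispersion alpha (variance mu + alpha*mu^2), the same convention as the DE
module.  The mean for gene g in sample s is

    mu_gs = baseline_mean_g * 2^(planted_log2fc_g * is_tumor(s))
            * library_size_factor_s * gene_sample_factor_gs

with log-normal gene-by-sample factors emulating residual gene-specific
bias (GC content, length).  IHC tallies are multinomial draws over the four
ordinal staining levels.  The demo study plants a known overexpression
pattern (by default α6 and β4, whose product is the only β4 receptor) so
the end-to-end pipeline has a deterministic expected heterodimer set.

All randomness flows from a single seeded numpy Generator; a fixed seed
reproduces every table byte for byte.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .catalog import load_catalog
from .diffexpr import CountMatrix

__all__ = ["SimulationConfig", "simulate_counts", "simulate_ihc",
           "make_demo_study", "write_demo_study", "nb_draw"]

# demo-study defaults: effect and cohort sizes at which the planted truth is
# recovered essentially surely (log2fc=2 at 50/50 gives Wald power ~1)
DEMO_LOG2FC = 2.0
DEMO_N_PER_GROUP = 50
DEMO_FPKM_PLANTED = 50.0
DEMO_FPKM_OTHER = 5.0
DEMO_N_BACKGROUND = 150


@dataclass
class SimulationConfig:
    """Parameters of one synthetic tumor/normal cohort.

    ``planted_log2fc`` maps gene -> true tumor/normal log2 fold change
    (genes absent default to 0); ``dispersion`` maps gene -> NB dispersion
    (scalar allowed).  ``gene_factor_sd`` is the standard deviation of the
    log gene-by-sample factors (0 disables them).
    """

    genes: list[str]
    n_tumor: int = DEMO_N_PER_GROUP
    n_normal: int = DEMO_N_PER_GROUP
    baseline_mean: float | dict = 200.0
    dispersion: float | dict = 0.1
    planted_log2fc: dict = field(default_factory=dict)
    library_size_factors: np.ndarray | None = None
    gene_factor_sd: float = 0.0
    fpkm_map: dict = field(default_factory=dict)
    ihc_pattern: dict = field(default_factory=dict)  # gene -> (probs[4], normal_level)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_tumor < 1 or self.n_normal < 1:
            raise ValueError("need at least one sample per condition")
        if self.gene_factor_sd < 0:
            raise ValueError("gene_factor_sd must be non-negative")
        for g, mu in self._per_gene(self.baseline_mean).items():
            if mu <= 0:
                raise ValueError(f"baseline mean for {g} must be positive")
        for g, a in self._per_gene(self.dispersion).items():
            if a < 0:
                raise ValueError(f"dispersion for {g} must be non-negative")

    def _per_gene(self, value) -> dict:
        if isinstance(value, dict):
            return {g: value.get(g, 0.0) for g in self.genes}
        return {g: value for g in self.genes}

    @property
    def sample_ids(self) -> list[str]:
        return [f"T{i+1:03d}" for i in range(self.n_tumor)] + [
            f"N{i+1:03d}" for i in range(self.n_normal)
        ]

    @property
    def condition(self) -> pd.Series:
        labels = ["tumor"] * self.n_tumor + ["normal"] * self.n_normal
        return pd.Series(labels, index=self.sample_ids, name="condition")


def nb_draw(rng: np.random.Generator, mean, dispersion) -> np.ndarray:
    """NB(mean, variance = mean + dispersion*mean^2) samples; Poisson at 0."""
    mean = np.asarray(mean, float)
    dispersion = np.asarray(dispersion, float)
    out = np.empty(np.broadcast(mean, dispersion).shape, dtype=np.int64)
    mean, dispersion = np.broadcast_arrays(mean, dispersion)
    pois = dispersion <= 1e-12
    if pois.any():
        out[pois] = rng.poisson(mean[pois])
    if (~pois).any():
        n = 1.0 / dispersion[~pois]
        p = n / (n + mean[~pois])
        out[~pois] = rng.negative_binomial(n, p)
    return out


def simulate_counts(
    config: SimulationConfig, rng: np.random.Generator | None = None
) -> tuple[CountMatrix, pd.DataFrame]:
    """Draw a count matrix plus its ground-truth table.

    Returns (CountMatrix, truth) where truth is indexed by gene with columns
    true_log2fc and true_dispersion.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    genes = list(config.genes)
    n_s = config.n_tumor + config.n_normal
    mu0 = np.array([config._per_gene(config.baseline_mean)[g] for g in genes])
    disp = np.array([config._per_gene(config.dispersion)[g] for g in genes])
    lfc = np.array([config.planted_log2fc.get(g, 0.0) for g in genes])
    is_tumor = np.array([1.0] * config.n_tumor + [0.0] * config.n_normal)

    lib = config.library_size_factors
    if lib is None:
        lib = np.ones(n_s)
    lib = np.asarray(lib, float)
    if lib.shape != (n_s,) or (lib <= 0).any():
        raise ValueError("library_size_factors must be positive, one per sample")

    mu = mu0[:, None] * 2.0 ** (lfc[:, None] * is_tumor[None, :]) * lib[None, :]
    if config.gene_factor_sd > 0:
        gf = np.exp(rng.normal(0.0, config.gene_factor_sd, size=mu.shape))
        gf /= np.exp(np.log(gf).mean(axis=1, keepdims=True))  # row geomean 1
        mu = mu * gf
    counts = nb_draw(rng, mu, disp[:, None])

    cm = CountMatrix(
        counts=pd.DataFrame(
            counts, index=pd.Index(genes, name="gene"), columns=config.sample_ids
        ),
        condition=config.condition,
    )
    truth = pd.DataFrame(
        {"true_log2fc": lfc, "true_dispersion": disp}, index=pd.Index(genes, name="gene")
    )
    return cm, truth


def simulate_ihc(
    config: SimulationConfig,
    n_samples: int = 20,
    cancer: str = "DEMO",
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Multinomial IHC tallies per gene from the config's level probabilities.

    ``ihc_pattern`` maps gene -> (p_not_detected, p_low, p_medium, p_high,
    normal_level); probabilities must sum to 1.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed + 1)
    rows = []
    for gene in config.genes:
        if gene not in config.ihc_pattern:
            continue
        probs, normal_level = config.ihc_pattern[gene]
        probs = np.asarray(probs, float)
        if probs.shape != (4,) or (probs < 0).any() or abs(probs.sum() - 1.0) > 1e-9:
            raise ValueError(f"level probabilities for {gene} must be 4 values summing to 1")
        tally = rng.multinomial(n_samples, probs)
        rows.append(
            dict(
                gene=gene, cancer=cancer,
                n_not_detected=int(tally[0]), n_low=int(tally[1]),
                n_medium=int(tally[2]), n_high=int(tally[3]),
                normal_level=normal_level,
            )
        )
    return pd.DataFrame(
        rows,
        columns=["gene", "cancer", "n_not_detected", "n_low", "n_medium",
                 "n_high", "normal_level"],
    )


def make_demo_study(
    seed: int = 0,
    planted: tuple[str, ...] = ("ITGA6", "ITGB4"),
    log2fc: float = DEMO_LOG2FC,
    n_per_group: int = DEMO_N_PER_GROUP,
    cancer: str = "DEMO",
) -> dict:
    """Build a self-consistent miniature one-cancer study with planted truth.

    The 27 integrin genes are simulated together with background genes (for
    stable size-factor estimation).  Planted genes get the stated fold
    change, FPKM above the cutoff, and an all-high IHC pattern; every other
    integrin is null with FPKM below the cutoff, so the strict heterodimer
    call set is exactly the receptors formable from the planted genes.

    Returns a dict with keys: counts (CountMatrix), truth, fpkm (Series),
    ihc (tally DataFrame), catalog, config, cancer.
    """
    catalog = load_catalog()
    integrins = list(catalog.genes)
    background = [f"BG{i:04d}" for i in range(DEMO_N_BACKGROUND)]
    genes = integrins + background

    rng = np.random.default_rng(seed)
    baseline = {g: 200.0 for g in integrins}
    baseline.update({g: float(m) for g, m in zip(background, rng.uniform(50, 2000, len(background)))})
    fpkm = {g: (DEMO_FPKM_PLANTED if g in planted else DEMO_FPKM_OTHER) for g in integrins}

    ihc_pattern = {}
    for g in integrins:
        if g in ("ITGA4", "ITGA10"):   # no protein-level data in the demo
            continue
        if g in planted:
            ihc_pattern[g] = ((0.0, 0.0, 0.0, 1.0), "medium")
        else:
            ihc_pattern[g] = ((0.0, 0.0, 1.0, 0.0), "medium")

    config = SimulationConfig(
        genes=genes,
        n_tumor=n_per_group,
        n_normal=n_per_group,
        baseline_mean=baseline,
        dispersion=0.1,
        planted_log2fc={g: log2fc for g in planted},
        library_size_factors=np.exp(rng.normal(0.0, 0.15, size=2 * n_per_group)),
        gene_factor_sd=0.05,
        fpkm_map=fpkm,
        ihc_pattern=ihc_pattern,
        seed=seed,
    )
    counts, truth = simulate_counts(config, rng)
    ihc = simulate_ihc(config, n_samples=20, cancer=cancer, rng=rng)
    return dict(
        counts=counts,
        truth=truth,
        fpkm=pd.Series(fpkm, name="fpkm").rename_axis("gene"),
        ihc=ihc,
        catalog=catalog,
        config=config,
        cancer=cancer,
    )


def write_demo_study(outdir: str | Path, seed: int = 0, **kwargs) -> dict:
    """Write the demo bundle as the TSV dialects the pipeline reads."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    bundle = make_demo_study(seed=seed, **kwargs)
    cm: CountMatrix = bundle["counts"]
    cm.counts.rename_axis("gene").to_csv(outdir / "counts.tsv", sep="\t")
    meta = pd.DataFrame({"sample_id": cm.sample_ids, "condition": cm.condition.values})
    meta.to_csv(outdir / "meta.tsv", sep="\t", index=False)
    bundle["fpkm"].reset_index().to_csv(outdir / "fpkm.tsv", sep="\t", index=False)
    bundle["ihc"].to_csv(outdir / "ihc.tsv", sep="\t", index=False)
    bundle["truth"].to_csv(outdir / "truth.tsv", sep="\t")
    return bundle
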