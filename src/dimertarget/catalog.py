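"""Integrin subunit catalog and heterodimer pairing rules.

Integrins are obligate heterodimers of one α and one β transmembrane
subunit.  The human repertoire comprises 27 genes — 18 α chains and 9 β
chains — which assemble into 24 functional receptors under fixed pairing
combinatorics (β1 is the most promiscuous chain with 12 partners; β4 pairs
only with α6; ITGBL1 has no known α partner and therefore appears in no
receptor).  This module ships that catalog and rule set as a packaged JSON
resource, validates user-supplied overrides against the same invariants,
and enumerates the legal heterodimers deterministically.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable

__all__ = [
    "Subunit",
    "SubunitCatalog",
    "PairingRules",
    "Heterodimer",
    "load_catalog",
    "load_pairing_rules",
    "enumerate_heterodimers",
    "partners_of",
]

N_GENES = 27
N_ALPHA = 18
N_BETA = 9

CHAINS = ("alpha", "beta")


class CatalogError(ValueError):
    """Malformed or invariant-violating catalog/rules resource."""


@dataclass(frozen=True)
class Subunit:
    """One integrin gene: HGNC symbol, chain class and display name (e.g. 'αv')."""

    gene: str
    chain: str
    display: str

    def __post_init__(self) -> None:
        if self.chain not in CHAINS:
            raise CatalogError(
                f"subunit {self.gene!r}: chain must be one of {CHAINS}, got {self.chain!r}"
            )


@dataclass(frozen=True)
class SubunitCatalog:
    """The validated set of integrin subunit genes (18 α + 9 β = 27)."""

    entries: tuple[Subunit, ...]
    _by_gene: dict = field(default_factory=dict, repr=False, compare=False)

    def __post_init__(self) -> None:
        genes = [e.gene for e in self.entries]
        dupes = {g for g in genes if genes.count(g) > 1}
        if dupes:
            raise CatalogError(f"duplicate gene symbols in catalog: {sorted(dupes)}")
        n_alpha = sum(e.chain == "alpha" for e in self.entries)
        n_beta = sum(e.chain == "beta" for e in self.entries)
        if len(self.entries) != N_GENES or n_alpha != N_ALPHA or n_beta != N_BETA:
            raise CatalogError(
                f"catalog must contain exactly {N_ALPHA} alpha and {N_BETA} beta "
                f"subunits ({N_GENES} total); got {n_alpha} alpha, {n_beta} beta, "
                f"{len(self.entries)} total"
            )
        object.__setattr__(self, "_by_gene", {e.gene: e for e in self.entries})

    def __contains__(self, gene: str) -> bool:
        return gene in self._by_gene

    def __len__(self) -> int:
        return len(self.entries)

    def __getitem__(self, gene: str) -> Subunit:
        try:
            return self._by_gene[gene]
        except KeyError:
            raise CatalogError(f"unknown gene symbol {gene!r}") from None

    def chain_of(self, gene: str) -> str:
        return self[gene].chain

    @property
    def genes(self) -> tuple[str, ...]:
        return tuple(e.gene for e in self.entries)

    @property
    def alpha_genes(self) -> tuple[str, ...]:
        return tuple(e.gene for e in self.entries if e.chain == "alpha")

    @property
    def beta_genes(self) -> tuple[str, ...]:
        return tuple(e.gene for e in self.entries if e.chain == "beta")


@dataclass(frozen=True)
class PairingRules:
    """Allowed (α gene, β gene) combinations; each pair is one heterodimer."""

    pairs: frozenset  # of (alpha_gene, beta_gene) tuples

    def validate(self, catalog: SubunitCatalog) -> "PairingRules":
        for alpha, beta in self.pairs:
            for gene, chain in ((alpha, "alpha"), (beta, "beta")):
                if gene not in catalog:
                    raise CatalogError(f"pairing rule references unknown gene {gene!r}")
                if catalog.chain_of(gene) != chain:
                    raise CatalogError(
                        f"pairing rule ({alpha}, {beta}): {gene} is a "
                        f"{catalog.chain_of(gene)} chain, expected {chain}"
                    )
        return self

    def __len__(self) -> int:
        return len(self.pairs)

    def __contains__(self, pair: tuple[str, str]) -> bool:
        return tuple(pair) in self.pairs


@dataclass(frozen=True)
class Heterodimer:
    """A legal α/β receptor, identified by gene symbols with a cosmetic display name."""

    alpha_gene: str
    beta_gene: str
    display: str  # e.g. "αvβ3"

    @property
    def id(self) -> str:
        return f"{self.alpha_gene}/{self.beta_gene}"

    def __str__(self) -> str:
        return self.id


def _read_resource(path_or_default: str | Path | None) -> dict:
    if path_or_default is None:
        text = resources.files("dimertarget.data").joinpath("integrin_catalog.json").read_text("utf-8")
    else:
        text = Path(path_or_default).read_text("utf-8")
    try:
        doc = json.loads(text)
    except json.JSONDecodeError as exc:
        raise CatalogError(f"catalog resource is not valid JSON: {exc}") from exc
    if not isinstance(doc, dict) or "genes" not in doc:
        raise CatalogError("catalog resource must be a JSON object with a 'genes' key")
    return doc


def load_catalog(path_or_default: str | Path | None = None) -> SubunitCatalog:
    """Load and validate the subunit catalog (packaged default when no path given).

    Raises :class:`CatalogError` naming the offending row on malformed input,
    and a cardinality error when the 18 α / 9 β counts do not hold.
    """
    doc = _read_resource(path_or_default)
    entries = []
    for i, row in enumerate(doc["genes"]):
        try:
            entries.append(Subunit(gene=row["gene"], chain=row["chain"], display=row["display"]))
        except (KeyError, TypeError) as exc:
            raise CatalogError(f"malformed catalog row {i}: {row!r}") from exc
    return SubunitCatalog(entries=tuple(entries))


def load_pairing_rules(
    path_or_default: str | Path | None = None,
    catalog: SubunitCatalog | None = None,
) -> PairingRules:
    """Load the (α, β) pairing rules and validate them against ``catalog``."""
    doc = _read_resource(path_or_default)
    if "pairs" not in doc:
        raise CatalogError("rules resource must contain a 'pairs' key")
    pairs = set()
    for i, row in enumerate(doc["pairs"]):
        if not (isinstance(row, (list, tuple)) and len(row) == 2):
            raise CatalogError(f"malformed pairing rule {i}: {row!r} (want [alpha, beta])")
        pairs.add((str(row[0]), str(row[1])))
    rules = PairingRules(pairs=frozenset(pairs))
    if catalog is None:
        catalog = load_catalog(path_or_default)
    return rules.validate(catalog)


def enumerate_heterodimers(
    catalog: SubunitCatalog, rules: PairingRules
) -> list[Heterodimer]:
    """All legal heterodimers, each exactly once, sorted by (β gene, α gene)."""
    rules.validate(catalog)
    out = []
    for alpha, beta in sorted(rules.pairs, key=lambda p: (p[1], p[0])):
        display = catalog[alpha].display + catalog[beta].display
        out.append(Heterodimer(alpha_gene=alpha, beta_gene=beta, display=display))
    return out


def partners_of(gene: str, rules: PairingRules, catalog: SubunitCatalog | None = None) -> set[str]:
    """Obligate partner chains of ``gene`` under ``rules`` (empty for ITGBL1)."""
    if catalog is None:
        catalog = load_catalog()
    if gene not in catalog:
        raise CatalogError(f"unknown gene symbol {gene!r}")
    partners: set[str] = set()
    for alpha, beta in rules.pairs:
        if alpha == gene:
            partners.add(beta)
        elif beta == gene:
            partners.add(alpha)
    return partners
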