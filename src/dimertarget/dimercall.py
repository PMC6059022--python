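"""Combine per-subunit RNA and IHC calls into heterodimer target predictions.

A heterodimer is callable only if its (α, β) pair is a legal receptor under
the pairing rules.  Two calling modes:

* strict  — both subunits must pass the per-subunit filter (Metric-eligible
  and FPKM >= cutoff for RNA; protein overexpressed for IHC);
* relaxed — one passing subunit suffices, on the premise that high
  expression of one chain can drive receptor assembly with a partner at
  normal levels.  Strict calls are always a subset of relaxed calls.

RNA- and IHC-derived call sets are then merged into evidence classes:
``both`` (modalities agree), ``rna_only``, ``ihc_only``.  IHC resources
often group cancers by organ (e.g. one lung record covering LUAD and LUSC);
an explicit organ-to-subtype mapping expands such records rather than
relying on name matching.
"""

from __future__ import annotations

import pandas as pd

from .catalog import PairingRules, SubunitCatalog

__all__ = [
    "call_strict",
    "call_relaxed",
    "integrate_evidence",
    "calls_table",
    "expand_organ_map",
]


def _validate_pass_set(pass_set, catalog: SubunitCatalog | None) -> set[str]:
    pass_set = set(pass_set)
    if catalog is not None:
        unknown = {g for g in pass_set if g not in catalog}
        if unknown:
            raise ValueError(f"pass set contains unknown genes: {sorted(unknown)}")
    return pass_set


def call_strict(
    pass_set, rules: PairingRules, catalog: SubunitCatalog | None = None
) -> set[tuple[str, str]]:
    """Heterodimers whose α and β subunits both pass the subunit filter."""
    p = _validate_pass_set(pass_set, catalog)
    return {(a, b) for a, b in rules.pairs if a in p and b in p}


def call_relaxed(
    pass_set, rules: PairingRules, catalog: SubunitCatalog | None = None
) -> dict[tuple[str, str], int]:
    """Heterodimers with at least one passing subunit.

    Returns pair -> number of passing subunits (2 means it is also a strict
    call).  A gene with no pairing partner (ITGBL1) can never anchor a call.
    """
    p = _validate_pass_set(pass_set, catalog)
    out = {}
    for a, b in rules.pairs:
        n = int(a in p) + int(b in p)
        if n >= 1:
            out[(a, b)] = n
    return out


def integrate_evidence(rna_calls, ihc_calls) -> dict[tuple[str, str], str]:
    """Classify each called heterodimer by which modality supports it.

    The classes partition rna ∪ ihc: pairs in both sets map to "both", the
    others to "rna_only" / "ihc_only"; uncalled pairs are absent.
    """
    rna = {tuple(p) for p in rna_calls}
    ihc = {tuple(p) for p in ihc_calls}
    out = {}
    for pair in rna | ihc:
        if pair in rna and pair in ihc:
            out[pair] = "both"
        elif pair in rna:
            out[pair] = "rna_only"
        else:
            out[pair] = "ihc_only"
    return out


def calls_table(
    cancer: str,
    rna_pass,
    ihc_pass,
    rules: PairingRules,
    catalog: SubunitCatalog,
    mode: str = "strict",
) -> pd.DataFrame:
    """Tabulate heterodimer calls for one cancer with evidence classes.

    ``rna_pass`` / ``ihc_pass`` are the subunit gene sets passing the RNA
    (Metric + FPKM) and IHC (protein overexpression) filters.  ``mode``
    selects strict or relaxed pairing for both modalities.
    """
    if mode not in ("strict", "relaxed"):
        raise ValueError(f"mode must be 'strict' or 'relaxed', got {mode!r}")
    if mode == "strict":
        rna = {p: 2 for p in call_strict(rna_pass, rules, catalog)}
        ihc = {p: 2 for p in call_strict(ihc_pass, rules, catalog)}
    else:
        rna = call_relaxed(rna_pass, rules, catalog)
        ihc = call_relaxed(ihc_pass, rules, catalog)
    evidence = integrate_evidence(rna, ihc)
    rows = []
    for (a, b) in sorted(evidence, key=lambda p: (p[1], p[0])):
        n_pass = max(rna.get((a, b), 0), ihc.get((a, b), 0))
        rows.append(
            dict(
                cancer=cancer,
                heterodimer=catalog[a].display + catalog[b].display,
                alpha_gene=a,
                beta_gene=b,
                mode=mode,
                n_pass_subunits=n_pass,
                evidence=evidence[(a, b)],
            )
        )
    return pd.DataFrame(
        rows,
        columns=["cancer", "heterodimer", "alpha_gene", "beta_gene",
                 "mode", "n_pass_subunits", "evidence"],
    )


def expand_organ_map(
    ihc_scores: pd.DataFrame, organ_map: dict[str, list[str]]
) -> pd.DataFrame:
    """Replicate organ-level IHC score rows onto each mapped cancer subtype.

    ``organ_map`` maps an IHC cancer label (e.g. "lung") to the study
    subtypes it covers (e.g. ["LUAD", "LUSC"]).  Unmapped labels pass
    through unchanged.
    """
    frames = []
    for label, grp in ihc_scores.groupby("cancer", sort=False):
        targets = organ_map.get(label, [label])
        for t in targets:
            g = grp.copy()
            g["cancer"] = t
            frames.append(g)
    return pd.concat(frames, ignore_index=True)
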