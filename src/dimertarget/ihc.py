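"""Quantify ordinal immunohistochemistry (IHC) staining and call overexpression.

Pathology databases report IHC staining per sample as one of four ordinal
descriptors.  These map to numeric values

    not detected = 0, low = 0.33, medium = 0.66, high = 1

and a cohort of tumor samples is summarized by the weighted average

    (1*n_high + 0.66*n_medium + 0.33*n_low + 0*n_not_detected) / n_total.

A gene is called overexpressed at the protein level in a cancer when that
weighted average strictly exceeds the numeric value of the single staining
level assigned to the matching normal tissue; equality is not
overexpression.  Gene/cancer combinations with no tally at all are emitted
with reason "no_data" so downstream integration can distinguish absence of
evidence from negative evidence.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

__all__ = ["LEVELS", "IHCTally", "level_value", "weighted_average",
           "call_overexpression", "score_table"]

LEVELS = {"not_detected": 0.0, "low": 0.33, "medium": 0.66, "high": 1.0}

COUNT_COLS = ("n_not_detected", "n_low", "n_medium", "n_high")


class IHCError(ValueError):
    pass


@dataclass(frozen=True)
class IHCTally:
    """Per gene, per cancer: sample counts at each staining level plus the
    single qualitative level assigned to normal tissue."""

    gene: str
    cancer: str
    n_not_detected: int
    n_low: int
    n_medium: int
    n_high: int
    normal_level: str

    def __post_init__(self) -> None:
        for col in COUNT_COLS:
            if getattr(self, col) < 0:
                raise IHCError(f"{self.gene}/{self.cancer}: {col} must be non-negative")
        if self.normal_level not in LEVELS:
            raise IHCError(
                f"{self.gene}/{self.cancer}: unknown staining level "
                f"{self.normal_level!r}; expected one of {sorted(LEVELS)}"
            )

    @property
    def total(self) -> int:
        return self.n_not_detected + self.n_low + self.n_medium + self.n_high


def level_value(level: str) -> float:
    """Numeric value of an ordinal staining descriptor."""
    try:
        return LEVELS[level]
    except KeyError:
        raise IHCError(
            f"unknown staining level {level!r}; expected one of {sorted(LEVELS)}"
        ) from None


def weighted_average(tally: IHCTally) -> float:
    """Mean staining value over the tumor samples of a tally (in [0, 1])."""
    if tally.total < 1:
        raise IHCError(f"{tally.gene}/{tally.cancer}: no samples, score undefined")
    num = (
        1.0 * tally.n_high
        + LEVELS["medium"] * tally.n_medium
        + LEVELS["low"] * tally.n_low
    )
    return num / tally.total


def call_overexpression(tally: IHCTally) -> dict:
    """Score one tally and apply the strict '>' overexpression rule."""
    wa = weighted_average(tally)
    nv = level_value(tally.normal_level)
    over = wa > nv
    return dict(
        gene=tally.gene,
        cancer=tally.cancer,
        weighted_average=wa,
        normal_value=nv,
        overexpressed=over,
        reason="overexpressed" if over else "not_overexpressed",
    )


def score_table(
    tallies: pd.DataFrame,
    genes=None,
    cancers=None,
) -> pd.DataFrame:
    """Score every tally row; optionally emit no_data rows for missing combos.

    ``tallies`` columns: gene, cancer, n_not_detected, n_low, n_medium,
    n_high, normal_level (an optional antibody_id column is carried through).
    When ``genes`` and ``cancers`` are given, every absent (gene, cancer)
    combination is emitted with overexpressed=False and reason "no_data".
    """
    rows = []
    seen = set()
    for _, rec in tallies.iterrows():
        tally = IHCTally(
            gene=rec["gene"],
            cancer=rec["cancer"],
            n_not_detected=int(rec["n_not_detected"]),
            n_low=int(rec["n_low"]),
            n_medium=int(rec["n_medium"]),
            n_high=int(rec["n_high"]),
            normal_level=rec["normal_level"],
        )
        out = call_overexpression(tally)
        if "antibody_id" in tallies.columns:
            out["antibody_id"] = rec["antibody_id"]
        rows.append(out)
        seen.add((tally.gene, tally.cancer))
    if genes is not None and cancers is not None:
        for cancer in cancers:
            for gene in genes:
                if (gene, cancer) not in seen:
                    rows.append(
                        dict(
                            gene=gene, cancer=cancer,
                            weighted_average=float("nan"),
                            normal_value=float("nan"),
                            overexpressed=False, reason="no_data",
                        )
                    )
    return pd.DataFrame(rows).reset_index(drop=True)
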