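"""Semiquantitative neuropathology scoring.

Frontal-cortex amyloid (X_Abeta) and tau (X_tau) burden are graded 0-4 from
plaque and mature-NFT densities averaged over three random 1-mm^2 grey-matter
fields.  The rule set:

X_Abeta (plaques per mm^2)
  0: < 1 plaque
  1: < 1 dense-cored plaque but >= 2 total plaques
  2: >= 1 dense-cored but < 2 neuritic plaques
  3: >= 5 dense-cored and 2-15 neuritic plaques
  4: >= 15 neuritic plaques

X_tau (mature NFTs per mm^2)
  0: < 1;  1: [1, 5);  2: [5, 12);  3: [12, 25);  4: >= 25

The printed Abeta rows are not an exhaustive partition of count space, so
scoring evaluates each row's lower-bound conditions and returns the highest
satisfied score (upper bounds treated as descriptive).  Counts matching no row
score 0 with ``gap_flag`` set.  Interval boundaries shared by adjacent tau rows
belong to the higher score, which keeps scoring monotone in every count.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

#: tau cutpoints; boundary values belong to the higher score
TAU_CUTPOINTS = (1.0, 5.0, 12.0, 25.0)


@dataclass(frozen=True)
class FieldCounts:
    """Marker densities per 1-mm^2 field (fractional after averaging)."""

    total_plaques: float
    dense_cored_plaques: float
    neuritic_plaques: float
    mature_nfts: float

    def __post_init__(self) -> None:
        for name in (
            "total_plaques",
            "dense_cored_plaques",
            "neuritic_plaques",
            "mature_nfts",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be nonnegative")
        if self.dense_cored_plaques > self.total_plaques:
            raise ValueError("dense-cored plaques cannot exceed total plaques")
        if self.neuritic_plaques > self.total_plaques:
            raise ValueError("neuritic plaques cannot exceed total plaques")


@dataclass(frozen=True)
class PathologyScores:
    x_abeta: int
    x_tau: int
    rule_trace: str
    gap_flag: bool = False


def average_fields(fields: list[FieldCounts]) -> FieldCounts:
    """Arithmetic mean of per-field counts (the three-field average)."""
    if not fields:
        raise ValueError("at least one field is required")
    return FieldCounts(
        total_plaques=float(np.mean([f.total_plaques for f in fields])),
        dense_cored_plaques=float(np.mean([f.dense_cored_plaques for f in fields])),
        neuritic_plaques=float(np.mean([f.neuritic_plaques for f in fields])),
        mature_nfts=float(np.mean([f.mature_nfts for f in fields])),
    )


def _abeta_rules(c: FieldCounts) -> list[tuple[int, bool, str]]:
    return [
        (4, c.neuritic_plaques >= 15, ">=15 neuritic plaques"),
        (
            3,
            c.dense_cored_plaques >= 5 and c.neuritic_plaques >= 2,
            ">=5 dense-cored and >=2 neuritic plaques",
        ),
        (2, c.dense_cored_plaques >= 1, ">=1 dense-cored plaque"),
        (
            1,
            c.total_plaques >= 2 and c.dense_cored_plaques < 1,
            "<1 dense-cored but >=2 total plaques",
        ),
        (0, c.total_plaques < 1, "<1 plaque/mm^2"),
    ]


def score_abeta(counts: FieldCounts) -> int:
    """X_Abeta grade 0-4 (highest satisfied rule; gap cases score 0)."""
    for score, hit, _ in _abeta_rules(counts):
        if hit:
            return score
    return 0


def score_tau(counts: FieldCounts) -> int:
    """X_tau grade 0-4 from the mature-NFT density cutpoints."""
    return int(np.searchsorted(TAU_CUTPOINTS, counts.mature_nfts, side="right"))


def score_pathology(counts: FieldCounts) -> PathologyScores:
    """Both grades plus the fired rule and the boundary-gap flag."""
    x_tau = score_tau(counts)
    for score, hit, desc in _abeta_rules(counts):
        if hit:
            return PathologyScores(
                x_abeta=score,
                x_tau=x_tau,
                rule_trace=f"abeta[{score}]: {desc}; tau[{x_tau}]",
            )
    return PathologyScores(
        x_abeta=0,
        x_tau=x_tau,
        rule_trace=f"abeta[gap->0]; tau[{x_tau}]",
        gap_flag=True,
    )


def score_table(counts_table: pd.DataFrame) -> pd.DataFrame:
    """Score a counts CSV table.

    Expects columns case_id, field_id, total_plaques, dense_cored, neuritic,
    mature_nfts; fields are averaged per case before scoring.  Returns one row
    per case with x_abeta, x_tau, rule_trace, gap_flag.
    """
    rows = []
    for case_id, sub in counts_table.groupby("case_id", sort=True):
        fields = [
            FieldCounts(
                total_plaques=r.total_plaques,
                dense_cored_plaques=r.dense_cored,
                neuritic_plaques=r.neuritic,
                mature_nfts=r.mature_nfts,
            )
            for r in sub.itertuples()
        ]
        scores = score_pathology(average_fields(fields))
        rows.append(
            {
                "case_id": case_id,
                "x_abeta": scores.x_abeta,
                "x_tau": scores.x_tau,
                "rule_trace": scores.rule_trace,
                "gap_flag": scores.gap_flag,
            }
        )
    return pd.DataFrame(rows)
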