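"""Presence/absence calls for DNA methylation from bimodality descriptors.

Two rules are provided. The primary rule calls methylation *present* when
the distance ``d`` between the two component means is at or above a
threshold (default 0.25, chosen conservatively; 0.2 trades a few extra true
positives for a false positive, 0.3 only adds false negatives). The
alternative three-way rule of Provataris-style surveys classifies the
distribution as "bimodal depleted" (d > 0.25, low mean < 0.7, smaller
component holding > 10% of the data), "unimodal indicative" (low component
holding >= 36% of the data) or "unimodal not indicative".
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Optional

from .mixture import BimodalitySummary

Category = Literal["bimodal_depleted", "unimodal_indicative", "unimodal_not_indicative"]


@dataclass
class MethylationVerdict:
    """A species-level call with the rule and threshold that produced it."""

    species: str
    present: bool
    distance_d: float
    threshold: float
    rule: Literal["distance", "provataris"]
    category: Optional[Category] = None


def call_by_distance(
    summary: BimodalitySummary,
    threshold: float = 0.25,
    species: str = "",
) -> MethylationVerdict:
    """Present iff ``d >= threshold`` (the boundary counts as present)."""
    if threshold < 0:
        raise ValueError("threshold must be non-negative")
    return MethylationVerdict(
        species=species,
        present=summary.distance_d >= threshold,
        distance_d=summary.distance_d,
        threshold=threshold,
        rule="distance",
    )


def call_provataris(summary: BimodalitySummary, species: str = "") -> MethylationVerdict:
    """Three-way bimodality classification.

    bimodal_depleted: d > 0.25 and mean_low < 0.7 and the smaller component
    (min of the two weights) holds > 0.1 of the data. Otherwise
    unimodal_indicative when pct_low >= 0.36, else unimodal_not_indicative.
    Present = anything but unimodal_not_indicative.
    """
    d = summary.distance_d
    pct_low = summary.pct_low
    smaller = min(pct_low, 1.0 - pct_low)
    if d > 0.25 and summary.mean_low < 0.7 and smaller > 0.1:
        category: Category = "bimodal_depleted"
    elif pct_low >= 0.36:
        category = "unimodal_indicative"
    else:
        category = "unimodal_not_indicative"
    return MethylationVerdict(
        species=species,
        present=category != "unimodal_not_indicative",
        distance_d=d,
        threshold=0.25,
        rule="provataris",
        category=category,
    )
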