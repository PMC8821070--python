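"""Per-CDS CpG observed/expected ratios and distribution summaries.

The O/E CpG ratio of a CDS of length ``l`` with mononucleotide counts ``C``
and ``G`` and overlapping-dinucleotide count ``CG`` is

    O/E = (CG * l) / (C * G)

Values well below 1 mark historical CpG depletion, the mutational footprint
of germline methylation. A mononucleotide shuffle of each CDS destroys the
dinucleotide structure while preserving composition and length, and is the
negative control: shuffled data should be unimodal around O/E ~ 1.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import stats

from .io import CdsRecord

#: returned by :func:`oe_cpg` when C == 0 or G == 0 and the ratio is undefined
DEGENERATE = None


@dataclass
class OeCpgProfile:
    """A species' vector of per-CDS O/E CpG values plus exclusion counts."""

    species: str
    values: np.ndarray
    n_excluded_degenerate: int = 0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.size and not np.all(np.isfinite(self.values)):
            raise ValueError("O/E profile contains non-finite values")
        if self.values.size and np.any(self.values < 0):
            raise ValueError("O/E profile contains negative values")


@dataclass
class DistributionSummary:
    """Mean, sample sd (n-1) and adjusted Fisher–Pearson skewness."""

    mean: float
    sd: float | None
    skewness: float | None


def cpg_counts(seq: str) -> tuple[int, int, int]:
    """Return (C, G, CG) counts for a normalized sequence.

    ``CG`` is the overlapping scan of adjacent pairs. ``N`` contributes to
    neither the mononucleotide nor the dinucleotide counts, so masked bases
    never create or destroy a CpG.
    """
    c = seq.count("C")
    g = seq.count("G")
    cg = seq.count("CG")
    return c, g, cg


def oe_cpg(record: CdsRecord) -> float | None:
    """O/E CpG of one CDS, or :data:`DEGENERATE` (None) when C=0 or G=0."""
    c, g, cg = cpg_counts(record.seq)
    if c == 0 or g == 0:
        return DEGENERATE
    return (cg * record.length) / (c * g)


def oe_profile(records: Sequence[CdsRecord], species: str = "") -> OeCpgProfile:
    """Per-CDS O/E values for a filtered record set, in input order.

    Degenerate records are excluded from the value vector and tallied in
    ``n_excluded_degenerate``.
    """
    values: list[float] = []
    n_degenerate = 0
    for rec in records:
        v = oe_cpg(rec)
        if v is DEGENERATE:
            n_degenerate += 1
        else:
            values.append(v)
    if records and not values:
        warnings.warn(f"species {species!r}: all {len(records)} CDS are degenerate")
    return OeCpgProfile(
        species=species,
        values=np.array(values, dtype=float),
        n_excluded_degenerate=n_degenerate,
    )


def shuffle_mononucleotide(record: CdsRecord, seed: int) -> CdsRecord:
    """Uniform random permutation of the record's characters.

    Composition and length are exactly preserved; the permutation is a
    deterministic function of ``(seed, record.id, record.seq)`` so that whole
    species files can be shuffled reproducibly record by record.
    """
    # per-record stream: fold the record id into the seed so records of a
    # species file get independent permutations under one top-level seed
    rng = np.random.default_rng([seed, *record.id.encode()])
    chars = np.frombuffer(record.seq.encode(), dtype=np.uint8)
    shuffled = rng.permutation(chars)
    return CdsRecord(id=record.id, seq=shuffled.tobytes().decode(), length=record.length)


def summarize_distribution(profile: OeCpgProfile) -> DistributionSummary:
    """Mean, sample standard deviation and skewness of the O/E values.

    The sd uses the n-1 denominator and needs >= 2 values; the skewness is
    the adjusted Fisher–Pearson standardized third moment (bias-corrected
    g1) and needs >= 3 values and non-zero variance. Fields that cannot be
    computed are returned as None rather than raising.
    """
    x = profile.values
    n = x.size
    mean = float(np.mean(x)) if n else math.nan
    sd = float(np.std(x, ddof=1)) if n >= 2 else None
    skew: float | None = None
    if n >= 3 and sd is not None and sd > 0:
        skew = float(stats.skew(x, bias=False))
    return DistributionSummary(mean=mean, sd=sd, skewness=skew)


def write_cds_table(records: Sequence[CdsRecord], path) -> None:
    """Per-CDS TSV: cds_id, length, C, G, CG, oe_cpg ('NA' when degenerate)."""
    with open(path, "w") as fh:
        fh.write("cds_id\tlength\tC\tG\tCG\toe_cpg\n")
        for rec in records:
            c, g, cg = cpg_counts(rec.seq)
            v = oe_cpg(rec)
            val = "NA" if v is DEGENERATE else f"{v:.6f}"
            fh.write(f"{rec.id}\t{rec.length}\t{c}\t{g}\t{cg}\t{val}\n")
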