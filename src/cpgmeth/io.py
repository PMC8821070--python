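"""Coding-sequence FASTA input and inclusion filtering.

Records are normalized to the uppercase alphabet ``{A, C, G, T, N}``:
``U`` becomes ``T`` and every other IUPAC ambiguity code becomes ``N``,
so the downstream N-fraction filter and dinucleotide counting see a closed
alphabet. Filtering follows the standard inclusion rule for CpG O/E surveys:
drop CDS shorter than 100 nt or with more than 5% N.
"""

from __future__ import annotations

import gzip
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

from Bio import SeqIO

logger = logging.getLogger(__name__)

_VALID = frozenset("ACGTN")
# str.translate table: uppercase, U->T, other IUPAC ambiguity codes -> N
_NORMALIZE = {}
for _c in "ACGTN":
    _NORMALIZE[ord(_c)] = _c
    _NORMALIZE[ord(_c.lower())] = _c
for _c in "Uu":
    _NORMALIZE[ord(_c)] = "T"
for _c in "RYSWKMBDHVryswkmbdhv":
    _NORMALIZE[ord(_c)] = "N"


@dataclass(frozen=True)
class CdsRecord:
    """One coding sequence: FASTA id, normalized sequence, length in nt."""

    id: str
    seq: str
    length: int

    def __post_init__(self) -> None:
        if self.length != len(self.seq):
            raise ValueError(
                f"record {self.id!r}: length {self.length} != len(seq) {len(self.seq)}"
            )
        bad = set(self.seq) - _VALID
        if bad:
            raise ValueError(f"record {self.id!r}: invalid characters {sorted(bad)}")


@dataclass
class FilterReport:
    """Tally of kept/excluded CDS, one counter per exclusion reason."""

    n_input: int = 0
    n_kept: int = 0
    n_too_short: int = 0
    n_too_many_n: int = 0
    n_degenerate: int = 0

    def as_dict(self) -> dict:
        return {
            "n_input": self.n_input,
            "n_kept": self.n_kept,
            "n_too_short": self.n_too_short,
            "n_too_many_n": self.n_too_many_n,
            "n_degenerate": self.n_degenerate,
        }


def normalize_sequence(seq: str) -> str:
    """Uppercase, map U->T and non-N ambiguity codes to N.

    Raises ``ValueError`` on characters outside the IUPAC nucleotide codes.
    """
    out = seq.translate(_NORMALIZE)
    bad = set(out) - _VALID
    if bad:
        raise ValueError(f"non-nucleotide characters in sequence: {sorted(bad)}")
    return out


def read_cds_fasta(path: str | Path) -> list[CdsRecord]:
    """Read a (plain or gzip-compressed) CDS FASTA file.

    Returns one :class:`CdsRecord` per entry, normalized. Entries with an
    empty sequence are skipped with a warning; an empty file yields an empty
    list with a warning.
    """
    path = Path(path)
    opener = gzip.open if path.suffix == ".gz" else open
    records: list[CdsRecord] = []
    with opener(path, "rt") as handle:
        for entry in SeqIO.parse(handle, "fasta"):
            seq = normalize_sequence(str(entry.seq))
            if not seq:
                warnings.warn(f"skipping empty-sequence record {entry.id!r} in {path}")
                continue
            records.append(CdsRecord(id=entry.id, seq=seq, length=len(seq)))
    if not records:
        warnings.warn(f"no sequence records read from {path}")
    return records


def filter_cds(
    records: Sequence[CdsRecord],
    min_length: int = 100,
    max_n_fraction: float = 0.05,
) -> tuple[list[CdsRecord], FilterReport]:
    """Apply the inclusion filters for O/E CpG analysis.

    A record is kept iff ``length >= min_length`` (so "shorter than 100 nt"
    is excluded, exactly 100 nt is kept) and its N fraction is
    ``<= max_n_fraction`` (so exactly 5% N is kept, more is excluded).
    Order is preserved; each exclusion reason is tallied in the report.
    Degenerate records (no C or no G) are *not* removed here — the O/E
    computation marks them — but the report field exists so callers can
    merge both tallies.
    """
    report = FilterReport(n_input=len(records))
    kept: list[CdsRecord] = []
    for rec in records:
        if rec.length < min_length:
            report.n_too_short += 1
            continue
        if rec.seq.count("N") / rec.length > max_n_fraction:
            report.n_too_many_n += 1
            continue
        kept.append(rec)
    report.n_kept = len(kept)
    logger.info(
        "filter_cds: kept %d/%d (too_short=%d, too_many_n=%d)",
        report.n_kept,
        report.n_input,
        report.n_too_short,
        report.n_too_many_n,
    )
    return kept, report


def write_fasta(records: Iterable[CdsRecord], path: str | Path, width: int = 70) -> None:
    """Write records as plain FASTA with fixed line width."""
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f">{rec.id}\n")
            for i in range(0, rec.length, width):
                fh.write(rec.seq[i : i + width] + "\n")


def write_filter_report(report: FilterReport, path: str | Path) -> None:
    """Write the filter report as a two-column TSV (reason, count)."""
    with open(path, "w") as fh:
        fh.write("reason\tcount\n")
        for key, val in report.as_dict().items():
            fh.write(f"{key}\t{val}\n")
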