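"""DNMT family classification from Pfam domain architecture.

DNA methyltransferases are distinguished by the regulatory domains flanking
the shared catalytic DNA_methylase (PF00145) domain: DNMT1 (maintenance)
carries DNMT1-RFD, zf-CXXC and BAH; DNMT3 (de novo) carries PWWP and
ADD; DNMT2 (a tRNA methyltransferase) carries the catalytic domain alone.

The input is HMMER3 per-domain tabular output (``--domtblout`` of
``hmmsearch`` run with the Pfam models against a predicted proteome).
Candidate selection requires a DNA_methylase hit with full-sequence
e-value < 0.001; the candidate's architecture is then the union of all its
annotated domains among the eight models, and a small rule system maps the
architecture to a class and a full/partial completeness level.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal, Mapping, Sequence

#: the eight Pfam models annotated on DNMT candidates
DOMAIN_PFAM: dict[str, str] = {
    "DNA_methylase": "PF00145",
    "ADD_DNMT3": "PF17980",
    "PWWP": "PF00855",
    "BAH": "PF01426",
    "DMAP_binding": "PF06464",
    "DNMT1_RFD": "PF12047",
    "zf_CXXC": "PF02008",
    "CH": "PF00307",
}

# model names as they appear in Pfam/HMMER output -> canonical names above
_NAME_ALIASES = {
    "DNMT1-RFD": "DNMT1_RFD",
    "zf-CXXC": "zf_CXXC",
}

#: domains diagnostic for DNMT1 (S1) and DNMT3 (S3)
DNMT1_DOMAINS = frozenset({"DNMT1_RFD", "zf_CXXC", "BAH"})
DNMT3_DOMAINS = frozenset({"PWWP", "ADD_DNMT3"})

DnmtClass = Literal["DNMT1", "DNMT2", "DNMT3", "ambiguous", "none"]
Completeness = Literal["full", "partial", "not_applicable"]


@dataclass(frozen=True)
class DomainHit:
    """One row of a domtblout file: a domain model hit on a protein."""

    protein_id: str
    domain_name: str
    pfam_acc: str
    full_seq_evalue: float
    domain_ievalue: float
    env_start: int
    env_end: int
    known: bool = True

    def __post_init__(self) -> None:
        if self.env_start > self.env_end:
            raise ValueError(
                f"{self.protein_id}/{self.domain_name}: env_start > env_end"
            )
        if self.full_seq_evalue < 0 or self.domain_ievalue < 0:
            raise ValueError("e-values must be positive")


@dataclass
class DnmtCall:
    """Per-protein classification with completeness and supporting domains."""

    protein_id: str
    dnmt_class: DnmtClass
    completeness: Completeness
    domains_present: frozenset[str]
    flags: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        in13 = self.dnmt_class in ("DNMT1", "DNMT3")
        if in13 and self.completeness not in ("full", "partial"):
            raise ValueError("DNMT1/3 calls need full or partial completeness")
        if not in13 and self.completeness != "not_applicable":
            raise ValueError("completeness only applies to DNMT1/3")

    @property
    def needs_review(self) -> bool:
        return "needs_review" in self.flags


def parse_domtblout(path: str | Path) -> list[DomainHit]:
    """Parse a HMMER3 per-domain tabular (``--domtblout``) file.

    Layout: whitespace-delimited, 22 fixed columns plus free-text
    description, '#' comment lines. For ``hmmsearch`` the target (column 1)
    is the protein and the query (column 4) the Pfam model. Models outside
    the eight-domain set are kept but flagged ``known=False``. Malformed
    rows raise with the offending line number.
    """
    hits: list[DomainHit] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.split()
            if len(fields) < 22:
                raise ValueError(
                    f"{path}:{lineno}: expected >=22 domtblout columns, got {len(fields)}"
                )
            name = _NAME_ALIASES.get(fields[3], fields[3])
            try:
                hit = DomainHit(
                    protein_id=fields[0],
                    domain_name=name,
                    pfam_acc=fields[4].split(".")[0],
                    full_seq_evalue=float(fields[6]),
                    domain_ievalue=float(fields[12]),
                    env_start=int(fields[19]),
                    env_end=int(fields[20]),
                    known=name in DOMAIN_PFAM,
                )
            except (ValueError, IndexError) as exc:
                raise ValueError(f"{path}:{lineno}: malformed domtblout row: {exc}") from exc
            hits.append(hit)
    return hits


def select_candidates(
    hits: Sequence[DomainHit],
    evalue_cutoff: float = 0.001,
) -> dict[str, frozenset[str]]:
    """Map DNMT candidate proteins to their annotated domain architecture.

    A protein is a candidate iff it has at least one DNA_methylase hit with
    full-sequence e-value strictly below the cutoff. For candidates the
    architecture is the union of all its known domain names at any e-value
    (the cutoff gates candidacy only, matching how the accessory domains
    are annotated after the catalytic-domain screen).
    """
    candidates = {
        h.protein_id
        for h in hits
        if h.domain_name == "DNA_methylase" and h.full_seq_evalue < evalue_cutoff
    }
    out: dict[str, set[str]] = {p: set() for p in candidates}
    for h in hits:
        if h.protein_id in candidates and h.known:
            out[h.protein_id].add(h.domain_name)
    return {p: frozenset(s) for p, s in out.items()}


def classify_dnmt(domains: Iterable[str], protein_id: str = "") -> DnmtCall:
    """Classify one candidate's domain architecture into a DNMT family.

    Requires DNA_methylase in ``domains``. With S1 the DNMT1-diagnostic
    domains present and S3 the DNMT3-diagnostic ones:

    * S3 empty, all three of S1      -> DNMT1 full
    * S3 empty, one or two of S1     -> DNMT1 partial
    * S1 empty, both of S3           -> DNMT3 full
    * S1 empty, one of S3            -> DNMT3 partial
    * only DNA_methylase             -> DNMT2
    * S1 and S3 both non-empty       -> ambiguous (flagged needs_review)
    * no diagnostic domain but extra DMAP_binding/CH -> DNMT2, flagged
      extra_domain (surfaced for manual review rather than discarded)
    """
    dset = frozenset(domains)
    if "DNA_methylase" not in dset:
        raise ValueError(f"protein {protein_id!r}: not a candidate (no DNA_methylase)")
    s1 = dset & DNMT1_DOMAINS
    s3 = dset & DNMT3_DOMAINS
    if s1 and s3:
        return DnmtCall(protein_id, "ambiguous", "not_applicable", dset, ("needs_review",))
    if not s3 and len(s1) == 3:
        return DnmtCall(protein_id, "DNMT1", "full", dset)
    if not s3 and 1 <= len(s1) <= 2:
        return DnmtCall(protein_id, "DNMT1", "partial", dset)
    if not s1 and len(s3) == 2:
        return DnmtCall(protein_id, "DNMT3", "full", dset)
    if not s1 and len(s3) == 1:
        return DnmtCall(protein_id, "DNMT3", "partial", dset)
    # S1 and S3 both empty from here on
    if dset == {"DNA_methylase"}:
        return DnmtCall(protein_id, "DNMT2", "not_applicable", dset)
    return DnmtCall(protein_id, "DNMT2", "not_applicable", dset, ("extra_domain",))


def classify_file(path: str | Path, evalue_cutoff: float = 0.001) -> list[DnmtCall]:
    """Parse a domtblout file and classify every candidate protein."""
    hits = parse_domtblout(path)
    arch = select_candidates(hits, evalue_cutoff=evalue_cutoff)
    return [classify_dnmt(dset, protein_id=pid) for pid, dset in sorted(arch.items())]


def presence_summary(calls: Sequence[DnmtCall]) -> dict[str, str]:
    """Species-level presence of each family: present_full/present_partial/absent."""
    out: dict[str, str] = {}
    for family in ("DNMT1", "DNMT2", "DNMT3"):
        members = [c for c in calls if c.dnmt_class == family]
        if not members:
            out[family] = "absent"
        elif family == "DNMT2":
            out[family] = "present"
        elif any(c.completeness == "full" for c in members):
            out[family] = "present_full"
        else:
            out[family] = "present_partial"
    return out


def write_calls_tsv(calls: Sequence[DnmtCall], path: str | Path) -> None:
    """Per-protein TSV: protein_id, class, completeness, domains, flags."""
    with open(path, "w") as fh:
        fh.write("protein_id\tdnmt_class\tcompleteness\tdomains_present\tflags\n")
        for c in calls:
            doms = ",".join(sorted(c.domains_present))
            flags = ",".join(c.flags)
            fh.write(f"{c.protein_id}\t{c.dnmt_class}\t{c.completeness}\t{doms}\t{flags}\n")
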