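"""Synthetic data with known ground truth.

Two generators back the test strategy:

* CDS sets drawn from a first-order Markov chain over {A,C,G,T} whose
  stationary composition matches a requested GC content and whose C->G
  transition probability is tuned so the asymptotic O/E CpG of a long
  sequence equals a requested target. O/E CpG is a function of mono- and
  dinucleotide frequencies only, so the chain gives an analytic handle on
  the statistic: mixing two target values across a record set emulates the
  methylated/unmethylated two-class structure that the mixture model is
  meant to recover.

* HMMER3 ``domtblout`` tables whose parse -> candidate selection ->
  classification round trip reproduces a requested set of DNMT calls,
  with distractor rows (sub-threshold e-values, unknown models) mixed in.

Construction of the transition matrix. Let ``pi`` be the target stationary
distribution (C and G each gc/2, A and T each (1-gc)/2) and ``t`` the target
O/E. Set ``P(G|C) = t * pi_G``. For the other rows set ``P(G|x) = g`` with
``g = pi_G (1 - t pi_C) / (1 - pi_C)`` so that the G column averages to
``pi_G`` under ``pi``; each row's remaining mass is spread over A, C, T
proportionally to ``pi``. Then ``pi`` is exactly stationary and the long-run
dinucleotide frequency gives ``f_CG / (f_C f_G) = t`` exactly.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .dnmt import DOMAIN_PFAM, DNMT1_DOMAINS, DNMT3_DOMAINS
from .io import CdsRecord

_ALPHABET = np.frombuffer(b"ACGT", dtype=np.uint8)
_IDX = {"A": 0, "C": 1, "G": 2, "T": 3}


@dataclass
class MixtureSpec:
    """Parameters of a synthetic two-class CDS set.

    Defaults emulate an invertebrate species with gene-body methylation:
    a balanced split between a depleted class at O/E 0.6 and an
    unmethylated class at O/E 1.0, GC content 0.42, and transcript lengths
    from a shifted geometric distribution (mean 1500 nt, floor 300 nt).
    """

    n_cds: int = 5000
    frac_low: float = 0.5
    oe_low: float = 0.6
    oe_high: float = 1.0
    gc_content: float = 0.42
    length_mean: int = 1500
    length_min: int = 300
    n_fraction: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.frac_low <= 1.0:
            raise ValueError("frac_low must be in [0, 1]")
        if self.oe_low > self.oe_high:
            raise ValueError("oe_low must not exceed oe_high")
        if not 0.0 < self.gc_content < 1.0:
            raise ValueError("gc_content must be in (0, 1)")
        if self.length_min < 1 or self.length_mean < self.length_min:
            raise ValueError("need length_mean >= length_min >= 1")
        if self.n_fraction < 0:
            raise ValueError("n_fraction must be >= 0")


def stationary_distribution(gc_content: float) -> np.ndarray:
    """Target base frequencies in A, C, G, T order."""
    at = (1.0 - gc_content) / 2.0
    gc = gc_content / 2.0
    return np.array([at, gc, gc, at])


def transition_matrix(target_oe: float, gc_content: float) -> np.ndarray:
    """First-order transition matrix with the documented closed form.

    Raises on infeasible targets (any probability outside [0, 1]).
    """
    if target_oe < 0:
        raise ValueError("target_oe must be non-negative")
    pi = stationary_distribution(gc_content)
    pi_c, pi_g = pi[1], pi[2]
    p_g_from_c = target_oe * pi_g
    g_other = pi_g * (1.0 - target_oe * pi_c) / (1.0 - pi_c)
    if not (0.0 <= p_g_from_c <= 1.0 and 0.0 <= g_other <= 1.0):
        raise ValueError(
            f"target_oe={target_oe} infeasible at gc_content={gc_content}"
        )
    P = np.empty((4, 4))
    for x in range(4):
        pg = p_g_from_c if x == _IDX["C"] else g_other
        P[x, 2] = pg
        rest = (1.0 - pg) / (1.0 - pi_g)
        for y in (0, 1, 3):
            P[x, y] = pi[y] * rest
    if np.any(P < 0) or np.any(P > 1):
        raise ValueError("infeasible target_oe/gc_content combination")
    return P


def expected_oe(target_oe: float, gc_content: float) -> float:
    """Asymptotic O/E of the constructed chain, by direct computation.

    Recomputes ``f_CG / (f_C * f_G)`` from the matrix's true stationary
    vector (left eigenvector) rather than trusting the construction; used
    as the generator's self-check and by the tests.
    """
    P = transition_matrix(target_oe, gc_content)
    vals, vecs = np.linalg.eig(P.T)
    k = int(np.argmin(np.abs(vals - 1.0)))
    pi = np.real(vecs[:, k])
    pi = pi / pi.sum()
    f_cg = pi[1] * P[1, 2]
    return float(f_cg / (pi[1] * pi[2]))


def _sample_batch(
    lengths: np.ndarray, P: np.ndarray, pi: np.ndarray, rng: np.random.Generator
) -> list[str]:
    """Sample one Markov sequence per entry of ``lengths``, vectorized
    across sequences position by position."""
    n = lengths.size
    if n == 0:
        return []
    max_len = int(lengths.max())
    cum = np.cumsum(P, axis=1)
    cum[:, -1] = 1.0
    out = np.zeros((n, max_len), dtype=np.int8)
    state = (rng.random(n)[:, None] > np.cumsum(pi)[None, :3]).sum(axis=1)
    out[:, 0] = state
    for pos in range(1, max_len):
        u = rng.random(n)
        state = (u[:, None] > cum[state, :3]).sum(axis=1)
        out[:, pos] = state
    seqs = []
    for i in range(n):
        seqs.append(_ALPHABET[out[i, : lengths[i]]].tobytes().decode())
    return seqs


def generate_cds(
    target_oe: float,
    gc_content: float,
    length: int,
    seed: int,
    record_id: str = "synthetic_cds",
) -> CdsRecord:
    """One synthetic CDS from the constructed chain; seed-deterministic."""
    rng = np.random.default_rng(seed)
    P = transition_matrix(target_oe, gc_content)
    pi = stationary_distribution(gc_content)
    seq = _sample_batch(np.array([length]), P, pi, rng)[0]
    return CdsRecord(id=record_id, seq=seq, length=length)


def generate_mixture(spec: MixtureSpec) -> tuple[list[CdsRecord], np.ndarray]:
    """A two-class synthetic CDS set with its ground-truth labels.

    Each CDS is independently assigned to the depleted (low O/E) class with
    probability ``frac_low``; lengths are ``length_min`` plus a geometric
    draw with overall mean ``length_mean``; N characters are injected
    i.i.d. at rate ``n_fraction``. Returns the records and a 0/1 label
    vector (1 = low/depleted class).
    """
    rng = np.random.default_rng(spec.seed)
    labels = (rng.random(spec.n_cds) < spec.frac_low).astype(int)
    if spec.length_mean == spec.length_min:
        lengths = np.full(spec.n_cds, spec.length_min)
    else:
        p = 1.0 / (spec.length_mean - spec.length_min + 1)
        lengths = spec.length_min + rng.geometric(p, size=spec.n_cds) - 1
    pi = stationary_distribution(spec.gc_content)

    seqs: list[str | None] = [None] * spec.n_cds
    for label, target in ((1, spec.oe_low), (0, spec.oe_high)):
        idx = np.flatnonzero(labels == label)
        P = transition_matrix(target, spec.gc_content)
        for i, s in zip(idx, _sample_batch(lengths[idx], P, pi, rng)):
            seqs[i] = s

    records = []
    for i in range(spec.n_cds):
        seq = seqs[i]
        if spec.n_fraction > 0:
            arr = np.frombuffer(seq.encode(), dtype=np.uint8).copy()
            mask = rng.random(arr.size) < spec.n_fraction
            arr[mask] = ord("N")
            seq = arr.tobytes().decode()
        records.append(CdsRecord(id=f"cds_{i:05d}", seq=seq, length=int(lengths[i])))
    return records, labels


# ---------------------------------------------------------------------------
# synthetic domtblout tables

_ACHIEVABLE = {
    ("DNMT1", "full"),
    ("DNMT1", "partial"),
    ("DNMT3", "full"),
    ("DNMT3", "partial"),
    ("DNMT2", "not_applicable"),
    ("ambiguous", "not_applicable"),
    ("none", "not_applicable"),
}


def _domains_for_class(
    dnmt_class: str, completeness: str, rng: np.random.Generator
) -> set[str]:
    s1 = sorted(DNMT1_DOMAINS)
    s3 = sorted(DNMT3_DOMAINS)
    if dnmt_class == "DNMT1":
        if completeness == "full":
            return {"DNA_methylase", *s1}
        k = int(rng.integers(1, 3))  # one or two diagnostic domains
        return {"DNA_methylase", *rng.choice(s1, size=k, replace=False)}
    if dnmt_class == "DNMT3":
        if completeness == "full":
            return {"DNA_methylase", *s3}
        return {"DNA_methylase", str(rng.choice(s3))}
    if dnmt_class == "DNMT2":
        return {"DNA_methylase"}
    if dnmt_class == "ambiguous":
        return {"DNA_methylase", str(rng.choice(s1)), str(rng.choice(s3))}
    raise AssertionError(dnmt_class)


def _domtbl_row(
    protein: str,
    model: str,
    acc: str,
    full_evalue: float,
    rng: np.random.Generator,
    tlen: int = 900,
) -> str:
    qlen = int(rng.integers(80, 300))
    start = int(rng.integers(1, tlen - qlen))
    end = start + qlen - 1
    score = float(rng.uniform(20, 300))
    fields = [
        protein, "-", str(tlen), model, acc, str(qlen),
        f"{full_evalue:.2g}", f"{score:.1f}", "0.1",
        "1", "1", f"{full_evalue:.2g}", f"{full_evalue:.2g}",
        f"{score:.1f}", "0.1",
        "1", str(qlen), str(start), str(end), str(start), str(end),
        "0.95", "synthetic protein",
    ]
    return " ".join(fields) + "\n"


def generate_domtblout(
    classes: Mapping[str, tuple[str, str]],
    path: str | Path,
    seed: int,
    n_distractors: int = 3,
) -> dict[str, set[str]]:
    """Write a synthetic HMMER3 domtblout realizing the requested calls.

    ``classes`` maps protein ids to ``(dnmt_class, completeness)``; use
    completeness ``"not_applicable"`` for DNMT2/ambiguous, and class
    ``"none"`` for a protein whose only catalytic-domain hit is
    sub-threshold (so it must not become a candidate). Unachievable
    requests (e.g. DNMT2 full) raise. Distractor rows — unknown models and
    sub-threshold hits — are interleaved. Returns the domain architecture
    written per protein (the generation manifest).
    """
    rng = np.random.default_rng(seed)
    lines = [
        "#                                                               --- full sequence --- -------------- this domain -------------   hmm coord   ali coord   env coord\n",
        "# target name        accession   tlen query name           accession   qlen   E-value  score  bias   #  of  c-Evalue  i-Evalue  score  bias  from    to  from    to  from    to  acc description of target\n",
        "#------------------- ---------- ----- -------------------- ---------- ----- --------- ------ ----- --- --- --------- --------- ------ ----- ----- ----- ----- ----- ----- ----- ---- ---------------------\n",
    ]
    manifest: dict[str, set[str]] = {}
    for protein, (dnmt_class, completeness) in classes.items():
        if (dnmt_class, completeness) not in _ACHIEVABLE:
            raise ValueError(
                f"unachievable request for {protein!r}: ({dnmt_class}, {completeness})"
            )
        if dnmt_class == "none":
            # catalytic hit present but above the candidacy cutoff
            lines.append(
                _domtbl_row(protein, "DNA_methylase", DOMAIN_PFAM["DNA_methylase"],
                            float(rng.uniform(0.01, 1.0)), rng)
            )
            manifest[protein] = set()
            continue
        domains = _domains_for_class(dnmt_class, completeness, rng)
        manifest[protein] = domains
        for dom in sorted(domains):
            ev = 10.0 ** float(rng.uniform(-60, -10)) if dom == "DNA_methylase" \
                else 10.0 ** float(rng.uniform(-30, -4))
            acc = DOMAIN_PFAM[dom] + ".1"
            # emit the hyphenated model names HMMER/Pfam actually print
            model = {"DNMT1_RFD": "DNMT1-RFD", "zf_CXXC": "zf-CXXC"}.get(dom, dom)
            lines.append(_domtbl_row(protein, model, acc, ev, rng))
    for i in range(n_distractors):
        lines.append(
            _domtbl_row(f"unrelated_{i}", "WD40", "PF00400.2",
                        10.0 ** float(rng.uniform(-20, -3)), rng)
        )
    order = rng.permutation(len(lines) - 3)
    body = [lines[3 + k] for k in order]
    with open(path, "w") as fh:
        fh.writelines(lines[:3])
        fh.writelines(body)
        fh.write("#\n# Program:         hmmsearch\n")
    return manifest
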