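"""Nucleotide primitives and guide/PAM matching rules.

These are the sequence-level rules of the off-target screen: Hamming
mismatch counting over the protospacer, degenerate-PAM matching (NGG for
design, NRG for attribution), the PAM-proximal seed test, and the blunt
cleavage-site prediction 3 bp upstream of the PAM.

Coordinates are 1-based inclusive throughout (VCF convention).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import pandas as pd

from .errors import AlphabetError, ContractError

ALPHABET = frozenset("ACGTN")
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

#: IUPAC nucleotide codes -> the set of concrete bases they stand for.
IUPAC_CODES: dict[str, frozenset[str]] = {
    "A": frozenset("A"),
    "C": frozenset("C"),
    "G": frozenset("G"),
    "T": frozenset("T"),
    "R": frozenset("AG"),
    "Y": frozenset("CT"),
    "S": frozenset("CG"),
    "W": frozenset("AT"),
    "K": frozenset("GT"),
    "M": frozenset("AC"),
    "B": frozenset("CGT"),
    "D": frozenset("AGT"),
    "H": frozenset("ACT"),
    "V": frozenset("ACG"),
    "N": frozenset("ACGT"),
}

#: Default seed length: the PAM-proximal stretch where mismatches abolish cleavage.
SEED_LEN = 10


def clean_sequence(bases: str) -> str:
    """Uppercase and validate a nucleotide string over {A,C,G,T,N}."""
    seq = str(bases).upper()
    if not seq:
        raise AlphabetError("empty sequence")
    bad = set(seq) - ALPHABET
    if bad:
        raise AlphabetError(f"invalid symbols {sorted(bad)} in sequence")
    return seq


def revcomp(seq: str) -> str:
    """Reverse complement; N maps to N.

    Raises :class:`AlphabetError` on symbols outside {A,C,G,T,N}.
    """
    seq = clean_sequence(seq)
    return seq.translate(_COMPLEMENT)[::-1]


def base_matches(base: str, code: str) -> bool:
    """True iff a genomic base satisfies an IUPAC pattern code.

    A genomic ``N`` (unknown base) never matches any code, including ``N``:
    ambiguous reference sequence must not create an attribution.
    """
    if base not in ALPHABET:
        raise AlphabetError(f"invalid genomic base {base!r}")
    if code not in IUPAC_CODES:
        raise AlphabetError(f"invalid IUPAC code {code!r}")
    if base == "N":
        return False
    return base in IUPAC_CODES[code]


@dataclass(frozen=True)
class PamPattern:
    """A PAM expressed in IUPAC codes, e.g. NGG (design) or NRG (attribution)."""

    codes: str

    def __post_init__(self) -> None:
        codes = str(self.codes).upper()
        if not codes:
            raise AlphabetError("empty PAM pattern")
        bad = set(codes) - set(IUPAC_CODES)
        if bad:
            raise AlphabetError(f"invalid IUPAC codes {sorted(bad)} in PAM pattern")
        object.__setattr__(self, "codes", codes)

    def __len__(self) -> int:
        return len(self.codes)

    def __str__(self) -> str:
        return self.codes


def as_pattern(pattern: "PamPattern | str") -> PamPattern:
    return pattern if isinstance(pattern, PamPattern) else PamPattern(str(pattern))


@dataclass(frozen=True)
class GuideRNA:
    """A single-guide RNA: protospacer plus PAM conventions and cut offset.

    Parameters
    ----------
    name:
        Guide label (e.g. ``gRHAG``).
    protospacer:
        The 5'->3' protospacer sequence, PAM-distal first (default length 20).
    pam_design:
        IUPAC PAM required for on-target cleavage by SpCas9 (NGG).
    pam_attribution:
        Relaxed IUPAC PAM used when attributing off-target mutations (NRG).
    cut_offset:
        Blunt-cut position, bp 5' of the PAM (3 for SpCas9).
    target_gene:
        Gene the guide was designed against (e.g. ``RHAG``).
    """

    name: str
    protospacer: str
    pam_design: PamPattern = field(default_factory=lambda: PamPattern("NGG"))
    pam_attribution: PamPattern = field(default_factory=lambda: PamPattern("NRG"))
    cut_offset: int = 3
    target_gene: str = ""

    def __post_init__(self) -> None:
        proto = clean_sequence(self.protospacer)
        if "N" in proto:
            raise AlphabetError("protospacer must be unambiguous (A/C/G/T)")
        if len(proto) < SEED_LEN:
            raise ContractError(
                f"protospacer length {len(proto)} shorter than seed length {SEED_LEN}"
            )
        if not 0 < self.cut_offset < len(proto):
            raise ContractError(
                f"cut_offset {self.cut_offset} outside (0, {len(proto)})"
            )
        object.__setattr__(self, "protospacer", proto)
        object.__setattr__(self, "pam_design", as_pattern(self.pam_design))
        object.__setattr__(self, "pam_attribution", as_pattern(self.pam_attribution))

    @property
    def length(self) -> int:
        return len(self.protospacer)


@dataclass(frozen=True)
class SiteMatch:
    """One candidate gRNA alignment inside a flank window.

    ``protospacer_start`` is the 1-based offset of the protospacer within the
    window *read in the guide's orientation* (the reverse complement of the
    window for minus-strand matches). ``predicted_cut`` is the 1-based
    reference coordinate of the base on the PAM-distal side of the blunt-cut
    bond.
    """

    window_id: str
    strand: str
    protospacer_start: int
    observed_protospacer: str
    observed_pam: str
    mismatch_count: int
    pam_ok: bool
    seed_ok: bool
    predicted_cut: int


def count_protospacer_mismatches(site: str, guide: GuideRNA) -> int:
    """Gapless Hamming distance over the protospacer positions.

    Genomic ``N`` counts as a mismatch (the guide is unambiguous, so plain
    inequality realises that rule).
    """
    site = clean_sequence(site)
    if len(site) != guide.length:
        raise ContractError(
            f"site length {len(site)} != protospacer length {guide.length}"
        )
    return sum(a != b for a, b in zip(site, guide.protospacer))


def pam_matches(pam: str, pattern: "PamPattern | str") -> bool:
    """True iff every PAM position satisfies its IUPAC code."""
    pam = clean_sequence(pam)
    pattern = as_pattern(pattern)
    if len(pam) != len(pattern):
        raise ContractError(f"PAM length {len(pam)} != pattern length {len(pattern)}")
    return all(base_matches(b, c) for b, c in zip(pam, pattern.codes))


def seed_match(site: str, guide: GuideRNA, seed_len: int = SEED_LEN) -> bool:
    """True iff the PAM-proximal ``seed_len`` bases match the guide exactly."""
    site = clean_sequence(site)
    if len(site) != guide.length:
        raise ContractError(
            f"site length {len(site)} != protospacer length {guide.length}"
        )
    if seed_len > guide.length:
        raise ContractError(f"seed_len {seed_len} > protospacer length {guide.length}")
    if seed_len == 0:
        return True
    if "N" in site[-seed_len:]:
        return False
    return site[-seed_len:] == guide.protospacer[-seed_len:]


def cut_coordinate(span_start: int, strand: str, length: int, cut_offset: int) -> int:
    """Reference coordinate of the blunt cut for a protospacer+PAM site.

    ``span_start`` is the leftmost 1-based reference coordinate of the full
    protospacer+PAM span (length ``length + 3``). The cut bond lies
    ``cut_offset`` bp 5' of the PAM; the returned coordinate is the base on the
    PAM-distal side of that bond, which for ``cut_offset`` 0 degenerates to the
    last protospacer base.
    """
    if strand not in "+-":
        raise ContractError(f"invalid strand {strand!r}")
    if not 0 <= cut_offset < length:
        raise ContractError(f"cut_offset {cut_offset} outside [0, {length})")
    if strand == "+":
        return span_start + length - 1 - cut_offset
    return span_start + 3 + cut_offset


def predicted_cut_position(match_start: int, strand: str, guide: GuideRNA) -> int:
    """Cut coordinate for a match whose full span starts at ``match_start``.

    On the plus strand the span start coincides with the protospacer start
    (PAM to the right); on the minus strand the PAM occupies the three
    leftmost reference bases of the span.
    """
    return cut_coordinate(match_start, strand, guide.length, guide.cut_offset)


GUIDE_COLUMNS = ["name", "protospacer", "pam_design", "target_gene", "cut_offset"]


def load_guides(path: "str | Path") -> list[GuideRNA]:
    """Read guides from TSV (columns: name, protospacer, pam_design,
    target_gene, optional cut_offset). Sequences are validated on load."""
    frame = pd.read_csv(path, sep="\t", dtype=str)
    required = {"name", "protospacer"}
    missing = required - set(frame.columns)
    if missing:
        raise ContractError(f"guide TSV missing columns {sorted(missing)}")
    guides = []
    for row in frame.itertuples(index=False):
        kwargs: dict = {"name": row.name, "protospacer": row.protospacer}
        if "pam_design" in frame.columns and pd.notna(row.pam_design):
            kwargs["pam_design"] = PamPattern(row.pam_design)
        if "target_gene" in frame.columns and pd.notna(row.target_gene):
            kwargs["target_gene"] = row.target_gene
        if "cut_offset" in frame.columns and pd.notna(row.cut_offset):
            kwargs["cut_offset"] = int(row.cut_offset)
        guides.append(GuideRNA(**kwargs))
    return guides


def write_guides(guides: Iterable[GuideRNA], path: "str | Path") -> None:
    rows = [
        {
            "name": g.name,
            "protospacer": g.protospacer,
            "pam_design": str(g.pam_design),
            "target_gene": g.target_gene,
            "cut_offset": g.cut_offset,
        }
        for g in guides
    ]
    pd.DataFrame(rows, columns=GUIDE_COLUMNS).to_csv(path, sep="\t", index=False)
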