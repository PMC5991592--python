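"""Variant records, normalization and VCF input/output.

Variants are VCF-style (1-based, explicit REF/ALT strings). Normalization is
the standard parsimony + left-alignment procedure: shared suffixes are
trimmed (extending left through the reference when an allele would empty),
then shared prefixes are trimmed. Edited-vs-parent somatic differencing
compares normalized records by exact (chrom, pos, ref, alt) key.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import pysam

from .errors import ContractError, DataError
from .sequence import clean_sequence


def fetch(reference: Mapping[str, str], chrom: str, start: int, end: int) -> str:
    """1-based inclusive slice of a contig from a dict-like or pyfaidx Fasta."""
    try:
        contig = reference[chrom]
    except KeyError as exc:
        raise DataError(f"contig {chrom!r} absent from reference") from exc
    seq = contig[start - 1 : end]
    return str(seq).upper()


def contig_length(reference: Mapping[str, str], chrom: str) -> int:
    try:
        return len(reference[chrom])
    except KeyError as exc:
        raise DataError(f"contig {chrom!r} absent from reference") from exc


@dataclass(frozen=True, order=True)
class Variant:
    """A normalized-comparable SNV/indel record (1-based anchor coordinate)."""

    chrom: str
    pos: int
    ref: str
    alt: str

    def __post_init__(self) -> None:
        object.__setattr__(self, "ref", clean_sequence(self.ref))
        object.__setattr__(self, "alt", clean_sequence(self.alt))
        if self.ref == self.alt:
            raise ContractError(f"ref == alt ({self.ref!r}) at {self.chrom}:{self.pos}")
        if self.pos < 1:
            raise ContractError(f"position {self.pos} < 1")

    @property
    def vclass(self) -> str:
        if len(self.ref) == len(self.alt):
            return "SNV" if len(self.ref) == 1 else "MNV"
        return "DEL" if len(self.ref) > len(self.alt) else "INS"

    @property
    def indel_len(self) -> int:
        return abs(len(self.ref) - len(self.alt))

    @property
    def key(self) -> tuple[str, int, str, str]:
        return (self.chrom, self.pos, self.ref, self.alt)

    @property
    def anchor(self) -> int:
        """Coordinate used for cut-proximity: SNV/MNV/INS -> pos; DEL ->
        midpoint of the deleted span (resection is treated symmetrically)."""
        if self.vclass == "DEL":
            # deleted bases occupy pos+1 .. pos+indel_len under VCF anchoring
            start = self.pos + 1
            return start + (self.indel_len - 1) // 2
        return self.pos


@dataclass(frozen=True)
class Callset:
    """Per-sample variant collection, sorted and deduplicated."""

    sample: str
    variants: tuple[Variant, ...]
    reference: str | None = None

    @classmethod
    def from_variants(
        cls,
        sample: str,
        variants: Iterable[Variant],
        reference: str | None = None,
    ) -> "Callset":
        unique = sorted(set(variants))
        return cls(sample=sample, variants=tuple(unique), reference=reference)

    def __len__(self) -> int:
        return len(self.variants)

    def keys(self) -> set[tuple[str, int, str, str]]:
        return {v.key for v in self.variants}


def normalize_variant(v: Variant, reference: Mapping[str, str]) -> Variant:
    """Trim shared prefix/suffix and left-align indels against the reference.

    Idempotent; raises :class:`DataError` if the REF allele disagrees with the
    reference sequence at its position.
    """
    observed = fetch(reference, v.chrom, v.pos, v.pos + len(v.ref) - 1)
    if observed != v.ref:
        raise DataError(
            f"REF {v.ref!r} at {v.chrom}:{v.pos} does not match reference {observed!r}"
        )
    pos, ref, alt = v.pos, v.ref, v.alt
    # right-trim, extending left through the reference when an allele would
    # empty; at the contig start the representation is already leftmost
    while ref[-1] == alt[-1]:
        if len(ref) > 1 and len(alt) > 1:
            ref, alt = ref[:-1], alt[:-1]
        elif pos > 1:
            base = fetch(reference, v.chrom, pos - 1, pos - 1)
            ref, alt, pos = base + ref, base + alt, pos - 1
        else:
            break
    # left-trim while both alleles keep at least one base
    while len(ref) > 1 and len(alt) > 1 and ref[0] == alt[0]:
        ref, alt, pos = ref[1:], alt[1:], pos + 1
    return Variant(v.chrom, pos, ref, alt)


def normalize_callset(cs: Callset, reference: Mapping[str, str]) -> Callset:
    return Callset.from_variants(
        cs.sample, (normalize_variant(v, reference) for v in cs.variants), cs.reference
    )


def read_vcf(path: "str | Path", sample: str | None = None) -> Callset:
    """Read SNV/indel records from a VCF; symbolic alleles are rejected."""
    path = str(path)
    variants = []
    with pysam.VariantFile(path) as vcf:
        name = sample or (list(vcf.header.samples) or [Path(path).stem])[0]
        for rec in vcf.fetch() if vcf.index is not None else vcf:
            if rec.alts is None:
                continue
            for alt in rec.alts:
                if alt is None or any(c in alt for c in "<>[]*.") :
                    raise DataError(
                        f"symbolic/breakend allele {alt!r} at {rec.chrom}:{rec.pos}"
                    )
                variants.append(Variant(rec.chrom, rec.pos, rec.ref, alt))
    return Callset.from_variants(name, variants)


def write_vcf(
    cs: Callset,
    path: "str | Path",
    contigs: Mapping[str, int],
) -> None:
    """Write a minimal sites-only VCF (CHROM POS ID REF ALT QUAL FILTER INFO)."""
    header = pysam.VariantHeader()
    for name, length in contigs.items():
        header.contigs.add(name, length=length)
    with pysam.VariantFile(str(path), "w", header=header) as out:
        for v in cs.variants:
            rec = out.new_record(
                contig=v.chrom, start=v.pos - 1, alleles=(v.ref, v.alt)
            )
            out.write(rec)
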