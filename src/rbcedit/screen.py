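"""WGS-based CRISPR on/off-target verification.

The procedure mirrors how an edited clone is screened against its parent
line: somatic SNVs and indels (up to 50 nt) unique to the edited sample are
identified by exact-key differencing of normalized callsets; each mutation's
wild-type neighbourhood (100 bp of flank either side) is extracted from the
reference; every guide is scanned against the window on both strands at
every gapless offset; and a mutation is attributed to Cas9 when some site
has a valid attribution PAM (NRG), a predicted blunt cut proximal to the
mutation, and either fewer than six protospacer mismatches or a perfectly
conserved 10-bp PAM-proximal seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import ContractError, DataError
from .sequence import (
    GuideRNA,
    IUPAC_CODES,
    PamPattern,
    SiteMatch,
    as_pattern,
    cut_coordinate,
    pam_matches,
    revcomp,
)
from .variants import Callset, Variant, contig_length, fetch, normalize_callset


@dataclass(frozen=True)
class AttributionConfig:
    """Numeric constants of the attribution criteria.

    ``max_mismatch`` 5 encodes "fewer than 6" protospacer mismatches;
    ``cut_proximity_tol`` bounds |predicted cut - variant anchor| (the
    criteria only require the cut to be "proximal", so the tolerance is
    explicit and configurable); ``pam_strict`` keeps PAM positions out of the
    mismatch count and instead requires the attribution PAM to be satisfied.
    """

    flank: int = 100
    max_indel_nt: int = 50
    max_mismatch: int = 5
    seed_len: int = 10
    pam_attribution: PamPattern = field(default_factory=lambda: PamPattern("NRG"))
    cut_proximity_tol: int = 5
    pam_strict: bool = True

    def __post_init__(self) -> None:
        object.__setattr__(self, "pam_attribution", as_pattern(self.pam_attribution))
        for name in ("flank", "max_indel_nt", "max_mismatch", "seed_len",
                     "cut_proximity_tol"):
            if getattr(self, name) < 0:
                raise ContractError(f"{name} must be nonnegative")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["pam_attribution"] = str(self.pam_attribution)
        return d


@dataclass(frozen=True)
class FlankedSite:
    """A somatic variant with its wild-type reference window."""

    variant: Variant
    window_start: int
    window_seq: str
    flank: int
    truncated_left: bool = False
    truncated_right: bool = False

    @property
    def window_end(self) -> int:
        return self.window_start + len(self.window_seq) - 1

    @property
    def window_id(self) -> str:
        v = self.variant
        return f"{v.chrom}:{v.pos}:{v.ref}>{v.alt}"


@dataclass
class AttributionResult:
    """Verdict for one somatic variant against all guides."""

    variant: Variant
    matches: dict[str, list[SiteMatch]]
    attributed: bool
    attributed_guides: list[str]
    reason: str  # pam_proximal_low_mismatch | pam_proximal_seed | none
    on_target: bool = False
    best: tuple[str, SiteMatch] | None = None


@dataclass
class ScreenReport:
    """Partition of all unique somatic variants for an edited/control pair."""

    edited_sample: str
    control_sample: str
    n_somatic_unique: int
    on_target: list[AttributionResult]
    off_target_attributed: list[AttributionResult]
    unattributed: int
    config: AttributionConfig

    def __post_init__(self) -> None:
        total = len(self.on_target) + len(self.off_target_attributed) + self.unattributed
        if total != self.n_somatic_unique:
            raise ContractError(
                f"partition broken: {total} != {self.n_somatic_unique} somatic variants"
            )

    def to_dict(self) -> dict:
        def brief(r: AttributionResult) -> dict:
            v = r.variant
            return {
                "chrom": v.chrom, "pos": v.pos, "ref": v.ref, "alt": v.alt,
                "class": v.vclass, "guides": r.attributed_guides, "reason": r.reason,
            }

        return {
            "edited_sample": self.edited_sample,
            "control_sample": self.control_sample,
            "n_somatic_unique": self.n_somatic_unique,
            "n_on_target": len(self.on_target),
            "n_off_target_attributed": len(self.off_target_attributed),
            "n_unattributed": self.unattributed,
            "on_target": [brief(r) for r in self.on_target],
            "off_target_attributed": [brief(r) for r in self.off_target_attributed],
            "config": self.config.to_dict(),
        }


def somatic_difference(
    edited: Callset, control: Callset, cfg: AttributionConfig
) -> Callset:
    """Variants unique to the edited sample, capped at ``max_indel_nt``.

    Both callsets must already be normalized against the same reference;
    matching is by exact (chrom, pos, ref, alt) key.
    """
    if (
        edited.reference is not None
        and control.reference is not None
        and edited.reference != control.reference
    ):
        raise ContractError(
            f"callsets use different references: "
            f"{edited.reference!r} vs {control.reference!r}"
        )
    control_keys = control.keys()
    unique = [
        v
        for v in edited.variants
        if v.key not in control_keys and v.indel_len <= cfg.max_indel_nt
    ]
    return Callset.from_variants(edited.sample, unique, edited.reference)


def extract_flanks(
    v: Variant, reference: Mapping[str, str], flank: int = 100
) -> FlankedSite:
    """Wild-type window of ``flank`` bases either side of the REF-allele span,
    truncated at contig edges (with the truncation recorded)."""
    end_of_contig = contig_length(reference, v.chrom)
    start = v.pos - flank
    end = v.pos + len(v.ref) - 1 + flank
    truncated_left = start < 1
    truncated_right = end > end_of_contig
    start = max(1, start)
    end = min(end_of_contig, end)
    return FlankedSite(
        variant=v,
        window_start=start,
        window_seq=fetch(reference, v.chrom, start, end),
        flank=flank,
        truncated_left=truncated_left,
        truncated_right=truncated_right,
    )


def _pam_position_masks(pattern: PamPattern) -> list[np.ndarray]:
    """Per-position allowed-byte arrays; genomic N is never allowed."""
    return [
        np.frombuffer("".join(sorted(IUPAC_CODES[c])).encode(), dtype=np.uint8)
        for c in pattern.codes
    ]


def _scan_oriented(
    oriented: str,
    strand: str,
    window_start: int,
    window_len: int,
    window_id: str,
    guide: GuideRNA,
    cfg: AttributionConfig,
) -> list[SiteMatch]:
    L = guide.length
    total = L + 3
    n = len(oriented) - total + 1
    if n <= 0:
        return []
    arr = np.frombuffer(oriented.encode(), dtype=np.uint8)
    windows = np.lib.stride_tricks.sliding_window_view(arr, total)
    guide_arr = np.frombuffer(guide.protospacer.encode(), dtype=np.uint8)
    proto = windows[:, :L]
    neq = proto != guide_arr
    mismatches = neq.sum(axis=1)
    seed_ok = ~neq[:, L - cfg.seed_len :].any(axis=1)
    # a genomic N never matches the guide, so `neq` already covers N; the seed
    # is likewise broken by N because the guide is unambiguous
    pam = windows[:, L:]
    pam_ok = np.ones(n, dtype=bool)
    for j, allowed in enumerate(_pam_position_masks(cfg.pam_attribution)):
        pam_ok &= np.isin(pam[:, j], allowed)
    out = []
    for j in range(n):
        if strand == "+":
            span_start = window_start + j
        else:
            span_start = window_start + window_len - total - j
        out.append(
            SiteMatch(
                window_id=window_id,
                strand=strand,
                protospacer_start=j + 1,
                observed_protospacer=oriented[j : j + L],
                observed_pam=oriented[j + L : j + total],
                mismatch_count=int(mismatches[j]),
                pam_ok=bool(pam_ok[j]),
                seed_ok=bool(seed_ok[j]),
                predicted_cut=cut_coordinate(span_start, strand, L, guide.cut_offset),
            )
        )
    return out


def scan_window(
    site: FlankedSite, guide: GuideRNA, cfg: AttributionConfig
) -> list[SiteMatch]:
    """Exhaustive gapless scan of every protospacer+PAM offset, both strands.

    Order is deterministic: plus strand by ascending offset, then minus
    strand by ascending offset in the reverse-complemented window. A window
    shorter than the query yields an empty list.
    """
    seq = site.window_seq
    matches = _scan_oriented(
        seq, "+", site.window_start, len(seq), site.window_id, guide, cfg
    )
    matches += _scan_oriented(
        revcomp(seq), "-", site.window_start, len(seq), site.window_id, guide, cfg
    )
    return matches


def _pam_mismatches(pam: str, pattern: PamPattern) -> int:
    from .sequence import base_matches

    return sum(not base_matches(b, c) for b, c in zip(pam, pattern.codes))


def _eligible(m: SiteMatch, anchor: int, cfg: AttributionConfig) -> bool:
    if abs(m.predicted_cut - anchor) > cfg.cut_proximity_tol:
        return False
    if cfg.pam_strict:
        if not m.pam_ok:
            return False
        return m.mismatch_count <= cfg.max_mismatch or m.seed_ok
    # relaxed mode: PAM mismatches join the protospacer count, no PAM gate
    effective = m.mismatch_count + _pam_mismatches(m.observed_pam, cfg.pam_attribution)
    return effective <= cfg.max_mismatch or (m.seed_ok and m.pam_ok)


def attribute_variant(
    site: FlankedSite,
    matches: Mapping[str, Sequence[SiteMatch]],
    cfg: AttributionConfig,
) -> AttributionResult:
    """Apply the attribution criteria to per-guide scan results.

    Attributed iff some match has a valid attribution PAM, a predicted cut
    within ``cut_proximity_tol`` of the variant anchor, and (mismatches <=
    ``max_mismatch`` OR an intact seed). The recorded reason comes from the
    lowest-mismatch eligible match.
    """
    anchor = site.variant.anchor
    attributed_guides: list[str] = []
    best: tuple[str, SiteMatch] | None = None
    for guide_name, guide_matches in matches.items():
        eligible = [m for m in guide_matches if _eligible(m, anchor, cfg)]
        if eligible:
            attributed_guides.append(guide_name)
            top = min(
                eligible,
                key=lambda m: (m.mismatch_count, abs(m.predicted_cut - anchor)),
            )
            if best is None or top.mismatch_count < best[1].mismatch_count:
                best = (guide_name, top)
    if best is not None:
        reason = (
            "pam_proximal_low_mismatch"
            if best[1].mismatch_count <= cfg.max_mismatch
            else "pam_proximal_seed"
        )
    else:
        reason = "none"
    kept = {
        name: [m for m in ms if m.pam_ok] for name, ms in matches.items()
    }
    return AttributionResult(
        variant=site.variant,
        matches=kept,
        attributed=best is not None,
        attributed_guides=sorted(attributed_guides),
        reason=reason,
        best=best,
    )


TargetLoci = Mapping[str, Sequence[tuple[str, int, int]]]


def classify_on_target(
    result: AttributionResult,
    guides: Mapping[str, GuideRNA],
    target_loci: TargetLoci,
) -> AttributionResult:
    """Flag attributed variants whose evidence is a perfect design-PAM match
    cutting inside a registered on-target locus."""
    for name in result.attributed_guides:
        if name not in guides:
            raise ContractError(f"unknown guide label {name!r}")
    result.on_target = False
    if not result.attributed:
        return result
    chrom = result.variant.chrom
    for name in result.attributed_guides:
        guide = guides[name]
        loci = [
            (s, e) for (c, s, e) in target_loci.get(name, []) if c == chrom
        ]
        if not loci:
            continue
        for m in result.matches.get(name, []):
            if m.mismatch_count != 0:
                continue
            if not pam_matches(m.observed_pam, guide.pam_design):
                continue
            if any(s <= m.predicted_cut <= e for s, e in loci):
                result.on_target = True
                return result
    return result


def run_screen(
    edited: Callset,
    control: Callset,
    reference: Mapping[str, str],
    guides: Sequence[GuideRNA],
    cfg: AttributionConfig,
    target_loci: TargetLoci | None = None,
) -> tuple[ScreenReport, list[AttributionResult]]:
    """Full pipeline: normalize -> difference -> flank -> scan -> attribute
    -> on/off-target partition. Returns the report and per-variant results."""
    names = [g.name for g in guides]
    if len(set(names)) != len(names):
        raise ContractError("duplicate guide names")
    guide_map = {g.name: g for g in guides}
    loci = target_loci or {}
    edited_n = normalize_callset(edited, reference)
    control_n = normalize_callset(control, reference)
    somatic = somatic_difference(edited_n, control_n, cfg)
    results: list[AttributionResult] = []
    for v in somatic.variants:
        site = extract_flanks(v, reference, cfg.flank)
        matches = {g.name: scan_window(site, g, cfg) for g in guides}
        result = attribute_variant(site, matches, cfg)
        result = classify_on_target(result, guide_map, loci)
        results.append(result)
    on_target = [r for r in results if r.on_target]
    off_target = [r for r in results if r.attributed and not r.on_target]
    unattributed = sum(1 for r in results if not r.attributed)
    report = ScreenReport(
        edited_sample=edited.sample,
        control_sample=control.sample,
        n_somatic_unique=len(somatic),
        on_target=on_target,
        off_target_attributed=off_target,
        unattributed=unattributed,
        config=cfg,
    )
    return report, results


def write_report_json(report: ScreenReport, path: "str | Path") -> None:
    Path(path).write_text(json.dumps(report.to_dict(), indent=2) + "\n")


def attribution_table(results: Iterable[AttributionResult]) -> pd.DataFrame:
    """Human-readable per-variant attribution rows."""
    rows = []
    for r in results:
        v = r.variant
        guide, m = r.best if r.best is not None else (None, None)
        rows.append(
            {
                "chrom": v.chrom,
                "pos": v.pos,
                "ref": v.ref,
                "alt": v.alt,
                "class": v.vclass,
                "guide": guide or "",
                "strand": m.strand if m else "",
                "mismatches": m.mismatch_count if m else "",
                "seed": m.seed_ok if m else "",
                "pam": m.observed_pam if m else "",
                "predicted_cut": m.predicted_cut if m else "",
                "distance": abs(m.predicted_cut - v.anchor) if m else "",
                "verdict": (
                    "on_target"
                    if r.on_target
                    else "off_target_attributed" if r.attributed else "unattributed"
                ),
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "chrom", "pos", "ref", "alt", "class", "guide", "strand",
            "mismatches", "seed", "pam", "predicted_cut", "distance", "verdict",
        ],
    )
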