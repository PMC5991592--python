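"""Seeded generators for every input the pipeline consumes.

The generators produce a random genome, implant guide-similar sites with
exactly specified mismatch structure, place Cas9-style indels at predicted
cut sites, sprinkle germline-shared and clone-private background SNVs, and
emit a ground-truth registry sufficient to predict the screen's report.
They also reconstruct a patient cohort consistent with the published survey
marginals and a TMT-style protein quantification table around planted
abundance ratios.

Every generator is a pure function of (parameters, seed); the orchestrators
derive per-stage streams from one master seed via ``numpy``'s
``SeedSequence.spawn`` in a fixed documented order (genome, implant, edits,
background, cohort, proteome), so adding a stage never perturbs the others.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from . import datasets
from .coverage import (
    BloodGroupSystem,
    Cohort,
    KnockoutPanel,
    PatientProfile,
    TABLE_ORDER,
)
from .errors import ContractError, GenerationError
from .proteome import MEMBRANE, OTHER, ProteinQuant
from .sequence import GuideRNA, cut_coordinate, revcomp
from .variants import Callset, Variant, normalize_variant

BASES = "ACGT"

#: The five knockout target genes, used to name synthetic guides.
TARGET_GENES = ("GYPB", "KEL", "ACKR1", "FUT1", "RHAG")


# ---------------------------------------------------------------------------
# guides and genome


def _has_long_run(seq: str, max_run: int = 3) -> bool:
    run, prev = 1, ""
    for b in seq:
        run = run + 1 if b == prev else 1
        if run > max_run:
            return True
        prev = b
    return False


def synth_guides(
    n: int = 5, length: int = 20, seed: int = 0
) -> list[GuideRNA]:
    """Random unambiguous protospacers, one per knockout target gene.

    Homopolymer runs longer than 3 nt are rejected so that planted cut-site
    indels stay put under left-alignment.
    """
    rng = np.random.default_rng(seed)
    guides = []
    for i in range(n):
        gene = TARGET_GENES[i % len(TARGET_GENES)]
        while True:
            proto = "".join(rng.choice(list(BASES), size=length))
            if not _has_long_run(proto):
                break
        suffix = "" if i < len(TARGET_GENES) else f"_{i // len(TARGET_GENES) + 1}"
        guides.append(
            GuideRNA(name=f"g{gene}{suffix}", protospacer=proto, target_gene=gene)
        )
    return guides


def protospacer_hits(
    seq: str, protospacer: str, max_mm: int
) -> list[tuple[int, str, int]]:
    """All (span_start, strand, mismatches) with <= ``max_mm`` protospacer
    mismatches in ``seq``, vectorised over every gapless offset."""
    L = len(protospacer)
    hits = []
    for strand, oriented in (("+", seq), ("-", revcomp(seq))):
        if len(oriented) < L:
            continue
        arr = np.frombuffer(oriented.encode(), dtype=np.uint8)
        windows = np.lib.stride_tricks.sliding_window_view(arr, L)
        mm = (windows != np.frombuffer(protospacer.encode(), np.uint8)).sum(axis=1)
        for j in np.nonzero(mm <= max_mm)[0]:
            if strand == "+":
                start = int(j) + 1
            else:
                start = len(seq) - (int(j) + L) + 1
            hits.append((start, strand, int(mm[j])))
    return hits


def make_reference(
    guides: Sequence[GuideRNA],
    n_contigs: int = 1,
    contig_len: int = 100_000,
    gc_fraction: float = 0.41,
    seed: int = 0,
    max_attempts: int = 20,
) -> dict[str, str]:
    """Reproducible random genome with no accidental near-copy (<= 1 mismatch)
    of any registered guide; regenerated up to ``max_attempts`` times."""
    if contig_len < 1000:
        raise ContractError("contig_len must be >= 1 kb")
    rng = np.random.default_rng(seed)
    p = [(1 - gc_fraction) / 2, gc_fraction / 2, gc_fraction / 2, (1 - gc_fraction) / 2]
    for _ in range(max_attempts):
        contigs = {
            f"chr{i + 1}": "".join(rng.choice(list(BASES), size=contig_len, p=p))
            for i in range(n_contigs)
        }
        clean = all(
            not protospacer_hits(seq, g.protospacer, max_mm=1)
            for seq in contigs.values()
            for g in guides
        )
        if clean:
            return contigs
    raise GenerationError(
        f"could not generate a guide-free genome in {max_attempts} attempts"
    )


# ---------------------------------------------------------------------------
# site implantation and edits


@dataclass(frozen=True)
class SiteSpec:
    """A guide-similar locus to implant: which mismatches, which PAM."""

    guide: str
    contig: str
    start: int  # leftmost 1-based coordinate of the protospacer+PAM span
    strand: str
    planted_mismatch_positions: frozenset[int] = frozenset()
    planted_pam: str = "AGG"
    is_target_locus: bool = False

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "planted_mismatch_positions",
            frozenset(int(i) for i in self.planted_mismatch_positions),
        )
        if self.strand not in "+-":
            raise ContractError(f"invalid strand {self.strand!r}")
        if len(self.planted_pam) != 3:
            raise ContractError("planted_pam must be 3 nt")


@dataclass(frozen=True)
class ImplantedSite:
    """A realized SiteSpec: the written sequence and its predicted cut."""

    spec: SiteSpec
    span_start: int
    span_end: int
    site_protospacer: str  # guide orientation
    predicted_cut: int

    def to_dict(self) -> dict:
        return {
            "guide": self.spec.guide,
            "contig": self.spec.contig,
            "strand": self.spec.strand,
            "span_start": self.span_start,
            "span_end": self.span_end,
            "mismatches": sorted(self.spec.planted_mismatch_positions),
            "pam": self.spec.planted_pam,
            "is_target_locus": self.spec.is_target_locus,
            "predicted_cut": self.predicted_cut,
        }


@dataclass(frozen=True)
class EditSpec:
    """A Cas9-style indel to place at a site's predicted cut."""

    site: ImplantedSite
    edit_class: str  # DEL | INS
    length: int
    offset_from_cut: int = 0
    biallelic: bool = True

    def __post_init__(self) -> None:
        if self.edit_class not in ("DEL", "INS"):
            raise ContractError(f"edit_class {self.edit_class!r}")
        if not 1 <= self.length <= 50:
            raise ContractError("edit length must be in 1..50")


def implant_sites(
    contigs: Mapping[str, str],
    guides: Mapping[str, GuideRNA],
    specs: Sequence[SiteSpec],
    seed: int = 0,
) -> tuple[dict[str, str], list[ImplantedSite]]:
    """Write each specified site into the genome so a scan reports exactly the
    specified mismatch count, PAM and strand. Sites must not overlap."""
    rng = np.random.default_rng(seed)
    occupied: dict[str, list[tuple[int, int]]] = {}
    editable = {name: list(seq) for name, seq in contigs.items()}
    implanted: list[ImplantedSite] = []
    for spec in specs:
        guide = guides[spec.guide]
        L = guide.length
        span = (spec.start, spec.start + L + 2)
        if spec.contig not in editable:
            raise ContractError(f"contig {spec.contig!r} absent")
        if span[0] < 1 or span[1] > len(editable[spec.contig]):
            raise ContractError(f"site span {span} outside contig")
        for s, e in occupied.get(spec.contig, []):
            if span[0] <= e and s <= span[1]:
                raise ContractError(f"overlapping site specs at {spec.contig}:{span}")
        occupied.setdefault(spec.contig, []).append(span)
        proto = list(guide.protospacer)
        for pos in spec.planted_mismatch_positions:
            if not 1 <= pos <= L:
                raise ContractError(f"mismatch position {pos} outside 1..{L}")
            alternatives = [b for b in BASES if b != proto[pos - 1]]
            proto[pos - 1] = str(rng.choice(alternatives))
        site_proto = "".join(proto)
        full = site_proto + spec.planted_pam.upper()
        if spec.strand == "-":
            full = revcomp(full)
        seq = editable[spec.contig]
        seq[span[0] - 1 : span[1]] = list(full)
        implanted.append(
            ImplantedSite(
                spec=spec,
                span_start=span[0],
                span_end=span[1],
                site_protospacer=site_proto,
                predicted_cut=cut_coordinate(
                    span[0], spec.strand, L, guide.cut_offset
                ),
            )
        )
    return {name: "".join(seq) for name, seq in editable.items()}, implanted


def simulate_edits(
    contigs: Mapping[str, str],
    edits: Sequence[EditSpec],
    seed: int = 0,
) -> list[tuple[EditSpec, Variant]]:
    """Indels anchored at each site's predicted cut (+offset), normalized.

    Deletions are centred on the cut bond (resection is bidirectional);
    insertions are placed into the bond itself.
    """
    rng = np.random.default_rng(seed)
    out = []
    for edit in edits:
        site = edit.site
        cut = site.predicted_cut + edit.offset_from_cut
        contig = contigs[site.spec.contig]
        if edit.edit_class == "DEL":
            # try shrinking lengths if left-alignment would drag the anchor
            # away from the cut (local repeats); virtually never needed
            v = None
            for length in range(edit.length, 1, -1):
                del_start = cut - (length - 1) // 2
                pos = del_start - 1
                if pos < 1:
                    raise ContractError("deletion would run off the contig start")
                ref = contig[pos - 1 : pos + length]
                alt = ref[0]
                cand = normalize_variant(
                    Variant(site.spec.contig, pos, ref, alt), contigs
                )
                if abs(cand.anchor - cut) <= 3:
                    v = cand
                    break
            if v is None:
                raise GenerationError(f"could not anchor deletion at cut {cut}")
        else:
            pos = cut
            ref = contig[pos - 1]
            # last inserted base differs from the anchor base, so the record
            # is already normalized and stays anchored at the cut
            insert = [str(rng.choice(list(BASES))) for _ in range(edit.length)]
            if insert[-1] == ref:
                insert[-1] = str(rng.choice([b for b in BASES if b != ref]))
            v = normalize_variant(
                Variant(site.spec.contig, pos, ref, ref + "".join(insert)), contigs
            )
        out.append((edit, v))
    return out


# ---------------------------------------------------------------------------
# background variation


def simulate_background(
    contigs: Mapping[str, str],
    sites: Sequence[ImplantedSite],
    snp_rate: float,
    shared_fraction: float,
    seed: int = 0,
    exclusion_pad: int = 123,  # flank (100) + protospacer (20) + PAM (3)
    exclude_near_sites: bool = True,
) -> tuple[list[Variant], list[Variant]]:
    """Background SNVs: a shared (germline-like) set present in both samples
    and a clone-private set present only in the edited sample.

    Returns (shared, edited_unique). By default no variant lands within
    ``exclusion_pad`` of an implanted guide-similar site, keeping ground
    truth unambiguous.
    """
    if not 0 < snp_rate <= 0.01:
        raise ContractError("snp_rate must be in (0, 0.01]")
    if not 0 <= shared_fraction <= 1:
        raise ContractError("shared_fraction must be in [0, 1]")
    rng = np.random.default_rng(seed)
    shared: list[Variant] = []
    edited_unique: list[Variant] = []
    for name, seq in contigs.items():
        n = int(round(snp_rate * len(seq)))
        if n == 0:
            continue
        allowed = np.ones(len(seq), dtype=bool)
        allowed[:1] = False
        if exclude_near_sites:
            for site in sites:
                if site.spec.contig != name:
                    continue
                lo = max(0, site.span_start - 1 - exclusion_pad)
                hi = min(len(seq), site.span_end + exclusion_pad)
                allowed[lo:hi] = False
        candidates = np.nonzero(allowed)[0]
        if len(candidates) < n:
            raise GenerationError("not enough positions for background variants")
        positions = rng.choice(candidates, size=n, replace=False) + 1
        n_shared = int(round(shared_fraction * n))
        for i, pos in enumerate(sorted(int(p) for p in positions)):
            ref = seq[pos - 1]
            alt = str(rng.choice([b for b in BASES if b != ref]))
            v = Variant(name, pos, ref, alt)
            (shared if i < n_shared else edited_unique).append(v)
    return shared, edited_unique


# ---------------------------------------------------------------------------
# full screen scenario


@dataclass
class ScreenDataset:
    """A complete synthetic screen input with its ground-truth registry."""

    seed: int
    contigs: dict[str, str]
    guides: list[GuideRNA]
    sites: list[ImplantedSite]
    edits: list[tuple[EditSpec, Variant]]
    shared_background: list[Variant]
    edited_background: list[Variant]
    edited: Callset
    control: Callset
    target_loci: dict[str, list[tuple[str, int, int]]]

    @property
    def expected_on_target(self) -> set[tuple[str, int, str, str]]:
        return {
            v.key for e, v in self.edits if e.site.spec.is_target_locus
        }

    @property
    def expected_off_target(self) -> set[tuple[str, int, str, str]]:
        """Edits at attributable (<=5 mismatch, NRG) non-target sites."""
        out = set()
        for e, v in self.edits:
            spec = e.site.spec
            if spec.is_target_locus:
                continue
            if len(spec.planted_mismatch_positions) <= 5:
                out.add(v.key)
        return out

    @property
    def expected_unattributed_edits(self) -> set[tuple[str, int, str, str]]:
        """Near-miss edits (6 mismatches, broken seed) that must stay
        unattributed."""
        return {
            v.key
            for e, v in self.edits
            if not e.site.spec.is_target_locus
            and len(e.site.spec.planted_mismatch_positions) > 5
        }

    def registry_dict(self) -> dict:
        return {
            "seed": self.seed,
            "contigs": {n: len(s) for n, s in self.contigs.items()},
            "guides": [g.name for g in self.guides],
            "sites": [s.to_dict() for s in self.sites],
            "edits": [
                {
                    "guide": e.site.spec.guide,
                    "class": e.edit_class,
                    "length": e.length,
                    "biallelic": e.biallelic,
                    "variant": list(v.key),
                    "is_target_locus": e.site.spec.is_target_locus,
                }
                for e, v in self.edits
            ],
            "background": {
                "shared": [list(v.key) for v in self.shared_background],
                "edited_unique": [list(v.key) for v in self.edited_background],
            },
            "target_loci": {
                g: [list(t) for t in loci] for g, loci in self.target_loci.items()
            },
        }


def _place_spans(
    rng: np.random.Generator,
    contig_len: int,
    n: int,
    span: int,
    min_gap: int = 500,
    edge: int = 600,
) -> list[int]:
    """Non-overlapping random span starts, pairwise >= ``min_gap`` apart."""
    starts: list[int] = []
    for _ in range(10_000):
        if len(starts) == n:
            return sorted(starts)
        cand = int(rng.integers(edge, contig_len - edge - span))
        if all(abs(cand - s) >= span + min_gap for s in starts):
            starts.append(cand)
    raise GenerationError("could not place non-overlapping sites")


def simulate_screen_dataset(
    guides: Sequence[GuideRNA] | None = None,
    contig_len: int = 100_000,
    n_background: int = 200,
    shared_fraction: float = 0.5,
    adversarial: bool = False,
    seed: int = 0,
) -> ScreenDataset:
    """One full scenario: genome, on-target sites+biallelic cut indels per
    guide, background SNVs kept away from guide-similar neighbourhoods, and
    (optionally) adversarial near-miss and attributable off-target sites.

    Near-miss sites carry 6 mismatches, one inside the 10-bp seed, under a
    valid NRG PAM: attributable by neither criterion-(ii) clause. The
    attributable off-target sites carry 3 PAM-distal mismatches under a
    non-NGG NRG PAM.
    """
    ss = np.random.SeedSequence(seed)
    s_guides, s_genome, s_implant, s_edits, s_background = (
        int(c.generate_state(1)[0] % (2**31)) for c in ss.spawn(5)
    )
    if guides is None:
        guides = synth_guides(seed=s_guides)
    guide_map = {g.name: g for g in guides}
    contigs = make_reference(guides, contig_len=contig_len, seed=s_genome)
    rng = np.random.default_rng(s_implant)
    contig = next(iter(contigs))
    per_guide = 3 if adversarial else 1
    L = guides[0].length
    starts = _place_spans(rng, contig_len, per_guide * len(guides), L + 3)
    starts = [starts[i] for i in rng.permutation(len(starts))]
    specs: list[SiteSpec] = []
    for i, g in enumerate(guides):
        strand = "+" if i % 2 == 0 else "-"
        specs.append(
            SiteSpec(
                guide=g.name,
                contig=contig,
                start=starts[per_guide * i],
                strand=strand,
                planted_mismatch_positions=frozenset(),
                planted_pam="AGG",
                is_target_locus=True,
            )
        )
        if adversarial:
            # near-miss: 6 mismatches with the last one breaking the seed
            near_positions = frozenset({1, 3, 5, 7, 9, g.length})
            specs.append(
                SiteSpec(
                    guide=g.name,
                    contig=contig,
                    start=starts[per_guide * i + 1],
                    strand="+" if i % 2 else "-",
                    planted_mismatch_positions=near_positions,
                    planted_pam="TAG",
                    is_target_locus=False,
                )
            )
            # attributable off-target: 3 PAM-distal mismatches, intact seed
            specs.append(
                SiteSpec(
                    guide=g.name,
                    contig=contig,
                    start=starts[per_guide * i + 2],
                    strand=strand,
                    planted_mismatch_positions=frozenset({2, 5, 8}),
                    planted_pam="CAG",
                    is_target_locus=False,
                )
            )
    contigs, sites = implant_sites(contigs, guide_map, specs, seed=s_implant)
    edit_specs = [
        EditSpec(
            site=site,
            edit_class="DEL" if i % 3 else "INS",
            length=int(rng.integers(2, 13)),
            biallelic=True,
        )
        for i, site in enumerate(sites)
    ]
    edits = simulate_edits(contigs, edit_specs, seed=s_edits)
    snp_rate = n_background / sum(len(s) for s in contigs.values())
    shared, edited_unique = simulate_background(
        contigs, sites, snp_rate=snp_rate, shared_fraction=shared_fraction,
        seed=s_background,
    )
    edited = Callset.from_variants(
        "5xKO", [v for _, v in edits] + shared + edited_unique, "synthetic"
    )
    control = Callset.from_variants("parent", shared, "synthetic")
    target_loci: dict[str, list[tuple[str, int, int]]] = {g.name: [] for g in guides}
    for site in sites:
        if site.spec.is_target_locus:
            target_loci[site.spec.guide].append(
                (site.spec.contig, site.span_start, site.span_end)
            )
    return ScreenDataset(
        seed=seed,
        contigs=contigs,
        guides=list(guides),
        sites=sites,
        edits=edits,
        shared_background=shared,
        edited_background=edited_unique,
        edited=edited,
        control=control,
        target_loci=target_loci,
    )


# ---------------------------------------------------------------------------
# cohort


@dataclass(frozen=True)
class CohortSummary:
    """Marginals of the patient survey; defaults reproduce the published
    summary (56 patients, 2 McLeod, 19 multi-system, Duffy count including
    the two untransfused Fy(a-b-) individuals)."""

    system_counts: Mapping[BloodGroupSystem, int] = field(
        default_factory=lambda: dict(datasets.SURVEY_SYSTEM_COUNTS)
    )
    n_patients: int = datasets.SURVEY_SUMMARY["n_patients"]
    n_mcleod: int = datasets.SURVEY_SUMMARY["n_mcleod"]
    n_multi: int = datasets.SURVEY_SUMMARY["n_multi"]
    n_untransfused_duffy: int = datasets.SURVEY_SUMMARY["n_untransfused_duffy"]


MAJORS = TABLE_ORDER[:5]
MINORS = TABLE_ORDER[5:]  # Lutheran, Kidd


def validate_cohort(cohort: Cohort, summary: CohortSummary) -> None:
    """Check every cohort invariant; raise GenerationError on any failure."""
    problems = []
    if len(cohort) != summary.n_patients:
        problems.append(f"{len(cohort)} patients != {summary.n_patients}")
    if cohort.n_mcleod != summary.n_mcleod:
        problems.append(f"{cohort.n_mcleod} McLeod != {summary.n_mcleod}")
    counts = cohort.system_counts()
    for s, want in summary.system_counts.items():
        if counts[s] != want:
            problems.append(f"{s.value}: {counts[s]} != {want}")
    if cohort.n_multi != summary.n_multi:
        problems.append(f"{cohort.n_multi} multi-system != {summary.n_multi}")
    minor_patients: dict[BloodGroupSystem, set[str]] = {m: set() for m in MINORS}
    for p in cohort.patients:
        for m in MINORS:
            if m in p.required_systems:
                minor_patients[m].add(p.id)
                extra = p.required_systems - {m} - set(MAJORS)
                if extra:
                    problems.append(
                        f"{p.id}: {m.value} co-requirements outside majors"
                    )
    if minor_patients[MINORS[0]] & minor_patients[MINORS[1]]:
        problems.append("Lutheran and Kidd patient sets overlap")
    n_untransfused = sum(p.untransfused for p in cohort.patients)
    if n_untransfused != summary.n_untransfused_duffy:
        problems.append(f"{n_untransfused} untransfused != expected")
    for p in cohort.patients:
        if p.untransfused and BloodGroupSystem.DUFFY not in p.required_systems:
            problems.append(f"{p.id}: untransfused but not Duffy-requiring")
    if problems:
        raise GenerationError("cohort invariants violated: " + "; ".join(problems))


def _allocate_major_requirements(
    rng: np.random.Generator, counts: dict[BloodGroupSystem, int], n_multi: int,
    n_patients_major: int,
) -> list[frozenset[BloodGroupSystem]]:
    total = sum(counts.values())
    n_single = n_patients_major - n_multi
    extra = total - n_single - 2 * n_multi  # instances beyond two per multi
    if n_single < 0 or extra < 0 or extra > n_multi * (len(MAJORS) - 2):
        raise GenerationError("infeasible multi-system allocation")
    sizes = [3] * extra + [2] * (n_multi - extra) if extra <= n_multi else None
    if sizes is None:
        raise GenerationError("infeasible multi-system allocation (sizes)")
    remaining = dict(counts)
    profiles: list[frozenset[BloodGroupSystem]] = []
    for size in sizes:
        order = sorted(
            MAJORS, key=lambda s: (-remaining[s], rng.random())
        )
        chosen = order[:size]
        if any(remaining[s] <= 0 for s in chosen):
            raise GenerationError("ran out of system instances during allocation")
        for s in chosen:
            remaining[s] -= 1
        profiles.append(frozenset(chosen))
    if any(v < 0 for v in remaining.values()) or sum(remaining.values()) != n_single:
        raise GenerationError("allocation does not close")
    for s in MAJORS:
        profiles.extend([frozenset({s})] * remaining[s])
    return profiles


def synth_cohort(
    summary: CohortSummary | None = None, seed: int = 0, max_attempts: int = 50
) -> Cohort:
    """A cohort realisation satisfying every survey invariant.

    The minor-system (Lutheran/Kidd) patients are single-system and mutually
    disjoint; multi-system antibodies are allocated over the five major
    systems. Constraint-checked before return; different seeds give
    different allocations but identical panel-coverage arithmetic.
    """
    summary = summary or CohortSummary()
    counts = {BloodGroupSystem(s): int(c) for s, c in summary.system_counts.items()}
    major_counts = {s: counts.get(s, 0) for s in MAJORS}
    minor_counts = {s: counts.get(s, 0) for s in MINORS}
    n_profiled = summary.n_patients - summary.n_mcleod
    n_major_patients = n_profiled - sum(minor_counts.values())
    last_error: Exception | None = None
    for attempt in range(max_attempts):
        rng = np.random.default_rng(
            int(np.random.SeedSequence([seed, attempt]).generate_state(1)[0] % (2**31))
        )
        try:
            major_profiles = _allocate_major_requirements(
                rng, major_counts, summary.n_multi, n_major_patients
            )
            requirement_sets = list(major_profiles)
            for m in MINORS:
                requirement_sets.extend([frozenset({m})] * minor_counts[m])
            requirement_sets = [
                requirement_sets[i] for i in rng.permutation(len(requirement_sets))
            ]
            duffy_singles = [
                i for i, req in enumerate(requirement_sets)
                if req == frozenset({BloodGroupSystem.DUFFY})
            ]
            if len(duffy_singles) < summary.n_untransfused_duffy:
                raise GenerationError("too few Duffy-only patients to mark untransfused")
            untransfused = set(duffy_singles[: summary.n_untransfused_duffy])
            patients = [
                PatientProfile(
                    id=f"PT{i + 1:02d}",
                    required_systems=req,
                    untransfused=i in untransfused,
                )
                for i, req in enumerate(requirement_sets)
            ]
            patients += [
                PatientProfile(
                    id=f"PT{n_profiled + j + 1:02d}",
                    required_systems=frozenset(),
                    mcleod=True,
                )
                for j in range(summary.n_mcleod)
            ]
            cohort = Cohort(tuple(patients))
            validate_cohort(cohort, summary)
            return cohort
        except GenerationError as exc:
            last_error = exc
    raise GenerationError(f"cohort generation failed: {last_error}")


# ---------------------------------------------------------------------------
# proteome


def synth_proteome(
    n_proteins: int = 1000,
    planted: Mapping[str, float] | None = None,
    noise_cv: float = 0.05,
    seed: int = 0,
    genes: Mapping[str, str] | None = None,
    membrane_fraction: float = 0.25,
    frac_twofold_reduced: float = 0.02,
) -> list[ProteinQuant]:
    """TMT-style quant table around planted abundance ratios.

    ``planted`` maps accession -> true KO:UT ratio; those records are always
    membrane/cytoskeletal and pass the FDR/peptide filters. Background
    proteins sit near ratio 1, except that ``frac_twofold_reduced`` of the
    membrane background is drawn at >= twofold reduction — the residual
    disruption level the knockout line exhibits. With ``noise_cv`` 0 every
    recovered ratio equals its planted value exactly.
    """
    if planted and any(r < 0 for r in planted.values()):
        raise ContractError("planted ratios must be >= 0")
    rng = np.random.default_rng(seed)
    planted = dict(planted or {})
    genes = dict(genes or {})
    records: list[ProteinQuant] = []

    def replicates(mean: float) -> tuple[float, float]:
        if noise_cv == 0:
            return (mean, mean)
        vals = mean * (1.0 + noise_cv * rng.standard_normal(2))
        return tuple(float(max(v, mean * 1e-3)) for v in vals)  # type: ignore[return-value]

    def record(acc: str, gene: str, ratio: float, category: str,
               n_pep: int, fdr: float) -> ProteinQuant:
        ut_mean = float(rng.lognormal(mean=13.0, sigma=1.0))
        return ProteinQuant(
            accession=acc,
            gene=gene,
            n_peptides=n_pep,
            n_unique=max(1, n_pep - int(rng.integers(0, max(1, n_pep // 3) + 1))),
            abundance_ko=replicates(ratio * ut_mean),
            abundance_ut=replicates(ut_mean),
            fdr_q=fdr,
            category=category,
        )

    for acc, ratio in planted.items():
        records.append(
            record(
                acc, genes.get(acc, acc), ratio, MEMBRANE,
                n_pep=int(rng.integers(2, 30)), fdr=float(rng.uniform(0.0, 0.009)),
            )
        )
    n_background = n_proteins - len(records)
    for i in range(max(0, n_background)):
        acc = f"SYN{i + 1:05d}"
        category = MEMBRANE if rng.random() < membrane_fraction else OTHER
        if category == MEMBRANE and rng.random() < frac_twofold_reduced:
            ratio = float(rng.uniform(0.1, 0.5))
        else:
            ratio = float(rng.lognormal(mean=0.0, sigma=0.08))
        n_pep = 1 if rng.random() < 0.05 else int(rng.integers(2, 40))
        fdr = float(rng.uniform(0.011, 0.2)) if rng.random() < 0.03 \
            else float(rng.uniform(0.0, 0.009))
        records.append(record(acc, acc, ratio, category, n_pep, fdr))
    return records


# ---------------------------------------------------------------------------
# file emission


def write_fasta(contigs: Mapping[str, str], path: "str | Path", width: int = 60) -> None:
    with open(path, "w") as fh:
        for name, seq in contigs.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def write_registry(dataset: ScreenDataset, path: "str | Path") -> None:
    Path(path).write_text(json.dumps(dataset.registry_dict(), indent=2) + "\n")
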