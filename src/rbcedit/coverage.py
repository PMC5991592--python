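"""Blood-group knockout panels versus an alloimmunised patient cohort.

The question: which patients with rare or multiple alloantibodies could be
transfused with red cells from an erythroblast line in which a given set of
blood-group systems has been knocked out? A patient is served when every
system they hold (or would form) antibodies against is absent from the cell.
McLeod-syndrome patients are never servable here: the missing protein (XK)
cannot be removed without producing acanthocytic cells, so XK is not a
candidate knockout.

Systems are modelled at the system level (one knockout gene per system;
Rh_null is reached via RHAG), matching how the knockouts were engineered.
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

from .errors import ContractError, DataError


class BloodGroupSystem(str, Enum):
    """The seven systems of the transfusion-need survey, in table row order."""

    MNS_GPB = "MNS_GPB"
    RH = "RH"
    DUFFY = "DUFFY"
    KELL = "KELL"
    H = "H"
    LUTHERAN = "LUTHERAN"
    KIDD = "KIDD"


#: Genetic basis of each system's antigens (knockout target gene).
SYSTEM_GENES: dict[BloodGroupSystem, str] = {
    BloodGroupSystem.MNS_GPB: "GYPB",
    BloodGroupSystem.RH: "RHAG (RHD/RHCE)",
    BloodGroupSystem.DUFFY: "ACKR1",
    BloodGroupSystem.KELL: "KEL",
    BloodGroupSystem.H: "FUT1",
    BloodGroupSystem.LUTHERAN: "BCAM",
    BloodGroupSystem.KIDD: "SLC14A1",
}

TABLE_ORDER: tuple[BloodGroupSystem, ...] = tuple(BloodGroupSystem)

#: The five systems removed in the quintuple-knockout line.
FIVE_MAJOR: frozenset[BloodGroupSystem] = frozenset(
    {
        BloodGroupSystem.MNS_GPB,
        BloodGroupSystem.RH,
        BloodGroupSystem.DUFFY,
        BloodGroupSystem.KELL,
        BloodGroupSystem.H,
    }
)

ALL_SEVEN: frozenset[BloodGroupSystem] = frozenset(BloodGroupSystem)


@dataclass(frozen=True)
class PatientProfile:
    """One surveyed patient: the systems their antibodies require removed."""

    id: str
    required_systems: frozenset[BloodGroupSystem]
    mcleod: bool = False
    untransfused: bool = False

    def __post_init__(self) -> None:
        object.__setattr__(
            self,
            "required_systems",
            frozenset(BloodGroupSystem(s) for s in self.required_systems),
        )
        if not self.mcleod and not self.required_systems:
            raise ContractError(f"patient {self.id}: empty requirement set")


@dataclass(frozen=True)
class KnockoutPanel:
    """A set of blood-group systems removed from the cell line."""

    systems: frozenset[BloodGroupSystem]

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "systems", frozenset(BloodGroupSystem(s) for s in self.systems)
        )

    @classmethod
    def of(cls, *systems: "BloodGroupSystem | str") -> "KnockoutPanel":
        return cls(frozenset(BloodGroupSystem(s) for s in systems))

    @classmethod
    def parse(cls, text: str) -> "KnockoutPanel":
        labels = [t.strip() for t in text.split(",") if t.strip()]
        return cls.of(*labels)

    def __contains__(self, s: BloodGroupSystem) -> bool:
        return s in self.systems

    def __len__(self) -> int:
        return len(self.systems)


@dataclass(frozen=True)
class Cohort:
    """The surveyed patient universe."""

    patients: tuple[PatientProfile, ...]

    def __len__(self) -> int:
        return len(self.patients)

    @property
    def n_mcleod(self) -> int:
        return sum(p.mcleod for p in self.patients)

    @property
    def n_multi(self) -> int:
        return sum(
            1 for p in self.patients if not p.mcleod and len(p.required_systems) >= 2
        )

    def system_counts(self) -> dict[BloodGroupSystem, int]:
        counts = {s: 0 for s in TABLE_ORDER}
        for p in self.patients:
            for s in p.required_systems:
                counts[s] += 1
        return counts

    @classmethod
    def from_tsv(cls, path: "str | Path") -> "Cohort":
        frame = pd.read_csv(path, sep="\t", dtype=str)
        required = {"id", "systems", "mcleod", "untransfused"}
        missing = required - set(frame.columns)
        if missing:
            raise DataError(f"cohort TSV missing columns {sorted(missing)}")
        patients = []
        for row in frame.itertuples(index=False):
            systems = frozenset(
                BloodGroupSystem(s) for s in str(row.systems).split(";") if s and s != "nan"
            )
            patients.append(
                PatientProfile(
                    id=row.id,
                    required_systems=systems,
                    mcleod=str(row.mcleod).lower() in ("true", "1", "yes"),
                    untransfused=str(row.untransfused).lower() in ("true", "1", "yes"),
                )
            )
        return cls(tuple(patients))

    def to_tsv(self, path: "str | Path") -> None:
        rows = [
            {
                "id": p.id,
                "systems": ";".join(
                    s.value for s in sorted(p.required_systems, key=TABLE_ORDER.index)
                ),
                "mcleod": p.mcleod,
                "untransfused": p.untransfused,
            }
            for p in self.patients
        ]
        pd.DataFrame(rows, columns=["id", "systems", "mcleod", "untransfused"]).to_csv(
            path, sep="\t", index=False
        )


@dataclass
class CoverageReport:
    n_served: int
    n_unserved: int
    unserved_ids: list[str]
    marginal_gains: dict[BloodGroupSystem, int]

    def to_dict(self) -> dict:
        return {
            "n_served": self.n_served,
            "n_unserved": self.n_unserved,
            "unserved_ids": self.unserved_ids,
            "marginal_gains": {s.value: g for s, g in self.marginal_gains.items()},
        }


def is_served(p: PatientProfile, panel: KnockoutPanel) -> bool:
    """True iff the patient's whole requirement set is knocked out and the
    patient is not McLeod (XK removal is rejected)."""
    if p.mcleod:
        return False
    return p.required_systems <= panel.systems


def coverage(c: Cohort, panel: KnockoutPanel, gains: bool = True) -> CoverageReport:
    served = [p for p in c.patients if is_served(p, panel)]
    unserved = [p for p in c.patients if not is_served(p, panel)]
    marginal = {}
    if gains:
        for s in TABLE_ORDER:
            if s not in panel.systems:
                marginal[s] = marginal_gain(c, panel, s)
    return CoverageReport(
        n_served=len(served),
        n_unserved=len(unserved),
        unserved_ids=[p.id for p in unserved],
        marginal_gains=marginal,
    )


def marginal_gain(c: Cohort, panel: KnockoutPanel, s: BloodGroupSystem) -> int:
    """Extra patients served by adding one more system to the panel."""
    s = BloodGroupSystem(s)
    if s in panel.systems:
        raise ContractError(f"{s.value} already in panel")
    widened = KnockoutPanel(panel.systems | {s})
    base = sum(is_served(p, panel) for p in c.patients)
    more = sum(is_served(p, widened) for p in c.patients)
    return more - base


def greedy_panel(c: Cohort, k: int) -> KnockoutPanel:
    """Grow a panel by repeatedly adding the largest-gain system.

    Ties break toward the earlier system in table row order; deterministic.
    """
    if not 0 <= k <= len(TABLE_ORDER):
        raise ContractError(f"k={k} outside [0, {len(TABLE_ORDER)}]")
    panel = KnockoutPanel(frozenset())
    for _ in range(k):
        candidates = [s for s in TABLE_ORDER if s not in panel.systems]
        best = max(candidates, key=lambda s: (marginal_gain(c, panel, s),
                                              -TABLE_ORDER.index(s)))
        panel = KnockoutPanel(panel.systems | {best})
    return panel


def optimal_panel(c: Cohort, k: int) -> KnockoutPanel:
    """Exhaustive best panel of size <= k (at most 2^7 subsets).

    Ties go to the first subset in lexicographic table order, which also
    prefers smaller panels at equal coverage.
    """
    if not 0 <= k <= len(TABLE_ORDER):
        raise ContractError(f"k={k} outside [0, {len(TABLE_ORDER)}]")
    best_panel = KnockoutPanel(frozenset())
    best_served = sum(is_served(p, best_panel) for p in c.patients)
    for size in range(1, k + 1):
        for combo in itertools.combinations(TABLE_ORDER, size):
            panel = KnockoutPanel(frozenset(combo))
            served = sum(is_served(p, panel) for p in c.patients)
            if served > best_served:
                best_panel, best_served = panel, served
    return best_panel


def write_coverage_json(report: CoverageReport, path: "str | Path") -> None:
    Path(path).write_text(json.dumps(report.to_dict(), indent=2) + "\n")
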