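"""Run configuration: parsing, defaults, validation and the run manifest."""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from datetime import datetime, timezone
from pathlib import Path

import yaml

from .errors import ValidationError
from .proteome import ProteomeConfig
from .screen import AttributionConfig
from .sequence import PamPattern

STAGES = ("simulate", "screen", "coverage", "proteome")

_ATTRIBUTION_KEYS = {
    "flank", "max_indel_nt", "max_mismatch", "seed_len",
    "pam_attribution", "cut_proximity_tol", "pam_strict",
}
_PROTEOME_KEYS = {"fdr_max", "min_peptides", "fold_threshold", "n_replicates"}
_TOP_KEYS = {
    "stages", "seed", "out", "log_level",
    "attribution", "proteome", "cohort_file", "simulate",
}
_SIMULATE_KEYS = {"contig_len", "n_background", "shared_fraction",
                  "adversarial", "n_proteins", "noise_cv"}


@dataclass
class RunConfig:
    stages: tuple[str, ...] = STAGES
    seed: int = 0
    out: str = "results/run"
    log_level: str = "INFO"
    attribution: AttributionConfig = field(default_factory=AttributionConfig)
    proteome: ProteomeConfig = field(default_factory=ProteomeConfig)
    cohort_file: str | None = None
    simulate: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "stages": list(self.stages),
            "seed": self.seed,
            "out": self.out,
            "log_level": self.log_level,
            "attribution": self.attribution.to_dict(),
            "proteome": self.proteome.to_dict(),
            "cohort_file": self.cohort_file,
            "simulate": dict(self.simulate),
        }


def validate_config(raw: dict | None) -> RunConfig:
    """Apply defaults and validate; unknown keys are rejected and every
    failure is reported at once."""
    raw = dict(raw or {})
    errors: list[str] = []
    unknown = set(raw) - _TOP_KEYS
    if unknown:
        errors.append(f"unknown keys: {sorted(unknown)}")
    stages = tuple(raw.get("stages", STAGES))
    for s in stages:
        if s not in STAGES:
            errors.append(f"unknown stage {s!r}")
    seed = raw.get("seed", 0)
    if not isinstance(seed, int) or isinstance(seed, bool):
        errors.append(f"seed must be an integer, got {seed!r}")
    attribution_raw = dict(raw.get("attribution") or {})
    unknown = set(attribution_raw) - _ATTRIBUTION_KEYS
    if unknown:
        errors.append(f"unknown attribution keys: {sorted(unknown)}")
    proteome_raw = dict(raw.get("proteome") or {})
    unknown = set(proteome_raw) - _PROTEOME_KEYS
    if unknown:
        errors.append(f"unknown proteome keys: {sorted(unknown)}")
    simulate_raw = dict(raw.get("simulate") or {})
    unknown = set(simulate_raw) - _SIMULATE_KEYS
    if unknown:
        errors.append(f"unknown simulate keys: {sorted(unknown)}")
    cohort_file = raw.get("cohort_file")
    if cohort_file is not None and not Path(cohort_file).exists():
        errors.append(f"cohort_file {cohort_file!r} does not exist")
    attribution = proteome = None
    if not errors:
        try:
            if "pam_attribution" in attribution_raw:
                attribution_raw["pam_attribution"] = PamPattern(
                    attribution_raw["pam_attribution"]
                )
            attribution = AttributionConfig(**attribution_raw)
        except Exception as exc:
            errors.append(f"attribution: {exc}")
        try:
            proteome = ProteomeConfig(**proteome_raw)
        except Exception as exc:
            errors.append(f"proteome: {exc}")
    if errors:
        raise ValidationError(errors)
    return RunConfig(
        stages=stages,
        seed=seed,
        out=str(raw.get("out", "results/run")),
        log_level=str(raw.get("log_level", "INFO")),
        attribution=attribution,  # type: ignore[arg-type]
        proteome=proteome,  # type: ignore[arg-type]
        cohort_file=cohort_file,
        simulate=simulate_raw,
    )


def load_config(path: "str | Path | None") -> RunConfig:
    raw = yaml.safe_load(Path(path).read_text()) if path else {}
    return validate_config(raw)


def file_checksum(path: "str | Path") -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()


@dataclass
class RunManifest:
    version: str
    config: dict
    input_checksums: dict[str, str]
    stage_counts: dict[str, dict]
    started: str
    finished: str = ""

    @classmethod
    def start(cls, config: RunConfig) -> "RunManifest":
        return cls(
            version=_package_version(),
            config=config.to_dict(),
            input_checksums={},
            stage_counts={},
            started=datetime.now(timezone.utc).isoformat(),
        )

    def write(self, path: "str | Path") -> None:
        self.finished = datetime.now(timezone.utc).isoformat()
        tmp = Path(str(path) + ".tmp")
        tmp.write_text(json.dumps(self.__dict__, indent=2) + "\n")
        tmp.replace(path)  # atomic publish


def _package_version() -> str:
    from importlib.metadata import version

    try:
        return version("rbcedit")
    except Exception:
        return "unknown"
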