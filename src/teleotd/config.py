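"""Pipeline configuration: defaults, strict validation, provenance echo."""

from __future__ import annotations

import logging
from dataclasses import asdict, dataclass, field, fields

import yaml

from .distribution_classifier import ClassifierConfig, DividingLine

log = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "validate_config", "load_config"]


@dataclass
class PipelineConfig:
    """Effective configuration of the stage chain.

    Thresholds carry the conventional defaults: aKRAB in genome translations
    30; aKRAB in proteins absent <= 20 / present >= 50; ePR-SET 180;
    consensus-score alignment filter 250.
    """

    seed: int = 1
    dialect: str = "auto"
    stages: list[str] = field(
        default_factory=lambda: [
            "simulate", "introns", "classify", "scan", "distance", "tree",
            "classes", "infer-events",
        ]
    )
    bin_width: float = 0.25
    line_intercept: float = 0.08
    line_slope: float = 0.25
    min_introns: int = 1000
    dedupe: bool = True
    akrab_genome_threshold: float = 30.0
    akrab_protein_absent: float = 20.0
    akrab_protein_present: float = 50.0
    eprset_threshold: float = 180.0
    consensus_threshold: float = 250.0
    n_genes: int = 300
    n_proteins: int = 24
    substitution_rate: float = 0.05

    def classifier_config(self) -> ClassifierConfig:
        return ClassifierConfig(
            bin_width=self.bin_width,
            line=DividingLine(self.line_intercept, self.line_slope),
            min_introns=self.min_introns,
            dedupe=self.dedupe,
        )

    def thresholds(self) -> dict[str, dict[str, float]]:
        return {
            "akrab": {
                "genome": self.akrab_genome_threshold,
                "protein_absent": self.akrab_protein_absent,
                "protein_present": self.akrab_protein_present,
            },
            "eprset": {
                "protein": self.eprset_threshold,
                "genome": self.eprset_threshold,
            },
        }


_KNOWN_STAGES = {
    "simulate", "introns", "classify", "scan", "distance", "tree",
    "classes", "infer-events",
}


def validate_config(raw: dict | None) -> PipelineConfig:
    """Inject defaults, reject unknown keys, and range-check everything.

    All violations are reported together; the effective configuration is
    echoed to the log for provenance.
    """
    raw = dict(raw or {})
    known = {f.name for f in fields(PipelineConfig)}
    unknown = set(raw) - known
    if unknown:
        raise ValueError(
            f"unknown config key(s): {', '.join(sorted(unknown))}"
        )
    cfg = PipelineConfig(**raw)
    problems: list[str] = []
    if cfg.bin_width <= 0:
        problems.append(f"bin_width must be > 0 (got {cfg.bin_width})")
    if cfg.min_introns < 1:
        problems.append("min_introns must be >= 1")
    if cfg.line_slope < 0:
        problems.append("line_slope must be >= 0")
    for name in ("akrab_genome_threshold", "akrab_protein_absent",
                 "akrab_protein_present", "eprset_threshold",
                 "consensus_threshold"):
        if getattr(cfg, name) <= 0:
            problems.append(f"{name} must be positive")
    if cfg.akrab_protein_absent >= cfg.akrab_protein_present:
        problems.append(
            "akrab_protein_absent must be below akrab_protein_present"
        )
    if cfg.dialect not in {"genbank", "refseq", "auto"}:
        problems.append(f"unknown dialect {cfg.dialect!r}")
    if not (0.0 <= cfg.substitution_rate < 1.0):
        problems.append("substitution_rate must be in [0, 1)")
    bad_stages = set(cfg.stages) - _KNOWN_STAGES
    if bad_stages:
        problems.append(f"unknown stage(s): {', '.join(sorted(bad_stages))}")
    if problems:
        raise ValueError("invalid config: " + "; ".join(problems))
    log.info("effective config: %s", asdict(cfg))
    return cfg


def load_config(path: str | None) -> PipelineConfig:
    """Load and validate a YAML config file (None -> all defaults)."""
    if path is None:
        return validate_config({})
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise ValueError(f"config root must be a mapping, got {type(raw)}")
    return validate_config(raw)
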