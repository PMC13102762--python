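"""Pipeline configuration: a single YAML file with per-stage blocks.

Unknown keys are rejected so typos fail loudly; every stage records the seed
and a hash of the resolved configuration in its run manifest, making reruns
bit-for-bit comparable.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import yaml

__all__ = ["PipelineConfig", "load_config", "config_hash", "write_manifest"]

_KNOWN_BLOCKS = {"cohort", "model", "fit", "bootstrap", "vpc", "pta"}
_KNOWN_TOP = _KNOWN_BLOCKS | {"seed", "outdir"}

_KNOWN_KEYS = {
    "cohort": {"n_subjects", "dose_mg", "tau_h", "tinf_h", "samples_per_subject",
               "crcl_preset"},
    "model": {"theta_cl", "theta_vc", "theta_cov", "crcl_ref", "omega_cl",
              "omega_vc", "rho", "residual", "sigma_add", "sigma_prop"},
    "fit": {"residual", "use_published_covariates", "compute_rse", "max_iter"},
    "bootstrap": {"n_replicates"},
    "vpc": {"n_sim"},
    "pta": {"n_subjects_per_cell", "pta_threshold", "free_fraction",
            "crcl_sampling"},
}


@dataclass
class PipelineConfig:
    """Validated pipeline configuration."""

    seed: int = 0
    outdir: Path = Path("meropk_out")
    cohort: dict = field(default_factory=dict)
    model: dict = field(default_factory=dict)
    fit: dict = field(default_factory=dict)
    bootstrap: dict = field(default_factory=dict)
    vpc: dict = field(default_factory=dict)
    pta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not isinstance(self.seed, int):
            raise ValueError(f"seed must be an integer, got {self.seed!r}")
        self.outdir = Path(self.outdir)
        for block in _KNOWN_BLOCKS:
            values = getattr(self, block)
            if not isinstance(values, dict):
                raise ValueError(f"config block {block!r} must be a mapping")
            unknown = set(values) - _KNOWN_KEYS[block]
            if unknown:
                raise ValueError(
                    f"unknown key(s) in config block {block!r}: {sorted(unknown)}"
                )

    def to_dict(self) -> dict:
        return {
            "seed": self.seed,
            "outdir": str(self.outdir),
            **{b: getattr(self, b) for b in sorted(_KNOWN_BLOCKS)},
        }


def load_config(path: str | Path | None) -> PipelineConfig:
    """Load and validate a YAML config; ``None`` yields the defaults."""
    if path is None:
        return PipelineConfig()
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"config file not found: {path}")
    raw = yaml.safe_load(path.read_text()) or {}
    if not isinstance(raw, dict):
        raise ValueError(f"config root must be a mapping: {path}")
    unknown = set(raw) - _KNOWN_TOP
    if unknown:
        raise ValueError(f"unknown top-level config key(s): {sorted(unknown)}")
    return PipelineConfig(**raw)


def config_hash(config: PipelineConfig) -> str:
    """Stable short hash of the resolved configuration."""
    canon = json.dumps(config.to_dict(), sort_keys=True)
    return hashlib.sha256(canon.encode()).hexdigest()[:16]


def write_manifest(path: str | Path, command: str, config: PipelineConfig,
                   seed: int, outputs: list[str]) -> None:
    """Run manifest: command, seed, config hash, package version, outputs.

    Deliberately excludes wall-clock time so identical reruns are
    byte-identical.
    """
    from . import __version__

    payload = {
        "command": command,
        "seed": seed,
        "config_hash": config_hash(config),
        "version": __version__,
        "outputs": outputs,
    }
    Path(path).write_text(json.dumps(payload, indent=2) + "\n")
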