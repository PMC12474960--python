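"""Pipeline configuration: YAML-backed, with the analysis defaults baked in."""

from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

DEFAULT_SEED = 20250101

# trait group → mixed-model form
MODEL_FORMS = ("biometric", "emergence", "growth", "physiological")


@dataclass
class PipelineConfig:
    """End-to-end run settings.

    ``trait_groups`` maps each trait to one of the four model forms
    (biometric, emergence, growth, physiological), which determines its
    fixed/random terms and residual structure. Thresholds default to the
    analysis constants: VIF 5, Mojena k 1.25, Mantel 5000 permutations.
    """

    phenotypes: str | None = None
    ssr: str | None = None
    emergence_counts: str | None = None
    output_dir: str = "jucara_out"
    trait_groups: dict[str, str] = field(default_factory=dict)
    path_response: str = "DQI"
    candidate_structures: tuple[str, ...] = ("idv", "diag")
    selection_criterion: str = "aic"
    vif_threshold: float = 5.0
    mojena_k: float = 1.25
    mantel_permutations: int = 5000
    seed: int | None = None
    dqi_diameter_in_cm: bool = False

    def __post_init__(self) -> None:
        if self.vif_threshold <= 0 or self.mojena_k < 0 or self.mantel_permutations < 1:
            raise ValueError("thresholds must be positive")
        for trait, group in self.trait_groups.items():
            if group not in MODEL_FORMS:
                raise ValueError(f"trait {trait!r} assigned to unknown group {group!r}")
        for attr in ("phenotypes", "ssr", "emergence_counts"):
            p = getattr(self, attr)
            if p is not None and not Path(p).exists():
                raise FileNotFoundError(f"{attr} file not found: {p}")
        if self.seed is None:
            warnings.warn(
                f"no seed configured; using documented default {DEFAULT_SEED}",
                stacklevel=2,
            )
            self.seed = DEFAULT_SEED

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        if "candidate_structures" in raw:
            raw["candidate_structures"] = tuple(raw["candidate_structures"])
        return cls(**raw)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self)))

    def digest(self) -> str:
        """Stable hash of the analysis settings, stamped on every output.

        The output directory is excluded: it does not affect any number.
        """
        d = asdict(self)
        d.pop("output_dir", None)
        blob = json.dumps(d, sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:12]
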