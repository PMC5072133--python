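"""Pipeline configuration, YAML round-trip included for provenance."""

from __future__ import annotations

from dataclasses import asdict, dataclass, field, replace
from pathlib import Path

import yaml

from .errors import ValidationError


@dataclass(frozen=True)
class PipelineConfig:
    """Options for one assemblage's end-to-end analysis.

    Diatom defaults: keep the ``top_k_taxa`` most abundant taxa and model the
    sqrt CV directly.  Bacteria defaults: keep OTUs present in at least
    ``min_prevalence`` slides, detrend CVs against log mean abundance and
    model the residuals with >3 SD outliers excluded.
    """

    assemblage: str = "diatom"
    top_k_taxa: int = 8
    min_prevalence: int = 30
    detrend: bool | None = None  # None = assemblage default (on for bacteria)
    outlier_sd: float = 3.0
    drop_outliers: bool = True
    response: str | None = None  # None = assemblage default
    n_perm: int = 999
    seed: int = 0
    n_drop_low_diversity: int = 0
    detection_limit: float = 0.0
    community_path: str | None = None
    design_path: str | None = None
    out_dir: str | None = None

    def __post_init__(self):
        if self.assemblage not in ("diatom", "bacteria"):
            raise ValidationError("assemblage must be 'diatom' or 'bacteria'")
        if self.top_k_taxa < 1 or self.min_prevalence < 1:
            raise ValidationError("top_k_taxa and min_prevalence must be positive")
        if self.outlier_sd <= 0:
            raise ValidationError("outlier_sd must be positive")
        if self.n_perm < 1:
            raise ValidationError("n_perm must be >= 1")
        if self.response not in (None, "sqrt_cv", "residual"):
            raise ValidationError("response must be 'sqrt_cv' or 'residual'")
        if self.n_drop_low_diversity < 0:
            raise ValidationError("n_drop_low_diversity must be >= 0")

    @property
    def use_detrend(self) -> bool:
        return self.assemblage == "bacteria" if self.detrend is None else self.detrend

    @property
    def response_column(self) -> str:
        if self.response is not None:
            return self.response
        return "residual" if self.assemblage == "bacteria" else "sqrt_cv"

    def with_overrides(self, **kwargs) -> "PipelineConfig":
        kwargs = {k: v for k, v in kwargs.items() if v is not None}
        return replace(self, **kwargs) if kwargs else self

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=False))

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        known = cls.__dataclass_fields__.keys()
        unknown = sorted(set(data) - set(known))
        if unknown:
            raise ValidationError(f"unknown config keys: {unknown}")
        return cls(**data)
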