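"""Run configuration: validated, serializable, written into every output
directory for provenance."""

from __future__ import annotations

from pathlib import Path

import yaml
from pydantic import BaseModel, ConfigDict, Field, field_validator

from .editing_model import EditorSpec, get_editor


class RunConfig(BaseModel):
    """All tunable parameters of a design/simulate/analyze run.

    Unknown keys are rejected so silent typos cannot change a run.
    """

    model_config = ConfigDict(extra="forbid")

    editor: str = "CBE"
    window: tuple[int, int] = (4, 8)
    pam: str = "NGG"
    acidic_set: str = "DE"
    basic_set: str = "KRH"
    keep_nonsense: bool = False
    n_controls: int = Field(default=400, ge=0)
    pseudocount: float = Field(default=1.0, gt=0)
    fold_threshold: float = Field(default=2.0, gt=1)
    alpha: float = Field(default=0.05, gt=0, lt=1)
    n_perm: int = Field(default=1000, ge=1)
    seed: int = Field(default=0, ge=0)

    @field_validator("editor")
    @classmethod
    def _known_editor(cls, v: str) -> str:
        get_editor(v)
        return v.upper()

    def editor_spec(self) -> EditorSpec:
        return get_editor(self.editor, window=tuple(self.window), pam=self.pam)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.model_dump(), sort_keys=True))
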