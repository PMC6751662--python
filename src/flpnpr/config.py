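"""Run configuration: calling thresholds, grading cutpoints, panel
specification, and a validated top-level config with JSON round-trip."""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Literal, Optional

from pydantic import BaseModel, Field, model_validator


class Thresholds(BaseModel):
    """Activity thresholds of the two-concentration screen.

    Stimulatory readouts call activity at >= ``fold_of_basal`` (default
    2-fold over the buffer control); the Gi/o readout at <=
    ``fold_of_forskolin`` (default 0.8, i.e. 20% inhibition of the
    forskolin-stimulated signal). Boundaries are inclusive.
    """

    fold_of_basal: float = 2.0
    fold_of_forskolin: float = 0.8
    alpha: float = 0.05

    @model_validator(mode="after")
    def _check(self) -> "Thresholds":
        if self.fold_of_basal <= 1:
            raise ValueError("fold_of_basal threshold must be > 1")
        if not 0 < self.fold_of_forskolin < 1:
            raise ValueError("fold_of_forskolin threshold must be in (0, 1)")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")
        return self


class GradeCutpoints(BaseModel):
    """Numeric cutpoints behind the five-shade interaction-matrix grades.

    ``full`` quantifies "full/maximal activation", ``mid`` the "~50% of
    maximal" boundary between the two lightest shades, and ``equality_delta``
    the margin within which the responses at both screening concentrations
    count as equal (the partial-agonism asterisk).
    """

    full: float = 0.8
    mid: float = 0.35
    equality_delta: float = 0.10

    @model_validator(mode="after")
    def _check(self) -> "GradeCutpoints":
        if not 0 < self.mid < self.full <= 1.0:
            raise ValueError("need 0 < mid < full <= 1")
        if self.equality_delta < 0:
            raise ValueError("equality_delta must be >= 0")
        return self


class ReceptorSpec(BaseModel):
    """One receptor of the panel: species, designated readout pathway
    (its endogenous coupling), and — for human receptors — the established
    endogenous agonist that defines the maximal signal."""

    id: str
    species: Literal["celegans", "human"]
    pathway: str
    endogenous_agonist: Optional[str] = None

    @model_validator(mode="after")
    def _check(self) -> "ReceptorSpec":
        if self.species == "human" and not self.endogenous_agonist:
            raise ValueError(
                f"human receptor {self.id!r} needs a declared endogenous agonist"
            )
        return self


class PanelSpec(BaseModel):
    """Ordered receptor and peptide panels of a screen."""

    receptors: list[ReceptorSpec]
    peptides: list[str]

    @model_validator(mode="after")
    def _check(self) -> "PanelSpec":
        ids = [r.id for r in self.receptors]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate receptor ids in panel")
        if len(set(self.peptides)) != len(self.peptides):
            raise ValueError("duplicate peptide ids in panel")
        return self

    def receptor(self, receptor_id: str) -> ReceptorSpec:
        for r in self.receptors:
            if r.id == receptor_id:
                return r
        raise KeyError(f"receptor {receptor_id!r} not in panel")


class RunConfig(BaseModel):
    """Top-level configuration of a pipeline run."""

    seed: int = 0
    thresholds: Thresholds = Field(default_factory=Thresholds)
    cutpoints: GradeCutpoints = Field(default_factory=GradeCutpoints)
    sign_convention: Literal["as_printed", "avoidance_positive"] = "as_printed"
    outdir: str = "results"

    def config_hash(self) -> str:
        payload = json.dumps(self.model_dump(), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:12]

    def dump(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.model_dump(), indent=2) + "\n")

    @classmethod
    def load(cls, path: str | Path) -> "RunConfig":
        return cls.model_validate(json.loads(Path(path).read_text()))
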