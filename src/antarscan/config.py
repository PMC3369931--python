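"""Pipeline configuration: one flat, validated set of named defaults.

Every tunable of the scanner, terminator finder and classifier appears here
as a named key with its documented default.  Configs load from YAML
(``--config`` on the command line); unknown keys are rejected so typos
cannot silently fall back to defaults.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, fields, replace
from pathlib import Path

import yaml

from .terminator import TerminatorParams

__all__ = ["PipelineConfig", "ConfigError"]


class ConfigError(ValueError):
    """Raised when a configuration file is malformed or inconsistent."""


@dataclass(frozen=True)
class PipelineConfig:
    """All pipeline defaults as named keys.

    Motif scan: ``threshold`` (bit-score cutoff), ``pseudocount``
    (Laplace smoothing), ``min_stem``/``stem_max`` (pairs per hairpin
    stem), ``allow_gu`` (count G-U wobble as a legal stem pair),
    ``linker_min``/``linker_max`` (enumeration bounds; ``None`` keeps the
    trained model's observed range), ``background`` (``sequence``,
    ``model`` or ``uniform``), ``both_strands``.

    Terminator screen: ``term_stem_min``/``term_stem_max``,
    ``term_loop_min``/``term_loop_max``, ``term_max_mismatches``,
    ``term_hairpin_min_score``, ``term_tail_min_score``,
    ``term_tail_window``, ``term_tail_decay``.

    Classification: ``overlap_min`` (nt the terminator's transcript-5' arm
    must share with the second hairpin), ``rbs_min_match`` and
    ``rbs_spacing_min``/``rbs_spacing_max`` (Shine-Dalgarno detection).

    ``seed`` feeds every stochastic fixture generator.
    """

    threshold: float = 10.0
    pseudocount: float = 0.5
    min_stem: int = 3
    stem_max: int = 8
    allow_gu: bool = True
    linker_min: int | None = None
    linker_max: int | None = None
    background: str = "sequence"
    both_strands: bool = True

    term_stem_min: int = 4
    term_stem_max: int = 20
    term_loop_min: int = 3
    term_loop_max: int = 26
    term_max_mismatches: int = 1
    term_hairpin_min_score: float = 8.0
    term_tail_min_score: float = 3.0
    term_tail_window: int = 12
    term_tail_decay: float = 0.9

    overlap_min: int = 1
    rbs_min_match: int = 4
    rbs_spacing_min: int = 4
    rbs_spacing_max: int = 16

    seed: int = 0

    def __post_init__(self) -> None:
        if self.threshold != self.threshold:  # NaN guard
            raise ConfigError("threshold must be a number")
        if self.pseudocount < 0:
            raise ConfigError("pseudocount must be >= 0")
        if not 1 <= self.min_stem <= self.stem_max:
            raise ConfigError("need 1 <= min_stem <= stem_max")
        if (self.linker_min is None) != (self.linker_max is None):
            raise ConfigError("linker_min and linker_max must be set together")
        if self.linker_min is not None and not 1 <= self.linker_min <= self.linker_max:
            raise ConfigError("need 1 <= linker_min <= linker_max")
        if self.background not in ("sequence", "model", "uniform"):
            raise ConfigError(f"unknown background mode {self.background!r}")
        if not 1 <= self.term_stem_min <= self.term_stem_max:
            raise ConfigError("need 1 <= term_stem_min <= term_stem_max")
        if not 0 <= self.term_loop_min <= self.term_loop_max:
            raise ConfigError("need 0 <= term_loop_min <= term_loop_max")
        if not 0.0 < self.term_tail_decay <= 1.0:
            raise ConfigError("term_tail_decay must be in (0, 1]")
        if self.overlap_min < 1:
            raise ConfigError("overlap_min must be >= 1")
        if not 1 <= self.rbs_min_match <= 6:
            raise ConfigError("rbs_min_match must be in 1..6")
        if self.rbs_spacing_min > self.rbs_spacing_max:
            raise ConfigError("rbs_spacing_min must be <= rbs_spacing_max")

    # -- derived -----------------------------------------------------------
    def terminator_params(self) -> TerminatorParams:
        return TerminatorParams(
            stem_min=self.term_stem_min, stem_max=self.term_stem_max,
            loop_min=self.term_loop_min, loop_max=self.term_loop_max,
            max_mismatches=self.term_max_mismatches,
            hairpin_min_score=self.term_hairpin_min_score,
            tail_min_score=self.term_tail_min_score,
            tail_window=self.term_tail_window,
            tail_decay=self.term_tail_decay,
        )

    @property
    def linker_bounds(self) -> tuple[int, int] | None:
        if self.linker_min is None:
            return None
        return (self.linker_min, self.linker_max)

    # -- load / dump -------------------------------------------------------
    @classmethod
    def from_mapping(cls, data: dict) -> "PipelineConfig":
        known = {f.name for f in fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        try:
            return cls(**data)
        except TypeError as exc:
            raise ConfigError(str(exc)) from exc

    @classmethod
    def load(cls, path: str | Path) -> "PipelineConfig":
        text = Path(path).read_text()
        data = yaml.safe_load(text)
        if data is None:
            data = {}
        if not isinstance(data, dict):
            raise ConfigError(f"{path} must contain a YAML mapping")
        return cls.from_mapping(data)

    def with_overrides(self, **kwargs) -> "PipelineConfig":
        """A copy with the given keys replaced (None values are ignored)."""
        updates = {k: v for k, v in kwargs.items() if v is not None}
        return replace(self, **updates)

    def to_dict(self) -> dict:
        return asdict(self)

    def dump(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))
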