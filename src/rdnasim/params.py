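"""Scenario parameterisation and configuration-file handling.

A :class:`ScenarioParams` instance fully describes one simulated condition:
the germline geometry (number of flies, GSCs per fly, divisions, cyst
size), the unequal sister chromatid exchange (USCE) rates in the stem-cell
and transit-amplifying compartments, and the inheritance bias of the
expanded chromatid at asymmetric GSC divisions.

Configuration files (YAML or JSON) map scenario labels to parameter
mappings; unknown keys are rejected so that a typo never silently falls
back to a default.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping, Optional

import yaml

#: Conventions for the per-event copy-number change ``delta``.
#:
#: ``"signed"``   -- the drawn Normal(sqrt(CN), sqrt(CN)) value is kept as
#:                   drawn (a negative draw reverses which daughter gains);
#:                   preserves the stated mean of the change exactly.
#: ``"censored"`` -- negative draws are truncated to 0, so every USCE event
#:                   moves copies toward the designated gaining daughter.
DELTA_MODES = ("signed", "censored")

#: Placement schemes for USCE within the 15 cell divisions of one cyst.
SG_USCE_MODES = ("per_cyst", "per_division")


@dataclass(frozen=True)
class ScenarioParams:
    """Full parameter set of one simulated scenario.

    Parameters
    ----------
    initial_cn
        rDNA copy number of every GSC at the start of the simulation.
    n_divisions
        Number of asymmetric GSC divisions per lineage (28 = one division
        every 12 h for two weeks).
    division_interval_h
        Hours between GSC divisions.  Informational only; the simulation
        is event-driven per division.
    n_gsc_per_fly, n_flies
        Germline geometry: independent GSC lineages per testis and number
        of animals simulated.
    usce_freq_gsc
        Probability that a GSC division involves a USCE event.
    usce_freq_sg
        Probability that the cyst descending from one GSC division
        experiences a USCE event during its transit-amplifying divisions.
    gsc_gain_bias
        Probability that the self-renewing GSC (rather than the
        gonialblast) receives the chromatid carrying the drawn copy-number
        change.  0.5 is unbiased inheritance.
    sperm_per_division
        Terminal cells produced per GSC division (16, from four symmetric
        spermatogonial doublings).  Meiosis is not modelled.
    sg_rounds
        Number of symmetric doublings in the cyst; must satisfy
        ``sperm_per_division == 2 ** sg_rounds``.
    seed
        Top-level seed; per-fly and per-GSC substreams are derived from it
        deterministically.
    delta_mode, delta_discrete
        Convention for the USCE magnitude draw (see :data:`DELTA_MODES`);
        when ``delta_discrete`` the draw is rounded to an integer count of
        repeat units.
    sg_usce_mode
        ``"per_cyst"`` places at most one USCE event uniformly among the
        15 cyst divisions with probability ``usce_freq_sg``;
        ``"per_division"`` gives each of the 15 divisions an independent
        event probability ``usce_freq_sg / 15`` (same expected event
        count, different tail behaviour).
    pool_last_k
        If set, only sperm from the last ``k`` GSC divisions enter the
        pooled output (sensitivity switch; default pools all divisions).
    delta_override
        Test-only hook: fixes every delta draw at a constant, making
        lineage trajectories exactly computable.  Never set in scientific
        presets.
    label
        Scenario name used in outputs and logs.
    """

    initial_cn: int = 100
    n_divisions: int = 28
    division_interval_h: float = 12.0
    n_gsc_per_fly: int = 10
    n_flies: int = 100
    usce_freq_gsc: float = 0.04
    usce_freq_sg: float = 0.0
    gsc_gain_bias: float = 0.5
    sperm_per_division: int = 16
    sg_rounds: int = 4
    seed: int = 0
    delta_mode: str = "signed"
    delta_discrete: bool = True
    sg_usce_mode: str = "per_cyst"
    pool_last_k: Optional[int] = None
    delta_override: Optional[int] = None
    label: str = ""

    def __post_init__(self) -> None:
        if self.initial_cn < 0:
            raise ValueError("initial_cn must be >= 0")
        for name in ("n_divisions", "n_gsc_per_fly", "n_flies",
                     "sperm_per_division", "sg_rounds"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        for name in ("usce_freq_gsc", "usce_freq_sg", "gsc_gain_bias"):
            p = getattr(self, name)
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {p}")
        if self.sperm_per_division != 2 ** self.sg_rounds:
            raise ValueError(
                "sperm_per_division must equal 2**sg_rounds "
                f"({self.sperm_per_division} != 2**{self.sg_rounds})"
            )
        if self.delta_mode not in DELTA_MODES:
            raise ValueError(f"delta_mode must be one of {DELTA_MODES}")
        if self.sg_usce_mode not in SG_USCE_MODES:
            raise ValueError(f"sg_usce_mode must be one of {SG_USCE_MODES}")
        if self.pool_last_k is not None and not (
            1 <= self.pool_last_k <= self.n_divisions
        ):
            raise ValueError("pool_last_k must be in [1, n_divisions]")
        if self.delta_override is not None and self.delta_override < 0:
            raise ValueError("delta_override must be >= 0")

    # -- (de)serialisation -------------------------------------------------

    @classmethod
    def from_mapping(cls, mapping: Mapping[str, Any],
                     **overrides: Any) -> "ScenarioParams":
        """Build params from a config mapping, rejecting unknown keys."""
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(mapping) - known
        if unknown:
            raise ValueError(
                f"unknown scenario parameter(s): {sorted(unknown)}"
            )
        merged = {**dict(mapping), **overrides}
        return cls(**merged)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def replace(self, **changes: Any) -> "ScenarioParams":
        return dataclasses.replace(self, **changes)

    @property
    def cyst_divisions(self) -> int:
        """Cell divisions within one cyst (1 -> 2 -> ... -> 16: 15)."""
        return 2 ** self.sg_rounds - 1


@dataclass(frozen=True)
class ComparisonRequest:
    """A requested shift-equivalence comparison between two scenarios."""

    x: str
    y: str
    margin: float = 1.0
    threshold: float = 0.95

    def __post_init__(self) -> None:
        if self.margin < 0:
            raise ValueError("margin must be >= 0")
        if not 0.0 < self.threshold < 1.0:
            raise ValueError("threshold must be in (0, 1)")


@dataclass
class RunConfig:
    """A scenario set plus optional comparison requests (one config file)."""

    scenarios: dict[str, ScenarioParams] = field(default_factory=dict)
    comparisons: list[ComparisonRequest] = field(default_factory=list)

    def __post_init__(self) -> None:
        for cmp_ in self.comparisons:
            for lbl in (cmp_.x, cmp_.y):
                if lbl not in self.scenarios:
                    raise ValueError(
                        f"comparison references unknown scenario {lbl!r}"
                    )

    @classmethod
    def from_mapping(cls, mapping: Mapping[str, Any],
                     seed: Optional[int] = None) -> "RunConfig":
        # "expected" blocks (written by fixture serialisation) are read by
        # the test harness only and ignored here.
        unknown = set(mapping) - {"scenarios", "comparisons", "expected"}
        if unknown:
            raise ValueError(f"unknown config section(s): {sorted(unknown)}")
        raw = mapping.get("scenarios", {})
        if not isinstance(raw, Mapping):
            raise ValueError("'scenarios' must map labels to parameter sets")
        scenarios: dict[str, ScenarioParams] = {}
        for label, entry in raw.items():
            overrides: dict[str, Any] = {"label": str(label)}
            if seed is not None:
                overrides["seed"] = seed
            scenarios[str(label)] = ScenarioParams.from_mapping(
                entry or {}, **overrides
            )
        comparisons = [
            ComparisonRequest(**entry)
            for entry in mapping.get("comparisons", [])
        ]
        return cls(scenarios=scenarios, comparisons=comparisons)

    @classmethod
    def from_file(cls, path: str | Path,
                  seed: Optional[int] = None) -> "RunConfig":
        path = Path(path)
        text = path.read_text()
        if path.suffix.lower() == ".json":
            mapping = json.loads(text)
        else:
            mapping = yaml.safe_load(text)
        if mapping is None:
            mapping = {}
        return cls.from_mapping(mapping, seed=seed)
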