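"""Self-validating synthetic test scenarios with known ground truth.

A :class:`FixtureSpec` bundles a scenario, a seed, and an ``expected``
block describing what its pooled sperm distribution must look like.
Expected entries are either exact (degenerate scenarios whose outcome is
forced) or ``{"center": c, "tol": t}`` bands for stochastic checks.
Running :func:`validate_fixture` is a complete test with no external
files.

The deterministic fixtures exploit two degenerate limits of the model:
with both USCE frequencies at zero every sperm carries the initial copy
number exactly, and with ``usce_freq_gsc = 1``, a fixed ``delta_override``
and bias 0 or 1 the GSC trajectory is an arithmetic progression (until
the copy number floor engages).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Any, Optional

import numpy as np
import yaml

from .params import ScenarioParams
from .runner import simulate_scenario

__all__ = [
    "FixtureSpec",
    "ValidationReport",
    "make_zero_usce_fixture",
    "make_forced_usce_fixture",
    "make_study_presets",
    "validate_fixture",
]


@dataclass(frozen=True)
class FixtureSpec:
    """A named scenario plus its expected summary values."""

    name: str
    params: ScenarioParams
    expected: dict[str, Any]
    seed: int

    def to_dict(self) -> dict:
        return {
            "name": self.name,
            "params": self.params.to_dict(),
            "expected": self.expected,
            "seed": self.seed,
        }

    def to_yaml(self) -> str:
        """Serialise in the user config format plus an ``expected`` block."""
        return yaml.safe_dump(
            {"scenarios": {self.name: self.params.to_dict()},
             "expected": {self.name: self.expected}},
            sort_keys=False,
        )


@dataclass
class ValidationReport:
    """Outcome of checking one fixture against its expected block."""

    name: str
    passed: bool
    checks: dict[str, dict] = field(default_factory=dict)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def make_zero_usce_fixture(
    initial_cn: int,
    n_divisions: int,
    n_flies: int,
    seed: int = 0,
    n_gsc_per_fly: int = 10,
) -> FixtureSpec:
    """Scenario with no USCE anywhere: every sperm equals ``initial_cn``."""
    params = ScenarioParams(
        label=f"zero-usce-cn{initial_cn}",
        initial_cn=initial_cn,
        n_divisions=n_divisions,
        n_flies=n_flies,
        n_gsc_per_fly=n_gsc_per_fly,
        usce_freq_gsc=0.0,
        usce_freq_sg=0.0,
        seed=seed,
    )
    n_sperm = (n_flies * n_gsc_per_fly * n_divisions
               * params.sperm_per_division)
    return FixtureSpec(
        name=params.label,
        params=params,
        expected={
            "n_sperm": n_sperm,
            "constant_cn": initial_cn,
            "mean_cn": initial_cn,
            "median_cn": initial_cn,
            "max_cn": initial_cn,
        },
        seed=seed,
    )


def make_forced_usce_fixture(
    initial_cn: int,
    bias: float,
    delta: int = 5,
    n_divisions: int = 4,
    seed: int = 0,
) -> FixtureSpec:
    """Deterministic-USCE stress fixture (event every division, fixed delta).

    With bias 1 the GSC gains ``delta`` at every division and the
    gonialblast mirrors it; with bias 0 the GSC loses until the copy
    number floor at 0 engages (the delta is capped at the current copy
    number, so the lineage is absorbed at 0).  The expected GSC
    trajectory is computed in closed form.
    """
    if bias not in (0.0, 1.0, 0, 1):
        raise ValueError("forced fixture requires bias 0 or 1")
    params = ScenarioParams(
        label=f"forced-usce-bias{int(bias)}",
        initial_cn=initial_cn,
        n_divisions=n_divisions,
        n_flies=1,
        n_gsc_per_fly=1,
        usce_freq_gsc=1.0,
        usce_freq_sg=0.0,
        gsc_gain_bias=float(bias),
        delta_override=delta,
        seed=seed,
    )
    sign = 1 if bias else -1
    gsc_traj: list[int] = []
    gb_traj: list[int] = []
    c = initial_cn
    for _ in range(n_divisions):
        step = min(delta, c)  # delta capped at current CN
        gsc = c + sign * step
        gb = c - sign * step
        gsc_traj.append(gsc)
        gb_traj.append(gb)
        c = gsc
    return FixtureSpec(
        name=params.label,
        params=params,
        expected={"gsc_trajectory": gsc_traj, "gb_trajectory": gb_traj},
        seed=seed,
    )


def make_study_presets(seed: int = 0) -> list[FixtureSpec]:
    """The six canonical scenarios with their expected pooled means.

    Stochastic centers carry a +/-5% tolerance, covering Monte-Carlo
    error plus the discretisation and truncation conventions that the
    model leaves open; qualitative expectations are encoded as bounds.
    """
    from .runner import panel_presets

    presets = {p.label: p for p in panel_presets(seed)}
    expected: dict[str, dict[str, Any]] = {
        "nonmagnifying": {
            "mean_cn": {"center": 200.0, "tol": 2.0},
            "frac_above_twofold": {"max": 0.001},
        },
        "gsc-usce-bias20": {"mean_cn": {"max": 100.0}},
        "gsc-usce-bias50": {"mean_cn": {"center": 100.0, "tol": 5.0}},
        "gsc-usce-bias80": {
            "mean_cn": {"center": 136.3, "tol": 136.3 * 0.05},
            "frac_above_twofold": {"min": 0.001},
            "frac_below_initial": {"min": 0.001},
        },
        "sg-usce-bias80": {"mean_cn": {"center": 100.0, "tol": 5.0}},
        "gsc-sg-usce-bias80": {
            "mean_cn": {"center": 135.9, "tol": 135.9 * 0.05},
        },
    }
    return [
        FixtureSpec(name=label, params=presets[label],
                    expected=expected[label], seed=seed)
        for label in presets
    ]


def _check(value: float, spec: Any) -> tuple[bool, str]:
    if isinstance(spec, dict):
        ok = True
        parts = []
        if "center" in spec:
            ok &= abs(value - spec["center"]) <= spec["tol"]
            parts.append(f"|{value:.3f} - {spec['center']}| <= {spec['tol']}")
        if "min" in spec:
            ok &= value >= spec["min"]
            parts.append(f"{value:.4f} >= {spec['min']}")
        if "max" in spec:
            ok &= value <= spec["max"]
            parts.append(f"{value:.4f} <= {spec['max']}")
        return bool(ok), "; ".join(parts)
    return value == spec, f"{value} == {spec}"


def validate_fixture(fixture: FixtureSpec) -> ValidationReport:
    """Run a fixture's scenario and compare against its expected block."""
    params = fixture.params.replace(seed=fixture.seed)
    pool, summary = simulate_scenario(params)
    report = ValidationReport(name=fixture.name, passed=True)

    summary_fields = summary.to_dict()
    for key, spec in fixture.expected.items():
        if key == "constant_cn":
            ok = bool((pool["sperm_cn"] == spec).all())
            detail = f"all sperm CN == {spec}"
        elif key in ("gsc_trajectory", "gb_trajectory"):
            side = "gsc_cn" if key.startswith("gsc") else "gb_cn"
            trace_params = params
            from .runner import simulate_lineage

            trace = simulate_lineage(
                trace_params, np.random.SeedSequence(fixture.seed)
            )
            actual = [getattr(r, side) for r in trace.records]
            ok = actual == list(spec)
            detail = f"{side} trajectory {actual} == {list(spec)}"
        elif key in summary_fields:
            ok, detail = _check(summary_fields[key], spec)
        else:
            ok, detail = False, f"unknown expected field {key!r}"
        report.checks[key] = {"passed": bool(ok), "detail": detail}
        report.passed &= bool(ok)
    return report


def validate_all(fixtures: Optional[list[FixtureSpec]] = None
                 ) -> list[ValidationReport]:
    """Validate a list of fixtures (default: deterministic ones + presets)."""
    if fixtures is None:
        fixtures = [
            make_zero_usce_fixture(100, 3, 2),
            make_zero_usce_fixture(0, 5, 1),
            make_forced_usce_fixture(100, 1),
            make_forced_usce_fixture(100, 0),
            make_forced_usce_fixture(10, 0, delta=20),
            *make_study_presets(),
        ]
    return [validate_fixture(f) for f in fixtures]
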