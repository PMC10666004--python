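"""Whole-scenario orchestration: lineages -> flies -> pooled sperm.

One scenario simulates ``n_flies * n_gsc_per_fly`` independent GSC
lineages.  Each lineage runs ``n_divisions`` asymmetric GSC divisions;
every division's gonialblast is expanded into 16 terminal cells
("sperm"), and sperm from all divisions of all lineages are pooled into
one distribution per scenario.

Randomness is organised as a spawn tree of :class:`numpy.random.SeedSequence`:
the scenario seed spawns one child per fly, each fly one child per GSC,
and each GSC two independent streams (GSC divisions / cyst expansions).
Fly-level results are therefore reproducible and order-independent, and
scenarios differing only in cyst-level activity share identical GSC
trajectories when run with the same seed (common random numbers).
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Sequence, Union

import numpy as np
import pandas as pd

from .core import DivisionRecord, LineageState, cyst_expansion, gsc_division
from .params import ScenarioParams

__all__ = [
    "LineageTrace",
    "ScenarioSummary",
    "PanelSuiteResult",
    "simulate_lineage",
    "simulate_scenario",
    "run_panel_suite",
    "panel_presets",
    "write_pool",
]

logger = logging.getLogger(__name__)

#: Columns of a sperm-pool table.
POOL_COLUMNS = ("fly_id", "gsc_id", "division_index", "sperm_cn")

RandomSource = Union[int, np.random.SeedSequence, np.random.Generator]


@dataclass
class LineageTrace:
    """Full trace of one GSC lineage: division records and per-division sperm."""

    records: list[DivisionRecord]
    sperm: list[np.ndarray]
    final_state: LineageState

    @property
    def all_sperm(self) -> np.ndarray:
        return np.concatenate(self.sperm) if self.sperm else np.empty(0, int)


@dataclass
class ScenarioSummary:
    """Summary statistics of one scenario's pooled sperm distribution."""

    label: str
    n_sperm: int
    mean_cn: float
    median_cn: float
    frac_above_initial: float
    frac_below_initial: float
    frac_above_twofold: float
    max_cn: int
    per_fly_means: list[float]
    params: dict

    @property
    def mean_of_fly_means(self) -> float:
        return float(np.mean(self.per_fly_means))

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["mean_of_fly_means"] = self.mean_of_fly_means
        return d


def _streams(entropy: RandomSource) -> tuple[np.random.Generator, np.random.Generator]:
    """Derive the (GSC-division, cyst-expansion) stream pair."""
    if isinstance(entropy, np.random.Generator):
        return entropy, entropy
    if not isinstance(entropy, np.random.SeedSequence):
        entropy = np.random.SeedSequence(entropy)
    gsc_ss, cyst_ss = entropy.spawn(2)
    return np.random.default_rng(gsc_ss), np.random.default_rng(cyst_ss)


def simulate_lineage(params: ScenarioParams, entropy: RandomSource) -> LineageTrace:
    """Simulate one GSC lineage over ``params.n_divisions`` divisions.

    ``entropy`` may be an integer seed, a :class:`~numpy.random.SeedSequence`
    (two independent substreams are derived for GSC divisions and cyst
    expansions), or an existing :class:`~numpy.random.Generator` (used for
    both, e.g. in micro-tests).
    """
    gsc_rng, cyst_rng = _streams(entropy)
    state = LineageState(current_cn=params.initial_cn)
    records: list[DivisionRecord] = []
    sperm: list[np.ndarray] = []
    for _ in range(params.n_divisions):
        rec = gsc_division(state, params, gsc_rng)
        records.append(rec)
        sperm.append(cyst_expansion(rec.gb_cn, params, cyst_rng))
    return LineageTrace(records=records, sperm=sperm, final_state=state)


def _summarise(label: str, pool: pd.DataFrame,
               params: ScenarioParams) -> ScenarioSummary:
    cn = pool["sperm_cn"].to_numpy()
    initial = params.initial_cn
    per_fly = (
        pool.groupby("fly_id", sort=True)["sperm_cn"].mean().tolist()
    )
    return ScenarioSummary(
        label=label,
        n_sperm=int(cn.size),
        mean_cn=float(cn.mean()),
        median_cn=float(np.median(cn)),
        frac_above_initial=float((cn > initial).mean()),
        frac_below_initial=float((cn < initial).mean()),
        frac_above_twofold=float((cn > 2 * initial).mean()),
        max_cn=int(cn.max()),
        per_fly_means=per_fly,
        params=params.to_dict(),
    )


def simulate_scenario(
    params: ScenarioParams,
) -> tuple[pd.DataFrame, ScenarioSummary]:
    """Simulate a whole scenario and pool sperm across flies and divisions.

    Returns the sperm pool (one row per sperm: ``fly_id``, ``gsc_id``,
    ``division_index``, ``sperm_cn``) and its :class:`ScenarioSummary`.
    Fully reproducible given ``params.seed``.
    """
    label = params.label or "scenario"
    logger.info(
        "simulating scenario %s: %d flies x %d GSCs x %d divisions",
        label, params.n_flies, params.n_gsc_per_fly, params.n_divisions,
    )
    root = np.random.SeedSequence(params.seed)
    fly_seqs = root.spawn(params.n_flies)

    first_kept = 1
    if params.pool_last_k is not None:
        first_kept = params.n_divisions - params.pool_last_k + 1

    fly_ids: list[np.ndarray] = []
    gsc_ids: list[np.ndarray] = []
    div_idx: list[np.ndarray] = []
    cns: list[np.ndarray] = []
    spd = params.sperm_per_division
    for fly, fly_ss in enumerate(fly_seqs):
        logger.debug("fly %d: spawning %d GSC substreams",
                     fly, params.n_gsc_per_fly)
        for gsc, gsc_ss in enumerate(fly_ss.spawn(params.n_gsc_per_fly)):
            trace = simulate_lineage(params, gsc_ss)
            for rec, cells in zip(trace.records, trace.sperm):
                if rec.division_index < first_kept:
                    continue
                cns.append(cells)
                div_idx.append(np.full(spd, rec.division_index, np.int64))
                gsc_ids.append(np.full(spd, gsc, np.int64))
                fly_ids.append(np.full(spd, fly, np.int64))

    pool = pd.DataFrame(
        {
            "fly_id": np.concatenate(fly_ids),
            "gsc_id": np.concatenate(gsc_ids),
            "division_index": np.concatenate(div_idx),
            "sperm_cn": np.concatenate(cns),
        }
    )
    summary = _summarise(label, pool, params)
    logger.info(
        "scenario %s: n=%d sperm, mean CN %.1f, median CN %.1f",
        label, summary.n_sperm, summary.mean_cn, summary.median_cn,
    )
    return pool, summary


# ---------------------------------------------------------------------------
# Built-in scenario presets (the magnifying / nonmagnifying study matrix)
# ---------------------------------------------------------------------------

def panel_presets(seed: int) -> list[ScenarioParams]:
    """The six canonical scenarios of the simulation study.

    * ``nonmagnifying`` -- initial CN 200, rare USCE (4%) in GSCs only,
      unbiased inheritance.
    * ``gsc-usce-bias{20,50,80}`` -- magnifying condition (initial CN
      100), USCE in GSCs at 50% of divisions, inheritance bias 20/50/80%.
    * ``sg-usce-bias80`` -- USCE mainly in the transit-amplifying cyst
      (50% per cyst), GSC USCE kept at the 4% baseline with bias 80%.
    * ``gsc-sg-usce-bias80`` -- USCE at 50% in both compartments,
      bias 80%.

    All presets share ``seed`` so that scenarios differing only in cyst
    activity are coupled through common GSC-division random numbers.
    """
    common = dict(seed=seed)
    return [
        ScenarioParams(
            label="nonmagnifying", initial_cn=200,
            usce_freq_gsc=0.04, usce_freq_sg=0.0, gsc_gain_bias=0.5,
            **common,
        ),
        ScenarioParams(
            label="gsc-usce-bias20", initial_cn=100,
            usce_freq_gsc=0.5, usce_freq_sg=0.0, gsc_gain_bias=0.2,
            **common,
        ),
        ScenarioParams(
            label="gsc-usce-bias50", initial_cn=100,
            usce_freq_gsc=0.5, usce_freq_sg=0.0, gsc_gain_bias=0.5,
            **common,
        ),
        ScenarioParams(
            label="gsc-usce-bias80", initial_cn=100,
            usce_freq_gsc=0.5, usce_freq_sg=0.0, gsc_gain_bias=0.8,
            **common,
        ),
        ScenarioParams(
            label="sg-usce-bias80", initial_cn=100,
            usce_freq_gsc=0.04, usce_freq_sg=0.5, gsc_gain_bias=0.8,
            **common,
        ),
        ScenarioParams(
            label="gsc-sg-usce-bias80", initial_cn=100,
            usce_freq_gsc=0.5, usce_freq_sg=0.5, gsc_gain_bias=0.8,
            **common,
        ),
    ]


@dataclass
class PanelSuiteResult:
    """Outcome of a batch of scenarios."""

    summaries: pd.DataFrame
    pools: dict[str, pd.DataFrame] = field(default_factory=dict)
    errors: dict[str, str] = field(default_factory=dict)


_SUMMARY_TABLE_COLS = [
    "label", "n_sperm", "mean_cn", "median_cn", "frac_above_initial",
    "frac_below_initial", "frac_above_twofold", "max_cn",
    "mean_of_fly_means",
]


def run_panel_suite(
    scenarios: Sequence[ScenarioParams],
    out_dir: Optional[Union[str, Path]] = None,
    fmt: str = "tsv",
    keep_pools: bool = True,
) -> PanelSuiteResult:
    """Run a set of scenarios, collecting one summary row per scenario.

    Scenario labels must be unique.  A failing scenario is reported under
    its label and the suite continues.  With ``out_dir`` set, each pool is
    persisted (TSV or JSON) together with a combined ``summary.json`` that
    echoes every effective parameter.
    """
    labels = [s.label for s in scenarios]
    dupes = {l for l in labels if labels.count(l) > 1}
    if dupes:
        raise ValueError(f"duplicate scenario labels: {sorted(dupes)}")

    out_path = Path(out_dir) if out_dir is not None else None
    if out_path is not None:
        out_path.mkdir(parents=True, exist_ok=True)

    rows: list[dict] = []
    pools: dict[str, pd.DataFrame] = {}
    errors: dict[str, str] = {}
    summaries_json: dict[str, dict] = {}
    for params in scenarios:
        try:
            pool, summary = simulate_scenario(params)
        except Exception as exc:  # pragma: no cover - defensive
            logger.error("scenario %s failed: %s", params.label, exc)
            errors[params.label] = str(exc)
            continue
        row = summary.to_dict()
        rows.append({k: row[k] for k in _SUMMARY_TABLE_COLS})
        summaries_json[params.label] = summary.to_dict()
        if keep_pools:
            pools[params.label] = pool
        if out_path is not None:
            write_pool(pool, out_path / f"{params.label}.{fmt}", fmt=fmt)
    if out_path is not None:
        (out_path / "summary.json").write_text(
            json.dumps(summaries_json, indent=2) + "\n"
        )
    table = pd.DataFrame(rows, columns=_SUMMARY_TABLE_COLS)
    return PanelSuiteResult(summaries=table, pools=pools, errors=errors)


def write_pool(pool: pd.DataFrame, path: Union[str, Path],
               fmt: str = "tsv") -> None:
    """Persist a sperm pool as TSV (tab-separated, Unix newlines) or JSON."""
    path = Path(path)
    if fmt == "tsv":
        pool.to_csv(path, sep="\t", index=False, lineterminator="\n")
    elif fmt == "json":
        pool.to_json(path, orient="records")
    else:
        raise ValueError(f"unknown pool format {fmt!r}")


def read_pool(path: Union[str, Path]) -> pd.DataFrame:
    """Read a sperm pool written by :func:`write_pool` (TSV or JSON)."""
    path = Path(path)
    if path.suffix == ".json":
        pool = pd.read_json(path, orient="records")
    else:
        pool = pd.read_csv(path, sep="\t")
    missing = set(POOL_COLUMNS) - set(pool.columns)
    if missing:
        raise ValueError(f"pool file {path} lacks column(s) {sorted(missing)}")
    return pool
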