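"""Per-division stochastic engine for rDNA copy-number change.

Three primitives:

* :func:`draw_usce_delta` -- the magnitude of one unequal sister chromatid
  exchange (USCE), drawn from Normal(sqrt(CN), sqrt(CN)).
* :func:`gsc_division` -- one asymmetric germline stem cell division with
  biased inheritance of the exchanged chromatid.
* :func:`cyst_expansion` -- four symmetric transit-amplifying doublings of
  the gonialblast, yielding 16 terminal cells, with optional USCE within
  the cyst.

Every exchange is reciprocal: one daughter gains what the other loses, so
the two daughters of any division always sum to exactly twice the parent
copy number.  A single exchange can at most double a chromatid (the gain
is capped at the parent copy number), and copy numbers never go negative;
a lineage that reaches 0 copies stays there.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional

import numpy as np

from .params import ScenarioParams

__all__ = [
    "LineageState",
    "DivisionRecord",
    "draw_usce_delta",
    "gsc_division",
    "cyst_expansion",
]


@dataclass
class LineageState:
    """Current copy number of one GSC lineage plus its division count."""

    current_cn: int
    divisions_completed: int = 0

    def __post_init__(self) -> None:
        if self.current_cn < 0:
            raise ValueError("current_cn must be >= 0")
        if self.divisions_completed < 0:
            raise ValueError("divisions_completed must be >= 0")


@dataclass(frozen=True)
class DivisionRecord:
    """Outcome of one GSC division.

    ``delta`` is the signed copy-number change applied to the GSC side
    (the gonialblast receives the opposite change), so
    ``gsc_cn + gb_cn == 2 * parent_cn`` always holds.  Without USCE,
    ``delta`` is 0 and both daughters equal the parent.
    """

    division_index: int
    usce_occurred: bool
    delta: int
    gsc_cn: int
    gb_cn: int


def draw_usce_delta(
    current_cn: int,
    rng: np.random.Generator,
    *,
    mode: str = "signed",
    discrete: bool = True,
    override: Optional[float] = None,
):
    """Draw the copy-number change of one USCE event.

    The change follows Normal(mean=sqrt(current_cn), sd=sqrt(current_cn)),
    bounded so that neither chromatid can drop below zero copies
    (``|delta| <= current_cn``; one exchange at most doubles a chromatid).

    Parameters
    ----------
    current_cn
        Copy number of the cell at the time of the exchange.
    rng
        Seeded :class:`numpy.random.Generator`.
    mode
        ``"signed"`` keeps the draw as drawn: a negative value means the
        nominally gaining chromatid actually loses copies, preserving the
        stated mean sqrt(CN) of the change exactly.  ``"censored"``
        truncates negative draws to 0, so the event is always a transfer
        toward the gaining chromatid (this inflates the mean change to
        ~1.083*sqrt(CN)).
    discrete
        Round to the nearest whole repeat unit (default).
    override
        Test-only constant replacing the random draw.

    Returns
    -------
    int or float
        The change; in ``"censored"`` mode within ``[0, current_cn]``, in
        ``"signed"`` mode within ``[-current_cn, current_cn]``.
    """
    if current_cn < 0:
        raise ValueError("current_cn must be >= 0")
    if override is not None:
        d = float(override)
    else:
        root = math.sqrt(current_cn)
        d = rng.normal(root, root) if current_cn > 0 else 0.0
    if mode == "censored":
        d = min(max(d, 0.0), float(current_cn))
    elif mode == "signed":
        d = min(max(d, -float(current_cn)), float(current_cn))
    else:
        raise ValueError(f"unknown delta mode {mode!r}")
    return int(round(d)) if discrete else d


def gsc_division(
    state: LineageState,
    params: ScenarioParams,
    rng: np.random.Generator,
) -> DivisionRecord:
    """Perform one asymmetric GSC division, advancing ``state`` in place.

    With probability ``usce_freq_gsc`` a USCE occurs and a change is
    drawn; with probability ``gsc_gain_bias`` the self-renewing GSC
    receives the chromatid carrying the drawn change (parent + delta) and
    the gonialblast the reciprocal (parent - delta), otherwise the roles
    are swapped.  Without USCE both daughters inherit the parent copy
    number unchanged.

    Stream discipline (one division consumes, in order): the event
    uniform; if an event occurred, the Normal draw and the direction
    uniform.
    """
    parent = state.current_cn
    idx = state.divisions_completed + 1
    if rng.random() < params.usce_freq_gsc:
        d = draw_usce_delta(
            parent,
            rng,
            mode=params.delta_mode,
            discrete=params.delta_discrete,
            override=params.delta_override,
        )
        if rng.random() < params.gsc_gain_bias:
            applied = d
        else:
            applied = -d
        record = DivisionRecord(
            division_index=idx,
            usce_occurred=True,
            delta=applied,
            gsc_cn=parent + applied,
            gb_cn=parent - applied,
        )
    else:
        record = DivisionRecord(
            division_index=idx,
            usce_occurred=False,
            delta=0,
            gsc_cn=parent,
            gb_cn=parent,
        )
    state.current_cn = record.gsc_cn
    state.divisions_completed = idx
    return record


def cyst_expansion(
    gb_cn: int,
    params: ScenarioParams,
    rng: np.random.Generator,
) -> np.ndarray:
    """Expand one gonialblast into ``sperm_per_division`` terminal cells.

    The gonialblast undergoes ``sg_rounds`` symmetric doublings
    (1 -> 2 -> 4 -> 8 -> 16 cells; 15 cell divisions in total).  USCE may
    occur within the cyst: in ``"per_cyst"`` mode, with probability
    ``usce_freq_sg`` exactly one event is applied at a uniformly chosen
    division; in ``"per_division"`` mode each division is an independent
    Bernoulli event with rate ``usce_freq_sg / 15`` (matched expected
    event count).  The affected division's daughters receive C + delta
    and C - delta in random (50/50) order -- the direction of change in
    the transit-amplifying compartment is always unbiased.

    Because every exchange is reciprocal, the sum of the returned values
    is exactly ``sperm_per_division * gb_cn`` regardless of events.
    """
    if gb_cn < 0:
        raise ValueError("gb_cn must be >= 0")
    n_cyst_div = params.cyst_divisions
    freq = params.usce_freq_sg

    event_divisions: frozenset[int]
    if freq == 0.0:
        event_divisions = frozenset()
    elif params.sg_usce_mode == "per_cyst":
        if rng.random() < freq:
            event_divisions = frozenset(
                {int(rng.integers(n_cyst_div))}
            )
        else:
            event_divisions = frozenset()
    else:  # per_division
        q = freq / n_cyst_div
        event_divisions = frozenset(
            i for i in range(n_cyst_div) if rng.random() < q
        )

    if not event_divisions:
        return np.full(params.sperm_per_division, gb_cn, dtype=np.int64)

    cells = [gb_cn]
    div_counter = 0
    for _ in range(params.sg_rounds):
        nxt: list[int] = []
        for cell in cells:
            if div_counter in event_divisions:
                d = draw_usce_delta(
                    cell,
                    rng,
                    mode=params.delta_mode,
                    discrete=params.delta_discrete,
                    override=params.delta_override,
                )
                if rng.random() < 0.5:
                    nxt.extend((cell + d, cell - d))
                else:
                    nxt.extend((cell - d, cell + d))
            else:
                nxt.extend((cell, cell))
            div_counter += 1
        cells = nxt
    return np.asarray(cells, dtype=np.int64)
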