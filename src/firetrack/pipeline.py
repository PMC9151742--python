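"""Season-level run loop tying ingest, tracker and outputs together.

``run_tracking`` advances an :class:`~firetrack.tracker.AllFires` state
over a step sequence, writing per-step serialization and snapshot files,
and returns the final state plus the accumulated :class:`RunHistory` from
which the large-fire and summary products are derived.  A run can start
from scratch or resume from any saved state file; resuming mid-season
produces outputs identical to an uninterrupted run.
"""

from __future__ import annotations

import logging
import os

from shapely.geometry.base import BaseGeometry

from firetrack.attributes import FuelMoistureField, LandCoverGrid
from firetrack.config import TrackerConfig
from firetrack.ingest import PixelRecord, TimeStep, filter_records, step_sequence
from firetrack.outputs import (
    RunHistory,
    save_state,
    write_largefire_series,
    write_snapshot,
    write_summary,
)
from firetrack.tracker import AllFires, advance

logger = logging.getLogger(__name__)


def run_tracking(
    records: list[PixelRecord],
    roi: BaseGeometry,
    start: TimeStep,
    end: TimeStep,
    config: TrackerConfig | None = None,
    lct_grid: LandCoverGrid | None = None,
    fm_field: FuelMoistureField | None = None,
    outdir: str | None = None,
    restart_state: AllFires | None = None,
    mode: str = "archive",
    write_products: bool = True,
) -> tuple[AllFires, RunHistory]:
    """Track fires over [start, end] and optionally write the data suite.

    With ``restart_state`` the loop resumes at that state's next step
    (``start`` is ignored); otherwise a fresh state is created one step
    before ``start``.  When ``outdir`` is given and ``write_products`` is
    true, each step writes a state file and a three-layer snapshot, and
    the season ends with the large-fire series and summary files.
    """
    config = config or TrackerConfig()
    if restart_state is not None:
        state = restart_state
        steps = step_sequence(state.t.next(), end)
    else:
        state = AllFires(t=_pred(start), config=config)
        steps = step_sequence(start, end)
    history = RunHistory()
    for step in steps:
        batch = filter_records(records, roi, step, mode=mode,
                               utc_offset_hours=config.utc_offset_hours)
        advance(state, batch, step, lct_grid=lct_grid, fm_field=fm_field)
        history.record(state)
        logger.info("step %s: %d detections, %d valid fires (%d new, %d expanded,"
                    " %d merged)", step, len(batch), len(state.valid_fires()),
                    len(state.fids_new), len(state.fids_expanded),
                    len(state.fids_merged))
        if outdir and write_products:
            sdir = os.path.join(outdir, "Serialization")
            os.makedirs(sdir, exist_ok=True)
            save_state(state, os.path.join(sdir, f"{step}.json"))
            write_snapshot(state, step, os.path.join(outdir, "Snapshot"))
    if outdir and write_products and steps:
        year = steps[-1].date.year
        write_largefire_series(history, state, year,
                               os.path.join(outdir, "Largefire"))
        write_summary(history, state, year, os.path.join(outdir, "Summary"))
    return state, history


def _pred(step: TimeStep) -> TimeStep:
    """The step immediately before ``step``."""
    import datetime as _dt
    if step.half == "PM":
        return TimeStep(step.date, "AM")
    return TimeStep(step.date - _dt.timedelta(days=1), "PM")
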