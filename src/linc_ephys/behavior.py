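"""Recognition-memory scoring: discrimination index, exclusions, summaries.

Scores two-object investigation sessions from the object-location (OLM),
object-recognition (ORM) and odor-recognition (OdorRM) tasks. Bout
annotation is an input (manual scoring in practice); this module sums
investigation time per object, forms the discrimination index

    DI = 100 · (novel − familiar) / (novel + familiar),

applies the exclusion rules (|encoding-day DI| strictly greater than 20,
or total investigation under 3 s for OLM/ORM / 2 s for OdorRM in either
phase), and assembles per-genotype × task summary tables.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .config import AnalysisConfig

logger = logging.getLogger(__name__)

_DEFAULT_CFG = AnalysisConfig()

TASKS = ("OLM", "ORM", "OdorRM")
PHASES = ("encoding", "retrieval")


@dataclass
class SessionRecord:
    """One animal's bout list for one task phase."""

    animal_id: str
    genotype: str
    task: str
    phase: str
    bouts: pd.DataFrame  # columns: object (novel|familiar), start, duration

    def __post_init__(self) -> None:
        if self.task not in TASKS:
            raise ValueError(f"task must be one of {TASKS}")
        if self.phase not in PHASES:
            raise ValueError(f"phase must be one of {PHASES}")
        if len(self.bouts) and (self.bouts["duration"] <= 0).any():
            raise ValueError("bout durations must be positive")

    def object_time(self, obj: str) -> float:
        if len(self.bouts) == 0:
            return 0.0
        return float(self.bouts.loc[self.bouts["object"] == obj, "duration"].sum())

    @property
    def total_time(self) -> float:
        return float(self.bouts["duration"].sum()) if len(self.bouts) else 0.0


@dataclass(frozen=True)
class DIResult:
    """Discrimination index of one session (None when un-scorable)."""

    di: float | None
    total_time: float
    n_bouts: int


@dataclass(frozen=True)
class ExclusionReport:
    animal_id: str
    task: str
    excluded: bool
    reasons: tuple[str, ...]  # from {"encoding-DI", "low-investigation"}


def discrimination_index(novel_time: float, familiar_time: float) -> float:
    """DI = 100·(novel − familiar)/(novel + familiar); bounded in [−100, 100]."""
    if novel_time < 0 or familiar_time < 0:
        raise ValueError("investigation times must be non-negative")
    total = novel_time + familiar_time
    if total == 0:
        raise ValueError("zero total investigation time: DI undefined")
    di = 100.0 * (novel_time - familiar_time) / total
    # guard the [−100, 100] bound against floating-point rounding
    return float(np.clip(di, -100.0, 100.0))


def score_session(session: SessionRecord) -> DIResult:
    """Sum bout durations per object and form the DI; flag empty sessions."""
    if len(session.bouts) == 0:
        logger.warning("empty session %s/%s/%s: un-scorable",
                       session.animal_id, session.task, session.phase)
        return DIResult(di=None, total_time=0.0, n_bouts=0)
    di = discrimination_index(session.object_time("novel"),
                              session.object_time("familiar"))
    return DIResult(di=di, total_time=session.total_time,
                    n_bouts=len(session.bouts))


def apply_exclusions(
    sessions: list[tuple[SessionRecord, SessionRecord]],
    config: AnalysisConfig = _DEFAULT_CFG,
) -> list[ExclusionReport]:
    """Apply the exclusion rules to (encoding, retrieval) session pairs.

    An animal is excluded when |encoding DI| strictly exceeds 20, or when
    its total investigation in *either* phase falls below the task minimum
    (3 s for OLM/ORM, 2 s for OdorRM). DI exactly ±20 is retained.
    """
    reports = []
    for enc, ret in sessions:
        if enc.phase != "encoding" or ret.phase != "retrieval":
            raise ValueError(
                f"expected (encoding, retrieval) pair for {enc.animal_id}, "
                f"got ({enc.phase}, {ret.phase})"
            )
        reasons: list[str] = []
        enc_score = score_session(enc)
        if enc_score.di is not None and abs(enc_score.di) > config.di_exclusion_bound:
            reasons.append("encoding-DI")
        minimum = (config.min_investigation_odor if enc.task == "OdorRM"
                   else config.min_investigation_olm_orm)
        if enc.total_time < minimum or ret.total_time < minimum:
            reasons.append("low-investigation")
        reports.append(ExclusionReport(
            animal_id=enc.animal_id, task=enc.task,
            excluded=bool(reasons), reasons=tuple(reasons),
        ))
    return reports


def pulse_train_schedule(
    on: float, off: float, epoch: float = 3.0, inter_epoch: float = 30.0,
    session: float = 600.0,
) -> tuple[pd.DataFrame, float]:
    """Pulse-onset schedule and duty cycle for an on/off light train.

    Pulses of ``on`` s recur every ``on + off`` s within each ``epoch``-long
    light delivery, epochs starting every ``inter_epoch`` s over the
    session. Duty cycle is 100·on/(on+off) — 33.3% for the 50 ms on /
    100 ms off behavioral train.
    """
    if on <= 0 or off <= 0:
        raise ValueError("on and off must be positive")
    if epoch > inter_epoch:
        raise ValueError("epoch must not exceed the inter-epoch interval")
    period = on + off
    if epoch < period:
        raise ValueError(
            f"epoch of {epoch:g} s shorter than one {period:g} s pulse period"
        )
    n_pulses = int(np.floor(epoch / period + 1e-9))
    rows = []
    t = 0.0
    while t + epoch <= session:
        for p in range(n_pulses):
            rows.append({"epoch_start": t, "pulse_onset": t + p * period,
                         "pulse_width": on})
        t += inter_epoch
    duty = 100.0 * on / period
    return pd.DataFrame(rows), duty


def behavior_summary(
    results: list[tuple[SessionRecord, DIResult]],
    exclusions: list[ExclusionReport],
) -> pd.DataFrame:
    """Per-genotype × task table of retrieval DIs, excluded animals omitted.

    Columns: mean DI, SD, SEM, n and mean total investigation time per
    group — the table handed to external inferential tests.
    """
    excluded = {(r.animal_id, r.task) for r in exclusions if r.excluded}
    rows = []
    for session, di in results:
        if (session.animal_id, session.task) in excluded:
            continue
        if di.di is None:
            continue
        rows.append({
            "animal_id": session.animal_id, "genotype": session.genotype,
            "task": session.task, "di": di.di, "total_time": di.total_time,
        })
    if not rows:
        raise ValueError("all animals excluded or un-scorable")
    df = pd.DataFrame(rows)
    grouped = df.groupby(["task", "genotype"])
    out = grouped.agg(
        mean_di=("di", "mean"), sd_di=("di", "std"), n=("di", "count"),
        mean_total_time=("total_time", "mean"),
    ).reset_index()
    out["sem_di"] = out["sd_di"] / np.sqrt(out["n"])
    return out
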