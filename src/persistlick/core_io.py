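"""Shared domain types and session file I/O.

A *session* is a directory of plain UTF-8 tab-separated tables sharing one
clock (seconds from recording start):

``meta.tsv``
    two columns ``key\\tvalue``; must contain ``session_duration_s``.
``units.tsv``
    columns ``unit_id, region`` — the unit roster (kept separately so a
    silent unit survives a round-trip).
``spikes.tsv``
    columns ``unit_id, region, time_s``; times ascending within unit.
``events.tsv``
    columns ``time_s, kind, liquid``; kinds are LO (lick onset), DO (liquid
    delivery onset), DELIVERY_OFF, LASER_ON, LASER_OFF, SHOCK.
``facial.tsv`` (optional)
    columns ``time_s, activity`` — a facial-motion trace.
``wheel.tsv`` (optional)
    column ``time_s`` — wheel-encoder pulse times.
``truth.tsv`` / ``truth_edges.tsv`` (optional)
    generator ground truth: per-unit class labels and planted directed edges.

All analysis windows are half-open ``[start, end)`` so no event is counted
twice on a bin edge.
"""

from __future__ import annotations

import enum
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger("persistlick")

# ---------------------------------------------------------------------------
# enums
# ---------------------------------------------------------------------------


class Region(str, enum.Enum):
    IC = "IC"
    M1 = "M1"
    mPFC = "mPFC"


class EventKind(str, enum.Enum):
    LO = "LO"
    DO = "DO"
    DELIVERY_OFF = "DELIVERY_OFF"
    LASER_ON = "LASER_ON"
    LASER_OFF = "LASER_OFF"
    SHOCK = "SHOCK"


class Liquid(str, enum.Enum):
    WATER = "water"
    SUCROSE = "sucrose"
    QUININE = "quinine"
    NONE = "none"


class ValenceClass(str, enum.Enum):
    LICK = "LICK"
    PV = "PV"
    NV = "NV"
    MV = "MV"
    UV = "UV"


class PhaseClass(str, enum.Enum):
    INITIAL_PRE = "INITIAL_PRE"
    INITIAL_POST = "INITIAL_POST"
    TERMINAL = "TERMINAL"
    UNRELATED = "UNRELATED"


# ---------------------------------------------------------------------------
# errors
# ---------------------------------------------------------------------------


class SessionParseError(ValueError):
    """A session file is malformed (names the file and offending row)."""


class SessionValidationError(ValueError):
    """A session violates a structural invariant."""


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass
class Unit:
    unit_id: str
    region: Region
    spike_times: np.ndarray  # seconds, strictly increasing

    def __post_init__(self) -> None:
        self.spike_times = np.asarray(self.spike_times, dtype=float)
        self.region = Region(self.region)


@dataclass
class SpikeTrainSet:
    units: list[Unit]
    session_duration: float

    def validate(self) -> None:
        for u in self.units:
            st = u.spike_times
            if st.size and not np.all(np.diff(st) > 0):
                raise SessionValidationError(
                    f"unit {u.unit_id}: spike times not strictly increasing"
                )
            if st.size and (st[0] < 0 or st[-1] > self.session_duration):
                raise SessionValidationError(
                    f"unit {u.unit_id}: spike times outside "
                    f"[0, {self.session_duration}]"
                )

    def unit_ids(self) -> list[str]:
        return [u.unit_id for u in self.units]

    def __getitem__(self, unit_id: str) -> Unit:
        for u in self.units:
            if u.unit_id == unit_id:
                return u
        raise KeyError(unit_id)


@dataclass
class EventLog:
    events: pd.DataFrame  # columns: time_s, kind, liquid

    @classmethod
    def from_records(
        cls, records: Sequence[tuple[float, EventKind | str, Liquid | str]]
    ) -> "EventLog":
        df = pd.DataFrame(records, columns=["time_s", "kind", "liquid"])
        df["kind"] = df["kind"].map(lambda k: EventKind(k).value)
        df["liquid"] = df["liquid"].map(lambda x: Liquid(x).value)
        return cls(df)

    def validate(self) -> None:
        t = self.events["time_s"].to_numpy()
        if t.size and np.any(np.diff(t) < 0):
            raise SessionValidationError("event times must be non-decreasing")
        do = self.events[self.events["kind"] == EventKind.DO.value]
        if (do["liquid"] == Liquid.NONE.value).any():
            raise SessionValidationError("DO events must carry a liquid type")

    def times(self, kind: EventKind, liquid: Optional[Liquid] = None) -> np.ndarray:
        m = self.events["kind"] == kind.value
        if liquid is not None:
            m &= self.events["liquid"] == liquid.value
        return self.events.loc[m, "time_s"].to_numpy(dtype=float)

    def delivery_epochs(
        self, liquid: Optional[Liquid] = None
    ) -> list[tuple[float, float, Liquid]]:
        """(onset, offset, liquid) triples, pairing each DO with the next
        DELIVERY_OFF."""
        ev = self.events
        out: list[tuple[float, float, Liquid]] = []
        offs = ev.loc[ev["kind"] == EventKind.DELIVERY_OFF.value, "time_s"].to_numpy()
        for _, row in ev[ev["kind"] == EventKind.DO.value].iterrows():
            liq = Liquid(row["liquid"])
            if liquid is not None and liq != liquid:
                continue
            later = offs[offs > row["time_s"]]
            end = float(later[0]) if later.size else np.inf
            out.append((float(row["time_s"]), end, liq))
        return out

    def licks_in(self, start: float, end: float) -> np.ndarray:
        lo = self.times(EventKind.LO)
        return lo[(lo >= start) & (lo < end)]


@dataclass
class AnalysisWindow:
    """Event-anchored half-open window [start_offset, end_offset).

    The small (S) window is (-0.100, +0.080) s around each lick onset and
    targets valence coding; the large (L) window is (-2, +3) s around the
    first lick onset of a trial and targets movement-phase coding.
    """

    kind: str  # "S" or "L"
    start_offset: float
    end_offset: float
    anchor: str  # "LO" or "FIRST_LO"

    @classmethod
    def small(cls) -> "AnalysisWindow":
        return cls("S", -0.100, 0.080, "LO")

    @classmethod
    def large(cls) -> "AnalysisWindow":
        return cls("L", -2.0, 3.0, "FIRST_LO")


@dataclass
class FacialTrace:
    times: np.ndarray
    activity: np.ndarray


@dataclass
class WheelPulseTrain:
    pulse_times: np.ndarray


@dataclass
class GeneratorTruth:
    """Ground-truth labels written by the synthetic-session generator."""

    valence: dict[str, ValenceClass]
    phase: dict[str, PhaseClass]
    edges: list[tuple[str, str, float, float]] = field(default_factory=list)
    # edges: (src unit, dst unit, lag seconds, transfer probability)
    facial_truth: Optional[np.ndarray] = None


@dataclass
class SessionBundle:
    spikes: SpikeTrainSet
    events: EventLog
    facial: Optional[FacialTrace] = None
    wheel: Optional[WheelPulseTrain] = None
    ground_truth: Optional[GeneratorTruth] = None

    def validate(self) -> None:
        self.spikes.validate()
        self.events.validate()


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------


def _read_tsv(path: Path, columns: list[str]) -> pd.DataFrame:
    if not path.exists():
        raise SessionParseError(f"{path}: missing required session file")
    try:
        df = pd.read_csv(path, sep="\t", dtype=str)
    except Exception as exc:  # pragma: no cover - pandas error text varies
        raise SessionParseError(f"{path}: {exc}") from exc
    missing = [c for c in columns if c not in df.columns]
    if missing:
        raise SessionParseError(f"{path}: missing columns {missing}")
    return df


def _to_float(df: pd.DataFrame, col: str, path: Path) -> np.ndarray:
    try:
        return df[col].astype(float).to_numpy()
    except ValueError as exc:
        bad = df.index[pd.to_numeric(df[col], errors="coerce").isna()][0]
        raise SessionParseError(
            f"{path}: line {bad + 2}: non-numeric value in column {col!r}"
        ) from exc


def read_session(path: str | Path) -> SessionBundle:
    """Read and validate a session directory."""
    path = Path(path)
    meta = _read_tsv(path / "meta.tsv", ["key", "value"])
    meta_map = dict(zip(meta["key"], meta["value"]))
    if "session_duration_s" not in meta_map:
        raise SessionParseError(f"{path / 'meta.tsv'}: missing session_duration_s")
    duration = float(meta_map["session_duration_s"])

    sp = _read_tsv(path / "spikes.tsv", ["unit_id", "region", "time_s"])
    times = _to_float(sp, "time_s", path / "spikes.tsv")
    sp = sp.assign(time_s=times)
    by_unit = {str(uid): grp for uid, grp in sp.groupby("unit_id", sort=False)}

    roster: list[tuple[str, str]] = []
    if (path / "units.tsv").exists():
        ro = _read_tsv(path / "units.tsv", ["unit_id", "region"])
        roster = [(str(r["unit_id"]), r["region"]) for _, r in ro.iterrows()]
    else:  # roster derived from the spike table
        roster = [(uid, grp["region"].iloc[0]) for uid, grp in by_unit.items()]

    units: list[Unit] = []
    for uid, region in roster:
        try:
            region = Region(region)
        except ValueError as exc:
            raise SessionParseError(f"{path}: unknown region {region!r}") from exc
        grp = by_unit.get(uid)
        st = grp["time_s"].to_numpy() if grp is not None else np.empty(0)
        units.append(Unit(uid, region, st))
    spikes = SpikeTrainSet(units, duration)

    ev = _read_tsv(path / "events.tsv", ["time_s", "kind", "liquid"])
    ev_times = _to_float(ev, "time_s", path / "events.tsv")
    try:
        events = EventLog.from_records(
            list(zip(ev_times, ev["kind"], ev["liquid"]))
        )
    except ValueError as exc:
        raise SessionParseError(f"{path / 'events.tsv'}: {exc}") from exc

    facial = None
    if (path / "facial.tsv").exists():
        fa = _read_tsv(path / "facial.tsv", ["time_s", "activity"])
        facial = FacialTrace(
            _to_float(fa, "time_s", path / "facial.tsv"),
            _to_float(fa, "activity", path / "facial.tsv"),
        )
    wheel = None
    if (path / "wheel.tsv").exists():
        wh = _read_tsv(path / "wheel.tsv", ["time_s"])
        wheel = WheelPulseTrain(_to_float(wh, "time_s", path / "wheel.tsv"))

    truth = None
    if (path / "truth.tsv").exists():
        tr = _read_tsv(path / "truth.tsv", ["unit_id", "valence_class", "phase_class"])
        valence = {
            str(r["unit_id"]): ValenceClass(r["valence_class"]) for _, r in tr.iterrows()
        }
        phase = {
            str(r["unit_id"]): PhaseClass(r["phase_class"]) for _, r in tr.iterrows()
        }
        edges: list[tuple[str, str, float, float]] = []
        if (path / "truth_edges.tsv").exists():
            ed = _read_tsv(
                path / "truth_edges.tsv", ["src", "dst", "lag_s", "strength"]
            )
            for _, r in ed.iterrows():
                edges.append(
                    (str(r["src"]), str(r["dst"]), float(r["lag_s"]), float(r["strength"]))
                )
        truth = GeneratorTruth(valence, phase, edges)

    bundle = SessionBundle(spikes, events, facial, wheel, truth)
    bundle.validate()
    return bundle


def write_session(bundle: SessionBundle, path: str | Path) -> None:
    """Write a bundle so that :func:`read_session` inverts it."""
    bundle.validate()
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)

    pd.DataFrame(
        {"key": ["session_duration_s"], "value": [repr(bundle.spikes.session_duration)]}
    ).to_csv(path / "meta.tsv", sep="\t", index=False)

    pd.DataFrame(
        {
            "unit_id": [u.unit_id for u in bundle.spikes.units],
            "region": [u.region.value for u in bundle.spikes.units],
        }
    ).to_csv(path / "units.tsv", sep="\t", index=False)
    rows = []
    for u in bundle.spikes.units:
        for t in u.spike_times:
            rows.append((u.unit_id, u.region.value, repr(float(t))))
    pd.DataFrame(rows, columns=["unit_id", "region", "time_s"]).to_csv(
        path / "spikes.tsv", sep="\t", index=False
    )

    ev = bundle.events.events.copy()
    ev["time_s"] = ev["time_s"].map(lambda t: repr(float(t)))
    ev.to_csv(path / "events.tsv", sep="\t", index=False)

    if bundle.facial is not None:
        pd.DataFrame(
            {
                "time_s": [repr(float(t)) for t in bundle.facial.times],
                "activity": [repr(float(a)) for a in bundle.facial.activity],
            }
        ).to_csv(path / "facial.tsv", sep="\t", index=False)
    if bundle.wheel is not None:
        pd.DataFrame(
            {"time_s": [repr(float(t)) for t in bundle.wheel.pulse_times]}
        ).to_csv(path / "wheel.tsv", sep="\t", index=False)
    if bundle.ground_truth is not None:
        gt = bundle.ground_truth
        pd.DataFrame(
            {
                "unit_id": list(gt.valence),
                "valence_class": [gt.valence[u].value for u in gt.valence],
                "phase_class": [gt.phase[u].value for u in gt.valence],
            }
        ).to_csv(path / "truth.tsv", sep="\t", index=False)
        if gt.edges:
            pd.DataFrame(
                [
                    (s, d, repr(float(l)), repr(float(w)))
                    for s, d, l, w in gt.edges
                ],
                columns=["src", "dst", "lag_s", "strength"],
            ).to_csv(path / "truth_edges.tsv", sep="\t", index=False)


def bundles_equal(a: SessionBundle, b: SessionBundle, atol: float = 0.0) -> bool:
    """Structural equality up to float round-trip (used by tests and the CLI)."""
    if a.spikes.unit_ids() != b.spikes.unit_ids():
        return False
    if a.spikes.session_duration != b.spikes.session_duration:
        return False
    for ua, ub in zip(a.spikes.units, b.spikes.units):
        if ua.region != ub.region or not np.allclose(
            ua.spike_times, ub.spike_times, atol=atol, rtol=0
        ):
            return False
    ea, eb = a.events.events, b.events.events
    if len(ea) != len(eb):
        return False
    if not np.allclose(ea["time_s"], eb["time_s"], atol=atol, rtol=0):
        return False
    if not (ea["kind"].to_numpy() == eb["kind"].to_numpy()).all():
        return False
    if not (ea["liquid"].to_numpy() == eb["liquid"].to_numpy()).all():
        return False
    if (a.facial is None) != (b.facial is None):
        return False
    if a.facial is not None and not (
        np.allclose(a.facial.times, b.facial.times, atol=atol, rtol=0)
        and np.allclose(a.facial.activity, b.facial.activity, atol=atol, rtol=0)
    ):
        return False
    if (a.wheel is None) != (b.wheel is None):
        return False
    if a.wheel is not None and not np.allclose(
        a.wheel.pulse_times, b.wheel.pulse_times, atol=atol, rtol=0
    ):
        return False
    return True
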