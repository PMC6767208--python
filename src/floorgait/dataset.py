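"""Domain types and file I/O for floor-sensor recordings.

A recording is a K-channel pressure signal sampled at 100 Hz together with
an event annotation: the activity class (single walk, multiple walks,
wheelchair, pushed wheelchair, cart walk, other), the status of the people
on the floor (medical staff or elderly resident), and, for walk-bearing
events, the ground-truth step boxes — half-open ``[start, end)`` intervals
on the raw sample grid marking individual footsteps.

Recordings travel as delimited text (one column per channel, two comment
header lines carrying the sampling rate and channel count) with a JSON
sidecar ``<stem>.json`` for the annotation.  An ``.npz`` container is
accepted as a faster alternative.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, replace
from enum import Enum
from pathlib import Path

import numpy as np

__all__ = [
    "EventClass",
    "PersonStatus",
    "StepBox",
    "EventAnnotation",
    "Recording",
    "Dataset",
    "activity_group",
    "read_recording",
    "write_recording",
    "stratified_split",
]


class EventClass(str, Enum):
    WALK_SINGLE = "walk_single"
    WALK_MULTI = "walk_multi"
    WHEELCHAIR = "wheelchair"
    WHEELCHAIR_PUSHED = "wheelchair_pushed"
    CART_WALK = "cart_walk"
    OTHER = "other"


class PersonStatus(str, Enum):
    STAFF = "staff"
    ELDERLY = "elderly"


#: The three activity labels used for stratification and per-label ROC:
#: single walk, multiple simultaneous walks, and everything else.
_ACTIVITY_GROUPS = {
    EventClass.WALK_SINGLE: "single",
    EventClass.WALK_MULTI: "multi",
    EventClass.WHEELCHAIR: "other",
    EventClass.WHEELCHAIR_PUSHED: "other",
    EventClass.CART_WALK: "other",
    EventClass.OTHER: "other",
}


def activity_group(event_class: EventClass) -> str:
    """Map a fine event class onto the coarse activity label
    (``single`` / ``multi`` / ``other``) used for stratification."""
    return _ACTIVITY_GROUPS[EventClass(event_class)]


@dataclass(frozen=True, order=True)
class StepBox:
    """Half-open interval ``[start, end)`` of raw samples covering one step."""

    start: int
    end: int

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(f"invalid step box [{self.start}, {self.end})")

    def __len__(self) -> int:
        return self.end - self.start


@dataclass
class EventAnnotation:
    event_class: EventClass = EventClass.OTHER
    person_status: PersonStatus = PersonStatus.STAFF
    n_persons: int = 1
    step_boxes: list[StepBox] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.event_class = EventClass(self.event_class)
        self.person_status = PersonStatus(self.person_status)
        if self.n_persons < 1:
            raise ValueError("n_persons must be a positive integer")
        if self.event_class is EventClass.WALK_SINGLE and self.n_persons != 1:
            raise ValueError("walk_single implies n_persons == 1")
        if self.event_class is EventClass.WALK_MULTI and self.n_persons <= 1:
            raise ValueError("walk_multi implies n_persons > 1")

    def to_dict(self) -> dict:
        return {
            "event_class": self.event_class.value,
            "person_status": self.person_status.value,
            "n_persons": self.n_persons,
            "step_boxes": [[b.start, b.end] for b in self.step_boxes],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "EventAnnotation":
        return cls(
            event_class=EventClass(d["event_class"]),
            person_status=PersonStatus(d["person_status"]),
            n_persons=int(d.get("n_persons", 1)),
            step_boxes=[StepBox(int(s), int(e)) for s, e in d.get("step_boxes", [])],
        )


@dataclass
class Recording:
    """K-channel floor-sensor signal (rows = channels) plus its annotation."""

    channels: np.ndarray
    rate_hz: float = 100.0
    id: str = ""
    annotation: EventAnnotation = field(default_factory=EventAnnotation)

    def __post_init__(self) -> None:
        self.channels = np.atleast_2d(np.asarray(self.channels, dtype=float))
        if self.channels.ndim != 2 or self.channels.shape[1] == 0:
            raise ValueError("channels must be a K x T matrix with T > 0")
        if self.rate_hz <= 0:
            raise ValueError("rate_hz must be positive")
        for b in self.annotation.step_boxes:
            if b.end > self.n_samples:
                raise ValueError(f"step box {b} exceeds recording length {self.n_samples}")

    @property
    def n_channels(self) -> int:
        return self.channels.shape[0]

    @property
    def n_samples(self) -> int:
        return self.channels.shape[1]


class FormatError(ValueError):
    """Malformed recording file (bad header or ragged sample rows)."""


@dataclass
class Dataset:
    recordings: list[Recording]

    def __len__(self) -> int:
        return len(self.recordings)

    def __iter__(self):
        return iter(self.recordings)

    @property
    def manifest(self) -> dict[tuple[str, str], int]:
        """Counts per (event_class, person_status)."""
        counts: dict[tuple[str, str], int] = {}
        for r in self.recordings:
            key = (r.annotation.event_class.value, r.annotation.person_status.value)
            counts[key] = counts.get(key, 0) + 1
        return counts

    def event_counts(self) -> dict[str, int]:
        """Counts per event class, statuses pooled."""
        counts: dict[str, int] = {}
        for r in self.recordings:
            k = r.annotation.event_class.value
            counts[k] = counts.get(k, 0) + 1
        return counts

    def filter(self, predicate) -> "Dataset":
        return Dataset([r for r in self.recordings if predicate(r)])

    def write_manifest(self, path: str | Path) -> Path:
        path = Path(path)
        lines = ["event_class,person_status,count"]
        for (ec, st), n in sorted(self.manifest.items()):
            lines.append(f"{ec},{st},{n}")
        path.write_text("\n".join(lines) + "\n")
        return path


# ---------------------------------------------------------------------------
# File I/O


def _sidecar_path(path: Path) -> Path:
    return path.with_suffix(".json")


def write_recording(rec: Recording, path: str | Path) -> Path:
    """Write a recording plus its JSON annotation sidecar.

    ``.npz`` paths get a binary container; anything else gets delimited
    text with two comment header lines (rate, channel count), one row per
    sample and one column per channel.
    """
    path = Path(path)
    if path.suffix == ".npz":
        np.savez(path, channels=rec.channels, rate_hz=rec.rate_hz, id=rec.id)
    else:
        header = f"# rate_hz={rec.rate_hz:g}\n# channels={rec.n_channels}\n"
        with open(path, "w") as fh:
            fh.write(header)
            np.savetxt(fh, rec.channels.T, delimiter=",", fmt="%.10g")
    with open(_sidecar_path(path), "w") as fh:
        json.dump(rec.annotation.to_dict(), fh, indent=1)
    return path


def _parse_header_value(line: str, key: str, lineno: int) -> float:
    body = line.lstrip("#").strip()
    if "=" not in body:
        raise FormatError(f"line {lineno}: expected '# {key}=<value>', got {line!r}")
    name, _, value = body.partition("=")
    if name.strip() != key:
        raise FormatError(f"line {lineno}: expected header key {key!r}, got {name.strip()!r}")
    try:
        return float(value)
    except ValueError as exc:
        raise FormatError(f"line {lineno}: cannot parse {key} value {value!r}") from exc


def read_recording(path: str | Path) -> Recording:
    """Read a recording written by :func:`write_recording`.

    Raises :class:`FormatError` naming the offending line for a malformed
    header or ragged sample rows; a missing sidecar yields an empty
    annotation and a warning.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if path.suffix == ".npz":
        with np.load(path, allow_pickle=False) as z:
            channels = z["channels"]
            rate_hz = float(z["rate_hz"])
            rec_id = str(z["id"])
    else:
        with open(path) as fh:
            lines = fh.read().splitlines()
        if len(lines) < 3:
            raise FormatError("file too short: need 2 header lines and at least 1 sample row")
        rate_hz = _parse_header_value(lines[0], "rate_hz", 1)
        n_channels = int(_parse_header_value(lines[1], "channels", 2))
        rows = []
        for i, line in enumerate(lines[2:], start=3):
            if not line.strip():
                continue
            fields = line.split(",")
            if len(fields) != n_channels:
                raise FormatError(
                    f"line {i}: expected {n_channels} columns, got {len(fields)}"
                )
            try:
                rows.append([float(v) for v in fields])
            except ValueError as exc:
                raise FormatError(f"line {i}: non-numeric sample value") from exc
        channels = np.asarray(rows, dtype=float).T
        rec_id = path.stem

    sidecar = _sidecar_path(path)
    if sidecar.exists():
        with open(sidecar) as fh:
            annotation = EventAnnotation.from_dict(json.load(fh))
    else:
        warnings.warn(f"no annotation sidecar for {path}; using empty annotation")
        annotation = EventAnnotation()
    return Recording(channels=channels, rate_hz=rate_hz, id=rec_id, annotation=annotation)


def read_dataset(directory: str | Path, pattern: str = "*.csv") -> Dataset:
    """Load every recording matching ``pattern`` under ``directory``."""
    directory = Path(directory)
    paths = [p for p in sorted(directory.glob(pattern)) if p.name != "manifest.csv"]
    return Dataset([read_recording(p) for p in paths])


def write_dataset(ds: Dataset, directory: str | Path) -> Path:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    for rec in ds:
        write_recording(rec, directory / f"{rec.id}.csv")
    ds.write_manifest(directory / "manifest.csv")
    return directory


# ---------------------------------------------------------------------------
# Stratified split


def _stratum_key(rec: Recording) -> tuple[str, str]:
    a = rec.annotation
    return (activity_group(a.event_class), a.person_status.value)


def stratified_split(
    ds: Dataset, test_fraction: float, seed: int
) -> tuple[Dataset, Dataset]:
    """Deterministic stratified train/test split.

    Strata are (activity label in {single, multi, other}) x (staff/elderly).
    Within each stratum the test count is ``round(n * test_fraction)``
    (half-up), clamped to ``[1, n - 1]`` whenever the stratum holds at
    least two signals so that neither side is left empty.
    """
    if not 0.0 < test_fraction < 1.0:
        raise ValueError("test_fraction must lie strictly between 0 and 1")
    if len(ds) == 0:
        raise ValueError("cannot split an empty dataset")
    rng = np.random.default_rng(seed)
    strata: dict[tuple[str, str], list[Recording]] = {}
    for rec in ds:
        strata.setdefault(_stratum_key(rec), []).append(rec)

    train: list[Recording] = []
    test: list[Recording] = []
    for key in sorted(strata):
        members = strata[key]
        n = len(members)
        n_test = int(np.floor(n * test_fraction + 0.5))
        if n >= 2:
            n_test = min(max(n_test, 1), n - 1)
        else:
            n_test = 0
        order = rng.permutation(n)
        test.extend(members[i] for i in order[:n_test])
        train.extend(members[i] for i in order[n_test:])
    return Dataset(train), Dataset(test)
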