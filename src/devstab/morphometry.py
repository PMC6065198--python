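"""Wing landmark I/O and size traits.

The study's morphometric unit is a single digitized wing: an ordered set of
planar landmarks (15 in the full design) captured once per measurement
session for the left and the right wing of each fly.  Two size traits are
derived from the landmarks:

* **centroid size** — the square root of the summed squared distances of the
  landmarks from their centroid, the standard size measure of geometric
  morphometrics; and
* **wing length** — the Euclidean distance between two named landmarks
  (3 and 13 in the study's numbering).

Landmark indices are 1-based in every user-facing interface, matching the
field's numbering convention; conversion to 0-based arrays is confined to
this module.
"""

from __future__ import annotations

import math
import warnings
from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import FormatError, ParameterError

#: Accepted spellings for each wing side (matched case-insensitively).
SIDE_ALIASES = {
    "l": "left", "left": "left", "side1": "left", "1": "left",
    "r": "right", "right": "right", "side2": "right", "2": "right",
}

LEFT = "left"
RIGHT = "right"

#: Default landmark pair delimiting wing length.
WING_LENGTH_LANDMARKS = (3, 13)


def normalize_side(label: object) -> str:
    """Map a side label dialect (``L``, ``side2``, ``1`` ...) to left/right."""
    key = str(label).strip().lower()
    try:
        return SIDE_ALIASES[key]
    except KeyError:
        raise FormatError(f"unrecognized side label {label!r}") from None


@dataclass(frozen=True)
class LandmarkRecord:
    """One digitization of one wing in one measurement session."""

    individual_id: str
    genotype: str
    side: str                      # "left" | "right"
    session: int                   # 1..M
    landmarks: np.ndarray = field(repr=False)  # (k, 2) float array

    def __post_init__(self) -> None:
        lm = np.asarray(self.landmarks, dtype=float)
        if lm.ndim != 2 or lm.shape[1] != 2:
            raise ParameterError(
                f"landmarks must be a (k, 2) array, got shape {lm.shape}"
            )
        object.__setattr__(self, "landmarks", lm)
        if self.side not in (LEFT, RIGHT):
            raise ParameterError(f"side must be left/right, got {self.side!r}")

    @property
    def n_landmarks(self) -> int:
        return self.landmarks.shape[0]


def centroid_size(landmarks: Sequence | np.ndarray) -> float:
    """Centroid size of a planar landmark configuration.

    sqrt(sum of squared distances of all landmarks from their centroid).
    Zero iff all points coincide; scales linearly under uniform scaling and
    is invariant under rotation and translation.
    """
    pts = np.asarray(landmarks, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2 or pts.shape[0] < 2:
        raise ParameterError("centroid size needs at least 2 planar points")
    centred = pts - pts.mean(axis=0)
    return float(np.sqrt(np.sum(centred ** 2)))


def interlandmark_distance(
    landmarks: Sequence | np.ndarray, i: int, j: int
) -> float:
    """Euclidean distance between landmarks ``i`` and ``j`` (1-based)."""
    pts = np.asarray(landmarks, dtype=float)
    k = pts.shape[0]
    if i == j:
        raise ParameterError("landmark indices must differ")
    for idx in (i, j):
        if not 1 <= idx <= k:
            raise ParameterError(
                f"landmark index {idx} out of range 1..{k}"
            )
    return float(math.dist(pts[i - 1], pts[j - 1]))


# ---------------------------------------------------------------------------
# Landmark CSV I/O
#
# Schema: genotype, individual, side, session, x1, y1, ..., xk, yk
# ---------------------------------------------------------------------------

def _coordinate_columns(columns: Iterable[str]) -> list[str]:
    cols = [c for c in columns if c[0] in "xy" and c[1:].isdigit()]
    k = len(cols) // 2
    expected = [f"{axis}{i}" for i in range(1, k + 1) for axis in "xy"]
    if sorted(cols) != sorted(expected) or not cols:
        raise FormatError(
            "coordinate columns must be x1,y1,...,xk,yk; "
            f"found {sorted(cols)}"
        )
    return expected


def read_landmarks(path, strict: bool = True) -> list[LandmarkRecord]:
    """Read a landmark CSV into validated :class:`LandmarkRecord` rows.

    Side labels are dialect-normalized; duplicate (individual, side, session)
    rows and inconsistent landmark counts raise :class:`FormatError` naming
    the row.  Design balance is checked with :func:`validate_design`; in
    strict mode an unbalanced design raises :class:`DesignError`.
    """
    df = pd.read_csv(path)
    required = {"genotype", "individual", "side", "session"}
    missing = required - set(df.columns)
    if missing:
        raise FormatError(f"missing required columns: {sorted(missing)}")
    if "unit" in df.columns:
        units = sorted(df["unit"].astype(str).unique())
        if len(units) > 1:
            # FA comparisons are scale-dependent; mixing pixel/µm exports
            # silently would corrupt every downstream variance
            warnings.warn(
                f"{path}: mixed coordinate units declared: {units}",
                stacklevel=2,
            )
    coord_cols = _coordinate_columns(df.columns)

    records: list[LandmarkRecord] = []
    seen: set[tuple] = set()
    for row_no, row in enumerate(df.itertuples(index=False), start=2):
        rowd = row._asdict()
        side = normalize_side(rowd["side"])
        try:
            session = int(rowd["session"])
        except (TypeError, ValueError):
            raise FormatError(
                f"row {row_no}: session {rowd['session']!r} is not an integer"
            ) from None
        key = (str(rowd["individual"]), side, session)
        if key in seen:
            raise FormatError(
                f"row {row_no}: duplicate record for individual "
                f"{key[0]!r} side {side} session {session}"
            )
        seen.add(key)
        coords = np.array(
            [float(rowd[c]) for c in coord_cols], dtype=float
        ).reshape(-1, 2)
        if not np.all(np.isfinite(coords)):
            raise FormatError(f"row {row_no}: non-finite coordinate")
        records.append(
            LandmarkRecord(
                individual_id=str(rowd["individual"]),
                genotype=str(rowd["genotype"]),
                side=side,
                session=session,
                landmarks=coords,
            )
        )
    validate_design(records, strict=strict)
    return records


def validate_design(
    records: Sequence[LandmarkRecord], strict: bool = True
) -> list[str]:
    """Check that every (individual, side) has all M sessions.

    Returns human-readable problem descriptions; raises in strict mode.
    """
    from .errors import DesignError

    problems: list[str] = []
    if not records:
        return problems
    k_counts = Counter(r.n_landmarks for r in records)
    if len(k_counts) > 1:
        problems.append(f"inconsistent landmark counts: {dict(k_counts)}")
    sessions = sorted({r.session for r in records})
    individuals = sorted({r.individual_id for r in records})
    for ind in individuals:
        for side in (LEFT, RIGHT):
            have = sorted(
                r.session for r in records
                if r.individual_id == ind and r.side == side
            )
            if have != sessions:
                problems.append(
                    f"individual {ind!r} side {side}: sessions {have} "
                    f"(expected {sessions})"
                )
    if problems and strict:
        raise DesignError("; ".join(problems))
    return problems


def write_landmarks(records: Sequence[LandmarkRecord], path) -> None:
    """Write records back to the landmark CSV schema."""
    if not records:
        raise ParameterError("no records to write")
    k = records[0].n_landmarks
    coord_cols = [f"{a}{i}" for i in range(1, k + 1) for a in "xy"]
    rows = []
    for r in records:
        row = {
            "genotype": r.genotype,
            "individual": r.individual_id,
            "side": r.side,
            "session": r.session,
        }
        row.update(zip(coord_cols, r.landmarks.ravel()))
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False)


def read_tps(path, genotype: str = "unknown") -> list[LandmarkRecord]:
    """Minimal TPS reader (LM=, optional ID=) for interoperability.

    Side/session are parsed from an ID of the form ``ind_side_session``;
    records lacking one default to left / session 1.
    """
    records: list[LandmarkRecord] = []
    with open(path) as fh:
        lines = [ln.strip() for ln in fh if ln.strip()]
    i, count = 0, 0
    while i < len(lines):
        if not lines[i].upper().startswith("LM="):
            raise FormatError(f"line {i + 1}: expected LM= block")
        k = int(lines[i].split("=", 1)[1])
        pts = []
        for j in range(k):
            parts = lines[i + 1 + j].split()
            pts.append((float(parts[0]), float(parts[1])))
        i += 1 + k
        ident, side, session = f"specimen{count}", LEFT, 1
        while i < len(lines) and "=" in lines[i] and not lines[i].upper().startswith("LM="):
            tag, value = lines[i].split("=", 1)
            if tag.upper() == "ID":
                bits = value.split("_")
                ident = bits[0]
                if len(bits) > 1:
                    side = normalize_side(bits[1])
                if len(bits) > 2:
                    session = int(bits[2])
            i += 1
        records.append(
            LandmarkRecord(ident, genotype, side, session, np.array(pts))
        )
        count += 1
    return records


# ---------------------------------------------------------------------------
# Size tables
# ---------------------------------------------------------------------------

def compute_sizes(
    records: Sequence[LandmarkRecord],
    trait: str = "centroid_size",
    i: int = WING_LENGTH_LANDMARKS[0],
    j: int = WING_LENGTH_LANDMARKS[1],
    log: bool = False,
) -> pd.DataFrame:
    """Tidy SizeMeasure table: one row per (individual, side, session).

    ``trait`` is ``centroid_size`` or ``wing_length`` (distance between
    1-based landmarks ``i`` and ``j``).  ``log=True`` returns natural-log
    values, the scale on which the wing simulator's variance components act.
    """
    if trait not in ("centroid_size", "wing_length"):
        raise ParameterError(f"unknown trait {trait!r}")
    rows = []
    for r in records:
        if trait == "centroid_size":
            value = centroid_size(r.landmarks)
        else:
            value = interlandmark_distance(r.landmarks, i, j)
        if log:
            if value <= 0:
                raise ParameterError(
                    f"non-positive size for individual {r.individual_id!r}; "
                    "cannot take log"
                )
            value = math.log(value)
        rows.append(
            {
                "genotype": r.genotype,
                "individual": r.individual_id,
                "side": r.side,
                "session": r.session,
                "trait": trait + ("_log" if log else ""),
                "value": value,
            }
        )
    return pd.DataFrame(rows)
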