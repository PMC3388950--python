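"""MET-based intensity classification of physical-activity facilities.

Each facility type carries a typical metabolic-equivalent-of-task (MET)
value — a multiple of resting energy expenditure — and is graded by the
standard cut-points: light below 3 METs, moderate from 3 to 6 METs
inclusive, vigorous above 6 METs. A small curated type->MET lookup ships
with the package as an editable CSV; unknown hall-like venues fall back to
moderate, the convention used for church and occasional sports halls on
the assumption that activities such as badminton and table tennis are what
actually happens in them.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from typing import Iterable, Sequence

import pandas as pd

LIGHT, MODERATE, VIGOROUS = "light", "moderate", "vigorous"
INTENSITIES = (LIGHT, MODERATE, VIGOROUS)

#: substrings marking venue types that default to moderate when unmatched
_HALL_FALLBACK_TOKENS = ("hall", "community centre", "pavilion")


@dataclass(frozen=True)
class IntensityRule:
    """Cut-points on the MET scale: light < ``light_upper`` <= moderate <=
    ``moderate_upper`` < vigorous."""

    light_upper: float = 3.0
    moderate_upper: float = 6.0

    def __post_init__(self):
        if not 0 < self.light_upper < self.moderate_upper:
            raise ValueError("require 0 < light_upper < moderate_upper")


@dataclass
class MetLookup:
    """Facility-type -> MET mapping (case-insensitive on lookup)."""

    entries: dict[str, float]

    def __post_init__(self):
        self.entries = {str(k).strip().lower(): float(v) for k, v in self.entries.items()}
        if any(v <= 0 for v in self.entries.values()):
            raise ValueError("MET values must be positive")

    @classmethod
    def default(cls) -> "MetLookup":
        with resources.files("modaccess.data").joinpath("met_lookup.csv").open() as fh:
            df = pd.read_csv(fh)
        return cls(entries=dict(zip(df["facility_type"], df["met"])))

    @classmethod
    def from_csv(cls, path) -> "MetLookup":
        df = pd.read_csv(path)
        return cls(entries=dict(zip(df["facility_type"], df["met"])))

    def get(self, facility_type: str) -> float | None:
        return self.entries.get(str(facility_type).strip().lower())

    @property
    def types(self) -> list[str]:
        return sorted(self.entries)


@dataclass
class Facility:
    facility_id: str
    facility_type: str
    x: float
    y: float
    met: float
    intensity: str


@dataclass
class ClassificationResult:
    """Deduplicated classified facilities plus per-category counts and any
    unmatchable records (never silently dropped)."""

    facilities: list[Facility]
    counts: dict[str, int]
    n_duplicates_removed: int
    rejects: list[dict] = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "facility_id": f.facility_id,
                    "facility_type": f.facility_type,
                    "x": f.x,
                    "y": f.y,
                    "met": f.met,
                    "intensity": f.intensity,
                }
                for f in self.facilities
            ],
            columns=["facility_id", "facility_type", "x", "y", "met", "intensity"],
        )


def intensity_category(met: float, rule: IntensityRule = IntensityRule()) -> str:
    """Grade a MET value: light < 3, moderate in [3, 6], vigorous > 6
    (default cut-points; both bounds of the moderate band are inclusive)."""
    if not met > 0:
        raise ValueError(f"MET value must be positive, got {met}")
    if met < rule.light_upper:
        return LIGHT
    if met <= rule.moderate_upper:
        return MODERATE
    return VIGOROUS


def _fallback_met(facility_type: str, rule: IntensityRule) -> float | None:
    """Moderate fallback for hall-like venues; midpoint of the moderate band."""
    name = facility_type.strip().lower()
    if any(tok in name for tok in _HALL_FALLBACK_TOKENS):
        return 0.5 * (rule.light_upper + rule.moderate_upper)
    return None


def classify_facilities(
    raw: Iterable[tuple[str, float, float]] | pd.DataFrame,
    lookup: MetLookup | None = None,
    rule: IntensityRule = IntensityRule(),
) -> ClassificationResult:
    """Deduplicate and classify raw facility records.

    ``raw`` is an iterable of ``(facility_type, x, y)`` or a DataFrame with
    columns ``facility_type, x, y`` (an optional ``facility_id`` is kept).
    Duplicate facilities of the same type at identical coordinates collapse
    to a single record. Types missing from the lookup use the hall fallback
    (moderate) where it applies and otherwise land in ``rejects``.
    """
    lookup = lookup or MetLookup.default()
    if not lookup.entries:
        raise ValueError("MET lookup is empty")
    if isinstance(raw, pd.DataFrame):
        records = [
            (str(r.facility_type), float(r.x), float(r.y), getattr(r, "facility_id", None))
            for r in raw.itertuples(index=False)
        ]
    else:
        records = [(str(t), float(x), float(y), None) for t, x, y in raw]

    seen: set[tuple[str, float, float]] = set()
    facilities: list[Facility] = []
    rejects: list[dict] = []
    n_dup = 0
    for i, (ftype, x, y, fid) in enumerate(records):
        key = (ftype.strip().lower(), x, y)
        if key in seen:
            n_dup += 1
            continue
        seen.add(key)
        met = lookup.get(ftype)
        if met is None:
            met = _fallback_met(ftype, rule)
        if met is None:
            rejects.append({"facility_type": ftype, "x": x, "y": y, "reason": "unknown type"})
            continue
        facilities.append(
            Facility(
                facility_id=fid if fid is not None else f"F{len(facilities):05d}",
                facility_type=ftype,
                x=x,
                y=y,
                met=met,
                intensity=intensity_category(met, rule),
            )
        )
    counts = {lab: sum(1 for f in facilities if f.intensity == lab) for lab in INTENSITIES}
    return ClassificationResult(
        facilities=facilities, counts=counts, n_duplicates_removed=n_dup, rejects=rejects
    )


def drop_light(facilities: Sequence[Facility]) -> list[Facility]:
    """Light-intensity venues are excluded from accessibility counting by
    default (too few to analyse in the source setting)."""
    return [f for f in facilities if f.intensity != LIGHT]
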