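"""Segmental LGE data model for arrhythmogenic-cardiomyopathy differentials.

Late gadolinium enhancement (LGE) at cardiovascular MR is scored visually on
a 17-segment left-ventricular model (standard AHA segmentation: 6 basal,
6 mid, 4 apical segments plus the true apex) and a 7-segment right-ventricular
model (basal inferior/lateral, mid inferior/lateral, apical inferior/lateral,
and the RV outflow tract).  LV segments additionally carry a transmurality
class (subepicardial, mid-myocardial, subendocardial, transmural);
transmurality is not graded in the thin RV wall.  Extra-ventricular LGE
(atrial, valvular, papillary muscle, moderator band) and the "Whale's Tail"
sign are recorded as boolean flags.

Septal insertion-point ("junctional") LGE is a common finding in healthy
subjects and is deliberately *not* recorded as segmental LGE: a patient with
junctional enhancement only carries the ``junctional_only_septal_lge`` flag,
and no rule or feature in this package ever counts it.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, replace
from typing import Iterable, Iterator, Mapping, Optional

__all__ = [
    "LVSegment",
    "RVSegment",
    "Transmurality",
    "Diagnosis",
    "MiscLGEFlags",
    "SegmentalLGEMap",
    "PatientRecord",
    "Cohort",
    "FeatureVector",
    "FEATURE_NAMES",
    "SEPTAL_LV_SEGMENTS",
    "extract_features",
    "validate_patient",
]


class Wall(str, enum.Enum):
    """LV wall groups as used in regional prevalence tables."""

    ANTERIOR = "anterior"
    ANTEROSEPTAL = "anteroseptal"
    INFEROSEPTAL = "inferoseptal"
    INFERIOR = "inferior"
    INFEROLATERAL = "inferolateral"
    ANTEROLATERAL = "anterolateral"
    APICAL = "apical"
    TRUE_APEX = "true_apex"


class Level(str, enum.Enum):
    BASAL = "basal"
    MID = "mid"
    APICAL = "apical"
    APEX = "apex"


class LVSegment(enum.IntEnum):
    """The 17 AHA left-ventricular segments.

    Indices 1-6 are basal, 7-12 mid-cavity, 13-16 apical, 17 the true apex.
    """

    BASAL_ANTERIOR = 1
    BASAL_ANTEROSEPTAL = 2
    BASAL_INFEROSEPTAL = 3
    BASAL_INFERIOR = 4
    BASAL_INFEROLATERAL = 5
    BASAL_ANTEROLATERAL = 6
    MID_ANTERIOR = 7
    MID_ANTEROSEPTAL = 8
    MID_INFEROSEPTAL = 9
    MID_INFERIOR = 10
    MID_INFEROLATERAL = 11
    MID_ANTEROLATERAL = 12
    APICAL_ANTERIOR = 13
    APICAL_SEPTAL = 14
    APICAL_INFERIOR = 15
    APICAL_LATERAL = 16
    TRUE_APEX = 17

    @property
    def wall(self) -> Wall:
        return _LV_WALL[self]

    @property
    def level(self) -> Level:
        if self.value <= 6:
            return Level.BASAL
        if self.value <= 12:
            return Level.MID
        if self.value <= 16:
            return Level.APICAL
        return Level.APEX


_LV_WALL: dict[LVSegment, Wall] = {
    LVSegment.BASAL_ANTERIOR: Wall.ANTERIOR,
    LVSegment.BASAL_ANTEROSEPTAL: Wall.ANTEROSEPTAL,
    LVSegment.BASAL_INFEROSEPTAL: Wall.INFEROSEPTAL,
    LVSegment.BASAL_INFERIOR: Wall.INFERIOR,
    LVSegment.BASAL_INFEROLATERAL: Wall.INFEROLATERAL,
    LVSegment.BASAL_ANTEROLATERAL: Wall.ANTEROLATERAL,
    LVSegment.MID_ANTERIOR: Wall.ANTERIOR,
    LVSegment.MID_ANTEROSEPTAL: Wall.ANTEROSEPTAL,
    LVSegment.MID_INFEROSEPTAL: Wall.INFEROSEPTAL,
    LVSegment.MID_INFERIOR: Wall.INFERIOR,
    LVSegment.MID_INFEROLATERAL: Wall.INFEROLATERAL,
    LVSegment.MID_ANTEROLATERAL: Wall.ANTEROLATERAL,
    LVSegment.APICAL_ANTERIOR: Wall.APICAL,
    LVSegment.APICAL_SEPTAL: Wall.APICAL,
    LVSegment.APICAL_INFERIOR: Wall.APICAL,
    LVSegment.APICAL_LATERAL: Wall.APICAL,
    LVSegment.TRUE_APEX: Wall.TRUE_APEX,
}

#: LV segments adjacent to the RV insertion points; junctional-only LGE is
#: annotated by flag and must never be recorded as segmental LGE here.
SEPTAL_LV_SEGMENTS: frozenset[LVSegment] = frozenset(
    {
        LVSegment.BASAL_ANTEROSEPTAL,
        LVSegment.BASAL_INFEROSEPTAL,
        LVSegment.MID_ANTEROSEPTAL,
        LVSegment.MID_INFEROSEPTAL,
        LVSegment.APICAL_SEPTAL,
    }
)


class PaduaRegion(str, enum.Enum):
    INLET = "inlet"
    OUTLET = "outlet"
    APEX = "apex"
    NONE = "none"


class RVSegment(enum.IntEnum):
    """The 7 right-ventricular segments, numbered 18-24.

    The mid-cavity free-wall segments (21, 22) belong to no Padua region and
    never satisfy the RV criterion; the remaining five cover the RV inlet
    (18, 19), outlet (20, the RVOT) and apex (23, 24).
    """

    BASAL_INFERIOR = 18
    BASAL_LATERAL = 19
    RVOT = 20
    MID_INFERIOR = 21
    MID_LATERAL = 22
    APICAL_INFERIOR = 23
    APICAL_LATERAL = 24

    @property
    def padua_region(self) -> PaduaRegion:
        return _RV_REGION[self]


_RV_REGION: dict[RVSegment, PaduaRegion] = {
    RVSegment.BASAL_INFERIOR: PaduaRegion.INLET,
    RVSegment.BASAL_LATERAL: PaduaRegion.INLET,
    RVSegment.RVOT: PaduaRegion.OUTLET,
    RVSegment.MID_INFERIOR: PaduaRegion.NONE,
    RVSegment.MID_LATERAL: PaduaRegion.NONE,
    RVSegment.APICAL_INFERIOR: PaduaRegion.APEX,
    RVSegment.APICAL_LATERAL: PaduaRegion.APEX,
}


class Transmurality(str, enum.Enum):
    """Radial location of LGE within the LV wall (one dominant class/segment)."""

    SUBEPICARDIAL = "subepi"
    MID_MYOCARDIAL = "mid"
    SUBENDOCARDIAL = "subendo"
    TRANSMURAL = "transmural"


#: Transmurality classes that satisfy the Padua LV-LGE condition.
PADUA_LV_PATTERNS = frozenset({Transmurality.SUBEPICARDIAL, Transmurality.MID_MYOCARDIAL})


class Diagnosis(str, enum.Enum):
    ARVC = "ARVC"
    DCM = "DCM"
    MYOCARDITIS = "myocarditis"
    SARCOIDOSIS = "sarcoidosis"
    AMYLOIDOSIS = "amyloidosis"

    @property
    def is_arvc(self) -> bool:
        return self is Diagnosis.ARVC


#: The four ARVC differentials ("non-ARVC").
NON_ARVC: tuple[Diagnosis, ...] = (
    Diagnosis.DCM,
    Diagnosis.MYOCARDITIS,
    Diagnosis.SARCOIDOSIS,
    Diagnosis.AMYLOIDOSIS,
)


@dataclass(frozen=True)
class MiscLGEFlags:
    """Extra-ventricular LGE findings plus the Whale's Tail sign."""

    atrial: bool = False
    valvular: bool = False
    papillary: bool = False
    moderator_band: bool = False
    whales_tail: bool = False

    @property
    def any_misc(self) -> bool:
        return (
            self.atrial
            or self.valvular
            or self.papillary
            or self.moderator_band
            or self.whales_tail
        )


@dataclass(frozen=True)
class SegmentalLGEMap:
    """Per-patient segmental LGE scores.

    ``lv`` maps every LV segment to its dominant transmurality class, or
    ``None`` for no enhancement; ``rv`` maps every RV segment to a presence
    bit.  ``unconfirmed`` lists segment indices whose LGE was not confirmed
    in two orthogonal views; such segments are excluded from the Padua rules
    (by default every recorded segment is taken as confirmed).
    """

    lv: Mapping[LVSegment, Optional[Transmurality]]
    rv: Mapping[RVSegment, bool]
    misc: MiscLGEFlags = MiscLGEFlags()
    junctional_only_septal_lge: bool = False
    unconfirmed: frozenset[int] = frozenset()

    @classmethod
    def from_positive(
        cls,
        lv: Optional[Mapping[LVSegment, Transmurality]] = None,
        rv: Optional[Iterable[RVSegment]] = None,
        misc: MiscLGEFlags = MiscLGEFlags(),
        junctional_only_septal_lge: bool = False,
        unconfirmed: Iterable[int] = (),
    ) -> "SegmentalLGEMap":
        """Build a full map from the positive entries only."""
        lv = dict(lv or {})
        rv_pos = set(rv or ())
        full_lv = {s: lv.get(s) for s in LVSegment}
        full_rv = {s: (s in rv_pos) for s in RVSegment}
        return cls(full_lv, full_rv, misc, junctional_only_septal_lge, frozenset(unconfirmed))

    @classmethod
    def empty(cls) -> "SegmentalLGEMap":
        return cls.from_positive()

    def lv_positive(self) -> dict[LVSegment, Transmurality]:
        return {s: t for s, t in self.lv.items() if t is not None}

    def rv_positive(self) -> frozenset[RVSegment]:
        return frozenset(s for s, on in self.rv.items() if on)


@dataclass(frozen=True)
class PatientRecord:
    id: str
    diagnosis: Diagnosis
    lge: SegmentalLGEMap
    genotype_positive: Optional[bool] = None


@dataclass(frozen=True)
class Cohort:
    """An ordered collection of labelled patients — the unit of every
    classifier and statistic in this package."""

    patients: tuple[PatientRecord, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "patients", tuple(self.patients))

    def __len__(self) -> int:
        return len(self.patients)

    def __iter__(self) -> Iterator[PatientRecord]:
        return iter(self.patients)

    def ids(self) -> list[str]:
        return [p.id for p in self.patients]

    def group_sizes(self) -> dict[Diagnosis, int]:
        sizes = {d: 0 for d in Diagnosis}
        for p in self.patients:
            sizes[p.diagnosis] += 1
        return sizes

    def subset(
        self,
        diagnoses: Optional[Iterable[Diagnosis]] = None,
        genotype_positive: Optional[bool] = None,
    ) -> "Cohort":
        """Restrict to given diagnoses and/or genotype status.

        ``genotype_positive=True`` keeps only patients with a recorded
        positive genotype (used for the genetically-proven-ARVC sensitivity
        analysis); non-ARVC patients without genotype data are kept when
        filtering diagnoses only.
        """
        kept = self.patients
        if diagnoses is not None:
            wanted = set(diagnoses)
            kept = tuple(p for p in kept if p.diagnosis in wanted)
        if genotype_positive is not None:
            kept = tuple(
                p
                for p in kept
                if p.diagnosis is not Diagnosis.ARVC
                or p.genotype_positive is genotype_positive
            )
        return Cohort(kept)


# ---------------------------------------------------------------------------
# Feature extraction
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class FeatureVector:
    """Derived LGE predictors feeding the fixed decision tree and CART.

    Counts are segment counts (LV 0-17, RV 0-7); the ``*_lv`` wall flags
    follow the regional grouping of the prevalence tables, with
    ``anteroseptal_lv`` / ``inferolateral_lv`` meaning LGE in the basal or
    mid segment of that wall.  ``lv_midmyo_count`` counts LV segments whose
    dominant pattern is mid-myocardial.
    """

    any_rv: bool
    any_lv: bool
    rv_segment_count: int
    lv_segment_count: int
    lv_midmyo_count: int
    anterior_lv: bool
    anteroseptal_lv: bool
    inferoseptal_lv: bool
    inferior_lv: bool
    inferolateral_lv: bool
    anterolateral_lv: bool
    apical_lv: bool
    true_apex_lv: bool
    any_misc: bool

    def as_dict(self) -> dict[str, float]:
        return {name: float(getattr(self, name)) for name in FEATURE_NAMES}

    def __getitem__(self, name: str) -> float:
        if name not in _FEATURE_SET:
            raise KeyError(f"unknown feature {name!r}")
        return float(getattr(self, name))


FEATURE_NAMES: tuple[str, ...] = (
    "any_rv",
    "any_lv",
    "rv_segment_count",
    "lv_segment_count",
    "lv_midmyo_count",
    "anterior_lv",
    "anteroseptal_lv",
    "inferoseptal_lv",
    "inferior_lv",
    "inferolateral_lv",
    "anterolateral_lv",
    "apical_lv",
    "true_apex_lv",
    "any_misc",
)
_FEATURE_SET = frozenset(FEATURE_NAMES)

_WALL_FEATURE: dict[Wall, str] = {
    Wall.ANTERIOR: "anterior_lv",
    Wall.ANTEROSEPTAL: "anteroseptal_lv",
    Wall.INFEROSEPTAL: "inferoseptal_lv",
    Wall.INFERIOR: "inferior_lv",
    Wall.INFEROLATERAL: "inferolateral_lv",
    Wall.ANTEROLATERAL: "anterolateral_lv",
    Wall.APICAL: "apical_lv",
    Wall.TRUE_APEX: "true_apex_lv",
}


def extract_features(patient: PatientRecord) -> FeatureVector:
    """Derive the predictor vector from a validated patient record.

    Junctional-only septal LGE contributes to no count or flag: it is not
    recorded in the segment map in the first place (enforced by
    :func:`validate_patient`), so no special-casing is required here.
    """
    lv_pos = patient.lge.lv_positive()
    rv_pos = patient.lge.rv_positive()
    walls = {s.wall for s in lv_pos}
    return FeatureVector(
        any_rv=bool(rv_pos),
        any_lv=bool(lv_pos),
        rv_segment_count=len(rv_pos),
        lv_segment_count=len(lv_pos),
        lv_midmyo_count=sum(1 for t in lv_pos.values() if t is Transmurality.MID_MYOCARDIAL),
        anterior_lv=Wall.ANTERIOR in walls,
        anteroseptal_lv=Wall.ANTEROSEPTAL in walls,
        inferoseptal_lv=Wall.INFEROSEPTAL in walls,
        inferior_lv=Wall.INFERIOR in walls,
        inferolateral_lv=Wall.INFEROLATERAL in walls,
        anterolateral_lv=Wall.ANTEROLATERAL in walls,
        apical_lv=Wall.APICAL in walls,
        true_apex_lv=Wall.TRUE_APEX in walls,
        any_misc=patient.lge.misc.any_misc,
    )


def validate_patient(patient: PatientRecord) -> list[str]:
    """Check all structural invariants; returns violation descriptors.

    An empty list means the record is well-formed.  Violations are returned
    rather than raised so that a CSV reader can report every problem row.
    """
    v: list[str] = []
    lge = patient.lge

    lv_keys = set(lge.lv.keys())
    missing_lv = set(LVSegment) - lv_keys
    if missing_lv:
        v.append(
            "lv coverage: missing segment(s) "
            + ", ".join(str(int(s)) for s in sorted(missing_lv))
        )
    extra_lv = lv_keys - set(LVSegment)
    if extra_lv:
        v.append(f"lv coverage: unknown key(s) {sorted(extra_lv)!r}")
    for s, t in lge.lv.items():
        if t is not None and not isinstance(t, Transmurality):
            v.append(f"lv segment {int(s)}: invalid transmurality {t!r}")

    rv_keys = set(lge.rv.keys())
    missing_rv = set(RVSegment) - rv_keys
    if missing_rv:
        v.append(
            "rv coverage: missing segment(s) "
            + ", ".join(str(int(s)) for s in sorted(missing_rv))
        )
    extra_rv = rv_keys - set(RVSegment)
    if extra_rv:
        v.append(f"rv coverage: unknown key(s) {sorted(extra_rv)!r}")

    if lge.junctional_only_septal_lge:
        recorded = sorted(
            int(s) for s in SEPTAL_LV_SEGMENTS if isinstance(lge.lv.get(s), Transmurality)
        )
        if recorded:
            v.append(
                "junctional_only_septal_lge: flag set but non-junctional LGE "
                f"recorded in septal segment(s) {recorded}"
            )

    bad_unconfirmed = [i for i in lge.unconfirmed if not (1 <= int(i) <= 24)]
    if bad_unconfirmed:
        v.append(f"unconfirmed: segment index out of range {sorted(bad_unconfirmed)}")

    if not patient.id:
        v.append("id: must be non-empty")
    return v


def with_segment(patient: PatientRecord, segment: int,
                 transmurality: Optional[Transmurality] = None) -> PatientRecord:
    """Return a copy of ``patient`` with one additional LGE-positive segment.

    LV segments (1-17) require a transmurality class; RV segments (18-24)
    ignore it.  Used by monotonicity property tests.
    """
    lge = patient.lge
    if 1 <= segment <= 17:
        if transmurality is None:
            raise ValueError("LV segment needs a transmurality class")
        lv = dict(lge.lv)
        lv[LVSegment(segment)] = transmurality
        new = replace(lge, lv=lv)
    elif 18 <= segment <= 24:
        rv = dict(lge.rv)
        rv[RVSegment(segment)] = True
        new = replace(lge, rv=rv)
    else:
        raise ValueError(f"segment index {segment} out of range 1-24")
    return replace(patient, lge=new)
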