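import pytest

from lgedx.segments import (
    Diagnosis,
    FeatureVector,
    LVSegment,
    MiscLGEFlags,
    PatientRecord,
    RVSegment,
    SegmentalLGEMap,
    Transmurality,
)
from lgedx.synthetic import build_fixture_cohort


def make_patient(
    pid="p1",
    diagnosis=Diagnosis.ARVC,
    lv=None,
    rv=(),
    misc=MiscLGEFlags(),
    junctional=False,
):
    """Convenience constructor: lv maps segment index -> Transmurality,
    rv is an iterable of segment indices."""
    lv = {LVSegment(k): v for k, v in (lv or {}).items()}
    rv = {RVSegment(s) for s in rv}
    return PatientRecord(
        id=pid,
        diagnosis=diagnosis,
        lge=SegmentalLGEMap.from_positive(
            lv=lv, rv=rv, misc=misc, junctional_only_septal_lge=junctional
        ),
    )


def make_fv(**kwargs):
    """FeatureVector with all-zero defaults, overridden by kwargs."""
    base = dict(
        any_rv=False,
        any_lv=False,
        rv_segment_count=0,
        lv_segment_count=0,
        lv_midmyo_count=0,
        anterior_lv=False,
        anteroseptal_lv=False,
        inferoseptal_lv=False,
        inferior_lv=False,
        inferolateral_lv=False,
        anterolateral_lv=False,
        apical_lv=False,
        true_apex_lv=False,
        any_misc=False,
    )
    base.update(kwargs)
    return FeatureVector(**base)


SUBEPI = Transmurality.SUBEPICARDIAL
MID = Transmurality.MID_MYOCARDIAL
SUBENDO = Transmurality.SUBENDOCARDIAL
TRANSMURAL = Transmurality.TRANSMURAL


@pytest.fixture(scope="session")
def fixture_cohort():
    """The margin-exact 132-patient cohort (minimal realization)."""
    return build_fixture_cohort(seed=1)


@pytest.fixture(scope="session")
def extended_fixture_cohort():
    """The fixture with best-effort per-segment marginal matching."""
    return build_fixture_cohort(seed=1, extended=True)
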