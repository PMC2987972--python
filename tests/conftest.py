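import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci", derandomize=True,
    suppress_health_check=[HealthCheck.too_slow], deadline=None)
settings.load_profile("ci")


@pytest.fixture
def tiny_persons():
    return pd.DataFrame({
        "person_id": ["a", "b", "c", "d", "e"],
        "birth_year": [1950, 1960, 1970, 1980, 1990],
        "sex": ["F", "M", "F", "F", "M"],
        "plan": ["medicare", "commercial", "commercial", "commercial", "commercial"],
    })


@pytest.fixture
def tiny_claims():
    return pd.DataFrame({
        "person_id": ["a", "a", "b", "c", "d"],
        "service_date": pd.to_datetime(
            ["2006-08-01", "2007-01-15", "2006-12-31", "2005-07-02", "2007-06-30"]),
        "icd9": ["7140", "4019", "6920", "7140", "4019"],
        "claim_kind": ["encounter", "encounter", "encounter", "lab", "encounter"],
    })


@pytest.fixture
def tiny_enrollment():
    return pd.DataFrame({
        "person_id": ["a", "b", "c", "d", "e"],
        "start": pd.to_datetime(["2005-01-01"] * 5),
        "end": pd.to_datetime(["2007-12-31"] * 5),
    })


def _person(pid, birth_year=1960, sex="F", plan="commercial"):
    return {"person_id": pid, "birth_year": birth_year, "sex": sex, "plan": plan}


def _claim(pid, date, icd9="7140", kind="encounter"):
    return {"person_id": pid, "service_date": pd.Timestamp(date),
            "icd9": icd9, "claim_kind": kind}


@pytest.fixture
def cohort_fixture():
    """12 persons; four violate exactly one eligibility rule each.

    Rules: (a) >=2 matching eligible claims, (b) enrolled on 2007-06-30,
    (c) >=1 matching claim before 2006-07-01, (d) age >= 16 at index.
    Violators: p02 (a), p03 (c), p05 (b), p06 (d); the other eight qualify.
    """
    persons = pd.DataFrame([
        _person("p01"),
        _person("p02"),
        _person("p03"),
        _person("p04", sex="M"),
        _person("p05"),
        _person("p06", birth_year=1995),
        _person("p07", plan="medicare"),
        _person("p08"),
        _person("p09", sex="M"),
        _person("p10"),
        _person("p11", birth_year=1930, plan="medicare"),
        _person("p12"),
    ])
    claims = pd.DataFrame([
        _claim("p01", "2006-01-15"), _claim("p01", "2006-09-01"),
        _claim("p02", "2006-01-15"),                       # only 1 matching
        _claim("p03", "2006-07-01"), _claim("p03", "2007-02-01"),  # none pre-cutoff
        _claim("p04", "2006-03-01"), _claim("p04", "2006-10-01"),
        _claim("p04", "2006-11-01", kind="lab"),           # lab claim is extra
        _claim("p05", "2006-02-01"), _claim("p05", "2006-08-01"),  # not enrolled
        _claim("p06", "2006-05-01"), _claim("p06", "2006-12-01"),  # age 11
        _claim("p07", "2005-08-01"), _claim("p07", "2007-02-01"),
        _claim("p08", "2006-04-01"), _claim("p08", "2006-05-01"),
        _claim("p08", "2007-01-01"),
        _claim("p09", "2006-06-01"), _claim("p09", "2006-09-15"),
        _claim("p09", "2006-09-15", icd9="4019"),          # non-matching extra
        _claim("p10", "2006-06-30"), _claim("p10", "2007-06-30"),  # boundary dates
        _claim("p11", "2005-07-01"), _claim("p11", "2006-01-01"),
        _claim("p12", "2006-06-29", icd9="7142"),          # other 714.x subcode
        _claim("p12", "2007-03-01", icd9="7143"),
    ])
    enrollment = pd.DataFrame(
        [{"person_id": f"p{i:02d}",
          "start": pd.Timestamp("2004-01-01"),
          "end": pd.Timestamp("2007-06-29" if i == 5 else "2007-12-31")}
         for i in range(1, 13)])
    return persons, claims, enrollment
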