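import numpy as np
import pandas as pd
import pytest

from tbmsm import SimulationConfig, build_person_period, simulate_cohort


def make_baseline(rows):
    return pd.DataFrame(rows, columns=["subject_id", "enrollment_date",
                                       "age_years", "sex", "who_stage",
                                       "cd4_class", "arm"])


def make_visits(rows):
    return pd.DataFrame(rows, columns=["subject_id", "month", "on_haart",
                                       "cd4_class", "who_stage", "adherence",
                                       "cpt", "status", "tb_event"])


@pytest.fixture
def two_subject_cohort():
    """A hand-written 2-child cohort: one TB event, one censoring."""
    subjects = make_baseline([
        ("A", "", 4.0, "male", "II", "above_threshold", "haart"),
        ("B", "", 9.5, "female", "I", "below_threshold", "non_haart"),
    ])
    visits = make_visits([
        ("A", 0.0, False, "above_threshold", "II", "good", True, "active", False),
        ("A", 3.0, True, "above_threshold", "II", "good", True, "active", False),
        ("A", 6.0, True, "below_threshold", "III", "fair", True, "active", True),
        ("B", 0.0, False, "below_threshold", "I", "good", False, "active", False),
        ("B", 4.0, False, "below_threshold", "I", "poor", False, "lost", False),
    ])
    visits["cpt"] = visits["cpt"].astype(object)
    return subjects, visits


@pytest.fixture(scope="session")
def small_cohort():
    """A simulated 400-child cohort shared across tests (fixed seed)."""
    cfg = SimulationConfig(n_subjects=400, seed=1234)
    subjects, visits = simulate_cohort(cfg)
    pp = build_person_period(subjects, visits)
    return cfg, subjects, visits, pp


@pytest.fixture(scope="session")
def default_cohort():
    """One cohort from the default configuration (n=800, frozen seed)."""
    cfg = SimulationConfig()
    subjects, visits = simulate_cohort(cfg)
    pp = build_person_period(subjects, visits)
    return cfg, subjects, visits, pp


def write_cohort_csvs(tmp_path, subjects, visits):
    from tbmsm import write_cohort
    b, v = tmp_path / "baseline.csv", tmp_path / "visits.csv"
    write_cohort(subjects, visits, b, v)
    return b, v
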