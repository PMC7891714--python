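import numpy as np
import pytest

from nirsload.synthetic import (
    LayoutConfig,
    StudyConfig,
    build_layout,
    draw_profile,
    make_schedule,
    simulate_subject,
)

SMALL_COUNTS = {1.5: 6, 2.12: 4, 3.0: 6, 3.35: 4}


@pytest.fixture(scope="session")
def default_layout():
    return build_layout()


@pytest.fixture(scope="session")
def small_layout_config():
    return LayoutConfig(class_counts=dict(SMALL_COUNTS))


@pytest.fixture(scope="session")
def small_layout(small_layout_config):
    return build_layout(small_layout_config)


@pytest.fixture(scope="session")
def short_schedule():
    return make_schedule(task_s=60.0)


@pytest.fixture(scope="session")
def small_study_config(small_layout_config):
    return StudyConfig(
        n_students=4,
        n_attendings=4,
        task_s=60.0,
        layout=small_layout_config,
    )


@pytest.fixture
def student_profile(small_study_config):
    return draw_profile(
        "student", "S01", small_study_config, np.random.default_rng(42)
    )


@pytest.fixture
def simulated_subject(student_profile, small_layout, short_schedule):
    return simulate_subject(student_profile, small_layout, short_schedule, seed=7)
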