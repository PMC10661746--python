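import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def bundled_report():
    """Summary-mode study report over the bundled MES interaction estimates."""
    from isobolo.pipeline import run_study
    from isobolo.study_data import load_study_config

    return run_study(load_study_config())


@pytest.fixture(scope="session")
def combination_rows(bundled_report):
    """Combination table indexed by combination label."""
    return {
        row["combination"]: row
        for row in bundled_report.combinations.to_dict("records")
    }
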