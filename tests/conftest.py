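import pytest

from sicklemark import (
    BiomarkerDescriptor,
    CohortTable,
    Measurement,
    SubjectRecord,
    builtin_panel_registry,
)


@pytest.fixture(scope="session")
def registry():
    return builtin_panel_registry()


@pytest.fixture
def tiny_cohort():
    """2 HD subjects (values 1, 2) and 2 SCA subjects (values 3, 4) on a
    single uncensored biomarker: pooled median cut-off 2.5 splits the
    groups cleanly."""
    reg = [BiomarkerDescriptor("M1", "cytokine", "mfi")]
    subjects = [
        SubjectRecord("HD1", "HD", measurements={"M1": Measurement(1.0)}),
        SubjectRecord("HD2", "HD", measurements={"M1": Measurement(2.0)}),
        SubjectRecord("SCA1", "SCA", measurements={"M1": Measurement(3.0)}),
        SubjectRecord("SCA2", "SCA", measurements={"M1": Measurement(4.0)}),
    ]
    return CohortTable(registry=reg, subjects=subjects)


def make_cohort(values_by_group, biomarker="M1", unit="mfi", covariates=None):
    """Cohort with one biomarker from per-group value lists; optional
    per-subject covariate dicts keyed like the values."""
    reg = [BiomarkerDescriptor(biomarker, "cytokine", unit)]
    subjects = []
    for group, values in values_by_group.items():
        for i, v in enumerate(values):
            kwargs = {}
            if covariates:
                kwargs = covariates.get(group, [{}] * len(values))[i]
            subjects.append(
                SubjectRecord(
                    f"{group}{i}",
                    group,
                    measurements={biomarker: Measurement(float(v))},
                    **kwargs,
                )
            )
    return CohortTable(registry=reg, subjects=subjects)
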