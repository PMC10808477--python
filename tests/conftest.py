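import pytest

from masscnv import Fragment, FragmentPanel, IntensityRecord, brca_fixture_panel


@pytest.fixture(scope="session")
def fixture_panel() -> FragmentPanel:
    """The four-well BRCA1/BRCA2 panel used across the suite."""
    return brca_fixture_panel()


@pytest.fixture(scope="session")
def small_panel() -> FragmentPanel:
    """Minimal panel: two targets plus the three reference genes in one well."""
    return FragmentPanel(
        name="mini",
        fragments=(
            Fragment("T1", "BRCA1", "ex1", "target", "W1", order_index=1),
            Fragment("T2", "BRCA1", "ex2", "target", "W1", order_index=2),
            Fragment("R_ALB", "ALB", "ex1", "reference", "W1"),
            Fragment("R_EIF", "EIF2C1", "ex1", "reference", "W1"),
            Fragment("R_RNP", "RNaseP", "ex1", "reference", "W1"),
        ),
    )


def records_for(sample_id, intensity_map):
    """Build IntensityRecords from {fragment_id: (template, competitor)}."""
    return [
        IntensityRecord(sample_id, fid, float(t), float(c))
        for fid, (t, c) in intensity_map.items()
    ]


@pytest.fixture
def flat_records(small_panel):
    """All peaks equal: the diploid identity case (every TR = 1)."""
    return records_for("S1", {f.fragment_id: (1000.0, 1000.0) for f in small_panel.fragments})
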