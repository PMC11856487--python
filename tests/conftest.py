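import pytest

import ssrbridge as sb
from ssrbridge.panel import MATCHING_CORRECTIONS, TABLE_CORRECTIONS


@pytest.fixture(scope="session")
def panel():
    return sb.load_marker_panel()


@pytest.fixture(scope="session")
def fixture_profiles():
    return sb.load_genotype_table()


def _by_platform(profiles):
    out = {}
    for p in profiles:
        out.setdefault(p.platform, {})[p.sample_id] = p
    return out


@pytest.fixture(scope="session")
def by_platform(fixture_profiles):
    """Verbatim fixture profiles keyed platform -> genotype."""
    return _by_platform(fixture_profiles)


@pytest.fixture(scope="session")
def by_platform_corrected(fixture_profiles):
    """Fixture with the documented table correction (G30 capillary Dvit6)."""
    return _by_platform(sb.apply_corrections(fixture_profiles, TABLE_CORRECTIONS))


@pytest.fixture(scope="session")
def by_platform_matching(fixture_profiles):
    """Fixture with all documented corrections used for genotype matching."""
    return _by_platform(sb.apply_corrections(fixture_profiles, MATCHING_CORRECTIONS))


@pytest.fixture(scope="session")
def reference_panel(by_platform):
    return sb.ReferencePanel(profiles=by_platform["polyacrylamide"])
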