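import shutil
from importlib import resources
from pathlib import Path

import pytest

from cellcalib import fixtures


@pytest.fixture
def valid_settings(tmp_path: Path) -> Path:
    """Writable copy of the shipped valid fixture settings file."""
    src = resources.files("cellcalib") / "data" / "settings_valid.xml"
    dst = tmp_path / "settings_valid.xml"
    with resources.as_file(src) as p:
        shutil.copy(p, dst)
    return dst


@pytest.fixture
def invalid_settings(tmp_path: Path) -> Path:
    """Writable copy of the shipped constraint-violating settings file."""
    src = resources.files("cellcalib") / "data" / "settings_invalid.xml"
    dst = tmp_path / "settings_invalid.xml"
    with resources.as_file(src) as p:
        shutil.copy(p, dst)
    return dst


@pytest.fixture
def short_chemotaxis_settings(tmp_path: Path) -> Path:
    """Settings for a fast mock-executable chemotaxis run (5 min of walk)."""
    return fixtures.write_fixture_settings(
        tmp_path / "settings_short.xml", max_time=5.0
    )
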