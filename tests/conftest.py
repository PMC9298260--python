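import pytest

from dendrimap.fixtures import table1_records
from dendrimap.notation import parse_notation


@pytest.fixture(scope="session")
def table1():
    """Audited designed-compound records keyed by name."""
    return {r.name: r for r in table1_records()}


@pytest.fixture(scope="session")
def topologies(table1):
    """Parsed topologies of every bundled designed compound."""
    return {name: parse_notation(r.notation, name) for name, r in table1.items()}
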