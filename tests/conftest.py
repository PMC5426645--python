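import pytest

from edgefill import SyntheticConfig, TwoStageParams, generate
from edgefill.go_semsim import GoDag, TermInfo

#: Stage-2 parameters scaled to the 300-node synthetic scenario.
SCENARIO_PARAMS = dict(k=45, rank_threshold=60)


@pytest.fixture(scope="session")
def default_scenario():
    """The default study conditions: 300 nodes, 10% hidden (matching),
    36 samples, rho_edge 0.99."""
    return generate(SyntheticConfig(seed=1))


@pytest.fixture(scope="session")
def hub_scenario():
    """Scenario where designated essential proteins' edges are
    preferentially hidden (stage-2 selection conditions)."""
    return generate(SyntheticConfig(seed=1, hide_mode="hub"))


@pytest.fixture(scope="session")
def scenario_params():
    return TwoStageParams(**SCENARIO_PARAMS)


@pytest.fixture()
def toy_dag():
    """Five-term DAG: root <-is_a- b, c; b <-is_a- d; c <-part_of- e."""
    return GoDag(
        terms={
            "T:root": TermInfo(namespace="BP", parents=()),
            "T:b": TermInfo(namespace="BP", parents=(("T:root", "is_a"),)),
            "T:c": TermInfo(namespace="BP", parents=(("T:root", "is_a"),)),
            "T:d": TermInfo(namespace="BP", parents=(("T:b", "is_a"),)),
            "T:e": TermInfo(namespace="BP", parents=(("T:c", "part_of"),)),
        }
    )


TOY_OBO = """\
format-version: 1.2
ontology: toy

[Term]
id: T:0001
name: root
namespace: biological_process

[Term]
id: T:0002
name: left child
namespace: biological_process
is_a: T:0001
alt_id: T:0099

[Term]
id: T:0003
name: right child
namespace: biological_process
is_a: T:0001

[Term]
id: T:0004
name: grandchild
namespace: biological_process
relationship: part_of T:0002

[Term]
id: T:0005
name: gone
namespace: biological_process
is_a: T:0001
is_obsolete: true
"""


@pytest.fixture()
def toy_obo_path(tmp_path):
    p = tmp_path / "toy.obo"
    p.write_text(TOY_OBO)
    return p
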