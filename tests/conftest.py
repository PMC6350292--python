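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

# Tree encoding the worked pairing example: conspecific strain pair
# (strain1 aerobic / strain2 anaerobic), an anaerobic clade sp4-6 sister to
# an aerobic clade sp7-8 (sp6/sp7 slow, sp5/sp8 fast), sp10 anaerobic sister
# to sp11 aerobic, and anaerobic sp1-3 and sp9 elsewhere.
FIG1A_NEWICK = (
    "((strain1:0.10,strain2:0.10):0.90,"
    "(((sp1:0.30,sp2:0.30):0.10,sp3:0.40):0.30,"
    "((((sp4:0.30,sp5:0.35):0.05,sp6:0.20):0.15,(sp7:0.20,sp8:0.30):0.20):0.10,"
    "(sp9:0.50,(sp10:0.20,sp11:0.20):0.30):0.10):0.20):0.30);"
)

FIG1A_STATES = {
    **{t: "anaerobe" for t in
       ["strain2", "sp1", "sp2", "sp3", "sp4", "sp5", "sp6", "sp9", "sp10"]},
    **{t: "aerobe" for t in ["strain1", "sp7", "sp8", "sp11"]},
}


@pytest.fixture
def fig1a_tree():
    from oxygc.treekit import read_newick

    return read_newick(FIG1A_NEWICK, rooted=True)


@pytest.fixture
def fig1a_states():
    return dict(FIG1A_STATES)
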