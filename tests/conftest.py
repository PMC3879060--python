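import json

import pytest

from pathmqtl.knowledgebase import FilterConfig, build_knowledgebase


@pytest.fixture
def chain_doc():
    """Linear reaction chain C1 -R1{gA}- C2 -R2{gB}- C3 -R3{gC}- C4."""
    return {
        "source": "toy",
        "compounds": [{"id": c, "name": c} for c in ["C1", "C2", "C3", "C4"]],
        "reactions": [
            {"id": "R1", "participants": ["C1", "C2"], "genes": ["gA"]},
            {"id": "R2", "participants": ["C2", "C3"], "genes": ["gB"]},
            {"id": "R3", "participants": ["C3", "C4"], "genes": ["gC"]},
        ],
        "pathways": [],
    }


@pytest.fixture
def chain_kb(chain_doc):
    return build_knowledgebase(chain_doc, FilterConfig(), "toy")


@pytest.fixture
def pathway_doc():
    """Compound X in pathways P1 {g1,g2} and P2 {g3}; P2 is excludable."""
    return {
        "source": "toy",
        "compounds": [{"id": "X", "name": "X"}, {"id": "Y", "name": "Y"}],
        "reactions": [],
        "pathways": [
            {"id": "P1", "name": "one", "compounds": ["X"], "genes": ["g1", "g2"]},
            {"id": "P2", "name": "two", "compounds": ["X", "Y"], "genes": ["g3"]},
        ],
    }


@pytest.fixture
def write_doc(tmp_path):
    def _write(doc, name="kb.json"):
        path = tmp_path / name
        path.write_text(json.dumps(doc))
        return path

    return _write
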