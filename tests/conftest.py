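import pytest

from regulonkit.evidence import EvidenceRecord
from regulonkit.mor import RegulonNetwork, SignedEdge
from regulonkit.regulators import TFClassification


@pytest.fixture
def classification_files(tmp_path):
    """Small classification + prior-role TSV snapshot on disk."""
    class_file = tmp_path / "classes.tsv"
    class_file.write_text(
        "symbol\tclass\n"
        "TP53\tdbTF\n"
        "TP53\tcoTF\n"
        "JUN\tdbTF\n"
        "FOS\tdbTF\n"
        "MYC\tdbTF\n"
        "REST\tdbTF\n"
        "ZNF10\tdbTF\n"
        "MED1\tcoTF\n"
        "GTF2B\tGTF\n"
    )
    prior_file = tmp_path / "priors.tsv"
    prior_file.write_text(
        "symbol\tgo_role\tuniprot_role\tkrab\teffector_role\n"
        "MYC\tactivator\tactivator\tfalse\tactivator\n"
        "REST\trepressor\trepressor\tfalse\trepressor\n"
        "ZNF10\tunknown\tunknown\ttrue\tunknown\n"
        "TP53\tactivator\trepressor\tfalse\tunknown\n"
    )
    return class_file, prior_file


@pytest.fixture
def all_dbtf_classification():
    """Classification that accepts any regulator named TFxx (synthetic nets)."""
    def make(network: RegulonNetwork) -> TFClassification:
        return TFClassification(
            class_membership={tf: {"dbTF"} for tf in network.tfs}
        )
    return make


@pytest.fixture
def simple_records():
    return [
        EvidenceRecord("TF1", "G1", "resA", frozenset({"111"}), "activation"),
        EvidenceRecord("TF1", "G1", "resB", frozenset({"111"}), "activation"),
        EvidenceRecord("TF1", "G2", "resA", frozenset({"222", "333"}), "repression"),
        EvidenceRecord("TF2", "G1", "resB", frozenset(), "unknown"),
    ]


@pytest.fixture
def tiny_network():
    return RegulonNetwork(
        edges=[
            SignedEdge("TF1", "G1", 1),
            SignedEdge("TF1", "G2", 1),
            SignedEdge("TF1", "G3", -1),
            SignedEdge("TF2", "G2", -1),
            SignedEdge("TF2", "G4", 1),
        ]
    )
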