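import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


def make_records(
    gene_ids,
    nem_status,
    busted_p,
    dn,
    ds=None,
    branch_sel_prop=None,
    go_terms=None,
):
    """Assemble a small gene-statistics frame by hand."""
    n = len(gene_ids)
    if ds is None:
        ds = [0.2] * n
    if branch_sel_prop is None:
        branch_sel_prop = [np.array([0.0, 0.1, 0.0])] * n
    if go_terms is None:
        go_terms = [frozenset()] * n
    return pd.DataFrame(
        {
            "gene_id": list(gene_ids),
            "nem_status": list(nem_status),
            "busted_p": list(busted_p),
            "dn": list(dn),
            "ds": list(ds),
            "branch_sel_prop": list(branch_sel_prop),
            "go_terms": list(go_terms),
        }
    )


@pytest.fixture
def busted_doc():
    """Minimal HyPhy BUSTED result document."""
    return {
        "analysis": {"info": "BUSTED"},
        "input": {"file name": "astacin.fasta", "number of sequences": 8},
        "test results": {"LRT": 9.93, "p-value": 0.007},
    }


@pytest.fixture
def absrel_doc():
    """Minimal HyPhy aBSREL result with three branches of mixed rate classes."""
    return {
        "analysis": {"info": "aBSREL"},
        "input": {"file name": "lectin.fasta"},
        "branch attributes": {
            "0": {
                "Node1": {
                    "Rate Distributions": [[0.1, 0.9], [5.2, 0.1]],
                    "Corrected P-value": 0.01,
                },
                "Leaf_A": {
                    "Rate Distributions": [[0.3, 1.0]],
                    "Corrected P-value": 1.0,
                },
                "Leaf_B": {
                    "Rate Distributions": [[0.0, 0.55], [1.5, 0.25], [9.0, 0.2]],
                    "Corrected P-value": 0.2,
                },
            }
        },
    }
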