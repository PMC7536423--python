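import numpy as np
import pandas as pd
import pytest

from surfdyn import QuantMatrix, simulate_glyco_evidence


def parse_fasta_text(text: str) -> dict[str, str]:
    seqs: dict[str, str] = {}
    acc = None
    for line in text.splitlines():
        if line.startswith(">"):
            acc = line[1:].split()[0]
            seqs[acc] = ""
        elif acc is not None:
            seqs[acc] += line.strip()
    return seqs


@pytest.fixture(scope="session")
def glyco_fixture():
    """Three-protein evidence fixture with shared and multi-mapping peptides."""
    fasta, evidence, truth = simulate_glyco_evidence(3, seed=0)
    return parse_fasta_text(fasta), evidence, truth


def toy_quant(values_by_condition: dict[str, dict[str, list[float]]]) -> QuantMatrix:
    """Build a one-pool QuantMatrix from {feature: {condition: replicate values}}."""
    rows = []
    design_rows = {}
    for feature, conds in values_by_condition.items():
        for cond, values in conds.items():
            for r, v in enumerate(values, start=1):
                sid = f"{cond}_R{r}"
                rows.append((feature, "P1", sid, float(v)))
                design_rows[sid] = {
                    "sample_id": sid, "pool": "surface", "condition": cond,
                    "replicate": r, "time_value": np.nan,
                }
    data = pd.DataFrame(rows, columns=["feature_id", "protein_group", "sample_id", "log2_intensity"])
    design = pd.DataFrame(list(design_rows.values()))
    return QuantMatrix(data, design)
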