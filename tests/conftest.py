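import pandas as pd
import pytest

from diame.report_io import ReportTable

RECORD_DEFAULTS = dict(
    intensity=100.0,
    q_run=0.001,
    q_global=0.001,
    pgq_run=0.001,
    pgq_global=0.001,
    species="unknown",
    provenance="first_pass",
)


def make_report(rows: list[dict]) -> ReportTable:
    """Build a ReportTable from partial row dicts (run_id, protein_group,
    precursor_id required; everything else defaulted)."""
    return ReportTable(pd.DataFrame([{**RECORD_DEFAULTS, **r} for r in rows]))


@pytest.fixture
def toy_report() -> ReportTable:
    rows = []
    for run in ("A", "B"):
        for i, (prot, species) in enumerate(
            [("HUMAN_P1", "human"), ("HUMAN_P2", "human"), ("ECOLI_P1", "entrapment")]
        ):
            rows.append(
                dict(
                    run_id=run,
                    protein_group=prot,
                    precursor_id=f"PEP{i}/2",
                    intensity=2.0 ** (6 + i),
                    species=species,
                )
            )
    return make_report(rows)


@pytest.fixture
def toy_annotations() -> pd.DataFrame:
    return pd.DataFrame(
        {
            "run_id": ["A", "B"],
            "role": ["analyte", "analyte"],
            "condition": ["c1", "c1"],
            "replicate": [1, 2],
        }
    )
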