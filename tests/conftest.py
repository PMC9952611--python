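import numpy as np
import pandas as pd
import pytest

import pvsignal as pv

TARGET = "piperacillin\\tazobactam"
PLANTED_EVENT = "hypokalaemia"
PLANTED_LAMBDA = 4.0
E2E_N_REPORTS = 50_000
E2E_SEEDS = (11, 12)


@pytest.fixture(scope="session")
def drug_dictionary():
    return pv.load_drug_dictionary()


@pytest.fixture(scope="session")
def event_queries():
    return pv.load_event_queries()


def run_end_to_end(seed: int, tmpdir) -> dict:
    """Generate a quarter with one planted association and run the full
    file-based ETL: write, parse, clean, pair."""
    cfg = pv.SynthConfig(
        n_reports=E2E_N_REPORTS,
        seed=seed,
        lambda_matrix={(TARGET, PLANTED_EVENT): PLANTED_LAMBDA},
    )
    _, truth = pv.generate_quarter(cfg, tmpdir)
    qd = pv.parse_quarter(tmpdir)
    clean, tally = pv.clean_quarter(qd)
    pairs = pv.build_pairs(clean, pv.load_drug_dictionary())
    return {"config": cfg, "truth": truth, "qd": qd, "clean": clean, "tally": tally, "pairs": pairs}


@pytest.fixture(scope="session")
def e2e_runs(tmp_path_factory):
    """Two independent 50k-report synthetic quarters pushed through the
    whole pipeline; shared across tests because generation dominates cost."""
    runs = []
    for seed in E2E_SEEDS:
        d = tmp_path_factory.mktemp(f"e2e_{seed}")
        runs.append(run_end_to_end(seed, d))
    return runs


def small_clean_set(
    demo_rows: list[dict], drug_rows: list[dict], reac_rows: list[dict], outc_rows: list[dict] | None = None
) -> pv.CleanReportSet:
    """Hand-built CleanReportSet for fixture tests."""
    demo = pd.DataFrame(demo_rows)
    for col, default in (
        ("sex", ""),
        ("occupation", ""),
        ("country", ""),
        ("age_years", np.nan),
        ("age_group", "unknown"),
        ("quarter", "18Q1"),
    ):
        if col not in demo.columns:
            demo[col] = default
    return pv.CleanReportSet(
        demo=demo,
        drugs=pd.DataFrame(drug_rows, columns=["report_id", "drugname", "role_cod"]),
        reacs=pd.DataFrame(reac_rows, columns=["report_id", "pt"]),
        outc=pd.DataFrame(outc_rows or [], columns=["report_id", "outc_cod"]),
    )
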