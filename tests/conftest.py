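import numpy as np
import pandas as pd
import pytest

import sterolome as st


@pytest.fixture(scope="session")
def registry():
    return st.load_registry()


@pytest.fixture(scope="session")
def study_manifest():
    return st.load_study_manifest()


@pytest.fixture(scope="session")
def noiseless_study():
    config = st.preset("noiseless")
    config.seed = 11
    return st.generate_study(config)


@pytest.fixture(scope="session")
def paperlike_study():
    config = st.preset("paperlike")
    config.seed = 11
    return st.generate_study(config)


def run_pipeline(study, registry, annotated_only=True):
    """Raw peaks -> annotated signal table -> per-mille composition."""
    filtered = st.extract_signals(study.peaks)
    table = st.bin_signals(filtered)
    table = st.blank_filter(table, study.manifest)
    table = st.annotate(table, registry)
    composition = st.normalize_per_mille(
        table,
        sample_ids=study.manifest.ids_with_role("sample"),
        annotated_only=annotated_only,
    )
    return table, composition


@pytest.fixture(scope="session")
def paperlike_pipeline(paperlike_study, registry):
    return run_pipeline(paperlike_study, registry)


def make_signal_table(areas: dict, meta: dict) -> st.SignalTable:
    """Hand-build a SignalTable.

    ``areas``: signal_id -> {sample_id: area}; ``meta``: signal_id ->
    (mz_bin, rt, level, class_label, name, is_internal_standard,
    blank_pass).
    """
    ids = list(areas)
    area_frame = pd.DataFrame(areas).T.fillna(0.0).loc[ids]
    signals = pd.DataFrame(
        [meta[sid] for sid in ids],
        index=ids,
        columns=[
            "mz_bin", "rt", "level", "class_label", "name",
            "is_internal_standard", "blank_pass",
        ],
    )
    return st.SignalTable(signals, area_frame)
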