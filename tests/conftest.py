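import numpy as np
import pandas as pd
import pytest

from screenkit.io import ArrayScan, ExperimentSet


def scan_from_ratios(
    log_ratios,
    array_id="a1",
    dye_set="A",
    replicate_id=1,
    query="HAC1",
    reference="Reference",
    background=100.0,
    ref_signal=1000.0,
    prefix="P",
):
    """Build a scan whose query/reference foregrounds encode given log2 ratios."""
    ratios = np.asarray(log_ratios, dtype=float)
    n = ratios.size
    ref_fg = np.full(n, ref_signal) + background
    query_fg = ref_signal * 2.0**ratios + background
    if dye_set == "A":
        f1, f2 = query_fg, ref_fg
        assignment = {"ch1": query, "ch2": reference}
    else:
        f1, f2 = ref_fg, query_fg
        assignment = {"ch1": reference, "ch2": query}
    features = pd.DataFrame(
        {
            "feature_id": [f"{prefix}{i:04d}" for i in range(1, n + 1)],
            "f_ch1": f1,
            "b_ch1": background,
            "f_ch2": f2,
            "b_ch2": background,
        }
    )
    return ArrayScan(
        array_id=array_id,
        features=features,
        channel_assignment=assignment,
        query=query,
        replicate_id=replicate_id,
        dye_set=dye_set,
    )


@pytest.fixture
def tiny_features():
    return pd.DataFrame(
        {
            "feature_id": ["P0001", "P0002"],
            "gene": ["YPT1", "GIS2"],
            "probe_class": ["na", "na"],
            "f_ch1": [200.0, 300.0],
            "b_ch1": [100.0, 100.0],
            "f_ch2": [400.0, 150.0],
            "b_ch2": [100.0, 100.0],
        }
    )


@pytest.fixture
def tiny_scan(tiny_features):
    return ArrayScan(
        array_id="arr1",
        features=tiny_features,
        channel_assignment={"ch1": "HAC1", "ch2": "Reference"},
        query="HAC1",
    )


@pytest.fixture
def screen_set():
    """Six consistent dye-swap scans over a shared 20-protein universe."""
    rng = np.random.default_rng(7)
    scans = []
    for i in range(6):
        dye_set = "A" if i < 3 else "B"
        scans.append(
            scan_from_ratios(
                rng.normal(0, 1, 20),
                array_id=f"arr{i}",
                dye_set=dye_set,
                replicate_id=i % 3 + 1,
            )
        )
    return ExperimentSet(scans=scans, design="screen")
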