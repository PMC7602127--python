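import numpy as np
import pytest

from metabocomp import (
    DetectionParams,
    Scan,
    SimConfig,
    detect_features,
    simulate_ms1_dataset,
)

#: detector settings matched to the simulator's chromatography: 0.01 Da
#: association tolerance, apex threshold 5x above any plausible noise peak
BENCH_PARAMS = DetectionParams(
    mz_tol=0.01, rt_tol=0.2, min_height=5e3, min_scans=4, max_gap_scans=1,
    edge_frac=0.01,
)


def make_scan(index, mz, intensities, rt=None, ms_level=1, precursor=None):
    return Scan(
        scan_index=index,
        ms_level=ms_level,
        rt=float(index) if rt is None else rt,
        mz_values=np.asarray(mz, dtype=float),
        intensities=np.asarray(intensities, dtype=float),
        precursor_mz=precursor,
    )


@pytest.fixture(scope="session")
def chemogeo_dataset():
    """The benchmark chemogeographic dataset: 5 regions x 3 samples."""
    return simulate_ms1_dataset(SimConfig(seed=11))


@pytest.fixture(scope="session")
def chemogeo_features(chemogeo_dataset):
    runs, _ = chemogeo_dataset
    return {run.sample_id: detect_features(run, BENCH_PARAMS) for run in runs}
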