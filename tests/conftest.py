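import numpy as np
import pytest

from myelinquant import CalibrationConfig, SceneSpec


@pytest.fixture
def cal() -> CalibrationConfig:
    return CalibrationConfig()


@pytest.fixture
def small_scan_cal() -> CalibrationConfig:
    """Calibration scaled for 64x64 fixtures (size floor ~20 px)."""
    return CalibrationConfig(pixel_size=1.0, expected_ol_diameter=11.3, threshold_count=7)


def match_cells_to_truth(result, truth):
    """Map each ground-truth OL to its detected cell row by mask overlap.

    Returns a list of (planted_fraction, row-or-None); independent of the
    pipeline's own bookkeeping, so it can serve as a recovery oracle.
    """
    out = []
    for planted, mask in zip(truth.planted_fractions, truth.ol_masks):
        labs = result.labels[mask]
        labs = labs[labs > 0]
        if labs.size == 0:
            out.append((planted, None))
            continue
        lab = int(np.bincount(labs).argmax())
        rows = result.cells[result.cells["label"] == lab]
        out.append((planted, rows.iloc[0] if len(rows) else None))
    return out


def coculture_spec(**kw) -> SceneSpec:
    return SceneSpec(**kw)
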