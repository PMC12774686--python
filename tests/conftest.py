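import numpy as np
import pandas as pd
import pytest

from decimap.cell_model import ROIFrame, SampleMeta
from decimap.phenotype import default_panel


@pytest.fixture(scope="session")
def panel():
    return default_panel()


def make_roi(
    xy,
    labels,
    roi_id="R0",
    sample_id="S0",
    width=1000.0,
    height=1000.0,
    label_col="lineage",
):
    """Minimal ROI for spatial tests: positions + one label column."""
    xy = np.asarray(xy, dtype=float)
    df = pd.DataFrame(
        {
            "sample_id": sample_id,
            "roi_id": roi_id,
            "cell_id": [f"{roi_id}_c{i:04d}" for i in range(len(xy))],
            "x_um": xy[:, 0],
            "y_um": xy[:, 1],
            label_col: list(labels),
        }
    )
    return ROIFrame(
        roi_id=roi_id,
        sample_id=sample_id,
        width_um=width,
        height_um=height,
        basalis_area_mm2=width * height / 1e6,
        cells=df,
    )


def marker_row(panel, positive, frac_pos=0.7, frac_neg=0.02):
    """One cell's marker fractions: listed markers positive, rest negative."""
    return {
        f"{m}_frac": (frac_pos if m in positive else frac_neg) for m in panel.markers
    }


def make_cell_frame(panel, positive_sets, sample_id="S0", roi_id="R0"):
    """Cell table with one row per positive-marker set (archetypal cells)."""
    rows = []
    for i, positive in enumerate(positive_sets):
        rows.append(
            {
                "sample_id": sample_id,
                "roi_id": roi_id,
                "cell_id": f"c{i:04d}",
                "x_um": float(10 * (i + 1)),
                "y_um": 10.0,
                **marker_row(panel, positive),
            }
        )
    return pd.DataFrame(rows)


@pytest.fixture
def sample_meta():
    return SampleMeta("S0", "fully_allo_healthy", "nulliparous")
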