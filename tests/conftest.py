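import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from tmespatial import CoreSample
from tmespatial.geometry import CircularWindow
from tmespatial.phenotype import MARKERS

settings.register_profile("ci", derandomize=True, max_examples=50)
settings.load_profile("ci")


def csr_points(rng: np.random.Generator, n: int, radius: float = 300.0) -> np.ndarray:
    """n uniform points in a disc of the given radius centered at the origin."""
    r = radius * np.sqrt(rng.random(n))
    theta = rng.random(n) * 2 * np.pi
    return np.column_stack([r * np.cos(theta), r * np.sin(theta)])


def make_core(
    phenotype_xy: dict[str, np.ndarray],
    core_id: str = "C1",
    patient_id: str = "P1",
    radius: float = 300.0,
    hladr: float = 10.0,
    states: dict[str, np.ndarray] | None = None,
) -> CoreSample:
    """Build a core directly from phenotype->coordinates arrays."""
    from tmespatial.synthetic import _LINEAGE_FLAGS

    rows = []
    i = 0
    for ph, xy in phenotype_xy.items():
        for j in range(len(xy)):
            row = {"cell_id": f"{core_id}_c{i}", "x": xy[j, 0], "y": xy[j, 1]}
            for m in MARKERS:
                row[m] = _LINEAGE_FLAGS[ph].get(m, 0)
            if states is not None:
                for m, flags in states.items():
                    row[m] = int(flags[ph][j]) if ph in flags else row[m]
            row["phenotype"] = ph
            rows.append(row)
            i += 1
    cells = pd.DataFrame(rows) if rows else pd.DataFrame(
        columns=["cell_id", "x", "y", *MARKERS, "phenotype"]
    )
    for m in MARKERS:
        cells[m] = cells[m].astype(np.int8)
    return CoreSample(
        core_id=core_id,
        patient_id=patient_id,
        cells=cells,
        window=CircularWindow(0.0, 0.0, radius),
        hladr_area_pct=hladr,
    )


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
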