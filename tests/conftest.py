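"""Shared fixtures: phantom series and pipeline results reused across tests."""

import numpy as np
import pytest

from redoxtrack.phantom import PhantomConfig, generate_phantom_series
from redoxtrack.pipeline import process_well


@pytest.fixture(scope="session")
def control_phantom():
    """Default 512x512 control phantom: 8 organoids, 6 frames, 2 px drift."""
    cfg = PhantomConfig(seed=1)
    series, truth = generate_phantom_series(cfg)
    return cfg, series, truth


@pytest.fixture(scope="session")
def segmented_frame0(control_phantom):
    from redoxtrack.segmentation import segment_frame

    _, series, _ = control_phantom
    return segment_frame(series.frames[0][0])


@pytest.fixture(scope="session")
def control_well_result(control_phantom):
    """Full image-analysis chain on the control phantom (registration ->
    segmentation -> tracking -> features)."""
    _, series, _ = control_phantom
    return process_well(series)


@pytest.fixture(scope="session")
def mixed_phenotype_features():
    """Feature table quantified from ground-truth masks of a half-hollow
    phantom (bypasses segmentation; exercises quantification and PCA)."""
    from redoxtrack.registration import compute_orr
    from redoxtrack.features import quantify_organoid
    import pandas as pd

    cfg = PhantomConfig(seed=5, n_organoids=16, hollow_fraction=0.5,
                        radius_range=(22, 40), drift_px=(0, 0))
    series, truth = generate_phantom_series(cfg)
    rows = []
    for ti, ((nadh, fad), mask) in enumerate(zip(series.frames, truth.masks)):
        orr = compute_orr(nadh, fad).pixels
        t = nadh.time_h
        for oid in np.unique(mask)[1:]:
            rec = quantify_organoid(mask == oid, nadh.pixels, fad.pixels, orr)
            ph = truth.per_organoid.query(
                "organoid_id == @oid and time_h == @t"
            )["phenotype"].iloc[0]
            rec.update(
                organoid_id=int(oid), well=series.well_id, treatment="control",
                time_h=nadh.time_h, border_touching=False, phenotype=ph,
            )
            rows.append(rec)
    return pd.DataFrame(rows)
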