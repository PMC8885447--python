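"""Shared fixtures: small ground-truthed synthetic image sets.

Everything is generated at test time from seeded simulator specs; session
scope keeps the image-heavy fixtures to one rendering per run.
"""

import warnings

import numpy as np
import pandas as pd
import pytest

from inclusionprofiler.cytoprofile import normalize_features
from inclusionprofiler.simgen import SceneSpec, generate_field

warnings.filterwarnings("ignore", category=FutureWarning)


@pytest.fixture(scope="session")
def field_set():
    """Six default two-channel fields (noise and vignette on) with truth."""
    return [generate_field(SceneSpec(seed=s)) for s in range(1, 7)]


@pytest.fixture(scope="session")
def noise_free_set():
    """Twelve noise-free fields with the default vignette, for oracle checks.

    Twelve fields keep the pixelwise median free of cell-signal leakage
    (sparse cells overlap a given pixel in under half the fields).
    """
    return [generate_field(SceneSpec(seed=s, noise=(0.0, 0.0))) for s in range(1, 13)]


@pytest.fixture(scope="session")
def balanced_pool():
    """Cytoprofiles of ~600 segmented cells at balanced phenotype prevalence.

    Cells go through the same correct-segment-profile route used to score
    plates (a reviewer labels segmented thumbnails, not ground-truth masks);
    labels come from IoU matching against the simulator truth.  Returns raw
    profiles (with a ``field`` column disambiguating source fields),
    ground-truth labels, the z-scored frame and the retained normalization
    stats.
    """
    from inclusionprofiler.pipeline import labeled_pool

    pool, labels = labeled_pool(seeds=range(100, 115), prevalence=0.5)
    norm, stats = normalize_features(pool)
    return {"profiles": pool, "labels": labels, "normalized": norm, "stats": stats}
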