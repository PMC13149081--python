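"""Shared fixtures: phantom cohorts and the two trained reduced-scale models.

Training fixtures are session-scoped so the expensive fits run once; every
test that needs a fitted model shares them.  All randomness is seeded.
"""

from __future__ import annotations

import numpy as np
import pytest

from cestmix.models import (
    MixBranchNetGenotypeClassifier,
    MixBranchNetSegmenter,
    records_to_patch_arrays,
    records_to_seg_arrays,
)
from cestmix.phantom import PhantomConfig, generate_phantom


@pytest.fixture(scope="session")
def offsets():
    from cestmix.phantom import default_offsets

    return default_offsets()


@pytest.fixture(scope="session")
def seg_cohort():
    """16 easy phantoms (high tumor contrast, sigma 0.01): 12 train, 4 held out."""
    cfg = PhantomConfig(
        n_patients=16, image_size=64, seed=7,
        tumor_radius_range=(8.0, 13.0), noise_sigma=0.01,
    )
    records = generate_phantom(cfg)
    return records[:12], records[12:]


@pytest.fixture(scope="session")
def geno_cohort():
    """30 phantoms with the default (large) genotype APT effect: 24 train, 6 held out."""
    cfg = PhantomConfig(
        n_patients=30, image_size=96, seed=11,
        tumor_radius_range=(18.0, 28.0), noise_sigma=0.01,
    )
    records = generate_phantom(cfg)
    return records[:24], records[24:]


@pytest.fixture(scope="session")
def trained_segmenter(seg_cohort):
    train, _ = seg_cohort
    X, y = records_to_seg_arrays(train)
    seg = MixBranchNetSegmenter(
        base_width=8, learning_rate=0.1, batch_size=8,
        max_epochs=200, patience=150, val_frac=0.25, seed=42,
    )
    return seg.fit(X, y)


@pytest.fixture(scope="session")
def trained_genotype(geno_cohort):
    train, _ = geno_cohort
    X, y, m = records_to_patch_arrays(train, task="idh")
    geno = MixBranchNetGenotypeClassifier(
        base_width=8, learning_rate=0.05, batch_size=16,
        max_epochs=30, patience=29, val_frac=0.2, seed=42,
    )
    return geno.fit(X, y, pixel_mask=m)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
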