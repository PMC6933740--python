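import numpy as np
import pytest

from petscreen import (
    Cohort,
    Provenance,
    Subject,
    cohort_moments,
    default_config,
    simulate_cohort,
)


def _subjects(spec):
    """Build subjects from (count, genotype, pet_positive, abeta42) tuples."""
    subjects = []
    i = 0
    for count, genotype, pet, ab42 in spec:
        for _ in range(count):
            i += 1
            subjects.append(
                Subject(
                    subject_id=f"F{i:03d}",
                    genotype=genotype,
                    pet_positive=pet,
                    abeta40=50.0,
                    abeta42=ab42,
                    tau=20.0,
                )
            )
    return subjects


@pytest.fixture(scope="session")
def study_margin_cohort():
    """52-subject synthetic cohort reproducing the published genotype x PET
    margins: 12 of 14 e4 carriers PET+, 10 of 38 non-carriers PET+, all 7
    e2-only subjects PET-.  Marker values are arbitrary placeholders (PET+
    low, PET- high) — only genotype/PET structure matters here.
    """
    spec = [
        (12, "e3e4", True, 15.0),
        (2, "e3e4", False, 19.0),
        (10, "e3e3", True, 15.0),
        (21, "e3e3", False, 19.0),
        (7, "e2e3", False, 19.0),
    ]
    return Cohort(subjects=_subjects(spec), provenance=Provenance(source="external file"))


@pytest.fixture(scope="session")
def large_default_cohort():
    """n = 20 000 cohort from the calibrated default configuration."""
    config = default_config(n_subjects=20_000, seed=123)
    return simulate_cohort(config)


@pytest.fixture(scope="session")
def large_default_moments(large_default_cohort):
    return cohort_moments(large_default_cohort)


@pytest.fixture
def rng():
    return np.random.default_rng(20260923)


def random_scores_labels(rng, n_max=30, ensure_ties=True):
    """A random small scored instance with both classes (ties likely)."""
    n = int(rng.integers(4, n_max + 1))
    # coarse grid of score values makes ties frequent
    scores = rng.integers(0, 8, n).astype(float) if ensure_ties else rng.normal(size=n)
    labels = rng.random(n) < 0.5
    if labels.all():
        labels[int(rng.integers(0, n))] = False
    if not labels.any():
        labels[int(rng.integers(0, n))] = True
    return scores, labels
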