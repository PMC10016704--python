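import numpy as np
import pytest

from scemila.mil import MILConfig
from scemila.synthetic import SyntheticCohortSpec, generate_feature_bags

#: reduced-scale MIL configuration used throughout the tests (the full-scale
#: defaults in MILConfig train for hours on CPU at full dimensionality)
DESK_MIL = dict(embed_dim=64, attention_dim=32, learning_rate=1e-3,
                patience=5, max_epochs=30)


@pytest.fixture(scope="session")
def small_cohort():
    """Tiny separable cohort for fast training tests: 3 classes, d=16."""
    spec = SyntheticCohortSpec(
        n_classes=3, bags_per_class=12, bag_size_range=(20, 40), feature_dim=16,
        planted_fraction=(0.3, 0.3, 0.0), signature_separation=5.0, seed=42,
        class_names=("A", "B", "control"))
    return spec, generate_feature_bags(spec)


@pytest.fixture(scope="session")
def small_results(small_cohort):
    """A model trained once on the tiny cohort, shared across tests."""
    from scemila.mil import AttentionMIL

    spec, bags = small_cohort
    cfg = MILConfig(class_names=spec.class_names, seed=7, **DESK_MIL)
    return AttentionMIL(bags, cfg).fit()


@pytest.fixture(scope="session")
def small_cv(small_cohort):
    """3-fold cross-validation of the tiny cohort, shared across tests."""
    from scemila.mil import cross_validate

    spec, bags = small_cohort
    cfg = MILConfig(class_names=spec.class_names, seed=1, **DESK_MIL)
    return cross_validate(bags, cfg, k=3)
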