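import numpy as np
import pytest

from cancerlectin.pipeline import RunConfig, encode_records
from cancerlectin.sequence_io import AMINO_ACIDS, FeatureMatrix, load_dataset
from cancerlectin.simulate import SyntheticSpec, generate_dataset


def random_sequence(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(list(AMINO_ACIDS), size=length))


def gaussian_matrix(
    n_per_class: tuple[int, int],
    d: int = 10,
    shift: float = 2.0,
    n_informative: int | None = None,
    seed: int = 0,
) -> FeatureMatrix:
    """Two-class Gaussian feature matrix; the first *n_informative* features
    (default: all) have class means separated by *shift* SDs."""
    rng = np.random.default_rng(seed)
    n_neg, n_pos = n_per_class
    if n_informative is None:
        n_informative = d
    X = rng.normal(size=(n_neg + n_pos, d))
    X[n_neg:, :n_informative] += shift
    y = np.concatenate([np.zeros(n_neg, dtype=int), np.ones(n_pos, dtype=int)])
    return FeatureMatrix(
        values=X,
        feature_names=[f"f{i}" for i in range(d)],
        ids=[f"s{i}" for i in range(n_neg + n_pos)],
        labels=y,
    )


@pytest.fixture(scope="session")
def synthetic_paths(tmp_path_factory):
    """A small separable synthetic dataset with PSSM and disorder files."""
    spec = SyntheticSpec(n_per_class=20, separation=0.25, seed=11)
    return generate_dataset(spec, tmp_path_factory.mktemp("synth"))


@pytest.fixture(scope="session")
def synthetic_features(synthetic_paths):
    """The 365-column feature matrix encoded from the session dataset."""
    dataset = load_dataset(synthetic_paths.positives, synthetic_paths.negatives)
    config = RunConfig(
        pssm_dir=str(synthetic_paths.pssm_dir),
        disorder_dir=str(synthetic_paths.disorder_dir),
    )
    return encode_records(dataset, config)
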