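import numpy as np
import pytest

from pigmount.evaluation import make_folds, grid_search_cv
from pigmount.geometry_features import frames_to_feature_table
from pigmount.segmentation_io import InstanceMask
from pigmount.synthetic_scenes import SceneConfig, simulate_dataset

# one shared synthetic study: 300 frames at the default scene configuration,
# split 200 train / 100 held-out, used by the end-to-end tests
STUDY_SEED = 101
N_TRAIN, N_TEST = 200, 100
GAMMAS = [0.001, 0.01, 0.1, 1.0]
CS = [1.0, 10.0, 100.0, 1000.0]


def random_blob_mask(rng, h=36, w=36):
    """A random non-empty blobby mask for property tests."""
    field = rng.normal(size=(h, w))
    from scipy import ndimage

    smooth = ndimage.gaussian_filter(field, sigma=3.0)
    mask = smooth > np.quantile(smooth, 0.75)
    if not mask.any():
        mask[h // 2, w // 2] = True
    return InstanceMask(mask)


@pytest.fixture(scope="session")
def synthetic_study():
    """300 default-config frames with their feature table (seeded)."""
    frames, manifest = simulate_dataset(SceneConfig(), N_TRAIN + N_TEST, 0.5, seed=STUDY_SEED)
    table = frames_to_feature_table([f.record for f in frames])
    feat_cols = [c for c in table.columns if c not in ("frame_id", "label")]
    X = table[feat_cols].to_numpy(float)
    y = table["label"].tolist()
    return {
        "frames": frames,
        "manifest": manifest,
        "table": table,
        "X_train": X[:N_TRAIN],
        "y_train": y[:N_TRAIN],
        "X_test": X[N_TRAIN:],
        "y_test": y[N_TRAIN:],
    }


@pytest.fixture(scope="session")
def tuned_models(synthetic_study):
    """Fivefold grid-searched KELM models fit on the training partition."""
    plan = make_folds(N_TRAIN, K=5, seed=STUDY_SEED)
    return grid_search_cv(
        synthetic_study["X_train"], synthetic_study["y_train"], GAMMAS, CS, plan
    )
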