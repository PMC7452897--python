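import numpy as np
import pandas as pd
import pytest

from radsurv.io import ROIMask, VolumetricImage


@pytest.fixture
def ball_mask():
    """Digital ball of radius 10 voxels on a 25^3 grid, 1 mm spacing."""
    g = np.indices((25, 25, 25)) - 12
    return ROIMask(((g**2).sum(axis=0) <= 100).astype(np.uint8))


@pytest.fixture
def random_image_mask():
    rng = np.random.default_rng(42)
    img = VolumetricImage(rng.standard_normal((9, 9, 9)))
    vox = np.zeros((9, 9, 9), dtype=np.uint8)
    vox[2:7, 2:7, 2:7] = 1
    return img, ROIMask(vox)


def make_survival_features(
    seed: int, n: int = 300, n_noise: int = 20, betas=(0.8,), baseline=0.02,
    admin: float = 60.0, censor_scale: float = 80.0
):
    """Feature-level survival study: planted features + pure noise columns."""
    rng = np.random.default_rng(seed)
    p = n_noise + len(betas)
    X = rng.standard_normal((n, p))
    beta = np.concatenate([np.asarray(betas, float), np.zeros(n_noise)])
    lam = baseline * np.exp(X @ beta)
    t_event = rng.exponential(1.0 / lam)
    t_cens = np.minimum(rng.exponential(censor_scale, n), admin)
    idx = pd.Index([f"p{i:04d}" for i in range(n)], name="patient_id")
    surv = pd.DataFrame(
        {
            "time_months": np.minimum(t_event, t_cens),
            "event": (t_event <= t_cens).astype(int),
        },
        index=idx,
    )
    cols = [f"true{i}" for i in range(len(betas))] + [f"noise{i}" for i in range(n_noise)]
    feats = pd.DataFrame(X, columns=cols, index=idx)
    return feats, surv, X @ beta
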