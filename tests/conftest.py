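import numpy as np
import pytest

import tucker3pcovr as tp


def subspace_congruence(M1: np.ndarray, M2: np.ndarray) -> float:
    """Mean cosine of the principal angles between two column spaces."""
    q1, _ = np.linalg.qr(np.asarray(M1, float))
    q2, _ = np.linalg.qr(np.asarray(M2, float))
    return float(np.linalg.svd(q1.T @ q2, compute_uv=False).mean())


@pytest.fixture(scope="session")
def congruence():
    return subspace_congruence


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def noisy_fit():
    """A converged (2,2,2) fit on an 8x7x6 + 8x10 coupled dataset at SNR 10."""
    dataset, truth = tp.generate(8, 7, 6, 10, (2, 2, 2), snr_x=10, snr_y=10, seed=7)
    pre, info = tp.preprocess_dataset(dataset)
    fit = tp.fit(
        pre,
        tp.FitConfig(alpha=0.5, ranks=tp.Ranks(2, 2, 2), n_starts=5, seed=3),
        preprocess=info,
    )
    return {"dataset": dataset, "pre": pre, "info": info, "truth": truth, "fit": fit}


@pytest.fixture(scope="session")
def tall_fit():
    """A (3,2,2) fit, so rank-2 displays are genuine truncations."""
    dataset, _ = tp.generate(12, 5, 4, 8, (3, 2, 2), snr_x=8, snr_y=8, seed=11)
    pre, info = tp.preprocess_dataset(dataset)
    fit = tp.fit(
        pre,
        tp.FitConfig(alpha=0.5, ranks=tp.Ranks(3, 2, 2), n_starts=4, seed=5),
        preprocess=info,
    )
    return fit


def random_parameter_set(rng, I=6, J=4, K=3, L=5, R=(2, 2, 2)):
    """An arbitrary (not fitted) parameter set plus data blocks."""
    R1, R2, R3 = R
    return dict(
        A=rng.standard_normal((I, R1)),
        B=rng.standard_normal((J, R2)),
        C=rng.standard_normal((K, R3)),
        G=rng.standard_normal((R1, R2, R3)),
        P_X=rng.standard_normal((L, R1)),
        X=rng.standard_normal((I, L)),
        Y_A=rng.standard_normal((I, J * K)),
    )
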