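"""Coupled-data generator with known Tucker3-PCovR ground truth.

The generator draws a low-rank object-score matrix shared by both blocks and
builds

* ``X = A P_X' + E_X`` with ``A`` lying in the column space of the noiseless
  X (so ``A = X W_X`` holds exactly at infinite SNR), and
* ``Y_A = A G_A (C (x) B)' + E_A`` with orthonormal B, C and a random core,

then adds i.i.d. Gaussian noise per block scaled to a requested
signal-to-noise ratio ``SNR = ||signal||_F / ||noise||_F``, matching the
least-squares error model of the estimation criterion.  Raw (un-preprocessed)
blocks are returned together with the generating parameters, which recovery
tests compare against the estimates.

The default dimensions (8 objects x 7 attributes x 6 sources with 10
covariates, complexity (2, 2, 2)) mirror a small personality-psychology
design: a handful of persons rating emotional reactions to situations, with
dispositions as predictors.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import CoupledDataset, Ranks, unfold_core, fold

__all__ = ["SyntheticTruth", "generate"]


@dataclass(frozen=True)
class SyntheticTruth:
    """Ground-truth parameters behind one generated dataset."""

    A: np.ndarray
    B: np.ndarray
    C: np.ndarray
    G: np.ndarray
    P_X: np.ndarray
    W_X: np.ndarray
    noise_sd_x: float
    noise_sd_y: float
    snr_x: float
    snr_y: float
    seed: int


def _orthonormal(rng: np.random.Generator, n: int, r: int) -> np.ndarray:
    Q, R = np.linalg.qr(rng.standard_normal((n, r)))
    return Q * np.sign(np.diag(R))


def generate(
    I: int = 8,
    J: int = 7,
    K: int = 6,
    L: int = 10,
    ranks: Ranks | tuple[int, int, int] = (2, 2, 2),
    snr_x: float = 10.0,
    snr_y: float = 10.0,
    seed: int = 0,
) -> tuple[CoupledDataset, SyntheticTruth]:
    """Generate one coupled dataset with Tucker3-PCovR structure.

    ``snr_x``/``snr_y`` are Frobenius signal-to-noise ratios per block;
    ``np.inf`` gives noiseless data.  Same seed, same data.
    """
    if not isinstance(ranks, Ranks):
        ranks = Ranks(*ranks)
    ranks.validate_for(I, J, K, L)
    if ranks.R1 > L:
        raise ValueError(
            f"the generator requires R1 <= L so the scores can live in the "
            f"predictor column space (got R1={ranks.R1}, L={L})"
        )
    if snr_x <= 0 or snr_y <= 0:
        raise ValueError("signal-to-noise ratios must be positive (or np.inf)")
    rng = np.random.default_rng(seed)

    A = rng.standard_normal((I, ranks.R1))
    P_X = rng.standard_normal((L, ranks.R1))
    B = _orthonormal(rng, J, ranks.R2)
    C = _orthonormal(rng, K, ranks.R3)
    G = rng.standard_normal((ranks.R1, ranks.R2, ranks.R3))

    X_signal = A @ P_X.T
    # weights reproducing A from the noiseless predictors: A = X_signal W_X
    W_X = np.linalg.pinv(X_signal) @ A
    Y_signal_A = A @ unfold_core(G, "A") @ np.kron(C, B).T

    def _noisy(signal: np.ndarray, snr: float) -> tuple[np.ndarray, float]:
        if np.isinf(snr):
            return signal.copy(), 0.0
        sd = np.linalg.norm(signal) / (snr * np.sqrt(signal.size))
        return signal + sd * rng.standard_normal(signal.shape), float(sd)

    X, sd_x = _noisy(X_signal, snr_x)
    Y_A, sd_y = _noisy(Y_signal_A, snr_y)
    dataset = CoupledDataset(X=X, Y=fold(Y_A, "A", (I, J, K)))
    truth = SyntheticTruth(
        A=A, B=B, C=C, G=G, P_X=P_X, W_X=W_X,
        noise_sd_x=sd_x, noise_sd_y=sd_y,
        snr_x=float(snr_x), snr_y=float(snr_y), seed=seed,
    )
    return dataset, truth
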