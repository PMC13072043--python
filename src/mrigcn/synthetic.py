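"""Synthetic embedding generator with four controllable class clusters.

Produces feature tables whose geometry mirrors what the pipeline assumes
of real CNN embeddings: tight same-class clusters, one pair of classes
(glioma/meningioma by default) pulled closer together, and the healthy
class well separated. Class proportions default to the source dataset's
training-split ratios so weighted metrics are exercised.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.model_selection import train_test_split

from mrigcn.embeddings import CLASS_NAMES, EmbeddingTable

# training-split class proportions of the reference dataset, scaled down
_DEFAULT_COUNTS = (92, 94, 102, 112)


class SyntheticConfigError(ValueError):
    pass


class StratificationError(ValueError):
    """A class has fewer samples than its split slots."""


@dataclass
class SyntheticConfig:
    n_per_class: tuple[int, int, int, int] = _DEFAULT_COUNTS
    dim: int = 2048
    prototype_separation: float = np.pi / 3
    overlap_pairs: tuple[tuple[int, int, float], ...] = ((0, 1, 0.6),)
    # per-component sd; within-class cosine ~ 1/(1 + dim*sd^2), so keep
    # dim*sd^2 well below 1 (default is tuned for dim=2048; use ~0.1 at dim=32)
    noise_sd: float = 0.012
    seed: int = 42

    def __post_init__(self) -> None:
        if len(self.n_per_class) != 4 or any(n < 1 for n in self.n_per_class):
            raise SyntheticConfigError("n_per_class must be 4 positive integers")
        if self.noise_sd <= 0:
            raise SyntheticConfigError("noise_sd must be positive")
        if not 0 <= self.prototype_separation <= np.pi / 2:
            raise SyntheticConfigError("prototype_separation must lie in [0, pi/2]")
        for a, b, o in self.overlap_pairs:
            if not 0.0 <= o <= 1.0:
                raise SyntheticConfigError("extra_overlap must lie in [0, 1]")
            if not (0 <= a < 4 and 0 <= b < 4 and a != b):
                raise SyntheticConfigError("overlap pair indices must be distinct classes")


def generate_prototypes(cfg: SyntheticConfig) -> np.ndarray:
    """Four unit-norm cluster centers with controlled pairwise angles.

    Construction: a shared direction ``u`` plus one orthonormal direction
    per class gives equal pairwise cosine ``cos(separation)``; overlap
    pairs are then linearly interpolated toward their midpoint by
    ``extra_overlap`` and renormalized (overlap 1 makes them identical).
    """
    if cfg.dim < 5:
        raise SyntheticConfigError("dim must be >= 5 to fit four separated prototypes")
    rng = np.random.default_rng(cfg.seed)
    basis, _ = np.linalg.qr(rng.standard_normal((cfg.dim, 5)))
    u, es = basis[:, 0], basis[:, 1:]
    t = np.cos(cfg.prototype_separation)  # target pairwise cosine, >= 0
    protos = np.sqrt(t) * u[None, :] + np.sqrt(1 - t) * es.T
    for a, b, o in cfg.overlap_pairs:
        mid = 0.5 * (protos[a] + protos[b])
        pa = (1 - o) * protos[a] + o * mid
        pb = (1 - o) * protos[b] + o * mid
        protos[a], protos[b] = pa, pb
    protos /= np.linalg.norm(protos, axis=1, keepdims=True)
    return protos


def sample_embeddings(cfg: SyntheticConfig) -> EmbeddingTable:
    """Draw ``n_per_class[c]`` rows per class around each prototype."""
    rng = np.random.default_rng(cfg.seed)
    protos = generate_prototypes(cfg)
    rows, labels = [], []
    for c, n in enumerate(cfg.n_per_class):
        noise = rng.normal(scale=cfg.noise_sd, size=(n, cfg.dim))
        rows.append(protos[c][None, :] + noise)
        labels.extend([c] * n)
    X = np.vstack(rows)
    y = np.asarray(labels, dtype=np.int64)
    perm = rng.permutation(len(y))
    ids = [f"synth_{i:05d}" for i in range(len(y))]
    return EmbeddingTable(vectors=X[perm], ids=ids, labels=y[perm])


def make_split(
    labels: np.ndarray,
    test_fraction: float,
    val_fraction: float,
    seed: int,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Stratified boolean train/val/test masks.

    ``test_fraction`` applies to the full data; ``val_fraction`` to the
    remainder after the test split (the validation-split convention of
    the training configuration).
    """
    labels = np.asarray(labels)
    if not (0 < test_fraction < 1 and 0 < val_fraction < 1) or test_fraction + val_fraction >= 1:
        raise ValueError("fractions must lie in (0,1) and sum below 1")
    idx = np.arange(len(labels))
    try:
        rest, test_idx = train_test_split(
            idx, test_size=test_fraction, stratify=labels, random_state=seed
        )
        train_idx, val_idx = train_test_split(
            rest, test_size=val_fraction, stratify=labels[rest], random_state=seed
        )
    except ValueError as exc:
        raise StratificationError(str(exc)) from exc
    masks = []
    for part in (train_idx, val_idx, test_idx):
        m = np.zeros(len(labels), dtype=bool)
        m[part] = True
        masks.append(m)
    return tuple(masks)
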