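"""Small shared helpers."""
from __future__ import annotations

import numpy as np

SeedLike = "int | np.random.Generator | np.random.SeedSequence | None"


def as_rng(seed) -> np.random.Generator:
    """Coerce an int / SeedSequence / Generator / None into a Generator."""
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def unit_phasors(data: np.ndarray) -> np.ndarray:
    """Normalise complex samples to unit modulus; zero samples are an error upstream."""
    mod = np.abs(data)
    if np.any(mod == 0):
        bad = np.argwhere(mod == 0)
        raise ValueError(
            f"zero-amplitude sample(s), first at (sample, source)={tuple(bad[0])}"
        )
    return data / mod


def upper_triangle_values(matrix: np.ndarray) -> np.ndarray:
    """Off-diagonal upper-triangle entries of a square matrix, row-major order."""
    i, j = np.triu_indices(matrix.shape[0], k=1)
    return matrix[i, j]


def check_square(matrix: np.ndarray, name: str = "matrix") -> np.ndarray:
    matrix = np.asarray(matrix)
    if matrix.ndim != 2 or matrix.shape[0] != matrix.shape[1]:
        raise ValueError(f"{name} must be square, got shape {matrix.shape}")
    return matrix
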