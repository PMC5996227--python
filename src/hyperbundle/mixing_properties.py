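"""Mixing properties of a source space, estimated from null simulations.

Passing uncorrelated ("null") narrowband series X through a mixing model and
comparing originals with the modeled series X^ yields, per iteration:

* mixing function   f_mix[i, j] = PLV(X_i, X^_j)      — cross-talk between a
  source's original signal and another source's modeled signal;
* residual spread   PLV0[i, j]  = PLV(X^_i, X^_j)     — the artificial
  synchrony floor between two modeled signals;
* parcel fidelity   f_p[i]      = Re cPLV(X_i, X^_i)  — modeling accuracy of a
  parcel (real part, so a systematic phase error lowers fidelity);
* edge fidelity     f_e[i, j]   = max(f_p[i], 0) * max(f_p[j], 0).

Estimates are averaged over iterations (fresh null series each time); the
chance level for a null PLV with n independent samples is sqrt(pi / (4 n)).

The intractable-edge-mask (IEM) deletes edges whose endpoints are too poorly
modeled (low f_e) or too mutually mixed (high PLV0) to be interpretable.
"""
from __future__ import annotations

import dataclasses
import math

import numpy as np

from ._util import as_rng, check_square, unit_phasors, upper_triangle_values
from .mixing import MixingModel, apply_mixing
from .signals import decimate_independent, decimation_step, morlet_noise

__all__ = [
    "MixingProperties",
    "IntractableEdgeMask",
    "null_plv_chance_level",
    "estimate_mixing_properties",
    "edge_fidelity",
    "build_iem",
    "group_mean",
]


def null_plv_chance_level(n_samples: int) -> float:
    """Expected PLV of two uncoupled sources with n independent samples."""
    return math.sqrt(math.pi / (4.0 * n_samples))


@dataclasses.dataclass
class MixingProperties:
    f_mix: np.ndarray  # symmetrised on output
    plv0: np.ndarray
    f_p: np.ndarray
    f_e: np.ndarray
    n_iterations: int
    n_samples: int

    def __post_init__(self):
        for name in ("f_mix", "plv0", "f_e"):
            setattr(self, name, check_square(np.asarray(getattr(self, name)), name))
        self.f_p = np.asarray(self.f_p, dtype=float)

    @property
    def n_parcels(self) -> int:
        return len(self.f_p)

    @property
    def chance_level(self) -> float:
        return null_plv_chance_level(self.n_samples)

    def parcel_mean_plv0(self) -> np.ndarray:
        """Mean off-diagonal residual spread per parcel."""
        off = self.plv0.copy()
        np.fill_diagonal(off, np.nan)
        return np.nanmean(off, axis=1)


@dataclasses.dataclass
class IntractableEdgeMask:
    mask: np.ndarray  # boolean, True = edge deleted; symmetric, diagonal True
    fe_cutoff: float
    plv0_cutoff: float
    deleted_fraction: float

    def __post_init__(self):
        self.mask = check_square(np.asarray(self.mask, dtype=bool), "mask")
        if not np.array_equal(self.mask, self.mask.T):
            raise ValueError("mask must be symmetric")
        if not np.all(np.diag(self.mask)):
            raise ValueError("diagonal is deleted by definition")


def edge_fidelity(f_p: np.ndarray) -> np.ndarray:
    """f_e[i, j] = max(f_p[i], 0) * max(f_p[j], 0)."""
    f_p = np.asarray(f_p, dtype=float)
    if np.any(f_p < -1) or np.any(f_p > 1):
        raise ValueError("parcel fidelities must lie in [-1, 1]")
    clipped = np.clip(f_p, 0.0, None)
    return np.outer(clipped, clipped)


def estimate_mixing_properties(
    model: MixingModel,
    n_iter: int = 10,
    n_samples: int = 1000,
    seed=None,
    f0: float = 10.0,
    m: float = 5.0,
    fs: float = 100.0,
) -> MixingProperties:
    """Average f_mix, PLV0 and f_p over `n_iter` null simulations through `model`.

    Each iteration draws fresh uncorrelated Morlet-noise series, decimates them
    to `n_samples` independent samples, measures them through the model and
    compares original with modeled phasors.  f_mix is directional per
    iteration (original i vs modeled j) and symmetrised on output.
    """
    if n_iter < 1:
        raise ValueError("n_iter must be >= 1")
    rng = as_rng(seed)
    n = model.n_sources
    step = decimation_step(f0, m, fs)
    n_raw = (n_samples - 1) * step + 1
    f_mix = np.zeros((n, n))
    plv0 = np.zeros((n, n))
    f_p = np.zeros(n)
    for _ in range(n_iter):
        raw = morlet_noise(n_raw, n, f0=f0, m=m, fs=fs, seed=rng)
        x = decimate_independent(raw, n_samples, step=step)
        xh = apply_mixing(x, model, seed=rng)
        zx = unit_phasors(x.data)
        zh = unit_phasors(xh.data)
        cross = (zx.T @ np.conj(zh)) / n_samples  # cPLV(X_i, X^_j)
        f_mix += np.abs(cross)
        f_p += np.real(np.diag(cross))
        chh = (zh.T @ np.conj(zh)) / n_samples
        p0 = np.abs(chh)
        np.fill_diagonal(p0, 1.0)
        plv0 += p0
    f_mix /= n_iter
    plv0 /= n_iter
    f_p /= n_iter
    f_mix = (f_mix + f_mix.T) / 2.0
    plv0 = (plv0 + plv0.T) / 2.0
    return MixingProperties(
        f_mix=f_mix,
        plv0=plv0,
        f_p=f_p,
        f_e=edge_fidelity(np.clip(f_p, -1.0, 1.0)),
        n_iterations=n_iter,
        n_samples=n_samples,
    )


def build_iem(
    props: MixingProperties,
    fe_cutoff: float = 0.1,
    plv0_cutoff: float | None = None,
    target_deleted_fraction: float | None = None,
) -> IntractableEdgeMask:
    """Mask edges with f_e < fe_cutoff OR PLV0 > plv0_cutoff.

    Give either an explicit `plv0_cutoff` or a `target_deleted_fraction`; in
    the latter case the PLV0 cutoff is tuned so the total deleted fraction of
    unique edges matches the target to within one edge.
    """
    if plv0_cutoff is not None and target_deleted_fraction is not None:
        raise ValueError("give plv0_cutoff or target_deleted_fraction, not both")
    if not 0.0 <= fe_cutoff <= 1.0:
        raise ValueError("fe_cutoff must be in [0, 1]")
    n = props.n_parcels
    iu = np.triu_indices(n, k=1)
    fe_vals = props.f_e[iu]
    plv0_vals = props.plv0[iu]
    fe_deleted = fe_vals < fe_cutoff
    n_pairs = fe_vals.size
    if target_deleted_fraction is not None:
        if not 0.0 < target_deleted_fraction < 1.0:
            raise ValueError("target_deleted_fraction must be in (0, 1)")
        want = int(round(target_deleted_fraction * n_pairs))
        have = int(fe_deleted.sum())
        if have > want:
            raise ValueError(
                f"f_e cutoff alone already deletes {have}/{n_pairs} edges, above the "
                f"target {want}; lower fe_cutoff or give plv0_cutoff explicitly"
            )
        remaining = np.sort(plv0_vals[~fe_deleted])[::-1]
        extra = want - have
        if extra == 0:
            plv0_cut = np.inf
        elif extra >= remaining.size:
            plv0_cut = -np.inf
        else:
            plv0_cut = (remaining[extra - 1] + remaining[extra]) / 2.0
    else:
        plv0_cut = np.inf if plv0_cutoff is None else float(plv0_cutoff)
    deleted = fe_deleted | (plv0_vals > plv0_cut)
    mask = np.zeros((n, n), dtype=bool)
    mask[iu] = deleted
    mask |= mask.T
    np.fill_diagonal(mask, True)
    return IntractableEdgeMask(
        mask=mask,
        fe_cutoff=fe_cutoff,
        plv0_cutoff=float(plv0_cut),
        deleted_fraction=float(deleted.sum()) / n_pairs,
    )


def group_mean(props_list) -> MixingProperties:
    """Arithmetic mean of mixing properties across subjects/models."""
    props_list = list(props_list)
    if not props_list:
        raise ValueError("empty group")
    n = props_list[0].n_parcels
    if any(p.n_parcels != n for p in props_list):
        raise ValueError("all members must share the parcellation size")
    f_p = np.mean([p.f_p for p in props_list], axis=0)
    return MixingProperties(
        f_mix=np.mean([p.f_mix for p in props_list], axis=0),
        plv0=np.mean([p.plv0 for p in props_list], axis=0),
        f_p=f_p,
        f_e=edge_fidelity(np.clip(f_p, -1.0, 1.0)),
        n_iterations=sum(p.n_iterations for p in props_list),
        n_samples=props_list[0].n_samples,
    )


def upper_pair_values(matrix: np.ndarray) -> np.ndarray:  # convenience re-export
    return upper_triangle_values(matrix)
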