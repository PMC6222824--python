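"""Stimulus spaces: finite candidate grids, normalization, feature embedding.

All inference in this package operates on a *normalized* stimulus space in
which every stimulus dimension has zero mean and unit standard deviation over
the candidate set.  Normalization makes the weight prior isotropic in a
meaningful way: a bias weight is the average log-odds over the space, and a
unit step along any weight dimension has a comparable effect on the choice
probabilities.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["StimulusSpace", "normalize_space", "grid_candidates"]


def grid_candidates(mins, maxs, n_points) -> np.ndarray:
    """Build a regular rectangular grid of candidate stimuli.

    Parameters
    ----------
    mins, maxs : sequence of float, length d
        Per-dimension extents (inclusive).
    n_points : int or sequence of int
        Number of grid points per dimension.

    Returns
    -------
    (n, d) array in row-major (last dimension fastest) order.
    """
    mins = np.atleast_1d(np.asarray(mins, dtype=float))
    maxs = np.atleast_1d(np.asarray(maxs, dtype=float))
    if np.isscalar(n_points) or np.ndim(n_points) == 0:
        n_points = [int(n_points)] * len(mins)
    axes = [np.linspace(lo, hi, n) for lo, hi, n in zip(mins, maxs, n_points)]
    mesh = np.meshgrid(*axes, indexing="ij")
    return np.stack([m.ravel() for m in mesh], axis=-1)


@dataclass(frozen=True)
class StimulusSpace:
    """A finite candidate set of d-dimensional stimulus vectors.

    Attributes
    ----------
    candidates : (n, d) array
        Normalized candidate stimuli (zero mean, unit SD per dimension,
        unless ``normalized`` is False).
    offset, scale : (d,) arrays
        The affine map from raw to normalized coordinates:
        ``normalized = (raw - offset) / scale``.
    feature_map_id : str
        Identifier of the feature embedding; the default ``"affine"``
        embedding is φ(x) = [1, x], giving one bias plus d sensitivity
        weights per response category.
    """

    candidates: np.ndarray
    offset: np.ndarray
    scale: np.ndarray
    feature_map_id: str = "affine"
    normalized: bool = True
    _features: np.ndarray | None = field(default=None, repr=False, compare=False)

    def __post_init__(self):
        cand = np.asarray(self.candidates, dtype=float)
        if cand.ndim != 2:
            raise ValueError("candidates must be a 2-D array of shape (n, d)")
        object.__setattr__(self, "candidates", cand)
        object.__setattr__(self, "offset", np.asarray(self.offset, dtype=float))
        object.__setattr__(self, "scale", np.asarray(self.scale, dtype=float))

    @property
    def n_candidates(self) -> int:
        return self.candidates.shape[0]

    @property
    def d(self) -> int:
        return self.candidates.shape[1]

    @property
    def n_features(self) -> int:
        return self.d + 1

    def to_normalized(self, raw: np.ndarray) -> np.ndarray:
        raw = np.asarray(raw, dtype=float)
        return (raw - self.offset) / self.scale

    def to_raw(self, normalized: np.ndarray) -> np.ndarray:
        normalized = np.asarray(normalized, dtype=float)
        return normalized * self.scale + self.offset

    def features(self, x: np.ndarray | None = None) -> np.ndarray:
        """Feature embedding φ(x) = [1, x] of normalized stimuli.

        With ``x=None``, returns the (n, d+1) feature matrix of the whole
        candidate set (cached).
        """
        if x is None:
            if self._features is None:
                feats = self.features(self.candidates)
                object.__setattr__(self, "_features", feats)
            return self._features
        x = np.atleast_2d(np.asarray(x, dtype=float))
        ones = np.ones((x.shape[0], 1))
        return np.concatenate([ones, x], axis=1)

    def feature(self, x: np.ndarray) -> np.ndarray:
        """φ(x) for a single stimulus vector, as a 1-D array."""
        return self.features(np.atleast_2d(x))[0]


def normalize_space(
    raw_candidates,
    feature_map_id: str = "affine",
    normalize: bool = True,
) -> StimulusSpace:
    """Normalize a raw candidate set to zero mean and unit SD per dimension.

    Uses the population standard deviation over the candidate set (the grid is
    the whole space, not a sample from it).  The affine transform is retained
    on the returned :class:`StimulusSpace` for raw↔normalized round-tripping.

    Raises
    ------
    ValueError
        If fewer than two distinct candidates are given or any dimension is
        constant across the set (its scale would be undefined).
    """
    raw = np.atleast_2d(np.asarray(raw_candidates, dtype=float))
    if raw.ndim != 2:
        raise ValueError("raw_candidates must be a (n, d) array")
    if np.unique(raw, axis=0).shape[0] < 2:
        raise ValueError("need at least 2 distinct candidate stimuli")
    if not normalize:
        d = raw.shape[1]
        return StimulusSpace(
            candidates=raw,
            offset=np.zeros(d),
            scale=np.ones(d),
            feature_map_id=feature_map_id,
            normalized=False,
        )
    offset = raw.mean(axis=0)
    scale = raw.std(axis=0)  # population SD
    constant = np.nonzero(scale == 0.0)[0]
    if constant.size:
        raise ValueError(
            f"stimulus dimension(s) {constant.tolist()} are constant across the "
            "candidate set; their normalization scale is undefined"
        )
    return StimulusSpace(
        candidates=(raw - offset) / scale,
        offset=offset,
        scale=scale,
        feature_map_id=feature_map_id,
    )
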