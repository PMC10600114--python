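"""Dot-product MRF pattern matching and parameter-map comparison.

Each masked pixel trajectory and every dictionary row are scaled to unit
Euclidean norm; the dictionary row with the maximal inner product (cosine
similarity) supplies the pixel's parameters.  Matching is therefore
invariant to any positive per-pixel scaling (arbitrary receive gain), ties
break to the lowest row index, and all-zero pixels get score 0 and NaN maps.

The dictionary is streamed in fixed-size chunks so memory stays bounded for
~1e6-row dictionaries; results are independent of the chunk size.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Optional

import nibabel as nib
import numpy as np
import pandas as pd
from skimage.metrics import structural_similarity
from sklearn.base import BaseEstimator

from .dictionary import Dictionary
from .metrics import nrmse as _nrmse

DEFAULT_MATCH_CHUNK = 65536


@dataclass
class ImageSeries:
    """An N-frame image series (frames first: (N, H, W))."""

    data: np.ndarray
    mask: Optional[np.ndarray] = None
    protocol_ref: str = ""

    def __post_init__(self):
        self.data = np.asarray(self.data, float)
        if self.data.ndim != 3:
            raise ValueError("image series must be (n_frames, height, width)")
        if self.mask is not None:
            self.mask = np.asarray(self.mask, bool)
            if self.mask.shape != self.data.shape[1:]:
                raise ValueError("mask shape does not match the image frames")

    @property
    def n_frames(self) -> int:
        return self.data.shape[0]

    def to_nifti(self, path) -> None:
        # stored as (H, W, 1, N) so standard viewers treat frames as volumes
        vol = np.transpose(self.data, (1, 2, 0))[:, :, None, :]
        nib.save(nib.Nifti1Image(vol, np.eye(4)), str(path))

    @classmethod
    def from_nifti(cls, path, mask=None) -> "ImageSeries":
        vol = np.asarray(nib.load(str(path)).get_fdata())
        if vol.ndim != 4:
            raise ValueError("expected a 4-D NIfTI volume")
        return cls(np.transpose(vol[:, :, 0, :], (2, 0, 1)), mask=mask)


@dataclass
class QuantMaps:
    """Per-pixel matched parameter maps plus match quality."""

    maps: Dict[str, np.ndarray]
    score: np.ndarray          # normalized inner product in [-1, 1]
    index: np.ndarray          # matched dictionary row, -1 where unmatched
    mask: np.ndarray

    def to_nifti(self, prefix) -> None:
        for name, arr in {**self.maps, "score": self.score}.items():
            safe = name.replace(".", "_")
            nib.save(nib.Nifti1Image(arr[..., None], np.eye(4)),
                     f"{prefix}_{safe}.nii.gz")

    def summary(self) -> pd.DataFrame:
        rows = []
        for name, arr in self.maps.items():
            vals = arr[self.mask & np.isfinite(arr)]
            rows.append({
                "parameter": name,
                "mean": vals.mean() if vals.size else np.nan,
                "std": vals.std() if vals.size else np.nan,
                "min": vals.min() if vals.size else np.nan,
                "max": vals.max() if vals.size else np.nan,
            })
        return pd.DataFrame(rows)


def match_trajectories(
    queries: np.ndarray,
    signals: np.ndarray,
    chunk_size: int = DEFAULT_MATCH_CHUNK,
):
    """Cosine-similarity argmax of each query row over the dictionary rows.

    Returns ``(index, score)``; zero-norm queries give index -1, score 0.
    """
    queries = np.asarray(queries, float)
    signals = np.asarray(signals, float)
    if queries.shape[-1] != signals.shape[-1]:
        raise ValueError("query and dictionary trajectory lengths differ")
    if signals.shape[0] == 0:
        raise ValueError("empty dictionary")
    qn = np.linalg.norm(queries, axis=1)
    ok = qn > 0
    q = np.zeros_like(queries)
    q[ok] = queries[ok] / qn[ok, None]

    best_idx = np.full(len(queries), -1, dtype=np.int64)
    best_score = np.full(len(queries), -np.inf)
    for lo in range(0, len(signals), chunk_size):
        chunk = signals[lo:lo + chunk_size]
        norms = np.linalg.norm(chunk, axis=1)
        norms[norms == 0] = 1.0
        scores = q @ (chunk / norms[:, None]).T
        idx = np.argmax(scores, axis=1)          # first max within the chunk
        val = scores[np.arange(len(q)), idx]
        better = val > best_score                # strict: earliest row wins ties
        best_idx[better] = idx[better] + lo
        best_score[better] = val[better]
    best_idx[~ok] = -1
    best_score[~ok] = 0.0
    return best_idx, best_score


class DotProductMatcher(BaseEstimator):
    """Nearest-dictionary-entry matcher under cosine similarity."""

    def __init__(self, chunk_size: int = DEFAULT_MATCH_CHUNK):
        self.chunk_size = chunk_size

    def fit(self, dictionary: Dictionary, y=None) -> "DotProductMatcher":
        self.params_ = dictionary.params.reset_index(drop=True)
        self.signals_ = np.asarray(dictionary.signals, float)
        self.n_features_in_ = self.signals_.shape[1]
        return self

    def predict(self, x):
        """Match trajectories (rows) or an :class:`ImageSeries`.

        Array input returns the matched parameter table; an image series
        returns :class:`QuantMaps`.
        """
        if not hasattr(self, "signals_"):
            raise RuntimeError("matcher is not fitted")
        if isinstance(x, ImageSeries):
            return self._predict_series(x)
        x = np.asarray(x, float)
        idx, score = match_trajectories(x, self.signals_, self.chunk_size)
        out = self.params_.iloc[np.maximum(idx, 0)].reset_index(drop=True)
        out[idx < 0] = np.nan
        out["match_score"] = score
        out["match_index"] = idx
        return out

    def _predict_series(self, series: ImageSeries) -> QuantMaps:
        n, h, w = series.data.shape
        if n != self.n_features_in_:
            raise ValueError(
                f"series has {n} frames but the dictionary trajectories "
                f"have {self.n_features_in_} elements"
            )
        mask = series.mask if series.mask is not None else np.ones((h, w), bool)
        traj = series.data.reshape(n, -1).T[mask.reshape(-1)]
        idx, score = match_trajectories(traj, self.signals_, self.chunk_size)

        maps = {}
        for col in self.params_.columns:
            m = np.full((h, w), np.nan)
            vals = self.params_[col].to_numpy(float)[np.maximum(idx, 0)]
            vals[idx < 0] = np.nan
            m[mask] = vals
            maps[col] = m
        score_map = np.zeros((h, w))
        score_map[mask] = score
        index_map = np.full((h, w), -1, dtype=np.int64)
        index_map[mask] = idx
        return QuantMaps(maps=maps, score=score_map, index=index_map, mask=mask)


def dot_product_match(
    series: ImageSeries,
    dictionary: Dictionary,
    chunk_size: int = DEFAULT_MATCH_CHUNK,
) -> QuantMaps:
    """One-shot dot-product MRF reconstruction of an image series."""
    return DotProductMatcher(chunk_size).fit(dictionary).predict(series)


def compare_maps(
    maps_a: QuantMaps,
    maps_b: QuantMaps,
    parameters=None,
) -> pd.DataFrame:
    """Agreement metrics (NRMSE, SSIM, Pearson r) between two map sets.

    NRMSE is normalized by map b's masked dynamic range; SSIM uses the
    standard 7x7 window with ``data_range`` equal to map b's masked range,
    computed on images whose outside-mask pixels are zeroed in both inputs.
    """
    mask = maps_a.mask & maps_b.mask
    if not mask.any():
        raise ValueError("empty comparison mask")
    if parameters is None:
        parameters = [p for p in maps_a.maps if p in maps_b.maps]
    rows = []
    for p in parameters:
        a = maps_a.maps[p]
        b = maps_b.maps[p]
        valid = mask & np.isfinite(a) & np.isfinite(b)
        av, bv = a[valid], b[valid]
        rng = bv.max() - bv.min()
        a_img = np.where(valid, a, 0.0)
        b_img = np.where(valid, b, 0.0)
        ssim = structural_similarity(
            a_img, b_img, data_range=rng if rng > 0 else 1.0
        )
        if np.allclose(av, av[0]) or np.allclose(bv, bv[0]):
            r = 1.0 if np.allclose(av, bv) else np.nan
        else:
            r = float(np.corrcoef(av, bv)[0, 1])
        if rng > 0:
            err = _nrmse(av, bv)
        else:
            # constant reference map: zero error iff the maps agree
            err = 0.0 if np.allclose(av, bv) else np.inf
        rows.append({
            "parameter": p,
            "nrmse": err,
            "nrmse_percent": 100 * err,
            "ssim": float(ssim),
            "pearson_r": r,
            "n_pixels": int(valid.sum()),
        })
    return pd.DataFrame(rows)
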