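"""Signal dictionaries: (parameter combination -> trajectory) collections.

A :class:`Dictionary` pairs a parameter table with a trajectory matrix and
the per-element schedule that produced it.  Dictionaries back both surrogate
training (random corpora with varied schedules) and MRF dot-product matching
(grid dictionaries sharing one fixed protocol).  Storage is HDF5 with a
schema tag and a provenance record.
"""

from __future__ import annotations

import json
import time
from dataclasses import dataclass, field
from typing import Dict, Optional, Sequence, Tuple, Union

import h5py
import numpy as np
import pandas as pd
from joblib import Parallel, delayed

from .presets import ScenarioPreset
from .simulator import simulate_batch

SCHEMA_TAG = "cestgen-dictionary-1"
#: refuse cartesian grids larger than this unless the caller raises the cap
DEFAULT_GRID_CAP = 5_000_000
#: rows per simulation chunk; fixed so results are worker-count invariant
DEFAULT_CHUNK = 2048


class DictionarySchemaError(RuntimeError):
    """Raised when a dictionary file is unreadable or of the wrong schema."""


# ---------------------------------------------------------------------------
# parameter grids


@dataclass(frozen=True)
class GridAxis:
    """One parameter axis: an explicit value list or a (min, max, count)
    specification with linear or log spacing."""

    name: str
    values: Optional[Sequence[float]] = None
    start: Optional[float] = None
    stop: Optional[float] = None
    count: Optional[int] = None
    spacing: str = "linear"

    def materialize(self) -> np.ndarray:
        if self.values is not None:
            return np.asarray(self.values, float)
        if None in (self.start, self.stop, self.count):
            raise ValueError(f"axis {self.name!r}: incomplete specification")
        if self.count < 1 or self.start > self.stop:
            raise ValueError(f"axis {self.name!r}: invalid range")
        if self.spacing == "linear":
            return np.linspace(self.start, self.stop, self.count)
        if self.spacing == "log":
            if self.start <= 0:
                raise ValueError(f"axis {self.name!r}: log spacing needs > 0")
            return np.geomspace(self.start, self.stop, self.count)
        raise ValueError(f"axis {self.name!r}: unknown spacing {self.spacing!r}")


@dataclass(frozen=True)
class ParameterGrid:
    """Cartesian or random-uniform sampling plan over named axes."""

    axes: Tuple[GridAxis, ...]
    mode: str = "cartesian"
    n_samples: Optional[int] = None
    seed: Optional[int] = None
    cap: int = DEFAULT_GRID_CAP

    def __post_init__(self):
        object.__setattr__(self, "axes", tuple(self.axes))
        if self.mode not in ("cartesian", "random-uniform"):
            raise ValueError(f"unknown sampling mode {self.mode!r}")
        if self.mode == "random-uniform":
            if self.seed is None:
                raise ValueError("random-uniform sampling requires a seed")
            if not self.n_samples or self.n_samples < 1:
                raise ValueError("random-uniform sampling requires n_samples")


def enumerate_grid(grid: ParameterGrid) -> pd.DataFrame:
    """Materialize a grid as a parameter table.

    Cartesian mode enumerates the product in odometer order (last axis
    fastest); random-uniform mode draws ``n_samples`` rows reproducibly from
    the axis bounds.
    """
    if grid.mode == "cartesian":
        vals = [ax.materialize() for ax in grid.axes]
        total = int(np.prod([len(v) for v in vals]))
        if total > grid.cap:
            raise ValueError(
                f"grid of {total} rows exceeds the cap of {grid.cap}"
            )
        mesh = np.meshgrid(*vals, indexing="ij")
        data = {ax.name: m.reshape(-1) for ax, m in zip(grid.axes, mesh)}
        return pd.DataFrame(data)
    rng = np.random.default_rng(grid.seed)
    data = {}
    for ax in grid.axes:
        v = ax.materialize()
        data[ax.name] = rng.uniform(v.min(), v.max(), grid.n_samples)
    return pd.DataFrame(data)


# ---------------------------------------------------------------------------
# dictionary container


@dataclass
class Dictionary:
    """Paired parameter table and trajectory matrix."""

    params: pd.DataFrame
    signals: np.ndarray
    b1_ut: np.ndarray            # (N,) or (n_entries, N)
    offset_ppm: np.ndarray       # (N,) or (n_entries, N)
    preset_name: str = ""
    fixed: Dict = field(default_factory=dict)      # shape, n_segments, gap_s
    ranges: Dict = field(default_factory=dict)     # column -> (min, max)
    provenance: Dict = field(default_factory=dict)

    def __post_init__(self):
        self.signals = np.asarray(self.signals, float)
        if len(self.params) != len(self.signals):
            raise ValueError("parameter table and signals disagree in rows")
        if np.isnan(self.signals).any():
            raise ValueError("signals contain NaN")

    @property
    def n_entries(self) -> int:
        return len(self.params)

    @property
    def n_elements(self) -> int:
        return self.signals.shape[1]

    def element_schedule(self) -> Dict[str, np.ndarray]:
        """Per-element scanner values broadcast to (n_entries, N)."""
        b, n = self.signals.shape
        out = {
            "b1_ut": np.broadcast_to(self.b1_ut, (b, n)),
            "offset_ppm": np.broadcast_to(self.offset_ppm, (b, n)),
        }
        for col in ("tp_s", "trec_s", "fa_deg", "b0_t", "n_p"):
            vals = self.params[col].to_numpy(float)[:, None]
            out[col] = np.broadcast_to(vals, (b, n))
        return out

    def subset(self, idx) -> "Dictionary":
        idx = np.asarray(idx)
        return Dictionary(
            params=self.params.iloc[idx].reset_index(drop=True),
            signals=self.signals[idx],
            b1_ut=self.b1_ut[idx] if self.b1_ut.ndim == 2 else self.b1_ut,
            offset_ppm=(self.offset_ppm[idx] if self.offset_ppm.ndim == 2
                        else self.offset_ppm),
            preset_name=self.preset_name,
            fixed=dict(self.fixed),
            ranges=dict(self.ranges),
            provenance=dict(self.provenance),
        )


# ---------------------------------------------------------------------------
# generation


def _simulate_rows(preset: ScenarioPreset, params: pd.DataFrame,
                   b1_ut, offset_ppm) -> np.ndarray:
    systems = preset.system_batch(params)
    sched = preset.batch_schedule(params, b1_ut=b1_ut, offset_ppm=offset_ppm)
    return simulate_batch(systems, sched)


def _surrogate_rows(model, params, b1_ut, offset_ppm) -> np.ndarray:
    return model.predict_signals(params, b1_ut, offset_ppm)


def generate_dictionary(
    grid: Union[ParameterGrid, pd.DataFrame],
    preset: ScenarioPreset,
    generator: str = "bm",
    model=None,
    workers: int = 1,
    chunk_size: int = DEFAULT_CHUNK,
    b1_ut: Optional[np.ndarray] = None,
    offset_ppm: Optional[np.ndarray] = None,
    validate: bool = True,
) -> Dictionary:
    """Simulate one trajectory per grid row under the preset's protocol.

    ``generator`` is ``"bm"`` (Bloch-McConnell) or ``"surrogate"`` (requires
    a fitted ``model``).  Chunking is fixed by ``chunk_size``, so the result
    is independent of ``workers`` (bitwise for the BM generator).
    """
    params = grid if isinstance(grid, pd.DataFrame) else enumerate_grid(grid)
    params = params.reset_index(drop=True)
    for col in ("tp_s", "trec_s", "fa_deg", "b0_t", "n_p"):
        if col not in params.columns:
            default = {"b0_t": preset.b0_t}.get(
                col, preset.scan_defaults.get(col, 90.0 if col == "fa_deg" else 1)
            )
            params[col] = default
    if validate:
        preset.validate_params(params)

    if generator == "bm":
        runner = lambda p, b1, off: _simulate_rows(preset, p, b1, off)
    elif generator == "surrogate":
        if model is None:
            raise ValueError("surrogate generation requires a fitted model")
        runner = lambda p, b1, off: _surrogate_rows(model, p, b1, off)
    else:
        raise ValueError(f"unknown generator {generator!r}")

    b1_full = (np.asarray(b1_ut, float) if b1_ut is not None
               else preset.b1_series_ut)
    off_full = (np.asarray(offset_ppm, float) if offset_ppm is not None
                else preset.offset_series_ppm)

    n = len(params)
    starts = list(range(0, n, chunk_size))

    def run_chunk(lo):
        hi = min(lo + chunk_size, n)
        sl = params.iloc[lo:hi].reset_index(drop=True)
        b1c = b1_full[lo:hi] if b1_full.ndim == 2 else b1_full
        offc = off_full[lo:hi] if off_full.ndim == 2 else off_full
        try:
            return runner(sl, b1c, offc)
        except Exception as exc:  # surface the offending rows
            raise RuntimeError(
                f"generation failed for rows {lo}:{hi} "
                f"(first row: {sl.iloc[0].to_dict()})"
            ) from exc

    if workers == 1 or len(starts) == 1:
        chunks = [run_chunk(lo) for lo in starts]
    else:
        chunks = Parallel(n_jobs=workers)(delayed(run_chunk)(lo) for lo in starts)
    signals = np.vstack(chunks)

    return Dictionary(
        params=params,
        signals=signals,
        b1_ut=b1_full,
        offset_ppm=off_full,
        preset_name=preset.name,
        fixed={
            "pulse_shape": preset.pulse_shape,
            "n_segments": preset.n_segments,
            "gap_s": preset.gap_s,
        },
        ranges={
            **{k: tuple(v) for k, v in preset.free_parameter_ranges.items()},
            **({"b1_ut": tuple(preset.b1_range_ut)}
               if preset.b1_range_ut is not None else {}),
            "offset_ppm": tuple(preset.offset_range_ppm),
        },
        provenance={
            "generator": generator,
            "preset": preset.name,
            "b0_t": preset.b0_t,
            "created": time.strftime("%Y-%m-%dT%H:%M:%S"),
        },
    )


def random_corpus(
    preset: ScenarioPreset,
    n: int,
    seed: int,
    vary_schedule: bool = False,
    generator: str = "bm",
    model=None,
    workers: int = 1,
    chunk_size: int = DEFAULT_CHUNK,
) -> Dictionary:
    """Random training/test corpus: ``n`` trajectories drawn from the
    preset's free ranges (log-uniformly on multi-decade axes).

    By default every trajectory uses the scenario's fixed acquisition
    schedule, the condition under which per-scenario test sets and MRF
    dictionaries are built; with ``vary_schedule`` the scan scalars, B0 and
    the per-element B1 series are additionally randomized per trajectory
    (the regime for training schedule-generalizing surrogates)."""
    params, b1, off = preset.sample_parameters(n, seed, vary_schedule)
    d = generate_dictionary(
        params, preset, generator=generator, model=model, workers=workers,
        chunk_size=chunk_size, b1_ut=b1, offset_ppm=off,
    )
    d.provenance.update({"seed": seed, "vary_schedule": vary_schedule})
    return d


# ---------------------------------------------------------------------------
# HDF5 round trip


def save_dictionary(d: Dictionary, path) -> None:
    with h5py.File(path, "w") as h5:
        h5.attrs["schema"] = SCHEMA_TAG
        h5.attrs["preset"] = d.preset_name
        h5.attrs["fixed"] = json.dumps(d.fixed)
        h5.attrs["ranges"] = json.dumps({k: list(v) for k, v in d.ranges.items()})
        h5.attrs["provenance"] = json.dumps(d.provenance)
        h5.attrs["columns"] = json.dumps(list(d.params.columns))
        h5.create_dataset("params", data=d.params.to_numpy(float))
        h5.create_dataset("signals", data=d.signals)
        h5.create_dataset("b1_ut", data=np.asarray(d.b1_ut, float))
        h5.create_dataset("offset_ppm", data=np.asarray(d.offset_ppm, float))


def load_dictionary(path) -> Dictionary:
    try:
        with h5py.File(path, "r") as h5:
            if h5.attrs.get("schema") != SCHEMA_TAG:
                raise DictionarySchemaError(
                    f"{path}: not a {SCHEMA_TAG} file"
                )
            cols = json.loads(h5.attrs["columns"])
            params = pd.DataFrame(h5["params"][()], columns=cols)
            return Dictionary(
                params=params,
                signals=h5["signals"][()],
                b1_ut=h5["b1_ut"][()],
                offset_ppm=h5["offset_ppm"][()],
                preset_name=str(h5.attrs.get("preset", "")),
                fixed=json.loads(h5.attrs["fixed"]),
                ranges={k: tuple(v) for k, v in
                        json.loads(h5.attrs["ranges"]).items()},
                provenance=json.loads(h5.attrs["provenance"]),
            )
    except (OSError, KeyError) as exc:
        raise DictionarySchemaError(f"{path}: unreadable dictionary ({exc})")


def export_params_csv(d: Dictionary, path) -> None:
    d.params.to_csv(path, index=False)
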