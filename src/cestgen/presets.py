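"""Named imaging-scenario presets.

A :class:`ScenarioPreset` bundles everything one simulation study needs: a
template :class:`~cestgen.pools.TissueSystem`, the acquisition schedule, the
free tissue/scan parameters with their allowed ranges, and samplers that
draw reproducible random parameter tables from those ranges.

Two-pool scenarios (l-arginine, amide, amine, rnoe, iohexol, semisolid-mt)
use a continuous-wave pulse with a pseudo-random per-element B1 series; the
seven-pool-brain scenario uses a fixed 34-offset sinc-Gaussian pulse-train
schedule.  The numbers live in packaged YAML files and are validated against
the scenario's training ranges at load time.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field
from typing import Dict, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
import yaml

from .constants import SUPPORTED_B0
from .pools import LINESHAPE_FULL, Pool, TissueSystem
from .sequences import (
    DEFAULT_N_SEGMENTS,
    SHAPE_CW,
    Protocol,
    uniform_protocol,
)
from .simulator import BatchSchedule, SystemBatch

TWO_POOL_SCENARIOS = (
    "l-arginine", "amide", "amine", "rnoe", "iohexol", "semisolid-mt",
)
PRESET_NAMES = TWO_POOL_SCENARIOS + ("seven-pool-brain",)

_SCAN_COLUMNS = ("tp_s", "trec_s", "fa_deg", "b0_t", "n_p")


def _load_yaml(name: str) -> dict:
    ref = importlib.resources.files("cestgen.data") / name
    with ref.open() as fh:
        return yaml.safe_load(fh)


@dataclass
class ScenarioPreset:
    """A fully specified, reproducible imaging scenario."""

    name: str
    b0_t: float
    template: TissueSystem
    n_elements: int
    pulse_shape: str
    n_segments: int
    gap_s: float
    free_parameter_ranges: Dict[str, Tuple[float, float]]
    scan_free: Tuple[str, ...]
    scan_defaults: Dict[str, float]
    b1_range_ut: Tuple[float, float]
    offset_range_ppm: Tuple[float, float]
    b1_series_ut: np.ndarray          # fixed per-element series (N,)
    offset_series_ppm: np.ndarray     # fixed per-element series (N,)
    offset_series_range: Optional[Tuple[float, float]] = None  # varied offsets
    schedule_seed: int = 0
    b0_choices: Tuple[float, ...] = SUPPORTED_B0

    # -- fixed protocol ----------------------------------------------------
    @property
    def protocol(self) -> Protocol:
        sd = self.scan_defaults
        return uniform_protocol(
            self.b0_t,
            self.b1_series_ut,
            self.offset_series_ppm,
            tp_s=sd["tp_s"],
            trec_s=sd["trec_s"],
            fa_deg=sd.get("fa_deg", 90.0),
            shape=self.pulse_shape,
            n_p=int(sd.get("n_p", 1)),
            gap_s=self.gap_s,
            n_segments=self.n_segments,
        )

    @property
    def tissue_free(self) -> Tuple[str, ...]:
        return tuple(c for c in self.free_parameter_ranges if "." in c)

    # -- sampling ----------------------------------------------------------
    def sample_parameters(
        self,
        n: int,
        seed: int,
        vary_schedule: bool = True,
    ):
        """Draw ``n`` random parameter sets from the preset ranges.

        Returns ``(params, b1_ut, offset_ppm)``: a DataFrame with the free
        tissue columns plus the scan scalar columns ``tp_s, trec_s, fa_deg,
        b0_t, n_p``, a per-element B1 array and a per-element offset array.
        With ``vary_schedule=False`` scan parameters stay at the preset
        defaults and the recorded fixed series is used for every row.
        """
        rng = np.random.default_rng(seed)
        cols = {}
        for col in self.tissue_free:
            lo, hi = self.free_parameter_ranges[col]
            if lo > 0 and hi / lo > 100.0:
                # multi-decade axes (exchange rates, volume fractions, T2s)
                # are sampled log-uniformly so the physically dense low end
                # is covered as well as the top decade
                cols[col] = 10.0 ** rng.uniform(np.log10(lo), np.log10(hi), n)
            else:
                cols[col] = rng.uniform(lo, hi, n)
        sd = self.scan_defaults
        for col in ("tp_s", "trec_s", "fa_deg"):
            if vary_schedule and col in self.scan_free:
                lo, hi = self.free_parameter_ranges[col]
                cols[col] = rng.uniform(lo, hi, n)
            else:
                cols[col] = np.full(n, float(sd.get(col, 90.0)))
        if vary_schedule and "n_p" in self.scan_free:
            lo, hi = self.free_parameter_ranges["n_p"]
            cols["n_p"] = rng.integers(int(lo), int(hi) + 1, n)
        else:
            cols["n_p"] = np.full(n, int(sd.get("n_p", 1)))
        if vary_schedule:
            cols["b0_t"] = rng.choice(np.asarray(self.b0_choices, float), n)
        else:
            cols["b0_t"] = np.full(n, self.b0_t)
        # all-float tables survive the float HDF5 round trip losslessly
        params = pd.DataFrame(cols).astype(float)

        n_el = self.n_elements
        if vary_schedule and self.b1_range_ut is not None:
            b1 = rng.uniform(*self.b1_range_ut, (n, n_el))
        else:
            b1 = np.broadcast_to(self.b1_series_ut, (n, n_el)).copy()
        if self.offset_series_range is not None and vary_schedule:
            off = rng.uniform(*self.offset_series_range, (n, n_el))
        else:
            off = np.broadcast_to(self.offset_series_ppm, (n, n_el)).copy()
        return params, b1, off

    # -- batching ----------------------------------------------------------
    def system_batch(self, params: pd.DataFrame) -> SystemBatch:
        return SystemBatch.from_table(self.template, params)

    def batch_schedule(
        self,
        params: pd.DataFrame,
        b1_ut: Optional[np.ndarray] = None,
        offset_ppm: Optional[np.ndarray] = None,
    ) -> BatchSchedule:
        """Assemble the stacked schedule for a parameter table."""
        n = len(params)
        n_el = self.n_elements

        def scan(col, default):
            if col in params.columns:
                return params[col].to_numpy(float)[:, None]
            return np.full((n, 1), float(default))

        sd = self.scan_defaults
        return BatchSchedule(
            b0_t=(params["b0_t"].to_numpy(float) if "b0_t" in params.columns
                  else np.asarray(self.b0_t)),
            b1_ut=(np.asarray(b1_ut, float) if b1_ut is not None
                   else np.asarray(self.b1_series_ut)),
            offset_ppm=(np.asarray(offset_ppm, float) if offset_ppm is not None
                        else np.asarray(self.offset_series_ppm)),
            tp_s=scan("tp_s", sd["tp_s"]),
            trec_s=scan("trec_s", sd["trec_s"]),
            fa_deg=scan("fa_deg", sd.get("fa_deg", 90.0)),
            n_p=scan("n_p", sd.get("n_p", 1)).astype(int),
            gap_s=np.full((n, 1), self.gap_s),
            shapes=[(self.pulse_shape, self.n_segments)] * n_el,
        )

    # -- validation --------------------------------------------------------
    def validate_params(self, params: pd.DataFrame) -> None:
        """Raise if any free-parameter value falls outside its range."""
        for col, (lo, hi) in self.free_parameter_ranges.items():
            if col in params.columns:
                vals = params[col].to_numpy(float)
                if (vals < lo).any() or (vals > hi).any():
                    raise ValueError(
                        f"{self.name}: parameter {col!r} outside "
                        f"[{lo}, {hi}]"
                    )


def _check_inside(name, free_ranges, table_ranges):
    for col, (lo, hi) in free_ranges.items():
        if col not in table_ranges:
            raise ValueError(f"{name}: no training range for {col!r}")
        tlo, thi = table_ranges[col]
        if lo < tlo or hi > thi:
            raise ValueError(
                f"{name}: free range for {col!r} [{lo}, {hi}] is outside "
                f"the training range [{tlo}, {thi}]"
            )


def _two_pool_preset(name: str, b0_t: float) -> ScenarioPreset:
    doc = _load_yaml("two_pool_scenarios.yaml")
    table = {k: tuple(v) for k, v in doc["training_ranges"].items()}
    sc = doc["scenarios"][name]
    n_el = int(sc["n_elements"])
    lineshape = sc.get("lineshape", LINESHAPE_FULL)
    tmpl_vals = sc["template"]
    water = Pool("water", tmpl_vals["water.t1_s"], tmpl_vals["water.t2_s"])
    solute = Pool(
        "solute",
        tmpl_vals["solute.t1_s"],
        tmpl_vals["solute.t2_s"],
        tmpl_vals["solute.f"],
        tmpl_vals["solute.k_sw"],
        float(sc["delta_ppm"]),
        lineshape,
    )
    if lineshape == LINESHAPE_FULL:
        template = TissueSystem(water, (solute,))
    else:
        template = TissueSystem(water, (), solute)

    free = {c: table[c] for c in sc["free"]}
    scan_free = tuple(sc.get("scan_free", ()))
    free.update({c: table[c] for c in scan_free})
    _check_inside(name, free, table)

    seed = int(sc["b1_series_seed"])
    rng = np.random.default_rng(seed)
    b1_series = rng.uniform(*table["b1_ut"], n_el)
    if sc.get("offset_policy") == "series":
        off_range = tuple(sc["offset_series_ppm"])
        offsets = rng.uniform(*off_range, n_el)
    else:
        off_range = None
        offsets = np.full(n_el, float(sc["delta_ppm"]))

    return ScenarioPreset(
        name=name,
        b0_t=b0_t,
        template=template,
        n_elements=n_el,
        pulse_shape=sc.get("pulse_shape", SHAPE_CW),
        n_segments=1 if sc.get("pulse_shape", SHAPE_CW) == SHAPE_CW
        else DEFAULT_N_SEGMENTS,
        gap_s=float(sc["scan_defaults"].get("gap_s", 0.0)),
        free_parameter_ranges=free,
        scan_free=scan_free,
        scan_defaults={k: float(v) for k, v in sc["scan_defaults"].items()},
        b1_range_ut=tuple(table["b1_ut"]),
        offset_range_ppm=tuple(table["offset_ppm"]),
        b1_series_ut=b1_series,
        offset_series_ppm=offsets,
        offset_series_range=off_range,
        schedule_seed=seed,
    )


def _seven_pool_preset(b0_t: float) -> ScenarioPreset:
    doc = _load_yaml("seven_pool_brain.yaml")
    table = {k: tuple(v) for k, v in doc["training_ranges"].items()}
    pools = doc["pools"]
    water = Pool("water", pools["water"]["t1_s"], pools["water"]["t2_s"])
    solutes = []
    semisolid = None
    for pname, pv in pools.items():
        if pname == "water":
            continue
        pool = Pool(
            pname, pv["t1_s"], pv["t2_s"], pv["f"], pv["k_sw"],
            pv["delta_ppm"], pv.get("lineshape", LINESHAPE_FULL),
        )
        if pool.lineshape == LINESHAPE_FULL:
            solutes.append(pool)
        else:
            semisolid = pool
    template = TissueSystem(water, tuple(solutes), semisolid)

    free = {c: table[c] for c in doc["free"]}
    scan_free = tuple(doc.get("scan_free", ()))
    free.update({c: table[c] for c in scan_free})
    _check_inside("seven-pool-brain", free, table)

    offsets = np.asarray(doc["offsets_ppm"], float)
    n_el = int(doc["n_elements"])
    if offsets.size != n_el:
        raise ValueError("seven-pool-brain: offset list length mismatch")
    pulse = doc["pulse"]
    b1_fixed = float(pulse.get("b1_ut", 2.0))
    sd = dict(doc["scan_defaults"])
    sd.setdefault("fa_deg", pulse.get("fa_deg", 90.0))

    return ScenarioPreset(
        name="seven-pool-brain",
        b0_t=b0_t,
        template=template,
        n_elements=n_el,
        pulse_shape=pulse["shape"],
        n_segments=int(pulse.get("n_segments", DEFAULT_N_SEGMENTS)),
        gap_s=float(pulse.get("gap_s", 0.0)),
        free_parameter_ranges=free,
        scan_free=scan_free,
        scan_defaults={k: float(v) for k, v in sd.items()},
        b1_range_ut=None,  # B1 is fixed in this scenario
        offset_range_ppm=(float(offsets.min()), float(offsets.max())),
        b1_series_ut=np.full(n_el, b1_fixed),
        offset_series_ppm=offsets,
        offset_series_range=None,
        schedule_seed=0,
    )


def load_preset(name: str, b0_t: float = 9.4) -> ScenarioPreset:
    """Load a named scenario preset at one of the supported field strengths."""
    if name not in PRESET_NAMES:
        raise KeyError(f"unknown preset {name!r}; choose from {PRESET_NAMES}")
    if float(b0_t) not in SUPPORTED_B0:
        raise ValueError(f"B0 = {b0_t} T is not one of {SUPPORTED_B0}")
    if name == "seven-pool-brain":
        return _seven_pool_preset(float(b0_t))
    return _two_pool_preset(name, float(b0_t))
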