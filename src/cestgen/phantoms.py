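"""Digital phantoms emulating the in-vitro and in-vivo experiments.

Two generators are provided:

* a three-vial L-arginine phantom whose amine proton volume fraction follows
  from the molar concentration and whose exchange rate follows a
  base-catalyzed pH dependence ``k(pH) = k_cal * 10**(pH - pH_cal)``;
* a two-region (white-/gray-matter-like) semisolid-MT brain phantom with
  distinct volume fraction and exchange rate per region.

Rendering a phantom yields an :class:`~cestgen.matching.ImageSeries` with
per-pixel trajectories from the pixel's tissue system plus seeded Gaussian
noise on the normalized magnitude signal (Rician effects are ignored at
these signal levels).  The calibration constants of the pH map are
assumptions configurable by the caller; no specific vial exchange rate is
asserted as ground truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Optional, Sequence

import numpy as np
import pandas as pd

from .constants import WATER_PROTON_MM

from .dictionary import generate_dictionary
from .matching import ImageSeries
from .presets import ScenarioPreset, load_preset

#: default amine exchange rate at the calibration pH (assumed, editable)
DEFAULT_K_CAL = 100.0
DEFAULT_PH_CAL = 5.0
#: exchangeable amine protons per L-arginine molecule (assumed, editable)
DEFAULT_PROTONS_PER_MOLECULE = 3.0


@dataclass
class DigitalPhantom:
    """Label image + per-label tissue parameters."""

    labels: np.ndarray                     # (H, W) int, 0 = background
    label_params: Dict[int, Dict[str, float]]  # label -> free-parameter values
    preset: ScenarioPreset
    noise_sigma: float = 0.0
    seed: int = 0
    geometry: Dict = field(default_factory=dict)

    def __post_init__(self):
        self.labels = np.asarray(self.labels, int)
        if self.noise_sigma < 0:
            raise ValueError("noise sigma must be >= 0")
        present = set(np.unique(self.labels)) - {0}
        if present - set(self.label_params):
            raise ValueError("labels without parameters present in the image")

    @property
    def mask(self) -> np.ndarray:
        return self.labels > 0

    def params_table(self) -> pd.DataFrame:
        """One row per label, in ascending label order."""
        rows = [dict(self.label_params[lab])
                for lab in sorted(self.label_params)]
        return pd.DataFrame(rows)


def concentration_to_f(
    concentration_mm: float,
    protons_per_molecule: float = DEFAULT_PROTONS_PER_MOLECULE,
    water_protons_mm: float = WATER_PROTON_MM,
) -> float:
    """Solute proton volume fraction from a molar concentration (mM)."""
    return concentration_mm * protons_per_molecule / water_protons_mm


def ph_to_k(ph, k_cal: float = DEFAULT_K_CAL, ph_cal: float = DEFAULT_PH_CAL):
    """Base-catalyzed amine exchange rate, s^-1 (calibration is an assumption)."""
    return k_cal * 10.0 ** (np.asarray(ph, float) - ph_cal)


def _disk(labels, cy, cx, r, value):
    h, w = labels.shape
    yy, xx = np.ogrid[:h, :w]
    sel = (yy - cy) ** 2 + (xx - cx) ** 2 <= r**2
    if (labels[sel] != 0).any():
        raise ValueError("vials overlap at the requested size")
    labels[sel] = value


def make_larginine_phantom(
    ph_values: Sequence[float] = (5.0, 5.5, 6.0),
    concentration_mm: float = 50.0,
    size: int = 64,
    noise_sigma: float = 0.005,
    seed: int = 0,
    b0_t: float = 9.4,
    k_cal: float = DEFAULT_K_CAL,
    ph_cal: float = DEFAULT_PH_CAL,
    protons_per_molecule: float = DEFAULT_PROTONS_PER_MOLECULE,
) -> DigitalPhantom:
    """Three-vial L-arginine phantom on the l-arginine preset.

    Vials share the concentration-derived amine volume fraction and differ
    in the pH-derived exchange rate.
    """
    if concentration_mm <= 0:
        raise ValueError("concentration must be positive")
    if len(ph_values) != 3:
        raise ValueError("exactly three vial pH values expected")
    if size < 16:
        raise ValueError("size too small for three distinct vials")
    preset = load_preset("l-arginine", b0_t)
    labels = np.zeros((size, size), int)
    r = size // 6
    centers = [
        (size * 0.3, size * 0.3),
        (size * 0.3, size * 0.7),
        (size * 0.72, size * 0.5),
    ]
    f = concentration_to_f(concentration_mm, protons_per_molecule)
    label_params = {}
    for i, (ph, (cy, cx)) in enumerate(zip(ph_values, centers), start=1):
        _disk(labels, cy, cx, r, i)
        row = {c: preset.template.pool_by_name(c.split(".")[0]).__getattribute__(
            c.split(".")[1]) for c in preset.tissue_free}
        row["solute.f"] = f
        row["solute.k_sw"] = float(ph_to_k(ph, k_cal, ph_cal))
        label_params[i] = row
    return DigitalPhantom(
        labels=labels,
        label_params=label_params,
        preset=preset,
        noise_sigma=noise_sigma,
        seed=seed,
        geometry={"kind": "three-vial", "radius_px": r, "centers": centers,
                  "ph_values": list(ph_values),
                  "concentration_mm": concentration_mm},
    )


def make_mt_brain_phantom(
    size: int = 64,
    seed: int = 0,
    noise_sigma: float = 0.005,
    b0_t: float = 9.4,
) -> DigitalPhantom:
    """Two-region brain-like semisolid-MT phantom.

    An elliptical "brain" is split into a white-matter-like outer region
    (higher macromolecular fraction) and a gray-matter-like inner region;
    (f_ss, k_ssw) are drawn per seed from fixed sub-ranges of the scenario's
    training range.
    """
    if size < 16:
        raise ValueError("size too small for a two-region layout")
    preset = load_preset("semisolid-mt", b0_t)
    rng = np.random.default_rng(seed)
    h = w = size
    yy, xx = np.ogrid[:h, :w]
    cy, cx = h / 2, w / 2
    brain = ((yy - cy) / (0.42 * h)) ** 2 + ((xx - cx) / (0.36 * w)) ** 2 <= 1
    inner = ((yy - cy) / (0.24 * h)) ** 2 + ((xx - cx) / (0.18 * w)) ** 2 <= 1
    labels = np.zeros((h, w), int)
    labels[brain] = 1          # white-matter-like shell
    labels[brain & inner] = 2  # gray-matter-like core

    wm = {"solute.f": rng.uniform(0.12, 0.2),
          "solute.k_sw": rng.uniform(30.0, 60.0)}
    gm = {"solute.f": rng.uniform(0.05, 0.1),
          "solute.k_sw": rng.uniform(10.0, 30.0)}
    base = {c: getattr(preset.template.pool_by_name(c.split(".")[0]),
                       c.split(".")[1]) for c in preset.tissue_free}
    label_params = {1: {**base, **wm}, 2: {**base, **gm}}
    return DigitalPhantom(
        labels=labels,
        label_params=label_params,
        preset=preset,
        noise_sigma=noise_sigma,
        seed=seed,
        geometry={"kind": "two-region-brain"},
    )


def render_series(
    phantom: DigitalPhantom,
    generator: str = "bm",
    model=None,
    noise_sigma: Optional[float] = None,
    seed: Optional[int] = None,
    workers: int = 1,
) -> ImageSeries:
    """Render the phantom into an image series under its preset protocol.

    One trajectory is simulated per label and painted into the label's
    pixels; seeded Gaussian noise (std ``noise_sigma`` on the normalized
    signal) is then added to in-mask pixels.  Background pixels are zero.
    """
    sigma = phantom.noise_sigma if noise_sigma is None else float(noise_sigma)
    seed = phantom.seed if seed is None else int(seed)
    table = phantom.params_table()
    d = generate_dictionary(
        table, phantom.preset, generator=generator, model=model,
        workers=workers,
    )
    h, w = phantom.labels.shape
    n = d.n_elements
    data = np.zeros((n, h, w))
    for row, lab in enumerate(sorted(phantom.label_params)):
        sel = phantom.labels == lab
        data[:, sel] = d.signals[row][:, None]
    if sigma > 0:
        rng = np.random.default_rng(seed)
        noise = rng.normal(0.0, sigma, data.shape)
        data[:, phantom.mask] += noise[:, phantom.mask]
    return ImageSeries(data=data, mask=phantom.mask,
                       protocol_ref=phantom.preset.name)
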