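"""Multi-pool Bloch-McConnell simulator.

The engine propagates the coupled linear ODE ``dM/dt = A M + b`` through an
acquisition schedule.  All RF intervals are piecewise-constant (continuous
wave directly; shaped pulses via segment discretization), so every interval
is advanced with one exact matrix exponential; pulse trains reuse the
single-pulse propagator through a batched matrix power.

Everything is vectorized over a batch of tissue systems sharing one pool
structure, which is what dictionary generation needs; the single-system
operations (:func:`simulate_trajectory`, :func:`simulate_zspectrum`, ...)
are thin wrappers over a batch of size one.

Conventions (rotating frame at the saturation frequency, RF along +x):

* ``dMx = -Mx/T2 + dw My``; ``dMy = -dw Mx - My/T2 + w1 Mz``;
  ``dMz = -w1 My - (Mz - f)/T1`` with ``dw = (delta - omega_rf)`` in rad/s.
* Solute pools exchange with water only (star topology) with detailed
  balance: solute -> water at ``k_sw``, water -> solute at ``k_sw * f``.
* A lineshape-approximated semisolid pool keeps only Mz, exchanging with
  water Mz and saturated at ``W = pi w1^2 g(dw)``.
* Readout: ``S = sin(FA) |Mz_water|``; water transverse magnetization is
  spoiled and water Mz is scaled by ``cos(FA)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .constants import GAMMA_H, ppm_to_rad, ut_to_rad
from .lineshape import lineshape_g
from .linalg import (
    affine_propagator,
    apply_propagator,
    matrix_power_batched,
)

from .pools import Pool, TissueSystem
from .sequences import Protocol, ScheduleElement, pulse_envelope

#: Half-width (ppm) of the on-resonance interpolation band for the
#: super-Lorentzian lineshape.
SL_INTERP_BAND_PPM = 1.0


@dataclass
class SignalTrajectory:
    """Normalized readout magnitudes of one simulated schedule."""

    values: np.ndarray
    normalization: str = "M0w"

    def __post_init__(self):
        self.values = np.asarray(self.values, float)

    def __len__(self):
        return len(self.values)


# ---------------------------------------------------------------------------
# batched parameter containers


class SystemBatch:
    """A batch of tissue systems sharing one pool structure.

    ``template`` fixes the structure (pool count, names, lineshapes) and the
    default parameter values; ``overrides`` maps ``"<pool>.<field>"`` (field
    in ``t1_s, t2_s, f, k_sw, delta_ppm``) to per-entry arrays.
    """

    _FIELDS = ("t1_s", "t2_s", "f", "k_sw", "delta_ppm")

    def __init__(self, template: TissueSystem, n: int = 1, overrides=None):
        self.template = template
        self.n = int(n)
        self.overrides = {}
        pool_names = {p.name for p in template.pools}
        for key, val in (overrides or {}).items():
            pool, _, fld = key.partition(".")
            if pool not in pool_names or fld not in self._FIELDS:
                raise KeyError(f"unknown system parameter {key!r}")
            arr = np.broadcast_to(np.asarray(val, float), (self.n,))
            self.overrides[key] = arr
        self._validate()

    def param(self, pool: Pool, fld: str) -> np.ndarray:
        key = f"{pool.name}.{fld}"
        if key in self.overrides:
            return self.overrides[key]
        return np.full(self.n, getattr(pool, fld))

    def _validate(self):
        for p in self.template.pools:
            t1 = self.param(p, "t1_s")
            t2 = self.param(p, "t2_s")
            if (t1 <= 0).any() or (t2 <= 0).any():
                raise ValueError(f"pool {p.name!r}: non-positive relaxation time")
            if (self.param(p, "k_sw") < 0).any():
                raise ValueError(f"pool {p.name!r}: negative exchange rate")
        non_water = [p for p in self.template.pools if p.name != self.template.water.name]
        if non_water:
            total_f = sum(self.param(p, "f") for p in non_water)
            if (total_f >= 1).any():
                raise ValueError("non-water volume fractions must sum to < 1")

    @classmethod
    def from_table(cls, template: TissueSystem, table) -> "SystemBatch":
        """Build from a DataFrame whose columns are ``"<pool>.<field>"``
        overrides (other columns are ignored)."""
        pool_names = {p.name for p in template.pools}
        overrides = {}
        for col in table.columns:
            pool, _, fld = str(col).partition(".")
            if pool in pool_names and fld in cls._FIELDS:
                overrides[col] = np.asarray(table[col], float)
        return cls(template, len(table), overrides)


@dataclass
class BatchSchedule:
    """Per-element schedule arrays, broadcastable to (batch, N).

    ``shapes`` is one ``(pulse_shape, n_segments)`` pair per element; the
    pulse shape may differ between elements but not across the batch.
    """

    b0_t: np.ndarray          # (B,) or scalar
    b1_ut: np.ndarray         # (B, N) or (N,)
    offset_ppm: np.ndarray
    tp_s: np.ndarray
    trec_s: np.ndarray
    fa_deg: np.ndarray
    n_p: np.ndarray           # integer
    gap_s: np.ndarray
    shapes: Sequence = field(default_factory=list)

    @property
    def n_elements(self) -> int:
        return len(self.shapes)

    @classmethod
    def from_protocol(cls, protocol: Protocol) -> "BatchSchedule":
        t = protocol.to_table()
        return cls(
            b0_t=np.asarray(protocol.b0_t, float),
            b1_ut=t["b1_ut"].to_numpy(float),
            offset_ppm=t["offset_ppm"].to_numpy(float),
            tp_s=t["tp_s"].to_numpy(float),
            trec_s=t["trec_s"].to_numpy(float),
            fa_deg=t["fa_deg"].to_numpy(float),
            n_p=t["n_p"].to_numpy(int),
            gap_s=t["gap_s"].to_numpy(float),
            shapes=[(e.pulse.shape, e.pulse.n_segments) for e in protocol.elements],
        )

    def col(self, name: str, b: int, i: int) -> np.ndarray:
        """Column ``i`` of a schedule array, broadcast to batch size ``b``."""
        arr = np.asarray(getattr(self, name))
        if arr.ndim == 2:
            col = arr[:, 0] if arr.shape[1] == 1 else arr[:, i]
        elif arr.ndim == 1:
            col = arr[i]
        else:
            col = arr
        return np.broadcast_to(col, (b,))

    def b0(self, b: int) -> np.ndarray:
        return np.broadcast_to(np.asarray(self.b0_t, float), (b,))


# ---------------------------------------------------------------------------
# matrix assembly


def _gather_pools(systems: SystemBatch):
    tmpl = systems.template
    full = [
        {fld: systems.param(p, fld) for fld in SystemBatch._FIELDS}
        for p in tmpl.full_pools
    ]
    approx = None
    ap = tmpl.approx_pool
    if ap is not None:
        approx = {fld: systems.param(ap, fld) for fld in SystemBatch._FIELDS}
        approx["lineshape"] = ap.lineshape
    return full, approx


def _bm_matrix(full, approx, omega_rf_rad, omega1_rad, b0_t, g_ss=None,
               gamma: float = GAMMA_H):
    """Assemble stacked (A, b) for one constant-RF interval.

    ``full`` / ``approx`` are the pool parameter dicts from
    :func:`_gather_pools`; all rate arguments are (B,) arrays in rad/s.
    ``g_ss`` is the precomputed lineshape value for the approx pool.
    """
    b = len(omega_rf_rad)
    nf = len(full)
    na = 1 if approx is not None else 0
    d = 3 * nf + na
    a = np.zeros((b, d, d))
    drive = np.zeros((b, d))

    k_list = [p["k_sw"] for p in full[1:]]
    f_list = [p["f"] for p in full[1:]]
    loss_t = sum((k * f for k, f in zip(k_list, f_list)), np.zeros(b))
    loss_z = loss_t.copy()
    if approx is not None:
        loss_z = loss_z + approx["k_sw"] * approx["f"]

    for p_idx, p in enumerate(full):
        x, y, z = 3 * p_idx, 3 * p_idx + 1, 3 * p_idx + 2
        r1 = 1.0 / p["t1_s"]
        r2 = 1.0 / p["t2_s"]
        dw = ppm_to_rad(p["delta_ppm"], b0_t, gamma) - omega_rf_rad
        if p_idx == 0:  # water
            a[:, x, x] = -r2 - loss_t
            a[:, y, y] = -r2 - loss_t
            a[:, z, z] = -r1 - loss_z
            for s_idx, (k, f) in enumerate(zip(k_list, f_list), start=1):
                sx = 3 * s_idx
                a[:, x, sx] = k
                a[:, y, sx + 1] = k
                a[:, z, sx + 2] = k
            if approx is not None:
                a[:, z, 3 * nf] = approx["k_sw"]
        else:
            k = p["k_sw"]
            kf = k * p["f"]
            a[:, x, x] = -r2 - k
            a[:, y, y] = -r2 - k
            a[:, z, z] = -r1 - k
            a[:, x, 0] = kf
            a[:, y, 1] = kf
            a[:, z, 2] = kf
        a[:, x, y] = dw
        a[:, y, x] = -dw
        a[:, y, z] = omega1_rad
        a[:, z, y] = -omega1_rad
        drive[:, z] = p["f"] / p["t1_s"]

    if approx is not None:
        zz = 3 * nf
        k = approx["k_sw"]
        w_sat = np.pi * omega1_rad**2 * (g_ss if g_ss is not None else 0.0)
        a[:, zz, zz] = -1.0 / approx["t1_s"] - k - w_sat
        a[:, zz, 2] = k * approx["f"]
        drive[:, zz] = approx["f"] / approx["t1_s"]
    return a, drive


# ---------------------------------------------------------------------------
# schedule execution


def _equilibrium_aug(full, approx, b):
    d = 3 * len(full) + (1 if approx is not None else 0)
    m = np.zeros((b, d + 1))
    for i, p in enumerate(full):
        m[:, 3 * i + 2] = p["f"]
    if approx is not None:
        m[:, d - 1] = approx["f"]
    m[:, -1] = 1.0
    return m


def simulate_batch(
    systems: SystemBatch,
    schedule: BatchSchedule,
    spoil_interpulse: bool = False,
    initial_state: Optional[np.ndarray] = None,
    return_state: bool = False,
    gamma: float = GAMMA_H,
):
    """Simulate signal trajectories for a batch of systems.

    Returns an (B, N) array of normalized readout magnitudes (and the final
    magnetization states if ``return_state``).
    """
    b = systems.n
    n_el = schedule.n_elements
    if n_el < 1:
        raise ValueError("schedule has no elements")
    full, approx = _gather_pools(systems)
    b0 = schedule.b0(b)
    if (b0 <= 0).any():
        raise ValueError("B0 must be positive")

    state = _equilibrium_aug(full, approx, b)
    if initial_state is not None:
        state[:, :-1] = np.broadcast_to(np.asarray(initial_state, float),
                                        state[:, :-1].shape)
    signals = np.empty((b, n_el))

    for i in range(n_el):
        orf = ppm_to_rad(schedule.col("offset_ppm", b, i), b0, gamma)
        zeros = np.zeros(b)
        g_ss = None
        if approx is not None:
            dw_ss = ppm_to_rad(approx["delta_ppm"], b0, gamma) - orf
            band = ppm_to_rad(SL_INTERP_BAND_PPM, b0, gamma)
            g_ss = lineshape_g(dw_ss, approx["t2_s"], approx["lineshape"],
                               interp_band_rad=band)
        a0, d0 = _bm_matrix(full, approx, orf, zeros, b0, g_ss, gamma)

        trec = schedule.col("trec_s", b, i)
        if (trec > 0).any():
            state = apply_propagator(affine_propagator(a0, d0, trec), state)

        # one saturation pulse, segment by segment
        shape, n_seg = schedule.shapes[i]
        env = pulse_envelope(shape, n_seg)
        b1 = schedule.col("b1_ut", b, i)
        seg_dt = schedule.col("tp_s", b, i) / n_seg

        def _seg_prop(amp):
            om1 = ut_to_rad(b1 * amp, gamma)
            a_s, d_s = _bm_matrix(full, approx, orf, om1, b0, g_ss, gamma)
            return affine_propagator(a_s, d_s, seg_dt)

        if n_seg > 2 and np.allclose(env, env[::-1]):
            # symmetric envelope: segments s and n-1-s share one propagator,
            # so the pulse needs only n/2 exponentials:
            # P_total = (P_1 P_2 ... P_h) [P_mid] (P_h ... P_2 P_1)
            half = n_seg // 2
            fwd = rev = None
            for s in range(half):
                p_seg = _seg_prop(env[s])
                fwd = p_seg if fwd is None else fwd @ p_seg
                rev = p_seg if rev is None else p_seg @ rev
            if n_seg % 2:
                fwd = fwd @ _seg_prop(env[half])
            p_pulse = fwd @ rev
        else:
            p_pulse = None
            for amp in env:
                p_seg = _seg_prop(amp)
                p_pulse = p_seg if p_pulse is None else p_seg @ p_pulse

        n_p = schedule.col("n_p", b, i).astype(np.int64)
        if (n_p > 1).any():
            gap = schedule.col("gap_s", b, i)
            if (gap > 0).any():
                p_gap = affine_propagator(a0, d0, gap)
            else:
                p_gap = np.broadcast_to(np.eye(p_pulse.shape[-1]), p_pulse.shape)
            if spoil_interpulse:
                spoil = np.eye(p_pulse.shape[-1])
                for p_idx in range(len(full)):
                    spoil[3 * p_idx, 3 * p_idx] = 0.0
                    spoil[3 * p_idx + 1, 3 * p_idx + 1] = 0.0
                p_gap = spoil @ p_gap
            p_train = p_pulse @ matrix_power_batched(p_gap @ p_pulse, n_p - 1)
        else:
            p_train = p_pulse
        state = apply_propagator(p_train, state)

        # readout: instantaneous excitation of the water pool
        fa = np.deg2rad(schedule.col("fa_deg", b, i))
        signals[:, i] = np.sin(fa) * np.abs(state[:, 2])
        state[:, 0] = 0.0
        state[:, 1] = 0.0
        state[:, 2] = state[:, 2] * np.cos(fa)

    if return_state:
        return signals, state[:, :-1]
    return signals


# ---------------------------------------------------------------------------
# single-system API


def build_generator(system: TissueSystem, b1_ut: float, offset_ppm: float,
                    b0_t: float, gamma: float = GAMMA_H):
    """Assemble (A, b) of ``dM/dt = A M + b`` for one constant-RF interval.

    The matrix dimension is ``3 * n_full_pools + n_lineshape_pools``; the
    drive vector ``b`` carries the T1 recovery terms ``f / T1``.
    """
    batch = SystemBatch(system, 1)
    full, approx = _gather_pools(batch)
    b0 = np.asarray([float(b0_t)])
    orf = ppm_to_rad(np.asarray([float(offset_ppm)]), b0, gamma)
    om1 = ut_to_rad(np.asarray([float(b1_ut)]), gamma)
    g_ss = None
    if approx is not None:
        dw_ss = ppm_to_rad(approx["delta_ppm"], b0, gamma) - orf
        band = ppm_to_rad(SL_INTERP_BAND_PPM, b0, gamma)
        g_ss = lineshape_g(dw_ss, approx["t2_s"], approx["lineshape"],
                           interp_band_rad=band)
    a, d = _bm_matrix(full, approx, orf, om1, b0, g_ss, gamma)
    return a[0], d[0]


def propagate_interval(state: np.ndarray, a: np.ndarray, b: np.ndarray,
                       dt: float) -> np.ndarray:
    """Exact propagation of ``dM/dt = A M + b`` over ``dt``."""
    if dt <= 0:
        raise ValueError("dt must be positive")
    state = np.asarray(state, float)
    p = affine_propagator(a, b, float(dt))
    aug = np.concatenate([state, [1.0]])
    return (p @ aug)[:-1]


def equilibrium_state(system: TissueSystem) -> np.ndarray:
    return system.equilibrium()


def run_schedule_element(
    state: np.ndarray,
    element: ScheduleElement,
    system: TissueSystem,
    b0_t: float,
    spoil_interpulse: bool = False,
):
    """Execute one schedule element from ``state``; returns ``(S, new_state)``."""
    batch = SystemBatch(system, 1)
    sched = BatchSchedule.from_protocol(Protocol(b0_t, (element,)))
    sig, new_state = simulate_batch(
        batch, sched, spoil_interpulse=spoil_interpulse,
        initial_state=np.asarray(state, float)[None, :], return_state=True,
    )
    return float(sig[0, 0]), new_state[0]


def simulate_trajectory(
    system: TissueSystem,
    protocol: Protocol,
    spoil_interpulse: bool = False,
) -> SignalTrajectory:
    """Simulate one full schedule from thermal equilibrium."""
    batch = SystemBatch(system, 1)
    sched = BatchSchedule.from_protocol(protocol)
    sig = simulate_batch(batch, sched, spoil_interpulse=spoil_interpulse)
    return SignalTrajectory(sig[0])


def simulate_zspectrum(
    system: TissueSystem,
    offsets_ppm,
    base_element: ScheduleElement,
    b0_t: float,
    reset_each: bool = True,
) -> SignalTrajectory:
    """Z-spectrum: sweep the saturation offset of ``base_element``.

    With ``reset_each`` (default) every offset is acquired from thermal
    equilibrium, the standard Z-spectrum convention; otherwise offsets are
    chained sequentially as one protocol.
    """
    offsets = np.atleast_1d(np.asarray(offsets_ppm, float))
    if offsets.size == 0:
        raise ValueError("offset list is empty")
    if not np.isfinite(offsets).all():
        raise ValueError("offsets must be finite")
    if reset_each:
        # each offset is an independent single-element schedule -> batch them
        batch = SystemBatch(system, offsets.size)
        sched = BatchSchedule(
            b0_t=np.asarray(b0_t, float),
            b1_ut=offsets[:, None] * 0 + base_element.pulse.b1_ut,
            offset_ppm=offsets[:, None],
            tp_s=np.full((offsets.size, 1), base_element.pulse.tp_s),
            trec_s=np.full((offsets.size, 1), base_element.trec_s),
            fa_deg=np.full((offsets.size, 1), base_element.fa_deg),
            n_p=np.full((offsets.size, 1), base_element.n_p, dtype=int),
            gap_s=np.full((offsets.size, 1), base_element.gap_s),
            shapes=[(base_element.pulse.shape, base_element.pulse.n_segments)],
        )
        sig = simulate_batch(batch, sched)
        return SignalTrajectory(sig[:, 0])
    elements = tuple(base_element.replace(offset_ppm=float(o)) for o in offsets)
    return simulate_trajectory(system, Protocol(b0_t, elements))
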