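"""Surrogate multichannel recordings with controllable phase-locking.

The generator emulates the statistical structure of intracranial recordings
around an epileptic seizure without modelling neural tissue: channels are
narrowband oscillators sharing a common carrier, and a global two-state
(locked/unlocked) renewal process controls their phase relationship.

* During a **locked** dwell every channel's phase offset is pulled to a
  small common value, so all pairwise phase differences sit near zero and
  the pair coherence is high — the analysis pipeline sees one phase-lock
  interval per pair per dwell.
* During an **unlocked** dwell each channel drifts independently (random
  detuning plus phase diffusion), so phase differences rotate and locking
  is destroyed.

Locked dwell times are drawn from a continuous power law (Pareto) with a
configurable density exponent — the ground truth the pipeline should
recover.  Unlocked dwell times are exponential (memoryless), which keeps
the locked-dwell distribution identifiable.  Three regimes modulate the
locked dwells:

* ``baseline`` — pure power-law dwells (pre-ictal surrogate),
* ``seizure`` — dwells multiplied by ``lock_excess`` > 1 (excess long
  locking, the ictal signature),
* ``recovery`` — the excess decays exponentially back to 1 with time
  constant ``relax_tau_s`` (post-ictal relaxation).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from .ecog_pipeline import MultichannelRecording

__all__ = [
    "RegimeSpec",
    "SynthConfig",
    "dwell_time_sampler",
    "generate_recording",
    "write_recording",
]


@dataclass
class RegimeSpec:
    """One homogeneous stretch of the surrogate recording."""

    name: str  # baseline | seizure | recovery
    duration_s: float
    target_alpha: float = 2.5  # power-law density exponent of locked dwells
    lock_excess: float = 1.0  # multiplier on locked dwell durations (seizure)
    relax_tau_s: float = 30.0  # decay constant of the excess (recovery)

    def __post_init__(self) -> None:
        if self.name not in ("baseline", "seizure", "recovery"):
            raise ValueError(f"unknown regime name {self.name!r}")
        if self.duration_s <= 0:
            raise ValueError("duration_s must be positive")
        if self.target_alpha <= 1:
            raise ValueError("target_alpha must exceed 1 for a normalizable tail")
        if self.lock_excess < 1:
            raise ValueError("lock_excess must be >= 1")


@dataclass
class SynthConfig:
    """Full generator configuration.

    The carrier band must sit inside one wavelet scale's dyadic band so a
    single scale captures the locking structure (e.g. 30–40 Hz inside the
    scale-2 band 25–50 Hz at fs = 200).
    """

    n_channels: int = 8
    fs: float = 200.0
    carrier_band: tuple[float, float] = (30.0, 40.0)
    regimes: list[RegimeSpec] = field(
        default_factory=lambda: [RegimeSpec("baseline", 600.0)]
    )
    noise_sigma: float = 0.2
    seed: int = 0
    xmin_s: float = 0.2  # lower cutoff of locked dwell times, seconds
    unlocked_mean_s: float = 0.3  # mean of exponential unlocked dwells
    detune_hz: float = 4.0  # max channel detuning while unlocked
    phase_jitter: float = 0.05  # rad; spread of offsets while locked

    def __post_init__(self) -> None:
        if self.n_channels < 2:
            raise ValueError("need at least 2 channels")
        lo, hi = self.carrier_band
        if not (0 < lo < hi < self.fs / 2):
            raise ValueError(
                f"carrier_band {self.carrier_band} must lie inside (0, fs/2)="
                f"(0, {self.fs / 2})"
            )
        if not self.regimes:
            raise ValueError("at least one regime required")


def dwell_time_sampler(
    alpha: float,
    xmin: float,
    size: int,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """I.i.d. Pareto draws via the inverse CDF.

    The density is ``p(x) = (alpha-1)/xmin * (x/xmin)**-alpha`` for
    ``x >= xmin``, so ``X = xmin * (1 - U) ** (-1/(alpha - 1))``; e.g.
    alpha = 2, xmin = 1, U = 0.75 gives 4.0.
    """
    if alpha <= 1:
        raise ValueError("alpha must exceed 1")
    if xmin <= 0:
        raise ValueError("xmin must be positive")
    if size < 0:
        raise ValueError("size must be >= 0")
    if rng is None:
        rng = np.random.default_rng(seed)
    u = rng.random(size)
    return xmin * np.power(1.0 - u, -1.0 / (alpha - 1.0))


def _regime_at(regimes: list[RegimeSpec], bounds: np.ndarray, t: float) -> tuple[RegimeSpec, float]:
    """Regime active at time t and the regime's start time."""
    idx = int(np.searchsorted(bounds, t, side="right") - 1)
    idx = min(max(idx, 0), len(regimes) - 1)
    return regimes[idx], float(bounds[idx])


def _lock_multiplier(regimes: list[RegimeSpec], bounds: np.ndarray, t: float) -> float:
    reg, t0 = _regime_at(regimes, bounds, t)
    if reg.name == "seizure":
        return reg.lock_excess
    if reg.name == "recovery":
        # decays from the preceding seizure's excess toward 1
        idx = int(np.searchsorted(bounds, t, side="right") - 1)
        prev_excess = next(
            (r.lock_excess for r in reversed(regimes[:idx]) if r.name == "seizure"),
            reg.lock_excess,
        )
        return 1.0 + (prev_excess - 1.0) * float(np.exp(-(t - t0) / reg.relax_tau_s))
    return 1.0


def generate_recording(cfg: SynthConfig) -> MultichannelRecording:
    """Synthesize a surrogate recording under the configured regimes.

    Deterministic given ``cfg.seed``.  Regime boundaries, the lock-state
    timeline and all ground-truth parameters are stored in the recording's
    ``metadata`` (and survive a write/read round trip through the sidecar).
    """
    rng = np.random.default_rng(cfg.seed)
    fs = cfg.fs
    bounds = np.concatenate([[0.0], np.cumsum([r.duration_s for r in cfg.regimes])])
    total_s = float(bounds[-1])
    n = int(round(total_s * fs))
    alpha0 = cfg.regimes[0].target_alpha

    # --- global two-state renewal timeline --------------------------------
    # locked[i] True where the network is in a locking dwell
    locked = np.zeros(n, dtype=bool)
    lock_spans: list[tuple[float, float]] = []
    t = 0.0
    state_locked = False  # start unlocked so the first lock onset is sampled
    while t < total_s:
        if state_locked:
            reg, _ = _regime_at(cfg.regimes, bounds, t)
            base = float(dwell_time_sampler(reg.target_alpha, cfg.xmin_s, 1, rng=rng)[0])
            dwell = base * _lock_multiplier(cfg.regimes, bounds, t)
            a, b = int(round(t * fs)), int(round(min(t + dwell, total_s) * fs))
            locked[a:b] = True
            lock_spans.append((t, min(t + dwell, total_s)))
        else:
            dwell = float(rng.exponential(cfg.unlocked_mean_s))
        t += dwell
        state_locked = not state_locked

    # --- channel phases ---------------------------------------------------
    f_c = 0.5 * (cfg.carrier_band[0] + cfg.carrier_band[1])
    dt = 1.0 / fs
    phi0 = 2.0 * np.pi * f_c * np.arange(n) * dt  # common carrier
    half_bw = 0.5 * (cfg.carrier_band[1] - cfg.carrier_band[0])
    detune_max = min(cfg.detune_hz, half_bw)
    m = cfg.n_channels
    # Detunings while unlocked are evenly spaced in [-detune_max, detune_max]
    # and shuffled across channels, so every pair's phase difference rotates
    # at >= 2*detune_max/(m-1) Hz — false locking while unlocked is then
    # bounded by a fraction of a rotation period.  (With many channels the
    # pairwise separation shrinks; prefer few channels per generated record.)
    detune_grid = np.linspace(-detune_max, detune_max, m)
    theta = np.zeros((n, m))
    cur = rng.normal(0.0, cfg.phase_jitter, m)
    detune = rng.permutation(detune_grid)
    sigma_w = 0.5  # rad / sqrt(s) phase diffusion while unlocked
    for i in range(n):
        if locked[i]:
            if i == 0 or not locked[i - 1]:  # lock onset: resynchronize
                cur = rng.normal(0.0, cfg.phase_jitter, m)
        else:
            if i > 0 and locked[i - 1]:  # unlock onset: abrupt desync
                cur = rng.uniform(-np.pi, np.pi, m)
                detune = rng.permutation(detune_grid)
            cur = cur + 2.0 * np.pi * detune * dt + sigma_w * np.sqrt(dt) * rng.normal(
                0.0, 1.0, m
            )
        theta[i] = cur

    data = np.cos(phi0[:, None] + theta)
    if cfg.noise_sigma > 0:
        data = data + cfg.noise_sigma * rng.standard_normal(data.shape)

    meta = {
        "generator": "plicrit.synth",
        "seed": cfg.seed,
        "fs": fs,
        "carrier_band": list(cfg.carrier_band),
        "target_alpha": alpha0,
        "xmin_s": cfg.xmin_s,
        "regimes": [asdict(r) | {"start_s": float(bounds[k])} for k, r in enumerate(cfg.regimes)],
        "n_lock_spans": len(lock_spans),
    }
    labels = [f"ch{k:02d}" for k in range(cfg.n_channels)]
    return MultichannelRecording(data=data, fs=fs, channel_labels=labels, metadata=meta)


def write_recording(rec: MultichannelRecording, path: str | Path) -> Path:
    """Write a recording as TSV plus a JSON sidecar (fs, labels, metadata)."""
    path = Path(path)
    np.savetxt(path, rec.data, delimiter="\t", fmt="%.6g")
    sidecar = path.with_suffix(path.suffix + ".json")
    payload = {
        "fs": rec.fs,
        "channel_labels": list(rec.channel_labels),
        "metadata": rec.metadata,
    }
    sidecar.write_text(json.dumps(payload, indent=1))
    return sidecar
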