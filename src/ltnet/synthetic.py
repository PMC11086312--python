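"""Seeded synthetic e-nose datasets for the acetone/ethanol experiment.

Emulates a 16-channel metal-oxide (MOS) sensor array in a static gas
chamber: each exposure runs ~120 s of response followed by ~120 s of
recovery at 1 Hz. The response model is standard MOS phenomenology —
per-sensor power-law steady state with first-order kinetics:

    r_s(t) = baseline_s
             + sum_gas S[s, gas] * C_gas^alpha_s * (1 - exp(-t / tau_rise_s))
             (+ the same steady-state term decaying with tau_decay_s
                after the exposure ends)
             + drift * t + Gaussian noise.

Mixture responses are additive in the per-gas steady-state terms, with an
optional multiplicative interaction knob. The dosing helper computes the
liquid volume to inject for a target chamber concentration by the static
volumetric method.

Everything is reproducible: a master seed drives per-record seeds through a
counter-keyed ``numpy`` ``SeedSequence`` (splitmix-style), so a record's
content depends on its index, not on generation order.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field

import numpy as np

from .gaf import Snapshot

GASES = ("ethanol", "acetone")
CLASS_LABELS = ("acetone", "ethanol", "mixture")

#: Sensor roster of the physical array: four FIGARO MOS models, each
#: replicated four times across the 16 channels, with the operating current
#: (mA) tuned per model.
SENSOR_ROSTER = (
    ("TGS2600", ("ethanol", "hydrogen"), (1.0, 30.0), 45.0),
    ("TGS2602", ("ammonia", "ethanol"), (1.0, 30.0), 50.0),
    ("TGS2610", ("organic compounds",), (500.0, 10000.0), 55.0),
    ("TGS2620", ("ethanol", "organic compounds"), (50.0, 5000.0), 43.0),
)


@dataclass(frozen=True)
class SensorSpec:
    sensor_id: int
    model_name: str
    target_gases: tuple[str, ...]
    detection_range_ppm: tuple[float, float]
    operating_current_mA: float

    def __post_init__(self):
        lo, hi = self.detection_range_ppm
        if not (1 <= self.sensor_id <= 16):
            raise ValueError("sensor_id must be 1..16")
        if lo >= hi:
            raise ValueError("detection range low must be < high")
        if self.operating_current_mA <= 0:
            raise ValueError("operating current must be positive")


def sensor_array() -> list[SensorSpec]:
    """The 16-channel array: the four-model roster cycled across channels."""
    out = []
    for i in range(16):
        model, gases, rng_ppm, current = SENSOR_ROSTER[i % 4]
        out.append(SensorSpec(i + 1, model, gases, rng_ppm, current))
    return out


@dataclass(frozen=True)
class GasExposure:
    ethanol_ppm: float
    acetone_ppm: float
    class_label: str
    replicate_id: int = 0

    def __post_init__(self):
        if self.ethanol_ppm < 0 or self.acetone_ppm < 0:
            raise ValueError("concentrations must be nonnegative")
        if self.class_label not in CLASS_LABELS:
            raise ValueError(f"class_label must be one of {CLASS_LABELS}")
        if self.class_label == "ethanol" and self.acetone_ppm != 0:
            raise ValueError("ethanol-only exposure must have acetone_ppm = 0")
        if self.class_label == "acetone" and self.ethanol_ppm != 0:
            raise ValueError("acetone-only exposure must have ethanol_ppm = 0")
        if self.class_label == "mixture" and not (self.ethanol_ppm > 0 and self.acetone_ppm > 0):
            raise ValueError("mixture exposure needs both gases > 0")


_PURE_GRID_PPM = (1, 3, 5, 7, 9, 11, 13, 15)
_MIX_GRID_PPM = tuple((e, a) for e in (1, 5, 10, 15) for a in (1, 5, 10, 15))


def concentration_grid(replicate_id: int = 0) -> list[GasExposure]:
    """The 32-row experimental grid: 8 acetone-only, 8 ethanol-only and 16
    binary-mixture concentration settings in 1–15 ppm per gas."""
    rows = [GasExposure(0.0, float(a), "acetone", replicate_id) for a in _PURE_GRID_PPM]
    rows += [GasExposure(float(e), 0.0, "ethanol", replicate_id) for e in _PURE_GRID_PPM]
    rows += [GasExposure(float(e), float(a), "mixture", replicate_id)
             for e, a in _MIX_GRID_PPM]
    return rows


# ---------------------------------------------------------------------------
# Dosing helper
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class DosingInputs:
    """Inputs of the static volumetric dosing calculation.

    V_chamber_mL: chamber volume; C_target_ppm: target gas concentration;
    M_gpermol: molecular weight; d_fraction: test-liquid concentration
    (mass fraction, diluted to 0.1 in the experiment); r_gpercm3: liquid
    density; T_lab_C / T_chamber_C: ambient and chamber temperatures.
    """

    V_chamber_mL: float
    C_target_ppm: float
    M_gpermol: float
    d_fraction: float
    r_gpercm3: float
    T_lab_C: float = 25.0
    T_chamber_C: float = 25.0

    def __post_init__(self):
        if min(self.V_chamber_mL, self.M_gpermol, self.r_gpercm3) <= 0:
            raise ValueError("V, M and r must be positive")
        if not (0 < self.d_fraction <= 1):
            raise ValueError("d must be in (0, 1]")
        if self.C_target_ppm < 0:
            raise ValueError("target concentration must be nonnegative")
        if self.T_lab_C <= -273 or self.T_chamber_C <= -273:
            raise ValueError("temperatures must exceed absolute zero")


def liquid_volume(inputs: DosingInputs) -> float:
    """Volume of test liquid (mL) to inject for the target concentration:

        Q = (V * C * M) / (22.4 * d * r) * 1e-9 * (273 + T_lab) / (273 + T_chamber)
    """
    i = inputs
    return (i.V_chamber_mL * i.C_target_ppm * i.M_gpermol
            / (22.4 * i.d_fraction * i.r_gpercm3) * 1e-9
            * (273.0 + i.T_lab_C) / (273.0 + i.T_chamber_C))


# ---------------------------------------------------------------------------
# Simulation
# ---------------------------------------------------------------------------

@dataclass
class SimConfig:
    """Full description of the simulated array; all per-sensor arrays have
    length 16. ``None`` fields are drawn once from ``seed`` (log-uniform
    sensitivities in [0.5, 5] a.u./ppm^alpha, exponents uniform in
    [0.5, 1.0], rise/decay constants in [10, 30] / [20, 40] s, baselines
    log-uniform in [0.5, 2] a.u.) so the 16 channels are diverse but
    reproducible."""

    sensitivity: np.ndarray | None = None      # (16, 2): columns ethanol, acetone
    exponent: np.ndarray | None = None         # (16,) in (0, 1]
    tau_rise_s: np.ndarray | None = None       # (16,)
    tau_decay_s: np.ndarray | None = None      # (16,)
    baseline: np.ndarray | None = None         # (16,)
    noise_sd: float = 0.05
    drift_per_s: float = 1e-4
    interaction: float = 0.0                   # optional multiplicative cross-term
    exposure_s: float = 120.0
    recovery_s: float = 120.0
    sample_rate_hz: float = 1.0
    seed: int = 0
    n_sensors: int = 16

    def __post_init__(self):
        rng = np.random.default_rng(np.random.SeedSequence(self.seed, spawn_key=(0,)))
        n = self.n_sensors
        if self.sensitivity is None:
            self.sensitivity = np.exp(rng.uniform(np.log(0.5), np.log(5.0), size=(n, 2)))
        if self.exponent is None:
            self.exponent = rng.uniform(0.5, 1.0, size=n)
        if self.tau_rise_s is None:
            self.tau_rise_s = rng.uniform(10.0, 30.0, size=n)
        if self.tau_decay_s is None:
            self.tau_decay_s = rng.uniform(20.0, 40.0, size=n)
        if self.baseline is None:
            self.baseline = np.exp(rng.uniform(np.log(0.5), np.log(2.0), size=n))
        for name in ("sensitivity", "exponent", "tau_rise_s", "tau_decay_s", "baseline"):
            setattr(self, name, np.asarray(getattr(self, name), dtype=float))
        if self.sensitivity.shape != (n, 2):
            raise ValueError("sensitivity must be (n_sensors, 2)")
        if np.any(self.sensitivity < 0):
            raise ValueError("sensitivities must be nonnegative")
        if np.any((self.exponent <= 0) | (self.exponent > 1)):
            raise ValueError("exponents must lie in (0, 1]")
        if (np.any(self.tau_rise_s <= 0) or np.any(self.tau_decay_s <= 0)
                or np.any(self.baseline <= 0)):
            raise ValueError("kinetic constants and baselines must be positive")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be nonnegative")
        if min(self.exposure_s, self.recovery_s, self.sample_rate_hz) <= 0:
            raise ValueError("exposure, recovery and sample rate must be positive")

    def digest(self) -> str:
        payload = {k: (v.tolist() if isinstance(v, np.ndarray) else v)
                   for k, v in vars(self).items()}
        return hashlib.sha256(
            json.dumps(payload, sort_keys=True).encode()).hexdigest()[:16]


@dataclass
class ExposureRecord:
    exposure: GasExposure
    times_s: np.ndarray
    responses: np.ndarray              # (T, 16)
    sim_config_digest: str

    def __post_init__(self):
        if np.any(np.diff(self.times_s) <= 0):
            raise ValueError("times must be strictly increasing")
        if not np.all(np.isfinite(self.responses)):
            raise ValueError("responses must be finite")


def _steady_state(cfg: SimConfig, exposure: GasExposure) -> np.ndarray:
    conc = np.array([exposure.ethanol_ppm, exposure.acetone_ppm])
    terms = cfg.sensitivity * np.power(conc[None, :], cfg.exponent[:, None],
                                       where=conc[None, :] > 0,
                                       out=np.zeros((cfg.n_sensors, 2)))
    ss = terms.sum(axis=1)
    if cfg.interaction and np.all(conc > 0):
        ss = ss + cfg.interaction * np.sqrt(terms[:, 0] * terms[:, 1])
    return ss


def simulate_exposure(cfg: SimConfig, exposure: GasExposure,
                      seed: int | None = None) -> ExposureRecord:
    """One exposure+recovery trace; identical (cfg, exposure, seed) are
    bit-identical."""
    seed = cfg.seed if seed is None else seed
    rng = np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(1,)))
    dt = 1.0 / cfg.sample_rate_hz
    n_ticks = int(round((cfg.exposure_s + cfg.recovery_s) * cfg.sample_rate_hz))
    t = np.arange(n_ticks) * dt
    ss = _steady_state(cfg, exposure)
    resp = np.empty((n_ticks, cfg.n_sensors))
    in_exposure = t <= cfg.exposure_s
    rise = 1.0 - np.exp(-t[in_exposure, None] / cfg.tau_rise_s[None, :])
    resp[in_exposure] = ss[None, :] * rise
    level_end = ss * (1.0 - np.exp(-cfg.exposure_s / cfg.tau_rise_s))
    t_rec = t[~in_exposure] - cfg.exposure_s
    resp[~in_exposure] = level_end[None, :] * np.exp(
        -t_rec[:, None] / cfg.tau_decay_s[None, :])
    resp += cfg.baseline[None, :] + cfg.drift_per_s * t[:, None]
    if cfg.noise_sd > 0:
        resp += rng.normal(0.0, cfg.noise_sd, size=resp.shape)
    return ExposureRecord(exposure=exposure, times_s=t, responses=resp,
                          sim_config_digest=cfg.digest())


# ---------------------------------------------------------------------------
# Snapshot extraction & dataset generation
# ---------------------------------------------------------------------------

def _select_ticks(record: ExposureRecord, policy: str, exposure_s: float) -> np.ndarray:
    t = record.times_s
    if policy == "end":
        idx = np.where(t <= exposure_s)[0]
        sel = idx[-1:]
    elif policy == "second-half":
        sel = np.where((t >= 0.5 * exposure_s) & (t <= exposure_s))[0]
    elif policy.startswith("last_k:"):
        k = int(policy.split(":", 1)[1])
        idx = np.where(t <= exposure_s)[0]
        sel = idx[-k:]
    else:
        raise ValueError(f"unknown snapshot policy {policy!r}")
    if sel.size == 0:
        raise ValueError("snapshot policy selected no ticks")
    return sel


def extract_snapshots(record: ExposureRecord, policy: str = "second-half",
                      exposure_s: float = 120.0) -> list[Snapshot]:
    """Slice the trace at the ticks named by ``policy``:

    * ``"end"`` — the last tick of the exposure phase;
    * ``"second-half"`` — every tick in [exposure_s / 2, exposure_s];
    * ``"last_k:N"`` — the last N exposure-phase ticks.
    """
    sel = _select_ticks(record, policy, exposure_s)
    return [Snapshot(values=record.responses[k].copy(),
                     class_label=record.exposure.class_label,
                     meta={"tick": int(k), "time_s": float(record.times_s[k]),
                           "ethanol_ppm": record.exposure.ethanol_ppm,
                           "acetone_ppm": record.exposure.acetone_ppm,
                           "replicate_id": record.exposure.replicate_id,
                           "digest": record.sim_config_digest})
            for k in sel]


def record_seed(master_seed: int, record_index: int) -> int:
    """Per-record seed derived from the master seed by a counter-keyed
    SeedSequence, so records are independent of generation order."""
    return int(np.random.SeedSequence(master_seed,
                                      spawn_key=(record_index,)).generate_state(1)[0])


def generate_dataset(cfg: SimConfig, grid: list[GasExposure] | None = None,
                     replicates: int = 1, seed: int = 0,
                     policy: str = "second-half"):
    """Simulate ``replicates`` passes over ``grid`` (default: the 32-row
    concentration grid) and extract labeled snapshots.

    Returns ``(snapshots, manifest)``; the manifest is JSON-serializable and
    byte-identical for identical (cfg, grid, replicates, seed, policy).
    """
    if replicates < 1:
        raise ValueError("replicates must be >= 1")
    grid = concentration_grid() if grid is None else list(grid)
    if not grid:
        raise ValueError("grid must be nonempty")
    snapshots: list[Snapshot] = []
    items = []
    idx = 0
    for rep in range(replicates):
        for row in grid:
            exp = GasExposure(row.ethanol_ppm, row.acetone_ppm, row.class_label, rep)
            rseed = record_seed(seed, idx)
            rec = simulate_exposure(cfg, exp, seed=rseed)
            snaps = extract_snapshots(rec, policy=policy, exposure_s=cfg.exposure_s)
            for s in snaps:
                s.meta["item_id"] = len(snapshots)
                snapshots.append(s)
            items.append({"record_index": idx, "replicate": rep,
                          "class_label": exp.class_label,
                          "ethanol_ppm": exp.ethanol_ppm,
                          "acetone_ppm": exp.acetone_ppm,
                          "record_seed": rseed, "n_snapshots": len(snaps)})
            idx += 1
    manifest = {
        "units": {"concentration": "ppm", "time": "s",
                  "response": "arbitrary resistance-like units"},
        "master_seed": seed, "replicates": replicates, "policy": policy,
        "sim_config_digest": cfg.digest(), "n_records": idx,
        "n_snapshots": len(snapshots), "items": items,
    }
    return snapshots, manifest


def write_record_csv(record: ExposureRecord, path) -> None:
    """`time_s,s01..s16` CSV, one row per tick."""
    header = "time_s," + ",".join(f"s{i:02d}" for i in range(1, record.responses.shape[1] + 1))
    data = np.column_stack([record.times_s, record.responses])
    np.savetxt(path, data, delimiter=",", header=header, comments="", fmt="%.9g")
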