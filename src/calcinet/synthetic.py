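"""Seeded simulator of neuron-glial culture calcium recordings.

The generator emulates a 2D dissociated hippocampal culture imaged with a
calcium-sensitive dye: neurons and astrocytes are scattered on a rectangular
field, neurons are wired into a distance-decaying structural network, and
spontaneous activity is produced by a Poisson network drive whose bursts
recruit the structural neighbours of a randomly chosen seed neuron.
Astrocytes fire slow independent transients.  Every cell additionally sees a
shared slow background component (Ornstein-Uhlenbeck) and white measurement
noise, and a configurable fraction of cells is silent.

Regime presets (`apply_regime`) encode the experimental groups of the
hypoxia study: an intact culture, an untreated hypoxic culture, and four
drug-treatment arms.  Presets differ only in four parameters — silent
fraction, burst participation probability, structural connection density and
shared-background amplitude — and their values are package calibration
constants chosen so the downstream analysis pipeline reproduces the group
medians reported for real cultures (≈50% vs ≈25% active cells; mean adjacent
correlation ≈0.21 intact vs ≈0.10 post-hypoxia).

All randomness in one recording is drawn from a single `numpy` Generator
seeded from ``config.seed``; identical configs give bit-identical output.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .errors import (
    MalformedRecordingError,
    PlacementInfeasibleError,
    UnknownPresetError,
)

__all__ = [
    "SimulationConfig",
    "CellGeometry",
    "GroundTruthNetwork",
    "Recording",
    "REGIME_PRESETS",
    "apply_regime",
    "place_cells",
    "sample_structural_network",
    "simulate_activity",
    "simulate_recording",
    "write_recording",
    "read_recording",
    "render_tiff",
]


# --------------------------------------------------------------------------
# configuration and domain types
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of one simulated recording.

    Distances are in micrometres, times in seconds, rates in events per
    minute, amplitudes in ΔF/F units (the raw trace is reconstructed around
    a 100 a.u. baseline).
    """

    field_width: float = 400.0
    field_height: float = 400.0
    n_cells: int = 60
    astrocyte_fraction: float = 0.3
    soma_radius_mean: float = 10.0
    soma_radius_sd: float = 2.0
    min_separation: float = 15.0
    frame_rate: float = 2.0          # Hz; confocal time series at 2 fps
    duration: float = 600.0          # s
    connect_p0: float = 0.6          # connection probability at zero distance
    connect_lambda: float = 150.0    # µm decay length of connectivity
    burst_rate: float = 8.0          # network-drive bursts per minute
    participation_prob: float = 0.6  # neighbour joins a burst
    silent_fraction: float = 0.5     # cells with no events at all
    astro_event_rate: float = 0.4    # astrocyte transients per minute
    kernel_tau_rise: float = 0.3     # s
    kernel_tau_decay: float = 3.0    # s
    astro_kernel_scale: float = 2.0  # astrocyte transients are slower
    event_amplitude: float = 1.0     # ΔF/F peak of a single transient
    background_amplitude: float = 0.02   # sd of shared OU component, ΔF/F
    background_tau: float = 10.0     # s, OU correlation time
    noise_sd: float = 0.03           # white measurement noise, ΔF/F
    seed: int = 0

    def __post_init__(self):
        for name in ("astrocyte_fraction", "silent_fraction",
                     "participation_prob", "connect_p0"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.frame_rate <= 0:
            raise ValueError("frame_rate must be > 0")
        if self.duration <= 0:
            raise ValueError("duration must be > 0")
        if self.connect_lambda <= 0:
            raise ValueError("connect_lambda must be > 0")
        if self.min_separation < 0:
            raise ValueError("min_separation must be >= 0")
        if self.n_cells < 1:
            raise ValueError("n_cells must be >= 1")

    @property
    def n_frames(self) -> int:
        return int(round(self.frame_rate * self.duration))


@dataclass(frozen=True)
class CellGeometry:
    """Soma geometry of one cell; origin top-left, y increases downward."""

    cell_id: int
    x: float
    y: float
    radius: float
    cell_type: str  # "neuron" | "astrocyte"


@dataclass
class GroundTruthNetwork:
    """Planted structural edges (neurons only) and per-cell event onsets."""

    edges: set[tuple[int, int]] = field(default_factory=set)
    event_trains: dict[int, np.ndarray] = field(default_factory=dict)

    def n_events(self) -> int:
        return int(sum(len(t) for t in self.event_trains.values()))


@dataclass
class Recording:
    """One culture's recording: geometry plus a frames × cells trace matrix."""

    group_label: str
    frame_rate: float
    cells: list[CellGeometry]
    traces: np.ndarray  # shape (n_frames, n_cells), a.u., > 0
    seed: int | None = None

    @property
    def n_frames(self) -> int:
        return int(self.traces.shape[0])

    @property
    def n_cells(self) -> int:
        return len(self.cells)

    @property
    def duration(self) -> float:
        return self.n_frames / self.frame_rate

    def cell_ids(self) -> list[int]:
        return [c.cell_id for c in self.cells]


# --------------------------------------------------------------------------
# regime presets
# --------------------------------------------------------------------------

#: The six experimental groups.  Presets differ only in the four parameters
#: the insult and the drug plausibly act on: how many cells fall silent, how
#: reliably neighbours are recruited into network bursts, how dense the
#: surviving structural connectivity is, and the amplitude of the shared
#: slow background.  Values are calibration constants (see docs/methods.md).
REGIME_PRESETS: dict[str, dict[str, float]] = {
    "intact": dict(
        silent_fraction=0.50, participation_prob=0.80,
        connect_p0=0.70, background_amplitude=0.030),
    "hypoxia": dict(
        silent_fraction=0.75, participation_prob=0.02,
        connect_p0=0.05, background_amplitude=0.016),
    "hypoxia_1uM_immediate": dict(
        silent_fraction=0.50, participation_prob=0.55,
        connect_p0=0.45, background_amplitude=0.026),
    "hypoxia_15uM_immediate": dict(
        silent_fraction=0.52, participation_prob=0.30,
        connect_p0=0.30, background_amplitude=0.021),
    "hypoxia_1uM_post": dict(
        silent_fraction=0.70, participation_prob=0.04,
        connect_p0=0.07, background_amplitude=0.016),
    "hypoxia_15uM_post": dict(
        silent_fraction=0.54, participation_prob=0.04,
        connect_p0=0.07, background_amplitude=0.016),
}


def apply_regime(preset_name: str, **overrides) -> SimulationConfig:
    """Return the shipped :class:`SimulationConfig` for a regime preset.

    Extra keyword arguments (e.g. ``seed``, ``n_cells``, ``duration``)
    override the preset's defaults.
    """
    try:
        preset = REGIME_PRESETS[preset_name]
    except KeyError:
        raise UnknownPresetError(
            f"unknown regime preset {preset_name!r}; known presets: "
            + ", ".join(sorted(REGIME_PRESETS))
        ) from None
    kwargs = dict(preset)
    kwargs.update(overrides)
    return SimulationConfig(**kwargs)


# --------------------------------------------------------------------------
# geometry
# --------------------------------------------------------------------------

_MAX_ATTEMPTS_PER_CELL = 2000


def place_cells(config: SimulationConfig,
                rng: np.random.Generator | None = None) -> list[CellGeometry]:
    """Scatter somata uniformly with a hard minimum centroid separation.

    Rejection sampling; raises :class:`PlacementInfeasibleError` (reporting
    the attempt count) if the field cannot accommodate ``n_cells`` at the
    requested separation.
    """
    rng = np.random.default_rng(config.seed) if rng is None else rng
    placed_xy: list[tuple[float, float]] = []
    attempts = 0
    budget = _MAX_ATTEMPTS_PER_CELL * config.n_cells
    min_sep2 = config.min_separation ** 2
    while len(placed_xy) < config.n_cells:
        if attempts >= budget:
            raise PlacementInfeasibleError(
                len(placed_xy), config.n_cells, attempts)
        attempts += 1
        x = rng.uniform(0.0, config.field_width)
        y = rng.uniform(0.0, config.field_height)
        if all((x - px) ** 2 + (y - py) ** 2 >= min_sep2
               for px, py in placed_xy):
            placed_xy.append((x, y))

    n_astro = int(round(config.astrocyte_fraction * config.n_cells))
    types = np.array(["neuron"] * config.n_cells, dtype=object)
    astro_ids = rng.choice(config.n_cells, size=n_astro, replace=False)
    types[astro_ids] = "astrocyte"

    radii = rng.normal(config.soma_radius_mean, config.soma_radius_sd,
                       size=config.n_cells)
    radii = np.maximum(radii, 1.0)  # truncate: somata never below 1 µm

    return [
        CellGeometry(cell_id=i, x=placed_xy[i][0], y=placed_xy[i][1],
                     radius=float(radii[i]), cell_type=str(types[i]))
        for i in range(config.n_cells)
    ]


def sample_structural_network(cells: list[CellGeometry],
                              config: SimulationConfig,
                              rng: np.random.Generator | None = None,
                              ) -> GroundTruthNetwork:
    """Wire neurons with distance-decaying Bernoulli edges.

    Each unordered neuron pair (i, j) becomes an edge independently with
    probability ``connect_p0 * exp(-d_ij / connect_lambda)``; astrocytes
    receive no structural edges.
    """
    rng = np.random.default_rng(config.seed) if rng is None else rng
    neurons = [c for c in cells if c.cell_type == "neuron"]
    edges: set[tuple[int, int]] = set()
    for a_idx in range(len(neurons)):
        a = neurons[a_idx]
        for b in neurons[a_idx + 1:]:
            d = math.hypot(a.x - b.x, a.y - b.y)
            p = config.connect_p0 * math.exp(-d / config.connect_lambda)
            if rng.random() < p:
                edges.add((min(a.cell_id, b.cell_id),
                           max(a.cell_id, b.cell_id)))
    return GroundTruthNetwork(edges=edges, event_trains={})


# --------------------------------------------------------------------------
# activity
# --------------------------------------------------------------------------

def _event_kernel(t: np.ndarray, tau_rise: float, tau_decay: float,
                  amplitude: float) -> np.ndarray:
    """Difference-of-exponentials transient, peak-normalised to *amplitude*."""
    t = np.asarray(t, dtype=float)
    k = np.exp(-t / tau_decay) - np.exp(-t / tau_rise)
    t_peak = (tau_rise * tau_decay / (tau_decay - tau_rise)
              * math.log(tau_decay / tau_rise))
    peak = math.exp(-t_peak / tau_decay) - math.exp(-t_peak / tau_rise)
    out = amplitude * k / peak
    out[t < 0] = 0.0
    return out


def _add_events(signal: np.ndarray, onsets: np.ndarray, frame_rate: float,
                tau_rise: float, tau_decay: float, amplitude: float) -> None:
    """Convolve an onset train into *signal* in place."""
    n = signal.shape[0]
    support = int(math.ceil(8.0 * tau_decay * frame_rate))
    for t0 in onsets:
        i0 = int(math.ceil(t0 * frame_rate))
        if i0 >= n:
            continue
        i1 = min(n, i0 + support)
        t = np.arange(i0, i1) / frame_rate - t0
        signal[i0:i1] += _event_kernel(t, tau_rise, tau_decay, amplitude)


def _poisson_times(rng: np.random.Generator, rate_per_min: float,
                   duration: float) -> np.ndarray:
    n = rng.poisson(rate_per_min * duration / 60.0)
    return np.sort(rng.uniform(0.0, duration, size=n))


def _ou_process(rng: np.random.Generator, n: int, dt: float, tau: float,
                sd: float) -> np.ndarray:
    """Stationary Ornstein-Uhlenbeck path with marginal standard deviation sd."""
    x = np.empty(n)
    a = math.exp(-dt / tau)
    b = sd * math.sqrt(1.0 - a * a)
    x[0] = sd * rng.standard_normal()
    innov = rng.standard_normal(n - 1)
    for i in range(1, n):
        x[i] = a * x[i - 1] + b * innov[i - 1]
    return x


def simulate_activity(cells: list[CellGeometry],
                      network: GroundTruthNetwork,
                      config: SimulationConfig,
                      rng: np.random.Generator | None = None,
                      group_label: str = "custom",
                      ) -> tuple[Recording, GroundTruthNetwork]:
    """Generate fluorescence traces and fill the ground-truth event trains.

    Activity model:

    * a Poisson network drive at ``burst_rate`` picks a seed neuron per
      burst among the non-silent neurons; each structural neighbour of the
      seed joins with ``participation_prob`` (recruitment stops one hop
      from the seed, with a small onset lag per recruit);
    * a seeded choice of ``silent_fraction`` of the cells receives no
      events at all;
    * non-silent astrocytes fire independent Poisson transients at
      ``astro_event_rate``, with a slower kernel
      (``astro_kernel_scale`` × the neuronal time constants);
    * every event is convolved with a difference-of-exponentials kernel;
    * one shared Ornstein-Uhlenbeck background plus per-cell white noise is
      added, and traces are rebuilt around a positive 100 a.u. baseline.
    """
    rng = np.random.default_rng(config.seed) if rng is None else rng
    n_cells = len(cells)
    n_frames = config.n_frames
    id_to_index = {c.cell_id: i for i, c in enumerate(cells)}

    # silent cells: a fixed-count seeded choice keeps the active fraction
    # tight across cultures, as in a confluent culture scored post hoc
    n_silent = int(round(config.silent_fraction * n_cells))
    silent = set(rng.choice([c.cell_id for c in cells], size=n_silent,
                            replace=False).tolist())

    neighbours: dict[int, list[int]] = {c.cell_id: [] for c in cells}
    for a, b in sorted(network.edges):
        neighbours[a].append(b)
        neighbours[b].append(a)

    trains: dict[int, list[float]] = {c.cell_id: [] for c in cells}

    active_neurons = [c.cell_id for c in cells
                      if c.cell_type == "neuron" and c.cell_id not in silent]
    burst_times = _poisson_times(rng, config.burst_rate, config.duration)
    for t0 in burst_times:
        if not active_neurons:
            break
        seed_id = int(rng.choice(active_neurons))
        trains[seed_id].append(float(t0))
        for nb in neighbours[seed_id]:
            if nb in silent:
                continue
            if rng.random() < config.participation_prob:
                trains[nb].append(float(t0 + rng.uniform(0.0, 0.25)))

    for c in cells:
        if c.cell_type == "astrocyte" and c.cell_id not in silent:
            trains[c.cell_id].extend(
                _poisson_times(rng, config.astro_event_rate,
                               config.duration).tolist())

    event_trains = {cid: np.sort(np.asarray(ts, dtype=float))
                    for cid, ts in trains.items()}

    background = _ou_process(rng, n_frames, 1.0 / config.frame_rate,
                             config.background_tau,
                             config.background_amplitude) \
        if config.background_amplitude > 0 else np.zeros(n_frames)

    traces = np.empty((n_frames, n_cells))
    for c in cells:
        sig = np.zeros(n_frames)
        if c.cell_type == "astrocyte":
            tr = config.kernel_tau_rise * config.astro_kernel_scale
            td = config.kernel_tau_decay * config.astro_kernel_scale
        else:
            tr, td = config.kernel_tau_rise, config.kernel_tau_decay
        _add_events(sig, event_trains[c.cell_id], config.frame_rate,
                    tr, td, config.event_amplitude)
        noise = rng.normal(0.0, config.noise_sd, size=n_frames) \
            if config.noise_sd > 0 else 0.0
        f = 100.0 * (1.0 + sig + background + noise)
        traces[:, id_to_index[c.cell_id]] = np.maximum(f, 0.1)

    recording = Recording(group_label=group_label,
                          frame_rate=config.frame_rate,
                          cells=list(cells), traces=traces,
                          seed=config.seed)
    return recording, GroundTruthNetwork(edges=set(network.edges),
                                         event_trains=event_trains)


def simulate_recording(config: SimulationConfig, group_label: str = "custom",
                       ) -> tuple[Recording, GroundTruthNetwork]:
    """Place cells, wire the network and simulate activity in one call.

    A single Generator seeded from ``config.seed`` drives all three stages,
    so identical configs yield bit-identical recordings.
    """
    rng = np.random.default_rng(config.seed)
    cells = place_cells(config, rng)
    net = sample_structural_network(cells, config, rng)
    return simulate_activity(cells, net, config, rng, group_label=group_label)


# --------------------------------------------------------------------------
# on-disk format
# --------------------------------------------------------------------------

def write_recording(recording: Recording, out_dir: str | Path) -> Path:
    """Persist a recording as three text files in *out_dir*.

    ``geometry.csv`` (cell_id, x, y, radius, cell_type), ``traces.csv``
    (frames × cells, one headered column per cell) and ``metadata.txt``
    (flat ``key=value`` lines: group, frame_rate, n_frames, seed).
    """
    import pandas as pd

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    geo = pd.DataFrame(
        [(c.cell_id, c.x, c.y, c.radius, c.cell_type)
         for c in recording.cells],
        columns=["cell_id", "x", "y", "radius", "cell_type"])
    geo.to_csv(out_dir / "geometry.csv", index=False)

    tr = pd.DataFrame(recording.traces,
                      columns=[f"cell_{c.cell_id}" for c in recording.cells])
    tr.to_csv(out_dir / "traces.csv", index=False, float_format="%.6f")

    meta = {
        "group": recording.group_label,
        "frame_rate": repr(recording.frame_rate),
        "n_frames": str(recording.n_frames),
        "seed": "" if recording.seed is None else str(recording.seed),
    }
    (out_dir / "metadata.txt").write_text(
        "".join(f"{k}={v}\n" for k, v in meta.items()))
    return out_dir


def read_recording(in_dir: str | Path) -> Recording:
    """Load a recording written by :func:`write_recording`, with validation."""
    import pandas as pd

    in_dir = Path(in_dir)
    for name in ("geometry.csv", "traces.csv", "metadata.txt"):
        if not (in_dir / name).exists():
            raise MalformedRecordingError(f"missing file {name} in {in_dir}")

    meta: dict[str, str] = {}
    for line in (in_dir / "metadata.txt").read_text().splitlines():
        if "=" in line:
            k, v = line.split("=", 1)
            meta[k.strip()] = v.strip()
    try:
        frame_rate = float(meta["frame_rate"])
        n_frames = int(meta["n_frames"])
        group = meta["group"]
    except (KeyError, ValueError) as exc:
        raise MalformedRecordingError(f"bad metadata.txt: {exc}") from exc

    geo = pd.read_csv(in_dir / "geometry.csv", float_precision="round_trip")
    required = {"cell_id", "x", "y", "radius", "cell_type"}
    if not required.issubset(geo.columns):
        raise MalformedRecordingError(
            f"geometry.csv missing columns {sorted(required - set(geo.columns))}")
    if geo["cell_id"].duplicated().any():
        dup = geo.loc[geo["cell_id"].duplicated(), "cell_id"].iloc[0]
        raise MalformedRecordingError(f"duplicate cell_id {dup} in geometry.csv")

    tr = pd.read_csv(in_dir / "traces.csv")
    if len(tr) != n_frames:
        raise MalformedRecordingError(
            f"traces.csv has {len(tr)} frame rows, metadata says {n_frames}")
    for cid in geo["cell_id"]:
        col = f"cell_{cid}"
        if col not in tr.columns:
            raise MalformedRecordingError(f"traces.csv missing column {col}")
    traces = tr[[f"cell_{cid}" for cid in geo["cell_id"]]].to_numpy(float)
    if not np.all(np.isfinite(traces)) or np.any(traces <= 0):
        bad = np.argwhere(~(np.isfinite(traces) & (traces > 0)))[0]
        raise MalformedRecordingError(
            f"non-positive or non-finite fluorescence at frame {bad[0]}, "
            f"column {tr.columns[bad[1]]}")

    cells = [CellGeometry(int(r.cell_id), float(r.x), float(r.y),
                          float(r.radius), str(r.cell_type))
             for r in geo.itertuples()]
    seed = int(meta["seed"]) if meta.get("seed") else None
    return Recording(group_label=group, frame_rate=frame_rate, cells=cells,
                     traces=traces, seed=seed)


def render_tiff(recording: Recording, path: str | Path,
                pixel_um: float = 2.0, max_frames: int | None = None) -> Path:
    """Render the recording as a multi-page grayscale TIFF (visualisation only).

    Cells are drawn as Gaussian blobs (sigma = soma radius / 2) scaled by
    instantaneous fluorescence.
    """
    import tifffile

    # modest raster; this is a QC visualisation, not data
    w = max(int(math.ceil(max(c.x for c in recording.cells) / pixel_um)) + 8, 16)
    h = max(int(math.ceil(max(c.y for c in recording.cells) / pixel_um)) + 8, 16)
    n = recording.n_frames if max_frames is None \
        else min(max_frames, recording.n_frames)
    yy, xx = np.mgrid[0:h, 0:w]
    blobs = []
    for c in recording.cells:
        sigma = max(c.radius / (2.0 * pixel_um), 0.5)
        g = np.exp(-(((xx - c.x / pixel_um) ** 2 + (yy - c.y / pixel_um) ** 2)
                     / (2.0 * sigma ** 2)))
        blobs.append(g.astype(np.float32))
    stack = np.zeros((n, h, w), dtype=np.float32)
    for t in range(n):
        frame = np.zeros((h, w), dtype=np.float32)
        for i, g in enumerate(blobs):
            frame += g * recording.traces[t, i]
        stack[t] = frame
    stack = (stack / stack.max() * 65535.0).astype(np.uint16)
    path = Path(path)
    tifffile.imwrite(path, stack, photometric="minisblack")
    return path
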