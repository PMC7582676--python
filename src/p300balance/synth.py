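"""Synthetic oddball-paradigm EEG sessions and 2-D toy datasets.

The generator emulates the recording design of a visual oddball
brain-computer interface: a session is a sequence of *blocks*, each block
one full selection in which every stimulus is highlighted ``n_reps`` times
in random order (62.5 ms highlight + 62.5 ms inter-trial interval).  One
stimulus per block is the attended *target*; its highlights evoke a P300 —
a positive potential peaking 250-500 ms after onset — modelled as a
Gaussian-in-time bump scaled by a per-channel topography and added to
background activity.  Nontarget highlights carry background only.

The default background is *rhythmic*: a handful of narrowband oscillatory
sources (slow drift through theta/alpha frequencies) with fixed spatial
patterns — one of them the P300 topography itself, i.e. ongoing activity
of the same cortical configuration — plus a small white sensor-noise
floor.  This low-rank structure is what makes the downstream target /
nontarget feature clouds genuinely overlap the way real ERP data do;
spatially and temporally white noise of the same power would render every
training set linearly separable with a wide margin and turn balancing into
a geometric no-op.  A plain white background remains available via
``background="white"`` for calibration checks.

Single-trial realism of the target response: each target highlight elicits
the P300 only with probability ``p300_prob`` (attention fluctuates), and
the peak latency jitters from trial to trial.  Subject quality is
controlled by ``p300_amplitude`` (and ``p300_prob``) against ``noise_sd``.

Everything is driven by :class:`numpy.random.Generator` seeded explicitly,
so sessions are bit-reproducible.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

__all__ = [
    "SyntheticConfig",
    "BlockRecording",
    "SessionRecording",
    "ToyDataset",
    "generate_session",
    "generate_cohort",
    "generate_toy_2d",
    "save_session",
    "load_session",
    "save_toy",
    "load_toy",
    "default_topography",
]

#: samples of padding kept before the first onset / after the last offset of
#: a block, so that [-200, 600) ms epochs never leave the recorded signal.
_PAD_PRE_MS = 250.0
_PAD_POST_MS = 700.0


def default_topography(n_channels: int) -> np.ndarray:
    """Midline-weighted evoked topography.

    A fixed smooth weight vector peaking at the middle channel, mimicking
    the centro-parietal dominance of the P300 without reproducing any
    specific montage.  Values in (0, 1], maximum exactly 1.
    """
    idx = np.arange(n_channels, dtype=float)
    center = (n_channels - 1) / 2.0
    spread = max(n_channels / 4.0, 1.0)
    w = 0.25 + 0.75 * np.exp(-0.5 * ((idx - center) / spread) ** 2)
    return w / w.max()


@dataclass(frozen=True)
class SyntheticConfig:
    """Design parameters of one synthetic oddball session.

    Defaults follow the 4-stimulus appliance-control design: 32 channels at
    500 Hz, 10 highlights per stimulus per block, 50 training and 30 test
    blocks, 62.5 ms stimulus duration and 62.5 ms inter-trial interval
    (125 ms per trial).
    """

    n_channels: int = 32
    sampling_rate: float = 500.0
    n_stimuli: int = 4
    n_reps: int = 10
    n_train_blocks: int = 50
    n_test_blocks: int = 30
    stim_duration: float = 62.5  # ms
    iti: float = 62.5  # ms
    p300_amplitude: float = 14.0  # µV at the topography peak
    p300_latency: float = 350.0  # ms post-onset
    p300_width: float = 55.0  # Gaussian SD, ms
    p300_prob: float = 0.6  # per-highlight elicitation probability
    latency_jitter_sd: float = 40.0  # ms, trial-to-trial peak jitter
    noise_sd: float = 10.0  # µV, total background SD
    background: str = "rhythmic"  # "rhythmic" or "white"
    n_noise_sources: int = 4  # spatial patterns of the rhythmic background
    noise_freqs: tuple[float, ...] = (0.6, 1.5, 2.9, 4.8, 7.2)  # Hz
    sensor_noise_frac: float = 0.02  # white floor, fraction of noise_sd
    channel_topography: tuple[float, ...] | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_stimuli not in (4, 6):
            raise ValueError(f"n_stimuli must be 4 or 6, got {self.n_stimuli}")
        if self.p300_amplitude < 0:
            raise ValueError("p300_amplitude must be >= 0")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if not 0.0 <= self.p300_prob <= 1.0:
            raise ValueError("p300_prob must lie in [0, 1]")
        if self.latency_jitter_sd < 0:
            raise ValueError("latency_jitter_sd must be >= 0")
        for name in ("stim_duration", "iti", "p300_latency", "p300_width"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if self.n_channels < 1 or self.n_reps < 1:
            raise ValueError("n_channels and n_reps must be >= 1")
        if self.background not in ("rhythmic", "white"):
            raise ValueError("background must be 'rhythmic' or 'white'")
        if self.n_noise_sources < 1 or len(self.noise_freqs) < 1:
            raise ValueError("need at least one noise source and frequency")
        if not 0.0 <= self.sensor_noise_frac <= 1.0:
            raise ValueError("sensor_noise_frac must lie in [0, 1]")
        if self.channel_topography is not None and len(self.channel_topography) != self.n_channels:
            raise ValueError("channel_topography length must equal n_channels")

    @property
    def trial_ms(self) -> float:
        """Trial duration in ms (highlight + inter-trial interval)."""
        return self.stim_duration + self.iti

    @property
    def trials_per_block(self) -> int:
        return self.n_stimuli * self.n_reps

    def topography(self) -> np.ndarray:
        if self.channel_topography is not None:
            return np.asarray(self.channel_topography, dtype=float)
        return default_topography(self.n_channels)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


@dataclass
class BlockRecording:
    """Continuous signal of one block plus its event log.

    ``events`` rows are (stimulus_id, onset_sample, is_target); onsets are
    strictly increasing and spaced ``trial_ms`` on average (62 / 63 samples
    alternating at 500 Hz, see :func:`trial_onsets`).
    """

    signal: np.ndarray  # channels x samples, µV
    events: np.ndarray  # trials x 3 int array
    target_id: int


@dataclass
class SessionRecording:
    """All blocks of one subject's session, training blocks first."""

    config: SyntheticConfig
    train_blocks: list[BlockRecording]
    test_blocks: list[BlockRecording]

    @property
    def blocks(self) -> list[BlockRecording]:
        return self.train_blocks + self.test_blocks


@dataclass
class ToyDataset:
    """Two-class 2-D Gaussian point clouds for sampler illustration."""

    points: np.ndarray  # n x 2
    labels: np.ndarray  # n, 1 = minority, 0 = majority
    seed: int
    minority_mean: tuple[float, float] = (0.0, 0.0)
    majority_mean: tuple[float, float] = (0.0, 0.0)
    spread: float = 1.0


def trial_onsets(config: SyntheticConfig, n_trials: int) -> np.ndarray:
    """Onset samples of consecutive trials within one block.

    The nominal spacing ``trial_ms * fs / 1000`` is generally fractional
    (62.5 samples at 500 Hz); onsets are ``floor(pad + i * spacing)`` so the
    realized spacing alternates 62/63 and averages exactly 62.5.
    """
    pad = int(round(_PAD_PRE_MS * config.sampling_rate / 1000.0))
    spacing = config.trial_ms * config.sampling_rate / 1000.0
    return (pad + np.floor(np.arange(n_trials) * spacing)).astype(np.int64)


def _block_n_samples(config: SyntheticConfig) -> int:
    onsets = trial_onsets(config, config.trials_per_block)
    return int(onsets[-1]) + int(round(_PAD_POST_MS * config.sampling_rate / 1000.0))


def _noise_patterns(config: SyntheticConfig) -> np.ndarray:
    """Unit-norm spatial patterns of the rhythmic background sources.

    The first pattern is the P300 topography itself (ongoing activity of
    the ERP-generating configuration); the rest are cosine harmonics over
    the channel axis, mimicking spatially smooth, distinct source maps.
    """
    ch = np.arange(config.n_channels, dtype=float)
    topo = config.topography()
    pats = [topo / np.linalg.norm(topo)]
    for j in range(1, config.n_noise_sources):
        v = np.cos(np.pi * (j + 0.5) * (ch + 0.5) / config.n_channels)
        pats.append(v / np.linalg.norm(v))
    return np.stack(pats, axis=1)


def _noise(rng: np.random.Generator, config: SyntheticConfig, n_samples: int) -> np.ndarray:
    """Background activity for one block (channels x samples, µV).

    Rhythmic mode: each spatial pattern carries a sum of sinusoids at the
    configured frequencies with per-block Rayleigh amplitudes (weighted
    1/sqrt(f)) and uniform phases; the mixture is normalized to the target
    power per block and a white sensor floor of relative SD
    ``sensor_noise_frac`` is superimposed.  White mode: iid Gaussian.
    """
    if config.noise_sd == 0:
        return np.zeros((config.n_channels, n_samples))
    if config.background == "white":
        return rng.normal(0.0, config.noise_sd, size=(config.n_channels, n_samples))
    A = _noise_patterns(config)
    t = np.arange(n_samples) / config.sampling_rate
    src = np.zeros((A.shape[1], n_samples))
    for s in range(A.shape[1]):
        for f in config.noise_freqs:
            a = rng.rayleigh(1.0) / np.sqrt(f)
            phase = rng.uniform(0.0, 2.0 * np.pi)
            src[s] += a * np.sin(2.0 * np.pi * f * t + phase)
    shared = A @ src
    sd = shared.std()
    if sd > 0:
        shared /= sd
    wf = config.sensor_noise_frac
    out = np.sqrt(max(1.0 - wf * wf, 0.0)) * shared
    if wf > 0:
        out = out + wf * rng.normal(0.0, 1.0, size=shared.shape)
    return config.noise_sd * out


def _evoked_bump(config: SyntheticConfig, n_samples: int, onset: int, latency_ms: float) -> np.ndarray:
    """Gaussian-in-time P300 template (1-D over samples), peak = 1."""
    t_ms = (np.arange(n_samples) - onset) * 1000.0 / config.sampling_rate - latency_ms
    return np.exp(-0.5 * (t_ms / config.p300_width) ** 2)


def _generate_block(config: SyntheticConfig, target_id: int, rng: np.random.Generator) -> BlockRecording:
    n_samples = _block_n_samples(config)
    onsets = trial_onsets(config, config.trials_per_block)
    # each stimulus highlighted exactly n_reps times, in random order
    order = np.repeat(np.arange(config.n_stimuli), config.n_reps)
    rng.shuffle(order)
    signal = _noise(rng, config, n_samples)
    topo = config.topography()
    events = np.empty((config.trials_per_block, 3), dtype=np.int64)
    for i, (stim, onset) in enumerate(zip(order, onsets)):
        is_target = int(stim == target_id)
        events[i] = (stim, onset, is_target)
        if is_target and config.p300_amplitude > 0:
            if config.p300_prob < 1.0 and rng.uniform() >= config.p300_prob:
                continue  # attention lapse: no evoked response this trial
            lat = config.p300_latency
            if config.latency_jitter_sd > 0:
                lat += rng.normal(0.0, config.latency_jitter_sd)
            bump = _evoked_bump(config, n_samples, onset, lat)
            signal += config.p300_amplitude * topo[:, None] * bump[None, :]
    return BlockRecording(signal=signal, events=events, target_id=int(target_id))


def generate_session(config: SyntheticConfig, seed: int | None = None) -> SessionRecording:
    """Generate one subject's full session (training + test blocks).

    Per block one target stimulus is drawn uniformly; target highlights get
    the evoked template added on top of background noise.  Fixed
    ``(config, seed)`` gives bit-identical output.
    """
    rng = np.random.default_rng(config.seed if seed is None else seed)
    train = [
        _generate_block(config, rng.integers(config.n_stimuli), rng)
        for _ in range(config.n_train_blocks)
    ]
    test = [
        _generate_block(config, rng.integers(config.n_stimuli), rng)
        for _ in range(config.n_test_blocks)
    ]
    return SessionRecording(config=config, train_blocks=train, test_blocks=test)


def generate_cohort(configs: list[SyntheticConfig], seed: int = 0) -> list[SessionRecording]:
    """Generate independent sessions for a cohort of subjects.

    Per-subject seeds are spawned deterministically from the master ``seed``
    via :class:`numpy.random.SeedSequence`, so a cohort is reproducible as a
    whole while subjects stay statistically independent.
    """
    if len(configs) == 0:
        raise ValueError("cohort needs at least one subject config")
    children = np.random.SeedSequence(seed).spawn(len(configs))
    return [
        generate_session(cfg, seed=child.generate_state(1)[0] % (2**31))
        for cfg, child in zip(configs, children)
    ]


def generate_toy_2d(
    n_minority: int,
    n_majority: int,
    separation: float = 2.0,
    seed: int = 0,
    spread: float = 1.0,
) -> ToyDataset:
    """Two isotropic Gaussian clusters with controllable overlap.

    ``separation`` is the distance between cluster means in units of
    ``spread``; small values give the overlapping borderline situation the
    DANGER-set construction of borderline oversampling targets.
    """
    if n_minority < 0 or n_majority < 0:
        raise ValueError("class sizes must be >= 0")
    rng = np.random.default_rng(seed)
    maj_mean = np.zeros(2)
    min_mean = np.array([separation * spread, 0.0])
    maj = rng.normal(0.0, spread, size=(n_majority, 2)) + maj_mean
    mino = rng.normal(0.0, spread, size=(n_minority, 2)) + min_mean
    points = np.vstack([maj, mino])
    labels = np.concatenate([np.zeros(n_majority, dtype=int), np.ones(n_minority, dtype=int)])
    return ToyDataset(
        points=points,
        labels=labels,
        seed=seed,
        minority_mean=tuple(min_mean),
        majority_mean=tuple(maj_mean),
        spread=spread,
    )


# ---------------------------------------------------------------------------
# Disk round-trip: one directory per session with per-block .npy arrays and a
# JSON sidecar carrying events, config and seed.


def save_session(session: SessionRecording, path: str | Path) -> None:
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    meta: dict = {"config": session.config.to_dict(), "train": [], "test": []}
    for split, blocks in (("train", session.train_blocks), ("test", session.test_blocks)):
        for i, blk in enumerate(blocks):
            fname = f"{split}_{i:03d}.npy"
            np.save(path / fname, blk.signal)
            meta[split].append(
                {
                    "file": fname,
                    "target_id": blk.target_id,
                    "events": blk.events.tolist(),
                }
            )
    (path / "session.json").write_text(json.dumps(meta))


def load_session(path: str | Path) -> SessionRecording:
    path = Path(path)
    meta = json.loads((path / "session.json").read_text())
    config = SyntheticConfig(**{
        k: (tuple(v) if k in ("channel_topography", "noise_freqs") and v is not None else v)
        for k, v in meta["config"].items()
    })
    blocks: dict[str, list[BlockRecording]] = {}
    for split in ("train", "test"):
        blocks[split] = [
            BlockRecording(
                signal=np.load(path / rec["file"]),
                events=np.asarray(rec["events"], dtype=np.int64),
                target_id=rec["target_id"],
            )
            for rec in meta[split]
        ]
    return SessionRecording(config=config, train_blocks=blocks["train"], test_blocks=blocks["test"])


def save_toy(toy: ToyDataset, path: str | Path) -> None:
    """Delimited text: x <TAB> y <TAB> label, one point per row."""
    arr = np.column_stack([toy.points, toy.labels])
    np.savetxt(path, arr, delimiter="\t", header="x\ty\tlabel", comments="")


def load_toy(path: str | Path) -> ToyDataset:
    arr = np.loadtxt(path, delimiter="\t", skiprows=1, ndmin=2)
    if arr.size == 0:
        arr = arr.reshape(0, 3)
    return ToyDataset(points=arr[:, :2], labels=arr[:, 2].astype(int), seed=-1)
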