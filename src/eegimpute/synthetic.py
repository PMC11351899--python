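"""Synthetic EEG-amplitude-like tables with known ground truth.

Real scalp-EEG amplitude tables show strong cross-channel correlation
because every electrode sees a mixture of a few underlying cortical
sources.  The generator reproduces exactly that structure: a small number
of latent band-limited oscillations (sinusoid pairs with frequencies in
the 1-30 Hz EEG bands plus AR(1) roughness) are linearly mixed into the
channels, squashed by tanh so amplitudes stay inside (-1, 1), and a
continuous cognitive-state index is formed as an affine combination of the
channels rescaled to roughly the [-2.03, 1.78] range.

Because channels share latent sources, a masked channel is predictable
from the others — the property the transformer imputer exploits — and the
pre-masking table is retained, so every imputed cell can be scored against
its true value.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .tabular import TabularDataset

TIMESTAMP_COL = "Timestamp"
TARGET_COL = "Cognitive_State_Index"


@dataclass(frozen=True)
class SyntheticConfig:
    """Conditions for one synthetic recording.

    ``channel_noise_sd`` perturbs each channel before the tanh squash
    (sensor noise); ``target_noise_sd`` is additive on the index.  With
    both at zero the index is an exact affine function of the channels.
    """

    n_rows: int = 2000
    n_channels: int = 19
    n_latent: int = 4
    sampling_rate: float = 256.0
    channel_noise_sd: float = 0.05
    target_noise_sd: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_rows < 2:
            raise ValueError("n_rows must be >= 2")
        if not 1 <= self.n_latent <= self.n_channels:
            raise ValueError("need 1 <= n_latent <= n_channels")
        if self.channel_noise_sd < 0 or self.target_noise_sd < 0:
            raise ValueError("noise standard deviations must be >= 0")
        if self.sampling_rate <= 0:
            raise ValueError("sampling_rate must be positive")


@dataclass(frozen=True)
class MissingnessSpec:
    """How to knock cells out of a complete table.

    mechanism ``mcar`` masks each eligible cell independently with
    probability ``rate``; ``burst`` masks contiguous per-channel runs
    (geometric lengths, mean ``burst_len_mean``) until the overall masked
    fraction reaches ``rate``, mimicking electrode drop-outs.  Columns in
    ``exempt_cols`` are never masked and at least ``min_complete_rows``
    fully observed rows must survive (the whole mask is redrawn otherwise).
    """

    mechanism: str = "mcar"
    rate: float = 0.1
    burst_len_mean: float = 5.0
    exempt_cols: tuple[str, ...] = (TIMESTAMP_COL, TARGET_COL)
    min_complete_rows: int = 30
    seed: int = 0
    max_retries: int = 20

    def __post_init__(self) -> None:
        if self.mechanism not in ("mcar", "burst"):
            raise ValueError(f"unknown mechanism {self.mechanism!r}")
        if not 0.0 <= self.rate < 1.0:
            raise ValueError("rate must be in [0, 1)")
        if self.burst_len_mean < 1:
            raise ValueError("burst_len_mean must be >= 1")
        if self.min_complete_rows < 1:
            raise ValueError("min_complete_rows must be >= 1")


@dataclass(frozen=True)
class SyntheticTruth:
    """Complete table, its masked twin, and the withheld true values."""

    complete: TabularDataset
    masked: TabularDataset
    held_out: tuple[tuple[int, str, float], ...]


def generate_complete(cfg: SyntheticConfig) -> TabularDataset:
    """Deterministically generate a complete EEG-like table from a config."""
    rng = np.random.default_rng(cfg.seed)
    n, c, k = cfg.n_rows, cfg.n_channels, cfg.n_latent
    t = np.arange(n) / cfg.sampling_rate

    # latent sources: two EEG-band sinusoids each, plus AR(1) roughness
    sources = np.empty((n, k))
    for j in range(k):
        freqs = rng.uniform(1.0, 30.0, size=2)
        phases = rng.uniform(0.0, 2 * np.pi, size=2)
        amps = rng.uniform(0.5, 1.0, size=2)
        wave = sum(a * np.sin(2 * np.pi * f * t + p)
                   for f, p, a in zip(freqs, phases, amps))
        ar = np.empty(n)
        eps = rng.normal(0.0, 0.3, size=n)
        ar[0] = eps[0]
        for i in range(1, n):
            ar[i] = 0.95 * ar[i - 1] + eps[i]
        src = wave + ar
        sources[:, j] = (src - src.mean()) / src.std()

    mixing = rng.normal(size=(k, c))
    mixing /= np.linalg.norm(mixing, axis=0, keepdims=True)
    pre = sources @ mixing
    if cfg.channel_noise_sd > 0:
        pre = pre + rng.normal(0.0, cfg.channel_noise_sd, size=pre.shape)
    channels = np.tanh(pre)

    # index: affine map of channels with realised range ~ [-2.03, 1.78]
    w_raw = rng.normal(size=c)
    raw = channels @ w_raw
    lo, hi = raw.min(), raw.max()
    scale = (1.78 - (-2.03)) / (hi - lo)
    intercept = -2.03 - scale * lo
    index = scale * raw + intercept
    if cfg.target_noise_sd > 0:
        index = index + rng.normal(0.0, cfg.target_noise_sd, size=n)

    names = ([TIMESTAMP_COL] + [f"Channel_{j + 1}" for j in range(c)]
             + [TARGET_COL])
    values = np.column_stack([t, channels, index])
    return TabularDataset(values, names, np.arange(n))


def channel_columns(ds: TabularDataset) -> list[str]:
    """Channel-amplitude feature columns of a generated table."""
    return [c for c in ds.col_names if c.startswith("Channel_")]


def _draw_mask(shape: tuple[int, int], eligible: np.ndarray,
               spec: MissingnessSpec, rng: np.random.Generator) -> np.ndarray:
    n_rows, _ = shape
    mask = np.zeros(shape, dtype=bool)
    cols = np.flatnonzero(eligible)
    if spec.rate == 0.0 or cols.size == 0:
        return mask
    if spec.mechanism == "mcar":
        mask[:, cols] = rng.random((n_rows, cols.size)) < spec.rate
        return mask
    # burst: contiguous per-channel runs until the target fraction is hit
    target = int(round(spec.rate * n_rows * cols.size))
    p = 1.0 / spec.burst_len_mean
    guard = 0
    while mask[:, cols].sum() < target and guard < 100_000:
        j = rng.choice(cols)
        start = rng.integers(0, n_rows)
        length = rng.geometric(p)
        mask[start:start + length, j] = True
        guard += 1
    return mask


def inject_missingness(ds: TabularDataset, spec: MissingnessSpec
                       ) -> SyntheticTruth:
    """Mask cells of a complete table, retaining the truth of every cell.

    Deterministic given ``spec.seed``.  Raises if the rate and the
    ``min_complete_rows`` floor cannot be satisfied jointly within
    ``max_retries`` redraws.
    """
    if ds.mask.any():
        raise ValueError("input table must be complete")
    # default exempts name the generator's bookkeeping columns; a bespoke
    # table may lack them, so only exempts that exist are enforced
    eligible = np.array([c not in spec.exempt_cols for c in ds.col_names])

    rng = np.random.default_rng(spec.seed)
    for _ in range(spec.max_retries):
        mask = _draw_mask(ds.values.shape, eligible, spec, rng)
        n_complete = int((~mask.any(axis=1)).sum())
        if n_complete >= spec.min_complete_rows:
            break
    else:
        raise ValueError(
            f"could not keep {spec.min_complete_rows} complete rows at "
            f"rate {spec.rate} after {spec.max_retries} redraws")

    masked_values = ds.values.copy()
    masked_values[mask] = np.nan
    masked = TabularDataset(masked_values, list(ds.col_names),
                            ds.row_ids.copy(), mask)
    rows, cols = np.nonzero(mask)
    held_out = tuple(
        (int(ds.row_ids[i]), ds.col_names[j], float(ds.values[i, j]))
        for i, j in zip(rows, cols))
    return SyntheticTruth(complete=ds.copy(), masked=masked,
                          held_out=held_out)
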