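"""Structured cycle database, waveform PCA with variance-based retention, and
multi-component reconstruction (MCR).

Every propulsion cycle becomes one row of a fixed-layout feature vector:

    [ time(101) | x(76 x 101) | y(76 x 101) | z(76 x 101) | upper(101) | lower(101) | rta(101) ]

i.e. 101 x (1 + 228 + 3) = 23,432 features. The time block is the cycle's
un-normalized time axis (0 .. duration), so cadence variation enters the
decomposition; coordinate blocks are millimetres in the aligned frame; power
blocks are mass-normalized W/kg with shoulders summed into "upper" and knees
into "lower" (RTA kept separate at this stage). Unit blocks are amplitude
normalized — one scalar each — so seconds, millimetres and W/kg occupy
comparable ranges before the (column-mean-centered, unstandardized) PCA.

MCR rebuilds exaggerated "beginner" and "elite" avatars from the mean cycle
plus selected loading vectors weighted by extreme-percentile scores:
x_hat = x_bar + sum_i u_i * z_i(95th or 5th), the tail chosen by the sign of
each PC's relationship with skill.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .body import PointModel
from .preprocess import N_SAMPLES, Cycle

log = logging.getLogger(__name__)

N_POINTS = 76
N_COORD_CHANNELS = 3 * N_POINTS  # 228
N_POWER_CHANNELS = 3  # upper, lower, rta
N_CHANNELS = 1 + N_COORD_CHANNELS + N_POWER_CHANNELS  # 232
N_FEATURES = N_SAMPLES * N_CHANNELS  # 23,432

_TIME = slice(0, N_SAMPLES)
_COORDS = slice(N_SAMPLES, N_SAMPLES * (1 + N_COORD_CHANNELS))
_POWER = slice(N_SAMPLES * (1 + N_COORD_CHANNELS), N_FEATURES)

BLOCKS = {"time": _TIME, "coords": _COORDS, "power": _POWER}


def row_from_cycle(cycle: Cycle) -> np.ndarray:
    """Flatten one cycle into the fixed database layout."""
    time_block = cycle.time_norm * cycle.duration_s
    coords = np.transpose(cycle.coords, (2, 1, 0)).ravel()  # axis, point, sample
    p = cycle.power / cycle.meta.body_mass_kg
    upper = p[:, 0] + p[:, 1]
    lower = p[:, 2] + p[:, 3]
    rta = p[:, 4]
    return np.concatenate([time_block, coords, upper, lower, rta])


def unpack_row(row: np.ndarray) -> dict[str, np.ndarray]:
    """Inverse of row_from_cycle: time (101,), coords (101, 76, 3) mm,
    power (101, 3) W/kg (upper, lower, rta)."""
    row = np.asarray(row, dtype=float)
    if row.shape != (N_FEATURES,):
        raise ValueError(f"row must have {N_FEATURES} features, got {row.shape}")
    time_block = row[_TIME]
    coords = row[_COORDS].reshape(3, N_POINTS, N_SAMPLES).transpose(2, 1, 0)
    power = row[_POWER].reshape(N_POWER_CHANNELS, N_SAMPLES).T
    return {"time": time_block, "coords": coords, "power": power}


@dataclass
class CycleDatabase:
    """n_cycles x 23,432 feature matrix plus per-row metadata."""

    X: np.ndarray
    meta: pd.DataFrame  # participant, skill, effort, technique, cycle_index, duration_s
    block_scalars: dict[str, float] | None = None  # None -> raw (unnormalized)

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        if self.X.ndim != 2 or self.X.shape[1] != N_FEATURES:
            raise ValueError(f"database must have exactly {N_FEATURES} columns")
        if len(self.meta) != len(self.X):
            raise ValueError("metadata rows must match database rows")

    @property
    def n_cycles(self) -> int:
        return len(self.X)


def build_database(cycles: list[Cycle]) -> CycleDatabase:
    """Assemble the raw (unnormalized) database from time-normalized cycles."""
    if not cycles:
        raise ValueError("no cycles to assemble")
    X = np.stack([row_from_cycle(c) for c in cycles])
    meta = pd.DataFrame({
        "participant": [c.meta.participant for c in cycles],
        "skill": [c.meta.skill for c in cycles],
        "effort": [c.meta.effort for c in cycles],
        "technique": [c.technique for c in cycles],
        "cycle_index": [c.cycle_index for c in cycles],
        "duration_s": [c.duration_s for c in cycles],
        "body_mass_kg": [c.meta.body_mass_kg for c in cycles],
    })
    return CycleDatabase(X=X, meta=meta, block_scalars=None)


def amplitude_normalize(db: CycleDatabase) -> CycleDatabase:
    """Scale each unit block by one scalar so its pooled amplitude range
    matches the coordinate block's range; scalars are stored for exact
    inversion. A zero-range block keeps scalar 1 with a warning.
    """
    if db.block_scalars is not None:
        raise ValueError("database is already amplitude-normalized")
    ranges = {name: float(np.ptp(db.X[:, sl])) for name, sl in BLOCKS.items()}
    target = ranges["coords"]
    scalars = {}
    for name, rng in ranges.items():
        if rng == 0.0 or target == 0.0:
            if rng == 0.0:
                log.warning("block %r has zero amplitude range; scalar set to 1", name)
            scalars[name] = 1.0
        else:
            scalars[name] = target / rng
    X = db.X.copy()
    for name, sl in BLOCKS.items():
        X[:, sl] *= scalars[name]
    return CycleDatabase(X=X, meta=db.meta.copy(), block_scalars=scalars)


def invert_normalization(db: CycleDatabase) -> CycleDatabase:
    if db.block_scalars is None:
        raise ValueError("database is not amplitude-normalized")
    X = db.X.copy()
    for name, sl in BLOCKS.items():
        X[:, sl] /= db.block_scalars[name]
    return CycleDatabase(X=X, meta=db.meta.copy(), block_scalars=None)


def unscale_vector(x: np.ndarray, block_scalars: dict[str, float]) -> np.ndarray:
    """Invert the block amplitude scaling on a single feature vector."""
    out = np.asarray(x, dtype=float).copy()
    for name, sl in BLOCKS.items():
        out[sl] /= block_scalars[name]
    return out


@dataclass
class PCModel:
    """Column-mean-centered PCA of the cycle database."""

    mean: np.ndarray  # (p,)
    loadings: np.ndarray  # (k, p) orthonormal rows, descending variance
    explained_var: np.ndarray  # (k,) percentages summing to 100 (if var > 0)
    scores: np.ndarray  # (n, k)
    retained_k: int
    block_scalars: dict[str, float] | None = None
    meta: pd.DataFrame | None = None

    @property
    def cumulative_var(self) -> np.ndarray:
        return np.cumsum(self.explained_var)


def _fix_signs(loadings: np.ndarray, scores: np.ndarray):
    """Make each loading's largest-magnitude element positive so score signs
    (and hence the 95/5 tail choice) are reproducible across runs."""
    idx = np.argmax(np.abs(loadings), axis=1)
    signs = np.sign(loadings[np.arange(len(loadings)), idx])
    signs[signs == 0] = 1.0
    return loadings * signs[:, None], scores * signs[None, :]


def fit_pca(db: CycleDatabase | np.ndarray, retention_pct: float = 90.0) -> PCModel:
    """PCA via SVD of the centered matrix (no per-column standardization —
    unit blocks were amplitude-normalized instead)."""
    if isinstance(db, CycleDatabase):
        X = db.X
        scalars, meta = db.block_scalars, db.meta
    else:
        X = np.asarray(db, dtype=float)
        scalars, meta = None, None
    n = len(X)
    if n < 2:
        raise ValueError("PCA needs at least 2 cycles")
    mean = X.mean(axis=0)
    Xc = X - mean
    u, s, vt = np.linalg.svd(Xc, full_matrices=False)
    variances = s**2 / (n - 1)
    total = variances.sum()
    if total == 0:
        explained = np.zeros_like(variances)
    else:
        explained = 100.0 * variances / total
    loadings, scores = _fix_signs(vt, u * s)
    if total == 0:
        retained = 0
    else:
        retained = retain_components(explained, threshold_pct=retention_pct)
    return PCModel(mean=mean, loadings=loadings, explained_var=explained,
                   scores=scores, retained_k=retained, block_scalars=scalars,
                   meta=meta)


def retain_components(explained_var, threshold_pct: float = 90.0) -> int:
    """Smallest K whose cumulative explained variance reaches the threshold.

    If the percentages never reach it, all components are retained with a
    warning.
    """
    ev = np.asarray(explained_var, dtype=float)
    if np.any(ev < 0):
        raise ValueError("explained variances must be nonnegative")
    cum = np.cumsum(ev)
    reached = np.nonzero(cum >= threshold_pct - 1e-9)[0]
    if reached.size == 0:
        log.warning("cumulative variance %.1f%% never reaches %.1f%%; retaining all %d",
                    cum[-1] if len(cum) else 0.0, threshold_pct, len(ev))
        return len(ev)
    return int(reached[0]) + 1


def reconstruct_rows(model: PCModel, scores: np.ndarray | None = None,
                     k: int | None = None) -> np.ndarray:
    """x_hat = mean + scores[:, :k] @ loadings[:k] (all components by default)."""
    z = model.scores if scores is None else np.asarray(scores)
    k = z.shape[1] if k is None else k
    return model.mean + z[:, :k] @ model.loadings[:k]


@dataclass
class Reconstruction:
    """Beginner/elite avatar pair from extreme-percentile PC scores."""

    x_beginner: np.ndarray
    x_elite: np.ndarray
    pcs: tuple[int, ...]  # 0-based PC indices
    directions: tuple[int, ...]  # +1 / -1 skill relationship per PC
    z_elite: np.ndarray = field(default_factory=lambda: np.array([]))
    z_beginner: np.ndarray = field(default_factory=lambda: np.array([]))
    block_scalars: dict[str, float] | None = None

    def unscaled(self, which: str) -> dict[str, np.ndarray]:
        """Animation form: block scaling inverted, reshaped to 101-sample
        channels (time, coords (101,76,3) mm, power (101,3) W/kg)."""
        x = {"beginner": self.x_beginner, "elite": self.x_elite}[which]
        if self.block_scalars is not None:
            x = unscale_vector(x, self.block_scalars)
        return unpack_row(x)


def mcr_reconstruct(model: PCModel, pcs, directions) -> Reconstruction:
    """Multi-component reconstruction per the extreme-percentile rule.

    For each selected PC, the elite avatar uses the 95th percentile of the
    score distribution when the PC's skill relationship is positive and the
    5th when negative; the beginner avatar takes the opposite tail.
    Percentiles use linear interpolation between order statistics. An empty
    selection returns the mean cycle as both avatars with a warning.
    """
    pcs = tuple(int(p) for p in pcs)
    directions = tuple(int(np.sign(d)) for d in directions)
    if len(pcs) != len(directions):
        raise ValueError("one direction per selected PC required")
    if any(d == 0 for d in directions):
        raise ValueError("directions must be +1 or -1")
    if any(p < 0 or p >= model.retained_k for p in pcs):
        raise ValueError(f"selected PCs {pcs} outside the retained range "
                         f"(K={model.retained_k})")
    if not pcs:
        log.warning("empty PC selection: both avatars equal the mean cycle")
        empty = np.array([])
        return Reconstruction(x_beginner=model.mean.copy(), x_elite=model.mean.copy(),
                              pcs=(), directions=(), z_elite=empty, z_beginner=empty,
                              block_scalars=model.block_scalars)
    z_el = np.empty(len(pcs))
    z_be = np.empty(len(pcs))
    for i, (p, d) in enumerate(zip(pcs, directions)):
        col = model.scores[:, p]
        if np.ptp(col) == 0:
            raise ValueError(f"PC{p + 1} score distribution is degenerate")
        hi, lo = np.percentile(col, [95.0, 5.0])
        z_el[i] = hi if d > 0 else lo
        z_be[i] = lo if d > 0 else hi
    u_sel = model.loadings[list(pcs)]
    return Reconstruction(
        x_beginner=model.mean + z_be @ u_sel,
        x_elite=model.mean + z_el @ u_sel,
        pcs=pcs, directions=directions, z_elite=z_el, z_beginner=z_be,
        block_scalars=model.block_scalars)


def export_animation(rec: Reconstruction, model: PointModel, path: str | Path,
                     which: str = "elite") -> None:
    """Write one avatar as a 101-frame long table of the 76-point cloud.

    Numbers are identical to ``Reconstruction.unscaled(which)``.
    """
    data = rec.unscaled(which)
    coords = data["coords"]
    rows = []
    n = coords.shape[0]
    frames_idx = np.repeat(np.arange(n), N_POINTS)
    rows = pd.DataFrame({
        "frame": frames_idx,
        "time_s": np.repeat(data["time"], N_POINTS),
        "label": np.tile(np.asarray(model.labels, dtype=object), n),
        "x_mm": coords[:, :, 0].ravel(),
        "y_mm": coords[:, :, 1].ravel(),
        "z_mm": coords[:, :, 2].ravel(),
    })
    rows.to_csv(path, index=False)


def read_animation(path: str | Path, model: PointModel) -> np.ndarray:
    """Read an exported avatar back to a (101, 76, 3) array."""
    df = pd.read_csv(path)
    n = df["frame"].nunique()
    coords = np.full((n, N_POINTS, 3), np.nan)
    codes = pd.Categorical(df["label"], categories=list(model.labels)).codes
    coords[df["frame"].to_numpy(), codes, :] = df[["x_mm", "y_mm", "z_mm"]].to_numpy()
    return coords
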