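"""Reading regional time series, assembling analysis-ready segments, and QC.

Regional scans are delimited-text matrices (rows = timepoints, columns =
regions) with side-car metadata. Because directed connectivity is estimated
from lagged regressions, every manipulation that splices rows (decimation,
block concatenation, motion scrubbing) records segment boundaries so that no
lagged (predictor, response) pair is ever formed across a splice junction.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from statsmodels.stats.stattools import durbin_watson
from statsmodels.tsa.stattools import adfuller

__all__ = [
    "RegionalScan",
    "MotionTrace",
    "StationarityReport",
    "read_scan",
    "write_scan",
    "truncate_to_common_length",
    "decimate_concat",
    "concat_blocks",
    "framewise_displacement",
    "scrub",
    "stationarity_tests",
]


@dataclass
class RegionalScan:
    """One scan's time x regions matrix plus metadata and segment structure.

    ``segments`` is an ordered list of half-open ``[start, end)`` row
    intervals partitioning the retained rows into blocks that were contiguous
    in the original recording.
    """

    data: np.ndarray
    tr: float
    subject_id: str = ""
    condition: str = ""
    run: str = ""
    segments: list[tuple[int, int]] = field(default_factory=list)
    region_names: list[str] | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("data must be a 2-D (time x regions) matrix")
        if not self.segments:
            self.segments = [(0, self.n_timepoints)]
        self._check_segments()

    def _check_segments(self) -> None:
        prev_end = 0
        for start, end in self.segments:
            if start != prev_end or end <= start:
                raise ValueError(
                    f"segments must be sorted, disjoint and cover all rows; got {self.segments}"
                )
            prev_end = end
        if prev_end != self.n_timepoints:
            raise ValueError(
                f"segments cover {prev_end} rows but scan has {self.n_timepoints}"
            )

    @property
    def n_timepoints(self) -> int:
        return self.data.shape[0]

    @property
    def n_regions(self) -> int:
        return self.data.shape[1]

    def segment_arrays(self) -> list[np.ndarray]:
        return [self.data[s:e] for s, e in self.segments]

    def with_data(self, data: np.ndarray, segments=None, **meta) -> "RegionalScan":
        kwargs = dict(
            tr=self.tr,
            subject_id=self.subject_id,
            condition=self.condition,
            run=self.run,
            region_names=self.region_names,
        )
        kwargs.update(meta)
        return RegionalScan(
            data=data,
            segments=list(segments) if segments is not None else [(0, len(data))],
            **kwargs,
        )


@dataclass
class MotionTrace:
    """Per-frame rigid-body motion: translations (mm) then rotations (rad)."""

    translations: np.ndarray  # (T, 3), mm
    rotations: np.ndarray  # (T, 3), radians

    def __post_init__(self) -> None:
        self.translations = np.atleast_2d(np.asarray(self.translations, float))
        self.rotations = np.atleast_2d(np.asarray(self.rotations, float))
        if self.translations.shape != self.rotations.shape or self.translations.shape[1] != 3:
            raise ValueError("translations and rotations must both be (T, 3)")
        if not (np.isfinite(self.translations).all() and np.isfinite(self.rotations).all()):
            raise ValueError("motion parameters must be finite")

    @property
    def n_frames(self) -> int:
        return self.translations.shape[0]


@dataclass
class StationarityReport:
    """Result of the four stationarity / model-adequacy diagnostics."""

    log_spectral_radius: float
    consistency_pct: float
    dw_pass_fraction: float
    adf_pass_fraction: float
    passed: dict[str, bool]

    def all_passed(self) -> bool:
        return all(self.passed.values())

    def to_dict(self) -> dict:
        return {
            "log_spectral_radius": self.log_spectral_radius,
            "consistency_pct": self.consistency_pct,
            "dw_pass_fraction": self.dw_pass_fraction,
            "adf_pass_fraction": self.adf_pass_fraction,
            "passed": dict(self.passed),
        }


def read_scan(
    path: str | Path,
    tr: float,
    subject_id: str = "",
    condition: str = "",
    run: str = "",
    sep: str | None = None,
) -> RegionalScan:
    """Read a delimited time x regions text file into a :class:`RegionalScan`.

    A header row of region names is detected automatically (first row not
    fully numeric). The returned scan has a single segment covering all rows.
    """
    path = Path(path)
    if sep is None:
        sep = "\t" if path.suffix.lower() in {".tsv", ".txt"} else ","
    first = pd.read_csv(path, sep=sep, header=None, nrows=1)
    has_header = not all(_is_number(v) for v in first.iloc[0])
    try:
        df = pd.read_csv(path, sep=sep, header=0 if has_header else None)
        data = df.to_numpy(dtype=float)
    except (ValueError, TypeError) as exc:
        raise ValueError(f"non-numeric cell in {path}: {exc}") from exc
    if not np.isfinite(data).all():
        raise ValueError(f"non-finite values in {path}")
    t, r = data.shape
    if t <= r:
        raise ValueError(
            f"scan has T={t} timepoints for R={r} regions; need T > R for VAR estimation"
        )
    names = [str(c) for c in df.columns] if has_header else None
    return RegionalScan(
        data=data, tr=tr, subject_id=subject_id, condition=condition, run=run,
        region_names=names,
    )


def write_scan(scan: RegionalScan, path: str | Path, with_sidecar: bool = True) -> None:
    """Write a scan as TSV plus a JSON metadata side-car (``<path>.json``)."""
    path = Path(path)
    df = pd.DataFrame(scan.data, columns=scan.region_names)
    df.to_csv(path, sep="\t", index=False, header=scan.region_names is not None)
    if with_sidecar:
        meta = {
            "tr": scan.tr,
            "subject_id": scan.subject_id,
            "condition": scan.condition,
            "run": scan.run,
            "segments": [list(s) for s in scan.segments],
        }
        Path(str(path) + ".json").write_text(json.dumps(meta, indent=1))


def _is_number(v) -> bool:
    try:
        float(v)
        return True
    except (TypeError, ValueError):
        return False


def truncate_to_common_length(scans: Sequence[RegionalScan]) -> list[RegionalScan]:
    """Truncate every scan to the minimum length over the input scans.

    Connectivity magnitudes depend on the number of samples used in the
    estimation, so scans compared by a classifier are first cut to a common
    length. The initial rows are kept; segment lists are re-clipped.
    """
    if len(scans) < 2:
        raise ValueError("need at least two scans to truncate to a common length")
    t_min = min(s.n_timepoints for s in scans)
    out = []
    for s in scans:
        segs = [(a, min(b, t_min)) for a, b in s.segments if a < t_min]
        out.append(s.with_data(s.data[:t_min], segments=segs))
    return out


def decimate_concat(scan: RegionalScan, factor: int, offset: int = 0) -> RegionalScan:
    """Split a scan into ``factor`` interleaved subsampled series and concatenate.

    Row k of phase q is original row ``offset + q + k*factor`` (within each
    original segment), so the output retains every original row exactly once
    (for ``offset = 0``) while each phase is a series sampled at
    ``factor * tr``. Segment boundaries are inserted at every concatenation
    junction so no lagged pair spans a junction.
    """
    if factor < 2:
        raise ValueError("decimation factor must be >= 2")
    blocks: list[np.ndarray] = []
    for q in range(factor):
        for a, b in scan.segments:
            block = scan.data[a:b][(offset + q) % factor :: factor]
            if len(block):
                blocks.append(block)
    segs, pos = [], 0
    for blk in blocks:
        segs.append((pos, pos + len(blk)))
        pos += len(blk)
    return scan.with_data(np.vstack(blocks), segments=segs, tr=scan.tr * factor)


def concat_blocks(scan: RegionalScan, blocks: Sequence[tuple[int, int]]) -> RegionalScan:
    """Extract frame intervals (e.g. task blocks) and concatenate them.

    Block order is preserved and each block becomes one segment, so lagged
    regressions never span the junction between two non-contiguous blocks.
    """
    prev_end = -1
    for a, b in blocks:
        if a < 0 or b > scan.n_timepoints or b <= a:
            raise ValueError(f"block [{a}, {b}) outside scan of length {scan.n_timepoints}")
        if a < prev_end:
            raise ValueError("blocks must be disjoint and sorted")
        prev_end = b
    parts = [scan.data[a:b] for a, b in blocks]
    segs, pos = [], 0
    for p in parts:
        segs.append((pos, pos + len(p)))
        pos += len(p)
    return scan.with_data(np.vstack(parts), segments=segs)


def framewise_displacement(motion: MotionTrace, rotation_radius_mm: float = 50.0) -> np.ndarray:
    """Per-frame framewise displacement (FD, mm).

    FD[t] = sum of absolute frame-to-frame changes of the three translations
    (mm) plus the three rotations converted to arc length on a sphere of
    radius ``rotation_radius_mm`` (Power-style convention). FD[0] = 0.
    """
    if motion.n_frames < 2:
        raise ValueError("need at least two frames to compute framewise displacement")
    dt = np.abs(np.diff(motion.translations, axis=0)).sum(axis=1)
    dr = np.abs(np.diff(motion.rotations, axis=0)).sum(axis=1) * rotation_radius_mm
    return np.concatenate([[0.0], dt + dr])


def scrub(
    scan: RegionalScan,
    fd: np.ndarray,
    threshold: float = 0.5,
    n_neighbors: int = 1,
) -> RegionalScan:
    """Discard high-motion frames (FD > threshold) plus neighbors on each side.

    Because directed connectivity uses lagged pairs, ``n_neighbors`` frames
    before and after every flagged frame are also removed (one per side for
    the typical model order 1; use the fitted order for p > 1). Remaining
    contiguous runs become segments.
    """
    fd = np.asarray(fd, float)
    if len(fd) != scan.n_timepoints:
        raise ValueError("FD vector length must equal the scan length")
    bad = fd > threshold
    flagged = np.flatnonzero(bad)
    drop = np.zeros(scan.n_timepoints, bool)
    for t in flagged:
        drop[max(0, t - n_neighbors) : t + n_neighbors + 1] = True
    # restrict to frames allowed by the existing segment structure
    keep_rows = []
    new_segs = []
    pos = 0
    for a, b in scan.segments:
        t = a
        while t < b:
            if drop[t]:
                t += 1
                continue
            u = t
            while u < b and not drop[u]:
                u += 1
            keep_rows.append(scan.data[t:u])
            new_segs.append((pos, pos + (u - t)))
            pos += u - t
            t = u
    if not keep_rows:
        raise ValueError("all frames flagged by motion scrubbing; nothing retained")
    return scan.with_data(np.vstack(keep_rows), segments=new_segs)


def stationarity_tests(scan: RegionalScan, model, adf_alpha: str = "5%") -> StationarityReport:
    """Run the four stationarity / model-adequacy diagnostics on a fitted VAR.

    1. stability: log spectral radius of the companion matrix < 0;
    2. consistency: >= 80% of the lag-0/lag-1 correlation structure captured
       by the model (Ding-style consistency statistic);
    3. residual whiteness: Durbin-Watson statistic in (1, 3) for > 90% of the
       regional residual series;
    4. unit roots: ADF statistic below its critical value for > 90% of the
       regional series.
    """
    from . import gc_core  # local import to avoid a cycle

    rho = gc_core.companion_spectral_radius(model)
    log_rho = math.log(rho) if rho > 0 else -math.inf
    stable = log_rho < 0

    # Ding-style consistency: model-implied vs empirical lag-0/lag-1 covariance
    emp = [gc_core.lagged_covariance(scan, lag).matrix for lag in (0, 1)]
    if stable:
        gammas = gc_core.var_autocovariances(model, 1)
        num = sum(np.linalg.norm(g - e, "fro") ** 2 for g, e in zip(gammas, emp))
        den = sum(np.linalg.norm(e, "fro") ** 2 for e in emp)
        consistency_pct = 100.0 * (1.0 - math.sqrt(num / den))
    else:
        consistency_pct = 0.0

    resid = gc_core.var_residuals(scan, model)
    dw = durbin_watson(resid, axis=0)
    dw_frac = float(np.mean((dw > 1.0) & (dw < 3.0)))

    adf_pass = []
    for col in scan.data.T:
        stat, _, _, _, crit, *_ = adfuller(col, autolag="AIC")
        adf_pass.append(stat < crit[adf_alpha])
    adf_frac = float(np.mean(adf_pass))

    return StationarityReport(
        log_spectral_radius=log_rho,
        consistency_pct=consistency_pct,
        dw_pass_fraction=dw_frac,
        adf_pass_fraction=adf_frac,
        passed={
            "stability": stable,
            "consistency": consistency_pct >= 80.0,
            "whiteness": dw_frac > 0.9,
            "adf": adf_frac > 0.9,
        },
    )


def read_motion(path: str | Path, rotations_first: bool = False) -> MotionTrace:
    """Read a 6-column whitespace-delimited motion-parameter file.

    Columns are translations (mm) then rotations (radians) by default;
    ``rotations_first`` flips the convention.
    """
    arr = np.loadtxt(path)
    if arr.ndim != 2 or arr.shape[1] != 6:
        raise ValueError("motion file must have six columns")
    a, b = (arr[:, 3:], arr[:, :3]) if rotations_first else (arr[:, :3], arr[:, 3:])
    return MotionTrace(translations=a, rotations=b)
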