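"""Seed-to-voxel connectivity mapping and statistical thresholding.

Implements the r-map -> t-map -> Bonferroni threshold -> binary map chain
used to identify, per stimulation target, every voxel whose low-frequency
BOLD fluctuation is significantly coupled to the seed across a normative
cohort:

1. average the seed voxels' time courses (``extract_seed_timecourse``),
2. correlate that seed time course with every voxel (``seed_to_voxel_rmap``),
3. variance-stabilise with Fisher's z (``fisher_z``),
4. test the per-subject z values against zero voxelwise (``group_tmap``),
5. threshold at the Bonferroni |t| cutoff and binarise
   (``bonferroni_t_threshold``, ``threshold_binarize``).

All volumes are carried as :class:`StatMap` objects so grid shape, affine
and the statistic's kind travel together through the chain.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy import stats

__all__ = [
    "SubjectScan",
    "SeedMask",
    "StatMap",
    "GridMismatchError",
    "extract_seed_timecourse",
    "seed_to_voxel_rmap",
    "fisher_z",
    "group_tmap",
    "average_r_tmap",
    "bonferroni_t_threshold",
    "threshold_binarize",
]

#: |r| = 1 is clamped to this before atanh so z-maps stay finite.
R_CLAMP = 1.0 - 1e-7


class GridMismatchError(ValueError):
    """Two volumes that must share a grid do not."""


def _check_grid(shape_a, affine_a, shape_b, affine_b, atol: float = 1e-4) -> None:
    if tuple(shape_a) != tuple(shape_b):
        raise GridMismatchError(f"grid shapes differ: {tuple(shape_a)} vs {tuple(shape_b)}")
    if not np.allclose(affine_a, affine_b, atol=atol):
        raise GridMismatchError("affines differ beyond tolerance")


@dataclass
class SubjectScan:
    """One subject's 4-D BOLD volume (x, y, z, t) with its grid geometry."""

    data: np.ndarray
    affine: np.ndarray
    tr_seconds: float = 3.0
    subject_id: str = ""

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        self.affine = np.asarray(self.affine, dtype=np.float64)
        if self.data.ndim != 4:
            raise ValueError("SubjectScan.data must be 4-D (x, y, z, t)")
        if self.data.shape[3] < 8:
            raise ValueError("SubjectScan needs at least 8 time points")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("SubjectScan.data contains non-finite values")

    @property
    def grid_shape(self) -> tuple:
        return self.data.shape[:3]

    @property
    def n_timepoints(self) -> int:
        return self.data.shape[3]


@dataclass
class SeedMask:
    """Binary 3-D region mask for one stimulation target (e.g. ANT, CMT, HC)."""

    name: str
    mask: np.ndarray
    affine: np.ndarray

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask).astype(bool)
        self.affine = np.asarray(self.affine, dtype=np.float64)
        if self.mask.ndim != 3:
            raise ValueError("SeedMask.mask must be 3-D")
        if not self.mask.any():
            raise ValueError(f"SeedMask {self.name!r} is empty")

    @property
    def n_voxels(self) -> int:
        return int(self.mask.sum())


@dataclass
class StatMap:
    """A voxelwise statistic volume: r, z, t or binary.

    ``df`` is carried for t-maps (n_subjects - 1 under the per-subject
    scheme); ``qc`` accumulates counts flagged along the chain, e.g. the
    number of zero-variance voxels forced to r = 0.
    """

    kind: str
    data: np.ndarray
    affine: np.ndarray
    source_seed: str = ""
    df: Optional[int] = None
    qc: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.kind not in ("r", "z", "t", "binary"):
            raise ValueError(f"unknown StatMap kind {self.kind!r}")
        self.data = np.asarray(self.data, dtype=np.float64)
        self.affine = np.asarray(self.affine, dtype=np.float64)
        if self.data.ndim != 3:
            raise ValueError("StatMap.data must be 3-D")
        if self.kind == "r" and np.nanmax(np.abs(self.data), initial=0.0) > 1.0 + 1e-12:
            raise ValueError("r-map values must lie in [-1, 1]")
        if self.kind == "binary":
            uniq = np.unique(self.data)
            if not np.all(np.isin(uniq, (0.0, 1.0))):
                raise ValueError("binary map values must be exactly {0, 1}")
        if self.kind == "t" and self.df is not None and self.df < 1:
            raise ValueError("t-map df must be >= 1")

    @property
    def grid_shape(self) -> tuple:
        return self.data.shape


def extract_seed_timecourse(scan: SubjectScan, seed: SeedMask) -> np.ndarray:
    """Mean time course over the seed's voxels.

    Returns a 1-D array of length ``scan.n_timepoints``: the arithmetic mean
    of the seed voxels' series at each time point.
    """
    _check_grid(scan.grid_shape, scan.affine, seed.mask.shape, seed.affine)
    series = scan.data[seed.mask]          # (n_seed_voxels, t)
    if series.shape[0] == 0:
        raise ValueError(f"seed {seed.name!r} covers no voxels on this grid")
    return series.mean(axis=0)


def seed_to_voxel_rmap(
    scan: SubjectScan, seed_tc: np.ndarray, source_seed: str = ""
) -> StatMap:
    """Voxelwise Pearson correlation of every voxel with the seed time course.

    Zero-variance voxels (or a zero-variance seed) yield r = 0 rather than
    NaN; their count is recorded under ``qc["zero_variance_voxels"]``.
    """
    seed_tc = np.asarray(seed_tc, dtype=np.float64)
    if seed_tc.ndim != 1 or seed_tc.size != scan.n_timepoints:
        raise ValueError("seed time course length must match the scan's t dimension")
    x = scan.data - scan.data.mean(axis=3, keepdims=True)
    s = seed_tc - seed_tc.mean()
    ss = float(np.sqrt((s * s).sum()))
    xnorm = np.sqrt((x * x).sum(axis=3))
    denom = xnorm * ss
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (x * s).sum(axis=3) / denom
    bad = denom == 0
    r[bad] = 0.0
    np.clip(r, -1.0, 1.0, out=r)
    return StatMap(
        kind="r",
        data=r,
        affine=scan.affine,
        source_seed=source_seed,
        qc={"zero_variance_voxels": int(bad.sum())},
    )


def fisher_z(rmap: StatMap) -> StatMap:
    """Fisher variance-stabilising transform z = atanh(r).

    |r| = 1 is clamped to 1 - 1e-7 first; the number of clamped voxels is
    recorded under ``qc["clamped_voxels"]``.
    """
    if rmap.kind != "r":
        raise ValueError("fisher_z expects an r-map")
    r = rmap.data
    clamped = int((np.abs(r) >= 1.0).sum())
    z = np.arctanh(np.clip(r, -R_CLAMP, R_CLAMP))
    qc = dict(rmap.qc)
    qc["clamped_voxels"] = clamped
    return StatMap(kind="z", data=z, affine=rmap.affine,
                   source_seed=rmap.source_seed, qc=qc)


def group_tmap(zmaps: list) -> StatMap:
    """One-sample t of per-subject z values against zero, voxelwise.

    df = n_subjects - 1. Voxels with zero cross-subject variance get a
    signed-infinity sentinel when the mean is nonzero and t = 0 when the
    mean is zero too; both cases are counted in ``qc``.
    """
    if len(zmaps) < 2:
        raise ValueError("group_tmap needs at least 2 subjects")
    first = zmaps[0]
    for zm in zmaps[1:]:
        _check_grid(first.grid_shape, first.affine, zm.grid_shape, zm.affine)
        if zm.kind != "z":
            raise ValueError("group_tmap expects z-maps")
    stack = np.stack([zm.data for zm in zmaps], axis=0)
    n = stack.shape[0]
    mean = stack.mean(axis=0)
    sd = stack.std(axis=0, ddof=1)
    se = sd / np.sqrt(n)
    with np.errstate(invalid="ignore", divide="ignore"):
        t = mean / se
    degenerate = se == 0
    t[degenerate & (mean == 0)] = 0.0
    t[degenerate & (mean > 0)] = np.inf
    t[degenerate & (mean < 0)] = -np.inf
    seed = first.source_seed
    return StatMap(
        kind="t", data=t, affine=first.affine, source_seed=seed, df=n - 1,
        qc={"zero_variance_voxels": int(degenerate.sum())},
    )


def average_r_tmap(rmaps: list) -> StatMap:
    """Alternative group statistic: average the r-maps, then one t per voxel.

    Per-subject r-maps are Fisher-z transformed, averaged across subjects,
    back-transformed to an average r, and converted with the one-correlation
    statistic t = r * sqrt(n - 2) / sqrt(1 - r^2), df = n - 2 where n is the
    subject count. Secondary to the default per-subject scheme.
    """
    if len(rmaps) < 3:
        raise ValueError("average_r_tmap needs at least 3 subjects (df = n - 2)")
    zstack = np.stack([fisher_z(rm).data for rm in rmaps], axis=0)
    n = zstack.shape[0]
    rbar = np.tanh(zstack.mean(axis=0))
    with np.errstate(invalid="ignore", divide="ignore"):
        t = rbar * np.sqrt(n - 2) / np.sqrt(1.0 - rbar ** 2)
    t[np.abs(rbar) >= 1.0] = np.sign(rbar[np.abs(rbar) >= 1.0]) * np.inf
    return StatMap(kind="t", data=t, affine=rmaps[0].affine,
                   source_seed=rmaps[0].source_seed, df=n - 2)


def bonferroni_t_threshold(alpha: float, n_tests: int, df: int) -> float:
    """Two-tailed Bonferroni |t| cutoff for ``n_tests`` voxelwise tests.

    The smallest t* whose two-tailed tail probability under t(df) is at most
    alpha / n_tests. At alpha = 0.05, 67 000 in-brain voxels and df = 999
    this evaluates to about 4.98, consistent with the published whole-brain
    cutoff of 5.1.
    """
    if not 0 < alpha < 1:
        raise ValueError("alpha must lie in (0, 1)")
    if n_tests < 1:
        raise ValueError("n_tests must be >= 1")
    if df < 1:
        raise ValueError("df must be >= 1")
    return float(stats.t.isf(alpha / n_tests / 2.0, df))


def threshold_binarize(tmap: StatMap, t_threshold: float) -> StatMap:
    """Binary map of voxels with |t| >= t_threshold.

    The suprathreshold count is recorded under ``qc["suprathreshold_voxels"]``.
    """
    if tmap.kind != "t":
        raise ValueError("threshold_binarize expects a t-map")
    if not t_threshold > 0:
        raise ValueError("t_threshold must be > 0")
    binary = (np.abs(tmap.data) >= t_threshold).astype(np.float64)
    qc = dict(tmap.qc)
    qc["suprathreshold_voxels"] = int(binary.sum())
    qc["t_threshold"] = float(t_threshold)
    return StatMap(kind="binary", data=binary, affine=tmap.affine,
                   source_seed=tmap.source_seed, qc=qc)
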