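"""Synthetic resting-state phantom with planted seed-network covariance.

Emulates the acquisition geometry of a 3 T normative resting-state cohort —
3 x 3 x 3 mm voxels, 124 time points at TR = 3 s, signal band-limited below
0.08 Hz — on a small synthetic grid, so that the whole connectivity pipeline
can be validated by parameter recovery without any data download.

Generative model
----------------
Each latent network k carries an independent band-limited unit-variance
signal ``s_k(t)`` (white Gaussian noise low-pass filtered, then re-scaled to
unit sample variance, times ``signal_sd``), drawn fresh per subject. A voxel
v inside a region with loadings ``a_vk`` observes

    x_v(t) = sum_k a_vk * s_k(t) + noise_sd * eps_v(t),

with i.i.d. white Gaussian eps. Voxels outside every region carry pure
noise. Because the latents have exactly unit variance, the population
seed-to-voxel correlation has the closed form

    rho = a * sigma_s / sqrt(a^2 * sigma_s^2 + sigma^2)

for a single-network voxel, which the recovery tests exploit.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import nibabel as nib
import numpy as np
import yaml

from .seedmap import SeedMask, SubjectScan

__all__ = [
    "PhantomSpecError",
    "NetworkSpec",
    "RegionSpec",
    "PhantomSpec",
    "lowpass_filter",
    "simulate_bold",
    "write_phantom",
    "read_phantom",
]


class PhantomSpecError(ValueError):
    """A phantom specification violates one of its invariants."""


@dataclass
class NetworkSpec:
    """One latent network: a band-limited signal shared by its regions."""

    name: str
    cutoff_hz: float = 0.08
    signal_sd: float = 1.0


@dataclass
class RegionSpec:
    """A set of voxels with loadings onto one or more latent networks.

    ``voxels`` are 0-based (x, y, z) index triples; ``network_loadings``
    maps network name -> amplitude a (unitless loading on that network's
    latent signal). A region with empty loadings is a pure-noise region.
    """

    name: str
    voxels: Sequence[Tuple[int, int, int]]
    network_loadings: Dict[str, float] = field(default_factory=dict)


@dataclass
class PhantomSpec:
    """Full description of a synthetic multi-subject resting-state dataset."""

    grid_shape: Tuple[int, int, int]
    n_subjects: int
    regions: List[RegionSpec] = field(default_factory=list)
    networks: List[NetworkSpec] = field(default_factory=list)
    n_timepoints: int = 124
    tr_seconds: float = 3.0
    voxel_size_mm: float = 3.0
    noise_sd: float = 1.0
    rng_seed: int = 0

    def __post_init__(self) -> None:
        self.validate()

    @property
    def nyquist_hz(self) -> float:
        return 1.0 / (2.0 * self.tr_seconds)

    @property
    def affine(self) -> np.ndarray:
        aff = np.diag([self.voxel_size_mm] * 3 + [1.0])
        return aff

    def validate(self) -> None:
        if len(self.grid_shape) != 3 or any(g < 1 for g in self.grid_shape):
            raise PhantomSpecError("grid_shape axes must all be >= 1")
        if self.n_subjects < 1:
            raise PhantomSpecError("n_subjects must be >= 1")
        if self.n_timepoints < 8:
            raise PhantomSpecError("n_timepoints must be >= 8")
        if not self.tr_seconds > 0:
            raise PhantomSpecError("tr_seconds must be > 0")
        if not self.noise_sd > 0:
            raise PhantomSpecError("noise_sd must be > 0")
        names = [n.name for n in self.networks]
        if len(set(names)) != len(names):
            raise PhantomSpecError("network names must be unique")
        for net in self.networks:
            if not 0 < net.cutoff_hz <= self.nyquist_hz:
                raise PhantomSpecError(
                    f"network {net.name!r}: cutoff_hz must lie in (0, Nyquist="
                    f"{self.nyquist_hz:g}]"
                )
            if net.signal_sd < 0:
                raise PhantomSpecError(f"network {net.name!r}: signal_sd must be >= 0")
        seen = set()
        rnames = [r.name for r in self.regions]
        if len(set(rnames)) != len(rnames):
            raise PhantomSpecError("region names must be unique")
        for reg in self.regions:
            if len(reg.voxels) == 0:
                raise PhantomSpecError(f"region {reg.name!r} has no voxels")
            for v in reg.voxels:
                if len(v) != 3 or any(
                    not 0 <= v[i] < self.grid_shape[i] for i in range(3)
                ):
                    raise PhantomSpecError(
                        f"region {reg.name!r}: voxel {tuple(v)} outside grid "
                        f"{tuple(self.grid_shape)}"
                    )
                if tuple(v) in seen:
                    raise PhantomSpecError(
                        f"region {reg.name!r}: voxel {tuple(v)} claimed twice"
                    )
                seen.add(tuple(v))
            for net_name, a in reg.network_loadings.items():
                if net_name not in names:
                    raise PhantomSpecError(
                        f"region {reg.name!r} loads on unknown network {net_name!r}"
                    )
                if not np.isfinite(a):
                    raise PhantomSpecError(
                        f"region {reg.name!r}: non-finite loading on {net_name!r}"
                    )

    def region_mask(self, name: str) -> SeedMask:
        """Binary mask for one region, on the phantom's grid."""
        for reg in self.regions:
            if reg.name == name:
                mask = np.zeros(self.grid_shape, dtype=bool)
                idx = tuple(np.array(reg.voxels).T)
                mask[idx] = True
                return SeedMask(name=name, mask=mask, affine=self.affine)
        raise KeyError(name)


def lowpass_filter(
    series: np.ndarray, cutoff_hz: float, tr_seconds: float
) -> np.ndarray:
    """Zero-phase FFT brick-wall low-pass along the last axis.

    The real FFT of the series is taken, every bin with frequency strictly
    above ``cutoff_hz`` is zeroed, and the inverse transform returned. The
    zero-frequency component is untouched, the filter is exactly linear, and
    attenuation at any retained-vs-removed bin boundary is total (leakage of
    an off-bin sinusoid is the only residual energy).
    """
    series = np.asarray(series, dtype=np.float64)
    n = series.shape[-1]
    if n < 8:
        raise ValueError("series must have at least 8 time points")
    nyquist = 1.0 / (2.0 * tr_seconds)
    if cutoff_hz >= nyquist:
        raise ValueError(f"cutoff {cutoff_hz:g} Hz is not below Nyquist {nyquist:g} Hz")
    if cutoff_hz <= 0:
        raise ValueError("cutoff_hz must be > 0")
    freqs = np.fft.rfftfreq(n, d=tr_seconds)
    spectrum = np.fft.rfft(series, axis=-1)
    spectrum[..., freqs > cutoff_hz] = 0.0
    return np.fft.irfft(spectrum, n=n, axis=-1)


def _latent_signal(rng: np.random.Generator, net: NetworkSpec,
                   n_timepoints: int, tr_seconds: float) -> np.ndarray:
    """One band-limited latent series, re-standardised to sd = signal_sd."""
    white = rng.standard_normal(n_timepoints)
    banded = lowpass_filter(white, net.cutoff_hz, tr_seconds)
    banded = banded - banded.mean()
    sd = banded.std(ddof=1)
    if sd == 0:          # pathological: cutoff below first nonzero bin
        return np.zeros(n_timepoints)
    return net.signal_sd * banded / sd


def simulate_bold(
    spec: PhantomSpec, return_latents: bool = False
) -> List[SubjectScan] | Tuple[List[SubjectScan], List[Dict[str, np.ndarray]]]:
    """Generate one synthetic 4-D scan per subject.

    Deterministic given ``spec.rng_seed``: the same spec yields bit-identical
    volumes on every call. With ``return_latents=True`` the per-subject latent
    network signals are returned alongside, for oracle-based validation.
    """
    spec.validate()
    rng = np.random.default_rng(spec.rng_seed)
    shape = tuple(spec.grid_shape)
    scans: List[SubjectScan] = []
    all_latents: List[Dict[str, np.ndarray]] = []
    region_idx = [
        (tuple(np.array(reg.voxels).T), reg.network_loadings) for reg in spec.regions
    ]
    for subj in range(spec.n_subjects):
        latents = {
            net.name: _latent_signal(rng, net, spec.n_timepoints, spec.tr_seconds)
            for net in spec.networks
        }
        data = spec.noise_sd * rng.standard_normal(shape + (spec.n_timepoints,))
        for idx, loadings in region_idx:
            signal = np.zeros(spec.n_timepoints)
            for net_name, a in loadings.items():
                signal += a * latents[net_name]
            data[idx] += signal
        scans.append(
            SubjectScan(
                data=data,
                affine=spec.affine,
                tr_seconds=spec.tr_seconds,
                subject_id=f"sub-{subj:03d}",
            )
        )
        all_latents.append(latents)
    if return_latents:
        return scans, all_latents
    return scans


def write_phantom(scans: List[SubjectScan], spec: PhantomSpec, directory) -> dict:
    """Write the phantom as NIfTI volumes plus a YAML manifest.

    One 4-D NIfTI per subject (``sub-XXX_bold.nii``), one 3-D mask per region
    (``region-<name>_mask.nii``) and ``phantom_manifest.yaml`` describing the
    planted structure. Returns the manifest dictionary.
    """
    os.makedirs(directory, exist_ok=True)
    if len(scans) != spec.n_subjects:
        raise ValueError("scan count does not match spec.n_subjects")
    scan_files = []
    for scan in scans:
        fname = f"{scan.subject_id}_bold.nii"
        nib.Nifti1Image(scan.data, scan.affine).to_filename(
            os.path.join(directory, fname)
        )
        scan_files.append(fname)
    mask_files = {}
    for reg in spec.regions:
        seed = spec.region_mask(reg.name)
        fname = f"region-{reg.name}_mask.nii"
        nib.Nifti1Image(seed.mask.astype(np.uint8), spec.affine).to_filename(
            os.path.join(directory, fname)
        )
        mask_files[reg.name] = fname
    manifest = {
        "grid_shape": list(spec.grid_shape),
        "voxel_size_mm": spec.voxel_size_mm,
        "n_subjects": spec.n_subjects,
        "n_timepoints": spec.n_timepoints,
        "tr_seconds": spec.tr_seconds,
        "noise_sd": spec.noise_sd,
        "rng_seed": spec.rng_seed,
        "networks": [
            {"name": n.name, "cutoff_hz": n.cutoff_hz, "signal_sd": n.signal_sd}
            for n in spec.networks
        ],
        "regions": [
            {
                "name": r.name,
                "n_voxels": len(r.voxels),
                "voxels": [list(map(int, v)) for v in r.voxels],
                "network_loadings": {k: float(a) for k, a in r.network_loadings.items()},
            }
            for r in spec.regions
        ],
        "scans": scan_files,
        "region_masks": mask_files,
    }
    with open(os.path.join(directory, "phantom_manifest.yaml"), "w") as fh:
        yaml.safe_dump(manifest, fh, sort_keys=False)
    return manifest


def read_phantom(directory) -> Tuple[List[SubjectScan], PhantomSpec]:
    """Load a phantom written by :func:`write_phantom`; exact round trip."""
    with open(os.path.join(directory, "phantom_manifest.yaml")) as fh:
        manifest = yaml.safe_load(fh)
    spec = PhantomSpec(
        grid_shape=tuple(manifest["grid_shape"]),
        n_subjects=manifest["n_subjects"],
        n_timepoints=manifest["n_timepoints"],
        tr_seconds=manifest["tr_seconds"],
        voxel_size_mm=manifest["voxel_size_mm"],
        noise_sd=manifest["noise_sd"],
        rng_seed=manifest["rng_seed"],
        networks=[NetworkSpec(**n) for n in manifest["networks"]],
        regions=[
            RegionSpec(
                name=r["name"],
                voxels=[tuple(v) for v in r["voxels"]],
                network_loadings=r["network_loadings"],
            )
            for r in manifest["regions"]
        ],
    )
    scans = []
    for fname in manifest["scans"]:
        img = nib.load(os.path.join(directory, fname))
        scans.append(
            SubjectScan(
                data=np.asarray(img.dataobj, dtype=np.float64),
                affine=img.affine,
                tr_seconds=spec.tr_seconds,
                subject_id=fname.replace("_bold.nii", ""),
            )
        )
    return scans, spec
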