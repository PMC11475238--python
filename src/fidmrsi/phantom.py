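"""Synthetic multi-subject 3D FID-MRSI phantom cohort with known ground truth.

The phantom is an ellipsoidal head: a WM core, a cortical GM shell, CSF in
central "ventricles" and a thin peripheral rim, surrounded by a scalp ring
that carries lipid signal.  Tissue fractions are smooth and sum to one
inside the head.  Per-subject metabolite concentrations are drawn
log-normally around GM/WM tissue means with a configurable inter-subject CV,
and per-voxel FIDs are synthesized for the water-suppressed metabolite scan
and the unsuppressed water-reference scan, including T1 saturation weighting
(Ernst factors), a macromolecular background, scalp lipid bleeding into
peripheral brain voxels, and complex Gaussian noise.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import h5py
import numpy as np
from scipy import ndimage

from .basis import (
    AcquisitionParams,
    BasisSet,
    METABOLITE_SCAN,
    WATER_SCAN,
    build_basis_set,
    build_water_basis,
    default_resonance_table,
    lipid_resonances,
    simulate_compound_fid,
)
from .quantify import RelaxationTable, ernst_factor

# Default GM/WM tissue concentration means [mM].  Chosen to sit inside the
# per-ROI ranges observed for the five reliably mapped metabolites, with a
# GM > WM glutamate contrast; these are documented approximations, not
# measured values.
DEFAULT_TISSUE_MEANS_MM: dict[str, tuple[float, float]] = {
    "NAA": (10.0, 9.6),
    "tCr": (7.8, 7.0),
    "tCho": (1.7, 2.1),
    "Glu": (8.8, 7.0),
    "mIns": (5.5, 5.0),
}

MM_AMPLITUDE_DEFAULT = 2.0  # macromolecular background, mM-equivalent per unit tissue


@dataclass
class ROISpec:
    """Geometric ROI definition on the normalized brain radius rho.

    ``tissue`` restricts to GM- or WM-dominant voxels; ``side`` picks an
    anterior/posterior half-space.
    """

    name: str
    rho_min: float = 0.0
    rho_max: float = 1.0
    tissue: str | None = None  # "GM" | "WM" | None
    side: str | None = None  # "anterior" | "posterior" | None


DEFAULT_ROI_SPEC = [
    ROISpec("deep-WM", 0.30, 0.60, tissue="WM"),
    ROISpec("cortical-GM", 0.72, 0.90, tissue="GM"),
    ROISpec("mixed-anterior", 0.40, 0.90, side="anterior"),
    ROISpec("mixed-posterior", 0.40, 0.90, side="posterior"),
]


@dataclass
class PhantomCohort:
    grid_shape: tuple[int, int, int]
    voxel_size_mm: float
    fraction_maps: np.ndarray  # (3, *grid): f_GM, f_WM, f_CSF
    roi_labels: np.ndarray  # int map, 0 = unlabeled
    roi_names: dict[int, str]
    brain_mask: np.ndarray
    scalp_mask: np.ndarray
    rho: np.ndarray  # normalized brain radius
    seed: int
    truth_concentrations: dict[str, np.ndarray] = field(default_factory=dict)
    # ^ compound -> (n_subjects, *grid) voxel concentration [mM]
    subject_factors: dict[str, np.ndarray] = field(default_factory=dict)
    subject_flags: list[set[str]] = field(default_factory=list)
    inter_subject_cv: float = 0.0
    tissue_means: dict[str, tuple[float, float]] = field(default_factory=dict)
    relaxation: RelaxationTable = field(default_factory=RelaxationTable)
    metabolite_acq: AcquisitionParams = METABOLITE_SCAN
    water_acq: AcquisitionParams = WATER_SCAN

    @property
    def n_subjects(self) -> int:
        return len(self.subject_flags)

    @property
    def f_gm(self) -> np.ndarray:
        return self.fraction_maps[0]

    @property
    def f_wm(self) -> np.ndarray:
        return self.fraction_maps[1]

    @property
    def f_csf(self) -> np.ndarray:
        return self.fraction_maps[2]

    def roi_mask(self, name: str) -> np.ndarray:
        label = {v: k for k, v in self.roi_names.items()}[name]
        return self.roi_labels == label

    def save_niftis(self, out_dir) -> None:
        """Write fraction maps, ROI labels and truth maps as NIfTI."""
        import nibabel as nib
        from pathlib import Path

        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        affine = np.diag([self.voxel_size_mm] * 3 + [1.0])
        for i, name in enumerate(["f_gm", "f_wm", "f_csf"]):
            nib.save(nib.Nifti1Image(self.fraction_maps[i].astype(np.float32), affine), out / f"{name}.nii")
        nib.save(nib.Nifti1Image(self.roi_labels.astype(np.int16), affine), out / "roi_labels.nii")
        for comp, maps in self.truth_concentrations.items():
            for s in range(maps.shape[0]):
                nib.save(
                    nib.Nifti1Image(maps[s].astype(np.float32), affine),
                    out / f"truth_{comp}_sub{s:02d}.nii",
                )


@dataclass
class SubjectDataset:
    """One subject's two MRSI scans on the phantom grid."""

    metabolite_fids: np.ndarray  # (*grid, n_points) complex
    water_fids: np.ndarray  # (*grid, n_water_points) complex
    brain_mask: np.ndarray
    scalp_mask: np.ndarray
    metabolite_acq: AcquisitionParams
    water_acq: AcquisitionParams
    noise_sd: float
    subject_index: int = 0
    flags: set[str] = field(default_factory=set)

    def __post_init__(self) -> None:
        if self.metabolite_fids.shape[:-1] != self.water_fids.shape[:-1]:
            raise ValueError("metabolite and water scans must share the spatial grid")
        if np.any(self.brain_mask & self.scalp_mask):
            raise ValueError("brain and scalp masks overlap")

    def to_hdf5(self, path) -> None:
        with h5py.File(path, "w") as f:
            f.create_dataset("metabolite_fids", data=self.metabolite_fids)
            f.create_dataset("water_fids", data=self.water_fids)
            f.create_dataset("brain_mask", data=self.brain_mask)
            f.create_dataset("scalp_mask", data=self.scalp_mask)
            f.attrs["noise_sd"] = self.noise_sd
            f.attrs["subject_index"] = self.subject_index
            f.attrs["flags"] = sorted(self.flags)


def _hamming_kernel_3d(size: int = 5) -> np.ndarray:
    w = np.hamming(size)
    k = w[:, None, None] * w[None, :, None] * w[None, None, :]
    return k / k.sum()


def build_phantom(
    grid_shape: tuple[int, int, int] = (32, 32, 16),
    voxel_size_mm: float = 3.4,
    roi_spec: list[ROISpec] | None = None,
    seed: int = 0,
) -> PhantomCohort:
    """Construct the geometric scaffold: smooth tissue fractions + ROI labels."""
    if any(n < m for n, m in zip(grid_shape, (16, 16, 8))):
        raise ValueError("grid must be at least 16x16x8")
    roi_spec = DEFAULT_ROI_SPEC if roi_spec is None else roi_spec
    if not roi_spec:
        raise ValueError("roi_spec is empty")

    nx, ny, nz = grid_shape
    x, y, z = np.meshgrid(
        np.arange(nx) - (nx - 1) / 2,
        np.arange(ny) - (ny - 1) / 2,
        np.arange(nz) - (nz - 1) / 2,
        indexing="ij",
    )
    # normalized brain radius; brain ends at rho = 1
    ax, ay, az = 0.36 * nx, 0.36 * ny, 0.36 * nz
    rho = np.sqrt((x / ax) ** 2 + (y / ay) ** 2 + (z / az) ** 2)

    ventricle = rho < 0.25
    wm = (rho >= 0.25) & (rho < 0.72)
    gm = (rho >= 0.72) & (rho < 0.94)
    rim = (rho >= 0.94) & (rho <= 1.0)
    brain = rho <= 1.0
    scalp = (rho >= 1.10) & (rho <= 1.30)

    sig = 0.7
    f_gm = ndimage.gaussian_filter(gm.astype(float), sig)
    f_wm = ndimage.gaussian_filter(wm.astype(float), sig)
    f_csf = ndimage.gaussian_filter((ventricle | rim).astype(float), sig)
    total = f_gm + f_wm + f_csf
    inside = brain & (total > 1e-6)
    for f in (f_gm, f_wm, f_csf):
        f[inside] /= total[inside]
        f[~inside] = 0.0
    # ventricle core is pure CSF (no smoothed-in tissue)
    core = rho < 0.23
    f_gm[core] = 0.0
    f_wm[core] = 0.0
    f_csf[core] = 1.0

    labels = np.zeros(grid_shape, dtype=np.int16)
    names: dict[int, str] = {}
    for i, spec in enumerate(roi_spec, start=1):
        sel = brain & (rho >= spec.rho_min) & (rho <= spec.rho_max) & (labels == 0)
        if spec.tissue == "WM":
            sel &= f_wm > 0.5
        elif spec.tissue == "GM":
            sel &= f_gm > 0.4
        if spec.side == "anterior":
            sel &= y > 0
        elif spec.side == "posterior":
            sel &= y < 0
        if not sel.any():
            raise ValueError(f"ROI {spec.name!r} has zero voxels on this grid")
        labels[sel] = i
        names[i] = spec.name

    return PhantomCohort(
        grid_shape=grid_shape,
        voxel_size_mm=voxel_size_mm,
        fraction_maps=np.stack([f_gm, f_wm, f_csf]),
        roi_labels=labels,
        roi_names=names,
        brain_mask=brain,
        scalp_mask=scalp,
        rho=rho,
        seed=seed,
    )


def assign_truth_concentrations(
    phantom: PhantomCohort,
    tissue_means: dict[str, tuple[float, float]] | None = None,
    inter_subject_cv: float = 10.0,
    n_subjects: int = 5,
    seed: int = 0,
    motion_subjects: tuple[int, ...] = (),
) -> PhantomCohort:
    """Draw per-subject concentrations and build voxel ground-truth maps.

    Each subject gets one log-normal multiplier per metabolite (applied to
    both GM and WM means) with the stated coefficient of variation, so an
    ROI's true inter-subject CV equals ``inter_subject_cv`` regardless of
    its GM/WM mix.  Voxel truth is f_GM*C_GM + f_WM*C_WM; CSF carries no
    metabolites.
    """
    if inter_subject_cv < 0:
        raise ValueError("cv must be >= 0")
    if n_subjects < 2:
        raise ValueError("need at least 2 subjects")
    tissue_means = DEFAULT_TISSUE_MEANS_MM if tissue_means is None else tissue_means
    for comp, (c_gm, c_wm) in tissue_means.items():
        if c_gm < 0 or c_wm < 0:
            raise ValueError(f"negative tissue mean for {comp}")

    rng = np.random.default_rng(seed)
    cv = inter_subject_cv / 100.0
    sigma = np.sqrt(np.log1p(cv**2))
    phantom.truth_concentrations = {}
    phantom.subject_factors = {}
    for comp, (c_gm, c_wm) in tissue_means.items():
        # mean-preserving log-normal: E[factor] = 1, CV[factor] = cv
        factors = rng.lognormal(mean=-0.5 * sigma**2, sigma=sigma, size=n_subjects)
        phantom.subject_factors[comp] = factors
        base = phantom.f_gm * c_gm + phantom.f_wm * c_wm
        phantom.truth_concentrations[comp] = factors[:, None, None, None] * base[None]
    phantom.subject_flags = [
        {"motion"} if s in motion_subjects else set() for s in range(n_subjects)
    ]
    phantom.inter_subject_cv = inter_subject_cv
    phantom.tissue_means = dict(tissue_means)
    return phantom


def _metabolite_signal_amplitudes(
    phantom: PhantomCohort, subject_index: int, compounds: list[str]
) -> np.ndarray:
    """Per-voxel Ernst-weighted signal amplitude for each compound [mM units].

    amplitude = f_GM * C_GM * E(theta, TR, T1_GM) + f_WM * C_WM * E(..., T1_WM)
    """
    acq = phantom.metabolite_acq
    table = phantom.relaxation
    amps = []
    for comp in compounds:
        c_gm, c_wm = phantom.tissue_means[comp]
        factor = phantom.subject_factors[comp][subject_index]
        t1_gm, t1_wm = table.metabolite_t1(comp)
        e_gm = ernst_factor(acq.flip_deg, acq.tr_ms, t1_gm)
        e_wm = ernst_factor(acq.flip_deg, acq.tr_ms, t1_wm)
        amps.append(factor * (phantom.f_gm * c_gm * e_gm + phantom.f_wm * c_wm * e_wm))
    return np.stack(amps, axis=-1)  # (*grid, n_compounds)


def water_signal_amplitude(phantom: PhantomCohort) -> np.ndarray:
    """Per-voxel water-scan amplitude: sum_c f_c * W_c * E(theta_w, TR_w, T1_w,c).

    W_c are compartment water concentrations in mol/L; the amplitude is
    expressed in mM (x1000) so metabolite and water scans share units.
    """
    acq = phantom.water_acq
    t = phantom.relaxation
    amp = np.zeros(phantom.grid_shape)
    for frac, conc, t1 in [
        (phantom.f_gm, t.water_gm_mol_l, t.water_t1_gm),
        (phantom.f_wm, t.water_wm_mol_l, t.water_t1_wm),
        (phantom.f_csf, t.water_csf_mol_l, t.water_t1_csf),
    ]:
        amp += frac * conc * 1000.0 * ernst_factor(acq.flip_deg, acq.tr_ms, t1)
    return amp


def synthesize_subject(
    phantom: PhantomCohort,
    subject_index: int,
    basis: BasisSet | None = None,
    noise_sd: float = 0.0,
    lipid_amplitude: float = 0.0,
    seed: int = 0,
    mm_amplitude: float = MM_AMPLITUDE_DEFAULT,
    gain: float = 1.0,
    spatial_smoothing: bool = False,
    motion_t2_star: float = 0.005,
) -> SubjectDataset:
    """Synthesize both scans for one subject of the cohort.

    Motion-flagged subjects get severely broadened lines (all resonances
    decayed to an effective T2* of ``motion_t2_star``) plus a spatial
    first-order phase ramp, which downstream quality masking must catch.
    """
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    if not phantom.truth_concentrations:
        raise ValueError("assign_truth_concentrations must run first")
    if basis is None:
        basis = build_basis_set(default_resonance_table(), phantom.metabolite_acq)
    if basis.n_points != phantom.metabolite_acq.n_points:
        raise ValueError("basis does not match the metabolite acquisition parameters")

    compounds = [c for c in basis.compound_names if c in phantom.truth_concentrations]
    amps = _metabolite_signal_amplitudes(phantom, subject_index, compounds)
    sig_matrix = np.stack([basis.signal(c) for c in compounds])  # (M, N)

    grid = phantom.grid_shape
    n = basis.n_points
    fids = amps.reshape(-1, len(compounds)).astype(complex) @ sig_matrix
    fids = fids.reshape(*grid, n)

    if "MM" in basis.compound_names and mm_amplitude > 0:
        tissue = phantom.f_gm + phantom.f_wm
        fids += (mm_amplitude * tissue)[..., None] * basis.signal("MM")

    macq = phantom.metabolite_acq
    if lipid_amplitude > 0:
        lipid_fid = simulate_compound_fid(
            lipid_resonances(),
            macq.bandwidth_hz,
            macq.readout_s,
            macq.acquisition_delay_s,
            macq.reference_frequency_mhz,
            macq.carrier_ppm,
        )
        lipid_map = phantom.scalp_mask.astype(float) * lipid_amplitude
        # scalp signal bleeds into peripheral brain voxels via the same
        # Hamming point-spread used for spatial smoothing
        lipid_map = ndimage.convolve(lipid_map, _hamming_kernel_3d(5), mode="constant")
        lipid_map[phantom.scalp_mask] = lipid_amplitude
        fids += lipid_map[..., None] * lipid_fid

    flags = phantom.subject_flags[subject_index] if phantom.subject_flags else set()
    t_axis = np.arange(n) / macq.bandwidth_hz
    if "motion" in flags:
        # collapse all lines to ~motion_t2_star and add a phase ramp along x
        extra_rate = max(1.0 / motion_t2_star - 1.0 / 0.090, 0.0)
        fids *= np.exp(-extra_rate * t_axis)
        nx = grid[0]
        ramp_hz = np.linspace(-10.0, 10.0, nx)
        fids *= np.exp(2j * np.pi * ramp_hz[:, None, None, None] * t_axis)

    # water-reference scan
    wacq = phantom.water_acq
    water_basis = build_water_basis(wacq)
    w_amp = water_signal_amplitude(phantom)
    water_fids = w_amp[..., None].astype(complex) * water_basis.signal("water")

    if spatial_smoothing:
        k = _hamming_kernel_3d(3)
        for arr in (fids, water_fids):
            arr.real = ndimage.convolve(arr.real, k[..., None], mode="constant")
            arr.imag = ndimage.convolve(arr.imag, k[..., None], mode="constant")

    fids *= gain
    water_fids *= gain
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        fids += noise_sd * (rng.standard_normal(fids.shape) + 1j * rng.standard_normal(fids.shape))
        water_fids += noise_sd * (
            rng.standard_normal(water_fids.shape) + 1j * rng.standard_normal(water_fids.shape)
        )

    return SubjectDataset(
        metabolite_fids=fids,
        water_fids=water_fids,
        brain_mask=phantom.brain_mask,
        scalp_mask=phantom.scalp_mask,
        metabolite_acq=macq,
        water_acq=wacq,
        noise_sd=noise_sd,
        subject_index=subject_index,
        flags=set(flags),
    )
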