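"""Metabolite, macromolecular, lipid and water basis simulation.

Each compound is modeled as a sum of Lorentzian resonances (singlets or
simple multiplet approximations).  A free induction decay acquired a short
delay after excitation carries a first-order phase: the stored signal starts
at t = delay, so every resonance enters with phase 2*pi*f*delay at the first
sample.  This is the convention used throughout the package — the delay is
part of the signal model, never a sample shift.

The basis is a deliberate singlet-level approximation: no J-coupling
evolution or density-matrix simulation is attempted.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import h5py
import numpy as np
import pandas as pd

PROTON_FREQ_7T_MHZ = 297.2
CARRIER_PPM = 4.7


@dataclass(frozen=True)
class Resonance:
    """A single Lorentzian line: position [ppm], proton weighting, T2* [s]."""

    chemical_shift: float
    relative_amplitude: float
    t2_star: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.chemical_shift <= 10.0):
            raise ValueError(f"chemical shift {self.chemical_shift} ppm outside 0-10 ppm")
        if self.relative_amplitude <= 0:
            raise ValueError("relative_amplitude must be > 0")
        if self.t2_star <= 0:
            raise ValueError("t2_star must be > 0")


@dataclass(frozen=True)
class AcquisitionParams:
    """Parameters of one FID-MRSI scan."""

    tr_ms: float
    flip_deg: float
    bandwidth_hz: float
    readout_s: float
    acquisition_delay_s: float = 1.3e-3
    reference_frequency_mhz: float = PROTON_FREQ_7T_MHZ
    carrier_ppm: float = CARRIER_PPM

    @property
    def n_points(self) -> int:
        return int(round(self.bandwidth_hz * self.readout_s))


# The two scans of the acquisition protocol: a water-suppressed metabolite
# scan (TR 450 ms, 39 deg, 2778 Hz over 345 ms) and an unsuppressed water
# reference (TR 200 ms, 27 deg, 606 Hz over 158 ms).
METABOLITE_SCAN = AcquisitionParams(tr_ms=450.0, flip_deg=39.0, bandwidth_hz=2778.0, readout_s=0.345)
WATER_SCAN = AcquisitionParams(tr_ms=200.0, flip_deg=27.0, bandwidth_hz=606.0, readout_s=0.158)


@dataclass
class BasisSet:
    """Per-compound complex time-domain basis signals on a shared grid."""

    compound_names: list[str]
    signals: np.ndarray  # (n_compounds, n_points) complex
    sampling_bandwidth: float
    n_points: int
    acquisition_delay: float
    reference_frequency: float
    carrier_ppm: float = CARRIER_PPM
    resonance_table: dict[str, list[Resonance]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.signals = np.asarray(self.signals, dtype=complex)
        if self.signals.shape != (len(self.compound_names), self.n_points):
            raise ValueError("signals shape inconsistent with names/n_points")
        if len(set(self.compound_names)) != len(self.compound_names):
            raise ValueError("duplicate compound names")

    @property
    def ppm_axis(self) -> np.ndarray:
        """Monotone increasing ppm axis of the fftshifted spectrum."""
        freqs = np.fft.fftshift(np.fft.fftfreq(self.n_points, d=1.0 / self.sampling_bandwidth))
        return self.carrier_ppm + freqs / self.reference_frequency

    def index(self, name: str) -> int:
        return self.compound_names.index(name)

    def signal(self, name: str) -> np.ndarray:
        return self.signals[self.index(name)]

    def subset(self, names: list[str]) -> "BasisSet":
        idx = [self.index(n) for n in names]
        return BasisSet(
            compound_names=list(names),
            signals=self.signals[idx].copy(),
            sampling_bandwidth=self.sampling_bandwidth,
            n_points=self.n_points,
            acquisition_delay=self.acquisition_delay,
            reference_frequency=self.reference_frequency,
            carrier_ppm=self.carrier_ppm,
            resonance_table={n: self.resonance_table[n] for n in names if n in self.resonance_table},
        )

    def to_hdf5(self, path) -> None:
        with h5py.File(path, "w") as f:
            f.create_dataset("signals", data=self.signals)
            f.attrs["compound_names"] = [n.encode() for n in self.compound_names]
            f.attrs["sampling_bandwidth"] = self.sampling_bandwidth
            f.attrs["n_points"] = self.n_points
            f.attrs["acquisition_delay"] = self.acquisition_delay
            f.attrs["reference_frequency"] = self.reference_frequency
            f.attrs["carrier_ppm"] = self.carrier_ppm
            grp = f.create_group("resonances")
            for name, res in self.resonance_table.items():
                arr = np.array([[r.chemical_shift, r.relative_amplitude, r.t2_star] for r in res])
                grp.create_dataset(name, data=arr)

    @classmethod
    def from_hdf5(cls, path) -> "BasisSet":
        with h5py.File(path, "r") as f:
            names = [n.decode() if isinstance(n, bytes) else str(n) for n in f.attrs["compound_names"]]
            table = {}
            if "resonances" in f:
                for name in f["resonances"]:
                    table[name] = [
                        Resonance(float(a), float(b), float(c)) for a, b, c in f["resonances"][name][...]
                    ]
            return cls(
                compound_names=names,
                signals=f["signals"][...],
                sampling_bandwidth=float(f.attrs["sampling_bandwidth"]),
                n_points=int(f.attrs["n_points"]),
                acquisition_delay=float(f.attrs["acquisition_delay"]),
                reference_frequency=float(f.attrs["reference_frequency"]),
                carrier_ppm=float(f.attrs["carrier_ppm"]),
                resonance_table=table,
            )

    def resonance_dataframe(self) -> pd.DataFrame:
        rows = [
            {"compound": name, "chemical_shift_ppm": r.chemical_shift,
             "relative_amplitude": r.relative_amplitude, "t2_star_s": r.t2_star}
            for name, res in self.resonance_table.items()
            for r in res
        ]
        return pd.DataFrame(rows)


def simulate_compound_fid(
    resonances: list[Resonance],
    bandwidth: float,
    readout: float,
    delay: float = 1.3e-3,
    ref_freq: float = PROTON_FREQ_7T_MHZ,
    carrier_ppm: float = CARRIER_PPM,
) -> np.ndarray:
    """Simulate one compound's FID as a sum of decaying complex exponentials.

    Sample n sits at t_n = n / bandwidth, and the model is evaluated at
    t_n + delay, so the acquisition-delay first-order phase
    exp(i*2*pi*f*delay) is built into the first sample.
    """
    if not resonances:
        raise ValueError("resonance list is empty")
    if bandwidth <= 0 or readout <= 0 or ref_freq <= 0:
        raise ValueError("bandwidth, readout and ref_freq must be positive")
    if delay < 0:
        raise ValueError("delay must be non-negative")
    n = int(round(bandwidth * readout))
    t = np.arange(n) / bandwidth + delay
    fid = np.zeros(n, dtype=complex)
    for r in resonances:
        f_hz = (r.chemical_shift - carrier_ppm) * ref_freq  # ref_freq MHz -> Hz/ppm
        fid += r.relative_amplitude * np.exp((2j * np.pi * f_hz - 1.0 / r.t2_star) * t)
    return fid


def fid_to_spectrum(
    fid: np.ndarray,
    bandwidth: float,
    ref_freq: float = PROTON_FREQ_7T_MHZ,
    carrier_ppm: float = CARRIER_PPM,
):
    """Orthonormal DFT of an FID with its ppm axis (monotone increasing).

    The 1/sqrt(N) normalization preserves energy (Parseval), so a noise
    standard deviation per complex component carries over unchanged from
    time to frequency domain.
    """
    fid = np.asarray(fid)
    if fid.shape[-1] == 0:
        raise ValueError("empty FID")
    n = fid.shape[-1]
    spec = np.fft.fftshift(np.fft.fft(fid, axis=-1), axes=-1) / np.sqrt(n)
    freqs = np.fft.fftshift(np.fft.fftfreq(n, d=1.0 / bandwidth))
    ppm = carrier_ppm + freqs / ref_freq
    return spec, ppm


# ---------------------------------------------------------------------------
# Built-in resonance table
# ---------------------------------------------------------------------------

_T2S_MET = 0.090  # s, typical metabolite T2* at 7 T
_T2S_MM = 0.010  # s, broad macromolecular background
_T2S_LIPID = 0.025  # s, subcutaneous lipid


def default_resonance_table() -> dict[str, list[Resonance]]:
    """Singlet/simple-multiplet chemical-shift table for the fitted compounds.

    Positions follow standard proton shift compilations; amplitudes are
    rough proton weightings.  tCr's 3.02 ppm methyl line is the reference
    for SNR and linewidth maps.
    """

    def r(ppm, amp, t2=_T2S_MET):
        return Resonance(ppm, amp, t2)

    table: dict[str, list[Resonance]] = {
        "NAA": [r(2.01, 3.0), r(2.49, 0.8), r(2.67, 0.8)],
        "NAAG": [r(2.04, 3.0), r(2.18, 0.6)],
        "tCr": [r(3.02, 3.0), r(3.93, 2.0)],
        "tCho": [r(3.20, 9.0), r(3.52, 2.0)],
        "Glu": [r(2.34, 2.0), r(2.08, 2.0), r(3.74, 1.0)],
        "Gln": [r(2.44, 2.0), r(2.12, 2.0), r(3.76, 1.0)],
        "mIns": [r(3.52, 1.0), r(3.61, 4.0), r(3.27, 1.0)],
    }
    return table


def mm_resonances() -> list[Resonance]:
    """Broad macromolecular background: short-T2* Lorentzians 0.9-3.9 ppm."""
    positions = [0.93, 1.24, 1.70, 2.05, 2.29, 3.00, 3.21, 3.75]
    amps = [1.0, 0.8, 0.6, 1.0, 0.7, 0.9, 0.6, 1.2]
    return [Resonance(p, a, _T2S_MM) for p, a in zip(positions, amps)]


def lipid_resonances() -> list[Resonance]:
    """Scalp lipid resonances concentrated in the 1.2-1.8 ppm band."""
    return [
        Resonance(1.30, 6.0, _T2S_LIPID),
        Resonance(1.59, 2.0, _T2S_LIPID),
        Resonance(0.90, 1.5, _T2S_LIPID),
        Resonance(2.05, 1.0, _T2S_LIPID),
    ]


def water_resonances(t2_star: float = 0.050) -> list[Resonance]:
    return [Resonance(CARRIER_PPM, 2.0, t2_star)]


def build_basis_set(
    compound_table: dict[str, list[Resonance]],
    acq: AcquisitionParams = METABOLITE_SCAN,
    include_mm: bool = True,
) -> BasisSet:
    """Simulate one FID per compound on the scan's sampling grid.

    When ``include_mm`` is set, a broad macromolecular background compound
    ("MM") is appended unless the table already provides one.
    """
    if not compound_table:
        raise ValueError("compound table is empty")
    names = list(compound_table.keys())
    if len(set(names)) != len(names):
        raise ValueError("duplicate compound names")
    table = dict(compound_table)
    if include_mm and "MM" not in table:
        table["MM"] = mm_resonances()
        names.append("MM")
    signals = np.stack(
        [
            simulate_compound_fid(
                table[name],
                acq.bandwidth_hz,
                acq.readout_s,
                acq.acquisition_delay_s,
                acq.reference_frequency_mhz,
                acq.carrier_ppm,
            )
            for name in names
        ]
    )
    return BasisSet(
        compound_names=names,
        signals=signals,
        sampling_bandwidth=acq.bandwidth_hz,
        n_points=acq.n_points,
        acquisition_delay=acq.acquisition_delay_s,
        reference_frequency=acq.reference_frequency_mhz,
        carrier_ppm=acq.carrier_ppm,
        resonance_table=table,
    )


def build_water_basis(acq: AcquisitionParams = WATER_SCAN, t2_star: float = 0.050) -> BasisSet:
    """Single-compound water basis for the unsuppressed reference scan."""
    return build_basis_set({"water": water_resonances(t2_star)}, acq, include_mm=False)
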