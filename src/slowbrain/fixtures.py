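"""Synthetic fixture data emulating the empirical inputs of the study.

Real subject data (DTI connectomes, resting-state BOLD, N3 sleep EEG
spectra) are not redistributable, so every downstream module is exercised
against generated surrogates with the salient statistical features:

* an 80-region connectome with distance-decaying, heavy-tailed weights and
  an anterior-to-posterior in-degree gradient (anterior less connected),
* per-subject functional connectivity derived from a shared latent
  covariance plus subject-specific noise (inter-subject FC correlation
  well above 0.5, as for real cohorts),
* an N3-sleep-like EEG power spectrum: a 1/f-type falloff with a strong
  slow-oscillation peak near 1 Hz.

Everything is deterministic given the seed.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .evolve import FitTargets
from .network import Connectome, synthetic_connectome
from .objectives import compute_fc

__all__ = ["FixtureSet", "generate_fixtures", "n3_like_spectrum"]


def n3_like_spectrum(
    fmax: float = 45.0,
    df: float = 0.1,
    slope: float = 1.5,
    so_freq: float = 1.0,
    so_width: float = 0.35,
    so_amp: float = 5.0,
):
    """Deep-sleep-like EEG power spectrum: a * f^-slope with a Gaussian
    slow-oscillation peak.  Returns (freqs Hz, power, arbitrary units)."""
    f = np.arange(df, fmax + df / 2, df)
    power = (f + 0.1) ** (-slope) + so_amp * np.exp(
        -0.5 * ((f - so_freq) / so_width) ** 2
    )
    return f, power


@dataclass
class FixtureSet:
    """Synthetic study inputs; see :func:`generate_fixtures`."""

    connectome: Connectome
    bold: list            # K arrays (N, T) at 0.5 Hz
    fcs: list             # K (N, N) correlation matrices
    spectrum_freqs: np.ndarray
    spectrum_power: np.ndarray
    seed: int

    @property
    def K(self) -> int:
        return len(self.fcs)

    def targets(self) -> FitTargets:
        fcds = []
        for y in self.bold:
            try:
                fcds.append(compute_fcd_from_array(y))
            except ValueError:
                pass
        return FitTargets(
            fcs=self.fcs, fcds=fcds,
            spectrum_freqs=self.spectrum_freqs,
            spectrum_power=self.spectrum_power,
        )

    def save(self, outdir) -> None:
        """Write plain-text fixture files plus the connectome bundle."""
        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        self.connectome.save(out / "connectome.h5")
        np.savetxt(out / "connectome_weights.tsv", self.connectome.C,
                   delimiter="\t")
        np.savetxt(out / "connectome_lengths.tsv", self.connectome.L,
                   delimiter="\t")
        np.savetxt(out / "connectome_coords.tsv", self.connectome.coords,
                   delimiter="\t")
        (out / "connectome_labels.txt").write_text(
            "\n".join(self.connectome.labels) + "\n"
        )
        for k, (fc, y) in enumerate(zip(self.fcs, self.bold)):
            np.savetxt(out / f"subject_{k:02d}_fc.tsv", fc, delimiter="\t")
            np.savetxt(out / f"subject_{k:02d}_bold.tsv", y, delimiter="\t")
        np.savetxt(
            out / "eeg_spectrum_n3.tsv",
            np.column_stack([self.spectrum_freqs, self.spectrum_power]),
            delimiter="\t", header="freq_hz\tpower",
        )


def compute_fcd_from_array(y: np.ndarray) -> np.ndarray:
    from .bold import BoldTrace
    from .objectives import compute_fcd

    t = np.arange(y.shape[1]) / 0.5
    return compute_fcd(BoldTrace(t=t, y=y, fs=0.5))


def generate_fixtures(
    N: int = 80,
    K: int = 5,
    seed: int = 0,
    duration_s: float = 720.0,
    subject_noise: float = 0.6,
    connectome: Connectome | None = None,
) -> FixtureSet:
    """Generate the full synthetic fixture set.

    Subject BOLD series share a latent signal whose covariance blends
    spatial proximity and structural connectivity; ``subject_noise`` sets
    the amplitude of independent per-subject noise relative to the latent
    signal (0.6 keeps inter-subject FC correlations well above 0.5).
    """
    if N < 10:
        raise ValueError("need at least 10 regions")
    rng = np.random.default_rng(seed)
    conn = connectome if connectome is not None else synthetic_connectome(N, seed=seed)

    # latent spatial covariance: proximity plus structural coupling
    diff = conn.coords[:, None, :] - conn.coords[None, :, :]
    dist = np.sqrt((diff**2).sum(axis=-1))
    cov = 0.6 * np.exp(-dist / 40.0) + 0.4 * conn.C
    cov = 0.5 * (cov + cov.T)
    cov += (1.0 - np.diag(cov).min() + 0.05) * np.eye(N)
    Lch = np.linalg.cholesky(cov)

    T = int(round(duration_s * 0.5))  # 0.5 Hz sampling
    latent = Lch @ rng.standard_normal((N, T))
    bold, fcs = [], []
    for _ in range(K):
        y = latent + subject_noise * rng.standard_normal((N, T))
        bold.append(y)
        fcs.append(compute_fc(y))

    f, power = n3_like_spectrum()
    return FixtureSet(
        connectome=conn, bold=bold, fcs=fcs,
        spectrum_freqs=f, spectrum_power=power, seed=seed,
    )
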