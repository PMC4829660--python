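"""Genome-size estimation from DNA flow-cytometry histograms.

The G0/G1 peak of an internal diploid reference population and the G1
peak of the sample are each fitted with a Gaussian; the ratio of their
positions gives the relative DNA amount, which is converted to picograms
against the diploid human reference (7 pg) with configurable
species/sex correction factors and finally to megabase pairs
(978 Mbp per pg by default).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import curve_fit

from repliconscope.datatypes import DnaHistogram

__all__ = [
    "PeakFit",
    "GenomePeaks",
    "ReferenceContext",
    "GenomeSizeResult",
    "fit_g1_peaks",
    "dna_content_pg",
    "pg_to_mbp",
    "genome_size",
]


@dataclass(frozen=True)
class PeakFit:
    """A fitted Gaussian peak."""

    mean: float
    sigma: float
    amplitude: float
    mean_stderr: float

    @property
    def cv(self) -> float:
        return self.sigma / self.mean


@dataclass(frozen=True)
class GenomePeaks:
    reference: PeakFit
    sample: PeakFit
    ratio: float
    ratio_stderr: float


@dataclass(frozen=True)
class ReferenceContext:
    """Reference DNA amount and correction factors for the pg conversion."""

    human_diploid_pg: float = 7.0
    genome_size_factor: float = 1.06
    sex_factor: float = 1.016


@dataclass(frozen=True)
class GenomeSizeResult:
    reference_channel: float
    sample_channel: float
    relative_amount: float
    genomic_dna_pg: float
    genome_size_mbp: float
    peak_position_uncertainty: float  # fractional


def _gaussian(x: np.ndarray, amp: float, mu: float, sigma: float) -> np.ndarray:
    return amp * np.exp(-0.5 * ((x - mu) / sigma) ** 2)


def _fit_window(hist: DnaHistogram, window: tuple[float, float]) -> PeakFit:
    sel = hist.window_slice(window)
    x = hist.channels[sel]
    y = hist.counts[sel]
    if x.size < 4 or y.max() <= 0:
        raise ValueError(f"window {window} contains no usable peak")
    mu0 = float(x[np.argmax(y)])
    sigma0 = max((window[1] - window[0]) / 6.0, 0.5)
    try:
        popt, pcov = curve_fit(
            _gaussian,
            x,
            y,
            p0=(float(y.max()), mu0, sigma0),
            maxfev=10000,
        )
    except RuntimeError as exc:  # pragma: no cover - diagnostic path
        raise RuntimeError(
            f"Gaussian fit failed in window {window}: {exc}"
        ) from exc
    amp, mu, sigma = popt
    if not np.isfinite(mu) or mu <= 0:
        raise RuntimeError(f"Gaussian fit diverged in window {window}")
    stderr = float(np.sqrt(np.abs(pcov[1, 1]))) if np.all(np.isfinite(pcov)) else np.nan
    return PeakFit(float(mu), abs(float(sigma)), float(amp), stderr)


def fit_g1_peaks(hist: DnaHistogram) -> GenomePeaks:
    """Fit the reference and sample G1 peaks and return their ratio."""
    if hist.reference_window is None or hist.sample_window is None:
        raise ValueError("histogram must carry reference and sample window annotations")
    ref = _fit_window(hist, hist.reference_window)
    sam = _fit_window(hist, hist.sample_window)
    ratio = sam.mean / ref.mean
    rel = np.sqrt(
        (sam.mean_stderr / sam.mean) ** 2 + (ref.mean_stderr / ref.mean) ** 2
    )
    return GenomePeaks(ref, sam, float(ratio), float(ratio * rel))


def dna_content_pg(
    relative_amount: float, reference: ReferenceContext | None = None
) -> float:
    """Convert a relative DNA amount to picograms per cell.

    pg = relative * human_diploid_pg / (genome_size_factor * sex_factor).
    """
    reference = reference or ReferenceContext()
    if relative_amount <= 0:
        raise ValueError("relative DNA amount must be positive")
    if min(reference.human_diploid_pg, reference.genome_size_factor,
           reference.sex_factor) <= 0:
        raise ValueError("reference context values must be positive")
    return (
        relative_amount
        * reference.human_diploid_pg
        / (reference.genome_size_factor * reference.sex_factor)
    )


def pg_to_mbp(pg: float, mbp_per_pg: float = 978.0) -> float:
    """Convert a DNA mass in picograms to megabase pairs."""
    if pg < 0:
        raise ValueError("DNA mass must be >= 0")
    if mbp_per_pg <= 0:
        raise ValueError("conversion constant must be positive")
    return pg * mbp_per_pg


def genome_size(
    hist: DnaHistogram,
    *,
    reference: ReferenceContext | None = None,
    mbp_per_pg: float = 978.0,
) -> GenomeSizeResult:
    """Full chain: peak fitting -> relative amount -> pg -> Mbp."""
    peaks = fit_g1_peaks(hist)
    pg = dna_content_pg(peaks.ratio, reference)
    mbp = pg_to_mbp(pg, mbp_per_pg)
    frac = peaks.ratio_stderr / peaks.ratio if peaks.ratio else float("nan")
    return GenomeSizeResult(
        reference_channel=peaks.reference.mean,
        sample_channel=peaks.sample.mean,
        relative_amount=peaks.ratio,
        genomic_dna_pg=pg,
        genome_size_mbp=mbp,
        peak_position_uncertainty=float(frac),
    )
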