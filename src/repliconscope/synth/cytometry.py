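"""Synthetic DNA flow-cytometry histograms.

A histogram mixes a non-cycling reference population (single G0/G1
Gaussian peak) with a cycling sample population (G1 Gaussian, an S-phase
plateau and a G2 Gaussian at twice the G1 position). Peak widths follow
a common coefficient of variation.
"""

from __future__ import annotations

import numpy as np

from repliconscope.datatypes import DnaHistogram

__all__ = ["generate_dna_histogram"]


def generate_dna_histogram(
    reference_peak_channel: float,
    sample_relative_amount: float,
    peak_cv: float,
    s_fraction: float,
    g2_fraction: float,
    n_cells: int,
    *,
    n_reference_cells: int | None = None,
    n_channels: int = 256,
    window_sigmas: float = 3.0,
    seed: int = 0,
) -> DnaHistogram:
    """Generate a channel/count DNA histogram with annotated peak windows.

    ``sample_relative_amount`` positions the sample G1 peak at
    ``reference_peak_channel * sample_relative_amount``; the G2 peak sits
    at twice the sample G1 channel and the S plateau spans the range in
    between.
    """
    if not 0 < peak_cv < 0.1:
        raise ValueError("peak CV must lie in (0, 0.1)")
    if sample_relative_amount <= 0:
        raise ValueError("sample relative amount must be positive")
    for frac in (s_fraction, g2_fraction):
        if not 0.0 <= frac <= 1.0:
            raise ValueError("population fractions must lie in [0, 1]")
    if s_fraction + g2_fraction > 1.0:
        raise ValueError("population fractions must sum to <= 1")
    if n_cells < 1:
        raise ValueError("n_cells must be >= 1")
    if not 0 < reference_peak_channel < n_channels - 1:
        raise ValueError("reference peak channel outside histogram range")

    c_ref = float(reference_peak_channel)
    c_g1 = c_ref * float(sample_relative_amount)
    c_g2 = 2.0 * c_g1
    if c_g2 >= n_channels:
        raise ValueError(
            "sample G2 peak would fall outside the histogram; "
            "increase n_channels or lower the reference channel"
        )

    rng = np.random.default_rng(seed)
    n_ref = n_cells if n_reference_cells is None else n_reference_cells

    n_g2 = int(round(n_cells * g2_fraction))
    n_s = int(round(n_cells * s_fraction))
    n_g1 = n_cells - n_g2 - n_s

    values = [rng.normal(c_ref, peak_cv * c_ref, size=n_ref)]
    if n_g1:
        values.append(rng.normal(c_g1, peak_cv * c_g1, size=n_g1))
    if n_s:
        # S-phase DNA content uniform between 1x and 2x G1, blurred by the
        # same relative measurement spread
        base = rng.uniform(c_g1, c_g2, size=n_s)
        values.append(rng.normal(base, peak_cv * base))
    if n_g2:
        values.append(rng.normal(c_g2, peak_cv * c_g2, size=n_g2))

    samples = np.concatenate(values)
    idx = np.clip(np.rint(samples).astype(int), 0, n_channels - 1)
    counts = np.bincount(idx, minlength=n_channels)

    # windows must span enough discrete channels for a 3-parameter fit
    w_ref = max(window_sigmas * peak_cv * c_ref, 4.0)
    w_g1 = max(window_sigmas * peak_cv * c_g1, 4.0)
    return DnaHistogram(
        channels=np.arange(n_channels, dtype=float),
        counts=counts.astype(float),
        reference_window=(c_ref - w_ref, c_ref + w_ref),
        sample_window=(c_g1 - w_g1, c_g1 + w_g1),
    )
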