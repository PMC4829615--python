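"""Figure-style plots: group mean spectra and contrast difference curves."""

from __future__ import annotations

from typing import Mapping, Sequence

import numpy as np

from .bands import BandScheme
from .spectra import ComponentSpectrum

__all__ = ["plot_group_spectra", "plot_difference"]


def _group_mean_sem(specs: Sequence[ComponentSpectrum], groups: Mapping[str, str]):
    by_group: dict[str, list[np.ndarray]] = {}
    freqs = specs[0].freqs
    for s in specs:
        by_group.setdefault(groups.get(s.subject_id, ""), []).append(s.best)
    out = {}
    for g, arrs in by_group.items():
        a = np.vstack(arrs)
        out[g] = (a.mean(axis=0), a.std(axis=0, ddof=1) / np.sqrt(len(arrs)))
    return freqs, out


def plot_group_spectra(
    specs: Sequence[ComponentSpectrum],
    groups: Mapping[str, str],
    scheme: BandScheme | None = None,
    ax=None,
    fmax: float = 0.1,
):
    """Mean smoothed spectrum per group with +-SEM shading."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    freqs, stats = _group_mean_sem(specs, groups)
    sel = freqs <= fmax
    for g, (mean, sem) in sorted(stats.items()):
        ax.plot(freqs[sel], mean[sel], label=g)
        ax.fill_between(freqs[sel], (mean - sem)[sel], (mean + sem)[sel], alpha=0.3)
    if scheme is not None:
        for edge in (scheme["slow5"].lo, scheme["slow5"].hi):
            ax.axvline(edge, color="k", lw=0.8)
        ax.axvline(scheme["slow4"].hi, color="k", lw=0.8, ls=":")
    ax.set_xlabel("frequency (Hz)")
    ax.set_ylabel("amplitude")
    ax.legend()
    return ax


def plot_difference(
    specs: Sequence[ComponentSpectrum],
    groups: Mapping[str, str],
    pair: tuple[str, str],
    ax=None,
    fmax: float = 0.1,
):
    """Difference of group mean spectra (pair[0] minus pair[1])."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    freqs, stats = _group_mean_sem(specs, groups)
    diff = stats[pair[0]][0] - stats[pair[1]][0]
    sel = freqs <= fmax
    ax.plot(freqs[sel], diff[sel], label=f"{pair[0]} - {pair[1]}")
    ax.axhline(0.0, color="k", lw=0.8)
    ax.set_xlabel("frequency (Hz)")
    ax.set_ylabel("amplitude difference")
    ax.legend()
    return ax
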