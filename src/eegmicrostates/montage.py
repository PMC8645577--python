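"""Idealized 2-D electrode layouts used for template construction.

The 64-channel case uses the standard 10/20-extended positions bundled with
MNE ("biosemi64"); any other channel count gets a deterministic sunflower
layout on the unit disc. Coordinates follow the head-map convention:
x increases to the subject's right, y increases toward the front.
"""

from __future__ import annotations

import numpy as np

from .errors import ParameterError

__all__ = ["layout_positions"]


def _standard_64() -> tuple[list[str], np.ndarray]:
    import mne

    montage = mne.channels.make_standard_montage("biosemi64")
    pos3d = montage.get_positions()["ch_pos"]
    names = list(montage.ch_names)
    xy = np.array([pos3d[name][:2] for name in names], dtype=float)
    # normalize to roughly the unit disc
    xy /= np.abs(xy).max()
    return names, xy


def _sunflower(n: int) -> tuple[list[str], np.ndarray]:
    # Fibonacci/sunflower disc sampling: even coverage for any n, no seed.
    idx = np.arange(1, n + 1, dtype=float)
    golden = (1 + np.sqrt(5)) / 2
    r = np.sqrt(idx / n)
    theta = 2 * np.pi * idx / golden**2
    xy = np.column_stack([r * np.cos(theta), r * np.sin(theta)])
    names = [f"E{i}" for i in range(1, n + 1)]
    return names, xy


def layout_positions(n_channels: int = 64) -> tuple[list[str], np.ndarray]:
    """Return ``(channel_names, xy)`` for an idealized scalp layout.

    Parameters
    ----------
    n_channels
        Number of electrodes. 64 maps to the standard 10/20-extended
        montage; other values use a deterministic sunflower disc layout.

    Returns
    -------
    names : list of str
    xy : ndarray, shape (n_channels, 2)
        Positions scaled to the unit disc.
    """
    if n_channels < 2:
        raise ParameterError("a scalp layout needs at least 2 electrodes")
    if n_channels == 64:
        return _standard_64()
    return _sunflower(n_channels)
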