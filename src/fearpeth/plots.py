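"""PSTH and population heat-map figures for z-score profiles."""

from __future__ import annotations

import numpy as np

from .perievent import ClassifierParams, ZScoreProfile


def plot_psth(profile: ZScoreProfile, params: ClassifierParams | None = None, ax=None):
    """Bar PSTH of one unit's trial-averaged z profile around the event."""
    import matplotlib.pyplot as plt

    params = params or ClassifierParams()
    if ax is None:
        _, ax = plt.subplots(figsize=(4, 3))
    left = params.bin_edges[:-1]
    ax.bar(left, profile.z, width=params.bin_width, align="edge", color="0.4")
    ax.axvline(0.0, color="k", lw=0.8)
    ax.axhline(params.z_threshold, color="r", ls="--", lw=0.8)
    ax.axhline(-params.z_threshold, color="r", ls="--", lw=0.8)
    ax.set_xlabel("time from event (s)")
    ax.set_ylabel("z")
    ax.set_title(f"{profile.unit_id} · {profile.event_label} · {profile.n_events} events")
    return ax


def plot_population_heatmap(
    profiles: list[ZScoreProfile], params: ClassifierParams | None = None, ax=None
):
    """Units × bins heat map of z profiles, rows sorted by peak latency.

    Peak latency is the earliest largest-|z| response bin, so units with
    the fastest responses appear at the top.
    """
    import matplotlib.pyplot as plt

    params = params or ClassifierParams()
    if not profiles:
        raise ValueError("no profiles to plot")
    z = np.vstack([p.z for p in profiles])
    peaks = [int(np.argmax(np.abs(p.z[params.response_bins]))) for p in profiles]
    order = np.argsort(peaks, kind="stable")
    if ax is None:
        _, ax = plt.subplots(figsize=(5, 4))
    extent = (params.bin_edges[0], params.bin_edges[-1], len(profiles), 0)
    im = ax.imshow(z[order], aspect="auto", cmap="RdBu_r", vmin=-4, vmax=4, extent=extent)
    ax.axvline(0.0, color="k", lw=0.8)
    ax.set_xlabel("time from event (s)")
    ax.set_ylabel("unit (sorted by peak latency)")
    ax.figure.colorbar(im, ax=ax, label="z")
    return ax
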