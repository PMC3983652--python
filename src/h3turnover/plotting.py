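"""Minimal plotting helpers for profiles and turnover distributions."""

from __future__ import annotations

import numpy as np


def plot_profiles(profiles, spec, group: str = "all", ax=None):
    """Line plot of metagene profiles over time for one expression group.

    ``profiles`` is the hours -> DataFrame mapping from
    :func:`h3turnover.metagene.timecourse_profiles`.
    """
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(7, 3.5))
    for hours, df in profiles.items():
        if group not in df.index:
            continue
        ax.plot(np.arange(spec.n_windows), df.loc[group].to_numpy(),
                label=f"{hours:g} h", lw=1)
    for x in (spec.n_upstream, spec.n_upstream + spec.body_windows):
        ax.axvline(x, color="grey", lw=0.5, ls="--")
    ax.set_xticks([0, spec.n_upstream, spec.n_upstream + spec.body_windows,
                   spec.n_windows - 1])
    ax.set_xticklabels([f"-{spec.upstream // 1000} kb", "TSS", "TES",
                        f"+{spec.downstream // 1000} kb"])
    ax.set_ylabel("reads / base / M")
    ax.legend(fontsize=7, ncol=2)
    return ax


def plot_ti_distribution(fits, bins: int = 40, ax=None):
    """Histogram of scaled turnover indices."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(5, 3))
    ax.hist([f.ti_scaled for f in fits], bins=bins, color="steelblue")
    ax.set_xlabel("turnover index (scaled)")
    ax.set_ylabel("peaks")
    return ax
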