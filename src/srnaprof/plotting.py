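"""Optional plots: per-sample length histograms and stacked category bars."""

from __future__ import annotations

from typing import Mapping, Sequence

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402

from .annotation import CATEGORIES, CategoryProfile
from .profiling import LengthProfile


def plot_length_profiles(profiles: Mapping[str, LengthProfile], path: str) -> None:
    fig, axes = plt.subplots(len(profiles), 1, sharex=True,
                             figsize=(6, 1.8 * len(profiles)), squeeze=False)
    for ax, (sid, lp) in zip(axes.ravel(), profiles.items()):
        s = lp.as_series()
        ax.bar(s.index, s.values, width=0.8)
        ax.set_ylabel(sid, fontsize=8)
    axes.ravel()[-1].set_xlabel("insert length (nt)")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_category_profiles(profiles: Mapping[str, CategoryProfile],
                           path: str,
                           categories: Sequence[str] = CATEGORIES) -> None:
    samples = list(profiles)
    fig, ax = plt.subplots(figsize=(1.0 + 0.8 * len(samples), 4))
    bottoms = [0.0] * len(samples)
    for cat in categories:
        vals = [profiles[s].percentages.get(cat, 0.0) for s in samples]
        ax.bar(samples, vals, bottom=bottoms, label=cat)
        bottoms = [b + v for b, v in zip(bottoms, vals)]
    ax.set_ylabel("% of annotated reads")
    ax.legend(fontsize=7, ncol=2)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
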