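"""Benchmark figures: FHD and PVMS across stance, per geometry."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402

__all__ = ["plot_fhd", "plot_pvms"]

_COLORS = {
    "inertia_relief": "k",
    "fixed_knee": "tab:red",
    "springs": "tab:green",
    "isostatic": "tab:orange",
    "mid_shaft": "tab:purple",
    "biomechanical": "tab:blue",
}


def plot_fhd(outcomes: dict, geometry: str, path) -> None:
    """2x2 panel of FHD components over stance for one geometry."""
    comps = ["fhd_si", "fhd_ml", "fhd_ap", "fhd_resultant"]
    titles = ["superior-inferior", "medial-lateral", "anterior-posterior", "resultant"]
    fig, axes = plt.subplots(2, 2, figsize=(9, 7), sharex=True)
    for ax, comp, title in zip(axes.ravel(), comps, titles):
        for (geom, method), series in sorted(outcomes.items()):
            if geom != geometry:
                continue
            y = getattr(series, comp)
            x = [i / (len(y) - 1) for i in range(len(y))]
            ax.plot(x, y, label=method, color=_COLORS.get(method))
        ax.set_title(title)
        ax.set_ylabel("FHD (mm)")
        ax.grid(alpha=0.3)
    axes[1, 0].set_xlabel("stance fraction")
    axes[1, 1].set_xlabel("stance fraction")
    axes[0, 0].legend(fontsize=7)
    fig.suptitle(f"Femoral head deflection, {geometry}")
    fig.tight_layout()
    fig.savefig(path, dpi=110)
    plt.close(fig)


def plot_pvms(outcomes: dict, geometry: str, path) -> None:
    """Peak von Mises stress over stance for one geometry."""
    fig, ax = plt.subplots(figsize=(6, 4))
    for (geom, method), series in sorted(outcomes.items()):
        if geom != geometry:
            continue
        y = series.pvms
        x = [i / (len(y) - 1) for i in range(len(y))]
        ax.plot(x, y, label=method, color=_COLORS.get(method))
    ax.set_xlabel("stance fraction")
    ax.set_ylabel("PVMS (MPa)")
    ax.set_title(f"Peak von Mises stress, {geometry}")
    ax.grid(alpha=0.3)
    ax.legend(fontsize=7)
    fig.tight_layout()
    fig.savefig(path, dpi=110)
    plt.close(fig)
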