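"""Figure rendering: kymographs and phase-diagram maps."""

from __future__ import annotations

import numpy as np

_DIRECTION_COLORS = {
    "downstream": "#c0392b",
    "upstream": "#2e6da4",
    "multistable": "#27ae60",
    "no_pattern": "#bdbdbd",
    "mixed": "#f1c40f",
}


def kymograph_figure(kymo: np.ndarray, times, length, species: str = "m_d",
                     path=None):
    """Space–time map with axes in μm and s; writes ``path`` if given."""
    import matplotlib
    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 4))
    im = ax.imshow(kymo, aspect="auto", origin="lower", cmap="inferno",
                   extent=(0.0, float(length), float(times[0]),
                           float(times[-1])))
    ax.set_xlabel("x (μm)")
    ax.set_ylabel("t (s)")
    fig.colorbar(im, ax=ax, label=f"{species} (1/μm²)")
    if path is not None:
        fig.savefig(path, dpi=150, bbox_inches="tight")
        plt.close(fig)
    return fig


def phase_diagram_figure(points, path=None):
    """Direction map over (E:D, v_f) from a list of PhasePoints."""
    import matplotlib
    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt
    from minflow.sweeps import phase_point_label

    fig, ax = plt.subplots(figsize=(5, 4))
    for pt in points:
        label = phase_point_label(pt)
        ax.scatter(pt.ed_ratio, pt.v_f, s=120, marker="s",
                   color=_DIRECTION_COLORS.get(label, "#000000"))
    ax.set_xlabel("E:D ratio")
    ax.set_ylabel("flow velocity (μm/s)")
    handles = [plt.Line2D([], [], marker="s", ls="", color=c, label=l)
               for l, c in _DIRECTION_COLORS.items()]
    ax.legend(handles=handles, fontsize=7, loc="best")
    if path is not None:
        fig.savefig(path, dpi=150, bbox_inches="tight")
        plt.close(fig)
    return fig
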