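"""Static figure export (optional; requires matplotlib).

Panels mirror the study's standard views: normalized impulse responses of
the four pathway transfer functions, and per-subject fit overlays.
"""

from __future__ import annotations

import numpy as np

from .reduction import reference_tf


def plot_impulse_responses(path, horizon: float = 12.0, dt: float = 1e-3):
    """Normalized impulse responses of the four reference pathway TFs."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    t = np.arange(0.0, horizon, dt)
    fig, ax = plt.subplots(figsize=(6, 4))
    for pw in (1, 2, 3, 4):
        tf = reference_tf(pw)
        h = tf.impulse_response(t)
        ax.plot(t, h / np.max(np.abs(h)), label=f"pathway {pw}")
    ax.set_xlabel("time (s)")
    ax.set_ylabel("normalized impulse response")
    ax.legend(frameon=False)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
    return path


def plot_fit(times, data, prediction, path, title: str = ""):
    """Overlay of a normalized tHb series and a model prediction."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 3.2))
    ax.plot(times, data, lw=0.8, color="0.4", label="tHb (normalized)")
    ax.plot(times, prediction, lw=1.4, color="crimson", label="model")
    ax.set_xlabel("time (s)")
    ax.set_ylabel("normalized tHb")
    if title:
        ax.set_title(title)
    ax.legend(frameon=False)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
    return path
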