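"""Small plotting helpers for per-joint time series."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt  # noqa: E402
import numpy as np  # noqa: E402


def plot_joint_moments(series: dict, joints, path, title=None):
    """Per-joint net-moment magnitude traces, one panel per joint.

    ``series`` maps a label (e.g. 'dynamic'/'static') to a
    JointLoadSeries; layouts mirror the usual side-by-side comparison of
    static and dynamic estimates.
    """
    joints = list(joints)
    fig, axes = plt.subplots(len(joints), 1, figsize=(8, 2.2 * len(joints)),
                             sharex=True, squeeze=False)
    for ax, joint in zip(axes[:, 0], joints):
        for label, jls in series.items():
            t = np.arange(jls.n_frames) / jls.frame_rate
            ax.plot(t, jls.moment_norm(joint), label=label)
        ax.set_ylabel(f"{joint}\n|M| (N·m)")
        ax.legend(loc="upper right", fontsize=8)
    axes[-1, 0].set_xlabel("time (s)")
    if title:
        fig.suptitle(title)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return path
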