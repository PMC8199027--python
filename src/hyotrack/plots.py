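"""Report figures: trace overlays, precision plot, per-frame error plot."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np

from .metrics import EvalReport
from .trace import GroundTruthTrack, Trace

__all__ = ["plot_trace_overlay", "plot_precision", "plot_center_error"]


def plot_trace_overlay(trace: Trace, gt: GroundTruthTrack, path=None):
    """2D path plus per-axis traces between hyoid onset and offset."""
    onset = gt.events["hyoid_onset"]
    offset = gt.events["hyoid_offset"]
    ref = gt.points[onset]
    g = gt.points[onset : offset + 1] - ref
    p = trace.points[onset : offset + 1] - ref
    frames = np.arange(onset, offset + 1)

    fig, axes = plt.subplots(1, 3, figsize=(12, 3.5))
    axes[0].plot(g[:, 0], g[:, 1], "-", color="tab:blue", label="ground truth")
    axes[0].plot(p[:, 0], p[:, 1], "-", color="tab:orange", label="inference")
    axes[0].invert_yaxis()
    axes[0].set_xlabel("x (px)")
    axes[0].set_ylabel("y (px)")
    axes[0].set_title("hyoid path (onset to offset)")
    axes[0].legend(fontsize=8)
    for k, (ax, lbl) in enumerate(zip(axes[1:], ("x", "y"))):
        ax.plot(frames, g[:, k], color="tab:blue")
        ax.plot(frames, p[:, k], color="tab:orange")
        ax.set_xlabel("frame")
        ax.set_ylabel(f"{lbl} (px, rel. onset)")
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=120)
        plt.close(fig)
    return fig


def plot_precision(summary: dict, path=None):
    """Mean precision over sequences vs center-error threshold."""
    curve = np.asarray(summary["precision_curve"])
    fig, ax = plt.subplots(figsize=(5, 4))
    p10 = summary["precision_at_10"]["mean"]
    ax.plot(curve[:, 0], curve[:, 1], label=f"precision@10px = {100 * p10:.1f}%")
    ax.set_xlabel("center-error threshold (px)")
    ax.set_ylabel("precision")
    ax.set_ylim(0, 1.02)
    ax.legend(loc="lower right")
    ax.grid(alpha=0.3)
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=120)
        plt.close(fig)
    return fig


def plot_center_error(report: EvalReport, path=None):
    """Per-frame center error for one sequence."""
    fig, ax = plt.subplots(figsize=(7, 3))
    ax.plot(np.asarray(report.ce_series))
    ax.set_xlabel("frame")
    ax.set_ylabel("center error (px)")
    ax.set_title(report.sequence_id)
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=120)
        plt.close(fig)
    return fig
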