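"""Optional diagnostic plots (PNG); no analysis logic lives here.

matplotlib is imported lazily so the core pipeline has no hard plotting
dependency.
"""

from __future__ import annotations

import os

import numpy as np

from .pipeline import ResultTables
from .transients import RegionTrace

__all__ = ["plot_trace", "plot_result"]


def plot_trace(trace: RegionTrace, peak_indices, path: str) -> str:
    """Trace with detected peaks marked."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(8, 3))
    ax.plot(trace.times_ms, trace.values, lw=0.8, color="tab:blue")
    peaks = np.asarray(peak_indices, dtype=int)
    if peaks.size:
        ax.plot(trace.times_ms[peaks], trace.values[peaks], "v", color="tab:red", ms=6)
    ax.set_xlabel("time (ms)")
    ax.set_ylabel("mean intensity")
    ax.set_title(f"region {trace.region_label}")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return path


def plot_result(result: ResultTables, outdir: str) -> list[str]:
    """Per-slice local AR heat strip + global pair ratios for one image."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    os.makedirs(outdir, exist_ok=True)
    written: list[str] = []
    if result.report is None:
        return written
    stem = os.path.splitext(result.image)[0] or "image"

    fig, (ax0, ax1) = plt.subplots(
        2, 1, figsize=(7, 5), gridspec_kw={"height_ratios": [2, 1]}
    )
    im = ax0.imshow(
        result.report.local_ratios,
        aspect="auto",
        origin="lower",
        cmap="viridis",
        vmin=0.0,
    )
    ax0.set_xlabel("beat pair")
    ax0.set_ylabel("slice")
    ax0.set_title("local alternans ratio (max +dF/dt)")
    fig.colorbar(im, ax=ax0, label="AR")

    pairs = [p.pair_index for p in result.report.global_pairs]
    ratios = [p.ratio for p in result.report.global_pairs]
    ax1.bar(pairs, ratios, color="tab:gray")
    ax1.set_xlabel("beat pair")
    ax1.set_ylabel("global AR")
    ax1.set_ylim(0, 1)
    fig.tight_layout()
    path = os.path.join(outdir, f"{stem}_alternans.png")
    fig.savefig(path, dpi=120)
    plt.close(fig)
    written.append(path)
    return written
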