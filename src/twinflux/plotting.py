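"""Basic ITD-distribution figure (optional; requires matplotlib)."""

from __future__ import annotations

from .tables import ITDMatrix


def itd_histogram(itd: ITDMatrix, md: float | None = None, ax=None, bins: int = 40):
    """Histogram of all pair-by-genus ITD cells with the grand mean marked.

    Returns the matplotlib Axes.
    """
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(6, 4))
    values = itd.itd.to_numpy().ravel()
    ax.hist(values, bins=bins, color="#4878a8", edgecolor="white")
    if md is None:
        md = float(values.mean())
    ax.axvline(md, color="#b0413e", linestyle="--", label=f"MD = {md:.3f}")
    ax.set_xlabel("intra-twin difference (ITD)")
    ax.set_ylabel("pair x genus cells")
    ax.legend(frameon=False)
    return ax
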