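"""Isoslope diagnostic plot.

The log10–log10 scatter of absolute absorbed dose against applied dose,
with the identity line (100 % relative absorption) drawn solid and
slope-1 "isoslopes" at tenfold-spaced intercepts marking 10, 1 and 0.1 %
relative absorption drawn dotted.  Fitted lines running parallel to the
isoslopes indicate dose-proportional absorption; their height reads off
the relative absorption value directly.
"""

from __future__ import annotations

import numpy as np

from .loglog import LogLogFit
from .study_data import Endpoint, StudyTable, endpoint_series

__all__ = ["isoslope_plot"]

#: relative absorption levels (%) of the dotted reference lines
ISOSLOPE_LEVELS = (10.0, 1.0, 0.1)


def isoslope_plot(
    table: StudyTable,
    fits: list[LogLogFit] | None = None,
    endpoint: Endpoint | str = Endpoint.RF,
    path=None,
    ax=None,
):
    """Draw the isoslope diagnostic plot; optionally save to ``path``.

    Returns the matplotlib Axes. ``fits`` are overplotted per stratum
    over the x-range of the data.
    """
    import matplotlib.pyplot as plt

    pairs = np.asarray(endpoint_series(table, endpoint), dtype=float)
    pairs = pairs[(pairs > 0).all(axis=1)]
    if pairs.size == 0:
        raise ValueError("no positive (applied, absorbed) pair to plot")
    if ax is None:
        _, ax = plt.subplots(figsize=(6, 5))
    x, y = pairs[:, 0], pairs[:, 1]
    ax.scatter(x, y, s=25, zorder=3, color="0.2", label=None)
    xline = np.array([min(x.min(), 10 ** -2), max(x.max(), 10 ** 3)])
    ax.plot(xline, xline, "-", color="black", lw=1, label="100% (identity)")
    for level in ISOSLOPE_LEVELS:
        ax.plot(xline, xline * level / 100.0, ":", color="grey", lw=1)
        ax.annotate(
            f"{level:g}%",
            (xline[1], xline[1] * level / 100.0),
            fontsize=8,
            color="grey",
        )
    for fit in fits or []:
        xr = np.array([x.min(), x.max()])
        yr = 10 ** (fit.intercept + fit.slope * np.log10(xr))
        ax.plot(xr, yr, "-", lw=1.5, label=fit.stratum or None, zorder=4)
    ax.set_xscale("log")
    ax.set_yscale("log")
    ax.set_xlabel("applied dose (µg/cm²)")
    ax.set_ylabel("absorbed dose (µg/cm²)")
    if fits:
        ax.legend(fontsize=8)
    if path is not None:
        ax.figure.savefig(path, bbox_inches="tight")
    return ax
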