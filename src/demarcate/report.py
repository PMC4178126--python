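"""Colour-coded identity-matrix figures and identity-frequency histograms.

The matrix rendering mirrors the classic demarcation display: a square
heat map with sequence labels written horizontally on the left and
vertically along the bottom, a colour key, and optionally a taxonomic
demarcation threshold that splits the colour scale in two (cells at or
above the threshold in shades of one colour, cells below in another).
Troughs in the identity histogram mark candidate demarcation cut-offs.

All figure output is deterministic: fixed fonts, fixed SVG hash salt, no
embedded timestamps.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import matplotlib
import numpy as np

matplotlib.use("Agg")
import matplotlib.pyplot as plt
from matplotlib.colors import BoundaryNorm, ListedColormap

from .identity import IdentityMatrix, PairRecord

matplotlib.rcParams["svg.hashsalt"] = "demarcate"

#: metadata passed to savefig so re-renders are byte-identical
_NO_TIMESTAMP = {"svg": {"Date": None}, "pdf": {"CreationDate": None},
                 "png": {}}

DEFAULT_CONTINUOUS_CMAP = "viridis"
DEFAULT_THRESHOLD_COLOURS = ("#3b4cc0", "#b40426")  # below, above
ANNOTATE_MAX_SEQUENCES = 30


class ReportError(ValueError):
    """Raised for invalid rendering input."""


def reorder_matrix(matrix: IdentityMatrix, order: Sequence[str]) -> IdentityMatrix:
    """Simultaneous row+column permutation of an identity matrix."""
    return matrix.reorder(order)


@dataclass
class IdentityHistogram:
    """Frequency distribution of pairwise identities, in percent bins.

    Bins are half-open [lo, hi) except the last, which includes 100.
    Proportions are counts divided by the number of pairs (each unique pair
    counted once), so they sum to 1.
    """

    bin_edges: np.ndarray
    proportions: np.ndarray

    def __post_init__(self) -> None:
        self.bin_edges = np.asarray(self.bin_edges, dtype=float)
        self.proportions = np.asarray(self.proportions, dtype=float)
        if self.proportions.size != self.bin_edges.size - 1:
            raise ReportError("need one proportion per bin")

    def write_csv(self, path) -> None:
        with open(path, "w", newline="\n") as fh:
            fh.write("bin_lo,bin_hi,proportion\n")
            for lo, hi, p in zip(self.bin_edges[:-1], self.bin_edges[1:],
                                 self.proportions):
                fh.write(f"{lo:g},{hi:g},{p!r}\n")


def identity_histogram(pairs: Iterable[PairRecord],
                       bin_width: float = 1.0) -> IdentityHistogram:
    """Histogram of percent identities over unique pairs."""
    pairs = list(pairs)
    if not pairs:
        raise ReportError("cannot histogram an empty pair set")
    if bin_width <= 0 or abs(100 / bin_width - round(100 / bin_width)) > 1e-9:
        raise ReportError("bin_width must be positive and divide 100")
    edges = np.linspace(0.0, 100.0, int(round(100 / bin_width)) + 1)
    pct = np.array([100.0 * p.identity for p in pairs])
    counts, _ = np.histogram(pct, bins=edges)  # last bin closed at 100
    return IdentityHistogram(edges, counts / len(pairs))


@dataclass
class ColourScheme:
    """Colour mapping for the identity matrix.

    ``continuous`` maps the observed identity range onto a colour map
    (data-ranged, to maximise contrast); ``thresholded`` paints each
    interval between consecutive percent cut-offs (e.g. a species
    demarcation threshold) in its own colour.
    """

    mode: str = "continuous"
    thresholds: tuple[float, ...] = ()
    colours: tuple[str, ...] = ()
    cmap: str = DEFAULT_CONTINUOUS_CMAP

    def __post_init__(self) -> None:
        if self.mode not in ("continuous", "thresholded"):
            raise ReportError(f"unknown colour mode {self.mode!r}")
        ts = tuple(float(t) for t in self.thresholds)
        if any(not (0 < t < 100) for t in ts):
            raise ReportError("thresholds must lie strictly inside (0, 100)")
        if any(b <= a for a, b in zip(ts, ts[1:])):
            raise ReportError("thresholds must be strictly ascending")
        self.thresholds = ts
        if self.mode == "thresholded":
            if not ts:
                raise ReportError("thresholded mode needs at least one cut-off")
            if not self.colours:
                if len(ts) == 1:
                    self.colours = DEFAULT_THRESHOLD_COLOURS
                else:
                    cm = plt.get_cmap("coolwarm")
                    self.colours = tuple(
                        matplotlib.colors.to_hex(cm(x))
                        for x in np.linspace(0, 1, len(ts) + 1)
                    )
            if len(self.colours) != len(ts) + 1:
                raise ReportError("need one colour per threshold interval")

    @classmethod
    def thresholded(cls, *thresholds: float,
                    colours: tuple[str, ...] = ()) -> "ColourScheme":
        return cls(mode="thresholded", thresholds=tuple(thresholds),
                   colours=colours)


def _cmap_and_norm(scheme: ColourScheme, pct: np.ndarray, s: int):
    if scheme.mode == "thresholded":
        bounds = [0.0, *scheme.thresholds, 100.0 + 1e-7]
        cmap = ListedColormap(list(scheme.colours))
        return cmap, BoundaryNorm(bounds, cmap.N)
    off = pct[~np.eye(s, dtype=bool)]
    vmin = float(off.min()) if off.size else 0.0
    vmax = 100.0
    if vmin >= vmax:
        vmin = vmax - 1.0
    return plt.get_cmap(scheme.cmap), matplotlib.colors.Normalize(vmin, vmax)


def cell_colours(matrix: IdentityMatrix,
                 scheme: ColourScheme | None = None) -> list[list[str]]:
    """Hex colour assigned to each matrix cell under a scheme.

    This is the mapping :func:`render_matrix` paints with; exposed so the
    colour semantics (e.g. which cells fall below a demarcation threshold)
    can be inspected without parsing image files.
    """
    scheme = scheme or ColourScheme()
    s = len(matrix.ids)
    pct = 100.0 * matrix.values
    cmap, norm = _cmap_and_norm(scheme, pct, s)
    return [[matplotlib.colors.to_hex(cmap(norm(v))) for v in row]
            for row in pct]


def _savefig(fig, path) -> None:
    path = Path(path)
    fmt = path.suffix.lstrip(".").lower()
    if fmt not in ("png", "svg", "pdf"):
        raise ReportError(f"unsupported figure format {fmt!r}")
    fig.savefig(path, format=fmt, metadata=_NO_TIMESTAMP[fmt] or None)
    plt.close(fig)


def render_matrix(matrix: IdentityMatrix, scheme: ColourScheme | None,
                  path, annotate: bool | None = None) -> Path:
    """Render a (tree-ordered) identity matrix as a colour-coded heat map.

    Percent values are printed in the cells for small matrices (S <= 30 by
    default).  Output format follows the file suffix (png/svg/pdf).
    """
    scheme = scheme or ColourScheme()
    s = len(matrix.ids)
    pct = 100.0 * matrix.values
    if annotate is None:
        annotate = s <= ANNOTATE_MAX_SEQUENCES

    side = max(4.0, 0.32 * s + 1.8)
    fig, ax = plt.subplots(figsize=(side + 1.6, side))
    cmap, norm = _cmap_and_norm(scheme, pct, s)
    grid = np.arange(s + 1)
    im = ax.pcolormesh(grid, grid, pct, cmap=cmap, norm=norm,
                       edgecolors="none")
    ax.invert_yaxis()  # first sequence at the top, as in a tree drawing
    ax.set_aspect("equal")
    centres = np.arange(s) + 0.5
    ax.set_xticks(centres)
    ax.set_yticks(centres)
    ax.set_xticklabels(matrix.ids, rotation=90, fontsize=7)
    ax.set_yticklabels(matrix.ids, fontsize=7)
    ax.xaxis.set_ticks_position("bottom")
    ax.yaxis.set_ticks_position("left")
    if annotate:
        for i in range(s):
            for j in range(s):
                ax.text(j + 0.5, i + 0.5, f"{pct[i, j]:.0f}", ha="center",
                        va="center", fontsize=6, color="white")
    cbar = fig.colorbar(im, ax=ax, fraction=0.046, pad=0.04)
    cbar.set_label("pairwise identity (%)")
    fig.tight_layout()
    _savefig(fig, path)
    return Path(path)


def render_histogram(hist: IdentityHistogram, path,
                     thresholds: Sequence[float] = ()) -> Path:
    """Bar plot of the identity distribution, optional threshold markers."""
    fig, ax = plt.subplots(figsize=(7, 4))
    widths = np.diff(hist.bin_edges)
    ax.bar(hist.bin_edges[:-1], hist.proportions, width=widths,
           align="edge", color="#4878b0", edgecolor="none")
    for t in thresholds:
        ax.axvline(float(t), color="#b40426", linestyle="--", linewidth=1)
    ax.set_xlabel("pairwise identity (%)")
    ax.set_ylabel("proportion of pairs")
    ax.set_xlim(0, 100)
    fig.tight_layout()
    _savefig(fig, path)
    return Path(path)
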