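"""Manhattan-style figures for marker and bin statistics.

One panel per requested statistic, markers coloured per chromosome from a
named palette, with a depth-weighted moving-average overlay, a dashed
Bonferroni threshold on p-value panels and an averaged confidence band on
delta(SNP-index) panels.  Appearance is controlled by a JSON style file
(palettes, dot size, transparency, line width, resolution, figure size and
chromosome display aliases); a caption file is emitted beside each figure.
"""

from __future__ import annotations

import copy
import json
import math
from pathlib import Path
from typing import Mapping, Sequence

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from .bsa_statistics import (
    bonferroni_threshold,
    boost,
    delta_ci_bounds,
    ed_power_series,
    weighted_moving_average,
)

FORMATS = ("eps", "jpg", "pdf", "png", "svg")

DEFAULT_STYLE: dict = {
    "palette": "standard",
    "palettes": {
        "standard": ["#1f77b4", "#ff7f0e", "#2ca02c", "#d62728", "#9467bd", "#8c564b"],
        # Wong (2011) colour-blind-safe palette
        "colorblind": ["#0072B2", "#E69F00", "#009E73", "#CC79A7", "#56B4E9", "#D55E00"],
    },
    "dot_size": 3.0,
    "alpha": 0.6,
    "line_width": 1.5,
    "dpi": 300,
    "figure_width": 12.0,
    "panel_height": 2.6,
    "chromosome_aliases": {},
}

#: plottable columns in display order, with axis labels
PLOTTABLE = {
    "SNPIDX_R": "SNP-index (R)",
    "SNPIDX_D": "SNP-index (D)",
    "SNPIDX_H": "SNP-index (H)",
    "SNPIDX_L": "SNP-index (L)",
    "DELTA": "delta(SNP-index)",
    "PVALUE": "-log10(p)",
    "GSTAT": "G statistic",
    "ED": "ED (marker)",
    "ED100": "ED100^4",
    "BOOST": "boost",
}


class StyleError(ValueError):
    pass


def load_style(path: str | Path | None = None) -> dict:
    """Merge user JSON overrides into the built-in defaults.

    An absent path returns the defaults; unknown top-level keys are
    rejected so typos do not silently do nothing.
    """
    style = copy.deepcopy(DEFAULT_STYLE)
    if path is None:
        return style
    with open(path) as fh:
        try:
            user = json.load(fh)
        except json.JSONDecodeError as exc:
            raise StyleError(f"malformed style JSON: {exc}") from exc
    for key, value in user.items():
        if key not in DEFAULT_STYLE:
            raise StyleError(
                f"unknown style key {key!r}; valid keys: "
                + ", ".join(sorted(DEFAULT_STYLE))
            )
        if key in ("palettes", "chromosome_aliases"):
            style[key].update(value)
        else:
            style[key] = value
    return style


def _palette(style: Mapping, name: str | None) -> list[str]:
    name = name or style.get("palette", "standard")
    palettes = style["palettes"]
    if name not in palettes:
        raise StyleError(
            f"unknown palette {name!r}; available: " + ", ".join(sorted(palettes))
        )
    return list(palettes[name])


def _weights(df: pd.DataFrame) -> np.ndarray | None:
    count_cols = [c for c in df.columns if c.endswith(("_A", "_B"))]
    if not count_cols:
        return None
    return df[count_cols].sum(axis=1).to_numpy(dtype=float)


def render(
    rows: Sequence[Mapping],
    out_prefix: str | Path,
    statistics: Sequence[str] | None = None,
    chromosomes: Sequence[str] | None = None,
    style: Mapping | None = None,
    fmt: str = "png",
    palette: str | None = None,
    window: int = 25,
    alpha_level: float = 0.05,
    ed_window: int = 100,
) -> dict:
    """Render the requested panels and an auto-generated caption.

    Statistics default to every plottable column found in the rows (plus
    ED100^4 when per-marker distances are present).  Returns a dict with
    the figure path, the caption path, the threshold drawn on p-value
    panels and the number of markers plotted.  Rendering never mutates the
    input rows; SVG output is byte-stable for fixed input and style.
    """
    if fmt not in FORMATS:
        raise ValueError(f"unsupported format {fmt!r}; choose from {', '.join(FORMATS)}")
    style = style or load_style(None)
    colors = _palette(style, palette)
    df = pd.DataFrame(list(rows))
    if df.empty:
        raise ValueError("no rows to plot")
    all_chroms = list(dict.fromkeys(df["CHROM"]))
    if chromosomes is None:
        chroms = all_chroms
    else:
        chroms = list(chromosomes)
        if not chroms:
            raise ValueError("empty chromosome selection")
        unknown = [c for c in chroms if c not in all_chroms]
        if unknown:
            raise ValueError(f"unknown chromosome(s): {', '.join(unknown)}")
    df = df[df["CHROM"].isin(chroms)].reset_index(drop=True)

    if statistics is None:
        stats = [c for c in PLOTTABLE if c in df.columns]
        if "ED" in df.columns:
            stats.append("ED100")
    else:
        stats = list(statistics)
        for s in stats:
            if s not in PLOTTABLE:
                raise ValueError(f"unknown statistic {s!r}")
            if s not in df.columns and s not in ("ED100", "BOOST"):
                raise ValueError(f"statistic {s!r} not present in the input header")
    if not stats:
        raise ValueError("no plottable statistics in input")

    n_markers = len(df)
    threshold = bonferroni_threshold(alpha_level, n_markers)
    aliases = style.get("chromosome_aliases", {})

    # genome-wide x coordinate: chromosomes laid end to end
    offsets: dict[str, float] = {}
    ticks, tick_labels = [], []
    run = 0.0
    for c in chroms:
        sub = df[df["CHROM"] == c]
        offsets[c] = run
        span = float(sub["POS"].max()) if len(sub) else 0.0
        ticks.append(run + span / 2.0)
        tick_labels.append(str(aliases.get(c, c)))
        run += span * 1.02

    with plt.rc_context({"svg.hashsalt": "bulkmap"}):
        fig, axes = plt.subplots(
            len(stats), 1, sharex=True, squeeze=False,
            figsize=(style["figure_width"], style["panel_height"] * len(stats)),
        )
        axes = axes[:, 0]
        for ax, stat in zip(axes, stats):
            for ci, c in enumerate(chroms):
                sub = df[df["CHROM"] == c]
                x = sub["POS"].to_numpy(dtype=float) + offsets[c]
                color = colors[ci % len(colors)]
                w = _weights(sub)
                if stat == "ED100":
                    ed = sub["ED"].to_numpy(dtype=float)
                    series = ed_power_series(ed, window=ed_window)
                    if series.size:
                        ax.plot(
                            x[ed_window - 1 :], series, color=color,
                            lw=style["line_width"],
                        )
                    continue
                if stat == "BOOST":
                    src = next(
                        (s for s in ("SNPIDX_R", "SNPIDX_H") if s in sub.columns), None
                    )
                    if src is None:
                        continue
                    ma = weighted_moving_average(
                        sub[src].to_numpy(dtype=float), w, window
                    )
                    ax.plot(x, boost(ma), color=color, lw=style["line_width"])
                    continue
                y = sub[stat].to_numpy(dtype=float)
                if stat == "PVALUE":
                    y = -np.log10(np.maximum(y, 1e-300))
                ax.scatter(
                    x, y, s=style["dot_size"], alpha=style["alpha"],
                    color=color, linewidths=0, rasterized=False,
                )
                ax.plot(
                    x, weighted_moving_average(y, w, window),
                    color=color, lw=style["line_width"],
                )
                if stat == "DELTA" and {"D_A", "R_A"} <= set(sub.columns) or (
                    stat == "DELTA" and {"H_A", "L_A"} <= set(sub.columns)
                ):
                    top, bot = ("D", "R") if "D_A" in sub.columns else ("H", "L")
                    lows, highs = [], []
                    for _, r in sub.iterrows():
                        lo, hi = delta_ci_bounds(
                            (int(r[f"{top}_A"]), int(r[f"{top}_B"])),
                            (int(r[f"{bot}_A"]), int(r[f"{bot}_B"])),
                            alpha=alpha_level, n_tests=n_markers,
                        )
                        lows.append(lo)
                        highs.append(hi)
                    ax.fill_between(
                        x,
                        weighted_moving_average(lows, w, window),
                        weighted_moving_average(highs, w, window),
                        color=color, alpha=0.2, linewidth=0,
                    )
            if stat == "PVALUE":
                ax.axhline(threshold, ls="--", color="black", lw=1.0)
            ax.set_ylabel(PLOTTABLE[stat])
        axes[-1].set_xticks(ticks)
        axes[-1].set_xticklabels(tick_labels)
        axes[-1].set_xlabel("chromosome")
        fig.align_ylabels(axes)
        fig.tight_layout()

        out_prefix = Path(out_prefix)
        out_prefix.parent.mkdir(parents=True, exist_ok=True)
        fig_path = out_prefix.with_suffix(f".{fmt}")
        metadata = {"Date": None} if fmt in ("svg", "eps") else None
        if fmt == "pdf":
            metadata = {"CreationDate": None}
        fig.savefig(fig_path, dpi=style["dpi"], format=fmt, metadata=metadata)
        plt.close(fig)

    caption = _caption(stats, chroms, aliases, window, n_markers, alpha_level, threshold)
    caption_path = out_prefix.parent / (out_prefix.name + "_caption.txt")
    caption_path.write_text(caption)
    return {
        "figure": fig_path,
        "caption": caption_path,
        "threshold": threshold,
        "n_markers": n_markers,
    }


def _caption(
    stats: Sequence[str],
    chroms: Sequence[str],
    aliases: Mapping,
    window: int,
    n_markers: int,
    alpha_level: float,
    threshold: float,
) -> str:
    shown = ", ".join(str(aliases.get(c, c)) for c in chroms)
    parts = [
        f"Bulked-segregant scan across {shown}. "
        f"Each dot corresponds to an individual biallelic marker segregating "
        f"in the mapping population ({n_markers} markers plotted)."
    ]
    letters = "abcdefghijklmnopqrstuvwxyz"
    for i, stat in enumerate(stats):
        label = PLOTTABLE[stat]
        line = f"({letters[i]}) {label}."
        if stat == "PVALUE":
            line += (
                f" The dashed line marks the Bonferroni-corrected "
                f"{alpha_level * 100:g}% significance threshold "
                f"(-log10(p) = {threshold:.3f}, n = {n_markers} tests)."
            )
        elif stat == "DELTA":
            line += (
                " The shaded band averages the per-marker limits of the "
                "Bonferroni-corrected confidence intervals for a difference "
                "of two proportions."
            )
        elif stat == "ED100":
            line += (
                " Fourth power of the sum of per-marker Euclidean distances "
                "over 100 consecutive markers; drawn only for chromosomes "
                "with enough markers."
            )
        parts.append(line)
    if any(s not in ("ED100",) for s in stats):
        parts.append(
            f"Lines show weighted moving averages over a sliding window of "
            f"{window} adjacent markers."
        )
    return "\n".join(parts) + "\n"
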