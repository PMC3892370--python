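"""Summary surfaces: burn frequencies, fire-danger trends, class tables,
climate-biomass correlations.  Pure functions of run outputs."""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .biogeography import VegClass, vegetation_fractions
from .simulator import RunOutput

__all__ = [
    "effective_burn_frequency",
    "bui_exceedance_days",
    "climate_biomass_correlation",
    "class_fraction_table",
    "representative_forested_cell",
    "summarize_run",
    "plot_class_map",
    "CLASS_COLORS",
]

#: Vegetation-class color ramp used for rendered maps (cosmetic only).
CLASS_COLORS = {
    VegClass.GRASSLAND: "#e8d86f",
    VegClass.SHRUBLAND: "#c2a14d",
    VegClass.WOODLAND: "#7faa5d",
    VegClass.FOREST: "#2d6a2f",
}


def plot_class_map(veg_classes, path, title: str | None = None) -> None:
    """Render a vegetation-class grid as a raster image (PNG/PDF by suffix)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    from matplotlib.colors import BoundaryNorm, ListedColormap

    arr = np.asarray(veg_classes)
    cmap = ListedColormap([CLASS_COLORS[vc] for vc in VegClass])
    norm = BoundaryNorm(np.arange(-0.5, len(VegClass)), cmap.N)
    fig, ax = plt.subplots(figsize=(4, 4))
    im = ax.imshow(arr, cmap=cmap, norm=norm, interpolation="nearest")
    cbar = fig.colorbar(im, ax=ax, ticks=range(len(VegClass)), shrink=0.8)
    cbar.ax.set_yticklabels([vc.name.lower() for vc in VegClass])
    ax.set_xlabel("x (west - east)")
    ax.set_ylabel("y (north - south)")
    if title:
        ax.set_title(title)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def effective_burn_frequency(burn_fractions, period_years: float) -> float:
    """Fires per century: sum of burned cell fractions over the period.

    ``burn_fractions`` is the sequence of per-fire burned fractions for one
    cell; two full burns in 100 years give 2.0, ten one-tenth burns 1.0.
    """
    if period_years <= 0:
        raise ValueError("period must be positive")
    return float(np.sum(burn_fractions)) / period_years * 100.0


def bui_exceedance_days(annual_counts, years=None):
    """Annual BUI-exceedance day counts with a least-squares trend.

    Returns ``(counts, slope)`` where ``slope`` is days yr^-1 per year.
    """
    counts = np.asarray(annual_counts, float)
    if years is None:
        years = np.arange(len(counts))
    slope = float(np.polyfit(np.asarray(years, float), counts, 1)[0]) \
        if len(counts) > 1 else 0.0
    return counts, slope


def climate_biomass_correlation(tree_c_mean, tmean_cell, ppt_cell):
    """Pearson r of cell-mean live tree C against cell-mean climate.

    Returns ``(r_vs_tmean, r_vs_ppt)``.  Requires >= 3 cells and
    non-constant inputs.
    """
    tree = np.asarray(tree_c_mean, float).ravel()
    t = np.asarray(tmean_cell, float).ravel()
    p = np.asarray(ppt_cell, float).ravel()
    if tree.size < 3:
        raise ValueError("need at least 3 cells")
    if np.ptp(tree) == 0 or np.ptp(t) == 0 or np.ptp(p) == 0:
        raise ValueError("constant inputs have undefined correlation")
    return (float(stats.pearsonr(tree, t)[0]), float(stats.pearsonr(tree, p)[0]))


def class_fraction_table(veg_classes) -> pd.DataFrame:
    """Vegetation-class percentage table for one classified grid."""
    fr = vegetation_fractions(veg_classes)
    return pd.DataFrame({"class": list(fr), "percent": list(fr.values())})


def representative_forested_cell(out: RunOutput) -> int:
    """Index of the median-fire-count cell among cells wooded at run end.

    Ties resolve to the lower fire count / lower cell index.
    """
    wooded = np.nonzero(out.veg_class[-1] >= VegClass.WOODLAND)[0]
    if wooded.size == 0:
        raise ValueError("no wooded cells at end of run")
    counts = out.fire_counts()[wooded]
    order = np.argsort(counts, kind="stable")
    return int(wooded[order[len(order) // 2]])


def summarize_run(out: RunOutput) -> dict:
    """Headline numbers for one run: class fractions, fires, burn frequency."""
    period = len(out.years)
    counts = out.fire_counts()
    eff = out.fire_counts(effective=True) / period * 100.0
    return {
        "class_percent": vegetation_fractions(out.veg_class[-1]),
        "mean_fires_per_cell": float(counts.mean()),
        "mean_effective_burn_frequency": float(eff.mean()),
        "mean_final_tree_c": float(out.tree_c[-1].mean()),
        "mean_bui_days": float(out.bui_days.mean()),
    }
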