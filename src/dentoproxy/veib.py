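"""Von Ebner incremental-band chronology.

One incremental band (a dark + light dentine couplet) records one day of
tooth formation, so the band count along a complete transect from
first-formed dentine to the pulp margin is the tooth formation time in
days; on worn or incomplete transects it is a minimum.  Band widths on the
working (occluding) versus balancing side of a crown quantify asymmetric
daily dentine deposition, and a fully erupted functional tooth with no
detectable replacement germ bounds the replacement rate from below by the
formation time.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .surfaces import BandTransect


@dataclass
class BandStats:
    n_bands: int
    mean_width: float  # µm, mean of per-band widths
    span_mean_width: float  # µm, (last - first boundary) / n_bands
    widths: np.ndarray
    side: str
    trend_slope: float  # µm per band index
    is_minimum: bool  # True when the transect is incomplete/worn
    specimen: str = ""

    @property
    def formation_days(self) -> int:
        """Days of formation (a minimum when ``is_minimum``)."""
        return self.n_bands


@dataclass
class AsymmetryResult:
    working_mean_width: float
    balancing_mean_width: float
    ratio: float  # working / balancing


@dataclass
class ReplacementBound:
    """Lower bound on the tooth replacement interval, if inferable."""

    bound_days: int | None
    formation_days: int
    fully_erupted_unworn: bool
    replacement_germ_present: bool


def band_stats(transect: BandTransect) -> BandStats:
    """Per-band widths, their mean and linear trend along the transect."""
    widths = np.diff(transect.boundaries)
    n = len(widths)
    idx = np.arange(n)
    slope = float(np.polyfit(idx, widths, 1)[0]) if n > 1 else 0.0
    span = float(transect.boundaries[-1] - transect.boundaries[0])
    return BandStats(
        n_bands=n,
        mean_width=float(widths.mean()),
        span_mean_width=span / n,
        widths=widths,
        side=transect.side,
        trend_slope=slope,
        is_minimum=not transect.complete,
        specimen=transect.specimen,
    )


def asymmetry(working: BandTransect, balancing: BandTransect) -> AsymmetryResult:
    """Working/balancing mean band widths and their ratio."""
    wm = float(np.diff(working.boundaries).mean())
    bm = float(np.diff(balancing.boundaries).mean())
    return AsymmetryResult(working_mean_width=wm, balancing_mean_width=bm, ratio=wm / bm)


def min_replacement_rate(
    formation_days: int,
    fully_erupted_unworn: bool,
    replacement_germ_present: bool,
) -> ReplacementBound:
    """Lower bound on the replacement interval from a germ-free functional
    tooth.

    If a fully erupted, essentially unworn functional tooth has no
    detectable replacement germ, the next tooth has not begun mineralising,
    so replacement cannot be faster than forming that tooth: the bound is
    the formation time.  A visible germ carries no such bound.
    """
    if formation_days <= 0:
        raise ValueError("formation_days must be positive")
    bound = None
    if fully_erupted_unworn and not replacement_germ_present:
        bound = int(formation_days)
    return ReplacementBound(
        bound_days=bound,
        formation_days=int(formation_days),
        fully_erupted_unworn=fully_erupted_unworn,
        replacement_germ_present=replacement_germ_present,
    )
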