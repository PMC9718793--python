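"""Traditional 2D microwear: pit/scratch classification and summary variables.

Wear features digitized on a micrograph are line segments with a width.
Features with a length:width ratio below 4:1 are pits, above 4:1 scratches;
anything whose largest dimension exceeds 0.5 mm is macrowear and is excluded
from microwear statistics.  Four summary variables are computed per
micrograph and pooled per tooth: percentage incidence of pitting, mean
scratch width, mean pit width, and mean pit length.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from skimage.measure import label, regionprops

from .errors import EmptyDataError

#: Microwear/macrowear size boundary in micrometres (0.5 mm).
MACROWEAR_THRESHOLD_UM = 500.0

#: Length:width ratio separating pits from scratches.
PIT_SCRATCH_RATIO = 4.0


@dataclass
class MicrowearFeature:
    """One digitized wear feature in the micrograph frame (µm)."""

    p1: tuple[float, float]
    p2: tuple[float, float]
    width: float
    micrograph_id: str = ""

    def __post_init__(self):
        if self.width <= 0:
            raise ValueError(f"feature width must be positive, got {self.width}")

    @property
    def length(self) -> float:
        return float(np.hypot(self.p2[0] - self.p1[0], self.p2[1] - self.p1[1]))

    @property
    def midpoint(self) -> tuple[float, float]:
        return (
            0.5 * (self.p1[0] + self.p2[0]),
            0.5 * (self.p1[1] + self.p2[1]),
        )


@dataclass
class MicrowearSummary:
    """The four 2D microwear variables plus dispersion and bookkeeping."""

    n_features: int
    n_pits: int
    n_scratches: int
    pit_percent: float
    mean_scratch_width: float
    mean_pit_width: float
    mean_pit_length: float
    sd_scratch_width: float
    sd_pit_width: float
    sd_pit_length: float
    n_macrowear_excluded: int

    def as_dict(self) -> dict:
        return dict(self.__dict__)


def classify_feature(
    feature: MicrowearFeature,
    ratio_threshold: float = PIT_SCRATCH_RATIO,
    macrowear_um: float = MACROWEAR_THRESHOLD_UM,
) -> str:
    """Classify one feature as ``'pit'``, ``'scratch'`` or ``'macrowear'``.

    The macrowear gate tests the feature's largest dimension
    (max of length and width) against 0.5 mm.  A ratio exactly equal to the
    threshold is classed as a scratch; the pit definition is a strict
    inequality and the boundary case must land somewhere deterministic.
    """
    length = feature.length
    if max(length, feature.width) > macrowear_um:
        return "macrowear"
    if length / feature.width < ratio_threshold:
        return "pit"
    return "scratch"


def _sd(values: np.ndarray) -> float:
    # sample SD; a single value has no dispersion estimate -> 0 by convention
    if len(values) < 2:
        return 0.0
    return float(np.std(values, ddof=1))


def summarize(features: list[MicrowearFeature] | pd.DataFrame, **classify_kw) -> MicrowearSummary:
    """Compute the four microwear variables over a feature collection.

    Accepts either a list of :class:`MicrowearFeature` or a DataFrame with
    columns ``x1,y1,x2,y2,width_um`` (``micrograph_id`` optional).
    Macrowear-sized features are excluded and counted separately.
    """
    if isinstance(features, pd.DataFrame):
        features = features_from_frame(features)
    classes = [classify_feature(f, **classify_kw) for f in features]
    pits = [f for f, c in zip(features, classes) if c == "pit"]
    scratches = [f for f, c in zip(features, classes) if c == "scratch"]
    n_macro = sum(1 for c in classes if c == "macrowear")
    n = len(pits) + len(scratches)
    if n == 0:
        raise EmptyDataError("no microwear features remain after macrowear exclusion")

    pit_w = np.array([f.width for f in pits])
    pit_l = np.array([f.length for f in pits])
    scr_w = np.array([f.width for f in scratches])

    return MicrowearSummary(
        n_features=n,
        n_pits=len(pits),
        n_scratches=len(scratches),
        pit_percent=100.0 * len(pits) / n,
        mean_scratch_width=float(scr_w.mean()) if len(scr_w) else float("nan"),
        mean_pit_width=float(pit_w.mean()) if len(pit_w) else float("nan"),
        mean_pit_length=float(pit_l.mean()) if len(pit_l) else float("nan"),
        sd_scratch_width=_sd(scr_w),
        sd_pit_width=_sd(pit_w),
        sd_pit_length=_sd(pit_l),
        n_macrowear_excluded=n_macro,
    )


def summarize_by_micrograph(
    features: list[MicrowearFeature], **classify_kw
) -> dict[str, MicrowearSummary]:
    """Per-micrograph summaries keyed by micrograph id."""
    by_id: dict[str, list[MicrowearFeature]] = {}
    for f in features:
        by_id.setdefault(f.micrograph_id, []).append(f)
    return {mid: summarize(fs, **classify_kw) for mid, fs in sorted(by_id.items())}


def features_from_frame(df: pd.DataFrame) -> list[MicrowearFeature]:
    """Build feature objects from a ``x1,y1,x2,y2,width_um`` table."""
    out = []
    for row in df.itertuples(index=False):
        out.append(
            MicrowearFeature(
                p1=(float(row.x1), float(row.y1)),
                p2=(float(row.x2), float(row.y2)),
                width=float(row.width_um),
                micrograph_id=str(getattr(row, "micrograph_id", "")),
            )
        )
    return out


def features_to_frame(features: list[MicrowearFeature]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "micrograph_id": [f.micrograph_id for f in features],
            "x1": [f.p1[0] for f in features],
            "y1": [f.p1[1] for f in features],
            "x2": [f.p2[0] for f in features],
            "y2": [f.p2[1] for f in features],
            "width_um": [f.width for f in features],
        }
    )


def detect_features(
    binary_image: np.ndarray, spacing: float, micrograph_id: str = ""
) -> list[MicrowearFeature]:
    """Extract features from a binary wear-feature mask.

    Connected components are reduced to their best-fit ellipse; the major
    axis becomes the feature segment (endpoints along the axis through the
    centroid) and the minor axis the width.  ``spacing`` converts pixels to
    micrometres.  An empty mask yields an empty list.
    """
    lab = label(binary_image > 0)
    out: list[MicrowearFeature] = []
    for rp in regionprops(lab):
        major = rp.axis_major_length * spacing
        minor = rp.axis_minor_length * spacing
        if minor <= 0:  # degenerate 1-px-wide component
            minor = spacing
        if major <= 0:
            major = spacing
        cy, cx = rp.centroid
        # regionprops orientation: angle of major axis vs row axis, in
        # (-pi/2, pi/2]; convert to an (x, y) direction in image coords
        th = rp.orientation
        dx, dy = np.sin(th), np.cos(th)
        half = 0.5 * major
        cxu, cyu = cx * spacing, cy * spacing
        out.append(
            MicrowearFeature(
                p1=(cxu - half * dx, cyu - half * dy),
                p2=(cxu + half * dx, cyu + half * dy),
                width=minor,
                micrograph_id=micrograph_id,
            )
        )
    return out
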