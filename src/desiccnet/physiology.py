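"""Physiological scoring: relative water content, survival after
gradual-then-rapid drying, and the Evans Blue cell-death index.

RWC (relative water content) is the standard hydration measure
``100 * (FW - DW) / (TW - DW)`` from fresh, dry and turgid weights.
The survival summary finds the wettest pre-drying RWC band at and
below which every band's plants resurrected after rapid desiccation —
the point at which desiccation tolerance has been induced. The Evans
Blue index rescales A600 dye readings between a hydrated negative
control and a boiled positive control to a 0-1 cell-death scale, making
readings comparable across instruments.
"""

from __future__ import annotations

import warnings
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .simulate import RWC_BANDS

__all__ = ["compute_rwc", "survival_threshold", "cell_death_index",
           "DegenerateControlsError"]


class DegenerateControlsError(ValueError):
    """Positive (boiled) control does not exceed the negative control."""


def compute_rwc(fresh_weight: float, dry_weight: float,
                turgid_weight: float) -> float:
    """Relative water content in percent.

    ``RWC = 100 * (FW - DW) / (TW - DW)``. Values outside [0, 100]
    (fresh weight outside the dry/turgid bracket, typically turgid-weight
    measurement error) trigger a warning but are returned unclamped.

    Raises
    ------
    ValueError
        If ``turgid_weight <= dry_weight`` (RWC undefined).
    """
    if turgid_weight <= dry_weight:
        raise ValueError(
            f"turgid weight ({turgid_weight}) must exceed dry weight "
            f"({dry_weight}); RWC is undefined"
        )
    rwc = 100.0 * (fresh_weight - dry_weight) / (turgid_weight - dry_weight)
    if not 0.0 <= rwc <= 100.0:
        warnings.warn(
            f"RWC {rwc:.2f}% outside [0, 100]: fresh weight outside the "
            "dry/turgid bracket", stacklevel=2)
    return rwc


def compute_rwc_table(weights: pd.DataFrame) -> pd.DataFrame:
    """Vectorised RWC over a weight-record table; adds an ``rwc`` column."""
    out = weights.copy()
    out["rwc"] = [
        compute_rwc(r.fresh_weight, r.dry_weight, r.turgid_weight)
        for r in weights.itertuples()
    ]
    return out


def survival_threshold(survival: pd.DataFrame,
                       min_frac: float = 1.0,
                       band_order: Sequence[str] = RWC_BANDS):
    """Wettest RWC band at and below which all plants resurrected.

    Parameters
    ----------
    survival : DataFrame
        Columns ``rwc_band``, ``n_plants``, ``n_resurrected``. Rows whose
        band is not in ``band_order`` (e.g. the hydrated control) are
        ignored for thresholding.
    min_frac : float
        Minimum resurrected fraction for a band to count as surviving.
        Resurrection at 72 h is an all-or-nothing outcome, hence the
        default 1.0.
    band_order : sequence
        Bands ordered wettest to driest.

    Returns
    -------
    str or None
        The threshold band label, or None if no band qualifies.
    """
    if len(survival) == 0:
        raise ValueError("empty survival table")
    frac = {}
    for r in survival.itertuples():
        if r.rwc_band in band_order:
            if not 0 <= r.n_resurrected <= r.n_plants:
                raise ValueError(
                    f"invalid counts for band {r.rwc_band}: "
                    f"{r.n_resurrected}/{r.n_plants}")
            frac[r.rwc_band] = r.n_resurrected / r.n_plants
    bands = [b for b in band_order if b in frac]
    if not bands:
        raise ValueError("no recognised RWC bands in survival table")
    # scan wettest -> driest; need every band from the candidate down
    for i, band in enumerate(bands):
        if all(frac[b] >= min_frac for b in bands[i:]):
            return band
    return None


def cell_death_index(viability: pd.DataFrame,
                     positive: str = "boiled-positive",
                     negative: str = "hydrated-negative") -> dict:
    """Evans Blue cell-death index per treatment, on a 0-1 scale.

    ``index(t) = (mean A600(t) - mean A600(neg)) / (mean A600(pos) -
    mean A600(neg))``, clipped to [0, 1]. 1 means as much dye uptake as
    boiled (dead) tissue, 0 as little as healthy hydrated tissue.

    Raises
    ------
    DegenerateControlsError
        If the positive-control mean does not exceed the negative.
    """
    if (viability["a600"] < 0).any():
        raise ValueError("A600 readings must be non-negative")
    means = viability.groupby("treatment")["a600"].mean()
    for ctrl in (positive, negative):
        if ctrl not in means.index:
            raise ValueError(f"missing control treatment {ctrl!r}")
    pos, neg = means[positive], means[negative]
    if pos <= neg:
        raise DegenerateControlsError(
            f"positive-control mean ({pos:.3g}) must exceed negative "
            f"({neg:.3g})")
    return {
        t: float(np.clip((m - neg) / (pos - neg), 0.0, 1.0))
        for t, m in means.items()
        if t not in (positive, negative)
    }
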