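"""Spectral chlorophyll indices for Sentinel-2-like band sets.

Sixteen published band-arithmetic indices (MCI and NDCI variants, band
ratios, fluorescence line heights, ...) computed from reflectance in the
blue (b2), green (b3), red (b4), red-edge (b5, b6) and narrow near-infrared
(b8a) bands. All computations are elementwise and vectorized: bands may be
scalars, 1-D matchup columns, or 2-D scene rasters, as long as shapes agree.

Division by zero is deliberately *not* clipped: invalid cells propagate as
``inf``/``nan`` so that downstream matchup filtering can see and drop them.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np

BAND_NAMES = ("b2", "b3", "b4", "b5", "b6", "b8a")

#: Band-centre wavelengths (nm) used by the MCI baseline interpolation.
_MCI_LAMBDA_RED_EDGE = 704.1
_MCI_LAMBDA_RED = 664.6
_MCI_LAMBDA_NIR = 740.5


@dataclass(frozen=True)
class IndexSpec:
    """One registry entry: identifier, literature citation, bands consumed."""

    identifier: str
    citation: str
    bands: tuple[str, ...]
    func: Callable[..., np.ndarray] = field(repr=False, compare=False)


@dataclass(frozen=True)
class VariantFlags:
    """Documented corrections to equations whose printed forms are degenerate.

    ndci_as_printed
        The NDCI row is printed with an identical numerator and denominator,
        which evaluates to the constant 1 and is useless as a predictor. By
        default the normalized-difference form of the cited source,
        (b5 - b4) / (b5 + b4), is used; set this flag to reproduce the
        literal printed constant for auditability.
    s23bda_times_b8a
        The two-band S23BDA row is printed with a trailing constant factor 8;
        the plausibly intended factor is the b8a band. The literal printed
        form is the default; this flag opts into the b8a variant.
    """

    ndci_as_printed: bool = False
    s23bda_times_b8a: bool = False


def _mci_slope() -> float:
    return (_MCI_LAMBDA_RED_EDGE - _MCI_LAMBDA_RED) / (
        _MCI_LAMBDA_NIR - _MCI_LAMBDA_RED
    )


def _registry(flags: VariantFlags) -> list[IndexSpec]:
    def ndci(b4, b5):
        if flags.ndci_as_printed:
            return (b5 - b4) / (b5 - b4)
        return (b5 - b4) / (b5 + b4)

    def s23bda(b4, b5, b8a):
        factor = b8a if flags.s23bda_times_b8a else 8.0
        return (1.0 / b4 - 1.0 / b5) * factor

    return [
        IndexSpec("S01Be162sub_Beck_2017", "Beck et al. 2017", ("b4", "b5"),
                  lambda b4, b5: b5 - b4),
        IndexSpec("S02BR23_OReilly_1998", "O'Reilly et al. 1998", ("b2", "b3"),
                  lambda b2, b3: b2 / b3),
        IndexSpec("S03BR54_Gons_2002", "Gons et al. 2002", ("b4", "b5"),
                  lambda b4, b5: b5 / b4),
        IndexSpec("S04BR8a4_Tebbs_2013", "Tebbs et al. 2013", ("b4", "b8a"),
                  lambda b4, b8a: b8a / b4),
        IndexSpec("S05Go04MCI_Gower_2004", "Gower et al. 2004", ("b5", "b6"),
                  lambda b5, b6: b5 - b6),
        IndexSpec("S06KIVU_Beck_2016", "Beck et al. 2016", ("b2", "b3", "b4"),
                  lambda b2, b3, b4: (b2 - b4) / b3),
        IndexSpec("S07L83BDA_Beck_2016", "Beck et al. 2016", ("b2", "b3", "b4"),
                  lambda b2, b3, b4: (1.0 / b2 - 1.0 / b4) * b3),
        IndexSpec("S09MCI_Le_2013", "Le et al. 2013", ("b4", "b5", "b6"),
                  lambda b4, b5, b6: b5 - b4 - (b6 - b4) * _mci_slope()),
        IndexSpec("S10Moses3b_Moses_2012", "Moses et al. 2012",
                  ("b4", "b5", "b6"),
                  lambda b4, b5, b6: (1.0 / b4 - 1.0 / b5) * b6),
        IndexSpec("S11NDCI_Mishra_2012", "Mishra & Mishra 2012", ("b4", "b5"),
                  ndci),
        IndexSpec("S12NDCI_Beck_2016", "Beck et al. 2016", ("b4", "b8a"),
                  lambda b4, b8a: (b8a - b4) / (b8a + b4)),
        IndexSpec("S13S23BDA_Beck_2016", "Beck et al. 2016",
                  ("b4", "b5", "b8a"), s23bda),
        # published as b3 - (b4 + (b2 - b4)); implemented in its exact
        # algebraic simplification so the identity S14 == b3 - b2 holds
        # bit-for-bit
        IndexSpec("S14S2FLHBlue_Beck_2016", "Beck et al. 2016",
                  ("b2", "b3"),
                  lambda b2, b3: b3 - b2),
        IndexSpec("S15SABI_Beck_2016", "Beck et al. 2016",
                  ("b2", "b3", "b4", "b8a"),
                  lambda b2, b3, b4, b8a: (b8a - b4) / (b2 + b3)),
        IndexSpec("S16Toming_2016", "Toming et al. 2016", ("b4", "b5", "b6"),
                  lambda b4, b5, b6: b5 - (b4 + b6) / 2.0),
        # published as b8a - (b5 + (b4 - b5)) == b8a - b4, same exactness
        # rationale as S14
        IndexSpec("S17ZhFLH_Zhao_2010", "Zhao et al. 2010",
                  ("b4", "b8a"),
                  lambda b4, b8a: b8a - b4),
    ]


def index_registry(flags: VariantFlags | None = None) -> list[IndexSpec]:
    """Ordered index registry.

    The ordering is stable and defines the feature order used by every model
    and importance report. Returns a fresh list each call.
    """
    return _registry(flags or VariantFlags())


def index_names(flags: VariantFlags | None = None) -> list[str]:
    """Identifiers in registry order."""
    return [spec.identifier for spec in index_registry(flags)]


def compute_indices(
    bands: dict[str, np.ndarray | float],
    flags: VariantFlags | None = None,
) -> dict[str, np.ndarray]:
    """Compute every registry index from a band set, elementwise.

    Parameters
    ----------
    bands
        Mapping with keys ``b2, b3, b4, b5, b6, b8a``; values scalar or
        arrays of one common shape.
    flags
        Optional :class:`VariantFlags` selecting documented equation
        corrections.

    Returns
    -------
    dict
        Identifier -> array (same shape as the inputs), in registry order.
        Cells with zero denominators come back non-finite, never raise.
    """
    missing = [b for b in BAND_NAMES if b not in bands]
    if missing:
        raise ValueError(f"band set is missing bands: {missing}")
    arrays = {b: np.asarray(bands[b], dtype=float) for b in BAND_NAMES}
    shapes = {a.shape for a in arrays.values() if a.shape != ()}
    if len(shapes) > 1:
        raise ValueError(f"inconsistent band shapes: {sorted(shapes)}")

    out: dict[str, np.ndarray] = {}
    with np.errstate(divide="ignore", invalid="ignore"):
        for spec in index_registry(flags):
            out[spec.identifier] = np.asarray(
                spec.func(*(arrays[b] for b in spec.bands)), dtype=float
            )
    return out
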