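"""DNA-combing fork statistics and DRIP-qPCR enrichment quantification.

Fibers carry the track lengths of two sequential thymidine-analog pulses
(IdU then CldU, 30 min each by default). Fork speed is the total labelled
length over total labelling time, (d_I + d_Cl) / (t_I + t_Cl), in kb/min;
fork symmetry is the IdU/CldU length ratio (1 for a symmetric bidirectional
fork). Fibers missing one analog track are excluded from both statistics
rather than imputed.

qPCR recovery of an immunoprecipitated locus is expressed as percent of the
diluted input: the input Ct is first corrected for the dilution factor
(Ct_input - log2(dilution)), then %input = 100 * 2^(Ct_corrected - Ct_DRIP).
Fold enrichment of a positive over a negative (R-loop-free) locus is the
ratio of the two recoveries, and equals the ratio of %input values
algebraically. Plate QC expects %input in [1, 15] and fold enrichment in
[20, 300].
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .stats import mann_whitney

__all__ = [
    "Fiber",
    "QpcrMeasurement",
    "fork_speed",
    "fork_symmetry",
    "fibers_from_micrometers",
    "compare_fiber_groups",
    "percent_input",
    "fold_enrichment",
    "normalize_to_negative_locus",
    "PERCENT_INPUT_RANGE",
    "FOLD_ENRICHMENT_RANGE",
]

PERCENT_INPUT_RANGE = (1.0, 15.0)
FOLD_ENRICHMENT_RANGE = (20.0, 300.0)

# combing convention for converting measured track lengths to kb
KB_PER_MICROMETER = 2.0


@dataclass(frozen=True)
class Fiber:
    """One combed DNA fiber: IdU and CldU track lengths (kb) and pulse
    durations (min)."""

    d_idu: float
    d_cldu: float
    t_idu: float = 30.0
    t_cldu: float = 30.0

    def __post_init__(self) -> None:
        if self.d_idu < 0 or self.d_cldu < 0:
            raise ValueError("track lengths must be non-negative")
        if self.t_idu <= 0 or self.t_cldu <= 0:
            raise ValueError("pulse durations must be positive")
        if self.d_idu == 0 and self.d_cldu == 0:
            raise ValueError("fiber with no labelled track is rejected")

    @property
    def has_both_labels(self) -> bool:
        return self.d_idu > 0 and self.d_cldu > 0


def fibers_from_micrometers(
    d_idu_um: float, d_cldu_um: float, kb_per_um: float = KB_PER_MICROMETER, **kwargs
) -> Fiber:
    """Build a fiber from lengths measured in micrometers on the slide."""
    return Fiber(d_idu_um * kb_per_um, d_cldu_um * kb_per_um, **kwargs)


def fork_speed(fiber: Fiber) -> float:
    """(d_I + d_Cl) / (t_I + t_Cl) in kb/min; requires both labels."""
    if not fiber.has_both_labels:
        raise ValueError("speed requires both analog tracks")
    return (fiber.d_idu + fiber.d_cldu) / (fiber.t_idu + fiber.t_cldu)


def fork_symmetry(fiber: Fiber) -> float | None:
    """IdU/CldU length ratio, or None when CldU track is absent."""
    if fiber.d_cldu == 0:
        return None
    if fiber.d_idu == 0:
        raise ValueError("symmetry requires both analog tracks")
    return fiber.d_idu / fiber.d_cldu


def compare_fiber_groups(
    speeds_a: Sequence[float],
    speeds_b: Sequence[float],
    min_fibers: int = 200,
) -> dict:
    """Two-sided Mann-Whitney comparison of fork speeds with group summaries.

    Warns when a group holds fewer than ``min_fibers`` fibers (the combing
    convention is to measure at least 200 per group).
    """
    a = np.asarray(speeds_a, dtype=float)
    b = np.asarray(speeds_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be non-empty")
    for label, arr in (("a", a), ("b", b)):
        if arr.size < min_fibers:
            warnings.warn(
                f"group {label} has only {arr.size} fibers (< {min_fibers})"
            )
    result = mann_whitney(a, b)
    return {
        "p_value": result.p_value,
        "statistic": result.statistic,
        "exact": result.exact,
        "mean_a": float(a.mean()),
        "sd_a": float(a.std(ddof=1)) if a.size > 1 else float("nan"),
        "n_a": int(a.size),
        "mean_b": float(b.mean()),
        "sd_b": float(b.std(ddof=1)) if b.size > 1 else float("nan"),
        "n_b": int(b.size),
    }


@dataclass(frozen=True)
class QpcrMeasurement:
    """A qPCR Ct for one locus in one role (input, drip or drip_rnh1)."""

    locus: str
    role: str
    ct: float
    input_dilution_factor: float = 10.0

    def __post_init__(self) -> None:
        if self.role not in ("input", "drip", "drip_rnh1"):
            raise ValueError(f"unknown role {self.role!r}")
        if self.ct <= 0:
            raise ValueError("Ct must be positive")
        if self.input_dilution_factor <= 1:
            raise ValueError("input dilution factor must exceed 1")

    @property
    def corrected_ct(self) -> float:
        """Dilution-corrected Ct (meaningful for the input role)."""
        return self.ct - math.log2(self.input_dilution_factor)


def percent_input(
    m_input: QpcrMeasurement, m_drip: QpcrMeasurement
) -> tuple[float, str]:
    """%input = 100 * 2^(Ct_input_corrected - Ct_DRIP) with a QC flag.

    The flag is "ok" when the recovery lies in the expected 1-15% window
    and "out_of_range" otherwise.
    """
    if m_input.role != "input" or m_drip.role not in ("drip", "drip_rnh1"):
        raise ValueError("roles must be (input, drip/drip_rnh1)")
    if m_input.locus != m_drip.locus:
        raise ValueError("measurements must target the same locus")
    pct = 100.0 * 2.0 ** (m_input.corrected_ct - m_drip.ct)
    lo, hi = PERCENT_INPUT_RANGE
    flag = "ok" if lo <= pct <= hi else "out_of_range"
    return pct, flag


def fold_enrichment(
    pos_input: QpcrMeasurement,
    pos_drip: QpcrMeasurement,
    neg_input: QpcrMeasurement,
    neg_drip: QpcrMeasurement,
) -> tuple[float, str]:
    """Recovery of a positive locus over a negative one, with QC flag.

    fold = 2^(Ct_input_pos_corr - Ct_drip_pos) / 2^(Ct_input_neg_corr -
    Ct_drip_neg); flagged "ok" inside the expected [20, 300] window.
    """
    if pos_input.locus == neg_input.locus:
        raise ValueError("positive and negative loci must be distinct")
    pos = 2.0 ** (pos_input.corrected_ct - pos_drip.ct)
    neg = 2.0 ** (neg_input.corrected_ct - neg_drip.ct)
    fold = pos / neg
    lo, hi = FOLD_ENRICHMENT_RANGE
    flag = "ok" if lo <= fold <= hi else "out_of_range"
    return fold, flag


def normalize_to_negative_locus(
    signals: Mapping[str, float], neg_locus: str
) -> dict[str, float]:
    """Divide each locus's %input by the negative (R-loop-free) locus's."""
    if neg_locus not in signals:
        raise ValueError(f"negative locus {neg_locus!r} missing from signals")
    neg = signals[neg_locus]
    if neg <= 0:
        raise ValueError("negative locus signal must be positive")
    return {locus: value / neg for locus, value in signals.items()}
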