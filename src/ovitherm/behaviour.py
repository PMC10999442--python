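"""Behavioural scoring and blood-assay utilities.

Covers the non-thermal phenotyping arms of the temperament workflow:

* isolation-box test (IBT) agitation scores normalised to a fixed
  calibration weight (live-weight-normalised score, "IBT-LWT");
* classification of animals into low/high stress-responder phenotypes from
  their first-session IBT-LWT scores;
* open-field arena counts (bleats, sector crosses) and the composite
  3-axis accelerometer activity score;
* four-parameter logistic (4PL) calibration curves for ELISA readouts and
  the oxidised/non-oxidised albumin band-intensity ratio.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import curve_fit

__all__ = [
    "AnimalRecord",
    "AssayPanel",
    "FourPLCurve",
    "ClassificationResult",
    "DETECTION_LIMITS",
    "normalise_ibt",
    "classify_phenotype",
    "activity_composite",
    "fit_4pl",
    "invert_4pl",
    "oxidation_ratio",
]

GENOTYPES = ("A/A", "A/G", "G/G")
SESSIONS = ("S1", "S2")

#: assay lower limits of detection (same units as AssayPanel fields)
DETECTION_LIMITS = {
    "cortisol": 0.25,  # ng/ml
    "prolactin": 5.0,  # µIU/ml
    "dhea": 0.045,  # ng/ml
    "bdnf": 10.0,  # pg/ml
}


@dataclass
class AnimalRecord:
    """Identity, genotype, weight and behaviour scores for one animal.

    ``raw_ibt``, ``ibt_lwt``, ``bleats`` and ``crosses`` are keyed by
    session label (``"S1"``, ``"S2"``).  The phenotype class is assigned
    only from session-1 normalised scores.
    """

    animal_id: str
    genotype: str
    live_weight: float
    raw_ibt: dict[str, float] = field(default_factory=dict)
    ibt_lwt: dict[str, float] = field(default_factory=dict)
    bleats: dict[str, int] = field(default_factory=dict)
    crosses: dict[str, int] = field(default_factory=dict)
    phenotype: str = "unassigned"
    group: str = ""

    def __post_init__(self) -> None:
        if self.genotype not in GENOTYPES:
            raise ValueError(f"unknown genotype {self.genotype!r}")
        if not self.live_weight > 0:
            raise ValueError("live_weight must be positive")
        for session, n in list(self.bleats.items()) + list(self.crosses.items()):
            if n < 0:
                raise ValueError(f"negative count in session {session}")


@dataclass
class AssayPanel:
    """One animal's blood-assay results for one test session.

    Hormone concentrations at or below the assay's detection limit are
    flagged (``below_detection``) rather than imputed.  Oxidative stress is
    the dimensionless oxidised/non-oxidised albumin band ratio before
    (``oxy_pre``) and after (``oxy_post``) the behavioural tests.
    """

    animal_id: str
    session: str
    cortisol: float  # ng/ml
    prolactin: float  # µIU/ml
    dhea: float  # ng/ml
    bdnf: float  # pg/ml
    oxy_pre: float
    oxy_post: float

    def __post_init__(self) -> None:
        if self.session not in SESSIONS:
            raise ValueError(f"unknown session {self.session!r}")
        for name in ("oxy_pre", "oxy_post"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")

    @property
    def below_detection(self) -> list[str]:
        """Analytes at or below the assay detection limit."""
        return [
            a for a, lim in DETECTION_LIMITS.items() if getattr(self, a) < lim
        ]


def normalise_ibt(
    raw_ibt: float, live_weight: float, calibration_weight: float = 27.0
) -> float:
    """Normalise a raw IBT agitation score for live weight.

    The agitation meter is calibrated with a standard device of known mass
    (27 kg), so the score is rescaled as
    ``raw_ibt / live_weight × calibration_weight``; an animal at exactly
    the calibration weight keeps its raw score.
    """
    if not live_weight > 0:
        raise ValueError("live_weight must be positive")
    return raw_ibt / live_weight * calibration_weight


@dataclass
class ClassificationResult:
    """Phenotype labels plus a report of any score ties at the boundaries."""

    labels: dict[str, str]
    ties: list[str] = field(default_factory=list)

    def __getitem__(self, animal_id: str) -> str:
        return self.labels[animal_id]


def classify_phenotype(
    scores: dict[str, float], n_low: int, n_high: int
) -> ClassificationResult:
    """Split animals into low/high responders by session-1 IBT-LWT score.

    The ``n_low`` smallest scores become ``"low"``, the ``n_high`` largest
    ``"high"``, everything between ``"unassigned"``.  Ties across a class
    boundary are broken by stable animal-id order and the tied ids are
    reported so the arbitrariness is visible, never silent.
    """
    ids = list(scores)
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate animal ids")
    if n_low < 0 or n_high < 0 or n_low + n_high > len(ids):
        raise ValueError("n_low + n_high must not exceed the number of animals")
    order = sorted(ids, key=lambda a: (scores[a], a))
    labels = {a: "unassigned" for a in ids}
    for a in order[:n_low]:
        labels[a] = "low"
    for a in order[len(order) - n_high :]:
        labels[a] = "high"
    ties: list[str] = []
    for cut in (n_low, len(order) - n_high):
        if 0 < cut < len(order) and scores[order[cut - 1]] == scores[order[cut]]:
            boundary = scores[order[cut]]
            ties.extend(a for a in order if scores[a] == boundary and a not in ties)
    return ClassificationResult(labels=labels, ties=ties)


def activity_composite(axis_means: tuple[float, float, float]) -> float:
    """Composite per-epoch activity: the sum of the three axis means."""
    x, y, z = axis_means
    if x < 0 or y < 0 or z < 0:
        raise ValueError("axis means must be non-negative")
    return float(x + y + z)


@dataclass
class FourPLCurve:
    """Four-parameter logistic calibration curve.

    ``response(c) = bottom + (top - bottom) / (1 + (ec50 / c) ** hill)``.
    ``hill`` may be negative for a descending curve (e.g. competitive
    immunoassays); ``ec50`` is the concentration giving the half-maximal
    response.
    """

    bottom: float
    top: float
    ec50: float
    hill: float

    def __post_init__(self) -> None:
        if self.top == self.bottom:
            raise ValueError("top and bottom must differ")
        if not self.ec50 > 0:
            raise ValueError("ec50 must be positive")

    def response(self, concentration):
        c = np.asarray(concentration, dtype=float)
        return self.bottom + (self.top - self.bottom) / (
            1.0 + (self.ec50 / c) ** self.hill
        )


def _4pl(c, bottom, top, log_ec50, hill):
    return bottom + (top - bottom) / (1.0 + (np.exp(log_ec50) / c) ** hill)


def fit_4pl(standards: list[tuple[float, float]]) -> FourPLCurve:
    """Least-squares 4PL fit to calibration standards.

    Fitted on the log-concentration scale with a deterministic multi-start
    over candidate Hill slopes (±1, ±2) from moment-based initial values,
    so refits of the same standards always return the same curve.

    Parameters
    ----------
    standards : list of (concentration, response)
        At least five standards spanning the half-maximal concentration.
    """
    if len(standards) < 5:
        raise ValueError("need at least 5 calibration standards")
    c = np.array([s[0] for s in standards], dtype=float)
    r = np.array([s[1] for s in standards], dtype=float)
    if (c <= 0).any():
        raise ValueError("standard concentrations must be positive")
    span = r.max() - r.min()
    if span == 0:
        raise ValueError("standard responses are constant")
    # moment-based starts: asymptotes from the response extremes, ec50 from
    # the concentration whose response is nearest the midpoint
    mid = (r.max() + r.min()) / 2.0
    log_ec50_0 = math.log(c[np.argmin(np.abs(r - mid))])
    best = None
    for hill0 in (1.0, -1.0, 2.0, -2.0):
        p0 = [r.min() - 0.05 * span, r.max() + 0.05 * span, log_ec50_0, hill0]
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                popt, _ = curve_fit(_4pl, c, r, p0=p0, maxfev=20000)
        except RuntimeError:
            continue
        rss = float(np.sum((r - _4pl(c, *popt)) ** 2))
        if best is None or rss < best[0]:
            best = (rss, popt)
    if best is None:
        raise RuntimeError("4PL fit failed to converge from all starts")
    bottom, top, log_ec50, hill = best[1]
    if bottom > top:
        # exact reparameterisation symmetry: swapping the asymptotes and
        # negating the Hill slope leaves the curve unchanged; canonicalise
        # to bottom < top so descending curves carry a negative slope
        bottom, top, hill = top, bottom, -hill
    return FourPLCurve(bottom=float(bottom), top=float(top),
                       ec50=float(math.exp(log_ec50)), hill=float(hill))


def invert_4pl(curve: FourPLCurve, response: float) -> float:
    """Closed-form inverse of the 4PL curve: response → concentration.

    Responses outside the open interval (bottom, top) cannot be inverted;
    they are flagged with a warning and returned as NaN.
    """
    lo, hi = sorted((curve.bottom, curve.top))
    if not lo < response < hi:
        warnings.warn(
            f"response {response} outside the curve range ({lo}, {hi}); "
            "flagged out-of-range",
            stacklevel=2,
        )
        return math.nan
    ratio = (curve.top - curve.bottom) / (response - curve.bottom) - 1.0
    return float(curve.ec50 / ratio ** (1.0 / curve.hill))


def oxidation_ratio(oxidised_intensity: float, nonoxidised_intensity: float) -> float:
    """Oxidised/non-oxidised albumin band-intensity ratio."""
    if oxidised_intensity < 0 or nonoxidised_intensity < 0:
        raise ValueError("band intensities must be non-negative")
    if nonoxidised_intensity == 0:
        raise ValueError("non-oxidised band intensity must be positive")
    return oxidised_intensity / nonoxidised_intensity
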