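"""Quality control for peak tables.

Input checks: a peak whose label count exceeds the atoms its formula
provides, or a peak duplicating an isotopologue already seen in the same
dataset, is annotated (never silently dropped from the output — flagged
rows are excluded from the correction array but still echoed with their
error message appended).

Output check: after correction, the re-contaminated reconstruction
predicts the intensity every isotopologue *should* show.  Predicted
intensities at or above a configurable threshold that have no observed
peak are appended as predicted-peak rows, alerting the researcher to
peaks their identification step may have missed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from enum import Enum
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .formula import MolecularFormula, max_label_count

__all__ = [
    "QCCode",
    "QCAnnotation",
    "ThresholdSpec",
    "validate_dataset",
    "resolve_threshold",
    "find_missing_predicted",
]

log = logging.getLogger(__name__)


class QCCode(str, Enum):
    COUNT_EXCEEDS_FORMULA = "count_exceeds_formula"
    DUPLICATE_ISOTOPOLOGUE = "duplicate_isotopologue"
    MALFORMED_ROW = "malformed_row"
    PREDICTED_NOT_OBSERVED = "predicted_not_observed"


@dataclass(frozen=True)
class QCAnnotation:
    """One QC flag attached to a peak record; never alters intensities."""

    code: QCCode
    message: str

    def __str__(self) -> str:
        return f"{self.code.value}: {self.message}"


@dataclass(frozen=True)
class ThresholdSpec:
    """Predicted-peak inclusion threshold.

    The absolute cutoff is ``percent`` % of a summary statistic
    (``minimum``, ``maximum`` or ``average``) of the observed peak
    intensities, taken either over the whole data ``collection`` or over
    each ``dataset`` individually.  Disabled means no predicted rows.
    """

    percent: float = 0.0
    statistic: str = "minimum"
    scope: str = "collection"
    enabled: bool = False

    def __post_init__(self) -> None:
        if self.percent < 0:
            raise ValueError(f"threshold percent must be >= 0: {self.percent}")
        if self.statistic not in ("minimum", "maximum", "average"):
            raise ValueError(f"unknown statistic {self.statistic!r}")
        if self.scope not in ("collection", "dataset"):
            raise ValueError(f"unknown scope {self.scope!r}")


def validate_dataset(records: Sequence, formula: MolecularFormula, order) -> None:
    """Annotate out-of-range label counts and duplicate isotopologues.

    Records must belong to one molecule/group.  The first record of each
    isotopologue index wins (file order); later ones are flagged as
    duplicates.  Annotations are appended in place.
    """
    seen: Dict[Tuple[int, ...], int] = {}
    for rec in records:
        if rec.counts is None:
            continue
        bad = False
        for iso, count in zip(order, rec.counts):
            nmax = max_label_count(formula, iso)
            if count > nmax:
                rec.annotations.append(
                    QCAnnotation(
                        QCCode.COUNT_EXCEEDS_FORMULA,
                        f"{iso.label} count {count} exceeds the {nmax} "
                        f"{iso.element} atom(s) of {formula}",
                    )
                )
                bad = True
        if bad:
            continue
        if rec.counts in seen:
            rec.annotations.append(
                QCAnnotation(
                    QCCode.DUPLICATE_ISOTOPOLOGUE,
                    f"isotopologue {rec.counts} already observed in this dataset",
                )
            )
        else:
            seen[rec.counts] = 1


def resolve_threshold(
    spec: ThresholdSpec,
    collection_intensities: Sequence[float],
    dataset_intensities: Sequence[float],
) -> Optional[float]:
    """Turn a relative threshold spec into an absolute intensity cutoff.

    Statistics are computed over observed (nonzero) intensities only;
    implicit zeros from densification are not peaks.  Returns ``None``
    when the spec is disabled or the relevant scope has no observed
    peaks (the predicted-peak step is then skipped with a warning).
    """
    if not spec.enabled:
        return None
    pool = (
        collection_intensities if spec.scope == "collection" else dataset_intensities
    )
    pool = [v for v in pool if v > 0]
    if not pool:
        log.warning(
            "threshold %s/%s requested but no observed peaks in scope; "
            "skipping predicted-peak inclusion",
            spec.statistic,
            spec.scope,
        )
        return None
    if spec.statistic == "minimum":
        stat = min(pool)
    elif spec.statistic == "maximum":
        stat = max(pool)
    else:
        stat = sum(pool) / len(pool)
    return spec.percent / 100.0 * stat


def find_missing_predicted(
    reconstructed: np.ndarray,
    observed_mask: np.ndarray,
    threshold: Optional[float],
) -> List[Tuple[Tuple[int, ...], float, QCAnnotation]]:
    """Indices predicted at/above *threshold* but never observed.

    ``reconstructed`` is the re-contaminated corrected array; an index is
    reported when its predicted intensity reaches the threshold and the
    observed mask is false there.  Observed peaks are never re-added.
    """
    if threshold is None:
        return []
    out = []
    for idx in np.ndindex(reconstructed.shape):
        pred = float(reconstructed[idx])
        if pred >= threshold and not observed_mask[idx]:
            out.append(
                (
                    idx,
                    pred,
                    QCAnnotation(
                        QCCode.PREDICTED_NOT_OBSERVED,
                        f"predicted intensity {pred:g} at isotopologue {idx} "
                        f"meets threshold {threshold:g} but was not observed",
                    ),
                )
            )
    return out
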