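"""End-to-end collection processing: read, validate, correct, QC, write.

Each per-molecule dataset is densified into an n-dimensional array
spanning label counts 0..N_e (unobserved isotopologues are zeros),
corrected independently, and written back row by row.  Dataset
corrections share nothing, so they may be distributed over worker
processes; results are gathered and written in input order, making the
output identical for any worker count.
"""

from __future__ import annotations

import logging
import multiprocessing
import time
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .correction import LabelOrder, NACorrector
from .formula import max_label_count
from .isotopes import IsotopeSpec, TableCache
from .qc import find_missing_predicted, resolve_threshold, validate_dataset
from .tabio import (
    CollectionConfig,
    Dataset,
    read_collection,
    write_collection,
)

__all__ = ["RunReport", "run"]

log = logging.getLogger(__name__)


@dataclass
class RunReport:
    """Summary of one collection run; counts reconcile with the output file."""

    datasets: int = 0
    peaks: int = 0
    rows_written: int = 0
    flagged: Dict[str, int] = field(default_factory=dict)
    predicted_added: int = 0
    iterations: Dict[Tuple[str, ...], int] = field(default_factory=dict)
    cache_hits: int = 0
    cache_misses: int = 0
    elapsed: float = 0.0


def _dense_arrays(
    ds: Dataset, maxima: Sequence[int]
) -> Tuple[np.ndarray, np.ndarray]:
    """Dense intensity array and observed mask from a dataset's usable rows."""
    shape = tuple(m + 1 for m in maxima)
    data = np.zeros(shape)
    mask = np.zeros(shape, dtype=bool)
    for rec in ds.records:
        if rec.usable:
            data[rec.counts] = rec.intensity
            mask[rec.counts] = True
    return data, mask


def _correct_payload(
    payload: Tuple[Tuple[int, ...], Tuple[Tuple[str, str, float], ...], np.ndarray, int]
) -> Tuple[np.ndarray, np.ndarray, int, float]:
    """Worker entry point: correct one dense array (no shared state)."""
    maxima, iso_tuples, data, max_iterations = payload
    order = LabelOrder(tuple(IsotopeSpec(*t) for t in iso_tuples))
    corrector = NACorrector(maxima, order, cache=None)
    res = corrector.correct(data, max_iterations=max_iterations)
    return res.corrected, res.reconstructed, res.iterations, res.residual


def run(config: CollectionConfig) -> RunReport:
    """Process one collection according to *config* and write the output.

    Per-row problems only annotate; configuration and I/O problems raise
    :class:`~nacorr.tabio.ConfigError` or ``OSError``.
    """
    t0 = time.monotonic()
    report = RunReport()
    header, datasets = read_collection(config)
    order = config.label_order()
    iso_tuples = tuple((iso.label, iso.element, iso.p) for iso in order)
    cache = TableCache(enabled=config.cache)

    # validation first: flags determine which rows enter the arrays
    for ds in datasets:
        if ds.formula is not None:
            validate_dataset(ds.records, ds.formula, order)

    correctable: List[Tuple[int, Tuple[int, ...], np.ndarray, np.ndarray]] = []
    for i, ds in enumerate(datasets):
        if ds.formula is None:
            continue
        maxima = tuple(max_label_count(ds.formula, iso) for iso in order)
        data, mask = _dense_arrays(ds, maxima)
        correctable.append((i, maxima, data, mask))

    # correct (optionally across processes; gathered in input order)
    payloads = [
        (maxima, iso_tuples, data, config.max_iterations)
        for (_i, maxima, data, _mask) in correctable
    ]
    if config.processes > 1 and payloads:
        with multiprocessing.Pool(config.processes) as pool:
            results = pool.map(_correct_payload, payloads)
    else:
        results = []
        for maxima, _iso, data, max_it in payloads:
            corrector = NACorrector(maxima, order, cache=cache)
            res = corrector.correct(data, max_iterations=max_it)
            results.append(
                (res.corrected, res.reconstructed, res.iterations, res.residual)
            )

    # thresholds need observed-intensity statistics
    collection_intensities = [
        rec.intensity
        for ds in datasets
        for rec in ds.records
        if rec.intensity is not None
    ]

    predicted: Dict[Tuple[str, ...], List[Tuple[Tuple[int, ...], float]]] = {}
    for (i, maxima, data, mask), (corrected, reconstructed, iters, resid) in zip(
        correctable, results
    ):
        ds = datasets[i]
        for rec in ds.records:
            if rec.usable:
                rec.corrected = float(corrected[rec.counts])
        report.iterations[ds.key] = iters
        dataset_intensities = [
            rec.intensity for rec in ds.records if rec.intensity is not None
        ]
        thr = resolve_threshold(
            config.threshold, collection_intensities, dataset_intensities
        )
        hits = find_missing_predicted(reconstructed, mask, thr)
        if hits:
            ds_pred = [(idx, value) for idx, value, _ann in hits]
            predicted[ds.key] = ds_pred
            report.predicted_added += len(ds_pred)
        log.debug(
            "dataset %s: %d iterations, residual %g", ds.key, iters, resid
        )

    report.rows_written = write_collection(header, datasets, predicted, config)
    report.datasets = len(datasets)
    report.peaks = sum(len(ds.records) for ds in datasets)
    for ds in datasets:
        for rec in ds.records:
            for ann in rec.annotations:
                code = ann.code.value
                report.flagged[code] = report.flagged.get(code, 0) + 1
    report.cache_hits = cache.hits
    report.cache_misses = cache.misses
    report.elapsed = time.monotonic() - t0
    log.info(
        "processed %d datasets (%d peaks) in %.2fs; cache %d hits / %d misses",
        report.datasets,
        report.peaks,
        report.elapsed,
        report.cache_hits,
        report.cache_misses,
    )
    return report
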