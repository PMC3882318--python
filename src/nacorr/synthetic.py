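"""Seeded generators for clean and contaminated isotopologue fixtures.

Real SIRM peak tables are sparse — most molecules show a handful of
isotopologues out of the dozens their formula admits — with long-tailed
positive intensities.  This module generates arrays and collection-scale
CSV files with those gross features (sparsity, skewed intensities,
replicate groups, optional injected QC defects) so the full pipeline can
be exercised end to end without instrument data.  Everything is
deterministic per seed.

Two fixed single-isotope reference distributions used throughout the
validation suite are exposed as constants: a 9-carbon and a 6-nitrogen
molecule's normalized clean isotopologue vectors.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import List, Optional, Sequence, Tuple

import numpy as np

from .correction import LabelOrder, add_na
from .isotopes import DEFAULT_ISOTOPES, IsotopeSpec

__all__ = [
    "SIMULATED_CARBON9",
    "SIMULATED_NITROGEN6",
    "SyntheticSpec",
    "make_clean",
    "outer_dataset",
    "make_collection_file",
]

#: Normalized clean isotopologue vector of a 9-carbon molecule
#: (counts 0..9); used to validate multi- against single-isotope paths.
SIMULATED_CARBON9 = np.array([0.5, 0, 0, 0.15, 0.1, 0, 0, 0, 0, 0.25])

#: Normalized clean isotopologue vector of a 6-nitrogen molecule
#: (counts 0..6).
SIMULATED_NITROGEN6 = np.array([0.5, 0, 0, 0.1, 0, 0, 0.4])

for _v in (SIMULATED_CARBON9, SIMULATED_NITROGEN6):
    _v.setflags(write=False)


@dataclass(frozen=True)
class SyntheticSpec:
    """Parameters of a synthetic isotopologue array or collection.

    ``sparsity`` is the expected fraction of nonzero isotopologues
    (default 0.3, mimicking real tables where most admissible counts are
    unobserved); intensities are log-normal, then normalized to unit sum
    when ``normalize`` is set.
    """

    shape: Tuple[int, ...]
    sparsity: float = 0.3
    seed: int = 0
    isotopes: Tuple[IsotopeSpec, ...] = (DEFAULT_ISOTOPES["13C"],)
    normalize: bool = True

    def __post_init__(self) -> None:
        if not 0 < self.sparsity <= 1:
            raise ValueError(f"sparsity must be in (0, 1]: {self.sparsity}")
        if len(self.shape) != len(self.isotopes):
            raise ValueError("one isotope per array dimension required")


def make_clean(spec: SyntheticSpec) -> np.ndarray:
    """Generate a sparse nonnegative clean isotopologue array.

    At least one entry is always nonzero; identical seeds give identical
    arrays.
    """
    rng = np.random.default_rng(spec.seed)
    arr = np.zeros(spec.shape)
    mask = rng.random(spec.shape) < spec.sparsity
    if not mask.any():
        flat = rng.integers(0, arr.size)
        mask.flat[flat] = True
    values = rng.lognormal(mean=0.0, sigma=1.5, size=int(mask.sum()))
    arr[mask] = values
    if spec.normalize:
        arr /= arr.sum()
    return arr


def outer_dataset(vectors: Sequence[np.ndarray]) -> np.ndarray:
    """Outer product of per-dimension 1-D isotopologue vectors.

    Models independent labeling across elements: the multi-isotope
    distribution of a molecule whose per-element label distributions are
    the given vectors.  The result's total equals the product of the
    vectors' totals; a single vector is returned unchanged.
    """
    vectors = [np.asarray(v, dtype=float) for v in vectors]
    if not vectors:
        raise ValueError("at least one vector required")
    out = vectors[0]
    for v in vectors[1:]:
        out = np.multiply.outer(out, v)
    return out


def _random_formula(rng: np.random.Generator) -> Tuple[str, int, dict]:
    """A plausible small-metabolite formula with its element counts."""
    n_c = int(rng.integers(2, 30))
    n_h = int(rng.integers(n_c, 2 * n_c + 4))
    n_n = int(rng.integers(0, 7))
    n_o = int(rng.integers(1, 15))
    parts = [f"C{n_c}", f"H{n_h}"]
    if n_n:
        parts.append(f"N{n_n}")
    parts.append(f"O{n_o}")
    return "".join(parts), n_c, {"C": n_c, "H": n_h, "N": n_n, "O": n_o}


def make_collection_file(
    n_molecules: int,
    spec: SyntheticSpec,
    path: str | Path,
    n_samples: int = 1,
    inject_duplicates: int = 0,
    inject_overflow: int = 0,
    inject_malformed: int = 0,
) -> Path:
    """Write a synthetic peak-collection CSV readable by the pipeline.

    One dataset per molecule per sample: random formula, sparse observed
    isotopologues with counts within the formula's element bounds, a
    pass-through ``mz`` metadata column.  The ``inject_*`` arguments add
    that many defective rows (duplicate isotopologues, counts exceeding
    the formula, unparseable intensities) for QC testing.  Output bytes
    are fully determined by the arguments.

    Columns: formula, sample, then one ``<label>_count`` column per
    isotope in *spec*, intensity, mz.
    """
    rng = np.random.default_rng(spec.seed)
    path = Path(path)
    labels = [iso.label for iso in spec.isotopes]
    header = (
        ["formula", "sample"]
        + [f"{label}_count" for label in labels]
        + ["intensity", "mz"]
    )
    rows: List[List[str]] = []
    defect_rows: List[List[str]] = []
    for _ in range(n_molecules):
        formula, n_c, counts_by_element = _random_formula(rng)
        maxima = [counts_by_element.get(iso.element, 0) for iso in spec.isotopes]
        for sample in range(n_samples):
            sample_name = f"S{sample + 1}"
            full = [tuple(idx) for idx in np.ndindex(*(m + 1 for m in maxima))]
            n_obs = max(1, int(round(spec.sparsity * len(full))))
            chosen = rng.choice(len(full), size=min(n_obs, len(full)), replace=False)
            chosen = sorted(int(c) for c in chosen)
            mz_base = float(rng.uniform(100, 1200))
            mol_rows = []
            for flat in chosen:
                counts = full[flat]
                intensity = float(rng.lognormal(mean=8.0, sigma=1.5))
                mol_rows.append(
                    [formula, sample_name]
                    + [str(c) for c in counts]
                    + [f"{intensity:.4f}", f"{mz_base + sum(counts):.5f}"]
                )
            rows.extend(mol_rows)
            if inject_duplicates > 0:
                defect_rows.append(list(mol_rows[0]))
                inject_duplicates -= 1
            if inject_overflow > 0:
                bad = (
                    [formula, sample_name]
                    + [str(m + 1) for m in maxima]
                    + ["100.0", f"{mz_base:.5f}"]
                )
                defect_rows.append(bad)
                inject_overflow -= 1
            if inject_malformed > 0:
                bad = (
                    [formula, sample_name]
                    + ["0"] * len(maxima)
                    + ["not-a-number", f"{mz_base:.5f}"]
                )
                defect_rows.append(bad)
                inject_malformed -= 1
    rows.extend(defect_rows)
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(header)
        writer.writerows(rows)
    return path
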