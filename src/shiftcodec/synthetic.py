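"""Seeded synthetic chemical-shift data with known class structure.

Emulates class-conditional (helix / sheet / coil) per-atom shift
distributions: each atom's shift is a class mean plus a deterministic
per-residue-type offset plus Gaussian noise, with atoms dropped
independently at a configurable missing rate.  Default ppm baselines and
class offsets loosely follow known secondary-shift directions (CA higher in
helix than sheet, CB higher in sheet, HA lower in helix); they are test
scaffolding with realistic magnitudes, not a physical shift predictor.

``generate_pair`` plants a contiguous perturbed patch into a bound-state
copy of a free-state protein, emulating free/bound chemical-shift
perturbation data with a known interaction patch.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from .cs_io import ProteinShiftTable, ShiftRecord, STANDARD_AA, _HAS_CB, _HAS_HB
from .errors import ParameterError

CLASSES = ("helix", "sheet", "coil")

#: coil baseline ppm per atom
BASE_PPM = {
    "N": 119.0, "H": 8.30, "CA": 57.5, "CB": 38.5,
    "C": 176.0, "HA": 4.35, "HB": 2.00,
}
#: additive class offsets in ppm (coil = 0)
CLASS_OFFSETS = {
    "helix": {"N": -1.6, "H": -0.25, "CA": 2.8, "CB": -0.4,
              "C": 1.9, "HA": -0.35, "HB": -0.10},
    "sheet": {"N": 2.2, "H": 0.35, "CA": -1.5, "CB": 2.0,
              "C": -1.6, "HA": 0.45, "HB": 0.10},
    "coil": {a: 0.0 for a in BASE_PPM},
}
#: within-class Gaussian sd in ppm
DEFAULT_SD = {
    "N": 2.2, "H": 0.45, "CA": 1.2, "CB": 1.4,
    "C": 1.1, "HA": 0.30, "HB": 0.35,
}
#: unit of the deterministic per-residue-type offset, per atom
TYPE_OFFSET_UNIT = {
    "N": 1.0, "H": 0.08, "CA": 0.8, "CB": 1.2,
    "C": 0.5, "HA": 0.06, "HB": 0.08,
}


def type_offset(residue_type: str, atom: str) -> float:
    """Deterministic per-type ppm offset: spreads the 20 types around the
    class mean without randomness."""
    k = STANDARD_AA.index(residue_type)
    return ((k % 7) - 3) * TYPE_OFFSET_UNIT.get(atom, 0.0)


def _atoms_present(residue_type: str) -> list[str]:
    atoms = ["N", "C", "CA", "HA"]
    if residue_type != "P":
        atoms.append("H")
    if residue_type in _HAS_CB:
        atoms.append("CB")
    if residue_type in _HAS_HB:
        atoms.append("HB")
    return atoms


@dataclass
class SyntheticSpec:
    """Specification of a synthetic chemical-shift pool.

    class_fractions are (helix, sheet, coil) and must sum to 1; class_means
    maps class -> atom -> ppm mean (defaults: coil baseline plus class
    offsets); sds maps atom -> ppm standard deviation; missing_rate drops
    each atom independently.  ``block_length`` > 1 produces contiguous
    same-class segments instead of per-residue i.i.d. classes.

    A ``misreference_rate`` fraction of residues carries a shared-sign
    offset of ``misreference_sd`` standard deviations on every atom,
    emulating chemical-shift referencing errors; these whole-residue
    artifacts are exactly what the training-pool percentile filter removes.
    """

    n_proteins: int = 50
    length: tuple[int, int] = (50, 150)
    class_fractions: tuple[float, float, float] = (0.35, 0.25, 0.40)
    class_means: Mapping[str, Mapping[str, float]] = field(
        default_factory=lambda: {
            cls: {a: BASE_PPM[a] + CLASS_OFFSETS[cls][a] for a in BASE_PPM}
            for cls in CLASSES
        }
    )
    sds: Mapping[str, float] = field(default_factory=lambda: dict(DEFAULT_SD))
    missing_rate: float = 0.0
    misreference_rate: float = 0.03
    misreference_sd: float = 6.0
    block_length: int = 1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_proteins < 1:
            raise ParameterError("n_proteins must be >= 1")
        lo, hi = self.length
        if not 1 <= lo <= hi:
            raise ParameterError("length must be (min, max) with 1 <= min <= max")
        if abs(sum(self.class_fractions) - 1.0) > 1e-9:
            raise ParameterError("class_fractions must sum to 1")
        if any(f < 0 for f in self.class_fractions):
            raise ParameterError("class_fractions must be nonnegative")
        if any(sd <= 0 for sd in self.sds.values()):
            raise ParameterError("sds must be positive")
        if not 0 <= self.missing_rate < 1:
            raise ParameterError("missing_rate must be in [0, 1)")
        if not 0 <= self.misreference_rate < 1:
            raise ParameterError("misreference_rate must be in [0, 1)")
        if self.misreference_sd <= 0:
            raise ParameterError("misreference_sd must be positive")
        if self.block_length < 1:
            raise ParameterError("block_length must be >= 1")

    @classmethod
    def two_class(
        cls, separation: float = 3.0, sds: Mapping[str, float] | None = None,
        **kwargs,
    ) -> "SyntheticSpec":
        """Helix/sheet pool with class means ``separation`` sd apart per atom.

        Handy for structure-recovery experiments where the ground-truth
        classes must be resolvable from the shifts.
        """
        sds = dict(sds or DEFAULT_SD)
        means = {
            "helix": {a: BASE_PPM[a] - 0.5 * separation * sds[a] for a in BASE_PPM},
            "sheet": {a: BASE_PPM[a] + 0.5 * separation * sds[a] for a in BASE_PPM},
            "coil": dict(BASE_PPM),
        }
        kwargs.setdefault("class_fractions", (0.5, 0.5, 0.0))
        return cls(class_means=means, sds=sds, **kwargs)


@dataclass
class GroundTruth:
    """Labels for generated residues.

    ``labels`` maps (entry_id, chain_id, residue_number) to a class name;
    ``patch`` holds the residue numbers of a planted perturbation patch (for
    paired generation).
    """

    labels: dict[tuple[str, str, int], str] = field(default_factory=dict)
    patch: set[int] = field(default_factory=set)

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "entry_id": e, "chain": c, "residue_number": r,
                "label": lab, "in_patch": r in self.patch,
            }
            for (e, c, r), lab in self.labels.items()
        ]
        return pd.DataFrame(rows)


def _draw_classes(
    rng: np.random.Generator, n: int, spec: SyntheticSpec
) -> list[str]:
    if spec.block_length == 1:
        picks = rng.choice(3, size=n, p=spec.class_fractions)
        return [CLASSES[i] for i in picks]
    labels: list[str] = []
    while len(labels) < n:
        cls = CLASSES[rng.choice(3, p=spec.class_fractions)]
        labels.extend([cls] * spec.block_length)
    return labels[:n]


def _make_protein(
    rng: np.random.Generator, spec: SyntheticSpec, entry_id: str
) -> tuple[ProteinShiftTable, list[str]]:
    lo, hi = spec.length
    n = int(rng.integers(lo, hi + 1))
    seq = [STANDARD_AA[i] for i in rng.integers(0, 20, size=n)]
    classes = _draw_classes(rng, n, spec)
    records = []
    for pos, (aa, cls) in enumerate(zip(seq, classes), start=1):
        # occasional misreferenced residue: shared-sign offset on every atom,
        # emulating referencing errors (what the percentile filter removes)
        offset_sign = 0.0
        if spec.misreference_rate and rng.random() < spec.misreference_rate:
            offset_sign = float(rng.choice([-1.0, 1.0]))
        shifts = {}
        for atom in _atoms_present(aa):
            if spec.missing_rate and rng.random() < spec.missing_rate:
                continue
            mean = spec.class_means[cls][atom] + type_offset(aa, atom)
            mean += offset_sign * spec.misreference_sd * spec.sds[atom]
            shifts[atom] = float(mean + rng.normal(0.0, spec.sds[atom]))
        records.append(ShiftRecord("A", pos, aa, shifts))
    return ProteinShiftTable(entry_id, records), classes


def generate_dataset(
    spec: SyntheticSpec,
) -> tuple[list[ProteinShiftTable], GroundTruth]:
    """Generate a pool of proteins with per-residue class ground truth.

    Fully reproducible from ``spec.seed``: residues are drawn i.i.d. given
    class; shift = class mean + residue-type offset + Gaussian noise.
    """
    rng = np.random.default_rng(spec.seed)
    tables = []
    truth = GroundTruth()
    for p in range(spec.n_proteins):
        entry_id = f"syn{p:04d}"
        table, classes = _make_protein(rng, spec, entry_id)
        tables.append(table)
        for rec, cls in zip(table, classes):
            truth.labels[(entry_id, rec.chain_id, rec.residue_number)] = cls
    return tables, truth


def generate_pair(
    spec: SyntheticSpec,
    patch_length: int = 5,
    perturbation: float = 4.0,
) -> tuple[ProteinShiftTable, ProteinShiftTable, GroundTruth]:
    """Generate a free/bound pair with a planted perturbation patch.

    The bound state equals the free state except for a contiguous patch of
    ``patch_length`` residues whose present atoms are all shifted by
    ``perturbation`` standard deviations.  The patch location is recorded in
    the returned ground truth.
    """
    if perturbation <= 0:
        raise ParameterError("perturbation must be > 0 (in sd units)")
    rng = np.random.default_rng(spec.seed)
    free, classes = _make_protein(rng, spec, "free")
    n = len(free)
    if patch_length >= n:
        raise ParameterError("patch_length must be < protein length")
    start = int(rng.integers(1, n - patch_length + 1))
    patch = set(range(start, start + patch_length))
    bound_records = []
    for rec in free:
        shifts = dict(rec.shifts)
        if rec.residue_number in patch:
            shifts = {
                atom: val + perturbation * spec.sds[atom]
                for atom, val in shifts.items()
            }
        bound_records.append(
            ShiftRecord(rec.chain_id, rec.residue_number, rec.residue_type, shifts)
        )
    bound = ProteinShiftTable("bound", bound_records)
    truth = GroundTruth(patch=patch)
    for rec, cls in zip(free, classes):
        truth.labels[("free", rec.chain_id, rec.residue_number)] = cls
        truth.labels[("bound", rec.chain_id, rec.residue_number)] = cls
    return free, bound, truth
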