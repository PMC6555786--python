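"""Per-amino-acid-type percentile filtering and min-max scaling.

Training pools are curated by removing whole residues that carry any atom
outside the [1st, 99th] percentile of its (residue type, atom) distribution
— a guard against misreferenced shifts.  The surviving pool defines, per
(residue type, atom), the min/max used to scale shifts into [0, 1]:

    x_scaled = (x - min) / (max - min)

Scaling is strictly monotone per atom; at inference time out-of-range values
are clipped to [0, 1] rather than rejected, and filtering is not applied.
"""

from __future__ import annotations

import json
import warnings
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from sklearn.base import BaseEstimator

from .cs_io import AtomScheme, ShiftRecord, get_scheme, select_atoms
from .errors import FittingError, ParameterError

Key = tuple[str, str]  # (residue_type, atom)


def _resolve_scheme(scheme: str | AtomScheme) -> AtomScheme:
    return scheme if isinstance(scheme, AtomScheme) else get_scheme(scheme)


def _grouped_values(
    records: Iterable[ShiftRecord], scheme: AtomScheme
) -> dict[Key, list[float]]:
    by_key: dict[Key, list[float]] = {}
    for rec in records:
        for atom in scheme.atoms(rec.residue_type):
            val = rec.shifts.get(atom)
            if val is not None:
                by_key.setdefault((rec.residue_type, atom), []).append(val)
    return by_key


class PercentileFilter(BaseEstimator):
    """Whole-residue outlier filter on per-(type, atom) percentile bounds.

    Parameters
    ----------
    scheme:
        Atom scheme name or :class:`AtomScheme`; only scheme atoms are
        examined.
    lower, upper:
        Percentile bounds in [0, 100]; defaults 1 and 99.  Percentiles use
        linear interpolation between order statistics.
    min_samples:
        Below this many present values per (type, atom) a warning is issued
        (the percentiles are still computed).

    Attributes
    ----------
    bounds_:
        Mapping (residue_type, atom) -> (p_low, p_high) in ppm.
    """

    def __init__(
        self,
        scheme: str | AtomScheme = "common",
        lower: float = 1.0,
        upper: float = 99.0,
        min_samples: int = 100,
    ):
        self.scheme = scheme
        self.lower = lower
        self.upper = upper
        self.min_samples = min_samples

    def fit(self, records: Iterable[ShiftRecord], y=None) -> "PercentileFilter":
        if not 0 <= self.lower <= self.upper <= 100:
            raise ParameterError("need 0 <= lower <= upper <= 100")
        scheme = _resolve_scheme(self.scheme)
        records = list(records)
        by_key = _grouped_values(records, scheme)
        seen_types = {r.residue_type for r in records}
        for rtype in seen_types:
            for atom in scheme.atoms(rtype):
                if (rtype, atom) not in by_key:
                    raise FittingError(
                        f"no present values to fit filter for "
                        f"({rtype}, {atom})"
                    )
        self.bounds_ = {}
        for key, vals in by_key.items():
            if len(vals) < self.min_samples:
                warnings.warn(
                    f"only {len(vals)} values for {key}; percentile bounds "
                    f"may be unstable",
                    stacklevel=2,
                )
            arr = np.asarray(vals)
            lo = float(np.percentile(arr, self.lower, method="linear"))
            hi = float(np.percentile(arr, self.upper, method="linear"))
            self.bounds_[key] = (lo, hi)
        return self

    def is_outlier(self, record: ShiftRecord) -> bool:
        """True if any present scheme atom lies strictly outside its bounds."""
        scheme = _resolve_scheme(self.scheme)
        for atom in scheme.atoms(record.residue_type):
            val = record.shifts.get(atom)
            if val is None:
                continue
            bounds = self.bounds_.get((record.residue_type, atom))
            if bounds is None:
                continue
            lo, hi = bounds
            if val < lo or val > hi:
                return True
        return False

    def transform(self, records: Iterable[ShiftRecord]) -> list[ShiftRecord]:
        """Remove whole residues with any out-of-bounds present scheme atom."""
        return [r for r in records if not self.is_outlier(r)]

    def to_dict(self) -> dict:
        return {
            "scheme": _resolve_scheme(self.scheme).name,
            "lower": self.lower,
            "upper": self.upper,
            "bounds": {f"{k[0]}:{k[1]}": v for k, v in self.bounds_.items()},
        }

    @classmethod
    def from_dict(cls, payload: dict) -> "PercentileFilter":
        obj = cls(
            scheme=payload["scheme"],
            lower=payload["lower"],
            upper=payload["upper"],
        )
        obj.bounds_ = {
            tuple(k.split(":")): tuple(v) for k, v in payload["bounds"].items()
        }
        return obj


class ShiftScaler(BaseEstimator):
    """Per-(residue type, atom) min-max scaler to [0, 1].

    ``scale`` maps a scheme-ordered ppm vector to [0, 1] (clipping values
    outside the training range); ``unscale`` inverts exactly for unclipped
    values.  Masked (NaN) slots propagate.

    Attributes
    ----------
    ranges_:
        Mapping (residue_type, atom) -> (min_val, max_val) in ppm, the
        observed extremes of the (filtered) training pool.
    """

    def __init__(self, scheme: str | AtomScheme = "common"):
        self.scheme = scheme

    def fit(self, records: Iterable[ShiftRecord], y=None) -> "ShiftScaler":
        scheme = _resolve_scheme(self.scheme)
        by_key = _grouped_values(records, scheme)
        self.ranges_ = {}
        for key, vals in by_key.items():
            lo, hi = float(min(vals)), float(max(vals))
            if hi <= lo:
                raise FittingError(
                    f"degenerate atom {key}: all {len(vals)} values equal {lo}"
                )
            self.ranges_[key] = (lo, hi)
        return self

    def _range_array(
        self, residue_type: str, n: int
    ) -> tuple[np.ndarray, np.ndarray]:
        scheme = _resolve_scheme(self.scheme)
        atoms = scheme.atoms(residue_type)
        if len(atoms) != n:
            raise ParameterError(
                f"vector length {n} does not match scheme "
                f"{scheme.name!r} for {residue_type} ({len(atoms)} atoms)"
            )
        lows = np.empty(n)
        highs = np.empty(n)
        for i, atom in enumerate(atoms):
            try:
                lows[i], highs[i] = self.ranges_[(residue_type, atom)]
            except KeyError:
                raise FittingError(
                    f"scaler not fitted for ({residue_type}, {atom})"
                ) from None
        return lows, highs

    def scale(
        self,
        values: np.ndarray,
        mask: np.ndarray | None = None,
        residue_type: str = "A",
    ) -> np.ndarray:
        """Scale a scheme-ordered ppm vector (or matrix) into [0, 1]."""
        values = np.asarray(values, dtype=float)
        lo, hi = self._range_array(residue_type, values.shape[-1])
        scaled = (values - lo) / (hi - lo)
        scaled = np.clip(scaled, 0.0, 1.0)
        if mask is not None:
            scaled = np.where(mask, np.nan, scaled)
        return scaled

    def unscale(self, scaled: np.ndarray, residue_type: str = "A") -> np.ndarray:
        """Invert :meth:`scale` (exact for values that were not clipped)."""
        scaled = np.asarray(scaled, dtype=float)
        lo, hi = self._range_array(residue_type, scaled.shape[-1])
        return scaled * (hi - lo) + lo

    def transform(
        self, records: Iterable[ShiftRecord]
    ) -> dict[str, np.ndarray]:
        """Scale a record pool into per-type matrices (NaN where missing)."""
        scheme = _resolve_scheme(self.scheme)
        rows: dict[str, list[np.ndarray]] = {}
        for rec in records:
            vals, mask = select_atoms(rec, scheme)
            rows.setdefault(rec.residue_type, []).append(
                self.scale(vals, mask, rec.residue_type)
            )
        return {k: np.vstack(v) for k, v in rows.items()}

    def to_dict(self) -> dict:
        return {
            "scheme": _resolve_scheme(self.scheme).name,
            "ranges": {f"{k[0]}:{k[1]}": v for k, v in self.ranges_.items()},
        }

    @classmethod
    def from_dict(cls, payload: dict) -> "ShiftScaler":
        obj = cls(scheme=payload["scheme"])
        obj.ranges_ = {
            tuple(k.split(":")): tuple(v) for k, v in payload["ranges"].items()
        }
        return obj


def complete_case_matrix(
    records: Iterable[ShiftRecord],
    scheme: AtomScheme,
    residue_type: str,
    scaler: ShiftScaler | None = None,
) -> np.ndarray:
    """Stack residues of one type that have every scheme atom present.

    Returns an (n, n_atoms) matrix of ppm values, scaled to [0, 1] when a
    fitted ``scaler`` is given.
    """
    rows = []
    for rec in records:
        if rec.residue_type != residue_type:
            continue
        vals, mask = select_atoms(rec, scheme)
        if mask.any():
            continue
        rows.append(vals)
    if not rows:
        return np.empty((0, len(scheme.atoms(residue_type))))
    X = np.vstack(rows)
    if scaler is not None:
        X = scaler.scale(X, residue_type=residue_type)
    return X


# Functional wrappers -------------------------------------------------------

def fit_filter(
    pool: Iterable[ShiftRecord], scheme: str | AtomScheme = "common", **kwargs
) -> PercentileFilter:
    return PercentileFilter(scheme=scheme, **kwargs).fit(pool)


def apply_filter(
    records: Iterable[ShiftRecord], params: PercentileFilter
) -> list[ShiftRecord]:
    return params.transform(records)


def fit_scaler(
    pool: Iterable[ShiftRecord], scheme: str | AtomScheme = "common"
) -> ShiftScaler:
    return ShiftScaler(scheme=scheme).fit(pool)


def save_params(
    path: str | Path, filter_: PercentileFilter, scaler: ShiftScaler
) -> None:
    Path(path).write_text(
        json.dumps({"filter": filter_.to_dict(), "scaler": scaler.to_dict()})
    )


def load_params(path: str | Path) -> tuple[PercentileFilter, ShiftScaler]:
    payload = json.loads(Path(path).read_text())
    return (
        PercentileFilter.from_dict(payload["filter"]),
        ShiftScaler.from_dict(payload["scaler"]),
    )
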