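"""Compare ShiftCrypt profiles between proteins or protein states.

Two profiles are aligned globally on their sequences; per aligned pair the
absolute index difference is taken, and positions whose difference is
improbable (two-sided p < alpha) under a Gaussian fitted to all observed
differences are flagged as divergent.  For free/bound state pairs the amide
chemical-shift perturbation d = sqrt(ddH^2 + (w * ddN)^2) and a naive
consensus (min-max-scaled CSP + min-max-scaled index difference, range
[0, 2]) highlight interaction patches; Wilcoxon rank-sum and signed-rank
tests quantify patch-versus-rest and paired-distribution differences.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd
from Bio import Align
from Bio.Align import substitution_matrices
from scipy import stats

from .cs_io import AA1_TO_3, ShiftCryptProfile, ShiftRecord
from .errors import FittingError, ParameterError


@dataclass
class CompareParams:
    """Knobs for profile comparison.

    alpha is the Gaussian divergence significance level; gap penalties follow
    the score convention (non-positive); nh_weight scales the nitrogen term
    of the amide CSP composite.
    """

    alpha: float = 0.05
    gap_open: float = -10.0
    gap_extend: float = -0.5
    nh_weight: float = 0.14
    matrix: str = "BLOSUM62"

    def __post_init__(self) -> None:
        if not 0 < self.alpha <= 1:
            raise ParameterError("alpha must be in (0, 1]")
        if self.gap_open > 0 or self.gap_extend > 0:
            raise ParameterError("gap penalties must be <= 0")


class TestResult(NamedTuple):
    statistic: float
    pvalue: float


Pair = tuple[int | None, int | None]


def align_sequences(
    seqA: str, seqB: str, params: CompareParams | None = None
) -> list[Pair]:
    """Global pairwise alignment; returns (i, j) pairs with None for gaps.

    Every position of each sequence appears exactly once; indices are
    0-based positions into the input sequences and are monotone.
    """
    params = params or CompareParams()
    for name, seq in (("A", seqA), ("B", seqB)):
        if not seq:
            raise ParameterError(f"sequence {name} is empty")
        bad = set(seq) - set(AA1_TO_3)
        if bad:
            raise ParameterError(
                f"sequence {name} has invalid residue letters: {sorted(bad)}"
            )
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.substitution_matrix = substitution_matrices.load(params.matrix)
    aligner.open_gap_score = params.gap_open
    aligner.extend_gap_score = params.gap_extend
    alignment = aligner.align(seqA, seqB)[0]
    pairs: list[Pair] = []
    ia = ib = 0
    blocks_a, blocks_b = alignment.aligned
    for (a0, a1), (b0, b1) in zip(blocks_a, blocks_b):
        while ia < a0:
            pairs.append((ia, None))
            ia += 1
        while ib < b0:
            pairs.append((None, ib))
            ib += 1
        for off in range(a1 - a0):
            pairs.append((a0 + off, b0 + off))
        ia, ib = a1, b1
    while ia < len(seqA):
        pairs.append((ia, None))
        ia += 1
    while ib < len(seqB):
        pairs.append((None, ib))
        ib += 1
    return pairs


def _check_mapping(mapping: Sequence[Pair], lenA: int, lenB: int) -> None:
    seenA = [i for i, _ in mapping if i is not None]
    seenB = [j for _, j in mapping if j is not None]
    if sorted(seenA) != list(range(lenA)) or sorted(seenB) != list(range(lenB)):
        raise ParameterError(
            "mapping inconsistent with profile lengths "
            f"({lenA}, {lenB})"
        )


def profile_deltas(
    profileA: ShiftCryptProfile,
    profileB: ShiftCryptProfile,
    mapping: Sequence[Pair],
) -> np.ndarray:
    """Per-pair |indexA - indexB|; NaN at gaps or missing indices."""
    _check_mapping(mapping, len(profileA), len(profileB))
    va, vb = profileA.values, profileB.values
    out = np.full(len(mapping), np.nan)
    for k, (i, j) in enumerate(mapping):
        if i is None or j is None:
            continue
        out[k] = abs(va[i] - vb[j])
    return out


def detect_divergent(
    deltas: np.ndarray, params: CompareParams | None = None
) -> pd.DataFrame:
    """Flag positions whose delta is a Gaussian outlier.

    A normal distribution (mean, sample sd with divisor n-1) is fitted to
    the present deltas; each delta gets a two-sided p and is flagged iff
    p < alpha.  With zero spread the distribution is degenerate: nothing is
    flagged.
    """
    params = params or CompareParams()
    deltas = np.asarray(deltas, dtype=float)
    present = np.isfinite(deltas)
    if present.sum() < 5:
        raise ParameterError(
            f"need >= 5 present deltas, got {int(present.sum())}"
        )
    mean = float(np.mean(deltas[present]))
    sd = float(np.std(deltas[present], ddof=1))
    z = np.full_like(deltas, np.nan)
    p = np.full_like(deltas, np.nan)
    if sd < 1e-12:
        warnings.warn(
            "degenerate delta distribution (zero sd); no positions flagged",
            stacklevel=2,
        )
        flagged = np.zeros(len(deltas), dtype=bool)
    else:
        z[present] = (deltas[present] - mean) / sd
        p[present] = 2.0 * stats.norm.sf(np.abs(z[present]))
        flagged = present & (p < params.alpha)
    return pd.DataFrame({"delta": deltas, "z": z, "p": p, "flagged": flagged})


def csp_nh(
    recordsA: Sequence[ShiftRecord],
    recordsB: Sequence[ShiftRecord],
    mapping: Sequence[Pair],
    params: CompareParams | None = None,
) -> np.ndarray:
    """Composite amide N-H chemical-shift perturbation per aligned pair.

    d = sqrt((ddH)^2 + (w * ddN)^2) with w = ``params.nh_weight``; NaN when
    either record lacks N or H (prolines, gaps, unassigned amides).
    """
    params = params or CompareParams()
    out = np.full(len(mapping), np.nan)
    for k, (i, j) in enumerate(mapping):
        if i is None or j is None:
            continue
        a, b = recordsA[i], recordsB[j]
        try:
            dH = a.shifts["H"] - b.shifts["H"]
            dN = a.shifts["N"] - b.shifts["N"]
        except KeyError:
            continue
        out[k] = math.sqrt(dH**2 + (params.nh_weight * dN) ** 2)
    return out


def consensus_score(
    deltas: np.ndarray, csp: np.ndarray, mapping: Sequence[Pair] | None = None
) -> np.ndarray:
    """Naive consensus: min-max-scaled CSP plus min-max-scaled index delta.

    Each component is scaled to [0, 1] over the pairs where it is present;
    the consensus (range [0, 2]) is defined where both are present.
    """
    deltas = np.asarray(deltas, dtype=float)
    csp = np.asarray(csp, dtype=float)
    if deltas.shape != csp.shape:
        raise ParameterError("deltas and csp must share the mapping length")

    def scaled(x: np.ndarray, name: str) -> np.ndarray:
        present = np.isfinite(x)
        if not present.any():
            raise FittingError(f"all {name} values missing; consensus undefined")
        lo, hi = np.min(x[present]), np.max(x[present])
        if hi == lo:
            out = np.where(present, 0.0, np.nan)
        else:
            out = (x - lo) / (hi - lo)
        return out

    return scaled(deltas, "index-delta") + scaled(csp, "CSP")


# ---------------------------------------------------------------------------
# Rank tests
# ---------------------------------------------------------------------------

_EXACT_RANKSUM_MAX = 12
_EXACT_SIGNEDRANK_MAX = 15


def ranksum_test(
    valuesA: Sequence[float], valuesB: Sequence[float]
) -> TestResult:
    """Wilcoxon rank-sum (Mann-Whitney U) two-sided test.

    Exact enumeration of all C(n, nA) rank assignments (midranks for ties)
    when nA + nB <= 12; otherwise the tie-corrected normal approximation.
    The statistic is U for group A.
    """
    a = np.asarray(valuesA, dtype=float)
    b = np.asarray(valuesB, dtype=float)
    if len(a) == 0 or len(b) == 0:
        raise ParameterError("both groups must be non-empty")
    combined = np.concatenate([a, b])
    if np.all(combined == combined[0]):
        warnings.warn("all values tied across both groups", stacklevel=2)
        return TestResult(len(a) * len(b) / 2.0, 1.0)
    nA, n = len(a), len(combined)
    ranks = stats.rankdata(combined)
    W = float(ranks[:nA].sum())
    U = W - nA * (nA + 1) / 2.0
    if n <= _EXACT_RANKSUM_MAX:
        mean_W = nA * (n + 1) / 2.0
        obs = abs(W - mean_W)
        count = 0
        total = 0
        for subset in itertools.combinations(range(n), nA):
            Wp = ranks[list(subset)].sum()
            if abs(Wp - mean_W) >= obs - 1e-12:
                count += 1
            total += 1
        return TestResult(U, count / total)
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method="asymptotic")
    return TestResult(float(res.statistic), float(res.pvalue))


def signedrank_test(differences: Sequence[float]) -> TestResult:
    """Wilcoxon signed-rank two-sided test on paired differences.

    Zero differences are dropped.  Exact enumeration of all 2^n sign
    patterns (midranks for tied magnitudes) when n <= 15; otherwise the
    normal approximation.  The statistic is W+ (sum of positive ranks).
    """
    d = np.asarray(differences, dtype=float)
    d = d[d != 0]
    if len(d) == 0:
        warnings.warn("all differences zero", stacklevel=2)
        return TestResult(0.0, 1.0)
    n = len(d)
    ranks = stats.rankdata(np.abs(d))
    w_plus = float(ranks[d > 0].sum())
    if n <= _EXACT_SIGNEDRANK_MAX:
        mean = n * (n + 1) / 4.0
        obs = abs(w_plus - mean)
        signs = np.array(list(itertools.product([0, 1], repeat=n)))
        w_all = signs @ ranks
        count = int(np.sum(np.abs(w_all - mean) >= obs - 1e-12))
        return TestResult(w_plus, count / len(signs))
    res = stats.wilcoxon(d, alternative="two-sided", method="approx")
    return TestResult(float(res.statistic), float(res.pvalue))


# ---------------------------------------------------------------------------
# Top-level comparison
# ---------------------------------------------------------------------------

@dataclass
class ComparisonResult:
    """Aligned per-pair comparison of two profiles.

    ``table`` columns: posA, posB (author residue numbers, <NA> at gaps),
    aaA, aaB, indexA, indexB, delta, z, p, flagged, and — when shift records
    were supplied — csp and consensus.
    """

    table: pd.DataFrame
    params: CompareParams

    @property
    def flagged_positions(self) -> pd.DataFrame:
        return self.table[self.table["flagged"]]


def compare_profiles(
    profileA: ShiftCryptProfile,
    profileB: ShiftCryptProfile,
    recordsA: Sequence[ShiftRecord] | None = None,
    recordsB: Sequence[ShiftRecord] | None = None,
    params: CompareParams | None = None,
) -> ComparisonResult:
    """Align two profiles and assemble the full per-pair comparison.

    When both record lists are given (profile order), the amide CSP and the
    consensus score are included.
    """
    params = params or CompareParams()
    mapping = align_sequences(profileA.sequence, profileB.sequence, params)
    deltas = profile_deltas(profileA, profileB, mapping)
    try:
        div = detect_divergent(deltas, params)
    except ParameterError:
        warnings.warn(
            "too few present deltas for divergence calling", stacklevel=2
        )
        div = pd.DataFrame(
            {
                "delta": deltas,
                "z": np.full(len(mapping), np.nan),
                "p": np.full(len(mapping), np.nan),
                "flagged": np.zeros(len(mapping), dtype=bool),
            }
        )
    rows = {
        "posA": pd.array(
            [None if i is None else profileA.entries[i].residue_number
             for i, _ in mapping],
            dtype="Int64",
        ),
        "posB": pd.array(
            [None if j is None else profileB.entries[j].residue_number
             for _, j in mapping],
            dtype="Int64",
        ),
        "aaA": ["-" if i is None else profileA.entries[i].residue_type
                for i, _ in mapping],
        "aaB": ["-" if j is None else profileB.entries[j].residue_type
                for _, j in mapping],
        "indexA": [np.nan if i is None else profileA.values[i]
                   for i, _ in mapping],
        "indexB": [np.nan if j is None else profileB.values[j]
                   for _, j in mapping],
    }
    table = pd.DataFrame(rows)
    table = pd.concat([table, div.reset_index(drop=True)], axis=1)
    if recordsA is not None and recordsB is not None:
        csp = csp_nh(recordsA, recordsB, mapping, params)
        table["csp"] = csp
        try:
            table["consensus"] = consensus_score(deltas, csp)
        except FittingError:
            table["consensus"] = np.nan
    return ComparisonResult(table, params)
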