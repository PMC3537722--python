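"""Pairwise sequence divergence, uncorrected and corrected for multiple hits.

Supported corrections:

``uncorrected``
    The raw proportion of differing sites, *p*.
``jc69``
    Jukes & Cantor 1969: ``d = -(3/4) ln(1 - 4p/3)``.
``k2p``
    Kimura 1980 two-parameter model separating transitions (P) from
    transversions (Q): ``d = -(1/2) ln(1 - 2P - Q) - (1/4) ln(1 - 2Q)``.
``k81``
    Kimura 1981 three-substitution-type model splitting transversions into
    two classes (A<->T/G<->C vs A<->C/G<->T):
    ``d = -(1/4) [ln(1-2P-2Q1) + ln(1-2P-2Q2) + ln(1-2Q1-2Q2)]``.

Sites where either residue is not an unambiguous A/C/G/T are excluded
pairwise (pairwise deletion), so gaps and ambiguity codes reduce the number
of compared sites *m* for that pair only.

Within-clade diversity (pi, theta) is always computed from uncorrected
differences; corrections apply only to between-clade divergence K.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import numpy as np

from .errors import NoComparableSitesError, SaturationError, TreeError
from .seqio import _ENCODE, Alignment

__all__ = [
    "MODELS",
    "SiteCounts",
    "DistanceMatrix",
    "count_site_patterns",
    "correct_distance",
    "distance_matrix",
]

MODELS = ("uncorrected", "jc69", "k2p", "k81")


@dataclass(frozen=True)
class SiteCounts:
    """Substitution-class tallies for one sequence pair.

    ``m`` is the number of pairwise-complete sites; ``P``, ``Q1`` and ``Q2``
    are the transition, class-1 transversion (A<->T, G<->C) and class-2
    transversion (A<->C, G<->T) proportions of ``m``.  ``P + Q1 + Q2 == p``.
    """

    m: int
    n_diff: int
    P: float
    Q1: float
    Q2: float

    @property
    def p(self) -> float:
        return self.n_diff / self.m

    @property
    def Q(self) -> float:
        """Total transversion proportion (K2P's Q)."""
        return self.Q1 + self.Q2


def _as_codes(seq) -> np.ndarray:
    if isinstance(seq, str):
        seq = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
        return _ENCODE[seq]
    arr = np.asarray(seq)
    if arr.dtype == np.int8:
        return arr
    if arr.dtype.kind == "S":
        return _ENCODE[arr.view(np.uint8)]
    return _ENCODE[arr.astype(np.uint8)]


def count_site_patterns(a, b) -> SiteCounts:
    """Tally substitution classes between two equal-length sequence rows.

    Accepts strings, byte arrays, or pre-encoded int8 code arrays.  Raises
    :class:`NoComparableSitesError` when no site has an unambiguous base in
    both rows.
    """
    ca, cb = _as_codes(a), _as_codes(b)
    if ca.shape != cb.shape:
        raise ValueError("sequences must have equal length")
    valid = (ca >= 0) & (cb >= 0)
    m = int(valid.sum())
    if m == 0:
        raise NoComparableSitesError("no comparable (unambiguous) sites between the pair")
    diff = (ca != cb) & valid
    # parity trick: A(0), G(2) are even; C(1), T(3) odd -> same parity = transition
    ts = diff & ((ca & 1) == (cb & 1))
    s = ca + cb
    q1 = diff & ~ts & (s == 3)  # {A,T} or {G,C}
    q2 = diff & ~ts & ((s == 1) | (s == 5))  # {A,C} or {G,T}
    return SiteCounts(
        m=m,
        n_diff=int(diff.sum()),
        P=float(ts.sum()) / m,
        Q1=float(q1.sum()) / m,
        Q2=float(q2.sum()) / m,
    )


def _safe_log(x: float, context: str) -> float:
    if x <= 0.0:
        raise SaturationError(
            f"distance correction undefined ({context}): substitution proportions "
            "are at or beyond the model boundary (saturated pair)"
        )
    return math.log(x)


def correct_distance(counts: SiteCounts, model: str) -> float:
    """Evolutionary distance (substitutions/site) under a named model.

    Raises :class:`SaturationError` when a logarithm argument is <= 0.
    """
    model = model.lower()
    if model not in MODELS:
        raise ValueError(f"unknown model {model!r}; choose from {MODELS}")
    p, P, Q1, Q2 = counts.p, counts.P, counts.Q1, counts.Q2
    if model == "uncorrected":
        return p
    if model == "jc69":
        return -0.75 * _safe_log(1.0 - 4.0 * p / 3.0, "JC69")
    if model == "k2p":
        Q = Q1 + Q2
        return -0.5 * _safe_log(1.0 - 2.0 * P - Q, "K2P") - 0.25 * _safe_log(1.0 - 2.0 * Q, "K2P")
    # K81
    return -0.25 * (
        _safe_log(1.0 - 2.0 * P - 2.0 * Q1, "K81")
        + _safe_log(1.0 - 2.0 * P - 2.0 * Q2, "K81")
        + _safe_log(1.0 - 2.0 * Q1 - 2.0 * Q2, "K81")
    )


@dataclass
class DistanceMatrix:
    """Symmetric pairwise distance matrix under a named substitution model.

    ``saturated`` flags entries whose correction was undefined; those entries
    hold ``inf``.  All other entries are finite and nonnegative with a zero
    diagonal.
    """

    labels: tuple[str, ...]
    values: np.ndarray
    model: str
    saturated: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.labels = tuple(self.labels)
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.labels)
        if self.values.shape != (n, n):
            raise TreeError("distance matrix shape does not match label count")
        if self.saturated is None:
            self.saturated = np.zeros((n, n), dtype=bool)
        finite = self.values[~self.saturated]
        if not np.allclose(self.values, self.values.T, equal_nan=True):
            raise TreeError("distance matrix is not symmetric")
        if np.any(np.diag(self.values) != 0.0):
            raise TreeError("distance matrix diagonal must be zero")
        if finite.size and (np.any(~np.isfinite(finite)) or np.any(finite < 0)):
            raise TreeError("unflagged distance entries must be finite and nonnegative")

    @property
    def n(self) -> int:
        return len(self.labels)

    def index(self, label: str) -> int:
        return self.labels.index(label)

    def __getitem__(self, pair: tuple[str, str]) -> float:
        a, b = pair
        return float(self.values[self.index(a), self.index(b)])

    def submatrix(self, labels: Iterable[str]) -> "DistanceMatrix":
        idx = [self.index(l) for l in labels]
        return DistanceMatrix(
            labels=tuple(self.labels[i] for i in idx),
            values=self.values[np.ix_(idx, idx)].copy(),
            model=self.model,
            saturated=self.saturated[np.ix_(idx, idx)].copy(),
        )

    def write_lower_triangle(self, dest) -> None:
        """Tab-separated lower triangle with a header row (spreadsheet style)."""
        lines = ["\t".join(("",) + self.labels)]
        for i, lab in enumerate(self.labels):
            cells = [lab] + [f"{self.values[i, j]:.6f}" for j in range(i)]
            lines.append("\t".join(cells))
        text = "\n".join(lines) + "\n"
        if isinstance(dest, (str, Path)):
            Path(dest).write_text(text)
        else:
            dest.write(text)


def _pair_class_counts(codes: np.ndarray):
    """Vectorized per-pair tallies: m, n_diff, transitions, Q1, Q2 (all n x n)."""
    A = codes[:, None, :]
    B = codes[None, :, :]
    valid = (A >= 0) & (B >= 0)
    diff = (A != B) & valid
    ts = diff & ((A & 1) == (B & 1))
    s = A + B
    q1 = diff & ~ts & (s == 3)
    q2 = diff & ~ts & ((s == 1) | (s == 5))
    return (
        valid.sum(axis=2),
        diff.sum(axis=2),
        ts.sum(axis=2),
        q1.sum(axis=2),
        q2.sum(axis=2),
    )


def p_distance_matrix(aln: Alignment) -> DistanceMatrix:
    """Uncorrected proportion-of-differences matrix (fast path)."""
    return distance_matrix(aln, "uncorrected")


def distance_matrix(
    aln: Alignment, model: str = "uncorrected", on_saturation: str = "raise"
) -> DistanceMatrix:
    """All-pairs distance matrix for an alignment under *model*.

    ``on_saturation`` is ``"raise"`` (default) or ``"flag"``; flagged entries
    are set to ``inf`` and marked in :attr:`DistanceMatrix.saturated` rather
    than silently dropped.
    """
    model = model.lower()
    if model not in MODELS:
        raise ValueError(f"unknown model {model!r}; choose from {MODELS}")
    if aln.n < 2:
        raise ValueError("need at least two sequences for a distance matrix")
    m, ndiff, ts, q1, q2 = _pair_class_counts(aln.codes)
    offdiag = ~np.eye(aln.n, dtype=bool)
    if np.any((m == 0) & offdiag):
        i, j = np.argwhere((m == 0) & offdiag)[0]
        raise NoComparableSitesError(
            f"sequences {aln.ids[i]!r} and {aln.ids[j]!r} share no comparable sites"
        )
    with np.errstate(divide="ignore", invalid="ignore"):
        msafe = np.where(m == 0, 1, m)
        p = ndiff / msafe
        P = ts / msafe
        Q1 = q1 / msafe
        Q2 = q2 / msafe
        if model == "uncorrected":
            values = p
            bad = np.zeros_like(p, dtype=bool)
        elif model == "jc69":
            arg = 1.0 - 4.0 * p / 3.0
            bad = arg <= 0.0
            values = -0.75 * np.log(np.where(bad, 1.0, arg))
        elif model == "k2p":
            Q = Q1 + Q2
            a1, a2 = 1.0 - 2.0 * P - Q, 1.0 - 2.0 * Q
            bad = (a1 <= 0.0) | (a2 <= 0.0)
            values = -0.5 * np.log(np.where(bad, 1.0, a1)) - 0.25 * np.log(np.where(bad, 1.0, a2))
        else:  # k81
            a1 = 1.0 - 2.0 * P - 2.0 * Q1
            a2 = 1.0 - 2.0 * P - 2.0 * Q2
            a3 = 1.0 - 2.0 * Q1 - 2.0 * Q2
            bad = (a1 <= 0.0) | (a2 <= 0.0) | (a3 <= 0.0)
            values = -0.25 * (
                np.log(np.where(bad, 1.0, a1))
                + np.log(np.where(bad, 1.0, a2))
                + np.log(np.where(bad, 1.0, a3))
            )
    bad &= offdiag
    if np.any(bad):
        if on_saturation == "raise":
            i, j = np.argwhere(bad)[0]
            raise SaturationError(
                f"pair ({aln.ids[i]!r}, {aln.ids[j]!r}) is saturated under {model}"
            )
        values = np.where(bad, np.inf, values)
    values = np.where(offdiag, values, 0.0)
    # enforce exact symmetry against floating-point asymmetries
    values = (values + values.T) / 2.0 if not np.any(bad) else values
    return DistanceMatrix(labels=aln.ids, values=values, model=model, saturated=bad)
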