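"""Observed-data containers and sufficient statistics for the 3-leaf problem.

Data enter either as an 8-entry site-frequency vector (pattern counts in the
fixed binary order) or as a 3-sequence alignment over a binary alphabet.  The
statistics computed here -- the split collapse ``sbar``, the agreement counts
``M+/M-`` per leaf pair, the correlations ``B_ij = (M+ - M-)/N`` and the CFN
distance estimates ``-1/2 log B_ij`` -- are everything the maximum-likelihood
solver needs, together with the two genericity diagnostics (every split class
observed; B values nonzero and distinct) under which the closed-form solution
is valid.

All branching-relevant quantities are kept as exact integers (``N*B`` is the
integer ``M+ - M-``), so downstream sign tests and ties are decided exactly,
never by float comparison.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from Bio import SeqIO

from .model import PATTERN_LABELS, SPLIT_LABELS, SPLIT_OF_PATTERN

__all__ = [
    "PAIRS",
    "PAIR_LABELS",
    "CountsParseError",
    "AlignmentError",
    "EmptyDataError",
    "SiteFrequencyVector",
    "SplitFrequencyVector",
    "BStatistics",
    "GenericityReport",
    "read_counts",
    "read_alignment",
    "split_collapse",
    "compute_B",
    "check_genericity",
    "cfn_distances",
]

#: leaf pairs in the fixed order (1,2), (1,3), (2,3) -- zero-based internally.
PAIRS = ((0, 1), (0, 2), (1, 2))
PAIR_LABELS = ("12", "13", "23")

#: Default alignment character map.  Purines (A, G, R) -> -1, pyrimidines
#: (C, T, U, Y) -> +1; also accepts literal binary alphabets.
DEFAULT_ALPHABET_MAP = {
    "A": -1, "G": -1, "R": -1,
    "C": +1, "T": +1, "U": +1, "Y": +1,
    "0": -1, "1": +1,
    "-": -1, "+": +1,
}


class CountsParseError(ValueError):
    """Raised when a counts source is malformed (arity, sign, non-integer)."""


class AlignmentError(ValueError):
    """Raised for alignments that are not 3 equal-length binary sequences."""


class EmptyDataError(ValueError):
    """Raised when statistics are requested for N = 0 sites."""


@dataclass(frozen=True)
class SiteFrequencyVector:
    """Counts of the 8 site patterns over N sites, in the fixed binary order."""

    s: tuple[int, ...]

    def __post_init__(self):
        if len(self.s) != 8:
            raise CountsParseError(f"expected 8 pattern counts, got {len(self.s)}")
        for label, c in zip(PATTERN_LABELS, self.s):
            if not isinstance(c, (int, np.integer)) or isinstance(c, bool):
                raise CountsParseError(f"count for pattern {label} is not an integer: {c!r}")
            if c < 0:
                raise CountsParseError(f"count for pattern {label} is negative: {c}")
        object.__setattr__(self, "s", tuple(int(c) for c in self.s))

    @property
    def N(self) -> int:
        return sum(self.s)

    def as_array(self) -> np.ndarray:
        return np.asarray(self.s, dtype=np.int64)

    def to_dict(self) -> dict:
        return {"counts": list(self.s), "N": self.N}


@dataclass(frozen=True)
class SplitFrequencyVector:
    """Counts of the 4 split classes {}, {1}, {2}, {1,2} over N sites."""

    sbar: tuple[int, ...]

    def __post_init__(self):
        if len(self.sbar) != 4:
            raise CountsParseError(f"expected 4 split counts, got {len(self.sbar)}")
        if any(c < 0 for c in self.sbar):
            raise CountsParseError(f"split counts must be nonnegative: {self.sbar}")
        object.__setattr__(self, "sbar", tuple(int(c) for c in self.sbar))

    @property
    def N(self) -> int:
        return sum(self.sbar)

    def as_array(self) -> np.ndarray:
        return np.asarray(self.sbar, dtype=np.int64)

    def to_dict(self) -> dict:
        return {"sbar": list(self.sbar), "N": self.N}


@dataclass(frozen=True)
class BStatistics:
    """Per-pair agreement counts and correlations.

    ``m_plus[p]``/``m_minus[p]`` count sites where the two leaves of pair ``p``
    agree/disagree (``m_plus + m_minus = N``); ``nb = m_plus - m_minus`` is the
    exact integer ``N*B``, and ``b = nb / N`` the empirical correlation, a
    consistent estimator of the Fourier coordinate ``theta_i * theta_j``.
    """

    n: int
    m_plus: tuple[int, int, int]
    m_minus: tuple[int, int, int]

    @property
    def nb(self) -> tuple[int, int, int]:
        return tuple(p - m for p, m in zip(self.m_plus, self.m_minus))

    @property
    def b(self) -> np.ndarray:
        if self.n == 0:
            raise EmptyDataError("B statistics undefined for N = 0")
        return np.asarray(self.nb, dtype=float) / float(self.n)

    def pair_value(self, i: int, j: int) -> float:
        """B for the (1-based, order-free) leaf pair {i, j}."""
        key = tuple(sorted((i - 1, j - 1)))
        return float(self.b[PAIRS.index(key)])

    def to_dict(self) -> dict:
        b = self.b
        return {
            "N": self.n,
            **{f"B{lbl}": float(bv) for lbl, bv in zip(PAIR_LABELS, b)},
            **{f"M_plus_{lbl}": mp for lbl, mp in zip(PAIR_LABELS, self.m_plus)},
            **{f"M_minus_{lbl}": mm for lbl, mm in zip(PAIR_LABELS, self.m_minus)},
        }


@dataclass(frozen=True)
class GenericityReport:
    """Diagnostics for the two assumptions behind the closed-form solver.

    A.1: every split class observed at least once (no zero in sbar).
    A.2: the three B values are nonzero and pairwise distinct (checked on the
    integers N*B, so exact ties are detected exactly).
    """

    a1_holds: bool
    a2_holds: bool
    violations: tuple[str, ...] = field(default_factory=tuple)

    @property
    def generic(self) -> bool:
        return self.a1_holds and self.a2_holds

    def to_dict(self) -> dict:
        return {
            "a1_holds": self.a1_holds,
            "a2_holds": self.a2_holds,
            "violations": list(self.violations),
        }


def read_counts(source) -> SiteFrequencyVector:
    """Parse a site-frequency vector from flexible plain-text input.

    Accepts a sequence of 8 integers, a comma/whitespace-separated string,
    a JSON string/object with a ``"counts"`` key, or a path to a file holding
    either of the text forms.
    """
    if isinstance(source, SiteFrequencyVector):
        return source
    if isinstance(source, Path):
        source = source.read_text()
    if isinstance(source, dict):
        if "counts" not in source:
            raise CountsParseError("JSON object must have a 'counts' key")
        return _counts_from_list(source["counts"])
    if isinstance(source, str):
        text = source.strip()
        if text.startswith("{") or text.startswith("["):
            try:
                obj = json.loads(text)
            except json.JSONDecodeError as exc:
                raise CountsParseError(f"invalid JSON counts: {exc}") from exc
            if isinstance(obj, dict):
                return read_counts(obj)
            return _counts_from_list(obj)
        tokens = text.replace(",", " ").split()
        return _counts_from_list(tokens)
    return _counts_from_list(source)


def _counts_from_list(values) -> SiteFrequencyVector:
    values = list(values)
    if len(values) != 8:
        raise CountsParseError(f"expected 8 pattern counts, got {len(values)}")
    parsed = []
    for label, v in zip(PATTERN_LABELS, values):
        if isinstance(v, bool):
            raise CountsParseError(f"count for pattern {label} is not an integer: {v!r}")
        if isinstance(v, str):
            try:
                v = int(v)
            except ValueError as exc:
                raise CountsParseError(
                    f"count for pattern {label} is not an integer: {v!r}"
                ) from exc
        if isinstance(v, float):
            if not v.is_integer():
                raise CountsParseError(f"count for pattern {label} is not an integer: {v!r}")
            v = int(v)
        parsed.append(v)
    return SiteFrequencyVector(tuple(parsed))


def read_alignment(
    path,
    alphabet_map: dict[str, int] | None = None,
    ambiguous: str = "drop",
) -> SiteFrequencyVector:
    """Tally the 8 column patterns of a 3-sequence FASTA alignment.

    Characters map to states via ``alphabet_map`` (default: purine/pyrimidine
    plus literal binary alphabets).  Columns containing unmapped characters are
    dropped and counted (``ambiguous="drop"``, the default) or raise
    (``ambiguous="error"``).  Returns the site-frequency vector; the number of
    dropped columns is available as its ``dropped_columns`` attribute.
    """
    if ambiguous not in ("drop", "error"):
        raise ValueError(f"ambiguous policy must be 'drop' or 'error', got {ambiguous!r}")
    charmap = dict(DEFAULT_ALPHABET_MAP if alphabet_map is None else alphabet_map)
    records = list(SeqIO.parse(str(path), "fasta"))
    if len(records) != 3:
        raise AlignmentError(f"expected exactly 3 sequences, found {len(records)}")
    seqs = [str(r.seq).upper() for r in records]
    if len({len(s) for s in seqs}) != 1:
        raise AlignmentError(
            "sequences have unequal lengths: "
            + ", ".join(f"{r.id}={len(r.seq)}" for r in records)
        )
    counts = [0] * 8
    dropped = 0
    for col in zip(*seqs):
        states = []
        for rec, ch in zip(records, col):
            if ch not in charmap:
                if ambiguous == "error":
                    raise AlignmentError(
                        f"unmapped character {ch!r} in sequence {rec.id}"
                    )
                states = None
                break
            states.append(charmap[ch])
        if states is None:
            dropped += 1
            continue
        idx = sum((1 if x > 0 else 0) << shift for x, shift in zip(states, (2, 1, 0)))
        counts[idx] += 1
    sfv = SiteFrequencyVector(tuple(counts))
    object.__setattr__(sfv, "dropped_columns", dropped)
    return sfv


def split_collapse(s: SiteFrequencyVector) -> SplitFrequencyVector:
    """Collapse the 8 pattern counts to the 4 split-class counts (conserves N)."""
    sbar = [0, 0, 0, 0]
    for count, alpha in zip(s.s, SPLIT_OF_PATTERN):
        sbar[alpha] += count
    return SplitFrequencyVector(tuple(sbar))


def compute_B(s: SiteFrequencyVector) -> BStatistics:
    """Agreement counts and correlations for the three leaf pairs.

    Computed two independent ways -- directly from the 8 pattern counts
    (summing over patterns with matching/mismatching states at the pair) and
    from the split collapse via the signed-sum identities -- and asserted equal
    exactly, as a structural self-check.
    """
    if s.N == 0:
        raise EmptyDataError("cannot compute B statistics from 0 sites")
    from .model import PATTERNS  # local import to keep module load order simple

    m_plus, m_minus = [], []
    for (i, j) in PAIRS:
        agree = PATTERNS[:, i] * PATTERNS[:, j] == 1
        m_plus.append(int(np.sum(s.as_array()[agree])))
        m_minus.append(int(np.sum(s.as_array()[~agree])))
    stats = BStatistics(n=s.N, m_plus=tuple(m_plus), m_minus=tuple(m_minus))

    # second route: signed sums of the split counts (must agree bit-for-bit)
    sb = split_collapse(s).sbar
    nb_from_split = (
        sb[0] - sb[1] - sb[2] + sb[3],
        sb[0] - sb[1] + sb[2] - sb[3],
        sb[0] + sb[1] - sb[2] - sb[3],
    )
    if stats.nb != nb_from_split:
        raise AssertionError(
            f"internal inconsistency: N*B via patterns {stats.nb} != via splits {nb_from_split}"
        )
    return stats


def check_genericity(s: SiteFrequencyVector) -> GenericityReport:
    """Evaluate the two genericity assumptions on exact integers."""
    sbar = split_collapse(s)
    violations = []
    a1 = True
    for label, c in zip(SPLIT_LABELS, sbar.sbar):
        if c == 0:
            a1 = False
            violations.append(f"split class {label} unobserved (sbar = 0)")
    a2 = True
    if s.N > 0:
        nb = compute_B(s).nb
        for label, v in zip(PAIR_LABELS, nb):
            if v == 0:
                a2 = False
                violations.append(f"B{label} = 0")
        for (la, va), (lb, vb) in (
            ((PAIR_LABELS[0], nb[0]), (PAIR_LABELS[1], nb[1])),
            ((PAIR_LABELS[0], nb[0]), (PAIR_LABELS[2], nb[2])),
            ((PAIR_LABELS[1], nb[1]), (PAIR_LABELS[2], nb[2])),
        ):
            if va == vb:
                a2 = False
                violations.append(f"B{la} = B{lb} (exact tie)")
    else:
        a2 = False
        violations.append("no data (N = 0)")
    return GenericityReport(a1_holds=a1, a2_holds=a2, violations=tuple(violations))


def cfn_distances(b: BStatistics) -> np.ndarray:
    """CFN distance estimates ``D_ij = -1/2 log(B_ij)`` per leaf pair.

    Infinite when ``B_ij <= 0`` (more mismatches than matches -- the pair looks
    at least as divergent as independent sequences).
    """
    bvals = b.b
    out = np.full(3, np.inf)
    pos = bvals > 0
    out[pos] = -0.5 * np.log(bvals[pos])
    return out
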