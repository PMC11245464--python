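"""Seeded data generator for the CFN process on the 3-leaf star tree.

Each site is generated independently: the state at the internal vertex is
uniform on {-1, +1}, and the state at leaf ``i`` equals the internal state
with probability ``(1 + theta_i) / 2``.  Draw order per simulation is fixed
and documented (the root vector first, then the flip vectors for leaves 1, 2,
3 in order, each as one vectorized draw from ``numpy.random.default_rng``),
so streams are reproducible for a fixed seed.

Also provided is a constructive fixture factory that produces count vectors
whose exact integer correlations fall in a requested maximizer regime, by
inverting the linear relation between split counts and correlations
(``4 sbar_alpha / N = 1 ± B12 ± B13 ± B23``) at integer-compatible B triples.
"""

from __future__ import annotations

import numpy as np

from .model import theta_from_lengths
from .stats import SiteFrequencyVector, compute_B, check_genericity

__all__ = [
    "simulate_sites",
    "simulate_alignment",
    "simulate_boundary_scenarios",
    "counts_from_split",
    "write_fasta",
]

_STATE_CHAR = {-1: "R", +1: "Y"}


def _rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def simulate_sites(theta=None, n_sites: int = 100, seed=0, lengths=None) -> SiteFrequencyVector:
    """Draw ``n_sites`` iid sites and tally the 8 patterns.

    Exactly one of ``theta`` (Hadamard parameters in [0,1]^3) or ``lengths``
    (branch lengths in [0, inf]^3) must be given.  Deterministic for a fixed
    seed.
    """
    states = _simulate_states(theta, n_sites, seed, lengths)
    idx = ((states > 0) * np.array([4, 2, 1])[None, :]).sum(axis=1)
    counts = np.bincount(idx, minlength=8)
    return SiteFrequencyVector(tuple(int(c) for c in counts))


def simulate_alignment(theta=None, n_sites: int = 100, seed=0, lengths=None) -> list[str]:
    """Like :func:`simulate_sites` but return the three leaf sequences.

    States map to characters R (purine, -1) / Y (pyrimidine, +1); identical
    (parameters, seed) give the alignment whose column tally equals the
    corresponding :func:`simulate_sites` output.
    """
    states = _simulate_states(theta, n_sites, seed, lengths)
    return [
        "".join(_STATE_CHAR[int(x)] for x in states[:, leaf]) for leaf in range(3)
    ]


def _simulate_states(theta, n_sites, seed, lengths) -> np.ndarray:
    if (theta is None) == (lengths is None):
        raise ValueError("give exactly one of theta or lengths")
    if lengths is not None:
        theta = theta_from_lengths(lengths)
    theta = np.asarray(theta, dtype=float)
    if theta.shape != (3,) or np.any(theta < 0) or np.any(theta > 1):
        raise ValueError(f"theta must lie in [0,1]^3, got {theta}")
    if n_sites < 1:
        raise ValueError(f"n_sites must be >= 1, got {n_sites}")
    rng = _rng(seed)
    root = np.where(rng.random(n_sites) < 0.5, -1, 1).astype(np.int8)
    leaves = np.empty((n_sites, 3), dtype=np.int8)
    for i in range(3):
        flip_prob = (1.0 - theta[i]) / 2.0
        flips = rng.random(n_sites) < flip_prob
        leaves[:, i] = np.where(flips, -root, root)
    return leaves


def write_fasta(sequences: list[str], path, ids=("taxon1", "taxon2", "taxon3")) -> None:
    """Write three leaf sequences as a FASTA alignment."""
    with open(path, "w") as fh:
        for name, seq in zip(ids, sequences):
            fh.write(f">{name}\n{seq}\n")


def counts_from_split(sbar) -> SiteFrequencyVector:
    """A canonical 8-pattern count vector with the given split collapse.

    Each split class count is divided between its two patterns as evenly as
    possible (floor half to the lexicographically smaller pattern).  Any such
    division yields the same B statistics, since they depend on the data only
    through the split collapse.
    """
    sbar = [int(c) for c in sbar]
    if len(sbar) != 4 or any(c < 0 for c in sbar):
        raise ValueError(f"need 4 nonnegative split counts, got {sbar}")
    # pattern index pairs per split class {}, {1}, {2}, {1,2}
    class_patterns = ((0, 7), (3, 4), (2, 5), (1, 6))
    s = [0] * 8
    for c, (lo, hi) in zip(sbar, class_patterns):
        s[lo] = c // 2
        s[hi] = c - c // 2
    return SiteFrequencyVector(tuple(s))


def _split_from_nb(n: int, nb: tuple[int, int, int]) -> tuple[int, ...] | None:
    """Invert the count/correlation relation: sbar_alpha = (N ± nb terms) / 4.

    Returns None when the inversion is not integral or yields a negative
    class count.
    """
    combos = ((1, 1, 1), (-1, -1, 1), (-1, 1, -1), (1, -1, -1))
    sbar = []
    for signs in combos:
        num = n + sum(sg * v for sg, v in zip(signs, nb))
        if num < 0 or num % 4 != 0:
            return None
        sbar.append(num // 4)
    return tuple(sbar)


def _draw_nb(regime: str, n: int, rng: np.random.Generator) -> tuple[int, int, int]:
    """Draw a candidate integer N*B triple inside the requested regime region."""
    if regime == "INTERIOR":
        # draw a plausible tree and round its pair products
        th = rng.uniform(0.35, 0.9, size=3)
        target = np.array([th[0] * th[1], th[0] * th[2], th[1] * th[2]]) * n
        return tuple(int(round(v)) for v in target)
    if regime == "FACE_THETA_ONE":
        bi = rng.uniform(0.4, 0.9)
        bj = rng.uniform(0.4, 0.9)
        bk = rng.uniform(0.02, 0.8) * bi * bj  # violates the product bound
        vals = [bi, bj, bk]
        order = rng.permutation(3)
        out = [0, 0, 0]
        for slot, v in zip(order, vals):
            out[slot] = int(round(v * n))
        return tuple(out)
    if regime == "CURVE_THETA_ZERO":
        pos_slot = rng.integers(0, 3)
        out = []
        for slot in range(3):
            if slot == pos_slot:
                out.append(int(round(rng.uniform(0.1, 0.9) * n)))
            else:
                out.append(-int(round(rng.uniform(0.05, 0.6) * n)))
        return tuple(out)
    if regime == "INDEPENDENCE_UNION":
        return tuple(-int(round(rng.uniform(0.05, 0.6) * n)) for _ in range(3))
    raise ValueError(f"unknown regime {regime!r}")


def simulate_boundary_scenarios(regime: str, seed=0, n_sites: int = 100) -> SiteFrequencyVector:
    """Construct counts whose exact B statistics fall in the requested regime.

    ``regime`` is one of INTERIOR, FACE_THETA_ONE, CURVE_THETA_ZERO,
    INDEPENDENCE_UNION.  Candidate integer correlation triples are drawn
    inside the regime's region, inverted exactly to split counts, expanded to
    a pattern vector, and verified post-hoc with the solver's own exact
    dispatch; raises if no valid vector is found at this ``n_sites``.
    """
    from .solver import Regime, solve_mle  # deferred: solver imports stats too

    regime = str(regime)
    if regime not in Regime.__members__ or regime == "NUMERIC_FALLBACK":
        raise ValueError(f"unknown regime {regime!r}")
    rng = _rng(seed)
    for _ in range(500):
        nb = _draw_nb(regime, n_sites, rng)
        # parity fix: nudge components so the linear inversion is integral
        nb = _parity_adjust(n_sites, nb)
        if nb is None:
            continue
        sbar = _split_from_nb(n_sites, nb)
        if sbar is None or any(c == 0 for c in sbar):
            continue
        s = counts_from_split(sbar)
        if not check_genericity(s).generic:
            continue
        if tuple(compute_B(s).nb) != nb:
            continue
        if solve_mle(s).regime.value != regime:
            continue
        return s
    raise ValueError(
        f"could not construct a {regime} count vector with N={n_sites}; "
        "try a larger number of sites"
    )


def _parity_adjust(n: int, nb: tuple[int, int, int]) -> tuple[int, int, int] | None:
    """Adjust an integer triple so all four class counts are integral.

    Needs every ``n ± nb1 ± nb2 ± nb3`` (even-sign combinations) divisible by
    4: sufficient that all nb_i share n's parity and appropriate sums are
    0 mod 4; we fix up by decrementing magnitudes by at most 1 each and
    checking directly.
    """
    base = list(nb)
    for d1 in (0, -1, 1):
        for d2 in (0, -1, 1):
            for d3 in (0, -1, 1):
                cand = (base[0] + d1, base[1] + d2, base[2] + d3)
                if any(v == 0 or abs(v) >= n for v in cand):
                    continue
                if _split_from_nb(n, cand) is not None:
                    return cand
    return None
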