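"""Classical q-ary coding-theory bounds.

These quantify what any code with the dimensions of the punctured two-base +
ECC scheme (k bases encoded into n = 6k/5 colors, alphabet size q = 4) could
possibly achieve, independent of its construction: the Hamming, Johnson and
Singleton bounds limit performance from above, and the Gilbert bound
guarantees from below that some code of a given minimum distance exists.

All arithmetic is exact (Python integers); quantities like q^(n-k) run to
4^15 and beyond and must not round.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import comb

__all__ = [
    "sphere_volume",
    "hamming_max_correctable",
    "gilbert_guaranteed_distance",
    "varshamov_guaranteed_distance",
    "singleton_max_distance",
    "johnson_max_codewords",
    "distance_capabilities",
    "DistanceCapabilities",
    "bounds_table",
]


def sphere_volume(n: int, r: int, q: int) -> int:
    """Number of q-ary words within Hamming distance ``r`` of a word of
    length ``n``:  sum_{i=0..r} C(n,i) (q-1)^i."""
    if not 0 <= r <= n:
        raise ValueError(f"radius must satisfy 0 <= r <= n, got r={r}, n={n}")
    return sum(comb(n, i) * (q - 1) ** i for i in range(r + 1))


def hamming_max_correctable(n: int, k: int, q: int) -> int:
    """Largest ``t`` a length-``n``, ``q^k``-word code could possibly be
    guaranteed to correct (sphere-packing): the balls of radius ``t`` around
    the ``q^k`` codewords must fit in the space, so
    ``sphere_volume(n, t, q) <= q^(n-k)``."""
    if k > n:
        raise ValueError("k must not exceed n")
    budget = q ** (n - k)
    t = 0
    while t < n and sphere_volume(n, t + 1, q) <= budget:
        t += 1
    return t


def gilbert_guaranteed_distance(n: int, k: int, q: int) -> int:
    """Largest minimum distance ``d`` for which the Gilbert argument
    guarantees a (not necessarily linear) code with ``q^k`` words exists:
    greedy codeword picking succeeds while
    ``q^k * sphere_volume(n, d-1, q) <= q^n``."""
    if k > n:
        raise ValueError("k must not exceed n")
    budget = q ** (n - k)
    d = 1
    while d < n and sphere_volume(n, d, q) <= budget:
        d += 1
    return d


def varshamov_guaranteed_distance(n: int, k: int, q: int) -> int:
    """Varshamov's linear-code form of the existence bound: a linear
    ``[n, k]`` code of minimum distance ``d`` exists whenever
    ``sphere_volume(n-1, d-2, q) < q^(n-k)``.

    Strictly stronger than the Gilbert form for most parameters; both are
    provided, clearly labelled, since "the best code that exists" is often
    quoted from either.
    """
    if k > n:
        raise ValueError("k must not exceed n")
    budget = q ** (n - k)
    d = 1
    while d + 1 <= n and sphere_volume(n - 1, d - 1, q) < budget:
        d += 1
    return d


def singleton_max_distance(n: int, k: int) -> int:
    """Singleton bound: no code with q^k words has minimum distance above
    ``n - k + 1``."""
    if k > n:
        raise ValueError("k must not exceed n")
    return n - k + 1


def johnson_max_codewords(n: int, d: int, q: int) -> int:
    """Upper bound on ``A_q(n, d)``, the maximum number of q-ary codewords of
    length ``n`` at pairwise distance >= ``d``.

    Variant: the Plotkin-Johnson recursion.  When ``q d > (q-1) n`` the
    averaging (Plotkin) argument gives ``A_q(n,d) <= floor(qd / (qd -
    (q-1)n))``; otherwise shorten the code, ``A_q(n,d) <= q A_q(n-1,d)``,
    until the averaging regime is reached.  Both steps are valid upper
    bounds, so the result never undercuts the true optimum.
    """
    if not 1 <= d <= n:
        raise ValueError(f"distance must satisfy 1 <= d <= n, got d={d}, n={n}")
    if d == 1:
        return q ** n
    multiplier = 1
    while q * d <= (q - 1) * n:
        multiplier *= q
        n -= 1
    return multiplier * (q * d // (q * d - (q - 1) * n))


@dataclass(frozen=True)
class DistanceCapabilities:
    """Error-handling guarantees of a code with minimum distance ``d``."""

    d: int
    correct: int            # floor((d-1)/2)
    detect: int             # d - 1
    simultaneous: tuple[tuple[int, int], ...]  # (correct c, detect e) with c <= e, c+e <= d-1

    def __str__(self) -> str:
        return f"d={self.d}: correct {self.correct}, detect {self.detect}"


def distance_capabilities(d: int) -> DistanceCapabilities:
    """What minimum distance ``d`` buys: correct floor((d-1)/2) errors,
    detect d-1, or any simultaneous (c, e) with c <= e and c + e <= d - 1."""
    if d < 1:
        raise ValueError("minimum distance must be at least 1")
    pairs = tuple(
        (c, e) for c in range((d - 1) // 2 + 1) for e in range(c, d - c) if c + e <= d - 1
    )
    return DistanceCapabilities(d=d, correct=(d - 1) // 2, detect=d - 1, simultaneous=pairs)


def _johnson_max_distance(n: int, k: int, q: int) -> int:
    """Largest d not excluded by the Johnson bound for a q^k-word code."""
    d = 1
    while d < n and johnson_max_codewords(n, d + 1, q) >= q ** k:
        d += 1
    return d


def bounds_table(n: int, k: int, q: int) -> dict[str, object]:
    """Summary of what the implemented bounds say about an (n, k, q) code.

    Returns guaranteed-existence figures (Gilbert and Varshamov forms) and,
    per upper bound, the maximum number of errors a code could be guaranteed
    to correct.
    """
    g = gilbert_guaranteed_distance(n, k, q)
    v = varshamov_guaranteed_distance(n, k, q)
    singleton_d = singleton_max_distance(n, k)
    johnson_d = _johnson_max_distance(n, k, q)
    upper = {
        "hamming": hamming_max_correctable(n, k, q),
        "singleton": distance_capabilities(singleton_d).correct,
        "johnson": distance_capabilities(johnson_d).correct,
    }
    return {
        "n": n,
        "k": k,
        "q": q,
        "gilbert_distance": g,
        "gilbert_capabilities": distance_capabilities(g),
        "varshamov_distance": v,
        "max_correctable_by_bound": upper,
        "max_correctable": min(upper.values()),
    }
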