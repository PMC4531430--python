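"""Independent brute-force oracles used to pin the statistical components.

Everything here is deliberately naive — direct term summation, exact
integer arithmetic, per-element scans — and shares no code with the
implementation it checks.
"""

from __future__ import annotations

import math
from fractions import Fraction


def poisson_tail_terms(x: int, r: float):
    """Yield P(Y = k | x) for k = 0, 1, 2, ... under the tag-count model
    P(Y=k|x) = r^k (x+k)! / (x! k! (1+r)^{x+k+1}), via the term recurrence."""
    term = (1.0 / (1.0 + r)) ** (x + 1)
    k = 0
    while True:
        yield term
        term *= r * (x + k + 1) / ((k + 1) * (1.0 + r))
        k += 1


def poisson_p_oracle(x: int, y: int, r: float) -> float:
    """Two-sided p by direct summation of pmf terms (tails to < 1e-15 mass)."""
    lower = 0.0
    for k, term in zip(range(y + 1), poisson_tail_terms(x, r)):
        lower += term
    upper = 0.0
    gen = poisson_tail_terms(x, r)
    for k, term in enumerate(gen):
        if k < y:
            continue
        upper += term
        # geometric-decay bound on the remaining tail mass
        ratio = r * (x + k + 2) / ((k + 2) * (1.0 + r))
        if ratio < 1.0 and term * ratio / (1.0 - ratio) < 1e-15:
            break
        if k > y + 10_000:  # safety net; never reached for tested sizes
            break
    return min(1.0, 2.0 * min(lower, upper))


def bh_oracle(p_values):
    """Hand-executed step-up: adj_(i) = min_{j >= i} (p_(j) * m / j)."""
    m = len(p_values)
    order = sorted(range(m), key=lambda i: p_values[i])
    adj_sorted = [0.0] * m
    running = 1.0
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        running = min(running, p_values[i] * m / rank)
        adj_sorted[rank - 1] = running
    out = [0.0] * m
    for rank, i in enumerate(order):
        out[i] = adj_sorted[rank]
    return out


def fisher_oracle(a: int, b: int, c: int, d: int, alternative: str = "two-sided") -> float:
    """Exact-rational enumeration of all tables with the observed margins.

    Two-sided: sum point probabilities <= observed * (1 + 1e-7); the
    tolerance comparison is done in exact integer arithmetic.
    """
    n = a + b + c + d
    r1, c1 = a + b, a + c
    lo = max(0, c1 - (n - r1))
    hi = min(r1, c1)
    denom = math.comb(n, c1)
    nums = {k: math.comb(r1, k) * math.comb(n - r1, c1 - k) for k in range(lo, hi + 1)}
    if alternative == "greater":
        total = sum(num for k, num in nums.items() if k >= a)
        return float(Fraction(total, denom))
    obs = nums[a]
    total = sum(num for num in nums.values() if num * 10**7 <= obs * (10**7 + 1))
    return float(Fraction(total, denom))


def hypergeom_upper_oracle(k: int, n: int, K: int, N: int) -> float:
    """P(X >= k) for overlap of a size-n query with a size-K set in universe N,
    by direct summation of exact hypergeometric terms."""
    denom = math.comb(N, n)
    total = sum(
        math.comb(K, i) * math.comb(N - K, n - i)
        for i in range(k, min(n, K) + 1)
        if n - i <= N - K
    )
    return float(Fraction(total, denom))


def nod_oracle(edges):
    """Per-miRNA NOD by a per-gene regulator scan over the raw edge list."""
    regulators: dict[str, set[str]] = {}
    mirnas = set()
    for mirna, gene in edges:
        mirnas.add(mirna)
        regulators.setdefault(gene, set()).add(mirna)
    out = {m: 0 for m in mirnas}
    for gene, regs in regulators.items():
        if len(regs) == 1:
            out[next(iter(regs))] += 1
    return out


def components_oracle(edges, nodes):
    """Connected-component count via union-find on the undirected edge list."""
    parent = {v: v for v in nodes}

    def find(v):
        while parent[v] != v:
            parent[v] = parent[parent[v]]
            v = parent[v]
        return v

    for u, v in edges:
        parent[find(u)] = find(v)
    return len({find(v) for v in nodes})
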