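"""Independent brute-force oracles used by the test suite.

These deliberately avoid the package's algorithms: trees are nested tuples,
Fisher probabilities are exact rational arithmetic, and minimal loss counts
come from explicit set-cover search over candidate loss subtrees.
"""

from __future__ import annotations

import itertools
import math
from fractions import Fraction
from math import comb, sqrt

from scipy import stats

# ---------------------------------------------------------------------------
# nested-tuple trees


def leaves(node) -> frozenset:
    if isinstance(node, str):
        return frozenset({node})
    return leaves(node[0]) | leaves(node[1])


def subtrees(node):
    yield node
    if not isinstance(node, str):
        yield from subtrees(node[0])
        yield from subtrees(node[1])


def to_newick(node) -> str:
    def render(n):
        if isinstance(n, str):
            return n
        return f"({render(n[0])},{render(n[1])})"

    return render(node) + ";"


def root_to_focal_path(tree, focal: str) -> list:
    """Chain of nested-tuple nodes from the root down to the focal leaf."""
    path = []
    node = tree
    while True:
        path.append(node)
        if isinstance(node, str):
            assert node == focal
            return path
        node = node[0] if focal in leaves(node[0]) else node[1]


def all_labeled_topologies(labels: tuple):
    """Every rooted binary labeled topology on ``labels`` ((2n-3)!! of them)."""
    if len(labels) == 1:
        yield labels[0]
        return
    first, rest = labels[0], labels[1:]
    for k in range(0, len(rest)):
        for right_labels in itertools.combinations(rest, len(rest) - k):
            left_labels = (first,) + tuple(x for x in rest if x not in right_labels)
            if not right_labels:
                continue
            for left in all_labeled_topologies(left_labels):
                for right in all_labeled_topologies(tuple(right_labels)):
                    yield (left, right)


def dollo_oracle(tree, focal: str, present: set, absent: set) -> tuple[int, int]:
    """Single-gain reconstruction by exhaustive search.

    Among all gain placements covering every present leaf, minimize the
    number of loss events (each deleting one whole subtree, found by minimum
    set cover over candidate loss subtrees); ties broken by the deepest gain
    node.  Returns (branch index on root-to-focal path, min losses).
    """
    assert focal in present
    path = root_to_focal_path(tree, focal)

    def min_losses_below(gain_node) -> int:
        # candidate loss subtrees: strict descendants with no present leaf
        candidates = [
            s
            for s in subtrees(gain_node)
            if s is not gain_node and not (leaves(s) & present)
        ]
        # deduplicate identical leaf-sets (string leaves repeat as objects)
        cand_sets = []
        seen = set()
        for s in candidates:
            ls = leaves(s)
            if ls not in seen:
                seen.add(ls)
                cand_sets.append(ls)
        to_cover = leaves(gain_node) & absent
        if not to_cover:
            return 0
        for size in range(1, len(cand_sets) + 1):
            for combo in itertools.combinations(cand_sets, size):
                covered = frozenset().union(*combo)
                if to_cover <= covered:
                    return size
        raise AssertionError("uncoverable absences")

    best = None
    for idx, node in enumerate(path):
        if not (present <= leaves(node) if not isinstance(node, str) else present == {node}):
            continue
        losses = min_losses_below(node)
        # minimize losses; ties -> deepest (largest idx)
        if best is None or losses < best[1] or (losses == best[1] and idx > best[0]):
            best = (idx, losses)
    assert best is not None
    return best


# ---------------------------------------------------------------------------
# exact Fisher test by enumeration


def fisher_oracle(a: int, b: int, c: int, d: int) -> float:
    """Two-sided Fisher p by exact rational enumeration over the margins."""
    r1, r2, c1 = a + b, c + d, a + c
    n = r1 + r2
    denom = comb(n, c1)
    lo, hi = max(0, c1 - r2), min(r1, c1)
    p_obs = Fraction(comb(r1, a) * comb(r2, c1 - a), denom)
    total = Fraction(0)
    for x in range(lo, hi + 1):
        px = Fraction(comb(r1, x) * comb(r2, c1 - x), denom)
        if px <= p_obs:
            total += px
    return float(total)


# ---------------------------------------------------------------------------
# Welch t from its defining formula


def welch_oracle(a, b) -> tuple[float, float, float]:
    na, nb = len(a), len(b)
    ma = sum(a) / na
    mb = sum(b) / nb
    va = sum((x - ma) ** 2 for x in a) / (na - 1)
    vb = sum((x - mb) ** 2 for x in b) / (nb - 1)
    se2 = va / na + vb / nb
    t = (ma - mb) / sqrt(se2)
    df = se2**2 / ((va / na) ** 2 / (na - 1) + (vb / nb) ** 2 / (nb - 1))
    p = 2.0 * stats.t.sf(abs(t), df)
    return t, df, p


# ---------------------------------------------------------------------------
# error-propagated SE for the qPCR round trip


def qpcr_roundtrip_se(efficiency: float, noise_sd: float, n_reps: int) -> float:
    """First-order SE of the recovered percent-of-control estimate."""
    var_ddct = 4.0 * noise_sd**2 / n_reps  # 4 well means, each var sd^2/n
    return math.log(2.0) * efficiency * math.sqrt(var_ddct)
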