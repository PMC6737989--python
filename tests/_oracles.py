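"""Independent brute-force oracles used to cross-check the implementation.

Everything here is deliberately naive (positional scans, exhaustive
enumeration, textbook formulas) and shares no code with the package.
"""

from __future__ import annotations

import itertools

import numpy as np

_COMP = {"A": "U", "U": "A", "G": "C", "C": "G"}

# admissible duplex pairs (Watson-Crick + G:U), mirrored independently
PAIRS = {("A", "U"), ("U", "A"), ("G", "C"), ("C", "G"), ("G", "U"), ("U", "G")}
WEIGHT = {("G", "C"): 1.6, ("C", "G"): 1.6, ("A", "U"): 1.1, ("U", "A"): 1.1,
          ("G", "U"): 0.5, ("U", "G"): 0.5}
INIT, OPEN, EXT = 4.1, 4.0, 0.5


def revcomp(seq: str) -> str:
    return "".join(_COMP[c] for c in reversed(seq))


def seed_sites_by_scan(mirna: str, utr: str) -> list[tuple[int, str, tuple[int, int]]]:
    """Window-by-window scan of every anchor against the three site
    definitions (8mer > 7mer-m8 > 7mer-A1)."""
    match28 = revcomp(mirna[1:8])
    match27 = revcomp(mirna[1:7])
    out = []
    for q in range(len(utr) + 1):
        has_a = q < len(utr) and utr[q] == "A"
        s28 = q >= 7 and utr[q - 7 : q] == match28
        s27 = q >= 6 and utr[q - 6 : q] == match27
        if s28 and has_a:
            out.append((q - 7, "8mer", (q - 7, q + 1)))
        elif s28:
            out.append((q - 7, "7mer-m8", (q - 7, q)))
        elif s27 and has_a:
            out.append((q - 6, "7mer-A1", (q - 6, q + 1)))
    return out


def duplex_mfe_by_enumeration(a: str, b: str) -> float:
    """Minimum energy over ALL antiparallel non-crossing pairings,
    by recursive exhaustive extension (viable only for tiny strings)."""
    cells = [(i, j) for i in range(len(a)) for j in range(len(b))
             if (a[i], b[j]) in PAIRS]
    best = 0.0

    def energy(chain):
        e = INIT
        for k in range(1, len(chain)):
            (pi, pj), (i, j) = chain[k - 1], chain[k]
            if i == pi + 1 and j == pj - 1:
                e += -(WEIGHT[(a[pi], b[pj])] + WEIGHT[(a[i], b[j])])
            else:
                e += OPEN + EXT * ((i - pi - 1) + (pj - j - 1))
        return e

    def extend(chain):
        nonlocal best
        if chain:
            best = min(best, energy(chain))
        last = chain[-1] if chain else None
        for (i, j) in cells:
            if last is None or (i > last[0] and j < last[1]):
                extend(chain + [(i, j)])

    extend([])
    return best


def bh_stepup(p: list[float]) -> list[float]:
    """Benjamini-Hochberg step-up, straight from the definition."""
    m = len(p)
    order = sorted(range(m), key=lambda i: p[i])
    adj = [0.0] * m
    running = 1.0
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        running = min(running, p[i] * m / rank)
        adj[i] = running
    return adj


def pearson_with_p(x, y) -> tuple[float, float]:
    """Pearson r and its two-sided p via the t transform, textbook form."""
    from scipy import stats

    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(x)
    r = float(
        np.sum((x - x.mean()) * (y - y.mean()))
        / np.sqrt(np.sum((x - x.mean()) ** 2) * np.sum((y - y.mean()) ** 2))
    )
    if abs(r) >= 1.0:
        return r, 0.0
    t = r * np.sqrt((n - 2) / (1 - r * r))
    return r, float(2 * stats.t.sf(abs(t), n - 2))


def median_of_ratios(counts: np.ndarray) -> np.ndarray:
    """Size factors from the definition: median over all-positive
    features of the ratio to the per-feature geometric mean."""
    allpos = (counts > 0).all(axis=1)
    sub = counts[allpos].astype(float)
    ref = np.exp(np.mean(np.log(sub), axis=1))
    return np.array(
        [float(np.median(sub[:, j] / ref)) for j in range(counts.shape[1])]
    )


def rand_index(labels_a: dict, labels_b: dict) -> float:
    items = sorted(labels_a)
    agree = total = 0
    for u, v in itertools.combinations(items, 2):
        same_a = labels_a[u] == labels_a[v]
        same_b = labels_b.get(u) == labels_b.get(v) and labels_b.get(u) is not None
        if (labels_b.get(u) is None) or (labels_b.get(v) is None):
            same_b = False
        agree += same_a == same_b
        total += 1
    return agree / total
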