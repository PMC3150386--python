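"""Independent brute-force oracles used by the test suite.

These deliberately avoid the package's own algorithms: gene-dropping Monte
Carlo for kinship, exhaustive enumeration for call matching, and a per-base
bitmap for interval coverage.
"""

from __future__ import annotations

from itertools import combinations

import numpy as np

from cnvpop.model import Pedigree


def gene_drop_kinship(
    pedigree: Pedigree,
    pairs: list[tuple[str, str]],
    n_drops: int = 1_000_000,
    seed: int = 0,
    chunk: int = 250_000,
) -> dict[tuple[str, str], float]:
    """Monte-Carlo kinship: drop founder alleles down the pedigree and count
    identity-by-descent of randomly drawn alleles.

    For a pair (i, j) the estimate is the mean over drops of
    (1/4) * sum over the four allele combinations of [allele_i == allele_j];
    for i == j the same formula gives 0.5 + 0.5 P(autozygous).
    """
    order = pedigree.individuals
    idx = {ind.id: i for i, ind in enumerate(order)}
    rng = np.random.default_rng(seed)
    sums = {p: 0.0 for p in pairs}
    done = 0
    while done < n_drops:
        n = min(chunk, n_drops - done)
        alleles = np.empty((len(order), 2, n), dtype=np.int32)
        label = 0
        rows = np.arange(n)
        for i, ind in enumerate(order):
            for k, parent in enumerate((ind.father, ind.mother)):
                if parent is None:
                    alleles[i, k, :] = label
                    label += 1
                else:
                    pick = rng.integers(0, 2, n)
                    alleles[i, k, :] = alleles[idx[parent], pick, rows]
        for a, b in pairs:
            ia, ib = idx[a], idx[b]
            s = 0
            for ka in (0, 1):
                for kb in (0, 1):
                    s += np.count_nonzero(alleles[ia, ka] == alleles[ib, kb])
            sums[(a, b)] += s / 4.0
        done += n
    return {p: v / n_drops for p, v in sums.items()}


def valid_pairs(calls_a, calls_b, min_fraction=0.5, min_length=1, max_length=10**9):
    """Admissible (i, j, overlap) triples under the reciprocal-overlap
    consensus rule, computed from first principles."""
    out = []
    for i, a in enumerate(calls_a):
        if a.copy_number == 2:
            continue
        type_a = "del" if a.copy_number < 2 else "amp"
        for j, b in enumerate(calls_b):
            if b.copy_number == 2 or a.chrom != b.chrom:
                continue
            type_b = "del" if b.copy_number < 2 else "amp"
            if type_a != type_b:
                continue
            ov = min(a.end, b.end) - max(a.start, b.start) + 1
            if ov <= 0:
                continue
            if not (ov > min_fraction * (a.end - a.start + 1) and ov > min_fraction * (b.end - b.start + 1)):
                continue
            if not (min_length <= ov <= max_length):
                continue
            out.append((i, j, ov))
    return out


def exhaustive_best_matchings(pairs):
    """All one-to-one matchings over admissible pairs that maximise total
    overlap.  Returns (max_total, set of frozensets of (i, j))."""
    best_total = 0
    best: set[frozenset] = {frozenset()}

    def rec(k, used_a, used_b, total, chosen):
        nonlocal best_total, best
        if k == len(pairs):
            if total > best_total:
                best_total = total
                best = {frozenset(chosen)}
            elif total == best_total:
                best.add(frozenset(chosen))
            return
        rec(k + 1, used_a, used_b, total, chosen)
        i, j, ov = pairs[k]
        if i not in used_a and j not in used_b:
            rec(k + 1, used_a | {i}, used_b | {j}, total + ov, chosen + [(i, j)])

    rec(0, set(), set(), 0, [])
    return best_total, best


def coverage_runs(events, size):
    """Per-base bitmap of event coverage on one chromosome; returns the
    maximal runs of covered bases as (start, end) 1-based inclusive."""
    bitmap = np.zeros(size + 2, dtype=bool)
    for ev in events:
        bitmap[ev.start : ev.end + 1] = True
    runs = []
    start = None
    for pos in range(1, size + 2):
        if bitmap[pos] and start is None:
            start = pos
        elif not bitmap[pos] and start is not None:
            runs.append((start, pos - 1))
            start = None
    return runs
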