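"""Pedigree kinship and the carrier-relatedness permutation test.

The kinship coefficient k_ij is the probability that two alleles drawn at
random, one from each individual, are identical by descent.  It is computed
by the standard pedigree recursion: founders have k_ii = 0.5 and k_ij = 0;
a non-founder c with parents f and m has k_cj = (k_fj + k_mj) / 2 for any j
processed earlier and k_cc = 0.5 + k_fm / 2.

For a CNVR with Mn carriers in a population, the carrier statistic compares
K_n — the Mn(Mn-1)/2 off-diagonal kinship coefficients among carriers —
against K_pop, the off-diagonal coefficients among all population members,
with a one-sided Welch t-test (carriers more related).  Because the
population pool is shared and the pairs are dependent, the raw p-value is
adjusted by permutation: Mn individuals are redrawn uniformly without
replacement from the population n_perm times, the same statistic is
recomputed, and p_nadj is the fraction of permuted p-values not exceeding
the observed one.
"""

from __future__ import annotations

import logging
import zlib
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy import stats

from .model import Cnvr, Panel, Pedigree

logger = logging.getLogger(__name__)


class KinshipMatrix:
    """Pairwise kinship coefficients over a pedigree (topological id order)."""

    def __init__(self, ids: Sequence[str], matrix: np.ndarray):
        self.ids = tuple(ids)
        self.matrix = np.asarray(matrix, dtype=float)
        if self.matrix.shape != (len(self.ids), len(self.ids)):
            raise ValueError("matrix shape does not match ids")
        self._index = {iid: i for i, iid in enumerate(self.ids)}

    def index_of(self, individual_id: str) -> int:
        try:
            return self._index[individual_id]
        except KeyError:
            raise KeyError(f"individual {individual_id!r} not in kinship matrix") from None

    def value(self, id_i: str, id_j: str) -> float:
        return float(self.matrix[self.index_of(id_i), self.index_of(id_j)])

    def submatrix(self, ids: Sequence[str]) -> np.ndarray:
        idx = np.array([self.index_of(i) for i in ids])
        return self.matrix[np.ix_(idx, idx)]

    def offdiag_pairs(self, ids: Sequence[str]) -> np.ndarray:
        """The len(ids)*(len(ids)-1)/2 distinct pairwise coefficients."""
        sub = self.submatrix(ids)
        iu = np.triu_indices(len(ids), k=1)
        return sub[iu]

    def __contains__(self, individual_id: str) -> bool:
        return individual_id in self._index


def kinship_matrix(pedigree: Pedigree) -> KinshipMatrix:
    """Compute the full kinship matrix by the pedigree recursion."""
    order = pedigree.individuals
    n = len(order)
    index = {ind.id: i for i, ind in enumerate(order)}
    K = np.zeros((n, n))
    for i, ind in enumerate(order):
        fi = index[ind.father] if ind.father is not None else None
        mi = index[ind.mother] if ind.mother is not None else None
        if fi is None and mi is None:
            K[i, i] = 0.5
            continue
        row = np.zeros(i)
        if fi is not None:
            row += K[fi, :i]
        if mi is not None:
            row += K[mi, :i]
        row *= 0.5
        K[i, :i] = row
        K[:i, i] = row
        k_fm = K[fi, mi] if (fi is not None and mi is not None) else 0.0
        K[i, i] = 0.5 + 0.5 * k_fm
    return KinshipMatrix([ind.id for ind in order], K)


def population_kinship_summary(
    K: KinshipMatrix, panel: Panel, population: str
) -> tuple[float, float]:
    """Mean and SD of the off-diagonal pairwise coefficients within one
    population."""
    ids = [s for s in panel.samples(population) if s in K]
    if len(ids) < 2:
        raise ValueError(f"population {population!r} has fewer than 2 individuals in the matrix")
    pairs = K.offdiag_pairs(ids)
    return float(pairs.mean()), float(pairs.std(ddof=1))


def _welch_p(
    m1: np.ndarray,
    v1: np.ndarray,
    n1: int,
    m2: float,
    v2: float,
    n2: int,
    alternative: str,
) -> np.ndarray:
    """Vectorised Welch t-test p-value of sample-1 mean vs sample-2 mean.

    Degenerate cases (a single pair, or zero variance on one side) drop the
    vanishing variance term and take the remaining degrees of freedom; when
    both collections are constant the p-value is 1 where m1 <= m2 and 0
    otherwise.  The permutation adjustment only requires the observed and
    permuted statistics to be computed identically, which this guarantees.
    """
    m1 = np.atleast_1d(np.asarray(m1, dtype=float))
    v1 = np.atleast_1d(np.asarray(v1, dtype=float))
    a = np.where(n1 > 1, v1 / max(n1, 1), 0.0)
    b = v2 / n2 if n2 > 0 else 0.0
    se2 = a + b
    with np.errstate(divide="ignore", invalid="ignore"):
        t = (m1 - m2) / np.sqrt(se2)
        df_num = se2**2
        df_den = np.where(n1 > 1, a**2 / max(n1 - 1, 1), 0.0) + (
            b**2 / (n2 - 1) if n2 > 1 else 0.0
        )
        df = np.where(df_den > 0, df_num / np.where(df_den > 0, df_den, 1.0), 1.0)
    p = np.ones_like(m1)
    ok = se2 > 0
    if alternative == "greater":
        p[ok] = stats.t.sf(t[ok], df[ok])
    elif alternative == "two-sided":
        p[ok] = 2 * stats.t.sf(np.abs(t[ok]), df[ok])
    else:
        raise ValueError("alternative must be 'greater' or 'two-sided'")
    degenerate = ~ok
    p[degenerate] = np.where(m1[degenerate] <= m2, 1.0, 0.0)
    return p


@dataclass(frozen=True)
class KinshipResult:
    """Outcome of the carrier-relatedness test for one CNVR in one
    population."""

    cnvr_id: str
    population: str
    m_n: int
    mean_kn: float
    mean_kpop: float
    p_n: float
    p_nadj: float
    n_perm: int
    seed: int

    @property
    def p_nadj_str(self) -> str:
        """Display form: a permutation-adjusted p of zero means the observed
        p was smaller than every permuted one, reported as < 1/n_perm."""
        if self.p_nadj == 0.0:
            return f"<{1 / self.n_perm:g}"
        return f"{self.p_nadj:g}"


def _pair_values(K: np.ndarray, draws: np.ndarray) -> np.ndarray:
    """Gather the off-diagonal pairwise coefficients for each row of
    index-draws: (n_draws, Mn) -> (n_draws, Mn*(Mn-1)/2)."""
    m = draws.shape[1]
    iu, ju = np.triu_indices(m, k=1)
    return K[draws[:, iu], draws[:, ju]]


def carrier_kinship_test(
    cnvr: Cnvr,
    K: KinshipMatrix,
    panel: Panel,
    population: str,
    n_perm: int = 1_000,
    seed: int = 0,
    alternative: str = "greater",
) -> KinshipResult:
    """Test whether a CNVR's carriers are more related than the population
    average, with permutation adjustment (see module docstring)."""
    pop_ids = [s for s in panel.samples(population) if s in K]
    carriers = sorted(cnvr.carriers_in(panel, population))
    for c in carriers:
        if c not in K:
            raise ValueError(f"carrier {c!r} not in kinship matrix")
    m_n = len(carriers)
    if m_n < 2:
        raise ValueError(f"{cnvr.cnvr_id}: needs >=2 carriers in {population!r}, got {m_n}")
    kn = K.offdiag_pairs(carriers)
    kpop = K.offdiag_pairs(pop_ids)
    n2 = kpop.size
    m2, v2 = float(kpop.mean()), float(kpop.var(ddof=1)) if n2 > 1 else 0.0
    n1 = kn.size
    v1 = float(kn.var(ddof=1)) if n1 > 1 else 0.0
    p_n = float(_welch_p(kn.mean(), v1, n1, m2, v2, n2, alternative)[0])

    rng = np.random.default_rng(seed)
    pop_idx = np.array([K.index_of(s) for s in pop_ids])
    u = rng.random((n_perm, len(pop_idx)))
    draws = pop_idx[np.argpartition(u, m_n - 1, axis=1)[:, :m_n]]
    vals = _pair_values(K.matrix, draws)
    means = vals.mean(axis=1)
    vars_ = vals.var(axis=1, ddof=1) if n1 > 1 else np.zeros(n_perm)
    p_perm = _welch_p(means, vars_, n1, m2, v2, n2, alternative)
    p_nadj = float(np.count_nonzero(p_perm <= p_n) / n_perm)
    return KinshipResult(
        cnvr_id=cnvr.cnvr_id,
        population=population,
        m_n=m_n,
        mean_kn=float(kn.mean()),
        mean_kpop=m2,
        p_n=p_n,
        p_nadj=p_nadj,
        n_perm=n_perm,
        seed=seed,
    )


def _subseed(seed: int, cnvr_id: str, population: str) -> int:
    """Stable per-test sub-seed (independent of process hash randomisation)."""
    return zlib.crc32(f"{seed}:{cnvr_id}:{population}".encode()) & 0x7FFFFFFF


def batch_kinship_tests(
    cnvrs: Sequence[Cnvr],
    K: KinshipMatrix,
    panel: Panel,
    n_perm: int = 1_000,
    seed: int = 0,
    alternative: str = "greater",
) -> tuple[list[KinshipResult], dict[str, float]]:
    """Run the carrier test for every CNVR within every population where it
    has >=2 carriers.

    Returns the results and, per population, the fraction of tested CNVRs
    with p_nadj < 0.05.  CNVRs with fewer than two carriers in a population
    are skipped (logged).  Deterministic given ``seed``: each test derives
    its own sub-seed by stable hashing of (seed, cnvr_id, population).
    """
    results: list[KinshipResult] = []
    tested: dict[str, int] = {p: 0 for p in panel.populations}
    significant: dict[str, int] = {p: 0 for p in panel.populations}
    skipped = 0
    for cnvr in cnvrs:
        for population in panel.populations:
            m_n = len(cnvr.carriers_in(panel, population))
            if m_n < 2:
                skipped += 1
                continue
            res = carrier_kinship_test(
                cnvr,
                K,
                panel,
                population,
                n_perm=n_perm,
                seed=_subseed(seed, cnvr.cnvr_id, population),
                alternative=alternative,
            )
            results.append(res)
            tested[population] += 1
            if res.p_nadj < 0.05:
                significant[population] += 1
    if skipped:
        logger.info("skipped %d CNVR/population combinations with <2 carriers", skipped)
    fractions = {
        p: (significant[p] / tested[p]) if tested[p] else float("nan")
        for p in panel.populations
    }
    return results, fractions
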