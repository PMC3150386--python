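"""Synthetic pedigreed isolate populations with segregating CNV alleles and
noisy dual-caller call sets.

The generator emulates the study design the pipeline targets: several
population isolates, each built from multi-generation families with
configurable intermarriage (spouses drawn from within the population rather
than immigrating), a catalogue of CNV alleles that are either private to
one population or shared, dominant (presence/absence) Mendelian
transmission with probability 1/2 per carrier parent, and two caller
outputs that independently miss true events, jitter their boundaries and
add spurious calls.  Everything is deterministic under a fixed seed, and
the recorded truth serves as the oracle for every downstream stage.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np

from .model import (
    AMPLIFICATION,
    DELETION,
    AnnotationTrack,
    CnvCall,
    ConsensusEvent,
    Individual,
    Panel,
    Pedigree,
    SnpMap,
    chrom_sort_key,
)

DEFAULT_POPULATIONS = ("Vis", "Orkney", "SouthTyrol")


@dataclass(frozen=True)
class GenomeModel:
    """A reduced autosome model: chromosome lengths, centromere intervals
    and a uniform SNP density (per Mb) matching a 300K-style array on a
    ~2.8 Gb genome (~110 SNPs/Mb)."""

    chrom_lengths: dict[str, int] = field(
        default_factory=lambda: {
            "1": 200_000_000,
            "2": 160_000_000,
            "3": 120_000_000,
            "4": 90_000_000,
        }
    )
    centromeres: dict[str, tuple[int, int]] = field(
        default_factory=lambda: {
            "1": (90_000_000, 93_000_000),
            "2": (70_000_000, 73_000_000),
            "3": (55_000_000, 58_000_000),
            "4": (40_000_000, 43_000_000),
        }
    )
    snp_density_per_mb: float = 110.0

    def centromere_track(self) -> AnnotationTrack:
        return AnnotationTrack(
            "centromeres",
            [(c, s, e, "cen") for c, (s, e) in self.centromeres.items()],
        )

    def simulate_snp_map(self, rng: np.random.Generator) -> SnpMap:
        positions = {}
        for chrom, length in self.chrom_lengths.items():
            n = int(round(self.snp_density_per_mb * length / 1e6))
            positions[chrom] = np.sort(
                rng.choice(np.arange(1, length + 1, dtype=np.int64), size=n, replace=False)
            )
        return SnpMap(positions)


@dataclass(frozen=True)
class CnvAllele:
    """One segregating CNV allele: a locus, a type, and per-population
    founder carrier frequencies.  Private alleles have non-zero frequency
    in exactly one population."""

    allele_id: str
    chrom: str
    start: int
    end: int
    cnv_type: str
    founder_frequency: dict[str, float]

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError("allele start > end")
        for f in self.founder_frequency.values():
            if not (0.0 <= f <= 1.0):
                raise ValueError("founder frequency must be in [0, 1]")

    @property
    def private(self) -> bool:
        return sum(1 for f in self.founder_frequency.values() if f > 0) == 1

    @property
    def length(self) -> int:
        return self.end - self.start + 1


@dataclass(frozen=True)
class SimConfig:
    """Study-design parameters of the simulator.

    Pedigree structure: per population, ``families_per_population``
    founder couples grown over ``family_depth`` generations; children marry
    a new unrelated founder with probability ``immigrant_rate``, otherwise
    a non-sibling member of their own generation (intermarriage — the
    isolate feature).  ``children_per_couple`` fixes sibship size;
    when None it is Poisson(``mean_children``).

    Caller noise: each true event is missed by each caller independently
    with ``false_negative_rate`` (the measured miss rate of an LBF-10
    HMM caller on pseudo-deletions, 2.6%); boundaries jitter with SD
    ``boundary_jitter_sd`` bp; each caller adds on average
    ``false_positive_rate`` spurious calls per true call, of which
    ``neutral_call_rate`` are copy-neutral (discarded downstream); the
    false-positive load is calibrated so roughly 18% of one caller's calls
    lack a partner in the other's output.
    """

    n_populations: int = 3
    population_names: tuple[str, ...] = DEFAULT_POPULATIONS
    families_per_population: int = 20
    family_depth: int = 3
    mean_children: float = 2.5
    children_per_couple: Optional[int] = None
    immigrant_rate: float = 0.5
    singletons_per_population: int = 5
    allele_catalogue: Optional[tuple[CnvAllele, ...]] = None
    n_private_alleles_per_population: int = 16
    n_shared_alleles: int = 12
    n_gain_loss_pairs: int = 2
    de_novo_rate: float = 0.0
    boundary_jitter_sd: float = 5_000.0
    false_negative_rate: float = 0.026
    false_positive_rate: float = 0.19
    neutral_call_rate: float = 0.2
    genome: GenomeModel = field(default_factory=GenomeModel)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_populations < 1:
            raise ValueError("need at least one population")
        if self.families_per_population < 1 and self.singletons_per_population < 1:
            raise ValueError("impossible structure: no founders")
        if self.boundary_jitter_sd < 0:
            raise ValueError("jitter must be >= 0")
        for rate in (self.false_negative_rate, self.false_positive_rate, self.de_novo_rate):
            if rate < 0:
                raise ValueError("rates must be >= 0")

    @property
    def populations(self) -> tuple[str, ...]:
        names = list(self.population_names)
        while len(names) < self.n_populations:
            names.append(f"Pop{len(names) + 1}")
        return tuple(names[: self.n_populations])


def simulate_pedigrees(config: SimConfig, seed: int) -> tuple[Pedigree, Panel]:
    """Generate the multi-population pedigree and its panel."""
    rng = np.random.default_rng(seed)
    individuals: list[Individual] = []
    membership: dict[str, str] = {}
    for pop in config.populations:
        counter = 0

        def new_id() -> str:
            nonlocal counter
            counter += 1
            return f"{pop}_{counter:05d}"

        def add(father: Optional[str], mother: Optional[str], sex: str) -> str:
            iid = new_id()
            individuals.append(
                Individual(id=iid, father=father, mother=mother, sex=sex, population=pop)
            )
            membership[iid] = pop
            return iid

        couples: list[tuple[str, str]] = []
        for _ in range(config.families_per_population):
            couples.append((add(None, None, "M"), add(None, None, "F")))
        for _generation in range(1, config.family_depth):
            children: list[tuple[str, str, tuple[str, str]]] = []  # id, sex, parents
            for father, mother in couples:
                n_children = (
                    config.children_per_couple
                    if config.children_per_couple is not None
                    else int(rng.poisson(config.mean_children))
                )
                for _ in range(n_children):
                    sex = "M" if rng.random() < 0.5 else "F"
                    children.append((add(father, mother, sex), sex, (father, mother)))
            if _generation == config.family_depth - 1:
                break
            order = rng.permutation(len(children))
            unmatched: list[tuple[str, str, tuple[str, str]]] = [children[i] for i in order]
            couples = []
            while unmatched:
                cid, sex, parents = unmatched.pop()
                if rng.random() < config.immigrant_rate:
                    partner = add(None, None, "F" if sex == "M" else "M")
                else:
                    match_idx = next(
                        (
                            k
                            for k, (_oid, osex, opar) in enumerate(unmatched)
                            if osex != sex and opar != parents
                        ),
                        None,
                    )
                    if match_idx is None:
                        partner = add(None, None, "F" if sex == "M" else "M")
                    else:
                        partner = unmatched.pop(match_idx)[0]
                couples.append((cid, partner) if sex == "M" else (partner, cid))
        for _ in range(config.singletons_per_population):
            add(None, None, "M" if rng.random() < 0.5 else "F")
    return Pedigree(individuals), Panel(membership)


def _draw_locus(
    genome: GenomeModel, rng: np.random.Generator, length: int
) -> tuple[str, int, int]:
    """Place an interval of the given length uniformly on a chromosome arm
    (never spanning a centromere)."""
    chroms = sorted(genome.chrom_lengths, key=chrom_sort_key)
    weights = np.array([genome.chrom_lengths[c] for c in chroms], dtype=float)
    for _ in range(1_000):
        chrom = str(rng.choice(chroms, p=weights / weights.sum()))
        clen = genome.chrom_lengths[chrom]
        cen_s, cen_e = genome.centromeres[chrom]
        arm = (1, cen_s - 1) if rng.random() < (cen_s / clen) else (cen_e + 1, clen)
        if arm[1] - arm[0] + 1 <= length:
            continue
        start = int(rng.integers(arm[0], arm[1] - length + 2))
        return chrom, start, start + length - 1
    raise ValueError("could not place allele: lengths exceed chromosome arms")


def _draw_length(rng: np.random.Generator) -> int:
    # lognormal with mean ~200 kb, clipped into the pipeline's 1kb-3Mb window
    return int(np.clip(rng.lognormal(mean=np.log(120_000), sigma=1.0), 5_000, 2_500_000))


def default_allele_catalogue(config: SimConfig, rng: np.random.Generator) -> tuple[CnvAllele, ...]:
    """Allele catalogue matching the study conditions: mostly rare
    population-private alleles plus a minority of shared ones, lengths
    averaging ~200 kb, deletions and amplifications in equal measure, and a
    few co-located deletion/amplification pairs (the recurrent-mutation
    source of gain-and-loss regions)."""
    pops = config.populations
    alleles: list[CnvAllele] = []
    counter = 0

    def next_id() -> str:
        nonlocal counter
        counter += 1
        return f"AL{counter:04d}"

    for pop in pops:
        for _ in range(config.n_private_alleles_per_population):
            length = _draw_length(rng)
            chrom, start, end = _draw_locus(config.genome, rng, length)
            freq = float(rng.uniform(0.005, 0.04)) if rng.random() < 0.8 else float(
                rng.uniform(0.04, 0.1)
            )
            alleles.append(
                CnvAllele(
                    allele_id=next_id(),
                    chrom=chrom,
                    start=start,
                    end=end,
                    cnv_type=DELETION if rng.random() < 0.5 else AMPLIFICATION,
                    founder_frequency={pop: freq},
                )
            )
    for _ in range(config.n_shared_alleles):
        length = _draw_length(rng)
        chrom, start, end = _draw_locus(config.genome, rng, length)
        base = rng.uniform(0.02, 0.1)
        freq = {
            pop: float(np.clip(base * (1 + rng.normal(0, 0.25)), 0.005, 0.3)) for pop in pops
        }
        alleles.append(
            CnvAllele(
                allele_id=next_id(),
                chrom=chrom,
                start=start,
                end=end,
                cnv_type=DELETION if rng.random() < 0.5 else AMPLIFICATION,
                founder_frequency=freq,
            )
        )
    for _ in range(config.n_gain_loss_pairs):
        length = _draw_length(rng)
        chrom, start, end = _draw_locus(config.genome, rng, length + 20_000)
        base = rng.uniform(0.02, 0.08)
        freq = {pop: float(base) for pop in pops}
        alleles.append(
            CnvAllele(
                allele_id=next_id(),
                chrom=chrom,
                start=start,
                end=end - 20_000,
                cnv_type=DELETION,
                founder_frequency=freq,
            )
        )
        alleles.append(
            CnvAllele(
                allele_id=next_id(),
                chrom=chrom,
                start=start + 20_000,
                end=end,
                cnv_type=AMPLIFICATION,
                founder_frequency=freq,
            )
        )
    return tuple(alleles)


@dataclass(frozen=True)
class TrueCnv:
    """One individual's true copy of a CNV allele."""

    sample_id: str
    allele_id: str
    chrom: str
    start: int
    end: int
    cnv_type: str

    def to_event(self) -> ConsensusEvent:
        return ConsensusEvent(
            sample_id=self.sample_id,
            chrom=self.chrom,
            start=self.start,
            end=self.end,
            cnv_type=self.cnv_type,
        )

    @property
    def length(self) -> int:
        return self.end - self.start + 1


@dataclass(frozen=True)
class CnvTruth:
    """Ground truth of a simulated cohort."""

    events: tuple[TrueCnv, ...]
    catalogue: tuple[CnvAllele, ...]
    carriers_by_allele: dict[str, frozenset[str]]
    samples: tuple[str, ...]


def simulate_cnv_genotypes(
    pedigree: Pedigree,
    panel: Panel,
    config: SimConfig,
    seed: int,
) -> CnvTruth:
    """Draw founder carriers by population frequency and transmit each
    allele down the pedigree (dominant presence model: each carrier parent
    transmits independently with probability 1/2)."""
    rng = np.random.default_rng(seed)
    catalogue = (
        config.allele_catalogue
        if config.allele_catalogue is not None
        else default_allele_catalogue(config, rng)
    )
    if not catalogue:
        raise ValueError("allele catalogue is empty")
    for al in catalogue:
        if al.chrom not in config.genome.chrom_lengths:
            raise ValueError(f"allele {al.allele_id}: chromosome {al.chrom!r} not in genome model")
    events: list[TrueCnv] = []
    carriers_by_allele: dict[str, frozenset[str]] = {}
    for allele in catalogue:
        carrier: dict[str, bool] = {}
        for ind in pedigree.individuals:
            pop = panel.population_of(ind.id)
            if ind.is_founder:
                has = rng.random() < allele.founder_frequency.get(pop, 0.0)
            else:
                has = False
                for parent in (ind.father, ind.mother):
                    if parent is not None and carrier.get(parent, False):
                        if rng.random() < 0.5:
                            has = True
            if not has and config.de_novo_rate > 0 and rng.random() < config.de_novo_rate:
                has = True
            carrier[ind.id] = has
            if has:
                events.append(
                    TrueCnv(
                        sample_id=ind.id,
                        allele_id=allele.allele_id,
                        chrom=allele.chrom,
                        start=allele.start,
                        end=allele.end,
                        cnv_type=allele.cnv_type,
                    )
                )
        carriers_by_allele[allele.allele_id] = frozenset(
            i for i, h in carrier.items() if h
        )
    return CnvTruth(
        events=tuple(events),
        catalogue=tuple(catalogue),
        carriers_by_allele=carriers_by_allele,
        samples=tuple(ind.id for ind in pedigree.individuals),
    )


def _jitter_call(
    true_event: TrueCnv,
    caller: str,
    config: SimConfig,
    rng: np.random.Generator,
) -> CnvCall:
    clen = config.genome.chrom_lengths[true_event.chrom]
    sd = config.boundary_jitter_sd
    start = true_event.start + (int(round(rng.normal(0, sd))) if sd > 0 else 0)
    end = true_event.end + (int(round(rng.normal(0, sd))) if sd > 0 else 0)
    start, end = min(start, end), max(start, end)
    start = max(1, min(start, clen))
    end = max(start, min(end, clen))
    if true_event.cnv_type == DELETION:
        cn = int(rng.integers(0, 2))
    else:
        cn = int(rng.integers(3, 5))
    confidence = float(rng.uniform(10, 60)) if caller == "A" else None
    return CnvCall(
        sample_id=true_event.sample_id,
        chrom=true_event.chrom,
        start=start,
        end=end,
        copy_number=cn,
        caller=caller,
        confidence=confidence,
    )


def simulate_caller_outputs(
    truth: CnvTruth,
    config: SimConfig,
    seed: int,
) -> tuple[list[CnvCall], list[CnvCall]]:
    """Produce the two callers' noisy call tables from the truth.

    Each true event is reported by each caller independently with
    probability 1 - false_negative_rate, with jittered boundaries; false
    positives (typed or copy-neutral) are added at the configured rate per
    caller, placed uniformly on chromosome arms.
    """
    if not truth.events:
        raise ValueError("truth is empty")
    rng = np.random.default_rng(seed)
    outputs: dict[str, list[CnvCall]] = {"A": [], "B": []}
    for caller in ("A", "B"):
        for ev in truth.events:
            if rng.random() < config.false_negative_rate:
                continue
            outputs[caller].append(_jitter_call(ev, caller, config, rng))
        n_fp = rng.poisson(config.false_positive_rate * len(truth.events))
        for _ in range(n_fp):
            sample = str(rng.choice(truth.samples))
            length = _draw_length(rng)
            chrom, start, end = _draw_locus(config.genome, rng, length)
            if rng.random() < config.neutral_call_rate:
                cn = 2
            else:
                cn = int(rng.integers(0, 2)) if rng.random() < 0.5 else int(rng.integers(3, 5))
            outputs[caller].append(
                CnvCall(
                    sample_id=sample,
                    chrom=chrom,
                    start=start,
                    end=end,
                    copy_number=cn,
                    caller=caller,
                    confidence=float(rng.uniform(10, 60)) if caller == "A" else None,
                )
            )
    return outputs["A"], outputs["B"]


@dataclass(frozen=True)
class SimulatedDataset:
    pedigree: Pedigree
    panel: Panel
    truth: CnvTruth
    calls_a: tuple[CnvCall, ...]
    calls_b: tuple[CnvCall, ...]
    snp_map: SnpMap
    centromeres: AnnotationTrack


def simulate_dataset(config: SimConfig, seed: Optional[int] = None) -> SimulatedDataset:
    """All stages in sequence with sub-seeds derived from one master seed."""
    master = config.seed if seed is None else seed
    ss = np.random.SeedSequence(master).spawn(4)
    seeds = [int(s.generate_state(1)[0] & 0x7FFFFFFF) for s in ss]
    pedigree, panel = simulate_pedigrees(config, seeds[0])
    truth = simulate_cnv_genotypes(pedigree, panel, config, seeds[1])
    calls_a, calls_b = simulate_caller_outputs(truth, config, seeds[2])
    snp_map = config.genome.simulate_snp_map(np.random.default_rng(seeds[3]))
    return SimulatedDataset(
        pedigree=pedigree,
        panel=panel,
        truth=truth,
        calls_a=tuple(calls_a),
        calls_b=tuple(calls_b),
        snp_map=snp_map,
        centromeres=config.genome.centromere_track(),
    )
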