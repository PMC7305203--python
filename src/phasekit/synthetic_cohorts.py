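"""Synthetic inputs with known ground truth.

Everything the pipeline consumes can be generated here: phased
population VCFs drawn from an explicit haplotype pool, proband+parent
trios, case/control cohorts with a controlled compound-het enrichment
(rejection sampling, so the target relative frequency is exactly
known), and intercross litters thinned by per-genotype viability.

One seeded :class:`numpy.random.Generator` drives a run; the seed is
written into every emitted file header so fixtures are bit-reproducible.
Linkage disequilibrium is expressed only through explicit haplotype
frequencies.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .errors import SimulationError
from .io_formats import (
    GenotypeCall,
    Individual,
    Pedigree,
    VariantRecord,
    VcfTable,
)

__all__ = [
    "HaplotypePool",
    "SimConfig",
    "GroundTruth",
    "pool_from_mafs",
    "sample_population",
    "sample_trios",
    "build_case_control",
    "build_exact_cohort",
    "simulate_intercross",
    "read_sim_config",
]

_FREQ_TOL = 1e-9


@dataclass(frozen=True)
class HaplotypePool:
    """Explicit haplotypes over a site list, with frequencies summing
    to 1."""

    sites: tuple[VariantRecord, ...]
    haplotypes: tuple[tuple[int, ...], ...]
    frequencies: tuple[float, ...]

    def __post_init__(self) -> None:
        if len(self.haplotypes) != len(self.frequencies):
            raise SimulationError("haplotypes and frequencies differ in number")
        for hap in self.haplotypes:
            if len(hap) != len(self.sites):
                raise SimulationError("haplotype length != site count")
            for allele, site in zip(hap, self.sites):
                if not 0 <= allele <= len(site.alts):
                    raise SimulationError(
                        f"allele index {allele} out of range at {site.key}"
                    )
        if any(f < 0 for f in self.frequencies):
            raise SimulationError("negative haplotype frequency")
        if abs(sum(self.frequencies) - 1.0) > _FREQ_TOL:
            raise SimulationError(
                f"haplotype frequencies sum to {sum(self.frequencies)!r}, not 1"
            )

    @property
    def site_keys(self) -> list[str]:
        return [s.key for s in self.sites]

    def true_maf(self, site_index: int) -> float:
        """Marginal alt-allele frequency at one site."""
        return sum(
            f
            for hap, f in zip(self.haplotypes, self.frequencies)
            if hap[site_index] > 0
        )

    def true_comphet_prob(self) -> float:
        """Exact probability that a random diploid (two independent pool
        draws) is a compound het: some pair of distinct sites with alt
        alleles on opposite haplotypes (the hom-forced case included)."""
        p = 0.0
        for (h1, f1), (h2, f2) in itertools.product(
            zip(self.haplotypes, self.frequencies), repeat=2
        ):
            if _is_comphet_pair(h1, h2):
                p += f1 * f2
        return p


def _is_comphet_pair(h1: Sequence[int], h2: Sequence[int]) -> bool:
    """True compound het: two distinct sites whose alt alleles sit on
    opposite haplotypes."""
    for i, j in itertools.permutations(range(len(h1)), 2):
        if h1[i] > 0 and h2[j] > 0 and i != j:
            return True
    return False


@dataclass(frozen=True)
class SimConfig:
    """Run parameters; every probability must be in [0, 1] and the seed
    is mandatory (it is stamped into all output headers)."""

    seed: int
    n_cases: int = 0
    n_controls: int = 0
    n_trios: int = 0
    mafs: tuple[float, ...] = ()
    enrichment_rho: float = 1.0
    genotyping_error: float = 0.0
    intercross_n: int = 0
    viability: tuple[float, float, float] = (1.0, 1.0, 1.0)

    def __post_init__(self) -> None:
        for p in (*self.mafs, self.genotyping_error, *self.viability):
            if not 0.0 <= p <= 1.0:
                raise SimulationError(f"probability {p} outside [0, 1]")
        if self.enrichment_rho < 1.0:
            raise SimulationError("enrichment rho must be >= 1")


@dataclass
class GroundTruth:
    """True haplotypes per individual, plus derived truth flags."""

    haplotypes: dict[str, tuple[tuple[int, ...], tuple[int, ...]]]
    comphet: dict[str, bool] = field(default_factory=dict)

    def pair_phase(self, individual_id: str, i: int, j: int) -> str:
        """True phase of the alt alleles at sites i and j: trans, cis,
        or none when either site carries no alt."""
        h1, h2 = self.haplotypes[individual_id]
        a_on = [h1[i] > 0, h2[i] > 0]
        b_on = [h1[j] > 0, h2[j] > 0]
        if not any(a_on) or not any(b_on):
            return "none"
        same = (a_on[0] and b_on[0]) or (a_on[1] and b_on[1])
        opposite = (a_on[0] and b_on[1]) or (a_on[1] and b_on[0])
        if opposite:
            return "trans"
        if same:
            return "cis"
        return "none"


def pool_from_mafs(
    mafs: Sequence[float],
    chrom: str = "16",
    start_pos: int = 1000,
    spacing: int = 1000,
) -> HaplotypePool:
    """Independent-site pool: 2^k haplotypes with product frequencies.

    Sites are synthetic biallelic A>G SNVs placed ``spacing`` apart.
    """
    k = len(mafs)
    if k == 0:
        raise SimulationError("need at least one site")
    sites = tuple(
        VariantRecord(
            chrom=chrom,
            pos=start_pos + i * spacing,
            id=f"site{i + 1}",
            ref="A",
            alts=("G",),
        )
        for i in range(k)
    )
    haplotypes = []
    freqs = []
    for alleles in itertools.product((0, 1), repeat=k):
        f = 1.0
        for a, maf in zip(alleles, mafs):
            f *= maf if a else (1.0 - maf)
        haplotypes.append(alleles)
        freqs.append(f)
    total = sum(freqs)
    freqs = [f / total for f in freqs]  # guard against float drift
    return HaplotypePool(sites, tuple(haplotypes), tuple(freqs))


def _seed_header(seed: int) -> list[str]:
    return [f"##phasekit_simulation_seed={seed}"]


def _draw_haplotype_indices(
    pool: HaplotypePool, n: int, rng: np.random.Generator
) -> np.ndarray:
    return rng.choice(len(pool.haplotypes), size=n, p=np.asarray(pool.frequencies))


def _table_from_haplotypes(
    pool: HaplotypePool,
    sample_ids: Sequence[str],
    hap_pairs: Sequence[tuple[tuple[int, ...], tuple[int, ...]]],
    seed: int,
    phased: bool = True,
) -> VcfTable:
    calls: list[list[GenotypeCall]] = []
    for site_idx in range(len(pool.sites)):
        row = [
            GenotypeCall(
                (h1[site_idx], h2[site_idx]), phased, sid
            )
            for sid, (h1, h2) in zip(sample_ids, hap_pairs)
        ]
        calls.append(row)
    return VcfTable(
        samples=list(sample_ids),
        variants=list(pool.sites),
        calls=calls,
        header_lines=_seed_header(seed),
    )


def sample_population(
    pool: HaplotypePool,
    n: int,
    seed: int,
    sample_prefix: str = "S",
    phased: bool = True,
) -> tuple[VcfTable, GroundTruth]:
    """Draw ``n`` diploids, two independent haplotypes each, emitted
    phased.  Deterministic given the seed."""
    rng = np.random.default_rng(seed)
    idx = _draw_haplotype_indices(pool, 2 * n, rng).reshape(n, 2)
    sample_ids = [f"{sample_prefix}{i + 1:05d}" for i in range(n)]
    hap_pairs = [
        (pool.haplotypes[a], pool.haplotypes[b]) for a, b in idx
    ]
    truth = GroundTruth(
        haplotypes=dict(zip(sample_ids, hap_pairs)),
        comphet={
            sid: _is_comphet_pair(h1, h2)
            for sid, (h1, h2) in zip(sample_ids, hap_pairs)
        },
    )
    return _table_from_haplotypes(pool, sample_ids, hap_pairs, seed, phased), truth


def sample_trios(
    pool: HaplotypePool,
    n_trios: int,
    seed: int,
    genotyping_error: float = 0.0,
) -> tuple[VcfTable, Pedigree, GroundTruth]:
    """Draw trios: parents from the pool, the child one random gamete
    from each parent.  Genotypes are emitted unphased (the trio route is
    the point); optional per-genotype error flips one allele."""
    rng = np.random.default_rng(seed)
    sample_ids: list[str] = []
    hap_pairs: list[tuple[tuple[int, ...], tuple[int, ...]]] = []
    individuals: list[Individual] = []
    for t in range(n_trios):
        fid, mid, cid = (f"F{t + 1:05d}", f"M{t + 1:05d}", f"C{t + 1:05d}")
        fa = tuple(
            pool.haplotypes[i] for i in _draw_haplotype_indices(pool, 2, rng)
        )
        mo = tuple(
            pool.haplotypes[i] for i in _draw_haplotype_indices(pool, 2, rng)
        )
        child = (fa[rng.integers(2)], mo[rng.integers(2)])
        sample_ids += [fid, mid, cid]
        hap_pairs += [fa, mo, child]
        individuals += [
            Individual(fid, None, None, "1", False, family_id=f"FAM{t + 1}"),
            Individual(mid, None, None, "2", False, family_id=f"FAM{t + 1}"),
            Individual(cid, fid, mid, "0", True, family_id=f"FAM{t + 1}"),
        ]
    table = _table_from_haplotypes(pool, sample_ids, hap_pairs, seed, phased=False)
    if genotyping_error > 0:
        _inject_errors(table, genotyping_error, rng)
    truth = GroundTruth(
        haplotypes=dict(zip(sample_ids, hap_pairs)),
        comphet={
            sid: _is_comphet_pair(h1, h2)
            for sid, (h1, h2) in zip(sample_ids, hap_pairs)
        },
    )
    return table, Pedigree(individuals), truth


def _inject_errors(
    table: VcfTable, rate: float, rng: np.random.Generator
) -> None:
    """Flip one allele of a call with probability ``rate`` (truth is
    recorded before injection)."""
    for i, rec in enumerate(table.variants):
        n_alt = len(rec.alts)
        for j, call in enumerate(table.calls[i]):
            if call.is_missing or rng.random() >= rate:
                continue
            a, b = call.allele_indices
            slot = rng.integers(2)
            current = a if slot == 0 else b
            choices = [x for x in range(n_alt + 1) if x != current]
            new = int(rng.choice(choices))
            alleles = (new, b) if slot == 0 else (a, new)
            table.calls[i][j] = GenotypeCall(alleles, call.phased, call.sample_id)


def build_case_control(
    pool: HaplotypePool,
    n_cases: int,
    n_controls: int,
    rho: float,
    seed: int,
) -> tuple[VcfTable, VcfTable, GroundTruth, GroundTruth]:
    """Case/control cohorts with a rho-fold compound-het enrichment.

    Controls are plain pool draws.  Cases are drawn by rejection:
    compound-het draws are always accepted, others with probability
    1/rho, so the case compound-het odds are exactly rho-fold.
    """
    if rho < 1.0:
        raise SimulationError("rho must be >= 1")
    q = pool.true_comphet_prob()
    accept_rate = q + (1.0 - q) / rho
    if accept_rate * 1e6 < 1.0:
        raise SimulationError(
            "expected < 1 acceptance per 1e6 draws; "
            "raise the haplotype frequencies or lower rho"
        )
    rng = np.random.default_rng(seed)

    ctrl_idx = _draw_haplotype_indices(pool, 2 * n_controls, rng).reshape(-1, 2)
    ctrl_ids = [f"CTRL{i + 1:05d}" for i in range(n_controls)]
    ctrl_pairs = [(pool.haplotypes[a], pool.haplotypes[b]) for a, b in ctrl_idx]

    case_ids = [f"CASE{i + 1:05d}" for i in range(n_cases)]
    case_pairs: list[tuple[tuple[int, ...], tuple[int, ...]]] = []
    while len(case_pairs) < n_cases:
        a, b = _draw_haplotype_indices(pool, 2, rng)
        pair = (pool.haplotypes[a], pool.haplotypes[b])
        if _is_comphet_pair(*pair) or rng.random() < 1.0 / rho:
            case_pairs.append(pair)

    case_truth = GroundTruth(
        haplotypes=dict(zip(case_ids, case_pairs)),
        comphet={
            sid: _is_comphet_pair(h1, h2)
            for sid, (h1, h2) in zip(case_ids, case_pairs)
        },
    )
    ctrl_truth = GroundTruth(
        haplotypes=dict(zip(ctrl_ids, ctrl_pairs)),
        comphet={
            sid: _is_comphet_pair(h1, h2)
            for sid, (h1, h2) in zip(ctrl_ids, ctrl_pairs)
        },
    )
    case_table = _table_from_haplotypes(pool, case_ids, case_pairs, seed)
    ctrl_table = _table_from_haplotypes(pool, ctrl_ids, ctrl_pairs, seed)
    return case_table, ctrl_table, case_truth, ctrl_truth


def build_exact_cohort(
    sites: Sequence[VariantRecord],
    n: int,
    n_comphet: int,
    seed: int,
    sample_prefix: str = "S",
) -> tuple[VcfTable, GroundTruth]:
    """Deterministic cohort with exactly ``n_comphet`` compound hets.

    The first ``n_comphet`` individuals carry the alt of site 1 on one
    haplotype and the alt of site 2 on the other (cycling through site
    pairs); everyone else is hom-ref everywhere.  Which individuals are
    carriers is shuffled with the seed.
    """
    if n_comphet > n:
        raise SimulationError("n_comphet exceeds cohort size")
    if len(sites) < 2 and n_comphet > 0:
        raise SimulationError("need >= 2 sites for compound hets")
    rng = np.random.default_rng(seed)
    k = len(sites)
    sample_ids = [f"{sample_prefix}{i + 1:05d}" for i in range(n)]
    carrier_positions = rng.choice(n, size=n_comphet, replace=False)
    ref_hap = tuple(0 for _ in range(k))
    pairs: list[tuple[tuple[int, ...], tuple[int, ...]]] = [
        (ref_hap, ref_hap) for _ in range(n)
    ]
    site_pairs = list(itertools.combinations(range(k), 2))
    for c, pos in enumerate(sorted(int(p) for p in carrier_positions)):
        i, j = site_pairs[c % len(site_pairs)]
        h1 = tuple(1 if s == i else 0 for s in range(k))
        h2 = tuple(1 if s == j else 0 for s in range(k))
        pairs[pos] = (h1, h2)
    pool = HaplotypePool(
        tuple(sites),
        (ref_hap,),
        (1.0,),
    )
    table = _table_from_haplotypes(pool, sample_ids, pairs, seed)
    truth = GroundTruth(
        haplotypes=dict(zip(sample_ids, pairs)),
        comphet={
            sid: _is_comphet_pair(h1, h2)
            for sid, (h1, h2) in zip(sample_ids, pairs)
        },
    )
    return table, truth


def simulate_intercross(
    n: int,
    viability: Sequence[float],
    seed: int,
) -> tuple[int, int, int]:
    """Draw a 1:2:1 litter of ``n`` conceptuses and thin each genotype
    class by its viability; returns surviving counts per class."""
    if len(viability) != 3:
        raise SimulationError("viability vector must have 3 entries")
    for v in viability:
        if not 0.0 <= v <= 1.0:
            raise SimulationError("viability outside [0, 1]")
    rng = np.random.default_rng(seed)
    conceived = rng.multinomial(n, [0.25, 0.5, 0.25])
    survived = tuple(
        int(rng.binomial(c, v)) for c, v in zip(conceived, viability)
    )
    return survived


def read_sim_config(path) -> SimConfig:
    """Parse the flat key=value simulation config format."""
    values: dict[str, str] = {}
    with open(path) as fh:
        for raw in fh:
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            key, _, value = line.partition("=")
            values[key.strip()] = value.strip()
    if "seed" not in values:
        raise SimulationError("config lacks mandatory seed")

    def _floats(key: str) -> tuple[float, ...]:
        return tuple(float(x) for x in values[key].split(",")) if key in values else ()

    viability = _floats("viability") or (1.0, 1.0, 1.0)
    if len(viability) != 3:
        raise SimulationError("viability must have 3 comma-separated entries")
    return SimConfig(
        seed=int(values["seed"]),
        n_cases=int(values.get("n_cases", 0)),
        n_controls=int(values.get("n_controls", 0)),
        n_trios=int(values.get("n_trios", 0)),
        mafs=_floats("mafs"),
        enrichment_rho=float(values.get("enrichment_rho", 1.0)),
        genotyping_error=float(values.get("genotyping_error", 0.0)),
        intercross_n=int(values.get("intercross_n", 0)),
        viability=tuple(viability),  # type: ignore[arg-type]
    )
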