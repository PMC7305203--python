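"""Compound-heterozygote detection.

Decides, per individual, whether two variant alleles from a defined site
set lie on opposite haplotypes (in trans).  Three evidence routes, tried
in this order for each pair of sites:

1. ``hom_trans`` — hom-alt at one site plus an alt at another: diploidy
   forces one alt onto each haplotype, no phasing needed.
2. ``population_phase`` — both calls phased (``|`` genotypes): haplotype
   columns are compared directly.
3. ``trio`` — exhaustive enumeration of parental transmissions
   consistent with the six genotypes (<= 16 configurations for two
   biallelic sites).

Counting is always at the individual level: an individual is a compound
het iff at least one pair of distinct sites is in trans.  Ambiguous-only
individuals are reported separately and never enter the numerator.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Optional, Sequence

from .io_formats import GenotypeCall, Pedigree, VcfTable

__all__ = [
    "PairPhase",
    "CompHetCall",
    "phase_pair_population",
    "phase_pair_trio",
    "classify_individual",
    "count_compound_hets",
]

_STATUSES = {"trans", "cis", "ambiguous", "mendelian_error", "unknown"}
_EVIDENCE = {"population_phase", "trio", "hom_trans", "none"}


@dataclass(frozen=True)
class PairPhase:
    status: str
    evidence: str

    def __post_init__(self) -> None:
        if self.status not in _STATUSES:
            raise ValueError(f"unknown status {self.status!r}")
        if self.evidence not in _EVIDENCE:
            raise ValueError(f"unknown evidence {self.evidence!r}")
        if (self.evidence == "none") != (
            self.status in {"ambiguous", "unknown"}
        ):
            raise ValueError(
                f"evidence {self.evidence!r} inconsistent with status "
                f"{self.status!r}"
            )


@dataclass
class CompHetCall:
    """Individual-level verdict with its evidence trail."""

    individual_id: str
    is_compound_het: bool
    qualifying_pairs: list[tuple[str, str, PairPhase]]
    ambiguous_pairs: list[tuple[str, str, PairPhase]] = field(default_factory=list)
    hom_trans_only: bool = False  # trans evidence is exclusively hom_trans
    has_data: bool = True


def _hom_trans_pair(gtA: GenotypeCall, gtB: GenotypeCall) -> Optional[PairPhase]:
    """Trans forced by diploidy when both haplotypes carry an alt at one
    site (hom-alt, or het between two alts) and the other site carries
    any alt."""
    if (gtA.alt_count() == 2 and gtB.alt_count() > 0) or (
        gtB.alt_count() == 2 and gtA.alt_count() > 0
    ):
        return PairPhase("trans", "hom_trans")
    return None


def phase_pair_population(gtA: GenotypeCall, gtB: GenotypeCall) -> PairPhase:
    """Phase a pair of calls in one sample from population phasing.

    Both calls phased and het: the haplotype columns carrying the alt
    alleles are compared directly.  Unphased het/het is ambiguous.
    """
    if gtA.sample_id != gtB.sample_id:
        raise ValueError(
            f"calls from different samples: {gtA.sample_id!r} vs {gtB.sample_id!r}"
        )
    if gtA.is_missing or gtB.is_missing:
        return PairPhase("unknown", "none")
    hom = _hom_trans_pair(gtA, gtB)
    if hom is not None:
        return hom
    if gtA.alt_count() == 0 or gtB.alt_count() == 0:
        return PairPhase("unknown", "none")
    # both het with exactly one alt each
    if gtA.phased and gtB.phased:
        col_a = 0 if gtA.allele_indices[0] > 0 else 1
        col_b = 0 if gtB.allele_indices[0] > 0 else 1
        status = "trans" if col_a != col_b else "cis"
        return PairPhase(status, "population_phase")
    return PairPhase("ambiguous", "none")


def _allele_options(call: Optional[GenotypeCall], child: GenotypeCall) -> set[int]:
    """Alleles a parent can transmit at one site.  A missing parent is
    unconstrained, so any allele seen in the child (plus ref) may come
    from them."""
    if call is None or call.is_missing:
        return set(a for a in child.allele_indices) | {0}
    return set(call.allele_indices)


def phase_pair_trio(
    proband: tuple[GenotypeCall, GenotypeCall],
    father: tuple[Optional[GenotypeCall], Optional[GenotypeCall]],
    mother: tuple[Optional[GenotypeCall], Optional[GenotypeCall]],
) -> PairPhase:
    """Phase a pair of proband calls from parental genotypes.

    All parental transmissions consistent with the six genotypes are
    enumerated.  Every consistent assignment placing the two alt alleles
    on different parental gametes -> trans; every assignment on the same
    gamete -> cis; both occur -> ambiguous; none consistent (e.g. a de
    novo allele) -> mendelian_error.
    """
    pA, pB = proband
    if pA.is_missing or pB.is_missing:
        return PairPhase("unknown", "none")
    hom = _hom_trans_pair(pA, pB)
    if hom is not None:
        return hom
    if pA.alt_count() == 0 or pB.alt_count() == 0:
        return PairPhase("unknown", "none")

    fa_opts = (_allele_options(father[0], pA), _allele_options(father[1], pB))
    mo_opts = (_allele_options(mother[0], pA), _allele_options(mother[1], pB))

    saw_trans = saw_cis = False
    child_a = tuple(sorted(pA.allele_indices))
    child_b = tuple(sorted(pB.allele_indices))
    for f1, f2, m1, m2 in itertools.product(
        fa_opts[0], fa_opts[1], mo_opts[0], mo_opts[1]
    ):
        if tuple(sorted((f1, m1))) != child_a:
            continue
        if tuple(sorted((f2, m2))) != child_b:
            continue
        # paternal gamete carries (f1, f2); maternal (m1, m2)
        alt_a_paternal = f1 > 0
        alt_b_paternal = f2 > 0
        if alt_a_paternal == alt_b_paternal:
            saw_cis = True
        else:
            saw_trans = True
    if saw_trans and saw_cis:
        return PairPhase("ambiguous", "none")
    if saw_trans:
        return PairPhase("trans", "trio")
    if saw_cis:
        return PairPhase("cis", "trio")
    return PairPhase("mendelian_error", "trio")


def _pair_phase(
    gtA: GenotypeCall,
    gtB: GenotypeCall,
    parent_calls: Optional[
        tuple[
            tuple[Optional[GenotypeCall], Optional[GenotypeCall]],
            tuple[Optional[GenotypeCall], Optional[GenotypeCall]],
        ]
    ],
) -> PairPhase:
    """Route one pair of calls through the best available evidence."""
    if gtA.is_missing or gtB.is_missing:
        return PairPhase("unknown", "none")
    hom = _hom_trans_pair(gtA, gtB)
    if hom is not None:
        return hom
    if gtA.alt_count() == 0 or gtB.alt_count() == 0:
        return PairPhase("unknown", "none")
    if gtA.phased and gtB.phased:
        return phase_pair_population(gtA, gtB)
    if parent_calls is not None:
        father, mother = parent_calls
        if any(c is not None and not c.is_missing for c in (*father, *mother)):
            return phase_pair_trio((gtA, gtB), father, mother)
    return PairPhase("ambiguous", "none")


def classify_individual(
    individual_id: str,
    calls: dict[str, GenotypeCall],
    parent_calls_by_site: Optional[
        tuple[dict[str, GenotypeCall], dict[str, GenotypeCall]]
    ] = None,
    sites: Optional[Sequence[str]] = None,
) -> CompHetCall:
    """Classify one individual across a variant set.

    ``calls`` maps site keys (``chrom:pos``) to this individual's calls;
    ``parent_calls_by_site`` optionally supplies (father, mother) call
    maps for trio phasing.  The verdict is invariant to site order and
    to duplicated sites.
    """
    if sites is None:
        sites = list(calls)
    site_list = sorted(set(sites))
    if len(site_list) < 2:
        raise ValueError("variant set must list >= 2 distinct sites")

    qualifying: list[tuple[str, str, PairPhase]] = []
    ambiguous: list[tuple[str, str, PairPhase]] = []
    any_data = False
    for keyA, keyB in itertools.combinations(site_list, 2):
        gtA, gtB = calls.get(keyA), calls.get(keyB)
        if gtA is None or gtB is None:
            continue
        if not (gtA.is_missing and gtB.is_missing):
            any_data = True
        parents = None
        if parent_calls_by_site is not None:
            fa, mo = parent_calls_by_site
            parents = (
                (fa.get(keyA), fa.get(keyB)),
                (mo.get(keyA), mo.get(keyB)),
            )
        phase = _pair_phase(gtA, gtB, parents)
        if phase.status == "trans":
            qualifying.append((keyA, keyB, phase))
        elif phase.status == "ambiguous":
            ambiguous.append((keyA, keyB, phase))

    is_ch = bool(qualifying)
    hom_only = is_ch and all(p.evidence == "hom_trans" for _, _, p in qualifying)
    return CompHetCall(
        individual_id=individual_id,
        is_compound_het=is_ch,
        qualifying_pairs=qualifying,
        ambiguous_pairs=ambiguous,
        hom_trans_only=hom_only,
        has_data=any_data,
    )


def count_compound_hets(
    table: VcfTable,
    sites: Sequence[str],
    pedigree: Optional[Pedigree] = None,
    population: Optional[str] = None,
    include_hom_trans: bool = True,
) -> tuple[int, int, list[CompHetCall]]:
    """Count compound-het individuals in a cohort.

    ``sites`` are ``chrom:pos`` keys that must exist in the table.
    Individuals acting only as parents of another sample (per the
    pedigree) are excluded from the cohort; a population filter keeps
    samples whose pedigree label matches.  Returns ``(count, n, calls)``
    where ``n`` counts individuals with a non-missing call at at least
    one site (sufficient data), and ``count`` those classified trans.
    Setting ``include_hom_trans=False`` recovers the stricter tally that
    ignores hom-forced trans evidence.
    """
    site_list = sorted(set(sites))
    if not site_list:
        raise ValueError("empty variant set")
    known = {v.key for v in table.variants}
    missing = [s for s in site_list if s not in known]
    if missing:
        raise KeyError(f"sites not in VCF: {', '.join(missing)}")

    parent_ids: set[str] = set()
    if pedigree is not None:
        for ind in pedigree:
            for pid in (ind.father_id, ind.mother_id):
                if pid is not None:
                    parent_ids.add(pid)

    count = 0
    n = 0
    results: list[CompHetCall] = []
    for sample in table.samples:
        if sample in parent_ids:
            continue
        if population is not None:
            ind = pedigree.get(sample) if pedigree is not None else None
            if ind is None or ind.population != population:
                continue
        calls = {
            k: c for k, c in table.sample_calls(sample).items() if k in site_list
        }
        parents = None
        if pedigree is not None:
            father_id, mother_id = pedigree.parents_of(sample)
            fa_calls = (
                table.sample_calls(father_id)
                if father_id in (table.samples or [])
                else {}
            )
            mo_calls = (
                table.sample_calls(mother_id)
                if mother_id in (table.samples or [])
                else {}
            )
            if fa_calls or mo_calls:
                parents = (fa_calls, mo_calls)
        verdict = classify_individual(sample, calls, parents, site_list)
        results.append(verdict)
        if verdict.has_data:
            n += 1
        qualifies = verdict.is_compound_het
        if not include_hom_trans and verdict.hom_trans_only:
            qualifies = False
        if qualifies:
            count += 1
    return count, n, results
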