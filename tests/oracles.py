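"""Independent brute-force oracles used by unit and acceptance tests.

These deliberately avoid the code paths they check: exact rational
arithmetic for the Fisher test, ordered-haplotype enumeration for trio
phasing, and full-CDS translation diffing for consequence calling.
"""

from __future__ import annotations

import itertools
from fractions import Fraction
from functools import lru_cache
from math import comb


# --- Fisher exact, exact rational arithmetic -------------------------------

def fisher_oracle(a: int, b: int, c: int, d: int) -> Fraction:
    """Two-sided Fisher p as an exact rational: sum of hypergeometric
    pmfs over all tables with the observed margins whose pmf is at most
    pmf(observed) * (1 + 1e-7), the same cutoff rule as the
    implementation but evaluated without floating point."""
    r1, c1, n = a + b, a + c, a + b + c + d
    if n == 0 or r1 in (0, n) or c1 in (0, n):
        return Fraction(1)
    r2 = n - r1
    k_lo = max(0, c1 - r2)
    k_hi = min(r1, c1)
    nums = {k: comb(r1, k) * comb(r2, c1 - k) for k in range(k_lo, k_hi + 1)}
    denom = comb(n, c1)
    # pmf_k <= pmf_a * (1 + 1e-7)  <=>  num_k * 10^7 <= num_a * (10^7 + 1)
    obs = nums[a]
    total = sum(
        num for num in nums.values() if num * 10**7 <= obs * (10**7 + 1)
    )
    return min(Fraction(total, denom), Fraction(1))


# --- Trio phasing, ordered-haplotype enumeration ---------------------------

def _phasings(gt1: tuple[int, int], gt2: tuple[int, int]):
    """All (hapA, hapB) orderings of a two-site unphased genotype."""
    configs = set()
    for o1 in (gt1, gt1[::-1]):
        for o2 in (gt2, gt2[::-1]):
            configs.add(((o1[0], o2[0]), (o1[1], o2[1])))
    return configs


def trio_phase_oracle(
    child: tuple[tuple[int, int], tuple[int, int]],
    father: tuple[tuple[int, int], tuple[int, int]],
    mother: tuple[tuple[int, int], tuple[int, int]],
) -> str:
    """Status for a double-het child given unphased parental genotypes,
    by enumerating every phased parental configuration and every gamete
    choice.  Returns trans / cis / ambiguous / mendelian_error."""
    c1, c2 = tuple(sorted(child[0])), tuple(sorted(child[1]))
    saw = set()
    for f_hapA, f_hapB in _phasings(*father):
        for m_hapA, m_hapB in _phasings(*mother):
            for f_gamete in (f_hapA, f_hapB):
                for m_gamete in (m_hapA, m_hapB):
                    got1 = tuple(sorted((f_gamete[0], m_gamete[0])))
                    got2 = tuple(sorted((f_gamete[1], m_gamete[1])))
                    if (got1, got2) != (c1, c2):
                        continue
                    paternal_alt = (f_gamete[0] > 0, f_gamete[1] > 0)
                    if paternal_alt[0] != paternal_alt[1]:
                        saw.add("trans")
                    else:
                        saw.add("cis")
    if not saw:
        return "mendelian_error"
    if saw == {"trans"}:
        return "trans"
    if saw == {"cis"}:
        return "cis"
    return "ambiguous"


# --- Consequence calling via whole-CDS translation diff --------------------

_CODON_TABLE = None


def _codon_table():
    global _CODON_TABLE
    if _CODON_TABLE is None:
        from Bio.Data.CodonTable import standard_dna_table

        table = dict(standard_dna_table.forward_table)
        for stop in standard_dna_table.stop_codons:
            table[stop] = "*"
        _CODON_TABLE = table
    return _CODON_TABLE


def translate(cds: str) -> str:
    table = _codon_table()
    return "".join(table[cds[i : i + 3]] for i in range(0, len(cds), 3))


def consequence_oracle(cds: str, mutated_cds: str):
    """(kind, protein_pos, ref_aa, alt_aa) by translating both coding
    sequences and diffing; identity -> synonymous at the affected codon."""
    assert len(cds) == len(mutated_cds)
    ref_prot = translate(cds)
    alt_prot = translate(mutated_cds)
    diffs = [i for i, (r, m) in enumerate(zip(ref_prot, alt_prot)) if r != m]
    changed_nt = [i for i, (r, m) in enumerate(zip(cds, mutated_cds)) if r != m]
    assert len(changed_nt) == 1
    codon_idx = changed_nt[0] // 3
    if not diffs:
        return ("synonymous", codon_idx + 1, ref_prot[codon_idx],
                alt_prot[codon_idx])
    assert diffs == [codon_idx]
    ref_aa, alt_aa = ref_prot[codon_idx], alt_prot[codon_idx]
    if alt_aa == "*":
        kind = "stop_gain"
    elif ref_aa == "*":
        kind = "stop_loss"
    else:
        kind = "missense"
    return (kind, codon_idx + 1, ref_aa, alt_aa)


# --- Compound-het truth from haplotypes ------------------------------------

def comphet_truth(h1, h2) -> bool:
    """An individual is a compound het iff two distinct sites carry alt
    alleles on opposite haplotypes."""
    return any(
        h1[i] > 0 and h2[j] > 0
        for i, j in itertools.permutations(range(len(h1)), 2)
    )


@lru_cache(maxsize=None)
def all_tables_up_to(n_max: int):
    """Every 2x2 table (a, b, c, d) with total N <= n_max, grouped by
    margins for efficient oracle evaluation."""
    tables = []
    for n in range(n_max + 1):
        for r1 in range(n + 1):
            for a in range(r1 + 1):
                for c in range(n - r1 + 1):
                    tables.append((a, r1 - a, c, n - r1 - c))
    return tables
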