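"""Readers and writers for the formats the pipeline touches.

Supported formats are deliberately narrow:

* VCF v4.x text, GT subfield only.  The phase flag of a call is taken
  solely from the ``|`` / ``/`` separator; no re-phasing happens here.
  Positions stay 1-based at this boundary (internal interval arithmetic
  elsewhere is 0-based half-open).
* 6+ column whitespace-delimited PED, with ``0`` meaning unknown parent
  and an optional 7th column carrying a population label.
* Aligned FASTA (equal-length sequences, ``-`` gaps, uppercased on load).

Multi-allelic sites are kept as-is; downstream code addresses alleles by
(record, alt index).  Only CHROM/POS/ID/REF/ALT/GT round-trip losslessly.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterator, Optional, Sequence

from Bio import SeqIO

from .errors import AlignmentError, PedigreeError, VcfFormatError, VcfParseError

__all__ = [
    "VariantRecord",
    "GenotypeCall",
    "Individual",
    "Pedigree",
    "VcfTable",
    "read_vcf",
    "write_vcf",
    "read_pedigree",
    "write_pedigree",
    "read_alignment",
]

_ALLELE_RE = re.compile(r"^[ACGTN]+$")


@dataclass(frozen=True)
class VariantRecord:
    """One VCF site: position is 1-based as in the file."""

    chrom: str
    pos: int
    id: Optional[str]
    ref: str
    alts: tuple[str, ...]

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"pos must be >= 1, got {self.pos}")
        if not _ALLELE_RE.match(self.ref):
            raise ValueError(f"invalid REF allele {self.ref!r}")
        if not self.alts:
            raise ValueError("alts must be non-empty")
        for alt in self.alts:
            if not _ALLELE_RE.match(alt):
                raise ValueError(f"invalid ALT allele {alt!r}")
            if alt == self.ref:
                raise ValueError(f"ALT equals REF ({alt!r})")

    @property
    def key(self) -> str:
        return f"{self.chrom}:{self.pos}"

    def is_snv(self, alt_index: int = 0) -> bool:
        return len(self.ref) == 1 and len(self.alts[alt_index]) == 1


@dataclass(frozen=True)
class GenotypeCall:
    """A diploid call for one sample at one site.

    ``allele_indices`` holds ``None`` for missing alleles; a single
    missing slot renders the whole call missing.  ``phased`` may be true
    only when both indices are present.
    """

    allele_indices: tuple[Optional[int], Optional[int]]
    phased: bool
    sample_id: str

    def __post_init__(self) -> None:
        a, b = self.allele_indices
        if (a is None) != (b is None):
            # one missing slot -> whole call missing
            object.__setattr__(self, "allele_indices", (None, None))
            a = b = None
        if self.phased and a is None:
            raise ValueError("phased call requires both allele indices")

    @property
    def is_missing(self) -> bool:
        return self.allele_indices[0] is None

    def alt_count(self) -> int:
        """Number of non-reference alleles carried (0 if missing)."""
        return sum(1 for i in self.allele_indices if i is not None and i > 0)

    def is_het(self) -> bool:
        a, b = self.allele_indices
        return a is not None and a != b

    def is_hom_alt(self) -> bool:
        a, b = self.allele_indices
        return a is not None and a == b and a > 0

    def gt_string(self) -> str:
        sep = "|" if self.phased else "/"
        a, b = self.allele_indices
        fmt = lambda x: "." if x is None else str(x)  # noqa: E731
        return f"{fmt(a)}{sep}{fmt(b)}"


@dataclass(frozen=True)
class Individual:
    individual_id: str
    father_id: Optional[str]
    mother_id: Optional[str]
    sex: str
    affected: bool
    population: Optional[str] = None
    family_id: str = "0"


class Pedigree:
    """An ordered collection of individuals with resolved parent links."""

    def __init__(self, individuals: Sequence[Individual]):
        self._by_id: dict[str, Individual] = {}
        for ind in individuals:
            if ind.individual_id in self._by_id:
                raise PedigreeError(f"duplicate individual id {ind.individual_id!r}")
            self._by_id[ind.individual_id] = ind
        self._check_acyclic()

    def _check_acyclic(self) -> None:
        state: dict[str, int] = {}  # 0=visiting, 1=done

        def visit(iid: str, stack: list[str]) -> None:
            if iid not in self._by_id:
                return
            if state.get(iid) == 1:
                return
            if state.get(iid) == 0:
                raise PedigreeError(
                    f"pedigree cycle involving {' -> '.join(stack + [iid])}"
                )
            state[iid] = 0
            ind = self._by_id[iid]
            for parent in (ind.father_id, ind.mother_id):
                if parent is not None:
                    visit(parent, stack + [iid])
            state[iid] = 1

        for iid in self._by_id:
            visit(iid, [])

    def __len__(self) -> int:
        return len(self._by_id)

    def __iter__(self) -> Iterator[Individual]:
        return iter(self._by_id.values())

    def __contains__(self, iid: str) -> bool:
        return iid in self._by_id

    def get(self, iid: str) -> Optional[Individual]:
        return self._by_id.get(iid)

    def parents_of(self, iid: str) -> tuple[Optional[str], Optional[str]]:
        ind = self._by_id.get(iid)
        if ind is None:
            return (None, None)
        return (ind.father_id, ind.mother_id)

    def ids(self) -> list[str]:
        return list(self._by_id)


@dataclass
class VcfTable:
    """Parsed GT-only view of a multi-sample VCF.

    ``calls[i][j]`` is the call of sample ``samples[j]`` at
    ``variants[i]``; sample order matches the file header.
    """

    samples: list[str]
    variants: list[VariantRecord]
    calls: list[list[GenotypeCall]]
    header_lines: list[str] = field(default_factory=list)

    def __iter__(self) -> Iterator[tuple[VariantRecord, list[GenotypeCall]]]:
        return iter(zip(self.variants, self.calls))

    def __len__(self) -> int:
        return len(self.variants)

    def sample_calls(self, sample_id: str) -> dict[str, GenotypeCall]:
        """Calls of one sample keyed by ``chrom:pos``."""
        j = self.samples.index(sample_id)
        return {v.key: row[j] for v, row in zip(self.variants, self.calls)}

    def site_calls(self, chrom: str, pos: int) -> list[GenotypeCall]:
        for v, row in zip(self.variants, self.calls):
            if v.chrom == chrom and v.pos == pos:
                return row
        raise KeyError(f"site {chrom}:{pos} not in table")


def _parse_gt(token: str, n_alts: int, sample_id: str, lineno: int) -> GenotypeCall:
    gt = token.split(":", 1)[0]
    phased = "|" in gt
    parts = re.split(r"[|/]", gt)
    if len(parts) == 1:  # haploid or '.' -> treated as missing diploid call
        parts = [parts[0], "."]
        phased = False
    if len(parts) != 2:
        raise VcfParseError(f"line {lineno}: cannot parse GT {gt!r}")
    indices: list[Optional[int]] = []
    for p in parts:
        if p == ".":
            indices.append(None)
        else:
            try:
                idx = int(p)
            except ValueError as exc:
                raise VcfParseError(f"line {lineno}: bad allele index {p!r}") from exc
            if idx < 0 or idx > n_alts:
                raise VcfParseError(
                    f"line {lineno}: allele index {idx} out of range [0, {n_alts}]"
                )
            indices.append(idx)
    if None in indices:
        return GenotypeCall((None, None), False, sample_id)
    return GenotypeCall((indices[0], indices[1]), phased, sample_id)


def read_vcf(path) -> VcfTable:
    """Parse a VCF v4.x text file (GT subfield only).

    Accepts v4.1 through v4.3 headers leniently.  Raises
    :class:`VcfParseError` naming the line number on malformed content
    and :class:`VcfFormatError` when GT is absent from FORMAT.
    """
    samples: Optional[list[str]] = None
    variants: list[VariantRecord] = []
    calls: list[list[GenotypeCall]] = []
    header_lines: list[str] = []

    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line:
                continue
            if line.startswith("##"):
                header_lines.append(line)
                continue
            if line.startswith("#CHROM"):
                cols = line.split("\t")
                if len(cols) < 10:
                    raise VcfParseError(
                        f"line {lineno}: #CHROM header has no sample columns"
                    )
                if cols[:9] != [
                    "#CHROM", "POS", "ID", "REF", "ALT",
                    "QUAL", "FILTER", "INFO", "FORMAT",
                ]:
                    raise VcfParseError(f"line {lineno}: malformed #CHROM header")
                samples = cols[9:]
                continue
            if samples is None:
                raise VcfParseError(f"line {lineno}: data line before #CHROM header")
            cols = line.split("\t")
            if len(cols) != 9 + len(samples):
                raise VcfParseError(
                    f"line {lineno}: expected {9 + len(samples)} columns, "
                    f"got {len(cols)}"
                )
            chrom, pos_s, vid, ref, alt_s = cols[0], cols[1], cols[2], cols[3], cols[4]
            try:
                pos = int(pos_s)
            except ValueError as exc:
                raise VcfParseError(f"line {lineno}: bad POS {pos_s!r}") from exc
            fmt_keys = cols[8].split(":")
            if "GT" not in fmt_keys:
                raise VcfFormatError(f"line {lineno}: FORMAT lacks GT")
            if fmt_keys[0] != "GT":
                raise VcfFormatError(f"line {lineno}: GT must be first FORMAT key")
            alts = tuple(alt_s.split(","))
            try:
                record = VariantRecord(
                    chrom=chrom,
                    pos=pos,
                    id=None if vid == "." else vid,
                    ref=ref,
                    alts=alts,
                )
            except ValueError as exc:
                raise VcfParseError(f"line {lineno}: {exc}") from exc
            row = [
                _parse_gt(tok, len(alts), sid, lineno)
                for tok, sid in zip(cols[9:], samples)
            ]
            variants.append(record)
            calls.append(row)

    if samples is None:
        raise VcfParseError("no #CHROM header found")
    return VcfTable(samples=samples, variants=variants, calls=calls,
                    header_lines=header_lines)


def write_vcf(table: VcfTable, path, extra_header: Sequence[str] = ()) -> None:
    """Write a GT-only VCF.  ``read_vcf(write_vcf(x)) == x`` for the
    CHROM/POS/ID/REF/ALT/GT fields."""
    for row in table.calls:
        if len(row) != len(table.samples):
            raise VcfFormatError(
                f"record has {len(row)} calls for {len(table.samples)} samples"
            )
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        for line in extra_header:
            fh.write(line.rstrip("\n") + "\n")
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(table.samples)
            + "\n"
        )
        for rec, row in zip(table.variants, table.calls):
            fields = [
                rec.chrom,
                str(rec.pos),
                rec.id or ".",
                rec.ref,
                ",".join(rec.alts),
                ".",
                ".",
                ".",
                "GT",
            ] + [call.gt_string() for call in row]
            fh.write("\t".join(fields) + "\n")


def read_pedigree(path) -> Pedigree:
    """Parse a 6+ column whitespace-delimited PED file.

    Column order: family, individual, father, mother, sex, phenotype,
    [population].  ``0`` marks an unknown parent.  Affected status is
    phenotype == "2".
    """
    individuals: list[Individual] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            cols = line.split()
            if len(cols) < 6:
                raise PedigreeError(
                    f"line {lineno}: expected >= 6 columns, got {len(cols)}"
                )
            fam, iid, father, mother, sex, pheno = cols[:6]
            pop = cols[6] if len(cols) > 6 else None
            if iid in (father, mother):
                raise PedigreeError(f"line {lineno}: {iid!r} is its own parent")
            individuals.append(
                Individual(
                    individual_id=iid,
                    father_id=None if father == "0" else father,
                    mother_id=None if mother == "0" else mother,
                    sex=sex,
                    affected=(pheno == "2"),
                    population=pop,
                    family_id=fam,
                )
            )
    return Pedigree(individuals)


def write_pedigree(ped: Pedigree, path) -> None:
    with open(path, "w") as fh:
        for ind in ped:
            cols = [
                ind.family_id,
                ind.individual_id,
                ind.father_id or "0",
                ind.mother_id or "0",
                ind.sex,
                "2" if ind.affected else "1",
            ]
            if ind.population is not None:
                cols.append(ind.population)
            fh.write("\t".join(cols) + "\n")


def read_alignment(path):
    """Load an aligned FASTA into a :class:`~phasekit.conservation.Alignment`.

    Sequences are uppercased; ragged lengths raise
    :class:`AlignmentError` listing the offending ids.
    """
    from .conservation import Alignment  # local import avoids cycle at import time

    ids: list[str] = []
    seqs: list[str] = []
    for rec in SeqIO.parse(str(path), "fasta"):
        ids.append(rec.id)
        seqs.append(str(rec.seq).upper())
    if not seqs:
        raise AlignmentError(f"no sequences in {path}")
    length = len(seqs[0])
    bad = [i for i, s in zip(ids, seqs) if len(s) != length]
    if bad:
        raise AlignmentError(f"ragged alignment; offending ids: {', '.join(bad)}")
    return Alignment(ids=ids, seqs=seqs)
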