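"""Isoform-aware protein consequence calling for SNVs.

A :class:`TranscriptModel` carries the exon/CDS structure of one isoform
together with the reference sequence of its locus, so a genomic variant
can be projected independently onto several isoforms of the same gene: a
position that is coding in one isoform may be intronic in another.

Coordinates: the public API accepts 1-based genomic positions (the VCF
convention); everything internal is 0-based half-open.  Minus-strand
transcripts count CDS offsets from the 3'-most CDS base and complement
alleles.

Only SNVs are supported; anything else raises
:class:`~phasekit.errors.UnsupportedVariantError` explicitly.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from typing import Optional, Sequence

from Bio.Seq import Seq

from .errors import TranscriptError, UnsupportedVariantError
from .io_formats import VariantRecord

__all__ = [
    "TranscriptModel",
    "Consequence",
    "DomainMap",
    "MOUSE_MLKL_DOMAINS",
    "map_genomic_to_cds",
    "call_codon_consequence",
    "annotate_variant",
    "classify_domain",
    "read_transcripts",
    "read_domain_map",
]

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def _revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class TranscriptModel:
    """Exon/CDS structure of one isoform plus its locus sequence.

    ``exons`` are 0-based half-open genomic intervals, ordered by
    position and non-overlapping.  ``cds_start``/``cds_end`` bound the
    coding region in genomic coordinates (0-based half-open, applied to
    each exon by intersection).  ``locus_start`` is the 0-based genomic
    coordinate of ``sequence[0]``.
    """

    transcript_id: str
    gene: str
    strand: str
    exons: tuple[tuple[int, int], ...]
    cds_start: int
    cds_end: int
    sequence: str
    locus_start: int = 0
    relaxed: bool = False  # skip start/stop codon checks (toy fixtures)

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise TranscriptError(f"strand must be + or -, got {self.strand!r}")
        prev_end = None
        for start, end in self.exons:
            if end <= start:
                raise TranscriptError(f"empty exon [{start}, {end})")
            if prev_end is not None and start < prev_end:
                raise TranscriptError("exons overlap or are unordered")
            prev_end = end
        for start, end in self.exons:
            if start < self.locus_start or end > self.locus_start + len(self.sequence):
                raise TranscriptError("exon outside the provided locus slice")
        cds = self.cds_genomic_positions()
        if len(cds) % 3 != 0:
            raise TranscriptError(
                f"CDS length {len(cds)} not divisible by 3 "
                f"({self.transcript_id})"
            )
        if not self.relaxed:
            prot = self.translate_cds()
            if not prot.startswith("M"):
                raise TranscriptError(f"{self.transcript_id}: CDS lacks start codon")
            if not prot.endswith("*"):
                raise TranscriptError(f"{self.transcript_id}: CDS lacks stop codon")

    def cds_genomic_positions(self) -> list[int]:
        """Genomic coordinates of spliced CDS bases, in translation order
        (reversed for minus strand)."""
        positions: list[int] = []
        for start, end in self.exons:
            lo = max(start, self.cds_start)
            hi = min(end, self.cds_end)
            positions.extend(range(lo, hi))
        if self.strand == "-":
            positions.reverse()
        return positions

    def base_at(self, genomic_pos0: int) -> str:
        """Reference base (forward strand) at a 0-based genomic position."""
        i = genomic_pos0 - self.locus_start
        if i < 0 or i >= len(self.sequence):
            raise TranscriptError(
                f"position {genomic_pos0 + 1} outside locus slice of "
                f"{self.transcript_id}"
            )
        return self.sequence[i]

    def cds_sequence(self) -> str:
        """Spliced coding sequence in reading orientation.

        ``cds_genomic_positions`` already orders bases 5'->3' for the
        transcript, so minus-strand sequences only need complementing.
        """
        bases = [self.base_at(p) for p in self.cds_genomic_positions()]
        if self.strand == "-":
            return "".join(b.translate(_COMPLEMENT) for b in bases)
        return "".join(bases)

    def translate_cds(self) -> str:
        return str(Seq(self.cds_sequence()).translate())

    @property
    def protein_length(self) -> int:
        """Length of the encoded protein, excluding the stop codon when
        present."""
        prot = self.translate_cds()
        return len(prot) - 1 if prot.endswith("*") else len(prot)

    def exon_span(self) -> tuple[int, int]:
        return (self.exons[0][0], self.exons[-1][1])


@dataclass(frozen=True)
class Consequence:
    """Protein-level effect of a variant on one isoform."""

    transcript_id: str
    kind: str  # missense | synonymous | stop_gain | stop_loss | non_coding | intronic
    protein_pos: Optional[int]
    ref_aa: Optional[str]
    alt_aa: Optional[str]
    label: Optional[str]

    KINDS = frozenset(
        {"missense", "synonymous", "stop_gain", "stop_loss", "non_coding", "intronic"}
    )

    def __post_init__(self) -> None:
        if self.kind not in self.KINDS:
            raise ValueError(f"unknown consequence kind {self.kind!r}")


@dataclass(frozen=True)
class DomainMap:
    """Named, non-overlapping 1-based inclusive residue ranges.

    Shipped defaults are configurable approximations; use a config file
    for anything beyond the mouse toy map.
    """

    ranges: tuple[tuple[str, int, int], ...]
    protein_length: int

    def __post_init__(self) -> None:
        occupied: set[int] = set()
        for name, start, end in self.ranges:
            if start < 1 or end > self.protein_length or end < start:
                raise ValueError(
                    f"domain {name!r} range {start}-{end} outside protein "
                    f"of length {self.protein_length}"
                )
            span = set(range(start, end + 1))
            if occupied & span:
                raise ValueError(f"domain {name!r} overlaps another range")
            occupied |= span


#: Mouse MLKL-style default map: 4HB 1-125, brace 126-180, pseudokinase rest.
MOUSE_MLKL_DOMAINS = DomainMap(
    ranges=(("4HB", 1, 125), ("brace", 126, 180), ("pseudokinase", 181, 464)),
    protein_length=464,
)


def map_genomic_to_cds(t: TranscriptModel, pos: int) -> Optional[int]:
    """0-based offset into the spliced CDS for a 1-based genomic position.

    Returns ``None`` for intronic / non-coding positions; raises
    :class:`TranscriptError` when ``pos`` lies outside the locus slice.
    """
    pos0 = pos - 1
    t.base_at(pos0)  # bounds check
    cds = t.cds_genomic_positions()
    try:
        return cds.index(pos0)
    except ValueError:
        return None


def _locate_kind(t: TranscriptModel, pos0: int) -> str:
    """Kind for a position with no CDS offset: intronic when between
    exons, otherwise non_coding (UTR exon or outside the transcript)."""
    span_lo, span_hi = t.exon_span()
    if not (span_lo <= pos0 < span_hi):
        return "non_coding"
    for start, end in t.exons:
        if start <= pos0 < end:
            return "non_coding"  # exonic but outside the CDS
    return "intronic"


def call_codon_consequence(
    t: TranscriptModel, v: VariantRecord, alt_index: int = 0
) -> Consequence:
    """Protein consequence of an SNV on one isoform, via the standard
    genetic code.  Stop is written ``X`` in labels (e.g. ``Q48X``)."""
    alt = v.alts[alt_index]
    if len(v.ref) != 1 or len(alt) != 1:
        raise UnsupportedVariantError(
            f"only SNVs supported for consequence calling, got "
            f"{v.ref}>{alt} at {v.chrom}:{v.pos}"
        )
    pos0 = v.pos - 1
    ref_base = t.base_at(pos0)
    if ref_base != v.ref:
        raise TranscriptError(
            f"REF mismatch at {v.chrom}:{v.pos}: VCF says {v.ref}, "
            f"locus slice has {ref_base}"
        )
    offset = map_genomic_to_cds(t, v.pos)
    if offset is None:
        kind = _locate_kind(t, pos0)
        return Consequence(t.transcript_id, kind, None, None, None, None)

    cds = t.cds_sequence()
    ref_allele, alt_allele = v.ref, alt
    if t.strand == "-":
        ref_allele = ref_allele.translate(_COMPLEMENT)
        alt_allele = alt_allele.translate(_COMPLEMENT)
    assert cds[offset] == ref_allele

    codon_idx = offset // 3
    within = offset % 3
    codon = cds[codon_idx * 3 : codon_idx * 3 + 3]
    mutated = codon[:within] + alt_allele + codon[within + 1 :]
    ref_aa = str(Seq(codon).translate())
    alt_aa = str(Seq(mutated).translate())
    protein_pos = codon_idx + 1

    if ref_aa == alt_aa:
        kind = "synonymous"
    elif alt_aa == "*":
        kind = "stop_gain"
    elif ref_aa == "*":
        kind = "stop_loss"
    else:
        kind = "missense"
    label = f"{_aa_label(ref_aa)}{protein_pos}{_aa_label(alt_aa)}"
    return Consequence(t.transcript_id, kind, protein_pos, ref_aa, alt_aa, label)


def _aa_label(aa: str) -> str:
    return "X" if aa == "*" else aa


def annotate_variant(
    v: VariantRecord,
    transcripts: Sequence[TranscriptModel],
    alt_index: int = 0,
) -> list[Consequence]:
    """One consequence per isoform, called independently."""
    return [call_codon_consequence(t, v, alt_index) for t in transcripts]


def classify_domain(protein_pos: int, dm: DomainMap) -> str:
    """Name of the domain containing ``protein_pos`` (1-based), or
    ``"unassigned"`` when no range covers it."""
    if protein_pos < 1 or protein_pos > dm.protein_length:
        raise ValueError(
            f"protein position {protein_pos} outside [1, {dm.protein_length}]"
        )
    for name, start, end in dm.ranges:
        if start <= protein_pos <= end:
            return name
    return "unassigned"


def read_transcripts(path) -> list[TranscriptModel]:
    """Load transcript models from the custom tab-separated format.

    Columns: transcript_id, gene, strand, exons (``start-end`` 1-based
    inclusive, comma separated), cds_start, cds_end (1-based inclusive),
    locus_start (1-based), sequence, relaxed (0/1).
    """
    models: list[TranscriptModel] = []
    with open(path) as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        required = {
            "transcript_id", "gene", "strand", "exons",
            "cds_start", "cds_end", "locus_start", "sequence",
        }
        if reader.fieldnames is None or not required.issubset(reader.fieldnames):
            raise TranscriptError(
                f"transcript table must have columns {sorted(required)}"
            )
        for row in reader:
            exons = []
            for part in row["exons"].split(","):
                lo, hi = part.split("-")
                exons.append((int(lo) - 1, int(hi)))  # to 0-based half-open
            models.append(
                TranscriptModel(
                    transcript_id=row["transcript_id"],
                    gene=row["gene"],
                    strand=row["strand"],
                    exons=tuple(exons),
                    cds_start=int(row["cds_start"]) - 1,
                    cds_end=int(row["cds_end"]),
                    sequence=row["sequence"].upper(),
                    locus_start=int(row["locus_start"]) - 1,
                    relaxed=row.get("relaxed", "0") == "1",
                )
            )
    return models


def read_domain_map(path) -> DomainMap:
    """Parse a key-value domain config::

        protein_length = 464
        4HB = 1-125
        brace = 126-180
        pseudokinase = 181-464
    """
    length: Optional[int] = None
    ranges: list[tuple[str, int, int]] = []
    with open(path) as fh:
        for raw in fh:
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            key, _, value = line.partition("=")
            key, value = key.strip(), value.strip()
            if key == "protein_length":
                length = int(value)
            else:
                lo, hi = value.split("-")
                ranges.append((key, int(lo), int(hi)))
    if length is None:
        raise ValueError("domain map config lacks protein_length")
    return DomainMap(ranges=tuple(ranges), protein_length=length)
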