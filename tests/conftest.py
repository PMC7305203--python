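"""Shared fixtures: toy transcripts, genotype helpers, small alignments.

All fixtures are generated programmatically; nothing binary ships with
the repo.
"""

from __future__ import annotations

import sys
from pathlib import Path

import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make oracles importable

from phasekit.io_formats import GenotypeCall, VariantRecord
from phasekit.transcript_annotation import TranscriptModel

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def gt(a, b, phased=False, sample="S1"):
    return GenotypeCall((a, b), phased, sample)


def snv(chrom, pos, ref, alt, vid=None):
    return VariantRecord(chrom=chrom, pos=pos, id=vid, ref=ref,
                         alts=(alt,))


def single_exon_transcript(codons, transcript_id="tx1", gene="toy",
                           utr5="", utr3=""):
    """Plus-strand single-exon transcript whose CDS is the given codon
    list; optional flanking UTR sequence."""
    cds = "".join(codons)
    seq = utr5 + cds + utr3
    return TranscriptModel(
        transcript_id=transcript_id,
        gene=gene,
        strand="+",
        exons=((0, len(seq)),),
        cds_start=len(utr5),
        cds_end=len(utr5) + len(cds),
        sequence=seq,
        locus_start=0,
    )


def minus_strand_twin(t: TranscriptModel) -> TranscriptModel:
    """The same transcript on the reverse-complemented locus: flipped
    strand, mirrored coordinates, identical protein."""
    length = len(t.sequence)
    origin = t.locus_start
    flip = lambda x: origin + (length - (x - origin))  # noqa: E731
    exons = tuple(sorted((flip(end), flip(start)) for start, end in t.exons))
    return TranscriptModel(
        transcript_id=t.transcript_id + "_rc",
        gene=t.gene,
        strand="-",
        exons=exons,
        cds_start=flip(t.cds_end),
        cds_end=flip(t.cds_start),
        sequence=revcomp(t.sequence),
        locus_start=origin,
        relaxed=t.relaxed,
    )


@pytest.fixture
def brace_transcript():
    """145-codon toy protein: M + 46x A + Q at 48 + 90x A + D at 139 +
    5x L + stop.  Codon 139 is GAT and codon 48 is CAA, so the D139V
    (A>T at codon position 2) and Q48X (C>T at position 1) toy variants
    land where the tests expect them."""
    codons = (
        ["ATG"]
        + ["GCT"] * 46          # residues 2-47
        + ["CAA"]               # residue 48: Q
        + ["GCT"] * 90          # residues 49-138
        + ["GAT"]               # residue 139: D
        + ["CTG"] * 5           # residues 140-144
        + ["TAA"]
    )
    return single_exon_transcript(codons)


@pytest.fixture
def spliced_transcript():
    """Two-exon plus-strand transcript with a 30 bp intron inside the
    CDS (exon1 = first 60 coding bases, exon2 = the rest)."""
    codons = ["ATG"] + ["GGT"] * 38 + ["TAA"]  # 40 codons, 120 nt
    cds = "".join(codons)
    intron = "GTAAGTATCTTTTTTTTCCCCCCTTTTAG"  # 29 nt; content irrelevant
    seq = cds[:60] + intron + cds[60:]
    return TranscriptModel(
        transcript_id="spliced",
        gene="toy",
        strand="+",
        exons=((0, 60), (60 + len(intron), len(seq))),
        cds_start=0,
        cds_end=len(seq),
        sequence=seq,
        locus_start=0,
    )


@pytest.fixture
def isoform_pair():
    """Two isoforms sharing a locus, emulating an isoform-specific
    coding extension.

    Isoform 1 (canonical) splices straight from exon A to exon C;
    isoform 2 retains an extra exon B ("exon-9 extension") whose codon
    202 is GGT, so an A>T-style G>T change there is missense G202V on
    isoform 2 but intronic on isoform 1.
    """
    # shared exon A: 300 coding bases (100 codons), starts with ATG
    exon_a = "ATG" + "GCT" * 99
    # isoform-2-only exon B: codons 101-210 of isoform 2; codon 202 GGT
    b_codons = ["GCT"] * 101 + ["GGT"] + ["GCT"] * 7 + ["TAA"]
    exon_b = "".join(b_codons)  # codon 202 sits 101 codons into exon B
    # shared exon C: isoform 1's tail (60 coding bases + stop)
    exon_c = "CCT" * 20 + "TAA"
    gap1 = "GT" + "A" * 46 + "AG"  # intron-like spacers
    gap2 = "GT" + "A" * 46 + "AG"
    seq = exon_a + gap1 + exon_b + gap2 + exon_c

    a_span = (0, len(exon_a))
    b_span = (len(exon_a) + len(gap1), len(exon_a) + len(gap1) + len(exon_b))
    c_span = (b_span[1] + len(gap2), len(seq))

    iso1 = TranscriptModel(
        transcript_id="iso1",
        gene="toy",
        strand="+",
        exons=(a_span, c_span),
        cds_start=0,
        cds_end=len(seq),
        sequence=seq,
        locus_start=0,
    )
    iso2 = TranscriptModel(
        transcript_id="iso2",
        gene="toy",
        strand="+",
        exons=(a_span, b_span),
        cds_start=0,
        cds_end=b_span[1],
        sequence=seq,
        locus_start=0,
    )
    # genomic position (1-based) of codon 202, base 2, on isoform 2:
    # codon 202 starts 101 codons into exon B
    g202_pos = b_span[0] + 101 * 3 + 2
    return iso1, iso2, g202_pos


@pytest.fixture
def small_alignment():
    from phasekit.conservation import Alignment

    return Alignment(
        ids=["ref", "s2", "s3", "s4"],
        seqs=[
            "ACDE-F",
            "ACDEGF",
            "AVDEGF",
            "AVDE-F",
        ],
    )


@pytest.fixture
def toy_pdb(tmp_path):
    """Three-residue, one-atom-per-residue PDB with fixed B-factors."""
    lines = []
    template = (
        "ATOM  {serial:>5} {name:<4}{alt}{res:<3} {chain}{resseq:>4}"
        "{icode}   {x:>8.3f}{y:>8.3f}{z:>8.3f}{occ:>6.2f}{b:>6.2f}"
        "          {elem:>2}  "
    )
    for i in range(3):
        lines.append(
            template.format(
                serial=i + 1, name=" CA ", alt=" ", res="ALA", chain="A",
                resseq=i + 1, icode=" ", x=1.0 * i, y=2.0 * i, z=3.0 * i,
                occ=1.0, b=99.99, elem="C",
            )
        )
    lines.append("TER")
    lines.append("END")
    path = tmp_path / "toy.pdb"
    path.write_text("\n".join(lines) + "\n")
    return path
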