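"""Per-column conservation of a protein multiple alignment.

Sequence-logo information content (R = log2(20) - H, optionally with
the small-sample correction 19 / (2 ln2 n)), letter heights p * R,
mapping of alignment columns onto a reference sequence's residue
numbering, and projection of per-residue scores into the B-factor field
of a fixed-width PDB file.

Gaps ``-`` and the ambiguity letter ``X`` are excluded from the
frequency normalisation; coverage (non-gap fraction) is reported
separately.  An optional gap penalty scales R by coverage instead.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

from .errors import AlignmentError, StructureParseError

__all__ = [
    "Alignment",
    "ConservationTrack",
    "MAX_BITS",
    "column_information",
    "column_coverage",
    "logo_matrix",
    "map_columns_to_reference",
    "conservation_track",
    "write_scores_to_structure",
]

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
_VALID = set(AMINO_ACIDS) | {"-", "X"}

#: Maximum information content of a 20-letter alphabet column.
MAX_BITS = math.log2(20)


@dataclass(frozen=True)
class Alignment:
    """n equal-length uppercase sequences over the amino-acid alphabet
    plus ``-`` and ``X``."""

    ids: list[str]
    seqs: list[str]

    def __post_init__(self) -> None:
        if not self.seqs:
            raise AlignmentError("empty alignment")
        if len(self.ids) != len(self.seqs):
            raise AlignmentError("ids and sequences differ in number")
        length = len(self.seqs[0])
        for sid, seq in zip(self.ids, self.seqs):
            if len(seq) != length:
                raise AlignmentError(f"sequence {sid!r} has length {len(seq)}")
            bad = set(seq) - _VALID
            if bad:
                raise AlignmentError(
                    f"sequence {sid!r} has invalid letters {sorted(bad)}"
                )

    @property
    def n(self) -> int:
        return len(self.seqs)

    @property
    def length(self) -> int:
        return len(self.seqs[0])

    def column(self, index: int) -> str:
        if not 0 <= index < self.length:
            raise IndexError(f"column {index} outside [0, {self.length})")
        return "".join(seq[index] for seq in self.seqs)


@dataclass(frozen=True)
class ConservationTrack:
    """Per-reference-residue information content (bits) with coverage."""

    scores: dict[int, float]  # residue number (1-based) -> bits
    coverage: dict[int, float]  # residue number -> non-gap fraction

    def __post_init__(self) -> None:
        for res, score in self.scores.items():
            if res < 1:
                raise ValueError(f"residue number {res} < 1")
            if not -1e-9 <= score <= MAX_BITS + 1e-9:
                raise ValueError(f"score {score} outside [0, log2 20]")


def _column_freqs(column: str) -> tuple[dict[str, float], int]:
    counts: dict[str, int] = {}
    for letter in column:
        if letter in ("-", "X"):
            continue
        counts[letter] = counts.get(letter, 0) + 1
    n = sum(counts.values())
    if n == 0:
        return {}, 0
    return {ltr: c / n for ltr, c in counts.items()}, n


def column_coverage(aln: Alignment, index: int) -> float:
    """Fraction of sequences with a residue (not ``-``/``X``) in the
    column."""
    column = aln.column(index)
    return sum(1 for c in column if c not in ("-", "X")) / aln.n


def column_information(
    aln: Alignment,
    index: int,
    small_sample_correction: bool = False,
    gap_penalty: bool = False,
) -> float:
    """Information content of one column in bits.

    R = log2(20) - H - e_n with H the Shannon entropy of the non-gap
    letter frequencies and e_n = 19 / (2 ln2 n) when the small-sample
    correction is requested; clamped to [0, log2 20].  An all-gap
    column scores 0 (flagged via coverage, not an error).
    """
    freqs, n = _column_freqs(aln.column(index))
    if n == 0:
        return 0.0
    entropy = -sum(p * math.log2(p) for p in freqs.values())
    r = MAX_BITS - entropy
    if small_sample_correction:
        r -= 19.0 / (2.0 * math.log(2.0) * n)
    if gap_penalty:
        r *= column_coverage(aln, index)
    return min(max(r, 0.0), MAX_BITS)


def logo_matrix(
    aln: Alignment,
    small_sample_correction: bool = False,
    gap_penalty: bool = False,
) -> list[dict[str, float]]:
    """Per-column letter heights height(l) = p(l) * R; heights in a
    column sum to R.  All-gap columns yield an empty stack."""
    matrix: list[dict[str, float]] = []
    for col in range(aln.length):
        freqs, n = _column_freqs(aln.column(col))
        if n == 0:
            matrix.append({})
            continue
        r = column_information(
            aln, col,
            small_sample_correction=small_sample_correction,
            gap_penalty=gap_penalty,
        )
        matrix.append({ltr: p * r for ltr, p in sorted(freqs.items())})
    return matrix


def map_columns_to_reference(aln: Alignment, reference_id: str) -> dict[int, int]:
    """Map alignment columns to 1-based residue numbers of the reference
    sequence; columns where the reference is gapped are unmapped."""
    try:
        ref_seq = aln.seqs[aln.ids.index(reference_id)]
    except ValueError as exc:
        raise KeyError(f"reference id {reference_id!r} not in alignment") from exc
    mapping: dict[int, int] = {}
    residue = 0
    for col, letter in enumerate(ref_seq):
        if letter == "-":
            continue
        residue += 1
        mapping[col] = residue
    return mapping


def conservation_track(
    aln: Alignment,
    reference_id: str,
    small_sample_correction: bool = False,
    gap_penalty: bool = False,
) -> ConservationTrack:
    """Per-residue conservation scores in the reference numbering."""
    mapping = map_columns_to_reference(aln, reference_id)
    scores: dict[int, float] = {}
    coverage: dict[int, float] = {}
    for col, residue in mapping.items():
        scores[residue] = column_information(
            aln, col,
            small_sample_correction=small_sample_correction,
            gap_penalty=gap_penalty,
        )
        coverage[residue] = column_coverage(aln, col)
    return ConservationTrack(scores=scores, coverage=coverage)


def write_scores_to_structure(
    pdb_path,
    chain: str,
    track: ConservationTrack,
    out_path,
) -> int:
    """Write per-residue scores into the B-factor columns of a PDB file.

    Only bytes 61-66 (1-based columns) of ATOM/HETATM records in the
    requested chain are replaced, formatted ``%6.2f``; every other byte
    round-trips unchanged.  Scores for residues absent from the chain
    warn; unparseable ATOM lines raise
    :class:`~phasekit.errors.StructureParseError` naming the line.
    Returns the number of rewritten records.
    """
    with open(pdb_path) as fh:
        lines = fh.readlines()

    seen_residues: set[int] = set()
    rewritten = 0
    out_lines: list[str] = []
    for lineno, line in enumerate(lines, start=1):
        if not line.startswith(("ATOM  ", "HETATM")):
            out_lines.append(line)
            continue
        stripped = line.rstrip("\n")
        if len(stripped) < 66:
            raise StructureParseError(
                f"line {lineno}: ATOM/HETATM record shorter than 66 columns"
            )
        try:
            res_seq = int(stripped[22:26])
        except ValueError as exc:
            raise StructureParseError(
                f"line {lineno}: cannot parse residue number "
                f"{stripped[22:26]!r}"
            ) from exc
        line_chain = stripped[21]
        if line_chain != chain or res_seq not in track.scores:
            if line_chain == chain:
                seen_residues.add(res_seq)
            out_lines.append(line)
            continue
        seen_residues.add(res_seq)
        bfac = f"{track.scores[res_seq]:6.2f}"
        if len(bfac) > 6:
            raise ValueError(f"score {track.scores[res_seq]} too wide for %6.2f")
        newline = stripped[:60] + bfac + stripped[66:]
        suffix = "\n" if line.endswith("\n") else ""
        out_lines.append(newline + suffix)
        rewritten += 1

    missing = sorted(set(track.scores) - seen_residues)
    if missing:
        warnings.warn(
            f"residues absent from chain {chain!r}: "
            f"{', '.join(map(str, missing))}",
            stacklevel=2,
        )
    with open(out_path, "w") as fh:
        fh.writelines(out_lines)
    return rewritten
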