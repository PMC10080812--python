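"""Reading and scaling of PSI-BLAST position-specific scoring matrices.

A PSSM produced by ``psiblast -out_ascii_pssm`` is an L x 20 matrix of
integer log-odds scores, one row per residue of the query sequence, with
columns in the fixed PSI-BLAST amino-acid order ``A R N D C Q E G H I L K M
F P S T W Y V``.  Everything downstream (feature extraction, classification)
operates on the sigmoid-scaled version of this matrix, whose entries lie in
the open interval (0, 1).

Rows are 1-based in the file and 0-based internally.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from Bio import SeqIO

#: Fixed amino-acid ordering of the 20 PSSM columns (PSI-BLAST convention).
AA_ORDER: str = "ARNDCQEGHILKMFPSTWYV"

#: IUPAC one-letter amino-acid codes, including ambiguity codes.
IUPAC_AA: frozenset[str] = frozenset("ACDEFGHIKLMNPQRSTVWYBZXJUO*")


class PssmParseError(ValueError):
    """Raised when an ASCII PSSM file cannot be parsed."""


@dataclass
class PssmProfile:
    """One protein's raw L x 20 log-odds matrix.

    Attributes
    ----------
    id : str
        Protein identifier.
    sequence : str
        Residue string of length L; ambiguity codes such as ``X`` are kept,
        since PSI-BLAST still emits a score row for them.
    scores : numpy.ndarray
        L x 20 array of log-odds values (integers in PSI-BLAST output,
        stored as floats).
    column_order : str
        Amino-acid ordering of the columns; always :data:`AA_ORDER`.
    """

    id: str
    sequence: str
    scores: np.ndarray
    column_order: str = AA_ORDER

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores, dtype=float)
        if self.scores.ndim != 2 or self.scores.shape[1] != 20:
            raise ValueError(
                f"PSSM must have exactly 20 score columns, got shape {self.scores.shape}"
            )
        if self.scores.shape[0] < 2:
            raise ValueError("PSSM needs at least 2 rows (dipeptide terms need two residues)")
        if len(self.sequence) != self.scores.shape[0]:
            raise ValueError(
                f"sequence length {len(self.sequence)} != matrix rows {self.scores.shape[0]}"
            )
        if self.column_order != AA_ORDER:
            raise ValueError(f"column_order must be {AA_ORDER!r}")

    @property
    def length(self) -> int:
        """Number of residues L."""
        return self.scores.shape[0]

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, PssmProfile):
            return NotImplemented
        return (
            self.id == other.id
            and self.sequence == other.sequence
            and np.array_equal(self.scores, other.scores)
        )


@dataclass
class ScaledPssm:
    """Sigmoid-mapped PSSM: every entry strictly inside (0, 1)."""

    id: str
    values: np.ndarray
    column_order: str = AA_ORDER

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2 or self.values.shape[1] != 20:
            raise ValueError(f"expected L x 20 matrix, got shape {self.values.shape}")

    @property
    def length(self) -> int:
        return self.values.shape[0]


def _try_parse_row(tokens: list[str]) -> tuple[int, str, list[float]] | None:
    """Interpret one whitespace-split line as a PSSM data row, else None.

    A data row is: position index, residue letter, then numeric columns.
    """
    if len(tokens) < 3:
        return None
    if not tokens[0].isdigit():
        return None
    if len(tokens[1]) != 1 or not tokens[1].isalpha():
        return None
    values: list[float] = []
    for tok in tokens[2:]:
        try:
            values.append(float(tok))
        except ValueError:
            return None
    return int(tokens[0]), tokens[1].upper(), values


def parse_pssm_ascii(source: str | Path, id: str | None = None) -> PssmProfile:
    """Parse an ASCII PSSM as written by ``psiblast -out_ascii_pssm``.

    Accepts both the 40-column dialect (20 log-odds + 20 weighted
    percentages, followed by two per-row statistics) and a bare 20-column
    dialect; the FIRST 20 numeric columns of each row are always taken as
    the log-odds scores.

    Parameters
    ----------
    source
        Path to a PSSM file, or the file's text content (anything containing
        a newline is treated as content).
    id
        Profile identifier; defaults to the file stem, or ``"pssm"`` for
        text input.

    Raises
    ------
    PssmParseError
        On rows with fewer than 20 numeric columns, inconsistent column
        counts, duplicate or non-consecutive position indices, or an empty
        matrix.
    """
    if isinstance(source, Path) or "\n" not in str(source):
        path = Path(source)
        text = path.read_text()
        profile_id = id if id is not None else path.stem
    else:
        text = str(source)
        profile_id = id if id is not None else "pssm"

    rows: list[list[float]] = []
    letters: list[str] = []
    seen_positions: set[int] = set()
    ncols: int | None = None

    for lineno, line in enumerate(text.splitlines(), start=1):
        parsed = _try_parse_row(line.split())
        if parsed is None:
            continue
        pos, letter, values = parsed
        if len(values) < 20:
            raise PssmParseError(
                f"line {lineno}: expected at least 20 numeric columns, found {len(values)}"
            )
        if ncols is None:
            ncols = len(values)
        elif len(values) != ncols:
            raise PssmParseError(
                f"line {lineno}: inconsistent column count {len(values)} (expected {ncols})"
            )
        if pos in seen_positions:
            raise PssmParseError(f"line {lineno}: duplicate position index {pos}")
        seen_positions.add(pos)
        rows.append(values[:20])
        letters.append(letter)

    if not rows:
        raise PssmParseError("no PSSM data rows found")
    if len(rows) < 2:
        raise PssmParseError("PSSM has fewer than 2 residue rows")

    return PssmProfile(id=profile_id, sequence="".join(letters), scores=np.array(rows))


def sigmoid_scale(profile: PssmProfile) -> ScaledPssm:
    """Map every log-odds entry x to 1/(1 + e^(-x)).

    The logistic sigmoid squashes the unbounded integer scores into (0, 1)
    so that composition and dipeptide features are commensurate across
    proteins.  Shape and column order are preserved.

    Raises
    ------
    ValueError
        If any entry is NaN or infinite.
    """
    x = profile.scores
    if not np.all(np.isfinite(x)):
        raise ValueError(f"profile {profile.id!r} contains non-finite scores")
    with np.errstate(over="ignore"):
        values = 1.0 / (1.0 + np.exp(-x))
    # float64 saturates to exactly 0/1 for |x| > ~37; clamp back into the
    # open interval so downstream (0,1) invariants hold for any finite score
    values = np.clip(values, np.nextafter(0.0, 1.0), np.nextafter(1.0, 0.0))
    return ScaledPssm(id=profile.id, values=values)


def read_fasta(path: str | Path) -> list[tuple[str, str]]:
    """Read a FASTA file into ``(id, sequence)`` pairs.

    IDs are the first whitespace-delimited token after ``>``; sequences are
    uppercased.  Residues outside the IUPAC amino-acid alphabet trigger a
    warning but are kept.
    """
    records: list[tuple[str, str]] = []
    for rec in SeqIO.parse(str(path), "fasta"):
        seq = str(rec.seq).upper()
        bad = sorted(set(seq) - IUPAC_AA)
        if bad:
            warnings.warn(
                f"record {rec.id!r}: non-IUPAC amino-acid characters {''.join(bad)!r}",
                stacklevel=2,
            )
        records.append((rec.id, seq))
    return records
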