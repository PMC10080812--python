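"""Synthetic labeled PSSM profiles for offline testing and benchmarking.

Real PSSM benchmark sets require a licensed protein dataset plus a
PSI-BLAST database, so this module emulates them: log-odds scores are drawn
as rounded Gaussians (mean 0), and the positive class receives a constant
mean shift on a designated subset of columns BEFORE sigmoid scaling, so the
class signal propagates through both the reduced-alphabet and the
composition/dipeptide feature families exactly as a real evolutionary
signal would.

What this emulates: class-dependent column statistics, integer scores,
variable sequence lengths, arbitrary class imbalance (including the
benchmark's 2533:9086 ratio).  What it does not: realistic inter-column
covariance of alignment-derived profiles, position autocorrelation, or any
actual amino-acid biochemistry — passing tests demonstrate pipeline
correctness, not real-data performance.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
from Bio.Seq import Seq
from Bio.SeqIO import write as seqio_write
from Bio.SeqRecord import SeqRecord

from .pssm_io import AA_ORDER, PssmProfile


@dataclass(frozen=True)
class SimulationSpec:
    """Conditions of a simulated binary PSSM classification problem.

    Parameters
    ----------
    n_pos, n_neg
        Sample counts per class.
    length_range
        Inclusive (min, max) protein length L; min must be >= 2.
    effect_size
        Mean log-odds shift added to ``signal_columns`` for the positive
        class, in raw (pre-sigmoid) score units; 0 means no class signal.
    signal_columns
        0-based indices (into the A..V column order) of shifted columns.
    noise_sd
        Standard deviation of the Gaussian score noise, in score units.
    seed
        Base seed for all randomness.
    """

    n_pos: int = 150
    n_neg: int = 150
    length_range: tuple[int, int] = (30, 80)
    effect_size: float = 2.0
    signal_columns: tuple[int, ...] = (0, 1, 2, 3)
    noise_sd: float = 2.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.effect_size < 0:
            raise ValueError("effect_size must be >= 0")
        if self.length_range[0] < 2 or self.length_range[0] > self.length_range[1]:
            raise ValueError("length_range min must be >= 2 and <= max")
        if not set(self.signal_columns) <= set(range(20)):
            raise ValueError("signal_columns must be 0-based indices into the 20 columns")


def gen_profile(
    L: int,
    class_label: int,
    spec: SimulationSpec,
    rng: np.random.Generator | None = None,
    id: str = "synthetic",
) -> PssmProfile:
    """Draw one synthetic profile of length L.

    Scores are Gaussian with mean 0 (plus ``effect_size`` on the signal
    columns when ``class_label`` is positive), rounded to integers to mimic
    PSI-BLAST output.  Each residue letter is the amino acid of its row's
    highest-scoring column, for plausibility only — downstream features
    never read the sequence.
    """
    rng = rng if rng is not None else np.random.default_rng(spec.seed)
    mean = np.zeros(20)
    if class_label == 1 and spec.signal_columns:
        mean[list(spec.signal_columns)] = spec.effect_size
    scores = np.rint(rng.normal(loc=mean, scale=spec.noise_sd, size=(L, 20)))
    sequence = "".join(AA_ORDER[j] for j in scores.argmax(axis=1))
    return PssmProfile(id=id, sequence=sequence, scores=scores)


def gen_dataset(spec: SimulationSpec) -> tuple[list[PssmProfile], dict[str, int]]:
    """Generate ``n_pos + n_neg`` labeled profiles, reproducible by seed.

    Returns ``(profiles, labels)`` with labels keyed by profile ID.
    """
    rng = np.random.default_rng(spec.seed)
    lo, hi = spec.length_range
    profiles: list[PssmProfile] = []
    labels: dict[str, int] = {}
    for label, count, prefix in ((1, spec.n_pos, "pos"), (0, spec.n_neg, "neg")):
        for i in range(count):
            L = int(rng.integers(lo, hi + 1))
            pid = f"{prefix}_{i:05d}"
            profiles.append(gen_profile(L, label, spec, rng=rng, id=pid))
            labels[pid] = label
    return profiles, labels


def gen_ascii_pssm(
    profile: PssmProfile, path: str | Path | None = None, wide: bool = False
) -> str:
    """Render a profile in the PSI-BLAST ``-out_ascii_pssm`` dialect.

    ``wide=True`` writes the 40-column variant (log-odds followed by 20
    weighted-percentage columns and two per-row statistics), used to test
    that parsers keep only the first 20 numeric columns.  Parsing the
    output reproduces the profile exactly.
    """
    header = AA_ORDER if not wide else AA_ORDER + AA_ORDER
    lines = [
        "",
        "Last position-specific scoring matrix computed, weighted observed percentages"
        " rounded down, information per position, and relative weight of gapped matches",
        "            " + "  ".join(header),
    ]
    for i in range(profile.length):
        cells = "".join(f"{int(v):4d}" for v in profile.scores[i])
        line = f"{i + 1:5d} {profile.sequence[i]} {cells}"
        if wide:
            pct = "".join(f"{0:4d}" for _ in range(20))
            line += pct + f"  {0.36:.2f} {1.00:.2f}"
        lines.append(line)
    lines += ["", "                      K         Lambda", "Standard Ungapped    0.1337     0.3176", ""]
    text = "\n".join(lines)
    if path is not None:
        Path(path).write_text(text)
    return text


def gen_fasta(records: list[tuple[str, str]], path: str | Path) -> None:
    """Write ``(id, sequence)`` pairs as FASTA (60-character line wrap)."""
    seq_records = [SeqRecord(Seq(seq), id=rid, description="") for rid, seq in records]
    with open(path, "w") as fh:
        seqio_write(seq_records, fh, "fasta")
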