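"""Circularization nucleotide-bias analysis for a single-strand DNA ligase.

The substrate library carries seven randomized nucleotides on each side of
the eventual ligation junction (acceptor block N7a on the 5'-phosphate side,
donor block N7b on the 3'-hydroxyl side).  After circularization, RNase A
re-linearization at the single ribonucleotide, PCR and sequencing, the 14
randomized positions appear at the start of Read1 as
``revcomp(N7a) + revcomp(N7b)`` followed by the 21-mer adapter anchor.

This module recovers the randomized window from each read, maps it back to
the original donor/acceptor orientation, and computes positional nucleotide
frequencies and the 16 junction dinucleotide frequencies against the uniform
null (100/16 = 6.25% per dinucleotide).  A Pearson chi-square goodness-of-fit
against uniformity is provided as a convenience on top of the descriptive
percentages.

Reporting orientation: positions are labeled -7..-1 (donor block, 5'->3')
and +1..+7 (acceptor block) in ORIGINAL substrate orientation; the junction
dinucleotide is (donor last base, acceptor first base), written 5'->3'
across the sealed junction.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .io import ReadRecord
from .oligo import revcomp

ADAPTER_ANCHOR = "AGATCGGAAGAGCACACGTCT"

#: position labels in original orientation: donor -7..-1 then acceptor +1..+7
POSITION_LABELS = tuple(range(-7, 0)) + tuple(range(1, 8))

DINUCLEOTIDES = tuple(d + a for d in "ACGT" for a in "ACGT")

EXPECTED_UNIFORM_PCT = 100.0 / 16  # 6.25


@dataclass(frozen=True)
class JunctionWindow:
    """The 14 recovered randomized bases in both orientations."""

    read_window: str      # bases 1-14 of the read
    donor_block: str      # N7b, original orientation
    acceptor_block: str   # N7a, original orientation

    @property
    def junction(self) -> str:
        return self.donor_block[-1] + self.acceptor_block[0]


def to_original_orientation(read_window: str) -> tuple[str, str]:
    """Map a 14-base read window to (donor N7b, acceptor N7a) blocks.

    Read bases 1-7 are the reverse complement of the acceptor block and
    bases 8-14 the reverse complement of the donor block — the composition
    of circularization at the N7b->N7a junction, re-linearization at the
    ribonucleotide, and sense-strand sequencing.
    """
    if len(read_window) != 14:
        raise ValueError("junction window must be exactly 14 bases")
    bad = set(read_window) - set("ACGT")
    if bad:
        raise ValueError(f"non-ACGT base in window: {sorted(bad)}")
    acceptor = revcomp(read_window[:7])
    donor = revcomp(read_window[7:])
    return donor, acceptor


def locate_window(read: ReadRecord, adapter_anchor: str = ADAPTER_ANCHOR,
                  max_mismatches: int = 1, min_phred: int = 20
                  ) -> JunctionWindow | None:
    """Extract the randomized window from a bias-library read, or None.

    Accepts reads whose bases 15-26 match the anchor's first 12 bases with
    at most ``max_mismatches`` mismatches and whose 14 window bases all have
    Phred >= ``min_phred``.
    """
    if len(read.sequence) < 35:
        return None
    probe = adapter_anchor[:12]
    window = read.sequence[:14]
    anchor_region = read.sequence[14:26]
    mm = sum(a != b for a, b in zip(anchor_region, probe))
    if mm > max_mismatches:
        return None
    if any(q < min_phred for q in read.quals[:14]):
        return None
    if set(window) - set("ACGT"):
        return None
    donor, acceptor = to_original_orientation(window)
    return JunctionWindow(window, donor, acceptor)


@dataclass
class PositionalFreqMatrix:
    """Base percentages at the 14 randomized positions (original orientation)."""

    matrix: dict[int, dict[str, float]]  # label -> base -> %
    n: int

    def min_max(self) -> tuple[float, float]:
        vals = [v for row in self.matrix.values() for v in row.values()]
        return min(vals), max(vals)

    def as_rows(self):
        for label in POSITION_LABELS:
            row = self.matrix[label]
            yield (label, row["A"], row["C"], row["G"], row["T"])


def positional_frequencies(windows: list[JunctionWindow]) -> PositionalFreqMatrix:
    """Per-position base percentages over all accepted windows."""
    if not windows:
        raise ValueError("no windows to tabulate")
    n = len(windows)
    matrix: dict[int, dict[str, float]] = {}
    for i, label in enumerate(POSITION_LABELS):
        counts = Counter()
        if label < 0:   # donor block positions -7..-1 = N7b bases 1..7
            j = label + 7
            for w in windows:
                counts[w.donor_block[j]] += 1
        else:           # acceptor block positions +1..+7 = N7a bases 1..7
            j = label - 1
            for w in windows:
                counts[w.acceptor_block[j]] += 1
        matrix[label] = {b: 100.0 * counts.get(b, 0) / n for b in "ACGT"}
    return PositionalFreqMatrix(matrix, n)


def junction_dinucleotides(windows: list[JunctionWindow]
                           ) -> dict[str, tuple[int, float]]:
    """Counts and percentages of the 16 junction dinucleotides (zeros kept)."""
    if not windows:
        raise ValueError("no windows to tabulate")
    n = len(windows)
    counts = Counter(w.junction for w in windows)
    return {d: (counts.get(d, 0), 100.0 * counts.get(d, 0) / n)
            for d in DINUCLEOTIDES}


def uniformity_test(counts) -> tuple[float, float]:
    """Pearson goodness-of-fit of category counts against uniformity.

    Degrees of freedom = categories - 1.  Returns (statistic, p-value).
    """
    counts = np.asarray(list(counts), dtype=float)
    if np.any(counts < 0):
        raise ValueError("counts must be >= 0")
    total = counts.sum()
    if total == 0:
        raise ValueError("cannot test an empty table")
    stat, p = stats.chisquare(counts)
    return float(stat), float(p)


@dataclass
class BiasReport:
    """Positional matrix, dinucleotide table, and uniformity statistics."""

    positional: PositionalFreqMatrix
    dinucleotides: dict[str, tuple[int, float]]
    expected_uniform_pct: float
    positional_min_pct: float
    positional_max_pct: float
    positional_tests: dict[int, tuple[float, float]]  # label -> (chi2, p)
    dinucleotide_test: tuple[float, float]
    n: int

    def as_dict(self) -> dict:
        return {
            "n": self.n,
            "expected_uniform_pct": self.expected_uniform_pct,
            "positional_pct": {
                str(k): v for k, v in self.positional.matrix.items()
            },
            "positional_min_pct": self.positional_min_pct,
            "positional_max_pct": self.positional_max_pct,
            "dinucleotide_pct": {d: pct for d, (_, pct) in
                                 self.dinucleotides.items()},
            "dinucleotide_counts": {d: c for d, (c, _) in
                                    self.dinucleotides.items()},
            "positional_chi2": {
                str(k): {"statistic": s, "p_value": p}
                for k, (s, p) in self.positional_tests.items()
            },
            "dinucleotide_chi2": {
                "statistic": self.dinucleotide_test[0],
                "p_value": self.dinucleotide_test[1],
            },
        }


def bias_report(windows: list[JunctionWindow]) -> BiasReport:
    """Assemble the full bias report from accepted windows."""
    matrix = positional_frequencies(windows)
    dinucs = junction_dinucleotides(windows)
    n = matrix.n
    pos_tests = {}
    for label in POSITION_LABELS:
        row = matrix.matrix[label]
        counts = [round(row[b] * n / 100.0) for b in "ACGT"]
        pos_tests[label] = uniformity_test(counts)
    dinuc_test = uniformity_test([c for c, _ in dinucs.values()])
    lo, hi = matrix.min_max()
    return BiasReport(
        positional=matrix,
        dinucleotides=dinucs,
        expected_uniform_pct=EXPECTED_UNIFORM_PCT,
        positional_min_pct=lo,
        positional_max_pct=hi,
        positional_tests=pos_tests,
        dinucleotide_test=dinuc_test,
        n=n,
    )


def run_ligbias(reads, *, adapter_anchor: str = ADAPTER_ANCHOR,
                max_mismatches: int = 1, min_phred: int = 20
                ) -> tuple[BiasReport, dict]:
    """Extract windows from reads and build the bias report.

    Returns (report, stage ledger dict with input/accepted counts).
    """
    n_in, windows = 0, []
    for read in reads:
        n_in += 1
        w = locate_window(read, adapter_anchor, max_mismatches, min_phred)
        if w is not None:
            windows.append(w)
    ledger = {"stage": "locate_window", "input": n_in,
              "retained": len(windows), "rejected": n_in - len(windows)}
    return bias_report(windows), ledger
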