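"""Transcript 5'/3' end-heterogeneity analysis for circular templates.

Reads from a single-adapter circularization library are adapter-trimmed,
stripped of the single dC added during library preparation, size-selected to
the monomer transcript range, and their terminal 20-mers extracted, quality
filtered (every base Phred >= 20), collapsed, and mapped back onto the
circular template to give per-position transcription initiation and
termination percentages.  Percentages are computed against the
quality-filtered reference totals; raw counts are carried alongside so
alternative denominators can be recomputed.

Mapping convention: the transcript 5'->3' walks the written template strand
in descending index order, so a 5'-end k-mer maps to the template position
pairing with the transcript's first base (initiation site) and a 3'-end
k-mer — already reverse complemented, hence running ascending in template
space — maps to the position pairing with the last base (termination site).
The first base of a 5'-end k-mer may mismatch the template; such reads are
kept and classed as non-templated with the observed base.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from functools import lru_cache

from .io import ReadRecord
from .oligo import CircularTemplate, circular_slice, revcomp

ADAPTER3_CORE = "AGATCGGAAGAGCACACGTCT"

_DNA_COMP = str.maketrans("ACGTN", "TGCAN")


@dataclass
class StageCount:
    """One ledger row: counts in, counts retained, rejects by reason."""

    stage: str
    input: int
    retained: int
    rejects: dict[str, int] = field(default_factory=dict)

    @property
    def fraction(self) -> float:
        return self.retained / self.input if self.input else 0.0

    def as_dict(self) -> dict:
        return {"stage": self.stage, "input": self.input,
                "retained": self.retained, "fraction": self.fraction,
                "rejects": self.rejects}


@dataclass(frozen=True)
class Insert:
    """A read insert (adapter removed) with its per-base qualities."""

    sequence: str
    quals: tuple[int, ...]

    def __len__(self) -> int:
        return len(self.sequence)


def trim_adapter(read: ReadRecord, anchor: str = ADAPTER3_CORE,
                 max_mismatches: int = 1) -> Insert | None:
    """Locate the adapter and return the insert before it, or None.

    The leftmost occurrence of the anchor's first 12 bases, allowing at most
    ``max_mismatches`` mismatches, marks the insert end.  The insert keeps
    the terminal dC added during library preparation.
    """
    if len(anchor) < 12:
        raise ValueError("adapter anchor must be at least 12 bases")
    probe = anchor[:12]
    seq = read.sequence
    # exact match is the overwhelmingly common case; scan only on miss
    pos = seq.find(probe)
    if pos < 0 and max_mismatches > 0:
        for i in range(len(seq) - 12 + 1):
            mm = 0
            window = seq[i:i + 12]
            for a, b in zip(window, probe):
                if a != b:
                    mm += 1
                    if mm > max_mismatches:
                        break
            else:
                pos = i
                break
    if pos < 0:
        return None
    return Insert(seq[:pos], read.quals[:pos])


def strip_terminal_c(insert: Insert) -> tuple[Insert, bool]:
    """Remove the single 3'-terminal dC; returns (trimmed, flagged).

    ``flagged`` is True when the removed base was not a C — the read is
    still trimmed but counted in a diagnostics channel.
    """
    if len(insert) == 0:
        raise ValueError("cannot strip the terminal base of an empty insert")
    flagged = insert.sequence[-1] != "C"
    return Insert(insert.sequence[:-1], insert.quals[:-1]), flagged


def size_select(inserts: list[Insert], lo: int = 60, hi: int = 71
                ) -> tuple[list[Insert], StageCount]:
    """Retain inserts with lo <= length <= hi (inclusive on both ends)."""
    if lo > hi:
        raise ValueError(f"size range [{lo}, {hi}] is empty")
    kept = [ins for ins in inserts if lo <= len(ins) <= hi]
    sc = StageCount("size_select", len(inserts), len(kept),
                    {"out_of_range": len(inserts) - len(kept)})
    return kept, sc


def extract_end_kmers(inserts: list[Insert], end_type: str, k: int = 20
                      ) -> tuple[list[Insert], StageCount]:
    """Terminal k-mers: 5' = first k bases; 3' = first k of the revcomp.

    Qualities follow the bases (reversed for the 3' side).  Inserts shorter
    than k are rejected and counted.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    if end_type not in ("five_prime", "three_prime"):
        raise ValueError(f"unknown end_type {end_type!r}")
    out, short = [], 0
    for ins in inserts:
        if len(ins) < k:
            short += 1
            continue
        if end_type == "five_prime":
            out.append(Insert(ins.sequence[:k], ins.quals[:k]))
        else:
            rc = revcomp(ins.sequence)
            out.append(Insert(rc[:k], ins.quals[::-1][:k]))
    sc = StageCount(f"extract_{end_type}_kmers", len(inserts), len(out),
                    {"shorter_than_k": short})
    return out, sc


def quality_filter(kmers: list[Insert], min_phred: int = 20
                   ) -> tuple[list[Insert], StageCount]:
    """Retain k-mers in which EVERY base has Phred >= ``min_phred``."""
    kept = [km for km in kmers if all(q >= min_phred for q in km.quals)]
    sc = StageCount("quality_filter", len(kmers), len(kept),
                    {"low_quality": len(kmers) - len(kept)})
    return kept, sc


def collapse(sequences: list[str]) -> list[tuple[str, int, float]]:
    """Collapse identical sequences to (sequence, count, percentage) rows.

    Sorted by count descending, ties broken lexicographically; percentages
    are against the input size.
    """
    n = len(sequences)
    counts = Counter(sequences)
    rows = sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))
    return [(seq, c, 100.0 * c / n) for seq, c in rows]


@lru_cache(maxsize=32)
def _five_prime_index(template: CircularTemplate, k: int):
    """Map sense-strand (k-1)-mer cores (positions 2..k) -> start positions."""
    idx: dict[str, list[int]] = {}
    full: dict[int, str] = {}
    for s in range(1, template.length + 1):
        sense = circular_slice(template, s, k, "descending").translate(_DNA_COMP)
        full[s] = sense
        idx.setdefault(sense[1:], []).append(s)
    return idx, full


@lru_cache(maxsize=32)
def _three_prime_index(template: CircularTemplate, k: int):
    """Map ascending template k-mers -> stop positions."""
    idx: dict[str, list[int]] = {}
    for t in range(1, template.length + 1):
        idx.setdefault(circular_slice(template, t, k, "ascending"), []).append(t)
    return idx


def map_end_to_template(kmer: str, template: CircularTemplate, end_type: str
                        ) -> tuple[int | None, str]:
    """Map a terminal k-mer to a template position.

    5' k-mers must match the transcript sense strand exactly at positions
    2..k; position 1 may mismatch and is then classed ``nontemplated:<base>``.
    3' k-mers (already reverse complemented) must match the template read
    ascending over all k positions.  Returns ``(position, class)`` where
    class is ``templated``, ``nontemplated:<base>``, ``ambiguous`` or
    ``unmapped`` (position None for the last two).
    """
    if len(kmer) < 12:
        raise ValueError("k-mers shorter than 12 are not uniquely mappable")
    bad = set(kmer) - set("ACGTN")
    if bad:
        raise ValueError(f"non-ACGTN characters in k-mer: {sorted(bad)}")
    if end_type == "five_prime":
        idx, full = _five_prime_index(template, len(kmer))
        hits = idx.get(kmer[1:], [])
        if not hits:
            return None, "unmapped"
        if len(hits) > 1:
            return None, "ambiguous"
        pos = hits[0]
        if full[pos][0] == kmer[0]:
            return pos, "templated"
        return pos, f"nontemplated:{kmer[0]}"
    if end_type == "three_prime":
        idx = _three_prime_index(template, len(kmer))
        hits = idx.get(kmer, [])
        if not hits:
            return None, "unmapped"
        if len(hits) > 1:
            return None, "ambiguous"
        return hits[0], "templated"
    raise ValueError(f"unknown end_type {end_type!r}")


@dataclass
class EndKmerTable:
    """Collapsed terminal k-mers with counts and reference percentages."""

    end_type: str
    k: int
    reference_total: int
    rows: list[tuple[str, int, float]]


@dataclass
class EndMapReport:
    """Aggregated initiation/termination map and stage ledger."""

    template_name: str
    stage_counts: list[StageCount]
    initiation: dict[int, float]          # position -> % of 5' reference total
    termination: dict[int, float]         # position -> % of 3' reference total
    excluded_initiation_pct: float        # mass below threshold or unmapped
    excluded_termination_pct: float
    nontemplated_first_base: dict[int, dict[str, float]]  # pos -> base -> %
    top_reads: list[tuple[str, int, float]]
    top_reads_total_pct: float
    read_length_hist: dict[int, int]
    five_prime_table: EndKmerTable
    three_prime_table: EndKmerTable
    threshold_pct: float

    def as_dict(self) -> dict:
        return {
            "template": self.template_name,
            "stages": [sc.as_dict() for sc in self.stage_counts],
            "initiation_pct": self.initiation,
            "termination_pct": self.termination,
            "excluded_initiation_pct": self.excluded_initiation_pct,
            "excluded_termination_pct": self.excluded_termination_pct,
            "nontemplated_first_base_pct": self.nontemplated_first_base,
            "top_reads": [
                {"sequence": s, "count": c, "pct": p} for s, c, p in self.top_reads
            ],
            "top_reads_total_pct": self.top_reads_total_pct,
            "read_length_hist": self.read_length_hist,
            "threshold_pct": self.threshold_pct,
        }


def _positional_percentages(kmer_rows, template, end_type, reference_total,
                            threshold_pct):
    """Aggregate collapsed k-mer rows into per-position percentage maps."""
    by_pos: dict[int, float] = {}
    nontemplated: dict[int, dict[str, float]] = {}
    unassigned = 0.0
    for seq, count, _ in kmer_rows:
        pct = 100.0 * count / reference_total
        pos, cls = map_end_to_template(seq, template, end_type)
        if pos is None:
            unassigned += pct
            continue
        by_pos[pos] = by_pos.get(pos, 0.0) + pct
        if cls.startswith("nontemplated:"):
            base = cls.split(":", 1)[1]
            nontemplated.setdefault(pos, {})
            nontemplated[pos][base] = nontemplated[pos].get(base, 0.0) + pct
    reported = {p: v for p, v in sorted(by_pos.items()) if v >= threshold_pct}
    excluded = unassigned + sum(v for p, v in by_pos.items() if p not in reported)
    return reported, excluded, nontemplated


def end_map_report(reads, template: CircularTemplate, *,
                   anchor: str = ADAPTER3_CORE, k: int = 20,
                   min_phred: int = 20, lo: int = 60, hi: int = 71,
                   threshold_pct: float = 1.0, top_k: int = 10) -> EndMapReport:
    """Run the full end-heterogeneity analysis on an iterable of reads."""
    stage_counts: list[StageCount] = []

    inserts, n_in, n_noadapter, n_empty = [], 0, 0, 0
    for read in reads:
        n_in += 1
        ins = trim_adapter(read, anchor)
        if ins is None:
            n_noadapter += 1
        elif len(ins) == 0:
            n_empty += 1
        else:
            inserts.append(ins)
    stage_counts.append(StageCount(
        "adapter_trim", n_in, len(inserts),
        {"no_adapter": n_noadapter, "empty_insert": n_empty},
    ))

    # read-length histogram: after adapter trimming, before dC stripping
    hist = Counter(len(ins) for ins in inserts)

    stripped, flagged = [], 0
    for ins in inserts:
        trimmed, flag = strip_terminal_c(ins)
        flagged += flag
        stripped.append(trimmed)
    stage_counts.append(StageCount(
        "strip_terminal_c", len(inserts), len(stripped),
        {"non_c_terminal_flagged": flagged},
    ))

    selected, sc = size_select(stripped, lo, hi)
    stage_counts.append(sc)

    five, sc5e = extract_end_kmers(selected, "five_prime", k)
    five, sc5q = quality_filter(five, min_phred)
    three, sc3e = extract_end_kmers(selected, "three_prime", k)
    three, sc3q = quality_filter(three, min_phred)
    sc5q.stage, sc3q.stage = "quality_filter_five_prime", "quality_filter_three_prime"
    stage_counts += [sc5e, sc5q, sc3e, sc3q]

    five_rows = collapse([km.sequence for km in five])
    three_rows = collapse([km.sequence for km in three])
    five_table = EndKmerTable("five_prime", k, len(five), five_rows)
    three_table = EndKmerTable("three_prime", k, len(three), three_rows)

    if five:
        initiation, excl5, nontemplated = _positional_percentages(
            five_rows, template, "five_prime", len(five), threshold_pct)
    else:
        initiation, excl5, nontemplated = {}, 0.0, {}
    if three:
        termination, excl3, _ = _positional_percentages(
            three_rows, template, "three_prime", len(three), threshold_pct)
    else:
        termination, excl3 = {}, 0.0

    whole_rows = collapse([ins.sequence for ins in selected])
    top = whole_rows[:top_k]
    return EndMapReport(
        template_name=template.name,
        stage_counts=stage_counts,
        initiation=initiation,
        termination=termination,
        excluded_initiation_pct=excl5,
        excluded_termination_pct=excl3,
        nontemplated_first_base=nontemplated,
        top_reads=top,
        top_reads_total_pct=sum(r[2] for r in top),
        read_length_hist=dict(sorted(hist.items())),
        five_prime_table=five_table,
        three_prime_table=three_table,
        threshold_pct=threshold_pct,
    )
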