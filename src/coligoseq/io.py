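"""FASTQ records, streaming I/O, flat config files, and run manifests.

Reads are Sanger Phred+33, 4-line records.  Parsing goes through Biopython's
low-level FASTQ iterator; records are re-validated so that a malformed
record raises an error naming its position.  Writing is deterministic:
records are emitted in input order and byte-identical across runs.
"""

from __future__ import annotations

import gzip
import json
from dataclasses import dataclass
from typing import Iterable, Iterator

from Bio.SeqIO.QualityIO import FastqGeneralIterator

PHRED_OFFSET = 33


@dataclass(frozen=True)
class ReadRecord:
    """A sequencing read: id line (without @), bases, per-base Phred scores."""

    id: str
    sequence: str
    quals: tuple[int, ...]

    def __post_init__(self):
        if len(self.sequence) != len(self.quals):
            raise ValueError(
                f"read {self.id}: sequence length {len(self.sequence)} != "
                f"quality length {len(self.quals)}"
            )

    @property
    def qual_string(self) -> str:
        return "".join(chr(q + PHRED_OFFSET) for q in self.quals)


def decode_quals(qual_string: str) -> tuple[int, ...]:
    return tuple(ord(c) - PHRED_OFFSET for c in qual_string)


def _open(path, mode: str):
    if str(path).endswith(".gz"):
        return gzip.open(path, mode + "t")
    return open(path, mode)


def read_fastq(path) -> Iterator[ReadRecord]:
    """Lazily yield :class:`ReadRecord` from a (optionally gzipped) FASTQ file."""
    with _open(path, "r") as fh:
        it = FastqGeneralIterator(fh)
        n = 0
        while True:
            try:
                title, seq, qual = next(it)
            except StopIteration:
                return
            except ValueError as exc:
                raise ValueError(f"{path}: malformed record {n + 1}: {exc}") from exc
            n += 1
            if len(seq) != len(qual):
                raise ValueError(
                    f"{path}: record {n} ({title}): sequence/quality length mismatch"
                )
            yield ReadRecord(title, seq, decode_quals(qual))


def write_fastq(records: Iterable[ReadRecord], path) -> int:
    """Write records as 4-line Phred+33 FASTQ; returns the record count."""
    n = 0
    with _open(path, "w") as fh:
        for rec in records:
            fh.write(f"@{rec.id}\n{rec.sequence}\n+\n{rec.qual_string}\n")
            n += 1
    return n


def write_truth_table(reads, path) -> None:
    """Write the ground-truth channel parsed from simulated read ids as TSV."""
    with open(path, "w") as fh:
        fh.write("read_id\tspecies\tstart\tstop\tlaps\tclass\n")
        for rec in reads:
            t = parse_truth_id(rec.id)
            fh.write(
                "{id}\t{species}\t{start}\t{stop}\t{laps}\t{cls}\n".format(**t)
            )


def make_truth_id(i: int, species: str, start, stop, laps, cls: str) -> str:
    """Encode ground truth in a read id (``|`` separated key=value)."""
    return (
        f"sim{i}|species={species}|start={start}|stop={stop}|laps={laps}|class={cls}"
    )


def parse_truth_id(read_id: str) -> dict:
    fields = read_id.split("|")
    out = {"id": fields[0], "species": "", "start": "", "stop": "", "laps": "",
           "cls": ""}
    for f in fields[1:]:
        k, _, v = f.partition("=")
        out[{"class": "cls"}.get(k, k)] = v
    return out


def read_flat_config(path) -> dict[str, str]:
    """Read a flat ``key=value`` config file; '#' starts a comment line."""
    out: dict[str, str] = {}
    with open(path) as fh:
        for ln in fh:
            ln = ln.strip()
            if not ln or ln.startswith("#"):
                continue
            if "=" not in ln:
                raise ValueError(f"{path}: malformed config line: {ln!r}")
            k, _, v = ln.partition("=")
            out[k.strip()] = v.strip()
    return out


def write_flat_config(config: dict, path) -> None:
    with open(path, "w") as fh:
        for k, v in config.items():
            fh.write(f"{k}={v}\n")


def write_manifest(path, *, command: str, config: dict, seed, stage_counts=None):
    """Write the run manifest: command, config, seed, version, stage ledger."""
    from coligoseq import __version__

    payload = {
        "command": command,
        "version": __version__,
        "seed": seed,
        "config": config,
        "stages": stage_counts or [],
    }
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2, default=str)
        fh.write("\n")
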