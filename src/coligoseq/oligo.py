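"""Synthetic oligonucleotide notation and circular template coordinates.

Vendors describe custom oligos in a compact inline notation: an optional 5'
end-modification token (``p`` monophosphate, ``App`` pre-adenylylated), a run
of base letters where each base may carry an ``r`` prefix marking a
ribonucleotide, ``N`` for a hand-mixed random position, and an optional 3'
``-R-NH2`` amino blocking group.  This module parses that notation into typed
records, renders it back canonically, validates a packaged catalog of oligos
against their declared lengths, and provides circular-coordinate utilities
for the coligo templates (circularized single-stranded DNA transcription
templates, template strand only, 1-based positions on the written strand).

Two extra tokens beyond the vendor notation keep parse/render total over the
end-modification enums used elsewhere in the package: ``ppp`` (5'
triphosphate, as found on primary polymerase transcripts) and ``-cP``
(2',3'-cyclic phosphate, the mark RNase A leaves at a cleavage site).
"""

from __future__ import annotations

import logging
import unicodedata
from dataclasses import dataclass, field
from importlib import resources
from typing import Iterable, Literal

log = logging.getLogger(__name__)

Base = Literal["A", "C", "G", "T", "U", "N"]
Sugar = Literal["deoxy", "ribo"]
FivePrime = Literal["hydroxyl", "monophosphate", "triphosphate", "adenylyl"]
ThreePrime = Literal["hydroxyl", "amino_blocker", "cyclic_phosphate"]

_BASES = frozenset("ACGTUN")

_FIVE_TOKENS = {"ppp": "triphosphate", "App": "adenylyl", "p": "monophosphate"}
_FIVE_RENDER = {v: k for k, v in _FIVE_TOKENS.items()} | {"hydroxyl": ""}
_THREE_TOKENS = {"-R-NH2": "amino_blocker", "-cP": "cyclic_phosphate"}
_THREE_RENDER = {v: k for k, v in _THREE_TOKENS.items()} | {"hydroxyl": ""}

_DNA_COMP = str.maketrans("ACGTN", "TGCAN")
_RNA_COMP = str.maketrans("ACGUN", "UGCAN")


class OligoParseError(ValueError):
    """Raised when an oligo notation string cannot be parsed."""


@dataclass(frozen=True)
class Residue:
    """One position of an oligo: base identity plus sugar."""

    base: Base
    sugar: Sugar = "deoxy"


@dataclass(frozen=True)
class OligoSpec:
    """A parsed oligo: ordered residues (5'->3') and end modifications."""

    name: str
    residues: tuple[Residue, ...]
    five_prime: FivePrime = "hydroxyl"
    three_prime: ThreePrime = "hydroxyl"

    def __len__(self) -> int:
        return len(self.residues)

    @property
    def sequence(self) -> str:
        """Plain base string, 5'->3', ignoring sugar and end marks."""
        return "".join(r.base for r in self.residues)

    @property
    def ribo_positions(self) -> tuple[int, ...]:
        """1-based positions of ribonucleotide residues."""
        return tuple(i + 1 for i, r in enumerate(self.residues) if r.sugar == "ribo")

    def realize(self, rng) -> str:
        """Replace each N with a uniformly random deoxy base; return the sequence."""
        out = []
        for r in self.residues:
            out.append("ACGT"[rng.integers(4)] if r.base == "N" else r.base)
        return "".join(out)


def parse_oligo_notation(notation: str, name: str = "") -> OligoSpec:
    """Parse vendor-style oligo notation into an :class:`OligoSpec`.

    Both the typographic apostrophe and the ASCII one are accepted in the
    leading ``5'``; input is NFC-normalized first.  Stray digits or other
    unrecognized single characters inside the body are skipped with a logged
    warning (they occur as typographic artifacts in printed tables) and do
    not count as residues.  An unrecognized multi-character token is an
    error naming its offset.
    """
    text = unicodedata.normalize("NFC", notation).strip().replace("’", "'")
    if not text.startswith("5'"):
        raise OligoParseError(f"{name or 'oligo'}: notation must begin with 5'")
    body = text[2:]

    five: FivePrime = "hydroxyl"
    for tok, mod in _FIVE_TOKENS.items():
        # 'p' only counts as a modification token, not a base; 'App' first
        # so its leading A is not taken as a residue.
        if body.startswith(tok):
            five, body = mod, body[len(tok):]
            break

    three: ThreePrime = "hydroxyl"
    for tok, mod in _THREE_TOKENS.items():
        if body.endswith(tok):
            three, body = mod, body[: -len(tok)]
            break

    residues: list[Residue] = []
    i = 0
    while i < len(body):
        ch = body[i]
        if ch == "r":
            if i + 1 >= len(body) or body[i + 1] not in _BASES:
                raise OligoParseError(
                    f"{name or 'oligo'}: dangling 'r' token at offset {i}"
                )
            residues.append(Residue(body[i + 1], "ribo"))
            i += 2
        elif ch in _BASES:
            residues.append(Residue(ch, "deoxy"))
            i += 1
        elif ch == "-":
            raise OligoParseError(
                f"{name or 'oligo'}: unknown token starting at offset {i}: "
                f"{body[i:i + 8]!r}"
            )
        else:
            log.warning(
                "%s: skipping unrecognized character %r at offset %d",
                name or "oligo", ch, i,
            )
            i += 1
    if not residues:
        raise OligoParseError(f"{name or 'oligo'}: empty body")
    return OligoSpec(name, tuple(residues), five, three)


def render_oligo(spec: OligoSpec) -> str:
    """Render canonical notation such that ``parse(render(x)) == x``."""
    parts = ["5'", _FIVE_RENDER[spec.five_prime]]
    for r in spec.residues:
        if r.sugar == "ribo":
            parts.append("r")
        parts.append(r.base)
    parts.append(_THREE_RENDER[spec.three_prime])
    return "".join(parts)


def revcomp(seq: str, alphabet: str = "DNA") -> str:
    """Reverse complement of ``seq`` over DNA (ACGTN) or RNA (ACGUN)."""
    table = _DNA_COMP if alphabet == "DNA" else _RNA_COMP
    allowed = "ACGTN" if alphabet == "DNA" else "ACGUN"
    bad = set(seq) - set(allowed)
    if bad:
        raise ValueError(f"characters {sorted(bad)} not in {alphabet} alphabet")
    return seq.translate(table)[::-1]


def complement(seq: str, alphabet: str = "DNA") -> str:
    """Base-wise complement without reversal."""
    table = _DNA_COMP if alphabet == "DNA" else _RNA_COMP
    return seq.translate(table)


@dataclass(frozen=True)
class CircularTemplate:
    """A circular single-stranded deoxy template (the written strand).

    Positions are 1-based, ``1..length``, and all arithmetic is modular.
    This is the TEMPLATE strand: transcripts are complementary to it.
    """

    name: str
    sequence: str

    def __post_init__(self):
        if not self.sequence:
            raise ValueError("circular template cannot be empty")
        bad = set(self.sequence) - set("ACGTN")
        if bad:
            raise ValueError(f"non-DNA characters in template: {sorted(bad)}")

    @property
    def length(self) -> int:
        return len(self.sequence)

    def base_at(self, pos: int) -> str:
        """Base at 1-based circular position (any integer accepted)."""
        return self.sequence[(pos - 1) % self.length]


def circular_slice(
    template: CircularTemplate,
    start: int,
    length: int,
    direction: str = "ascending",
) -> str:
    """Walk the circle from 1-based ``start`` for ``length`` bases.

    ``length`` may exceed the template length (multiple laps).  Descending
    walks move toward lower positions, the direction an RNA polymerase
    tracks a template it reads 3'->5'.
    """
    if not 1 <= start <= template.length:
        raise ValueError(f"start {start} out of range 1..{template.length}")
    if length < 1:
        raise ValueError("length must be >= 1")
    step = 1 if direction == "ascending" else -1
    seq = template.sequence
    n = template.length
    return "".join(seq[(start - 1 + step * i) % n] for i in range(length))


@dataclass
class CatalogEntry:
    name: str
    declared_length: int
    notation: str
    spec: OligoSpec


@dataclass
class OligoCatalog:
    """The packaged oligo catalog: name -> (declared length, notation, spec)."""

    entries: dict[str, CatalogEntry] = field(default_factory=dict)
    #: 1-based closed coordinate ranges of sequencing index regions
    #: (underlining in the printed table is not machine-readable, so the
    #: known 6-mer index positions are declared here instead).
    index_regions: dict[str, tuple[int, int]] = field(default_factory=dict)

    def __getitem__(self, name: str) -> CatalogEntry:
        return self.entries[name]

    def __contains__(self, name: str) -> bool:
        return name in self.entries

    def names(self) -> list[str]:
        return list(self.entries)

    def spec(self, name: str) -> OligoSpec:
        return self.entries[name].spec

    def sequence(self, name: str) -> str:
        return self.entries[name].spec.sequence

    def template(self, name: str) -> CircularTemplate:
        """Interpret a catalog entry as a circular template (coligo)."""
        return CircularTemplate(name, self.sequence(name))


_INDEX_REGIONS = {
    "Primer2R1": (25, 30),
    "Primer2R2": (25, 30),
    "Primer2R3": (25, 30),
    "Primer2R4": (25, 30),
}


def load_catalog() -> OligoCatalog:
    """Load and parse the packaged oligo catalog (TSV: name/length/notation)."""
    cat = OligoCatalog(index_regions=dict(_INDEX_REGIONS))
    text = (
        resources.files("coligoseq.data").joinpath("oligo_catalog.tsv").read_text()
    )
    lines = [ln for ln in text.splitlines() if ln.strip()]
    for ln in lines[1:]:
        name, declared, notation = ln.split("\t")
        cat.entries[name] = CatalogEntry(
            name, int(declared), notation, parse_oligo_notation(notation, name)
        )
    return cat


def validate_catalog(catalog: OligoCatalog):
    """Compare parsed residue counts to declared lengths.

    Returns ``(rows, all_pass)`` where rows are
    ``(name, declared, parsed, pass)`` tuples.
    """
    rows = []
    for e in catalog.entries.values():
        rows.append((e.name, e.declared_length, len(e.spec),
                     e.declared_length == len(e.spec)))
    return rows, all(r[3] for r in rows)


def write_fasta(records: Iterable[tuple[str, str]], path) -> None:
    """Write (name, sequence) pairs as FASTA (realized, N-free sequences)."""
    with open(path, "w") as fh:
        for name, seq in records:
            fh.write(f">{name}\n")
            for i in range(0, len(seq), 70):
                fh.write(seq[i:i + 70] + "\n")
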