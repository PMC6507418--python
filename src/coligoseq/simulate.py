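"""Ground-truth-annotated library simulation for single-adapter circularization
sequencing of circular-template (coligo) transcripts.

The simulator reproduces, step by step, the molecular transformations of the
protocol so that every downstream analysis stage can be tested against known
truth:

1. RNA polymerase III transcribes the circular single-stranded deoxy template.
   The written template strand is read 3'->5' by the polymerase, so the
   transcript 5'->3' corresponds to walking the written strand in DESCENDING
   index order; ``start_pos`` is the template position pairing with the
   transcript's first base and ``stop_pos`` with its last.  Failure to
   terminate on a lap yields tandem-repeat multimers (circumtranscription).
   Start and stop sites are sampled independently.  Transcripts carry a 5'
   triphosphate, which blocks ligation side reactions.
2. A 3' adapter with an extra 5' dC and a 3' amino blocker is ligated to the
   transcript 3' end (T4 Rnl1).  With a 5'-monophosphorylated input and ATP,
   self-circularization / multimerization side reactions are possible; the
   pre-adenylylated-adapter variant suppresses them.
3. Reverse transcription from a primer whose 3' segment anneals to the
   adapter and which carries both PCR primer sites in divergent orientation,
   separated by a single ribonucleotide (riboC).
4. The first-strand cDNA is circularized by a thermostable single-strand
   ligase (~90% efficient) and re-linearized by RNase A, which cuts 3' of the
   single ribonucleotide, converting the divergent primer sites into
   convergent ones.  Uncircularized cDNA is also cut and cannot amplify.
5. 110-cycle single-end reads with per-base Phred qualities, a substitution
   error rate, and a rare non-templated first transcript base.

All molecular strings are tracked in sense-strand DNA space (transcript U
written as T) once the adapter chimera is formed; the ribonucleotide of the
RT primer is tracked by index.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .io import ReadRecord, make_truth_id
from .oligo import CircularTemplate, OligoSpec, circular_slice, revcomp

#: 21-mer adapter core shared by the 3' adapters and the RT/PCR primers; the
#: full 3' adapter for coligo transcripts is this core preceded by one dC.
ADAPTER3_CORE = "AGATCGGAAGAGCACACGTCT"

#: bases of the re-linearized molecule (in read orientation) covered by the
#: Read1 sequencing primer: the single riboC complement plus the 25-nt
#: forward primer site; the read proper starts right after them.
READ1_PRIMER_SPAN = 26

_MIN_READ_LENGTH = 36  # shortest layout in which the adapter anchor is findable

_TRANSCRIBE = str.maketrans("ACGTN", "UGCAN")  # template DNA -> transcript RNA
_RNA2DNA = str.maketrans("U", "T")


@dataclass(frozen=True)
class EndProfile:
    """Independent transcription start-site and stop-site distributions.

    Keys are 1-based template positions; values are probabilities summing
    to 1.  Start and stop are sampled independently of one another.
    """

    start_dist: dict[int, float]
    stop_dist: dict[int, float]

    def validate(self, template: CircularTemplate) -> None:
        for label, dist in (("start", self.start_dist), ("stop", self.stop_dist)):
            if not dist:
                raise ValueError(f"empty {label} distribution")
            if abs(sum(dist.values()) - 1.0) > 1e-9:
                raise ValueError(f"{label} distribution does not sum to 1")
            for pos in dist:
                if not 1 <= pos <= template.length:
                    raise ValueError(f"{label} position {pos} outside template")


@dataclass(frozen=True)
class Transcript:
    """A sampled polymerase transcript from a circular template."""

    rna_sequence: str
    start_pos: int
    stop_pos: int
    laps: int = 1
    five_prime: str = "triphosphate"

    def __len__(self) -> int:
        return len(self.rna_sequence)

    @property
    def dna_sequence(self) -> str:
        return self.rna_sequence.translate(_RNA2DNA)


@dataclass
class LibraryPrepConfig:
    """Simulation parameters for one library preparation run.

    ``protocol`` selects the ligation chemistry: ``coligo_seq`` (5'ppp input,
    plain 3' adapter + ATP), ``preadenylylated_mirna`` (5'p input,
    pre-adenylylated adapter, no ATP, side reactions suppressed), or
    ``standard_two_adapter`` (5'p input with ATP; per-class 5'-adapter
    ligation efficiencies apply and self-ligation side reactions may occur).
    """

    seed: int
    protocol: str = "coligo_seq"
    adapter3_ligation_efficiency: float = 1.0
    circularization_efficiency: float = 0.9
    five_prime_ligation_efficiency_by_class: dict[str, float] = field(
        default_factory=dict
    )
    side_reaction_rates: dict[str, float] = field(default_factory=dict)
    read_length: int = 110
    substitution_error_rate: float = 0.0
    nontemplated_first_base_rate: float = 0.0
    quality_model: tuple[float, float] = (36.0, 0.05)  # (mean Phred, decay/cycle)
    quality_sd: float = 4.0

    def __post_init__(self):
        if self.seed is None:
            raise ValueError("seed is mandatory for reproducibility")
        for p in (self.adapter3_ligation_efficiency, self.circularization_efficiency,
                  self.substitution_error_rate, self.nontemplated_first_base_rate,
                  *self.side_reaction_rates.values()):
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"probability {p} outside [0, 1]")
        if self.protocol not in (
            "coligo_seq", "standard_two_adapter", "preadenylylated_mirna"
        ):
            raise ValueError(f"unknown protocol {self.protocol!r}")
        if self.protocol != "standard_two_adapter" and any(
            v > 0 for v in self.side_reaction_rates.values()
        ):
            raise ValueError(
                "self-ligation side reactions require the 5'p + ATP "
                "(standard_two_adapter) protocol"
            )

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)


def transcribe(template: CircularTemplate, start: int, stop: int, laps: int = 1,
               five_prime: str = "triphosphate") -> Transcript:
    """Build the transcript for given start/stop positions and lap count.

    Length = (descending arc from start to stop) + (laps - 1) * template
    length; the RNA is the complement of the template walked descending.
    """
    if laps < 1:
        raise ValueError("laps must be >= 1")
    arc = (start - stop) % template.length + 1
    total = arc + (laps - 1) * template.length
    walked = circular_slice(template, start, total, "descending")
    return Transcript(walked.translate(_TRANSCRIBE), start, stop, laps, five_prime)


def sample_transcripts(template: CircularTemplate, profile: EndProfile, n: int,
                       lap_dist: dict[int, float], rng: np.random.Generator,
                       five_prime: str = "triphosphate") -> list[Transcript]:
    """Sample ``n`` transcripts: start/stop independent, laps from ``lap_dist``."""
    profile.validate(template)
    if abs(sum(lap_dist.values()) - 1.0) > 1e-9:
        raise ValueError("lap distribution does not sum to 1")
    starts = rng.choice(list(profile.start_dist), n, p=list(profile.start_dist.values()))
    stops = rng.choice(list(profile.stop_dist), n, p=list(profile.stop_dist.values()))
    laps = rng.choice(list(lap_dist), n, p=list(lap_dist.values()))
    return [
        transcribe(template, int(s), int(t), int(k), five_prime)
        for s, t, k in zip(starts, stops, laps)
    ]


@dataclass(frozen=True)
class LigationOutcome:
    """Result of the 3'-adapter ligation: status and sense-strand DNA chimera."""

    status: str  # ligated | unligated | self_circle | multimer
    sense_sequence: str | None  # transcript(DNA) + adapter, when ligated


def ligate_adapter3(transcript: Transcript, adapter: OligoSpec,
                    config: LibraryPrepConfig,
                    rng: np.random.Generator) -> LigationOutcome:
    """Ligate the 3' adapter to the transcript 3' end.

    The adapter must be 3'-blocked (else it would concatemerize).  A 5'ppp
    transcript cannot self-ligate; in the pre-adenylylated (no ATP) mode the
    side reactions are suppressed by construction and must be configured 0.
    """
    if adapter.three_prime != "amino_blocker":
        raise ValueError(
            f"adapter {adapter.name} lacks the 3' blocking group required here"
        )
    if config.protocol == "coligo_seq" and transcript.five_prime != "triphosphate":
        raise ValueError("coligo_seq protocol expects 5'-triphosphate transcripts")
    # Self-ligation side reactions compete first, at absolute rates over the
    # input; the remainder ligates the adapter at the configured efficiency.
    rates = config.side_reaction_rates
    u = rng.random()
    acc = 0.0
    for cls in ("self_circle", "multimer"):
        acc += rates.get(cls, 0.0)
        if u < acc:
            seq = (transcript.dna_sequence * 2 + adapter.sequence
                   if cls == "multimer" else None)
            return LigationOutcome(cls, seq)
    if rng.random() < config.adapter3_ligation_efficiency:
        return LigationOutcome(
            "ligated", transcript.dna_sequence + adapter.sequence
        )
    return LigationOutcome("unligated", None)


def reverse_transcribe(ligated_sense: str, rt_primer: OligoSpec) -> tuple[str, int]:
    """First-strand cDNA synthesis from the divergent-site RT primer.

    The primer's 3'-terminal segment must be the reverse complement of the
    chimera's 3' end (the adapter core); this is validated, not assumed, and
    a mismatch models failed priming.  Returns the cDNA (5'->3', DNA space:
    full primer then the complement of the remaining template) and the
    1-based index of the primer's single ribonucleotide within the cDNA.
    """
    ribo = rt_primer.ribo_positions
    if len(ribo) != 1:
        raise ValueError(
            f"RT primer {rt_primer.name} must contain exactly one ribonucleotide"
        )
    primer = rt_primer.sequence
    anneal = 0
    for k in range(min(len(primer), len(ligated_sense)), 0, -1):
        if revcomp(primer[-k:]) == ligated_sense[-k:]:
            anneal = k
            break
    if anneal < 12:
        raise ValueError(
            f"RT primer {rt_primer.name} 3' end does not anneal to the adapter"
        )
    cdna = primer + revcomp(ligated_sense[: len(ligated_sense) - anneal])
    return cdna, ribo[0]


def circularize_relinearize(cdna: str, ribo_index: int,
                            circularization_efficiency: float,
                            rng: np.random.Generator) -> tuple[str, str | None]:
    """Circularize the cDNA, then cut 3' of the single ribonucleotide.

    With probability ``circularization_efficiency`` the molecule circularizes
    and RNase A reopens it at the ribonucleotide: the result is the rotation
    of the cDNA beginning at ``ribo_index + 1`` and ending with the retained
    ribo base (which carries a 2',3'-cyclic phosphate).  Otherwise the linear
    molecule is still cut at the ribo site, producing two fragments that
    cannot be amplified — flagged and dropped downstream.

    Returns ``(status, sequence)`` with status ``relinearized`` or
    ``linear_uncircularized``.
    """
    if not 1 <= ribo_index <= len(cdna):
        raise ValueError("cDNA has no ribonucleotide at the given index")
    if rng.random() < circularization_efficiency:
        return "relinearized", cdna[ribo_index:] + cdna[:ribo_index]
    return "linear_uncircularized", None


def _draw_quals(n_bases: int, config: LibraryPrepConfig,
                rng: np.random.Generator) -> tuple[int, ...]:
    mean0, decay = config.quality_model
    means = mean0 - decay * np.arange(n_bases)
    q = rng.normal(means, config.quality_sd)
    return tuple(int(v) for v in np.clip(np.rint(q), 2, 40))


def _mutate(seq: str, rate: float, rng: np.random.Generator) -> str:
    if rate <= 0.0:
        return seq
    arr = np.frombuffer(seq.encode(), dtype=np.uint8).copy()
    hits = np.nonzero(rng.random(len(arr)) < rate)[0]
    if hits.size == 0:
        return seq
    bases = np.frombuffer(b"ACGT", dtype=np.uint8)
    for i in hits:
        choices = bases[bases != arr[i]]
        arr[i] = rng.choice(choices)
    return arr.tobytes().decode()


def generate_reads(molecules, config: LibraryPrepConfig, rng: np.random.Generator,
                   downstream_filler: str = "",
                   read_start_offset: int = READ1_PRIMER_SPAN) -> list[ReadRecord]:
    """Sequence re-linearized molecules: Read1, ``config.read_length`` cycles.

    ``molecules`` is an iterable of ``(relinearized_sequence, truth_id)``
    pairs.  Read1 is the reverse complement of the re-linearized molecule
    starting just after the sequencing-primer region (``read_start_offset``
    bases), continuing into ``downstream_filler`` (the reverse complement of
    the PCR reverse-primer tail) when the insert is shorter than the read.
    For an error-free coligo-protocol molecule this composes to
    ``transcript_DNA + 'C' + adapter core + filler``.  Substitution errors,
    the rare non-templated first base, and per-base qualities are applied.
    """
    if config.read_length < _MIN_READ_LENGTH:
        raise ValueError(
            f"read_length {config.read_length} below the minimal read layout "
            f"({_MIN_READ_LENGTH})"
        )
    reads = []
    pad = "A"  # post-insert signal; real instruments read into the flow-cell adapter
    for relin, truth_id in molecules:
        tpl = revcomp(relin)[read_start_offset:] + downstream_filler
        if len(tpl) < config.read_length:
            tpl += pad * (config.read_length - len(tpl))
        seq = _mutate(tpl[: config.read_length], config.substitution_error_rate, rng)
        if (config.nontemplated_first_base_rate > 0.0
                and rng.random() < config.nontemplated_first_base_rate):
            others = [b for b in "ACGT" if b != tpl[0]]
            seq = others[int(rng.integers(3))] + seq[1:]
        reads.append(ReadRecord(truth_id, seq, _draw_quals(len(seq), config, rng)))
    return reads


@dataclass
class StageTally:
    """Per-stage ledger: input count and outcome counts by class."""

    name: str
    input: int = 0
    outcomes: dict[str, int] = field(default_factory=dict)

    def add(self, outcome: str) -> None:
        self.input += 1
        self.outcomes[outcome] = self.outcomes.get(outcome, 0) + 1

    def as_dict(self) -> dict:
        return {"stage": self.name, "input": self.input, "outcomes": self.outcomes}


def simulate_coligo_library(template: CircularTemplate, profile: EndProfile,
                            lap_dist: dict[int, float], n: int,
                            config: LibraryPrepConfig, catalog,
                            adapter_name: str = "Adapter3",
                            rt_primer_name: str = "RTprimer2",
                            pcr_reverse_name: str = "Primer2R2"):
    """Run the full composed protocol; returns (reads, truth, stage tallies).

    Truth rows are dicts carrying species/start/stop/laps/class for every
    input transcript, including those dropped before sequencing.
    """
    rng = config.rng()
    adapter = catalog.spec(adapter_name)
    rt_primer = catalog.spec(rt_primer_name)
    filler = revcomp(catalog.sequence(pcr_reverse_name)[:-len(ADAPTER3_CORE)])
    transcripts = sample_transcripts(template, profile, n, lap_dist, rng)
    lig_tally = StageTally("adapter3_ligation")
    circ_tally = StageTally("circularization")
    molecules, truth = [], []
    for i, tr in enumerate(transcripts):
        cls = "monomer" if tr.laps == 1 else f"multimer_lap{tr.laps}"
        row = {"species": template.name, "start": tr.start_pos,
               "stop": tr.stop_pos, "laps": tr.laps, "class": cls}
        out = ligate_adapter3(tr, adapter, config, rng)
        lig_tally.add(out.status)
        if out.status != "ligated":
            row["class"] = out.status if out.status != "unligated" else cls
            row["fate"] = f"dropped:{out.status}"
            truth.append(row)
            continue
        cdna, ribo = reverse_transcribe(out.sense_sequence, rt_primer)
        status, relin = circularize_relinearize(
            cdna, ribo, config.circularization_efficiency, rng
        )
        circ_tally.add(status)
        if status != "relinearized":
            row["fate"] = "dropped:uncircularized"
            truth.append(row)
            continue
        row["fate"] = "sequenced"
        truth.append(row)
        molecules.append(
            (relin, make_truth_id(i, template.name, tr.start_pos, tr.stop_pos,
                                  tr.laps, cls))
        )
    reads = generate_reads(molecules, config, rng, downstream_filler=filler)
    return reads, truth, [lig_tally, circ_tally]


def simulate_lbprimer_library(n: int, base_probs, bias_model: dict,
                              config: LibraryPrepConfig, catalog,
                              pcr_reverse_name: str = "Primer2R1"):
    """Simulate the randomized-junction circularization-bias library.

    The substrate is a 5'-phosphorylated 61-mer with seven hand-mixed random
    nucleotides on each side of the eventual ligation junction (5'-side block
    N7a, 3'-side block N7b) and the divergent PCR sites separated by one
    riboC in between.  Each realized molecule is accepted for circularization
    with probability proportional to
    ``bias_model[(donor, acceptor)]`` where donor = last base of N7b (the
    3'-OH end) and acceptor = first base of N7a (the 5'-p end); accepted
    circles are re-linearized at the riboC and sequenced.  Read1 layout:
    bases 1-7 = revcomp(N7a), 8-14 = revcomp(N7b), then the 21-mer adapter
    anchor.

    ``base_probs`` is a 14x4 array of per-position base probabilities in
    original-orientation order (N7a positions 1-7 then N7b positions 1-7),
    or None for uniform.  Returns (reads, truth) where truth rows are
    (N7a, N7b, junction) tuples.
    """
    if base_probs is None:
        base_probs = np.full((14, 4), 0.25)
    base_probs = np.asarray(base_probs, dtype=float)
    if base_probs.shape != (14, 4) or np.any(np.abs(base_probs.sum(1) - 1) > 1e-9):
        raise ValueError("base_probs must be 14 per-position distributions")
    if not bias_model or all(w == 0 for w in bias_model.values()):
        raise ValueError("bias model must have at least one positive weight")
    if any(w < 0 for w in bias_model.values()):
        raise ValueError("bias weights must be >= 0")
    rng = config.rng()
    lb = catalog.spec("LBprimer")
    body = lb.sequence  # Ns at 1-7 and 55-61; riboC at 33
    ribo = lb.ribo_positions[0]
    core5 = body[7:ribo - 1]          # forward primer site, 25 nt
    core3 = body[ribo:-7]             # adapter core, 21 nt
    filler = revcomp(catalog.sequence(pcr_reverse_name)[:-len(core3)])
    wmax = max(bias_model.values())

    bases = np.array(list("ACGT"))
    draws = np.empty((n, 14), dtype="U1")
    for j in range(14):
        draws[:, j] = rng.choice(bases, n, p=base_probs[j])
    accept_u = rng.random(n)

    molecules, truth = [], []
    for i in range(n):
        n7a = "".join(draws[i, :7])
        n7b = "".join(draws[i, 7:])
        junction = (n7b[-1], n7a[0])  # (donor 3' base, acceptor 5' base)
        if accept_u[i] >= bias_model.get(junction, 0.0) / wmax:
            continue
        substrate = n7a + core5 + "C" + core3 + n7b
        status, relin = circularize_relinearize(
            substrate, ribo, config.circularization_efficiency, rng
        )
        if status != "relinearized":
            continue
        truth.append((n7a, n7b, junction))
        molecules.append(
            (relin, make_truth_id(i, "LBprimer", n7a, n7b, 1, "".join(junction)))
        )
    reads = generate_reads(molecules, config, rng, downstream_filler=filler)
    return reads, truth


def uniform_bias_model() -> dict[tuple[str, str], float]:
    """Equal circularization weight for all 16 junction dinucleotides."""
    return {(d, a): 1.0 for d in "ACGT" for a in "ACGT"}


def simulate_protocol_comparison(species_proportions: dict[str, float],
                                 class_efficiencies: dict[str, float],
                                 n: int, seed: int,
                                 circularization_efficiency: float = 0.9):
    """Compare library representation: two-adapter protocol vs circularization.

    Each input molecule of a species passes the standard protocol's 5'-adapter
    ligation with the species' supplied efficiency (structure-dependent in
    reality; supplied by the user here, never predicted), while the
    single-adapter protocol applies one uniform circularization efficiency to
    every species.  Returns a DataFrame with input, standard-mode and
    coligo-mode fractions per species.
    """
    import pandas as pd

    if abs(sum(species_proportions.values()) - 1.0) > 1e-9:
        raise ValueError("species proportions must sum to 1")
    rng = np.random.default_rng(seed)
    names = list(species_proportions)
    labels = rng.choice(names, n, p=[species_proportions[s] for s in names])
    u_std = rng.random(n)
    u_col = rng.random(n)
    eff = np.array([class_efficiencies[s] for s in labels])
    std_keep = u_std < eff
    col_keep = u_col < circularization_efficiency
    rows = []
    for s in names:
        mask = labels == s
        rows.append({
            "species": s,
            "input_fraction": mask.mean(),
            "standard_fraction": (
                (mask & std_keep).sum() / max(std_keep.sum(), 1)
            ),
            "coligo_fraction": (
                (mask & col_keep).sum() / max(col_keep.sum(), 1)
            ),
        })
    return pd.DataFrame(rows)
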