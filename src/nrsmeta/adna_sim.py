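"""Ancient-DNA read simulator and factorial benchmark builder.

Emulates the benchmark design used throughout: fixed-length fragments
(20-100 bp) drawn uniformly from reference genomes at a configured depth,
end-biased post-mortem deamination (C->T damage decaying exponentially from
the 5' end, G->A from the 3' end), a uniform per-base sequencing error, and
an optional contaminant read admixture.  Every emitted read carries exactly
one ground-truth row (origin label, genome position, strand, damage and
error counts), and all randomness flows from a single seed: a fixed seed
reproduces the outputs byte for byte.

This is a deliberately simplified damage model (no indels, no fragment
length distribution, no quality-dependent errors); the per-site deamination
probability at distance i from the relevant end is d * 2^(-i/halflife).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from .seqio import SequenceRecord, write_fasta, write_fastq, write_tsv

__all__ = [
    "SimConfig",
    "TruthRow",
    "simulate_genomes",
    "fragment_reads",
    "apply_deamination",
    "apply_sequencing_errors",
    "simulate_sample",
    "build_benchmark",
    "read_truth_tsv",
    "TRUTH_COLUMNS",
]

# symbol indices
_A, _C, _G, _T = 0, 1, 2, 3

TRUTH_COLUMNS = ["read_id", "source_label", "position", "strand",
                 "n_deaminated", "n_errors"]


@dataclass(frozen=True)
class SimConfig:
    """One benchmark grid cell.

    read_length: fragment length in bp (>= 20 in the study design).
    deamination_rate: terminal C->T / G->A probability d in [0, 0.3].
    decay_halflife: positions over which the per-site damage probability
        halves (default 3, terminal-biased as in degraded DNA).
    depth: mean coverage; reads per genome = round(depth * |genome| / L).
    error_rate: uniform per-base substitution probability.
    contaminant_fraction: fraction of the final read set drawn from the
        contaminant genomes.
    """

    read_length: int = 60
    deamination_rate: float = 0.0
    decay_halflife: float = 3.0
    depth: float = 5.0
    error_rate: float = 0.0
    contaminant_fraction: float = 0.0
    seed: int = 13

    def __post_init__(self) -> None:
        if self.read_length < 1:
            raise ValueError("read_length must be >= 1")
        for name in ("deamination_rate", "error_rate", "contaminant_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        if self.depth <= 0:
            raise ValueError("depth must be > 0")
        if self.decay_halflife <= 0:
            raise ValueError("decay_halflife must be > 0")


@dataclass(frozen=True)
class TruthRow:
    read_id: str
    source_label: str
    position: int
    strand: str
    n_deaminated: int = 0
    n_errors: int = 0


def simulate_genomes(n: int, length: int, seed: int) -> list[SequenceRecord]:
    """n i.i.d.-uniform random genomes named genome_1..genome_n."""
    if n < 0:
        raise ValueError("n must be >= 0")
    if n and length < 1:
        raise ValueError("length must be >= 1")
    rng = np.random.default_rng(seed)
    return [
        SequenceRecord(
            f"genome_{i + 1}", "simulated",
            rng.integers(0, 4, size=length, dtype=np.int8),
        )
        for i in range(n)
    ]


def fragment_reads(
    genome: SequenceRecord,
    read_length: int,
    depth: float,
    rng: int | np.random.Generator,
    id_prefix: str | None = None,
) -> tuple[list[SequenceRecord], list[TruthRow]]:
    """Uniform fixed-length fragments: round(depth * |genome| / L) reads.

    Start positions and strands are uniform; minus-strand fragments are
    reverse-complemented.  Before damage, every read is an exact
    (reverse-complemented) substring of the genome.
    """
    if read_length > genome.length:
        raise ValueError(
            f"read_length {read_length} exceeds genome length {genome.length}"
        )
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    n_reads = int(round(depth * genome.length / read_length))
    starts = rng.integers(0, genome.length - read_length + 1, size=n_reads)
    strands = rng.integers(0, 2, size=n_reads)
    prefix = id_prefix or genome.id
    reads: list[SequenceRecord] = []
    truth: list[TruthRow] = []
    for i in range(n_reads):
        start = int(starts[i])
        frag = genome.symbols[start : start + read_length]
        if strands[i]:
            frag = (3 - frag[::-1]).astype(np.int8)
            strand = "-"
        else:
            frag = frag.copy()
            strand = "+"
        read_id = f"{prefix}_read_{i + 1}"
        reads.append(SequenceRecord(read_id, "", frag))
        truth.append(TruthRow(read_id, genome.id, start, strand))
    return reads, truth


def apply_deamination(
    read: SequenceRecord,
    d: float,
    decay_halflife: float,
    rng: int | np.random.Generator,
) -> tuple[SequenceRecord, int]:
    """End-biased damage: C->T from the 5' end, G->A from the 3' end.

    Position i from the 5' end deaminates C with probability
    d * 2^(-i / halflife); position j from the 3' end deaminates G with the
    same law.  Returns the damaged read and the substitution count.
    """
    if not 0.0 <= d <= 1.0:
        raise ValueError("deamination rate must lie in [0, 1]")
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    syms = read.symbols.copy()
    n = syms.size
    idx = np.arange(n, dtype=np.float64)
    p5 = d * np.exp2(-idx / decay_halflife)
    p3 = d * np.exp2(-(n - 1 - idx) / decay_halflife)
    u = rng.random(n)
    ct = (syms == _C) & (u < p5)
    ga = (syms == _G) & (u < p3)
    syms[ct] = _T
    syms[ga] = _A
    n_deaminated = int(ct.sum() + ga.sum())
    return SequenceRecord(read.id, read.description, syms, read.quality), n_deaminated


def apply_sequencing_errors(
    read: SequenceRecord,
    error_rate: float,
    rng: int | np.random.Generator,
) -> tuple[SequenceRecord, int]:
    """Uniform substitution errors; a hit base always changes identity."""
    if not 0.0 <= error_rate <= 1.0:
        raise ValueError("error_rate must lie in [0, 1]")
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    syms = read.symbols.copy()
    hit = rng.random(syms.size) < error_rate
    n_err = int(hit.sum())
    if n_err:
        shift = rng.integers(1, 4, size=n_err, dtype=np.int8)
        syms[hit] = (syms[hit] + shift) % 4
    return SequenceRecord(read.id, read.description, syms, read.quality), n_err


def simulate_sample(
    references: Sequence[SequenceRecord],
    contaminants: Sequence[SequenceRecord],
    config: SimConfig,
) -> tuple[list[SequenceRecord], list[TruthRow]]:
    """One grid cell in memory: damaged reads plus their ground truth.

    Target reads come from every reference at the configured depth; the
    contaminant pool contributes round(cf/(1-cf) * n_target) extra reads,
    split across contaminant genomes in proportion to length.  Damage and
    error are applied to contaminant reads too.
    """
    if not references:
        raise ValueError("at least one reference genome is required")
    rng = np.random.default_rng(config.seed)
    reads: list[SequenceRecord] = []
    truth: list[TruthRow] = []
    for genome in references:
        r, t = fragment_reads(genome, config.read_length, config.depth, rng)
        reads.extend(r)
        truth.extend(t)
    n_target = len(reads)
    if config.contaminant_fraction > 0 and contaminants:
        cf = config.contaminant_fraction
        n_cont_total = int(round(cf / (1.0 - cf) * n_target)) if cf < 1.0 else 0
        lengths = np.array([c.length for c in contaminants], dtype=np.float64)
        shares = lengths / lengths.sum()
        for genome, share in zip(contaminants, shares):
            n_this = int(round(n_cont_total * float(share)))
            if n_this == 0:
                continue
            depth_this = n_this * config.read_length / genome.length
            r, t = fragment_reads(
                genome, config.read_length, depth_this, rng,
                id_prefix=f"contam_{genome.id}",
            )
            reads.extend(r[:n_this])
            truth.extend(t[:n_this])
    damaged: list[SequenceRecord] = []
    truth_out: list[TruthRow] = []
    for read, row in zip(reads, truth):
        read, n_deam = apply_deamination(
            read, config.deamination_rate, config.decay_halflife, rng
        )
        read, n_err = apply_sequencing_errors(read, config.error_rate, rng)
        damaged.append(read)
        truth_out.append(replace(row, n_deaminated=n_deam, n_errors=n_err))
    return damaged, truth_out


def build_benchmark(
    references: Sequence[SequenceRecord],
    contaminants: Sequence[SequenceRecord],
    read_lengths: Sequence[int],
    deamination_rates: Sequence[float],
    depths: Sequence[float],
    out_dir: str | Path,
    base_config: SimConfig | None = None,
) -> list[dict]:
    """Factorial benchmark: one FASTQ + ground-truth TSV per grid cell.

    The grid is the cross product read_lengths x deamination_rates x depths
    (the full study design is 5 x 4 x 6 = 120 cells).  Each cell draws its
    randomness from a child seed spawned deterministically from the base
    seed and the cell index.  Returns the manifest (one dict per cell) and
    writes it as manifest.tsv.
    """
    if base_config is None:
        base_config = SimConfig()
    cells = [
        (L, d, dp) for L in read_lengths for d in deamination_rates for dp in depths
    ]
    if not cells:
        raise ValueError("empty benchmark grid")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest: list[dict] = []
    for idx, (L, d, dp) in enumerate(cells):
        child_seed = int(
            np.random.SeedSequence(base_config.seed, spawn_key=(idx,)).generate_state(1)[0]
            % (2**31)
        )
        cfg = replace(
            base_config, read_length=L, deamination_rate=d, depth=dp, seed=child_seed
        )
        reads, truth = simulate_sample(references, contaminants, cfg)
        stem = f"cell_L{L}_d{d:g}_x{dp:g}"
        reads_path = out_dir / f"{stem}.fq"
        truth_path = out_dir / f"{stem}.truth.tsv"
        write_fastq(reads, reads_path)
        write_tsv(
            [
                (r.read_id, r.source_label, r.position, r.strand,
                 r.n_deaminated, r.n_errors)
                for r in truth
            ],
            TRUTH_COLUMNS,
            truth_path,
        )
        manifest.append(
            {
                "cell": stem,
                "read_length": L,
                "deamination_rate": d,
                "depth": dp,
                "n_reads": len(reads),
                "reads": str(reads_path),
                "truth": str(truth_path),
            }
        )
    write_tsv(
        [
            (m["cell"], m["read_length"], float(m["deamination_rate"]),
             float(m["depth"]), m["n_reads"], m["reads"], m["truth"])
            for m in manifest
        ],
        ["cell", "read_length", "deamination_rate", "depth", "n_reads",
         "reads", "truth"],
        out_dir / "manifest.tsv",
    )
    return manifest


def read_truth_tsv(path: str | Path) -> dict[str, TruthRow]:
    """Load a ground-truth TSV back into read_id -> TruthRow."""
    truth: dict[str, TruthRow] = {}
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        col = {name: i for i, name in enumerate(header)}
        for line in fh:
            cells = line.rstrip("\n").split("\t")
            row = TruthRow(
                read_id=cells[col["read_id"]],
                source_label=cells[col["source_label"]],
                position=int(cells[col["position"]]),
                strand=cells[col["strand"]],
                n_deaminated=int(cells[col["n_deaminated"]]),
                n_errors=int(cells[col["n_errors"]]),
            )
            truth[row.read_id] = row
    return truth
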