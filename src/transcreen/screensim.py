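"""Synthetic screen data: pooled-library abundances, sorting-induced
enrichment, and long-read-style sequencing errors.

The generator emulates the data-shape of a pooled sort-seq disruption
screen: a plasmid library whose members are unevenly represented (log-normal
abundance skew), FACS-sorted pools in which chosen members are enriched by a
fold-change relative to the unsorted control, and barcoded amplicon reads
carrying i.i.d. substitution/insertion/deletion errors at long-read-like
rates.  Every draw is reproducible from the mandatory seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .seqcore import OrfRecord, reverse_complement

# Synthetic 24 nt sample barcodes, pairwise Hamming distance >= 12 (also vs
# reverse complements >= 10), generated once and frozen.
DEFAULT_BARCODES = (
    "ATTAAGTCTGGCCTGCCGACATAT",
    "CCCCACCGATCAAGGCGGCTCGCG",
    "GACGGGTTATGACTCATATATCAC",
    "AGCAATTTGCGCCCCAACACCATC",
    "GTTTCTGCTGAGACTGACTATTTG",
    "CGAGGATCGGGCGTCCTGTACGGT",
    "GCTCACGAAGGTACGTGGGGATAG",
    "AGATTTAGGGACAAGTCCCAACGG",
    "CGGACTCCGAAGAAATGGTACAGG",
    "ATGGCGGGGATACTCTGGACACAA",
    "TGGGTATCGCATAACCACTTGTAG",
    "ACTCTGCTTTCTTTGGAAGGCACG",
)

_STOPS = {"TAA", "TAG", "TGA"}
_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


@dataclass
class SimConfig:
    """Study conditions for one simulated screen.

    ``abundance_sigma`` controls the member skew of the plasmid/cell library
    (log-normal over members, drawn once and shared by all samples, as the
    library composition is fixed before sorting).  ``replicate_sigma`` is
    small log-normal jitter applied independently per replicate culture.
    ``spikes`` maps each condition to {gene_id: fold-change vs control}.
    Error rates are per base and i.i.d.
    """

    seed: int
    n_reads: int = 100_000
    abundance_mu: float = 0.0
    abundance_sigma: float = 1.5
    replicate_sigma: float = 0.2
    spikes: dict[str, dict[str, float]] = field(
        default_factory=lambda: {"control": {}, "max": {}, "min": {}}
    )
    substitution_rate: float = 0.05
    insertion_rate: float = 0.03
    deletion_rate: float = 0.03
    replicates: int = 3
    barcodes: Sequence[str] = DEFAULT_BARCODES

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ValueError("a seed is mandatory")
        for name in ("substitution_rate", "insertion_rate", "deletion_rate"):
            r = getattr(self, name)
            if not 0 <= r < 1:
                raise ValueError(f"{name} must be in [0, 1); got {r}")
        for cond, sp in self.spikes.items():
            for gid, fold in sp.items():
                if fold <= 0:
                    raise ValueError(
                        f"fold-change for {gid} in {cond} must be > 0"
                    )
        if self.abundance_sigma < 0 or self.replicate_sigma < 0:
            raise ValueError("sigmas must be non-negative")

    @property
    def conditions(self) -> list[str]:
        return list(self.spikes)

    def sample_names(self) -> list[str]:
        return [
            f"{cond}_rep{r + 1}"
            for cond in self.conditions
            for r in range(self.replicates)
        ]


# ---------------------------------------------------------------------------
# random ORFs (designable target sets for end-to-end runs)
# ---------------------------------------------------------------------------


def random_cds(length: int, rng: np.random.Generator) -> str:
    """A random open reading frame: ATG, random internal non-stop codons,
    and a terminal TAA.  ``length`` must be a multiple of 3, >= 9."""
    if length % 3 != 0 or length < 9:
        raise ValueError("CDS length must be a multiple of 3 and >= 9")
    n_internal = length // 3 - 2
    codons = []
    while len(codons) < n_internal:
        c = "".join("ACGT"[i] for i in rng.integers(0, 4, 3))
        if c not in _STOPS:
            codons.append(c)
    return "ATG" + "".join(codons) + "TAA"


def random_orfs(
    n: int,
    rng: np.random.Generator,
    cds_length: int = 900,
    n_essential: int = 0,
    prefix: str = "GENE",
) -> list[OrfRecord]:
    """``n`` synthetic single-gene records with random designable CDSs.

    The first ``n_essential`` records are flagged essential.  Each gene sits
    on its own synthetic contig with the CDS at offset 0.
    """
    out = []
    for i in range(n):
        gid = f"{prefix}{i + 1:04d}"
        out.append(OrfRecord(
            gene_id=gid, chrom=f"ctg_{gid}", start=0, end=cds_length,
            strand="+", cds_seq=random_cds(cds_length, rng),
            essential=i < n_essential,
        ))
    return out


# ---------------------------------------------------------------------------
# abundances
# ---------------------------------------------------------------------------


def simulate_abundances(
    genes: Sequence[str], config: SimConfig
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-sample member probabilities and the matching sample sheet.

    A base abundance per member is drawn once (log-normal, the fixed library
    composition); each condition multiplies spiked members by their
    fold-change; each replicate applies independent log-normal jitter.  All
    columns are normalised to sum to 1.

    Returns ``(probs, sample_sheet)``: probs is genes x samples;
    the sample sheet maps sample -> condition, replicate, barcode.
    """
    if len(genes) == 0:
        raise ValueError("empty library")
    rng = np.random.default_rng(config.seed)
    base = np.exp(rng.normal(config.abundance_mu, config.abundance_sigma,
                             len(genes)))
    cols: dict[str, np.ndarray] = {}
    sheet_rows = []
    n_samples = len(config.conditions) * config.replicates
    if n_samples > len(config.barcodes):
        raise ValueError(
            f"{n_samples} samples but only {len(config.barcodes)} barcodes"
        )
    bc_iter = iter(config.barcodes)
    gene_index = {g: i for i, g in enumerate(genes)}
    for cond in config.conditions:
        fold = np.ones(len(genes))
        for gid, f in config.spikes[cond].items():
            if gid not in gene_index:
                raise KeyError(f"spiked gene {gid!r} not in the library")
            fold[gene_index[gid]] = f
        expectation = base * fold
        for r in range(config.replicates):
            jitter = (
                np.exp(rng.normal(0.0, config.replicate_sigma, len(genes)))
                if config.replicate_sigma > 0 else 1.0
            )
            p = expectation * jitter
            name = f"{cond}_rep{r + 1}"
            cols[name] = p / p.sum()
            sheet_rows.append(dict(sample=name, condition=cond,
                                   replicate=r + 1, barcode=next(bc_iter)))
    probs = pd.DataFrame(cols, index=list(genes))
    return probs, pd.DataFrame(sheet_rows)


# ---------------------------------------------------------------------------
# reads
# ---------------------------------------------------------------------------


def _corrupt(seq: str, rng: np.random.Generator, sub: float, ins: float,
             dele: float) -> str:
    """Apply i.i.d. per-base substitution/insertion/deletion errors."""
    if sub == ins == dele == 0:
        return seq
    arr = np.frombuffer(seq.encode(), dtype=np.uint8).copy()
    n = arr.size
    # substitutions: replace by one of the three other bases
    sub_mask = rng.random(n) < sub
    if sub_mask.any():
        idx = np.where(sub_mask)[0]
        cur = np.searchsorted(_BASES, arr[idx])  # ACGT are sorted bytes
        shift = rng.integers(1, 4, idx.size)
        arr[idx] = _BASES[(cur + shift) % 4]
    # deletions
    keep = rng.random(n) >= dele
    arr = arr[keep]
    # insertions: at most one random base after each surviving position
    ins_mask = rng.random(arr.size) < ins
    if ins_mask.any():
        pos = np.where(ins_mask)[0] + 1
        extra = _BASES[rng.integers(0, 4, pos.size)]
        arr = np.insert(arr, pos, extra)
    return arr.tobytes().decode()


def simulate_reads(
    members: Mapping[str, str],
    probs: pd.DataFrame,
    sample_sheet: pd.DataFrame,
    config: SimConfig,
) -> tuple[dict[str, list[tuple[str, str]]], pd.DataFrame]:
    """Barcoded, error-corrupted amplicon reads for every sample.

    ``members`` maps gene_id to its amplicon (adaptored fragment) sequence.
    Each read is ``barcode + member sequence`` with per-base errors applied
    to the whole read, and is reverse-complemented with probability 1/2.
    Returns ``(reads, truth)`` where reads maps sample -> [(read_id, seq)]
    and truth records the member of origin of every read.
    """
    missing = [g for g in probs.index if g not in members]
    if missing:
        raise KeyError(f"no member sequence for genes: {missing[:5]}")
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 1]))
    genes = list(probs.index)
    reads: dict[str, list[tuple[str, str]]] = {}
    truth_rows = []
    for row in sample_sheet.itertuples(index=False):
        p = probs[row.sample].to_numpy()
        counts = rng.multinomial(config.n_reads, p)
        origin = np.repeat(np.arange(len(genes)), counts)
        rng.shuffle(origin)
        flip = rng.random(config.n_reads) < 0.5
        sample_reads = []
        for i, gi in enumerate(origin):
            gid = genes[gi]
            seq = row.barcode + members[gid]
            seq = _corrupt(seq, rng, config.substitution_rate,
                           config.insertion_rate, config.deletion_rate)
            if flip[i]:
                seq = reverse_complement(seq)
            rid = f"{row.sample}_read{i:07d}"
            sample_reads.append((rid, seq))
            truth_rows.append(dict(read_id=rid, sample=row.sample, gene_id=gid))
        reads[row.sample] = sample_reads
    return reads, pd.DataFrame(truth_rows)


def simulate_counts(
    genes: Sequence[str], config: SimConfig
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Multinomial per-sample read counts drawn directly from the abundance
    model, skipping sequence-level simulation.

    This is the scale-friendly route for testing the downstream statistics:
    the counts are exactly what an error-free sequencing + perfect assignment
    of ``n_reads`` reads would deliver.
    """
    probs, sheet = simulate_abundances(genes, config)
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 2]))
    counts = pd.DataFrame(
        {s: rng.multinomial(config.n_reads, probs[s].to_numpy())
         for s in probs.columns},
        index=probs.index,
    )
    return counts, sheet


# ---------------------------------------------------------------------------
# plain-text output
# ---------------------------------------------------------------------------


def write_fastq(reads: Iterable[tuple[str, str]], path: str | Path) -> None:
    """Write reads as Sanger-encoded FASTQ with constant placeholder quality."""
    with open(path, "w") as fh:
        for rid, seq in reads:
            fh.write(f"@{rid}\n{seq}\n+\n{'I' * len(seq)}\n")


def write_run(
    reads: dict[str, list[tuple[str, str]]],
    truth: pd.DataFrame,
    sample_sheet: pd.DataFrame,
    out_dir: str | Path,
) -> None:
    """Write one FASTQ per sample plus the truth table and sample sheet."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for sample, rs in reads.items():
        write_fastq(rs, out / f"{sample}.fastq")
    truth.to_csv(out / "truth.tsv", sep="\t", index=False)
    sample_sheet.to_csv(out / "samples.tsv", sep="\t", index=False)
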