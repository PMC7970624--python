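"""Sequence and annotation I/O plus the elementary sequence computations
used throughout guide/donor design and read quantification.

Coordinates are 0-based half-open internally; annotation tables at the I/O
boundary use 1-based inclusive coordinates (the common tabular convention).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq

DNA_ALPHABET = frozenset("ACGT")
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

#: columns required in the canonical annotation table (TSV)
ANNOTATION_COLUMNS = ["gene_id", "chrom", "start", "end", "strand", "essential"]


class SequenceError(ValueError):
    """Raised for malformed sequence input."""


def reverse_complement(seq: str) -> str:
    """Reverse complement of a DNA string (A/C/G/T/N)."""
    return seq.translate(_COMPLEMENT)[::-1]


def translate(cds: str) -> str:
    """Translate a nucleotide string with the standard genetic code.

    Stop codons are rendered as ``'*'`` and translation does not terminate
    at them, so frame-shifted sequences can be inspected for premature
    stops.  A trailing incomplete codon is ignored.

    Raises
    ------
    SequenceError
        if the sequence contains characters outside A/C/G/T.
    """
    bad = set(cds) - DNA_ALPHABET
    if bad:
        raise SequenceError(f"non-ACGT characters in sequence: {sorted(bad)}")
    usable = len(cds) - len(cds) % 3
    return str(Seq(cds[:usable]).translate())


def gc_fraction(seq: str) -> float:
    """(#G + #C) / length, on a non-empty A/C/G/T string."""
    if not seq:
        raise SequenceError("gc_fraction of empty sequence")
    bad = set(seq) - DNA_ALPHABET
    if bad:
        raise SequenceError(f"non-ACGT characters in sequence: {sorted(bad)}")
    return (seq.count("G") + seq.count("C")) / len(seq)


def max_homopolymer(seq: str) -> int:
    """Length of the longest run of a single repeated base."""
    if not seq:
        raise SequenceError("max_homopolymer of empty sequence")
    return max(len(list(g)) for _, g in itertools.groupby(seq))


# ---------------------------------------------------------------------------
# ORF records and annotation I/O
# ---------------------------------------------------------------------------


@dataclass
class OrfRecord:
    """A single target gene's coding sequence with its genomic placement.

    ``cds_seq`` is always on the coding strand (starts with ATG when valid).
    ``start``/``end`` are 0-based half-open genomic coordinates.  Records
    whose CDS violates the ORF invariants are kept but flagged via
    ``valid``/``invalid_reason`` so that callers can report rather than
    silently drop them.
    """

    gene_id: str
    chrom: str
    start: int
    end: int
    strand: str
    cds_seq: str
    essential: bool
    valid: bool = True
    invalid_reason: str = ""

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"{self.gene_id}: strand must be '+' or '-'")
        problems = []
        seq = self.cds_seq.upper()
        self.cds_seq = seq
        if set(seq) - DNA_ALPHABET:
            problems.append("non-ACGT characters")
        if len(seq) < 30:
            problems.append(f"CDS shorter than 30 nt ({len(seq)})")
        if len(seq) % 3 != 0:
            problems.append(f"CDS length {len(seq)} not divisible by 3")
        if not problems:
            aa = translate(seq)
            if not aa.startswith("M"):
                problems.append("CDS does not start with ATG")
            if "*" in aa[:-1]:
                problems.append(f"internal stop codon at aa {aa.index('*')}")
            if not aa.endswith("*"):
                problems.append("CDS lacks a terminal stop codon")
        if problems:
            self.valid = False
            self.invalid_reason = "; ".join(problems)

    @property
    def protein(self) -> str:
        """Amino-acid sequence without the terminal stop."""
        return translate(self.cds_seq).rstrip("*")


def read_annotation(annotation_path: str | Path) -> pd.DataFrame:
    """Read the canonical tab-separated annotation table.

    Expected columns: gene_id, chrom, start, end, strand, essential, with
    1-based inclusive start/end.  Tolerant of CRLF line endings.
    """
    tab = pd.read_csv(annotation_path, sep="\t", dtype={"gene_id": str, "chrom": str})
    missing = [c for c in ANNOTATION_COLUMNS if c not in tab.columns]
    if missing:
        raise ValueError(f"annotation table lacks columns: {missing}")
    tab["essential"] = tab["essential"].astype(bool)
    return tab


def gff3_to_annotation(
    gff3_path: str | Path, essential_ids: Iterable[str] = ()
) -> pd.DataFrame:
    """Convenience reader: derive the canonical annotation table from GFF3.

    Uses single-exon ``CDS`` features (falling back to ``gene``), taking the
    gene identifier from the ``ID``/``Name``/``gene_id`` attribute.  Genes
    whose id is in ``essential_ids`` are flagged essential.  Multi-exon
    genes are not supported by this convenience layer.
    """
    essential = set(essential_ids)
    rows = []
    seen = set()
    with open(gff3_path, newline="") as fh:
        for line in fh:
            line = line.rstrip("\r\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 9:
                continue
            chrom, _src, ftype, start, end, _score, strand, _frame, attrs = parts
            if ftype not in ("CDS", "gene"):
                continue
            attr = dict(
                kv.split("=", 1) for kv in attrs.split(";") if "=" in kv
            )
            gid = attr.get("gene_id") or attr.get("Name") or attr.get("ID")
            if gid is None:
                continue
            gid = gid.removeprefix("cds-").removeprefix("gene-")
            if (gid, ftype) in seen:
                raise ValueError(
                    f"gene {gid}: multiple {ftype} features; multi-exon genes "
                    "are not supported by the GFF3 convenience reader"
                )
            seen.add((gid, ftype))
            rows.append(
                dict(gene_id=gid, chrom=chrom, start=int(start), end=int(end),
                     strand=strand, essential=gid in essential, ftype=ftype)
            )
    tab = pd.DataFrame(rows)
    if tab.empty:
        raise ValueError(f"no gene/CDS features found in {gff3_path}")
    # prefer CDS features over gene features for the same id
    tab["pref"] = (tab["ftype"] != "CDS").astype(int)
    tab = (
        tab.sort_values(["gene_id", "pref"]).drop_duplicates("gene_id")
        .drop(columns=["ftype", "pref"]).reset_index(drop=True)
    )
    return tab[ANNOTATION_COLUMNS]


def read_fasta(fasta_path: str | Path) -> dict[str, str]:
    """FASTA file to an id → uppercase sequence mapping (wrapped/CRLF ok)."""
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(fasta_path), "fasta")}


def read_orfs(fasta_path: str | Path, annotation_path: str | Path) -> list[OrfRecord]:
    """Build one :class:`OrfRecord` per annotation row.

    The FASTA may hold genomic contigs (annotation ``chrom`` resolves to a
    FASTA id and the CDS is sliced out, reverse-complemented for minus-strand
    genes) or per-gene CDS sequences (FASTA id equals ``gene_id``, sequence
    taken as the coding strand).  A gene resolvable in neither way is a hard
    error.  Records that fail the ORF invariants are returned flagged
    invalid, never dropped.
    """
    seqs = read_fasta(fasta_path)
    tab = read_annotation(annotation_path)
    records: list[OrfRecord] = []
    for row in tab.itertuples(index=False):
        start0, end0 = int(row.start) - 1, int(row.end)
        if row.chrom in seqs:
            contig = seqs[row.chrom]
            if end0 > len(contig):
                raise ValueError(
                    f"gene {row.gene_id}: coordinates {row.start}-{row.end} exceed "
                    f"contig {row.chrom} length {len(contig)}"
                )
            chunk = contig[start0:end0]
            cds = reverse_complement(chunk) if row.strand == "-" else chunk
        elif row.gene_id in seqs:
            cds = seqs[row.gene_id]
        else:
            raise ValueError(
                f"gene {row.gene_id}: no sequence found (neither contig "
                f"{row.chrom!r} nor gene id present in FASTA)"
            )
        records.append(
            OrfRecord(
                gene_id=str(row.gene_id), chrom=str(row.chrom), start=start0,
                end=end0, strand=row.strand, cds_seq=cds,
                essential=bool(row.essential),
            )
        )
    return records


# ---------------------------------------------------------------------------
# Genome-wide PAM-site index for off-target distance
# ---------------------------------------------------------------------------

_ENC = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate("ACGT"):
    _ENC[ord(_b)] = _i


def _encode(seq: str) -> np.ndarray:
    return _ENC[np.frombuffer(seq.encode(), dtype=np.uint8)]


@dataclass
class GuideSite:
    contig: str
    pos: int          # 0-based position of the protospacer on the + strand span
    strand: str
    protospacer: str  # 20-mer in guide orientation


class GenomeIndex:
    """Exhaustive index of PAM(NGG)-adjacent 20-mers on both genome strands.

    Sites overlapping ambiguous bases (N etc.) are excluded — no guide is
    designed over unknown sequence, and such sites cannot be scored.  The
    index supports the off-target criterion: the minimum Hamming distance
    from a query protospacer to every *other* PAM-adjacent 20-mer.
    """

    guide_len = 20

    def __init__(self, contigs: Mapping[str, str]):
        self.contigs = {k: v.upper() for k, v in contigs.items()}
        self.sites: list[GuideSite] = []
        for cid, seq in self.contigs.items():
            n = len(seq)
            for i in range(n - 22):
                # + strand: [i, i+20) protospacer, PAM = N G G at i+20..i+23
                if seq[i + 21] == "G" and seq[i + 22] == "G":
                    proto = seq[i : i + 20]
                    if not set(proto) - DNA_ALPHABET:
                        self.sites.append(GuideSite(cid, i, "+", proto))
                # - strand: C C N at [i, i+3) then 20-mer; protospacer is the
                # reverse complement of seq[i+3:i+23]
                if seq[i] == "C" and seq[i + 1] == "C":
                    window = seq[i + 3 : i + 23]
                    if len(window) == 20 and not set(window) - DNA_ALPHABET:
                        self.sites.append(
                            GuideSite(cid, i + 3, "-", reverse_complement(window))
                        )
        if self.sites:
            self._matrix = np.stack([_encode(s.protospacer) for s in self.sites])
        else:
            self._matrix = np.empty((0, self.guide_len), dtype=np.uint8)

    @property
    def site_count(self) -> int:
        return len(self.sites)

    def min_mismatch_to_others(self, protospacer: str) -> int:
        """Smallest Hamming distance from ``protospacer`` to any other
        indexed 20-mer.

        One exact occurrence is treated as the query's own locus and
        excluded; additional exact occurrences count as distance-0
        off-targets.  With no other site in the index the distance is the
        guide length (nothing to cross-hybridise with).
        """
        if len(protospacer) != self.guide_len:
            raise ValueError("protospacer must be 20 nt")
        if self._matrix.shape[0] == 0:
            return self.guide_len
        dists = np.count_nonzero(self._matrix != _encode(protospacer), axis=1)
        zeros = int(np.count_nonzero(dists == 0))
        if zeros >= 2:
            return 0
        others = dists[dists > 0] if zeros == 1 else dists
        return int(others.min()) if others.size else self.guide_len
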