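"""From amplicon reads to a per-gene count table: barcode demultiplexing,
error-tolerant assignment of each read to a known library member, and
library-representation QC.

Assignment is mapping-free: every read is compared (by edit distance, both
orientations) against the full set of known member amplicon sequences, and
counted for the unique closest member within an edit-distance budget.
Equidistant minima are ambiguous and counted in neither member; distances
above the budget leave the read unassigned.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import edlib
import numpy as np
import pandas as pd
from Bio import SeqIO

from .seqcore import reverse_complement

DEFAULT_MAX_EDIT_FRACTION = 0.15
DEFAULT_MAX_BARCODE_MISMATCH = 4


class QuantifyError(ValueError):
    pass


def read_fastq(path: str | Path) -> list[tuple[str, str]]:
    """FASTQ file to [(read_id, sequence)] (qualities are not used)."""
    return [(rec.id, str(rec.seq).upper())
            for rec in SeqIO.parse(str(path), "fastq")]


@dataclass
class CountTable:
    """Sample x gene read counts with their condition/replicate structure.

    Invariant: per sample, assigned + ambiguous + unassigned equals the
    number of reads processed (checked by :meth:`validate`).
    """

    counts: pd.DataFrame              # genes x samples, non-negative ints
    sample_sheet: pd.DataFrame        # sample, condition, replicate[, barcode]
    unassigned: pd.Series             # per sample
    ambiguous: pd.Series              # per sample
    total_reads: pd.Series            # per sample

    def validate(self) -> None:
        for s in self.counts.columns:
            n = int(self.counts[s].sum() + self.unassigned[s] + self.ambiguous[s])
            if n != int(self.total_reads[s]):
                raise QuantifyError(
                    f"count conservation violated for sample {s}: "
                    f"{n} != {self.total_reads[s]}"
                )

    def replicates(self, condition: str) -> pd.DataFrame:
        names = self.sample_sheet.loc[
            self.sample_sheet["condition"] == condition, "sample"
        ]
        return self.counts[list(names)]


# ---------------------------------------------------------------------------
# demultiplexing
# ---------------------------------------------------------------------------


def _barcode_distance(read: str, barcode: str, slack: int) -> int:
    """Best edit distance of the barcode within the read's first bases."""
    window = read[: len(barcode) + slack]
    if not window:
        return len(barcode)
    return edlib.align(barcode, window, mode="HW", task="distance")["editDistance"]


def demultiplex(
    reads: Iterable[tuple[str, str]],
    sample_sheet: pd.DataFrame,
    max_barcode_mismatch: int = DEFAULT_MAX_BARCODE_MISMATCH,
) -> tuple[dict[str, list[tuple[str, str]]], list[tuple[str, str]]]:
    """Assign reads to samples by their barcode at either read end.

    A read goes to the unique barcode within ``max_barcode_mismatch`` edits
    of the read start in either orientation; otherwise it is returned in the
    unassigned list.  Barcode pairs closer than 2x the threshold (Hamming)
    are rejected up front as a configuration error.
    """
    barcodes = list(sample_sheet["barcode"])
    samples = list(sample_sheet["sample"])
    for (i, a), (j, b) in combinations(enumerate(barcodes), 2):
        if len(a) == len(b):
            d = sum(x != y for x, y in zip(a, b))
            if d <= 2 * max_barcode_mismatch:
                raise QuantifyError(
                    f"barcodes for samples {samples[i]!r} and {samples[j]!r} are "
                    f"only {d} apart; need > {2 * max_barcode_mismatch}"
                )
    out: dict[str, list[tuple[str, str]]] = {s: [] for s in samples}
    unassigned: list[tuple[str, str]] = []
    for rid, seq in reads:
        rc = reverse_complement(seq)
        best, second, best_sample = None, None, None
        for sample, bc in zip(samples, barcodes):
            d = min(_barcode_distance(seq, bc, max_barcode_mismatch),
                    _barcode_distance(rc, bc, max_barcode_mismatch))
            if best is None or d < best:
                best, second, best_sample = d, best, sample
            elif second is None or d < second:
                second = d
        if best is not None and best <= max_barcode_mismatch and (
            second is None or best < second
        ):
            out[best_sample].append((rid, seq))
        else:
            unassigned.append((rid, seq))
    return out, unassigned


# ---------------------------------------------------------------------------
# member assignment
# ---------------------------------------------------------------------------


def min_pairwise_member_distance(members: Mapping[str, str]) -> int:
    """Smallest pairwise edit distance among member sequences (their
    distinguishability budget)."""
    seqs = list(members.values())
    if len(seqs) < 2:
        return max((len(s) for s in seqs), default=0)
    return min(
        edlib.align(a, b, mode="NW", task="distance")["editDistance"]
        for a, b in combinations(seqs, 2)
    )


def assign_reads(
    reads: Iterable[tuple[str, str]],
    members: Mapping[str, str],
    max_edit_fraction: float = DEFAULT_MAX_EDIT_FRACTION,
) -> tuple[pd.Series, int, int, dict[str, str]]:
    """Count reads per library member by minimum edit distance.

    Each member sequence is aligned as an infix of the read (and of its
    reverse complement); the read counts for the member with the uniquely
    smallest distance, provided it is at most
    ``max_edit_fraction * len(member)``.

    Returns ``(counts, n_unassigned, n_ambiguous, assignments)`` where
    assignments maps read_id -> gene_id for the assigned reads.
    """
    if not members:
        raise QuantifyError("empty library")
    genes = list(members)
    thresholds = {g: max_edit_fraction * len(members[g]) for g in genes}
    counts = {g: 0 for g in genes}
    unassigned = ambiguous = 0
    assignments: dict[str, str] = {}
    for rid, seq in reads:
        rc = reverse_complement(seq)
        best_d, best_gene, tie = None, None, False
        for g in genes:
            q = members[g]
            d = min(
                edlib.align(q, seq, mode="HW", task="distance")["editDistance"],
                edlib.align(q, rc, mode="HW", task="distance")["editDistance"],
            )
            if best_d is None or d < best_d:
                best_d, best_gene, tie = d, g, False
            elif d == best_d:
                tie = True
        if best_d is None or best_d > thresholds[best_gene]:
            unassigned += 1
        elif tie:
            ambiguous += 1
        else:
            counts[best_gene] += 1
            assignments[rid] = best_gene
    return pd.Series(counts, name="count"), unassigned, ambiguous, assignments


def count_samples(
    reads_by_sample: Mapping[str, list[tuple[str, str]]],
    members: Mapping[str, str],
    sample_sheet: pd.DataFrame,
    max_edit_fraction: float = DEFAULT_MAX_EDIT_FRACTION,
) -> CountTable:
    """Assign every sample's reads and assemble the :class:`CountTable`."""
    counts, unas, ambi, totals = {}, {}, {}, {}
    for sample in sample_sheet["sample"]:
        rs = reads_by_sample.get(sample, [])
        c, u, a, _ = assign_reads(rs, members, max_edit_fraction)
        counts[sample], unas[sample], ambi[sample] = c, u, a
        totals[sample] = len(rs)
    table = CountTable(
        counts=pd.DataFrame(counts).astype(int),
        sample_sheet=sample_sheet.reset_index(drop=True),
        unassigned=pd.Series(unas, dtype=int),
        ambiguous=pd.Series(ambi, dtype=int),
        total_reads=pd.Series(totals, dtype=int),
    )
    table.validate()
    return table


# ---------------------------------------------------------------------------
# representation QC
# ---------------------------------------------------------------------------


def gini_coefficient(counts: Sequence[float] | np.ndarray) -> float:
    """Gini coefficient of member representation (0 = perfectly uniform)."""
    x = np.sort(np.asarray(counts, dtype=float))
    n = x.size
    if n == 0:
        raise QuantifyError("no members")
    total = x.sum()
    if total == 0:
        return 0.0
    ranks = np.arange(1, n + 1)
    return float(((2 * ranks - n - 1) * x).sum() / (n * total))


def library_uniformity(counts: pd.Series) -> dict:
    """Representation summary for one (plasmid-pool) sample.

    Reports min/max counts, dropped-out members (zero reads), the Gini
    coefficient and the fold-range (max/min over detected members; inf when
    any member is missing).
    """
    c = counts.astype(float)
    missing = sorted(c.index[c == 0])
    nonzero_min = float(c[c > 0].min()) if (c > 0).any() else 0.0
    cmax = float(c.max()) if len(c) else 0.0
    fold = float("inf") if missing else (cmax / nonzero_min if nonzero_min else 0.0)
    return {
        "min": float(c.min()) if len(c) else 0.0,
        "max": cmax,
        "n_members": int(len(c)),
        "missing": missing,
        "n_missing": len(missing),
        "gini": gini_coefficient(c.to_numpy()),
        "fold_range": fold,
    }


def fold_coverage(n_clones: int, n_members: int) -> float:
    """Library coverage: clones screened per library member."""
    if n_members <= 0:
        raise QuantifyError("n_members must be positive")
    return n_clones / n_members
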