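"""Guide selection, frameshift-donor construction, in-silico HDR validation
and synthesis-fragment assembly for pooled CRISPR-Cas9 gene disruption.

The disruption strategy: a Cas9 guide is chosen inside the target coding
sequence (preferentially its first quarter, so the truncated protein is
short), and a 165 bp repair donor replaces the 23 nt protospacer+PAM region
with a 22 nt sequence.  The net 1 bp deletion shifts the reading frame, the
rewritten bases guarantee an early premature termination codon (PTC), and
the destroyed PAM makes re-cutting of the repaired locus impossible.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml
from numpy.lib.stride_tricks import sliding_window_view

from .seqcore import (
    DNA_ALPHABET,
    GenomeIndex,
    OrfRecord,
    _encode,
    gc_fraction,
    max_homopolymer,
    reverse_complement,
    translate,
)

# --- default constant parts -------------------------------------------------
# Standard chimeric single-guide scaffold (tracrRNA-derived) with a 3 nt
# linker, 79 nt total, followed in the expression cassette by a 36 nt SUP4
# terminator.  With a 20 nt guide and 165 bp donor the synthesis core is
# 20 + 79 + 36 + 165 = 300 bp.
SGRNA_SCAFFOLD = (
    "GTTTTAGAGCTAGAAATAGCAAGTTAAAATAAGGCTAGTCCGTTATCAACTTGAAAAAGTGGCACCGAGTCGGTGC"
    "TTT"
)
SUP4_TERMINATOR = "TTTTTTTGTTTTTTATGTCTTGTTTATTTTTTGTTT"
# synthetic synthesis end adaptors (22 + 21 = 43 nt total)
SYNTH_ADAPTOR_5 = "AGCGTGACCTTGAGCATCTCAG"
SYNTH_ADAPTOR_3 = "CTGAGACCGTTAAGACCCGAT"

_IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}
_COMP = {"A": "T", "C": "G", "G": "C", "T": "A"}
_IUPAC_COMP = {
    "A": "T", "C": "G", "G": "C", "T": "A", "N": "N", "R": "Y", "Y": "R",
    "S": "S", "W": "W", "K": "M", "M": "K", "B": "V", "V": "B", "D": "H",
    "H": "D",
}

STOP_PREFERENCE = {"TAA": 0, "TAG": 1, "TGA": 2}


class DesignError(ValueError):
    """Raised when a guide/donor/fragment cannot be constructed."""


class UndesignableError(DesignError):
    """Raised when no guide for a gene satisfies the selection criteria."""


@dataclass
class DesignRules:
    """All tunable design parameters, with the library's defaults.

    ``replaced_span - replacement_len`` must equal 1: replacing the 23 nt
    protospacer+PAM with 22 nt is what produces the 1 bp frameshift.
    """

    pam: str = "NGG"
    guide_len: int = 20
    gc_max: float = 0.50
    max_run: int = 3
    position_fraction_max: float = 0.25
    fallback_tiers: tuple[float, ...] = (0.25, 0.5, 1.0)
    donor_len: int = 165
    replaced_span: int = 23
    replacement_len: int = 22
    deletion_donor_len: int = 150
    fragment_len: int = 300
    adaptor_len_total: int = 43
    # PTC acceptance: first stop of the edited frame must appear within
    # this many codons after the replacement and before this fraction of
    # the original protein length
    ptc_downstream_codons: int = 10
    ptc_max_fraction: float = 0.5
    scaffold_seq: str = SGRNA_SCAFFOLD
    terminator_seq: str = SUP4_TERMINATOR
    adaptor_5: str = SYNTH_ADAPTOR_5
    adaptor_3: str = SYNTH_ADAPTOR_3

    def __post_init__(self) -> None:
        if self.replaced_span - self.replacement_len != 1:
            raise ValueError(
                "replaced_span - replacement_len must be 1 (the frameshift); "
                f"got {self.replaced_span} - {self.replacement_len}"
            )
        if self.donor_len <= self.replacement_len:
            raise ValueError("donor_len must exceed replacement_len")
        if len(self.pam) != 3:
            raise ValueError("only 3 nt PAM motifs are supported")
        if self.deletion_donor_len % 2 != 0:
            raise ValueError("deletion_donor_len must be even (two equal flanks)")

    @property
    def left_arm_len(self) -> int:
        # 165 - 22 = 143 is odd; the extra base goes to the right arm
        return (self.donor_len - self.replacement_len) // 2

    @property
    def right_arm_len(self) -> int:
        return self.donor_len - self.replacement_len - self.left_arm_len

    @property
    def deletion_flank_len(self) -> int:
        return self.deletion_donor_len // 2

    @classmethod
    def from_yaml(cls, path: str | Path) -> "DesignRules":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        if "fallback_tiers" in data:
            data["fallback_tiers"] = tuple(data["fallback_tiers"])
        return cls(**data)


@dataclass
class GuideCandidate:
    """A PAM-adjacent 20-mer inside a target CDS, with its filter metrics."""

    gene_id: str
    protospacer: str
    pam: str
    strand: str                # relative to the coding strand
    span_start: int            # 0-based CDS offset of the 23 nt protospacer+PAM span
    cut_site: int              # 0-based CDS offset of the blunt cut (3 bp from PAM)
    position_fraction: float
    gc: float
    max_run: int
    offtarget_min_mismatch: int | None
    pass_flags: dict[str, bool] = field(default_factory=dict)
    fallback_tier: float | None = None  # set on the selected guide

    @property
    def passes_hard_filters(self) -> bool:
        return self.pass_flags["gc"] and self.pass_flags["run"]


@dataclass
class FrameshiftDonor:
    """The 165 bp repair template producing a 1 bp frameshift and early PTC."""

    gene_id: str
    seq: str
    left_arm: str
    right_arm: str
    replacement: str              # on the coding strand
    replaced_span: tuple[int, int]  # 0-based half-open CDS coordinates
    ptc_codon_index: int
    edited_protein_len: int
    protospacer: str              # guide orientation, for re-cut checks


@dataclass
class DeletionDonor:
    """150 bp donor of two 75 nt flanks that excises the ORF completely."""

    gene_id: str
    seq: str
    up_flank: str
    down_flank: str

    # duck-type as a donor for simulate_hdr_edit: deletion = empty replacement
    @property
    def left_arm(self) -> str:
        return self.up_flank

    @property
    def right_arm(self) -> str:
        return self.down_flank

    @property
    def replacement(self) -> str:
        return ""


@dataclass
class LibraryFragment:
    """One synthesis unit: guide + scaffold + terminator + donor (+ adaptors)."""

    gene_id: str
    guide20: str
    scaffold_seq: str
    terminator_seq: str
    donor_seq: str
    core_seq: str
    adaptored_seq: str


@dataclass
class EditReport:
    frameshift_bp: int            # net bases removed (negative = inserted)
    ptc_codon_index: int | None   # first stop codon of the edited frame
    edited_protein_len: int | None
    recut_possible: bool | None   # None when no protospacer was supplied


# ---------------------------------------------------------------------------
# guide enumeration and selection
# ---------------------------------------------------------------------------


def _matches_iupac(seq: str, motif: str) -> bool:
    return len(seq) == len(motif) and all(
        b in _IUPAC[m] for b, m in zip(seq, motif)
    )


def enumerate_guides(
    orf: OrfRecord, rules: DesignRules, genome: GenomeIndex | None = None
) -> list[GuideCandidate]:
    """Every PAM-adjacent 20-mer on both strands of the CDS, annotated.

    Windows containing ambiguous bases are disqualified.  Off-target
    distances are computed against ``genome`` when supplied, otherwise
    left as ``None`` and flagged unknown.
    """
    cds = orf.cds_seq
    gl, span = rules.guide_len, rules.replaced_span
    if len(cds) < gl + 3:
        raise DesignError(f"{orf.gene_id}: CDS shorter than guide + PAM")
    rc_pam = "".join(_IUPAC_COMP[m] for m in reversed(rules.pam))
    out: list[GuideCandidate] = []
    for i in range(len(cds) - span + 1):
        window = cds[i : i + span]
        if set(window) - DNA_ALPHABET:
            continue
        # + strand: protospacer then PAM
        if _matches_iupac(window[gl:], rules.pam):
            out.append(_make_candidate(orf, rules, genome, i, "+", window[:gl],
                                       window[gl:]))
        # - strand: the window is revcomp(protospacer + PAM)
        if _matches_iupac(window[:3], rc_pam):
            rc = reverse_complement(window)
            out.append(_make_candidate(orf, rules, genome, i, "-", rc[:gl],
                                       rc[gl:]))
    return out


def _make_candidate(
    orf: OrfRecord, rules: DesignRules, genome: GenomeIndex | None,
    span_start: int, strand: str, protospacer: str, pam: str,
) -> GuideCandidate:
    # blunt Cas9 cut 3 bp 5' of the PAM
    cut = span_start + 17 if strand == "+" else span_start + 6
    gc = gc_fraction(protospacer)
    run = max_homopolymer(protospacer)
    off = genome.min_mismatch_to_others(protospacer) if genome is not None else None
    frac = cut / len(orf.cds_seq)
    return GuideCandidate(
        gene_id=orf.gene_id, protospacer=protospacer, pam=pam, strand=strand,
        span_start=span_start, cut_site=cut, position_fraction=frac,
        gc=gc, max_run=run, offtarget_min_mismatch=off,
        pass_flags={
            "gc": gc <= rules.gc_max,
            "run": run <= rules.max_run,
            "position_q1": frac < rules.position_fraction_max,
            "offtarget_known": off is not None,
        },
    )


def _selection_key(c: GuideCandidate) -> tuple:
    off = c.offtarget_min_mismatch if c.offtarget_min_mismatch is not None else -1
    return (-off, c.cut_site, c.protospacer)


def rank_guides(
    candidates: Sequence[GuideCandidate], rules: DesignRules
) -> list[GuideCandidate]:
    """All hard-filter-passing candidates in selection order.

    GC and homopolymer filters are never relaxed.  Position in the CDS is a
    preference with fallback tiers (first quarter, then first half, then the
    whole CDS); within the first non-empty tier candidates are ordered by
    greatest off-target distance, then earliest cut site, then protospacer.
    Each returned candidate carries the tier at which it became eligible.
    """
    passing = [c for c in candidates if c.passes_hard_filters]
    ordered: list[GuideCandidate] = []
    seen: set[int] = set()
    for tier in rules.fallback_tiers:
        newly = [
            c for c in passing
            if c.position_fraction < tier and id(c) not in seen
        ]
        for c in sorted(newly, key=_selection_key):
            c.fallback_tier = tier
            ordered.append(c)
            seen.add(id(c))
    return ordered


def select_guide(
    candidates: Sequence[GuideCandidate], rules: DesignRules
) -> GuideCandidate:
    """Deterministically pick the best guide; see :func:`rank_guides`."""
    if not candidates:
        raise UndesignableError("no PAM-adjacent site in the CDS")
    ordered = rank_guides(candidates, rules)
    if not ordered:
        n_gc = sum(not c.pass_flags["gc"] for c in candidates)
        n_run = sum(not c.pass_flags["run"] for c in candidates)
        raise UndesignableError(
            f"no candidate passes the hard filters "
            f"({n_gc}/{len(candidates)} fail GC <= {rules.gc_max:.0%}, "
            f"{n_run}/{len(candidates)} fail homopolymer <= {rules.max_run})"
        )
    return ordered[0]


# ---------------------------------------------------------------------------
# frameshift donor construction
# ---------------------------------------------------------------------------


def _recut_possible(seq: str, protospacer: str, max_mm: int = 2) -> bool:
    """Does ``seq`` (either strand) still contain the protospacer with <=
    ``max_mm`` mismatches next to an intact NGG PAM?"""
    q = _encode(protospacer)
    g = int(_encode("G")[0])
    for s in (seq, reverse_complement(seq)):
        n = len(s)
        if n < len(protospacer) + 3:
            continue
        enc = _encode(s)
        wins = sliding_window_view(enc, len(protospacer))[: n - len(protospacer) - 2]
        mism = np.count_nonzero(wins != q, axis=1)
        pam_ok = (enc[len(protospacer) + 1 : n - 1] == g) & (
            enc[len(protospacer) + 2 : n] == g
        )
        if np.any((mism <= max_mm) & pam_ok):
            return True
    return False


def _ptc_of_edit(
    cds: str, span_start: int, replacement_cds: str, rules: DesignRules,
    orig_protein_len: int,
) -> tuple[int, str] | None:
    """First stop codon of the edited CDS, if it satisfies the PTC policy.

    Returns (codon index, stop codon) or None.  The stop must occur within
    the replacement or at most ``ptc_downstream_codons`` codons after it,
    and before ``ptc_max_fraction`` of the original protein length.
    """
    edited = cds[:span_start] + replacement_cds + cds[span_start + rules.replaced_span:]
    aa = translate(edited)
    i = aa.find("*")
    if i < 0:
        return None
    repl_end_codon = (span_start + len(replacement_cds) + 2) // 3
    if i > repl_end_codon + rules.ptc_downstream_codons:
        return None
    if i >= rules.ptc_max_fraction * orig_protein_len:
        return None
    return i, edited[3 * i : 3 * i + 3]


def design_frameshift_donor(
    orf: OrfRecord, guide: GuideCandidate, rules: DesignRules
) -> FrameshiftDonor:
    """Construct the 165 bp frameshift repair donor for a selected guide.

    The 23 nt protospacer+PAM span is replaced by a 22 nt sequence built
    deterministically: the base immediately 5' of the PAM is deleted (the
    1 bp frameshift), the PAM's GG is flipped to its complement (no re-cut),
    and, if the shifted frame does not already terminate early, up to four
    seed bases (protospacer positions 16-19) are rewritten minimally until
    an early stop codon appears (TAA preferred, then TAG, then TGA).  The
    donor is validated through :func:`simulate_hdr_edit` before return.
    """
    cds = orf.cds_seq
    s = guide.span_start
    la, ra = rules.left_arm_len, rules.right_arm_len
    if s < la or s + rules.replaced_span + ra > len(cds):
        raise DesignError(
            f"{orf.gene_id}: guide at CDS offset {s} lacks {la}/{ra} nt of "
            "flanking context for the homology arms; choose another guide"
        )
    left_arm = cds[s - la : s]
    right_arm = cds[s + rules.replaced_span : s + rules.replaced_span + ra]
    orig_protein_len = len(orf.protein)

    proto, pam = guide.protospacer, guide.pam
    # replacement in guide orientation: protospacer minus its PAM-proximal
    # base, PAM N kept, PAM GG complemented
    def build(seed: Mapping[int, str]) -> str:
        p = list(proto[:19])
        for pos, b in seed.items():
            p[pos] = b
        return "".join(p) + pam[0] + _COMP[pam[1]] + _COMP[pam[2]]

    seed_positions = [15, 16, 17, 18]
    best: tuple[tuple, str, int] | None = None
    for k in range(0, len(seed_positions) + 1):
        for combo in itertools.combinations(seed_positions, k):
            alt_bases = [
                [b for b in "ACGT" if b != proto[pos]] for pos in combo
            ]
            for assignment in itertools.product(*alt_bases):
                repl_guide = build(dict(zip(combo, assignment)))
                repl_cds = (
                    repl_guide if guide.strand == "+"
                    else reverse_complement(repl_guide)
                )
                ptc = _ptc_of_edit(cds, s, repl_cds, rules, orig_protein_len)
                if ptc is None:
                    continue
                edited = cds[:s] + repl_cds + cds[s + rules.replaced_span:]
                if _recut_possible(edited, proto):
                    continue
                key = (STOP_PREFERENCE.get(ptc[1], 3), repl_cds)
                if best is None or key < best[0]:
                    best = (key, repl_cds, ptc[0])
        if best is not None:
            break
    if best is None:
        raise DesignError(
            f"{orf.gene_id}: no 22 nt replacement for guide {proto} yields an "
            "early stop without a re-cuttable site; choose another guide"
        )
    _, replacement, ptc_index = best
    donor = FrameshiftDonor(
        gene_id=orf.gene_id,
        seq=left_arm + replacement + right_arm,
        left_arm=left_arm,
        right_arm=right_arm,
        replacement=replacement,
        replaced_span=(s, s + rules.replaced_span),
        ptc_codon_index=ptc_index,
        edited_protein_len=ptc_index,
        protospacer=proto,
    )
    # validate before returning
    _, report = simulate_hdr_edit(cds, donor, protospacer=proto)
    if report.frameshift_bp != 1 or report.recut_possible:
        raise DesignError(
            f"{orf.gene_id}: donor failed in-silico HDR validation "
            f"(frameshift {report.frameshift_bp} bp, recut {report.recut_possible})"
        )
    return donor


def design_deletion_donor(
    orf: OrfRecord, genome: GenomeIndex | Mapping[str, str], rules: DesignRules
) -> DeletionDonor:
    """150 bp full-ORF-deletion donor: 75 nt flanks immediately outside the ORF."""
    contigs = genome.contigs if isinstance(genome, GenomeIndex) else genome
    if orf.chrom not in contigs:
        raise DesignError(f"{orf.gene_id}: contig {orf.chrom!r} not in genome")
    contig = contigs[orf.chrom].upper()
    fl = rules.deletion_flank_len
    if orf.start < fl or orf.end + fl > len(contig):
        raise DesignError(
            f"{orf.gene_id}: fewer than {fl} nt of genomic context on one side "
            "of the ORF (contig edge)"
        )
    up = contig[orf.start - fl : orf.start]
    down = contig[orf.end : orf.end + fl]
    for name, flank in (("upstream", up), ("downstream", down)):
        if set(flank) - DNA_ALPHABET:
            raise DesignError(
                f"{orf.gene_id}: ambiguous bases in the {name} flank"
            )
    return DeletionDonor(
        gene_id=orf.gene_id, seq=up + down, up_flank=up, down_flank=down
    )


# ---------------------------------------------------------------------------
# in-silico HDR
# ---------------------------------------------------------------------------


def simulate_hdr_edit(
    locus_seq: str, donor, protospacer: str | None = None
) -> tuple[str, EditReport]:
    """Apply a donor to a locus by homology-arm splicing.

    Both arms must occur exactly once in the locus, left before right; the
    region between them is replaced by the donor's replacement.  When the
    locus is a CDS starting at its ATG, the report carries the codon index
    of the first stop of the edited frame.  When the donor's protospacer is
    supplied (or passed explicitly), the report states whether the edited
    locus still contains a Cas9-cuttable near-match (<= 2 mismatches, intact
    PAM).
    """
    left, right, repl = donor.left_arm, donor.right_arm, donor.replacement
    for name, arm in (("left", left), ("right", right)):
        hits = locus_seq.count(arm)
        if hits == 0:
            raise DesignError(f"{name} homology arm not found in locus")
        if hits > 1:
            raise DesignError(f"{name} homology arm occurs {hits} times in locus")
    i = locus_seq.find(left) + len(left)
    j = locus_seq.find(right)
    if j < i:
        raise DesignError("homology arms occur out of order in locus")
    edited = locus_seq[:i] + repl + locus_seq[j:]
    frameshift = len(locus_seq) - len(edited)

    ptc = protein_len = None
    if not set(edited) - DNA_ALPHABET and edited.startswith("ATG"):
        aa = translate(edited)
        k = aa.find("*")
        if k >= 0:
            ptc = k
            protein_len = k
    proto = protospacer or getattr(donor, "protospacer", None)
    recut = _recut_possible(edited, proto) if proto is not None else None
    return edited, EditReport(
        frameshift_bp=frameshift, ptc_codon_index=ptc,
        edited_protein_len=protein_len, recut_possible=recut,
    )


# ---------------------------------------------------------------------------
# fragment assembly and whole-library design
# ---------------------------------------------------------------------------


def assemble_fragment(
    guide: GuideCandidate, donor: FrameshiftDonor, rules: DesignRules
) -> LibraryFragment:
    """Concatenate guide + scaffold + terminator + donor into the synthesis core
    and wrap it in the synthesis end adaptors."""
    core = guide.protospacer + rules.scaffold_seq + rules.terminator_seq + donor.seq
    if len(core) != rules.fragment_len:
        raise DesignError(
            f"core fragment is {len(core)} nt, expected {rules.fragment_len} "
            f"({len(guide.protospacer)} guide + {len(rules.scaffold_seq)} scaffold "
            f"+ {len(rules.terminator_seq)} terminator + {len(donor.seq)} donor)"
        )
    n_adapt = len(rules.adaptor_5) + len(rules.adaptor_3)
    if n_adapt != rules.adaptor_len_total:
        raise DesignError(
            f"adaptors total {n_adapt} nt "
            f"({len(rules.adaptor_5)} + {len(rules.adaptor_3)}), "
            f"expected {rules.adaptor_len_total}"
        )
    return LibraryFragment(
        gene_id=guide.gene_id, guide20=guide.protospacer,
        scaffold_seq=rules.scaffold_seq, terminator_seq=rules.terminator_seq,
        donor_seq=donor.seq, core_seq=core,
        adaptored_seq=rules.adaptor_5 + core + rules.adaptor_3,
    )


def parse_fragment(core_seq: str, rules: DesignRules) -> dict[str, str]:
    """Decompose a core fragment back into guide / scaffold / terminator / donor.

    The constant parts are verified, so the decomposition is unambiguous.
    """
    gl = rules.guide_len
    ns, nt = len(rules.scaffold_seq), len(rules.terminator_seq)
    if len(core_seq) != rules.fragment_len:
        raise DesignError(
            f"core fragment is {len(core_seq)} nt, expected {rules.fragment_len}"
        )
    scaffold = core_seq[gl : gl + ns]
    terminator = core_seq[gl + ns : gl + ns + nt]
    if scaffold != rules.scaffold_seq or terminator != rules.terminator_seq:
        raise DesignError("constant scaffold/terminator parts do not match rules")
    return {
        "guide20": core_seq[:gl],
        "scaffold_seq": scaffold,
        "terminator_seq": terminator,
        "donor_seq": core_seq[gl + ns + nt :],
    }


def design_library(
    orfs: Iterable[OrfRecord],
    rules: DesignRules | None = None,
    genome: GenomeIndex | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Design one sgRNA-donor fragment per designable non-essential gene.

    Returns ``(library, qc)``.  ``library`` has one row per successful design
    (guide metrics, donor parts, PTC position, assembled core and adaptored
    sequences).  ``qc`` has one row per input record: designed genes with
    their fallback tier and number of guide candidates tried, and essential /
    invalid / undesignable genes with the reason.  The computation is a pure
    function of its inputs, so repeated runs are byte-identical.
    """
    rules = rules or DesignRules()
    lib_rows, qc_rows = [], []
    for orf in orfs:
        if orf.essential:
            qc_rows.append(dict(gene_id=orf.gene_id, status="skipped_essential",
                                reason="flagged essential"))
            continue
        if not orf.valid:
            qc_rows.append(dict(gene_id=orf.gene_id, status="invalid_orf",
                                reason=orf.invalid_reason))
            continue
        try:
            candidates = enumerate_guides(orf, rules, genome)
        except DesignError as exc:
            qc_rows.append(dict(gene_id=orf.gene_id, status="undesignable",
                                reason=str(exc)))
            continue
        ordered = rank_guides(candidates, rules)
        if not ordered:
            try:
                select_guide(candidates, rules)  # raises with the tallied reasons
            except UndesignableError as exc:
                qc_rows.append(dict(gene_id=orf.gene_id, status="undesignable",
                                    reason=str(exc)))
            continue
        designed = None
        last_err = ""
        for attempt, guide in enumerate(ordered, start=1):
            try:
                donor = design_frameshift_donor(orf, guide, rules)
                fragment = assemble_fragment(guide, donor, rules)
                designed = (guide, donor, fragment, attempt)
                break
            except DesignError as exc:
                last_err = str(exc)
        if designed is None:
            qc_rows.append(dict(
                gene_id=orf.gene_id, status="undesignable",
                reason=f"all {len(ordered)} passing guides failed donor "
                       f"construction; last: {last_err}",
            ))
            continue
        guide, donor, fragment, attempt = designed
        lib_rows.append(dict(
            gene_id=orf.gene_id,
            protospacer=guide.protospacer,
            pam=guide.pam,
            strand=guide.strand,
            cut_site=guide.cut_site,
            position_fraction=guide.position_fraction,
            gc=guide.gc,
            max_run=guide.max_run,
            offtarget_min_mismatch=guide.offtarget_min_mismatch,
            fallback_tier=guide.fallback_tier,
            replacement=donor.replacement,
            left_arm=donor.left_arm,
            right_arm=donor.right_arm,
            ptc_codon_index=donor.ptc_codon_index,
            edited_protein_len=donor.edited_protein_len,
            donor_seq=donor.seq,
            core_seq=fragment.core_seq,
            adaptored_seq=fragment.adaptored_seq,
        ))
        qc_rows.append(dict(
            gene_id=orf.gene_id, status="designed",
            reason="" if attempt == 1 else f"first {attempt - 1} guides rejected",
            fallback_tier=guide.fallback_tier, guides_tried=attempt,
            n_candidates=len(candidates),
        ))
    library = pd.DataFrame(lib_rows)
    qc = pd.DataFrame(qc_rows)
    return library, qc


def partition_sublibraries(
    library: pd.DataFrame,
    class_column: str,
    scheme: Mapping[str, str] | None = None,
) -> tuple[dict[str, pd.DataFrame], pd.DataFrame]:
    """Partition library members into sub-pools with an equimolar manifest.

    ``scheme`` maps class labels to pool names (identity when omitted).
    The manifest records, per pool, the member count and the equimolar
    mixing fraction of each member (fractions sum to 1 within each pool).
    """
    if class_column not in library.columns:
        raise KeyError(f"library has no column {class_column!r}")
    labels = library[class_column].astype(str)
    if scheme is None:
        scheme = {lab: lab for lab in labels.unique()}
    unknown = sorted(set(labels) - set(scheme))
    if unknown:
        raise KeyError(f"class labels without a pool mapping: {unknown}")
    pools: dict[str, pd.DataFrame] = {}
    manifest_rows = []
    pool_of = labels.map(scheme)
    for pool in sorted(pool_of.unique()):
        members = library.loc[pool_of == pool].copy()
        frac = 1.0 / len(members)
        members["mixing_fraction"] = frac
        pools[pool] = members.reset_index(drop=True)
        for gid in members["gene_id"]:
            manifest_rows.append(dict(pool=pool, gene_id=gid,
                                      n_members=len(members),
                                      mixing_fraction=frac))
    return pools, pd.DataFrame(manifest_rows)
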