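"""Desk-scale amplicon editing quantification.

Reimplements the standard amplicon-sequencing chain at laptop scale: end
quality trimming and N filtering, paired-read overlap merging, fit
("glocal") alignment of each merged read into the reference amplicon, and a
pileup from which per-adenosine A->G editing percentages are computed.

Conventions: edits are counted as A->G on the reference sense strand (the
sensor cDNA amplicon); reverse-strand reads are reverse-complemented by the
aligner before counting.  ``edit_pct`` is ``100 * G / (A + G)`` and is only
reported where ``A + G`` meets the minimum depth (default 50).  Bystander
positions are flagged above a 2% threshold, mirroring the sub-2% bystander
ceiling expected of a well-behaved sensor duplex.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from Bio import Align

from .errors import InputError
from .seqcore import NucSeq

_DNA_COMP = str.maketrans("ACGTN", "TGCAN")

DEFAULT_Q_CUT = 20
DEFAULT_N_FRAC = 0.10
DEFAULT_MIN_OVERLAP = 10
DEFAULT_MIN_IDENTITY = 0.9
DEFAULT_MIN_SCORE = 30
DEFAULT_MIN_DEPTH = 50
DEFAULT_BYSTANDER_PCT = 2.0


@dataclass
class ReadRecord:
    """One sequencing read: DNA bases (N allowed) and Phred qualities."""

    id: str
    bases: str
    quals: tuple[int, ...]
    mate: str = "single"  # "1" | "2" | "single"

    def __post_init__(self) -> None:
        if len(self.bases) != len(self.quals):
            raise InputError(f"read {self.id}: bases/quals length mismatch")
        if any(q < 0 or q > 60 for q in self.quals):
            raise InputError(f"read {self.id}: Phred scores must be in [0, 60]")

    def __len__(self) -> int:
        return len(self.bases)


def revcomp_read(rec: ReadRecord) -> ReadRecord:
    return ReadRecord(
        rec.id, rec.bases.translate(_DNA_COMP)[::-1], tuple(reversed(rec.quals)), rec.mate
    )


# -- quality control ------------------------------------------------------

@dataclass(frozen=True)
class FilterStats:
    kept: int
    discarded: int
    bases_trimmed: int


def quality_filter(
    reads: list[ReadRecord],
    q_cut: int = DEFAULT_Q_CUT,
    n_frac: float = DEFAULT_N_FRAC,
) -> tuple[list[ReadRecord], FilterStats]:
    """Trim low-quality bases from both ends and drop N-rich reads.

    Bases are removed from each end while the terminal quality is below
    ``q_cut``; a read is discarded if it empties out or if its N fraction
    exceeds ``n_frac``.
    """
    kept = []
    trimmed_total = 0
    discarded = 0
    for rec in reads:
        lo, hi = 0, len(rec)
        while lo < hi and rec.quals[lo] < q_cut:
            lo += 1
        while hi > lo and rec.quals[hi - 1] < q_cut:
            hi -= 1
        trimmed_total += len(rec) - (hi - lo)
        if hi == lo:
            discarded += 1
            continue
        bases = rec.bases[lo:hi]
        if bases.count("N") / len(bases) > n_frac:
            discarded += 1
            continue
        kept.append(ReadRecord(rec.id, bases, rec.quals[lo:hi], rec.mate))
    return kept, FilterStats(len(kept), discarded, trimmed_total)


# -- pair merging ---------------------------------------------------------

@dataclass(frozen=True)
class MergeResult:
    merged: ReadRecord | None
    overlap: int
    identity: float

    @property
    def ok(self) -> bool:
        return self.merged is not None


def merge_pairs(
    r1: ReadRecord,
    r2: ReadRecord,
    min_overlap: int = DEFAULT_MIN_OVERLAP,
    min_identity: float = DEFAULT_MIN_IDENTITY,
) -> MergeResult:
    """Merge a read pair via its suffix/prefix overlap.

    R2 is reverse-complemented, then the maximal-identity overlap of length
    >= ``min_overlap`` between the R1 suffix and the R2 prefix is taken (ties
    go to the longer overlap).  Overlap disagreements are resolved toward
    the higher-quality base (R1 wins exact quality ties); agreements keep
    the higher of the two qualities.
    """
    rc2 = revcomp_read(r2)
    a = np.frombuffer(r1.bases.encode(), dtype=np.uint8)
    b = np.frombuffer(rc2.bases.encode(), dtype=np.uint8)
    best = (-1.0, 0)  # (identity, overlap)
    max_ov = min(len(a), len(b))
    for ov in range(max_ov, min_overlap - 1, -1):
        ident = float(np.mean(a[len(a) - ov :] == b[:ov]))
        if ident > best[0]:
            best = (ident, ov)
            if ident == 1.0:
                break
    identity, ov = best
    if ov == 0 or identity < min_identity:
        return MergeResult(None, 0, max(identity, 0.0))
    start = len(a) - ov
    cons_bases = []
    cons_quals = []
    for k in range(ov):
        b1, q1 = r1.bases[start + k], r1.quals[start + k]
        b2, q2 = rc2.bases[k], rc2.quals[k]
        if b1 == b2:
            cons_bases.append(b1)
            cons_quals.append(max(q1, q2))
        elif q2 > q1:
            cons_bases.append(b2)
            cons_quals.append(q2)
        else:
            cons_bases.append(b1)
            cons_quals.append(q1)
    merged = ReadRecord(
        r1.id,
        r1.bases[:start] + "".join(cons_bases) + rc2.bases[ov:],
        r1.quals[:start] + tuple(cons_quals) + rc2.quals[ov:],
        "single",
    )
    return MergeResult(merged, ov, identity)


# -- alignment ------------------------------------------------------------

@dataclass(frozen=True)
class Alignment:
    read_id: str
    offset: int  # first aligned reference position
    end: int  # one past the last aligned reference position
    strand: str  # "+" or "-"
    score: float
    #: aligned blocks: list of ((ref_start, ref_end), (read_start, read_end))
    blocks: tuple[tuple[tuple[int, int], tuple[int, int]], ...]
    bases: str  # read bases in reference orientation


def _make_aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = 2
    aligner.mismatch_score = -3
    aligner.open_gap_score = -5
    aligner.extend_gap_score = -2
    # fit alignment: the read aligns globally, reference overhangs are free
    # (the unaligned reference ends appear as free end gaps in the read row)
    for side in ("left", "right"):
        try:
            setattr(aligner, f"open_{side}_deletion_score", 0)
            setattr(aligner, f"extend_{side}_deletion_score", 0)
        except AttributeError:
            setattr(aligner, f"query_{side}_open_gap_score", 0)
            setattr(aligner, f"query_{side}_extend_gap_score", 0)
    return aligner

_ALIGNER = _make_aligner()


def align_to_amplicon(
    read: ReadRecord, reference: NucSeq, min_score: float = DEFAULT_MIN_SCORE
) -> Alignment | None:
    """Fit-align a read into the reference amplicon.

    Scoring: match +2, mismatch -3, gap open -5, gap extend -2; reference
    end gaps are free.  Both strands are tried and the better one kept
    (forward wins ties); an exact substring hit short-circuits the dynamic
    programme.  Returns ``None`` when the best score falls below
    ``min_score``.
    """
    ref = reference.to_dna().residues
    if len(ref) > 2000:
        raise InputError("reference amplicons longer than 2000 nt are unsupported")

    exact = ref.find(read.bases)
    if exact >= 0 and "N" not in read.bases:
        n = len(read.bases)
        return Alignment(
            read.id, exact, exact + n, "+", 2.0 * n,
            (((exact, exact + n), (0, n)),), read.bases,
        )

    def _aln(bases: str):
        alns = _ALIGNER.align(ref, bases)
        return alns.score, alns[0]

    fwd_score, fwd = _aln(read.bases)
    rc = read.bases.translate(_DNA_COMP)[::-1]
    rev_score, rev = _aln(rc)
    if rev_score > fwd_score:
        score, aln, strand, bases = rev_score, rev, "-", rc
    else:
        score, aln, strand, bases = fwd_score, fwd, "+", read.bases
    if score < min_score:
        return None
    tblocks, qblocks = aln.aligned
    blocks = tuple(
        ((int(t0), int(t1)), (int(q0), int(q1)))
        for (t0, t1), (q0, q1) in zip(tblocks, qblocks)
    )
    if not blocks:
        return None
    return Alignment(
        read.id,
        offset=blocks[0][0][0],
        end=blocks[-1][0][1],
        strand=strand,
        score=float(score),
        blocks=blocks,
        bases=bases,
    )


# -- pileup and editing rates --------------------------------------------

_BASE_COLS = ("A", "C", "G", "T", "N", "del")


@dataclass
class EditingReport:
    """Per-position substitution counts and A->G percentages."""

    reference: str
    counts: pd.DataFrame  # index: reference position; columns: _BASE_COLS
    central_site: int
    min_depth: int
    bystander_threshold: float
    edit_pct: pd.Series = field(init=False)
    bystanders: list[tuple[int, float]] = field(init=False)
    central_pct: float | None = field(init=False)
    status: str = field(init=False)

    def __post_init__(self) -> None:
        ref = np.array(list(self.reference))
        a = self.counts["A"].to_numpy(float)
        g = self.counts["G"].to_numpy(float)
        depth_ag = a + g
        pct = np.full(len(ref), np.nan)
        mask = (ref == "A") & (depth_ag >= self.min_depth)
        with np.errstate(invalid="ignore"):
            pct[mask] = 100.0 * g[mask] / depth_ag[mask]
        self.edit_pct = pd.Series(pct, index=self.counts.index, name="edit_pct")
        self.bystanders = [
            (int(i), float(p))
            for i, p in self.edit_pct.items()
            if i != self.central_site and np.isfinite(p) and p >= self.bystander_threshold
        ]
        central = self.edit_pct.get(self.central_site, np.nan)
        central = np.nan if central is None else central
        if np.isfinite(central):
            self.central_pct = float(central)
            self.status = "ok"
        else:
            self.central_pct = None
            self.status = "insufficient_depth"

    def to_dataframe(self) -> pd.DataFrame:
        df = self.counts.copy()
        df["ref"] = list(self.reference)
        df["edit_pct"] = self.edit_pct
        return df

    def summary(self) -> dict:
        return {
            "central_site": self.central_site,
            "central_edit_pct": self.central_pct,
            "status": self.status,
            "min_depth": self.min_depth,
            "bystander_threshold_pct": self.bystander_threshold,
            "bystanders": [{"position": p, "edit_pct": e} for p, e in self.bystanders],
        }


def editing_rates(
    alignments: list[Alignment],
    reference: NucSeq,
    central_site: int,
    min_depth: int = DEFAULT_MIN_DEPTH,
    bystander_threshold: float = DEFAULT_BYSTANDER_PCT,
) -> EditingReport:
    """Pileup the alignments over the reference and compute per-A editing
    percentages, with the central-site rate and bystander flags."""
    ref = reference.to_dna().residues
    if not (0 <= central_site < len(ref)):
        raise InputError("central site outside the reference")
    if not any(a.offset <= central_site < a.end for a in alignments):
        raise InputError("no aligned read covers the central site")
    counts = np.zeros((len(ref), len(_BASE_COLS)), dtype=np.int64)
    col = {b: i for i, b in enumerate(_BASE_COLS)}
    for aln in alignments:
        prev_ref_end = None
        for (t0, t1), (q0, q1) in aln.blocks:
            if prev_ref_end is not None and t0 > prev_ref_end:
                counts[prev_ref_end:t0, col["del"]] += 1
            prev_ref_end = t1
            seg = aln.bases[q0:q1]
            for k, base in enumerate(seg):
                counts[t0 + k, col.get(base, col["N"])] += 1
    df = pd.DataFrame(counts, columns=list(_BASE_COLS))
    df.index.name = "position"
    return EditingReport(
        reference=ref,
        counts=df,
        central_site=central_site,
        min_depth=min_depth,
        bystander_threshold=bystander_threshold,
    )


def run_pipeline(
    pairs: list[tuple[ReadRecord, ReadRecord]] | list[ReadRecord],
    reference: NucSeq,
    central_site: int,
    q_cut: int = DEFAULT_Q_CUT,
    n_frac: float = DEFAULT_N_FRAC,
    min_overlap: int = DEFAULT_MIN_OVERLAP,
    min_depth: int = DEFAULT_MIN_DEPTH,
) -> tuple[EditingReport, dict]:
    """QC -> merge -> align -> pileup in one call.

    Accepts read pairs (merged before alignment) or single reads.  Returns
    the report plus per-stage counts.
    """
    stats: dict = {"input": len(pairs)}
    merged: list[ReadRecord] = []
    unmerged = 0
    for item in pairs:
        if isinstance(item, ReadRecord):
            merged.append(item)
            continue
        r1, r2 = item
        f1, _ = quality_filter([r1], q_cut=q_cut, n_frac=n_frac)
        f2, _ = quality_filter([r2], q_cut=q_cut, n_frac=n_frac)
        if not f1 or not f2:
            unmerged += 1
            continue
        res = merge_pairs(f1[0], f2[0], min_overlap=min_overlap)
        if res.ok:
            merged.append(res.merged)
        else:
            unmerged += 1
    stats["merged"] = len(merged)
    stats["unmerged_or_filtered"] = unmerged
    alignments = []
    for rec in merged:
        aln = align_to_amplicon(rec, reference)
        if aln is not None:
            alignments.append(aln)
    stats["aligned"] = len(alignments)
    report = editing_rates(alignments, reference, central_site, min_depth=min_depth)
    return report, stats


# -- FASTQ ----------------------------------------------------------------

def read_fastq(path) -> list[ReadRecord]:
    """Plain-text FASTQ reader (4-line records)."""
    records = []
    with open(path) as fh:
        while True:
            header = fh.readline()
            if not header:
                break
            bases = fh.readline().strip()
            fh.readline()
            quals = fh.readline().strip()
            records.append(
                ReadRecord(
                    header.strip().lstrip("@").split()[0],
                    bases.upper(),
                    tuple(ord(c) - 33 for c in quals),
                )
            )
    return records


def write_fastq(path, records: list[ReadRecord]) -> None:
    with open(path, "w") as fh:
        for rec in records:
            fh.write(
                f"@{rec.id}\n{rec.bases}\n+\n"
                + "".join(chr(q + 33) for q in rec.quals)
                + "\n"
            )
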