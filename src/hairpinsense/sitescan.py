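"""Scan a target transcript for candidate sensor sites.

The published workflow screened three to five binding sites per transcript
experimentally; the composite score here is an explicit in-silico heuristic
(context tier, duplex-adenosine penalty, junction-proximal GC bonus), not a
fitted model, and its weights are exposed on
:class:`~hairpinsense.design.DesignConfig`.

A candidate window of ``arm_length`` bases is accepted when (i) it is free
of ambiguity codes, (ii) the arm it implies carries no in-frame stop codon
under the cassette frame, and (iii) the target base adjacent to the window
can pair the retained sensor junction base (in ``cca_source="target"`` mode
this filter is replaced by requiring the target itself to present the full
opposite triplet, CCA by default).  Scanning is on the given strand only.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass

from .errors import InputError
from .seqcore import NucSeq, audit_frame, is_wc, reverse_complement
from .structure import EXTERNAL_OFFSET
from .design import DesignConfig, SensorConstruct


@dataclass(frozen=True)
class TargetSite:
    """A candidate sensor window on the target (0-based, half-open)."""

    start: int
    end: int
    junction_base: str
    context_tier: int
    stop_clean: bool
    bystander_count: int
    composite_score: float


@dataclass(frozen=True)
class ScanResult:
    sites: tuple[TargetSite, ...]
    reject_reasons: Counter

    def __iter__(self):
        return iter(self.sites)

    def __len__(self):
        return len(self.sites)


def _context_tier(triplet: str, config: DesignConfig) -> int:
    """Ordinal preference for the triplet opposite the UAG: the middle C
    (giving the A-C mismatch) is required for any credit, a 5'-neighbouring
    C is preferred, and the full CCA motif is top tier."""
    if triplet == config.triplet_opposite:
        return 3
    if len(triplet) == 3 and triplet[1] == "C":
        return 2 if triplet[0] == "C" else 1
    return 0


def _window_bystanders(window: str) -> int:
    """Adenosines on either strand of the would-be arm:target duplex: every
    A in the window sits opposite an arm U, and every window U puts an A on
    the arm.  Constant contributions from the fixed UAG:CCA region are the
    same for all windows and are left out of the ranking."""
    return window.count("A") + window.count("U")


def scan_target(target: NucSeq, config: DesignConfig | None = None) -> ScanResult:
    """Enumerate, filter and rank candidate sensor windows.

    Returns sites sorted by composite score (descending), ties broken by
    fewer duplex adenosines and then by 5'-most position.  When nothing
    passes, the ``reject_reasons`` histogram explains why.
    """
    if config is None:
        config = DesignConfig()
    L = config.arm_length
    trg = target.to_rna().residues
    target_mode = config.cca_source == "target"
    extra = 3 if target_mode else 1  # triplet vs junction base after the window
    if len(trg) < L + extra:
        raise InputError(f"target shorter than arm length + {extra}")
    reasons: Counter = Counter()
    sites = []
    for s in range(0, len(trg) - L - extra + 1):
        window = trg[s : s + L]
        if target_mode:
            triplet = trg[s + L : s + L + 3]
            junction_base = triplet[0]
            if triplet != config.triplet_opposite:
                reasons["triplet"] += 1
                continue
            tier = _context_tier(triplet, config)
        else:
            junction_base = trg[s + L]
            if not is_wc(config.junction_pair[0], junction_base):
                reasons["junction"] += 1
                continue
            tier = _context_tier(config.triplet_opposite, config)
        arm = reverse_complement(NucSeq.rna(window))
        if audit_frame(arm, 0).stop_positions:
            reasons["stop"] += 1
            continue
        bystanders = _window_bystanders(window)
        gc6 = sum(1 for c in window[-6:] if c in "GC")
        score = (
            config.tier_weight * tier
            + config.bystander_weight * bystanders
            + config.gc_junction_weight * gc6
        )
        sites.append(
            TargetSite(
                start=s,
                end=s + L,
                junction_base=junction_base,
                context_tier=tier,
                stop_clean=True,
                bystander_count=bystanders,
                composite_score=score,
            )
        )
    sites.sort(key=lambda t: (-t.composite_score, t.bystander_count, t.start))
    return ScanResult(tuple(sites), reasons)


@dataclass(frozen=True)
class BystanderRecord:
    position: int
    strand: str  # "sensor" or "target"
    opposite_base: str
    high_risk: bool  # a non-central A:C apposition


def bystander_audit(
    construct: SensorConstruct, target_window: NucSeq | None = None
) -> list[BystanderRecord]:
    """List every adenosine in either strand of the (active, if available)
    duplex with its opposing base; non-central A:C appositions are flagged
    as high-risk bystanders.  The list length is the count used by the site
    scanner's penalty term."""
    try:
        pmap = construct.pairing_map("active")
        win = (
            target_window.to_rna().residues
            if target_window is not None
            else construct.meta.get("target_window")
        )
        if win is None:
            raise InputError("active-state audit requires the target window")
    except InputError:
        if construct.active is not None:
            raise
        pmap = construct.pairing_map("resting")
        win = ""
    records = []
    seq = construct.sequence
    for i, j in sorted(pmap.all_opposing):
        external = (i, j) in pmap.external
        sensor_base = seq[i]
        partner_base = win[j - EXTERNAL_OFFSET] if external else seq[j]
        if sensor_base == "A":
            records.append(
                BystanderRecord(
                    position=i,
                    strand="sensor",
                    opposite_base=partner_base,
                    high_risk=partner_base == "C" and i != construct.edit_index,
                )
            )
        if partner_base == "A":
            records.append(
                BystanderRecord(
                    position=(j - EXTERNAL_OFFSET) if external else j,
                    strand="target" if external else "sensor",
                    opposite_base=sensor_base,
                    high_risk=sensor_base == "C"
                    and not (not external and j == construct.edit_index),
                )
            )
    return records
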