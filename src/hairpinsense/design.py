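"""Construct ADAR-recruiting hairpin RNA sensors and reporter cassettes.

The model substrate is a stem-loop with two helical domains a:a* and b:b*
flanking a central A-C mismatch: the editable adenosine sits in a UAG stop
codon opposite a CCA triplet, whose middle cytosine gives the mismatch that
ADAR prefers.  By convention ``len_a`` counts the base pairs of the a-side
helix *including* the G:C closure of the editing loop (the UAG's G paired
with the CCA's first C) and ``len_b`` counts the b-side helix including the
U:A pair, so the full duplex holds ``len_a + len_b`` Watson-Crick pairs
spanning ``len_a + len_b + 1`` positions with the mismatch.

Sensor variants:

* ``rna_sensor`` — domain a collapses to a single junction cytosine and
  domain a* is replaced by a sensing arm reverse-complementary to a target
  transcript window; target hybridisation restores the editable duplex.
* ``snv_sensor`` — the arm base adjacent to the UAG's G discriminates a
  single-nucleotide variant: it complements the variant allele, so the
  wild-type transcript leaves a second mismatch next to the editing site.
* ``aptamer_sensor`` — an aptamer:blocker stem sequesters the UAG triplet
  in its loop (the OFF state); ligand occupancy, modelled by forcing the
  aptamer unpaired, releases the blocker and restores the UAG:CCA duplex.

Stem filler bases are drawn from a seeded generator and rejected if they
create homopolymers longer than 3 or stop codons on either strand, so every
design is reproducible from its seed.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field, asdict
from typing import Sequence

from .errors import AssemblyError, DesignError, InputError, SiteRejectedError
from .seqcore import (
    NucSeq,
    audit_frame,
    contains_stop_any_frame,
    is_wc,
    reverse_complement,
)
from .structure import EXTERNAL_OFFSET, PairingMap, two_state_check

__version__ = "0.1.0"

DEFAULT_SEED = 7

#: Synthetic MS2-style tether hairpin (21 nt): an 8-bp GC stem closing a
#: 5-nt loop, deliberately U-free so it can never introduce a stop codon in
#: any reading frame.  It is a stand-in constant, not the phage sequence;
#: supply the real MS2 hairpin via config for wet-lab export.
MS2_DEFAULT = "GCGGCCGGGAAAGCCGGCCGC"
MS2_SPACER = "ACC"


@dataclass(frozen=True)
class HairpinParams:
    """Geometry of the hairpin substrate.

    ``junction_pair`` is the base pair stacked outside the G:C closure of
    the editing loop (N4 on the CCA side, N5 opposite) and
    ``junction_context`` the next base outward on the CCA side (N6).
    """

    len_a: int = 10
    len_b: int = 12
    loop_seq: str = "GCAA"
    triplet_sensor: str = "UAG"
    triplet_opposite: str = "CCA"
    junction_pair: tuple[str, str] = ("C", "G")
    junction_context: str = "C"
    seed: int = DEFAULT_SEED

    def __post_init__(self) -> None:
        if self.len_a < 1 or self.len_b < 1:
            raise DesignError("len_a and len_b must be >= 1")
        if len(self.loop_seq) < 3:
            raise DesignError("hairpin loop must be at least 3 nt")
        if len(self.triplet_sensor) != 3 or len(self.triplet_opposite) != 3:
            raise DesignError("sensor and opposite triplets must be 3 nt")
        if self.triplet_sensor[1] != "A":
            raise DesignError("the middle base of the sensor triplet must be the editable A")
        NucSeq.rna(self.loop_seq)
        NucSeq.rna(self.triplet_sensor)
        NucSeq.rna(self.triplet_opposite)


@dataclass(frozen=True)
class DesignConfig:
    """Tool-level knobs shared by the sensor designers and the site scanner."""

    arm_length: int = 39
    len_a: int = 10
    len_b: int = 12
    loop_seq: str = "GCAA"
    junction_pair: tuple[str, str] = ("C", "G")
    junction_context: str = "C"
    triplet_sensor: str = "UAG"
    triplet_opposite: str = "CCA"
    cca_source: str = "intramolecular"  # or "target"
    arm_side: str = "3prime"
    blocker_length: int = 18
    seed: int = DEFAULT_SEED
    force_site: bool = False
    # site-scoring heuristics (documented in sitescan)
    tier_weight: float = 10.0
    bystander_weight: float = -1.0
    gc_junction_weight: float = 0.5

    def hairpin(self) -> HairpinParams:
        return HairpinParams(
            len_a=self.len_a,
            len_b=self.len_b,
            loop_seq=self.loop_seq,
            triplet_sensor=self.triplet_sensor,
            triplet_opposite=self.triplet_opposite,
            junction_pair=self.junction_pair,
            junction_context=self.junction_context,
            seed=self.seed,
        )


@dataclass(frozen=True)
class AptamerSpec:
    """An aptamer and the window whose reverse complement forms the blocker."""

    name: str
    sequence: NucSeq
    blocker_window: tuple[int, int]
    kd_note: str = ""

    def __post_init__(self) -> None:
        s, e = self.blocker_window
        if not (0 <= s <= e <= len(self.sequence)):
            raise DesignError("blocker window must lie within the aptamer")

    @property
    def blocker_length(self) -> int:
        return self.blocker_window[1] - self.blocker_window[0]


@dataclass(frozen=True)
class SensorConstruct:
    """A designed RNA with annotated components and intended pairing maps.

    ``resting`` is the pairing map of the unbound molecule (for aptamer
    sensors it records the intended editing-competent duplex the ON state
    must recover); ``active`` adds the target-strand pairs for sensing
    modes, with target positions encoded via
    :data:`hairpinsense.structure.EXTERNAL_OFFSET`.
    """

    sequence: NucSeq
    features: tuple[tuple[str, int, int], ...]
    mode: str
    edit_index: int
    resting: PairingMap
    active: PairingMap | None = None
    meta: dict = field(default_factory=dict, compare=False)

    def __post_init__(self) -> None:
        n = len(self.sequence)
        prev = 0
        for name, start, end in self.features:
            if not (0 <= start <= end <= n):
                raise DesignError(f"feature {name} [{start},{end}) outside sequence")
            if start != prev:
                raise DesignError(f"feature {name} breaks the exact tiling at {start}")
            prev = end
        if prev != n:
            raise DesignError("features do not tile the full sequence")
        ts, te = self.feature("triplet_sensor")
        if not (ts <= self.edit_index < te):
            raise DesignError("edit_index must lie inside the sensor triplet")
        if self.sequence[self.edit_index] != "A":
            raise DesignError("the designated editable base must be A")

    def feature(self, name: str) -> tuple[int, int]:
        for fname, start, end in self.features:
            if fname == name:
                return (start, end)
        raise InputError(f"construct has no feature named {name!r}")

    def has_feature(self, name: str) -> bool:
        return any(f[0] == name for f in self.features)

    def feature_length(self, name: str) -> int:
        s, e = self.feature(name)
        return e - s

    def pairing_map(self, state: str = "resting") -> PairingMap:
        if state == "resting":
            return self.resting
        if state == "active":
            if self.active is None:
                raise InputError(f"{self.mode} construct has no active-state map")
            return self.active
        raise InputError(f"unknown state {state!r}")


# -- filler generation ----------------------------------------------------

def _has_homopolymer(s: str, run: int) -> bool:
    return any(s[i : i + run] == s[i] * run for i in range(len(s) - run + 1))


def _filler(rng: random.Random, length: int) -> str:
    """Seeded stem filler: no homopolymer > 3 and no stop triplet in any
    frame on either strand (the complement appears in the transcript too)."""
    if length <= 0:
        return ""
    for _ in range(20000):
        cand = "".join(rng.choice("ACGU") for _ in range(length))
        if _has_homopolymer(cand, 4):
            continue
        rc = reverse_complement(NucSeq.rna(cand)).residues
        if contains_stop_any_frame(cand) or contains_stop_any_frame(rc):
            continue
        return cand
    raise DesignError(
        f"could not generate a stop-free {length}-nt stem filler; "
        "loosen the constraints or change the seed"
    )


def _domain_a(rng: random.Random, params: HairpinParams) -> str:
    """5' arm of the a-side helix: ``len_a - 1`` bases ending with the N6
    context and the N4 junction base."""
    la = params.len_a - 1
    if la == 0:
        return ""
    if la == 1:
        return params.junction_pair[0]
    core = _filler(rng, la - 2)
    return core + params.junction_context + params.junction_pair[0]


def _layout(segments: Sequence[tuple[str, str]]):
    """Concatenate named segments, dropping empty ones; return sequence and
    feature tuples."""
    features = []
    pos = 0
    parts = []
    for name, seg in segments:
        if not seg:
            continue
        features.append((name, pos, pos + len(seg)))
        pos += len(seg)
        parts.append(seg)
    return "".join(parts), tuple(features)


def _classify(seq: str, tuples: Sequence[tuple[int, int]]):
    """Split opposing tuples into WC pairs and mismatches by sequence."""
    pairs, mismatches = set(), set()
    for i, j in tuples:
        if is_wc(seq[i], seq[j]):
            pairs.add((i, j))
        else:
            mismatches.add((i, j))
    return frozenset(pairs), frozenset(mismatches)


def _frame_clean(seq: str, uag_start: int) -> bool:
    """True if, read in the frame that codon-aligns the sensor UAG, the
    construct's only stop is that UAG."""
    audit = audit_frame(NucSeq.rna(seq), uag_start % 3)
    return audit.stop_positions == (uag_start,)


# -- builders -------------------------------------------------------------

def build_substrate(params: HairpinParams) -> SensorConstruct:
    """Build the hairpin substrate
    5'-[a]-[CCA]-[b*]-[loop]-[b]-[UAG]-[a*]-3'.

    The intended pairing map holds ``len_a + len_b`` Watson-Crick pairs plus
    the annotated central mismatch, a duplex spanning
    ``len_a + len_b + 1`` positions.
    """
    for attempt in range(60):
        rng = random.Random(f"substrate:{params.seed}:{attempt}")
        dom_a = _domain_a(rng, params)
        dom_b = _filler(rng, params.len_b - 1)
        dom_b_star = reverse_complement(NucSeq.rna(dom_b)).residues if dom_b else ""
        dom_a_star = reverse_complement(NucSeq.rna(dom_a)).residues if dom_a else ""
        if dom_a_star:
            # place N5 explicitly; non-WC junctions become annotated mismatches
            dom_a_star = params.junction_pair[1] + dom_a_star[1:]
        seq, features = _layout(
            [
                ("domain_a", dom_a),
                ("triplet_opposite", params.triplet_opposite),
                ("domain_b_star", dom_b_star),
                ("loop", params.loop_seq),
                ("domain_b", dom_b),
                ("triplet_sensor", params.triplet_sensor),
                ("domain_a_star", dom_a_star),
            ]
        )
        fdict = {name: (s, e) for name, s, e in features}
        c0 = fdict["triplet_opposite"][0]
        u0 = fdict["triplet_sensor"][0]
        tuples = [(c0, u0 + 2), (c0 + 1, u0 + 1), (c0 + 2, u0)]
        if dom_a:
            a_s, a_e = fdict["domain_a"]
            as_s, as_e = fdict["domain_a_star"]
            for t in range(len(dom_a)):
                tuples.append((a_s + t, as_e - 1 - t))
        if dom_b:
            b_s, b_e = fdict["domain_b"]
            bs_s, bs_e = fdict["domain_b_star"]
            for t in range(len(dom_b)):
                tuples.append((bs_s + t, b_e - 1 - t))
        pairs, mismatches = _classify(seq, tuples)
        if not _frame_clean(seq, u0):
            continue
        return SensorConstruct(
            sequence=NucSeq.rna(seq),
            features=features,
            mode="substrate",
            edit_index=u0 + 1,
            resting=PairingMap(pairs=pairs, mismatches=mismatches),
            meta={"params": asdict(params), "attempt": attempt},
        )
    raise DesignError("could not build a stop-free substrate for these parameters")


def build_inert_sensor(params: HairpinParams, arm: NucSeq) -> SensorConstruct:
    """Inert sensor: domain a reduced to the single junction cytosine, domain
    a* replaced by the sensing arm.  In the resting state only the b:b* helix
    and the UAG:CCA closures pair; the arm awaits its target."""
    if len(arm) == 0:
        raise DesignError("sensing arm must not be empty")
    arm_rna = arm.to_rna().residues
    for attempt in range(60):
        rng = random.Random(f"inert:{params.seed}:{attempt}")
        dom_b = _filler(rng, params.len_b - 1)
        dom_b_star = reverse_complement(NucSeq.rna(dom_b)).residues if dom_b else ""
        seq, features = _layout(
            [
                ("junction", params.junction_pair[0]),
                ("triplet_opposite", params.triplet_opposite),
                ("domain_b_star", dom_b_star),
                ("loop", params.loop_seq),
                ("domain_b", dom_b),
                ("triplet_sensor", params.triplet_sensor),
                ("sensing_arm", arm_rna),
            ]
        )
        fdict = {name: (s, e) for name, s, e in features}
        c0 = fdict["triplet_opposite"][0]
        u0 = fdict["triplet_sensor"][0]
        tuples = [(c0, u0 + 2), (c0 + 1, u0 + 1), (c0 + 2, u0)]
        if dom_b:
            b_s, b_e = fdict["domain_b"]
            bs_s, bs_e = fdict["domain_b_star"]
            for t in range(len(dom_b)):
                tuples.append((bs_s + t, b_e - 1 - t))
        pairs, mismatches = _classify(seq, tuples)
        if not _frame_clean(seq, u0):
            arm_audit = audit_frame(NucSeq.rna(arm_rna), 0)
            if arm_audit.stop_positions:
                pos = arm_audit.stop_positions[0]
                raise SiteRejectedError(
                    f"sensing arm holds an in-frame stop codon "
                    f"{arm_rna[pos:pos+3]} at arm position {pos}"
                )
            continue
        return SensorConstruct(
            sequence=NucSeq.rna(seq),
            features=features,
            mode="rna_sensor",
            edit_index=u0 + 1,
            resting=PairingMap(pairs=pairs, mismatches=mismatches),
            meta={
                "params": asdict(params),
                "attempt": attempt,
                "arm_state": "unpaired-awaiting-target",
            },
        )
    raise DesignError("could not build a stop-free inert sensor")


def _attach_target(
    construct: SensorConstruct,
    target: NucSeq,
    window_start: int,
    config: DesignConfig,
    mode: str,
    extra_meta: dict | None = None,
    window_override: str | None = None,
) -> SensorConstruct:
    """Add the active-state (target-hybridised) pairing map to an inert
    sensor.  ``window_override`` substitutes the hybridising window sequence
    (used by the SNV designer, whose arm complements the *mutant* allele)."""
    L = config.arm_length
    s = window_start
    window = window_override if window_override is not None else target.to_rna().residues[s : s + L]
    junction_base = target.to_rna().residues[s + L]
    arm_s, arm_e = construct.feature("sensing_arm")
    tuples = [(arm_s + t, EXTERNAL_OFFSET + (L - 1 - t)) for t in range(L)]
    jpos = construct.feature("junction")[0]
    tuples.append((jpos, EXTERNAL_OFFSET + L))
    ext_window = window + junction_base
    pairs, mismatches = set(), set()
    for i, j in tuples:
        if is_wc(construct.sequence[i], ext_window[j - EXTERNAL_OFFSET]):
            pairs.add((i, j))
        else:
            mismatches.add((i, j))
    external = frozenset(tuples)
    active = PairingMap(
        pairs=construct.resting.pairs | frozenset(pairs),
        mismatches=construct.resting.mismatches | frozenset(mismatches),
        external=external,
    )
    meta = dict(construct.meta)
    meta.update(
        {
            "window_start": s,
            "window_end": s + L,
            "target_window": ext_window,
            "junction_base": junction_base,
        }
    )
    if extra_meta:
        meta.update(extra_meta)
    return SensorConstruct(
        sequence=construct.sequence,
        features=construct.features,
        mode=mode,
        edit_index=construct.edit_index,
        resting=construct.resting,
        active=active,
        meta=meta,
    )


def design_rna_sensor(target: NucSeq, site, config: DesignConfig | None = None) -> SensorConstruct:
    """Design an endogenous-RNA sensor for a chosen target site.

    ``site`` is a :class:`~hairpinsense.sitescan.TargetSite` (anything with a
    ``start`` attribute) or an integer window start.  The sensing arm is the
    exact reverse complement of the target window; the engineered mismatch
    lives only in the intramolecular UAG:CCA region.
    """
    if config is None:
        config = DesignConfig()
    s = getattr(site, "start", site)
    L = config.arm_length
    trg = target.to_rna().residues
    if s < 0 or s + L >= len(trg):
        raise InputError(f"window [{s},{s + L}) plus junction base exceeds the target")
    window = NucSeq.rna(trg[s : s + L])
    arm = reverse_complement(window)
    arm_audit = audit_frame(arm, 0)
    if arm_audit.stop_positions:
        pos = arm_audit.stop_positions[0]
        raise SiteRejectedError(
            f"site {s} rejected: arm codon {arm.residues[pos:pos+3]} at arm "
            f"position {pos} is an in-frame stop"
        )
    junction_base = trg[s + L]
    if not is_wc(config.junction_pair[0], junction_base) and not config.force_site:
        raise SiteRejectedError(
            f"site {s} rejected: junction base {junction_base} cannot pair "
            f"the retained sensor {config.junction_pair[0]}"
        )
    inert = build_inert_sensor(config.hairpin(), arm)
    return _attach_target(inert, target, s, config, "rna_sensor")


@dataclass(frozen=True)
class Variant:
    """A substitution variant on the target transcript (0-based position)."""

    position: int
    ref_base: str
    alt_base: str


def design_snv_sensor(target_wt: NucSeq, variant: Variant, config: DesignConfig | None = None) -> SensorConstruct:
    """Design an SNV-discriminating sensor.

    The arm complements the *mutant* window, so its base adjacent to the
    UAG's G (the discriminator) is the complement of the variant allele.
    Against the mutant transcript the only duplex mismatch is the designed
    central A-C; against the wild type the discriminator adds a second,
    near-adjacent mismatch (wobble apposition is counted as a mismatch).
    Insertions and deletions are deliberately not detected.
    """
    if config is None:
        config = DesignConfig()
    ref, alt = variant.ref_base.upper().replace("T", "U"), variant.alt_base.upper().replace("T", "U")
    if ref == alt:
        raise DesignError("variant alt base equals the reference base")
    trg = target_wt.to_rna().residues
    pos = variant.position
    L = config.arm_length
    if trg[pos] != ref:
        raise InputError(f"target has {trg[pos]} at {pos}, expected ref base {ref}")
    s = pos - L + 1
    if s < 0 or pos + 1 >= len(trg):
        raise DesignError(
            f"variant at {pos} is too close to the transcript edge for a {L}-nt arm"
        )
    mut_window = trg[s:pos] + alt
    arm = reverse_complement(NucSeq.rna(mut_window))
    arm_audit = audit_frame(arm, 0)
    if arm_audit.stop_positions:
        p = arm_audit.stop_positions[0]
        raise SiteRejectedError(
            f"variant site rejected: arm codon {arm.residues[p:p+3]} at arm position {p} is a stop"
        )
    junction_base = trg[pos + 1]
    if not is_wc(config.junction_pair[0], junction_base) and not config.force_site:
        raise SiteRejectedError(
            f"variant site rejected: junction base {junction_base} cannot pair "
            f"the retained sensor {config.junction_pair[0]}"
        )
    inert = build_inert_sensor(config.hairpin(), arm)
    return _attach_target(
        inert,
        target_wt,
        s,
        config,
        "snv_sensor",
        extra_meta={
            "variant": asdict(variant),
            "wt_window": trg[s : s + L] + junction_base,
            "mut_window": mut_window + junction_base,
            "discriminator": arm.residues[0],
        },
        window_override=mut_window,
    )


def mismatch_count(construct: SensorConstruct, target_window: NucSeq) -> int:
    """Number of non-Watson-Crick appositions in the active duplex of a
    sensing construct hybridised to ``target_window`` (the window plus the
    junction base, as stored in ``meta['target_window']``)."""
    if construct.active is None:
        raise InputError("construct has no active-state pairing map")
    win = target_window.to_rna().residues
    count = 0
    for i, j in construct.active.all_opposing:
        if (i, j) in construct.active.external:
            partner = win[j - EXTERNAL_OFFSET]
        else:
            partner = construct.sequence[j]
        if not is_wc(construct.sequence[i], partner):
            count += 1
    return count


def design_aptamer_sensor(
    aptamer: AptamerSpec,
    params: HairpinParams | None = None,
    config: DesignConfig | None = None,
) -> SensorConstruct:
    """Design a ligand-responsive sensor with an aptamer:blocker OFF stem.

    Layout (5'->3'):
    ``[a]-[CCA]-[b*]-[loop]-[b]-[blocker]-[UAG]-[aptamer]-[a*]`` with short
    A-spacers around the blocker and aptamer.  In the OFF state the blocker
    pairs its aptamer window and the resulting stem encloses the UAG triplet
    in its loop, so any UAG:CCA pair would cross the stem and is forbidden;
    forcing the aptamer unpaired (the ligand proxy) releases the blocker and
    the UAG:CCA duplex re-forms.  Spacer lengths 0-4 are tried in increasing
    order and the first layout passing
    :func:`hairpinsense.structure.two_state_check` is returned.
    """
    if config is None:
        config = DesignConfig()
    if params is None:
        params = config.hairpin()
    ws, we = aptamer.blocker_window
    apt = aptamer.sequence.to_rna().residues
    if len(apt) < aptamer.blocker_length:
        raise DesignError("aptamer shorter than the requested blocker")
    blocker = (
        reverse_complement(NucSeq.rna(apt[ws:we])).residues if we > ws else ""
    )
    best_fail = None
    for spacer_len in range(0, 5):
        sp = "A" * spacer_len
        for attempt in range(20):
            rng = random.Random(f"aptamer:{params.seed}:{spacer_len}:{attempt}")
            dom_a = _domain_a(rng, params)
            dom_a_star = reverse_complement(NucSeq.rna(dom_a)).residues if dom_a else ""
            if dom_a_star:
                dom_a_star = params.junction_pair[1] + dom_a_star[1:]
            dom_b = _filler(rng, params.len_b - 1)
            dom_b_star = reverse_complement(NucSeq.rna(dom_b)).residues if dom_b else ""
            seq, features = _layout(
                [
                    ("domain_a", dom_a),
                    ("triplet_opposite", params.triplet_opposite),
                    ("domain_b_star", dom_b_star),
                    ("loop", params.loop_seq),
                    ("domain_b", dom_b),
                    ("spacer_5p", sp),
                    ("blocker", blocker),
                    ("spacer_blocker", sp),
                    ("triplet_sensor", params.triplet_sensor),
                    ("spacer_aptamer", sp),
                    ("aptamer", apt),
                    ("domain_a_star", dom_a_star),
                ]
            )
            fdict = {name: (f_s, f_e) for name, f_s, f_e in features}
            c0 = fdict["triplet_opposite"][0]
            u0 = fdict["triplet_sensor"][0]
            tuples = [(c0, u0 + 2), (c0 + 1, u0 + 1), (c0 + 2, u0)]
            if dom_a:
                a_s, a_e = fdict["domain_a"]
                as_s, as_e = fdict["domain_a_star"]
                for t in range(len(dom_a)):
                    tuples.append((a_s + t, as_e - 1 - t))
            if dom_b:
                b_s, b_e = fdict["domain_b"]
                bs_s, bs_e = fdict["domain_b_star"]
                for t in range(len(dom_b)):
                    tuples.append((bs_s + t, b_e - 1 - t))
            pairs, mismatches = _classify(seq, tuples)
            if not _frame_clean(seq, u0):
                continue
            construct = SensorConstruct(
                sequence=NucSeq.rna(seq),
                features=features,
                mode="aptamer_sensor",
                edit_index=u0 + 1,
                resting=PairingMap(pairs=pairs, mismatches=mismatches),
                meta={
                    "params": asdict(params),
                    "aptamer": aptamer.name,
                    "kd_note": aptamer.kd_note,
                    "blocker_window": list(aptamer.blocker_window),
                    "spacer_len": spacer_len,
                    "attempt": attempt,
                },
            )
            result = two_state_check(construct)
            if result.passed:
                return construct
            best_fail = (construct, result)
            break  # fillers were frame-clean; failure is structural, try next spacer
    if best_fail is not None:
        _, result = best_fail
        raise DesignError(
            "no two-state layout found in the spacer search; best failing "
            f"layout diagnostics: {result.diagnostics}"
        )
    raise DesignError("no frame-clean aptamer layout could be generated")


def add_ms2(construct: SensorConstruct, ms2_seq: NucSeq | None = None) -> SensorConstruct:
    """Prepend an MS2 tether hairpin (plus a 3-nt spacer) to a sensor.

    All feature coordinates, the edit index and the intramolecular pairing
    maps shift by ``len(ms2) + 3``.
    """
    if construct.has_feature("ms2"):
        raise DesignError("construct already carries an MS2 feature")
    ms2 = (ms2_seq.to_rna().residues if ms2_seq is not None else MS2_DEFAULT)
    shift = len(ms2) + len(MS2_SPACER)

    def shift_map(pmap: PairingMap | None) -> PairingMap | None:
        if pmap is None:
            return None

        def mv(t):
            i, j = t
            if (i, j) in pmap.external:
                return (i + shift, j)
            return (i + shift, j + shift)

        return PairingMap(
            pairs=frozenset(mv(t) for t in pmap.pairs),
            mismatches=frozenset(mv(t) for t in pmap.mismatches),
            external=frozenset(mv(t) for t in pmap.external),
        )

    features = (("ms2", 0, len(ms2)), ("ms2_spacer", len(ms2), shift)) + tuple(
        (name, s + shift, e + shift) for name, s, e in construct.features
    )
    meta = dict(construct.meta)
    meta["ms2"] = True
    return SensorConstruct(
        sequence=NucSeq.rna(ms2 + MS2_SPACER + construct.sequence.residues),
        features=features,
        mode=construct.mode,
        edit_index=construct.edit_index + shift,
        resting=shift_map(construct.resting),
        active=shift_map(construct.active),
        meta=meta,
    )


# -- reporter cassette ----------------------------------------------------

_P2A_NT = (
    "GGAAGCGGAGCCACCAACUUCAGCCUGCUGAAGCAGGCCGGAGACGUGGAAGAAAACCCAGGACCA"
)  # encodes the ribosomal-skipping peptide GSG-ATNFSLLKQAGDVEENPGP
_LINKER_NT = "GGAGGUGGCGGAAGCGGUGGAGGCGGUAGC"  # 2x GGGGS flexible linker


def _surrogate_orf(tag: str, n_codons: int, terminal_stop: bool) -> str:
    """Deterministic synthetic stand-in ORF for a fluorescent-protein gene.

    The cassette logic only needs codon-clean flanks of the right shape, so
    the shipped BFP/GFP flanks are seeded surrogates, not GenBank sequences;
    supply real ORFs via :class:`ReporterFlanks` for wet-lab export.
    """
    rng = random.Random(f"surrogate-orf:{tag}")
    codons = []
    while len(codons) < n_codons - 1:
        c = "".join(rng.choice("ACGU") for _ in range(3))
        if c in ("UAA", "UAG", "UGA") or c == "AUG":
            continue
        codons.append(c)
    body = "AUG" + "".join(codons)
    if terminal_stop:
        body += "UAA"
    return body


@dataclass(frozen=True)
class ReporterFlanks:
    bfp: str
    p2a: str
    linker: str
    gfp: str
    order: tuple[str, ...] = ("bfp", "p2a", "linker", "insert", "gfp")

    @classmethod
    def default(cls) -> "ReporterFlanks":
        return cls(
            bfp=_surrogate_orf("bfp", 40, terminal_stop=False),
            p2a=_P2A_NT,
            linker=_LINKER_NT,
            gfp=_surrogate_orf("gfp", 40, terminal_stop=True),
        )


@dataclass(frozen=True)
class ReporterCassette:
    """BFP-P2A-linker-sensor-GFP reporter: BFP expression is edit-independent
    (the internal normalisation reference) while GFP is gated by the sensor's
    in-frame UAG."""

    full_sequence: NucSeq
    elements: tuple[tuple[str, int, int], ...]
    sensor_offset: int
    edit_index: int
    construct: SensorConstruct

    def element(self, name: str) -> tuple[int, int]:
        for ename, s, e in self.elements:
            if ename == name:
                return (s, e)
        raise InputError(f"cassette has no element named {name!r}")

    def edited_sequence(self) -> NucSeq:
        """The cassette after in-silico A->G editing at the central site."""
        s = self.full_sequence.residues
        if s[self.edit_index] != "A":
            raise InputError("edit index does not hold an A")
        return NucSeq.rna(s[: self.edit_index] + "G" + s[self.edit_index + 1 :])


def assemble_reporter(
    construct: SensorConstruct, flanks: ReporterFlanks | None = None
) -> ReporterCassette:
    """Embed a sensor in the reporter ORF with frame padding.

    The insert is padded with 0-2 neutral bases (C preferred, then G) on
    each side so its length is a multiple of three and the sensor UAG is
    codon-aligned; the assembly audit requires exactly one in-frame stop
    (the sensor UAG) before the GFP terminator.
    """
    if flanks is None:
        flanks = ReporterFlanks.default()
    parts = {"bfp": flanks.bfp, "p2a": flanks.p2a, "linker": flanks.linker, "gfp": flanks.gfp}
    order = list(flanks.order)
    if "insert" not in order:
        raise AssemblyError("flank order must include the sensor 'insert'")
    for name in order:
        if name == "insert":
            continue
        if len(parts[name]) % 3 != 0:
            raise AssemblyError(f"flank {name} length is not a multiple of 3")
    idx = order.index("insert")
    prefix = "".join(parts[n] for n in order[:idx])
    suffix = "".join(parts[n] for n in order[idx + 1 :])
    if not suffix.startswith(parts["gfp"][:3]) and order[idx + 1 :]:
        pass  # arbitrary orders allowed; the audit below is authoritative
    u = construct.feature("triplet_sensor")[0]
    p = (-(len(prefix) + u)) % 3
    q = (-(p + len(construct.sequence))) % 3
    cseq = construct.sequence.residues
    last_audit = None
    for pad5 in dict.fromkeys(["C" * p, "G" * p]):
        for pad3 in dict.fromkeys(["C" * q, "G" * q]):
            full = prefix + pad5 + cseq + pad3 + suffix
            uag_pos = len(prefix) + len(pad5) + u
            gfp_off = full.rfind(parts["gfp"])
            terminal = gfp_off + len(parts["gfp"]) - 3
            audit = audit_frame(NucSeq.rna(full), 0)
            last_audit = audit
            expected = (uag_pos, terminal) if parts["gfp"].endswith(("UAA", "UAG", "UGA")) else (uag_pos,)
            if audit.stop_positions == expected and full.startswith("AUG"):
                elements = []
                pos = 0
                for n in order[:idx]:
                    elements.append((n, pos, pos + len(parts[n])))
                    pos += len(parts[n])
                if pad5:
                    elements.append(("pad5", pos, pos + len(pad5)))
                    pos += len(pad5)
                elements.append(("insert", pos, pos + len(cseq)))
                sensor_offset = pos
                pos += len(cseq)
                if pad3:
                    elements.append(("pad3", pos, pos + len(pad3)))
                    pos += len(pad3)
                for n in order[idx + 1 :]:
                    elements.append((n, pos, pos + len(parts[n])))
                    pos += len(parts[n])
                return ReporterCassette(
                    full_sequence=NucSeq.rna(full),
                    elements=tuple(elements),
                    sensor_offset=sensor_offset,
                    edit_index=sensor_offset + construct.edit_index,
                    construct=construct,
                )
    stops = list(last_audit.stop_positions) if last_audit else []
    raise AssemblyError(
        f"padding could not avoid stray in-frame stops; audit stops at {stops}"
    )


# -- shipped aptamers ------------------------------------------------------

#: The canonical 40-nt ATP-binding RNA aptamer (Sassanfar-Szostak class).
#: The blocker window was chosen so the 18-nt blocker is stop-free.
ATP_APTAMER = AptamerSpec(
    name="ATP",
    sequence=NucSeq.rna("GGGUUGGGAAGAAACUGUGGCACUUCGGUGCCAGCAACCC"),
    blocker_window=(22, 40),
    kd_note="ATP-binding RNA aptamer; low-micromolar dissociation constant",
)

#: Synthetic 29-nt stand-in for an NF-kB-binding RNA aptamer (the published
#: aptamer is a 29-mer with ~5 nM Kd whose sequence is not reproduced
#: here); stop-free in every reading frame.  Replace via config for wet-lab
#: use.
NFKB_APTAMER = AptamerSpec(
    name="NFKB-synthetic",
    sequence=NucSeq.rna("CCUACGUCGCAUAUCCUGGCCACUGGAGG"),
    blocker_window=(2, 20),
    kd_note="synthetic surrogate; published NF-kB aptamer Kd ~5 nM",
)


# -- serialisation --------------------------------------------------------

def design_record(construct: SensorConstruct, config: DesignConfig | None = None) -> dict:
    """JSON-serialisable design record: 0-based half-open features, index
    pairs, mode, config echo and tool version."""
    pmaps = {}
    for state in ("resting", "active"):
        try:
            pmap = construct.pairing_map(state)
        except InputError:
            continue
        pmaps[state] = {
            "pairs": sorted(list(p) for p in pmap.pairs),
            "mismatches": sorted(list(p) for p in pmap.mismatches),
            "external": sorted(list(p) for p in pmap.external),
        }
    return {
        "tool": "hairpinsense",
        "version": __version__,
        "sequence": construct.sequence.residues,
        "alphabet": construct.sequence.alphabet,
        "mode": construct.mode,
        "edit_index": construct.edit_index,
        "features": [list(f) for f in construct.features],
        "pairing": pmaps,
        "meta": {k: v for k, v in construct.meta.items()},
        "config": asdict(config) if config is not None else None,
    }


def construct_from_record(record: dict) -> SensorConstruct:
    """Rebuild a :class:`SensorConstruct` from a design record."""

    def pmap(d):
        return PairingMap(
            pairs=frozenset(tuple(p) for p in d["pairs"]),
            mismatches=frozenset(tuple(p) for p in d["mismatches"]),
            external=frozenset(tuple(p) for p in d["external"]),
        )

    pairing = record["pairing"]
    return SensorConstruct(
        sequence=NucSeq(record["sequence"], record["alphabet"]),
        features=tuple(tuple(f) for f in record["features"]),
        mode=record["mode"],
        edit_index=record["edit_index"],
        resting=pmap(pairing["resting"]),
        active=pmap(pairing["active"]) if "active" in pairing else None,
        meta=record.get("meta", {}),
    )
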