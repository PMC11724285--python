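"""Secondary-structure verification.

Folding here is a weighted Nussinov maximum-pairing dynamic programme, not a
thermodynamic model: it is desk-scale, exactly reproducible, and sufficient
for the presence/absence pairing checks the sensor designs require.  Pair
weights default to GC=3, AU=2, GU=1 (wobble pairs are allowed on the RNA
alphabet and excluded on DNA).  The minimum hairpin loop is 3 unpaired
bases, i.e. a pair (i, j) requires j - i >= 4.

The traceback is deterministic: scanning the region [i, j), the last
position is paired with the smallest admissible partner k achieving the
optimum, otherwise left unpaired.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import InputError
from .seqcore import NucSeq

DEFAULT_WEIGHTS = {"GC": 3.0, "AU": 2.0, "GU": 1.0}
MIN_LOOP = 3

#: Coordinate offset used to encode pairs whose 3' partner lives on a
#: separate target strand ("external" pairs): j = EXTERNAL_OFFSET + t where
#: t is the 0-based position inside the supplied target window.
EXTERNAL_OFFSET = 10**6


@dataclass(frozen=True)
class PairingMap:
    """A set of base-pair index tuples with mismatch and external annotations.

    ``pairs`` holds strict Watson-Crick (or wobble) pairs, ``mismatches``
    holds opposing positions annotated as non-WC (the designed A-C bubble),
    and ``external`` flags the subset of tuples whose second coordinate is
    target-strand space (encoded via :data:`EXTERNAL_OFFSET`).
    Intramolecular tuples must be disjoint, nested (no pseudoknots) and obey
    the minimum loop separation.
    """

    pairs: frozenset[tuple[int, int]]
    mismatches: frozenset[tuple[int, int]] = frozenset()
    external: frozenset[tuple[int, int]] = frozenset()

    def __post_init__(self) -> None:
        intra = [t for t in (self.pairs | self.mismatches) if t not in self.external]
        seen: set[int] = set()
        for i, j in intra:
            if i >= j:
                raise InputError(f"pair ({i},{j}) must have i < j")
            if j - i < MIN_LOOP + 1:
                raise InputError(f"pair ({i},{j}) violates the minimum loop")
            for p in (i, j):
                if p in seen:
                    raise InputError(f"position {p} appears in more than one pair")
                seen.add(p)
        ordered = sorted(intra)
        for a in range(len(ordered)):
            i1, j1 = ordered[a]
            for b in range(a + 1, len(ordered)):
                i2, j2 = ordered[b]
                if i1 < i2 < j1 < j2:
                    raise InputError(
                        f"pairs ({i1},{j1}) and ({i2},{j2}) cross (pseudoknot)"
                    )

    @property
    def all_opposing(self) -> frozenset[tuple[int, int]]:
        return self.pairs | self.mismatches

    @property
    def n_wc(self) -> int:
        return len(self.pairs)


@dataclass(frozen=True)
class FoldResult:
    """Optimal nested pairing returned by :func:`nussinov_fold`."""

    optimal_pairs: PairingMap
    objective: float
    constraints_applied: tuple[int, ...] = ()
    dot_bracket: str = ""


def _pair_weight_matrix(
    seq: str,
    alphabet: str,
    constraints: frozenset[int],
    weights: dict[str, float],
) -> np.ndarray:
    n = len(seq)
    w = np.full((n, n), -np.inf)
    lut = {}
    for a, b in (("G", "C"), ("A", "U"), ("G", "U")):
        key = a + b
        val = weights.get(key, 0.0)
        if key == "GU" and alphabet == "dna":
            continue
        if val > 0:
            lut[(a, b)] = val
            lut[(b, a)] = val
    rna = seq if alphabet == "rna" else seq.replace("T", "U")
    for i in range(n):
        if i in constraints:
            continue
        for j in range(i + MIN_LOOP + 1, n):
            if j in constraints:
                continue
            val = lut.get((rna[i], rna[j]))
            if val is not None:
                w[i, j] = val
    return w


def dot_bracket(n: int, pairs: frozenset[tuple[int, int]]) -> str:
    chars = ["."] * n
    for i, j in pairs:
        chars[i] = "("
        chars[j] = ")"
    return "".join(chars)


def nussinov_fold(
    seq: NucSeq,
    constraints: frozenset[int] | set[int] = frozenset(),
    weights: dict[str, float] | None = None,
) -> FoldResult:
    """Maximum-weight nested pairing honouring forced-unpaired constraints.

    Parameters
    ----------
    seq:
        Sequence to fold (RNA or DNA; wobble pairs only on RNA).
    constraints:
        Indices forced to stay unpaired (a ligand-occupancy proxy for
        aptamers, or a linker between concatenated strands).
    weights:
        Pair weights keyed ``"GC"``, ``"AU"``, ``"GU"``; defaults to 3/2/1.
    """
    n = len(seq)
    if n > 5000:
        raise InputError("sequences longer than 5000 nt are not supported")
    constraints = frozenset(constraints)
    for c in constraints:
        if not (0 <= c < n):
            raise InputError(f"constraint index {c} out of range for length {n}")
    if weights is None:
        weights = DEFAULT_WEIGHTS
    wmat = _pair_weight_matrix(seq.residues, seq.alphabet, constraints, weights)

    # V[i][j] = optimal score of the half-open region [i, j)
    V = np.zeros((n + 1, n + 1))
    for span in range(MIN_LOOP + 2, n + 1):
        for i in range(0, n - span + 1):
            j = i + span
            last = j - 1
            best = V[i, last]  # last position unpaired
            ks_hi = last - MIN_LOOP  # k in [i, last - MIN_LOOP - 1]
            if ks_hi > i:
                wv = wmat[i:ks_hi, last]
                cand = V[i, i:ks_hi] + V[i + 1 : ks_hi + 1, last] + wv
                m = cand.max()
                if m > best:
                    best = m
            V[i, j] = best

    pairs: set[tuple[int, int]] = set()
    stack = [(0, n)]
    while stack:
        i, j = stack.pop()
        if j - i < MIN_LOOP + 2 or V[i, j] <= 0:
            continue
        last = j - 1
        target = V[i, j]
        chosen = None
        # ties go to the outermost admissible partner (continues the
        # enclosing helix; score-equivalent multiloop relabelings exist
        # and are absorbed by the verification threshold, not chased here)
        for k in range(i, last - MIN_LOOP):
            w = wmat[k, last]
            if np.isfinite(w) and V[i, k] + V[k + 1, last] + w == target:
                chosen = k
                break
        if chosen is None:
            stack.append((i, last))
        else:
            pairs.add((chosen, last))
            stack.append((i, chosen))
            stack.append((chosen + 1, last))

    fpairs = frozenset(pairs)
    return FoldResult(
        optimal_pairs=PairingMap(pairs=fpairs),
        objective=float(V[0, n]),
        constraints_applied=tuple(sorted(constraints)),
        dot_bracket=dot_bracket(n, fpairs),
    )


# -- duplex metrics -------------------------------------------------------

def _helix_runs(tuples: list[tuple[int, int]]) -> list[list[tuple[int, int]]]:
    """Group opposing tuples into contiguous antiparallel stacks."""
    runs: list[list[tuple[int, int]]] = []
    for i, j in sorted(tuples):
        if runs and i == runs[-1][-1][0] + 1 and j == runs[-1][-1][1] - 1:
            runs[-1].append((i, j))
        else:
            runs.append([(i, j)])
    return runs


def duplex_metrics(pmap: PairingMap) -> dict[str, int]:
    """Summarise a duplex: WC pair count, contiguous span (mismatches
    included), mismatch count and the longest uninterrupted WC run."""
    if not pmap.all_opposing:
        raise InputError("pairing map is empty")
    all_runs = _helix_runs(list(pmap.all_opposing))
    wc_runs = _helix_runs(list(pmap.pairs))
    return {
        "n_paired": len(pmap.pairs),
        "span": max(len(r) for r in all_runs),
        "mismatch_count": len(pmap.mismatches),
        "max_contiguous": max((len(r) for r in wc_runs), default=0),
    }


# -- construct-level checks ----------------------------------------------

#: Forced-unpaired linker length used when concatenating a sensor with its
#: target window for active-state folding.
ACTIVE_LINKER = 10


def fold_construct(construct, state: str = "resting", target_window: NucSeq | None = None,
                   weights: dict[str, float] | None = None) -> FoldResult:
    """Fold a construct in its resting state, or concatenated with a target
    window (via a forced-unpaired linker) for the active state."""
    seq = construct.sequence
    if state == "resting":
        return nussinov_fold(seq, weights=weights)
    if state == "active":
        if target_window is None:
            tw = construct.meta.get("target_window")
            if tw is None:
                raise InputError("active-state folding requires a target window")
            target_window = NucSeq.rna(tw)
        combined = NucSeq.rna(seq.to_rna().residues + "A" * ACTIVE_LINKER
                              + target_window.to_rna().residues)
        linker = frozenset(range(len(seq), len(seq) + ACTIVE_LINKER))
        return nussinov_fold(combined, constraints=linker, weights=weights)
    raise InputError(f"unknown state {state!r}")


def resolve_external(pmap: PairingMap, sensor_len: int) -> frozenset[tuple[int, int]]:
    """Map a construct pairing map into concatenated-fold coordinates."""
    out = set()
    for i, j in pmap.pairs:
        if (i, j) in pmap.external:
            out.add((i, sensor_len + ACTIVE_LINKER + (j - EXTERNAL_OFFSET)))
        else:
            out.add((i, j))
    return frozenset(out)


def verify_intended_pairs(construct, state: str, fold: FoldResult) -> float:
    """Fraction of the construct's intended WC pairs present in a fold.

    For the active state the fold must have been computed on the
    sensor+linker+target concatenation (see :func:`fold_construct`).
    """
    pmap = construct.pairing_map(state)
    if state == "active":
        intended = resolve_external(pmap, len(construct.sequence))
        if any(j >= EXTERNAL_OFFSET for _, j in fold.optimal_pairs.pairs):
            raise InputError("fold coordinates do not match the active state")
    else:
        intended = pmap.pairs
        if pmap.external:
            raise InputError("resting-state map unexpectedly holds external pairs")
        n = len(construct.sequence)
        if any(j >= n for _, j in fold.optimal_pairs.pairs):
            raise InputError("fold coordinates do not match the resting state")
    if not intended:
        raise InputError("construct has no intended WC pairs")
    present = sum(1 for p in intended if p in fold.optimal_pairs.pairs)
    return present / len(intended)


@dataclass(frozen=True)
class TwoStateResult:
    passed: bool
    diagnostics: dict = field(default_factory=dict, compare=False)
    off_fold: FoldResult | None = None
    on_fold: FoldResult | None = None


def _triplet_region_pairs(construct) -> set[tuple[int, int]]:
    """All position tuples between the CCA-side and UAG-side triplets."""
    opp = construct.feature("triplet_opposite")
    sen = construct.feature("triplet_sensor")
    out = set()
    for i in range(*opp):
        for j in range(*sen):
            out.add((min(i, j), max(i, j)))
    return out


def two_state_check(construct, weights: dict[str, float] | None = None) -> TwoStateResult:
    """Verify OFF/ON switching of an aptamer sensor by constrained folding.

    OFF is the unconstrained optimal fold and must not contain any pair
    between the UAG and CCA triplets (the aptamer:blocker stem must cage
    the UAG in its loop).  ON models ligand occupancy by forcing the whole
    switch module — aptamer *and* blocker — unpaired, and must contain all
    intended b:b* and UAG:CCA-region pairs.  The blocker is included in the
    constraint because maximum-pairing scoring carries no loop-entropy
    penalty: a released single-stranded blocker would otherwise trade the
    intended (physically cooperative) duplex for isolated lone pairs that a
    thermodynamic model would never reward.
    """
    if construct.mode != "aptamer_sensor":
        raise InputError("two_state_check applies to aptamer sensors only")
    seq = construct.sequence
    region = _triplet_region_pairs(construct)
    switch_positions = frozenset(range(*construct.feature("aptamer")))
    if construct.has_feature("blocker"):  # a zero-length blocker is dropped
        switch_positions |= frozenset(range(*construct.feature("blocker")))

    off = nussinov_fold(seq, weights=weights)
    off_hits = sorted(p for p in off.optimal_pairs.pairs if p in region)

    on = nussinov_fold(seq, constraints=switch_positions, weights=weights)
    required = set()
    b_star = construct.feature("domain_b_star")
    for i, j in construct.pairing_map("resting").pairs:
        if b_star[0] <= i < b_star[1] or (min(i, j), max(i, j)) in region:
            required.add((i, j))
    missing = sorted(p for p in required if p not in on.optimal_pairs.pairs)

    diagnostics: dict = {}
    if off_hits:
        diagnostics["off_state"] = "OFF state active"
        diagnostics["off_triplet_pairs"] = off_hits
    if missing:
        diagnostics["on_state"] = "ON state incomplete"
        diagnostics["on_missing_pairs"] = missing
    return TwoStateResult(
        passed=not off_hits and not missing,
        diagnostics=diagnostics,
        off_fold=off,
        on_fold=on,
    )


# -- independent enumeration oracle (used by the test-suite) --------------

def enumerate_best_score(seq: NucSeq, weights: dict[str, float] | None = None,
                         constraints: frozenset[int] = frozenset()) -> float:
    """Best score over an explicit enumeration of every nested pairing.

    Exponential-time reference used to validate :func:`nussinov_fold` on
    short sequences; structured position-first rather than DP-recurrence so
    it is a genuinely independent computation.
    """
    if weights is None:
        weights = DEFAULT_WEIGHTS
    wmat = _pair_weight_matrix(seq.to_rna().residues if seq.alphabet == "rna"
                               else seq.residues, seq.alphabet, constraints, weights)

    def best(i: int, j: int) -> float:
        # region [i, j): first position unpaired, or paired with any m
        if j - i <= MIN_LOOP:
            return 0.0
        out = best(i + 1, j)
        for m in range(i + MIN_LOOP + 1, j):
            if np.isfinite(wmat[i, m]):
                out = max(out, wmat[i, m] + best(i + 1, m) + best(m + 1, j))
        return out

    return best(0, len(seq))
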