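"""Seeded synthetic-data generators.

Everything downstream of the designers is testable without any download:
transcripts with planted sensor sites, paired amplicon reads carrying
programmed per-site A->G conversion, and flow-cytometry event tables with a
programmed activation factor.  Every generator is a pure function of its
config and seed (byte-identical reruns), and every output ships with a
truth table recording the realised ground truth, which downstream checks
compare against instead of re-simulating.

What is emulated — and what is not: reads are uniform-quality (with a
configurable low-quality fraction to exercise trimming), substitution-only
and free of PCR duplicates or chimeras; flow channels are lognormal with a
per-cell multiplicative coupling between BFP and GFP and no spectral
spillover.  Passing tests therefore validate the estimators' logic and
calibration, not robustness to every artefact of real instruments.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import DesignError, InputError
from .editquant import ReadRecord
from .seqcore import NucSeq, reverse_complement, audit_frame

_DNA_COMP = str.maketrans("ACGTN", "TGCAN")


# -- transcripts ----------------------------------------------------------

@dataclass(frozen=True)
class TranscriptSimConfig:
    """A random transcript with an optional planted clean sensor site, an
    optional stop-poisoned site, and an optional SNV."""

    seed: int = 7
    length: int = 200
    arm_length: int = 39
    clean_site: int | None = 80
    poison_site: int | None = None
    snv: tuple[int, str, str] | None = None  # (position, ref, alt)

    def __post_init__(self) -> None:
        if self.length < self.arm_length + 20:
            raise InputError("transcript must be at least arm_length + 20 long")


def simulate_transcript(config: TranscriptSimConfig) -> tuple[NucSeq, dict]:
    """Generate a transcript plus a manifest of planted ground truth.

    The backbone is drawn from {A, C, U} so the junction filter (which needs
    a G on the target) fails everywhere except at the planted clean site;
    the clean window itself is rejection-sampled until its arm is stop-free.
    A poison site plants UAA in the arm frame; an SNV plant records a
    wild-type/mutant base pair at one position.
    """
    rng = np.random.default_rng(config.seed)
    L = config.arm_length
    bases = list(rng.choice(list("ACU"), size=config.length))
    manifest: dict = {"arm_length": L}

    def plant_window(start: int, poison: bool) -> None:
        if start < 0 or start + L + 1 > config.length:
            raise InputError("planted site does not fit the transcript")
        for _ in range(10000):
            window = "".join(rng.choice(list("ACGU"), size=L))
            arm = reverse_complement(NucSeq.rna(window)).residues
            stops = audit_frame(NucSeq.rna(arm), 0).stop_positions
            if poison and stops:
                break
            if not poison and not stops:
                break
        else:
            raise DesignError("could not sample a planted window")
        bases[start : start + L] = list(window)
        bases[start + L] = "G"  # junction base pairing the retained sensor C

    if config.clean_site is not None:
        plant_window(config.clean_site, poison=False)
        manifest["clean_site"] = config.clean_site
    if config.poison_site is not None:
        if config.clean_site is not None:
            lo, hi = sorted([config.clean_site, config.poison_site])
            if hi - lo < L + 1:
                raise InputError("planted sites overlap")
        plant_window(config.poison_site, poison=True)
        manifest["poison_site"] = config.poison_site
    transcript = NucSeq.rna("".join(bases))
    if config.snv is not None:
        pos, ref, alt = config.snv
        ref, alt = ref.upper().replace("T", "U"), alt.upper().replace("T", "U")
        if ref == alt:
            raise InputError("SNV ref and alt bases must differ")
        s = transcript.residues
        transcript = NucSeq.rna(s[:pos] + ref + s[pos + 1 :])
        manifest["snv"] = {"position": pos, "ref": ref, "alt": alt}
    return transcript, manifest


def snv_pair(transcript: NucSeq, position: int, ref: str, alt: str) -> tuple[NucSeq, NucSeq]:
    """Wild-type/mutant transcript pair differing at exactly one position."""
    s = transcript.to_rna().residues
    ref, alt = ref.upper().replace("T", "U"), alt.upper().replace("T", "U")
    wt = NucSeq.rna(s[:position] + ref + s[position + 1 :])
    mut = NucSeq.rna(s[:position] + alt + s[position + 1 :])
    return wt, mut


# -- amplicon reads -------------------------------------------------------

@dataclass(frozen=True)
class ReadSimConfig:
    """Paired 150-bp amplicon reads with programmed per-site editing.

    ``edit_sites`` maps 0-based reference positions (which must hold A on
    the sense strand) to per-molecule conversion probabilities.  Qualities
    default to a constant Q36 with a 2% sprinkling of Q12 to exercise end
    trimming; substitution errors are uniform over the three other bases.
    """

    seed: int = 11
    depth: int = 2000
    read_length: int = 150
    paired: bool = True
    edit_sites: dict[int, float] = field(default_factory=dict)
    error_rate: float = 0.001
    q_high: int = 36
    q_low: int = 12
    low_q_frac: float = 0.02
    start_jitter: int = 5

    def __post_init__(self) -> None:
        for pos, p in self.edit_sites.items():
            if not (0.0 <= p <= 1.0):
                raise InputError(f"edit probability at {pos} outside [0, 1]")
        if not (0.0 <= self.error_rate <= 0.25):
            raise InputError("error rate outside [0, 0.25]")


_BASE_IDX = {b: i for i, b in enumerate("ACGT")}
_IDX_BASE = np.array(list("ACGT"))


def simulate_reads(
    reference: NucSeq, config: ReadSimConfig
) -> tuple[list[tuple[ReadRecord, ReadRecord]] | list[ReadRecord], dict]:
    """Simulate reads over a (DNA) reference amplicon.

    Each simulated molecule is the reference with every edit site flipped
    A->G independently at its programmed probability; both mates observe
    the same molecule.  Returns the reads and a truth table of realised
    per-site edited fractions.
    """
    ref = reference.to_dna().residues
    n = len(ref)
    if config.read_length > n:
        raise InputError("read length exceeds the reference amplicon")
    for pos in config.edit_sites:
        if not (0 <= pos < n):
            raise InputError(f"edit site {pos} outside the reference")
        if ref[pos] != "A":
            raise InputError(f"edit site {pos} is {ref[pos]}, expected A (sense strand)")
    rng = np.random.default_rng(config.seed)
    truth = {
        pos: {"p": p, "edited": 0, "molecules": 0}
        for pos, p in sorted(config.edit_sites.items())
    }
    reads: list = []
    jmax = min(config.start_jitter, n - config.read_length)
    ref_arr = np.frombuffer(ref.encode(), dtype=np.uint8).copy()
    for m in range(config.depth):
        mol = ref_arr.copy()
        for pos, p in config.edit_sites.items():
            truth[pos]["molecules"] += 1
            if rng.random() < p:
                mol[pos] = ord("G")
                truth[pos]["edited"] += 1

        def make_read(seg: np.ndarray, rid: str, mate: str, rc: bool) -> ReadRecord:
            seg = seg.copy()
            err = rng.random(len(seg)) < config.error_rate
            if err.any():
                for k in np.nonzero(err)[0]:
                    choices = [b for b in "ACGT" if b != chr(seg[k])]
                    seg[k] = ord(choices[rng.integers(0, 3)])
            bases = seg.tobytes().decode()
            if rc:
                bases = bases.translate(_DNA_COMP)[::-1]
            quals = np.where(
                rng.random(len(seg)) < config.low_q_frac, config.q_low, config.q_high
            )
            return ReadRecord(rid, bases, tuple(int(q) for q in quals), mate)

        if config.paired:
            s1 = int(rng.integers(0, jmax + 1)) if jmax > 0 else 0
            s2 = int(rng.integers(0, jmax + 1)) if jmax > 0 else 0
            r1 = make_read(mol[s1 : s1 + config.read_length], f"m{m}", "1", rc=False)
            r2 = make_read(
                mol[n - s2 - config.read_length : n - s2], f"m{m}", "2", rc=True
            )
            reads.append((r1, r2))
        else:
            s1 = int(rng.integers(0, jmax + 1)) if jmax > 0 else 0
            reads.append(make_read(mol[s1 : s1 + config.read_length], f"m{m}", "single", rc=False))
    truth_table = {
        pos: {
            "p": rec["p"],
            "edited": rec["edited"],
            "molecules": rec["molecules"],
            "fraction": rec["edited"] / rec["molecules"] if rec["molecules"] else None,
        }
        for pos, rec in truth.items()
    }
    return reads, {"edit_sites": truth_table, "depth": config.depth}


# -- flow events ----------------------------------------------------------

@dataclass(frozen=True)
class FlowSimConfig:
    """Lognormal flow-cytometry channels with a programmed activation.

    Transfected cells express BFP lognormally; GFP is coupled per cell as
    ``GFP = BFP * baseline_ratio * noise`` (times ``activation`` in the
    plus-target condition), which mimics dose-dependent co-expression from
    one plasmid.  An untransfected fraction has near-zero (autofluorescent)
    BFP; small dead-cell and doublet fractions exercise the scatter gates.
    """

    seed: int = 7
    n_events: int = 10_000
    activation: float = 100.0
    bfp_mu: float = 7.0
    bfp_sigma: float = 0.5
    baseline_ratio: float = 0.005
    ratio_noise_sigma: float = 0.15
    untransfected_frac: float = 0.3
    dead_frac: float = 0.05
    doublet_frac: float = 0.05
    auto_mu: float = 2.0
    auto_sigma: float = 0.5

    def __post_init__(self) -> None:
        if self.n_events < 100:
            raise InputError("at least 100 events are required")
        for frac in (self.untransfected_frac, self.dead_frac, self.doublet_frac):
            if not (0.0 <= frac < 1.0):
                raise InputError("fractions must be in [0, 1)")
        if self.bfp_sigma <= 0 or self.ratio_noise_sigma < 0 or self.auto_sigma <= 0:
            raise InputError("lognormal sigma parameters must be positive")


def _scatter(rng: np.random.Generator, n: int, config: FlowSimConfig) -> pd.DataFrame:
    fsc = rng.lognormal(11.0, 0.25, n)
    ssc_h = rng.lognormal(10.0, 0.25, n)
    ssc_a = ssc_h * rng.lognormal(0.0, 0.05, n)
    dead = rng.random(n) < config.dead_frac
    fsc[dead] *= 0.12
    doublet = (~dead) & (rng.random(n) < config.doublet_frac)
    ssc_a[doublet] = 2.0 * ssc_h[doublet] * rng.lognormal(0.0, 0.03, doublet.sum())
    return pd.DataFrame({"FSC_A": fsc, "SSC_A": ssc_a, "SSC_H": ssc_h})


def _condition_table(
    rng: np.random.Generator, config: FlowSimConfig, activation: float, transfected_bfp: bool
) -> pd.DataFrame:
    n = config.n_events
    df = _scatter(rng, n, config)
    untransfected = rng.random(n) < config.untransfected_frac
    bfp = np.where(
        untransfected | (not transfected_bfp),
        rng.lognormal(config.auto_mu, config.auto_sigma, n),
        rng.lognormal(config.bfp_mu, config.bfp_sigma, n),
    )
    noise = rng.lognormal(0.0, config.ratio_noise_sigma, n)
    gfp = np.where(
        untransfected | (not transfected_bfp),
        rng.lognormal(config.auto_mu, config.auto_sigma, n),
        bfp * config.baseline_ratio * activation * noise,
    )
    df["BFP"] = bfp
    df["GFP"] = gfp
    df["untransfected"] = untransfected | (not transfected_bfp)
    return df


def simulate_events(
    config: FlowSimConfig,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame, dict]:
    """Generate (plus-target, minus-target, vector-control) event tables.

    The control table carries no reporter (autofluorescent BFP/GFP only)
    and is the quantile source for
    :meth:`hairpinsense.flowmetrics.GateConfig.from_control`.
    """
    rng = np.random.default_rng(config.seed)
    plus = _condition_table(rng, config, config.activation, transfected_bfp=True)
    minus = _condition_table(rng, config, 1.0, transfected_bfp=True)
    control = _condition_table(rng, config, 1.0, transfected_bfp=False)
    truth = {
        "activation": config.activation,
        "untransfected_frac": config.untransfected_frac,
        "baseline_ratio": config.baseline_ratio,
    }
    return plus, minus, control, truth
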