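"""Design of barcodes and bEXOmiR hairpin constructs.

A bEXOmiR is an artificial miR-30-backbone hairpin whose mature product is a
short barcode followed by the heptameric EXO motif (GGAGGAG), which promotes
sorting of the miRNA into extracellular vesicles. Barcodes are random 15-mers
filtered for moderate GC content, absence of homopolymer runs and of the
restriction sites used during library cloning, and held at a minimum pairwise
Hamming distance so that sequencing errors cannot move a read from one
barcode to another.

The designer draws random candidates, discards any that fail the
single-sequence rules, and grows the set greedily: a candidate joins the set
only if it is at least ``min_hamming`` substitutions away from every barcode
accepted so far. The whole procedure is deterministic given
``DesignConstraints.rng_seed``.
"""

from __future__ import annotations

import re
from collections.abc import Iterable, Mapping, Sequence
from dataclasses import dataclass, field

import numpy as np

from ._encoding import (
    BASES,
    encode_seqs,
    hamming_to_set,
    indices_to_seq,
    is_iupac,
    iupac_pattern,
    onehot_codes,
    revcomp,
)
from .errors import ConfigError, DesignError, ValidationError

#: Heptamer appended to every barcode; reported to enhance EV targeting.
EXO_MOTIF = "GGAGGAG"

#: Restriction enzymes used during cassette cloning; their sites must not
#: occur inside a barcode (IUPAC-degenerate, scanned on both strands).
DEFAULT_FORBIDDEN_SITES: Mapping[str, str] = {
    "EcoRI": "GAATTC",
    "MfeI": "CAATTG",
    "BlpI": "GCTNAGC",
    "BstXI": "CCANNNNNNTGG",
}

# Placeholder loop / flanking context supplied as defaults so that the
# assembly code runs out of the box. Production constructs should override
# these with the loop of the donor miRNA (miR-601) and miR-30a context via
# HairpinConfig; the defaults are synthetic stand-ins chosen only to be
# valid DNA free of the cloning sites.
DEFAULT_LOOP = "GTGAAGTCACAGATGTAC"
DEFAULT_CONTEXT_5P = "TGCTGTTGACAGTGAGCG"
DEFAULT_CONTEXT_3P = "TGCCTACTGCCTCGGA"

#: Passenger-strand substitution creating the hairpin-base mismatch, keyed
#: by the first barcode base: A-C, T-C, G-A and C-A pairings.
PASSENGER_MISMATCH_BASE = {"A": "C", "T": "C", "G": "A", "C": "A"}
VARIANT_BY_FIRST_BASE = {"A": "AC", "T": "TC", "G": "GA", "C": "CA"}
MISMATCH_VARIANTS = ("AC", "TC", "GA", "CA")


@dataclass(frozen=True)
class DesignConstraints:
    """Rules a barcode set must satisfy.

    Parameters
    ----------
    barcode_length
        Length of each barcode in nt.
    gc_min, gc_max
        Inclusive window for the GC fraction.
    min_hamming
        Minimum pairwise Hamming distance between any two barcodes.
    homopolymer_max_run
        Longest allowed run of a single base (3 forbids AAAA etc.).
    forbidden_sites
        Name -> IUPAC motif of restriction sites excluded from barcodes
        (scanned on both strands).
    candidate_budget
        Maximum number of random candidates the designer may draw.
    rng_seed
        Seed making the design reproducible.
    rc_hamming
        Strict mode: additionally require ``min_hamming`` to each accepted
        barcode's reverse complement.
    """

    barcode_length: int = 15
    gc_min: float = 0.40
    gc_max: float = 0.60
    min_hamming: int = 4
    homopolymer_max_run: int = 3
    forbidden_sites: Mapping[str, str] = field(
        default_factory=lambda: dict(DEFAULT_FORBIDDEN_SITES)
    )
    candidate_budget: int = 1_000_000
    rng_seed: int = 0
    rc_hamming: bool = False

    def __post_init__(self) -> None:
        if self.barcode_length <= 0:
            raise DesignError("barcode_length must be positive")
        if not (0.0 <= self.gc_min <= self.gc_max <= 1.0):
            raise DesignError("need 0 <= gc_min <= gc_max <= 1")
        if self.min_hamming < 0:
            raise DesignError("min_hamming must be non-negative")
        if self.homopolymer_max_run < 1:
            raise DesignError("homopolymer_max_run must be >= 1")
        for name, motif in self.forbidden_sites.items():
            if not motif or not is_iupac(motif):
                raise DesignError(f"forbidden site {name}: non-IUPAC motif {motif!r}")

    # -- derived helpers -------------------------------------------------
    def gc_count_bounds(self) -> tuple[int, int]:
        """Inclusive bounds on the number of G/C bases."""
        lo = int(np.ceil(self.gc_min * self.barcode_length - 1e-9))
        hi = int(np.floor(self.gc_max * self.barcode_length + 1e-9))
        return lo, hi

    def site_patterns(self) -> list[tuple[str, re.Pattern[str]]]:
        """Compiled forbidden-site regexes for both strands, deduplicated."""
        pats: list[tuple[str, re.Pattern[str]]] = []
        seen: set[str] = set()
        for name, motif in self.forbidden_sites.items():
            for strand_motif in (motif.upper(), revcomp(motif.upper())):
                if strand_motif not in seen:
                    seen.add(strand_motif)
                    pats.append((name, iupac_pattern(strand_motif)))
        return pats


@dataclass(frozen=True)
class Verdict:
    """Outcome of a single-barcode check; falsy when rejected."""

    accepted: bool
    reason: str | None = None
    detail: str | None = None

    def __bool__(self) -> bool:
        return self.accepted


def _max_run(seq: str) -> int:
    best = run = 1
    for a, b in zip(seq, seq[1:]):
        run = run + 1 if a == b else 1
        best = max(best, run)
    return best


def check_barcode(seq: str, constraints: DesignConstraints | None = None) -> Verdict:
    """Apply the single-sequence design rules to ``seq``.

    Returns an accepting verdict, or a rejection carrying the first rule
    that failed (length, GC window, homopolymer run, forbidden site, in
    that order). Non-ACGT characters raise ``DesignError``.
    """
    c = constraints or DesignConstraints()
    bad = set(seq.upper()) - set(BASES)
    if bad or not seq:
        raise DesignError(f"barcode must be non-empty ACGT, got {seq!r}")
    seq = seq.upper()
    if len(seq) != c.barcode_length:
        return Verdict(False, "length", f"{len(seq)} != {c.barcode_length}")
    gc = sum(seq.count(b) for b in "GC")
    lo, hi = c.gc_count_bounds()
    if not (lo <= gc <= hi):
        return Verdict(False, "gc_content", f"{gc / len(seq):.3f} outside [{c.gc_min}, {c.gc_max}]")
    run = _max_run(seq)
    if run > c.homopolymer_max_run:
        return Verdict(False, "homopolymer", f"run of {run} > {c.homopolymer_max_run}")
    for name, pat in c.site_patterns():
        m = pat.search(seq)
        if m:
            return Verdict(False, "forbidden_site", f"{name} at {m.start()}")
    return Verdict(True)


@dataclass(frozen=True)
class FeasibilityReport:
    """Bookkeeping of a design run."""

    requested: int | None
    designed: int
    candidates_tried: int
    candidate_budget: int
    complete: bool


class BarcodeSet(Sequence[str]):
    """An ordered, constraint-satisfying set of barcodes."""

    def __init__(self, sequences: list[str], constraints: DesignConstraints,
                 report: FeasibilityReport):
        self.sequences = sequences
        self.constraints = constraints
        self.report = report

    def __len__(self) -> int:
        return len(self.sequences)

    def __getitem__(self, i):
        return self.sequences[i]

    def __iter__(self):
        return iter(self.sequences)

    def __repr__(self) -> str:
        return (f"BarcodeSet(n={len(self)}, length={self.constraints.barcode_length}, "
                f"min_hamming={self.constraints.min_hamming})")


def _batch_self_ok(idx: np.ndarray, c: DesignConstraints) -> np.ndarray:
    """Vectorised GC-window and homopolymer filter for a batch of candidates."""
    lo, hi = c.gc_count_bounds()
    gc = ((idx == 1) | (idx == 2)).sum(axis=1)
    ok = (gc >= lo) & (gc <= hi)
    if c.barcode_length > c.homopolymer_max_run:
        eq = idx[:, 1:] == idx[:, :-1]
        w = c.homopolymer_max_run  # a run of w+1 bases = w consecutive equalities
        has_run = np.zeros(idx.shape[0], dtype=bool)
        # sliding AND over windows of width w
        csum = np.cumsum(eq, axis=1, dtype=np.int32)
        if eq.shape[1] >= w:
            win = csum[:, w - 1:].copy()
            win[:, 1:] -= csum[:, :-w]
            has_run = (win == w).any(axis=1)
        ok &= ~has_run
    return ok


def design_barcodes(n: int | None, constraints: DesignConstraints | None = None,
                    *, avoid: Iterable[str] = ()) -> BarcodeSet:
    """Design up to ``n`` barcodes by seeded rejection sampling + greedy growth.

    ``n=None`` keeps growing the set until the candidate budget is spent,
    returning the largest set found. ``avoid`` seeds the distance check with
    pre-existing barcodes (used when topping up a refined library) without
    including them in the result.

    Every returned barcode individually passes :func:`check_barcode` and all
    pairwise Hamming distances are >= ``min_hamming``. If the budget runs out
    before ``n`` barcodes are found the partial set is returned; the attached
    :class:`FeasibilityReport` says whether the request completed.
    """
    if n is not None and n < 1:
        raise DesignError("n must be >= 1 (or None for budget-limited design)")
    c = constraints or DesignConstraints()
    rng = np.random.default_rng(c.rng_seed)
    L = c.barcode_length
    patterns = c.site_patterns()
    need_rc = c.rc_hamming

    avoid = list(avoid)
    cap = (n or 0) + len(avoid) + 1024
    codes = np.zeros(cap, dtype=np.uint64)
    rc_codes = np.zeros(cap, dtype=np.uint64) if need_rc else None
    k = 0  # accepted (incl. avoid) occupying codes[:k]
    for seq in avoid:
        codes[k] = encode_seqs([seq])[0]
        if need_rc:
            rc_codes[k] = encode_seqs([revcomp(seq)])[0]
        k += 1
    n_avoid = k

    accepted: list[str] = []
    tried = 0
    budget = c.candidate_budget
    min_d2 = np.uint64(2 * c.min_hamming)  # popcount threshold
    batch_size = 8192

    while tried < budget and (n is None or len(accepted) < n):
        b = min(batch_size, budget - tried)
        idx = rng.integers(0, 4, size=(b, L), dtype=np.uint8)
        tried += b
        ok = _batch_self_ok(idx, c)
        if L > 16:
            raise DesignError("barcode_length > 16 not supported by the packed designer")
        cand_codes = onehot_codes(idx)
        for row in np.flatnonzero(ok):
            if n is not None and len(accepted) >= n:
                break
            code = cand_codes[row]
            if k:
                d2 = np.bitwise_count(codes[:k] ^ code)
                if d2.min() < min_d2:
                    continue
            seq = indices_to_seq(idx[row])
            if any(p.search(seq) for _, p in patterns):
                continue
            if need_rc:
                rc = encode_seqs([revcomp(seq)])[0]
                if k and (np.bitwise_count(rc_codes[:k] ^ code).min() < min_d2
                          or np.bitwise_count(codes[:k] ^ rc).min() < min_d2):
                    continue
            if k == cap:
                cap *= 2
                codes = np.resize(codes, cap)
                if need_rc:
                    rc_codes = np.resize(rc_codes, cap)
            codes[k] = code
            if need_rc:
                rc_codes[k] = rc
            k += 1
            accepted.append(seq)

    complete = n is not None and len(accepted) >= n
    report = FeasibilityReport(
        requested=n, designed=len(accepted), candidates_tried=tried,
        candidate_budget=budget, complete=complete,
    )
    assert k - n_avoid == len(accepted)
    return BarcodeSet(accepted, c, report)


def min_pairwise_hamming(seqs: Sequence[str]) -> int:
    """Minimum Hamming distance over all pairs (packed popcount scan)."""
    if len(seqs) < 2:
        raise DesignError("need at least two sequences")
    codes = encode_seqs(seqs)
    best = len(seqs[0]) + 1
    for i in range(len(codes) - 1):
        d = hamming_to_set(codes[i], codes[i + 1:])
        best = min(best, int(d.min()))
        if best == 0:
            break
    return best


# ---------------------------------------------------------------------------
# Hairpin assembly
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class HairpinConfig:
    """Loop and flanking-context sequences of the hairpin backbone.

    Defaults are documented placeholders; supply the construct's real
    miR-601-derived loop and miR-30a context sequences for production use.
    """

    loop_seq: str = DEFAULT_LOOP
    context_5p: str = DEFAULT_CONTEXT_5P
    context_3p: str = DEFAULT_CONTEXT_3P

    def __post_init__(self) -> None:
        for label, seq in (("loop_seq", self.loop_seq),
                           ("context_5p", self.context_5p),
                           ("context_3p", self.context_3p)):
            if seq is None:
                raise ConfigError(f"hairpin {label} missing")
            if seq and set(seq.upper()) - set(BASES):
                raise ConfigError(f"hairpin {label} contains non-ACGT characters")
        if not self.loop_seq:
            raise ConfigError("hairpin loop_seq must be non-empty")


@dataclass(frozen=True)
class HairpinConstruct:
    """A fully assembled pri-miRNA-style bEXOmiR hairpin (DNA coordinates)."""

    barcode: str
    exo_motif: str
    loop_seq: str
    context_5p: str
    context_3p: str
    mismatch_variant: str  # "none", "AC", "TC", "GA" or "CA"
    full_sequence: str
    mature_sequence: str


def assemble_mature(barcode: str) -> str:
    """Mature bEXOmiR sequence: barcode followed by the EXO motif."""
    if not barcode or set(barcode.upper()) - set(BASES):
        raise DesignError(f"invalid barcode {barcode!r}")
    return barcode.upper() + EXO_MOTIF


def assemble_hairpin(barcode: str, config: HairpinConfig | None = None,
                     mismatch_variant: str = "none") -> HairpinConstruct:
    """Assemble the hairpin: 5' context, sense arm (barcode+EXO), loop,
    passenger arm (reverse complement, optionally with the single base
    mismatch at the stem base), 3' context.

    The mismatch variant replaces the passenger base paired with the first
    barcode base (stem position 1) so that processing of the primary
    transcript mimics the bulge at the base of the miR-30 hairpin; it never
    changes the mature sequence.
    """
    cfg = config or HairpinConfig()
    mature = assemble_mature(barcode)
    barcode = barcode.upper()
    sense = mature
    passenger = revcomp(sense)
    if mismatch_variant != "none":
        expected = VARIANT_BY_FIRST_BASE[barcode[0]]
        if mismatch_variant != expected:
            raise DesignError(
                f"variant {mismatch_variant} incompatible with first base "
                f"{barcode[0]!r} (expected {expected})"
            )
        # stem position 1 pairs the first sense base with the last passenger base
        passenger = passenger[:-1] + PASSENGER_MISMATCH_BASE[barcode[0]]
    full = cfg.context_5p + sense + cfg.loop_seq + passenger + cfg.context_3p
    return HairpinConstruct(
        barcode=barcode, exo_motif=EXO_MOTIF, loop_seq=cfg.loop_seq,
        context_5p=cfg.context_5p, context_3p=cfg.context_3p,
        mismatch_variant=mismatch_variant, full_sequence=full,
        mature_sequence=mature,
    )


def make_mismatch_variants(barcode: str, which: str | Iterable[str] = "auto",
                           config: HairpinConfig | None = None) -> list[HairpinConstruct]:
    """Build hairpin constructs with the requested stem-base mismatches.

    ``which`` may be ``"auto"`` (the variant dictated by the first barcode
    base), ``"none"`` (perfect stem), ``"both"`` (perfect + auto, the
    two-version library expansion), or an iterable of explicit variant codes
    drawn from AC/TC/GA/CA — each must match the first base.
    """
    barcode = barcode.upper()
    if isinstance(which, str):
        if which == "auto":
            variants = [VARIANT_BY_FIRST_BASE[barcode[0]]]
        elif which == "none":
            variants = ["none"]
        elif which == "both":
            variants = ["none", VARIANT_BY_FIRST_BASE[barcode[0]]]
        else:
            variants = [which]
    else:
        variants = list(which)
    for v in variants:
        if v not in MISMATCH_VARIANTS and v != "none":
            raise DesignError(f"unknown mismatch variant {v!r}")
    return [assemble_hairpin(barcode, config, mismatch_variant=v) for v in variants]


# ---------------------------------------------------------------------------
# Cassette assembly
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CassetteConfig:
    """Restriction sites and sublibrary primer flanks of the synthesis oligo."""

    site_blpI: str = "GCTCAGC"   # concrete instance of GCTNAGC
    site_ecoRI: str = "GAATTC"
    primer_flank_5p: str = ""
    primer_flank_3p: str = ""


@dataclass(frozen=True)
class Cassette:
    """One sgRNA-bEXOmiR synthesis oligo."""

    sgrna_seq: str
    hairpin: HairpinConstruct
    site_blpI: str
    site_ecoRI: str
    primer_flank_5p: str
    primer_flank_3p: str
    full_oligo: str
    stray_sites: tuple[tuple[str, int], ...] = ()


def build_cassette(sgrna: str, hairpin: HairpinConstruct,
                   config: CassetteConfig | None = None, *, strict: bool = False,
                   forbidden_sites: Mapping[str, str] | None = None) -> Cassette:
    """Concatenate flank + sgRNA + BlpI + EcoRI + hairpin + flank.

    The internal region (everything between the primer flanks) is scanned
    for occurrences of the cloning enzymes' sites, on both strands, outside
    the two deliberately placed inter-module sites. In ``strict`` mode any
    stray occurrence raises :class:`ValidationError` listing positions;
    otherwise they are reported on ``Cassette.stray_sites``.
    """
    if not sgrna:
        raise DesignError("sgRNA sequence must be non-empty")
    if set(sgrna.upper()) - set(BASES):
        raise DesignError("sgRNA sequence must be plain ACGT")
    cfg = config or CassetteConfig()
    sgrna = sgrna.upper()
    full = (cfg.primer_flank_5p + sgrna + cfg.site_blpI + cfg.site_ecoRI
            + hairpin.full_sequence + cfg.primer_flank_3p)

    sites = forbidden_sites or DEFAULT_FORBIDDEN_SITES
    start = len(cfg.primer_flank_5p)
    end = len(full) - len(cfg.primer_flank_3p)
    blpI_at = start + len(sgrna)
    ecoRI_at = blpI_at + len(cfg.site_blpI)
    designated = {(blpI_at, blpI_at + len(cfg.site_blpI)),
                  (ecoRI_at, ecoRI_at + len(cfg.site_ecoRI))}
    stray: list[tuple[str, int]] = []
    seen_pat: set[str] = set()
    for name, motif in sites.items():
        for strand_motif in (motif.upper(), revcomp(motif.upper())):
            if strand_motif in seen_pat:
                continue
            seen_pat.add(strand_motif)
            pat = iupac_pattern(strand_motif)
            for m in pat.finditer(full, start, end):
                span = (m.start(), m.end())
                if span not in designated:
                    stray.append((name, m.start()))
    stray.sort(key=lambda t: t[1])
    if strict and stray:
        listing = ", ".join(f"{n}@{p}" for n, p in stray)
        raise ValidationError(f"stray restriction sites in cassette: {listing}")
    return Cassette(
        sgrna_seq=sgrna, hairpin=hairpin, site_blpI=cfg.site_blpI,
        site_ecoRI=cfg.site_ecoRI, primer_flank_5p=cfg.primer_flank_5p,
        primer_flank_3p=cfg.primer_flank_3p, full_oligo=full,
        stray_sites=tuple(stray),
    )


# ---------------------------------------------------------------------------
# Export
# ---------------------------------------------------------------------------

def constructs_to_frame(constructs: Mapping[str, HairpinConstruct]):
    """Tabulate constructs as element_id, barcode, mature, hairpin, variant."""
    import pandas as pd

    rows = [
        {"element_id": eid, "barcode": hp.barcode, "mature": hp.mature_sequence,
         "hairpin": hp.full_sequence, "variant": hp.mismatch_variant}
        for eid, hp in constructs.items()
    ]
    return pd.DataFrame(rows)


def write_constructs_fasta(constructs: Mapping[str, HairpinConstruct], path,
                           which: str = "mature") -> None:
    """Write mature or full-hairpin records to FASTA (IDs = element IDs)."""
    from Bio import SeqIO
    from Bio.Seq import Seq
    from Bio.SeqRecord import SeqRecord

    if which not in ("mature", "hairpin"):
        raise ConfigError("which must be 'mature' or 'hairpin'")
    records = [
        SeqRecord(Seq(hp.mature_sequence if which == "mature" else hp.full_sequence),
                  id=eid, description="")
        for eid, hp in constructs.items()
    ]
    SeqIO.write(records, str(path), "fasta")
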