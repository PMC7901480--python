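"""Design, assembly and validation of synthetic internal-standard sequences.

An internal standard is a synthetic DNA construct spiked into a sample at a
known copy number before DNA extraction so that sequencing read counts can be
converted into absolute abundances. Each construct carries, from 5' to 3':

* the forward bacterial universal primer (336F, 16S rRNA V3-V4),
* a short spacer,
* the forward fungal universal primer site (ITS3, ITS2 region),
* a long random "stuffer" constrained to resemble real amplicons,
* the reverse complement of the reverse fungal primer (ITS4),
* a second stuffer,
* the reverse complement of the reverse bacterial primer (806R).

Nesting the fungal sites inside the bacterial amplicon lets a single molecule
serve as a spike-in for both the 16S and the ITS sequencing libraries.

Stuffers are random sequences matched to the GC content and length of the
dominant community members, with composition guards (bounded homopolymers,
no long exact repeats, no long self-complementary regions) so the construct
amplifies cleanly and cannot be mistaken for a biological sequence. Each
standard additionally carries a specific primer pair used to recognise its
reads in sequencing output.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from importlib import resources
from typing import Iterable, Mapping, Sequence

import numpy as np

from .errors import AssemblyError, DesignError, InvalidSequenceError

# --------------------------------------------------------------------------
# IUPAC alphabet
# --------------------------------------------------------------------------

IUPAC_SETS: Mapping[str, str] = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}

_COMPLEMENT = {
    "A": "T", "C": "G", "G": "C", "T": "A",
    "R": "Y", "Y": "R", "S": "S", "W": "W", "K": "M", "M": "K",
    "B": "V", "V": "B", "D": "H", "H": "D", "N": "N",
}

UNIVERSAL_PRIMERS: Mapping[str, str] = {
    # bacterial 16S rRNA V3-V4
    "336F": "GTACTCCTACGGGAGGCAGCA",
    "806R": "GTGGACTACHVGGGTWTCTAAT",
    # fungal ITS2
    "ITS3": "GCATCGATGAAGAACGCAGC",
    "ITS4": "TCCTCCGCTTATTGATATGC",
}


def normalize_sequence(seq: str) -> str:
    """Uppercase a DNA string and map U to T."""
    return seq.upper().replace("U", "T")


def _check_alphabet(seq: str, alphabet: str = "ACGT") -> None:
    bad = set(seq) - set(alphabet)
    if bad:
        raise InvalidSequenceError(
            f"sequence contains non-{alphabet} characters: {sorted(bad)}"
        )


def reverse_complement(seq: str) -> str:
    """Reverse complement of a DNA string, honouring IUPAC degenerate codes.

    An involution: ``reverse_complement(reverse_complement(s)) == s``.
    """
    seq = normalize_sequence(seq)
    try:
        return "".join(_COMPLEMENT[b] for b in reversed(seq))
    except KeyError as exc:
        raise InvalidSequenceError(f"unknown IUPAC symbol {exc.args[0]!r}") from exc


def iupac_match(pattern: str, text: str) -> bool:
    """True if ``text`` (ACGT) matches ``pattern`` (IUPAC) position by position."""
    if len(pattern) != len(text):
        return False
    try:
        return all(t in IUPAC_SETS[p] for p, t in zip(pattern, text))
    except KeyError as exc:
        raise InvalidSequenceError(f"unknown IUPAC symbol {exc.args[0]!r}") from exc


def find_iupac(pattern: str, seq: str) -> int:
    """First 0-based occurrence of an IUPAC pattern in an ACGT sequence, or -1."""
    m = len(pattern)
    for i in range(len(seq) - m + 1):
        if iupac_match(pattern, seq[i : i + m]):
            return i
    return -1


# --------------------------------------------------------------------------
# Composition statistics
# --------------------------------------------------------------------------

def gc_fraction(seq: str) -> float:
    """Fraction of G+C bases in an ACGT sequence, in [0, 1]."""
    seq = normalize_sequence(seq)
    if not seq:
        raise InvalidSequenceError("empty sequence")
    _check_alphabet(seq)
    return (seq.count("G") + seq.count("C")) / len(seq)


def max_homopolymer_run(seq: str) -> int:
    """Length of the longest run of a single repeated base."""
    seq = normalize_sequence(seq)
    if not seq:
        raise InvalidSequenceError("empty sequence")
    best = run = 1
    for a, b in zip(seq, seq[1:]):
        run = run + 1 if a == b else 1
        if run > best:
            best = run
    return best


def longest_repeat(seq: str) -> int:
    """Length of the longest substring occurring at >= 2 distinct start positions.

    Exact-match repeat detection (a deterministic, stricter stand-in for a
    BLAST self-screen at these scales). Binary search over candidate lengths
    with a k-mer dictionary; expected O(n log n).
    """
    seq = normalize_sequence(seq)
    if len(seq) < 2:
        raise InvalidSequenceError("need length >= 2")

    def has_repeat(k: int) -> bool:
        seen: set[str] = set()
        for i in range(len(seq) - k + 1):
            kmer = seq[i : i + k]
            if kmer in seen:
                return True
            seen.add(kmer)
        return False

    lo, hi = 0, len(seq) - 1  # a repeat of length n is impossible
    while lo < hi:
        mid = (lo + hi + 1) // 2
        if has_repeat(mid):
            lo = mid
        else:
            hi = mid - 1
    return lo


def longest_self_complement(seq: str) -> int:
    """Longest substring whose reverse complement also occurs in the sequence.

    Occurrences may overlap (a perfect palindromic substring counts: its
    reverse complement occupies the same positions). This is a conservative
    superset of hairpin/dimer definitions.
    """
    seq = normalize_sequence(seq)
    if len(seq) < 2:
        raise InvalidSequenceError("need length >= 2")
    _check_alphabet(seq)

    def has_selfcomp(k: int) -> bool:
        kmers = {seq[i : i + k] for i in range(len(seq) - k + 1)}
        return any(reverse_complement(km) in kmers for km in kmers)

    lo, hi = 0, len(seq)
    while lo < hi:
        mid = (lo + hi + 1) // 2
        if has_selfcomp(mid):
            lo = mid
        else:
            hi = mid - 1
    return lo


# --------------------------------------------------------------------------
# Melting temperature (nearest-neighbor)
# --------------------------------------------------------------------------

# SantaLucia & Hicks (2004) unified NN parameters: (dH kcal/mol, dS cal/mol/K)
_NN_TABLE = {
    "AA": (-7.6, -21.3), "TT": (-7.6, -21.3),
    "AT": (-7.2, -20.4),
    "TA": (-7.2, -21.3),
    "CA": (-8.5, -22.7), "TG": (-8.5, -22.7),
    "GT": (-8.4, -22.4), "AC": (-8.4, -22.4),
    "CT": (-7.8, -21.0), "AG": (-7.8, -21.0),
    "GA": (-8.2, -22.2), "TC": (-8.2, -22.2),
    "CG": (-10.6, -27.2),
    "GC": (-9.8, -24.4),
    "GG": (-8.0, -19.9), "CC": (-8.0, -19.9),
}
_NN_INIT = (0.2, -5.7)
_NN_TERM_AT = (2.2, 6.9)  # per A/T terminal

TM_SODIUM_MM = 50.0    # monovalent cation, mM
TM_STRAND_NM = 25.0    # each strand concentration, nM
_R_GAS = 1.987         # cal/(mol K)


def melting_temperature(seq: str) -> float:
    """Nearest-neighbor melting temperature in degrees Celsius.

    Unified duplex parameters with an entropic salt correction at 50 mM Na+
    and 25 nM per strand. Degenerate bases are rejected: expand them first.
    """
    seq = normalize_sequence(seq)
    if len(seq) < 8:
        raise InvalidSequenceError("need length >= 8 for a meaningful Tm")
    _check_alphabet(seq)
    dh, ds = _NN_INIT
    for b in (seq[0], seq[-1]):
        if b in "AT":
            dh += _NN_TERM_AT[0]
            ds += _NN_TERM_AT[1]
    for i in range(len(seq) - 1):
        h, s = _NN_TABLE[seq[i : i + 2]]
        dh += h
        ds += s
    # entropic salt correction (0.368 * N/2-phosphates * ln[Na+])
    ds += 0.368 * (len(seq) - 1) * math.log(TM_SODIUM_MM / 1000.0)
    ct = (TM_STRAND_NM - TM_STRAND_NM / 2.0) * 1e-9
    return (1000.0 * dh) / (ds + _R_GAS * math.log(ct)) - 273.15


# --------------------------------------------------------------------------
# Constraint containers
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class DesignConstraints:
    """Composition constraints applied to stuffer segments.

    GC uniformity is a window of ``gc_tolerance`` (default +-1 percentage
    point) around ``target_gc``; homopolymers longer than ``max_homopolymer``
    (default 10 bp), exact repeats longer than ``max_repeat`` (default 16 bp)
    and self-complementary regions longer than ``max_self_complement``
    (default 10 bp) are rejected.
    """

    target_length: int
    target_gc: float
    gc_tolerance: float = 0.01
    max_homopolymer: int = 10
    max_repeat: int = 16
    max_self_complement: int = 10

    def __post_init__(self) -> None:
        if self.target_length <= 0:
            raise ValueError("target_length must be positive")
        if not 0.0 < self.target_gc < 1.0:
            raise ValueError("target_gc must be in (0, 1)")
        for name in ("max_homopolymer", "max_repeat", "max_self_complement"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")


@dataclass(frozen=True)
class PrimerCriteria:
    """Acceptance criteria for specific recognition primers."""

    length_range: tuple[int, int] = (18, 24)
    tm_window: tuple[float, float] = (55.0, 65.0)
    gc_window: tuple[float, float] = (0.40, 0.60)
    max_homopolymer: int = 3
    max_self_complement: int = 5

    def __post_init__(self) -> None:
        if self.length_range[0] > self.length_range[1]:
            raise ValueError("empty length_range")
        if self.tm_window[0] > self.tm_window[1]:
            raise ValueError("empty tm_window")
        if self.gc_window[0] > self.gc_window[1]:
            raise ValueError("empty gc_window")
        if self.max_homopolymer < 1:
            raise ValueError("max_homopolymer must be >= 1")


@dataclass(frozen=True)
class PrimerPair:
    name: str
    forward: str
    reverse: str
    tm_forward: float
    tm_reverse: float
    role: str = "specific"  # universal_bacterial | universal_fungal | specific

    def __post_init__(self) -> None:
        for seq in (self.forward, self.reverse):
            if not seq:
                raise InvalidSequenceError("primer sequence is empty")
            bad = set(seq) - set(IUPAC_SETS)
            if bad:
                raise InvalidSequenceError(f"non-IUPAC characters: {sorted(bad)}")


@dataclass(frozen=True)
class Segment:
    """One scaffold segment: a role plus either a fixed sequence or a length."""

    role: str
    sequence: str | None = None
    length: int | None = None

    def resolved_length(self) -> int:
        if self.sequence is not None:
            return len(self.sequence)
        if self.length is not None:
            return self.length
        raise AssemblyError(f"segment {self.role!r} has neither sequence nor length")


# A synthesised construct must be concrete DNA: degenerate positions in
# universal primers are instantiated with this fixed choice (the same
# realization the shipped reference standards use at the 806R site).
_DEGENERATE_RESOLUTION = {
    "R": "A", "Y": "C", "S": "G", "W": "A", "K": "G", "M": "A",
    "B": "T", "D": "G", "H": "A", "V": "G", "N": "A",
}


def resolve_degenerate(seq: str) -> str:
    """Replace IUPAC degenerate symbols with a fixed concrete base choice."""
    return "".join(_DEGENERATE_RESOLUTION.get(b, b) for b in normalize_sequence(seq))


FIXED_ROLES = {
    "fwd_universal_bact": UNIVERSAL_PRIMERS["336F"],
    "fwd_universal_fungal_site": UNIVERSAL_PRIMERS["ITS3"],
    "rc_rev_universal_fungal_site": reverse_complement(UNIVERSAL_PRIMERS["ITS4"]),
    "rc_rev_universal_bact": reverse_complement(UNIVERSAL_PRIMERS["806R"]),
}
VARIABLE_ROLES = {"spacer", "stuffer"}


@dataclass(frozen=True)
class ScaffoldLayout:
    """Ordered segment list; coordinates are 0-based half-open after assembly."""

    segments: tuple[Segment, ...]

    def __post_init__(self) -> None:
        roles = [s.role for s in self.segments]
        if not roles or roles[0] != "fwd_universal_bact":
            raise AssemblyError("layout must start with fwd_universal_bact")
        if roles[-1] != "rc_rev_universal_bact":
            raise AssemblyError("layout must end with rc_rev_universal_bact")
        for required in ("fwd_universal_fungal_site", "rc_rev_universal_fungal_site"):
            if required not in roles:
                raise AssemblyError(f"layout missing {required}")
        if roles.index("fwd_universal_fungal_site") > roles.index(
            "rc_rev_universal_fungal_site"
        ):
            raise AssemblyError("fungal sites out of order inside bacterial amplicon")
        unknown = set(roles) - set(FIXED_ROLES) - VARIABLE_ROLES
        if unknown:
            raise AssemblyError(f"unknown segment roles: {sorted(unknown)}")

    def coordinates(self) -> dict[int, tuple[int, int]]:
        """Segment index -> (start, end) half-open coordinates."""
        coords, pos = {}, 0
        for i, seg in enumerate(self.segments):
            n = len(FIXED_ROLES[seg.role]) if seg.role in FIXED_ROLES else seg.resolved_length()
            coords[i] = (pos, pos + n)
            pos += n
        return coords


def default_layout(spacer_len: int = 10, its2_stuffer_len: int = 324,
                   tail_stuffer_len: int = 55) -> ScaffoldLayout:
    """The 472-bp architecture of the shipped reference standards."""
    return ScaffoldLayout((
        Segment("fwd_universal_bact"),
        Segment("spacer", length=spacer_len),
        Segment("fwd_universal_fungal_site"),
        Segment("stuffer", length=its2_stuffer_len),
        Segment("rc_rev_universal_fungal_site"),
        Segment("stuffer", length=tail_stuffer_len),
        Segment("rc_rev_universal_bact"),
    ))


@dataclass
class InternalStandard:
    """A synthetic spike-in construct with resolved layout coordinates."""

    id: str
    sequence: str
    layout: ScaffoldLayout
    coordinates: dict[int, tuple[int, int]]
    specific_primers: PrimerPair | None = None

    def __post_init__(self) -> None:
        self.sequence = normalize_sequence(self.sequence)
        for start, end in self.coordinates.values():
            if not (0 <= start <= end <= len(self.sequence)):
                raise AssemblyError(
                    f"{self.id}: coordinates ({start}, {end}) outside sequence"
                )

    @property
    def length(self) -> int:
        return len(self.sequence)

    @property
    def gc_percent(self) -> float:
        return 100.0 * gc_fraction(self.sequence)

    def segment_sequence(self, index: int) -> str:
        start, end = self.coordinates[index]
        return self.sequence[start:end]

    def stuffers(self) -> list[str]:
        return [
            self.segment_sequence(i)
            for i, seg in enumerate(self.layout.segments)
            if seg.role in VARIABLE_ROLES
        ]

    def amplicon(self, region: str = "16S_V3V4") -> str:
        """The amplified sub-sequence for a region, primers included."""
        if region == "16S_V3V4":
            return self.sequence
        if region == "ITS2":
            roles = [s.role for s in self.layout.segments]
            i = roles.index("fwd_universal_fungal_site")
            j = roles.index("rc_rev_universal_fungal_site")
            return self.sequence[self.coordinates[i][0] : self.coordinates[j][1]]
        raise ValueError(f"unknown region {region!r}")


# --------------------------------------------------------------------------
# Stuffer generation and assembly
# --------------------------------------------------------------------------

def generate_stuffer(constraints: DesignConstraints, rng_seed: int,
                     max_tries: int = 500) -> str:
    """Draw a random ACGT sequence satisfying every composition constraint.

    The GC count is drawn uniformly from the integers inside the tolerance
    window and bases are shuffled, so the GC constraint holds by construction;
    homopolymer/repeat/self-complement guards are enforced by rejection.
    Reproducible for a given seed.
    """
    n = constraints.target_length
    if n < 20:
        raise DesignError("target_length < 20 is not supported")
    lo = math.ceil((constraints.target_gc - constraints.gc_tolerance) * n)
    hi = math.floor((constraints.target_gc + constraints.gc_tolerance) * n)
    lo, hi = max(lo, 0), min(hi, n)
    if lo > hi:
        raise DesignError(
            f"GC window [{constraints.target_gc - constraints.gc_tolerance:.4f}, "
            f"{constraints.target_gc + constraints.gc_tolerance:.4f}] admits no "
            f"integer GC count at length {n}"
        )
    rng = np.random.default_rng(rng_seed)
    failures: dict[str, int] = {"homopolymer": 0, "repeat": 0, "self_complement": 0}
    for _ in range(max_tries):
        gc = int(rng.integers(lo, hi + 1))
        bases = np.concatenate([rng.choice(list("GC"), size=gc),
                                rng.choice(list("AT"), size=n - gc)])
        rng.shuffle(bases)
        seq = "".join(bases)
        if max_homopolymer_run(seq) > constraints.max_homopolymer:
            failures["homopolymer"] += 1
            continue
        if longest_repeat(seq) > constraints.max_repeat:
            failures["repeat"] += 1
            continue
        if longest_self_complement(seq) > constraints.max_self_complement:
            failures["self_complement"] += 1
            continue
        return seq
    raise DesignError(
        f"no stuffer satisfying {constraints} in {max_tries} tries; "
        f"rejection counts: {failures}"
    )


def generate_spacer(length: int, target_gc: float, rng_seed: int,
                    max_homopolymer: int = 10) -> str:
    """Short random segment (< 20 bp) with GC count nearest the target.

    Spacers are too short for the windowed stuffer constraints; the GC count
    is simply rounded to the closest achievable integer.
    """
    if length < 1:
        raise DesignError("spacer length must be >= 1")
    rng = np.random.default_rng(rng_seed)
    gc = int(round(target_gc * length))
    for _ in range(200):
        bases = np.concatenate([rng.choice(list("GC"), size=gc),
                                rng.choice(list("AT"), size=length - gc)])
        rng.shuffle(bases)
        seq = "".join(bases)
        if max_homopolymer_run(seq) <= max_homopolymer:
            return seq
    raise DesignError(f"no spacer of length {length} found")


def assemble_internal_standard(layout: ScaffoldLayout, stuffers: Sequence[str],
                               id: str,
                               universal_primers: Mapping[str, str] | None = None,
                               ) -> InternalStandard:
    """Concatenate fixed primer sites and generated stuffers into a standard.

    ``stuffers`` fills the variable (spacer/stuffer) segments in layout order;
    lengths must match any length specs in the layout.
    """
    fixed = dict(FIXED_ROLES)
    if universal_primers is not None:
        fixed["fwd_universal_bact"] = normalize_sequence(universal_primers["336F"])
        fixed["fwd_universal_fungal_site"] = normalize_sequence(universal_primers["ITS3"])
        fixed["rc_rev_universal_fungal_site"] = reverse_complement(universal_primers["ITS4"])
        fixed["rc_rev_universal_bact"] = reverse_complement(universal_primers["806R"])
    variable = [s for s in layout.segments if s.role in VARIABLE_ROLES]
    if len(variable) != len(stuffers):
        raise AssemblyError(
            f"layout has {len(variable)} variable segments but {len(stuffers)} "
            "stuffers were supplied"
        )
    parts, coords, pos, k = [], {}, 0, 0
    for i, seg in enumerate(layout.segments):
        if seg.role in fixed:
            piece = resolve_degenerate(seg.sequence or fixed[seg.role])
        else:
            piece = normalize_sequence(stuffers[k])
            if seg.length is not None and len(piece) != seg.length:
                raise AssemblyError(
                    f"segment {i} expects length {seg.length}, got {len(piece)}"
                )
            k += 1
        parts.append(piece)
        coords[i] = (pos, pos + len(piece))
        pos += len(piece)
    return InternalStandard(id=id, sequence="".join(parts), layout=layout,
                            coordinates=coords)


def detect_layout(sequence: str, id: str = "IS") -> InternalStandard:
    """Recover the scaffold layout of a full internal-standard sequence.

    Anchors (336F prefix, ITS3 site, rc-ITS4 site, degenerate rc-806R suffix)
    are located by IUPAC-aware exact matching; everything between anchors is
    classified as spacer/stuffer.
    """
    seq = normalize_sequence(sequence)
    p336 = FIXED_ROLES["fwd_universal_bact"]
    its3 = FIXED_ROLES["fwd_universal_fungal_site"]
    rc_its4 = FIXED_ROLES["rc_rev_universal_fungal_site"]
    rc_806 = FIXED_ROLES["rc_rev_universal_bact"]
    if not seq.startswith(p336):
        raise AssemblyError(f"{id}: sequence does not start with 336F")
    if not iupac_match(rc_806, seq[-len(rc_806):]):
        raise AssemblyError(f"{id}: suffix does not match reverse complement of 806R")
    i3 = seq.find(its3)
    i4 = seq.find(rc_its4)
    if i3 < 0 or i4 < 0 or not (len(p336) <= i3 < i4):
        raise AssemblyError(f"{id}: fungal anchor sites missing or out of order")
    layout = default_layout(
        spacer_len=i3 - len(p336),
        its2_stuffer_len=i4 - (i3 + len(its3)),
        tail_stuffer_len=(len(seq) - len(rc_806)) - (i4 + len(rc_its4)),
    )
    return InternalStandard(id=id, sequence=seq, layout=layout,
                            coordinates=layout.coordinates())


def load_reference_standards() -> list[InternalStandard]:
    """The five shipped 472-bp reference standards (IS1..IS5)."""
    from Bio import SeqIO

    path = resources.files("gisaq.data") / "internal_standards.fasta"
    with path.open() as handle:
        records = list(SeqIO.parse(handle, "fasta"))
    return [detect_layout(str(r.seq), id=r.id) for r in records]


# --------------------------------------------------------------------------
# Specific primer design
# --------------------------------------------------------------------------

def _primer_ok(primer: str, criteria: PrimerCriteria) -> bool:
    if not criteria.gc_window[0] <= gc_fraction(primer) <= criteria.gc_window[1]:
        return False
    if max_homopolymer_run(primer) > criteria.max_homopolymer:
        return False
    if longest_self_complement(primer) > criteria.max_self_complement:
        return False
    tm = melting_temperature(primer)
    return criteria.tm_window[0] <= tm <= criteria.tm_window[1]


def _occurs_either_strand(primer: str, seq: str) -> bool:
    return primer in seq or reverse_complement(primer) in seq


def design_specific_primers(iss: InternalStandard,
                            criteria: PrimerCriteria | None = None,
                            other_standards: Iterable[InternalStandard] = (),
                            background: Iterable[str] = (),
                            rng_seed: int = 0,
                            amplicon_range: tuple[int, int] = (80, 400),
                            max_tries: int = 5000) -> PrimerPair:
    """Design a specific primer pair unique to one standard.

    Both primers are drawn from the standard's interior (between the
    universal anchors), satisfy the composition criteria, and have no exact
    occurrence (either strand) in any sibling standard or background
    sequence. The reverse primer is the reverse complement of a downstream
    window, so the pair amplifies a product of ``amplicon_range`` length.
    """
    criteria = criteria or PrimerCriteria()
    first = len(FIXED_ROLES["fwd_universal_bact"])
    last = iss.length - len(FIXED_ROLES["rc_rev_universal_bact"])
    interior = iss.sequence[first:last]
    min_len, max_len = criteria.length_range
    if len(interior) < max(amplicon_range[0], 2 * min_len):
        raise DesignError(f"{iss.id}: interior too short to host a primer pair")
    others = [o.sequence for o in other_standards if o.id != iss.id]
    others += [normalize_sequence(b) for b in background]
    rng = np.random.default_rng(rng_seed)
    for _ in range(max_tries):
        lf = int(rng.integers(min_len, max_len + 1))
        lr = int(rng.integers(min_len, max_len + 1))
        amp = int(rng.integers(amplicon_range[0], amplicon_range[1] + 1))
        if amp < lf + lr:
            continue
        start_max = len(interior) - amp
        if start_max < 0:
            continue
        i = int(rng.integers(0, start_max + 1))
        fwd = interior[i : i + lf]
        rev_site = interior[i + amp - lr : i + amp]
        rev = reverse_complement(rev_site)
        if not (_primer_ok(fwd, criteria) and _primer_ok(rev, criteria)):
            continue
        if abs(melting_temperature(fwd) - melting_temperature(rev)) > 5.0:
            continue
        if any(_occurs_either_strand(fwd, o) or _occurs_either_strand(rev, o)
               for o in others):
            continue
        return PrimerPair(name=f"{iss.id}-specific", forward=fwd, reverse=rev,
                          tm_forward=melting_temperature(fwd),
                          tm_reverse=melting_temperature(rev), role="specific")
    raise DesignError(
        f"{iss.id}: no specific pair found in {max_tries} tries; consider "
        "widening tm_window/gc_window or the amplicon range"
    )


def cross_amplification_matrix(standards: Sequence[InternalStandard]) -> np.ndarray:
    """In-silico PCR cross-check: entry (i, j) is True if primers of standard
    i find both their sites, correctly oriented, in standard j."""
    n = len(standards)
    out = np.zeros((n, n), dtype=bool)
    for i, si in enumerate(standards):
        if si.specific_primers is None:
            raise DesignError(f"{si.id} has no specific primers")
        fwd = si.specific_primers.forward
        rev_site = reverse_complement(si.specific_primers.reverse)
        for j, sj in enumerate(standards):
            for template in (sj.sequence, reverse_complement(sj.sequence)):
                pf = template.find(fwd)
                if pf >= 0 and template.find(rev_site, pf + len(fwd)) >= 0:
                    out[i, j] = True
                    break
    return out


# --------------------------------------------------------------------------
# Validation
# --------------------------------------------------------------------------

@dataclass
class RuleResult:
    rule: str
    target: str
    passed: bool
    observed: float
    bound: str


@dataclass
class ValidationReport:
    standard_id: str
    results: list[RuleResult] = field(default_factory=list)

    @property
    def passed(self) -> bool:
        return all(r.passed for r in self.results)

    def to_rows(self) -> list[dict]:
        return [
            {"standard": self.standard_id, "rule": r.rule, "target": r.target,
             "passed": r.passed, "observed": r.observed, "bound": r.bound}
            for r in self.results
        ]


def validate_internal_standard(iss: InternalStandard,
                               constraints: DesignConstraints | None = None,
                               criteria: PrimerCriteria | None = None,
                               ) -> ValidationReport:
    """Check a standard against the design rules.

    Composition constraints (GC window, homopolymer, repeat, self-complement)
    apply to stuffer segments only — the fixed universal-primer scaffold
    necessarily contains conserved sites. Full-sequence checks are limited to
    the homopolymer bound and anchor presence/order. If ``criteria`` is given
    and specific primers are attached, they are checked too.
    """
    report = ValidationReport(standard_id=iss.id)

    def add(rule: str, target: str, passed: bool, observed: float, bound: str) -> None:
        report.results.append(RuleResult(rule, target, bool(passed), observed, bound))

    cons = constraints
    variable = [(i, seg) for i, seg in enumerate(iss.layout.segments)
                if seg.role in VARIABLE_ROLES]
    for i, seg in variable:
        segment = iss.segment_sequence(i)
        label = f"{seg.role}[{i}]"
        is_stuffer = seg.role == "stuffer"
        if cons is not None and is_stuffer:
            gc = gc_fraction(segment)
            lo, hi = cons.target_gc - cons.gc_tolerance, cons.target_gc + cons.gc_tolerance
            add("gc_window", label, lo <= gc <= hi, gc, f"[{lo:.4f}, {hi:.4f}]")
        hp = max_homopolymer_run(segment)
        max_hp = cons.max_homopolymer if cons else 10
        add("homopolymer", label, hp <= max_hp, hp, f"<= {max_hp}")
        if is_stuffer and len(segment) >= 2:
            rep = longest_repeat(segment)
            max_rep = cons.max_repeat if cons else 16
            add("repeat", label, rep <= max_rep, rep, f"<= {max_rep}")
            sc = longest_self_complement(segment)
            max_sc = cons.max_self_complement if cons else 10
            add("self_complement", label, sc <= max_sc, sc, f"<= {max_sc}")

    hp_full = max_homopolymer_run(iss.sequence)
    add("homopolymer", "full", hp_full <= (cons.max_homopolymer if cons else 10),
        hp_full, f"<= {cons.max_homopolymer if cons else 10}")

    try:
        detect_layout(iss.sequence, id=iss.id)
        add("anchor_sites", "full", True, 1.0, "336F..ITS3..rcITS4..rc806R")
    except AssemblyError:
        add("anchor_sites", "full", False, 0.0, "336F..ITS3..rcITS4..rc806R")

    if criteria is not None and iss.specific_primers is not None:
        for which, primer in (("forward", iss.specific_primers.forward),
                              ("reverse", iss.specific_primers.reverse)):
            add("primer_criteria", which, _primer_ok(primer, criteria),
                len(primer), "composition+Tm")
    return report
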