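"""In-silico restriction-fragment-length-polymorphism (RFLP) genotyping.

Amplicons of the ITS rDNA region are digested in silico with BstNI, which
cuts at CC/WGG (W = A or T). Type I amplicons carry the recognition site
and produce a multi-band pattern (typically ~400 + ~600 bp, sometimes a
third band from length polymorphism between ITS copies); Type II amplicons
are not cut. The genotype call mimics reading the band pattern off an
agarose gel.
"""

from __future__ import annotations

from dataclasses import dataclass, field

IUPAC_SETS: dict[str, frozenset[str]] = {
    "A": frozenset("A"), "C": frozenset("C"), "G": frozenset("G"), "T": frozenset("T"),
    "R": frozenset("AG"), "Y": frozenset("CT"), "S": frozenset("CG"),
    "W": frozenset("AT"), "K": frozenset("GT"), "M": frozenset("AC"),
    "B": frozenset("CGT"), "D": frozenset("AGT"), "H": frozenset("ACT"),
    "V": frozenset("ACG"), "N": frozenset("ACGT"),
}

_COMPLEMENT = str.maketrans("ACGTRYSWKMBDHVN-", "TGCAYRSWMKVHDBN-")


class RflpError(ValueError):
    """Raised on invalid digest input."""


@dataclass(frozen=True)
class RestrictionEnzyme:
    """A restriction endonuclease as an IUPAC recognition motif plus the
    cut offset (bases from the motif start on the top strand)."""

    name: str
    recognition: str
    cut_offset: int

    def __post_init__(self) -> None:
        if len(self.recognition) < 1:
            raise RflpError("empty recognition motif")
        if not 0 <= self.cut_offset <= len(self.recognition):
            raise RflpError("cut offset outside the motif")
        for c in self.recognition:
            if c not in IUPAC_SETS:
                raise RflpError(f"non-IUPAC motif character {c!r}")


#: BstNI cuts at CC/WGG — between the CC and the WGG.
BSTNI = RestrictionEnzyme("BstNI", "CCWGG", 2)

ENZYMES = {"BstNI": BSTNI}


def reverse_complement(seq: str) -> str:
    return seq.upper().translate(_COMPLEMENT)[::-1]


def _site_matches(seq: str, pos: int, motif: str) -> bool:
    # A site matches when every sequence symbol is compatible with
    # (a subset of) the motif symbol, i.e. the cut is guaranteed for
    # any disambiguation of the sequence.
    for k, m in enumerate(motif):
        s = seq[pos + k]
        if s not in IUPAC_SETS:
            raise RflpError(f"invalid sequence character {s!r} at {pos + k}")
        if not IUPAC_SETS[s] <= IUPAC_SETS[m]:
            return False
    return True


def find_sites(seq: str, enzyme: RestrictionEnzyme = BSTNI) -> list[int]:
    """0-based motif start positions of all (possibly overlapping) sites."""
    seq = seq.upper().replace("U", "T")
    if "-" in seq:
        raise RflpError("gapped sequence: digest an ungapped amplicon")
    m = len(enzyme.recognition)
    return [p for p in range(len(seq) - m + 1) if _site_matches(seq, p, enzyme.recognition)]


@dataclass
class DigestResult:
    """Cut coordinates and resulting fragment lengths of a linear amplicon."""

    amplicon_length: int
    cut_positions: list[int]
    fragment_lengths: list[int] = field(init=False)

    def __post_init__(self) -> None:
        cuts = sorted(set(self.cut_positions))
        # cuts at the very ends produce no extra fragment
        cuts = [c for c in cuts if 0 < c < self.amplicon_length]
        self.cut_positions = cuts
        bounds = [0] + cuts + [self.amplicon_length]
        frags = [b - a for a, b in zip(bounds, bounds[1:])]
        self.fragment_lengths = sorted(frags, reverse=True)

    @property
    def n_fragments(self) -> int:
        return len(self.fragment_lengths)


def digest(seq: str, enzyme: RestrictionEnzyme = BSTNI) -> DigestResult:
    """Digest a linear amplicon; with no site, one full-length fragment."""
    seq = seq.upper().replace("U", "T")
    sites = find_sites(seq, enzyme)
    cuts = [p + enzyme.cut_offset for p in sites]
    return DigestResult(len(seq), cuts)


@dataclass(frozen=True)
class GenotypeCall:
    """RFLP (or sequence-cluster) genotype assignment with its evidence."""

    call: str  # "TypeI" | "TypeII" | "ambiguous"
    method: str = "RFLP"
    evidence: str = ""


def call_genotype(
    result: DigestResult,
    amplicon_length: int | None = None,
    strict: bool = False,
    band_tolerance: int = 100,
) -> GenotypeCall:
    """Assign a genotype from a digest band pattern.

    Lenient rule (default): two or more fragments mean the site is present
    (Type I); a single fragment spanning the whole amplicon means uncut
    (Type II). The strict rule additionally requires the two largest
    fragments to sit within ``band_tolerance`` bp of the canonical 400 and
    600 bp bands, otherwise the call is ambiguous.
    """
    if result.n_fragments == 0:
        raise RflpError("empty digest")
    if amplicon_length is None:
        amplicon_length = result.amplicon_length
    nb = result.n_fragments
    if nb == 1:
        if result.fragment_lengths[0] == amplicon_length:
            return GenotypeCall("TypeII", "RFLP", f"bands={nb}")
        return GenotypeCall("ambiguous", "RFLP", f"bands={nb};truncated")
    if strict:
        two = sorted(result.fragment_lengths, reverse=True)[:2]
        hi, lo = two[0], two[1]
        if abs(hi - 600) <= band_tolerance and abs(lo - 400) <= band_tolerance:
            return GenotypeCall("TypeI", "RFLP", f"bands={nb}")
        return GenotypeCall("ambiguous", "RFLP", f"bands={nb};off-size")
    return GenotypeCall("TypeI", "RFLP", f"bands={nb}")


@dataclass(frozen=True)
class GelBand:
    """A band on the gel: mean length of co-migrating fragments and the
    number of fragments it contains."""

    length: float
    weight: int


def gel_bands(result: DigestResult, resolution_bp: float = 0.0) -> list[GelBand]:
    """Merge fragments that co-migrate within the gel resolution.

    Fragments are single-linkage clustered: consecutive sorted lengths
    closer than ``resolution_bp`` fall in one band. Resolution 0 keeps
    every distinct length as its own band. Bands are returned largest
    first.
    """
    if resolution_bp < 0:
        raise RflpError("resolution must be >= 0")
    lengths = sorted(result.fragment_lengths, reverse=True)
    bands: list[list[int]] = []
    for L in lengths:
        if bands and (bands[-1][-1] - L) <= resolution_bp and (
            resolution_bp > 0 or bands[-1][-1] == L
        ):
            bands[-1].append(L)
        else:
            bands.append([L])
    return [GelBand(sum(b) / len(b), len(b)) for b in bands]
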