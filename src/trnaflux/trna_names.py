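"""Parsing of GtRNAdb-style tRNA isodecoder names and anticodon decoding.

GtRNAdb names identify a tRNA gene as
``tRNA-<AminoAcid>-<Anticodon>-<family>-<copy>`` (the copy index may be
absent for a family-level name such as ``tRNA-Ala-AGC-3``).  The anticodon
is read 5'->3'; its reverse complement is the cognate codon, and wobble
pairing at anticodon position 34 lets one isodecoder read additional
synonymous codons (e.g. anticodon AGC reads GCR = GCT/GCC/GCA).
"""

from __future__ import annotations

from dataclasses import dataclass

__all__ = [
    "IsodecoderID",
    "CodonSet",
    "TrnaNameError",
    "parse_trna_name",
    "format_trna_name",
    "cognate_codon",
    "degenerate_codons",
]

#: Three-letter codes of the 20 standard residues.
STANDARD_AMINO_ACIDS = frozenset(
    "Ala Arg Asn Asp Cys Gln Glu Gly His Ile Leu Lys Met Phe Pro Ser Thr Trp Tyr Val".split()
)

#: Dialect tokens GtRNAdb uses for nonstandard decoders; rejected unless
#: explicitly allowed.
NONSTANDARD_TOKENS = frozenset({"SeC", "iMet", "Sup", "Und"})

_COMPLEMENT = str.maketrans("ACGT", "TGCA")

_CODON_TABLE = {
    "TTT": "Phe", "TTC": "Phe", "TTA": "Leu", "TTG": "Leu",
    "CTT": "Leu", "CTC": "Leu", "CTA": "Leu", "CTG": "Leu",
    "ATT": "Ile", "ATC": "Ile", "ATA": "Ile", "ATG": "Met",
    "GTT": "Val", "GTC": "Val", "GTA": "Val", "GTG": "Val",
    "TCT": "Ser", "TCC": "Ser", "TCA": "Ser", "TCG": "Ser",
    "CCT": "Pro", "CCC": "Pro", "CCA": "Pro", "CCG": "Pro",
    "ACT": "Thr", "ACC": "Thr", "ACA": "Thr", "ACG": "Thr",
    "GCT": "Ala", "GCC": "Ala", "GCA": "Ala", "GCG": "Ala",
    "TAT": "Tyr", "TAC": "Tyr", "TAA": "*", "TAG": "*",
    "CAT": "His", "CAC": "His", "CAA": "Gln", "CAG": "Gln",
    "AAT": "Asn", "AAC": "Asn", "AAA": "Lys", "AAG": "Lys",
    "GAT": "Asp", "GAC": "Asp", "GAA": "Glu", "GAG": "Glu",
    "TGT": "Cys", "TGC": "Cys", "TGA": "*", "TGG": "Trp",
    "CGT": "Arg", "CGC": "Arg", "CGA": "Arg", "CGG": "Arg",
    "AGT": "Ser", "AGC": "Ser", "AGA": "Arg", "AGG": "Arg",
    "GGT": "Gly", "GGC": "Gly", "GGA": "Gly", "GGG": "Gly",
}

#: Wobble acceptance at anticodon position 34 (the 5' base, pairing with the
#: codon third position): which codon third-position bases the base can read.
#: The expansion is intersected with the cognate amino acid's synonymous
#: codon set, so degeneracy never crosses amino-acid identity.
WOBBLE_34 = {
    "A": frozenset("TCA"),
    "G": frozenset("CT"),
    "T": frozenset("AG"),
    "C": frozenset("G"),
}


class TrnaNameError(ValueError):
    """Structured parse/decode error naming the offending token."""

    def __init__(self, message: str, token: str | None = None):
        super().__init__(message)
        self.token = token


@dataclass(frozen=True)
class IsodecoderID:
    """A parsed GtRNAdb-style tRNA gene name."""

    raw_name: str
    amino_acid: str
    anticodon: str
    family_index: int
    copy_index: int | None = None

    def format(self) -> str:
        """Reassemble the canonical name (round-trips with the parser)."""
        parts = ["tRNA", self.amino_acid, self.anticodon, str(self.family_index)]
        if self.copy_index is not None:
            parts.append(str(self.copy_index))
        return "-".join(parts)


@dataclass(frozen=True)
class CodonSet:
    """Cognate codon plus the wobble-expanded synonymous codons it implies."""

    cognate_codon: str
    degenerate_codons: frozenset[str]
    amino_acid: str

    def __post_init__(self):
        if self.cognate_codon not in self.degenerate_codons:
            raise ValueError("cognate codon must be a member of the degenerate set")


def _canonical_nucleotides(seq: str, *, what: str) -> str:
    """Uppercase and map U->T; reject anything outside {A,C,G,T}."""
    canon = seq.strip().upper().replace("U", "T")
    bad = set(canon) - set("ACGT")
    if bad:
        raise TrnaNameError(
            f"{what} {seq!r} contains non-ACGT characters: {sorted(bad)}", token=seq
        )
    return canon


def parse_trna_name(name: str, *, allow_nonstandard: bool = False) -> IsodecoderID:
    """Parse ``tRNA-Ala-AGC-10-1`` style names.

    Parameters
    ----------
    name
        GtRNAdb-style gene name. A trailing copy index is optional
        (``tRNA-Ala-AGC-3`` parses with ``copy_index=None``).
    allow_nonstandard
        Accept the SeC/iMet/Sup/Und dialect tokens in the amino-acid slot.

    Raises
    ------
    TrnaNameError
        On the wrong token count, an unknown amino acid, a non-3-mer or
        non-ACGT anticodon, or a non-positive index; the error carries the
        offending token.
    """
    if not name or not name.strip():
        raise TrnaNameError("empty tRNA name")
    raw = name.strip()
    tokens = raw.split("-")
    if tokens[0] != "tRNA":
        raise TrnaNameError(f"name must start with 'tRNA': {raw!r}", token=tokens[0])
    if len(tokens) not in (4, 5):
        raise TrnaNameError(
            f"expected 4 or 5 '-'-separated tokens, got {len(tokens)}: {raw!r}",
            token=raw,
        )
    aa = tokens[1]
    if aa not in STANDARD_AMINO_ACIDS:
        if aa in NONSTANDARD_TOKENS:
            if not allow_nonstandard:
                raise TrnaNameError(
                    f"nonstandard decoder token {aa!r} rejected "
                    "(pass allow_nonstandard=True to accept)",
                    token=aa,
                )
        else:
            raise TrnaNameError(f"unknown amino-acid token {aa!r}", token=aa)
    anticodon = tokens[2]
    if len(anticodon) != 3:
        raise TrnaNameError(f"anticodon must be a 3-mer: {anticodon!r}", token=anticodon)
    anticodon = _canonical_nucleotides(anticodon, what="anticodon")

    def _index(tok: str, slot: str) -> int:
        try:
            value = int(tok)
        except ValueError:
            raise TrnaNameError(f"{slot} index not an integer: {tok!r}", token=tok) from None
        if value <= 0:
            raise TrnaNameError(f"{slot} index must be positive: {tok!r}", token=tok)
        return value

    family = _index(tokens[3], "family")
    copy = _index(tokens[4], "copy") if len(tokens) == 5 else None
    return IsodecoderID(
        raw_name=raw,
        amino_acid=aa,
        anticodon=anticodon,
        family_index=family,
        copy_index=copy,
    )


def format_trna_name(iso: IsodecoderID) -> str:
    return iso.format()


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def cognate_codon(anticodon: str) -> str:
    """The codon read by Watson-Crick pairing: the anticodon's reverse
    complement, both read 5'->3' (anticodon AGC -> codon GCT)."""
    anticodon = _canonical_nucleotides(anticodon, what="anticodon")
    if len(anticodon) != 3:
        raise TrnaNameError(f"anticodon must be a 3-mer: {anticodon!r}", token=anticodon)
    return reverse_complement(anticodon)


def translate_codon(codon: str) -> str:
    """Three-letter residue for a DNA codon under the standard code ('*' for stop)."""
    codon = _canonical_nucleotides(codon, what="codon")
    if len(codon) != 3:
        raise TrnaNameError(f"codon must be a 3-mer: {codon!r}", token=codon)
    return _CODON_TABLE[codon]


def synonymous_codons(amino_acid: str) -> frozenset[str]:
    """All codons coding `amino_acid` (three-letter code) in the standard code."""
    out = frozenset(c for c, aa in _CODON_TABLE.items() if aa == amino_acid)
    if not out:
        raise TrnaNameError(f"unknown amino acid {amino_acid!r}", token=amino_acid)
    return out


def degenerate_codons(anticodon: str) -> CodonSet:
    """Cognate codon plus position-34 wobble expansion, restricted to
    synonymous codons.

    Wobble rules (anticodon 5' base vs codon third position): A34 reads
    T/C/A, G34 reads C/T, T34 reads A/G, C34 reads G only.  The expansion
    is intersected with the cognate amino acid's synonymous codon set so
    the returned set always translates to a single residue (AGC -> GCR =
    {GCT, GCC, GCA}).
    """
    anticodon = _canonical_nucleotides(anticodon, what="anticodon")
    cognate = cognate_codon(anticodon)
    aa = _CODON_TABLE[cognate]
    if aa == "*":
        raise TrnaNameError(
            f"anticodon {anticodon!r} pairs with stop codon {cognate!r}; "
            "no amino-acid decoding is defined",
            token=anticodon,
        )
    wobble_base = anticodon[0]
    third_positions = WOBBLE_34[wobble_base]
    expanded = {cognate[:2] + third for third in third_positions}
    expanded.add(cognate)
    synonymous = synonymous_codons(aa)
    members = frozenset(expanded & synonymous)
    # Every member must translate identically; unreachable for the standard
    # code after the intersection, kept as an internal consistency check.
    if any(_CODON_TABLE[c] != aa for c in members):
        raise TrnaNameError(
            f"wobble expansion of {anticodon!r} crosses amino-acid identity"
        )
    return CodonSet(cognate_codon=cognate, degenerate_codons=members, amino_acid=aa)
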