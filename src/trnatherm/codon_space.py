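"""Genetic-code and codon–anticodon pairing engine.

Enumerates, for any codon and anticodon set, the cognate, pseudo-cognate and
near-cognate decoders under configurable bacterial wobble rules.  Anticodons
are written 5'→3', so the first character is position 34 (the wobble
position), which pairs antiparallel with the codon's third base.  All
sequences use the RNA alphabet internally; ``T`` is accepted on input and
mapped to ``U``.
"""

from __future__ import annotations

import enum
import itertools
from dataclasses import dataclass, field
from importlib import resources
from typing import Dict, Mapping, Set, Tuple

RNA_BASES = "ACGU"
_COMPLEMENT = {"A": "U", "U": "A", "G": "C", "C": "G"}

ALL_CODONS: Tuple[str, ...] = tuple(
    "".join(p) for p in itertools.product(RNA_BASES, repeat=3)
)
STOP_CODONS = frozenset({"UAA", "UAG", "UGA"})


class InvalidSequenceError(ValueError):
    """Raised for triplets outside the {A,C,G,U} 3-letter space."""


def normalize_rna(seq: str) -> str:
    """Uppercase a sequence and map DNA ``T`` to RNA ``U``."""
    return str(seq).strip().upper().replace("T", "U")


def _check_triplet(seq: str, kind: str) -> str:
    seq = normalize_rna(seq)
    if len(seq) != 3 or any(b not in RNA_BASES for b in seq):
        raise InvalidSequenceError(
            f"invalid {kind} {seq!r}: expected 3 letters over A/C/G/U (T accepted)"
        )
    return seq


def wc_decode(anticodon: str) -> str:
    """Watson–Crick decoded codon of an anticodon: the reverse complement.

    Involutive with :func:`anticodon_of`.
    """
    anticodon = _check_triplet(anticodon, "anticodon")
    return "".join(_COMPLEMENT[b] for b in reversed(anticodon))


def anticodon_of(codon: str) -> str:
    """The anticodon whose Watson–Crick decoded codon is ``codon``."""
    codon = _check_triplet(codon, "codon")
    return "".join(_COMPLEMENT[b] for b in reversed(codon))


# ---------------------------------------------------------------------------
# Genetic code


class GeneticCode:
    """Codon → amino-acid map (NCBI translation table 11 by default)."""

    def __init__(self, table: Mapping[str, str]):
        table = {_check_triplet(c, "codon"): aa for c, aa in table.items()}
        if set(table) != set(ALL_CODONS):
            missing = set(ALL_CODONS) - set(table)
            raise ValueError(f"genetic code must cover all 64 codons; missing {sorted(missing)}")
        self._table = table
        self.stop_codons = frozenset(c for c, aa in table.items() if aa == "*")
        self.sense_codons: Tuple[str, ...] = tuple(
            c for c in ALL_CODONS if table[c] != "*"
        )
        if len(self.stop_codons) != 3:
            raise ValueError("expected exactly 3 stop codons")

    @classmethod
    def bacterial(cls) -> "GeneticCode":
        """Load the bundled bacterial code (translation table 11)."""
        text = (
            resources.files("trnatherm.data")
            .joinpath("genetic_code_table11.tsv")
            .read_text()
        )
        table = {}
        for line in text.splitlines():
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            codon, aa = line.split("\t")
            table[codon] = aa
        return cls(table)

    def translate(self, codon: str) -> str:
        return self._table[_check_triplet(codon, "codon")]

    def is_stop(self, codon: str) -> bool:
        return self.translate(codon) == "*"

    def is_sense(self, codon: str) -> bool:
        return not self.is_stop(codon)

    def __len__(self) -> int:
        return len(self._table)


# Anticodons whose WC codon is a sense codon (61 of the 64).
def sense_decoding_anticodons(code: GeneticCode | None = None) -> Tuple[str, ...]:
    code = code or GeneticCode.bacterial()
    return tuple(anticodon_of(c) for c in code.sense_codons)


# ---------------------------------------------------------------------------
# Wobble rules


@dataclass(frozen=True)
class WobbleRuleTable:
    """Which codon third bases an anticodon-34 base can pair with.

    ``rules[base34]`` maps each recognized codon-3 base to an efficiency
    weight in (0, 1]; the Watson–Crick partner is always present with weight
    1.0.  The weights annotate pairing strength for downstream kinetic use —
    classification treats any positive weight as "recognized".
    """

    rules: Mapping[str, Mapping[str, float]]

    def __post_init__(self) -> None:
        wc34 = {"G": "C", "C": "G", "A": "U", "U": "A"}
        for b34 in RNA_BASES:
            partners = self.rules.get(b34)
            if not partners:
                raise ValueError(f"anticodon-34 base {b34} recognizes nothing")
            if partners.get(wc34[b34]) != 1.0:
                raise ValueError(
                    f"{b34} at position 34 must pair its Watson–Crick partner "
                    f"{wc34[b34]} with weight 1.0"
                )
            for b3, w in partners.items():
                if b3 not in RNA_BASES or not (0.0 < w <= 1.0):
                    raise ValueError(f"bad pairing {b34}:{b3} weight {w}")

    @classmethod
    def bacterial_default(
        cls, wobble_weight: float = 1.0, a34_as_inosine: bool = False
    ) -> "WobbleRuleTable":
        """Crick wobble for bacteria: G34 reads C and U, U34 reads A and G,
        C34 and A34 read only their Watson–Crick partners.

        With ``a34_as_inosine`` the A34 row behaves as inosine (I34) and
        additionally reads C and A.  Off by default: ANN anticodons are rare
        in bacterial pools precisely because unmodified A34 pairs poorly.
        """
        w = float(wobble_weight)
        rules: Dict[str, Dict[str, float]] = {
            "G": {"C": 1.0, "U": w},
            "U": {"A": 1.0, "G": w},
            "C": {"G": 1.0},
            "A": {"U": 1.0},
        }
        if a34_as_inosine:
            rules["A"] = {"U": 1.0, "C": w, "A": w}
        return cls(rules)

    @classmethod
    def wc_only(cls) -> "WobbleRuleTable":
        """Strict Watson–Crick table (no wobble); useful as a null model."""
        return cls({"G": {"C": 1.0}, "C": {"G": 1.0}, "A": {"U": 1.0}, "U": {"A": 1.0}})

    def recognized_third_bases(self, base34: str) -> Set[str]:
        return set(self.rules[base34])

    def pairing_weight(self, base34: str, codon3: str) -> float:
        return float(self.rules[base34].get(codon3, 0.0))


def recognized_codons(anticodon: str, rules: WobbleRuleTable) -> Set[str]:
    """All codons an anticodon reads: Watson–Crick at codon positions 1–2,
    rule-table pairing at position 3.  Always contains ``wc_decode(anticodon)``.
    """
    anticodon = _check_triplet(anticodon, "anticodon")
    stem = wc_decode(anticodon)[:2]  # codon positions 1-2, fixed by WC pairing
    return {stem + b3 for b3 in rules.recognized_third_bases(anticodon[0])}


# ---------------------------------------------------------------------------
# Pairing classification


class PairingClass(enum.Enum):
    """Relationship of an anticodon to a focal sense codon.

    The five classes partition the (codon, anticodon) space: a pair falls in
    exactly one.
    """

    COGNATE_WC = "cognate_wc"
    COGNATE_WOBBLE = "cognate_wobble"
    PSEUDO_COGNATE = "pseudo_cognate"
    NEAR_COGNATE = "near_cognate"
    NON_COGNATE = "non_cognate"


COGNATE_CLASSES = (PairingClass.COGNATE_WC, PairingClass.COGNATE_WOBBLE)


def classify_pair(
    codon: str,
    anticodon: str,
    code: GeneticCode,
    rules: WobbleRuleTable,
) -> PairingClass:
    """Classify an anticodon relative to a focal sense codon.

    Cognate: reads the codon Watson–Crick or through the wobble table.
    Pseudo-cognate: not cognate, but its WC codon encodes the same amino
    acid.  Near-cognate: not cognate/pseudo, WC codon one mismatch away and
    encoding a different amino acid.  Everything else is non-cognate.
    """
    codon = _check_triplet(codon, "codon")
    anticodon = _check_triplet(anticodon, "anticodon")
    if code.is_stop(codon):
        raise ValueError(f"focal codon {codon} is a stop codon; the model covers sense codons")

    wc = wc_decode(anticodon)
    if wc == codon:
        return PairingClass.COGNATE_WC
    if codon in recognized_codons(anticodon, rules):
        return PairingClass.COGNATE_WOBBLE
    if code.is_sense(wc) and code.translate(wc) == code.translate(codon):
        return PairingClass.PSEUDO_COGNATE
    mismatches = sum(a != b for a, b in zip(wc, codon))
    if mismatches == 1:
        # one WC mismatch, wrong amino acid (or a stop-decoding anticodon)
        return PairingClass.NEAR_COGNATE
    return PairingClass.NON_COGNATE


_CLASSIFICATION_CACHE: Dict[tuple, Dict[Tuple[str, str], PairingClass]] = {}


def classification_table(
    code: GeneticCode, rules: WobbleRuleTable
) -> Dict[Tuple[str, str], PairingClass]:
    """Memoized classification of all 61 × 64 (sense codon, anticodon) pairs.

    Whole-dataset rate computation is classification-bound; the table makes
    it a dictionary lookup.
    """
    key = (
        tuple(code.translate(c) for c in ALL_CODONS),
        tuple(sorted((b, tuple(sorted(p.items()))) for b, p in rules.rules.items())),
    )
    table = _CLASSIFICATION_CACHE.get(key)
    if table is None:
        table = {
            (codon, anticodon): classify_pair(codon, anticodon, code, rules)
            for codon in code.sense_codons
            for anticodon in ALL_CODONS
        }
        _CLASSIFICATION_CACHE[key] = table
    return table


@dataclass
class DecoderPartition:
    """Anticodons of a pool split by pairing class for one focal codon,
    carrying their tRNA gene copy numbers."""

    codon: str
    cognates: Dict[str, int] = field(default_factory=dict)
    pseudo_cognates: Dict[str, int] = field(default_factory=dict)
    near_cognates: Dict[str, int] = field(default_factory=dict)
    cognate_classes: Dict[str, PairingClass] = field(default_factory=dict)


def partition_decoders(
    codon: str,
    pool: Mapping[str, int],
    code: GeneticCode,
    rules: WobbleRuleTable,
) -> DecoderPartition:
    """Split a pool's anticodons into cognate / pseudo-cognate / near-cognate
    multisets for one focal codon.  Zero-count anticodons are skipped;
    non-cognate anticodons are dropped.
    """
    counts = getattr(pool, "counts", pool)
    if not any(n > 0 for n in counts.values()):
        raise ValueError("empty anticodon pool: no anticodon with positive copy number")
    out = DecoderPartition(codon=_check_triplet(codon, "codon"))
    for anticodon, n in counts.items():
        if n <= 0:
            continue
        anticodon = _check_triplet(anticodon, "anticodon")
        cls = classify_pair(codon, anticodon, code, rules)
        if cls in COGNATE_CLASSES:
            out.cognates[anticodon] = out.cognates.get(anticodon, 0) + int(n)
            out.cognate_classes[anticodon] = cls
        elif cls is PairingClass.PSEUDO_COGNATE:
            out.pseudo_cognates[anticodon] = out.pseudo_cognates.get(anticodon, 0) + int(n)
        elif cls is PairingClass.NEAR_COGNATE:
            out.near_cognates[anticodon] = out.near_cognates.get(anticodon, 0) + int(n)
    return out
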