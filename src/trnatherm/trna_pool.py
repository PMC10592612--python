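"""tRNA gene copy number (tGCN) tables and species-level pool statistics.

A species' tRNA pool is summarized by its tGCN: how many genomic tRNA genes
carry each anticodon.  From it we compute anticodon *diversity* (distinct
anticodons present, max 61 for sense-decoding anticodons), total gene count,
and the split between anticodons that Watson–Crick-read GC-ending versus
AT-ending codons.  Species are classed as psychrophile / mesophile /
thermophile by optimal growth temperature (OGT) with cut-offs at 15 °C and
45 °C.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence

import pandas as pd

from .codon_space import (
    ALL_CODONS,
    _check_triplet,
    normalize_rna,
    sense_decoding_anticodons,
    wc_decode,
)

logger = logging.getLogger(__name__)

PSYCHROPHILE = "psychrophile"
MESOPHILE = "mesophile"
THERMOPHILE = "thermophile"
TEMP_CLASSES = (PSYCHROPHILE, MESOPHILE, THERMOPHILE)

#: OGT cut-offs (°C): psychrophiles grow best below the lower bound,
#: thermophiles above the upper; boundary values fall to mesophile.
PSYCHRO_MAX_C = 15.0
THERMO_MIN_C = 45.0


def classify_temperature(ogt_celsius: float) -> str:
    """Temperature class from optimal growth temperature in °C."""
    ogt = float(ogt_celsius)
    if not math.isfinite(ogt):
        raise ValueError(f"non-finite optimal growth temperature: {ogt_celsius!r}")
    if ogt < PSYCHRO_MAX_C:
        return PSYCHROPHILE
    if ogt > THERMO_MIN_C:
        return THERMOPHILE
    return MESOPHILE


@dataclass
class AnticodonPool:
    """Per-species anticodon copy numbers (tGCN)."""

    species_id: str
    counts: Dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        cleaned: Dict[str, int] = {}
        for anticodon, n in self.counts.items():
            ac = _check_triplet(anticodon, "anticodon")
            n = int(n)
            if n < 0:
                raise ValueError(
                    f"species {self.species_id}: negative tGCN {n} for anticodon {ac}"
                )
            if ac in cleaned:
                raise ValueError(f"species {self.species_id}: duplicate anticodon {ac}")
            cleaned[ac] = n
        if not any(n > 0 for n in cleaned.values()):
            raise ValueError(f"species {self.species_id}: no anticodon with positive count")
        self.counts = cleaned

    def present(self) -> List[str]:
        return [a for a, n in self.counts.items() if n > 0]


@dataclass
class SpeciesMeta:
    """Growth-temperature and GC metadata for one species."""

    species_id: str
    ogt: float
    gc: float
    temp_class: str = ""

    def __post_init__(self) -> None:
        self.ogt = float(self.ogt)
        self.gc = float(self.gc)
        if self.gc > 1.0:
            # databases report GC as a percentage at least as often as a fraction
            logger.info("species %s: GC %.3f > 1 treated as %% and divided by 100",
                        self.species_id, self.gc)
            self.gc /= 100.0
        if not 0.0 <= self.gc <= 1.0:
            raise ValueError(f"species {self.species_id}: GC fraction {self.gc} outside [0, 1]")
        derived = classify_temperature(self.ogt)
        if self.temp_class and self.temp_class != derived:
            raise ValueError(
                f"species {self.species_id}: temp_class {self.temp_class!r} "
                f"inconsistent with OGT {self.ogt} °C ({derived})"
            )
        self.temp_class = derived


# ---------------------------------------------------------------------------
# Statistics


def diversity(pool: AnticodonPool, strict: bool = True) -> int:
    """Number of distinct anticodons with tGCN > 0.

    With ``strict`` (default) only the 61 anticodons whose Watson–Crick codon
    is a sense codon are counted, so a complete pool has diversity 61.
    """
    present = pool.present()
    if strict:
        sense = set(sense_decoding_anticodons())
        present = [a for a in present if a in sense]
    return len(present)


def total_tgcn(pool: AnticodonPool) -> int:
    """Total number of tRNA genes: the sum of copy numbers."""
    return sum(n for n in pool.counts.values() if n > 0)


def diversity_by_ending(pool: AnticodonPool, strict: bool = True) -> tuple[int, int]:
    """(gc_ending, at_ending) diversity split.

    An anticodon counts as GC-ending when its Watson–Crick decoded codon ends
    in G or C (no wobble considered), AT-ending when it ends in A or U.  The
    two components sum to :func:`diversity`.
    """
    present = pool.present()
    if strict:
        sense = set(sense_decoding_anticodons())
        present = [a for a in present if a in sense]
    gc_ending = sum(1 for a in present if wc_decode(a)[2] in "GC")
    return gc_ending, len(present) - gc_ending


# ---------------------------------------------------------------------------
# I/O

_VALID_ANTICODONS = set(ALL_CODONS)


def read_tgcn(path: str | Path) -> List[AnticodonPool]:
    """Read a tGCN table, wide or long format (autodetected).

    Wide: one row per species, first column the species id, remaining column
    headers anticodons.  Long: columns species/anticodon/count (any header
    spelling containing those words, or exactly three unnamed columns).
    ``T`` is mapped to ``U`` in anticodon labels.
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype=str)
    if df.shape[1] < 2:
        raise ValueError(f"{path}: expected a tab-separated table with ≥ 2 columns")

    header = [normalize_rna(c) for c in df.columns[1:]]
    is_wide = all(h in _VALID_ANTICODONS for h in header)
    if not is_wide and df.shape[1] == 3:
        return _read_long(df, path)
    if not is_wide:
        bad = [c for c, h in zip(df.columns[1:], header) if h not in _VALID_ANTICODONS]
        raise ValueError(
            f"{path}: malformed header — columns {bad} are not anticodons and the "
            "table is not 3-column long format"
        )

    pools: List[AnticodonPool] = []
    seen: set[str] = set()
    for row_i, row in df.iterrows():
        sp = str(row.iloc[0])
        if sp in seen:
            raise ValueError(f"{path}: duplicate species {sp!r} at row {row_i}")
        seen.add(sp)
        counts: Dict[str, int] = {}
        for col, anticodon in zip(df.columns[1:], header):
            raw = row[col]
            if pd.isna(raw) or str(raw).strip() == "":
                continue
            n = _parse_count(raw, path, sp, col)
            if n:
                counts[anticodon] = n
        try:
            pools.append(AnticodonPool(sp, counts))
        except ValueError as exc:
            raise ValueError(f"{path}: row {row_i}: {exc}") from exc
    return pools


def _read_long(df: pd.DataFrame, path: Path) -> List[AnticodonPool]:
    df = df.copy()
    df.columns = ["species", "anticodon", "count"]
    pools: Dict[str, Dict[str, int]] = {}
    for row_i, row in df.iterrows():
        sp = str(row["species"])
        ac = normalize_rna(row["anticodon"])
        if ac not in _VALID_ANTICODONS:
            raise ValueError(f"{path}: row {row_i}: unknown anticodon {row['anticodon']!r}")
        n = _parse_count(row["count"], path, sp, "count")
        bucket = pools.setdefault(sp, {})
        if ac in bucket:
            raise ValueError(f"{path}: row {row_i}: duplicate anticodon {ac} for species {sp}")
        bucket[ac] = n
    return [AnticodonPool(sp, counts) for sp, counts in pools.items()]


def _parse_count(raw, path: Path, species: str, col: str) -> int:
    try:
        n = int(str(raw).strip())
    except ValueError as exc:
        raise ValueError(
            f"{path}: species {species!r}, column {col!r}: non-integer count {raw!r}"
        ) from exc
    if n < 0:
        raise ValueError(
            f"{path}: species {species!r}, column {col!r}: negative count {n}"
        )
    return n


def write_tgcn(pools: Sequence[AnticodonPool], path: str | Path) -> None:
    """Write pools as a wide TSV (species + one column per present anticodon)."""
    anticodons = sorted({a for p in pools for a in p.present()})
    rows = [
        {"species": p.species_id, **{a: p.counts.get(a, 0) for a in anticodons}}
        for p in pools
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_metadata(path: str | Path) -> List[SpeciesMeta]:
    """Read species metadata TSV with columns species_id, ogt_celsius, gc."""
    path = Path(path)
    df = pd.read_csv(path, sep="\t")
    required = {"species_id", "ogt_celsius", "gc"}
    if not required.issubset(df.columns):
        raise ValueError(f"{path}: metadata requires columns {sorted(required)}")
    metas = []
    seen: set[str] = set()
    for row_i, row in df.iterrows():
        sp = str(row["species_id"])
        if sp in seen:
            raise ValueError(f"{path}: duplicate species {sp!r} at row {row_i}")
        seen.add(sp)
        metas.append(SpeciesMeta(sp, row["ogt_celsius"], row["gc"]))
    return metas


def write_metadata(metas: Sequence[SpeciesMeta], path: str | Path) -> None:
    pd.DataFrame(
        [
            {"species_id": m.species_id, "ogt_celsius": m.ogt, "gc": m.gc,
             "temp_class": m.temp_class}
            for m in metas
        ]
    ).to_csv(path, sep="\t", index=False)


def summarize_pools(
    pools: Sequence[AnticodonPool],
    metas: Optional[Sequence[SpeciesMeta]] = None,
    strict: bool = True,
) -> pd.DataFrame:
    """Per-species summary table: diversity, total tGCN, GC/AT-ending split,
    and (when metadata is given) GC fraction and temperature class.

    Species with tGCN but no metadata are kept with NaN metadata fields and
    logged; metadata-only species are ignored here.
    """
    meta_by_id = {m.species_id: m for m in metas} if metas else {}
    rows = []
    for p in pools:
        gc_end, at_end = diversity_by_ending(p, strict=strict)
        row = {
            "species_id": p.species_id,
            "diversity": diversity(p, strict=strict),
            "total_tgcn": total_tgcn(p),
            "gc_ending_diversity": gc_end,
            "at_ending_diversity": at_end,
        }
        m = meta_by_id.get(p.species_id)
        if metas:
            if m is None:
                logger.warning("species %s has tGCN but no metadata", p.species_id)
            row.update(
                {
                    "ogt_celsius": m.ogt if m else float("nan"),
                    "gc": m.gc if m else float("nan"),
                    "temp_class": m.temp_class if m else "",
                }
            )
        rows.append(row)
    return pd.DataFrame(rows)
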