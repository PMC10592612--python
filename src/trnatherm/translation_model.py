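"""Mechanistic per-codon elongation and missense-error model.

For each sense codon *i* of a species, the tRNA pool yields a cognate
elongation rate R_C(i) (Watson–Crick and wobble readers, weighted by copy
number) and a near-cognate elongation rate R_N(i) (single-mismatch wrong-
amino-acid readers at a small kinetic efficiency).  Competing with both is a
constant ribosome drop-off rate R_D.  The missense error rate is the
probability that a near-cognate wins the kinetic competition:

    ε_M(i) = R_N(i) / (R_C(i) + R_N(i) + R_D)

Per-species rates are calibrated by one multiplicative constant so that the
harmonic mean of the per-codon elongation rates over sense codons equals a
target translation speed (default 12.5 amino acids per second); R_D is not
rescaled, so ε_M is calibration-dependent by design.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from statistics import median
from typing import Dict, List, Literal, Optional

import numpy as np
import pandas as pd

from .codon_space import (
    GeneticCode,
    PairingClass,
    WobbleRuleTable,
    classification_table,
)
from .trna_pool import AnticodonPool

logger = logging.getLogger(__name__)

#: Ribosome drop-off rate (premature termination), per second.
DEFAULT_DROP_OFF_RATE = 3.146e-3
#: Calibration target for the harmonic-mean elongation rate, aa/s.
DEFAULT_TARGET_HARMONIC_MEAN = 12.5
#: Kinetic weight of a wobble (non-Watson–Crick cognate) pairing relative to
#: a Watson–Crick pairing.  A convention of this implementation, chosen so
#: complete E. coli-like pools land in the empirical 1e-4–1e-3 missense range.
DEFAULT_WOBBLE_EFFICIENCY = 0.64
#: Kinetic weight of a near-cognate (single mismatch, wrong amino acid).
DEFAULT_NEAR_EFFICIENCY = 7.8e-4


@dataclass(frozen=True)
class RateParams:
    """Kinetic parameters of the elongation/error model.

    ``pseudo_policy`` controls pseudo-cognates (same amino acid, non-wobble
    pairing): ``exclude`` (default) leaves them out of both rate terms;
    ``as_near_correct`` adds them to R_C at near-cognate efficiency, i.e.
    correct incorporation through a mismatched pairing.
    ``scale_on`` selects whether the harmonic-mean calibration targets the
    total per-codon rate R_C + R_N (default) or R_C alone.
    """

    drop_off_rate: float = DEFAULT_DROP_OFF_RATE
    target_harmonic_mean: float = DEFAULT_TARGET_HARMONIC_MEAN
    wobble_efficiency: float = DEFAULT_WOBBLE_EFFICIENCY
    near_efficiency: float = DEFAULT_NEAR_EFFICIENCY
    pseudo_policy: Literal["exclude", "as_near_correct"] = "exclude"
    scale_on: Literal["total", "cognate"] = "total"

    def __post_init__(self) -> None:
        if self.drop_off_rate <= 0 or self.target_harmonic_mean <= 0:
            raise ValueError("rates must be positive")
        if not 0.0 < self.wobble_efficiency <= 1.0:
            raise ValueError("wobble_efficiency must lie in (0, 1]")
        if not 0.0 < self.near_efficiency < self.wobble_efficiency:
            raise ValueError("need 0 < near_efficiency < wobble_efficiency")
        if self.pseudo_policy not in ("exclude", "as_near_correct"):
            raise ValueError(f"unknown pseudo_policy {self.pseudo_policy!r}")
        if self.scale_on not in ("total", "cognate"):
            raise ValueError(f"unknown scale_on {self.scale_on!r}")


@dataclass
class CodonRates:
    """Per-codon rates for one species.

    ``r_c`` / ``r_n`` map each decodable sense codon to its cognate /
    near-cognate elongation rate (1/s); ``undecodable`` lists sense codons
    with no cognate reader under the rule set — they carry no rates and are
    excluded from calibration and summaries.  ``epsilon_m`` is populated by
    :func:`missense_rates`.
    """

    species_id: str
    r_c: Dict[str, float]
    r_n: Dict[str, float]
    undecodable: List[str] = field(default_factory=list)
    epsilon_m: Dict[str, float] = field(default_factory=dict)
    scaled: bool = False

    def total_rates(self) -> Dict[str, float]:
        return {c: self.r_c[c] + self.r_n[c] for c in self.r_c}


def raw_rates(
    pool: AnticodonPool,
    code: GeneticCode,
    rules: WobbleRuleTable,
    params: RateParams = RateParams(),
) -> CodonRates:
    """Unscaled per-codon rates from a species' tGCN.

    R_C sums copy numbers of cognate anticodons (weight 1 for Watson–Crick,
    ``wobble_efficiency`` for wobble); R_N sums near-cognate copy numbers at
    ``near_efficiency``.  Codons with neither cognate nor near-cognate
    reader — possible in reduced pools that rely on base modifications this
    model does not represent — are flagged as undecodable.
    """
    table = classification_table(code, rules)
    present = [(a, n) for a, n in pool.counts.items() if n > 0]
    if not present:
        raise ValueError(f"species {pool.species_id}: empty anticodon pool")
    r_c: Dict[str, float] = {}
    r_n: Dict[str, float] = {}
    undecodable: List[str] = []
    for codon in code.sense_codons:
        rc = rn = 0.0
        for anticodon, n in present:
            cls = table[(codon, anticodon)]
            if cls is PairingClass.COGNATE_WC:
                rc += n
            elif cls is PairingClass.COGNATE_WOBBLE:
                rc += n * params.wobble_efficiency
            elif cls is PairingClass.NEAR_COGNATE:
                rn += n * params.near_efficiency
            elif (
                cls is PairingClass.PSEUDO_COGNATE
                and params.pseudo_policy == "as_near_correct"
            ):
                rc += n * params.near_efficiency
        if rc == 0.0 and rn == 0.0:
            undecodable.append(codon)
            continue
        if rc == 0.0:
            logger.warning(
                "species %s: codon %s has no cognate reader (near-cognates only)",
                pool.species_id, codon,
            )
        r_c[codon] = rc
        r_n[codon] = rn
    if undecodable:
        logger.warning(
            "species %s: %d undecodable codon(s) excluded: %s",
            pool.species_id, len(undecodable), ",".join(undecodable),
        )
    return CodonRates(pool.species_id, r_c, r_n, undecodable=undecodable)


def scale_rates(rates: CodonRates, params: RateParams = RateParams()) -> CodonRates:
    """Calibrate rates so the harmonic mean of per-codon elongation rates
    over (decodable) sense codons equals ``params.target_harmonic_mean``.

    One multiplicative constant is applied to both R_C and R_N of every
    codon; the drop-off rate is left untouched.
    """
    basis = rates.total_rates() if params.scale_on == "total" else dict(rates.r_c)
    zero = sorted(c for c, r in basis.items() if r <= 0.0)
    if not basis or zero:
        raise ValueError(
            f"species {rates.species_id}: harmonic-mean scaling undefined — "
            f"codons with zero rate: {zero or 'all (empty rate set)'}"
        )
    values = np.fromiter(basis.values(), dtype=float)
    current_hmean = len(values) / np.sum(1.0 / values)
    scale = params.target_harmonic_mean / current_hmean
    return replace(
        rates,
        r_c={c: r * scale for c, r in rates.r_c.items()},
        r_n={c: r * scale for c, r in rates.r_n.items()},
        epsilon_m={},
        scaled=True,
    )


def missense_rate(r_c: float, r_n: float, r_d: float) -> float:
    """ε_M = R_N / (R_C + R_N + R_D): probability a near-cognate elongates.

    Monotone increasing in R_N, decreasing in R_C and R_D; lies in [0, 1).
    """
    if min(r_c, r_n, r_d) < 0.0:
        raise ValueError("rates must be non-negative")
    denom = r_c + r_n + r_d
    if denom == 0.0:
        raise ValueError("all rates zero: missense rate undefined")
    return r_n / denom


def missense_rates(rates: CodonRates, params: RateParams = RateParams()) -> CodonRates:
    """Populate ε_M for every decodable codon."""
    rates.epsilon_m = {
        c: missense_rate(rates.r_c[c], rates.r_n[c], params.drop_off_rate)
        for c in rates.r_c
    }
    return rates


def species_rates(
    pool: AnticodonPool,
    code: GeneticCode,
    rules: WobbleRuleTable,
    params: RateParams = RateParams(),
) -> CodonRates:
    """Full per-species pipeline: raw rates → calibration → ε_M."""
    return missense_rates(scale_rates(raw_rates(pool, code, rules, params), params), params)


def species_error_summary(rates: CodonRates) -> Dict[str, float]:
    """Median/mean/min/max ε_M over decodable sense codons, plus the count of
    undecodable codons."""
    if not rates.epsilon_m:
        raise ValueError("epsilon_m not computed; run missense_rates first")
    eps = list(rates.epsilon_m.values())
    return {
        "species_id": rates.species_id,
        "median_epsilon_m": float(median(eps)),
        "mean_epsilon_m": float(np.mean(eps)),
        "min_epsilon_m": float(min(eps)),
        "max_epsilon_m": float(max(eps)),
        "n_codons": len(eps),
        "n_undecodable": len(rates.undecodable),
    }


def rates_frame(rates: CodonRates, code: GeneticCode) -> pd.DataFrame:
    """Long-format per-codon table: species, codon, amino acid, R_C, R_N, ε_M."""
    rows = [
        {
            "species_id": rates.species_id,
            "codon": c,
            "amino_acid": code.translate(c),
            "R_C": rates.r_c[c],
            "R_N": rates.r_n[c],
            "epsilon_M": rates.epsilon_m.get(c, float("nan")),
        }
        for c in rates.r_c
    ]
    return pd.DataFrame(rows)
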