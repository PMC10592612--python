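"""Synthetic trees, species metadata and tGCN tables.

Generates data with the statistical structure the downstream analysis
assumes: a Yule (pure-birth) time tree rescaled to unit depth; genome GC
evolving with phylogenetic signal (Brownian motion on a logit scale mapped
into an empirical-style range); temperature classes assigned by thresholding
a Brownian "thermo-affinity" so thermophiles form clades; anticodon
diversity following a linear mean structure in GC and class with a BM or OU
phylogenetic residual; and per-species anticodon pools built from a minimal
decodable core plus preferentially GC-ending extras, with shifted-geometric
copy numbers.

Default class proportions (5 psychrophiles : 334 mesophiles : 67
thermophiles) and effect sizes mirror the bacterial dataset the pipeline is
designed around.
"""

from __future__ import annotations

import json
import logging
import random
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import dendropy
import numpy as np
import pandas as pd
from dendropy.simulate import treesim
from scipy.special import expit
from scipy.stats import norm

from .codon_space import (
    GeneticCode,
    WobbleRuleTable,
    recognized_codons,
    sense_decoding_anticodons,
    wc_decode,
)
from .trna_pool import (
    AnticodonPool,
    SpeciesMeta,
    classify_temperature,
    write_metadata,
    write_tgcn,
)

logger = logging.getLogger(__name__)

#: Hard floor/ceiling for simulated anticodon diversity; the effective floor
#: is raised to the minimal decodable core so every pool can translate every
#: sense codon under the default wobble rules.
DIVERSITY_BOUNDS = (20, 61)


@dataclass
class SimConfig:
    """Study-condition parameters for the generator.

    Effect sizes are on the diversity scale: expected diversity =
    ``intercept + beta_gc·GC + beta_thermo·x_T + beta_psychro·x_P`` with GC a
    fraction.  ``residual_sigma2`` is the BM rate of the phylogenetic
    residual per unit tree depth (the tree is rescaled to depth 1, so its
    square root is the residual standard deviation at the tips).
    """

    n_species: int = 406
    seed: int = 0
    class_proportions: Dict[str, float] = field(
        default_factory=lambda: {
            "psychrophile": 5 / 406,
            "mesophile": 334 / 406,
            "thermophile": 67 / 406,
        }
    )
    gc_range: Tuple[float, float] = (0.26, 0.74)
    intercept: float = 29.90884
    beta_gc: float = 21.43034
    beta_thermo: float = 1.76894
    beta_psychro: float = -0.41211
    trait_model: str = "BM"
    ou_alpha: Optional[float] = None
    residual_sigma2: float = 4.0
    birth_rate: float = 1.0
    gc_logit_sigma: float = 1.5
    affinity_sigma: float = 1.0
    exact_class_counts: bool = False
    gc_ending_preference: float = 3.0
    copy_geometric_p: float = 0.85
    bimodal_mesophile_offset: float = 0.0

    def __post_init__(self) -> None:
        total = sum(self.class_proportions.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"class proportions sum to {total}, not 1")
        if self.n_species < 3:
            raise ValueError("need at least 3 species")
        if self.trait_model.upper() == "OU" and (self.ou_alpha or 0) <= 0:
            raise ValueError("OU residuals require ou_alpha > 0")


# ---------------------------------------------------------------------------
# Trees and trait evolution


def simulate_tree(n: int, birth_rate: float = 1.0, seed: int = 0) -> dendropy.Tree:
    """Yule (pure-birth) ultrametric tree with ``n`` tips, rescaled to unit
    root-to-tip depth.  Deterministic given the seed."""
    if n < 3:
        raise ValueError("need n >= 3 tips")
    rng = random.Random(seed)
    taxa = dendropy.TaxonNamespace([f"s{i:04d}" for i in range(n)])
    tree = treesim.birth_death_tree(
        birth_rate=birth_rate,
        death_rate=0.0,
        num_extant_tips=n,
        taxon_namespace=taxa,
        rng=rng,
    )
    # The simulator stops at the n-th speciation, leaving the two newest tips
    # with zero-length branches (a singular BM covariance).  Run the clock on
    # to the next unrealized event: every extant lineage grows by Exp(n·λ).
    extension = rng.expovariate(n * birth_rate)
    for leaf in tree.leaf_node_iter():
        leaf.edge.length = (leaf.edge.length or 0.0) + extension
    depth = max(leaf.distance_from_root() for leaf in tree.leaf_node_iter())
    for edge in tree.preorder_edge_iter():
        if edge.length is not None:
            edge.length /= depth
    return tree


def simulate_bm(
    tree: dendropy.Tree,
    sigma2: float,
    rng: np.random.Generator,
    root_value: float = 0.0,
) -> Dict[str, float]:
    """Brownian motion along branches; returns tip-label → value."""
    values: Dict[int, float] = {id(tree.seed_node): root_value}
    out: Dict[str, float] = {}
    for node in tree.preorder_node_iter():
        if node is not tree.seed_node:
            t = node.edge.length or 0.0
            parent = values[id(node.parent_node)]
            values[id(node)] = parent + rng.normal(0.0, np.sqrt(sigma2 * t))
        if node.is_leaf():
            out[node.taxon.label] = values[id(node)]
    return out


def simulate_ou(
    tree: dendropy.Tree,
    sigma2: float,
    alpha: float,
    rng: np.random.Generator,
    root_value: float = 0.0,
    theta: float = 0.0,
) -> Dict[str, float]:
    """Ornstein–Uhlenbeck along branches (exact transition sampling)."""
    values: Dict[int, float] = {id(tree.seed_node): root_value}
    out: Dict[str, float] = {}
    for node in tree.preorder_node_iter():
        if node is not tree.seed_node:
            t = node.edge.length or 0.0
            parent = values[id(node.parent_node)]
            mean = theta + (parent - theta) * np.exp(-alpha * t)
            var = sigma2 / (2.0 * alpha) * (1.0 - np.exp(-2.0 * alpha * t))
            values[id(node)] = mean + rng.normal(0.0, np.sqrt(var))
        if node.is_leaf():
            out[node.taxon.label] = values[id(node)]
    return out


# ---------------------------------------------------------------------------
# Minimal decodable core


def minimal_core(
    code: Optional[GeneticCode] = None, rules: Optional[WobbleRuleTable] = None
) -> List[str]:
    """Smallest-practical anticodon set covering every sense codon.

    Greedy set cover over the 61 sense-decoding anticodons, ties broken
    alphabetically, so rule-table changes propagate automatically.  Under
    the default bacterial wobble table this yields 31 anticodons (GNN
    readers for pyrimidine-ending codons, UNN for purine-ending, plus CCA
    for Trp).
    """
    code = code or GeneticCode.bacterial()
    rules = rules or WobbleRuleTable.bacterial_default()
    sense = set(code.sense_codons)
    reach = {
        a: frozenset(recognized_codons(a, rules) & sense)
        for a in sense_decoding_anticodons(code)
    }
    uncovered = set(sense)
    core: List[str] = []
    while uncovered:
        best = max(sorted(reach), key=lambda a: len(reach[a] & uncovered))
        gained = reach[best] & uncovered
        if not gained:
            raise RuntimeError(f"wobble rules cannot cover codons {sorted(uncovered)}")
        core.append(best)
        uncovered -= gained
    return sorted(core)


# ---------------------------------------------------------------------------
# Traits


def simulate_traits(
    tree: dendropy.Tree, config: SimConfig, rng: Optional[np.random.Generator] = None
) -> pd.DataFrame:
    """Per-tip GC, temperature class, OGT and anticodon diversity.

    GC: BM on a logit scale squashed into ``gc_range``.  Classes: a BM
    "thermo-affinity" thresholded at the marginal quantiles matching the
    target proportions (phylogenetically clumped; ``exact_class_counts``
    thresholds at empirical quantiles instead).  Diversity: linear mean
    structure plus a BM/OU residual, rounded and clamped to the decodable
    range.
    """
    rng = rng or np.random.default_rng(config.seed)
    tips = [leaf.taxon.label for leaf in tree.leaf_node_iter()]

    lo, hi = config.gc_range
    gc_latent = simulate_bm(tree, config.gc_logit_sigma**2, rng)
    gc = {s: lo + (hi - lo) * expit(gc_latent[s]) for s in tips}

    affinity = simulate_bm(tree, config.affinity_sigma**2, rng)
    temp_class = _assign_classes(affinity, tips, config)
    ogt = {s: _draw_ogt(temp_class[s], rng) for s in tips}

    if config.trait_model.upper() == "OU":
        resid = simulate_ou(tree, config.residual_sigma2, config.ou_alpha, rng)
    else:
        resid = simulate_bm(tree, config.residual_sigma2, rng)

    floor = max(DIVERSITY_BOUNDS[0], len(minimal_core()))
    rows = []
    for s in tips:
        mean = (
            config.intercept
            + config.beta_gc * gc[s]
            + config.beta_thermo * (temp_class[s] == "thermophile")
            + config.beta_psychro * (temp_class[s] == "psychrophile")
        )
        if config.bimodal_mesophile_offset and temp_class[s] == "mesophile":
            # optional two-component mesophile mean structure (off by default)
            if rng.random() < 0.2:
                mean -= config.bimodal_mesophile_offset
        div = int(np.clip(round(mean + resid[s]), floor, DIVERSITY_BOUNDS[1]))
        rows.append(
            {
                "species_id": s,
                "gc": gc[s],
                "ogt_celsius": ogt[s],
                "temp_class": temp_class[s],
                "diversity": div,
            }
        )
    return pd.DataFrame(rows)


def _assign_classes(
    affinity: Dict[str, float], tips: Sequence[str], config: SimConfig
) -> Dict[str, str]:
    p_psy = config.class_proportions["psychrophile"]
    p_thermo = config.class_proportions["thermophile"]
    u = np.array([affinity[s] for s in tips])
    if config.exact_class_counts:
        n = len(tips)
        n_psy = max(1, round(p_psy * n)) if p_psy > 0 else 0
        n_thermo = max(1, round(p_thermo * n)) if p_thermo > 0 else 0
        order = np.argsort(u)
        classes = np.array(["mesophile"] * n, dtype=object)
        classes[order[:n_psy]] = "psychrophile"
        classes[order[n - n_thermo:]] = "thermophile"
    else:
        # marginal tip distribution is N(0, affinity_sigma^2) on a unit-depth tree
        lo_thr = config.affinity_sigma * norm.ppf(p_psy)
        hi_thr = config.affinity_sigma * norm.ppf(1.0 - p_thermo)
        classes = np.where(u < lo_thr, "psychrophile",
                           np.where(u > hi_thr, "thermophile", "mesophile"))
    return dict(zip(tips, classes))


_OGT_BANDS = {"psychrophile": (2.0, 14.0), "mesophile": (20.0, 42.0),
              "thermophile": (47.0, 80.0)}


def _draw_ogt(temp_class: str, rng: np.random.Generator) -> float:
    lo, hi = _OGT_BANDS[temp_class]
    ogt = float(rng.uniform(lo, hi))
    assert classify_temperature(ogt) == temp_class
    return ogt


# ---------------------------------------------------------------------------
# tGCN pools


def simulate_tgcn(
    traits: pd.DataFrame,
    seed: int | np.random.Generator = 0,
    code: Optional[GeneticCode] = None,
    rules: Optional[WobbleRuleTable] = None,
    gc_ending_preference: float = 3.0,
    copy_geometric_p: float = 0.85,
) -> List[AnticodonPool]:
    """Anticodon pools matching each species' requested diversity exactly.

    Every pool contains the minimal decodable core, so no sense codon is
    left without a cognate reader; the remaining anticodons are sampled
    without replacement with weights exp(±b·(GC − ½)) favouring anticodons
    that Watson–Crick-read GC-ending codons as genome GC rises.  Copy
    numbers are geometric (support ≥ 1).
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    code = code or GeneticCode.bacterial()
    rules = rules or WobbleRuleTable.bacterial_default()
    core = minimal_core(code, rules)
    candidates = sorted(set(sense_decoding_anticodons(code)) - set(core))
    is_gc_ending = {a: wc_decode(a)[2] in "GC" for a in candidates}

    pools: List[AnticodonPool] = []
    for row in traits.itertuples():
        div = int(row.diversity)
        if div < len(core):
            raise ValueError(
                f"species {row.species_id}: requested diversity {div} below the "
                f"minimal decodable core of {len(core)} anticodons"
            )
        n_extra = min(div, 61) - len(core)
        b = gc_ending_preference * (row.gc - 0.5)
        weights = np.array([np.exp(b) if is_gc_ending[a] else np.exp(-b) for a in candidates])
        chosen = list(
            rng.choice(candidates, size=n_extra, replace=False, p=weights / weights.sum())
        ) if n_extra else []
        present = core + chosen
        counts = {a: int(rng.geometric(copy_geometric_p)) for a in present}
        pools.append(AnticodonPool(str(row.species_id), counts))
    return pools


# ---------------------------------------------------------------------------
# Parameter-recovery experiments


def parameter_recovery(
    n_replicates: int = 200,
    n_tips: int = 300,
    seed: int = 0,
    config: Optional[SimConfig] = None,
    model: str = "BM",
) -> pd.DataFrame:
    """Simulate-and-refit calibration study for the phylogenetic regression.

    Each replicate draws a Yule tree, a design (GC and phylogenetically
    clumped temperature classes with exact class counts, so every replicate
    contains all three classes), and a continuous response
    y = Xβ + BM(σ²) residual; the regression is then refit and per-term
    estimates, standard errors and 95% Wald-interval coverage recorded.

    Returns a long DataFrame with one row per replicate × term.
    """
    from .phylo_regression import design_matrix, ml_fit

    base = config or SimConfig(n_species=n_tips, exact_class_counts=True)
    truth = {
        "intercept": base.intercept,
        "thermophile": base.beta_thermo,
        "psychrophile": base.beta_psychro,
        "gc": base.beta_gc,
    }
    rows = []
    for rep in range(n_replicates):
        rep_seed = seed + rep
        tree = simulate_tree(n_tips, base.birth_rate, rep_seed)
        rng = np.random.default_rng(rep_seed)
        tips = [leaf.taxon.label for leaf in tree.leaf_node_iter()]
        traits = simulate_traits(tree, base, rng).set_index("species_id").loc[tips]
        X, names = design_matrix(traits, ["temp_class", "gc"])
        beta_true = np.array([truth[t] for t in names])
        resid = simulate_bm(tree, base.residual_sigma2, rng)
        y = X @ beta_true + np.array([resid[s] for s in tips])
        fit = ml_fit(y, X, tree, model, names, tip_order=tips)
        for term in names:
            est = fit.coefficients.loc[term, "estimate"]
            se = fit.coefficients.loc[term, "se"]
            half = 1.959963984540054 * se
            rows.append(
                {
                    "replicate": rep,
                    "term": term,
                    "truth": truth[term],
                    "estimate": est,
                    "se": se,
                    "covered": bool(est - half <= truth[term] <= est + half),
                }
            )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Whole datasets


def simulate_dataset(
    config: SimConfig,
) -> Tuple[dendropy.Tree, pd.DataFrame, List[AnticodonPool], List[SpeciesMeta]]:
    """Tree, trait table, tGCN pools and metadata for one synthetic study."""
    tree = simulate_tree(config.n_species, config.birth_rate, config.seed)
    rng = np.random.default_rng(config.seed)
    traits = simulate_traits(tree, config, rng)
    pools = simulate_tgcn(
        traits, rng,
        gc_ending_preference=config.gc_ending_preference,
        copy_geometric_p=config.copy_geometric_p,
    )
    metas = [
        SpeciesMeta(r.species_id, r.ogt_celsius, r.gc) for r in traits.itertuples()
    ]
    return tree, traits, pools, metas


def write_dataset(config: SimConfig, outdir: str | Path) -> Dict[str, str]:
    """Write tree (Newick), tGCN TSV, metadata TSV and a manifest JSON in the
    formats the pipeline consumes; returns the path map."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    tree, traits, pools, metas = simulate_dataset(config)
    paths = {
        "tree": str(outdir / "tree.nwk"),
        "tgcn": str(outdir / "tgcn.tsv"),
        "metadata": str(outdir / "metadata.tsv"),
        "manifest": str(outdir / "manifest.json"),
    }
    tree.write(path=paths["tree"], schema="newick", suppress_rooting=True)
    write_tgcn(pools, paths["tgcn"])
    write_metadata(metas, paths["metadata"])
    manifest = {"config": _jsonable(asdict(config)), "seed": config.seed}
    Path(paths["manifest"]).write_text(json.dumps(manifest, indent=2))
    return paths


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer, np.floating)):
        return obj.item()
    return obj
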