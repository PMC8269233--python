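"""Community-coalescence simulator emulating the seed x soil study design.

Two source-pool families are generated with lognormal species-abundance
distributions: four seed lots (two genotypes x two harvest years, Y2 lots
richer than Y1) drawn from a common seed metacommunity, and two soils —
a high-diversity pool (S1) and a low-diversity pool (S2) obtained from S1
by dilution-to-extinction (Poisson survival of a diluted inoculum followed
by regrowth to fixed biomass). Seedling root and stem communities assemble
by independent Bernoulli transmission of each source taxon with a
probability set by its abundance class (rare / intermediate / abundant),
plus an external "unknown origin" taxon pool. Reads are multinomial draws
at fixed depths. Every simulated dataset carries a complete ground-truth
record (:class:`SimTruth`) for parameter-recovery tests.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field

import numpy as np
import pandas as pd

from .tables_io import FeatureTable, ValidationError, rng_stream
from .transmission import classify_abundance

GENOTYPES = ("Boston", "Major")
YEARS = ("Y1", "Y2")
SOILS = ("S1", "S2")
STAGES = ("d07", "d14")
COMPARTMENTS_PLANT = ("root", "stem")
REPLICATES = ("A", "B", "C")


def _default_probs() -> dict:
    # class-wise transmission probabilities, keyed (source, compartment, class)
    p = {}
    for comp, (pa, pi, pr) in (("root", (0.95, 0.40, 0.28)), ("stem", (0.86, 0.40, 0.29))):
        p[("soil", comp, "abundant")] = pa
        p[("soil", comp, "intermediate")] = pi
        p[("soil", comp, "rare")] = pr
    for comp in COMPARTMENTS_PLANT:
        # seed-borne transmission is weak and favours rare taxa
        p[("seed", comp, "abundant")] = 0.015
        p[("seed", comp, "intermediate")] = 0.03
        p[("seed", comp, "rare")] = 0.10
    return p


@dataclass
class SimConfig:
    """Study-design parameters of one simulated coalescence experiment.

    Richness defaults anchor to the study system: seed lots of ~100 (Y1)
    and ~250 (Y2) ASVs, soils of ~800 (S1) and ~500 (S2) ASVs, read depths
    of 30,000 (source) and 1,000 (plant) with 3 replicates.
    """

    n_seed_taxa_y1: int = 100
    n_seed_taxa_y2: int = 250
    seed_metapool: int = 400
    seed_soil_overlap: int = 10        # soil taxa seeded into each lot
    n_soil_taxa_s1: int = 800
    n_soil_taxa_s2: int = 500          # expected post-dilution richness
    dilution_exponent_s2: int = 6
    sigma_pool: float = 1.5            # lognormal SAD sigma of source pools
    sigma_seedling: float = 1.0        # sigma of fresh seedling-abundance draws
    rho: float = 0.2                   # source-rank coupling weight in [0,1]
    unknown_richness: int = 300
    p_unknown: float = 0.5             # per-context inclusion prob of unknown taxa
    unknown_share: float = 0.2         # abundance share of unknown taxa
    depth_source: int = 30_000
    depth_plant: int = 1_000
    n_replicates: int = 3
    class_low: float = 1e-4
    class_high: float = 1e-2
    transmission_probs: dict = field(default_factory=_default_probs)
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 <= self.rho <= 1.0):
            raise ValidationError("rho must be in [0, 1]")
        if self.sigma_pool <= 0 or self.sigma_seedling <= 0:
            raise ValidationError("lognormal sigma must be > 0")
        if self.depth_source < 1 or self.depth_plant < 1:
            raise ValidationError("read depths must be >= 1")
        if self.seed_soil_overlap > min(self.n_seed_taxa_y1, self.n_soil_taxa_s1):
            raise ValidationError("overlap exceeds pool size")
        if not (0.0 <= self.unknown_share < 1.0) or not (0.0 <= self.p_unknown <= 1.0):
            raise ValidationError("unknown-pool parameters out of range")
        for k, v in self.transmission_probs.items():
            if not (0.0 <= v <= 1.0):
                raise ValidationError(f"transmission probability {k} out of [0,1]")


@dataclass
class SimTruth:
    """Ground truth of a simulated dataset.

    ``pools`` maps pool name -> taxon -> true relative abundance;
    ``transmitted`` maps seedling context key -> channel ('seed'/'soil'/
    'unknown') -> sorted taxa that truly entered that seedling community.
    """

    pools: dict
    transmitted: dict
    config: SimConfig

    def to_json(self) -> str:
        payload = {
            "pools": {k: dict(v) for k, v in self.pools.items()},
            "transmitted": self.transmitted,
            "config": {k: ({str(kk): vv for kk, vv in v.items()} if isinstance(v, dict) else v)
                       for k, v in asdict(self.config).items()},
        }
        return json.dumps(payload, indent=None, sort_keys=True)


def _lognormal_composition(n: int, sigma: float, rng: np.random.Generator) -> np.ndarray:
    w = np.exp(rng.normal(0.0, sigma, size=n))
    return w / w.sum()


def simulate_source_pools(cfg: SimConfig, rng: np.random.Generator):
    """Draw the seed-lot, soil and unknown pools.

    Returns (pools, truth_pools): pools maps e.g. ``seed_Boston_Y1`` /
    ``soil_S1`` / ``unknown`` to a composition Series summing to 1.
    """
    soil_taxa = np.array([f"sl{i:04d}" for i in range(cfg.n_soil_taxa_s1)])
    meta_taxa = np.array([f"sd{i:04d}" for i in range(cfg.seed_metapool)])
    unknown_taxa = np.array([f"uk{i:04d}" for i in range(cfg.unknown_richness)])

    pools: dict[str, pd.Series] = {}
    s1 = pd.Series(_lognormal_composition(len(soil_taxa), cfg.sigma_pool, rng), index=soil_taxa)
    pools["soil_S1"] = s1
    pools["soil_S2"] = _dilute_to_target(s1, cfg.dilution_exponent_s2, cfg.n_soil_taxa_s2, rng)

    for g in GENOTYPES:
        for y in YEARS:
            n = cfg.n_seed_taxa_y1 if y == "Y1" else cfg.n_seed_taxa_y2
            own = rng.choice(meta_taxa, size=n - cfg.seed_soil_overlap, replace=False)
            shared = rng.choice(soil_taxa, size=cfg.seed_soil_overlap, replace=False)
            taxa = np.concatenate([own, shared])
            pools[f"seed_{g}_{y}"] = pd.Series(
                _lognormal_composition(len(taxa), cfg.sigma_pool, rng), index=taxa
            )

    pools["unknown"] = pd.Series(
        _lognormal_composition(len(unknown_taxa), cfg.sigma_seedling, rng), index=unknown_taxa
    )
    return pools


def dilute_pool(pool: pd.Series, exponent: int, inoculum_size: float,
                rng: np.random.Generator) -> pd.Series:
    """Dilution-to-extinction of a source pool.

    Survivor counts are Poisson(inoculum * abundance * 10^-exponent); taxa
    with zero survivors go extinct and the surviving counts are
    renormalised (regrowth to fixed biomass).
    """
    if exponent < 0 or inoculum_size < 1:
        raise ValidationError("exponent must be >= 0 and inoculum >= 1")
    lam = inoculum_size * pool.to_numpy() * 10.0 ** (-exponent)
    counts = rng.poisson(lam)
    if counts.sum() == 0:
        raise ValidationError("dilution extinguished the whole pool")
    out = pd.Series(counts, index=pool.index, dtype=float)
    out = out[out > 0]
    return out / out.sum()


def _dilute_to_target(pool: pd.Series, exponent: int, target_richness: int,
                      rng: np.random.Generator) -> pd.Series:
    """Dilute with the inoculum calibrated so expected richness hits target."""
    a = pool.to_numpy()

    def expected(lam: float) -> float:
        return float((1.0 - np.exp(-lam * a)).sum())

    lo, hi = 1e-6, 1e12
    for _ in range(200):
        mid = np.sqrt(lo * hi)
        if expected(mid) < target_richness:
            lo = mid
        else:
            hi = mid
    lam = np.sqrt(lo * hi)
    return dilute_pool(pool, exponent, lam * 10.0 ** exponent, rng)


def simulate_seedling(
    seed_pool: pd.Series,
    soil_pool: pd.Series,
    unknown_pool: pd.Series,
    cfg: SimConfig,
    compartment: str,
    rng: np.random.Generator,
):
    """Assemble one seedling community from its seed, soil and unknown pools.

    Each source taxon transmits independently with the probability of its
    abundance class; a transmitted taxon's seedling abundance blends its
    source abundance (log-space weight ``rho``) with a fresh lognormal
    draw. Unknown-pool taxa are included with probability ``p_unknown``
    and given ``unknown_share`` of the community. Returns
    (composition Series, truth dict with 'seed'/'soil'/'unknown' taxa lists).
    """
    transmitted: dict[str, float] = {}
    truth = {"seed": [], "soil": [], "unknown": []}
    for source_name, pool in (("seed", seed_pool), ("soil", soil_pool)):
        classes = classify_abundance(pool, cfg.class_low, cfg.class_high)
        u = rng.random(len(pool))
        for (taxon, ab), cls, draw in zip(pool.items(), classes.to_numpy(), u):
            if draw < cfg.transmission_probs[(source_name, compartment, cls)]:
                truth[source_name].append(taxon)
                transmitted[taxon] = max(transmitted.get(taxon, 0.0), ab)

    included = unknown_pool.index[rng.random(len(unknown_pool)) < cfg.p_unknown]
    truth["unknown"] = sorted(included)
    if not transmitted and (cfg.unknown_share == 0.0 or len(included) == 0):
        raise ValidationError("empty seedling community: nothing transmitted and no unknown share")

    parts = []
    if transmitted:
        taxa = sorted(transmitted)
        src = np.array([transmitted[t] for t in taxa])
        z = rng.normal(0.0, cfg.sigma_seedling, size=len(taxa))
        w = np.exp(cfg.rho * np.log(src) + (1.0 - cfg.rho) * z)
        share = 1.0 - cfg.unknown_share if len(included) else 1.0
        parts.append(pd.Series(w / w.sum() * share, index=taxa))
    if len(included):
        w = np.exp(rng.normal(0.0, cfg.sigma_seedling, size=len(included)))
        share = cfg.unknown_share if transmitted else 1.0
        parts.append(pd.Series(w / w.sum() * share, index=list(included)))
    comp = pd.concat(parts)
    comp = comp / comp.sum()
    truth["seed"] = sorted(truth["seed"])
    truth["soil"] = sorted(truth["soil"])
    return comp, truth


def sample_reads(composition: pd.Series, depth: int, rng: np.random.Generator) -> pd.Series:
    """Multinomial read counts at fixed depth from a composition."""
    if depth < 1:
        raise ValidationError("read depth must be >= 1")
    p = composition.to_numpy(dtype=float)
    if abs(p.sum() - 1.0) > 1e-9:
        raise ValidationError("composition must sum to 1")
    counts = rng.multinomial(depth, p / p.sum())
    return pd.Series(counts, index=composition.index, dtype=np.int64)


def generate_dataset(cfg: SimConfig):
    """Simulate the full factorial experiment.

    Source samples: 4 seed lots x 3 replicates and 2 soils x 3 replicates
    at the source depth. Seedling samples: 2 compartments x 2 soils x
    4 lots x 2 stages x 3 replicates at the plant depth. The seedling
    composition is drawn once per (soil, lot, stage, compartment) context,
    so replicates differ only through read sampling. Deterministic given
    ``cfg.seed``.

    Returns (FeatureTable, SimTruth).
    """
    pools = simulate_source_pools(cfg, rng_stream(cfg.seed, "pools"))
    read_rng = rng_stream(cfg.seed, "reads")
    assembly_rng = rng_stream(cfg.seed, "assembly")
    reps = REPLICATES[: cfg.n_replicates]

    rows: dict[str, pd.Series] = {}
    meta: dict[str, dict] = {}
    transmitted: dict[str, dict] = {}

    for g in GENOTYPES:
        for y in YEARS:
            for r in reps:
                sid = f"seed_{g}_{y}_{r}"
                rows[sid] = sample_reads(pools[f"seed_{g}_{y}"], cfg.depth_source, read_rng)
                meta[sid] = {"compartment": "seed", "soil": pd.NA, "genotype": g,
                             "year": y, "stage": pd.NA, "replicate": r}
    for s in SOILS:
        for r in reps:
            sid = f"soil_{s}_{r}"
            rows[sid] = sample_reads(pools[f"soil_{s}"], cfg.depth_source, read_rng)
            meta[sid] = {"compartment": "soil", "soil": s, "genotype": pd.NA,
                         "year": pd.NA, "stage": pd.NA, "replicate": r}

    for s in SOILS:
        for g in GENOTYPES:
            for y in YEARS:
                for stage in STAGES:
                    for comp_name in COMPARTMENTS_PLANT:
                        ctx = f"{comp_name}|{s}|{g}|{y}|{stage}"
                        composition, truth = simulate_seedling(
                            pools[f"seed_{g}_{y}"], pools[f"soil_{s}"], pools["unknown"],
                            cfg, comp_name, assembly_rng,
                        )
                        transmitted[ctx] = truth
                        for r in reps:
                            sid = f"{comp_name}_{s}_{g}_{y}_{stage}_{r}"
                            rows[sid] = sample_reads(composition, cfg.depth_plant, read_rng)
                            meta[sid] = {"compartment": comp_name, "soil": s, "genotype": g,
                                         "year": y, "stage": stage, "replicate": r}

    all_taxa = sorted(set().union(*(set(r.index) for r in rows.values())))
    counts = pd.DataFrame(0, index=list(rows), columns=all_taxa, dtype=np.int64)
    for sid, r in rows.items():
        counts.loc[sid, r.index] = r.to_numpy()
    metadata = pd.DataFrame.from_dict(meta, orient="index")
    table = FeatureTable(counts, metadata)
    truth = SimTruth(
        pools={k: {t: float(v) for t, v in p.items()} for k, p in pools.items()},
        transmitted=transmitted,
        config=cfg,
    )
    return table, truth
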