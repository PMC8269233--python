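"""Detection, origin assignment and transmission-success analysis.

All operations here run on NON-rarefied counts: presence/absence detection
is deliberately exhaustive. An ASV is "present" in a sample group when it
has at least ``min_count`` reads in at least ``min_reps`` samples of that
group (defaults 1/1, the at-least-one-of-three-replicates rule). Seedling
ASVs are assigned an origin by set algebra against the matching seed and
soil source pools: ``both``, ``seed_only``, ``soil_only`` or ``unknown``.
Transmission success of a source pool is the percentage of its ASVs
detected in the recipient compartment; ASVs are additionally classed as
rare (< 0.01% mean relative abundance), intermediate (0.01-1%, boundaries
inclusive) or abundant (> 1%).
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .tables_io import FeatureTable, ValidationError

ORIGIN_CATEGORIES = ("seed_only", "soil_only", "both", "unknown")
ABUNDANCE_CLASSES = ("rare", "intermediate", "abundant")


@dataclass(frozen=True)
class PresenceSet:
    """ASVs deemed present in one compartment context."""

    key: str
    asvs: frozenset
    min_count: int = 1
    min_reps: int = 1

    def __len__(self) -> int:
        return len(self.asvs)


def detect(
    table: FeatureTable,
    context: dict,
    min_count: int = 1,
    min_reps: int = 1,
    key: str | None = None,
) -> PresenceSet:
    """Presence set of a metadata context on non-rarefied counts."""
    sub = table.select(**context)  # raises if the filter selects nothing
    hits = (sub.counts >= min_count).sum(axis=0)
    present = frozenset(hits.index[hits >= min_reps])
    if key is None:
        key = "|".join(f"{k}={v}" for k, v in sorted(context.items()))
    return PresenceSet(key, present, min_count, min_reps)


def prevalence_matrix(sets: list[PresenceSet]) -> pd.DataFrame:
    """Binary ASV x context matrix over the union of all presence sets."""
    if len(sets) < 2:
        raise ValidationError("prevalence matrix needs >= 2 contexts")
    keys = [s.key for s in sets]
    if len(set(keys)) != len(keys):
        raise ValidationError(f"duplicate context keys: {keys}")
    union = sorted(set().union(*(s.asvs for s in sets)))
    data = {s.key: [int(a in s.asvs) for a in union] for s in sets}
    return pd.DataFrame(data, index=union, dtype=np.int64)


def upset_intersections(matrix: pd.DataFrame) -> pd.Series:
    """Exclusive intersection counts per non-empty context combination.

    Keys are tuples of context names; an ASV counts toward exactly the
    combination of contexts it is present in, so counts sum to the number
    of distinct ASVs.
    """
    contexts = list(matrix.columns)
    combos = {}
    for r in range(1, len(contexts) + 1):
        for combo in itertools.combinations(contexts, r):
            mask = np.ones(len(matrix), dtype=bool)
            for c in contexts:
                want = c in combo
                mask &= matrix[c].to_numpy().astype(bool) == want
            n = int(mask.sum())
            if n:
                combos[combo] = n
    idx = pd.Index(list(combos.keys()), dtype=object, tupleize_cols=False)
    return pd.Series(list(combos.values()), index=idx, dtype=np.int64)


@dataclass
class OriginMap:
    """Per seedling context: ASV -> origin category."""

    seedling_key: str
    categories: dict
    seed_set: PresenceSet
    soil_set: PresenceSet

    def members(self, category: str) -> frozenset:
        if category == "soil_detected":  # soil_only | both
            return frozenset(a for a, c in self.categories.items() if c in ("soil_only", "both"))
        if category == "seed_detected":
            return frozenset(a for a, c in self.categories.items() if c in ("seed_only", "both"))
        return frozenset(a for a, c in self.categories.items() if c == category)


def assign_origin(seedling: PresenceSet, seed: PresenceSet, soil: PresenceSet) -> OriginMap:
    """Partition the seedling presence set by source detection.

    The seed set must be the sown genotype x year lot and the soil set the
    pot's soil; every seedling ASV lands in exactly one category.
    """
    cats = {}
    for a in seedling.asvs:
        in_seed, in_soil = a in seed.asvs, a in soil.asvs
        if in_seed and in_soil:
            cats[a] = "both"
        elif in_seed:
            cats[a] = "seed_only"
        elif in_soil:
            cats[a] = "soil_only"
        else:
            cats[a] = "unknown"
    return OriginMap(seedling.key, cats, seed, soil)


def origin_membership_fraction(om: OriginMap) -> dict:
    """Fraction of seedling ASVs per origin category (plus aggregates)."""
    n = len(om.categories)
    if n == 0:
        raise ValidationError("membership fractions undefined for empty seedling set")
    out = {c: len(om.members(c)) / n for c in ORIGIN_CATEGORIES}
    out["soil_detected"] = out["soil_only"] + out["both"]
    out["seed_detected"] = out["seed_only"] + out["both"]
    return out


def mean_relative_abundance(table: FeatureTable, context: dict) -> pd.Series:
    """Zero-inclusive mean relative abundance per ASV over a context.

    Each selected sample is normalised to relative abundances (zero-total
    samples are excluded with a warning), then averaged arithmetically with
    zeros kept for samples lacking the ASV.
    """
    sub = table.select(**context)
    rel = sub.relative_abundance()
    if rel.shape[0] == 0:
        raise ValidationError("all selected samples have zero total")
    return rel.mean(axis=0)


def origin_abundance_fraction(om: OriginMap, rel: pd.Series) -> dict:
    """Share of seedling community abundance per origin category."""
    missing = sorted(set(om.categories) - set(rel.index))
    if missing:
        raise ValidationError(f"no relative abundance for seedling ASVs: {missing}")
    total = float(sum(rel[a] for a in om.categories))
    if total <= 0:
        raise ValidationError("zero total abundance over the seedling set")
    out = {c: float(sum(rel[a] for a in om.members(c))) / total for c in ORIGIN_CATEGORIES}
    out["soil_detected"] = out["soil_only"] + out["both"]
    out["seed_detected"] = out["seed_only"] + out["both"]
    return out


@dataclass
class TransmissionSummary:
    source_key: str
    seedling_key: str
    n_source: int
    n_transmitted: int           # against the replicate-pooled union
    percentage: float            # pooled-union percentage
    per_replicate: list = field(default_factory=list)
    mean: float = np.nan
    se: float = np.nan
    abundance_class: str | None = None


def _mean_se(values) -> tuple[float, float]:
    v = np.asarray(values, dtype=float)
    mean = float(v.mean())
    se = float(v.std(ddof=1) / np.sqrt(len(v))) if len(v) > 1 else 0.0
    return mean, se


def transmission_success(source: PresenceSet, seedling_by_replicate: list[PresenceSet]) -> TransmissionSummary:
    """Percentage of the source pool detected in the seedling compartment.

    Per replicate: 100 * |source ∩ seedling_r| / |source|; summarised as
    mean ± SE (sd/√n) over replicates, with the replicate-pooled union
    percentage reported alongside.
    """
    if len(source) == 0:
        raise ValidationError("transmission undefined for empty source pool")
    per_rep = [100.0 * len(source.asvs & s.asvs) / len(source) for s in seedling_by_replicate]
    union = frozenset().union(*(s.asvs for s in seedling_by_replicate)) if seedling_by_replicate else frozenset()
    n_trans = len(source.asvs & union)
    mean, se = _mean_se(per_rep) if per_rep else (np.nan, np.nan)
    key = seedling_by_replicate[0].key if seedling_by_replicate else ""
    return TransmissionSummary(
        source.key, key, len(source), n_trans,
        100.0 * n_trans / len(source), per_rep, mean, se,
    )


def classify_abundance(rel: pd.Series, t_low: float = 1e-4, t_high: float = 1e-2) -> pd.Series:
    """Rare / intermediate / abundant classes from mean relative abundance.

    rare < t_low; abundant > t_high; boundaries belong to intermediate.
    """
    v = pd.Series(rel, dtype=float)
    if ((v < 0) | (v > 1)).any():
        raise ValidationError("relative abundances must lie in [0, 1]")
    out = pd.Series("intermediate", index=v.index, dtype=object)
    out[v < t_low] = "rare"
    out[v > t_high] = "abundant"
    return out


def class_transmission_rates(
    source: PresenceSet, source_classes: pd.Series, seedling: PresenceSet
) -> dict:
    """Per abundance class: % of the class's source ASVs found in seedling.

    Classes with no source members are reported as None (undefined), never 0.
    """
    missing = sorted(set(source.asvs) - set(source_classes.index))
    if missing:
        raise ValidationError(f"unclassified source ASVs: {missing}")
    out = {}
    for c in ABUNDANCE_CLASSES:
        members = [a for a in source.asvs if source_classes[a] == c]
        if not members:
            out[c] = None
        else:
            hit = sum(1 for a in members if a in seedling.asvs)
            out[c] = 100.0 * hit / len(members)
    return out


def abundance_pairing(source_rel: pd.Series, seedling_rel: pd.Series,
                      t_low: float = 1e-4, t_high: float = 1e-2) -> pd.DataFrame:
    """Source-vs-seedling relative abundance pairs for transmitted ASVs.

    Restricted to ASVs with positive abundance in both tables; flags
    ``above_line`` (seedling > source, strict) and ``became_abundant``
    (seedling relative abundance > t_high).
    """
    shared = sorted(set(source_rel.index[source_rel > 0]) & set(seedling_rel.index[seedling_rel > 0]))
    rows = []
    for a in shared:
        s, p = float(source_rel[a]), float(seedling_rel[a])
        rows.append({
            "asv": a,
            "source_class": classify_abundance(pd.Series({a: s}), t_low, t_high)[a],
            "source_rel": s,
            "seedling_rel": p,
            "above_line": p > s,
            "became_abundant": p > t_high,
        })
    return pd.DataFrame(rows, columns=["asv", "source_class", "source_rel", "seedling_rel",
                                       "above_line", "became_abundant"]).set_index("asv") if rows else pd.DataFrame(
        columns=["source_class", "source_rel", "seedling_rel", "above_line", "became_abundant"])


def taxon_group_abundance(table: FeatureTable, context: dict, genera: list[str]) -> tuple[float, float]:
    """Mean % (± SE over context samples) of reads in the given genera.

    Used for nitrifier guilds (e.g. AOB: Nitrosospira, Nitrosovibrio; NOB:
    Nitrobacter, Nitrospira). A genus absent from the table contributes 0.
    """
    if table.taxonomy is None or "genus" not in table.taxonomy.columns:
        raise ValidationError("taxonomy with a genus rank is required")
    sub = table.select(**context)
    rel = sub.relative_abundance()
    hit_asvs = [a for a in rel.columns
                if a in table.taxonomy.index and table.taxonomy.loc[a, "genus"] in set(genera)]
    per_sample = rel[hit_asvs].sum(axis=1) * 100.0 if hit_asvs else pd.Series(0.0, index=rel.index)
    return _mean_se(per_sample.to_numpy())
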