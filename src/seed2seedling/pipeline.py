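"""End-to-end analysis stages shared by the CLI and the acceptance script.

Stage order is fixed: ingest/simulate -> rarefy -> alpha diversity ->
beta diversity / PERMANOVA -> transmission. Transmission always reads the
NON-rarefied table; diversity and community structure read the rarefied
views. All randomness derives from one run seed via named streams.
"""

from __future__ import annotations

import pandas as pd

from . import diversity, structure, transmission
from .tables_io import FeatureTable, PipelineConfig, rng_stream

#: PERMANOVA terms of the seedling model, in table order
PLANT_TERMS = ["soil", "stage", "genotype:year", "soil:genotype:year"]


def rarefied_views(table: FeatureTable, cfg: PipelineConfig, seed: int):
    """Rarefied source (soil+seed) and plant tables; sources at the soil
    depth, root/stem at the plant depth."""
    rng = rng_stream(seed, "rarefy")
    source = table.select(compartment=["seed", "soil"])
    plant = table.select(compartment=["root", "stem"])
    return (
        diversity.rarefy(source, cfg.depth_soil_bacteria, rng),
        diversity.rarefy(plant, cfg.depth_plant, rng),
    )


def run_diversity(source_r: FeatureTable, plant_r: FeatureTable, cfg: PipelineConfig) -> dict:
    frames = []
    for tab, depth in ((source_r, cfg.depth_soil_bacteria), (plant_r, cfg.depth_plant)):
        af = diversity.alpha_frame(tab, metrics=("chao1", "observed_richness"), depth=depth)
        af = af.merge(tab.metadata, left_on="sample_id", right_index=True)
        frames.append(af)
    return {"alpha": pd.concat(frames, ignore_index=True)}


def run_structure(plant_r: FeatureTable, cfg: PipelineConfig, seed: int) -> dict:
    """Per-compartment PERMANOVA (sequential terms), dispersion and PCoA on
    log10+1 Bray-Curtis distances of the rarefied plant table."""
    out: dict[str, pd.DataFrame] = {}
    for comp in ("root", "stem"):
        sub = plant_r.select(compartment=comp)
        dm = structure.bray_curtis(structure.log10p1_transform(sub))
        res = structure.permanova(
            dm, sub.metadata, PLANT_TERMS, n_perm=cfg.n_permutations,
            rng=rng_stream(seed, f"permanova_{comp}"),
        )
        out[f"permanova_{comp}"] = res.reset_index()
        disp = structure.betadisper(dm, sub.metadata["soil"].astype(str))
        out[f"dispersion_{comp}"] = pd.DataFrame({
            "sample_id": disp.distances.index,
            "soil": disp.grouping.to_numpy(),
            "dist_to_centroid": disp.distances.to_numpy(),
            "wilcoxon_p": disp.pvalue,
        })
        ordn = structure.pcoa(dm)
        coords = ordn.coordinates.iloc[:, :2].copy()
        coords.columns = ["PC1", "PC2"]
        coords.insert(0, "sample_id", coords.index)
        out[f"ordination_{comp}"] = coords.reset_index(drop=True)
    return out


def seedling_contexts(table: FeatureTable):
    """All (compartment, soil, genotype, year, stage) contexts present."""
    md = table.metadata
    plant = md[md["compartment"].isin(["root", "stem"])]
    cols = ["compartment", "soil", "genotype", "year", "stage"]
    return [dict(zip(cols, vals)) for vals, _ in plant.groupby(cols, dropna=False)]


def run_transmission(table: FeatureTable, cfg: PipelineConfig) -> dict:
    """Detection, origin assignment, transmission success and abundance
    classes for every seedling context, on the non-rarefied table."""
    mc, mr = cfg.detect_min_count, cfg.detect_min_reps
    seed_sets = {}
    seed_rel = {}
    md = table.metadata
    for (g, y), _ in md[md["compartment"] == "seed"].groupby(["genotype", "year"]):
        ctx = {"compartment": "seed", "genotype": g, "year": y}
        seed_sets[(g, y)] = transmission.detect(table, ctx, mc, mr, key=f"seed_{g}_{y}")
        seed_rel[(g, y)] = transmission.mean_relative_abundance(table, ctx)
    soil_sets, soil_rel = {}, {}
    for s, _ in md[md["compartment"] == "soil"].groupby("soil"):
        ctx = {"compartment": "soil", "soil": s}
        soil_sets[s] = transmission.detect(table, ctx, mc, mr, key=f"soil_{s}")
        soil_rel[s] = transmission.mean_relative_abundance(table, ctx)

    # global prevalence matrix over the four habitats and its upset counts
    habitat_sets = [
        transmission.detect(table, {"compartment": c}, mc, mr, key=c)
        for c in ("seed", "soil", "root", "stem")
        if (md["compartment"] == c).any()
    ]
    prev = transmission.prevalence_matrix(habitat_sets)
    upset = transmission.upset_intersections(prev)
    upset_df = pd.DataFrame({
        "combination": ["+".join(k) for k in upset.index],
        "n_asvs": upset.to_numpy(),
    })

    origin_rows, trans_rows, class_rows, pairing_frames = [], [], [], []
    for ctx in seedling_contexts(table):
        comp, s, g, y, stage = (ctx[k] for k in ("compartment", "soil", "genotype", "year", "stage"))
        key = f"{comp}|{s}|{g}|{y}|{stage}"
        seedling = transmission.detect(table, ctx, mc, mr, key=key)
        reps = sorted(md.loc[table.select(**ctx).sample_ids, "replicate"].unique())
        rep_sets = [
            transmission.detect(table, {**ctx, "replicate": r}, mc, mr, key=f"{key}|{r}")
            for r in reps
        ]
        om = transmission.assign_origin(seedling, seed_sets[(g, y)], soil_sets[s])
        rel = transmission.mean_relative_abundance(table, ctx)
        memb = transmission.origin_membership_fraction(om) if len(seedling) else {}
        abund = transmission.origin_abundance_fraction(om, rel) if len(seedling) else {}
        for cat in list(transmission.ORIGIN_CATEGORIES) + ["soil_detected", "seed_detected"]:
            origin_rows.append({"context": key, "category": cat,
                                "membership_fraction": memb.get(cat),
                                "abundance_fraction": abund.get(cat)})

        for src_name, src_set, src_rel in (
            (f"seed_{g}_{y}", seed_sets[(g, y)], seed_rel[(g, y)]),
            (f"soil_{s}", soil_sets[s], soil_rel[s]),
        ):
            ts = transmission.transmission_success(src_set, rep_sets)
            trans_rows.append({
                "source": src_name, "context": key, "n_source": ts.n_source,
                "n_transmitted": ts.n_transmitted, "pooled_pct": ts.percentage,
                "mean_pct": ts.mean, "se_pct": ts.se,
            })
            classes = transmission.classify_abundance(
                src_rel.reindex(list(src_set.asvs)).fillna(0.0), cfg.class_low, cfg.class_high
            )
            rates = transmission.class_transmission_rates(src_set, classes, seedling)
            for cls in transmission.ABUNDANCE_CLASSES:
                n_cls = int((classes == cls).sum())
                class_rows.append({"source": src_name, "context": key, "class": cls,
                                   "n_source": n_cls, "pct_transmitted": rates[cls]})
            if stage == "d14":
                pair = transmission.abundance_pairing(src_rel, rel, cfg.class_low, cfg.class_high)
                pair = pair.reset_index()
                pair.insert(0, "context", key)
                pair.insert(1, "source", src_name)
                pairing_frames.append(pair)

    return {
        "prevalence": prev,
        "upset": upset_df,
        "origin_fractions": pd.DataFrame(origin_rows),
        "transmission": pd.DataFrame(trans_rows),
        "class_rates": pd.DataFrame(class_rows),
        "pairing": pd.concat(pairing_frames, ignore_index=True) if pairing_frames else pd.DataFrame(),
    }


def run_all(table: FeatureTable, cfg: PipelineConfig, seed: int) -> dict:
    """Execute every stage and return the named result tables."""
    source_r, plant_r = rarefied_views(table, cfg, seed)
    tables = {}
    tables.update(run_diversity(source_r, plant_r, cfg))
    tables.update(run_structure(plant_r, cfg, seed))
    tables.update(run_transmission(table, cfg))
    return tables
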